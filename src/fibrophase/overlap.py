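"""In vitro → ex vivo gene-signature comparison statistics.

The workflow mirrors a multi-step overlap method for relating
differential-expression signatures obtained from controlled macrophage /
fibroblast cultures (the *in vitro* signatures, each labeled by cell type
and by the experimental variable that discriminates its contrast) to the
differentially expressed genes of a fibrotic-vs-control tissue comparison
(the *ex vivo* set):

1. threshold DEG selection (FDR-based for in vitro contrasts; fold-change
   plus p-value for the ex vivo contrast),
2. set algebra between condition-paired DEG sets ("comparison of
   comparisons" at levels 2 and 3),
3. a pre-ranked enrichment screen (weighted Kolmogorov–Smirnov running
   sum over the logFC-ranked ex vivo list, permutation p-values),
4. the overlap statistics: explained fraction, univocal fractions per
   discriminating variable, per-signature unique contributions, the
   pairwise shared matrix and per-pathway contributions.

All overlap quantities are exact rational counts |A ∩ B| / |E|.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "Signature",
    "OverlapResult",
    "read_diff_table",
    "select_degs",
    "parse_condition_label",
    "multi_level_compare",
    "preranked_es",
    "overlap_analysis",
    "screen_signatures",
]

CELL_TYPES = ("Mphi", "Fb")
DISCRIMINATING_VARIABLES = ("inflammation", "IL4", "cell_interaction", "hypoxia")


@dataclass(frozen=True)
class Signature:
    """A named DEG set from one in vitro contrast.

    ``name`` follows the condition coding scheme, e.g. ``"MIvsM0_CC/24H"``
    (comparison, culture arm, time/oxygen).  ``direction`` is the
    enrichment sign of the first comparison term (+1 up, -1 down, 0
    unsigned).
    """

    name: str
    genes: FrozenSet[str]
    cell_type: str = "Mphi"
    discriminating_variable: str = "inflammation"
    direction: int = 0

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has an empty gene set")
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell_type {self.cell_type!r}")
        if self.discriminating_variable not in DISCRIMINATING_VARIABLES:
            raise ValueError(f"unknown discriminating_variable {self.discriminating_variable!r}")


@dataclass
class OverlapResult:
    explained_fraction: float
    unexplained_fraction: float
    univocal_fraction_by_variable: Dict[str, float]
    per_signature_unique_fraction: Dict[str, float]
    shared_matrix: pd.DataFrame  # signature x signature, fraction of ex vivo DEGs in both
    pathway_contribution: Optional[pd.DataFrame]  # pathway x signature
    n_exvivo: int

    @property
    def univocal_total(self) -> float:
        return sum(self.univocal_fraction_by_variable.values())

    def to_json_dict(self) -> dict:
        return {
            "explained_fraction": self.explained_fraction,
            "unexplained_fraction": self.unexplained_fraction,
            "univocal_fraction_by_variable": self.univocal_fraction_by_variable,
            "per_signature_unique_fraction": self.per_signature_unique_fraction,
            "shared_matrix": self.shared_matrix.to_dict(),
            "pathway_contribution": (
                None if self.pathway_contribution is None else self.pathway_contribution.to_dict()
            ),
            "n_exvivo": self.n_exvivo,
        }


def read_diff_table(path, uppercase: bool = True) -> pd.DataFrame:
    """Read a TSV differential-expression table (gene, logFC, pvalue, fdr)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    rename = {}
    for want, aliases in {
        "gene": ("gene", "gene_id", "symbol"),
        "logFC": ("logfc", "log2fc", "log2foldchange"),
        "pvalue": ("pvalue", "p", "p_value", "pval"),
        "fdr": ("fdr", "padj", "qvalue"),
    }.items():
        for a in aliases:
            if a in cols:
                rename[cols[a]] = want
                break
    df = df.rename(columns=rename)
    missing = {"gene", "logFC", "pvalue", "fdr"} - set(df.columns)
    if missing:
        raise ValueError(f"diff table {path} missing columns: {sorted(missing)}")
    if uppercase:
        df["gene"] = df["gene"].astype(str).str.upper()
    if df["gene"].duplicated().any():
        raise ValueError("duplicate gene identifiers in diff table")
    return df


def validate_diff_table(df: pd.DataFrame) -> None:
    for col in ("pvalue", "fdr"):
        bad = ~df[col].between(0.0, 1.0)
        if bad.any():
            raise ValueError(f"{col} outside [0, 1] for {int(bad.sum())} rows")
    if df["gene"].duplicated().any():
        raise ValueError("duplicate gene identifiers")


# default threshold rules: in vitro contrasts keep FDR <= 0.05; the ex vivo
# contrast keeps |logFC| >= 1 and p <= 0.01 (boundaries inclusive)
IN_VITRO_RULE = {"fdr": 0.05}
EX_VIVO_RULE = {"abs_logfc": 1.0, "p": 0.01}


def select_degs(table: pd.DataFrame, rule: Optional[Mapping[str, float]] = None) -> Set[str]:
    """Genes passing every active threshold in ``rule``.

    ``rule`` maps any of ``fdr``, ``p``, ``abs_logfc`` to its threshold;
    all comparisons are boundary-inclusive (``<=`` for p/FDR, ``>=`` for
    |logFC|).  Default rule: ``{"fdr": 0.05}``.
    """
    if rule is None:
        rule = IN_VITRO_RULE
    unknown = set(rule) - {"fdr", "p", "abs_logfc"}
    if unknown:
        raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
    validate_diff_table(table)
    if len(table) == 0:
        import warnings

        warnings.warn("select_degs called on an empty table", stacklevel=2)
        return set()
    mask = pd.Series(True, index=table.index)
    if "fdr" in rule:
        mask &= table["fdr"] <= rule["fdr"]
    if "p" in rule:
        mask &= table["pvalue"] <= rule["p"]
    if "abs_logfc" in rule:
        mask &= table["logFC"].abs() >= rule["abs_logfc"]
    return set(table.loc[mask, "gene"])


# ---------------------------------------------------------------------------
# condition coding and multi-level set comparisons


def parse_condition_label(label: str) -> dict:
    """Split a condition label like ``"MI/CC/24H"`` into its coded factors.

    Segments are separated by ``/``; the first segment is cell type code
    (``M``/``F``) plus immune cue (``0``/``I``/``F``), the middle segment
    the culture arm (``SC``/``CC``) and the last the time plus oxygen code
    (e.g. ``24H``, ``4N``).
    """
    parts = label.split("/")
    if len(parts) != 3:
        raise ValueError(f"cannot parse condition label {label!r}")
    cell_stim, culture, time_oxy = parts
    if len(cell_stim) < 2 or cell_stim[0] not in "MF":
        raise ValueError(f"bad cell/stimulus code {cell_stim!r} in {label!r}")
    return {
        "cell_type": cell_stim[0],
        "stimulus": cell_stim[1:],
        "culture": culture,
        "time": time_oxy[:-1],
        "oxygen": time_oxy[-1],
    }


def parse_signature_name(name: str) -> dict:
    """Parse a signature name like ``"MIvsM0_CC/24H"``.

    The part before ``_`` is the comparison (``AvsB``); the remainder
    encodes the shared culture and time/oxygen context.
    """
    head, _, rest = name.partition("_")
    a, sep, b = head.partition("vs")
    if not sep:
        raise ValueError(f"signature name {name!r} lacks a 'vs' comparison")
    ctx = rest.split("/") if rest else []
    return {"first": a, "second": b, "context": ctx}


def _pair_key(factors: dict, axis: str) -> Tuple:
    return tuple(v for k, v in sorted(factors.items()) if k != axis)


def multi_level_compare(
    signatures: Mapping[str, Set[str]],
    level: int,
    axis: str,
    mode: str = "venn",
) -> Dict[str, Set[str]]:
    """Set algebra between condition-paired DEG sets.

    Level 1 passes the direct-contrast DEG sets through unchanged.  Levels
    2 and 3 pair conditions that differ only in ``axis`` (e.g. oxygen for
    hypoxic-vs-normoxic pairing at level 2, culture for coculture-vs-single
    pairing at level 3) and combine each pair (A, B) according to ``mode``:

    * ``"venn"`` (default): the unique-vs-shared partition — three derived
      sets ``A_only``, ``shared``, ``B_only``;
    * ``"difference"``: ``A - B``;
    * ``"intersection"``: ``A & B``;
    * ``"union"``: ``A | B``.

    The applied mode is recorded in each derived-set key.
    """
    if level == 1:
        return {k: set(v) for k, v in signatures.items()}
    if level not in (2, 3):
        raise ValueError("level must be 1, 2 or 3")
    if mode not in ("venn", "difference", "intersection", "union"):
        raise ValueError(f"unknown mode {mode!r}")

    parsed = {label: parse_condition_label(label) for label in signatures}
    groups: Dict[Tuple, List[str]] = {}
    for label, fac in parsed.items():
        if axis not in fac:
            raise ValueError(f"axis {axis!r} not a condition factor")
        groups.setdefault(_pair_key(fac, axis), []).append(label)

    out: Dict[str, Set[str]] = {}
    for key, labels in groups.items():
        if len(labels) != 2:
            raise ValueError(
                f"conditions {labels} cannot be paired along axis {axis!r} "
                f"(need exactly 2 per group, got {len(labels)})"
            )
        la, lb = sorted(labels, key=lambda s: parsed[s][axis])
        A, B = set(signatures[la]), set(signatures[lb])
        tag = f"{la}|{lb}"
        if mode == "venn":
            out[f"{tag}:{la}_only"] = A - B
            out[f"{tag}:shared"] = A & B
            out[f"{tag}:{lb}_only"] = B - A
        elif mode == "difference":
            out[f"{tag}:difference"] = A - B
        elif mode == "intersection":
            out[f"{tag}:intersection"] = A & B
        else:
            out[f"{tag}:union"] = A | B
    return out


# ---------------------------------------------------------------------------
# pre-ranked enrichment


def _running_es(in_set: np.ndarray, weights: np.ndarray) -> float:
    """Signed maximum deviation of the weighted KS running sum."""
    n = in_set.size
    nh = int(in_set.sum())
    nr = float(weights[in_set].sum())
    if nh == 0 or nh == n:
        raise ValueError("gene set must overlap the ranked list strictly partially")
    hit_inc = (weights / nr) if nr > 0 else np.full(n, 1.0 / nh)
    inc = np.where(in_set, hit_inc, -1.0 / (n - nh))
    run = np.cumsum(inc)
    i = int(np.argmax(np.abs(run)))
    return float(run[i])


def preranked_es(
    ranked: Sequence[Tuple[str, float]] | pd.DataFrame,
    gene_set: Iterable[str] | Signature,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    exhaustive: bool = False,
) -> Tuple[float, float]:
    """Pre-ranked enrichment score and permutation p-value.

    ``ranked`` is the full gene list ordered by decreasing score (logFC),
    as (gene, score) pairs or a DataFrame with ``gene``/``logFC`` columns.
    The enrichment score is the maximum deviation of the running sum that
    increments by ``|score|**weight`` (normalized) at member genes and
    decrements by ``1/(N - N_hit)`` otherwise.  Significance is assessed
    by permuting gene labels (equivalently: redrawing the member positions
    uniformly), ``p = (1 + #{ES_perm at least as extreme, same sign}) /
    (1 + n_perm)``; with ``exhaustive=True`` every membership arrangement
    is enumerated instead (feasible only for tiny universes) and the exact
    fraction is returned.
    """
    if isinstance(ranked, pd.DataFrame):
        genes = ranked["gene"].astype(str).tolist()
        scores = ranked["logFC"].to_numpy(dtype=float)
    else:
        genes = [g for g, _ in ranked]
        scores = np.array([s for _, s in ranked], dtype=float)
    if len(set(genes)) != len(genes):
        raise ValueError("ranked list contains duplicate genes")
    order = np.argsort(-scores, kind="stable")
    genes = [genes[i] for i in order]
    scores = scores[order]

    members = set(gene_set.genes) if isinstance(gene_set, Signature) else set(gene_set)
    in_set = np.array([g in members for g in genes], dtype=bool)
    nh = int(in_set.sum())
    n = in_set.size
    if nh == 0:
        raise ValueError("gene set does not overlap the ranked universe")
    if nh == n:
        raise ValueError("gene set covers the entire ranked universe; ES undefined")

    w = np.abs(scores) ** weight
    es = _running_es(in_set, w)

    def es_for(mask: np.ndarray) -> float:
        return _running_es(mask, w)

    if exhaustive:
        count = 0
        total = 0
        for pos in itertools.combinations(range(n), nh):
            mask = np.zeros(n, dtype=bool)
            mask[list(pos)] = True
            e = es_for(mask)
            total += 1
            if (es >= 0 and e >= es) or (es < 0 and e <= es):
                count += 1
        return es, count / total

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=nh, replace=False)] = True
        e = es_for(mask)
        if (es >= 0 and e >= es) or (es < 0 and e <= es):
            count += 1
    return es, (1 + count) / (1 + n_perm)


# ---------------------------------------------------------------------------
# overlap statistics


def overlap_analysis(
    exvivo: Iterable[str],
    signatures: Sequence[Signature],
    pathways: Optional[Mapping[str, Iterable[str]]] = None,
) -> OverlapResult:
    """Explained / univocal / shared / pathway statistics for an ex vivo DEG set.

    * explained fraction: share of ex vivo DEGs present in at least one
      signature; unexplained is its complement.
    * univocal fractions: share explained by *exactly one* signature,
      grouped by that signature's discriminating variable.
    * per-signature unique fraction: same genes attributed per signature.
    * shared matrix: entry (i, j) is the fraction of ex vivo DEGs present
      in both signatures (diagonal: the signature's total overlap).
    * pathway contribution: for each pathway, the fraction of its ex vivo
      DEGs that each signature covers.
    """
    E = set(exvivo)
    if not E:
        raise ValueError("ex vivo gene set is empty")
    names = [s.name for s in signatures]
    if len(set(names)) != len(names):
        raise ValueError("duplicate signature names")
    nE = len(E)

    hits: Dict[str, Set[str]] = {s.name: E & set(s.genes) for s in signatures}
    union = set().union(*hits.values()) if hits else set()
    explained = len(union) / nE

    membership_count = {g: sum(g in h for h in hits.values()) for g in union}
    univocal_by_var: Dict[str, float] = {v: 0.0 for v in DISCRIMINATING_VARIABLES}
    unique_frac: Dict[str, float] = {}
    for s in signatures:
        uniq = {g for g in hits[s.name] if membership_count[g] == 1}
        unique_frac[s.name] = len(uniq) / nE
        univocal_by_var[s.discriminating_variable] += len(uniq) / nE

    mat = pd.DataFrame(0.0, index=names, columns=names)
    for a in signatures:
        for b in signatures:
            mat.loc[a.name, b.name] = len(hits[a.name] & hits[b.name]) / nE

    pw = None
    if pathways is not None:
        rows = {}
        for pname, pgenes in pathways.items():
            pE = E & set(pgenes)
            if not pE:
                rows[pname] = {n: 0.0 for n in names}
                continue
            rows[pname] = {s.name: len(pE & hits[s.name]) / len(pE) for s in signatures}
        pw = pd.DataFrame(rows).T.reindex(columns=names)

    return OverlapResult(
        explained_fraction=explained,
        unexplained_fraction=(nE - len(union)) / nE,
        univocal_fraction_by_variable=univocal_by_var,
        per_signature_unique_fraction=unique_frac,
        shared_matrix=mat,
        pathway_contribution=pw,
        n_exvivo=nE,
    )


def screen_signatures(
    ranked: pd.DataFrame,
    signatures: Sequence[Signature],
    exvivo: Optional[Set[str]] = None,
    p_threshold: float = 0.05,
    min_overlap: int = 1,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> List[Signature]:
    """Retain signatures that are both enriched and overlapping.

    A signature passes when its pre-ranked permutation p-value is at most
    ``p_threshold`` *and* it shares at least ``min_overlap`` genes with the
    ex vivo DEG set (default: the ranked universe itself when no explicit
    set is given).
    """
    universe = set(ranked["gene"].astype(str))
    target = exvivo if exvivo is not None else universe
    kept: List[Signature] = []
    for sig in signatures:
        ov = len(target & set(sig.genes))
        if ov < min_overlap:
            continue
        if not (set(sig.genes) & universe) or set(sig.genes) >= universe:
            continue
        _, p = preranked_es(ranked, sig, weight=weight, n_perm=n_perm, seed=seed)
        if p <= p_threshold:
            kept.append(sig)
    return kept
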