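"""Synthetic inputs for every pipeline stage.

Emulated data:

* the factorial condition grid of the culture experiment (cell type ×
  immune cue × culture arm × time/oxygen, 48 combinations minus a
  configured exclusion list; the study design comprised 44 conditions),
* DEG tables and signature collections with *planted* overlap truth so
  the exact overlap statistics can be asserted,
* logFC-ranked tables with a planted enriched gene set for calibrating
  the pre-ranked enrichment screen,
* labeled spatial point patterns (homogeneous Poisson or Thomas-type
  clustered) emulating exported mIHC cell coordinates,
* log-uniform parameter draws around a base model parameterization.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .model import ReducedParams
from .overlap import DISCRIMINATING_VARIABLES, OverlapResult, Signature, overlap_analysis
from .spatial import PHENOTYPES, ROI_UM

__all__ = [
    "DEFAULT_CONDITION_SCHEME",
    "generate_condition_grid",
    "PlantedOverlapSpec",
    "plant_overlap_instance",
    "plant_ranked_instance",
    "PointPatternSpec",
    "generate_point_pattern",
    "sample_parameters",
]


# ---------------------------------------------------------------------------
# condition grid

#: Demo condition scheme: cell type (M/F), immune cue (0 resting, I
#: LPS+IFNγ, F IL-4), culture arm (SC single / CC coculture) and
#: time+oxygen (4 h / 24 h, N normoxia / H hypoxia).  The shipped
#: exclusion list is a non-authoritative demo choice trimming the 48-cell
#: factorial to the 44-condition design size.
DEFAULT_CONDITION_SCHEME = {
    "segments": [["cell_type", "stimulus"], ["culture"], ["time_oxygen"]],
    "factors": {
        "cell_type": ["M", "F"],
        "stimulus": ["0", "I", "F"],
        "culture": ["SC", "CC"],
        "time_oxygen": ["4N", "24N", "4H", "24H"],
    },
    "exclusions": ["MF/SC/4N", "MF/SC/4H", "FF/SC/4N", "FF/SC/4H"],
}


def generate_condition_grid(scheme: Optional[Mapping] = None) -> List[str]:
    """Cartesian product of the declared condition factors minus exclusions.

    Labels join factor groups with ``/`` and concatenate codes within a
    group, e.g. ``"MI/CC/24H"``.
    """
    scheme = scheme or DEFAULT_CONDITION_SCHEME
    try:
        segments = scheme["segments"]
        factors = scheme["factors"]
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed condition scheme: {exc}") from exc
    exclusions = set(scheme.get("exclusions", []))
    names = [name for seg in segments for name in seg]
    for name in names:
        if not factors.get(name):
            raise ValueError(f"condition factor {name!r} is empty or missing")
    labels = []
    for combo in itertools.product(*(factors[name] for name in names)):
        values = dict(zip(names, combo))
        label = "/".join("".join(values[n] for n in seg) for seg in segments)
        if label not in exclusions:
            labels.append(label)
    return labels


# ---------------------------------------------------------------------------
# planted overlap instances


@dataclass(frozen=True)
class PlantedOverlapSpec:
    """Blueprint for an overlap instance with known ground truth.

    ``explained_fraction`` of the ``n_exvivo`` ex vivo DEGs will be
    covered by at least one signature; ``univocal_fractions`` allocates a
    part of the explained genes to exactly-one-signature membership per
    discriminating variable, the remainder is shared by >= 2 signatures.
    All fractions must be multiples of ``1/n_exvivo`` for exact planting.
    """

    universe_size: int = 1000
    n_exvivo: int = 200
    signature_sizes: Tuple[int, ...] = (60, 60, 60, 60)
    signature_variables: Tuple[str, ...] = ("inflammation", "IL4", "cell_interaction", "hypoxia")
    explained_fraction: float = 0.45
    univocal_fractions: Mapping[str, float] = field(default_factory=lambda: {"inflammation": 0.10})
    seed: int = 0

    def __post_init__(self):
        if len(self.signature_sizes) != len(self.signature_variables):
            raise ValueError("signature_sizes and signature_variables must align")
        for v in self.signature_variables:
            if v not in DISCRIMINATING_VARIABLES:
                raise ValueError(f"unknown discriminating variable {v!r}")


def _exact_count(fraction: float, total: int, what: str) -> int:
    c = fraction * total
    if abs(c - round(c)) > 1e-9:
        raise ValueError(f"{what} = {fraction} is not a multiple of 1/{total}; cannot plant exactly")
    return int(round(c))


def plant_overlap_instance(
    spec: PlantedOverlapSpec,
) -> Tuple[Set[str], List[Signature], OverlapResult]:
    """Construct (ex vivo set, signatures, ground truth) realizing the spec.

    Genes are assigned to signatures by bookkeeping so that
    ``overlap_analysis`` recovers the planted explained and univocal
    fractions exactly; the returned ground truth is computed from the
    construction, not from ``overlap_analysis``.
    """
    rng = np.random.default_rng(spec.seed)
    n_sig = len(spec.signature_sizes)
    if n_sig == 0:
        raise ValueError("need at least one signature")

    n_explained = _exact_count(spec.explained_fraction, spec.n_exvivo, "explained_fraction")
    univ_counts = {
        v: _exact_count(f, spec.n_exvivo, f"univocal_fractions[{v}]")
        for v, f in spec.univocal_fractions.items()
    }
    n_univocal = sum(univ_counts.values())
    if n_univocal > n_explained:
        raise ValueError(
            f"univocal total ({n_univocal}) exceeds explained count ({n_explained})"
        )
    n_shared = n_explained - n_univocal
    if n_shared > 0 and n_sig < 2:
        raise ValueError("shared (multiply-explained) genes require >= 2 signatures")
    for v in univ_counts:
        if v not in spec.signature_variables:
            raise ValueError(f"no signature carries discriminating variable {v!r}")

    if spec.n_exvivo > spec.universe_size:
        raise ValueError("n_exvivo exceeds universe size")
    width = max(4, len(str(spec.universe_size - 1)))
    universe = [f"G{i:0{width}d}" for i in range(spec.universe_size)]
    exvivo = list(rng.choice(spec.universe_size, size=spec.n_exvivo, replace=False))
    exvivo_genes = [universe[i] for i in sorted(exvivo)]
    order = rng.permutation(spec.n_exvivo)

    sig_members: List[Set[str]] = [set() for _ in range(n_sig)]
    cursor = 0
    # univocal genes: each goes to exactly one signature of the requested variable
    for v, cnt in univ_counts.items():
        carriers = [i for i, sv in enumerate(spec.signature_variables) if sv == v]
        for k in range(cnt):
            g = exvivo_genes[order[cursor]]
            cursor += 1
            sig_members[carriers[k % len(carriers)]].add(g)
    # shared genes: each goes to exactly two signatures (round-robin pairs)
    pairs = list(itertools.combinations(range(n_sig), 2))
    for k in range(n_shared):
        g = exvivo_genes[order[cursor]]
        cursor += 1
        i, j = pairs[k % len(pairs)]
        sig_members[i].add(g)
        sig_members[j].add(g)

    # fill signatures to size with genes outside the ex vivo set
    exvivo_set = set(exvivo_genes)
    filler_pool = [g for g in universe if g not in exvivo_set]
    rng.shuffle(filler_pool)
    fp = 0
    signatures: List[Signature] = []
    for i, (size, var) in enumerate(zip(spec.signature_sizes, spec.signature_variables)):
        members = set(sig_members[i])
        if len(members) > size:
            raise ValueError(
                f"signature {i} needs {len(members)} planted genes but size is {size}"
            )
        need = size - len(members)
        if fp + need > len(filler_pool):
            raise ValueError("universe too small to fill signatures without extra overlap")
        members |= set(filler_pool[fp : fp + need])
        fp += need
        signatures.append(
            Signature(
                name=f"SIG{i:02d}_{var}",
                genes=frozenset(members),
                cell_type="Mphi" if i % 2 == 0 else "Fb",
                discriminating_variable=var,
            )
        )

    # ground truth from the construction's own bookkeeping
    truth_univocal = {v: 0.0 for v in DISCRIMINATING_VARIABLES}
    for v, cnt in univ_counts.items():
        truth_univocal[v] = cnt / spec.n_exvivo
    truth = OverlapResult(
        explained_fraction=n_explained / spec.n_exvivo,
        unexplained_fraction=(spec.n_exvivo - n_explained) / spec.n_exvivo,
        univocal_fraction_by_variable=truth_univocal,
        per_signature_unique_fraction={
            s.name: sum(
                1
                for g in sig_members[i]
                if sum(g in sm for sm in sig_members) == 1
            )
            / spec.n_exvivo
            for i, s in enumerate(signatures)
        },
        shared_matrix=_truth_shared_matrix(signatures, sig_members, spec.n_exvivo),
        pathway_contribution=None,
        n_exvivo=spec.n_exvivo,
    )
    return exvivo_set, signatures, truth


def _truth_shared_matrix(signatures, sig_members, n_exvivo):
    names = [s.name for s in signatures]
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            mat.loc[a, b] = len(sig_members[i] & sig_members[j]) / n_exvivo
    return mat


# ---------------------------------------------------------------------------
# planted ranked lists


def plant_ranked_instance(
    universe_size: int,
    enriched_size: int,
    effect: float,
    seed: int = 0,
) -> Tuple[pd.DataFrame, Set[str]]:
    """Ranked DEG table with a planted enriched set.

    Null logFC values are standard normal (only rank structure matters to
    the pre-ranked screen); the planted set's scores are shifted upward by
    ``effect``.  Returns the table sorted by decreasing logFC and the set
    of planted gene names.
    """
    if enriched_size >= universe_size:
        raise ValueError("enriched set must be a strict subset of the universe")
    rng = np.random.default_rng(seed)
    width = max(4, len(str(universe_size - 1)))
    genes = [f"G{i:0{width}d}" for i in range(universe_size)]
    logfc = rng.standard_normal(universe_size)
    planted_idx = rng.choice(universe_size, size=enriched_size, replace=False)
    logfc[planted_idx] += effect
    df = pd.DataFrame(
        {
            "gene": genes,
            "logFC": logfc,
            "pvalue": rng.uniform(size=universe_size),
            "fdr": rng.uniform(size=universe_size),
        }
    ).sort_values("logFC", ascending=False, ignore_index=True)
    return df, {genes[i] for i in planted_idx}


# ---------------------------------------------------------------------------
# spatial point patterns


@dataclass(frozen=True)
class PointPatternSpec:
    """Blueprint for a labeled point pattern in one rectangular ROI.

    ``intensities`` maps phenotype to expected cells per µm² (homogeneous
    Poisson).  Phenotypes listed in ``clustered`` instead follow a
    Thomas process: Poisson parents of intensity ``parent_intensity``,
    each with Poisson(``offspring_mean``) offspring displaced by an
    isotropic Gaussian of scale ``dispersion_um``.
    """

    intensities: Mapping[str, float] = field(default_factory=dict)
    roi_um: Tuple[float, float] = ROI_UM
    clustered: Mapping[str, Tuple[float, float, float]] = field(default_factory=dict)
    compartment: str = "interstitium"
    region_id: str = "ROI_0"
    seed: int = 0

    def __post_init__(self):
        if self.roi_um[0] <= 0 or self.roi_um[1] <= 0:
            raise ValueError("ROI dimensions must be positive")
        for ph, lam in self.intensities.items():
            if lam < 0:
                raise ValueError(f"negative intensity for {ph!r}")


def generate_point_pattern(spec: PointPatternSpec) -> pd.DataFrame:
    """Seeded Poisson / Thomas point pattern as a cell table."""
    rng = np.random.default_rng(spec.seed)
    w, h = spec.roi_um
    rows = []

    def emit(ph, xs, ys):
        for x, y in zip(xs, ys):
            rows.append(
                {
                    "cell_id": f"c{len(rows)}",
                    "phenotype": ph,
                    "x_um": float(x),
                    "y_um": float(y),
                    "region_id": spec.region_id,
                    "compartment": spec.compartment,
                }
            )

    for ph in sorted(spec.intensities):
        if ph in spec.clustered:
            continue
        n = rng.poisson(spec.intensities[ph] * w * h)
        emit(ph, rng.uniform(0, w, n), rng.uniform(0, h, n))

    for ph in sorted(spec.clustered):
        parent_intensity, offspring_mean, dispersion = spec.clustered[ph]
        n_par = rng.poisson(parent_intensity * w * h)
        px = rng.uniform(0, w, n_par)
        py = rng.uniform(0, h, n_par)
        for cx, cy in zip(px, py):
            n_off = rng.poisson(offspring_mean)
            xs = np.clip(cx + rng.normal(0, dispersion, n_off), 0, w)
            ys = np.clip(cy + rng.normal(0, dispersion, n_off), 0, h)
            emit(ph, xs, ys)

    return pd.DataFrame(
        rows, columns=["cell_id", "phenotype", "x_um", "y_um", "region_id", "compartment"]
    )


# ---------------------------------------------------------------------------
# parameter draws


def sample_parameters(
    base: ReducedParams,
    relative_ranges: Mapping[str, float] | float,
    n: int,
    seed: int,
) -> List[ReducedParams]:
    """Log-uniform parameter draws around ``base``.

    ``relative_ranges`` gives the relative half-width per parameter (a
    scalar applies to all five); a value ``r`` draws the multiplicative
    factor log-uniformly on ``[1 - r, 1 + r]``.  ``r = 0`` reproduces the
    base exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    names = ("lam", "delta1", "delta2", "alpha", "beta")
    if isinstance(relative_ranges, (int, float)):
        relative_ranges = {k: float(relative_ranges) for k in names}
    for k, r in relative_ranges.items():
        if k not in names:
            raise ValueError(f"unknown parameter {k!r}")
        if not (0 <= r < 1):
            raise ValueError(f"relative range for {k!r} must be in [0, 1), got {r}")
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n):
        vals = {}
        for k in names:
            r = relative_ranges.get(k, 0.0)
            base_v = getattr(base, k)
            if r == 0:
                vals[k] = base_v
            else:
                lo, hi = math.log(1.0 - r), math.log(1.0 + r)
                vals[k] = base_v * math.exp(rng.uniform(lo, hi))
        draws.append(ReducedParams(**vals))
    return draws
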