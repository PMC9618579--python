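"""Cell density and fixed-radius neighborhood statistics for mIHC exports.

Input is a per-cell table (phenotype label, x/y coordinates in µm, region
and kidney-compartment labels) as exported from multiplexed
immunohistochemistry.  Two summaries are computed:

* per-phenotype cell density (cells/mm²) per region, with mean/SD across
  regions, using compartment areas supplied by the caller (default: the
  full 466 × 349 µm region-of-interest area);
* the neighborhood profile of a focal phenotype: for every focal cell,
  the relative frequency of each phenotype among all other cells within a
  Euclidean radius (default 7.5 µm, boundary inclusive), averaged across
  focal cells.

Focal cells with no neighbor inside the radius have an undefined relative
frequency and are excluded from the mean/SD; their count is reported.
No edge correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "PHENOTYPES",
    "ROI_UM",
    "roi_area_mm2",
    "read_cell_table",
    "cell_density",
    "NeighborhoodProfile",
    "neighborhood_profile",
]

PHENOTYPES = ("CD68+/CD206+", "CD68+/CD206-", "CD8+", "CD4+", "CD20+", "FAP+", "other")
COMPARTMENTS = ("glomerulus", "surrounding", "interstitium")
#: region-of-interest dimensions in µm (width, height)
ROI_UM = (466.0, 349.0)

REQUIRED_COLUMNS = ("cell_id", "phenotype", "x_um", "y_um", "region_id", "compartment")


def roi_area_mm2(roi_um: Sequence[float] = ROI_UM) -> float:
    return roi_um[0] * roi_um[1] / 1e6


def read_cell_table(path) -> pd.DataFrame:
    """Read a CSV cell table with columns cell_id, phenotype, x_um, y_um, region_id, compartment."""
    df = pd.read_csv(path)
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cell table missing columns: {sorted(missing)}")
    validate_cell_table(df)
    return df


def validate_cell_table(df: pd.DataFrame) -> None:
    if not np.isfinite(df[["x_um", "y_um"]].to_numpy(dtype=float)).all():
        raise ValueError("non-finite coordinates in cell table")
    bad = ~df["compartment"].isin(COMPARTMENTS)
    if bad.any():
        raise ValueError(f"unknown compartment labels: {sorted(df.loc[bad, 'compartment'].unique())}")


def cell_density(
    table: pd.DataFrame,
    compartment: str,
    areas_um2: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Per-phenotype density (cells/mm²) per region, plus mean/SD across regions.

    ``areas_um2`` maps region id to the analyzable area of that region in
    µm² (e.g. ROI area minus the glomerulus area for the "surrounding"
    compartment).  When omitted, the full ROI area is used for every
    region.  Returns a tidy frame with one row per (region, phenotype)
    and, under region id ``"__summary__"``, the across-region mean and SD.
    """
    if compartment not in COMPARTMENTS:
        raise ValueError(f"unknown compartment {compartment!r}")
    sub = table[table["compartment"] == compartment]
    regions = sorted(sub["region_id"].unique()) if len(sub) else []
    default_area = roi_area_mm2() * 1e6

    rows = []
    for region in regions:
        area_um2 = (areas_um2 or {}).get(region, default_area)
        if area_um2 <= 0:
            raise ValueError(f"non-positive area for region {region!r}")
        area_mm2 = area_um2 / 1e6
        counts = sub[sub["region_id"] == region]["phenotype"].value_counts()
        for ph in PHENOTYPES:
            rows.append(
                {
                    "region_id": region,
                    "phenotype": ph,
                    "count": int(counts.get(ph, 0)),
                    "density_per_mm2": counts.get(ph, 0) / area_mm2,
                }
            )
    df = pd.DataFrame(rows, columns=["region_id", "phenotype", "count", "density_per_mm2"])
    if len(df):
        summary = (
            df.groupby("phenotype", sort=False)["density_per_mm2"]
            .agg(["mean", "std"])
            .fillna(0.0)
            .reset_index()
        )
        summary.insert(0, "region_id", "__summary__")
        summary = summary.rename(columns={"mean": "density_per_mm2"})
        summary["count"] = np.nan
        df = pd.concat(
            [df, summary[["region_id", "phenotype", "count", "density_per_mm2", "std"]]],
            ignore_index=True,
        )
    return df


@dataclass
class NeighborhoodProfile:
    focal_phenotype: str
    mean_frequency: Dict[str, float]
    sd_frequency: Dict[str, float]
    n_focal_cells: int  # focal cells with >= 1 neighbor (enter the mean)
    n_isolated: int  # focal cells with no neighbor inside the radius
    radius_um: float

    @property
    def defined(self) -> bool:
        return self.n_focal_cells > 0


def neighborhood_profile(
    table: pd.DataFrame,
    focal_phenotype: str,
    radius_um: float = 7.5,
    neighbor_phenotypes: Optional[Sequence[str]] = None,
    include_other: bool = False,
) -> NeighborhoodProfile:
    """Mean ± SD relative phenotype frequencies within ``radius_um`` of focal cells.

    For every cell of ``focal_phenotype``, all *other* cells within the
    (inclusive) radius are collected and the relative frequency of each
    neighbor phenotype among them computed; the profile reports the mean
    and SD of those per-cell frequencies.  By default the denominator
    counts only the six named phenotypes; ``include_other=True`` adds the
    ``"other"`` class.
    """
    if radius_um <= 0:
        raise ValueError("radius must be > 0")
    if neighbor_phenotypes is None:
        neighbor_phenotypes = [p for p in PHENOTYPES if include_other or p != "other"]
    neighbor_phenotypes = list(neighbor_phenotypes)

    xy = table[["x_um", "y_um"]].to_numpy(dtype=float)
    phen = table["phenotype"].to_numpy()
    focal_idx = np.nonzero(phen == focal_phenotype)[0]
    if focal_idx.size == 0:
        return NeighborhoodProfile(
            focal_phenotype=focal_phenotype,
            mean_frequency={p: float("nan") for p in neighbor_phenotypes},
            sd_frequency={p: float("nan") for p in neighbor_phenotypes},
            n_focal_cells=0,
            n_isolated=0,
            radius_um=radius_um,
        )

    counted = np.isin(phen, neighbor_phenotypes)
    tree = cKDTree(xy)
    neighbor_lists = tree.query_ball_point(xy[focal_idx], r=radius_um)

    freqs = []
    n_isolated = 0
    for fi, neigh in zip(focal_idx, neighbor_lists):
        idx = np.array([j for j in neigh if j != fi and counted[j]], dtype=int)
        if idx.size == 0:
            n_isolated += 1
            continue
        labels = phen[idx]
        freqs.append([np.mean(labels == p) for p in neighbor_phenotypes])

    if not freqs:
        return NeighborhoodProfile(
            focal_phenotype=focal_phenotype,
            mean_frequency={p: float("nan") for p in neighbor_phenotypes},
            sd_frequency={p: float("nan") for p in neighbor_phenotypes},
            n_focal_cells=0,
            n_isolated=n_isolated,
            radius_um=radius_um,
        )
    arr = np.asarray(freqs)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(arr.shape[1])
    return NeighborhoodProfile(
        focal_phenotype=focal_phenotype,
        mean_frequency=dict(zip(neighbor_phenotypes, mean.tolist())),
        sd_frequency=dict(zip(neighbor_phenotypes, sd.tolist())),
        n_focal_cells=len(freqs),
        n_isolated=n_isolated,
        radius_um=radius_um,
    )
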