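"""Cell densities and 7.5 µm neighborhood profiles on a synthetic tissue map.

Emulates an exported multiplexed-IHC cell table for one 466 x 349 µm
region: macrophages and T cells scattered at random (complete spatial
randomness), B cells clustered (Thomas process).  The neighborhood
profile of a focal phenotype is the mean relative frequency of each
phenotype among all cells within 7.5 µm of a focal cell.
"""

import numpy as np

from fibrophase import PointPatternSpec, cell_density, generate_point_pattern, neighborhood_profile

spec = PointPatternSpec(
    intensities={"CD68+/CD206+": 1.5e-3, "CD8+": 1.0e-3},
    clustered={"CD20+": (2e-5, 60.0, 4.0)},  # parents/µm², offspring per parent, spread µm
    seed=11,
)
cells = generate_point_pattern(spec)
print(f"cells generated: {len(cells)} ({dict(cells.phenotype.value_counts())})")

dens = cell_density(cells, "interstitium")
per_region = dens[dens.region_id != "__summary__"]
for _, row in per_region[per_region["count"] > 0].iterrows():
    print(f"  {row.phenotype:13s} {row['count']:4.0f} cells  {row.density_per_mm2:8.1f} /mm²")

phenos = ["CD68+/CD206+", "CD8+", "CD20+"]
for focal in phenos:
    prof = neighborhood_profile(cells, focal, radius_um=7.5, neighbor_phenotypes=phenos)
    pretty = {p: round(prof.mean_frequency[p], 3) for p in phenos}
    print(
        f"neighbors of {focal:13s}: {pretty} "
        f"(n={prof.n_focal_cells}, isolated={prof.n_isolated})"
    )

n20 = (cells.phenotype == "CD20+").sum()
print(f"CSR expectation for CD20+ self-frequency would be ~{n20 / len(cells):.3f}")
print(
    "meaning: the clustered B cells neighbor themselves far above the "
    "random-mixing expectation, while the Poisson phenotypes mirror their "
    "global abundances."
)
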