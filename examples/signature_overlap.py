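"""In vitro signatures vs an ex vivo DEG set: explained/univocal statistics.

A planted synthetic instance stands in for the real data: 200 ex vivo
DEGs from a 1000-gene universe, four in vitro signatures labeled by their
discriminating variable, with 45% of the ex vivo set covered by at least
one signature and 10% attributable to inflammation alone.  The overlap
statistics are exact set arithmetic, so the planted truth is recovered
to the last digit.  A pre-ranked enrichment screen is run on top.
"""

from fibrophase import (
    PlantedOverlapSpec,
    Signature,
    overlap_analysis,
    plant_overlap_instance,
    plant_ranked_instance,
    preranked_es,
)

spec = PlantedOverlapSpec(
    universe_size=1000,
    n_exvivo=200,
    explained_fraction=0.45,
    univocal_fractions={"inflammation": 0.10},
    seed=7,
)
exvivo, signatures, truth = plant_overlap_instance(spec)
res = overlap_analysis(exvivo, signatures)

print(f"ex vivo DEGs: {res.n_exvivo}")
print(f"explained by >=1 in vitro signature: {res.explained_fraction:.1%}")
print(f"unexplained: {res.unexplained_fraction:.1%}")
for var, frac in sorted(res.univocal_fraction_by_variable.items()):
    if frac:
        print(f"  univocal via {var}: {frac:.1%}")
print("pairwise shared fractions (top-left of the matrix):")
print(res.shared_matrix.iloc[:3, :3].round(3))

# enrichment screen on a ranked list with one planted signal
ranked, planted = plant_ranked_instance(400, 25, effect=2.0, seed=7)
es, p = preranked_es(ranked, planted, n_perm=500, seed=7)
print(f"planted set: enrichment score {es:.3f}, permutation p = {p:.4f}")
print(
    "meaning: the explained share tells how much of the tissue's fibrotic "
    "transcriptome the culture conditions reproduce; univocal shares point "
    "at the variable (here inflammation) that uniquely accounts for genes."
)
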