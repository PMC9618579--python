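"""Map the inflammation-hypoxia plane into its three dynamical regimes.

Phase I: only the healthy, fibroblast-free state is stable.  Phase II:
healthy and fibrotic states coexist (bistability) — the fate depends on
the initial macrophage/fibroblast load.  Phase III: the healthy state has
lost stability and fibrosis is the only attractor.
"""

import numpy as np

from fibrophase import BASELINE_PARAMS, critical_hypoxia, critical_inflammation, phase_diagram

diag = phase_diagram(
    BASELINE_PARAMS, np.geomspace(0.05, 10.0, 100), np.linspace(0.0, 2.0, 100)
)
labels, counts = np.unique(diag.phase_labels, return_counts=True)
total = diag.phase_labels.size

print("regime share of the sampled (y, H) window:")
for lab, cnt in zip(labels, counts):
    print(f"  Phase {lab:>3}: {cnt / total:6.1%}")
print(f"distinct regimes: {sorted(diag.labels_present())}")

# the II/III boundary is analytic: H_cr = (delta2/beta)(lam + delta1/y)
print(f"critical hypoxia at y=1:        H_cr = {critical_hypoxia(BASELINE_PARAMS, 1.0):.4f}")
print(f"critical inflammation at H=0.5: y_cr = {critical_inflammation(BASELINE_PARAMS, 0.5):.4f}")
print(
    "meaning: above H_cr (equivalently beyond y_cr) the kidney tissue can no "
    "longer return to the fibroblast-free state on its own."
)
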