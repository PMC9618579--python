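"""Collapse the three-variable cell-count model to the reduced form.

The dimensional model tracks proinflammatory macrophages M1, profibrotic
macrophages M2 and activated fibroblasts F.  Because phenotype switching
is fast, the two macrophage pools stay in the ratio M1/M2 = lam*y and the
system reduces to two non-dimensional variables (m, f).  The reduction
map is exact (Box-canonical) when K = l*Y0/d1.
"""

import numpy as np

from fibrophase import DimensionalParams, DimensionalState, Environment, ReducedState, reduce_model
from fibrophase.simulate import integrate, integrate_dimensional

dp = DimensionalParams(
    l=2, d1=1, d2=1, d3=0.5, r=0.5, Y0=1, K=2, g=0.5, F0=4, k12=200, k21=200
)
rp, scales = reduce_model(dp)
print("reduced parameters:", {k: round(v, 4) for k, v in rp.to_dict().items()})
print(
    "scales: time x{time_scale:.3g}, macrophages x{macrophage_scale:.3g}, "
    "fibroblasts x{fibroblast_scale:.3g}, kappa={kappa:.3g} (canonical={canonical})".format(
        **scales
    )
)

env = Environment(y=1.0, H=1.0)
m0, f0 = 0.2, 0.25
M = m0 * scales["macrophage_scale"]
lam_y = rp.lam * env.y
dim0 = DimensionalState(M1=M * lam_y / (1 + lam_y), M2=M / (1 + lam_y), F=f0 * scales["fibroblast_scale"])

traj_dim = integrate_dimensional(dp, env, dim0, t_end=20.0, n_points=50)
traj_red = integrate(rp, env, ReducedState(m=m0, f=f0), t_end=20.0, n_points=50)
m_dim = (traj_dim.states[:, 0] + traj_dim.states[:, 1]) / scales["macrophage_scale"]
f_dim = traj_dim.states[:, 2] / scales["fibroblast_scale"]

err_m = np.abs(m_dim - traj_red.states[:, 0]).max()
err_f = np.abs(f_dim - traj_red.states[:, 1]).max()
print(f"max |m_dim - m_red| = {err_m:.2e}, max |f_dim - f_red| = {err_f:.2e}")
print(
    "meaning: with switching 200x faster than turnover, the rescaled "
    "three-variable trajectory is indistinguishable from the reduced model "
    "(discrepancy ~ d1/k12)."
)
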