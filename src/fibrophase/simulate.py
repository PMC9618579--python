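"""Trajectory integration and long-run attractor classification.

Both model forms integrate with SciPy's adaptive solvers.  The reduced
dynamics are forward-invariant on ``{m >= 0, 0 <= f <= 1}`` (df/dt vanishes
at f = 0, is negative at f = 1, and dm/dt >= 0 at m = 0), so trajectories
started inside the region stay inside up to solver tolerance.

``attractor_of`` integrates until the state dwells inside a small ball
around a known stable equilibrium, classifying the outcome as *healthy*
(fibroblast-free branch) or *fibrotic*.  ``fibrosis_temperature`` splits
fibrotic equilibria into "hot" (macrophage-rich, m well above the healthy
level) and "cold" (fibroblasts persist with few macrophages).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .equilibria import Equilibrium, find_steady_states, healthy_state
from .model import (
    DimensionalParams,
    DimensionalState,
    Environment,
    ReducedParams,
    ReducedState,
    full_rhs,
    reduced_rhs_arr,
)

__all__ = [
    "Trajectory",
    "integrate",
    "integrate_dimensional",
    "attractor_of",
    "fibrosis_temperature",
]

DEFAULT_T_END = 500.0
DEFAULT_DWELL = 10.0
ATTRACTOR_RADIUS = 1e-3


@dataclass
class Trajectory:
    """Time-indexed solution path of either model form."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, n_vars); columns (m, f) or (M1, M2, F)
    env: Environment
    params: object
    kind: str = "reduced"  # reduced | dimensional

    def terminal(self) -> np.ndarray:
        return self.states[-1]

    def to_tsv(self, path) -> None:
        header = "t\tm\tf" if self.kind == "reduced" else "t\tM1\tM2\tF"
        data = np.column_stack([self.times, self.states])
        np.savetxt(path, data, delimiter="\t", header=header, comments="")


class IntegrationError(RuntimeError):
    """Adaptive solver failed (step-size collapse or non-finite state)."""


def _solve(rhs, y0, t_end, reltol, abstol, method, t_eval=None):
    sol = solve_ivp(
        rhs,
        (0.0, float(t_end)),
        np.asarray(y0, dtype=float),
        method=method,
        rtol=reltol,
        atol=abstol,
        t_eval=t_eval,
        dense_output=False,
    )
    if not sol.success:
        raise IntegrationError(f"solver {method} failed: {sol.message}")
    return sol


def integrate(
    params: ReducedParams,
    env: Environment,
    initial: ReducedState,
    t_end: float = DEFAULT_T_END,
    reltol: float = 1e-8,
    abstol: float = 1e-10,
    method: str = "RK45",
    n_points: int = 400,
) -> Trajectory:
    """Integrate the reduced model from ``initial`` until ``t_end``."""
    if t_end <= 0:
        raise ValueError("t_end must be > 0")

    def rhs(_t, s):
        m = max(s[0], 0.0)
        f = min(max(s[1], 0.0), 1.0)
        return reduced_rhs_arr(m, f, params, env)

    t_eval = np.linspace(0.0, t_end, n_points)
    sol = _solve(rhs, initial.as_array(), t_end, reltol, abstol, method, t_eval)
    states = np.clip(sol.y.T, [0.0, 0.0], [np.inf, 1.0])
    return Trajectory(times=sol.t, states=states, env=env, params=params, kind="reduced")


def integrate_dimensional(
    params: DimensionalParams,
    env: Environment,
    initial: DimensionalState,
    t_end: float,
    reltol: float = 1e-8,
    abstol: float = 1e-10,
    method: str = "LSODA",
    n_points: int = 400,
) -> Trajectory:
    """Integrate the dimensional three-variable model (stiff-capable default)."""
    if t_end <= 0:
        raise ValueError("t_end must be > 0")

    def rhs(_t, s):
        st = DimensionalState(M1=max(s[0], 0.0), M2=max(s[1], 0.0), F=max(s[2], 0.0))
        return full_rhs(st, params, env)

    t_eval = np.linspace(0.0, t_end, n_points)
    sol = _solve(rhs, initial.as_array(), t_end, reltol, abstol, method, t_eval)
    return Trajectory(
        times=sol.t, states=np.clip(sol.y.T, 0.0, np.inf), env=env, params=params, kind="dimensional"
    )


def attractor_of(
    params: ReducedParams,
    env: Environment,
    initial: ReducedState,
    t_end: float = DEFAULT_T_END,
    dwell: float = DEFAULT_DWELL,
    radius: float = ATTRACTOR_RADIUS,
    equilibria: Optional[Sequence[Equilibrium]] = None,
) -> str:
    """Classify the long-run fate of ``initial`` as healthy/fibrotic/undecided.

    Integrates in chunks of length ``dwell``; once the trajectory stays
    within ``radius`` of a stable equilibrium for a full chunk, that
    equilibrium's branch is returned.  ``undecided`` is returned if the
    horizon ``t_end`` is exhausted first.
    """
    if equilibria is None:
        equilibria = find_steady_states(params, env)
    stable = [eq for eq in equilibria if eq.is_stable]
    if not stable:
        return "undecided"
    targets = np.array([[eq.state.m, eq.state.f] for eq in stable])
    branches = [eq.branch for eq in stable]

    def rhs(_t, s):
        m = max(s[0], 0.0)
        f = min(max(s[1], 0.0), 1.0)
        return reduced_rhs_arr(m, f, params, env)

    state = initial.as_array()
    t = 0.0
    current: Optional[int] = None
    while t < t_end:
        sol = _solve(rhs, state, dwell, 1e-9, 1e-11, "RK45", t_eval=np.linspace(0, dwell, 20))
        seg = np.clip(sol.y.T, [0.0, 0.0], [np.inf, 1.0])
        state = seg[-1]
        t += dwell
        # nearest stable equilibrium over the whole chunk
        d = np.linalg.norm(seg[:, None, :] - targets[None, :, :], axis=2)  # (n_t, n_eq)
        within = d.max(axis=0) <= radius  # stayed near eq for the full chunk
        hit = np.nonzero(within)[0]
        if hit.size:
            idx = int(hit[np.argmin(d[-1, hit])])
            if current == idx:
                br = branches[idx]
                return "healthy" if br == "healthy" else "fibrotic"
            current = idx
        else:
            current = None
    return "undecided"


def fibrosis_temperature(
    eq: Equilibrium,
    params: ReducedParams,
    env: Environment,
    hot_multiple: float = 2.0,
) -> str:
    """Label a stable equilibrium as hot/cold fibrosis or none (healthy).

    A fibrotic state is *hot* when its macrophage level exceeds
    ``hot_multiple`` times the healthy-state macrophage level at the same
    environment (macrophage-rich scarring); otherwise *cold* (fibroblasts
    persist without a macrophage infiltrate).
    """
    if not eq.is_stable:
        raise ValueError("fibrosis_temperature expects a stable equilibrium")
    if eq.branch == "healthy":
        return "none"
    m_healthy = healthy_state(params, env.y).m
    return "hot" if eq.state.m >= hot_multiple * m_healthy else "cold"
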