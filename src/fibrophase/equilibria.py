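"""Fixed points and linear stability of the reduced model.

The reduced system always admits the *healthy* equilibrium
``(m, f) = (y(1+lam*y)/(lam*y+delta1), 0)``.  Under hypoxia the non-trivial
fibroblast nullcline ``f(m) = 1 - delta2*(1+lam*y)/(beta*H*m)`` can
intersect the macrophage nullcline in up to two interior points: a saddle
and a *fibrotic* state.  The healthy state is linearly stable iff

    H < H_cr = (delta2/beta) * (lam + delta1/y),

equivalently iff the inflammation stays below the critical level
``y_cr = delta1 / ((beta/delta2)*H - lam)`` (defined only when
``(beta/delta2)*H > lam``; below that hypoxia level the healthy state is
stable at every inflammation).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .model import Environment, ReducedParams, ReducedState, reduced_rhs_arr

__all__ = [
    "Equilibrium",
    "healthy_state",
    "jacobian",
    "find_steady_states",
    "critical_hypoxia",
    "critical_inflammation",
    "export_equilibria_csv",
    "export_equilibria_json",
]

#: eigenvalue real parts smaller than this (in magnitude) are treated as zero
NONHYPERBOLIC_TOL = 1e-8
#: number of initial brackets for the interior-root scan
N_BRACKETS = 2048
#: relative tolerance of the bisection refinement
ROOT_RTOL = 1e-12
#: interior roots closer than this (relative) are merged as duplicates
MERGE_RTOL = 1e-6


@dataclass(frozen=True)
class Equilibrium:
    state: ReducedState
    eigenvalues: Tuple[complex, complex]
    stability_class: str  # stable_node | stable_focus | unstable_node | unstable_focus | saddle | nonhyperbolic
    branch: str  # healthy | fibrotic | saddle_branch

    @property
    def is_stable(self) -> bool:
        return self.stability_class in ("stable_node", "stable_focus")


def healthy_state(params: ReducedParams, y: float) -> ReducedState:
    """Fibroblast-free equilibrium ``(y(1+lam*y)/(lam*y+delta1), 0)``."""
    if y < 0:
        raise ValueError("y must be >= 0")
    m = y * (1.0 + params.lam * y) / (params.lam * y + params.delta1)
    return ReducedState(m=m, f=0.0)


def jacobian(state: ReducedState, params: ReducedParams, env: Environment) -> np.ndarray:
    """Analytic 2x2 Jacobian of the reduced right-hand side at ``state``."""
    lam, d1, d2, a, b = params.lam, params.delta1, params.delta2, params.alpha, params.beta
    y, H = env.y, env.H
    m, f = state.m, state.f
    B = 1.0 + lam * y
    # d(dm)/dm: derivative of a*H*(y+1)*m*f/(m+B) in m is a*H*(y+1)*f*B/(m+B)^2
    J11 = -(lam * y + d1) / B + a * H * (y + 1.0) * f * B / (m + B) ** 2
    J12 = a * H * (y + 1.0) * m / (m + B)
    J21 = b * H * f * (1.0 - f) / B
    J22 = b * H * m * (1.0 - 2.0 * f) / B - d2
    return np.array([[J11, J12], [J21, J22]], dtype=float)


def _classify(eigs: np.ndarray) -> str:
    re = eigs.real
    if np.any(np.abs(re) < NONHYPERBOLIC_TOL):
        return "nonhyperbolic"
    if re[0] * re[1] < 0:
        return "saddle"
    complex_pair = np.abs(eigs.imag).max() > NONHYPERBOLIC_TOL
    if np.all(re < 0):
        return "stable_focus" if complex_pair else "stable_node"
    return "unstable_focus" if complex_pair else "unstable_node"


def _make_equilibrium(
    m: float, f: float, params: ReducedParams, env: Environment, branch: str
) -> Equilibrium:
    st = ReducedState(m=max(m, 0.0), f=min(max(f, 0.0), 1.0))
    eigs = np.linalg.eigvals(jacobian(st, params, env))
    eigs = eigs[np.argsort(eigs.real)]
    cls = _classify(eigs)
    if branch == "interior":
        branch = "saddle_branch" if cls == "saddle" else "fibrotic"
    return Equilibrium(state=st, eigenvalues=(complex(eigs[0]), complex(eigs[1])), stability_class=cls, branch=branch)


def _interior_f(m, params: ReducedParams, env: Environment):
    """Non-trivial fibroblast nullcline f(m) = 1 - delta2*(1+lam*y)/(beta*H*m)."""
    B = 1.0 + params.lam * env.y
    return 1.0 - params.delta2 * B / (params.beta * env.H * m)


def _interior_mdot(m, params: ReducedParams, env: Environment):
    """dm/dt evaluated along the non-trivial fibroblast nullcline."""
    lam, d1, a = params.lam, params.delta1, params.alpha
    y, H = env.y, env.H
    B = 1.0 + lam * y
    f = _interior_f(m, params, env)
    return y - m * (lam * y + d1) / B + a * H * (y + 1.0) * m * f / (m + B)


def _interior_root_bound(params: ReducedParams, env: Environment) -> float:
    """Upper bound on interior-equilibrium m.

    Substituting the non-trivial f-nullcline into dm/dt = 0 and clearing
    denominators yields a quadratic in m,

        A m^2 + [A - y - alpha*H*(y+1)] B m + B^2 (alpha*delta2*(y+1)/beta - y) = 0

    with A = lam*y + delta1 and B = 1 + lam*y; the Cauchy bound
    1 + max(|b/a|, |c/a|) then provably contains every root.
    """
    lam, d1, d2, a, b = params.lam, params.delta1, params.delta2, params.alpha, params.beta
    y, H = env.y, env.H
    A = lam * y + d1
    B = 1.0 + lam * y
    cb = B * abs(A - y - a * H * (y + 1.0)) / A
    cc = B * B * abs(a * d2 * (y + 1.0) / b - y) / A
    return 1.0 + max(cb, cc)


def find_steady_states(params: ReducedParams, env: Environment) -> List[Equilibrium]:
    """All equilibria of the reduced model at the given environment.

    The healthy state is always returned.  For ``H > 0`` the non-trivial
    fibroblast nullcline is substituted into ``dm/dt = 0`` and the
    resulting scalar root problem in ``m`` is solved by a bracketing
    sign-change scan (``N_BRACKETS`` panels over a provably root-containing
    interval) followed by bisection refinement.  Roots whose fibroblast
    fraction falls outside (0, 1) are discarded as unphysical; duplicates
    within tolerance are merged.
    """
    hs = healthy_state(params, env.y)
    out = [_make_equilibrium(hs.m, hs.f, params, env, branch="healthy")]
    if env.H <= 0:
        return out

    m_max = _interior_root_bound(params, env)
    eps = 1e-12 * max(1.0, m_max)
    grid = np.linspace(eps, m_max, N_BRACKETS + 1)
    vals = _interior_mdot(grid, params, env)
    roots: List[float] = []
    sign = np.sign(vals)
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        r = brentq(
            lambda m: _interior_mdot(m, params, env),
            grid[i],
            grid[i + 1],
            xtol=1e-300,
            rtol=max(ROOT_RTOL, 4e-16),
        )
        roots.append(float(r))
    # exact grid hits (rare): keep them too
    for i in np.nonzero(vals == 0.0)[0]:
        roots.append(float(grid[i]))

    roots.sort()
    merged: List[float] = []
    for r in roots:
        if merged and abs(r - merged[-1]) <= MERGE_RTOL * max(1.0, abs(r)):
            continue
        merged.append(r)

    for r in merged:
        f = _interior_f(r, params, env)
        if not (0.0 < f < 1.0):
            continue
        if abs(r - hs.m) <= MERGE_RTOL * max(1.0, hs.m) and f < MERGE_RTOL:
            continue  # coincides with the healthy state (transcritical point)
        out.append(_make_equilibrium(r, f, params, env, branch="interior"))
    return out


def critical_hypoxia(params: ReducedParams, y: float) -> float:
    """Hypoxia threshold ``H_cr = (delta2/beta)*(lam + delta1/y)``.

    The healthy state is linearly stable iff ``H < H_cr``.  At ``y = 0``
    the threshold is infinite (healthy state stable for all H).
    """
    if y < 0:
        raise ValueError("y must be >= 0")
    if y == 0:
        return math.inf
    return (params.delta2 / params.beta) * (params.lam + params.delta1 / y)


def critical_inflammation(params: ReducedParams, H: float) -> Optional[float]:
    """Critical inflammation ``y_cr = delta1/((beta/delta2)*H - lam)``.

    Above ``y_cr`` the system cannot return to the healthy state.  Returns
    ``None`` when ``(beta/delta2)*H <= lam``: below that hypoxia level the
    healthy state stays stable at every inflammation level.
    """
    if H < 0:
        raise ValueError("H must be >= 0")
    denom = (params.beta / params.delta2) * H - params.lam
    if denom <= 0:
        return None
    return params.delta1 / denom


def export_equilibria_csv(equilibria: List[Equilibrium], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["m", "f", "eig_re_1", "eig_im_1", "eig_re_2", "eig_im_2", "class", "branch"])
        for eq in equilibria:
            e1, e2 = eq.eigenvalues
            w.writerow(
                [eq.state.m, eq.state.f, e1.real, e1.imag, e2.real, e2.imag, eq.stability_class, eq.branch]
            )


def export_equilibria_json(equilibria: List[Equilibrium], path) -> None:
    recs = [
        {
            "m": eq.state.m,
            "f": eq.state.f,
            "eigenvalues": [[e.real, e.imag] for e in eq.eigenvalues],
            "class": eq.stability_class,
            "branch": eq.branch,
        }
        for eq in equilibria
    ]
    with open(path, "w") as fh:
        json.dump(recs, fh, indent=2)
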