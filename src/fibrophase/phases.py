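"""Inflammation–hypoxia phase structure and basin separatrices.

Three dynamical regimes partition the (y, H) plane:

* **Phase I** — only the healthy (fibroblast-free) state is stable;
* **Phase II** — bistable: healthy and fibrotic states are both stable and
  the saddle's stable manifold separates their basins in (m, f) space;
* **Phase III** — the healthy state has lost stability and the fibrotic
  state attracts.

The II/III boundary is the analytic healthy-stability curve
``H = (delta2/beta)(lam + delta1/y)``; the I/II boundary (birth of the
stable fibrotic state) is located numerically.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .equilibria import (
    Equilibrium,
    critical_hypoxia,
    find_steady_states,
    healthy_state,
    jacobian,
)
from .model import Environment, ReducedParams, ReducedState, reduced_rhs_arr

__all__ = [
    "PhaseDiagram",
    "BasinSeparatrix",
    "classify_phase",
    "phase_diagram",
    "fold_boundary",
    "basin_separatrix",
    "robustness_sweep",
]


@dataclass
class PhaseDiagram:
    y_grid: np.ndarray
    H_grid: np.ndarray
    phase_labels: np.ndarray  # (|H_grid|, |y_grid|) of {"I","II","III","unresolved"}
    separatrix_curve: List[Tuple[float, float]]  # (y, H) on the healthy-stability boundary
    fold_curve: List[Tuple[float, float]]  # (y, H) where the stable fibrotic state is born

    def labels_present(self) -> set:
        labs = set(np.unique(self.phase_labels))
        labs.discard("unresolved")
        return labs

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["H\\y"] + [f"{y:.6g}" for y in self.y_grid])
            for i, H in enumerate(self.H_grid):
                w.writerow([f"{H:.6g}"] + list(self.phase_labels[i]))

    def curves_to_csv(self, sep_path, fold_path) -> None:
        for path, curve in ((sep_path, self.separatrix_curve), (fold_path, self.fold_curve)):
            with open(path, "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["y", "H"])
                w.writerows(curve)

    def plot(self, path=None, ax=None):
        """Render the phase labels as a heatmap with both boundary curves."""
        import matplotlib

        if path is not None:
            matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4.5))
        code = {"I": 0, "II": 1, "III": 2, "unresolved": 3}
        Z = np.vectorize(code.get)(self.phase_labels)
        ax.pcolormesh(
            self.y_grid, self.H_grid, Z, cmap="viridis", vmin=0, vmax=3, shading="nearest"
        )
        if self.separatrix_curve:
            ys, Hs = zip(*self.separatrix_curve)
            ax.plot(ys, Hs, "r-", lw=2, label="healthy-stability boundary (II/III)")
        if self.fold_curve:
            ys, Hs = zip(*self.fold_curve)
            ax.plot(ys, Hs, "w--", lw=1.5, label="fibrotic-state birth (I/II)")
        ax.set_xscale("log")
        ax.set_xlabel("inflammation y")
        ax.set_ylabel("hypoxia H")
        ax.legend(loc="upper right", fontsize=8)
        if path is not None:
            ax.figure.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(ax.figure)
        return ax


@dataclass
class BasinSeparatrix:
    env: Environment
    saddle: ReducedState
    curve: np.ndarray  # (n, 2) ordered polyline of (m, f) points through the saddle

    def side_of(self, state: ReducedState) -> float:
        """Signed side of the separatrix polyline for a query state.

        Positive/negative sign distinguishes the two basins; the sign
        convention is fixed by the caller (see ``classify_side``).  Uses
        the cross product of the nearest segment's tangent with the offset
        to the query point.
        """
        p = np.array([state.m, state.f])
        a = self.curve[:-1]
        b = self.curve[1:]
        ab = b - a
        denom = (ab**2).sum(axis=1)
        denom[denom == 0] = 1.0
        t = np.clip(((p - a) * ab).sum(axis=1) / denom, 0.0, 1.0)
        proj = a + t[:, None] * ab
        d2 = ((p - proj) ** 2).sum(axis=1)
        i = int(np.argmin(d2))
        cross = ab[i, 0] * (p[1] - a[i, 1]) - ab[i, 1] * (p[0] - a[i, 0])
        return float(cross)


def _stability_flags(eqs: Sequence[Equilibrium]) -> Tuple[bool, bool, bool]:
    healthy_stable = any(eq.branch == "healthy" and eq.is_stable for eq in eqs)
    fibrotic_stable = any(eq.branch == "fibrotic" and eq.is_stable for eq in eqs)
    fibrotic_exists = any(eq.branch in ("fibrotic", "saddle_branch") for eq in eqs)
    return healthy_stable, fibrotic_stable, fibrotic_exists


def classify_phase(params: ReducedParams, env: Environment) -> str:
    """Label the environment as Phase I, II, III or unresolved.

    I: healthy stable, no stable fibrotic state.  II: both stable.
    III: healthy unstable, fibrotic stable.  Anything else (e.g. healthy
    unstable with no stable fibrotic root inside the scan window) is
    reported as ``unresolved`` rather than coerced.
    """
    eqs = find_steady_states(params, env)
    healthy_stable, fibrotic_stable, _ = _stability_flags(eqs)
    if healthy_stable and not fibrotic_stable:
        return "I"
    if healthy_stable and fibrotic_stable:
        return "II"
    if not healthy_stable and fibrotic_stable:
        return "III"
    return "unresolved"


def phase_diagram(
    params: ReducedParams,
    y_grid: Sequence[float],
    H_grid: Sequence[float],
) -> PhaseDiagram:
    """Classify every (y, H) grid point and trace both boundary curves."""
    y_grid = np.asarray(y_grid, dtype=float)
    H_grid = np.asarray(H_grid, dtype=float)
    if y_grid.size == 0 or H_grid.size == 0:
        raise ValueError("phase_diagram requires non-empty grids")
    labels = np.empty((H_grid.size, y_grid.size), dtype=object)
    for j, y in enumerate(y_grid):
        for i, H in enumerate(H_grid):
            labels[i, j] = classify_phase(params, Environment(y=y, H=H))

    H_lo, H_hi = float(H_grid.min()), float(H_grid.max())
    sep = []
    fold = []
    for y in y_grid:
        Hc = critical_hypoxia(params, y)
        if H_lo <= Hc <= H_hi:
            sep.append((float(y), float(Hc)))
        Hf = fold_boundary(params, float(y), H_hi)
        if Hf is not None and H_lo <= Hf <= H_hi:
            fold.append((float(y), Hf))
    return PhaseDiagram(
        y_grid=y_grid, H_grid=H_grid, phase_labels=labels, separatrix_curve=sep, fold_curve=fold
    )


def _has_stable_fibrotic(params: ReducedParams, env: Environment) -> bool:
    return any(eq.branch == "fibrotic" and eq.is_stable for eq in find_steady_states(params, env))


def fold_boundary(
    params: ReducedParams, y: float, H_max: float, tol: float = 1e-9
) -> Optional[float]:
    """Smallest H at which a stable fibrotic state exists at inflammation y.

    Located by bisection on the stable-fibrotic-existence predicate
    between 0 and ``H_max`` (the predicate is monotone in H for this
    model: hypoxia fuels both growth terms).  Returns ``None`` when no
    stable fibrotic state exists anywhere below ``H_max``.
    """
    if not _has_stable_fibrotic(params, Environment(y=y, H=H_max)):
        return None
    lo, hi = 0.0, float(H_max)
    while hi - lo > tol * max(1.0, hi):
        mid = 0.5 * (lo + hi)
        if _has_stable_fibrotic(params, Environment(y=y, H=mid)):
            hi = mid
        else:
            lo = mid
    return hi


def basin_separatrix(
    params: ReducedParams,
    env: Environment,
    t_max: float = 500.0,
    n_points: int = 2000,
    eps: float = 1e-7,
    m_cap: Optional[float] = None,
) -> BasinSeparatrix:
    """Stable manifold of the saddle: the healthy/fibrotic basin boundary.

    Only defined in Phase II.  The manifold is traced by integrating the
    reduced dynamics *backwards* in time from two seeds offset by ``eps``
    along the saddle's stable eigenvector, stopping at the domain boundary
    (m = 0, m = m_cap, f = 0 or f = 1) or after ``t_max`` time units.
    """
    phase = classify_phase(params, env)
    if phase != "II":
        raise ValueError(f"basin_separatrix requires a Phase II environment, got Phase {phase}")
    eqs = find_steady_states(params, env)
    saddles = [eq for eq in eqs if eq.stability_class == "saddle"]
    if not saddles:
        raise RuntimeError("Phase II environment without a saddle — classification inconsistency")
    saddle = saddles[0]
    J = jacobian(saddle.state, params, env)
    evals, evecs = np.linalg.eig(J)
    stable_idx = int(np.argmin(evals.real))
    v = np.real(evecs[:, stable_idx])
    v = v / np.linalg.norm(v)

    if m_cap is None:
        fib_m = max((eq.state.m for eq in eqs if eq.branch == "fibrotic"), default=saddle.state.m)
        m_cap = 10.0 * max(1.0, fib_m, saddle.state.m)

    from scipy.integrate import solve_ivp

    def back_rhs(_t, s):
        dm, df = reduced_rhs_arr(s[0], s[1], params, env)
        return (-dm, -df)

    def leave_box(_t, s):
        return min(s[0], m_cap - s[0], s[1], 1.0 - s[1])

    leave_box.terminal = True
    leave_box.direction = -1

    branches = []
    for sgn in (+1.0, -1.0):
        seed = np.array([saddle.state.m, saddle.state.f]) + sgn * eps * v
        sol = solve_ivp(
            back_rhs,
            (0.0, t_max),
            seed,
            method="LSODA",
            rtol=1e-10,
            atol=1e-12,
            events=leave_box,
            t_eval=None,
            max_step=t_max / 50.0,
        )
        pts = sol.y.T
        if sol.t_events[0].size and sol.y_events[0].size:
            pts = np.vstack([pts, sol.y_events[0]])
        branches.append(pts)

    curve = np.vstack(
        [branches[1][::-1], [[saddle.state.m, saddle.state.f]], branches[0]]
    )
    # resample to a manageable, strictly ordered polyline
    if curve.shape[0] > n_points:
        idx = np.linspace(0, curve.shape[0] - 1, n_points).astype(int)
        curve = curve[idx]
    return BasinSeparatrix(env=env, saddle=saddle.state, curve=curve)


def classify_side(sep: BasinSeparatrix, params: ReducedParams, state: ReducedState) -> str:
    """Predict healthy/fibrotic fate from the side of the separatrix polyline.

    The sign convention is calibrated once with the healthy equilibrium.
    """
    healthy_side = np.sign(sep.side_of(healthy_state(params, sep.env.y)))
    s = np.sign(sep.side_of(state))
    return "healthy" if s == healthy_side else "fibrotic"


def robustness_sweep(
    base: ReducedParams,
    relative_ranges: Dict[str, float],
    n_draws: int,
    seed: int,
    y_window: Tuple[float, float] = (1e-3, 100.0),
    H_max: Optional[float] = None,
    n_y: int = 40,
    n_order: int = 12,
) -> dict:
    """Fraction of perturbed parameter sets preserving the I/II/III structure.

    Each draw perturbs the five reduced parameters log-uniformly within the
    per-parameter relative ranges (e.g. ``0.5`` means a multiplicative
    factor in [0.5, 1.5]).  For each draw, presence of the three regimes in
    the (y, H) plane is probed per inflammation column: Phase I at H = 0,
    Phase III just above the analytic healthy-stability boundary H_cr(y)
    and at a few multiples of it, Phase II at a ladder of hypoxia levels
    below H_cr (the bistable band sits somewhere inside (0, H_cr); its
    location varies with the draw, so a fixed raster in H would miss thin
    bands).  With ``H_max`` set, probes are confined to hypoxia levels up
    to ``H_max`` — the question then becomes whether all three phases are
    visible inside that window rather than anywhere in the plane.  The
    I→II→III ordering with increasing H is then checked along the column
    that exhibits Phase II.
    """
    from .synth import sample_parameters

    draws = sample_parameters(base, relative_ranges, n_draws, seed)
    y_vals = np.geomspace(y_window[0], y_window[1], n_y)
    order_rank = {"I": 0, "II": 1, "III": 2}
    cap = math.inf if H_max is None else float(H_max)
    below_fracs = (0.999, 0.99, 0.95, 0.9, 0.8, 0.6, 0.4, 0.2, 0.1, 0.05)
    above_fracs = (1.001, 1.05, 1.2, 1.5, 2.0, 5.0)

    records = []
    n_ok = 0
    for params in draws:
        has_I = has_II = has_III = False
        y_II = None
        for y in y_vals:
            Hc = critical_hypoxia(params, float(y))
            if classify_phase(params, Environment(y=float(y), H=0.0)) == "I":
                has_I = True
            if Hc > 0.0 and math.isfinite(Hc):
                if not has_II:
                    for fr in below_fracs:
                        H = Hc * fr
                        if H > cap:
                            continue
                        if classify_phase(params, Environment(y=float(y), H=H)) == "II":
                            has_II = True
                            y_II = float(y)
                            break
                if not has_III:
                    for fr in above_fracs:
                        H = Hc * fr
                        if H > cap:
                            break
                        if classify_phase(params, Environment(y=float(y), H=H)) == "III":
                            has_III = True
                            break
            if has_I and has_II and has_III:
                break

        ordered = True
        if y_II is not None:
            Hc = critical_hypoxia(params, y_II)
            probes = np.unique(
                np.concatenate(
                    [
                        np.linspace(0.0, min(Hc * 1.5, cap), n_order),
                        [min(Hc * (1.0 - 1e-3), cap), min(Hc * (1.0 + 1e-3), cap)],
                    ]
                )
            )
            last = -1
            for H in probes:
                lab = classify_phase(params, Environment(y=y_II, H=float(H)))
                if lab == "unresolved":
                    continue
                rank = order_rank[lab]
                if rank < last:
                    ordered = False
                    break
                last = rank
        ok = has_I and has_II and has_III and ordered
        n_ok += ok
        records.append(
            {
                "params": params.to_dict(),
                "has_I": has_I,
                "has_II": has_II,
                "has_III": has_III,
                "ordered": ordered,
                "preserved": ok,
            }
        )
    return {
        "fraction_preserved": n_ok / n_draws,
        "n_draws": n_draws,
        "seed": seed,
        "records": records,
    }
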