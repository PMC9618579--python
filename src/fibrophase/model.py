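"""Macrophage–fibroblast interaction model.

Two forms of the same dynamics are implemented:

* the *dimensional* three-variable system for proinflammatory macrophages
  ``M1``, profibrotic macrophages ``M2`` and activated fibroblasts ``F``,
  driven by an exogenous inflammation level ``Y`` and hypoxia ``H``;
* the *reduced* non-dimensional two-variable system for the total
  macrophage population ``m`` and the activated-fibroblast fraction ``f``,
  obtained by assuming the phenotypic switch between the two macrophage
  states equilibrates fast (quasi-steady state) and rescaling all
  quantities.

The reduced right-hand side is

.. math::

    \\dot m = y - m\\,\\frac{\\lambda y + \\delta_1}{1+\\lambda y}
              + \\alpha H \\frac{(y+1)\\,m}{m+1+\\lambda y}\\, f,
    \\qquad
    \\dot f = \\beta H \\frac{m}{1+\\lambda y} f(1-f) - \\delta_2 f,

with inflammation ``y`` and hypoxia ``H`` exogenous drivers and all
parameters positive and dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, fields
from typing import Tuple

import numpy as np

__all__ = [
    "DimensionalParams",
    "DimensionalState",
    "ReducedParams",
    "Environment",
    "ReducedState",
    "switching_term",
    "qss_inflammation_link",
    "full_rhs",
    "reduced_rhs",
    "reduce_model",
    "BASELINE_PARAMS",
]


def _require_positive(obj, names):
    for name in names:
        v = getattr(obj, name)
        if not math.isfinite(v) or v <= 0:
            raise ValueError(f"{type(obj).__name__}.{name} must be finite and > 0, got {v!r}")


def _require_nonneg(obj, names):
    for name in names:
        v = getattr(obj, name)
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"{type(obj).__name__}.{name} must be finite and >= 0, got {v!r}")


@dataclass(frozen=True)
class DimensionalParams:
    """Rate constants of the dimensional three-variable model.

    Attributes
    ----------
    l : macrophage recruitment per unit inflammation (cells/time).
    d1, d2, d3 : deactivation/death rates of proinflammatory macrophages,
        profibrotic macrophages and fibroblasts (1/time).
    r : profibrotic macrophage proliferation rate (1/time).
    Y0 : reference inflammation level (dimensionless).
    K : base inhibition of profibrotic macrophage proliferation (cells).
    g : fibroblast activation rate (1/(cells*time)).
    F0 : mean maximum fibroblast number in fibrosis (cells).
    k12 : switch rate proinflammatory -> profibrotic (1/time).
    k21 : switch rate profibrotic -> proinflammatory per unit inflammation
        (1/(inflammation*time)).
    """

    l: float
    d1: float
    d2: float
    d3: float
    r: float
    Y0: float
    K: float
    g: float
    F0: float
    k12: float
    k21: float

    def __post_init__(self):
        _require_positive(self, [f.name for f in fields(self)])

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class DimensionalState:
    """Cell counts (M1 proinflammatory Mφ, M2 profibrotic Mφ, F activated Fb)."""

    M1: float
    M2: float
    F: float

    def __post_init__(self):
        _require_nonneg(self, ("M1", "M2", "F"))

    def as_array(self) -> np.ndarray:
        return np.array([self.M1, self.M2, self.F], dtype=float)


@dataclass(frozen=True)
class ReducedParams:
    """Dimensionless constants of the reduced two-variable model.

    ``lam`` is the ratio of the macrophage switching rates, ``delta1`` the
    profibrotic-to-proinflammatory deactivation ratio, ``delta2`` the
    fibroblast-to-proinflammatory deactivation ratio, ``alpha`` scales the
    profibrotic macrophage proliferation and ``beta`` the fibroblast
    proliferation.
    """

    lam: float
    delta1: float
    delta2: float
    alpha: float
    beta: float

    def __post_init__(self):
        _require_positive(self, ("lam", "delta1", "delta2", "alpha", "beta"))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ReducedParams":
        return cls(**{k: float(d[k]) for k in ("lam", "delta1", "delta2", "alpha", "beta")})


@dataclass(frozen=True)
class Environment:
    """Exogenous drivers: non-dimensional inflammation ``y`` and hypoxia ``H``."""

    y: float
    H: float

    def __post_init__(self):
        _require_nonneg(self, ("y", "H"))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Environment":
        return cls(y=float(d["y"]), H=float(d["H"]))


@dataclass(frozen=True)
class ReducedState:
    """Non-dimensional state: total macrophages ``m`` >= 0, fibroblast fraction ``f`` in [0, 1]."""

    m: float
    f: float

    def __post_init__(self):
        if not (math.isfinite(self.m) and math.isfinite(self.f)):
            raise ValueError(f"non-finite state ({self.m}, {self.f})")
        if self.m < 0 or not (0.0 <= self.f <= 1.0):
            raise ValueError(f"state outside invariant region: m={self.m}, f={self.f}")

    def as_array(self) -> np.ndarray:
        return np.array([self.m, self.f], dtype=float)


#: Baseline parameter set used by demos and tests.  The model is analysed
#: over arbitrary positive parameters; this set merely places all three
#: dynamical regimes inside a convenient inflammation/hypoxia window.
BASELINE_PARAMS = ReducedParams(lam=1.0, delta1=1.0, delta2=0.5, alpha=1.0, beta=4.0)


def switching_term(M1: float, M2: float, Y: float, k12: float, k21: float) -> float:
    """Net phenotype-switch flux into the proinflammatory pool.

    ``E12 = -k12*M1 + k21*M2*Y``: proinflammatory cells convert to the
    profibrotic phenotype at rate ``k12`` while inflammation drives the
    reverse conversion at rate ``k21*Y``.
    """
    for name, v in (("M1", M1), ("M2", M2), ("Y", Y), ("k12", k12), ("k21", k21)):
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"switching_term: {name} must be finite and >= 0, got {v!r}")
    return -k12 * M1 + k21 * M2 * Y


def qss_inflammation_link(M1: float, M2: float, lam: float) -> float:
    """Inflammation level implied by the fast-switch equilibrium.

    At quasi-steady state of the phenotypic switch the pool ratio fixes the
    inflammation level: ``Y = (1/lam) * M1/M2`` with ``lam = k21/k12``.
    """
    if lam <= 0:
        raise ValueError("lam must be > 0")
    if M2 <= 0:
        raise ValueError("qss_inflammation_link undefined for M2 = 0")
    return (M1 / M2) / lam


def full_rhs(
    state: DimensionalState, params: DimensionalParams, env: Environment
) -> Tuple[float, float, float]:
    """Time derivatives (dM1/dt, dM2/dt, dF/dt) of the dimensional model.

    Inflammation enters as the exogenous dimensional level ``Y = env.y``;
    hypoxia ``H`` gates both the profibrotic-macrophage proliferation and
    the fibroblast activation terms.
    """
    M1, M2, F = state.M1, state.M2, state.F
    Y, H = env.y, env.H
    p = params
    E12 = switching_term(M1, M2, Y, p.k12, p.k21)
    dM1 = p.l * Y + E12 - p.d1 * M1
    dM2 = p.r * H * M2 * F * (Y + p.Y0) / (M2 + p.K) - E12 - p.d2 * M2
    dF = p.g * H * M2 * F * (p.F0 - F) - p.d3 * F
    return (dM1, dM2, dF)


def reduced_rhs(
    state: ReducedState, params: ReducedParams, env: Environment
) -> Tuple[float, float]:
    """Time derivatives (dm/dt, df/dt) of the reduced non-dimensional model."""
    return reduced_rhs_arr(state.m, state.f, params, env)


def reduced_rhs_arr(m, f, params: ReducedParams, env: Environment):
    """Array-friendly reduced right-hand side (m, f may be floats or ndarrays)."""
    m = np.asarray(m, dtype=float)
    f = np.asarray(f, dtype=float)
    if not (np.all(np.isfinite(m)) and np.all(np.isfinite(f))):
        raise ValueError("non-finite state passed to reduced_rhs")
    lam, d1, d2, a, b = params.lam, params.delta1, params.delta2, params.alpha, params.beta
    y, H = env.y, env.H
    B = 1.0 + lam * y
    dm = y - m * (lam * y + d1) / B + a * H * (y + 1.0) * m * f / (m + B)
    df = b * H * m * f * (1.0 - f) / B - d2 * f
    if dm.ndim == 0:
        return (float(dm), float(df))
    return (dm, df)


def reduce_model(dp: DimensionalParams) -> Tuple[ReducedParams, dict]:
    """Map dimensional rate constants onto the reduced dimensionless model.

    The quasi-steady-state assumption for the phenotypic switch collapses
    the two macrophage pools into ``M = M1 + M2`` with split
    ``M1/M2 = lam*y``.  The scales used here are

    * time: ``1/d1`` (proinflammatory deactivation sets the clock),
    * macrophages: ``l*Y0/d1`` (recruitment balance at reference inflammation),
    * fibroblasts: ``F0``,
    * inflammation: ``Y0``.

    This yields ``lam = (k21/k12)*Y0``, ``delta1 = d2/d1``,
    ``delta2 = d3/d1``, ``alpha = r*F0/l`` and ``beta = g*l*Y0*F0/d1**2``.
    The proliferation-saturation denominator rescales to
    ``m + kappa*(1 + lam*y)`` with shape factor ``kappa = K*d1/(l*Y0)``;
    the canonical reduced form assumes ``kappa = 1`` (i.e. ``K = l*Y0/d1``).
    The returned scale report carries all scales and ``kappa`` so a caller
    can check whether the canonical form is exact for its parameters.
    """
    m_scale = dp.l * dp.Y0 / dp.d1
    rp = ReducedParams(
        lam=dp.k21 * dp.Y0 / dp.k12,
        delta1=dp.d2 / dp.d1,
        delta2=dp.d3 / dp.d1,
        alpha=dp.r * dp.F0 / dp.l,
        beta=dp.g * dp.l * dp.Y0 * dp.F0 / dp.d1**2,
    )
    report = {
        "time_scale": 1.0 / dp.d1,
        "macrophage_scale": m_scale,
        "fibroblast_scale": dp.F0,
        "inflammation_scale": dp.Y0,
        "kappa": dp.K * dp.d1 / (dp.l * dp.Y0),
        "canonical": bool(abs(dp.K * dp.d1 / (dp.l * dp.Y0) - 1.0) < 1e-12),
    }
    return rp, report
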