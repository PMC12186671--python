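"""Mechanistic model of whole-cell biosensor growth and reporter dynamics.

Cell growth is a double logistic in time; its per-capita derivative is the
dilution rate mu(t) that dilutes every intracellular species. The sensing
cascade is a three-state ODE system: transcription of the transcription
factor's mRNA, its translation into active regulator protein (saturating in
mRNA, scaled by ribosome availability and RBS strength), and production of
the normalized reporter (GFP/OD) through a Hill-type activation with a fixed
half-saturation of 0.5 and exponent 2. Induction by the ligand is at the
saturating reference concentration, folded into the maximal reporter rate.

Medium-, promoter- and context-scoped rate constants let the same equations
describe the biosensor across media, supplements, promoters and RBSs.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .context import ContextKey

__all__ = [
    "GrowthParams",
    "KineticParameterSet",
    "ModelState",
    "Trajectory",
    "default_grid",
    "double_logistic",
    "dilution_rate",
    "ribosome_availability",
    "simulate",
    "steady_state_gain",
    "relative_gain",
    "half_time",
]

HORIZON_H = 16.0
SAMPLING_MIN = 10.0


def default_grid() -> np.ndarray:
    """10-min sampling over a 16-h assay: 97 points."""
    return np.linspace(0.0, HORIZON_H, int(HORIZON_H * 60 / SAMPLING_MIN) + 1)


@dataclass(frozen=True)
class GrowthParams:
    """Double-logistic growth parameters.

    L1, a1, t1 (asymptote, rate in 1/h, midpoint in h) are context-dependent;
    k1 (second-wave gain, OD units) and k2 (second-wave time factor) are
    shared globally across contexts.
    """

    L1: float
    a1: float
    t1: float
    k1: float = 0.0
    k2: float = 1.0

    def __post_init__(self) -> None:
        if not (self.L1 > 0 and self.a1 > 0 and self.t1 > 0):
            raise ValueError("L1, a1, t1 must be positive")
        if self.k1 < 0:
            raise ValueError("k1 must be >= 0")
        if self.k2 <= 0:
            raise ValueError("k2 must be positive")


def _lookup(value, key: str, what: str) -> float:
    """Resolve a scoped parameter: scalar applies to every level."""
    if isinstance(value, Mapping):
        try:
            return float(value[key])
        except KeyError:
            raise KeyError(f"{what} has no value for level {key!r}") from None
    return float(value)


@dataclass(frozen=True)
class KineticParameterSet:
    """Rate and strength constants of the sensing cascade, with their scopes.

    Scalars are global; dict-valued fields are scoped (medium level ->
    value, promoter level -> value, or context id -> value). A plain float
    given for a scoped field means "same value in every level", which is
    convenient for single-context work.
    """

    vmax_PROM: float = 1.0               # maximum promoter activity (global)
    K_Pk: float | Mapping[str, float] = 1.0       # transcriptional strength per promoter
    K_mRNAp: float | Mapping[str, float] = 1.0    # mRNA production constant per medium
    k_deg: float = 1.0                   # base mRNA degradation constant (global, 1/h)
    K_mRNAdeg: float | Mapping[str, float] = 1.0  # mRNA degradation multiplier per medium
    K_P: float | Mapping[str, float] = 1.0        # protein production constant per medium
    K_lysis: float | Mapping[str, float] = 1.0    # proteolysis constant per medium
    RBS_strength: float | Mapping[str, float] = 1.0  # translation strength per context id
    k_FDER: float = 1.0                  # regulator translation rate (global, 1/h)
    K_NFDER: float = 0.5                 # Michaelis constant for regulator translation
    k_deg_FDER: float = 0.1              # regulator degradation constant (global, 1/h)
    vmax_NAR: float = 1.0                # maximum reporter production rate (global)
    k_deg_GFP: float = 0.1               # reporter degradation constant (global, 1/h)
    hill_half: float = 0.5               # Hill half-saturation (fixed, not estimated)
    hill_exp: float = 2.0                # Hill exponent (fixed)
    R_basal: float = 0.5                 # baseline ribosome availability in [0, 1]

    def __post_init__(self) -> None:
        for name in ("vmax_PROM", "k_deg", "k_FDER", "K_NFDER", "k_deg_FDER",
                     "vmax_NAR", "k_deg_GFP", "hill_half", "hill_exp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.R_basal <= 1.0:
            raise ValueError("R_basal must lie in [0, 1]")

    def resolve(self, ctx: ContextKey) -> "ResolvedKinetics":
        """Collapse scoped fields to the scalars governing one context."""
        return ResolvedKinetics(
            vmax_PROM=self.vmax_PROM,
            K_Pk=_lookup(self.K_Pk, ctx.promoter, "K_Pk"),
            K_mRNAp=_lookup(self.K_mRNAp, ctx.medium, "K_mRNAp"),
            k_deg=self.k_deg,
            K_mRNAdeg=_lookup(self.K_mRNAdeg, ctx.medium, "K_mRNAdeg"),
            K_P=_lookup(self.K_P, ctx.medium, "K_P"),
            K_lysis=_lookup(self.K_lysis, ctx.medium, "K_lysis"),
            RBS_strength=_lookup(self.RBS_strength, ctx.context_id, "RBS_strength"),
            k_FDER=self.k_FDER,
            K_NFDER=self.K_NFDER,
            k_deg_FDER=self.k_deg_FDER,
            vmax_NAR=self.vmax_NAR,
            k_deg_GFP=self.k_deg_GFP,
            hill_half=self.hill_half,
            hill_exp=self.hill_exp,
            R_basal=self.R_basal,
        )


@dataclass(frozen=True)
class ResolvedKinetics:
    """Per-context scalar view of a KineticParameterSet."""

    vmax_PROM: float
    K_Pk: float
    K_mRNAp: float
    k_deg: float
    K_mRNAdeg: float
    K_P: float
    K_lysis: float
    RBS_strength: float
    k_FDER: float
    K_NFDER: float
    k_deg_FDER: float
    vmax_NAR: float
    k_deg_GFP: float
    hill_half: float
    hill_exp: float
    R_basal: float


@dataclass(frozen=True)
class ModelState:
    """Intracellular state: transcript, regulator protein, reporter/OD."""

    mRNA: float = 0.0
    FDER: float = 0.0
    GFP_per_OD: float = 0.0

    def __post_init__(self) -> None:
        if self.mRNA < 0 or self.FDER < 0 or self.GFP_per_OD < 0:
            raise ValueError("model states must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.mRNA, self.FDER, self.GFP_per_OD], dtype=float)


@dataclass(frozen=True)
class Trajectory:
    """Sampled model output on a strictly increasing time grid (hours)."""

    times: np.ndarray
    od: np.ndarray
    mrna: np.ndarray
    fder: np.ndarray
    gfp_per_od: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or len(t) == 0:
            raise ValueError("times must be a non-empty 1-D array")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        for name in ("od", "mrna", "fder", "gfp_per_od"):
            arr = getattr(self, name)
            if len(arr) != len(t):
                raise ValueError(f"{name} length does not match times")

    def __len__(self) -> int:
        return len(self.times)


def double_logistic(t, gp: GrowthParams):
    """Cell count N(t) as a sum of two logistic waves.

    The second wave's rate is k1*a1 and its midpoint k2*t1, so a single
    gain coefficient k1 both scales the wave and couples its steepness to
    the primary growth rate.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("time must be finite")
    first = gp.L1 / (1.0 + np.exp(-gp.a1 * (t - gp.t1)))
    second = gp.k1 / (1.0 + np.exp(-(gp.k1 * gp.a1) * (t - gp.k2 * gp.t1)))
    return first + second


def _dN_dt(t, gp: GrowthParams):
    t = np.asarray(t, dtype=float)
    s1 = 1.0 / (1.0 + np.exp(-gp.a1 * (t - gp.t1)))
    s2 = 1.0 / (1.0 + np.exp(-(gp.k1 * gp.a1) * (t - gp.k2 * gp.t1)))
    return gp.L1 * gp.a1 * s1 * (1.0 - s1) + gp.k1 * (gp.k1 * gp.a1) * s2 * (1.0 - s2)


def dilution_rate(t, gp: GrowthParams):
    """Per-capita growth rate mu = (1/N) dN/dt, evaluated analytically."""
    n = double_logistic(t, gp)
    if np.any(n <= 0):
        raise ValueError("cell count must be positive to define a dilution rate")
    return _dN_dt(t, gp) / n


def ribosome_availability(A, R_basal):
    """Available ribosome fraction R = A*(1-Rb) + (1-A)*Rb + A*Rb.

    Algebraically R = A + R_basal*(1-A): the baseline pool plus the
    growth-driven recruitment of the remaining capacity. Bounded in [0, 1]
    for arguments in [0, 1].
    """
    A = np.asarray(A, dtype=float)
    Rb = np.asarray(R_basal, dtype=float)
    if np.any(A < 0) or np.any(A > 1) or np.any(Rb < 0) or np.any(Rb > 1):
        raise ValueError("A and R_basal must lie in [0, 1]")
    out = A + Rb * (1.0 - A)
    return float(out) if out.ndim == 0 else out


def _mu_scalar(gp: GrowthParams) -> Callable[[float], float]:
    """Scalar-math dilution rate, the hot path inside the ODE right-hand side."""
    L1, a1, t1, k1, k2 = gp.L1, gp.a1, gp.t1, gp.k1, gp.k2
    a2 = k1 * a1
    t2 = k2 * t1

    def mu(t: float) -> float:
        s1 = 1.0 / (1.0 + math.exp(min(max(-a1 * (t - t1), -700.0), 700.0)))
        s2 = 1.0 / (1.0 + math.exp(min(max(-a2 * (t - t2), -700.0), 700.0)))
        n = L1 * s1 + k1 * s2
        dn = L1 * a1 * s1 * (1.0 - s1) + k1 * a2 * s2 * (1.0 - s2)
        return dn / n if n > 0 else 0.0

    return mu


def _growth_coupling(gp: GrowthParams, horizon: float) -> Callable[[float], float]:
    """A(t): ribosomal response coefficient tied to growth.

    Defined as mu(t) normalized by its maximum over the assay horizon,
    clipped to [0, 1] — ribosomes are most available at peak growth.
    """
    dense = np.linspace(0.0, horizon, 2001)
    mu_max = float(np.max(dilution_rate(dense, gp)))
    if mu_max <= 0:
        return lambda t: 0.0
    mu = _mu_scalar(gp)

    def A(t: float) -> float:
        return min(max(mu(t) / mu_max, 0.0), 1.0)

    return A


def simulate(
    ctx: ContextKey,
    gp: GrowthParams,
    kp: KineticParameterSet,
    grid: np.ndarray | None = None,
    init: ModelState | None = None,
    *,
    freeze_growth: bool = False,
    growth_coupling: Callable[[float], float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the sensing cascade for one context.

    ``freeze_growth`` sets the dilution rate to zero everywhere (and with it
    the growth-coupled ribosome recruitment), exposing the cascade's chemical
    steady states. ``growth_coupling`` overrides the default choice
    A(t) = mu(t)/max mu.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("time grid must be strictly increasing")
    init = ModelState() if init is None else init
    rk = kp.resolve(ctx)

    if freeze_growth:
        mu = lambda t: 0.0
        A = lambda t: 0.0
    else:
        mu = _mu_scalar(gp)
        A = growth_coupling if growth_coupling is not None else _growth_coupling(gp, float(grid[-1]))

    hh = rk.hill_half ** rk.hill_exp
    r_basal = rk.R_basal

    def rhs(t: float, y: np.ndarray) -> list[float]:
        mrna = max(y[0], 0.0)
        fder = max(y[1], 0.0)
        gfp = max(y[2], 0.0)
        mu_t = mu(t)
        a_t = A(t)
        r = a_t + r_basal * (1.0 - a_t)
        denom = mrna + rk.K_NFDER
        translation = rk.k_FDER * r * rk.RBS_strength * (mrna / denom if denom > 0 else 0.0)
        fh = fder ** rk.hill_exp
        hill = fh / (fh + hh) if (fh + hh) > 0 else 0.0
        d_mrna = rk.vmax_PROM * rk.K_Pk * rk.K_mRNAp - mu_t * mrna - rk.k_deg * rk.K_mRNAdeg * mrna
        d_fder = translation - rk.k_deg_FDER * fder * rk.K_lysis - mu_t * fder
        d_gfp = rk.vmax_NAR * rk.K_P * r * hill - rk.k_deg_GFP * gfp * rk.K_lysis - mu_t * gfp
        return [d_mrna, d_fder, d_gfp]

    sol = solve_ivp(
        rhs,
        (float(grid[0]), float(grid[-1])),
        init.as_array(),
        t_eval=grid,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed for context {ctx.context_id} ({sol.message}); kinetics: {rk}"
        )
    states = np.clip(sol.y, 0.0, None)
    od = np.zeros_like(grid) if freeze_growth else double_logistic(grid, gp)
    return Trajectory(times=grid, od=od, mrna=states[0], fder=states[1], gfp_per_od=states[2])


def steady_state_gain(traj: Trajectory) -> float:
    """Reporter gain: maximum GFP/OD over the assay horizon.

    The horizon maximum stands in for the steady-state response, matching
    how plate-reader screens summarize each well by its peak normalized
    fluorescence.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    return float(np.max(traj.gfp_per_od))


def relative_gain(gains) -> np.ndarray:
    """Gains as a percentage of the set maximum."""
    gains = np.asarray(gains, dtype=float)
    top = gains.max()
    if top <= 0:
        raise ValueError("no positive gain in the set")
    return gains / top * 100.0


def half_time(traj: Trajectory) -> float:
    """First time the reporter reaches 50% of its horizon maximum, in seconds.

    Linear interpolation between samples; if the first sample already exceeds
    half-maximum, the first grid time is returned. Reports commonly quote
    this in units of s x 10^3 — divide by 1e3 for that convention.
    """
    y = np.asarray(traj.gfp_per_od, dtype=float)
    peak = float(np.max(y))
    if peak <= 0:
        raise ValueError("no response: reporter signal is identically zero")
    target = 0.5 * peak
    t = np.asarray(traj.times, dtype=float)
    if y[0] >= target:
        return float(t[0]) * 3600.0
    idx = int(np.argmax(y >= target))
    t0, t1 = t[idx - 1], t[idx]
    y0, y1 = y[idx - 1], y[idx]
    crossing = t0 + (target - y0) / (y1 - y0) * (t1 - t0)
    return float(crossing) * 3600.0
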