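"""Weighted least-squares calibration of the mechanistic model.

The fit minimizes a discrete weighted sum of squared residuals between the
replicate-mean measurements (OD and GFP/OD) and the model output, with
inverse-variance diagonal weights estimated from the replicates to account
for heteroscedasticity. Rate-like parameters are searched on a log10 scale
inside box bounds; the optimizer is a budget-capped global stage
(differential evolution) followed by a local trust-region polish.

Parameter uncertainty is propagated by bootstrap aggregation (bagging):
replicate values are resampled per time point, the model is refit to each
realization (warm-started from the full-data fit), and the resulting
ensemble of parameter vectors is both the uncertainty summary and the
training set for the surrogate module.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import differential_evolution, least_squares

from .context import ContextKey
from .model_core import (
    GrowthParams,
    KineticParameterSet,
    Trajectory,
    double_logistic,
    simulate,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentTimeCourse",
    "Weights",
    "FitProblem",
    "FitResult",
    "EnsembleFit",
    "estimate_weights",
    "weighted_cost",
    "fit_growth",
    "calibrate",
    "bootstrap_resample",
    "bagging_ensemble",
    "make_fit_problem",
    "apply_parameters",
]


@dataclass(frozen=True)
class ExperimentTimeCourse:
    """Replicated OD and GFP/OD series for one context on a shared grid."""

    context: ContextKey
    times: np.ndarray
    od_replicates: np.ndarray   # shape (n_replicates, n_times)
    gfp_replicates: np.ndarray  # shape (n_replicates, n_times)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        od = np.atleast_2d(np.asarray(self.od_replicates, dtype=float))
        gfp = np.atleast_2d(np.asarray(self.gfp_replicates, dtype=float))
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od_replicates", od)
        object.__setattr__(self, "gfp_replicates", gfp)
        if od.shape[1] != len(t) or gfp.shape[1] != len(t):
            raise ValueError("replicate series must share the time grid")
        if od.shape[0] < 1 or gfp.shape[0] < 1:
            raise ValueError("at least one replicate is required")
        for arr, name in ((od, "od"), (gfp, "gfp")):
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"{name} replicates must be finite and non-negative")

    @property
    def n_replicates(self) -> int:
        return self.od_replicates.shape[0]

    @property
    def od_mean(self) -> np.ndarray:
        return self.od_replicates.mean(axis=0)

    @property
    def gfp_mean(self) -> np.ndarray:
        return self.gfp_replicates.mean(axis=0)


@dataclass(frozen=True)
class Weights:
    """Diagonal least-squares weights per output and time point."""

    od: np.ndarray
    gfp: np.ndarray


def estimate_weights(exp: ExperimentTimeCourse, smooth_window: int = 1) -> Weights:
    """Inverse-variance weights w_t = 1 / max(s_t^2, floor).

    s_t is the replicate standard deviation at time t; the floor
    (1e-3 x signal range)^2 keeps weights finite where replicates agree
    exactly. A single replicate yields uniform weights with a warning.

    With few replicates the raw s_t^2 is heavy-tailed (chi-square with
    n_rep - 1 dof), so ``smooth_window`` > 1 stabilizes it with a rolling
    mean over neighboring time points before inversion, preserving the
    heteroscedastic trend while damping per-point estimation noise.
    """

    def one(reps: np.ndarray) -> np.ndarray:
        if reps.shape[0] < 2:
            warnings.warn("single replicate: falling back to uniform weights", stacklevel=3)
            return np.ones(reps.shape[1])
        s2 = reps.std(axis=0, ddof=1) ** 2
        if smooth_window > 1 and len(s2) >= smooth_window:
            kernel = np.ones(smooth_window) / smooth_window
            s2 = np.convolve(s2, kernel, mode="same")
        signal_range = float(reps.mean(axis=0).max() - reps.mean(axis=0).min())
        floor = max((1e-3 * signal_range) ** 2, 1e-300)
        return 1.0 / np.maximum(s2, floor)

    return Weights(od=one(exp.od_replicates), gfp=one(exp.gfp_replicates))


# ---------------------------------------------------------------------------
# parameter vector <-> model objects


class _DefaultingMap(dict):
    """Scoped parameter map that falls back to a scalar default level value."""

    def __init__(self, default: float, *args, **kwargs):
        super().__init__(*args, **kwargs)
        self.default = float(default)

    def __missing__(self, key):
        return self.default


def apply_parameters(
    names: Sequence[str],
    values: Sequence[float],
    growth: dict[ContextKey, GrowthParams],
    kinetics: KineticParameterSet,
) -> tuple[dict[ContextKey, GrowthParams], KineticParameterSet]:
    """Substitute named parameter values into copies of the model objects.

    Names are ``field`` for globals (e.g. ``k_deg``, ``k1``),
    ``field[LEVEL]`` for medium/promoter-scoped entries (e.g.
    ``K_mRNAp[M0]``) and ``field[context_id]`` for context-scoped ones
    (e.g. ``RBS_strength[M0-S0-P1-R1]``). Growth fields (L1, a1, t1) are
    scoped by context id; k1 and k2 are global.
    """
    growth = dict(growth)
    kin_fields: dict = {}
    growth_updates: dict[str, dict[str, float]] = {}

    for name, value in zip(names, values):
        value = float(value)
        if "[" in name:
            fld, level = name[:-1].split("[", 1)
        else:
            fld, level = name, None
        if fld in ("L1", "a1", "t1"):
            if level is None:
                raise ValueError(f"growth parameter {fld} requires a context id scope")
            growth_updates.setdefault(level, {})[fld] = value
        elif fld in ("k1", "k2"):
            for ctx in growth:
                growth[ctx] = replace(growth[ctx], **{fld: value})
        else:
            if level is None:
                kin_fields[fld] = value
            else:
                current = kin_fields.get(fld, getattr(kinetics, fld))
                if hasattr(current, "items"):
                    mapping = (
                        _DefaultingMap(current.default, current)
                        if isinstance(current, _DefaultingMap)
                        else dict(current)
                    )
                else:
                    mapping = _DefaultingMap(current)
                mapping[level] = value
                kin_fields[fld] = mapping

    for ctx_id, upd in growth_updates.items():
        ctx = ContextKey.from_id(ctx_id)
        growth[ctx] = replace(growth[ctx], **upd)

    kinetics = replace(kinetics, **kin_fields) if kin_fields else kinetics
    return growth, kinetics


@dataclass
class FitProblem:
    """A weighted least-squares estimation problem over named parameters.

    ``param_names`` select the estimated entries (vector k); everything else
    in ``base_growth`` / ``base_kinetics`` stays fixed (vector v). Bounds are
    elementwise on the natural scale; optimization runs on log10(k) when
    ``log_scale`` is set (the default — rates span orders of magnitude).
    """

    dataset: list[ExperimentTimeCourse]
    param_names: list[str]
    k_lower: np.ndarray
    k_upper: np.ndarray
    base_growth: dict[ContextKey, GrowthParams]
    base_kinetics: KineticParameterSet
    weights: list[Weights] = field(default_factory=list)
    outputs: tuple[str, ...] = ("od", "gfp")
    log_scale: bool = True
    sim_rtol: float = 1e-6
    sim_atol: float = 1e-9

    def __post_init__(self) -> None:
        self.k_lower = np.asarray(self.k_lower, dtype=float)
        self.k_upper = np.asarray(self.k_upper, dtype=float)
        if len(self.k_lower) != len(self.param_names) or len(self.k_upper) != len(self.param_names):
            raise ValueError("bounds must match the number of estimated parameters")
        if np.any(self.k_lower > self.k_upper):
            raise ValueError("k_lower must be <= k_upper elementwise")
        if np.any(self.k_lower < 0):
            raise ValueError("parameters are constrained to be non-negative")
        if not self.weights:
            self.weights = [estimate_weights(exp) for exp in self.dataset]

    def build(self, k: np.ndarray) -> tuple[dict[ContextKey, GrowthParams], KineticParameterSet]:
        return apply_parameters(self.param_names, k, self.base_growth, self.base_kinetics)

    def residuals(self, k: np.ndarray) -> np.ndarray:
        """Weighted residual vector sqrt(w) * (y_m - y(k)) over all data."""
        growth, kinetics = self.build(k)
        res: list[np.ndarray] = []
        for exp, w in zip(self.dataset, self.weights):
            need_sim = "gfp" in self.outputs
            traj = None
            if need_sim:
                traj = simulate(
                    exp.context, growth[exp.context], kinetics,
                    grid=exp.times, rtol=self.sim_rtol, atol=self.sim_atol,
                )
            if "od" in self.outputs:
                od_model = (
                    traj.od if traj is not None
                    else double_logistic(exp.times, growth[exp.context])
                )
                res.append(np.sqrt(w.od) * (exp.od_mean - od_model))
            if "gfp" in self.outputs:
                res.append(np.sqrt(w.gfp) * (exp.gfp_mean - traj.gfp_per_od))
        return np.concatenate(res)


@dataclass(frozen=True)
class FitResult:
    k_hat: np.ndarray
    cost: float
    converged: bool
    n_evals: int
    param_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.cost < 0:
            raise ValueError("cost must be >= 0")

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.param_names, self.k_hat)}


@dataclass(frozen=True)
class EnsembleFit:
    """Calibrated parameter vectors from bagging iterations."""

    members: list[FitResult]
    n_iterations: int

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble must contain at least one member")

    @property
    def param_names(self) -> tuple[str, ...]:
        return self.members[0].param_names

    def parameter_matrix(self) -> np.ndarray:
        """Rows = members, columns = named parameters."""
        return np.vstack([m.k_hat for m in self.members])

    def mean(self) -> np.ndarray:
        return self.parameter_matrix().mean(axis=0)


def weighted_cost(k: np.ndarray, problem: FitProblem) -> float:
    """Discrete-sum approximation of the weighted least-squares integral.

    Sum over time points and outputs of w * (y_m - y(k))^2, with the
    replicate mean as y_m. Simulation failure returns +inf (logged) so that
    global optimizers can route around pathological parameter regions.
    """
    k = np.asarray(k, dtype=float)
    if np.any(k < problem.k_lower - 1e-12) or np.any(k > problem.k_upper + 1e-12):
        raise ValueError("k outside bounds")
    try:
        r = problem.residuals(k)
    except RuntimeError as err:
        logger.warning("simulation failed during cost evaluation: %s", err)
        return float("inf")
    return float(np.sum(r**2))


def make_fit_problem(
    dataset: list[ExperimentTimeCourse],
    param_names: Sequence[str],
    base_growth: dict[ContextKey, GrowthParams],
    base_kinetics: KineticParameterSet,
    lower: float | Sequence[float] = 1e-4,
    upper: float | Sequence[float] = 1e3,
    outputs: tuple[str, ...] = ("od", "gfp"),
) -> FitProblem:
    """Convenience constructor with the default [1e-4, 1e3] rate bounds."""
    n = len(param_names)
    lo = np.full(n, lower, dtype=float) if np.isscalar(lower) else np.asarray(lower, float)
    hi = np.full(n, upper, dtype=float) if np.isscalar(upper) else np.asarray(upper, float)
    return FitProblem(
        dataset=list(dataset),
        param_names=list(param_names),
        k_lower=lo,
        k_upper=hi,
        base_growth=dict(base_growth),
        base_kinetics=base_kinetics,
        outputs=outputs,
    )


# ---------------------------------------------------------------------------
# growth fitting


def fit_growth(
    exp: ExperimentTimeCourse,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_starts: int = 20,
    seed: int = 0,
) -> tuple[GrowthParams, FitResult]:
    """Fit the double-logistic growth law to the OD replicates.

    Weighted least squares on the replicate-mean OD with multistart local
    search: starts are data-informed (asymptote near the observed maximum,
    midpoint near the half-maximum crossing) plus seeded jitter.
    """
    t = exp.times
    y = exp.od_mean
    y_range = float(y.max() - y.min())
    if y_range <= 1e-12 or y.max() <= 0:
        raise ValueError("degenerate growth curve: OD signal is flat or zero")

    # rolling-window variance stabilization (~1 h of samples): at 3
    # replicates the per-point variance estimate is too noisy to invert raw
    w = estimate_weights(exp, smooth_window=7).od
    sw = np.sqrt(w)

    default_bounds = {
        "L1": (1e-3, 10.0 * y.max()),
        "a1": (1e-2, 20.0),
        "t1": (1e-2, 2.0 * float(t.max())),
        "k1": (0.0, 2.0 * y.max()),
        "k2": (0.5, 5.0),
    }
    if bounds:
        default_bounds.update(bounds)
    names = ("L1", "a1", "t1", "k1", "k2")
    lo = np.array([default_bounds[n][0] for n in names])
    hi = np.array([default_bounds[n][1] for n in names])

    # weak shrinkage on the second-wave gain: when k2 pushes the second
    # midpoint outside the assay window the wave is unidentifiable, and the
    # penalty collapses it to the nested single-logistic model
    lam = np.sqrt(1e-4 * float(np.median(w)))

    def resid(theta: np.ndarray) -> np.ndarray:
        gp = GrowthParams(*np.maximum(theta, [1e-9, 1e-9, 1e-9, 0.0, 1e-9]))
        return np.append(sw * (y - double_logistic(t, gp)), lam * theta[3])

    # data-informed anchor start
    half = y.min() + 0.5 * y_range
    t_half = float(t[np.argmax(y >= half)])
    anchor = np.array([y.max(), 1.0, max(t_half, 0.1), 0.05 * y.max(), 1.5])
    anchor = np.clip(anchor, lo + 1e-9, hi - 1e-9)

    rand = np.random.default_rng(seed)
    starts = [anchor]
    for _ in range(max(n_starts - 1, 0)):
        jitter = anchor * np.exp(rand.normal(0.0, 0.4, size=5))
        starts.append(np.clip(jitter, lo + 1e-9, hi - 1e-9))

    best = None
    n_evals = 0
    for x0 in starts:
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), method="trf")
        except Exception:  # noqa: BLE001 - a bad start must not kill the fit
            continue
        n_evals += sol.nfev
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("growth fit failed from every start")

    gp = GrowthParams(*best.x)
    result = FitResult(
        k_hat=best.x.copy(),
        cost=float(2.0 * best.cost),  # scipy reports 0.5 * sum r^2
        converged=bool(best.status > 0),
        n_evals=n_evals,
        param_names=names,
    )
    return gp, result


# ---------------------------------------------------------------------------
# global calibration


def calibrate(
    problem: FitProblem,
    seed: int = 0,
    budget: int = 4000,
    x0: np.ndarray | None = None,
    local_only: bool = False,
    popsize: int = 12,
) -> FitResult:
    """Global-then-local hybrid estimation of the parameter vector k.

    A population global stage (differential evolution on the log10 box)
    spends roughly the given budget of objective evaluations, then a
    trust-region least-squares polish refines the incumbent. With
    ``local_only`` (or an ``x0`` warm start and ``local_only=True``) the
    global stage is skipped — the mode used for bagging refits.
    Deterministic for a fixed seed.
    """
    lo, hi = problem.k_lower, problem.k_upper
    if np.allclose(lo, hi):
        k = lo.copy()
        return FitResult(
            k_hat=k, cost=weighted_cost(k, problem), converged=True, n_evals=1,
            param_names=tuple(problem.param_names),
        )

    if problem.log_scale:
        tlo, thi = np.log10(np.maximum(lo, 1e-300)), np.log10(hi)
        to_nat = lambda z: 10.0**np.asarray(z, dtype=float)
        to_opt = lambda k: np.log10(np.clip(k, np.maximum(lo, 1e-300), hi))
    else:
        tlo, thi = lo, hi
        to_nat = lambda z: np.asarray(z, dtype=float)
        to_opt = lambda k: np.asarray(k, dtype=float)

    n_evals = 0

    def obj(z: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        return weighted_cost(np.clip(to_nat(z), lo, hi), problem)

    incumbent = None
    if x0 is not None:
        incumbent = to_opt(np.asarray(x0, dtype=float))

    if not local_only:
        n_par = len(problem.param_names)
        maxiter = max(int(budget / max(popsize * n_par, 1)) - 1, 3)
        init = "latinhypercube"
        de = differential_evolution(
            obj,
            bounds=list(zip(tlo, thi)),
            seed=seed,
            maxiter=maxiter,
            popsize=popsize,
            tol=1e-8,
            polish=False,
            init=init,
            x0=incumbent,
        )
        incumbent = de.x
    elif incumbent is None:
        raise ValueError("local_only calibration requires a warm start x0")

    m = len(problem.outputs) * sum(len(exp.times) for exp in problem.dataset)

    def polish_resid(z: np.ndarray) -> np.ndarray:
        nonlocal n_evals
        n_evals += 1
        try:
            return problem.residuals(np.clip(to_nat(z), lo, hi))
        except RuntimeError:
            return np.full(m, 1e75)

    sol = least_squares(
        polish_resid, np.clip(incumbent, tlo, thi), bounds=(tlo, thi),
        method="trf", max_nfev=max(budget // 4, 50),
    )
    k_hat = np.clip(to_nat(sol.x), lo, hi)
    cost = weighted_cost(k_hat, problem)
    if not np.isfinite(cost):
        raise RuntimeError("calibration exhausted its budget without a finite-cost evaluation")
    return FitResult(
        k_hat=k_hat, cost=cost, converged=bool(sol.status > 0), n_evals=n_evals,
        param_names=tuple(problem.param_names),
    )


# ---------------------------------------------------------------------------
# bootstrap and bagging


def bootstrap_resample(exp: ExperimentTimeCourse, seed: int = 0) -> ExperimentTimeCourse:
    """Resample replicate values per time point, uniformly with replacement.

    The rebuilt dataset has the same shape as the original. OD and GFP/OD
    at a given time point and replicate slot are drawn from the same source
    replicate: the two outputs are co-measured in one well, so resampling
    keeps them paired.
    """
    if exp.n_replicates < 2:
        raise ValueError("bootstrap requires at least two replicates")
    rand = np.random.default_rng(seed)
    n_rep, n_t = exp.od_replicates.shape
    idx = rand.integers(0, n_rep, size=(n_rep, n_t))
    cols = np.arange(n_t)
    return ExperimentTimeCourse(
        context=exp.context,
        times=exp.times,
        od_replicates=exp.od_replicates[idx, cols],
        gfp_replicates=exp.gfp_replicates[idx, cols],
    )


def bagging_ensemble(
    problem: FitProblem,
    n_iterations: int = 300,
    seed: int = 0,
    budget: int = 4000,
    member_budget: int = 400,
    max_failure_fraction: float = 0.2,
) -> EnsembleFit:
    """Bootstrap-aggregated calibration.

    The full dataset is calibrated once (global + local); each bagging
    iteration then resamples every experiment's replicates, re-estimates the
    heteroscedastic weights, and refits locally from the full-data optimum.
    Failed members are dropped with a log entry; more than
    ``max_failure_fraction`` failures aborts the ensemble.
    """
    base = calibrate(problem, seed=seed, budget=budget)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_iterations)

    members: list[FitResult] = []
    failures = 0
    for child in children:
        child_seed = int(child.generate_state(1)[0] % (2**31))
        try:
            resampled = [
                bootstrap_resample(exp, seed=child_seed + j)
                for j, exp in enumerate(problem.dataset)
            ]
            sub = copy.copy(problem)
            sub.dataset = resampled
            sub.weights = [estimate_weights(exp) for exp in resampled]
            member = calibrate(
                sub, seed=child_seed, x0=base.k_hat, local_only=True, budget=member_budget
            )
            members.append(member)
        except (RuntimeError, ValueError) as err:
            failures += 1
            logger.warning("bagging member failed (seed %d): %s", child_seed, err)

    if failures > max_failure_fraction * n_iterations:
        raise RuntimeError(
            f"{failures}/{n_iterations} bagging members failed "
            f"(limit {max_failure_fraction:.0%})"
        )
    return EnsembleFit(members=members, n_iterations=n_iterations)
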