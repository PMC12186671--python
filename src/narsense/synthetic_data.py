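"""Synthetic ground truth and plate-reader-style time courses.

No public dataset accompanies the biosensor study design this package
implements, so every downstream stage (calibration, surrogates, selection)
is exercised on synthetic data with the same structure: replicated 16-h,
10-min-sampled OD and GFP/OD curves over the categorical factor space,
generated from a ground-truth parameter set whose variability scopes match
the mechanistic model (global / medium / promoter / context).

Context-scoped quantities (growth L1, a1, t1 and the RBS translation
strength) are built multiplicatively from factor-level effects plus a small
log-normal jitter. Systematic factor effects are what make context
dependence learnable at all — the premise of the modeling strategy — while
the jitter keeps every one of the 320 context values distinct.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import ExperimentTimeCourse
from .context import ContextKey, FactorSpace, default_factor_space
from .experimental_design import Design
from .model_core import GrowthParams, KineticParameterSet, default_grid, simulate

__all__ = [
    "GroundTruth",
    "NoiseSpec",
    "draw_ground_truth",
    "generate_experiment",
    "generate_library",
    "synthetic_ensemble_matrix",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Heteroscedastic measurement noise: y*(1+eps_p) + eps_a, clipped at 0.

    proportional_sd is the sd of eps_p (fraction of the signal); additive_sd
    scales eps_a by the signal range of the noiseless curve.
    """

    proportional_sd: float = 0.05
    additive_sd: float = 0.01
    replicates: int = 3

    def __post_init__(self) -> None:
        if self.proportional_sd < 0 or self.additive_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.replicates < 1:
            raise ValueError("at least one replicate is required")


@dataclass(frozen=True)
class GroundTruth:
    """True parameters behind a synthetic study, reproducible from seed."""

    space: FactorSpace
    growth: dict[ContextKey, GrowthParams]
    kinetics: KineticParameterSet
    seed: int


def _level_effects(levels, sd: float, rand) -> dict[str, float]:
    return {lvl: float(e) for lvl, e in zip(levels, rand.normal(0.0, sd, size=len(levels)))}


def _loguniform(rand, lo: float, hi: float, size=None):
    return np.exp(rand.uniform(np.log(lo), np.log(hi), size=size))


def draw_ground_truth(space: FactorSpace | None = None, seed: int = 0) -> GroundTruth:
    """Draw a scoped ground-truth parameter set.

    Scope structure: k1, k2 and all catalytic constants marked global are
    shared everywhere; K_Pk varies only with the promoter; mRNA production /
    degradation, protein production and proteolysis vary only with the
    medium (contexts sharing a medium share those values exactly); RBS
    strength and the growth triplet (L1, a1, t1) vary with the full context.

    Default ranges are chosen so that OD curves are sigmoids saturating
    within the 16-h horizon starting near 0.05 and the reporter rises over
    several hours — the qualitative regime of the plate-reader assays the
    generator emulates.
    """
    space = default_factor_space() if space is None else space
    rand = np.random.default_rng(seed)

    media = space.levels("medium")
    supplements = space.levels("supplement")
    promoters = space.levels("promoter")
    rbs_sites = space.levels("rbs")

    # --- growth: multiplicative factor effects on (L1, a1, t1), shared k1/k2
    k1 = float(rand.uniform(0.02, 0.15))
    k2 = float(rand.uniform(1.2, 2.0))
    base_L1 = float(_loguniform(rand, 0.7, 1.2))
    base_a1 = float(_loguniform(rand, 0.6, 1.1))
    base_t1 = float(rand.uniform(5.0, 7.0))
    eff = {}
    for pname, levels, sd in (
        ("medium", media, 0.15),
        ("supplement", supplements, 0.10),
        ("promoter", promoters, 0.05),
        ("rbs", rbs_sites, 0.05),
    ):
        eff[pname] = {
            "L1": _level_effects(levels, sd, rand),
            "a1": _level_effects(levels, sd, rand),
            "t1": _level_effects(levels, 0.6 * sd, rand),
        }

    growth: dict[ContextKey, GrowthParams] = {}
    contexts = space.all_contexts()
    jitter = rand.normal(0.0, 0.02, size=(len(contexts), 3))
    for i, ctx in enumerate(contexts):
        def total(param: str) -> float:
            return (
                eff["medium"][param][ctx.medium]
                + eff["supplement"][param][ctx.supplement]
                + eff["promoter"][param][ctx.promoter]
                + eff["rbs"][param][ctx.rbs]
            )

        growth[ctx] = GrowthParams(
            L1=base_L1 * float(np.exp(total("L1") + jitter[i, 0])),
            a1=base_a1 * float(np.exp(total("a1") + jitter[i, 1])),
            t1=base_t1 * float(np.exp(total("t1") + jitter[i, 2])),
            k1=k1,
            k2=k2,
        )

    # --- kinetics
    K_Pk = {p: float(v) for p, v in zip(promoters, _loguniform(rand, 0.3, 3.0, len(promoters)))}
    K_mRNAp = {m: float(v) for m, v in zip(media, _loguniform(rand, 0.5, 2.0, len(media)))}
    # reference medium M-first carries multiplier 1 by convention
    K_mRNAdeg = {m: float(v) for m, v in zip(media, _loguniform(rand, 0.6, 1.8, len(media)))}
    K_mRNAdeg[media[0]] = 1.0
    K_P = {m: float(v) for m, v in zip(media, _loguniform(rand, 0.5, 2.0, len(media)))}
    K_lysis = {m: float(v) for m, v in zip(media, _loguniform(rand, 0.5, 1.5, len(media)))}

    rbs_base = {r: float(v) for r, v in zip(rbs_sites, _loguniform(rand, 0.3, 2.5, len(rbs_sites)))}
    gamma = {
        "promoter": _level_effects(promoters, 0.10, rand),
        "medium": _level_effects(media, 0.15, rand),
        "supplement": _level_effects(supplements, 0.10, rand),
    }
    rbs_jitter = rand.normal(0.0, 0.05, size=len(contexts))
    RBS_strength = {
        ctx.context_id: rbs_base[ctx.rbs]
        * float(
            np.exp(
                gamma["promoter"][ctx.promoter]
                + gamma["medium"][ctx.medium]
                + gamma["supplement"][ctx.supplement]
                + rbs_jitter[i]
            )
        )
        for i, ctx in enumerate(contexts)
    }

    kinetics = KineticParameterSet(
        vmax_PROM=float(_loguniform(rand, 0.5, 1.5)),
        K_Pk=K_Pk,
        K_mRNAp=K_mRNAp,
        k_deg=float(_loguniform(rand, 0.8, 1.5)),
        K_mRNAdeg=K_mRNAdeg,
        K_P=K_P,
        K_lysis=K_lysis,
        RBS_strength=RBS_strength,
        k_FDER=float(_loguniform(rand, 0.8, 2.0)),
        K_NFDER=float(_loguniform(rand, 0.2, 0.8)),
        k_deg_FDER=float(_loguniform(rand, 0.1, 0.4)),
        vmax_NAR=float(_loguniform(rand, 1.5, 4.0)),
        k_deg_GFP=float(_loguniform(rand, 0.05, 0.2)),
        R_basal=float(rand.uniform(0.3, 0.7)),
    )
    return GroundTruth(space=space, growth=growth, kinetics=kinetics, seed=seed)


def generate_experiment(
    ctx: ContextKey,
    gt: GroundTruth,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> ExperimentTimeCourse:
    """Simulate one context and overlay replicated heteroscedastic noise."""
    noise = NoiseSpec() if noise is None else noise
    grid = default_grid() if grid is None else grid
    traj = simulate(ctx, gt.growth[ctx], gt.kinetics, grid=grid)
    rand = np.random.default_rng(seed)

    def noisy(signal: np.ndarray) -> np.ndarray:
        rng_range = float(np.max(signal) - np.min(signal))
        reps = np.empty((noise.replicates, len(signal)))
        for r in range(noise.replicates):
            eps_p = rand.normal(0.0, noise.proportional_sd, size=len(signal))
            eps_a = rand.normal(0.0, noise.additive_sd * rng_range, size=len(signal))
            reps[r] = signal * (1.0 + eps_p) + eps_a
        return np.clip(reps, 0.0, None)

    return ExperimentTimeCourse(
        context=ctx,
        times=np.asarray(grid, dtype=float),
        od_replicates=noisy(traj.od),
        gfp_replicates=noisy(traj.gfp_per_od),
    )


def generate_library(
    design: Design,
    gt: GroundTruth,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> list[ExperimentTimeCourse]:
    """One experiment per design run; child seeds derived from the master."""
    children = np.random.SeedSequence(seed).spawn(len(design.runs))
    return [
        generate_experiment(ctx, gt, noise=noise, seed=int(child.generate_state(1)[0] % (2**31)), grid=grid)
        for ctx, child in zip(design.runs, children)
    ]


def synthetic_ensemble_matrix(
    contexts,
    gt: GroundTruth,
    n_members: int = 25,
    member_sd: float = 0.05,
    seed: int = 0,
):
    """Emulated bagged-calibration ensemble for surrogate training.

    For each context the true context-scoped reporter parameters are
    resolved and perturbed by independent log-normal member noise (sd on
    the log scale), mimicking the spread of a bootstrap-bagged parameter
    ensemble without paying for the refits. Long-format frame: one row per
    (context, member), a ``context_id`` column plus one column per
    parameter.
    """
    import pandas as pd

    rand = np.random.default_rng(seed)
    param_fields = ("K_Pk", "K_mRNAp", "K_mRNAdeg", "K_P", "K_lysis", "RBS_strength")
    rows = []
    for ctx in contexts:
        rk = gt.kinetics.resolve(ctx)
        truth = np.array([getattr(rk, f) for f in param_fields])
        noise = rand.normal(0.0, member_sd, size=(n_members, len(param_fields)))
        values = truth[None, :] * np.exp(noise)
        for member in values:
            rows.append({"context_id": ctx.context_id,
                         **{f: float(v) for f, v in zip(param_fields, member)}})
    return pd.DataFrame(rows)
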