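"""Stage orchestration: reproducible runs of the full biosensor pipeline.

Each stage reads the previous stage's artifacts from the run directory,
writes its own versioned outputs, and records a manifest with the seeds and
a hash of the configuration, so two runs from one config are numerically
identical. Stages: doe -> generate -> fit -> bag -> train -> predict ->
rank, plus a standalone validate stage that scores a ranked table (by
default the shipped reference ranking) with the top-k overlap and the
one-tailed Kendall test.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .calibration import bagging_ensemble, fit_growth, make_fit_problem
from .context import ContextKey, default_factor_space
from .experimental_design import Design, augment, d_optimal
from .model_core import GrowthParams, default_grid
from .nnet import MLPConfig
from .selection import kendall_one_tailed, top_k_overlap
from .surrogate import (
    ContextEncoder,
    GrowthPredictor,
    cv_report,
    optimize_promoter_encoding,
    predict_response,
    train_growth_surrogate,
    train_reporter_surrogate,
)
from .synthetic_data import NoiseSpec, draw_ground_truth, generate_library

logger = logging.getLogger(__name__)

STAGES = ("doe", "generate", "fit", "bag", "train", "predict", "rank", "validate")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, with explicit seeds throughout.

    The default profile mirrors the two-round study layout: a 32-run
    D-optimal design augmented by 32 more, 48 training contexts with 16 for
    validation, 8 of 64 held out for the network, and 300 bagging
    iterations. The ``desk`` profile scales bagging down to 50 iterations
    and trims optimizer budgets for interactive work.
    """

    outdir: str = "runs/default"
    seed: int = 0
    profile: str = "full"
    n_runs_initial: int = 32
    n_augment: int = 32
    train_size: int = 48
    validation_size: int = 16
    nn_validation_size: int = 8
    bagging_iterations: int = 300
    optimizer_budget: int = 4000
    doe_restarts: int = 10
    promoter_budget: int = 30
    noise_proportional_sd: float = 0.05
    noise_additive_sd: float = 0.01
    replicates: int = 3
    rank_criterion: str = "gain"
    top_k: int = 10

    def __post_init__(self) -> None:
        if self.profile == "desk":
            self.bagging_iterations = min(self.bagging_iterations, 50)
            self.optimizer_budget = min(self.optimizer_budget, 1500)
        if self.train_size + self.validation_size > self.n_runs_initial + self.n_augment:
            raise ValueError("train/validation split exceeds the designed experiment count")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def noise(self) -> NoiseSpec:
        return NoiseSpec(
            proportional_sd=self.noise_proportional_sd,
            additive_sd=self.noise_additive_sd,
            replicates=self.replicates,
        )


def _outdir(config: RunConfig) -> Path:
    p = Path(config.outdir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _write_manifest(stage: str, config: RunConfig, outputs: list[str]) -> Path:
    path = _outdir(config) / f"manifest_{stage}.json"
    path.write_text(json.dumps({
        "stage": stage,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "outputs": sorted(outputs),
    }, indent=2, sort_keys=True))
    return path


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream artifact {path}; run the '{producer}' stage first"
        )
    return path


def run_stage(name: str, config: RunConfig) -> Path:
    """Execute one pipeline stage; returns the manifest path."""
    if name not in STAGES:
        raise ValueError(f"unknown stage {name!r}; expected one of {STAGES}")
    out = _outdir(config)
    space = default_factor_space()
    outputs: list[str] = []

    if name == "doe":
        design = d_optimal(space, n_runs=config.n_runs_initial, seed=config.seed,
                           n_restarts=config.doe_restarts)
        combined = augment(design, space, n_additional=config.n_augment,
                           seed=config.seed + 1, n_restarts=config.doe_restarts)
        nio.write_design_csv(design, out / "design_round1.csv")
        nio.write_design_csv(combined, out / "design_combined.csv")
        nio.write_params_json(
            {"round1_log_det": design.log_det, "combined_log_det": combined.log_det},
            out / "doe_report.json",
        )
        outputs = ["design_round1.csv", "design_combined.csv", "doe_report.json"]

    elif name == "generate":
        design = nio.read_design_csv(_require(out / "design_combined.csv", "doe"))
        gt = draw_ground_truth(space, seed=config.seed)
        library = generate_library(design, gt, noise=config.noise(), seed=config.seed + 10)
        nio.write_experiments_csv(library, out / "experiments.csv")
        truth = {
            "growth": {c.context_id: dataclasses.asdict(g) for c, g in gt.growth.items()},
            "kinetics": _kinetics_dict(gt.kinetics),
        }
        nio.write_params_json(truth, out / "ground_truth.json")
        outputs = ["experiments.csv", "ground_truth.json"]

    elif name == "fit":
        experiments = nio.read_experiments_csv(_require(out / "experiments.csv", "generate"))
        rows = []
        for i, exp in enumerate(experiments):
            gp, res = fit_growth(exp, seed=config.seed + i)
            rows.append({"context_id": exp.context.context_id, **dataclasses.asdict(gp),
                         "cost": res.cost})
        pd.DataFrame(rows).to_csv(out / "growth_fits.csv", index=False)
        outputs = ["growth_fits.csv"]

    elif name == "bag":
        experiments = nio.read_experiments_csv(_require(out / "experiments.csv", "generate"))
        fits = pd.read_csv(_require(out / "growth_fits.csv", "fit")).set_index("context_id")
        frames = []
        for i, exp in enumerate(experiments):
            cid = exp.context.context_id
            gp = GrowthParams(**{k: float(fits.loc[cid, k]) for k in ("L1", "a1", "t1", "k1", "k2")})
            names, problem = _single_context_problem(exp, gp)
            ensemble = bagging_ensemble(
                problem, n_iterations=config.bagging_iterations,
                seed=config.seed + 100 + i, budget=config.optimizer_budget,
            )
            frame = nio.ensemble_to_frame(ensemble)
            frame.insert(0, "context_id", cid)
            frames.append(frame)
        pd.concat(frames, ignore_index=True).to_csv(out / "ensemble_matrix.csv", index=False)
        outputs = ["ensemble_matrix.csv"]

    elif name == "train":
        outputs = _train_stage(config, out)

    elif name == "predict":
        outputs = _predict_stage(config, out, space)

    elif name == "rank":
        preds = pd.read_csv(_require(out / "predictions.csv", "predict"))
        ascending = config.rank_criterion == "half_time"
        preds = preds.sort_values(
            ["predicted", "context_id"], ascending=[ascending, True]
        ).reset_index(drop=True)
        if "observed" in preds.columns:
            preds["observed_rank"] = (
                preds["observed"].rank(method="min", ascending=ascending).astype(int)
            )
        table = preds.head(config.top_k).copy()
        parts = table["context_id"].str.split("-", expand=True)
        table[["medium", "supplement", "promoter", "rbs"]] = parts
        table.to_csv(out / "ranked_table.csv", index=False)
        outputs = ["ranked_table.csv"]

    elif name == "validate":
        path = out / "ranked_table.csv"
        if path.exists():
            table = pd.read_csv(path)
        else:
            ref = nio.load_reference_ranking(
                "high_gain" if config.rank_criterion == "gain" else "fast_response"
            )
            table = ref.rename(columns={
                "predicted_value": "predicted", "observed_value": "observed",
            })
        overlap = top_k_overlap(table, k=config.top_k)
        # agreement direction is the same for gain and half-time: a good
        # predictor correlates positively with the observation either way
        if len(table) >= 3:
            tau, p = kendall_one_tailed(table["predicted"], table["observed"])
        else:
            tau = p = None  # rank test undefined below three rows
        nio.write_params_json(
            {"top_k": config.top_k, "overlap": overlap, "kendall_tau": tau,
             "kendall_p_one_tailed": p},
            out / "validation_report.json",
        )
        outputs = ["validation_report.json"]

    return _write_manifest(name, config, outputs)


def _kinetics_dict(kp) -> dict:
    d = dataclasses.asdict(kp)
    return {k: (dict(v) if hasattr(v, "items") else v) for k, v in d.items()}


def _single_context_problem(exp, gp):
    """Reduced, identifiable per-context estimation problem.

    For a single context only products of parameters enter the dynamics, so
    the estimated vector holds one representative factor per product:
    transcription via K_mRNAp, translation via RBS_strength, regulator
    turnover via k_deg_FDER, reporter production via vmax_NAR and reporter
    turnover via k_deg_GFP; K_NFDER sets the translation saturation scale.
    """
    cid = exp.context.context_id
    names = [
        f"K_mRNAp[{exp.context.medium}]",
        f"RBS_strength[{cid}]",
        "k_deg_FDER",
        "vmax_NAR",
        "k_deg_GFP",
        "K_NFDER",
    ]
    from .model_core import KineticParameterSet  # local import avoids cycle at module load

    base = KineticParameterSet()
    problem = make_fit_problem(
        [exp], names, {exp.context: gp}, base,
        lower=1e-4, upper=1e3, outputs=("od", "gfp"),
    )
    return names, problem


def _train_stage(config: RunConfig, out: Path) -> list[str]:
    fits = pd.read_csv(_require(out / "growth_fits.csv", "fit"))
    ensemble = pd.read_csv(_require(out / "ensemble_matrix.csv", "bag"))

    rng = np.random.default_rng(config.seed + 7)
    ids = fits["context_id"].tolist()
    order = rng.permutation(len(ids))
    # splits cap at what the run actually produced (small desk runs)
    n_train = min(config.train_size, len(ids))
    train_ids = [ids[i] for i in order[:n_train]]
    val_ids = [ids[i] for i in order[n_train: n_train + config.validation_size]]

    contexts = [ContextKey.from_id(i) for i in train_ids]
    targets = fits.set_index("context_id").loc[train_ids, ["a1", "t1"]]
    pe = optimize_promoter_encoding(contexts, targets, seed=config.seed,
                                    budget=config.promoter_budget)
    encoder = ContextEncoder(pe)
    x = encoder.fit_transform(contexts)
    models, growth_report = train_growth_surrogate(x, targets, seed=config.seed)
    defaults = {
        "L1": float(fits["L1"].mean()), "k1": float(fits["k1"].mean()),
        "k2": float(fits["k2"].mean()),
    }

    bag_ids = ensemble["context_id"].unique()
    nn_val_n = min(config.nn_validation_size, max(0, len(bag_ids) - 2))
    nn_val = bag_ids[:nn_val_n].tolist()
    from .model_core import KineticParameterSet

    # the reporter model gets its own promoter values, optimized against the
    # training ensembles' consensus promoter-scoped strength
    reporter_pe = pe
    if "K_Pk" in ensemble.columns:
        train_rows = ensemble[~ensemble["context_id"].isin(nn_val)]
        consensus = train_rows.groupby("context_id")[["K_Pk"]].mean()
        reporter_pe = optimize_promoter_encoding(
            [ContextKey.from_id(i) for i in consensus.index],
            np.log(consensus), seed=config.seed + 1, budget=config.promoter_budget,
        )
    reporter = train_reporter_surrogate(
        ensemble, ContextEncoder(reporter_pe), KineticParameterSet(), seed=config.seed,
        validation_contexts=nn_val,
        config=MLPConfig(dropout=0.05, epochs=1200, lr=2e-3),
        target_names=tuple(c for c in ensemble.columns if c != "context_id"),
    )
    bundle = {
        "promoter_encoding": pe.values,
        "growth_defaults": defaults,
        "growth_loo_r2": growth_report.r2_per_target,
        "growth_q2": growth_report.q2,
        "reporter_q2": None if reporter.report is None else reporter.report.q2,
        "train_ids": train_ids,
        "validation_ids": val_ids,
    }
    nio.write_params_json(bundle, out / "surrogate_report.json")

    # persist predictors for the predict stage via in-process registry file
    import pickle  # noqa: PLC0415 - model bundle is a run-local scratch artifact

    predictor = GrowthPredictor(encoder=encoder, models=models, defaults=defaults,
                                report=growth_report)
    with open(out / "surrogate_bundle.pkl", "wb") as fh:
        pickle.dump({"growth": predictor, "reporter": reporter}, fh)
    return ["surrogate_report.json", "surrogate_bundle.pkl"]


def _predict_stage(config: RunConfig, out: Path, space) -> list[str]:
    import pickle

    with open(_require(out / "surrogate_bundle.pkl", "train"), "rb") as fh:
        bundle = pickle.load(fh)
    report = nio.read_params_json(_require(out / "surrogate_report.json", "train"))
    experiments = nio.read_experiments_csv(_require(out / "experiments.csv", "generate"))
    from .model_core import Trajectory, half_time as ht, steady_state_gain

    def criterion_of(times, signal) -> float:
        traj = Trajectory(times=times, od=np.ones_like(signal), mrna=signal,
                          fder=signal, gfp_per_od=signal)
        if config.rank_criterion == "gain":
            return steady_state_gain(traj)
        return ht(traj) / 1e3  # s x 10^3 convention

    observed = {
        exp.context.context_id: criterion_of(exp.times, exp.gfp_mean)
        for exp in experiments
    }

    rows = []
    for cid in report["validation_ids"]:
        ctx = ContextKey.from_id(cid)
        traj = predict_response(ctx, bundle["growth"], bundle["reporter"])
        if config.rank_criterion == "gain":
            value = steady_state_gain(traj)
        else:
            value = ht(traj) / 1e3
        rows.append({"context_id": cid, "predicted": value,
                     "observed": observed.get(cid, np.nan)})
    pd.DataFrame(rows).to_csv(out / "predictions.csv", index=False)
    return ["predictions.csv"]
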