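"""CSV/JSON interchange for time courses, designs and parameter tables."""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import EnsembleFit, ExperimentTimeCourse
from .context import ContextKey
from .experimental_design import Design

__all__ = [
    "experiments_to_frame",
    "frame_to_experiments",
    "write_experiments_csv",
    "read_experiments_csv",
    "design_to_frame",
    "frame_to_design",
    "write_design_csv",
    "read_design_csv",
    "ensemble_to_frame",
    "write_params_json",
    "read_params_json",
    "load_reference_ranking",
]

TRAJECTORY_COLUMNS = [
    "context_id", "medium", "supplement", "promoter", "rbs",
    "replicate", "time_h", "od", "gfp_per_od",
]


def experiments_to_frame(experiments: list[ExperimentTimeCourse]) -> pd.DataFrame:
    """Long-format trajectory table, one row per (replicate, time point).

    A context measured by more than one experiment (designs may repeat
    runs) keeps all series: replicate numbering continues across the
    repeats, so reading the table back yields one experiment per context
    with the pooled replicates.
    """
    records = []
    offsets: dict[str, int] = {}
    for exp in experiments:
        ctx = exp.context
        base = offsets.get(ctx.context_id, 0)
        offsets[ctx.context_id] = base + exp.n_replicates
        for r in range(exp.n_replicates):
            records.append(pd.DataFrame({
                "context_id": ctx.context_id,
                "medium": ctx.medium,
                "supplement": ctx.supplement,
                "promoter": ctx.promoter,
                "rbs": ctx.rbs,
                "replicate": base + r + 1,
                "time_h": exp.times,
                "od": exp.od_replicates[r],
                "gfp_per_od": exp.gfp_replicates[r],
            }))
    return pd.concat(records, ignore_index=True)[TRAJECTORY_COLUMNS]


def frame_to_experiments(df: pd.DataFrame) -> list[ExperimentTimeCourse]:
    out = []
    for context_id, group in df.groupby("context_id", sort=True):
        ctx = ContextKey.from_id(str(context_id))
        reps = sorted(group["replicate"].unique())
        times = np.sort(group["time_h"].unique())
        od, gfp = [], []
        for r in reps:
            sub = group[group["replicate"] == r].sort_values("time_h")
            od.append(sub["od"].to_numpy())
            gfp.append(sub["gfp_per_od"].to_numpy())
        out.append(ExperimentTimeCourse(
            context=ctx, times=times,
            od_replicates=np.vstack(od), gfp_replicates=np.vstack(gfp),
        ))
    return out


def write_experiments_csv(experiments: list[ExperimentTimeCourse], path) -> None:
    experiments_to_frame(experiments).to_csv(path, index=False)


def read_experiments_csv(path) -> list[ExperimentTimeCourse]:
    return frame_to_experiments(pd.read_csv(path))


def design_to_frame(design: Design) -> pd.DataFrame:
    return pd.DataFrame({
        "run_id": [f"E{i + 1}" for i in range(design.n_runs)],
        "promoter": [c.promoter for c in design.runs],
        "rbs": [c.rbs for c in design.runs],
        "medium": [c.medium for c in design.runs],
        "supplement": [c.supplement for c in design.runs],
    })


def frame_to_design(df: pd.DataFrame) -> Design:
    runs = [
        ContextKey(medium=row.medium, supplement=row.supplement,
                   promoter=row.promoter, rbs=row.rbs)
        for row in df.itertuples()
    ]
    return Design(runs=tuple(runs))


def write_design_csv(design: Design, path) -> None:
    design_to_frame(design).to_csv(path, index=False)


def read_design_csv(path) -> Design:
    return frame_to_design(pd.read_csv(path))


def ensemble_to_frame(ensemble: EnsembleFit) -> pd.DataFrame:
    """Rows = bagging iterations, columns = named parameters."""
    return pd.DataFrame(ensemble.parameter_matrix(), columns=list(ensemble.param_names))


def write_params_json(params: dict, path) -> None:
    Path(path).write_text(json.dumps(params, indent=2, sort_keys=True))


def read_params_json(path) -> dict:
    return json.loads(Path(path).read_text())


def load_reference_ranking(which: str = "high_gain") -> pd.DataFrame:
    """Published reference rankings shipped with the package.

    ``high_gain``: predicted vs observed relative steady-state gains (%) for
    the top-10 predicted high-gain constructs, with each construct's rank in
    the full experimental comparison set. ``fast_response``: the analogous
    table for response half-times (s x 10^3, ascending is better).
    """
    names = {"high_gain": "high_gain_top10.csv", "fast_response": "fast_response_top10.csv"}
    if which not in names:
        raise ValueError(f"unknown reference ranking {which!r}")
    with resources.files("narsense.datasets").joinpath(names[which]).open() as fh:
        return pd.read_csv(fh)
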