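"""D-optimal experimental design over categorical factors.

The response surface assumed for design purposes is a main-effects linear
model on reference-coded one-hot factors (first level of each factor is the
reference and is dropped), giving a 14-column model matrix over the
promoter/RBS/medium/supplement space: 1 + 3 + 4 + 3 + 3. D-optimality
maximizes det(X'X) — equivalently, minimizes the generalized variance of the
effect estimates. The search is a seeded coordinate-exchange over the full
factorial candidate set with restarts; augmentation runs the same exchange
on the new rows only, holding the existing runs fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .context import ContextKey, FactorSpace, default_factor_space

logger = logging.getLogger(__name__)

__all__ = ["Design", "model_matrix", "d_optimal", "augment", "log_det"]

_FIELD_BY_FACTOR = {"promoter": "promoter", "rbs": "rbs", "medium": "medium", "supplement": "supplement"}

# ridge used only inside the exchange search so it can climb out of
# singular starts; reported log-determinants never include it
_SEARCH_RIDGE = 1e-8


@dataclass(frozen=True)
class Design:
    """An ordered list of experimental runs, with its reported log-det."""

    runs: tuple[ContextKey, ...]
    log_det: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "runs", tuple(self.runs))

    @property
    def n_runs(self) -> int:
        return len(self.runs)


def _row(ctx: ContextKey, space: FactorSpace) -> np.ndarray:
    cols = [1.0]
    for fname, levels in space.factors:
        value = getattr(ctx, _FIELD_BY_FACTOR[fname])
        if value not in levels:
            raise ValueError(f"run {ctx.context_id}: unknown {fname} level {value!r}")
        cols.extend(1.0 if value == lvl else 0.0 for lvl in levels[1:])
    return np.asarray(cols)


def model_matrix(design: Design | list[ContextKey], space: FactorSpace | None = None) -> np.ndarray:
    """Intercept + reference-coded one-hot blocks, entries in {0, 1}."""
    space = default_factor_space() if space is None else space
    runs = design.runs if isinstance(design, Design) else design
    if not runs:
        raise ValueError("design has no runs")
    return np.vstack([_row(ctx, space) for ctx in runs])


def n_model_columns(space: FactorSpace) -> int:
    return 1 + sum(len(levels) - 1 for _, levels in space.factors)


def log_det(design: Design | list[ContextKey], space: FactorSpace | None = None) -> float:
    """log det(X'X) of the design's model matrix; -inf when singular."""
    x = model_matrix(design, space)
    sign, ld = np.linalg.slogdet(x.T @ x)
    return float(ld) if sign > 0 else float("-inf")


def _exchange(
    runs: list[ContextKey],
    fixed: list[ContextKey],
    candidates: list[ContextKey],
    cand_rows: np.ndarray,
    space: FactorSpace,
    max_sweeps: int = 50,
) -> list[ContextKey]:
    """Coordinate exchange on the mutable rows; greedy, until no improvement.

    Uses the matrix determinant lemma for O(p^2) swap evaluation:
    det(A - u u' + v v') = det(A) * [(1 + v'A^{-1}v)(1 - u'A^{-1}u)
    + (u'A^{-1}v)^2].
    """
    p = cand_rows.shape[1]
    rows = {ctx: cand_rows[i] for i, ctx in enumerate(candidates)}
    x_fixed = np.vstack([_row(c, space) for c in fixed]) if fixed else np.zeros((0, p))

    def xtx(current: list[ContextKey]) -> np.ndarray:
        x = np.vstack([x_fixed] + [rows[c][None, :] for c in current]) if current else x_fixed
        return x.T @ x + _SEARCH_RIDGE * np.eye(p)

    a = xtx(runs)
    a_inv = np.linalg.inv(a)

    improved = True
    sweeps = 0
    while improved and sweeps < max_sweeps:
        improved = False
        sweeps += 1
        for i in range(len(runs)):
            u = rows[runs[i]]
            au = a_inv @ u
            uau = float(u @ au)
            # gain factor for swapping u -> v, vectorized over candidates
            av = cand_rows @ a_inv  # (n_cand, p)
            vav = np.einsum("ij,ij->i", av, cand_rows)
            uav = cand_rows @ au
            gain = (1.0 + vav) * (1.0 - uau) + uav**2
            j = int(np.argmax(gain))
            if gain[j] > 1.0 + 1e-10 and candidates[j] != runs[i]:
                runs[i] = candidates[j]
                a = a - np.outer(u, u) + np.outer(cand_rows[j], cand_rows[j])
                a_inv = np.linalg.inv(a)
                improved = True
    return runs


def d_optimal(
    space: FactorSpace | None = None,
    n_runs: int = 32,
    seed: int = 0,
    n_restarts: int = 10,
    initial: list[ContextKey] | None = None,
) -> Design:
    """Seeded coordinate-exchange search for a D-optimal design.

    Best design over ``n_restarts`` random starts is returned with its
    (ridge-free) log det(X'X). An explicit ``initial`` design replaces the
    first random start — a deliberately singular start will be escaped via
    the ridge-regularized exchange.
    """
    space = default_factor_space() if space is None else space
    p = n_model_columns(space)
    if n_runs < p:
        raise ValueError(f"n_runs={n_runs} below estimability threshold ({p} model columns)")

    candidates = space.all_contexts()
    cand_rows = model_matrix(candidates, space)
    rand = np.random.default_rng(seed)

    best_runs: list[ContextKey] | None = None
    best_ld = float("-inf")
    for r in range(n_restarts):
        if r == 0 and initial is not None:
            start = list(initial)
            if len(start) != n_runs:
                raise ValueError("initial design size must equal n_runs")
        else:
            idx = rand.choice(len(candidates), size=n_runs, replace=n_runs > len(candidates))
            start = [candidates[i] for i in idx]
        runs = _exchange(start, [], candidates, cand_rows, space)
        ld = log_det(runs, space)
        if ld > best_ld:
            best_ld, best_runs = ld, list(runs)

    if best_runs is None or not np.isfinite(best_ld):
        raise RuntimeError("exchange search failed to reach a full-rank design")
    return Design(runs=tuple(best_runs), log_det=best_ld)


def augment(
    existing: Design,
    space: FactorSpace | None = None,
    n_additional: int = 32,
    seed: int = 0,
    n_restarts: int = 10,
) -> Design:
    """Add runs maximizing the combined det(X'X); existing rows are immutable.

    Information matrices only grow under augmentation, so the combined
    log-det is never below the existing design's.
    """
    space = default_factor_space() if space is None else space
    if n_additional == 0:
        return Design(runs=existing.runs, log_det=log_det(existing, space))

    candidates = space.all_contexts()
    cand_rows = model_matrix(candidates, space)
    fixed = list(existing.runs)
    rand = np.random.default_rng(seed)

    best_runs: list[ContextKey] | None = None
    best_ld = float("-inf")
    for _ in range(n_restarts):
        idx = rand.choice(len(candidates), size=n_additional, replace=True)
        new = _exchange([candidates[i] for i in idx], fixed, candidates, cand_rows, space)
        ld = log_det(fixed + new, space)
        if ld > best_ld:
            best_ld, best_runs = ld, new
    assert best_runs is not None
    return Design(runs=tuple(fixed + best_runs), log_det=best_ld)
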