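"""Backward feature elimination wrapped around the cross-validated network.

The parameter-decreasing method (PDM) starts from the full factor set,
scores it by the 3-CV fitness, then repeatedly tries deleting each
remaining factor in turn, commits the deletion that yields the highest
fitness (i.e. removes the least informative factor), and records the
trajectory down to a single factor.  The factors surviving longest are
the most informative; those removed early are redundant or irrelevant.

For a full set of N factors this costs 1 + sum_{k=2..N} k =
N(N+1)/2 network-triple evaluations, quadratic in the factor count, so
candidate scoring can run with a reduced epoch budget (``scoring_config``)
while committed steps use the full budget.

The study scanned hidden-layer sizes {1, 2, 4, 6, 8}; two modes are
provided: ``outer`` runs the full elimination once per hidden size and
returns the trajectory whose peak fitness is best (default), ``fixed``
picks the grid winner on the full factor set and eliminates once.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .ann import DEFAULT_HIDDEN_GRID, NetworkConfig
from .encoding import Cohort, EncodedMatrix, encode
from .evaluation import CVPlan, cross_validate, fitness

__all__ = ["EliminationRecord", "EliminationTrace", "run_pdm", "select_subset"]


@dataclass(frozen=True)
class EliminationRecord:
    """One step of the elimination: the surviving set at dimensionality N."""

    n_factors: int
    factor_indices: tuple[int, ...]
    removed: int | None  # factor removed to reach this set (None for full set)
    fitness: float
    mean_train: float
    mean_test: float
    n_hidden: int


@dataclass
class EliminationTrace:
    """Records for N = N_full .. 1, plus bookkeeping of the search cost."""

    records: list[EliminationRecord]
    factor_names: list[str]
    n_evaluations: int
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "N": r.n_factors,
                    "removed_factor": (
                        "" if r.removed is None else self.factor_names[r.removed]
                    ),
                    "fitness": round(r.fitness, 2),
                    "mean_train_accuracy": round(r.mean_train, 2),
                    "mean_test_accuracy": round(r.mean_test, 2),
                    "n_hidden": r.n_hidden,
                    "factors": ";".join(
                        self.factor_names[i] for i in r.factor_indices
                    ),
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        text = self.to_dataframe().to_json(orient="records")
        if path is not None:
            Path(path).write_text(text)
        return text

    @property
    def best_record(self) -> EliminationRecord:
        return max(self.records, key=lambda r: r.fitness)


def _as_matrix(data: Cohort | EncodedMatrix) -> EncodedMatrix:
    return encode(data) if isinstance(data, Cohort) else data


def _evaluate_subset(
    X: np.ndarray,
    y: np.ndarray,
    subset: Sequence[int],
    config: NetworkConfig,
    plan: CVPlan,
    eval_seed: int,
):
    cols = np.asarray(subset, dtype=int)
    cfg = replace(config, n_inputs=len(cols))
    return cross_validate(X[:, cols], y, cfg, plan, eval_seed, keep_networks=False)


def _pdm_single_hidden(
    X: np.ndarray,
    y: np.ndarray,
    config: NetworkConfig,
    plan: CVPlan,
    seed: int,
    scoring_config: NetworkConfig,
) -> tuple[list[EliminationRecord], int]:
    n_full = X.shape[1]
    current = list(range(n_full))
    n_evals = 1
    fr = _evaluate_subset(
        X, y, current, config, plan, derive_seed(seed, config.n_hidden, "full")
    )
    records = [
        EliminationRecord(
            n_factors=n_full,
            factor_indices=tuple(current),
            removed=None,
            fitness=fitness(fr),
            mean_train=fr.mean_train,
            mean_test=fr.mean_test,
            n_hidden=config.n_hidden,
        )
    ]
    while len(current) > 1:
        best_removed = None
        best_fr = None
        best_fit = -np.inf
        for cand in current:  # ascending index order; ties keep the first
            subset = [f for f in current if f != cand]
            fr = _evaluate_subset(
                X,
                y,
                subset,
                scoring_config,
                plan,
                derive_seed(seed, config.n_hidden, len(current), cand),
            )
            n_evals += 1
            f_val = fitness(fr)
            if f_val > best_fit:
                best_fit, best_removed, best_fr = f_val, cand, fr
        current = [f for f in current if f != best_removed]
        if scoring_config is not config:
            # re-score the committed subset at the full budget
            best_fr = _evaluate_subset(
                X,
                y,
                current,
                config,
                plan,
                derive_seed(seed, config.n_hidden, len(current), "commit"),
            )
            n_evals += 1
            best_fit = fitness(best_fr)
        records.append(
            EliminationRecord(
                n_factors=len(current),
                factor_indices=tuple(current),
                removed=best_removed,
                fitness=best_fit,
                mean_train=best_fr.mean_train,
                mean_test=best_fr.mean_test,
                n_hidden=config.n_hidden,
            )
        )
    return records, n_evals


def run_pdm(
    data: Cohort | EncodedMatrix,
    config: NetworkConfig,
    plan: CVPlan,
    seed: int,
    hidden_sizes: Sequence[int] | None = None,
    mode: Literal["outer", "fixed", "single"] = "single",
    scoring_config: NetworkConfig | None = None,
) -> EliminationTrace:
    """Serial backward elimination scored by the 3-CV fitness.

    ``mode="single"`` eliminates with ``config.n_hidden`` as given;
    ``mode="outer"`` repeats the elimination for every size in
    ``hidden_sizes`` (default {1,2,4,6,8}) and keeps the best-peak
    trajectory; ``mode="fixed"`` picks the grid winner at the full factor
    set, then eliminates once with it.  Per-candidate evaluation seeds
    derive from (seed, n_hidden, dimensionality, candidate), so reruns are
    bit-identical; ties between removals break to the lowest factor index.
    """
    mat = _as_matrix(data)
    if mat.X.shape[1] < 2:
        raise ValueError("need at least 2 factors to eliminate")
    base = replace(config, n_inputs=mat.X.shape[1])
    score_cfg = base if scoring_config is None else replace(
        scoring_config, n_inputs=mat.X.shape[1], n_hidden=base.n_hidden
    )
    grid = tuple(hidden_sizes) if hidden_sizes is not None else DEFAULT_HIDDEN_GRID

    if mode == "single":
        sizes = [base.n_hidden]
    elif mode == "outer":
        sizes = list(grid)
    elif mode == "fixed":
        best_h, best_f = grid[0], -np.inf
        for h in grid:
            cfg = replace(base, n_hidden=h)
            fr = _evaluate_subset(
                mat.X,
                mat.y,
                range(mat.X.shape[1]),
                cfg,
                plan,
                derive_seed(seed, h, "grid"),
            )
            if fitness(fr) > best_f:
                best_f, best_h = fitness(fr), h
        sizes = [best_h]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    best_trace: EliminationTrace | None = None
    total_evals = 0
    for h in sizes:
        cfg = replace(base, n_hidden=h)
        scfg = cfg if scoring_config is None else replace(score_cfg, n_hidden=h)
        records, n_evals = _pdm_single_hidden(mat.X, mat.y, cfg, plan, seed, scfg)
        total_evals += n_evals
        trace = EliminationTrace(
            records=records,
            factor_names=list(mat.factor_names),
            n_evaluations=n_evals,
            seed=seed,
        )
        if best_trace is None or (
            trace.best_record.fitness > best_trace.best_record.fitness
        ):
            best_trace = trace
    assert best_trace is not None
    best_trace.n_evaluations = (
        best_trace.n_evaluations if mode == "single" else total_evals
    )
    return best_trace


def select_subset(trace: EliminationTrace, tolerance: float = 2.0) -> tuple[int, ...]:
    """Plateau rule: smallest N whose fitness is within ``tolerance`` of the peak.

    The study kept factors while the fitness plateau lasted and stopped
    where it began to fall; with tolerance 0 this is the argmax-fitness
    set with the smallest N among exact ties.  The full trace remains
    available for selection by inspection.
    """
    if not trace.records:
        raise ValueError("empty trace")
    f_max = max(r.fitness for r in trace.records)
    eligible = [r for r in trace.records if r.fitness >= f_max - tolerance]
    chosen = min(eligible, key=lambda r: r.n_factors)
    return chosen.factor_indices
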