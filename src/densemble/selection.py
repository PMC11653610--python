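"""Forward stepwise construction of functional ensembles.

Starting from the best single functional (or a caller-chosen one), each
step refits the full ensemble with every remaining candidate added in
turn and keeps the candidate whose refit gives the lowest training
WTMAD-2.  The greedy criterion is deliberately WTMAD-2, not the ridge
loss the fit itself minimizes.  A brute-force oracle over all size-n
combinations validates the greedy path for small n.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from densemble.benchmark import Benchmark, EnergyTable, delta_matrix
from densemble.ensemble import EnsembleModel, FitConfig, fit
from densemble.metrics import global_constant, wtmad2

__all__ = [
    "SelectionStep",
    "SelectionTrace",
    "forward_select",
    "brute_force_select",
    "rank_by_weight",
    "execution_order",
    "individual_wtmad2",
    "save_trace",
]


@dataclass(frozen=True)
class SelectionStep:
    """One greedy addition: the functional added and the refit ensemble."""

    added: str
    model: EnsembleModel
    wtmad2_train: float
    wtmad2_full: float | None = None


@dataclass
class SelectionTrace:
    """Ordered record of a forward selection run."""

    steps: list[SelectionStep]
    start_functional: str

    @property
    def functionals(self) -> tuple[str, ...]:
        """Functionals in addition (accuracy) order."""
        return tuple(step.added for step in self.steps)

    @property
    def final_model(self) -> EnsembleModel:
        return self.steps[-1].model

    def to_dict(self) -> dict:
        return {
            "schema": "densemble/trace-v1",
            "start_functional": self.start_functional,
            "steps": [
                {
                    "added": s.added,
                    "wtmad2_train": s.wtmad2_train,
                    "wtmad2_full": s.wtmad2_full,
                    "model": s.model.to_dict(),
                }
                for s in self.steps
            ],
        }


def save_trace(trace: SelectionTrace, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(trace.to_dict(), fh, indent=1)
        fh.write("\n")


def individual_wtmad2(
    benchmark: Benchmark,
    table: EnergyTable,
    candidates: Sequence[str] | None = None,
    constant: float | None = None,
) -> dict[str, float]:
    """Raw (unfitted, unit-weight) WTMAD-2 of each candidate functional."""
    if candidates is None:
        candidates = table.functionals
    if constant is None:
        constant = global_constant(benchmark)
    dmat = delta_matrix(benchmark, table, candidates)
    out = {}
    for func in candidates:
        preds = dict(zip(dmat.index, dmat[func].astype(float)))
        out[func] = wtmad2(benchmark, preds, constant=constant).wtmad2
    return out


def _train_wtmad2(
    benchmark: Benchmark, dmat, model: EnsembleModel, constant: float
) -> float:
    return wtmad2(benchmark, model.predictions(dmat), constant=constant).wtmad2


def forward_select(
    benchmark: Benchmark,
    table: EnergyTable,
    candidates: Sequence[str] | None = None,
    config: FitConfig | None = None,
    max_n: int | None = None,
    start: str | None = None,
    full_benchmark: Benchmark | None = None,
) -> SelectionTrace:
    """Greedy forward selection of functionals by training WTMAD-2.

    Parameters
    ----------
    benchmark : Benchmark
        Training benchmark the per-step ensembles are fitted and scored on.
    candidates : sequence of functional ids
        Defaults to every column of ``table``.
    max_n : int
        Ensemble size to grow to; the trajectory is recorded all the way
        even if WTMAD-2 stops improving.
    start : str, optional
        First functional; defaults to the candidate with the smallest
        individual WTMAD-2.
    full_benchmark : Benchmark, optional
        When given (the held-out transferability protocol), each step also
        records WTMAD-2 on this benchmark, using its own global constant.

    Ties anywhere are broken lexicographically by functional id.
    """
    config = config or FitConfig()
    if candidates is None:
        candidates = list(table.functionals)
    if len(set(candidates)) != len(candidates):
        raise ValueError("duplicate candidate ids")
    if not candidates:
        raise ValueError("need at least one candidate")
    max_n = len(candidates) if max_n is None else max_n
    if not 1 <= max_n <= len(candidates):
        raise ValueError(f"max_n must be in [1, {len(candidates)}]")

    constant = global_constant(benchmark)
    dmat = delta_matrix(benchmark, table, candidates)
    full_dmat = None
    full_constant = None
    if full_benchmark is not None:
        full_dmat = delta_matrix(full_benchmark, table, candidates)
        full_constant = global_constant(full_benchmark)

    if start is None:
        scores = individual_wtmad2(benchmark, table, candidates, constant)
        start = min(sorted(scores), key=scores.get)
    elif start not in candidates:
        raise ValueError(f"start functional {start!r} not among candidates")

    chosen = [start]
    steps: list[SelectionStep] = []

    def record(added: str) -> None:
        model = fit(benchmark, table, chosen, config)
        score = _train_wtmad2(benchmark, dmat, model, constant)
        full_score = None
        if full_benchmark is not None:
            full_score = wtmad2(
                full_benchmark, model.predictions(full_dmat), constant=full_constant
            ).wtmad2
        steps.append(SelectionStep(added, model, score, full_score))

    record(start)
    remaining = sorted(set(candidates) - {start})
    while len(chosen) < max_n:
        best_func = None
        best_score = None
        for func in remaining:  # sorted: first-seen wins ties lexicographically
            model = fit(benchmark, table, chosen + [func], config)
            score = _train_wtmad2(benchmark, dmat, model, constant)
            if best_score is None or score < best_score:
                best_func, best_score = func, score
        chosen.append(best_func)
        remaining.remove(best_func)
        record(best_func)

    return SelectionTrace(steps=steps, start_functional=start)


def brute_force_select(
    benchmark: Benchmark,
    table: EnergyTable,
    candidates: Sequence[str] | None = None,
    config: FitConfig | None = None,
    n: int = 2,
    allow_large: bool = False,
) -> tuple[tuple[str, ...], float]:
    """Exhaustive search over all size-n ensembles; returns (best set, WTMAD-2).

    Combinatorial guard: n must be <= 4 unless ``allow_large=True``.  Ties
    are broken lexicographically by the sorted functional ids.
    """
    config = config or FitConfig()
    if candidates is None:
        candidates = list(table.functionals)
    if n > len(candidates):
        raise ValueError(f"n={n} exceeds candidate count {len(candidates)}")
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > 4 and not allow_large:
        raise ValueError("n > 4 is combinatorially expensive; pass allow_large=True")

    constant = global_constant(benchmark)
    dmat = delta_matrix(benchmark, table, candidates)
    best_combo = None
    best_score = None
    for combo in itertools.combinations(sorted(candidates), n):
        model = fit(benchmark, table, list(combo), config)
        score = _train_wtmad2(benchmark, dmat, model, constant)
        if best_score is None or score < best_score:
            best_combo, best_score = combo, score
    return best_combo, best_score


def rank_by_weight(model: EnsembleModel, top_k: int | None = None) -> tuple[str, ...]:
    """Functional ids sorted by descending absolute weight.

    Ties are broken lexicographically.  Returns the first ``top_k``
    entries (all, when omitted).
    """
    if top_k is None:
        top_k = len(model.functionals)
    if not 0 <= top_k <= len(model.functionals):
        raise ValueError(f"top_k must be in [0, {len(model.functionals)}]")
    order = sorted(
        model.functionals, key=lambda f: (-abs(model.weight_of(f)), f)
    )
    return tuple(order[:top_k])


def execution_order(
    trace: SelectionTrace,
    mode: str = "accuracy",
    costs: Mapping[str, float] | None = None,
) -> tuple[str, ...]:
    """Order the trace's functionals for sequential evaluation.

    ``accuracy`` returns the greedy addition order (largest metric drop
    first); ``cost`` returns the same functionals sorted by ascending
    relative cost.
    """
    funcs = trace.functionals
    if mode == "accuracy":
        return funcs
    if mode == "cost":
        if costs is None:
            raise ValueError("cost mode requires a cost mapping")
        missing = [f for f in funcs if f not in costs]
        if missing:
            raise KeyError(f"missing cost entries: {missing}")
        return tuple(sorted(funcs, key=lambda f: (costs[f], f)))
    raise ValueError(f"unknown mode {mode!r}")
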