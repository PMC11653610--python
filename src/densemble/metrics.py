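"""WTMAD-2 figure of merit and per-subset statistics.

The weighted total mean absolute deviation rescales each subset's MAD by
C / |dE|_i, where |dE|_i is the subset's mean absolute reference energy
and C a global energy constant, then averages with subset sizes:

    WTMAD-2 = sum_i N_i * (C / |dE|_i) * MAD_i / sum_i N_i

For ``dialect="gmtkn55"`` benchmarks C is pinned to 56.84 kcal/mol; for
generic benchmarks it defaults to the mean of the subset |dE|_i values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from densemble.benchmark import Benchmark

GMTKN55_CONSTANT = 56.84  # kcal/mol

__all__ = [
    "GMTKN55_CONSTANT",
    "MetricError",
    "MetricReport",
    "global_constant",
    "subset_mad",
    "wtmad2",
    "evaluate_split",
]


class MetricError(Exception):
    """Raised for inconsistent metric inputs."""


@dataclass(frozen=True)
class MetricReport:
    """WTMAD-2 with its per-subset breakdown.

    ``wtmad2`` is ``None`` when the report covers an empty restriction
    (e.g. the test partition of an all-train split); this is an explicit
    undefined marker, never silently zero.
    """

    wtmad2: float | None
    per_subset_mad: dict[str, float]
    per_subset_n: dict[str, int]
    per_subset_scale: dict[str, float]
    constant: float

    @property
    def defined(self) -> bool:
        return self.wtmad2 is not None

    def contribution(self, subset_id: str) -> float:
        """This subset's term N_i * (C/|dE|_i) * MAD_i before normalization."""
        return (
            self.per_subset_n[subset_id]
            * self.per_subset_scale[subset_id]
            * self.per_subset_mad[subset_id]
        )

    def to_dict(self) -> dict:
        return {
            "wtmad2": self.wtmad2,
            "constant": self.constant,
            "subsets": {
                sid: {
                    "n": self.per_subset_n[sid],
                    "mad": self.per_subset_mad[sid],
                    "scale": self.per_subset_scale[sid],
                }
                for sid in sorted(self.per_subset_mad)
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def global_constant(benchmark: Benchmark) -> float:
    """The global energy constant C in kcal/mol.

    The mean over subsets of |dE|_i for generic benchmarks; the fixed
    literature value for the gmtkn55 dialect.
    """
    if not benchmark.subsets:
        raise MetricError("empty benchmark has no global constant")
    if benchmark.dialect == "gmtkn55":
        return GMTKN55_CONSTANT
    return float(np.mean([s.mean_abs_ref for s in benchmark.subsets.values()]))


def subset_mad(predicted: np.ndarray, reference: np.ndarray) -> float:
    """Mean absolute deviation between two equal-length energy vectors."""
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if predicted.shape != reference.shape:
        raise MetricError(
            f"length mismatch: {predicted.shape} vs {reference.shape}"
        )
    if predicted.size == 0:
        raise MetricError("empty vectors have no MAD")
    return float(np.mean(np.abs(predicted - reference)))


def wtmad2(
    benchmark: Benchmark,
    predictions: Mapping[str, float],
    constant: float | None = None,
) -> MetricReport:
    """WTMAD-2 of a full set of per-reaction predictions.

    Parameters
    ----------
    benchmark : Benchmark
    predictions : mapping reaction id -> predicted relative energy, kcal/mol.
        Must cover every benchmark reaction.
    constant : float, optional
        Global constant C; defaults to :func:`global_constant`.
    """
    if constant is None:
        constant = global_constant(benchmark)
    mads: dict[str, float] = {}
    ns: dict[str, int] = {}
    scales: dict[str, float] = {}
    for sid, subset in benchmark.subsets.items():
        pred = []
        ref = []
        for rid in subset.reaction_ids:
            if rid not in predictions:
                raise MetricError(f"missing prediction for reaction {rid!r}")
            pred.append(predictions[rid])
            ref.append(benchmark.reactions[rid].reference_delta)
        mads[sid] = subset_mad(np.array(pred), np.array(ref))
        ns[sid] = subset.n_reactions
        scales[sid] = constant / subset.mean_abs_ref
    total_n = sum(ns.values())
    value = sum(ns[s] * scales[s] * mads[s] for s in mads) / total_n
    return MetricReport(
        wtmad2=float(value),
        per_subset_mad=mads,
        per_subset_n=ns,
        per_subset_scale=scales,
        constant=float(constant),
    )


def evaluate_split(
    benchmark: Benchmark,
    predictions: Mapping[str, float],
    train_subsets: set[str] | frozenset[str],
) -> tuple[MetricReport, MetricReport, MetricReport]:
    """WTMAD-2 on the train restriction, test restriction, and full benchmark.

    All three reports use the full benchmark's global constant, so the
    numbers are directly comparable.  An empty test partition yields a
    report with ``wtmad2=None``.
    """
    train_subsets = set(train_subsets)
    unknown = train_subsets - set(benchmark.subsets)
    if unknown:
        raise MetricError(f"unknown subset ids: {sorted(unknown)}")
    constant = global_constant(benchmark)
    full = wtmad2(benchmark, predictions, constant=constant)
    train = wtmad2(
        benchmark.restrict(train_subsets), predictions, constant=constant
    )
    test_ids = set(benchmark.subsets) - train_subsets
    if test_ids:
        test = wtmad2(
            benchmark.restrict(test_ids), predictions, constant=constant
        )
    else:
        test = MetricReport(
            wtmad2=None,
            per_subset_mad={},
            per_subset_n={},
            per_subset_scale={},
            constant=constant,
        )
    return train, test, full
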