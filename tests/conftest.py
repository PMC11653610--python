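import numpy as np
import pytest

from densemble.benchmark import Benchmark, EnergyTable, Reaction, Species
import pandas as pd


def build_benchmark(subset_refs: dict[str, list[float]], dialect: str = "generic") -> Benchmark:
    """Benchmark with one single-term reaction pair per reference value.

    Each reaction is P - M with E(M) = 0 conventionally, so a species
    potential reproducing the references always exists.
    """
    subsets = {}
    reactions = []
    species = {"M": Species(id="M")}
    for sid, refs in subset_refs.items():
        subsets[sid] = sid
        for j, ref in enumerate(refs):
            rid = f"{sid}r{j}"
            pid = f"{sid}p{j}"
            species[pid] = Species(id=pid)
            reactions.append(
                Reaction(
                    id=rid,
                    subset_id=sid,
                    terms=(("M", -1.0), (pid, 1.0)),
                    reference_delta=ref,
                )
            )
    return Benchmark(subsets, reactions, species.values(), dialect=dialect)


def table_from_deltas(benchmark: Benchmark, deltas: dict[str, list[float]]) -> EnergyTable:
    """Energy table whose reaction deltas (in reaction order) are given.

    Works for benchmarks from :func:`build_benchmark`: E(M) = 0 and each
    product species energy is set to the requested delta.
    """
    species_ids = sorted(benchmark.species)
    data = {}
    for func, vals in deltas.items():
        col = dict.fromkeys(species_ids, 0.0)
        for rid, val in zip(benchmark.reaction_order, vals):
            product = benchmark.reactions[rid].terms[1][0]
            col[product] = float(val)
        data[func] = [col[s] for s in species_ids]
    return EnergyTable(pd.DataFrame(data, index=species_ids))


@pytest.fixture
def two_subset_benchmark() -> Benchmark:
    """Hand-built fixture: N = (2, 3), |dE| = (10, 50), so C = 30."""
    return build_benchmark({"s1": [8.0, -12.0], "s2": [30.0, -50.0, 70.0]})


@pytest.fixture
def perfect_predictions(two_subset_benchmark):
    return {
        rid: two_subset_benchmark.reactions[rid].reference_delta
        for rid in two_subset_benchmark.reaction_order
    }


def oracle_delta(reaction: Reaction, energies: dict[str, float]) -> float:
    """Independent per-cell recomputation of a reaction delta."""
    return sum(c * energies[s] for s, c in reaction.terms)


def oracle_ridge(x: np.ndarray, y: np.ndarray, s: np.ndarray, alpha: float) -> np.ndarray:
    """Normal-equations ridge oracle on row-scaled data."""
    xs = s[:, None] * x
    ys = s * y
    k = xs.shape[1]
    return np.linalg.solve(xs.T @ xs + alpha * np.eye(k), xs.T @ ys)


def scaled_sse(benchmark: Benchmark, predictions: dict[str, float], constant: float) -> float:
    """Independent scaled sum-of-squares oracle."""
    total = 0.0
    for rid in benchmark.reaction_order:
        rx = benchmark.reactions[rid]
        scale = constant / benchmark.subsets[rx.subset_id].mean_abs_ref
        total += (scale * (predictions[rid] - rx.reference_delta)) ** 2
    return total
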