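"""Synthetic benchmarks, functional energy tables, and density fixtures.

Generates data with the structure the real benchmarks have — many subsets
whose mean absolute reference energies span orders of magnitude — and
per-functional energy tables with controlled systematic and random error,
so fitting, selection, and metric code can be exercised end to end with
known ground truth.

Synthetic functionals are defined at the species-energy level: a
consistent reference potential reproducing the reference relative
energies exactly is recovered first, then per-functional perturbations
are added on top.  This keeps ensemble linearity, size-consistency, and
the species-to-reaction equivalence honest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from densemble.benchmark import Benchmark, EnergyTable, Reaction, Species
from densemble.density import DensityGrid

__all__ = [
    "ErrorSpec",
    "make_benchmark",
    "make_functionals",
    "make_density_fixture",
    "make_functional_pool",
    "reference_potential",
]


@dataclass(frozen=True)
class ErrorSpec:
    """Error structure of synthetic functionals.

    Parameters
    ----------
    systematic_bias : float
        Scale (kcal/mol) of per-functional systematic species-energy
        offsets; shared across a functional's species, so it does not
        average out over reactions.
    noise_sd : float
        Standard deviation (kcal/mol) of independent species-level noise;
        reaction-level noise is of the same order (inflated by the root
        sum of squared stoichiometric coefficients).
    mixture_weights : tuple of float, optional
        Known weights w* summing to one.  When given, functionals are
        built as perturbations around an exact linear decomposition of
        the reference: sum_i w*_i dE_i = dE_ref holds exactly before
        noise, enabling parameter-recovery tests.
    correlation : float
        Fraction (0..1) of noise variance shared between functionals,
        mimicking correlated errors within functional families.
    seed : int
    """

    systematic_bias: float = 1.0
    noise_sd: float = 0.0
    mixture_weights: tuple[float, ...] | None = None
    correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.systematic_bias < 0:
            raise ValueError("systematic_bias must be >= 0")
        if not 0.0 <= self.correlation <= 1.0:
            raise ValueError("correlation must be in [0, 1]")
        if self.mixture_weights is not None:
            total = float(np.sum(self.mixture_weights))
            if abs(total - 1.0) > 1e-12:
                raise ValueError(
                    f"mixture_weights must sum to 1, got {total!r}"
                )


def make_benchmark(
    n_subsets: int,
    reactions_per_subset: int,
    scale_range: tuple[float, float] = (1.0, 300.0),
    seed: int = 0,
    dialect: str = "generic",
) -> Benchmark:
    """Generate a benchmark whose subset energy scales are log-uniform.

    Each subset gets a pool of shared reactant species plus one product
    species per reaction, so every reaction is a valid signed
    stoichiometric combination and a consistent species potential exists.
    The subset mean absolute reference energies land exactly on the drawn
    log-uniform scales, which are bounded by ``scale_range``.
    """
    low, high = scale_range
    if not (0.0 < low <= high):
        raise ValueError(f"degenerate scale_range {scale_range!r}")
    if n_subsets < 1 or reactions_per_subset < 1:
        raise ValueError("need at least one subset and one reaction per subset")

    rng = np.random.default_rng(seed)
    scales = np.exp(rng.uniform(np.log(low), np.log(high), size=n_subsets))

    subsets: dict[str, str] = {}
    reactions: list[Reaction] = []
    species: dict[str, Species] = {}
    for i in range(n_subsets):
        sid = f"S{i:02d}"
        subsets[sid] = f"synthetic subset {i}"
        pool = [f"{sid}m{k}" for k in range(3)]
        for name in pool:
            species[name] = Species(id=name)
        raw = rng.normal(0.0, 1.0, size=reactions_per_subset)
        while np.mean(np.abs(raw)) < 1e-6:  # pragma: no cover - negligible odds
            raw = rng.normal(0.0, 1.0, size=reactions_per_subset)
        refs = raw * (scales[i] / np.mean(np.abs(raw)))
        for j in range(reactions_per_subset):
            rid = f"{sid}r{j:02d}"
            n_reactants = int(rng.integers(1, 3))
            picks = rng.choice(len(pool), size=n_reactants, replace=False)
            terms = [(pool[int(p)], -float(rng.integers(1, 3))) for p in picks]
            product = f"{sid}p{j:02d}"
            species[product] = Species(id=product)
            terms.append((product, 1.0))
            reactions.append(
                Reaction(
                    id=rid,
                    subset_id=sid,
                    terms=tuple(terms),
                    reference_delta=float(refs[j]),
                )
            )
    return Benchmark(subsets, reactions, species.values(), dialect=dialect)


def reference_potential(benchmark: Benchmark) -> pd.Series:
    """Species energies whose reaction deltas reproduce the references.

    Solved by least squares on the stoichiometric incidence matrix; exact
    for benchmarks from :func:`make_benchmark` (each reaction introduces
    a fresh product species).  A warning is issued if the benchmark's
    references are not exactly representable by any species potential.
    """
    species_ids = sorted(benchmark.species)
    index = {s: i for i, s in enumerate(species_ids)}
    a = np.zeros((benchmark.n_reactions, len(species_ids)))
    for r, rid in enumerate(benchmark.reaction_order):
        for sp, coef in benchmark.reactions[rid].terms:
            a[r, index[sp]] += coef
    refs = benchmark.references()
    e0, *_ = np.linalg.lstsq(a, refs, rcond=None)
    residual = np.max(np.abs(a @ e0 - refs)) if refs.size else 0.0
    if residual > 1e-8 * max(1.0, np.max(np.abs(refs))):
        warnings.warn(
            "benchmark references are not consistent with any species "
            f"potential (max residual {residual:.3e}); synthetic functionals "
            "cannot reproduce them exactly",
            stacklevel=2,
        )
    return pd.Series(e0, index=species_ids)


def make_functionals(
    benchmark: Benchmark,
    n_functionals: int,
    spec: ErrorSpec | None = None,
) -> EnergyTable:
    """Per-functional species energies around the reference potential.

    Without mixture weights each functional is the reference potential
    plus a systematic per-functional offset field plus noise; with
    mixture weights the per-functional deviations are projected so the
    known mixture reproduces the reference exactly before noise.
    """
    spec = spec or ErrorSpec()
    if n_functionals < 1:
        raise ValueError("need at least one functional")
    if spec.mixture_weights is not None and len(spec.mixture_weights) != n_functionals:
        raise ValueError(
            f"mixture_weights length {len(spec.mixture_weights)} != "
            f"n_functionals {n_functionals}"
        )

    rng = np.random.default_rng(spec.seed)
    e0 = reference_potential(benchmark)
    n_species = len(e0)

    if spec.mixture_weights is not None:
        if spec.systematic_bias == 0.0:
            raise ValueError(
                "mixture_weights with systematic_bias=0 makes all functionals "
                "identical; the mixture is unidentifiable"
            )
        w = np.asarray(spec.mixture_weights, dtype=float)
        d = rng.normal(0.0, spec.systematic_bias, size=(n_species, n_functionals))
        deviations = d - (d @ w)[:, None]  # weighted mean removed: sum_i w_i dev_i = 0
    else:
        # Each functional gets its own error scale and its own independent
        # species-error field, so functionals differ in quality and their
        # errors are not collinear across the candidate pool.
        scales = np.abs(rng.normal(0.0, spec.systematic_bias, size=n_functionals))
        fields = rng.normal(0.0, 1.0, size=(n_species, n_functionals))
        deviations = fields * scales[None, :]

    values = e0.to_numpy()[:, None] + deviations
    if spec.noise_sd > 0:
        eps = rng.normal(0.0, spec.noise_sd, size=(n_species, n_functionals))
        if spec.correlation > 0:
            shared = rng.normal(0.0, spec.noise_sd, size=n_species)
            eps = (
                np.sqrt(spec.correlation) * shared[:, None]
                + np.sqrt(1.0 - spec.correlation) * eps
            )
        values = values + eps

    columns = [f"F{k:02d}" for k in range(n_functionals)]
    return EnergyTable(pd.DataFrame(values, index=e0.index, columns=columns))


def make_functional_pool(
    benchmark: Benchmark,
    biases: tuple[float, ...],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> EnergyTable:
    """A candidate pool of functionals with explicitly tiered quality.

    One functional per entry of ``biases``, each generated independently
    at that systematic-error scale — mimicking a pool that spans method
    classes of clearly different accuracy.  Columns are named G00, G01,
    ... in the given bias order.
    """
    frames = []
    for k, bias in enumerate(biases):
        table = make_functionals(
            benchmark,
            1,
            ErrorSpec(systematic_bias=bias, noise_sd=noise_sd, seed=seed * 1009 + k),
        )
        df = table.energies.copy()
        df.columns = [f"G{k:02d}"]
        frames.append(df)
    return EnergyTable(pd.concat(frames, axis=1))


def make_density_fixture(
    n_sources: int,
    grid_spec: dict | None = None,
    seed: int = 0,
) -> DensityGrid:
    """Analytic Gaussian-mixture densities on a shared quadrature grid.

    ``grid_spec`` keys: ``kind`` ("radial", the default, or "cartesian"),
    ``n_points``, ``r_max`` / ``extent``, and ``electrons`` (the common
    electron count every source integrates to, analytically exact and
    within quadrature tolerance numerically).  The reference density is
    an extra source named ``"reference"``.
    """
    spec = {"kind": "radial", "n_points": 200, "r_max": 12.0, "electrons": 10.0}
    spec.update(grid_spec or {})
    if n_sources < 1:
        raise ValueError("need at least one source")
    rng = np.random.default_rng(seed)

    if spec["kind"] == "radial":
        # Gauss-Legendre on [0, r_max]; spherical volume element folded
        # into the quadrature weights.
        nodes, gl_w = np.polynomial.legendre.leggauss(int(spec["n_points"]))
        r = 0.5 * spec["r_max"] * (nodes + 1.0)
        w = 0.5 * spec["r_max"] * gl_w * 4.0 * np.pi * r**2
        points = np.column_stack([r, np.zeros_like(r), np.zeros_like(r)])
    elif spec["kind"] == "cartesian":
        n = int(round(spec["n_points"] ** (1.0 / 3.0)))
        extent = spec.get("extent", spec["r_max"])
        axis = np.linspace(-extent, extent, n)
        h = axis[1] - axis[0] if n > 1 else 2.0 * extent
        xx, yy, zz = np.meshgrid(axis, axis, axis, indexing="ij")
        points = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
        w = np.full(points.shape[0], h**3)
        r = np.linalg.norm(points, axis=1)
    else:
        raise ValueError(f"unknown grid kind {spec['kind']!r}")

    n_e = float(spec["electrons"])
    values: dict[str, np.ndarray] = {}
    for name in [f"f{k}" for k in range(n_sources)] + ["reference"]:
        n_gauss = int(rng.integers(1, 4))
        fractions = rng.dirichlet(np.ones(n_gauss))
        sigmas = rng.uniform(0.6, 2.0, size=n_gauss)
        rho = np.zeros_like(r)
        for c, sigma in zip(fractions, sigmas):
            norm = (2.0 * np.pi * sigma**2) ** -1.5
            rho += n_e * c * norm * np.exp(-(r**2) / (2.0 * sigma**2))
        values[name] = rho

    return DensityGrid(
        points=points,
        quad_weights=w,
        values=values,
        reference_id="reference",
        unit="bohr",
    )
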