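"""Reaction benchmarks and per-functional energy tables.

A benchmark is a set of subsets, each holding reactions defined as signed
stoichiometric combinations of named species with a reference relative
energy in kcal/mol.  Per-functional total energies are kept in a dense
table keyed by (functional, species); ``delta_matrix`` bridges the two by
assembling the reactions-by-functionals matrix of relative energies that
all fitting and scoring downstream operates on.

All energies are kcal/mol internally.  Hartree input is converted on load
with the fixed constant ``HARTREE_TO_KCAL``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

HARTREE_TO_KCAL = 627.509474

__all__ = [
    "HARTREE_TO_KCAL",
    "BenchmarkError",
    "SchemaError",
    "DegenerateSubsetError",
    "MissingSpeciesError",
    "Species",
    "Reaction",
    "Subset",
    "Benchmark",
    "EnergyTable",
    "ForceTable",
    "load_benchmark",
    "save_benchmark",
    "load_energy_table",
    "save_energy_table",
    "reaction_delta",
    "delta_matrix",
]


class BenchmarkError(Exception):
    """Base class for benchmark data errors."""


class SchemaError(BenchmarkError):
    """Input file does not conform to the benchmark schema."""


class DegenerateSubsetError(BenchmarkError):
    """A subset has zero mean absolute reference energy."""


class MissingSpeciesError(BenchmarkError, KeyError):
    """A reaction references a species with no energy entry."""


@dataclass(frozen=True)
class Species:
    """A chemical system appearing in reactions.

    Parameters
    ----------
    id : str
        Unique label within a benchmark.
    xyz : str, optional
        Inline XYZ block for the geometry (pass-through only).
    charge : int, optional
    multiplicity : int, optional
        Spin multiplicity, >= 1 when given.
    """

    id: str
    xyz: str | None = None
    charge: int | None = None
    multiplicity: int | None = None

    def __post_init__(self) -> None:
        if self.multiplicity is not None and self.multiplicity < 1:
            raise SchemaError(f"species {self.id!r}: multiplicity must be >= 1")


@dataclass(frozen=True)
class Reaction:
    """A signed stoichiometric combination of species with a reference energy.

    Coefficient < 0 marks a reactant, > 0 a product; ``reference_delta``
    (kcal/mol) follows the same products-minus-reactants orientation.
    A reaction whose coefficients are all of one sign must be flagged
    ``absolute=True`` (an absolute-energy entry such as an atomization
    reference written one-sidedly).
    """

    id: str
    subset_id: str
    terms: tuple[tuple[str, float], ...]
    reference_delta: float
    absolute: bool = False

    def __post_init__(self) -> None:
        if not self.terms:
            raise SchemaError(f"reaction {self.id!r}: empty term list")
        coefs = [c for _, c in self.terms]
        if not self.absolute:
            if not (any(c < 0 for c in coefs) and any(c > 0 for c in coefs)):
                raise SchemaError(
                    f"reaction {self.id!r}: needs both reactants and products "
                    "(or set absolute=True)"
                )

    @property
    def species_ids(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.terms)


@dataclass(frozen=True)
class Subset:
    """A named group of reactions sharing an energy scale.

    ``n_reactions`` and ``mean_abs_ref`` are derived by the parent
    :class:`Benchmark` and enter the WTMAD-2 weighting.
    """

    id: str
    name: str
    reaction_ids: tuple[str, ...]
    n_reactions: int
    mean_abs_ref: float


class Benchmark:
    """A validated collection of subsets, reactions, and species.

    Reactions are kept in a deterministic order — lexicographic by
    (subset id, reaction id) — so design matrices are reproducible.
    """

    def __init__(
        self,
        subsets: Mapping[str, str] | Sequence[tuple[str, str]],
        reactions: Iterable[Reaction],
        species: Iterable[Species],
        dialect: str = "generic",
    ) -> None:
        if dialect not in ("generic", "gmtkn55"):
            raise SchemaError(f"unknown dialect {dialect!r}")
        self.dialect = dialect

        self.species: dict[str, Species] = {}
        for sp in species:
            if sp.id in self.species:
                raise SchemaError(f"duplicate species id {sp.id!r}")
            self.species[sp.id] = sp

        subset_names = dict(subsets)
        reactions = sorted(reactions, key=lambda r: (r.subset_id, r.id))
        self.reactions: dict[str, Reaction] = {}
        members: dict[str, list[str]] = {sid: [] for sid in subset_names}
        for rx in reactions:
            if rx.id in self.reactions:
                raise SchemaError(f"duplicate reaction id {rx.id!r}")
            if rx.subset_id not in subset_names:
                raise SchemaError(
                    f"reaction {rx.id!r}: unknown subset {rx.subset_id!r}"
                )
            for sp_id in rx.species_ids:
                if sp_id not in self.species:
                    raise SchemaError(
                        f"reaction {rx.id!r} references undefined species {sp_id!r}"
                    )
            self.reactions[rx.id] = rx
            members[rx.subset_id].append(rx.id)

        self.subsets: dict[str, Subset] = {}
        for sid in sorted(subset_names):
            rids = tuple(members[sid])
            if not rids:
                raise SchemaError(f"subset {sid!r} has no reactions")
            mean_abs = float(
                np.mean([abs(self.reactions[r].reference_delta) for r in rids])
            )
            if mean_abs <= 0.0:
                raise DegenerateSubsetError(
                    f"subset {sid!r}: mean absolute reference energy is zero"
                )
            self.subsets[sid] = Subset(
                id=sid,
                name=subset_names[sid],
                reaction_ids=rids,
                n_reactions=len(rids),
                mean_abs_ref=mean_abs,
            )

    @property
    def reaction_order(self) -> tuple[str, ...]:
        """Deterministic reaction ordering (by subset id, then reaction id)."""
        return tuple(self.reactions)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def subset_of(self, reaction_id: str) -> str:
        return self.reactions[reaction_id].subset_id

    def references(self) -> np.ndarray:
        """Reference relative energies in reaction order (kcal/mol)."""
        return np.array(
            [self.reactions[r].reference_delta for r in self.reaction_order]
        )

    def restrict(self, subset_ids: Iterable[str]) -> "Benchmark":
        """A new benchmark containing only the named subsets."""
        keep = set(subset_ids)
        unknown = keep - set(self.subsets)
        if unknown:
            raise SchemaError(f"unknown subset ids: {sorted(unknown)}")
        reactions = [r for r in self.reactions.values() if r.subset_id in keep]
        used = {s for r in reactions for s in r.species_ids}
        return Benchmark(
            {sid: self.subsets[sid].name for sid in keep},
            reactions,
            [sp for sp in self.species.values() if sp.id in used],
            dialect=self.dialect,
        )

    def to_dict(self) -> dict:
        return {
            "dialect": self.dialect,
            "subsets": [
                {"id": s.id, "name": s.name} for s in self.subsets.values()
            ],
            "reactions": [
                {
                    "id": r.id,
                    "subset": r.subset_id,
                    "terms": [[s, c] for s, c in r.terms],
                    "ref_kcal": r.reference_delta,
                    **({"absolute": True} if r.absolute else {}),
                }
                for r in self.reactions.values()
            ],
            "species": [
                {
                    "id": sp.id,
                    **({"xyz": sp.xyz} if sp.xyz is not None else {}),
                    **({"charge": sp.charge} if sp.charge is not None else {}),
                    **(
                        {"multiplicity": sp.multiplicity}
                        if sp.multiplicity is not None
                        else {}
                    ),
                }
                for sp in self.species.values()
            ],
        }

    @classmethod
    def from_dict(cls, data: dict, dialect: str | None = None) -> "Benchmark":
        try:
            subsets = {s["id"]: s.get("name", s["id"]) for s in data["subsets"]}
            reactions = [
                Reaction(
                    id=r["id"],
                    subset_id=r["subset"],
                    terms=tuple((str(s), float(c)) for s, c in r["terms"]),
                    reference_delta=float(r["ref_kcal"]),
                    absolute=bool(r.get("absolute", False)),
                )
                for r in data["reactions"]
            ]
            species = [
                Species(
                    id=sp["id"],
                    xyz=sp.get("xyz"),
                    charge=sp.get("charge"),
                    multiplicity=sp.get("multiplicity"),
                )
                for sp in data["species"]
            ]
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"malformed benchmark document: {exc}") from exc
        return cls(
            subsets,
            reactions,
            species,
            dialect=dialect or data.get("dialect", "generic"),
        )


def load_benchmark(path: str | Path, dialect: str | None = None) -> Benchmark:
    """Load a benchmark from its JSON interchange file.

    Parameters
    ----------
    path : path-like
        JSON document with ``subsets``, ``reactions``, and ``species`` keys.
    dialect : {"generic", "gmtkn55"}, optional
        Overrides the dialect recorded in the file.  ``gmtkn55`` pins the
        WTMAD-2 global constant to 56.84 kcal/mol.
    """
    with open(path) as fh:
        data = json.load(fh)
    return Benchmark.from_dict(data, dialect=dialect)


def save_benchmark(benchmark: Benchmark, path: str | Path) -> None:
    """Write the benchmark to its JSON interchange format."""
    with open(path, "w") as fh:
        json.dump(benchmark.to_dict(), fh, indent=1)
        fh.write("\n")


@dataclass
class EnergyTable:
    """Dense per-functional total energies, kcal/mol internally.

    ``energies`` is a DataFrame indexed by species id with one column per
    functional id.
    """

    energies: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.isfinite(self.energies.to_numpy(dtype=float)).all():
            bad = np.argwhere(~np.isfinite(self.energies.to_numpy(dtype=float)))
            r, c = bad[0]
            raise SchemaError(
                f"non-finite energy at species {self.energies.index[r]!r}, "
                f"functional {self.energies.columns[c]!r}"
            )

    @property
    def functionals(self) -> tuple[str, ...]:
        return tuple(self.energies.columns)

    @property
    def species_ids(self) -> tuple[str, ...]:
        return tuple(self.energies.index)

    def energy(self, functional: str, species: str) -> float:
        try:
            return float(self.energies.at[species, functional])
        except KeyError as exc:
            raise MissingSpeciesError(
                f"no energy for functional {functional!r}, species {species!r}"
            ) from exc

    def column(self, functional: str) -> dict[str, float]:
        """Energies of one functional as a species -> energy mapping."""
        if functional not in self.energies.columns:
            raise MissingSpeciesError(f"unknown functional {functional!r}")
        return self.energies[functional].to_dict()

    def select(self, functionals: Sequence[str]) -> "EnergyTable":
        missing = [f for f in functionals if f not in self.energies.columns]
        if missing:
            raise MissingSpeciesError(f"unknown functionals: {missing}")
        return EnergyTable(self.energies[list(functionals)].copy())


@dataclass
class ForceTable:
    """Per-functional nuclear forces, kcal/mol/Angstrom.

    ``forces[(functional, species)]`` is an (n_atoms, 3) array.
    """

    forces: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def add(self, functional: str, species: str, array: np.ndarray) -> None:
        array = np.asarray(array, dtype=float)
        if array.ndim != 2 or array.shape[1] != 3:
            raise SchemaError(
                f"force array for ({functional!r}, {species!r}) must be (n_atoms, 3), "
                f"got {array.shape}"
            )
        self.forces[(functional, species)] = array

    def get(self, functional: str, species: str) -> np.ndarray:
        try:
            return self.forces[(functional, species)]
        except KeyError as exc:
            raise MissingSpeciesError(
                f"no forces for functional {functional!r}, species {species!r}"
            ) from exc


def load_energy_table(path: str | Path, unit: str | None = None) -> EnergyTable:
    """Load a per-functional energy table from CSV.

    First column ``species``, one column per functional.  An optional
    leading comment line ``# unit: hartree`` (or ``kcal``) declares the
    input unit; the ``unit`` argument overrides it.  Values are stored in
    kcal/mol.
    """
    path = Path(path)
    file_unit = None
    with open(path) as fh:
        first = fh.readline()
    if first.lstrip().startswith("#"):
        directive = first.lstrip("#").strip().lower()
        if directive.startswith("unit:"):
            file_unit = directive.split(":", 1)[1].strip()
    unit = (unit or file_unit or "kcal").lower()
    if unit in ("kcal", "kcal/mol", "kcalmol"):
        factor = 1.0
    elif unit in ("hartree", "ha", "au"):
        factor = HARTREE_TO_KCAL
    else:
        raise SchemaError(f"unknown energy unit {unit!r}")

    df = pd.read_csv(path, comment="#", dtype={0: str})
    if df.columns[0] != "species":
        raise SchemaError(
            f"first column must be 'species', got {df.columns[0]!r}"
        )
    df = df.set_index("species")
    values = df.to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        r, c = bad[0]
        raise SchemaError(
            f"non-finite energy at row {r + 2} (species {df.index[r]!r}), "
            f"column {df.columns[c]!r}"
        )
    return EnergyTable(df.astype(float) * factor)


def save_energy_table(table: EnergyTable, path: str | Path) -> None:
    """Write a kcal/mol energy table to CSV with a unit directive."""
    with open(path, "w") as fh:
        fh.write("# unit: kcal\n")
        table.energies.to_csv(fh, index_label="species")


def reaction_delta(reaction: Reaction, energies: Mapping[str, float]) -> float:
    """Relative energy of one reaction from a species -> energy mapping.

    Returns sum(coefficient * energy) over the reaction terms; with the
    reactant/product sign convention this is products minus reactants.
    """
    total = 0.0
    for species_id, coef in reaction.terms:
        if species_id not in energies:
            raise MissingSpeciesError(
                f"reaction {reaction.id!r}: no energy for species {species_id!r}"
            )
        total += coef * energies[species_id]
    return total


def delta_matrix(
    benchmark: Benchmark,
    table: EnergyTable,
    functionals: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Reactions-by-functionals matrix of relative energies (kcal/mol).

    Rows follow ``benchmark.reaction_order``; columns follow the requested
    functional order (default: the table's column order).
    """
    if functionals is None:
        functionals = table.functionals
    out = np.empty((benchmark.n_reactions, len(functionals)))
    for j, func in enumerate(functionals):
        col = table.column(func)
        for i, rid in enumerate(benchmark.reaction_order):
            try:
                out[i, j] = reaction_delta(benchmark.reactions[rid], col)
            except MissingSpeciesError as exc:
                raise MissingSpeciesError(
                    f"functional {func!r}: {exc.args[0]}"
                ) from exc
    return pd.DataFrame(
        out, index=list(benchmark.reaction_order), columns=list(functionals)
    )
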