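# densemble

Weighted ensembles of electronic-structure methods, built from precomputed
per-functional data. The ensemble energy is a linear combination
`E = Σ ω_i E_i` of per-functional total energies, so relative energies and
forces inherit the same weights and the combination is size-consistent by
construction. Weights are fitted on reaction-energy benchmarks by
ridge-regularized weighted least squares, with each reaction scaled by its
subset's WTMAD-2 factor; electron densities are mixed with the normalized
weights.

No quantum-chemistry engine is involved: all inputs are plain tables of
total energies, forces, or grid-tabulated densities.

## What's inside

- `densemble.benchmark` — reaction benchmarks (subsets → reactions → signed
  stoichiometric species combinations with kcal/mol references),
  per-functional energy/force tables, and the reactions-by-functionals
  delta matrix. JSON/CSV interchange formats, Hartree→kcal/mol conversion.
- `densemble.metrics` — per-subset MAD and the WTMAD-2 figure of merit,
  including train/test/full split evaluation at a fixed global constant.
  The `gmtkn55` benchmark dialect pins the constant to 56.84 kcal/mol.
- `densemble.ensemble` — ridge fit of ensemble weights (default α = 10, no
  intercept), α search on a seeded 8:2 validation split, weight
  normalization, and energy/relative-energy/force prediction. Lasso and
  Lars-lasso penalties are available behind the same interface.
- `densemble.selection` — forward stepwise selection by training WTMAD-2,
  a brute-force oracle for small ensembles, ranking by absolute weight,
  and accuracy/cost execution orderings.
- `densemble.density` — mixing of grid-tabulated electron densities with
  normalized weights and the relative L2 density error.
- `densemble.synthetic` — generators for benchmarks with log-uniform
  subset energy scales, functional tables with controlled
  systematic/random error (including exact known-mixture construction for
  parameter-recovery tests), and analytic Gaussian density fixtures.
- `densemble.cli` — `simulate`, `fit`, `select`, `evaluate`, `predict`,
  and `mix-density` subcommands; every run writes a manifest with input
  hashes and the seed.

## CLI quick start

```sh
# synthetic dataset: 10 subsets x 20 reactions, 8 functionals
densemble simulate --subsets 10 --reactions 20 --functionals 8 \
    --noise 2.0 --seed 1 --out data/

# fit ensemble weights (ridge, alpha = 10)
densemble fit --benchmark data/benchmark.json --energies data/energies.csv \
    --alpha 10 --seed 42 --out model.json

# forward stepwise selection, tracking held-out performance
densemble select --benchmark data/benchmark.json --energies data/energies.csv \
    --max-n 4 --train-subsets S00,S01 --out trace.json

# score a model (or explicit predictions) with WTMAD-2
densemble evaluate --benchmark data/benchmark.json --model model.json \
    --energies data/energies.csv
```

`--config file.yaml` supplies defaults per subcommand (flat namespace,
e.g. `fit: {alpha: 10}`); explicit flags override it.

## File formats

- Benchmark JSON: `{"subsets": [{"id", "name"}], "reactions": [{"id",
  "subset", "terms": [["species", coef], ...], "ref_kcal": x}],
  "species": [{"id", "xyz"?}]}`. Coefficient < 0 marks a reactant, > 0 a
  product; references are products-minus-reactants in kcal/mol.
- Energy CSV: first column `species`, one column per functional, optional
  `# unit: hartree|kcal` directive on the first line.
- Density grid: whitespace-delimited text with `# unit:`, `# reference:`
  and `# columns: x y z w <source...>` headers, or an HDF5 file with the
  same datasets under `grid/`.
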