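# proptab

Margin-invariant proportional effect sizes for 2×2 contingency tables.

A 2×2 table of counts `(a, b / c, d)` factors as a product of a diagonal
matrix, a proportion matrix, and a second diagonal matrix, with the
marginal sums carried entirely by the diagonal factors. Four such
factorizations exist (column- or row-sum scaling × unit or dual grouping);
each yields a pair of points in the standard one-simplex that reduces to
center-of-mass coordinates `(delta, mu)` — half-difference and mean of the
pair. `proptab` provides:

- **tables** — the validated `CountTable2x2` type, the four
  `diag · P · diag` factorizations, unitary diagonal (u-)scaling, Yule
  symmetrization, and the marginal ratio product.
- **effect_sizes** — odds ratio, Yule's Q, relative risk, ratio difference,
  φ, the simple matching coefficient, Cramér's V and Goodman–Kruskal τ,
  all the `(delta, mu)` forms, the perspective-function identities relating
  them, and the `φ = M · D` factorizations into a margin factor times a
  proportional displacement.
- **monte_carlo** — table distributions under fixed-column-sum,
  fixed-row-sum, or fixed-total sampling; percentile and normal ±2σ
  confidence intervals for any registered statistic, with per-run
  convergence diagnostics.
- **cart** — single-node binary association scans of a continuous covariate
  against a binary class: per-threshold information gains (Gini/entropy),
  φ², Q, and the margin-invariant `delta_c`/`delta_r` coordinates, plus
  global-max and two-sided split selection. Every record satisfies
  `IG_Gini = G(parent) · φ²`.
- **logistic_adjust** — one-covariate logistic fit (Newton–Raphson) and the
  class-imbalance-adjusted reparameterization `(b, x0)` with
  `y(x0) = n_pos/(n_neg + n_pos)`, inverse-class-size proportion
  reweighting, and moving-average reference curves.
- **synthetic** — seeded generators for random positive-margin tables,
  two-class overlapping Gaussian covariate data with analytic
  density-crossing points, and imbalanced logistic samples.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end numerical anchors
(deterministic coordinates, Monte Carlo mean/sd, logistic arithmetic, and
the algebraic property suites over 1000 random tables).

## CLI

```sh
proptab effect-size table.json                 # full effect-size report
proptab factorize table.csv --side column --mode dual
proptab mc-ci table.json --scheme fixed_colsums --statistic delta_c_cma \
    --level 0.95 --seed 1
proptab cart-scan samples.csv --measure delta_c --mode two_sided \
    --scan-csv scan.csv
proptab logistic-adjust samples.csv --curve-csv curves.csv
proptab simulate --kind two-class --n-neg 3000 --n-pos 1200 --out data.csv
```

2×2 CSV input is row-major (`a,b` then `c,d`); JSON input is
`{"a": .., "b": .., "c": .., "d": ..}`. Sample CSVs have `x,y` columns with
`y` in {0, 1}. A YAML config (`--config`) may supply any option; explicit
flags win. All outputs embed the package version and the seed in effect.

## Conventions

- `delta` is always the halved difference `(p_beta − p_alpha)/2`; the
  un-halved difference is exposed as `displacement`, and the `φ = M · D`
  identities hold against the displacement.
- For the `csum_rows` form the pair is ordered (a-element, c-element), so
  its `delta` is the c-minus-a orientation; the a-minus-c orientation is
  its negation.
- Counts are nonnegative reals: rescaled and symmetrized tables are
  first-class values. No continuity corrections are applied anywhere.
- CART splits use `S1 = {x ≤ t}` with thresholds at midpoints of distinct
  values; ties in split selection go to the smallest threshold.
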