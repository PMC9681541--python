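# Methods

## Molecular graphs and edge partitions

Molecules are hydrogen-suppressed: vertices are heavy atoms, one edge per
bond regardless of bond order, no stereochemistry, charges or aromaticity
perception. Graphs must be simple and connected; violations are errors at
read time (the index formulas themselves would tolerate disconnection, but
the study data are all connected molecules, so a disconnected input almost
always signals a broken file). Vertex identifiers are opaque tokens —
element labels are irrelevant because every supported index depends only on
degrees. Degree pairs are stored unordered in canonical `(m, n)` form with
`m ≤ n`; all nine per-edge terms are symmetric, so nothing is lost.

Two computation routes exist on purpose: `compute_index` evaluates a
partition-weighted sum, `compute_from_graph` sums directly over edges. They
are algebraically identical, and the test suite holds them to 1e-9 relative
agreement on batches of random graphs; the direct sum is the oracle for the
partition code.

## Index arithmetic and rounding

All computation is full double precision; M1, M2, HM and F remain exact
integers because their per-edge terms are integer-valued. Printed tables in
this literature use fixed decimals, so presentation rounding is half-up
(ties away from zero, via `decimal`), never Python's default banker's
rounding, and is applied only at output time (`--round`, `IndexVector.rounded`).

Useful internal identities, all enforced by tests: `HM = F + 2·M2` exactly;
`M1 = Σ_v d(v)²` (the classical first-Zagreb identity); per-edge AM–GM
gives `H ≤ RA` and `GA ≤ |E|`, with equality in the latter exactly when
every edge class has `m = n`.

## Regression and reported statistics

Each (index, property) pair is fitted independently by OLS (scipy's
`linregress` behind the module surface) after pairwise deletion: a molecule
missing either value drops out of that model only. Two of the eleven drugs
lack a refractivity value, so all refractivity models have n = 9 while the
other properties have n = 11. Reported per fit: A, b, n, Pearson r,
r² = r², `se = sqrt(SSE/(n−2))`, `F = r²(n−2)/(1−r²)` (equal to the squared
slope t statistic) and the upper-tail p from the F(1, n−2) distribution.
Degenerate inputs raise typed errors: fewer than 3 complete pairs, zero
predictor variance, or zero response variance (r undefined). A perfect fit
reports se = 0, r² = 1 and an unbounded F (`inf`, p = 0) rather than a
division error.

A model is flagged "Significant" when `p < 0.05` OR `r > 0.6`, with both
sub-conditions recorded in the output. The disjunction is deliberate: the
source study labels every model significant while stating r > 0.6 as its
working criterion, and at least one of its rows has p = 0.059, so neither
condition alone reproduces its flags. No multiple-testing correction is
applied across the 45 models — the original analysis applies none, and the
report states the convention rather than silently changing it.

Property units are carried as opaque labels (`paper_data.PROPERTY_UNITS`);
no conversion is attempted, since the source mixes printed units.

## Prediction tables and printed-coefficient convention

The actual-vs-computed tables are generated from coefficients rounded
half-up to 3 decimals (`coef_digits=3`, the `--coef-round` flag). This
mirrors how such tables are produced in the source literature — e.g. the
psoralen complexity prediction under the first-Zagreb model is
`−214.531 + 6.269 × 78 = 274.451`, which only the 3-dp coefficients give
(the full-precision fit yields 274.463). `predict` defaults to full
precision for programmatic use.

## Bundled study data and the discrepancy ledger

The fixtures store the published values exactly as printed, including the
2-dp rounding of the non-integer indices; regressions run on these printed
values. Drug keys are normalised (lowercase, hyphens); "Fluticasone
propionate" and "Fluticasone" are distinct molecules and both kept. The
boiling-point column is shipped but never modelled.

The source tables conflict with themselves in places, and the package
records every known conflict as a `DiscrepancyRecord` rather than resolving
it silently: three property observations printed twice with different
values (monobenzone polarity 23.50 vs 35.50, azathioprine refractivity
69.94 vs 59.94, fluticasone molar volume 323.20 vs 336.6), three index
cells where the printed value disagrees with the definition evaluated on
the printed partition (azathioprine ABC and GA, psoralen RA — the printed
RA appears truncated rather than rounded), two proof-line typos (psoralen
HM printed 336 where the definition gives 386; azathioprine H printed 9.60
vs 8.60), and one correlation printed twice with different values
(H–polarity, 0.8663 vs 0.663). The default reading is always the main
property table or the definition formula; `--variant tables15-18` switches
the three property cells to their alternative reading so either can be
probed.

## What reproduces and what cannot

The `reproduce` command recomputes everything and compares each cell with
its printed counterpart at printed precision (a cell matches when the
recomputed value rounds half-up to the printed string). The outcome, stated
plainly:

- The worked index values reproduce exactly except the three ledgered cells.
- For the integer-valued descriptors (M1, M2, HM, F) the complexity models
  reproduce at printed precision (e.g. F/complexity: A = −88.525,
  b = 1.870, r = 0.952, F = 86.119, se = 101.327), as do the F and H
  enthalpy models.
- The non-integer descriptor columns (ABC, RA, S, GA, H) reproduce only
  approximately: the original regressions were evidently run on unrounded
  index values from structures that are not published, while only 2-dp
  values are printed.
- The polarity, refractivity and molar-volume statistics cannot be
  regenerated under either reading of the conflicting observations, and the
  enthalpy models for seven of the nine indices are not derivable from the
  published property table at all (their printed coefficients do not even
  approximately match any fit of the printed data). These blocks are
  flagged in `agreement.csv` and cross-referenced to the ledger; no attempt
  is made to force agreement.

## Synthetic data generator

`random_molecular_graph` grows a random spanning tree under a degree cap
(each new vertex attaches to a uniformly chosen existing vertex with spare
degree — always possible for cap ≥ 2) and then adds a random number of
extra edges (up to ~n/4) between non-adjacent degree-capped pairs, giving
tree-plus-rings topologies. The cap defaults to 4 as the carbon-valence
analogue; the study molecules have maximum degree 3, but the generator is
kept more general. Properties are simulated from the same line the fitter
estimates, `P = A + b·TI + ε` with iid Gaussian ε — Gaussian because it is
the conventional linear-model error; the source states no error model. All
randomness flows from explicit integer seeds through numpy's `default_rng`;
the recovery experiment records its derived per-graph and noise seeds for
replay.

What the generator does emulate: connected simple graphs with
chemistry-like degree ranges (1–4) and exactly linear property structure.
What it does not: realistic ring statistics, heteroatom or functional-group
distributions, correlated measurement error, or any nonlinearity between
structure and property. Passing recovery tests therefore demonstrate the
pipeline's correctness (noiseless closure to 1e-9, consistent estimation as
n grows on paired seeds), not that real properties are linear in any index.

## Problem sizes and numerical tolerances

Property tests run on random graphs of 2–40 vertices; the end-to-end
identity suite uses 1000 seeded graphs of 4–27 vertices — small molecules
by design, matching the 11–45-edge range of the study compounds. Dual-route
index agreement is asserted at 1e-9 relative; noiseless parameter recovery
at 1e-9 absolute; reproduction of printed statistics at the precision each
table prints (typically 3 decimals). OLS is the statistical cross-check
target as well: the fitter is validated against an independent statsmodels
OLS on the same data.

## Limitations

- Only the nine degree-based indices; no distance-based or spectral
  descriptors (Wiener, Estrada, ...).
- Univariate linear models only; no multivariate, regularised or
  cross-validated modelling, and no bioactivity (QSAR) endpoints.
- Nine of the eleven study molecules have no published edge partition;
  their descriptor values enter only through the printed table, so their
  structures cannot be re-derived or checked here.
- SMILES ingestion is out of the core contract; edge lists are the input
  format.
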