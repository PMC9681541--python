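# topoqspr

Degree-based topological indices of molecular graphs, and the univariate
QSPR (quantitative structure–property relationship) models built on them.

Medicinal chemists use topological indices — real-valued invariants of the
hydrogen-suppressed molecular graph — as cheap structural descriptors that
correlate with physicochemical properties. This package implements the nine
classical degree-based indices and the linear QSPR workflow around them for
a published study of eleven drugs used in vitiligo treatment (azathioprine,
psoralen, monobenzone, clobetasol propionate and other corticosteroids). It
ships the study's data tables as versioned fixtures, regenerates every
statistical table from them, and flags, cell by cell, where the printed
tables cannot be regenerated from the printed inputs.

## The model

A molecule is a simple connected graph `G(V, E)`: heavy atoms are vertices,
bonds are edges (multiplicity ignored), and `d_u` is the degree of vertex
`u`. Every index is a sum over edges `uv` of a symmetric function of
`(d_u, d_v)`, so it collapses to a weighted sum over the *edge partition*
`|E_{m,n}|` — the number of edges joining a degree-`m` to a degree-`n`
vertex:

| index | per-edge term |
|---|---|
| atom-bond connectivity `ABC` | `sqrt((d_u + d_v − 2)/(d_u d_v))` |
| Randić `RA` | `1/sqrt(d_u d_v)` |
| sum-connectivity `S` | `1/sqrt(d_u + d_v)` |
| geometric–arithmetic `GA` | `2 sqrt(d_u d_v)/(d_u + d_v)` |
| first / second Zagreb `M1`, `M2` | `d_u + d_v`, `d_u d_v` |
| harmonic `H` | `2/(d_u + d_v)` |
| hyper-Zagreb `HM` | `(d_u + d_v)²` |
| forgotten `F` | `d_u² + d_v²` |

Each physicochemical property `P` (refractivity, enthalpy, molar volume,
polarity, complexity) is then regressed on each index with the simple line

```
P = A + b · TI
```

fitted by ordinary least squares with pairwise deletion of missing values,
reporting `A`, `b`, `n`, Pearson `r`, `r²`, the standard error of estimate
`sqrt(SSE/(n−2))`, and the single-predictor F test with `(1, n−2)` degrees
of freedom. A seeded synthetic module (random degree-capped connected
graphs + Gaussian-noise linear properties) provides ground truth for the
whole pipeline.

## Worked example

Compute the indices of a molecule given as a plain-text edge list (one
`u v` pair per line; a six-ring with one substituent here):

```
$ topoqspr indices ring.edges --out desc.csv --round 2
wrote desc.csv (1 molecules)
$ cat desc.csv
# topoqspr 0.1.0
# inputs: {'ring.edges': '12618de192a3ffd8'}
# round: 2
name,ABC,RA,S,GA,M1,M2,H,HM,F
ring,5.06,3.39,3.39,6.83,30.0,31.0,3.3,130.0,68.0
```

`M1 = 30` is the sum of `d_u + d_v` over the seven bonds (equivalently the
sum of squared degrees); `HM = F + 2·M2 = 68 + 62 = 130` holds exactly, as
it must for any graph.

Regenerate the full study report from the bundled tables:

```
$ topoqspr reproduce --out report/
wrote report bundle to report; agreement: 171/333 cells match printed values,
162 flagged (see agreement.csv, column 'ledger')
```

`report/` contains one regression-parameter table per index, the
correlation / standard-error / r² matrices, one actual-vs-computed table
per property, and `agreement.csv`, which compares every recomputed cell
with its printed counterpart at the precision it was printed. For example
the forgotten-index/complexity model reproduces exactly
(`A = −88.525, b = 1.870, r = 0.952, F = 86.119`), while the flagged cells
trace back to internal conflicts of the source tables recorded in the
discrepancy ledger (`topoqspr.paper_data.known_discrepancies()`); see
`docs/methods.md` for which blocks reproduce and why the rest cannot.

Other subcommands: `topoqspr qspr` (fit your own descriptor/property CSVs)
and `topoqspr simulate --seed N` (synthetic data with known coefficients).

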