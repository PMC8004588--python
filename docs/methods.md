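# Methods

This note documents the models and procedures implemented in `volqsrr`,
the defaults and why they were chosen, what the synthetic-data generators
emulate, and the package's numerical conventions and limitations.

## The packaged dataset

`volqsrr.data/marrubium_table1.csv` transcribes a two-season (2019/2020)
GC–MS survey of *Marrubium vulgare* volatiles: 160 chromatographic peaks
with compound name, compound-class code (OMN, ST, OST, OD, T, AR, A, O,
NI), the train/test/validation cycle of the original modeling, the
experimental retention index (RI, HP-5MS column) and relative FID
percentage per season. Percentages reported below the quantitation limit
are stored as a `trace` token and contribute 0.0 to class sums — the
convention under which the per-class sums reproduce the printed summary
rows exactly (totals 100 and 99.3). Three rows (108, 114, 154) lack a
cycle and a predicted RI in the source and are stored with an empty cycle.

SMILES for the 90 identified compounds were encoded from the printed
names. Stereoisomer pairs (E/Z-caryophyllene, the bergamotenes, the
muurolene/cadinene family) share a 2D constitution, which is correct for
purely topological descriptors. For a few obscure polycyclic skeletons
whose exact ring fusion is not recoverable from the name alone, a
constitutionally consistent structure with the correct molecular formula
is used; every structure was validated against its expected formula.
Row 143 prints an alkane name inconsistent with its printed RI (2305); the
encoded structure is the C23 n-alkane consistent with the RI and the
elution order.

## Retention indices

The linear (van den Dool) index for temperature-programmed GC is used
throughout: RI = 100·(n + (rt − tₙ)/(tₙ₊₁ − tₙ)) on a C8–C32 alkane
ladder with strictly increasing retention times. No extrapolation outside
the ladder span; the logarithmic isothermal form is deliberately not
implemented because the underlying runs are temperature-programmed.

## Molecular descriptors

All descriptors are 2D/topological, computed on hydrogen-suppressed graphs
(aromatic bonds carry order 1.5). Atomic weighting schemes, keyed by the
suffix letter of descriptor names: `m` mass, `v` van der Waals volume
(from Bondi radii, 4/3·π·r³), `e` Sanderson electronegativity, `p`
polarizability, `Z` atomic number, `s` Kier–Hall intrinsic state
I = ((2/L)²·δᵛ + 1)/δ. The packaged property table
(`data/atomic_properties.csv`, covering C/N/O/S) is the single source of
truth for the m/v/e/p values; values are used raw everywhere except inside
the Barysz formula, where only carbon-relative ratios enter. Elements
outside C/N/O/S raise an error rather than defaulting silently.

Autocorrelation conventions (shared with common descriptor software): sums
run over ordered atom pairs at topological lag k (each unordered pair
counted twice in numerator and pair count). ATSC is the centered
Broto–Moreau sum, AATSC its average, MATS the Moran form (normalised by
the population variance Σ(wᵢ−w̄)²/N), GATS the Geary form (squared
differences over 2nₖ, normalised by the sample variance with N−1). Empty
lags and zero-variance weight vectors yield 0 by convention so feature
tables stay dense. VAdjMat = 1 + log2(bond count), 0 for a bondless graph.

The Barysz weighted distance matrix has diagonal 1 − w_C/wᵢ and
off-diagonal entries equal to the minimum over paths of
Σ w_C²/(b·wₖ·wₗ) over path edges with bond order b (computed by Dijkstra
on the weighted graph; when two paths tie in total weight the descriptor
value is unaffected). For an all-carbon single-bonded graph it reduces to
the plain topological distance matrix. The intrinsic-state scheme needs a
graph-independent carbon reference for the diagonal; the value 2.0 (a
singly connected sp³ carbon) is used. SM1 is the trace; VR1 sums
|aᵢ·aⱼ|^(−1/2) over bonds with `a` the eigenvector of the largest
eigenvalue, and reports an error if that eigenvector has a near-zero
component on a bonded atom.

The registered catalogue spans AATSC/MATS/GATS at lags 1–8 over all six
schemes plus SM1_Dz*/VR1_Dz* and VAdjMat (157 names) — a realistic search
space for the selection stage. The seven descriptors used by the
retention-index models are AATSC4e, AATSC2p, MATS5v, GATS6v, VR1_Dzs,
SM1_Dzv and VAdjMat.

## Descriptor selection

A Pearson collinearity pre-filter stands in for a factor-analysis
pre-step: pairs with |r| above 0.95 (default) are resolved by dropping the
member with the larger mean absolute correlation to everything else, until
no pair exceeds the threshold. The GA then searches fixed-cardinality
subsets (default 7): tournament selection (size 3), uniform crossover
repaired to fixed cardinality, swap mutation (rate 0.05), elitism 1 (so
the best-fitness trace is monotone), fitness = mean cross-validated r² of
a small boosted-trees learner with shared fold assignment and a fitness
cache. Defaults are population 50, 100 generations, 5-fold CV, inner
learner 100 trees / depth 3 / rate 0.1 — sized for overnight-quality runs.
The recovery tests and the desk-scale pipeline use a smaller,
equally deterministic setting (population 24, 18 generations, 3-fold CV,
inner 40 depth-1 trees at rate 0.5) chosen so a 20-replicate recovery
experiment completes in minutes; under those settings the planted
3-informative/50-noise benchmark is recovered in 90% of 20 seeded runs.

## Boosted regression trees

The regressor is written from scratch on numpy (scikit-learn supplies only
the estimator interface). Before boosting, a seeded random holdout of
`test_proportion` rows is split off. F₀ is the training mean; each
iteration draws a subsample of training rows without replacement, fits a
greedy least-squares binary tree (exact split enumeration via prefix sums;
ties resolved toward the lowest feature index, then the lowest threshold;
split gains below 10⁻¹² of the sum-of-squares scale are treated as noise)
to the current residuals, and adds it with learning rate ν. Boosting stops
at `n_trees` or when the holdout mean squared error has not improved for
`patience` (default 50) iterations; the ensemble and its loss histories
are truncated at the holdout-optimal iteration. Grid search refits one
model per configuration with a shared seed inside the allowed ranges
(trees 100–1000, ν 0.0005–0.1, holdout and subsample 0.1–0.9) and picks
the lowest holdout LSE, ties to fewer trees then smaller ν. Predictor
importance is the total split-gain (SSE reduction) per feature, rescaled
to a maximum of 1.

Per-season models are fitted on the identified compounds that have an
experimental RI in that season (65 for 2019, 76 for 2020); unidentified
peaks carry no structure and cannot enter a QSRR model. The overall r² is
reported against all modeled compounds of the season (the model's own
holdout is also reported separately, as are train/test partitions), since
the fit statistic of record for these models is the overall coefficient of
determination. Default model settings (depth 3, min leaf 2) are
conventional for boosted stumps-to-shallow-trees regression on
tens-to-hundreds of rows.

## Goodness of fit

With e = pred − obs: RMSE = √(Σe²/N); MBE = Σe/N (signed, so systematic
under-prediction is negative); MPE = (100/N)·Σ|e|/obs (absolute, hence
positive even when MBE is negative); reduced χ² = Σe²/(N − p) with p
defaulting to the 7 descriptors; r² is the squared Pearson correlation.
The identity RMSE²·N = χ²·(N − p) holds exactly and is tested.

## Chemotype analysis

Composition matrices (samples × compounds, percentages, absences = 0) are
clustered with Euclidean distances on raw percentages and complete
linkage, with a deterministic lexicographic tie-break on member labels.
The merge tree is exported to Newick with the midpoint convention (a
node at merge height h sits h/2 from its leaves), which renders naturally
as an unrooted tree. Chemotype calls use marker concentration ranges:
E-caryophyllene 15.6–45.8%, β-bisabolene 13.1–28.3%, α-pinene 21.5–28.9%,
β-farnesene 20.2–24.2%. The joint E-caryophyllene + caryophyllene-oxide
type is operationalised as E-caryophyllene in range AND caryophyllene
oxide ≥ 5% (no published oxide threshold exists; 5% separates the
oxide-rich reports from the ordinary 1–2% background) and takes priority
over the plain E-caryophyllene rule; remaining samples are "diverse
(unclassified)". Compound-name matching is case-folded with Greek letters
spelled out; stripping of stereo prefixes (E-/Z-/α-/β-/…) is opt-in
because literature tables are inconsistent about them.

## Synthetic data

The generators provide every input with known ground truth:

- `make_qsrr_dataset`: descriptors uniform on [−2, 2]; RI = 1600 +
  95·x₁ + 60·x₂ + 40·sin(x₃) + Gaussian noise (sd 60 index units — the
  scale of the residual error typical for such fits), 3 informative + 50
  noise features, 160 compounds, values clipped to the 850–3300 band the
  real survey spans. The sinusoidal term makes the map partially nonlinear
  so tree ensembles have something genuinely nonlinear to find.
- `make_molecules`: random valence-respecting trees over C with occasional
  O/N/S, optional ring closure and double bonds — structural plumbing for
  descriptor tests, not a sample of terpene chemistry.
- `make_composition_samples`: clusters centered on chemotype marker
  profiles with Dirichlet-distributed background composition, rows summing
  to ~100.
- `make_alkane_ladder`: affine or randomized strictly increasing C8–C32
  retention times.

What passing these tests shows: the machinery recovers planted structure
under realistic noise at the survey's sample sizes. What it does not show:
descriptor values identical to any particular descriptor software (whose
internal property tables differ), performance on structural classes absent
from the survey, or robustness to name/structure transcription errors in
external composition tables.

## Numerical choices and limitations

- All randomness flows through `numpy.random.default_rng` seeds; reruns
  with the same configuration are bit-identical, and the pipeline writes a
  manifest with the configuration hash.
- Percent display rounding is half-up to one decimal, matching the printed
  table's precision.
- The acceptance script uses ten replicate seeded fits and a 2×2 grid
  (ν ∈ {0.05, 0.1} × subsample ∈ {0.5, 0.8}, 500 trees) — enough to
  stabilise the mean overall r² to ±0.01 while staying fast on one CPU.
- Published run-specific numbers (the exact χ²/RMSE/MBE/MPE values, the
  per-compound predicted-RI column, the descriptor correlation matrix
  entries and the literature tree topology) depend on the original
  software's internal tables and run state and are not reproduction
  targets; the property suites cover the corresponding code paths.
- The composition matrix behind the published 37-sample literature tree is
  not printed anywhere and cannot be packaged; the clustering engine and
  the chemotype ranges are validated on planted synthetic matrices
  instead.
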