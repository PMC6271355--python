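# Methods

## Scope and data model

The package implements the classical chemometrics QSAR workflow on tabular
compound × descriptor data with a continuous activity column. Activity is
logRA = log10(IC50_ref / IC50_analog); the reference IC50 is a dataset-level
parameter (97 µM artemisinin for the built-in fixtures) rather than a
hard-coded constant, so other reference compounds can be used. The potency
boundary is logRA > 0 for "more potent"; exactly zero — the reference
compound itself — is classed "less potent".

The two fixture tables are stored as decimal strings in CSV data files and
parsed on load, so in-memory values equal the printed ones exactly and a
save/load round trip is byte-stable. The fixture's RA column is not stored:
one printed RA value is internally inconsistent with its IC50 at the fifth
significant digit, so consistency checks use logRA, which is reproducible
from the IC50 values to 3–4 decimals throughout.

## Preprocessing

Autoscaling uses arithmetic column means and **sample (n−1)** standard
deviations. The convention is not externally fixed: Pearson correlations are
convention-invariant, and all regression statistics are computed from
residuals in original activity units, so the choice affects only the
reported scaler internals. Models fitted on training data are applied
unchanged to new data (the test-set path never re-fits a scaler). Constant
columns abort with an error naming the column.

Descriptor screening keeps descriptors with |r(x_j, y)| ≥ cutoff
(default 0.20). Absolute correlation is used — a signed rule would discard
every inversely related descriptor, which contradicts the retention of
negatively correlated descriptors in the reference analysis — and ties at
the cutoff are kept, since only descriptors *under* the cutoff are
discarded. Inter-descriptor redundancy is deliberately not a criterion.

## PCA

PCA is correlation-based: the symmetric eigendecomposition of
**X**ᵀ**X**/(n−1) on the autoscaled matrix (not an SVD of the data), chosen
for clarity and cross-checked in the tests against an independent
power-iteration-with-deflation oracle at 1e−6. Explained variance is
λ_a/m × 100 %. Sign convention: each loading column is flipped so that its
first entry of non-negligible magnitude (> 1e−12, scanning in descriptor
order) is positive; this reproduces the published signs of the leading
component equations. Descriptor *selection* is reporting (variance table,
loadings, rendered equations, scores) rather than an automated chooser —
in the emulated workflow the analyst inspected score/loading plots across
attempts, a human-in-the-loop step no algorithm in this package claims to
replace.

On the fixture this reproduces the published cumulative explained variance
(48.3171 / 75.2996 / 90.7373 %) and both leading loading vectors to ±0.01.
The published per-component "Variance (%)" row (38.65/21.59/12.35) is
mutually inconsistent with its own cumulative row and cannot be derived
from the published 4-descriptor matrix (it plausibly refers to the
unpublished 213-descriptor matrix); it is not reproduced.

## HCA

Distances are Euclidean on autoscaled descriptors. The default linkage is
"incremental" — the name classical chemometrics software gives Ward's
minimum-variance criterion — implemented through SciPy's Lance–Williams
recurrence and verified merge-by-merge against a brute-force O(n³)
re-implementation and against explicit within-cluster sum-of-squares
computations (h² = 2·ΔESS) in the tests. Complete, single and average
linkage are available; heights are reported on the distance scale for all
linkages so the similarity mapping s = 1 − h/h_max is linkage-agnostic.
Cutting into k clusters undoes the last k−1 merges. Degenerate input (all
points identical) yields similarity 1 throughout with a warning.

Known limitation: on the fixture, the k = 2 incremental cut places the
borderline analog 18 (logRA = 0.3604, the weakest active, whose descriptor
vector lies nearer the inactive group) in the low-activity cluster,
yielding a 10/11 split rather than the 11/10 activity partition the source
analysis reports. This is not linkage-specific — complete, single, average,
centroid and median linkage, on raw, range-scaled or PC-score
representations, all agree on compound 18 — so the published partition is
taken to reflect the activity labels rather than a reproducible dendrogram
cut. The discrepancy is asserted, not hidden: one acceptance-level test
states the published partition and fails, while a unit test pins the
computed partition.

## PLS and PCR

Both models regress autoscaled y on autoscaled X, so the equations have no
intercept and coefficients are standardized. PLS1 uses NIPALS with
deterministic y-side initialization, convergence tolerance 1e−12 on the
score vector and a 500-iteration cap per component; with one response the
loop converges in a single pass, and the tests require agreement with
scikit-learn's independent NIPALS at 1e−8 and with an ordinary
least-squares oracle in the full-rank limit. PCR regresses y on the
leading PCA scores and back-projects. Requesting more components than the
effective rank raises a rank-deficiency error rather than returning a
degenerate component.

Leave-one-out cross-validation re-fits the autoscalers on every fold along
with the model — no statistic of the held-out compound leaks into its own
prediction. A fold whose training subset acquires a constant column aborts
with an error naming the fold.

### Component-count selection

`select_n_components` scans 1..a_max and picks the count minimizing LOO
PRESS (ties to the fewest). On the fixture this selects **one** component
for both PLS and PCR. That resolves an apparent inconsistency in the source
analysis, whose software examined three factors but reported the
PRESS-optimal model: the published regression equations are exactly
(4 d.p.) the 1-component PLS/PCR solutions, the published test-set
predictions follow from those 1-component models to 4 d.p., and the
published Q²/SEV equal the 1-component LOO statistics — while the published
calibration R² and residual sums of squares (0.8937 / 1.0745) are the
3-component values. The package therefore reports calibration statistics at
the requested component count and validation statistics at the
PRESS-optimal count, and both sets reproduce the published numbers.

### Statistics conventions

With n compounds and k descriptors:

* R² = 1 − PRESS_cal/TSS, Q² = 1 − PRESS_val/TSS, TSS about the full
  training mean;
* SEV = √(PRESS_val/n), identically (SEV²·n = PRESS_val exactly);
* R²adj = 1 − (1−R²)(n−1)/(n−k) and s = √(PRESS_cal/(n−k)) — the n−k
  divisor reproduces the published PCR s exactly (the published PLS s is a
  typographical outlier: the formula gives 0.2293, not 0.2280);
* F = (R²/k)/((1−R²)/(n−k−1)) with df (k, n−k−1) = (4, 16) on the fixture —
  the convention that matches the published F values to <0.15 despite their
  "(4,17)" typesetting;
* s_PRESS = √(PRESS_val/(n−k−1)), clearly labeled; no stated formula
  reproduces the published 0.0590/0.0647, and the quantity is excluded from
  reproduction checks.

Both PRESS_cal (calibration residual SS) and PRESS_val (true LOO PRESS) are
first-class outputs with unambiguous names, because the source analysis
prints the calibration quantity under the name "PRESS" while its Q² and SEV
derive from the validation quantity.

## Synthetic data

`generate_qsar_dataset` emulates the statistical structure of a wide QSAR
matrix: an equicorrelated (default pairwise r = 0.3, a typical mild
collinearity among related descriptors) standard-normal informative block;
activity = Xβ + Gaussian noise (default σ = 0.3 activity units, giving an
attainable R² ≈ 0.8 with the default β = (−0.3, −0.4, 0.4, 0.3), in the
range of acceptable QSAR models); redundant columns as jittered copies
(σ = 0.3); independent standard-normal noise columns. Randomness is one
seeded root stream with per-block child streams, so enlarging one block
never perturbs another. The ground-truth record carries β, the noise sd and
the signal variance, from which the oracle R² =
Var(Xβ)/(Var(Xβ)+σ²) follows.

`make_paperlike_dataset` mimics the artemisinin training table's shape:
21 compounds, 4 descriptors, 11 "potent" (activity uniform on [0.3, 2.4])
vs 10 "less potent" (activity at or just below 0), with per-descriptor
class-mean shifts of (−1.14, −2.13, 2.94, 0.85) within-class standard
deviations — the standardized class separation measured on the real table —
so two-class HCA recovery behaves like it does on the real data.

What the generator does *not* emulate: descriptor physics (no 3D structure,
no units), heavy-tailed or discrete descriptor marginals, nonlinear
structure–activity relations, and activity measurement heteroscedasticity.
Passing tests on synthetic data therefore demonstrate correct recovery of
*linear* Gaussian structure, not robustness to real-data pathologies.

## Pipeline and I/O

The pipeline runs screen → PCA → HCA → PLS & PCR with LOO → statistics →
optional test-set prediction, writing every table as CSV/JSON/Newick under
one output directory and logging each stage with its parameters to stderr.
Defaults equal the study settings: cutoff 0.20, three components examined,
incremental linkage, reference IC50 97 µM. Table output rounds to 4
decimal places (the convention of QSAR reports); a flag preserves full
precision. Config files are flat YAML mappings with CLI flags taking
precedence; unknown keys are rejected. Model files are human-diffable
key-value text with full-precision floats. All problem sizes here are
desk-scale (n = 21, m = 4); every test and the reproduction script run in
seconds on one CPU.
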