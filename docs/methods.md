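# Methods

## Problem and conventions

DLBCL cell-of-origin assignment is treated as a binary problem: GCB vs
non-GCB, with the GEP label as truth and the three-way GEP call (GCB /
ABC / UC) collapsed so that both ABC and UC count as non-GCB (the
original label is kept for reporting). Throughout, GCB is the positive
class: a true positive is a GEP-GCB case called GCB.

Staining is a percentage of positive tumor cells in [0, 100] per
antibody (CD10, BCL6, FOXP1, GCET1, MUM1; tags 1–5). A marker is
positive when its percentage is **greater than or equal to** the
cut-off; a published "30%" cut-off conventionally means "at least 30% of
cells stain". Cases lacking a marker required by a given classifier are
excluded from that classifier's evaluation and logged, rather than
imputed — the complete-scores rule of the source protocols.

## Decision trees

The eight trees are data, not code: `data/trees.json` holds each
structure and its cut-offs, transcribed from the original algorithm
publications (cut-offs: CD10/BCL6/MUM1 at 30%; FOXP1 at 80% in Nyman,
Choi and Choi\*, 60% in VY3/VY4; GCET1 at 80% in Choi/Choi\*, 60% in
VY4; MUM1 at 80% inside Choi/Choi\*). Custom trees load from the same
JSON schema, so a corrected transcription needs no code change. Trees
are deterministic — no ties are possible.

A noteworthy consequence of the published cut-offs: Hans and Colomo
induce the same decision function (GCB iff CD10+ or BCL6+ with MUM1−)
while testing markers in a different order. On complete data they agree
case-for-case; on data with missing stains their usable-case sets
differ, which is how the two can report different metrics in practice.

## Linear discriminant functions

Gaussian LDA with pooled within-class covariance `S` (divisor n − g)
gives one affine score per class,

    LDF_c(x) = ln π_c − ½ μ_cᵀ S⁻¹ μ_c + (S⁻¹ μ_c)ᵀ x,

the representation clinical LDA tools print as a per-class constant plus
per-antibody weights, and the form in which the published coefficient
table is stored verbatim (`data/ldf_published.json`). Numerical choices:

* **Input scale** defaults to positivity indicators in {0, 1} at the
  uniform 30% cut-off. The published weight magnitudes (≈1–7 against
  constants ≈−5..−2) are only coherent on a unit scale, and the source
  analysis declares cut-offs "indistinct" for LDA without stating the
  scale; percent/100 inputs are available via `scale="proportion"`.
* **Priors** default to empirical class frequencies; "equal" or explicit
  priors are configurable.
* **Ridge** ε = 1e-6 is added to the diagonal of `S` so collinear binary
  markers do not make it singular; ε = 0 raises an informative error.
* **Ties** go to non-GCB, consistent with the conservative merging of
  unclassified cases into non-GCB. The same tie-break applies to the
  Bayes classifiers at posterior exactly ½.

## Bayes family

All Bayes classifiers operate on panels binarized at one configurable
scheme (uniform 30% by default, since the source does not state the
discretization used for its ML features). The three structures are the
package's concrete reading of the loosely specified B / BS / BN family:

* **B** — joint-table Bayes: per-class empirical probabilities over all
  2^k patterns, α = 0, with a prior fallback (and warning) for patterns
  unseen in both classes; a guard refuses k > 10.
* **BS** — independence model with α = 0, failing over to α = 0.5 with a
  warning when a zero count yields a degenerate θ ∈ {0, 1}.
* **BN** — independence model with Laplace smoothing α = 1.

θ is estimated as (positives + α)/(n_c + 2α), the joint table as
(count + α)/(n_c + α·2^k). Posteriors are accumulated in log space. The
**PV preset** is BS over (1,3,4,5) — CD10, FOXP1, GCET1, MUM1, without
BCL6.

ANN and SVM structures are deliberately not implemented (their published
weights are unavailable); the harness accepts any scikit-learn estimator
through a plug-in adapter over binarized features, and the default
comparison grid fills its SVM/ANN slots that way (RBF SVC; one hidden
layer of 5 neurons for the perceptron, the recorded setting of the
source tool).

## Evaluation harness

Seven metrics from the confusion counts: Acc, Sens, Spec, PPV, NPV,
LR+ = Sens/(1−Spec), LR− = (1−Sens)/Spec. Metrics are kept at full
precision and rounded only in reports: several published LR cells cannot
be reproduced from their own rounded Sens/Spec, so internal rounding
would silently corrupt comparisons. Zero denominators yield an explicit
"undefined" (never 0); Spec = 1 with Sens > 0 yields LR+ = +∞.

Cohen's κ uses the marginal-product expected agreement; its p-value is a
Pearson chi-square on the 2×2 cross-table without continuity correction.
Bands: ≤0 no agreement, then poor / fair / moderate / good / very good
in 0.20-wide bands with inclusive upper edges. If both labelings are
constant and identical (expected agreement 1), κ is defined as 1.

Rankings sort by accuracy descending with alphabetical tie-break for
determinism. The comparison protocol splits a cohort 75/20/5 (stratified
on truth, floor-then-largest-remainder apportionment, all randomness
from one seed), trains trainable classifiers on the 75% and scores
everything on the merged 25% remainder; a resubstitution mode scores the
full cohort, matching how whole-database tree/LDA tables appear to have
been computed. On 475 cases the apportionment gives 356/95/24; the
exact 354/121 split reported for the reference database is not
derivable from the stated fractions and is not forced.

## Survival

Kaplan–Meier estimation and the two-sample log-rank test are delegated
to lifelines behind this package's interface: product-limit curves with
censored subjects kept in the risk set at their exact time, the log-rank
statistic from pooled hypergeometric moments at each distinct event time
(ties pooled, no continuity correction), chi-square with 1 df, α = 0.05.

## Synthetic cohorts

The generator reproduces the *structure* of the 475-case public
reference database: class ~ Bernoulli(0.486) (its GCB prevalence);
marker positivity conditionally independent given class with defaults
CD10 0.65/0.10, BCL6 0.85/0.55, FOXP1 0.35/0.80, GCET1 0.55/0.15, MUM1
0.15/0.85 (GCB/non-GCB) — chosen once so the germinal-center markers
favor GCB and FOXP1/MUM1 favor non-GCB at magnitudes that put the Hans
tree in the 0.80–0.95 accuracy band (analytically ≈0.86, bracketing the
0.85 reported for the real data) and reproduce the published LDF sign
pattern when refitted. Staining percentages are Beta-shaped on the
correct side of each marker's cut-off (positives in [cutoff, 100],
negatives in [0, 30)), so any binarization at 30–60% recovers the latent
flag exactly and Bayes parameter recovery is exact in expectation.
Survival is exponential per class (median 120 months GCB, 60 non-GCB,
i.e. hazard ratio 2, GCB better) under independent uniform censoring on
[0, 120]; non-GCB cases are labelled UC with probability 44/244. An
optional `marker_correlation` knob mixes a shared uniform latent into
the positivity draws to stress the joint-table classifier.

What the generator does **not** emulate: real marker covariance (IHC
stains co-vary through biology and assay batch), integer-rounded
scoring, missing stains, treatment heterogeneity, and non-exponential
hazards. Tests passing on synthetic cohorts therefore demonstrate
correctness of the algorithms and calibration of the harness under the
stated model — not field performance on clinical data, for which the
external reference database can be supplied as an ordinary cohort CSV.

## Problem sizes used in checks

Deterministic fixture checks are instant. Stochastic checks use: study
scale n = 475 for the end-to-end harness; n = 10,000 for prevalence and
LDA-vs-Bayes accuracy (two equal-covariance Gaussians, comparing with
Φ(Δ/2)); 2 × 20,000 cases for θ/π recovery (tolerance ±0.02); 2,000
null simulations of two censored exponential samples (n = 50 each) for
the log-rank type-I-error band [0.03, 0.07] at α = 0.05.

## Known limitations

* Tree cut-offs are transcriptions from the original publications;
  where later compilations disagree, the JSON is the single place to
  amend, and the built-in combinations are cross-checked at load time.
* The B/BS/BN naming maps to specific Weka structures only loosely; the
  implementations here are defined by their formulas above.
* Undefined metrics propagate as `None`; downstream tables show them as
  empty cells, which consumers should not coerce to 0.
* The published "25 possible combinations" count is not reconstructable
  (26 subsets of size ≥2 exist over five antibodies); the package
  supports arbitrary subsets and does not depend on that count.
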