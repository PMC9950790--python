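# Methods

## The screening model

The screen treats drug-combination discovery as binary classification of
unordered drug pairs. Known combinations are positives; because curated
non-combinations barely exist, the negative class is the (huge) set of
unannotated pairs, and the ~1:100 imbalance is handled by resampled
undersampling: R training sets, each containing every positive and
`ratio_neg_per_pos` (default 5) negatives per positive drawn uniformly
without replacement. One classifier is fitted per training set; a candidate
pair's score is its number of positive votes across the R members. The
protocol's full-scale defaults are R = 1000, 3×10-fold cross-validation, a
random forest with 300 trees, a 70% feature-retention cutoff, and a strict
">700 of 1000 votes" selection rule; every default lives in `RunConfig`.

All randomness flows from a single `master_seed` through
`derive_seed(master_seed, stage, index)` (SHA-256 of the token, reduced
below 2³¹), so any single resample, fold or fit is reproducible in
isolation.

## The 16 pair features

*Fingerprint.* Tanimoto similarity of binary fingerprint vectors (length
1024 by default). Fingerprints are inputs, not computed: the package accepts
any fixed-length bit-vector, which keeps the pipeline independent of any
particular fingerprinting software. An all-zero fingerprint is a degenerate
input (0/0) and is rejected.

*ADME.* Euclidean distance of min–max-normalized descriptor vectors. The
normalizer is computed once over the whole drug universe; a constant slot
contributes 0 after normalization (logged). The descriptor panel width K is
inferred from the drug-table header (default 12). Note this feature is a
dissimilarity; it is deliberately left on that scale.

*Sequence.* Smith–Waterman local alignment (Biopython `PairwiseAligner`,
BLOSUM62, gap open 10 / extend 0.5 by default). Raw local-alignment scores
are unbounded, so the similarity is sw(a,b)/√(sw(a,a)·sw(b,b)), which is 1
for self-comparison and bounded by Cauchy–Schwarz-style reasoning in
practice; a raw score below 0 is floored at 0. Per pair of drugs the
similarity is aggregated over all |A|×|B| target cross-pairs as
min/max/median/mean (median of an even count = mean of the central two).
Targets lacking a sequence are dropped from this family only.

*GO.* Wang's graph-based semantic similarity: S-values propagate through
child→parent edges with weights 0.8 (`is_a`) and 0.6 (`part_of`);
sim(x,y) = Σ_(t∈common ancestors)(S_x(t)+S_y(t)) / (ΣS_x + ΣS_y). Gene-level
similarity is the best-match average (BMA) over the two targets' term sets,
then aggregated over target cross-pairs like the sequence family. Wang's
measure was chosen because it needs no annotation corpus (information-
content measures do), making it self-contained on synthetic ontologies.

*Pathway.* The pathway universe is fixed per run: pathways over-represented
in the pooled target list of all drugs, by hypergeometric upper-tail p
(background = all known targets, including non-target PPI proteins) with
Benjamini–Hochberg q, both < 0.05, kept in stable input order. Each drug
gets a binary membership vector (bit k = 1 iff its targets intersect pathway
k); the feature is the cosine of the two vectors, defined as 0 when either
vector is all-zero (no shared pathway signal exists).

*PPI.* d(a,b) is the unweighted shortest-path distance on the interaction
graph. S_PPImin/max/med apply σ(d) = 1/(1+e^(−d)) to the min/max/median
cross-pair distance; S_PPImean applies σ to the mean cross distance; and
S_np = S_PPImean(A,B) − [S_PPImean(A,A)+S_PPImean(B,B)]/2. The within-set
terms use the same full |A|² ordered-pair mean (diagonal zeros included) as
the between term, so S_np(A,A) = 0 exactly and a singleton baseline is
σ(0) = 0.5. Disconnected target pairs receive d = diameter+1 (finite,
configurable to `drop-pair`). A `ppi_sigmoid_sign` switch ("as-printed" vs
"inverted-mean", default as-printed) controls the exponent sign of the mean
transform only, because published feature tables for this screen show a mean
transform in the opposite sigmoid regime from the min/max/median transforms;
the switch makes either reading available without guessing intent.

## Feature screening

Welch's unequal-variance t-test and the two-sided Mann–Whitney U test
(exact for small samples, tie-corrected normal approximation otherwise) run
once on positives vs the whole negative pool; a feature constant and
identical in both groups is degenerate and reported with p = 1. The RFE
stage mirrors the caret `rfe`/`rfFuncs` protocol: within each inner CV fold
the features are ranked once by random-forest importance, candidate subset
sizes 1..16 are scored by held-out accuracy, ties go to the smaller size,
and the final subset comes from a full-data ranking. The per-resample
selections over R training sets give per-feature frequencies; retention is
frequency ≥ cutoff (default 0.70, boundary inclusive). The ensemble then
trains every member on the globally retained subset — screening and
training are separate stages, not a per-member RFE.

## Evaluation

Stratified k-fold CV, repeated; confusion counts (threshold 0.5 on the
positive-class probability) and held-out scores are pooled over the folds of
one repeat; AUROC is the tie-aware trapezoid (equal to the normalized
Mann–Whitney U statistic) and AUPRC the right-continuous step integral of
the PR curve; the metric set reports mean ± sd over repeats (and over
members at the ensemble level). A 70/30 internal-validation holdout is
available via `eval_mode: holdout`. Zero-denominator rates are reported as 0
with a degenerate flag.

## Vote binning

With R = 1000 the printed cutpoints apply: >500, 100–500 (read as
(100, 500]), 1–100, and 0 votes; selection is strictly more than 700 votes.
For R ≠ 1000 the cutpoints rescale as the same fractions of R (0.5, 0.1,
selection 0.7R) so desk-scale runs keep four meaningful bins.

## Median-effect and combination-index math

fa/fu = (D/Dm)^m is fitted by least squares of log10(fa/fu) on log10(D)
after excluding zero doses and averaging replicate wells per dose. fa
observations are clipped into [0.005, 0.995] before the log transform (the
transform is undefined at 0 and 1); clips are logged, and a fit whose points
were all clipped, or whose slope is non-positive, is returned flagged
`degenerate` rather than raised. Dm = 10^(−intercept/m) equals the IC50;
report writers print "> max-dose" when Dm exceeds the tested range.
Dx = Dm·(fa/(1−fa))^(1/m); CI = D_A/(D_A)_x + D_B/(D_B)_x per combination
observation (one CI per dose pair, plus the per-pair minimum as a summary
column — no CI-vs-fa curve interpolation). Verdicts: synergistic (CI < 1),
additive (|CI−1| ≤ 1e−9), antagonistic (CI > 1). Log base 10 is fixed for
reported intercepts; (m, Dm) are base-invariant.

## Synthetic data

The generator emulates the statistical structure of the real inputs, not
their content: Bernoulli fingerprints (density 0.2), ADME slots coupled
through one latent factor per drug (pairwise-correlated, squashed into
per-slot ranges), uniform random amino-acid sequences (80–200 residues), a
GO DAG built as a random tree plus shortcut edges (80/20 is_a/part_of),
2–6 GO terms per target, 15 pathways of 4–12 targets, and a Barabási–Albert
PPI graph (200 nodes, attachment 2 — connected, scale-free-ish) in which the
60 targets occupy random nodes. Half the drugs are "pathway-focused" (most
targets drawn from one pathway), which makes pathway similarity genuinely
bimodal across pairs.

Labels are planted by a logistic model on z-scored true pair features,
default weights S_Pathway: 4, S_np: 2, with the intercept calibrated by root
finding so the marginal positive rate matches `base_rate` = 0.10. The rate
is set so a 20-drug universe (190 pairs, ≈19 positives) always leaves a
negative pool ≥ 5× the positives with comfortable margin. Because the signal
sits on real features, classifier and RFE recovery are meaningful checks —
but the generator does not mimic real chemistry: no SMILES, no real GO/KEGG
identifiers, no annotation-depth or degree biases of curated databases, and
fingerprint bits are independent rather than substructure-correlated.
Passing recovery tests therefore demonstrates that the protocol recovers a
planted signal of this shape, not that it would rank real drug pairs
correctly.

Dose–response simulation inverts the median-effect model (fa =
1/(1+(Dm/D)^m)) with multiplicative log-normal noise on fa, clipped to
[0, 1]. Combination rows with known ground truth solve for fa by Brent root
finding on CI(fa) = target (Loewe-additive: target 1; `fixed_ci`: any
target > 0) to ~1e−12; dose pairs that cannot reach the target inside
fa ∈ (1e−9, 1−1e−9) are flagged unachievable and skipped.

## Desk-scale configuration

The full-scale protocol (R = 1000 resamples of 2424 rows, 3×10-fold CV,
5-fold RFE with a 50-tree forest) is the `RunConfig` default. Recovery runs
and the acceptance script use `pipeline.toy_config`: R = 50 resamples on the
20-drug universe, 5-fold single-repeat member CV, and a 3-fold / 10-tree
forest inside the RFE. These sizes are the package's desk-scale choice: the
planted signal is strong enough that the screen's frequency ranking is
already saturated at this scale (S_Pathway is retained in essentially every
resample), and the whole ten-seed recovery study completes in minutes.

## Numerical choices and degenerate inputs

- Aggregate means/medians are clamped into [min, max] against 1-ulp drift.
- Pair identity is unordered; (a,b) is canonicalized by lexicographic sort,
  and featurization is symmetric by construction.
- Hypergeometric p uses the survival function at k−1 (upper tail including
  the observed overlap); zero overlap gives p = 1.
- Drug-table ADME values are written at 17 significant digits (exact
  round-trip); feature tables at 12 significant digits.
- RFE requires ≥ 20 rows, ≥ 2 features and both classes; CV requires each
  class to fill every fold.

## Known limitations

- The ADME panel's published description is ambiguous about its 12th
  descriptor; the package simply accepts K descriptor columns.
- The "as-printed" PPI mean transform maps all distances ≥ 0 to σ ≥ 0.5, so
  S_np ≥ −0.5 cannot reproduce strongly negative published proximity values;
  use `ppi_sigmoid_sign: inverted-mean` for that regime.
- Published benchmark metrics (e.g. mean CV AUROC of the full-scale screen)
  depend on proprietary real inputs and are not reproduction targets; the
  package validates arithmetic identities, oracle equivalences and
  planted-signal recovery instead.
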