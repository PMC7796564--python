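# Methods

## The problem

Drug-induced liver injury (DILI) is a leading cause of attrition in drug
development. A practical screening question is whether the DILI-concern
status of a compound (FDA four-class labelling: most / less / ambiguous /
no concern) can be predicted from two cheap data sources: transcriptional
responses of cultured human cell lines exposed to the compound, and
physicochemical descriptors computed from its structure. Both signals are
weak and high-dimensional, the class balance is skewed (roughly 3.3
concern compounds per no-concern compound), and the exposure data are
heavily replicated (several doses and incubation times per compound), which
makes naive cross-validation optimistic. `dilearn` implements the complete
modelling protocol for this setting and a synthetic-data generator that
reproduces its statistical structure so every stage can be tested without
any external download.

## Protocol overview

1. **Representative-sample selection.** Each (cell line, compound) pair may
   carry many exposure rows. One row is kept per compound: incubation time
   preferred in the order 24 h > 6 h > 48 h, then the highest available dose
   at the chosen time. This removes the replicate structure before
   compound-level modelling.
2. **Binary label aggregation.** The four concern classes are collapsed by
   one of five schemes; the default (scheme 5) treats classes 1–3 as
   DILI-concern and class 4 as no-concern. With the four-class counts
   (39, 90, 50, 54) this yields 179 positives and 54 negatives.
3. **In-fold feature filtering.** Inside every training fold, features are
   ranked — information-gain filtering for expression blocks, Welch t for
   descriptor blocks — and the 100 highest-scoring features per block are
   kept. Selection is rank-based rather than threshold-based because the
   expression signal is too weak for stable significance cut-offs.
4. **Base models.** A Random Forest per cell line on the early-integrated
   feature set: top-100 expression features of that line concatenated with
   the top-100 descriptors (block-prefixed ids, at most 200 columns).
   `restrict_features` optionally confines the expression universe to a
   user-supplied id list first (e.g. the ~978 directly measured landmark
   genes of an L1000-style assay, as opposed to the computationally
   inferred remainder); the list is an input, never hard-coded.
5. **Super learner.** Base models are cross-validated *internally* on the
   training set; their out-of-fold probabilities (averaged over internal
   repeats) form a meta-feature matrix on which a second-order combiner is
   fitted: best single model, mean of all, mean of the 5 best by internal
   AUC, a non-negative linear combination along the LDA direction, or an RF
   stacker.
6. **Nested evaluation.** The whole pipeline (selection, internal CV,
   combiner fitting) is re-run on every external training set and scored on
   the held-out external folds. The training-set AUC of each combiner is
   reported alongside as the deliberately biased reference; the
   internal-minus-external gap measures combiner overfitting.

## Models and estimators

**AUC** uses the Mann–Whitney pair formulation (ties credited 0.5),
computed via midranks; **MCC** the closed form on the 2×2 table with the
zero-factor → 0 convention and a 0.5 probability threshold. The expected
AUC range on new data is reported as `point ± 2·SD` of the repeated-CV AUC,
clipped to [0, 1].

**Welch ranking** scores each feature by |t| of the unequal-variance
two-sample test with Welch–Satterthwaite degrees of freedom; features
constant in both classes score 0 with p = 1.

**Information-gain filters.** A feature is discretized at `bins − 1` cut
points drawn uniformly from its empirical range; the 1D score is
`IG = H(y) − H(y | X_binned)` in bits, averaged over `n_discretizations`
independent draws (default 30, `bins = 2`). P-values use the G-test
identity `G = 2·n·ln2·IG` against chi-square with `bins − 1` df. The 2D
score of feature i is `max_j [IG(y; X_i, X_j) − IG(y; X_j)]` with the
per-pair conditional gain averaged over draws *before* the maximum
(lower-variance than maxing per draw), partners restricted to the top-200
1D features for tractability, and chi-square df `bins·(bins − 1)`. The
randomized-cut-point scheme makes the filters sensitive to non-monotone
univariate signal (1D) and to pure interactions such as XOR pairs (2D),
which marginal tests cannot see. The G-test calibration applies to a
single discretization; averaging over draws makes it mildly conservative,
which is acceptable because downstream selection uses ranks, not p-value
thresholds. `estimate_fdr` provides a BH-type expected-FDR estimate of a
rank cut for diagnostics only.

**Fold construction** is a seeded round-robin deal: entities (rows, or
whole compounds in grouped mode) are shuffled per class and dealt to folds
with a rotating starting fold, giving per-fold class counts within ±1 and
balanced fold sizes by construction. Per-repeat seeds derive
deterministically from the master seed. A class with fewer than k members
triggers a fallback to plain shuffling with a warning. Grouped
("clustered") plans assign all replicates of a compound to one fold and are
the defence against replicate leakage.

**nn_linear combiner.** The pooled within-class covariance direction
`w ∝ Σ⁻¹(μ₊ − μ₋)` with ridge `ε = 1e-6·trace(Σ)/B`, negative components
clipped to zero and the rest normalized to sum to 1; an all-nonpositive
direction falls back to uniform weights with a warning. The meta-features
the combiners see are averaged over internal repeats before fitting.

## The synthetic generator

All features are unit-variance Gaussian noise. Informative features gain a
mean shift of `d` standard deviations for compounds in the positive binary
super-class (classes 1–3). Replicate rows of a compound share a latent
vector: `x_rep = √ρ·z_compound + √(1−ρ)·ε`, so replicate pairs correlate at
ρ while total variance and the standardized shift are preserved. Dose and
time labels carry no systematic effect of their own; they exist to exercise
representative selection and the leakage mechanism.

Defaults emulate the study design: 233 compounds with class probabilities
(39, 90, 50, 54)/233; 13 expression blocks of which the first five are
informative with 50 informative features each at `d = 0.3` (the leading
block 1.6× stronger, playing the MCF7 role); a moderately informative
descriptor block (50 of 300 features at `d = 0.5`); replicates over 2 doses
× 3 times with ρ = 0.5. Desk-scale dimensions are 1000 expression features
per block and 300 descriptors (the real study has 12328 and 1660); full
sizes are reachable through the config. ρ is not reported by any study of
this kind that we rely on; it is a free parameter whose default (and the
0.9 used in the leakage experiments) reproduces the qualitative
pooled-vs-clustered CV contrast.

What the generator does **not** emulate: gene–gene correlation beyond the
shared compound latent, the landmark/inferred-gene structure of L1000-style
assays, heavy-tailed descriptor distributions, or any dose–response trend.
Consequently, passing tests demonstrate correctness of the machinery and
the qualitative phenomena (leakage inflation, ensemble benefit, stacker
overfitting, chance-level null calibration) — not the absolute performance
attainable on real data. In particular, at desk-scale dimensionality the
planted signal is easier to find than in the real 12k-dimensional data, so
absolute AUCs on synthetic bundles run higher than anything a real
cell-line panel would give.

## Problem sizes and numerical choices

The heavy experiments are run at desk scale as the package's default test
conditions: nested evaluation uses 10-fold external CV with 2 repeats (10
for the ensemble-benefit analysis, where the paired t-test needs repeats)
and 5-fold × 1 internal CV, with 50-tree forests; the leakage experiment
uses 10-fold CV and 100-tree forests. Forest size mainly adds Monte-Carlo
smoothing here; rank-based selection and AUC comparisons stabilize well
below the 500-tree library default. All randomness flows from explicit
seeds; fold plans, filter draws and forests derive their streams from the
master seed, so every reported number is bit-reproducible.

Degenerate cases are handled explicitly rather than by exception where a
sane value exists: single-class training folds predict their constant
class; AUC raises on single-class inputs (undefined); MCC returns 0 on any
zero margin; enrichment reports an infinity flag instead of a ratio when a
class is absent from the high-risk half; ranking ties break lexically by
feature id so every ordering is deterministic.

## Known limitations

* The 2D filter's partner loop is O(p · K) per discretization draw; it is
  meant for focused interaction queries, not for routine filtering of
  10k-feature blocks.
* The G-test p-values of the information filters are calibrated for one
  discretization draw and become conservative when gains are averaged;
  rank-based selection is unaffected.
* The enrichment split assigns the extra compound of an odd-sized cohort to
  the high-risk half; with tiny cohorts this choice is visible.
* Transferability compares rankings computed on the full data (by design —
  the question is ranking similarity, not generalization), so its overlap
  counts are not cross-validated quantities.
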