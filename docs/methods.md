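# Methods

## Problem and model

The package ranks doctors within a disease category by aggregating m=10
feature-induced rankings without supervision. Reliable ground-truth
rankings of doctors do not exist at scale, so the aggregation relies on
an internal-consistency principle: a feature whose ranking sits close to
the consensus of all features is treated as informative, one that
deviates as noisy.

Formally, each z-normalized feature column induces a ranked list πᵢ
(descending scores, average ranks on ties). The consensus is the
unweighted mean ranking π̄(d) = (1/m) Σᵢ πᵢ(d), the per-feature
inconsistency is the mean squared rank deviation
σᵢ = (1/n) Σ_d (πᵢ(d) − π̄(d))², and the weights minimize

  J(w) = Σᵢ wᵢ² σᵢ  subject to  wᵢ ≥ 0, Σᵢ wᵢ = 1.

The KKT solution is wᵢ ∝ 1/σᵢ (mass split uniformly over zero-σ features
if any); a projected-gradient solver is provided as an alternative and
agrees with the closed form wherever all σᵢ > 0. Final scores are
F(d, c) = Σᵢ wᵢ fᵢ(d, c) in feature space, and the output ranking sorts F
descending with average-rank ties, breaking residual ties by doctor id.

**Why the consensus is unweighted.** Re-estimating π̄ with the learned
weights and iterating looks like a natural refinement, but the coupled
iteration has degenerate attractors: the consensus drifts toward the
currently best-weighted feature, that feature's σ falls toward zero, and
its weight toward one, collapsing the aggregate onto a single list. The
quadratic objective against a *neutral* consensus keeps every feature's
inconsistency measured on the same yardstick and has a unique interior
solution. The iteration controls (`tol`, `max_iter`) therefore govern
only the projected-gradient solver.

**Assumptions.** (i) A majority of features rank approximately with true
expertise, so the consensus is anchored to the signal — with mostly
adversarial or mutually correlated noise features, consistency weighting
can amplify the wrong cluster. (ii) Rankings are comparable across
features after z-normalization (population SD; zero-spread columns map
to zeros and drop out of F). (iii) Linear score aggregation suffices;
no interactions between features are modeled.

## Expertise labels

Sparse manual labels (doctor, category, value ∈ [0,1]) are diffused over
the coauthorship network by normalized-adjacency diffusion with restart,
L ← αSL + (1−α)Y, S = D^(−1/2)AD^(−1/2). Defaults: α = 0.85, tol = 1e-6,
max_iter = 1000, seeds clamped after every sweep (manual labels are
trusted exactly). Isolated unseeded nodes stay at 0; isolated seeded
nodes keep their clamped value. Non-convergence returns a flagged
result rather than raising. The unclamped fixed point solves
(I − αS)L = (1−α)Y, which doubles as the test oracle. Multiple networks
(e.g. coauthorship plus a citation graph) combine by convex combination
of edge weights, equal weights by default; learning those weights is out
of scope.

## Feature conventions

* Academic title encodes 0–3 (none → full professor), professional
  title 0–5 (none → chief physician), hospital level 1–9 with grade
  dominating class (GI-C = 1 … GIII-A = 9); only the extremes of that
  scale are externally fixed, the grade-major total order is a design
  choice.
* Social recognition: 0 without a social network or with 0 fans, else
  ⌊log₁₀ fans⌋ + 1 — the unique simple rule through both anchor points
  (20 → 2, 100 → 3) that extrapolates by decade.
* Citation score defaults to "number of the doctor's publications in the
  category cited at least once in-corpus" (the literal reading), with a
  `total_citations` mode; only in-corpus links are counted.
* Doctors with no reviews in a category score 0 (not the global mean):
  deterministic, and after z-normalization a mild penalty for being
  unreviewed.

## Synthetic corpora

The generator plants latent quality q(d,c) = (1−s)·skill(d) + s·z(d,c)
with skill, z ~ Beta(2,2) and spread s = 0.5 by default, then emits
every observable as a noisy monotone transform of q. Defaults
(200 doctors, 5 categories, ~600 publications, 20 hospitals, 5 reviews
per doctor, 20% seed labels, 2% stars, noise SDs 0.15–0.5 on the quality
scale) are the study conditions used throughout the tests; they aim at
a desk-scale corpus with clearly detectable but far-from-clean signal,
not at national-registry magnitudes.

Structure emulated: review levels concentrate at 8–9 for high quality
and at 1 for low quality, with a thin noise-dependent middle band
(patients review at the extremes); follower counts are log-scaled in
skill over 10–10⁴ with a star multiplier ×100; profile fields are
quantile bins of noisy skill; publications are materialized per category
by packing per-doctor authorship counts a(d,c) = round(scale·q̃) into
papers of ≤3 authors within blocks of three consecutive doctors in
(count, quality)-sorted order — a block with counts A ≥ B ≥ C yields C
three-author, B−C two-author and A−B solo papers, so each doctor's
publication count is realized *exactly*. Papers whose every author
clears the median authorship count get cited (1 + 2·q̄ round-robin
citers), concentrating citations on high-quality collaborations.

This block construction is what makes the zero-noise regime provable:
blocks are contiguous in sorted count order, so a higher block's minimum
count is at least a lower block's maximum, and both the distinct-coauthor
count (0, 1 or 2 by block pattern) and the thresholded cited count are
non-decreasing along that order. At zero noise
(`SyntheticConfig.zero_noise()`: all noise SDs 0, spread 0, complete
exact seed matrix) every feature is a deterministic non-decreasing
transform of a single per-doctor skill, working years is strictly
increasing (kept at full float precision for exactly this reason), and
hence F is strictly increasing in quality: the aggregate ranking, the
planted KOL set and NDCG@K = 1 are recovered exactly. The degenerate
regime collapses category specialization deliberately — per-doctor
profile features cannot track per-category quality when categories are
decorrelated, so "every feature agrees with the planted order" is only
attainable in a single-skill world. Integer-valued features necessarily
tie nearby doctors, so "agrees with the planted order" is asserted as
zero discordant pairs (Goodman–Kruskal γ = 1), not tie-sensitive τ_b.

What the generator does **not** emulate: journal prestige, temporal
publication dynamics, multi-category papers, correlated measurement
error across features, adversarial review campaigns, and name ambiguity
beyond formatting noise. Passing tests show the pipeline recovers
planted monotone structure under independent per-feature noise; they do
not certify performance on real corpora with correlated or adversarial
noise.

The noise-ordering experiments use matrices whose columns are direct
noisy copies of planted quality (`noisy_feature_matrix`), five columns
with SDs log-spaced 0.05–0.5 (a 10× span, five levels kept well
separated on a ratio scale). Corpus observables pass through
heterogeneous transforms (ordinal binning vs continuous), so "the noise
level of feature i" is only well-defined in this controlled design.

## Record linkage

Doctor identity is (normalized name, hospital, normalized specialty);
normalization is NFKC + lowercase + punctuation stripping + whitespace
collapse (transliteration of source scripts is out of scope). Conflicts
resolve field-wise by source priority, then most recent source date,
then stable input order; absent values lose to present ones, and merges
never invent values. Ambiguous author→doctor matches are dropped and
logged rather than guessed — a false merge contaminates every
publication-derived feature of both doctors. Dates with missing day or
month precision snap to the first of the period.

## Evaluation

NDCG uses exponential gain (2^g − 1) and log2 discount, 0 when the ideal
DCG is 0. Graded judgments binarize at grade ≥ 3 for the binary metrics;
review-derived relevance marks mean level ≥ 8 relevant and ≤ 1
irrelevant, excluding the sparse middle band (both thresholds
configurable). Judgment-based ground truth takes the top 30 doctors by
mean judgment score. Planted graded judgments bin quality at quantiles
(0.50, 0.75, 0.90, 0.97) into grades 0–4 so grade 4 is rare, mirroring
"definite expertise". The Borda baseline is the unweighted mean-rank
consensus over the same lists the aggregate uses.

## Known limitations

* Consistency weighting is consensus-seeking: a bloc of mutually
  correlated weak features can outvote a single excellent one.
* σ compares rankings, not scores; two features with equal rankings but
  very different score gaps are indistinguishable to the weighting.
* The label-propagation variant and α are conventional choices; other
  diffusion kernels would change the expertise-label feature.
* In-corpus citation counting undercounts authority for doctors cited
  mainly from outside the corpus.
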