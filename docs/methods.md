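# Methods

This note documents the models, statistics, numerical choices and known
limitations of the package, stage by stage.

## Atlas identity mapping

**Model.** The identity of a query transcriptome is defined operationally:
the (region, stage) category of a reference atlas whose samples correlate
most strongly with the query. Correlation is Spearman's ρ computed from
within-profile gene ranks after the query and atlas are restricted to
their shared genes (default floor 500 shared genes; configurable). Because
only ranks enter, the pipeline is invariant under any strictly increasing
transform of any single profile — normalization differences between
platforms (the usual worry in cross-platform comparisons) change nothing
downstream, which is the reason this design is standard for atlas
comparisons.

**Category scoring.** For each query, the ρ values of each category are
compared with the background of *all* paired correlations for that query
using a one-sided Wilcoxon rank-sum test ("is this category's correlation
stochastically higher than the background?"). Two readings of
"background" are supported: inclusive (the category's own pairs stay in
the background; default) and exclusive. For categories that are small
relative to the atlas the two differ negligibly (tests assert rank-order
agreement and r > 0.99 between the two score vectors); the inclusive
default follows the literal protocol description. Scores are reported as
−log₁₀ p; the conventional significance line p = 0.05 prints as 1.30. No
multiple-testing correction is applied inside the map (the heatmap
convention is raw −log₁₀ p); a Benjamini–Hochberg q-value column is
emitted alongside for users who want calibrated calls across the 48
category cells.

**Rank-sum p-values.** The exact permutation null is enumerated by
dynamic programming when the pooled sample has ≤ 25 values and no ties;
otherwise a normal approximation with tie correction and 0.5 continuity
correction is used. The inclusive background duplicates the category's
values in the pooled sample, which always produces ties, so the mapping
stage effectively runs on the tie-corrected branch; the null-calibration
acceptance test confirms the resulting p-values are uniform under label
exchangeability (KS at α = 0.01 over 1000 independent replicates,
empirical type-I error within [0.04, 0.06]).

**Replicate handling.** Default is one identity map per query sample. A
pre-averaging mode collapses biological replicates by mean before ranking
— the appropriate mode when the deliverable is one heatmap column per
cell line from sequenced triplicates, and the mode used by the
category-recovery acceptance run. Averaging √3-reduces query noise and
raises recovery at the hardest planted-effect settings from ~93% to ~99%.

## Synthetic atlas generator

Baseline log₂ expression per gene is Normal(6, 2), shared by all samples;
rank-based downstream stages are indifferent to this choice. Each
(region, stage) cell owns a disjoint signature of `signature_size` genes
shifted up by `effect` log₂ units in that cell's samples; residual noise
is Normal(0, `noise_sd`) per gene and sample; linear values are 2^log₂.
Defaults: 4 regions × 12 stages (pcw8–pcw37, mo4, yr1), 3 replicates per
cell, 50-gene signatures, effect 2.0, noise 1.0 — a planted 4-fold
signature over unit log-fold noise, i.e. a clear but not overwhelming
regional program, at the effect = 2 × noise boundary the recovery
guarantee is stated for.

The default gene count is 2400 = 48 × 50: the gene space is exactly
partitioned into the category signatures. This models the *informative*
gene space — genes that belong to some category's co-expressed set —
rather than a whole transcriptome; it matters because recovery power is
governed by the signature fraction of the ranked profile. Genes outside
every signature only dilute the signal, and cross-platform intersection
in real analyses similarly concentrates the gene set. What the generator
deliberately does not model: the covariance structure of real atlases,
batch and donor effects, count-distribution noise, or stage-to-stage
autocorrelation of expression programs. Passing recovery tests therefore
demonstrate the statistical machinery, not performance on real data,
where adjacent stages are far more correlated than the independent
signatures simulated here.

## LFQ proteomics contrast

**Filtering and transform.** Rows flagged contaminant, reverse or
only-identified-by-site are dropped (counts logged per flag); intensities
are log₁₀-transformed; zeros in the input are coerced to missing with a
warning, matching the convention that 0 means "not quantified" in
MaxQuant exports.

**Testing.** Per protein, a two-tailed pooled-variance Student's t-test
between the two groups, requiring ≥ 2 quantified values per group (the
minimum for a variance estimate; no imputation — proteins below the floor
are excluded and counted rather than filled in). Welch's form is
available by flag. The volcano call is strict: significant ⇔
−log₁₀ p > 1.30 ⇔ p < 0.05; a protein exactly on the threshold is not
called. A BH q-value column is emitted for reference; the volcano itself
uses raw p, per field convention for these plots.

**Exclusivity.** Detected in ≥ 2 samples of one group and 0 of the other
(presence = non-missing, non-zero). Such proteins cannot be t-tested (one
group has no variance estimate), so the t-tested set and the exclusive
sets are disjoint by construction — the partition invariant the tests
assert.

**ORA.** Upper-tail hypergeometric p = P(X ≥ k | N, K, n) with enrichment
ratio (k/n)/(K/N). The universe defaults to the post-filter quantified
proteome (detected-background practice), not the genome; configurable.
Sets with K < 5 members in the universe are dropped.

**Synthetic LFQ.** Log₁₀ intensities Normal(mean ~ N(7, 0.8), sd 0.25);
3 samples per group; 50 differential proteins shifted +0.6 log₁₀ (~4-fold)
in group A; 20 exclusive proteins per group (fully detected in their
group, never in the other); 10% random detection dropout elsewhere; 5
flagged rows per flag kind, disjoint from all truth sets. Dropout is
repaired so that every non-planted row keeps at least one detection per
group — without this, ~2 background rows per 2000 satisfy the exclusivity
rule by chance (0.1³ ≈ 10⁻³ per group) and the ground-truth labels stop
being unambiguous. The Monte-Carlo power oracle in the acceptance suite
simulates exactly this detection model.

## Assay quantification

**qRT-PCR.** Technical replicates are averaged first. Relative quantity =
efficiency^−(Ct_gene − Ct_HK), with Ct_HK the arithmetic mean Ct of the
housekeeping genes — identical to the geometric mean of per-gene
quantities at a single fixed efficiency, so both naming conventions select
one code path. Efficiency defaults to 2.0 (the ΔΔCt convention); per-run
values are configurable. Two normalizations are distinct and both
provided: *cross-line anchoring* divides by a reference line's quantity in
the same condition (reference line ≡ 1 everywhere; used to compare lines
within a condition), and *fold over baseline* divides each line's
un-anchored quantities by its own baseline condition (the ΔΔCt induction
fold). Note the two do not compose: a condition effect shared by all lines
cancels out of the anchored values, which is why the fold computation
starts from `reference_line=None` quantities.

**Densitometry.** Band / loading-control ratio, rescaled to a reference
lane (≡ 1). Invariant to global rescaling of either intensity channel.

**Viability.** percent(t) = 100 × (S(t) − S̄_neg(t)) / (S(0) − S̄_neg(0)),
where S̄_neg is the mean detergent-killed negative-control signal at each
timepoint. The floor subtraction treats the negative control as the
zero-viability signal level; it is an interpretation (the protocol only
designates the negative control) and can be disabled, leaving a plain
rescale to the t = 0 signal. A plate whose baseline does not exceed the
floor is rejected as degenerate rather than silently producing negative
percentages.

**Group statistics.** Means and s.e.m. are computed over biological lines
— never over technical replicates, which are averaged beforehand. Two or
more groups are compared by pooled t or one-way ANOVA with all pairwise
post-hoc t comparisons corrected by Holm–Šídák (default; Bonferroni and
Benjamini–Hochberg available). The correction method used is logged with
every run.

## Problem sizes and determinism

All stochastic behaviour flows from explicit integer seeds;
`numpy.random.default_rng` streams make every generator a pure function
of its spec. The acceptance script runs: 1000 independent null atlases at
800 genes × 96 samples for calibration, 100 runs at generator defaults
(2400 × 144) for recovery, one 2000-protein LFQ fixture plus a
10,000-replicate power simulation, and the oracle sweeps (1000 Spearman
vectors, all rank-sum splits to pooled n = 10, six hypergeometric
configurations, 25 t cases). These sizes put Monte-Carlo error well below
the decision margins of each check while the full run stays around one
minute on a single core.

## Known limitations

- The Wilcoxon normal approximation is least accurate for category sizes
  of 1–2 against large backgrounds; calibration at the default 2–3
  replicates per cell is verified empirically, but single-sample
  categories should be interpreted with care.
- The exclusivity rule is a hard presence/absence dichotomy; near-misses
  (one stray detection) are invisible to it, as in the original protocol.
- ORA assumes exchangeability within the universe; with a detected-
  proteome universe, abundance-dependent detection bias is not modelled.
- The generators produce independent Gaussian noise; none of the
  correlated structure of real transcriptomes or proteomes is simulated,
  so the recovery guarantees are statements about the statistics, not
  about biological data.
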