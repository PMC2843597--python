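# Methods

## Coordinate conventions and alignment handling

All coordinates are 0-based, half-open, forward-strand.  MAF start/size
records are converted on read; reverse-strand rows are normalized to
forward coordinates at load time (the analysis never needs strand-aware
projection — both the synthetic maps and collinear orthology maps from
whole-genome aligners satisfy this).  Blocks overlapping within a genome
are an error rather than being merged: overlap means ambiguous orthology,
and peaks in such regions must not enter gain/loss denominators.  Peaks
falling in unaligned or ambiguous regions are classified `unalignable`
(aligned-coverage fraction of the 100 bp window below 0.5, configurable)
and excluded from all denominators; this replaces an explicit
duplicated-sequence screen with the same intent.  `column_stats` computes
identity over match/mismatch columns only, and counts indel *events*
(maximal gap runs in either row) per spanned column, since insertion and
deletion frequency is an event rate, not a gap-column fraction.

## Signal model

Each mapped tag contributes +1 coverage over `fragment_length` bases
extending 3′-ward from its 5′ end, truncated at chromosome ends; without
truncation total coverage is exactly `n_tags × fragment_length`.  Tracks
are stored at single-base resolution so downstream window maxima are
bit-exact; bedGraph export is run-length encoded.

Normalization has two stages.  Library-size scaling multiplies a track by
`target/actual` total tags; the target defaults to 10,000,000 (a fixed
round number — the analysis depends only on its being identical across
experiments, and it is exposed as a configuration value).  Comparative
scaling then regresses reference anchor strengths on the other genome's:
`s = Σmᵢyᵢ / Σyᵢ²` minimizes `Σ(mᵢ − s·yᵢ)²`.  The anchor set is the
top 50 target-gene-proximal peaks per genome, each expressed as a
(reference, other) strength pair through the alignment, unioned with
duplicate pairs removed — a reference-genome top peak and an other-genome
top peak that project onto each other enter once.

## Peak comparison

Summits are recomputed from the track as the leftmost argmax within the
called span; strength is the window maximum, so the spatial resolution of
the comparison is 50 bp.  The absence rule is inclusive: ortholog signal
`y ≤ m/10` (zero included) marks a peak absent.  Absence percentages are
reported to one decimal with standard rounding.  Target-gene proximity is
summit-to-5′-end distance ≤ 10 kb, inclusive, strand-aware.  Cohort
curves use overlapping cohorts of 250 peaks at stride 25 (the stride is a
smoothness/cost trade-off and configurable), ordered by reference-genome
binding rank; a trailing partial cohort is dropped, and fewer values than
one cohort collapse to a single cohort.

## Word discovery

Every k-mer is tested independently; a word and its reverse complement
share one instance set and are reported once (canonical form).  A word
instance must lie fully inside the 100 bp window and contain no softmasked
base.  An instance is conserved iff its k columns are aligned, gap-free,
contiguous within one block, and the orthologous bases spell the identical
word; any gap or substitution (or lack of alignment) makes it diverged —
"exactly conserved" cannot include indels.  A peak with j instances of a
word contributes j copies of its divergence value (instances are pooled,
not deduplicated; documented choice).  The divergence value is the
normalized strength difference (reference − other) in both calling
directions; only the peak set and the conservation direction flip.  Words
need at least 20 instances in each class to be testable (`min_count`,
configurable — KS on near-empty classes is meaningless).  Significance is
KS p < 0.01 per direction with no further multiple-testing correction;
the bidirectional intersection is the only additional filter, matching
the procedure the package implements.  The KS p-value uses the exact
small-sample distribution when sample sizes permit and the asymptotic one
otherwise; at the scan's typical class sizes this keeps the null rejection
rate at p < 0.01 within 1% ± 0.3% (verified by simulation in the test
suite).

### PWM matching

The Patser-style p-value of a word against a PWM is computed exactly: for
each offset and strand, the word's log-odds score over the k aligned
columns (`Σ ln(f_{b,i}/q_b)`) is compared with the full distribution of a
random background k-mer on those columns, obtained by dynamic programming
over integer-discretized column scores (bin 10⁻³).  Background is uniform
0.25 and the pseudocount 0.01 per cell before renormalization; these are
recorded in output metadata since the original tool's defaults are not
part of the published procedure.  `ln p < −4` declares a specificity
match; enumeration of all k-mers below `ln p < −8` reuses the same
scorer with per-offset tail tables.

## Divergence model

Features are signed instance-count differences (reference window minus
orthologous window) per DDW; multiple gains in one peak add.  Rows are
all matched peaks with at least one DDW instance in either genome — a
peak whose counts balance (equal in both species) stays in the table with
a zero feature, since "at least one instance in the two genomes" is a
presence condition, not a nonzero-difference condition.  The response is
the normalized strength difference (m − y), the same quantity the word
scan distributes; fractional divergence is available as a hook.  Columns
are standardized internally and coefficients back-transformed; the
intercept is unpenalized (divergence need not be mean-zero after
normalization).  The full lasso path comes from least angle regression
with the lasso modification; cross-validation evaluates each fold's path
on a common β grid (union of path breakpoints plus 100 log-spaced points)
and picks the β with minimum mean MSE, ties toward the sparser model.
Folds are a seeded unstratified permutation; the response is not
standardized.  Shuffled-word controls permute each word's nucleotides
(composition preserved), re-drawing on collision with the original or
another word, bounded retries (a homopolymer is kept as is).

## PCA

Union regions merge overlapping 100 bp windows across factors; the
representative window is centered on the strongest contributing summit.
Matrix values are linear-scale strengths (species modes) or signed
fractional divergence per factor (divergence mode); a log1p hook exists
for the species modes since whether near-zero strengths should be floored
or log-transformed is an open choice.  Columns are centered and scaled to
unit population variance; components come from SVD, with explained
fraction σᵢ²/Σσⱼ² and a deterministic sign convention (largest-magnitude
loading entry positive) so results are reproducible.  Coherence controls
permute one factor's column (or all columns independently) across rows
with a seeded generator.  Component-projected word discovery replaces the
per-peak response with the component score over the union windows, both
directions; other-genome windows are 100 bp windows centered on the
midpoint of each region's projected span, skipping regions under 50%
aligned.

## Synthetic data generator

The generator defines the study conditions; its defaults are fixed, not
tuned.  An ancestral chromosome concatenates, per peak, a 300 bp
softmasked spacer and a 500 bp window whose central 100 bp core carries
planted words: one distinct heptamer per factor (Poisson rate 0.5 per
core) and a shared-term heptamer CAGGTAG (rate 0.3), placed without
overlap.  Both lineages mutate independently: per-base substitutions at
0.05 (giving pairwise identity (1−p)² + p²/3 ≈ 0.90, the two-species
regime the analysis targets), indel events at 0.005 per site with
geometric lengths (mean 2), equal insertion/deletion probability.  The
alignment is taken from the edit history — no aligner is invoked — which
gives projection and conservation an exact oracle; it is emitted as one
MAF block per region.

Log binding is `log B = μ + λ·c + Σ a·n + ε` with baseline μ = 3, shared
term loading λ = 1, word effect a = 0.4 log-units per instance, noise
σ_ε = 0.3.  The shared term is `c = c_peak + Δc_species + γ·n_common`
with σ_c = 1.0, σ_Δc = 0.3, γ = 0.5 per shared-word instance — the
latent "chromatin" mode that makes all factors move together.  Word
counts n are recounted from the emitted sequences (both strands,
softmask-aware), so truth is always consistent with the files.  Tags are
Poisson with mean 2·B per peak (0.6× in the second species, exercising
library-size correction), triangular positional falloff of half-width
150 bp around the true summit, random strand, fragment length 225.
Fifty designated peaks get a pseudo target gene 200 bp upstream of the
window, exercising proximity annotation and the normalization anchors.
All randomness flows through one seeded generator and the seed is written
into every output header; regeneration is byte-identical.

What the generator does **not** emulate: mappability and GC bias,
duplicated sequence, chromatin-driven fragmentation differences,
background (non-peak) tags, peak-calling noise, and realistic gene
density (target genes are denser around peaks than in a real genome, so
proximity flags cover a larger fraction of peaks than in real data).
Passing tests therefore demonstrate correctness of the statistical
machinery under the generative model, not robustness to those artifacts.

## Benchmark problem sizes and checks

The validation suite and the reproduction script run at n = 2,000 peaks
per dataset (the scale of a per-factor peak set in the motivating
system).  Word recovery runs 12 seeded datasets × 6 factors at k = 7; a
run's discovery is counted correct when the factor's planted word is in
the final set, and a discovered word is a false positive only when it
shares no ≥ k−1-base single-shift overlap with the factor's word or the
shared word — one-off "shadow" variants of a planted word carry genuine
turnover signal (their instances coincide with the planted word's) and
are the word-family structure any k-mer scan produces, so counting them
as false would mislabel true signal.  KS calibration uses 10,000
same-distribution pairs of sizes 30/40.  Comparative-scale recovery
plants a global factor κ = 1.7 with 1% multiplicative anchor noise.  The
planted first-component share is computed in closed form for the
standardized log-binding matrix of one species via the equicorrelation
identity (leading-eigenvalue fraction (1 + (p−1)ρ̄)/p for p factors),
with word-count variance approximated as survival-thinned Poisson
planting plus the random-occurrence background; the check runs PCA on the
true log-binding matrix, where that quantity is defined.

## Known limitations

* Alignment accuracy masking (down-weighting uncertain columns) is not
  implemented; all aligned columns count equally.
* Only two-species alignments are supported, by design.
* The generator's binding model is log-additive with Gaussian noise;
  saturation and cooperative effects are out of scope.
* The divergence model is linear in count differences; interaction terms
  and PWM-score features are intentionally excluded (matching k-mers at a
  PWM threshold and reusing the same model covers the PWM-derived-words
  comparison).
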