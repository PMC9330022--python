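# Methods

## The design and its factor decomposition

The package assumes a balanced reciprocal-transplant layout: two breeds
(`TIB` high-altitude native, `PX` low-altitude native) × two rearing
environments (`HIGH`, `LOW`) × up to four tissues × n replicates
(default 3). Group labels (`TC`, `LTC`, `HLC`, `LC`) are always derived
from (breed, env), never assigned independently, and the screen's
effective/ineffective comparison structure is likewise derived from
(breed, env) differences at run time rather than hard-coded: a
comparison carries the environment factor iff its groups differ in
rearing environment, the breed factor iff they differ in breed, and the
experimental-error factor always. Tissues are screened independently
and never pooled.

## Differential expression

**Normalization.** Trimmed mean of M-values against a reference sample
(the one whose 0.75-quantile scaled count is closest to the across-sample
mean). 30% of M-values and 5% of A-values are trimmed from each tail;
surviving M-values are averaged with inverse asymptotic (delta-method
binomial) variance weights; factors are rescaled to geometric mean 1.
Trimming is rank-based with average ranks, so tied M-values move in and
out of the trimmed set together. CPM uses effective library sizes
(library size × factor); the log variant is
log2((y + p_s)/(N_s + 2 p_s)·10⁶) with the prior count p (default 2)
scaled by each sample's relative library size.

**Dispersion.** A single common negative-binomial dispersion φ
(Var = μ + φμ²) is estimated by conditional maximum likelihood on
pseudo-counts scaled to the geometric-mean effective library size: for a
group of n replicates with equal means, the split of the group total is
negative-hypergeometric with per-sample size 1/φ, and its likelihood is
free of the mean. The likelihood is maximized on a log grid
(10⁻⁴…10) and refined by bounded scalar optimization; estimates below
2·10⁻⁶ are reported as 0. A common (not tagwise or trended) dispersion
was chosen deliberately: it is the simplest member of the NB-testing
family and the only one whose conditional distribution admits an exact
brute-force enumeration oracle, which the test suite exploits.

**Exact test.** Counts are scaled to a common effective library size;
the rounded group sums (k_A, k_B) are referred to the conditional
distribution of the group-A sum given the total t = k_A + k_B, which is
negative-hypergeometric with sizes n_A/φ and n_B/φ (Binomial(t,
n_A/(n_A+n_B)) in the Poisson limit φ = 0). Two-sided p-values use the
doubled-tail convention — twice the smaller of the lower/upper tail
probabilities at the observed split, capped at 1 — chosen among the
common conventions for its oracle simplicity; under the null the
convention is calibrated (measured type-I rate ≈ 0.045–0.055 at
nominal 0.05 on the synthetic data). log₂FC is the ratio of normalized
group means with a prior count of 0.125; log₂CPM uses a prior of 2.
Both priors exist purely to stabilize zero counts.

**Calling.** DEMs: |log₂FC| ≥ 1.5 AND log₂CPM strictly > 2 AND
Benjamini–Hochberg FDR ≤ 0.05 (boundary semantics are intentional:
fold-change and FDR bounds inclusive, abundance bound strict). DEGs: a
Welch two-sample t-test on log₂ expression with Bonferroni-adjusted
p ≤ 0.05 and a linear fold change ≥ 2 (or ≤ 0.5), the fold change taken
as the ratio of group geometric means. The Welch/Bonferroni combination
is an interpretation of an ambiguously described procedure and both
pieces are configurable.

## The ENM screen

A candidate is a feature present in all four effective DE sets and in
neither ineffective one. Comparisons are canonicalized as unordered
pairs with direction signs relative to the high-altitude member (or the
first-listed member, in canonical group order, for same-environment
pairs), which makes the screen provably invariant to the orientation
the DE stage used. Altitude preference is HIGH when the feature is
up-regulated at high altitude in every effective comparison, LOW when
down-regulated in all, and INCONSISTENT otherwise; inconsistent
candidates are retained and flagged rather than dropped, since
direction consistency is a description of the interesting candidates,
not a stated exclusion rule.

## ANOVA confirmation

The two-way breed × environment ANOVA runs on log₂-CPM values — the
scale on which DE statistics and expression figures live; the source
procedure does not state a scale. Only balanced complete 2×2 designs
are accepted, where type-I and type-III sums of squares coincide, so
the closed-form cell-means decomposition used here (vectorized across
features) is unambiguous; the test suite cross-checks it against
statsmodels' `anova_lm`. The final call is ENM iff p_env ≤ α and
p_breed > α with α = 0.05 (no level is stated in the source; 0.05 is
the field default). Interaction significance is reported but excluded
from the call: the rule keys on main effects, which reproduces the
observation that interaction-affected candidates are not final ENMs.
Degenerate inputs: a constant response returns F = 0, p = 1; zero
residual variance with a nonzero effect returns F = ∞, p = 0.

## Sweep scan

The F_ST estimator is Weir & Cockerham (1984) two-population variance
components, aggregated per window as Σa / Σ(a+b+c) (ratio of sums); the
upstream description names only the statistic, not the estimator, and
W&C with ratio-of-sums aggregation is the conventional choice. A
Hudson-style estimator is available via `estimator="hudson"`. Sites
monomorphic across both populations, or with fewer than two called
alleles in either population, contribute (0, 0) and are effectively
skipped; a window with no contributing site reports missing F_ST and is
excluded from thresholding. Negative window F_ST is clamped to 0 for
thresholding, with the raw value retained in the output.

π per population is Σ 2p̂(1−p̂)·2n/(2n−1) over usable sites divided by
the window span in bp; the π ratio is π_pop2/π_pop1 with pop1 the
putatively selected (highland) population, so a ratio > 1 indicates
diversity loss in pop1. Both raw π values are always reported so the
direction convention is recoverable; the direction is configurable.

Windows are 40 kb sliding by 20 kb, starting at position 1; the final
partial window is retained and flagged but excluded from region calling
by default. Qualifying windows (F_ST ≥ 0.3) merge when overlapping or
book-ended; regions are then annotated with every gene interval
overlapping by ≥ 1 bp (BED read as 0-based half-open, GFF3 as 1-based
inclusive, both converted to 1-based inclusive internally). Thresholding
is windows-first (regions → overlapping genes), one of two defensible
readings of a region/gene count pairing; the alternative (thresholding
gene-overlapping windows directly) is not implemented.

## Synthetic data

The count generator draws NB(μ, φ) counts over the factorial design
with per-feature baselines log₂-uniform on [4, 10] (counts ≈ 16–1024 at
the reference library size), a single shared φ (default 0.05), library
sizes uniform on [0.8M, 1.2M], and planted effect classes: EN features
shift mean expression by ±2 log₂ units between environments regardless
of breed, BR features between breeds regardless of environment, INT
features only in the (TIB, HIGH) cell (defaults 10%/10%/5% of
features). These defaults are the regime the screen targets — few-fold
effects at moderate abundance with three replicates — and double as the
acceptance conditions. What the generator deliberately omits:
feature-to-feature dispersion variation, mean–dispersion trends,
correlated features, composition effects beyond the planted DE
fraction, and any tissue-specific baseline structure. Passing recovery
tests therefore demonstrate correctness of the screen's logic and
calibration of its tests under the stated model, not robustness to
real-data pathologies such as tagwise overdispersion.

The genotype generator draws unlinked biallelic sites (density 0.01/bp)
with a shared Beta(0.8, 0.8) frequency per neutral site (clipped to
[0.05, 0.95]) and pushes the two populations' frequencies apart by
±δ/2 (clipped to [0.02, 0.98], keeping both polymorphic) inside planted
non-overlapping 40-kb windows aligned to the window grid; genotypes are
Binomial(2, p) per diploid. No linkage disequilibrium, demography, or
sequencing error is modelled — the planted δ directly controls the
expected window F_ST, which is what the scan's recovery tests need.
Recovery scoring treats scan windows fully inside a planted span as
DIVERGED, windows with no overlap as NEUTRAL, and partially overlapping
windows as ambiguous (excluded from both rates), since their mixed
content dilutes F_ST by construction.

## Problem sizes and determinism

The acceptance script uses 2,000 features for null calibration, 1,500
features (150 planted EN) for pipeline recovery, 1,000 simulated
families of 100 genes for the Bonferroni FWER, and a 4-Mb chromosome
with 20+20 diploids and 10 planted windows for the sweep — sizes chosen
so each quantity's Monte-Carlo error is small relative to its
acceptance band while the whole script runs in seconds. All randomness
flows from `numpy.random.default_rng` seeded from the CLI/config seed;
pipelines are deterministic given their inputs, and every output TSV
records the tool version, a config hash, and the seed in a header
comment.

## Known limitations

* Common dispersion only; data with strong tagwise dispersion will be
  mis-calibrated (anticonservative for low-dispersion features,
  conservative for high).
* The exact test rounds pseudo-count group sums to integers; at very
  low totals this discretization makes p-values conservative.
* The screen is per-tissue and requires all six comparisons; it has no
  notion of borderline membership (a feature at FDR 0.051 in one
  effective comparison is simply absent).
* The sweep scan assumes autosomal diploid genotypes and ignores
  linkage when interpreting window counts as independent evidence.
* The curated worked-example membership tables reconstruct reported
  set structures; where per-comparison membership was not reported
  (heart), placeholder identifiers labelled synthetic fill the
  unconstrained cells, and one lung identifier is recorded under two
  reported spellings without resolving which was intended.
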