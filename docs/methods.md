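# Methods

This note documents the models behind `rawkit`, the parameters that matter,
the synthetic-data generator the test suite runs against, and the numerical
and design choices made where the method leaves room.

## Raw quantities

For a SNP probe with allele intensities A and B (both strictly positive),
the raw log R is the log2 Euclidean magnitude, `log2 sqrt(A^2 + B^2)`, and
the raw BAF is the allele fraction `B / (A + B)`.  Non-SNP probes use
`log2(intensity)` directly; the two probe classes are merged into a single
genome-ordered track during normalization.  Two per-sample covariates are
derived from the raw track: the **median hybridization** (genome-wide median
raw log R, a brightness proxy) and the **raw MAPD** (median absolute
difference between genomically adjacent autosomal probes of the raw track, a
copy-number-robust noise measure; the autosome restriction avoids sex
confounding).

## Reference model

A reference panel of at least 10 samples (at least 5 of the relevant sex for
X/Y probes; X-probe functions use female samples only, Y male only) is
condensed into three fitted parts.

**Per-probe reference functions.**  Each probe's expected raw log R is a
linear function of the sample covariates (median hybridization, raw MAPD).
The fit is iteratively reweighted least squares with a redescending
Tukey-bisquare weight (4 reweighting iterations, tuning constant 4.685 x the
residual MAD), so that the minority of panel samples carrying a copy number
variant at a probe does not drag its expectation.  Two adaptations matter for
small panels:

- *Slope moderation.*  The non-intercept coefficients are shrunk toward the
  across-probe median in proportion to their per-probe sampling variance
  (an empirical-Bayes posterior mean).  A panel of ~20 samples cannot
  support a free two-covariate slope per probe; without moderation the
  coefficient noise, multiplied by the query's covariates, is re-injected
  into every normalized sample.  When the panel genuinely supports
  probe-specific slopes (between-probe variance well above sampling
  variance) the shrinkage vanishes.
- *Backfitting.*  The model is fitted in rounds (default 2 after the initial
  pass): once the MDS component model (below) is available, each panel
  sample's fitted component contribution is removed and the probe functions,
  genotype slopes and MDS are refitted on the cleaned panel.  Otherwise the
  panel's own systematic variation inflates the intercept noise, which every
  query then inherits as a fixed noise field.

Degenerate panels (zero covariate variance, e.g. replicated samples) fall
back to a robust per-probe location with a warning.

**MDS component model.**  Residual autosomal log ratio of the panel (after
reference subtraction, GC/fragment-length centering and genotype adjustment)
is decomposed by classical metric MDS — principal coordinates on Euclidean
distances, computed from the eigendecomposition of the centered Gram matrix.
Six components are kept by default (configurable).  Per-probe loadings come
from regressing the panel matrix on the scores; scores and loadings are
rescaled so each loading vector has unit per-probe RMS, which makes a score
directly readable as log2 units of per-probe contribution.  Component signs
are fixed by making each score's correlation with panel raw MAPD
non-negative (samples far from the panel mean along a component are noisier,
so the association is meaningful); scores are column-centered by
construction.  Each component records the panel's observed score span as its
admissible interval.

**Per-SNP genotype-cluster functions.**  Panel raw BAF at each SNP is
clustered into three genotypes by deterministic 1-D 3-means (quantile
initialization at the 5th/50th/95th percentiles).  A SNP is **high-quality**
iff (a) all three clusters are occupied, (b) adjacent cluster centers are
separated by more than max(4 x within-cluster SD, 0.15) in raw BAF — without
this gap test, 3-means happily splits a single genotype cluster in half when
a homozygote is absent from the panel and mislabels the genotypes — and
(c) the cluster sum of squares per reference sample is at least 0.018.  The
score is the total sum of squares about the SNP's grand mean divided by the
number of panel samples: a separation measure that decreases continuously as
clusters converge, which is the reading under which a *lower bound* of 0.018
acts as a quality filter.  The threshold is a configuration default, not
hard-coded.

Each genotype cluster's expected raw BAF as a function of raw log R uses the
characteristic form

    g(x) = mu + (0.5 - mu) * min(exp(-k (x - x0)), 1)

which runs from the background composition (raw BAF 0.5 at and below the
background hybridization level x0) to the genotype asymptote mu at high
log R, and is monotone and bounded in [-0.25, 1.25] by construction.  The
decay rate k and the offset of x0 below the per-SNP panel log R minimum are
chip-global, selected on a fixed grid by pooled least squares over all SNPs;
only the asymptote mu is per SNP and genotype (closed-form given the shape).
One free parameter per cluster is what a 20-sample panel can actually
support; per-SNP three-parameter exponentials overfit catastrophically.
For low-quality SNPs the better-populated homozygous cluster (raw BAF bands
below 0.3 / above 0.7) is fitted and mirrored around 0.5 for the missing
homozygote, with a constant 0.5 line for AB; SNPs with no homozygous
evidence fall back to the global anchors (0.05, 0.5, 0.95).

The model (including per-SNP panel-mean raw BAF and moderated
genotype/log-ratio slopes) is persisted to a single versioned HDF5 container
keyed to a SHA-256 fingerprint of the annotation; using a model with a
different annotation is a hard error.

## Per-sample log ratio normalization

Steps run in a fixed order; each records MAPD before/after in a JSON-able
correction ledger:

1. **Reference subtraction** — subtract each probe's function value at the
   sample's (median hybridization, raw MAPD); re-center the genome median
   at 0.
2. **GC / fragment-length centering** — equalize the median log ratio within
   equal-count percentile bins of GC content and of fragment length,
   alternating between the covariates (up to 5 rounds, joint tolerance
   1e-6).  Default 100 bins per covariate; the bin count is reduced when it
   would leave fewer than 50 probes per bin.
3. **Genotype adjustment** — per SNP, subtract slope x (raw BAF - panel-mean
   raw BAF), removing the linear genotype/log-ratio coupling seen in the
   panel.
4. **MDS correction** — for components 1..6 sequentially, choose the score
   in the admissible interval that minimizes the autosomal MAPD of
   (log ratio - score x loading) and subtract at the argmin.  The search is
   a deterministic zooming grid (33-point grids, refined to a resolution of
   1e-3 of the interval width).  The empirical MAPD objective is piecewise
   linear with small local dips, so a bracketing line search (e.g.
   golden-section) can lock onto a local dip; the zooming grid argmin is
   robust at negligible extra cost.  Argmins at an interval edge are flagged
   (possible out-of-panel sample).
5. **Local reference** (optional) — subtract the per-probe median log ratio
   of >= 3 local samples processed through the identical preceding steps.
6. **Final median centering** (idempotent).

Missing probes stay NaN throughout and are excluded from all medians and
adjacent-pair differences; nothing is imputed.

## BAF normalization

The three genotype lines are evaluated at the sample's **raw** log R (the
cluster model is expressed in raw coordinates).  The observation is mapped
piecewise linearly with anchors (v_AA -> 0, v_AB -> 0.5, v_BB -> 1);
outside the outer lines the adjacent segment's slope extrapolates, so the
output is continuous, invertible and intentionally not truncated to [0, 1]
(homozygous SNPs slightly beyond an outer line stay slightly outside, rather
than piling up at the boundary).  A raw BAF exactly on the AB line maps to
exactly 0.5.  If the lines are non-monotone at the observed log R the SNP
falls back to the global anchors with a warning.  Low-quality SNPs are
excluded by default and included with a flag.

## Segmentation and derived statistics

**CBS.**  Per chromosome, the arc of probes maximizing the circular
mean-shift statistic |arc sum - expected| / sqrt(k(n-k)/n) is found
exhaustively (arc lengths bounded below by `min_probes`), and the split is
kept when a within-segment permutation test gives p < alpha (default 0.01,
100 permutations, early stopping once p < alpha is unreachable).  Recursion
continues in the resulting pieces; a final pass merges segments shorter than
`min_probes` into the neighbor with the closer median.  Deterministic given
the seed.  Exact parity with parent-specific CBS implementations is not a
goal; a fixed ~1 Mb window segmentation is provided separately for the
per-chromosome scatter statistics.

**Allelic imbalance.**  |BAF - 0.5| within a segment is clustered on two
means (deterministic 25th/75th-percentile initialization): the heterozygous
and homozygous bands.  AI = c_het / c_hom, near 0 for balanced segments and
near 1 for homozygous ones; the expectation for homologue copy numbers
(H_A, H_B) is |H_A - H_B| / (H_A + H_B) (0, 1/3, 1/2, 1 for 1:1, 1:2, 1:3,
0:2).  When the two-means split separates the centers by less than 3 x the
within-cluster spread the segment is treated as a single band (pure-noise
splits of an LOH segment would otherwise bias AI below 1); a single band
reads as homozygous (AI 1) when its center is >= 0.25 and balanced (AI 0)
otherwise.  Segments with fewer than 20 SNPs are flagged unreliable.

**Abundance calibration.**  Monotone piecewise-linear interpolation through
the empirically anchored points (log ratio -0.6 -> 0.5x, 0 -> 1x,
0.35 -> 1.5x, 0.6 -> 2x), extrapolating linearly with the edge slopes.

**MAPD / SAPD.**  MAPD is the median absolute difference of genomically
adjacent probes (never across chromosome boundaries).  For cross-tool
comparison, SAPD divides MAPD by the tool's copy-number effect size Delta
(spread between the two most extreme autosome medians) relative to the
cross-tool mean effect; samples with mean effect below 0.2 carry too little
signal and are excluded, and a non-positive Delta with adequate mean effect
is flagged undefined.

**Identity.**  BAF is discretized to B-allele presence (1 iff BAF >= 0.2,
inclusive) on the high-quality SNP mask; pairwise dissimilarity is the
fraction of shared non-missing SNPs that differ (raw difference counts are
also kept, and pairs sharing fewer than 100 SNPs are flagged uninformative).
Normalizing by the compared-SNP count makes batches with different masks
comparable.  Trio validation classifies child segments by median log ratio
(> 0.2 gain, < -0.3 loss) and validates an alteration when a same-direction
parental alteration covers >= 90% of its base-pair length (not reciprocal);
prediction accuracy is validated / detected.

## Synthetic data generator

Each probe has an affinity (log-normal, log2 SD 0.5).  Total concentration
(true abundance x affinity) passes through a Hill saturation curve with
additive background, `I = I_max (c^h / (c^h + K^h) + beta)`; the defaults
h = 0.8192, K = 20, beta = 0.0228 were solved once so the log2 response at
0.5x / 1.5x / 2x abundance reproduces the calibration anchors (-0.6 / 0.35 /
0.6) to better than 0.01 — those anchors are numerically close to a
0.6-exponent power law.  Allele intensities split the Euclidean magnitude on
the quarter circle: the genotype (with cross-hybridization implied by the
asymptotic cluster centers 0.05/0.5/0.95) sets the direction, and the
background fraction of the signal pulls the direction toward the probe's
background composition — drawn per probe as 0.5 +/- 0.4 in the B-channel
share — so raw BAF converges toward ~0.5 at low hybridization and carries a
probe-specific, intensity-dependent bias.  This construction keeps genotype
out of the log R mechanically; the genotype/log-ratio coupling real arrays
show is injected as its own explicit linear term (default slope 0.1).

Sample-specific structure, all in log2 units: brightness (SD 0.2), GC bias
(amplitude 0.3 x a sinusoid of the GC percentile, per-sample coefficient
~N(1, 0.3)), fragment-length bias (amplitude 0.2, same construction),
latent components (orthonormalized unit-RMS loadings; per-sample scores
N(0, 0.1) for queries and N(0, 0.3) for reference panels — panels are
deliberately assembled to span more technical variation than typical
queries, and quantitatively the component subtraction injects loading
estimation noise proportional to (query score / panel span)^2 / panel size,
so a panel that does not span the component space cannot support the
correction), and per-probe Gaussian noise (SD 0.1, per-sample scale
~U(0.85, 1.25)).  SNP allele frequencies are Beta(0.8, 0.8), which yields
realistic heterozygosity and a sizeable monomorphic/missing-homozygote
fraction to exercise the low-quality path (roughly half of SNPs at a
20-sample panel).  The heterozygous raw-BAF jitter (0.015 at full signal) is
chosen so the probe-specific background bias dominates raw heterozygous
spread, representing a modern high-quality chip.  Genotypes are drawn under
Hardy-Weinberg; trio children receive one allele from each parent, and child
CNVs are placed in a transmitting parent unless de novo.  All draws are
keyed to a mandatory seed; identical configurations are bit-identical.

What the generator does **not** emulate: physical array geometry and spatial
artifacts, probe cross-hybridization between different loci, wave structure
correlated with replication timing, ethnicity structure in allele
frequencies, and vendor-specific intensity summarization from multiple
physical probes.  Passing tests therefore demonstrate that each correction
removes the structure it targets and leaves ground-truth signals intact —
not that real-array noise is fully captured.

## Identifiability notes for truth comparisons

Fitted MDS components are only defined up to rotation within the latent
subspace (components of equal variance have degenerate eigenvalues) and up
to an additive constant per component (reference subtraction absorbs the
panel-mean contribution).  Truth comparisons therefore project the total
fitted contribution onto the generator's loading basis
(`synthetic_data.recovered_generator_scores`) and center both sides across
the query cohort before comparing scores.

## Problem sizes and runtime

The test suite and the acceptance script use 20,000 probes / 20 reference
samples for pipeline-level checks (a few seconds per reference build),
2,000-probe panels for BAF-model checks, 2,000-probe chromosomes for
segmentation checks, and segment-level trio tables for the trio accuracy
statistic (full intensity trios are exercised once for Mendelian and kinship
properties).  These sizes give statistical headroom comfortably inside the
stated tolerances while keeping a full run in minutes on one core.

## Known limitations

- Per-probe reference functions assume the covariate dependence is linear;
  strongly nonlinear brightness response would leave residual structure.
- The genotype characteristic functions share one decay rate and background
  offset chip-wide; probe-specific background kinetics are absorbed only
  through the per-SNP log R origin.
- With small panels (10-20 samples) roughly half of the SNPs carry an
  unobserved homozygote and fall back to the mirrored low-quality model;
  large panels recover the high-quality fraction.
- CBS here is single-track (log ratio); parent-specific joint segmentation
  of mirrored BAF is out of scope.
- Absolute copy number calling (purity/ploidy inference) is deliberately not
  performed; the calibrated abundance and AI scatter are inputs for such
  tools, not a replacement.
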