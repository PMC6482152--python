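# Methods

## Scope and model

The package implements the computational core of a MET-TF discovery and
epithelial-reprogramming quantification study as a reusable pipeline:
a correlation screen over an expression compendium, a cell-motility
statistic, ATAC/CAGE feature construction, gene-set state scoring, and
motif-accessibility deviation analysis. All stages start from processed
inputs (matrices, peak intervals, track tables); read mapping, peak
calling and tracking are upstream of this package.

## Synthetic data: what it emulates

The generators reproduce the *statistical structure* each analysis
assumes, not real biology.

**Expression compendium.** One latent epithelial–mesenchymal factor
u ~ N(0,1) per sample; E markers load +0.9·u, M markers −0.9·u, planted
TFs load l·u with l ∈ [−1,1], background genes are pure noise, all on a
baseline of 8 (array-intensity-like log scale, clipped at 0) with
Gaussian noise (default sd 0.3). A single latent factor is the simplest
structure that produces the anti-correlated CDH1/VIM geometry the screen
keys on; real compendia contain additional axes (tissue, batch), so
passing tests show tier recovery under the screen's own model, not
robustness to confounding. Default 300–500 samples mirrors the scale of
the ~1000-array compendium the screen is designed for, at desk size.

**Tracks.** Ballistic (constant speed, random heading), Brownian
(i.i.d. Gaussian steps of sd `step_sd` per frame) and persistent random
walk (AR(1) steps, s_k = p·s_{k−1} + √(1−p²)·η). Frames every
dt = 0.25 h emulate 15-minute live imaging. Real tracks have gaps,
drift and tracking errors; the functions tolerate irregular timestamps
but the generator does not emulate those artefacts.

**Peak counts.** Per-peak baseline means are Gamma(shape 4) around
`baseline_mean` (accessibility spread for background matching), counts
are negative binomial with size `dispersion` (var = μ + μ²/φ; φ → ∞
gives Poisson), motif membership is Bernoulli(`motif_density`), GC is
Uniform(0.3, 0.7). A planted effect multiplies the means of one motif's
peaks by a fold change in one sample group. Real motif matrices are
correlated across motif families; the independent-Bernoulli design makes
the "planted motif is top-z" check cleaner than real data would be.

All generators are deterministic given the spec seed (one global
`numpy` Generator per call, consumed in a fixed order).

## Numerical and design choices

**Pearson with missing data.** Pairwise-complete observations with a
minimum of 10 complete pairs (guards against spurious extreme r from
sparse overlap); zero variance raises an error rather than returning 0.
Tier boundaries are strict inequalities. Ties in marker-pair selection
and ranking break lexicographically so output order is reproducible.
Constant-expression TFs are reported with tier "NA", absent TFs with
"missing", so list attrition is auditable.

**MSD statistic.** Times are re-zeroed to the first observation; the
t = 0 point is excluded (the ratio is undefined there and the
displacement is identically zero). No per-timepoint filtering is applied
— no published criterion exists for one — but a minimum-track-duration
filter is exposed (`min_duration`, default off). The statistic is
exactly v² for ballistic tracks on any sampling grid, which the tests
exploit as a closed form.

**Interval engine.** BED-convention 0-based half-open coordinates.
Merging unions overlapping/abutting intervals, then joins regions whose
gap is *strictly* smaller than the threshold (default 100 bp; an exact
100 bp gap survives). Counting uses ≥ 1 bp overlap; a fragment spanning
two regions increments both. Closest-gene distance is TSS-to-peak-edge
(strand ignored; last covered base = end − 1), signed + downstream / −
upstream, 0 when contained; equidistant TSSs resolve to the smaller gene
id. Gene-level CAGE expression is the SUM of the gene's TSS tpms (the
natural additive choice for tag counts; mean/max are not exposed because
no downstream consumer needs them).

**Z-scores and tests.** Sample (n − 1) standard deviation; constant
genes yield an all-zero row and are flagged. The t-test is the
classical equal-variance Student form (Welch available via
`equal_var=False`). Gene-set tests pool member-gene Z values across a
condition's replicate columns and compare against the control pool; the
reference design is 4 conditions × 3 replicates, under which the test's
empirical type-I error at α = 0.01 is ≈ 0.013 (the mild inflation comes
from the negative cross-column correlation Z-scoring induces, −1/11 at
12 columns; with fewer columns it grows, which is why Z-scoring over
single-column conditions is not the default design). Significance stars:
* p<0.01, ** p<0.001, *** p<0.0001, **** p<0.00001.

**Clustering.** Average linkage on 1 − Spearman (average ranks for
ties) via scipy; constant profiles have undefined correlations and are
assigned the metric maximum distance 2 and flagged.

**Motif deviations.** Expected reads use the all-sample pooled fraction
of reads in a motif's peaks. Background matching bins peaks into a
10 × 10 grid of GC × mean-accessibility quantiles; each foreground peak
is paired, per background iteration (default 50), with a random peak
drawn with replacement from its bin. Draws are keyed to
lexicographically sorted peak ids, so a consistent permutation of peak
order reproduces identical z. Per-peak matched resampling (rather than
resampling whole matched sets without replacement) vectorises to one
draw matrix plus matmuls and is the scheme standard deviation-score
tools use. Background sd uses ddof = 1; cells with background spread
below 1e−10 get z = 0 when the observed deviation is equally null
(proportional-sample degeneracy) and NaN otherwise. Motifs matching
< 10 peaks are flagged but still scored.

**Differential motifs and reciprocity.** Two-tailed Student's t on z
between groups, BH q over all tested motifs, label only when q < 0.01
AND the group-mean z difference exceeds 5 in the favoured direction
(effect size and significance jointly required). Expression contrast:
lfc = log₂((mean_B + 1)/(mean_A + 1)), t-test on log₂(x + 1), BH q.
Both contrasts use the same sorted-label group ordering, which makes the
reciprocity call invariant to the arbitrary sign convention.
BH q-values are computed by the standard step-up; note the step-up is
*not* idempotent as a transform (reapplying it to q-values can only
increase them), so only determinism and rank-monotonicity are asserted.

## Problem sizes

Defaults throughout are desk-scale study conditions chosen once:
screens at 500 samples with 500 null genes; motility at 200 tracks per
group, 97 frames; interval oracles at thousands of random instances on
a 2 kb coordinate span; motif analysis at 2000 peaks × 6 samples × 50
motifs (planted recovery) and 1000 peaks × 808 motifs × 200 seeds (null
calibration); gene-set calibration at 2000 permuted 30-gene sets over a
1000-gene universe.

## Known limitations

* The synthetic compendium's single-factor structure cannot probe
  robustness to batch effects, multi-lineage structure or probe-level
  redundancy; the screen operates at the identifier level given.
* Deviation z-scores are calibrated against the generator's
  independent-Bernoulli motif model; overlapping motif families in real
  databases produce correlated z not represented here.
* The dual filter's z > 5 component is an effect-size gate on the
  deviation scale; its mapping to biological effect size depends on
  sequencing depth and peak count and should be revisited for datasets
  far from the defaults.
* Reciprocity calls require an explicit motif → TF map; shared family
  motifs (e.g. one motif for two paralogues) are mapped to every listed
  gene rather than disambiguated.
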