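# Methods

## The coactivation model

Each animal contributes one mean Fos-positive cell count per brain
region (a real number: manual counts are averaged over several images
per region). Within a condition, the counts of a region across animals
form a sample, and the coactivation of two regions is the sample Pearson
correlation of their counts. Sexes are pooled by default — the design's
per-sex group sizes (3–9) are too small for stable per-sex correlation
matrices — with optional stratified fits where n permits.

Significance of a pair uses the exact t re-expression of the Pearson
correlation, t = r·√(n−2)/√(1−r²) with df = n−2, two-tailed. Pairs with
p < α keep their signed r as an edge; all other correlations are set to
0 in the adjacency representation. α defaults to 0.05 per pair with no
multiplicity correction, matching the convention of the analysis this
implements; a Benjamini–Hochberg option provides a stricter mode. The
"independent substructures" of a network are the connected components of
the retained undirected graph, and "centrality" is degree centrality
(ties broken by the fixed region registry order), with betweenness
available on request — degree is the simplest defensible formalization
of a region being "central", and both are reported in the graph
attributes.

n is carried per pair (complete-case after pairwise deletion), not per
condition, because missing region measurements are common in sectioning.
A pair is undefined — excluded from the graph and flagged — when fewer
than 3 complete cases remain or a region is constant.

## The differential (subtraction) network

To contrast a task condition with its control, every raw pairwise
correlation is Fisher-transformed (z = ½ ln((1+r)/(1−r)), the
variance-stabilizing transform), the control z is subtracted from the
task z, the difference is back-transformed (r_diff = tanh(z_diff)), and
r_diff is re-tested with the same t formula at df = n_used − 2.

Three choices here were genuinely open:

- **Which matrices are subtracted.** The raw correlation matrices, not
  the significance-zeroed ones: zeroing first would manufacture large
  spurious differences at pairs that sit just on either side of the
  threshold. A `subtract_thresholded` flag reproduces the alternative
  reading.
- **Which n feeds the re-test.** The subtraction re-tests the task
  network, so the default is the task pair's complete-case n
  (`task_n`); `control_n` and `min_n` are selectable and the choice is
  recorded in the output.
- **Tailedness.** Two-tailed, since a coupling can strengthen or
  weaken.

### Known miscalibration of the re-test

The re-test treats r_diff as if it were a single correlation estimated
from n subjects, i.e. with null SD of z about 1/√(n−3). The actual
sampling SD of a difference of two independent Fisher z estimates is
√(2/(n−3)) — larger by √2 — so the procedure is anti-conservative under
the null hypothesis of equal correlations. Analytically, at α = 0.05 and
n = 15 the null retention rate of a pair with identical population
correlation in both conditions is ≈ 2·Φ̄(z_crit/√2) ≈ 0.16, and the
package's Monte-Carlo harness measures 0.13–0.17. This is a property of
the subtraction procedure itself, implemented faithfully; the acceptance
suite records it as a failed nominal-calibration check rather than
hiding it. Users who need calibrated differential inference should treat
retained differential edges as a screening set, or use the
Benjamini–Hochberg mode plus larger n. A corollary: in an 11-region
contrast (55 pairs), several chance edges are expected per run, which
also caps how often a planted hub tops the degree ranking (the
hub-recovery harness measures ≈ 0.5 at |r| = 0.85, n = 15, ties
included, in agreement with its brute-force oracle).

Degenerate inputs: |r| is clamped to 1 − 1e−12 before the transform so
small-n perfect correlations give a large finite z instead of an
infinity; |r_diff| = 1 maps to an infinite t and p = 0, flagged by sign.

## The synthetic-data generator

The generator exists because the per-animal raw data behind the analysis
are unpublished; it emulates the study conditions so that every stage of
the pipeline can be validated against known truth.

**Fos counts.** Per condition, n subjects (sexes alternating, so groups
are balanced) are drawn from a multivariate Gaussian whose marginal
means and SDs per (region, sex) default to the published group means and
SEM·√n_cell, with per-region n_cell taken as the midpoints of the
published figure-legend ranges (4–6; 4 where no range is stated).
Default group size is 8 per condition (4 per sex), consistent with the
published per-sex group sizes of 3–9; validation harnesses override this
per experiment. The correlation matrix starts from the identity, takes
user-planted pairwise entries, and is repaired to positive definite by
eigenvalue clipping at 1e−8 followed by rescaling to unit diagonal,
iterated to convergence; deviations of planted entries are reported and
a shift > 0.05 raises a warning (a Higham-style alternating projection
was considered and rejected as unnecessary at 11 dimensions). Draws are
left-censored at 0 — counts cannot be negative — and the censoring
fraction per region is reported, because censoring biases low-mean
regions (e.g. SON) upward and attenuates correlations that involve them.
Gaussian-with-censoring was chosen over Poisson/negative-binomial
because the observed quantities are per-animal averages (reals) and the
pipeline's statistic is the Pearson correlation.

**Drinking.** Day-1 intake = per-kg baseline (female 40, male
30 mL/kg, SD 8 — females drink more of the sweet reinforcer per kg) ×
body weight (female 250 g, male 350 g, SD 20). Day-2 intake = day-1 ×
expected D2/D1 × log-normal noise (σ = 0.25). The expected D2/D1 per
LiCl dose is {0: 1.0, 19: 0.6, 38: 0.35, 80: 0.15} mg/kg — a monotone
map consistent with a strong aversion at the 38 mg/kg conditioning dose
— and the config rejects non-monotone curves. The exact curve values
are conventions, not fitted quantities.

**USVs.** A two-part model per channel: a subject-level emitter
probability per (condition, sex) — reflecting that a substantial
fraction of animals do not vocalize at all, that 55 kHz (positive
affect) calls peak in anticipation of the reinforcer (BOT) and that
22 kHz (negative affect) calls are commonest in females in the
LiCl-paired task (BLT) — and, for emitters, per-minute
negative-binomial counts (55 kHz mean 15/min, 22 kHz mean 3/min, shape
2). The defaults are qualitative: no attempt is made to fit the
published effect sizes, which cannot be recovered without the raw data.

**Nausea.** Each 15-s block score is an ordinal cut (thresholds 0, 1, 2)
of a latent normal with mean = behavior baseline + 0.03·dose, giving
scores that increase stochastically with dose.

Everything is deterministic given the config seed (one PCG64 stream per
generator call).

What passing tests on these cohorts do **not** show: real Fos data are
integer-derived, spatially autocorrelated within animals, and subject to
batch effects in staining and counting; real behavioral effects have
unknown magnitudes. The synthetic checks validate the *procedures*
(estimators, thresholding, graph algebra, calibration under a known
law), not the biology.

## Validation harnesses and problem sizes

The Monte-Carlo harnesses (`fosnet.validation`) use an 11-region,
homogeneous high-mean scale (mean 100, SD 15) so censoring is
negligible and the sampling law is exactly multivariate normal:

- null calibration: 2000 replicates of 12 subjects × 11 independent
  regions; the retained-edge proportion's 95% CI (clustered by
  replicate, since pairs within a matrix are dependent) must cover α.
- differential sensitivity/specificity: 300–400 replicates at planted
  |r| = 0.85, n = 15 per condition, compared against brute-force
  Monte-Carlo oracles (loop-based correlations, numerically integrated
  t critical values) via pooled two-proportion tolerances.
- hub recovery: the hub is planted as a one-factor structure (hub–spoke
  r, spoke–spoke r²), the only valid correlation matrix for a
  high-r star; recovery counts degree ties.

The unit suite verifies all closed-form values (Fisher round-trip to
1e−12, hand-computed t values to 1e−4) and matches edge sets and
p-values against the brute-force implementation to 1e−10 on hundreds of
random small instances.

## Known limitations

- The differential re-test's anti-conservativeness (above) is inherent
  to the implemented procedure.
- Calibration cell SDs rely on SEM·√n with legend-midpoint n; true
  per-animal variance is unknown.
- Published per-condition subject identifiers and exact per-group n are
  unavailable, so exact published edge sets are not reproducible; all
  graph-level claims are validated on synthetic cohorts instead.
- The USV scorer takes manual per-minute call counts; no audio
  processing is included.
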