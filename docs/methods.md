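# Methods

`mosaicn` quantifies somatic copy-number mosaicism in single neuronal
nuclei and related population-level measurements. This note records the
models implemented, the parameters that matter, and the design choices
made where more than one reasonable convention exists.

## Relative copy number from qPCR

Amplification efficiency is estimated per assay from a dilution series:
a least-squares line of Ct against log10 template copies gives
`E = 10^(−1/slope) − 1`, and a curve is considered usable only when its
R² exceeds 0.99 (strictly greater). A slope of −1/log10(2) ≈ −3.32
corresponds to perfect doubling (E = 1).

Relative copy number for a diploid-referenced locus is

    RCN = 2 · (1 + E)^(−ΔΔCt)

where ΔCt is the target-minus-reference mean Ct of a unit (reference
gene default *SEMA4A*) and ΔΔCt subtracts the mean ΔCt of the unit's
paired-cerebellum calibrators. ΔΔCt = 0 therefore maps to RCN exactly
2.00. A single efficiency — the target assay's — is used in the default
form; observed TaqMan efficiencies (0.992–1.040) make target and
reference bases nearly identical, and a two-efficiency ratio form
(`rcn_two_efficiency`) is available when that assumption is not
acceptable.

Replicate design: in single-nucleus mode each nucleus is measured in 3
sample loads × 6 assay replicates = 18 replicates per assay. Replicates
are aggregated by a plain arithmetic mean with no outlier rejection by
default (an optional MAD filter exists behind a flag); a (nucleus,
assay) pair with fewer than 10 replicates fails QC and the nucleus is
dropped from that assay's analysis, with the drop logged.

### Confidence interval and the critical value

The 95% CI is computed on the ΔΔCt scale as

    CI_log = t_crit(df) · σ / √n,    σ = 0.25 cycles (system SD), n = 18

and mapped through the RCN formula, giving bounds that are symmetric on
the log scale (`ci_low = 2(1+E)^(−(ΔΔCt+CI_log))` evaluated on both
sides and ordered). The degrees of freedom default to 68; since the
nominal per-assay design would give 17, df is exposed as a parameter and
68 is treated as a pooled system-level property of the platform. Two
critical-value conventions are provided: the exact Student-t quantile
(t(68) ≈ 1.9955), used by default for per-nucleus CIs, and the value
rounded to 2.000, which the per-copy bound table is printed with. The
bounds builder defaults to the rounded convention so the modeled table
matches the published one to all printed decimals; the two agree to
about 2×10⁻⁴ relative.

## Copy-number bin calling

Per-copy acceptance intervals for k = 1..6 are modeled by evaluating the
CI at each integer copy number: with base efficiency E = 1 the modeled
RCN of k copies is k, so

    lower(k) = k · 2^(−CI_log),   upper(k) = k · 2^(+CI_log)

— exactly multiplicative in k. Under the defaults the intervals are
pairwise disjoint through k = 6 and first overlap at 6 vs 7
(upper(6) = 6.51070 > lower(7) ≈ 6.4509), which motivates the open ">6"
top bin: gains beyond six copies are detectable but no longer separable
into adjacent integer states.

A nucleus is assigned the bin whose interval its RCN CI overlaps.
Conventions where the procedure is under-determined:

* CI overlapping two intervals → nearest k by |log2(RCN) − log2(k)|,
  flagged `ambiguous` rather than dropped;
* CI entirely inside an inter-bin gap → nearest k on the log2 scale,
  flagged `gap_assigned`;
* estimates below lower(1) → bin 1 with the gap flag (no "<1" bin is
  emitted);
* ">6" requires the CI lower bound to clear upper(6) by default; a
  point-estimate variant (`gt_rule="point"`) is provided and takes
  precedence over interval overlap in that mode;
* for dual-assay concordance distances, ">6" counts as 7 copies.

The caller is verified against a brute-force interval scan on 10⁴
random estimates, and by parameter recovery on synthetic nuclei (true
CN 1–6, 18 replicates, Ct SD 0.25), where ≥95% of calls match the truth.

Cohort summaries report the mean RCN with a t-based 95% CI of the mean,
the bin histogram, the fractions of nuclei below / at / above two
copies, and the mean RCN among the gained (>2) subset.

## DNA content variation by flow cytometry

Events are propidium-iodide intensities per nucleus; chicken erythrocyte
nuclei (CEN) spiked into every tube provide an internal intensity
standard. The G0/G1 (2N) peak is located as the mode of a Gaussian-KDE-
smoothed histogram (1024 grid points over the data range, Silverman
bandwidth); when two modes are within 10% density of each other the
lower-intensity mode is chosen under the diploid assumption and a
warning is raised. The gate is mode ± 25% (configurable), and mean, SD,
CV (100·SD/mean; a robust MAD-based CV is optional) and the mode
skewness (mean − mode)/SD are computed over gated events. Doublet
exclusion by a forward-scatter-width cut is optional.

The DNA index of a sample against the lymphocyte reference is

    DI = (sample 2N mean / sample CEN mean) / (reference 2N mean / reference CEN mean)

and percent change = (DI − 1)·100. Normalising each tube by its own CEN
peak makes DI exactly invariant to per-tube detector gain. NeuN gating
thresholds the NeuN channel at the 99.9th percentile of an unlabeled
control tube. Group statistics use one-way ANOVA with Tukey HSD on
per-sample percent change / CV / skew, unpaired or paired t-tests for
two-sample designs, and least-squares regression for covariates (age,
post-mortem interval, Braak stage).

As a scale anchor, a gain of the largest human chromosome (chr1,
~250 Mb) is ~3.9% of the diploid genome (half of the ~12,800 Mb
tetraploid content), so population gains near 8–9% cannot be explained
by any single-chromosome hypersomy.

## FISH aneusomy

Counts per brain and observer are validated (class counts must sum to
the nuclei counted), converted to per-brain class rates by averaging
rates across observers (any observer count is supported), and compared
between two groups per class with an unpaired two-tailed t-test on
per-brain rates — the brain, not the nucleus, is the experimental unit.
A chi-squared test on pooled counts is reported as a secondary check
only, since pooling ignores between-brain variability.

## PNA-FISH quantification

Dot-blot validation fits intensity against the number of probe binding
sites (≥3 levels, e.g. 0/3/6/9) and flags linearity at R² ≥ 0.95; the
intercept estimates channel background. For nuclei, intensities are
already-extracted scalars per punctum; a nucleus's intensity is the
maximum over its non-excluded puncta (0–2 puncta per nucleus). Nuclei
without a telomere control signal are excluded as hybridization
failures, and lipofuscin-flagged puncta are excluded as pan-channel
autofluorescence; both rules are idempotent and order-independent. A
nucleus is positive when its intensity reaches the detection threshold —
either a fixed value or "auto", the maximum (configurable quantile) of
the designated negative-control records. Positive fractions are
monotone non-increasing in the threshold; group fractions are compared
with two-proportion z-tests.

## Synthetic data

Every input table has a forward simulator with a truth table, so each
stage is tested by recovery against its own generating model.

* **Ct tables.** All biological signal is placed in the target-gene Ct:
  a nucleus with true copy number CN has target mean
  `Ct₀ − log_{1+E}(CN/2)`; the reference gene and the dedicated
  calibrator nuclei sit at two copies. Replicates add N(0, 0.25²)
  cycles of noise, 18 per assay. Each brain carries 12 cerebellar
  calibrator nuclei — a realistic cerebellar sample per individual —
  and analyzed nuclei draw true CN from per-(group, region) mixtures.
  The default mixtures are fixed so their means are 3.80 / 2.23 / 1.60 /
  2.28 (AD cortex / AD cerebellum / ND cortex / ND cerebellum) with 58%
  of AD-cortex nuclei above two copies: this emulates the statistical
  structure of the published single-neuron profile; it does not
  reproduce its per-nucleus measurements, which are not derivable from
  summary statistics.
* **Flow events.** A Gaussian 2N peak (CV 5%) positioned by a
  configured true DI, an optional right-shifted shoulder subpopulation
  (+20% at a configurable fraction), a CEN peak at 35% of the reference
  mode, 2% uniform debris, and an optional bimodal NeuN channel. The
  configured DI is recovered within ±0.5% on clean (shoulder-free)
  tubes.
* **FISH counts.** Multinomial draws per brain and observer from class
  probabilities (default 3% / 92% / 3.5% / 1.5%), 500 nuclei per brain,
  9 vs 5 brains.
* **PNA records.** Log-normal intensities above or below the detection
  threshold according to per-group positive fractions (defaults 56% /
  22% / 14% for AD / ND / DS), with ~5% lipofuscin contamination, ~2%
  telomere dropout, and blank negative controls pinning the "auto"
  threshold.

What the generators deliberately omit: amplification bias between
exons, plate/batch effects and inter-run drift, cell-cycle (S/G2M)
populations and compensation effects in flow data, observer bias in
FISH counting, and spatially structured image artifacts. Passing
recovery tests therefore demonstrates correctness of the estimators
under the stated measurement model, not robustness to every artifact of
real data.

## Numerical and testing choices

Problem sizes in the test suite are chosen to keep the full run a few
minutes long: 60 nuclei per copy-number state for recovery, 2,000
Monte-Carlo replicates for null calibration (per-class type-I error is
asserted as the mean rejection rate over the four aneusomy classes,
binomial SE ≈ 0.005 at 2,000 reps), and 10⁴ random estimates for the
caller-oracle equivalence check. All simulations are seeded; identical
seed and configuration produce byte-identical CSV output.

Known limitations: Ct extraction from raw fluorescence, FCS binary
ingestion, image segmentation, and cell-cycle modeling are out of
scope; inputs are tidy CSV tables of already-extracted quantities. The
df = 68 default is adopted as given for the CI model rather than
derived from the replicate design.
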