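# Methods

## Partition statistics and quantification

A dPCR well distributes template molecules over `n` partitions of volume `V`
(nL). Under independent loading the per-partition copy number is Poisson, so
the fraction of positive partitions is `p = 1 − exp(−λ)` and the occupancy
estimate from counts is `λ̂ = −ln(1 − n_pos/n_total)`. Reaction concentration
is `λ̂ / V` (copies/µl), multiplied by the platform's volume precision factor
(VPF) on nanoplates, where partition geometry varies slightly between lots.

Confidence intervals: a two-sided 95% Clopper–Pearson interval on the
positive fraction is transformed through `−ln(1−p)`. The transform is
strictly monotone, so the exact binomial coverage carries over to λ and to
every linear rescaling of it (concentration at reaction or sample scale).
Saturated wells (`n_pos == n_total`) raise an error rather than returning an
infinite estimate: such a well carries no upper concentration information
and must be re-run at higher dilution.

Replicate pooling sums counts *before* estimation. Pooled counts remain
binomial, so the interval shrinks correctly; averaging per-well λ̂ values
would not propagate the partition counts.

Back-calculation to the starting sample multiplies by the
post-preamplification dilution factor (2 for the protocol's 1:1 TE
dilution), divides by the preamplification factor `A`, and rescales by the
reaction-to-template volume ratio. The volume basis for "copies/µl at sample
scale" is the template-extract volume; callers who prefer per-reaction units
pass `volume_ratio=1`.

## Threshold-gated preamplification model

Detectable output is modelled as `n = f(k)·k·A`, where `k` is the template
copy number entering the reaction, `A = exp(tv)` the amplification factor
(rate and time are not separately identifiable and are carried only as the
product), and `f(k)` a hard gate: 0 below the detection threshold `h`, 1 at
or above. `A` is fitted through the origin by least squares on (k, n)
observations — the model has no intercept, and a single calibration point
reduces to the ratio `n/k`. Predictions round to the nearest integer
droplet. Observed counts below 1% of prediction (configurable) are censored
to zero as artifacts: solitary positive droplets at high predicted yield
arise from spontaneous probe cleavage or non-specific binding, not from
amplified template. `h` has no empirically fixed value and defaults to 0;
it exists to express the observed all-or-nothing behaviour of low-copy
reactions and can be set from dilution-series data.

`fit_cycle_trend` regresses log(output) on cycle number to express the
exponential dependence of detectable product on cycle count; zero-variance
responses are reported as growth 1.0 with R² 1.0 (a flat trend fits such
data exactly; the usual R² formula is undefined at zero total variance).

## Low-copy sampling model

The mutant copies captured when pipetting `k` template molecules at variant
allele fraction `f` are Binomial(k, f). Capture probability is the exact
binomial tail by default; the de Moivre–Laplace normal approximation (with
continuity correction) is exposed both directly and via an `auto` mode that
switches at k ≥ 100. The approximation's absolute tail error at k = 100 is
below 0.01 for f ≥ 0.15 but reaches ≈ 0.015 near f = 0.05, where the
binomial (kf = 5) is still markedly skewed — the property test encodes
these bounds. Composing the binomial capture with the gated preamplification
prediction by exhaustive enumeration yields the distribution of expected
FAM-positive counts and the probability of meeting the 50-droplet
positivity rule; "captured" defaults to ≥ 1 mutant copy.

## Sample-calling rules

Thresholds are manual platform inputs, not learned: 2000/1500 RFU (FAM/HEX)
for the droplet platform, 40/20 RFU for the nanoplate platform. Boundary
conventions: amplitude equal to the threshold is positive; a FAM total of
exactly 50 satisfies "at least 50"; the HEX rule is strict ("more than 50").
The 50-droplet positive criterion is applied to the duplicate *total* with a
per-replicate reproducibility requirement (≥ 1 FAM droplet in each
replicate), because the negative rule is explicitly phrased on the duplicate
total; a stricter per-replicate reading (≥ 50 in each well) is selectable
via `positive_rule="per_replicate"`. Count configurations with FAM signal
below the positive rule and insufficient HEX evidence map to *ambiguous*;
wells with no FAM signal and ≤ 50 HEX droplets are *non-informative*
(too little amplifiable template to support any call). The rule set is
total: every count configuration yields exactly one verdict.

Isolate informativeness is a separate, upstream filter: an isolate whose
measured 150 bp amplifiable-fragment concentration is exactly zero cannot
carry the assay and is excluded; a missing measurement is an error, never an
implicit zero.

## Limit of detection

Dilution series are geometric (default ten two-fold steps from 600 pg). The
LoD is the smallest input mass whose duplicate-summed positive count reaches
50 in at least one channel — deliberately a hard count rule, not a probit
LoD95 model. Mass converts to haploid genome equivalents at 3.3 pg/genome
(standard human value; 9 pg ≈ 3 genomes). The conversion factor is exposed
because the equivalence as usually quoted (9 pg = 3 genomes) implies 3.0
pg/genome exactly.

## Bland–Altman agreement

Paired platform measurements are compared as differences of log10
concentrations (default orientation: newer platform minus reference, so a
positive bias means the newer platform reads higher). Bias is the mean
difference, SD the sample standard deviation (n − 1), limits of agreement
bias ± 1.96·SD, outliers the pairs outside the limits. Unpaired keys and
zero concentrations (log undefined) are excluded before analysis and
reported. Swapping platforms negates bias and limits and preserves SD and
the outlier set.

## Simulator

`dpcr_sim` generates droplet-level experiments with known truth, emulating
the features the analysis relies on:

- **Loading**: each allele's total stock copy number is Poisson with mean
  concentration × stock volume; molecules split multinomially over
  replicates, so per-replicate loads are marginally binomial with mean
  concentration × `sample_volume_ul` (default 5 µl, the template volume per
  reaction).
- **Preamplification**: a per-molecule Bernoulli branching process — every
  molecule duplicates with probability `preamp_efficiency` per cycle, so
  expectation is `k(1+e)^cycles` but low-copy wells experience genuine
  stochastic dropout. Defaults are 8 cycles at e = 0.4887, calibrated so the
  expected per-molecule amplification factor is ≈ 24.2, the protocol's
  empirically fitted value (which folds in post-amplification losses, hence
  the sub-ideal per-cycle efficiency).
- **Partitioning and fluorescence**: per-partition occupancy is Poisson at
  λ = post-preamplification copies / `n_partitions`; occupied partitions
  draw from the positive Gaussian cloud, empty ones from the negative cloud,
  with a `rain_fraction` (default 0.02) of template-driven positives drawn
  uniformly between (neg mean + 2 sd) and (pos mean − 2 sd). Double
  positives arise only from co-occupancy (independent loading), with no
  additional coupling.
- **Artifacts**: mutant-free partitions fire FAM spuriously at
  `fp_artifact_rate` (default 5 × 10⁻⁵ per partition ≈ 1 droplet per 20,000,
  matching the solitary artifact droplets seen in wild-type samples);
  `cross_hyb_rate` (default 0 — the optimised oligo concentrations suppress
  it) lets wild-type-occupied partitions fire FAM, the failure mode of
  over-concentrated probes.
- **Geometries**: droplet platform 20,000 × 0.85 nL, nanoplate 8,500 ×
  1.34 nL, both configurable; cloud defaults per platform are chosen so the
  published thresholds separate them cleanly.

What the simulator does *not* model: PCR chemistry kinetics, per-cycle
efficiency drift, droplet coalescence, optical crosstalk, fragment-length
effects, or extraction losses upstream of the reaction. Passing tests on
simulated data therefore demonstrate the correctness of the statistical
machinery under the model's assumptions (independent Poisson loading,
parametric amplitude clouds), not the behaviour of real instruments.

## Problem sizes and numerical choices in the test suite

Statistical properties are tested at sizes chosen to give stable
Monte-Carlo verdicts in seconds: estimator bias and 95% interval coverage
over 200 simulated wells of 20,000 partitions at λ = 0.1 (coverage compared
at three binomial standard errors plus the 1/n discreteness allowance);
calling specificity over 500 artifact-free duplicate experiments of 2,000
partitions with zero mutant template; VAF invariance under preamplification
over 120 paired-seed experiments of 5,000 partitions (pairing shares the
loading draw, so the comparison isolates the amplification step);
branching-process amplification-factor recovery over 30 seeds at 5%
relative tolerance. Hypothesis-based property tests run derandomised with
50 examples each.

## Known limitations

- The amplitude model is two Gaussians plus uniform rain; real rain is
  structured (partial amplification, satellite clusters) and real clouds are
  skewed. Threshold-setting itself is out of scope — thresholds are inputs.
- The preamplification factor is treated as allele-symmetric; allele-biased
  amplification (e.g., probe competition) would shift VAF and is not
  modelled.
- `estimate_lambda` assumes a single pooled threshold classification;
  partial (rain) droplets misclassified near the threshold bias λ in either
  direction and are only representable through the simulator's rain
  parameter.
- The LoD rule is the protocol's hard 50-droplet count; it is not a
  detection-probability model and should not be read as an LoD95.
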