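# Methods

This note documents the models, conventions and design choices behind
`adaptsig`, in the order data flows through the pipeline.

## Synthetic data model

The generator (`adaptsig.simulate`) emulates a dense drug-perturbation
study: by default 10 cell lines x 5 drugs x 7 doses (1:3.16 dilution from
3.2 uM, spanning ~3.2 nM–3.2 uM) x 5 signaling time points (1, 5, 10, 24,
48 h) x 21 antibodies, with 4 biological x 2 technical replicates each
measured by two scanners; phenotype counts at 24/48/72 h; two-marker
single-cell intensities; and a drug-combination grid.

Each cell line carries `n_latent` (default 3) latent pathway activities.
Latent *l* responds to drug *g* at dose *d* and time *t* as

    a_l(g, d, t) = effect_size * occ(d; EC50_lg, h_lg) * phi_l(t)

with `occ` a Hill occupancy in [0, 1] (zero at dose 0) and `phi_l` a time
profile equal to −1 before a switch time and ±1 after it — emulating
pathways down-regulated immediately after drug exposure and re-activated
(or not) later. Potency (EC50, Hill slope) varies per (cell line, drug,
latent); the direction profile (switch time, late sign) is a property of
the pathway within a cell line and is shared across drugs. That split is
deliberate: mechanistically similar inhibitors differ mainly in potency,
and drug-specific direction flips would cancel the pooled linear coupling
between signals and viability, leaving nothing for a regression model to
recover even at zero noise.

A random subset of signals (`informative_fraction`) reads out one latent
each with loading magnitude ~1 on the log2 scale; the remaining signals are
pure noise. Replicate values are `2^(baseline + latent + N(0, noise_sd))` —
additive Gaussian noise on log2, i.e. multiplicative on the raw scale,
matching the downstream log2 fold-change analysis. Scanner B re-measures
every replicate with an independent noise draw and a small per-antibody
gain offset (which cancels in fold changes, so the two analyses agree in
sign wherever the signal is real).

Viability relative to vehicle decays with cumulative latent magnitude,

    v(g, d, t) = exp(−(t / 72 h) · Σ_l β_l · effect_size · occ_l(d)),

so `effect_size = 0` yields flat signals and viability exactly 1.
`effect_size` is therefore both the signal amplitude (log2 units) and,
through the latent magnitudes, the strength of the viability link; it is
directly comparable to `noise_sd`. Phenotype counts follow
`total ~ Poisson(mean_total_cells)` and `apoptotic ~ Binomial(total, p)`
with `p = 1 − v·(1 − p0)` (`p0` = vehicle apoptotic fraction, default
0.02), chosen so the expected non-apoptotic viability equals the planted
`v` exactly — the simplest model consistent with per-cell imaging counts,
and one with a closed-form mean for testing. Single-cell log2 intensities
are two-component normal mixtures whose High-component weight shifts with
dose along a Hill curve; combination activities are Bliss predictions plus
a planted excess, clipped to [0, 1].

Each generator stage draws from its own pseudorandom stream split
deterministically from the master seed, so stages can be re-run
independently and identical configurations are bit-reproducible.

What the generator does **not** emulate: spatial array artifacts,
antibody cross-reactivity, batch/plate effects, cell-cycle-structured
intensity distributions, or heavy-tailed outliers beyond the Gaussian
noise. Passing tests therefore demonstrate correctness of the statistical
machinery on data satisfying the model's assumptions, not robustness to
every failure mode of real arrays.

## Preprocessing

* **Replicate outlier filter.** Values outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR]
  of the pooled 4 x 2 replicates for a condition are removed. Quartiles use
  linear interpolation between order statistics (the widespread "type 7"
  rule), making worked examples well-defined. The filter is applied to a
  fixed point — replicate sets converge in one or two passes — so it is
  idempotent; at least one value always survives.
* **Antibody QC.** Technical replicates are averaged, each biological
  replicate yields a condition profile, and an antibody's score is the mean
  pairwise Pearson correlation between profiles; antibodies scoring < 0.5
  for a cell line are dropped. Mean-of-pairs is symmetric and stable;
  antibodies with fewer than two complete profiles are flagged
  `insufficient` and retained with a warning rather than silently judged.
* **Collapse.** Retained replicates collapse to their median,
  log2-normalized to the time-matched vehicle control (each time point
  normalized to its own control — the only reading consistent with growth
  over 72 h). Missing controls raise, naming the (cell line, antibody,
  time).
* **Design matrix.** Rows are (drug, descending dose); columns (signal,
  time); z-scoring is per column across conditions with sample sd
  (ddof = 1), the standard autoscaling for PLSR — global scaling would
  leave columns with unequal variance and defeat the weighting. Zero-
  variance columns are flagged and set to 0, never divided. Missing cells
  are a hard error; column-mean imputation exists behind an explicit flag.
  Scaling parameters are stored, so the transform inverts exactly.
* **Dual-analysis consistency.** A variable is kept iff the sign of its
  condition-mean fold change agrees between the two quantifications — the
  simplest faithful reading of "consistent up- or down-regulation"; the
  fraction kept is reported so alternative rules can be compared.

## Response and dose-response summaries

Non-apoptotic viability is mean(total − apoptotic) over replicates,
normalized to the time-matched vehicle mean; the PLSR response averages the
48 h and 72 h values (absorbing cell-line differences in response timing),
falling back to 48 h alone with a warning when 72 h is unavailable.

Hill fits use `v(d) = E_inf + (1 − E_inf)/(1 + (d/EC50)^h)` by least
squares on log10 dose (multi-start trust-region, data-driven initial EC50,
`x_scale='jac'`; convergence accepted on solver success or on an
essentially-zero residual, since near-saturated curves sit on narrow
parameter ridges where the solver's step criteria trigger before its own
success flag). Conventions: **IC50** is the absolute 50%-viability crossing
of the fitted curve (reported absent beyond 100x the tested range) because
the sensitivity cutoff log10[IC50 M] < −6.5 is an absolute-concentration
rule, applied strictly (the boundary itself classifies resistant, as does
an absent IC50); **Emax** is the fractional effect at the top *tested* dose
(1 − v(top)), distinct from the asymptotic E_inf, because claims reference
tested dose ranges; **AUC** is the trapezoid over log10 dose normalized by
the log-dose span, so scores are comparable between 7- and 9-point designs,
and the relative-resistance score averages the 48 h and 72 h normalized
AUCs (1 = fully unresponsive).

## PLSR

NIPALS with deflation of both blocks (see README for the recursion), chosen
over SIMPLS because the VIP formula consumes per-component weights `w_nk`
directly and NIPALS defines them unambiguously; for a single response the
two coincide on predictions, which is asserted against scikit-learn's
implementation in the tests. Numerical conventions: each weight column's
largest-magnitude element is made positive (cross-platform sign
reproducibility); rank exhaustion truncates with a warning; a constant
response is an error. Cross-validation uses a seeded uniform partition into
near-equal folds and re-estimates centering and scaling inside every
training split, so no information leaks from held-out rows. Q² = 1 −
PRESS/TSS on the original response scale; MSPE = PRESS/n as a percent of
the response variance. Component selection returns the smallest count whose
Q² is within a tolerance (default 0.01) of the maximum — additional
components must improve prediction beyond noise to be accepted.

## VIP signatures and clustering

`VIP_k = sqrt(K Σ_n w_nk² SS_n / Σ_n SS_n)`; Σ VIP² = K identically and is
asserted to 1e−6 on every fit. Signs come from the Pearson correlation of
the predictor column with the response (zero correlation maps to +1, a
logged convention); the sign of the PLSR coefficient is available as an
alternative source for comparison, but raw correlation avoids dependence on
component rotation. Scores with |VIP| ≤ 1 are zeroed — the boundary value
exactly 1 is assigned to zero, the strict reading of an "importance > 1"
significance rule. Profiles from the two scanner analyses are merged by
dropping masked-out and sign-discordant variables (counted, not silent) and
averaging the rest. Cell lines are clustered on signed, thresholded vectors
with Euclidean distance and average linkage — average is robust to the
zero-inflated vectors thresholding produces; the metric is fixed, the
linkage a documented choice. Direct drug-target read-outs (pMEK, pERK, a
configurable list) are excluded from the distance: they reflect drug action
itself, not adaptation.

## Synergy and correlation screens

Bliss independence predicts `I_XY = I_X + I_Y − I_X·I_Y` for activity
fractions; excess over Bliss (observed − predicted) scores synergy per dose
pair. Activity is the apoptotic fraction by default (1 − relative viability
via configuration). Spearman correlations delegate to scipy (average ranks,
t-approximate p-values — adequate at the n ≈ 25–40 pairs typical of
biomarker screens); the first-order partial Spearman
`ρ_xy·z = (ρ_xy − ρ_xz ρ_yz)/sqrt((1−ρ_xz²)(1−ρ_yz²))` is computed on the
pairwise Spearman coefficients with n − 3 degrees of freedom, flagged
undefined when the control is perfectly correlated with either variable.
The biomarker screen ranks candidates by |ρ| against viability AUCs across
cell line/drug pairs and supports an exclusion list of cell lines (for
quantifying how much strongly-adapting lines degrade a marker), reporting
the reduced n.

## Single-cell gating

Thresholds are fitted, not drawn by eye: a two-component Gaussian mixture
on log intensities with the gate at the equal-posterior crossing between
the component means (closed-form quadratic). Fits judged unimodal — the
one-component model wins on BIC, or a component collapses below 2% weight —
are flagged degenerate with the threshold at +inf (all cells Low) and a
warning. Gates should be fitted on vehicle-control cells and applied
unchanged to every condition of the same cell line and marker, so
drug-induced shifts are measured against a fixed reference; refitting per
condition would confound the shift being measured. Quadrant assignment is
strict `> threshold`; cells missing either marker are excluded and counted.
Population shifts report per-quadrant fold changes (undefined flagged when
the reference quadrant is empty) and absolute differences.

## Problem sizes and determinism

The test suite and the acceptance script run everything at the design's
natural desk scale: one to three cell lines of the full 35 x 105 design
(a few times 10^4–10^5 replicate rows), 20-seed recovery studies, and
50,000-cell gating samples — sizes where every stage completes in seconds
while sampling error is far below the tested tolerances. All randomness
flows from explicit seeds (generator master seed with per-stage streams;
seeded CV partitions; seeded mixture fits), and identical configurations
reproduce byte-identical outputs, which the pipeline manifest verifies via
content digests.

## Known limitations

* Single-response PLSR only; no multi-response Y-block.
* The generator's latent model is linear in log2 signals with shared
  direction profiles across drugs; strongly drug-specific or non-monotone
  adaptation is outside its scope (and the regression model's).
* IC50/Emax conventions assume viability curves normalized to vehicle and
  decreasing in dose; paradoxical activation (v > 1) fits but the absolute
  IC50 may then be absent.
* The equal-posterior gate assumes approximately log-normal marker
  components; strongly skewed or >2-mode distributions will be flagged
  degenerate rather than gated.
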