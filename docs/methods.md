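# Methods

`uvtox` implements an acute aquatic toxicity analysis for organic UV
filters over four standardized biotests: luminescence inhibition of the
marine bacterium *Aliivibrio fischeri* (Microtox, 5/15/30 min), mortality
of the brine shrimp *Artemia franciscana* (48 h), immobilisation of the
water flea *Daphnia magna* (48 h), and growth inhibition of the duckweed
*Lemna minor* (7 d).  This note records the model, the numerical
choices, and what the synthetic-data tests do and do not show.

## Endpoint reduction

All assays are reduced to a common percent-effect scale per
concentration before fitting.

* **Luminescence.** Inhibition is computed with the standard drift
  correction: with f = control_t / control_t0 the corrected baseline is
  f·sample_t0 and I = 100·(f·sample_t0 − sample_t)/(f·sample_t0).
  Whether the original instrument software applied this correction or
  raw ratios is not recorded in the study; we adopt the correction
  because it is the ISO 11348-3 convention for the instrument.
  Stimulation (the sample brightening, observed for octocrylene) yields
  negative inhibition, which is preserved in effect tables and clipped
  to zero only inside the gamma transform.
* **Quantal counts.** Per-well percent affected is averaged over the
  three replicate wells (10 organisms per well for *Artemia*, 5 for
  *Daphnia*); dispersion is the sample (n − 1) standard deviation, the
  right choice at these small replicate counts.
* **Frond areas.** Growth inhibition defaults to the *yield* basis,
  I = 100·(1 − mean(A7 − A1)ₜ / mean(A7 − A1)𝒸), because the protocol
  measured leaf area; the specific-growth-rate basis
  μ = (ln A7 − ln A1)/6 d is available as an option (OECD 221 offers
  both).  The two bases agree only at zero inhibition; the worked
  example (control 10→40, treated 10→25) gives 50% on yield and ~33.9%
  on rate.

## Potency estimation

Effect–dose relationships are fitted by ordinary least squares in two
parameterisations, E = a + bC (linear) and E = a + b·ln C
(logarithmic); the reported fit is the one with the higher R² (ties
break to linear), and the ECx/LCx/ICx is the inverse prediction at
effect x (default 50%).  Natural log is used in the logarithmic model;
the displayed potency is invariant to the log base.  Estimates falling
outside the tested concentration range are *censored*: the result
carries the violated bound and a censoring label, never an
extrapolated number.  Controls (C = 0) are excluded from fits.

A third route mirrors the Microtox instrument's canonical method: with
Γ = I/(100 − I), OLS of log₁₀ Γ on log₁₀ C gives EC50 = 10^(−a/b),
exactly where the fitted Γ crosses 1.  For noiseless log-logistic data
this route recovers both the EC50 and the Hill slope exactly, which the
tests assert to 1e−9.

**Significance gating.**  Fit quality is compared against the critical
determination coefficient r²crit = t²/(t² + df) with t the two-sided
Student-t quantile at α (default 0.05).  Two degrees-of-freedom
conventions are exposed: `standard` uses the residual df of a
two-parameter line (n − 2); `total` uses df = n.  With three
observations the standard convention gives 0.99 and the df = 3
convention gives 0.77; the published critical value (0.77 at n = 3) is
reproduced only by the latter, so both are computed and labelled rather
than guessing an intent.

**Time trends.**  Toxicity dynamics over the 5/15/30-min exposure
window are summarised by OLS of effect on time, with a configurable
flatness band (default |slope| < 0.01 %/min) separating increasing,
flat and decreasing directions.

## Hazard classification

Potencies map onto the Persoone acute-hazard classes through monotone
bands.  mg/L scale (left-closed, right-open): [0, 0.1) very high
acute, [0.1, 1) high acute, [1, 10) acute, [10, 100) low acute, ≥ 100
non-toxic.  Percent-dilution scale: (0, 25) high acute, [25, 75)
acute, [75, 100] low acute; an EC50 not reached at full strength
(censored) is non-toxic, and "very high" is not assignable on this
scale.  The published band edges carry internally inconsistent
inequality signs (e.g. "non-toxic < 100 mg/L" alongside compounds at
15–55 mg/L classified low acute); the monotone scheme above reproduces
every class assignment the source text and tables actually make.  One
statement in the source — 1.38 mg/L described as *high* acute — is
inconsistent with its own 1–10 band and is not reproduced.  A potency
censored above a bound below 100 mg/L cannot be banded at all and is
reported "n.e." in the class matrix.

## Mixture toxic units

For a mixture with component concentrations C_i and single-compound
EC50_i at the matching exposure time, TU_mix = Σ C_i/EC50_i.  TU < 1
is synergism, TU = 1 additive, TU > 1 antagonism; the additive band is
degenerate at {1} by default and configurable (e.g. 0.8–1.2) for
practical use.  Ratios accumulate at full precision and are rounded
once at report time.  Any component lacking an EC50 renders the whole
mixture not estimable.

Recomputing the published 20-mixture table (every component at
10 mg/L, 30-min denominators) reproduces 16 computable TU values, all
above 1, and 4 not-estimable mixtures.  At the last printed digit the
published table is internally inconsistent: ten rows match
full-precision accumulation exactly; four rows (1.71, 8.31, 7.90,
10.32) match only if each ratio is rounded to 2 dp before summing
(full precision gives 0.01 less); one row (4.93) matches only full
precision.  Two further rows are inconsistent with their own printed
denominators — one prints a denominator of 9.52 where 4.52 is used
everywhere else (total 13.31 vs consistent 13.33), another prints 9.47
where its denominators sum to 11.47 — and are excluded from
value-level comparison while still counting in the interaction census.
The tests assert exact 2-dp agreement on the ten consistent rows and
agreement within one print digit on the four ratio-rounded rows.

## Synthetic bioassay generator

The generative truth is the two-parameter log-logistic (Hill) curve
E(C) = 100/(1 + (EC50/C)^h), E(0) = 0, with E(EC50) = 50 exactly.
Defaults, chosen once:

| parameter | default | rationale |
|---|---|---|
| Hill slope h | 2 | steep responses typical of acute aquatic assays |
| Microtox noise | Gaussian, sd 3 %-points | instrument-level scatter on a single reading |
| crustacean design | 3 wells × 10 (*Artemia*) / 5 (*Daphnia*), Binomial(n, E/100) | the protocols' replicate design |
| Lemna areas | lognormal, CV 10%; control growth 0.3 d⁻¹ | plausible frond-area measurement error and healthy control growth |
| dilution series | 2-fold from 81.9% of stock (Microtox basic test) | the instrument's standard series |
| recovery design | 7 concentrations, √2-fold, centred on the true EC50 | spans ~11–89% effect at h = 2, where the logarithmic approximation to the sigmoid is good |
| 4-MBC stock | 10 mg/L | not reported; all other non-benzophenone stocks are 10 mg/L |

Every simulator draws from a single seeded generator stream, so a
fixed seed reproduces a dataset byte for byte.

The generator emulates the *statistical* structure the analysis
assumes — monotone log-logistic response, binomial quantal counts,
lognormal growth — not the chemistry: no solvent-carrier effects
(controls are clean by construction), no hormesis (stimulation is
recorded but never fitted), no between-batch organism variability.
Passing recovery tests therefore shows the estimation pipeline is
correct and well-calibrated under its own assumptions; it cannot
validate those assumptions against real laboratory data.

**Recovery harness.**  Each run simulates a dataset, reduces it to
effect points, fits the logarithmic model and inverts at 50%.  Because
the log-logistic is symmetric in ln C about the EC50, a symmetric
design makes the noiseless inverse exact despite the model mismatch;
with default noise the 200-run crustacean experiment places ≥ 90% of
estimates within ±20% of truth (observed ≈ 99%), and the median
relative error decreases monotonically over Microtox noise levels
6 → 3 → 1 %-points.  Lemna recovery is scored on the growth-rate
basis: the generator defines its effect on that scale (day-7 area
grows at μ𝒸(1 − E/100)), and the yield basis is a known nonlinear
transform of it that targets a different quantile of the curve (~34%
lower at these settings) — the yield basis remains the reporting
default for real data.

## Problem sizes

The analysis drivers and tests use 200-run recovery experiments
(100 per noise level for the noise sweep), 7-concentration designs and
the study's 20-mixture table; the full suite runs in a few seconds.
All fits are deterministic; only the generators consume seeds.

## Known limitations

* The published laboratory EC50/LC50/IC50 values cannot be reproduced
  because the raw dose–response observations were never deposited;
  value-level checks are limited to the quantities derivable from the
  published summary tables (TU_mix, critical R², classifications).
* Potency figures not printed in the text (only drawn in figures) are
  absent from `uvtox.datasets`, so the class matrix covers the
  text-reported subset.
* No probit/logit quantal-likelihood fitting and no bootstrap
  confidence intervals: the analysis mirrors the regression-based
  summary the study reports, which carries no interval estimates.
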