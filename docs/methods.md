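# Methods

## The measurement being modeled

A DNA molecule is tethered between a glass surface and a bead and stretched
by laminar flow at ~2.6 pN.  Enzymatic activity (primer extension,
unwinding, leading-strand synthesis) changes the tether's ss/ds composition
and therefore its extension; the bead position, sampled at 2 Hz, is the raw
readout.  At the working force, ss↔ds conversion corresponds to a fixed
factor of 3.76 nt/nm.  Depending on the substrate, activity lengthens the
tether (bead moves with the flow; `direction_sign = +1`) or shortens it
(`direction_sign = −1`); each geometry carries this sign, and all analysis
outputs are reported activity-positive.

## Generative model (the simulator)

Each trace is a leading baseline, then alternating activity bursts and
pauses, then a trailing baseline (and, on the bare-helicase shortening
substrate, a re-annealing ramp back to the start length):

* burst length ~ Exp(`proc_mean_bp`), clamped to the remaining template;
* burst rate ~ positive truncated normal (mean, SD), or a two-component
  mixture (narrow normal peak + exponential upper tail) for the
  heavy-tailed FPC condition;
* after each burst the complex restarts with probability `p_restart`
  following a pause of 3 s + Exp(`pause_mean_s` − 3) (the analysis cannot see
  pauses shorter than 3 s, so the family is left-shifted by construction);
* baseline noise is i.i.d. Gaussian in bp-equivalent units (optional drift
  is deliberately excluded — the analysis assumes drift-free baselines);
* sampling is exactly 2 Hz; ground-truth intervals tile the trace.

Ensembles are reproducible element-wise: trace *i* uses the seed sequence
`(master_seed, i)` (numpy `SeedSequence`), so growing an ensemble never
changes earlier traces.

### Preset parameters and how they were chosen

| preset | rate (mean ± SD) | single-burst mean | p_restart | pause mean | noise SD |
|---|---|---|---|---|---|
| pol_delta_pe | 240 ± 72 nt/s | 0.4 knt | 0 | – | 100 nt |
| ltag_alone | 1.1 ± 0.33 bp/s | 0.15 kb | 0 | – | 150 bp |
| ltag_rpa | 1.4 ± 0.42 bp/s | 0.64 kb | 0.2 | 182 s | 150 bp |
| sv40_ssb | 5.3 ± 1.59 bp/s | 0.3 kb | 0.4 | 182 s | 150 bp |
| sv40_rpa | 4.5 ± 1.35 bp/s | 0.3 kb | 0.4 | 182 s | 150 bp |
| sv40_fpc_mcm10 | 3.8 ± 1.14 bp/s | 0.55 kb | 0.5 | 182 s | 150 bp |
| sv40_fpc | mixture: 0.7·N(3.8, 1) + 0.3·(3.8 + Exp(64)) | 0.4 kb | 0.3 | 100 s | 150 bp |

Rate means, single/multi-step processivities and the 182 s pause mean are
the published per-condition values; restart probabilities follow from the
identity multi = single/(1 − p).  Quantities the condition tables do not
pin down were fixed once, before any recovery testing, on plausibility
grounds: rate SD = 0.3 × mean for every truncated-normal preset; baseline
noise 150 bp for the long dsDNA substrates and 100 nt for the shorter
primer-extension tether (bead positional noise grows with tether length;
all values respect the < 200 bp premise of the resolution rule); leading and
trailing baselines of 60 s; re-annealing at 5 bp/s; the FPC mixture weights
calibrated so its arithmetic mean rate is 23 bp/s while its peak stays at
3.8 bp/s.  The restart-pause mean for `ltag_rpa` reuses 182 s, the only
printed pause statistic.

## Noise characterization and resolution

Baselines of unreplicated molecules are histogrammed and fitted with a
Gaussian; the worst-case fitted SD is the noise level.  If every SD is below
200 bp the spatial resolution is 200 bp (the floor); otherwise the largest
SD is rounded up to the next 100 bp.  The flatness comparison "run SD <
noise SD" is implemented as a one-sided variance test at the 5% level,
`SD < noise_sd·sqrt(χ²₀.₉₅(n−1)/(n−1))`, because a literal point comparison
would reject half of all true pauses by chance (the sample SD of pure noise
straddles its expectation).

## Segmentation

Boundaries come from a continuous piecewise-linear (free-knot linear
spline) least-squares fit.  The bead position is continuous, so forcing
segments to connect concentrates statistical power at the kinks; a flat-run
("pause-first") grower cannot work at this SNR because a 1 bp/s event is
indistinguishable from a pause on any sub-minute window.  Knots are inserted
greedily while the RSS gain exceeds `Q_INSERT = 7` noise variances —
deliberately below the max-selection null level (~2 ln n), because a missed
kink biases every downstream statistic while a spurious kink merely splits a
segment that classification re-merges — then swept with per-knot
reposition/eliminate passes at the unselected χ²(1) 1% level
(`Q_REMOVE = 6.6`).  Adjacent-sample knots are allowed so that true steps
(fast bursts) are representable.

Classification of the inter-knot segments applies the operational rules:
pause (≥6 samples, ≥3 s, flat by the variance test, |slope| < threshold),
event (Δ ≥ resolution, activity-signed, |rate| ≥ threshold), re-annealing
(post-final-event negative progress on shortening substrates), else
baseline.  Sub-resolution flat wiggles with |slope| below half the category
mean merge into the surrounding pause; genuine sub-resolution bursts are
faster and keep distinct pauses distinct.  A short steep candidate must
*persist* (step the level past the following segment) so single-sample noise
spikes are rejected.  With `threshold = 0` (pass 1) all rate criteria are
vacuous: events are collected exhaustively, as the two-pass procedure
requires.  The two-pass threshold (one tenth of the Gaussian-fitted mean
rate, rounded to one significant figure — reproducing the printed 0.1 and
0.5 bp/s) is iterated to a fixed point, because the exhaustive pass slightly
underestimates rates and can otherwise round the threshold one step low.

### Per-event estimators

Least-squares boundary estimates are biased outward at low SNR (narrowing a
fitted ramp incurs steep corner misfit, widening only a shallow wedge), so
naive delta/duration rates are diluted.  Instead, for an event flanked by
flat segments:

* **delta** = difference of the flanking plateau levels, measured ≥ 20 s
  away from the boundaries — the sharpest available estimate; candidates the
  plateaus place below the resolution are demoted to baseline;
* **midpoint** from a two-level step fit with both plateaus fixed
  (symmetric cost → unbiased, sharply localized);
* **rate**, slow regime: OLS slope over a window centred on the midpoint and
  sized to the ramp the delta implies at the category mean rate (10× the
  threshold), capped at half the fitted extent, so the window sits inside
  the true ramp without trusting the outward-biased boundaries;
* **rate**, steep regime (category mean per-sample rise ≥ 0.3 × noise SD,
  i.e. sampling-limited bursts like 240 nt/s primer extension): a
  fixed-plateau trapezoid scan over both kink positions, whose corner misfit
  dominates the noise there, with a half-sample grid correction (fitted
  kinks snap outward to the sampling grid).

Events without a flat reference on either side cannot be quantified against
the baseline noise and are not reported.

## Per-trace and ensemble statistics

Single-step processivity/lifetime/rate are per-event; multi-step
processivity is the **total fitted DNA length change** of the trace (up to
any re-annealing), which includes sub-resolution bursts before, between and
after the detected events — exactly what the tether length integrates.
Summing only detected steps would bias the multi-step mean low by ~15%
because sub-resolution bursts are individually invisible.  The multi-step
lifetime spans first event start to last event end, so interior pauses are
included; restart pauses are interior pauses only.

Rate histograms are fitted with an unconstrained Gaussian (bin width =
mean/8 by default; reported mean ± SE of the fitted mean parameter, with
the sample mean/SD as cross-check).  Processivities, lifetimes and pauses
are fitted with a single-exponential decay after excluding bins below the
cutoff (200 bp for lengths, 3 s for durations) *and* leading bins still
clearly rising (< 80% of the histogram maximum) — detection losses extend
above the nominal cutoff, and by memorylessness dropping such bins is
harmless for exponential data.  The reported decay constant is the
left-truncated maximum-likelihood estimate (mean of the exceedances), which
is unbiased at any cutoff; the binned least-squares value is retained as a
cross-check and agrees within 15% at n ≥ 100.  At the published sample sizes
(~40 traces) the unweighted sparse-histogram fit is systematically ~15% low,
which is why the MLE is primary.  The far tail beyond the 97.5% quantile is
cropped from the histogram so empty bins do not drag the fit.

## MST binding

The quadratic (ligand-depletion) isotherm is used because the labeled
target (20 nM) is comparable to the fitted K<sub>d</sub> (~7 nM); the
hyperbolic approximation mis-reads the bound fraction by up to ~0.3 in this
regime.  It is evaluated in the cancellation-free form
2A/(K+A+T+√((K+A+T)²−4AT)) so the K = 0 stoichiometric limit is exact.  The
titration is modeled as a 16-point two-fold dilution from 250 nM final
(500 nM series mixed 1:1 with the labeled protein); plateaus are fitted by
default and can be fixed.

## Problem sizes and tolerances

The end-to-end recovery battery (`scripts/acceptance.py`,
`tests/test_acceptance.py`) uses the published sample sizes — 151
primer-extension events, 51/81 unwinding events, 111/84 leading-strand
events, 39–40 traces for the multi-step fits, ≥100 traces for the
restart-pause and FPC+Mcm10 statistics, 50 MST replicates at 2% noise —
with traces of at most a few thousand samples, and reports medians over
five sub-seeds.  Gaussian rate means recover within 10%, exponential
means within 15%, the K<sub>d</sub> within 15% (≤0.1% noise-free).

## What passing recovery does and does not show

The simulator realizes exactly the statistical structure the analysis
assumes: ideal exponential/truncated-normal kinetics, i.i.d. Gaussian noise,
no drift, no tracking artifacts, no photobleaching or stage creep, no
correlated bead fluctuations, and step-free instantaneous transitions
between burst and pause.  Passing recovery therefore validates the
estimator chain under those assumptions; it does not certify performance on
real traces with drift, correlated noise, or non-exponential dwell times.
Known limitations: per-event rates of bursts shorter than ~2 samples are
quantization-limited; events below ~1.5× the noise SD are detected with
reduced recall near the 200 bp boundary; restart-pause pools are inflated a
few percent when an invisible sub-resolution burst joins two pauses.
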