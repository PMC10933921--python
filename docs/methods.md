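# Methods

This note describes the models and procedures implemented in `linerslip`,
the assumptions behind them, the numerical choices made where the design
was genuinely open, and what the synthetic-data tests do and do not
demonstrate about real milking data.

## 1. The measurement problem

A milking liner slip is a transient loss of the seal between the teat and
the liner mouthpiece. On the short milk tube (SMT) it appears as a rapid
vacuum drop of tens of kPa over a fraction of a second, superimposed on
two regular signal components: the pulsation-locked *cyclic* fluctuation
(60 cycles/min, a few kPa) and the slow flow-driven vacuum trend over the
milking. Three instruments flag slips at very different time scales:

| method | signal | rule | flag |
|---|---|---|---|
| milk meter | air-bleed index 0–255 | strictly above slip limit 175 for ≥ 30 s | `SLP_MM` |
| observers 1–3 | audible squawk | any duration, within the observer's station | `SLP_OB1..3`, `SLP_ANY` |
| vacuum recorder | 200 Hz SMT vacuum | drop ≥ 21 kPa at ≥ 100 kPa/s (type 1) or ≥ 14 kPa at ≥ 56 kPa/s (type 2) | `SLP_V1`, `SLP_V2` |

The analysis layer quantifies pairwise agreement between these binary
flags (Cohen's κ, Landis–Koch bands) and the diagnostic performance of
the milk meter against each alternative as gold standard (Se, Sp, PPV,
NPV with Wald 95 % intervals, plus the false-negative ratio c/(c+d)).

## 2. Synthetic milking observations

The generator (`linerslip.simulate`) emulates the statistical structure
this analysis depends on, not parlor physics. Per observation:

* **Unit-on time** ~ Normal(255 s, 56 s), **milk yield** ~ Normal(15.9 kg,
  4.2 kg), both truncated to positive values by resampling; days in milk
  and lactation-number distributions match typical herd structure.
* **Milk flow** is trapezoidal: a 30 s ramp, a plateau, a linear decline
  from 60 % of unit-on time down to a small residual flow, and a 2 s
  take-off. The curve is scaled so its integral equals the drawn yield
  (hence peak flows of ~3–6 kg/min and average flow ≈ 3.7 kg/min at the
  defaults). With probability `bimodality_prob` (0.3) a cosine dip to
  30 % of ramp flow between 15 s and 45 s models bimodal let-down; the
  ground-truth peak-flow onset then moves to the end of the dip.
* **SMT vacuum** = flow-responsive system vacuum − 2.5 kPa·(kg/min)⁻¹ ·
  flow + cyclic component + slips + Gaussian noise (sd 0.5 kPa), clipped
  to [0, 60] kPa. The regulation switches 42 → 46 kPa around
  2.3 kg/min through a logistic response of width 0.5 kg/min; the width
  is chosen so vacuum is strictly monotone in flow, which keeps the
  phase-boundary rules well posed. The cyclic component is a lightly
  smoothed 65:35 square wave, amplitude 3 kPa scaled by relative flow.
* **Slips**: per-phase Poisson counts with means
  (`slip_rate_begin/mid/end`, defaults 0.058/0.048/0.028 — the observed
  phase-wise slip frequencies of the audible-detection trial; in this
  rare-event regime the Poisson mean and the presence probability agree
  to well under a standard error). Event start times are uniform within
  the phase window but keep clear of the attachment transient and the
  final 4 s — a slip requires an attached, milking unit. Durations are
  log-normal (median 2 s, σ = 1 log-unit), magnitudes uniform on
  14–35 kPa, descent rates uniform on 56–200 kPa/s and floored at
  magnitude/duration so every event can realize its magnitude. The
  waveform is a linear descent at the event's rate, a hold at −magnitude,
  and an exponential recovery (τ = 0.3 s).
* **Air bleed** = baseline 40 + Gaussian noise (sd 10) + 7 × magnitude
  during each slip, clipped to [0, 255]. With the default 175 slip limit
  this makes type-1-sized events visible to the meter if (and only if)
  they last long enough.
* **Phases** for ground-truth labels: begin = first 25 % of unit-on time,
  end = last 15 %, mid = the rest, mirroring the three observer stations.

Reproducibility: every observation draws from
`SeedSequence(seed, spawn_key=(index, stream))` streams, so herds are
bit-identical across runs and safely parallelizable.

**What the generator does not contain**: mouthpiece-chamber vacuum,
pulsation-chamber dynamics, near-infrared sensor physics, cow behavior
(kick-offs), inter-cow correlation, or farm effects. Passing tests show
the *procedures* are correct and internally consistent under controlled
conditions; they do not validate detector performance on real parlors.

## 3. Detection procedures

**Milk meter** (`detect_meter_slip`): run-length scan of samples with
air-bleed strictly above the slip limit; present iff some run spans at
least the minimum duration (run length × sampling step, inclusive — at
200 Hz, 6000 samples = 30.0 s is present, 5999 samples is not). Traces
shorter than the minimum duration return absent with a warning. The flag
is binary only, like the physical device.

**Irregular vacuum fluctuations** (`detect_irregular_fluctuations`):

1. *Baseline*: a trailing 5 s moving median, then a 1 s moving mean.
   Trailing, because a centred window becomes majority-slip right at the
   onset of any event longer than half the window and erases it; 5 s,
   because a one-cycle (1 s) window would track and cancel the typical
   2 s slip itself; the mean smooths the median's step discontinuities so
   baseline catch-up jumps cannot masquerade as rapid descents
   (bounded at ~magnitude/1 s ≪ 56 kPa/s for realistic magnitudes).
2. *Candidates*: troughs of the 25 ms-smoothed residual with prominence
   ≥ min(8 kPa, 0.6 × the rule's magnitude) — above cyclic + noise
   excursions, below any magnitude threshold of interest. For each trough
   the pre-event maximum is sought up to 4 s back (the trough index can
   sit anywhere in a flat, noisy slip bottom) and the event minimum after
   it. A candidate whose minimum is not below −0.5 × its own magnitude is
   discarded: genuine slips descend *below* baseline, while
   baseline-catch-up artifacts decay from above.
3. *Measurements*: magnitude = residual maximum − minimum over the
   segment (raw, so an exact-threshold clean drop measures exactly its
   magnitude); descent rate = steepest drop of the smoothed residual over
   windows of 25–250 ms. Sub-25 ms windows are excluded — at 200 Hz with
   0.5 kPa noise, single-sample slopes have a noise sd of ~140 kPa/s.
4. *Merging and thresholds*: candidates closer than 0.5 s merge into one
   cluster (one physical squawk) **before** thresholding, and a cluster
   passes a rule iff its measured magnitude and rate both meet it.
   Because type-1 thresholds (100 kPa/s, 21 kPa) dominate type-2
   (56 kPa/s, 14 kPa) and both rules see identical clusters, the type-1
   event set is structurally a subset of the type-2 set on every trace.
   Merging after thresholding would not guarantee this (a type-2-only
   event can bridge two type-1 events).

Magnitude is measured from the local maximum, not a long-run pre-drop
baseline (the two differ by the cyclic amplitude at most); this
convention is configurable through the baseline window.

**Observer emulation** (`detect_observer`): present iff at least one
ground-truth event overlapping the observer's window (fractions of
unit-on time; defaults 0–25 %, 25–85 %, 85–100 %) is heard, each
overlapping event independently with probability 1 − `miss_prob`. The
default miss probability is 0: the phase-rate defaults already encode
*observed* audible frequencies, so the emulated observers record what is
there. Randomness is keyed on (seed, observer, observation).

**Phase segmentation** (`segment_phases`) replaces the human annotation
step with rules on a smoothed vacuum (1 s mean — cancels the duty-cycled
pulsation, whose running median would otherwise sit 0.7 × amplitude above
the mean — then a 15 s median, robust to slips shorter than ~7.5 s):
start of milking = first sample above 20 kPa; take-off = last sample
above 30 kPa; peak-flow start = first time the smoothed vacuum is within
0.8 kPa of its robust (10th-percentile) session minimum *and* locally
flat (centred 5 s slope ≥ −0.025 kPa/s, estimated on a lightly filtered
signal because the long median rounds the ramp-to-plateau corner);
cyclic-fluctuation start is identified with peak-flow start; overmilking
start = last crossing of the smoothed vacuum above (end-of-session level
− 2.5 kPa), the vacuum rebound as gland flow dies away, kept only when
at least 10 s precede take-off. The simulator's ground-truth overmilking
boundary applies the same rebound rule to the clean flow-driven vacuum
curve, which at default settings corresponds to flow falling to roughly
the cluster-remover threshold (~1.6 kg/min). On default herds the
recovered peak-flow and overmilking boundaries land within 5 s of ground
truth for ≳ 95 % of traces; the residual tail is caused by long slips
overlapping a boundary, and is a known limitation of the rule-based
stand-in rather than of the statistics layer.

**Average cyclic vacuum** (`avg_cyclic_vacuum`): the mean of the ten
per-cycle mean SMT vacuums over ten consecutive pulsation cycles starting
60 s after peak-flow start; errors name the required vs. available
duration.

## 4. Agreement statistics

`cohen_kappa` implements κ = (p_o − p_e)/(1 − p_e) with the asymptotic
variance of Fleiss, Cohen and Everitt (1969); the implementation is
cross-checked in the tests against `statsmodels.stats.inter_rater` to
14 decimal places but is authored here because the sample-size layer
reuses the variance at hypothesized tables. CIs are κ ± z₁₋α/₂·SE,
clamped to [−1, 1]; the degenerate p_e = 1 case raises. Landis–Koch
bands are applied to the value rounded half-up to two decimals so that
printed boundary values land in their printed band (0.60 → moderate,
0.61 → good).

`diagnostic_stats` uses the Wald interval p ± 1.96·√(p(1−p)/n) with the
z-value fixed at 1.96 (the interval definition used throughout this
analysis), clamped to [0, 1]; a zero denominator yields an undefined
marker, never 0. Bands: ≤ 0.60 low, 0.61–0.80 moderate, > 0.80 high, on
the 2-dp rounded value. Printed-precision comparisons round half-up to
two decimals (three where the published value carries three).

Missing flags are removed by pairwise-complete deletion before
cross-tabulation, with the dropped count logged.

Published κ confidence intervals are *not* asserted anywhere: the exact
SE variant behind the published intervals is not reconstructible (at
least one published diagnostic CI bound also differs from its own stated
formula), so only point values at printed precision are compared.

### Known discrepancies

`fixtures.KNOWN_DISCREPANCIES` records published values that conflict
with the published tables themselves: the trial-2 κ values (printed 0.13
and −0.18 vs. 0.22 and 0.09 from the table counts), the observer-1 κ
(0.25 vs. 0.26), one sensitivity (printed 0.10 vs. 47/496 = 0.095 →
0.09, although the printed CI matches the counts), and the
observer-combination rows, which require unpublished three-way joint
counts. The package reports table-derived values; these entries exist so
no user mistakes the difference for a bug.

### Rater simulation and sample size

For two binary raters, margins (π₁, π₂) plus κ pin down the joint
distribution: p₁₁ = κ√(π₁(1−π₁)π₂(1−π₂)) + π₁π₂, remaining cells from
the margins; infeasible combinations raise naming the offending cell.
`simulate_raters` draws multinomial tables from it; `kappa_sample_size`
evaluates the Fleiss–Cohen–Everitt SD at the null and alternative tables
and returns N = ⌈((z₁₋α/₂σ₀ + z_power σ₁)/(κ₁ − κ₀))²⌉ (Flack et al.
1988; no variance maximization is needed in the 2×2 case). The
Monte-Carlo power oracle applies the Wald z test — κ̂ standardized by its
estimated SE, equivalent to checking whether κ₀ falls outside the CI —
at the returned N; at the study design (5 %/5 %, 0.4 vs 0.6, α 0.05
two-sided, power 0.8 → N = 771) empirical power is ≈ 0.79.

CI-coverage properties are exercised at rater positive rates of 0.3,
where the Wald interval is well conditioned at n = 500; at 5 % positive
rates and n = 500 only ~25 positives exist per rater and the Wald
interval is known to undercover slightly — a property of the interval,
not of the implementation.

## 5. Problem sizes used by the test suite

Chosen to make Monte-Carlo error negligible relative to the asserted
tolerances: herd calibration at n = 1000–2039 observations (3-SE bands);
detector recall/precision over 500 traces (~600 injected events);
estimator recovery at n = 10⁵ pairs averaged over 40 replicates
(MC error ≈ 0.001 against a 0.01 bias bound); CI coverage and power over
2000 replicates (binomial SE ≈ 0.9 points).

## 6. Known limitations

* The generator's vacuum model is phenomenological; absolute levels
  (e.g. the average cyclic vacuum of simulated herds) are plausible but
  not calibrated to any instrument.
* Phase segmentation degrades when long slips overlap a phase boundary
  (section 3); traces shorter than ~15 s clamp their boundaries with a warning.
* Descent-rate measurement near the 100 kPa/s boundary can be inflated by
  a pulsation edge coinciding with a slip, so type-1 vs type-2
  classification of borderline events is noisier than event *detection*;
  the dominance relation is unaffected.
* The air-bleed channel inside the meter is modelled at the trace
  sampling rate; the real device's internal rate is unknown.
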