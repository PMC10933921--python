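# linerslip

Simulation and agreement analysis of milking **liner-slip** detection in
dairy cows: comparing an on-farm milk-meter sensor against audible
detection by parlor observers and against high-frequency vacuum
recordings.

A liner slip is a rapid air leakage past the mouthpiece of the milking
liner — audible as a squawk — and a risk factor for new intramammary
infection. Three very different instruments can flag it during a milking
observation:

* an electronic **milk flow meter** that raises a binary flag when its
  0–255 air-bleed index stays above a *slip limit* (175) for at least
  30 s (`SLP_MM`);
* **observers** stationed at the beginning / middle / end of milking who
  record any audible squawk (`SLP_OB1..3`, combined `SLP_ANY`);
* a 200 Hz **vacuum recorder** on the short milk tube, from which
  irregular vacuum fluctuations are extracted — type 1: a drop of
  ≥ 21 kPa at ≥ 100 kPa/s; type 2: ≥ 14 kPa at ≥ 56 kPa/s (`SLP_V1`,
  `SLP_V2`).

The package provides:

* `linerslip.simulate` — a synthetic generator of milking observations:
  200 Hz short-milk-tube vacuum traces with a 60 cycles/min
  pulsation-locked cyclic component, milk-flow–dependent vacuum, injected
  slip transients with controlled magnitude (kPa) and descent rate
  (kPa/s), an air-bleed channel, ground-truth event logs, and
  observation-level milking characteristics (milk yield 15.9 ± 4.2 kg,
  unit-on time 255 ± 56 s, ...);
* `linerslip.detect` — the three detection procedures plus rule-based
  milking-phase segmentation and the average-cyclic-vacuum summary;
* `linerslip.agreement` — the statistics layer, organised as a
  model/results pair: `RaterAgreement(table).fit()` returns Cohen's κ
  with its Fleiss–Cohen–Everitt asymptotic confidence interval and
  Landis–Koch band, sensitivity/specificity/PPV/NPV with Wald intervals
  (± 1.96·√(p(1−p)/n), clamped to [0, 1]), and the false-negative ratio
  c/(c+d);
* `linerslip.samplesize` — the two-rater κ sample-size calculation
  (Flack, Afifi, Lachenbruch & Schouten 1988);
* `linerslip.fixtures` — the published 2×2 contingency tables of both
  field trials (2039 and 904 milking observations), checksummed, plus a
  registry of published values that are inconsistent with those tables;
* a `linerslip` command-line interface (`simulate`, `detect`, `agree`,
  `samplesize`, `reproduce-paper`, `run`).

## The statistics at the core

For a 2×2 table (a, b, c, d) crossing a test method against a gold
standard (n = a+b+c+d):

```
κ  = (p_o − p_e) / (1 − p_e),   p_o = (a+d)/n,
p_e = [(a+b)(a+c) + (c+d)(b+d)] / n²
Se = a/(a+c)   Sp = d/(b+d)   PPV = a/(a+b)   NPV = d/(c+d)
```

κ's standard error is the Fleiss–Cohen–Everitt large-sample SE; the
sample size for testing H₀: κ = κ₀ against κ = κ₁ with rater positive
rates π₁, π₂ is

```
N = ⌈((z₁₋α/₂ σ₀ + z_power σ₁) / (κ₁ − κ₀))²⌉
```

with σ₀, σ₁ the per-observation SDs of κ̂ evaluated at the unique 2×2
joint distributions implied by the margins and κ
(p₁₁ = κ√(π₁(1−π₁)π₂(1−π₂)) + π₁π₂).

## Worked example

```python
>>> from linerslip import RaterAgreement, ContingencyTable2x2
>>> table = ContingencyTable2x2(69, 57, 28, 1885)   # milk meter vs observer 2
>>> res = RaterAgreement(table).fit()
>>> print(res.summary())
Two-rater slip-detection agreement
==================================
n = 2039   a=69  b=57  c=28  d=1885
test-positive: 126 (6.2%)   gold-positive: 97 (4.8%)
kappa = 0.60 (0.52-0.68)  [moderate]
Se  = 0.71 (0.62-0.80)  [moderate]
Sp  = 0.97 (0.96-0.98)  [high]
PPV = 0.55 (0.46-0.63)  [low]
NPV = 0.99 (0.98-0.99)  [high]
false-negative ratio = 1.5%
```

The milk meter agrees moderately with the mid-milking observer (κ 0.60),
catches 71 % of the slips that observer hears (Se), and almost never
flags a slip the observer did not confirm absent (Sp 0.97); only 1.5 % of
meter-negative observations hide a heard slip.

Simulating a herd dominated by short slips shows the central
under-detection effect — the 30 s duration requirement makes the meter
blind to most vacuum-detectable events:

```python
>>> from linerslip import run_pipeline
>>> stats = run_pipeline({"n": 60, "seed": 11, "simulation":
...     {"slip_rate_begin": 0.5, "slip_rate_mid": 0.4, "slip_rate_end": 0.3}},
...     "report/")
>>> stats["comparisons"]["slp_mm_vs_slp_v2"]["table"]
{'a': 1, 'b': 0, 'c': 42, 'd': 17, 'n': 60}
```

43 of 60 simulated observations contain a type-2 fluctuation but the
meter flags only one of them.

Sample size from the shell:

```bash
$ linerslip samplesize --pi1 0.05 --pi2 0.05 --k0 0.4 --k1 0.6 \
      --alpha 0.05 --power 0.8 --two-sided
771
```

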