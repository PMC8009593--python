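# aequosim

A desk-scale digital twin of a silicon-photomultiplier (SiPM) aequorin
luminometer, for instrument scientists and cell biophysicists who want to
reason quantitatively about photon-counting versus charge-integration
readout of bioluminescent Ca²⁺ probes before (or instead of) touching
hardware.

## The system being modelled

Aequorin (AEQ) is a consumable Ca²⁺ reporter: upon binding three Ca²⁺ ions
it oxidizes its substrate coelenterazine and emits one blue photon per
molecule. A finite pool *N(t)* of reconstituted molecules therefore
discharges under a calcium trajectory Ca(*t*) as

    dN/dt = −λ(Ca) · N,    L(t) = λ(Ca) · N(t),
    λ(Ca) = λ_max · Ca³ / (Ca³ + K½³),

where *L(t)* is the expected photoelectron rate at the sensor (collection
and detection efficiency are folded into the pool size, expressed directly
in photoelectrons). The SiPM output is read out through two parallel
branches:

* **SPC (single-photon counting)** — discriminated pulses counted in 100 ms
  windows. The 30 ns shaped-pulse duration τ acts as a paralyzable dead
  time, so the counted rate follows *n·e^(−nτ)* and pile-up limits the
  branch to a few MHz; the dark-count rate (DCR, 904 kHz) sets the noise
  floor, with the Poisson-limited detection threshold
  LoD = 3·√(DCR/Δt).
* **CI (charge integration)** — a gated integrator (4–32 µs gates, 272
  fC/photoelectron, 11.2 kHz sampling, 12-bit ADC) that is immune to
  pile-up up to ADC full scale, but pays an electronic-noise penalty that
  block averaging (5600 samples → 2 Hz traces) reduces.

The package generates the bench scenarios synthetically — 2-fold geometric
dilution series of AEQ lysate, live-cell ATP transients followed by Triton
X-100 lysis, sub-50-kHz spontaneous Ca²⁺ oscillations, a fast mitochondrial
uptake transient, and the stochastic single-photon LED train used to probe
CI sensitivity — and implements the full characterization pipeline:
baseline subtraction, integrated intensity in photoelectrons, peak
frequency, log₂–log₂ linearity fits with exclusion presets, analytic and
empirical limits of detection, and the A/T discharge-fraction statistic
(agonist over lysis integrals).

## Worked example

Closed-form figures of merit:

```python
>>> import aequosim as aq
>>> aq.lod_analytic(904e3, 0.1).lod_hz        # SPC, 100 ms windows
9019.977827023746
>>> aq.lod_analytic(904e3, 5e-6).lod_hz       # CI, 5 us gates
1275617.4975281581
>>> det = aq.DetectorConfig()
>>> aq.expected_counted_rate(2e6, det)        # 2 MHz after pile-up losses
1883529.0671684975
>>> aq.pileup_probability(2e6, det)
0.05823546641575128
```

So a 904 kHz dark floor gives a 9.0 kHz counting LoD per 100 ms window but
a 1.28 MHz LoD per 5 µs gate, and at 2 MHz a 30 ns pulse loses 5.8 % of
events to overlap.

End-to-end dilution-series characterization (12 dilutions, both branches,
5 noise seeds):

```text
$ aequosim simulate dilution_series --seed 7 --outdir out/dilution
a_spc_full_mean: 0.9825587788130452
a_spc_trimmed_mean: 0.9917137189920927
a_ci_full_mean: 0.9748433603692106
a_ci_trimmed_mean: 0.9956805219704051
q_spc_mean: 24.097991628324262
q_ci_mean: 24.220629930513248
ratio_2dq_mean: 0.9279728229770694
span_decades: 3.3113299523037933
```

The series spans 3.31 decades (log₁₀ 2¹¹). The SPC full fit is sublinear
(slope < 1) because the top dilutions peak near 10 MHz where pile-up clips
the burst; trimming the three highest concentrations restores slope ≈ 1.
The CI branch is linear once the three lowest points — which sit near its
noise floor — are excluded. Intercepts *q* are in log₂ photoelectrons, so
2^Δq compares branch sensitivities; in the twin both branches are converted
to the same photoelectron scale, so the simulated 2^Δq ≈ 1.

Live-cell recording (ATP transient consuming 3.75 % of the pool, then
lysis; fast ×0.1 duration preset):

```text
$ aequosim simulate live_cell --seed 7 --scale 0.1 --outdir out/live
at_ci_mean: 0.0386836513966734
at_spc_mean: 0.07167349763056433
```

The CI branch recovers the generative discharge ratio
A/T = 0.0375/0.9625 ≈ 0.039; the counting branch overestimates it because
the Triton burst drives extreme pile-up (the report also flags the 16-bit
scaler overrange during the burst).

Experiments accept YAML configuration files (`--config`), write trace
tables and a `report.yaml` embedding the fully resolved configuration, and
are bit-for-bit reproducible for a given seed.

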