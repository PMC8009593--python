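# Methods

This note documents the models, numerical choices and limitations of the
`aequosim` digital twin: a bioluminescence source model feeding two
simulated acquisition branches (single-photon counting, SPC; charge
integration, CI) and the analysis pipeline that characterizes them.

## Source model

Aequorin is consumed as it reports: each molecule emits at most one photon.
The pool obeys the survival equation dN/dt = −λ(Ca)·N with a Hill-form
hazard

    λ(Ca) = λ_max · Ca^h / (Ca^h + K½^h),      h = 3 by default,

the cooperativity reflecting the photoprotein's three Ca²⁺ binding sites.
The published record does not fix the rate law or the absolute Ca²⁺
calibration of the probe, so all kinetic constants are stand-ins and remain
configurable:

| parameter | default | rationale |
|---|---|---|
| λ_max | 1 s⁻¹ | saturating-Ca²⁺ discharge completes in seconds–minutes, matching recorded lysate traces |
| K½ | 5 µM | between resting (0.1 µM) and stimulated (1–50 µM) cytosolic levels, so resting glow is ~10⁻⁵·λ_max |
| resting Ca²⁺ | 100 nM | physiological cytosolic level |
| saturating Ca²⁺ | 10 mM | extracellular CaCl₂ excess after lysis/injection |
| n_total | per scenario | expected *photoelectrons*: geometric collection and the sensor's photon-detection efficiency are constant multipliers and are folded in, since nothing testable distinguishes them from pool size |

Integration uses the exact per-step exponential update
N_{k+1} = N_k·exp(−λ_k·Δt) with λ evaluated at the left grid edge —
unconditionally stable and positivity-preserving. Grids with λ·Δt > 0.1
anywhere are refused, bounding the quadrature error of the conservation
integral below 0.1 %. Conservation (∫L dt = N(0) − N(end)) is checked with
a hazard-midpoint quadrature, (N_k + N_{k+1})/2 · ln(N_k/N_{k+1}), which is
accurate to O((λΔt)²) even across discontinuous Ca²⁺ steps; a plain
trapezoid of the edge-sampled rate would smear a step by λΔt/2 and fail the
bound spuriously.

Calcium scenarios are ordered segments with a baseline and an optional
transient: a step (lysis, CaCl₂ injection), a normalized double-exponential
rise–decay (agonist responses; rise 2 s / decay 15 s by default for the ATP
transient, 1 s / 5 s for the faster mitochondrial uptake), or a periodic
train of rise–decay events (spontaneous oscillations, pool rescaled so the
peak emission stays below the 50 kHz regime where such signals are
observed).

The live-cell scenario solves the ATP transient peak by bisection (on
log Ca) so that the *transient-attributable* pool consumption in the
ATP window — the excess over resting-glow consumption — equals the
requested fraction. Solving for the excess rather than the raw pool drop
keeps the generative construction consistent with baseline-subtracted
measurements, which remove the resting glow together with the dark level;
at small fractions (1 %) the resting glow would otherwise bias the target
by ~14 %.

## Counting branch (SPC)

Arrivals are signal plus dark. Signal counts per grid interval are Poisson
with the interval's exact expected emission (the pool drop, not a sampled
rate), dark counts Poisson at DCR·Δt; in event mode arrival times are
placed uniformly within their interval, which realizes the inhomogeneous
process at the grid resolution. The configured DCR is the generative dark
arrival rate.

Dead time: the 30 ns full development of the shaped single-photoelectron
pulse. The default model is paralyzable — a leading-edge discriminator on
overlapping pulses re-extends occupancy, and the counted rate follows
n·e^(−nτ), consistent with losses growing smoothly to dominate around
3 MHz. The non-paralyzable alternative n/(1+nτ) is retained for sensitivity
analysis. The 50 % discriminator threshold affects only occupancy, never
single-event efficiency (an isolated single-pe pulse always crosses half of
its own amplitude).

Two simulation regimes agree in distribution where both apply:

* **event mode** — explicit times; dead time applied event by event;
* **binned mode** — per-bin Poisson counts; dead time as binomial thinning
  with survival probability R(r)/r, where R is the closed-form counted-rate
  law and r the bin's true total rate. The mean reproduces R exactly and
  the counts stay sub-Poisson, like real dead-time counting.

The automatic switch (total rate above 5 MHz) exists for direct API use;
the experiment drivers default to binned mode throughout, because
megahertz dark rates over minutes mean 10⁷–10⁸ events per trace and the
binned regime reproduces the same window statistics in milliseconds.

Counting windows are 100 ms. Window counts above the 16-bit scaler range
are always *flagged*; clipping at 2¹⁶−1 is opt-in, because the quoted
904 kHz dark level itself corresponds to 90,400 counts per 100 ms window —
above 16-bit full scale — so the physical readout must effectively recover
the full count, and clipped defaults would contradict the measured rates
the twin is built around.

## Charge-integration branch (CI)

Per 5 µs gate the photoelectron count is Poisson with mean
gate·(L(t)+DCR) — charge integration sees no dead-time loss, overlapping
pulses simply add charge. Charge is 272 fC per photoelectron plus white
Gaussian amplifier noise, an optional baseline random walk (off by
default), and a pedestal, then quantized to a 12-bit ADC with the overflow
flagged; noise-driven underflow is clipped at channel zero, as in hardware,
where the pedestal exists to make it rare.

Defaults: pedestal 50 channels and 40 fC/channel, chosen so a ~50 MHz lysis
burst spans ≈1700 channels of the 12-bit range — the dynamic-range regime
the instrument operates in. The amplifier gain stage (2.5×–10×) is absorbed
into the charge-per-channel figure. The white-noise default, 700 fC per
gate (≈2.6 pe), is a calibration: it places the single-gate empirical LoD
near 2 MHz and the 5600-sample-averaged LoD at a few tens of kHz, the
operating regime of the amplifier the twin emulates; it is a configuration
parameter, not a constant of nature.

Block averaging takes non-overlapping means (5600 samples → 2 Hz traces;
1000 for live-cell runs), drops the trailing partial block, and flags a
block if any member gate overflowed. With white noise only, block means
shrink the noise by exactly √K; the optional drift term exists to emulate
the slower-than-√K improvement seen with residual baseline fluctuations.

## Analysis pipeline

* **Baseline subtraction** — mean of a pre-stimulation window (≥10 samples;
  the 30 s pre-injection period by default), subtracted from all samples.
* **Integrated intensity** — in photoelectrons for both branches: total
  counts for SPC; for CI the per-gate photoelectron equivalents are
  rescaled by the gate duty cycle (sample spacing / gate), so both branches
  estimate the same number of oxidation reactions. The lysate signal window
  is [injection, injection + 4 discharge time constants] (98 % capture,
  identical at every dilution, hence irrelevant to fitted slopes).
* **Peak frequency** — maximum after a centered 3-sample moving average;
  the minimal smoothing stabilizes the maximum of a Poisson trace without
  distorting minute-scale kinetics. For transients whose counted rate bends
  on the 0.3 s scale (e.g. the mitochondrial uptake at λ ≈ 1 s⁻¹), the
  windowing itself lowers the observed peak by a few percent; the mito
  driver therefore reports both the instantaneous closed-form counted peak
  and the windowing-aware expectation of the estimator.
* **Linearity fits** — ordinary least squares of log₂(integral) on
  log₂(dilution factor). Base 2 is forced by the 2-fold dilution design:
  intercept differences then give sensitivity ratios directly as 2^Δq.
  Slope and intercept uncertainties are OLS standard errors. Exclusions are
  caller-specified index sets, with "lowest-3" and "highest-3" presets for
  the two standard trimmed fits; excluded points are dropped *before*
  taking logarithms, so a below-noise-floor (non-positive) integral among
  them is harmless, while a non-positive included integral is an error.
* **Limit of detection** — analytic: 3·√(DCR/Δt) (three Poisson standard
  deviations of the dark-rate estimate over the integration time; 9.0 kHz
  at 100 ms, 1.28 MHz at 5 µs for a 904 kHz DCR). Empirical: dark mean and
  SD of a stationary trace (≥100 samples), with the μ+3σ separation
  criterion converted to rate units through the channel's linear response
  (σ of window frequency for SPC, σ of per-gate photoelectrons divided by
  the gate for CI).
* **A/T statistic** — agonist and lysis integrals on disjoint windows of a
  baseline-subtracted trace; multiple replicates are aggregated as the mean
  of per-trace ratios, not the ratio of means.

## Experiment drivers

Five seeded, end-to-end drivers (`dilution_series`, `dark_dcr`, `led_lod`,
`live_cell`, `mito`) write trace tables and YAML reports embedding the
fully resolved configuration. Every stochastic stage draws from a substream
derived from the root seed and a stable label (e.g.
`dilution/rep2/point7/ci`), so identical spec + seed reproduce output files
bit for bit while stages remain statistically independent.

Choices worth noting:

* **dilution_series** — the discharge rate is set as
  λ_max = top peak rate / top pool (0.5 s⁻¹ for the default 10 MHz / 2×10⁷
  pe), since a saturating step makes the initial emission rate exactly
  λ_max·N. Dilutions 2⁰…2⁻¹¹ then share the same kinetics. The top three
  dilutions are pile-up-affected (peak 10, 5, 2.5 MHz), driving the SPC
  full fit below slope 1; the bottom three sit near the CI noise floor.
  The full (untrimmed) CI fit is reported only when all integrals are
  positive — near the noise floor they need not be.
* **dark_dcr** — skips the dead-time stage by default: the quoted dark
  level is the *observed* scaler rate, so re-applying dead time would
  double-count self pile-up (≈2.7 % at 904 kHz).
* **led_lod** — Poisson-timed trigger pulses each carrying Poisson(mean 1)
  photoelectrons (a Neyman type-A compound, slightly overdispersed relative
  to Poisson light — as in the bench setup that mimics stochastic
  single-photon illumination). The detection threshold is located by
  linear interpolation of the mean response across trigger frequencies; a
  crossing extrapolated beyond twice the probed range is reported as "not
  separable" rather than as a number.
* **live_cell** — both branches per replicate with independent noise; the
  report carries per-replicate and mean A/T, ADC-overflow and
  scaler-overrange flags during the lysis burst, and (optionally) a
  separate sub-50-kHz oscillation trace checked against the 9 kHz SPC
  detection limit. The default pool (5×10⁷ pe) puts the lysis burst near
  50 MHz — far beyond the SPC pile-up limit, yet within CI's ADC headroom.
* **mito** — a fast uptake transient rescaled to a configurable peak
  (2.2 MHz default, below the ≈3 MHz pile-up regime), with the counting
  loss budget at peak.

Replicate counts behind A/T means are not documented for the reference
instrument; the default is 5.

## Problem sizes

Default experiment durations follow the bench protocol (30 s baseline,
lysate discharge recorded for minutes, 7–8 min live-cell runs); the
simulations are desk-scale — binned SPC plus 10⁵–10⁷ CI gates per trace —
so the full dilution characterization (12 dilutions × 2 branches × 5
seeds) completes in a few seconds. A ×0.1 duration preset (`--scale 0.1`)
shrinks all time-like parameters and averaging blocks proportionally for
quick runs. The acceptance script uses the full default sizes.

## What the synthetic data does and does not show

The generators emulate Poisson photon statistics, dark counts, dead-time
losses, gated charge conversion, amplifier noise, quantization and
averaging — the instrument physics the analysis pipeline is sensitive to.
They do not emulate: SiPM correlated noise (optical crosstalk,
afterpulsing; never quantified for the reference device), temperature drift
of the DCR, injection/mixing hydrodynamics (Ca²⁺ steps are instantaneous),
biological variability between cultures, or absolute Ca²⁺ calibration of
the probe (no luminescence-to-concentration conversion is attempted).
Passing tests therefore validate the readout and analysis chain under
idealized source statistics, not the biology upstream of it. Two
consequences observed on real instruments follow analytically in the twin
and are worth remembering when comparing: a 904 kHz dark floor makes *any*
counted signal ≈5 % low (dark-induced pulse overlap, the e^(−DCR·τ) factor
survives baseline subtraction), and both branches here share one
photoelectron scale, so the twin's fitted sensitivity ratio 2^Δq ≈ 1 by
construction, whereas distinct amplifier chains yield branch-specific
values.
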