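# Methods

This note documents the models and procedures implemented in `neuroxkit`,
the parameters that matter, the numerical choices, and what the synthetic
benchmark does and does not demonstrate.

## Signal model and preprocessing

All channels are uniformly sampled `TimeSeries`. Filtering is zero-phase
throughout (forward-backward second-order sections): the triggered
averages, kernel fits and cross-correlations all depend on event timing,
and a causal filter would shift every onset by a design-dependent group
delay. The cost is non-causality, irrelevant for offline analysis. One
consequence worth knowing: a 0.1 Hz high-pass corner puts poles within
4×10⁻⁵ of the unit circle, so edge transients persist for tens of seconds —
band-pass results within ~30 s of a record's edges should not be trusted,
which is why the test suite evaluates long records away from their ends.

Polarographic currents are converted to mmHg with a two-point (zero /
air-saturated, 159.6 mmHg) calibration whose zero and span are linearly
interpolated in time between the pre- and post-experiment calibrations;
electrode drift is on the order of a few percent per hour, so the linear
model suffices. The electrode's ~0.3 s response time is deliberately not
deconvolved. Oxygen traces are low-passed at 1 Hz (5th-order Butterworth)
and decimated to the 30 Hz analysis rate with polyphase anti-aliasing.

## Behavior

Treadmill velocity is low-passed at 10 Hz (5th-order Butterworth),
differentiated by central differences, and binarized at
|acceleration| ≥ 3 cm/s² (inclusive). Runs separated by gaps below a
0.5 s `merge_gap` are bridged — without a merge rule the brief zero-
acceleration instants inside a bout fragment it; the value is configurable.
Evoked events require ≥ 3 s of quiescence before onset and ≥ 5 s of
locomotion (≥ 10 s for oxygen analyses); rest intervals start 4 s after a
run ends and must last ≥ 10 s (≥ 30 s for resting cross-correlations).
Session boundaries count as rest boundaries, so a fully quiet record is one
rest interval.

## Neural analysis

Spectrograms use Slepian multitapers on 1 s windows with 9 tapers. Nine
tapers require a time-bandwidth product of 5 (half-bandwidth 5 Hz on a 1 s
window); both knobs are exposed, and the taper count is treated as the
binding constraint. Gamma power integrates 40–100 Hz. Spike detection
thresholds are set in units of a median-absolute-deviation SD estimate
(×1.4826), which is robust to the spikes themselves. Firing rates count
threshold upcrossings in 1 ms bins and are smoothed with a 5 Hz Bessel
low-pass.

FS/RS classification extracts waveforms at 4 SD crossings, upsamples them
10× with a cubic spline, normalizes to unit action-potential peak, and
measures the peak-to-trough duration quantized at 0.05 ms. A two-component
Gaussian mixture (EM with k-means initialization and multiple restarts;
seed exposed) is fitted to the durations, and a spike is labeled only where
its posterior membership is ≥ 0.95. The posterior rule is converted into a
pair of duration thresholds confined to each component's side of the means
(an unequal-variance mixture can re-dominate in the far tail), which makes
labels monotone in duration by construction: FS below, unclassified
between, RS above.

## Response kernels

The neurovascular mapping is treated as linear and time-invariant: the
observed 30 Hz signal V is regressed on an intercept plus k lagged copies
of the binarized locomotion regressor (zero-padded at the record start, no
wraparound), and the kernel is the least-squares solution via
`numpy.linalg.lstsq` (QR/SVD) — never the explicit Gram inverse, which is
numerically equivalent but less stable. Default kernel length is 15 s
(k = 450 at 30 Hz), long enough for slow tissue-oxygen responses. No
regularization is applied by default, matching the plain least-squares
formulation. Kernel metrics: peak amplitude is the extremal value
(sign-aware), peak time its lag, and onset time the first lag exceeding
10 % of the peak in the peak's direction — the 10 % threshold is a
reporting convention, configurable.

## Coupling statistics

Cross-correlations 1 Hz low-pass both inputs, remove means, and normalize
globally; the sign convention is that a positive lag means the first
argument lags the second (feeding `y = delay(x, d)` peaks at +d; verified
against a shift-and-dot oracle). Significance bands come from circular
time shifts of one channel — shifts preserve each signal's autocorrelation,
which sample permutation would destroy, making shift surrogates the
conservative null for autocorrelated series.

Coherence and partial coherence are estimated from multitaper
cross-spectra averaged over ≥ 10 non-overlapping segments (5 tapers,
NW = 3 per segment by default). A single spectral estimate has coherence
identically 1 and is rejected. For independent signals the estimator's
known bias is ≈ 1/(segments × tapers), which the tests check. Partial
coherence uses the closed form

    PC² = |S_xy S_zz − S_xz S_zy|² /
          ((S_xx S_zz − |S_xz|²)(S_yy S_zz − |S_yz|²))

with the denominator floored at 10⁻¹⁴ of its natural scale: when a signal
is numerically fully explained by the conditioner both numerator and
denominator vanish and the limit is 0, not NaN. Frequencies where any
spectrum is below 10⁻¹² of its maximum are masked.

The exact Wilcoxon signed-rank test drops zero differences, midranks ties,
and enumerates all 2ⁿ sign assignments directly for n ≤ 16; for larger n
(≤ 25) the identical distribution is built by convolution over the
integer-scaled ranks. Two-sided p doubles the smaller tail and caps at 1.
Six all-positive pairs give 2/2⁶ = 0.03125; nine give 2/2⁹ = 0.00390625.

## Respiration-phase oximetry

Expiratory peaks are negative-going zero crossings of the thermocouple
derivative, with a prominence guard (10 % of signal range) against
flat-baseline jitter. Phase is defined as time since the last expiratory
peak — not a normalized phase fraction — matching the fixed 20 ms bin
width; cycles longer than mean + 3 SD are excluded. Regular-respiration
epochs require rate SD ≤ 0.6 Hz, mean/SD > 4, and no breath above 5 Hz.

Oximetry follows the Stern-Volmer relation 1/τ = 1/τ₀ + k_q·PaO2. The
probe constants are calibration inputs (defaults τ₀ = 40 µs,
k_q = 4×10⁻⁴ µs⁻¹ mmHg⁻¹, realistic for two-photon phosphorescent probes
but not authoritative). Lifetimes are fitted on averaged decays (groups of
3000 for the time series; per-20 ms-bin pools for the cycle profile) with a
three-parameter exponential after discarding the first 5.6 µs of each
1.25 MHz record. The per-decay estimates used by the surrogate test are
weighted log-linear fits sharing the pooled fit's background and restricted
to the first 3.5 lifetimes, where the signal dominates — estimating the
background from each record's tail would bias PaO2 upward by tens of mmHg
because the exponential has not decayed within the record.

Cycle profiles are smoothed with a first-order binomial filter
([1, 2, 1]/4, five repetitions) on a circular boundary — the cycle is
periodic — giving exactly unit DC gain and a sinusoidal attenuation of
cos¹⁰(π/n_bins). Tmin/Tmax are 40 ms (2-bin) windows at the smoothed
profile's extremes; the reported PaO2 means use the raw (unsmoothed) bins.

Respiration locking is tested on the power spectrum of the phase-binned
profile at the cycle fundamental, against surrogates that permute the PaO2
measurements across phase assignments (preserving the marginal PaO2
distribution). This is exact by exchangeability: under the null the
observed statistic and the surrogates are interchangeable, so the 95th-
percentile rule fires at 5 %. A `method="phase"` variant instead redraws
each measurement's phase uniformly within the cycle; classic Fourier
phase-randomization of the profile is *not* offered because it preserves
the power spectrum and is vacuous for a spectral-peak statistic.

## Oxygen transport model

Geometry is a Krogh-type cylinder: lumen radius R1 = 9 µm, tissue outer
radius R2 = 50 µm, length L_a = 200 µm. Oxygen tension p (mmHg) is the
working variable, converted to concentration by the solubility α. In blood,
total oxygen c_T = αp + 4·C_Hb·S(p) is advected by a quasi-static
Poiseuille profile (Stokes flow in a straight cylinder at these Reynolds
numbers) and free oxygen diffuses; in tissue, free oxygen diffuses and is
consumed at a uniform rate CMRO2. The Hill curve S(p) = pⁿ/(pⁿ + p50ⁿ)
couples free and bound oxygen.

Parameters with their provenance class:

| parameter | default | status |
| --- | --- | --- |
| D_O2 | 2800 µm²/s | published value |
| resting PaO2 (inlet) | 35 mmHg | published value |
| R1 / R2 | 9 / 50 µm | published values |
| resting CMRO2 | 3 µmole cm⁻³ min⁻¹ (= 50 µM/s) | published value |
| resting centerline velocity | 2 mm/s (sets the pressure head) | published value |
| α | 1.3 µM/mmHg | config, flagged default |
| p50, Hill n | 40 mmHg, 2.6 | config, flagged defaults |
| C_Hb | 2300 µM | config, flagged default |
| L_a | 200 µm | config, flagged default |
| locomotion scenarios | FL/HL: +10 % dilation, +15 % CMRO2; FC: −5 %, +4 % | published plateaus |
| inlet PaO2 rise during locomotion | +10 % plateau | free parameter, chosen once |
| blockade | CMRO2 × (1 − 0.75 × 0.82) = 1.155 ≈ 1.2 | published fractions |

Scenario time courses are cosine-smoothed trapezoids (2 s ramps, 10 s
plateau) — the plateau magnitudes are the substantive inputs; exact ramp
shapes are not asserted anywhere.

Numerics: cell-centered finite volumes on a single structured (r, z) grid
spanning both domains with the wall on a cell edge (both domains share
D·α, so the diffusive flux is continuous across the wall by construction).
Default grid 10 + 30 radial × 50 axial cells. Advection is first-order
upwind and implicit; the discrete fluxes telescope, so the global oxygen
balance (inlet minus outlet convection vs integrated consumption) closes
to well under 1 % — the residual is the physical diffusive influx at the
inlet face. Steady states are solved by Newton iteration with the exact
sparse Jacobian (relative residual < 10⁻⁸, typically 4–6 iterations);
saturation terms are evaluated at max(p, 0) so transiently negative Newton
iterates are harmless. Transients use linearized implicit Euler
(dt = 0.02 s default) with the hemoglobin buffering capacitance
c_T′(p) = α + 4·C_Hb·S′(p) lagged one step.

Vessel dilation is handled kinematically: blood cells scale with R1(t),
tissue cells are compressed into [R1(t), R2], field values ride on the
moving mesh, and the local CMRO2 is rescaled so its volume integral is
unchanged. This represents the near-incompressible elastic tissue response
(Poisson ratio 0.45) by its only observable consequences — interface motion
and conserved consumption; the elastic moduli are retained in the parameter
set but do not enter the solution. The ALE mesh-velocity term is neglected:
dilation time scales (seconds) are two orders slower than radial transport
(R2²/D ≈ 0.9 s), and the equilibrium-preservation test bounds the resulting
drift below 0.1 %.

Known numerical limitations: first-order upwinding adds numerical axial
diffusion ~v·dz/2 (comparable to D at the default grid), acceptable because
axial gradients are weak (extraction ≈ 8 % over L_a); the Krogh-annulus
oracle (advection off, fixed wall tension) agrees with the closed form to
0.24 % on the default grid and 0.005 % on a refined radial grid; halving
grid spacings changes the probe tissue PO2 by < 2 %.

The probe conventions: tissue PO2 at mid-annulus radius, mid-length;
arterial PaO2 at the centerline, mid-length; both configurable.

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical structure the analyses assume:
Poisson bout arrivals (2/min) with gamma-distributed durations (mean
≈ 12 s); 1/f LFP whose 40–100 Hz band is gain-modulated (×2) during bouts;
biphasic FS (0.3 ms) / RS (0.7 ms) spike templates with 0.05 ms duration
jitter at state-dependent rates; tissue oxygen that is exactly the
convolution of a known kernel with the binarized locomotion, plus a small
respiration-coupled sinusoid and white noise; a raised-cosine breath train
whose rate steps from 2.5 Hz (rest) to 4 Hz (locomotion); reflectance
frames produced by the Beer-Lambert forward map of a known (ΔHbO, ΔHbR)
pair; and Poisson photon decays whose lifetime follows the Stern-Volmer
map of instantaneous PaO2 with a configurable within-cycle modulation
depth (default 5 mmHg). Equal seeds give bit-identical sessions.

It does not emulate: electrode drift or motion artifacts, optical point
spread or camera noise, heart-rate pulsation, sighs/apneas or breath-shape
variability, spatial heterogeneity of vasculature, spike waveform overlap
beyond chance superposition, or any nonlinearity in the locomotion→oxygen
mapping. Passing tests therefore demonstrate that the estimators recover
what they assume — a linear, stationary world — not that real recordings
satisfy those assumptions.

Problem sizes in the shipped tests and acceptance script are scaled to a
desktop: sessions of 1.5–5 minutes, neural channels at 2 kHz except where
spike waveforms matter (20 kHz), decay records at 1000/s with 128 samples
(the instrument digitizes at 1.25 MHz and collects ~4000 decays/s; the
scaling preserves per-bin counts at the hundreds level). These are the
package's default study conditions, all configurable upward.

## Statistical conventions

Summary tests use the exact Wilcoxon enumeration for n ≤ 25. The
calibration of the respiration-locking test is itself a 50-draw binomial
at p ≈ 0.05, so its observed false-positive rate has an intrinsic ±3 %
spread — the acceptance band reflects that, not estimator slack.
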