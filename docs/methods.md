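# Methods

## Scope

`ecochg` implements a complete analysis chain for steady-state (AC)
electrocochleography — frame-synchronous Fourier extraction, sensitivity
and group-delay characterization, I/O-slope statistics, DP-grams with
damage localization, and a two-component sensory/neural classification —
together with a phenomenological forward model of the gerbil cochlea that
generates the three recorded channels (ear-canal pressure ECP,
round-window eCochG, remote/vertex eCochG).  The simulator stands in for
animal recordings: it is calibrated so that the pipeline recovers the
published hallmark observables, and every analysis result in this
repository is computed by running the pipeline on it.

## Recording protocol and spectral analysis

Stimuli are one or two tones, each snapped to an integer number of cycles
per 4096-sample frame at 200 kHz (bin width 48.828125 Hz), presented for
52 frames above 70 dB SPL or 402 frames at and below 70 dB SPL, with 5-ms
raised-cosine ramps.  The first and last frames (which carry the ramps)
are discarded and the remaining 50 or 400 frames averaged synchronously;
white channel noise therefore shrinks as 1/sqrt(n).  Because every
frequency of interest sits exactly on a DFT bin of the averaged frame,
amplitude (RMS convention) and phase (cycles, cosine reference) come from
a single bin with no window or leakage.  The remote channel is sampled at
25 kHz with 512-sample frames; 25000/512 equals 200000/4096, so both
channels share one bin grid and integer-cycle tones stay bin-exact after
decimation.

The noise floor of a component is the median amplitude of the six nearest
bins (three per side) that are not stimulus or intermodulation bins
(orders |m|+|n| <= 4) — a robust choice for an on-bin synchronous
paradigm; the floor estimation method itself is an implementation choice.
An estimate enters curve fits only when it clears its floor by 6 dB.

Sensitivity is 20 log10(|eCochG| / |ECP|); response phase is relative to
the ECP phase at the same bin, unwrapped across frequency (all adjacent
phase steps in the standard sweeps are well below half a cycle).  Group
delay is the negative least-squares slope of unwrapped phase (cycles)
versus frequency (Hz), by default over sliding windows of five valid
points; the headline band estimates fit one line over the whole band
sampled at 12 points/octave.  With phase in cycles no 2*pi factors enter;
delays are reported in ms.

## The cochlea model

The model is a tonotopic filterbank, not a micromechanical simulation.
Its structure and constants were calibrated once against the printed
observables (group delays of 2.5 vs 0.05 ms, 1 dB/dB growth with
compression near 90 dB SPL, compressive low-frequency growth below
~60 dB SPL, the ~20-dB remote-channel offset, DP notch localization) and
then frozen; they are all exposed on `CochlearModel`.

**Tonotopy.** 128 places, Greenwood-form map CF(x) = A(10^(a(1-x)) - k)
spanning 50 kHz (base) to 0.2 kHz (apex), k = 0.85.  The species map
constants are config-exposed, not fitted.

**Traveling-wave stage.** Each place responds through a zero-phase gain
profile times a pure place delay.  The gain profile is a flat basal tail
(every place responds to frequencies below its CF), a modest peak
(6 dB, sigma 0.25 oct) at CL, a steep apical cutoff (sigma 0.45 oct
above CF), and a global +6 dB/oct high-pass tilt below 2 kHz (the summed
sensory potential is high-pass in frequency, which is also what survives
neural silencing).  The delay profile is

    tau(CF) = tau_min + (tau_a + tau_b/CF - tau_min) / (1 + (CF/8 kHz)^6)

with tau_min = 0.037 ms, tau_a = 1.45 ms, tau_b = 0.75 ms*kHz.  Two
properties of this form do real work.  First, delays are small and nearly
equal over the extreme base, so basal contributions to any tone add
almost in phase, while the delay grows quickly toward CL so near-CL
contributions rotate and largely cancel: the summed CM is
basal-dominated, giving the short (~0.05 ms) sensory group delay and
making single-tone responses mostly blind to place-restricted damage.
Second, on the apical branch the term f * (tau_b/2f) is constant in
frequency, so the measured neural group delay is synaptic delay + tau_a
(~2.45 ms) even though the physical travel time to the 1-kHz place is
tau(1 kHz) = 2.2 ms — both printed values hold at once, with the neural
contribution drawn from one octave basal of CL (see below).

**Transduction.** Each place's drive passes a second-order Boltzmann
P(u) = 1/(1 + e^(-(u-a1)/s1) (1 + e^(-(u-a2)/s2))), normalized to unit
small-signal gain, scale `met_saturation_pa` = 0.25 Pa.  The second gate
sits on the negative limb (a2 = -3, s2 = 0.7), which keeps the operating
point near the steep part (no expansive growth region) and provides the
mild asymmetry that produces small even-order products while 2f1-f2
dominates.  The fundamental compresses by ~0.1 dB at 70, ~0.6 dB at 80
and ~4 dB at 90 dB SPL: growth is 1 dB/dB through the 40-70 dB range with
visible compression only at 90.  This stage is the sole source of
distortion products; `met_saturation_pa = inf` is an exactly linear
transduction used by the superposition/no-DP property tests.

**Neural stage.** Per place: half-wave rectification of the drive, a
compressive power law x^0.4, and a soft rate-saturation cap
(`neural_sat` = 0.12, engaging near 55-60 dB SPL drive), summed over a
log-Gaussian window (sigma 0.3 oct) centered one octave basal of each
tone's CL — the region the delay budget implicates once near-CL
cancellation and the weakness of extreme-base drives to low tones are
taken into account.  The summed signal is low-passed by the
phase-locking profile min(1, (f/1 kHz)^-4), hard-zeroed above 5 kHz,
delayed by the 1-ms synaptic delay, and scaled by `neural_gain` times
the damage map's `neural_scale`.  With these constants the neural
component exceeds the CM at 1 kHz below roughly 60 dB SPL (hence
compressive low-level growth and the 2.45-ms delay there), and is
negligible at 90 dB SPL and above 3 kHz.  The DC (summating-potential
like) component of rectification is discarded as out of scope.

**Distortion products.** Per place, intermodulation components (default
orders 2f1-f2, 3f1-2f2, f2-f1, 2f2-f1) are read from the Boltzmann
output at their exact bins.  Three signals are derived:

* *eCochG-DP (direct):* the electrode-weighted sum of the per-place DP
  currents — basal-spread and therefore only weakly place-specific.
* *eCochG-DP (place response):* the launched intracochlear DP propagates
  forward as a wave at its own frequency and peaks at its own CL.  Being
  tens of dB below the stimulus it rides the low-level cochlear-amplifier
  gain there (`dp_relay_amp` = 20, sigma 0.25 oct) that the loud,
  compression-saturated stimulus waves do not see.  The transduction
  currents of this re-entrant wave dominate the recorded eCochG-DP
  (`dp_relay_gain` = 6) and are what makes it place-specific: OHC damage
  at the DP frequency's place removes them, which is how the 4-kHz-notch
  preset is localized on the 2f1-f2 axis.
* *DPOAE:* the reverse-propagated, f2-envelope-weighted generation sum,
  scaled by a fixed emission constant and added to the ECP.  Reflection
  type emission (backward radiation from the DP's own CL) is deliberately
  not modeled; consequently the simulated ear-canal DPOAE change profile
  after notch damage is weak and unlocalized, and the ear-canal channel
  is the least place-specific of the three — the eCochG channels carry
  the localization.  High-level (>= 80 dB) basal secondary DP sources are
  likewise out of scope, so 80-dB bimodal change profiles are not
  reproduced.

**Electrodes, chains, noise.** The RW electrode weighs places with a mild
basal-proximity emphasis (1 + e^(-x/0.25)); the vertex electrode weighs
all places equally at a gain calibrated to put its 2-kHz response 20 dB
below the RW channel.  The RW chain is a first-order 0.1-30 kHz
bandpass; the remote chain a first-order 7.5-kHz low-pass followed by
exact band-limited decimation to 25 kHz.  Channel noise is white
Gaussian (ECP 1e-4 Pa, RW 2e-3 V, remote 5e-5 V per sample), seeded; the
real recordings' noise spectra are not characterized, so white noise is
an explicit simplification.

**Damage maps and presets.** `DamageMap` holds a per-place OHC factor in
[0, 1] applied multiplicatively to the drives and a global neural scale.
Presets: `healthy` (identity), `ka` (kainic acid, neural_scale 0),
`broadband_trauma` (uniform -20 dB OHC), `notch_4khz` (log-Gaussian dip,
-25 dB deep, sigma 0.25 oct ~ 0.5-oct full width, centered at the 4-kHz
place).  Simulated replicate animals jitter the electrode gains (2 dB),
neural gain (3 dB) and saturation point (1 dB) log-normally.

**Steady-state computation.** The protocol's stimuli are exactly
frame-periodic and every model stage preserves that periodicity, so the
simulator computes one steady-state frame (filters applied on the frame
spectrum, nonlinearities in the time domain) and tiles it to the full
protocol, then applies ramps, chains and noise.  Full 402-frame,
three-channel recordings synthesize in milliseconds, which is what keeps
the replicate-animal studies cheap.

## I/O decomposition and classification

The low-frequency I/O curve is fitted (least squares in dB, multistart
over the exponent) as the magnitude sum

    A(L) = 20 log10( 10^((g_s + L)/20) + 10^((g_n + c L)/20) ),

a 1 dB/dB sensory component of gain g_s plus a compressive neural
component of gain g_n and exponent c.  Components are summed in magnitude
without an interference phase; the fine-structure ripple this ignores
shows up as ~0.5-1 dB fit residual.  The exponent is bounded to
[0.05, 0.85]: near c = 1 the compressive component can impersonate the
linear one on purely linear (e.g. post-KA) curves and the decomposition
becomes unidentifiable.  The breakpoint (g_n - g_s)/(1 - c) is flagged
`extrapolated` outside the fitted range — expected for degenerate curves
(pure linear growth, or sensory loss pushing the transition above the
top level).  Classification compares baseline and test fits of the same
animal with threshold T = 6 dB on the gain reductions d_s, d_n:
normal (both < T), neural (d_n >= T only), sensory (d_s >= T and
d_s - d_n >= T/2), mixed otherwise when d_s >= T; non-converged fits give
`indeterminate`.  Both the functional form and the threshold are
implementation choices (the underlying diagram is qualitative) and are
config-exposed.  Classification I/O curves use 30-90 dB SPL in 10-dB
steps so the post-trauma linear segment lies inside the fitted range.
The slope-versus-unity test is a one-sample, one-sided t-test across
replicate animals at a fixed level, with the zero-variance boundary
convention p = 0.5.

## DP-grams and notch localization

DP-grams sweep f2 over 1.6-12.8 kHz at 6 points/octave (the sweep grid is
an implementation choice; published curves are drawn continuously) with
f2/f1 = 1.25 realized by snapping f2 first and f1 = snap(f2/1.25), which
keeps 2f1-f2 on the shared bin grid exactly.  Change profiles are
pointwise post-minus-pre dB differences where both sides are SNR-valid.
Localization 3-point-median-smooths the profile, takes the minimum
(ties to the lower frequency) as the notch center — reported on both the
2f1-f2 and f2 axes — requires it to reach -6 dB, and reports the
half-depth span in octaves as the width.

## What the simulator does and does not establish

Passing tests show that the analysis pipeline recovers, from waveforms
with the assumed signal structure (frame-synchronous tones, linear
short-delay sensory component, compressive long-delay neural component
confined below 5 kHz, transduction-born DPs with a place-specific
re-entrant component, white channel noise, the stated channel chains),
the quantities it is supposed to recover at the stated tolerances — and
that damage of known type and place is correctly classified and
localized under those conditions.  Real recordings differ in ways the
generator does not emulate: middle-ear transmission (including the
species' 6-kHz notch), onset CAPs, reflection-type emissions and DPOAE
fine structure, two-tone suppression, non-white and non-stationary
noise, electrode placement variability, and high-level secondary DP
sources.  Results on this simulator therefore validate the analysis
code, not the biology.

## Numerical choices and degenerate inputs

Off-grid extraction frequencies are rejected rather than estimated
(leakage would corrupt the single-bin estimate).  Zero-noise floors give
infinite SNR and count as valid when the amplitude is positive.
Unwrapping is deterministic (numpy convention) and direction-independent.
The level exactly 70 dB SPL takes the long protocol (more averaging).
SPL is RMS re 20 uPa; start phases default to zero and are configurable.
Group-delay windows skip SNR-invalid points; a window with fewer than
two valid points is dropped.  The two-component fit reports residual and
convergence rather than raising on hard curves.  Uniform OHC scaling can
only decrease the linear-model CM (tested); pointwise damage can
*increase* responses through cancellation release — that is a real
effect (post-notch enhancement near the damaged place), not a bug, so no
pointwise monotonicity is asserted.
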