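# Methods

## The problem

Essential tremor is a 4–12 Hz rhythmic oscillation of the limbs that occurs
mostly during posture and action. Clinical rating scales score it as a limb
displacement in centimetres, but a wrist-worn inertial measurement unit
(IMU) reports specific force (m/s², gravity included) and angular velocity
(rad/s) — several integrations and a frame change away from anything a
clinician recognises. Naive band-power methods over-estimate tremor whenever
voluntary movement shares the band, and a population-wide detection band
(4–12 Hz) invites false positives, because any one person's tremor occupies
only about ±1 Hz of it.

`tremorkit` implements a two-pass pipeline that addresses all three issues:

1. **Pass 1 — candidate peaks.** Every recording is converted to
   gravity-free Earth-frame acceleration and body angular velocity, and
   sliding-window power spectral densities (PSDs) are scanned for spectral
   peaks. Each peak's *power fraction*

   ρ = ∫[f_b, f_e] (p(f) − b(f)) df / max(p_min, ∫[f > f_T] p(f) df)

   measures how much of the segment's power the peak explains after
   subtracting a straight-line baseline b(f) between the peak's feet — the
   baseline stands in for concurrent broadband activity.
2. **Pass 1.5 — subject band.** All candidate peaks from all recordings,
   segments, sensors and both spectra (acceleration and angular velocity)
   are pooled; the power-fraction-weighted interquartile range of their
   frequencies, padded by δ_f = 1 Hz, is the subject's tremor band
   [f_l, f_u]. The weighted IQR makes the band robust to spurious peaks.
3. **Pass 2 — quantification.** Every segment is re-scanned against
   [f_l, f_u]. If the best in-band peak has ρ > ρ_d, tremor is declared and
   the above-baseline peak power P is modelled as a sinusoid of amplitude
   a = √(2P). Frequency-domain integration converts it to physical units at
   the peak frequency f: displacement a_p = a/(2πf)² (acceleration-source
   peaks, reported in cm) and rotation a_r = a/(2πf) (gyro-source peaks,
   reported in degrees). Amplitudes are half peak-to-peak of the modelled
   sinusoid.

A per-segment *action measure* (RMS displacement over 0.3–3 Hz from the
position PSD, p_p(f) = p_a(f)/(2πf)⁴) flags voluntary movement so that
amplitudes can be interpreted in context.

## Orientation estimation

Vendors ship proprietary attitude filters; the package uses a standard
quaternion complementary filter: strapdown integration of the gyroscope,
with the tilt component continuously pulled toward the measured
specific-force direction (time constant `ahrs_tau_s`, default 2 s, i.e.
tremor-band accelerations are attenuated ≳50× in the correction path). Two
robustness details matter in practice:

* the correction is confidence-weighted and applied only while the
  specific-force norm is within `ahrs_accel_gate` (default 30%) of 1 g —
  during vigorous movement the accelerometer does not point up, and an
  ungated filter demodulates large tremor accelerations into spurious
  low-frequency "displacement";
* the initial tilt is estimated from the first ~2 s using only samples
  whose norm is near 1 g; for oscillatory motion those are the
  zero-crossings of the motion acceleration, where the accelerometer points
  exactly up.

Without a magnetometer, yaw is arbitrary but fixed per recording. This is
harmless: per-channel PSDs are summed, and the channel-summed PSD (the
trace of the spectral matrix) is invariant under any fixed rotation,
including heading. The first `trim_s` (default 1 s) of every recording is
excluded from analysis as filter settling.

## Spectral estimation

Each analysis window (default `window_s` = 5 s, hop 1 s) is mean-removed,
Blackman-tapered, and its biased autocorrelation is re-tapered with a
Blackman lag window before Fourier transforming (Blackman–Tukey
correlogram). Normalisation divides by the taper's mean-square so that the
integral of each one-sided PSD equals the segment variance (Parseval);
negative excursions from the lag window's sidelobes are clipped at zero.

Numerical choices, and why:

* **Window 5 s.** Spectral peak estimation needs roughly ten or more
  oscillations per window; 5 s gives ≥20 cycles at 4 Hz while leaving ~10
  windows in a 15 s recording at 1 s hop. Equally important, amplitude
  accuracy requires the peak's spectral footprint (taper main lobe
  ~±0.6 Hz plus lag-window smoothing ~±0.3 Hz at this window) to fit well
  inside `max_peak_width` (3 Hz), or real peak power is clipped into the
  baseline.
* **Lag window over all lags** (`lag_fraction` = 1.0). The least-smoothed
  estimate; shorter lag windows smooth the PSD at the cost of smearing the
  peak and losing amplitude. Configurable for noisy exploratory use.
* **Grid ≤ 1/16 Hz** (`max_bin_hz` = 0.0625, FFT zero-padded to the next
  power of two that also holds the full two-sided lag sequence). On a
  coarser grid, peak-bound expansion for tones that fall between bins can
  stop on the main-lobe skirt instead of the null, and the chord baseline
  then eats ~0.3% of the amplitude. At 1/16 Hz this effect is below 10⁻⁵
  relative on noise-free probes.
* **Peak frequency by centroid.** The amplitude-to-physical-units
  conversion divides by (2πf)² or (2πf), so the frequency must be known
  much better than the grid spacing. The power-weighted centroid of the
  baseline-subtracted peak is used; the spectral window is symmetric about
  the true tone frequency, so the centroid is unbiased and accurate to
  ~10⁻³ Hz at bench signal-to-noise ratios.
* **Position PSD floor** (`f_pos_min` = 0.25 Hz). The (2πf)⁻⁴ conversion
  diverges at DC; bins below the floor are zeroed. The floor sits just
  below the action band (0.3 Hz), not at the tremor floor f_T = 1.5 Hz,
  because the action measure must see 0.3–1.5 Hz voluntary movement.
* **Action window 10 s** (`action_window_s`, clipped to the recording).
  The action band reaches down to 0.3 Hz; with the 5 s tremor window the
  spectral smear around a 1 Hz movement, amplified convexly by (2πf)⁻⁴,
  overstates the action RMS by ~15%. A 10 s window (≈3 cycles at 0.3 Hz)
  reduces this to ~3%. Each tremor segment is paired with the action
  window whose centre is nearest.

## Peak detection and stopping rules

Every strict interior local maximum of a PSD slice seeds a candidate whose
bounds expand one bin at a time (the side with the higher adjacent PSD
first) until the first of: (1) the width reaches `max_peak_width`; (2) both
ends reach local minima; (3) some interior sample falls below the chord
joining the current endpoints — the signature of crossing into a
neighbouring structure. The final chord is the baseline; the
baseline-subtracted integrand is clipped at zero because power cannot be
negative. Ties in the best-peak selection break toward the lower frequency
(less likely to be a harmonic). The implementation is verified
bin-for-bin against a brute-force expansion oracle on thousands of random
PSDs.

Conventions adopted where the defining formulas leave room:

* the power-fraction denominator uses the same-source PSD as the peak
  (acceleration peaks over acceleration total power, gyro over gyro);
* the minimum-significant-power floors are configured as physical
  amplitudes (`p_min_pos_cm` = 0.05 cm RMS displacement,
  `p_min_rot_deg` = 0.05° RMS rotation, converted at `p_min_ref_hz` = 5 Hz)
  and applied in each spectrum's own units;
* in the weighted-quantile crossings (largest j with w_j < 0.25, smallest
  with w_j > 0.75) an absolute ε = 10⁻⁹ keeps weights that land exactly on
  a quartile from flipping on floating-point rounding, and a degenerate
  distribution (first peak already ≥25% of weight) falls back to the
  first/last peak;
* when a session yields no qualifying peak, Stage 2 signals
  no-tremor-evidence and the caller substitutes the population band
  [4, 12] Hz (flagged `is_fallback` in reports);
* segments without a detection are excluded from per-recording amplitude
  summaries by default (`exclude_undetected`) rather than counted as
  zeros; both median and maximum are reported, median as the headline.

## The synthetic robot arm

`tremorkit.simulate` replaces a bench robot: it prescribes a rotation
θ(t) = A_r sin(2πf t) about a fixed body axis and/or a displacement
x(t) = A_p sin(2πf t) along a fixed Earth axis, and emits exactly what an
ideal strapdown IMU would measure — body rates A_r 2πf cos(2πf t) about the
axis, and specific force R(t)ᵀ(ẍ + g) including gravity as seen from the
rotating sensor — plus independent Gaussian noise per channel (defaults
0.02 m/s² and 0.002 rad/s RMS, consumer-IMU class; fixture choices, not
measured values). An optional low-frequency sinusoidal displacement
(`confound_rms_cm`, quoted as RMS) emulates voluntary movement, and a
linear frequency drift is available for stress tests. Ground truth
(orientation quaternions, displacement, angle) is emitted alongside.

Default conditions mirror the bench protocol scale: 15 s recordings at
128 Hz; validation grids span 4.0–6.4 Hz with rotations 0.25–10° and
displacements 0.1–5 cm.

What the simulator does *not* emulate — and hence what passing its grids
does not prove about patients: amplitude- and frequency-modulated tremor,
intermittent bursts, multi-joint kinematics with lever arms, gyro bias and
temperature drift, soft-tissue sensor wobble, and genuinely broadband
voluntary activity. The clean grids bound instrument error of the method,
not clinical agreement.

## Problem sizes used in the shipped checks

The acceptance script runs 30 clean rotational scenarios (5 frequencies ×
6 amplitudes), 30 clean translational ones, and 9-scenario adverse grids
(1 Hz 5 cm-RMS confounder, doubled noise) over 20 seeds each (180 + 180
recordings), reporting maximum absolute amplitude errors. The test suite
additionally checks band recovery on 4 × 500 synthetic peak-pool
replicates, confounder robustness over 50 paired runs, and oracle
equivalence on 1000 random PSDs.

## Known limitations

* Spectral estimation cannot quantify tremor present for only a few
  oscillations (e.g. brief intention-tremor transients); a segment needs
  ~10 cycles.
* The action RMS carries a small positive bias (~3% at 1 Hz) from spectral
  smear under the (2πf)⁻⁴ conversion; it is a detector, not a reported
  amplitude.
* With an accelerometer-only tilt reference, sustained non-gravitational
  acceleration that keeps the specific-force norm near 1 g (coordinated
  turns, swinging) can still bias tilt; irrelevant on the bench protocol,
  relevant for free-living data.
* Rotation and translation amplitudes are estimated independently from the
  gyro and accelerometer spectra; combined rototranslation at the same
  frequency is reported as both, not decomposed kinematically.

An optional `per_location_bounds` mode estimates the band separately per
sensor location (each location pools only its own peaks), for subjects
whose limbs tremble at different frequencies; off by default, matching the
subject-wide pooling of the main procedure.
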