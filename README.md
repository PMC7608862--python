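# tremorkit

Quantification of essential tremor from wearable inertial sensors, in the
physical units clinicians use: degrees of rotation and centimetres of
displacement.

Clinical tremor scales (e.g. TETRAS) score limb displacement in cm by eye;
an IMU measures specific force and angular velocity, and the action tremor
typical of essential tremor is intermittent, subject-specific in frequency
(≈ ±1 Hz inside the 4–12 Hz population range) and superposed on voluntary
movement. `tremorkit` implements a two-pass spectral pipeline built for
exactly those properties:

1. **Candidate peaks.** Orientation is estimated with a complementary
   attitude filter, gravity is subtracted in the Earth frame, and
   sliding-window channel-summed Blackman–Tukey PSDs of acceleration and
   angular velocity are scanned for spectral peaks. Each peak gets a
   *power fraction*

   ρ = ∫(p(f) − b(f)) df / max(p_min, ∫_{f>f_T} p(f) df),

   the share of segment power above a straight-line baseline b(f) that
   models concurrent non-tremor activity.
2. **Subject band.** Peaks pooled over all recordings and sensors vote,
   weighted by ρ, for the subject's tremor band [f_l, f_u]: the weighted
   interquartile range of peak frequencies padded by δ_f = 1 Hz.
3. **Quantification.** Each segment is re-scanned within [f_l, f_u]; a
   winning peak with ρ above the detection threshold is modelled as a
   sinusoid of amplitude a = √(2·∫(p − b) df) and converted by
   frequency-domain integration: displacement a_p = a/(2πf)² (cm, from the
   acceleration spectrum) and rotation a_r = a/(2πf) (degrees, from the
   gyro spectrum).

A virtual robot arm (`tremorkit.simulate`) synthesises prescribed
sinusoidal rotations and translations — with gravity seen from the rotating
sensor frame, sensor noise, and optional voluntary-movement confounders —
so the whole pipeline can be validated against exact ground truth without
hardware.

## Worked example

```python
from tremorkit import SyntheticScenario, TremorQuantifier, simulate_recording

session = []
for task, seed in [("postural", 1), ("wingbeat", 2)]:
    rec, truth = simulate_recording(
        SyntheticScenario(rot_amp_deg=2.0, rot_freq=5.2, seed=seed, task=task)
    )
    session.append(rec)

tq = TremorQuantifier().fit(session)      # passes 1-2: learn the subject band
b = tq.frequency_bounds_
print(f"subject band: [{b.f_l:.2f}, {b.f_u:.2f}] Hz from {b.n_peaks_used} peaks")

report = tq.predict()                      # pass 3: re-scan the session
for r in report.recordings:
    print(f"{r.task}: detected {r.n_detected}/{len(r.estimates)} segments, "
          f"median a_r = {r.median_a_r_deg:.3f} deg")
```

prints

```
subject band: [4.19, 6.19] Hz from 20 peaks
postural: detected 10/10 segments, median a_r = 2.000 deg
wingbeat: detected 10/10 segments, median a_r = 2.000 deg
```

The two 15 s recordings carried a programmed 2.0° rotational tremor at
5.2 Hz under default sensor noise; the learned band brackets 5.2 Hz
(5.2 ∓ 1 Hz padding, within a grid bin) and the recovered median amplitude
matches the programmed one to three decimals. `TremorQuantifier` follows
the scikit-learn estimator protocol (`get_params`/`set_params`/`clone`,
`fit`/`predict`/`transform`); `tremorkit.run_subject(recordings)` is the
equivalent one-call functional interface, and `report.to_json()` /
`report.to_frame()` export per-segment results.

The same pipeline is scriptable from the shell:

```sh
tremorkit simulate --seed 5 --freqs 5.2 --rot-amps 2.0 --pos-amps "" --out demo
tremorkit run --input demo --out demo/report.json
tremorkit validate --freqs 4.0,5.2,6.4          # amplitude-recovery table
tremorkit show-config > params.yaml             # all tunables, YAML
```

Recordings are exchanged as CSV (`time,ax,ay,az,gx,gy,gz` plus a YAML
sidecar declaring units and sample rate — unit-less files are refused) or
as an HDF5 container with one group per sensor location.

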