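# tapekin

Kinematics of tape-like unstable training surfaces (coordination-training
tapes, slacklines) estimated purely from orientation angles measured in the
tape sections next to the two anchor points.

The tape is modeled as an ideal rope: it carries only tension, so each
unloaded span is a straight segment between an anchor and the load.  The
pitch angles at the two anchors then locate the load in the sagittal plane
(longitudinal position and vertical displacement) by ray intersection; the
same construction on the yaw angles gives the lateral displacement.  Roll
under the load is extrapolated from the anchor-section rolls with a
piecewise-linear torsion model in which the spring segments may twist at a
different rate than the tape.

The package contains:

- `tapekin.model` — the closed-form inverse model (both the
  ray-intersection and the trigonometric formulation, cross-checked at run
  time), the flat-foot depth correction, four roll-prediction variants
  (RM/RS/RWS/RA), least-squares parameter calibration, and per-frame
  quality flags.
- `tapekin.simulator` — a forward geometric simulator producing ground-truth
  shapes, per-section angles, edge-marker clouds, clean "motion-capture"
  angle streams and IMU-like degraded streams (one-sided pitch drift, yaw
  random walk, white noise).
- `tapekin.pipeline` — offline signal conditioning: zero-phase Butterworth
  low-pass, resampling two streams onto a shared 200 Hz grid, foot-off frame
  exclusion (70 mm rule), pitch clamping/shifting and high-pass detrending
  for drift.
- `tapekin.sections` — marker-based rigid-section reconstruction (Kabsch
  fit, Tait–Bryan XYZ-intrinsic angles) with the 11-marker / 7-section tape
  layout.
- `tapekin.evaluation` — reference extraction, RMSE, 2/25/50/75/98
  percentile summaries and position-conditioned error profiles.
- `tapekin.cli` / `tapekin.io` — plain-text trial bundles (CSV/JSON/YAML)
  and the `tapekin` command-line tool.

## CLI

```sh
# synthesize a trial bundle from a keyframed scenario
tapekin simulate examples/walking.yaml out/demo

# run the inverse model on the clean or degraded stream
tapekin estimate out/demo --source mocap --out out/demo/estimates.csv
tapekin estimate out/demo --source imu --clamp --out out/demo/estimates_imu.csv

# fit model parameters from a bundle with ground truth
tapekin calibrate out/demo --target segment_ratio --target spring_coeff

# accuracy summary and position-conditioned error profiles
tapekin evaluate out/demo/estimates.csv out/demo \
    --out out/demo/summary.json --profiles out/demo/profiles.csv
```

Exit codes: 0 success, 2 usage error, 3 data error.  All angle units are
degrees, lengths are mm, timestamps are seconds; the device frame has its
origin mid-span with X along the tape, Y left and Z up.  Both normalized
input pitch angles are positive when the tape is displaced downward (the
physical front-sensor sign is flipped on ingest).

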