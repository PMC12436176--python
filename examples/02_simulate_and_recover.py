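"""Round-trip validation: prescribed gait waveforms vs. recovered angles.

Simulates five gait cycles of a typically developing foot twice -- once
noiseless and once with 1 mm Gaussian marker noise -- runs the full pipeline
(smoothing, calibration, rigid cluster tracking, Cardan decomposition), and
reports the recovery error per channel against the generator's ground truth.
"""

import numpy as np

from hffm import (
    GaitWaveformConfig,
    compute_angle_trajectories,
    generate_trial,
    make_template_foot,
    normalize_to_cycle,
)

template = make_template_foot("R")

for noise in (0.0, 1.0):
    cfg = GaitWaveformConfig(noise_sd_mm=noise, n_cycles=5, seed=7)
    traj, truth, events = generate_trial(template, cfg)
    recovered = compute_angle_trajectories(
        traj, calibration=template.neutral_frame(), smooth=noise > 0
    )
    print(f"\nmarker noise {noise:.1f} mm "
          f"({traj.n_samples} samples, {events.n_cycles} cycles)")
    print(f"  {'channel':32s} {'max |err|':>10s} {'curve RMSE':>11s}")
    for name, expected in truth.items():
        err = np.nanmax(np.abs(recovered[name] - expected))
        c_rec = normalize_to_cycle(recovered[name], events)
        c_true = normalize_to_cycle(expected, events)
        rmse = np.sqrt(np.mean((c_rec.values - c_true.values) ** 2))
        print(f"  {name:32s} {err:9.4f}  {rmse:9.4f}  deg")

print("""
Noiseless trajectories are recovered to numerical precision because the
generator pivots each segment about the model's own regressed joint centers.
With 1 mm marker noise the per-channel gait-curve RMSE stays near or below
one degree after the default 6 Hz-equivalent spline smoothing.""")
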