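"""Measure spatial accuracy and precision on simulated grid sessions.

A session with a known 1.0 deg calibration offset and 0.3 deg angular
noise is generated per grid distance; per-target metrics are averaged
per distance and summarized over distances, mirroring how a data-quality
report for a head-mounted eye tracker is assembled.
"""

import numpy as np

from gaze3d import (
    SimulationConfig,
    evaluate_against_ground_truth,
    simulate_recording,
    summarize_over_distances,
)

per_distance = []
print("distance   accuracy      precision   (mean over 9 targets)")
for distance in (0.5, 1.0, 2.0, 4.0):
    config = SimulationConfig(
        distances=(distance,),
        fixation_duration_s=3.0,
        offset_deg=1.0,
        noise_sd_deg=0.3,
        seed=11,
    )
    recording, truth = simulate_recording(config)
    results = evaluate_against_ground_truth(recording, truth)
    acc_cm = np.mean([r.accuracy_cm for r in results])
    acc_deg = np.mean([r.accuracy_deg for r in results])
    prec_cm = np.mean([r.precision_cm for r in results])
    prec_deg = np.mean([r.precision_deg for r in results])
    per_distance.append(results)
    print(f"{distance:5.1f} m  {acc_cm:5.2f} cm {acc_deg:5.2f} deg"
          f"  {prec_cm:5.2f} cm {prec_deg:5.2f} deg")

flat = [
    type(rs[0])(
        accuracy_deg=float(np.mean([r.accuracy_deg for r in rs])),
        precision_deg=float(np.mean([r.precision_deg for r in rs])),
    )
    for rs in per_distance
]
mean_acc, mean_prec = summarize_over_distances(flat)
print(f"\nmean over distances: accuracy {mean_acc} deg, precision {mean_prec} deg")
print("The cm error grows with distance while the angular error stays near the")
print("injected 1.0 deg offset; the angular precision reflects the 0.3 deg noise.")
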