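"""Simulate a 30 Hz gaze recording with timestamp faults and validate it.

The simulator injects duplicated device timestamps (delta 0 ms) and
dropped frames (delta a multiple of 33.33 ms).  Validation removes the
duplicates, flags the dropped-frame gaps, and reports the statistics of
the regular inter-sample intervals.
"""

import json

from gaze3d import SimulationConfig, simulate_recording, validate_timestamps

config = SimulationConfig(
    distances=(1.0,),
    fixation_duration_s=2.0,
    noise_sd_deg=0.3,
    duplicate_count=4,
    drop_frame_count=3,
    seed=42,
)
recording, truth = simulate_recording(config)
cleaned, report = validate_timestamps(recording)

print(f"samples recorded: {len(recording)}")
print(json.dumps(report.to_dict(), indent=2))
print(
    f"-> {report.n_duplicates} duplicate timestamps removed, "
    f"{report.n_dropped_frame_gaps} dropped-frame gaps retained; the mean "
    f"regular interval of {report.mean_delta:.2f} ms is the nominal 30 Hz frame time."
)
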