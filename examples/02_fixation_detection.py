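"""Detect fixations on a synthetic session with I-VT, I-DT and I-AOI.

Nine 3-second fixations on the target grid, joined by saccades.  All
three detectors should agree on the number of fixation events; their
exact extents differ slightly by construction (I-VT erodes boundary
samples whose velocity window straddles a saccade).
"""

from gaze3d import (
    DiscardParams,
    IAOIParams,
    IDTParams,
    IVTParams,
    SimulationConfig,
    discard_short_fixations,
    events_to_frame,
    iaoi,
    idt,
    ivt,
    simulate_recording,
)

config = SimulationConfig(
    distances=(2.0,), fixation_duration_s=3.0, noise_sd_deg=0.2, seed=7
)
recording, truth = simulate_recording(config)

labels, ivt_events = ivt(recording, IVTParams(velocity_threshold=30.0))
ivt_events = discard_short_fixations(ivt_events, DiscardParams(min_duration=60.0))
idt_events = idt(recording, IDTParams(dispersion_threshold=1.0, window_duration=250.0))
iaoi_events = iaoi(recording, IAOIParams(min_duration=100.0))

print(f"I-VT : {len(ivt_events)} fixation events")
print(f"I-DT : {len(idt_events)} fixation events")
print(f"I-AOI: {len(iaoi_events)} fixation events "
      f"(AOIs: {[e.aoi_name for e in iaoi_events[:3]]} ...)")
print()
print(events_to_frame(ivt_events).round(3).to_string(index=False))
print()
print("Each row is one fixation: time span and duration in ms, 3D centroid in")
print("metres (world frame), dispersion in degrees of visual angle.")
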