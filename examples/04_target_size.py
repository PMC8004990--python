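"""Minimum target sizes from measured accuracy and precision.

S = 2 (O + 2 sigma) gives the smallest target diameter such that about
95% of gaze samples land on the target, from the accuracy offset O and
precision sigma in cm.  Inputs below are the published per-distance
measurements of an AR headset's integrated eye tracker (resting and walking).
"""

from gaze3d import minimum_target_size
from gaze3d._util import round_half_up

RESTING = {0.5: (0.91, 0.40), 1.0: (1.56, 0.67), 2.0: (2.85, 1.35), 4.0: (5.03, 3.12)}
WALKING = {0.5: (2.29, 1.89), 1.0: (3.35, 3.33), 2.0: (5.07, 6.32), 4.0: (9.75, 12.58)}

print("distance   resting    walking")
for d in RESTING:
    s_rest = round_half_up(minimum_target_size(*RESTING[d]), 2)
    s_walk = round_half_up(minimum_target_size(*WALKING[d]), 2)
    print(f"{d:5.1f} m  {s_rest:6.2f} cm {s_walk:7.2f} cm")

s3 = round_half_up(minimum_target_size(0.34, 0.87), 2)
s1 = round_half_up(minimum_target_size(*RESTING[0.5]), 2)
print(f"\nstationary target: {s3:.2f} cm "
      f"({round((s3 / s1 - 1) * 100)}% larger than resting at 0.5 m)")
print("Walking roughly triples the required target size at every distance.")
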