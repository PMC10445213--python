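"""Detect fixations, saccades and a blink in a synthetic gaze trace.

A trace with two known fixations joined by a 5-deg saccade is rendered at
1000 Hz and run through the velocity/acceleration-threshold detector
(30 deg/s, 8000 deg/s^2); events bordering the planted blink are excluded.
"""

import pandas as pd

from trailgaze import detect_events, filter_events, generate_raw_samples

fixations = pd.DataFrame(
    {
        "onset_ms": [0.0, 432.0, 1100.0],
        "offset_ms": [400.0, 1070.0, 1600.0],
        "cx": [0.0, 5.0, 2.0],
        "cy": [0.0, 0.0, -3.0],
    }
)
blinks = pd.DataFrame({"onset_ms": [700.0], "offset_ms": [800.0]})
trace = generate_raw_samples(fixations, jitter_deg=0.0, seed=0, blinks=blinks)
print(f"rendered {len(trace)} samples ({trace['valid'].sum()} valid)")

fix, sacc, blk = detect_events(trace)
fix, sacc = filter_events(fix, sacc)
print("\nfixations (ms, deg):")
print(fix.round(2).to_string(index=False))
print("\nsaccades:")
print(sacc[["onset_ms", "offset_ms", "amplitude_deg", "peak_velocity"]].round(2).to_string(index=False))
print("\nblinks:")
print(blk.to_string(index=False))
print(
    "\nThe fixation interrupted by the blink is dropped entirely (events "
    "within 50 ms of a blink are excluded); the 5-deg saccade survives."
)
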