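"""Generate a trial layout and convert between pixel and degree space.

Targets are 1.35-deg circles placed one per cell of a centered 5x5 grid
(4.32-deg cells); part B uses the alternating number/letter sequence.
"""

import pandas as pd

from trailgaze import DEFAULT_GEOMETRY, generate_layout, pixels_to_degrees

layout = generate_layout("B", seed=7)
frame = layout.to_frame()
print(frame.head(6).to_string(index=False))
print(f"...\n{len(frame)} targets, part {layout.part}")

pos = layout.positions()
print(f"x range: {pos[:, 0].min():+.2f} to {pos[:, 0].max():+.2f} deg")

# the screen corner pixel, expressed as a visual angle at 71 cm viewing distance
corner = pd.DataFrame({"t_ms": [0.0], "x": [1024.0], "y": [0.0], "valid": [True]})
corner.attrs["unit"] = "px"
deg = pixels_to_degrees(corner, DEFAULT_GEOMETRY)
print(f"pixel (1024, 0) -> ({deg['x'][0]:.2f}, {deg['y'][0]:.2f}) deg from screen center")
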