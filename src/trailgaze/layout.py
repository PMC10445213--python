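"""Trial layouts: 25 circular targets on a 5x5 grid in degree space.

Targets are unfilled circles of 1.35 deg diameter placed one per cell of a
centered 5x5 grid with 4.32 x 4.32 deg cells.  Positions are uniform within
each cell subject to a margin keeping the full circle inside its cell,
which also guarantees the required minimum center-to-center separation of
1.35 deg between any two targets.  Sequence labels are "1".."25" for part A
and the alternating "1", "A", "2", "B", ..., "13" for part B.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import DEFAULT_GEOMETRY, ScreenGeometry

__all__ = ["TargetItem", "TrialLayout", "generate_layout", "part_labels"]

GRID_SIZE = 5
CELL_DEG = 4.32
TARGET_RADIUS_DEG = 0.675  # circumcircle of the 1.35 deg diameter circle
MIN_SEPARATION_DEG = 1.35


@dataclass(frozen=True)
class TargetItem:
    label: str
    seq_index: int  # 1..25, click order
    x: float  # degrees, screen-centered
    y: float
    radius: float = TARGET_RADIUS_DEG


@dataclass(frozen=True)
class TrialLayout:
    part: str  # "A" or "B"
    targets: tuple[TargetItem, ...]
    grid_cell_deg: float = CELL_DEG

    def __post_init__(self) -> None:
        if self.part not in ("A", "B"):
            raise ValueError("part must be 'A' or 'B'")
        if len(self.targets) != GRID_SIZE**2:
            raise ValueError(f"layout needs {GRID_SIZE**2} targets, got {len(self.targets)}")
        seqs = [t.seq_index for t in self.targets]
        if sorted(seqs) != list(range(1, GRID_SIZE**2 + 1)):
            raise ValueError("seq_index must be a permutation of 1..25")

    def target(self, seq_index: int) -> TargetItem:
        return next(t for t in self.targets if t.seq_index == seq_index)

    def positions(self) -> np.ndarray:
        """(25, 2) array of target centers ordered by seq_index."""
        ordered = sorted(self.targets, key=lambda t: t.seq_index)
        return np.array([(t.x, t.y) for t in ordered])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "label": [t.label for t in self.targets],
                "seq_index": [t.seq_index for t in self.targets],
                "x_deg": [t.x for t in self.targets],
                "y_deg": [t.y for t in self.targets],
                "radius_deg": [t.radius for t in self.targets],
            }
        ).sort_values("seq_index").reset_index(drop=True)
        df.attrs["part"] = self.part
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, part: str | None = None) -> "TrialLayout":
        part = part or df.attrs.get("part", "A")
        targets = tuple(
            TargetItem(str(r.label), int(r.seq_index), float(r.x_deg), float(r.y_deg), float(r.radius_deg))
            for r in df.itertuples()
        )
        return cls(part=part, targets=targets)


def part_labels(part: str) -> list[str]:
    """Sequence labels in click order: numbers for A, alternating for B."""
    if part == "A":
        return [str(i) for i in range(1, 26)]
    if part == "B":
        labels = []
        for i in range(1, 14):
            labels.append(str(i))
            if i <= 12:
                labels.append(chr(ord("A") + i - 1))
        return labels
    raise ValueError("part must be 'A' or 'B'")


def generate_layout(
    part: str,
    geometry: ScreenGeometry = DEFAULT_GEOMETRY,
    seed: int | np.random.Generator = 0,
    min_separation: float = MIN_SEPARATION_DEG,
    max_retries: int = 1000,
) -> TrialLayout:
    """Random layout: one target per grid cell, separation >= ``min_separation``.

    The grid (5 x 4.32 = 21.6 deg square) must fit on screen; the check
    uses the linear degrees-per-cm extent at screen center.  Cells are
    assigned to sequence positions in random order; within-cell placement
    is rejection-sampled until all pairwise separations hold.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    span = GRID_SIZE * CELL_DEG
    if span > geometry.width_deg_linear or span > geometry.height_deg_linear:
        raise ValueError(
            f"screen ({geometry.width_deg_linear:.1f} x {geometry.height_deg_linear:.1f} deg) "
            f"cannot contain the {span:.1f} deg target grid"
        )
    margin = TARGET_RADIUS_DEG
    half_free = CELL_DEG / 2 - margin
    if half_free < 0:
        raise ValueError("target radius exceeds grid cell")

    cell_centers = (np.arange(GRID_SIZE) - (GRID_SIZE - 1) / 2) * CELL_DEG
    cells = [(cx, cy) for cy in cell_centers for cx in cell_centers]
    order = rng.permutation(len(cells))  # cell of each sequence position

    for _ in range(max_retries):
        offsets = rng.uniform(-half_free, half_free, size=(len(cells), 2))
        pos = np.array([cells[c] for c in order]) + offsets
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.hypot(diff[..., 0], diff[..., 1])
        np.fill_diagonal(dist, np.inf)
        if dist.min() >= min_separation:
            labels = part_labels(part)
            targets = tuple(
                TargetItem(labels[i], i + 1, float(pos[i, 0]), float(pos[i, 1]))
                for i in range(len(cells))
            )
            return TrialLayout(part=part, targets=targets)
    raise RuntimeError(
        f"layout rejection sampling exhausted {max_retries} retries; "
        f"min_separation={min_separation} infeasible for this grid"
    )
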