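"""Velocity/acceleration-threshold detection of fixations, saccades, blinks.

The detector is an I-VT-style classifier operating on uniformly sampled
monocular gaze traces in degree space (1000 Hz default):

1. Runs of invalid samples at least ``blink_min_ms`` long become blinks;
   shorter dropouts are treated as tracker noise and linearly interpolated.
2. Within each valid segment, position is smoothed with a moving average
   (``smooth_window`` samples), and velocity / acceleration are computed by
   central finite differences.  Samples with velocity >= 30 deg/s or
   acceleration >= 8000 deg/s^2 are saccade samples; maximal supra-threshold
   runs become saccades and the complementary runs become fixations.
3. Saccade run boundaries are refined against the thresholds applied to the
   *unsmoothed* derivatives within one smoothing window, undoing the
   temporal smearing the filter introduces at event edges.
4. Fixations and saccades overlapping any blink window extended by
   ``blink_margin_ms`` on both sides are removed.

:func:`filter_events` then applies the analysis filters: fixations shorter
than 50 ms and saccades smaller than 0.1 deg (microsaccades) are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Fixation",
    "Saccade",
    "Blink",
    "detect_events",
    "filter_events",
]

FIX_COLUMNS = ["onset_ms", "offset_ms", "cx", "cy", "duration_ms"]
SACC_COLUMNS = ["onset_ms", "offset_ms", "x0", "y0", "x1", "y1", "amplitude_deg", "peak_velocity"]
BLINK_COLUMNS = ["onset_ms", "offset_ms"]


@dataclass(frozen=True)
class Fixation:
    onset_ms: float
    offset_ms: float
    cx: float
    cy: float

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass(frozen=True)
class Saccade:
    onset_ms: float
    offset_ms: float
    x0: float
    y0: float
    x1: float
    y1: float
    peak_velocity: float

    @property
    def amplitude_deg(self) -> float:
        return float(np.hypot(self.x1 - self.x0, self.y1 - self.y0))


@dataclass(frozen=True)
class Blink:
    onset_ms: float
    offset_ms: float


def _runs(mask: np.ndarray):
    """Yield (start, stop) index pairs of maximal True runs."""
    if mask.size == 0:
        return
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = list(edges[~mask[edges]] + 1)
    stops = list(edges[mask[edges]] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    yield from zip(starts, stops)


def _smooth(a: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return a
    pad = window // 2
    return np.convolve(np.pad(a, pad, mode="edge"), np.ones(window) / window, mode="valid")


def _derivative(a: np.ndarray, dt_s: float) -> np.ndarray:
    d = np.empty_like(a)
    if a.size < 3:
        d[:] = 0.0
        return d
    d[1:-1] = (a[2:] - a[:-2]) / (2 * dt_s)
    d[0], d[-1] = d[1], d[-2]
    return d


def _threshold_mask(x, y, dt_s, vthr, athr, window):
    xs, ys = _smooth(x, window), _smooth(y, window)
    vx, vy = _derivative(xs, dt_s), _derivative(ys, dt_s)
    speed = np.hypot(vx, vy)
    ax, ay = _derivative(vx, dt_s), _derivative(vy, dt_s)
    accel = np.hypot(ax, ay)
    return (speed >= vthr) | (accel >= athr), speed


def detect_events(
    samples: pd.DataFrame,
    rate_hz: float = 1000.0,
    velocity_threshold: float = 30.0,
    accel_threshold: float = 8000.0,
    smooth_window: int = 5,
    blink_min_ms: float = 10.0,
    blink_margin_ms: float = 50.0,
    refine: bool = True,
):
    """Classify a degree-space sample stream into fixations, saccades, blinks.

    Parameters
    ----------
    samples
        DataFrame with columns ``t_ms``, ``x``, ``y`` (degrees), ``valid``.
        Sampling must be uniform at ``rate_hz``.

    Returns
    -------
    (fixations, saccades, blinks) : three DataFrames with columns
    ``FIX_COLUMNS``, ``SACC_COLUMNS``, ``BLINK_COLUMNS``.
    """
    if samples.attrs.get("unit", "deg") != "deg":
        raise ValueError("detect_events expects samples in degrees; convert with pixels_to_degrees")
    t = samples["t_ms"].to_numpy(dtype=float)
    if t.size and (np.diff(t) <= 0).any():
        raise ValueError("sample timestamps must be strictly increasing")
    x = samples["x"].to_numpy(dtype=float)
    y = samples["y"].to_numpy(dtype=float)
    valid = samples["valid"].to_numpy(dtype=bool)
    dt_s = 1.0 / rate_hz
    dt_ms = 1000.0 * dt_s
    n = t.size

    empty = (
        pd.DataFrame(columns=FIX_COLUMNS, dtype=float),
        pd.DataFrame(columns=SACC_COLUMNS, dtype=float),
        pd.DataFrame(columns=BLINK_COLUMNS, dtype=float),
    )
    if not valid.any():
        logger.warning("degenerate trace: no valid samples")
        return empty

    # -- blinks and short-dropout interpolation ---------------------------
    blinks = []
    blink_mask = np.zeros(n, dtype=bool)
    for i0, i1 in _runs(~valid):
        if (i1 - i0) * dt_ms >= blink_min_ms:
            blinks.append((t[i0], t[i1 - 1] + dt_ms))
            blink_mask[i0:i1] = True
        else:  # interpolate single-sample-scale dropouts
            lo = i0 - 1
            hi = i1 if i1 < n else n - 1
            if lo < 0 or not valid[hi]:
                blink_mask[i0:i1] = True  # dropout at trace edge: treat as gap
                continue
            frac = (np.arange(i0, i1) - lo) / (hi - lo)
            x[i0:i1] = x[lo] + frac * (x[hi] - x[lo])
            y[i0:i1] = y[lo] + frac * (y[hi] - y[lo])

    min_seg = max(smooth_window, 3)
    usable = ~blink_mask
    if not blinks and n < min_seg:
        raise ValueError(f"trace too short: {n} samples < smoothing window {min_seg}")

    fixations, saccades = [], []
    for s0, s1 in _runs(usable):
        seg = slice(s0, s1)
        m = s1 - s0
        if m < min_seg:
            continue
        mask, speed = _threshold_mask(x[seg], y[seg], dt_s, velocity_threshold, accel_threshold, smooth_window)
        if refine and smooth_window > 1:
            raw_mask, _ = _threshold_mask(x[seg], y[seg], dt_s, velocity_threshold, accel_threshold, 1)
            mask = _refine_mask(mask, raw_mask, smooth_window)
        for i0, i1 in _runs(mask):
            saccades.append(
                dict(
                    onset_ms=t[s0 + i0],
                    offset_ms=t[s0 + i1 - 1] + dt_ms,
                    x0=x[s0 + i0], y0=y[s0 + i0],
                    x1=x[s0 + i1 - 1], y1=y[s0 + i1 - 1],
                    amplitude_deg=float(np.hypot(x[s0 + i1 - 1] - x[s0 + i0], y[s0 + i1 - 1] - y[s0 + i0])),
                    peak_velocity=float(speed[i0:i1].max()),
                )
            )
        for i0, i1 in _runs(~mask):
            fixations.append(
                dict(
                    onset_ms=t[s0 + i0],
                    offset_ms=t[s0 + i1 - 1] + dt_ms,
                    cx=float(x[s0 + i0 : s0 + i1].mean()),
                    cy=float(y[s0 + i0 : s0 + i1].mean()),
                )
            )

    fix = pd.DataFrame(fixations, columns=[c for c in FIX_COLUMNS if c != "duration_ms"])
    sacc = pd.DataFrame(saccades, columns=SACC_COLUMNS)
    blk = pd.DataFrame(blinks, columns=BLINK_COLUMNS)
    if len(fix):
        fix["duration_ms"] = fix["offset_ms"] - fix["onset_ms"]
    else:
        fix["duration_ms"] = pd.Series(dtype=float)

    # -- blink-margin exclusion -------------------------------------------
    for _, b in blk.iterrows():
        w0, w1 = b["onset_ms"] - blink_margin_ms, b["offset_ms"] + blink_margin_ms
        if len(fix):
            fix = fix[(fix["offset_ms"] <= w0) | (fix["onset_ms"] >= w1)]
        if len(sacc):
            sacc = sacc[(sacc["offset_ms"] <= w0) | (sacc["onset_ms"] >= w1)]

    fix = fix.sort_values("onset_ms").reset_index(drop=True)
    sacc = sacc.sort_values("onset_ms").reset_index(drop=True)
    return fix[FIX_COLUMNS], sacc, blk


def _refine_mask(mask: np.ndarray, raw_mask: np.ndarray, window: int) -> np.ndarray:
    """Snap run boundaries of ``mask`` to ``raw_mask`` within one window."""
    out = mask.copy()
    n = mask.size
    for i0, i1 in _runs(mask):
        lo = max(0, i0 - window)
        hi = min(n, i1 + window)
        local = np.flatnonzero(raw_mask[lo:hi])
        if local.size == 0:
            continue  # borderline event visible only after smoothing: keep as-is
        r0, r1 = lo + local[0], lo + local[-1] + 1
        out[i0:i1] = False
        out[r0:r1] = True
    return out


def filter_events(
    fixations: pd.DataFrame,
    saccades: pd.DataFrame,
    min_fixation_ms: float = 50.0,
    min_saccade_deg: float = 0.1,
):
    """Apply the analysis filters: keep fixations with duration >=
    ``min_fixation_ms`` and saccades with amplitude >= ``min_saccade_deg``."""
    fix = fixations
    sacc = saccades
    if len(fix):
        fix = fix[fix["duration_ms"] >= min_fixation_ms].reset_index(drop=True)
    if len(sacc):
        sacc = sacc[sacc["amplitude_deg"] >= min_saccade_deg].reset_index(drop=True)
    return fix, sacc
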