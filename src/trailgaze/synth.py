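"""Synthetic two-session trail-making datasets with known ground truth.

The generator emulates the structure of a computerized 25-target
trail-making experiment recorded with a 1000 Hz eye tracker and a 100 Hz
mouse: subjects carry latent traits (fixation-duration mean, searching
rate, eye-hand lag, click dispersion, movement speed) that are correlated
between sessions at a configurable intraclass correlation; trials are
event streams of searching and guiding fixations with clicks whose latency
follows the subject's eye-hand lag; raw gaze traces can be rendered from
the event streams for testing event detection.

Every planted quantity (per-trial searching/guiding counts, realized
eye-hand spans, scanpath length, completion time) is recorded in a
:class:`TrialGroundTruth`, so downstream scoring can be verified exactly.

Trait model
-----------
For each trait with mean m, sd s and reliability icc, the session-1 and
session-2 latent values across subjects are bivariate normal with equal
moments and between-session correlation c.  With ``icc_scale='average'``
(default) the configured icc is the *population ICC(A,2)* of the resulting
n x 2 table, i.e. c = icc / (2 - icc); with ``icc_scale='pair'`` the
configured icc is the pair correlation itself, c = icc (in which case the
average-measures ICC(A,2) converges to the Spearman-Brown value
2*icc/(1+icc)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import DEFAULT_GEOMETRY, ScreenGeometry
from .layout import TrialLayout, generate_layout

__all__ = [
    "TraitSpec",
    "SimulationConfig",
    "SubjectTraits",
    "TrialGroundTruth",
    "TrialEvents",
    "Dataset",
    "generate_cohort",
    "cohort_table",
    "generate_trial_events",
    "generate_raw_samples",
    "generate_dataset",
]

KEY_COLUMNS = ["subject", "session", "part", "instruction", "trial"]


@dataclass(frozen=True)
class TraitSpec:
    """Population distribution of one latent trait."""

    mean: float
    sd: float
    icc: float | None = None  # None -> SimulationConfig.true_icc
    lower: float = -math.inf  # truncation bounds keeping draws physical
    upper: float = math.inf


def _default_traits() -> dict[str, TraitSpec]:
    # means/sds chosen to land trial scores in the range healthy adults
    # produce on this task (completion ~35-65 s, ~5 searching fixations
    # per target, fixation durations ~180 ms, eye-hand lag ~1 s)
    return {
        "fix_dur_mean_ms": TraitSpec(180.0, 15.0, lower=90.0),
        "search_rate": TraitSpec(4.5, 1.0, lower=0.5),
        "eye_hand_lag_ms": TraitSpec(1000.0, 250.0, lower=300.0),
        "click_dispersion_deg": TraitSpec(0.30, 0.06, lower=0.02),
        "speed_factor": TraitSpec(1.0, 0.15, lower=0.4),
        # probability a target is clicked without a final guiding look,
        # which is what makes guiding-fixation counts vary across subjects
        "guide_skip_prob": TraitSpec(0.35, 0.10, lower=0.0, upper=0.9),
    }


@dataclass(frozen=True)
class SimulationConfig:
    n_subjects: int = 31
    true_icc: float = 0.6
    traits: dict[str, TraitSpec] = field(default_factory=_default_traits)
    trials_per_condition: int = 2
    seed: int = 0
    icc_scale: str = "average"  # 'average' (population ICC(A,2)) or 'pair'
    rate_hz: float = 1000.0
    fixation_jitter_deg: float = 0.0  # raw-sample rendering noise
    fix_pos_jitter_deg: float = 0.1  # fixation centroid offset from its object
    lag_noise_sd_ms: float = 50.0
    accuracy_lag_scale: float = 1.5
    accuracy_dispersion_scale: float = 0.5
    fixed_search_count: int | None = None  # override Poisson draw (testing)
    search_locality_deg: float | None = 4.0  # exp(-d/tau) weighting of search objects; None = uniform
    geometry: ScreenGeometry = field(default_factory=lambda: DEFAULT_GEOMETRY)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not 0.0 <= self.true_icc <= 1.0:
            raise ValueError("true_icc must be in [0, 1]")
        if self.icc_scale not in ("average", "pair"):
            raise ValueError("icc_scale must be 'average' or 'pair'")
        if any(t.sd < 0 for t in self.traits.values()):
            raise ValueError("trait SDs must be >= 0")
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")


@dataclass(frozen=True)
class SubjectTraits:
    subject_id: str
    session: int  # 1 or 2
    values: dict[str, float]


@dataclass(frozen=True)
class TrialGroundTruth:
    """Realized planted quantities for one trial."""

    n_fixations: int
    n_guiding: int
    n_searching: int
    eye_hand_span_ms: float  # median realized correct-click latency
    scanpath_length_deg: float
    completion_time_s: float
    median_fixation_duration_ms: float
    lag_ms: float  # the latent lag parameter used


@dataclass(frozen=True)
class TrialEvents:
    fixations: pd.DataFrame  # onset_ms, offset_ms, cx, cy, duration_ms, object, role
    saccades: pd.DataFrame  # onset_ms, offset_ms, x0, y0, x1, y1, amplitude_deg
    clicks: pd.DataFrame  # t_ms, x, y (degrees)
    ground_truth: TrialGroundTruth


def _pair_correlation(icc: float, scale: str) -> float:
    if scale == "pair":
        return icc
    return icc / (2.0 - icc)  # population ICC(A,2) == icc


def generate_cohort(config: SimulationConfig) -> list[SubjectTraits]:
    """Draw the latent two-session trait values for all subjects.

    Each trait's (session1, session2) values are bivariate normal across
    subjects with the between-session correlation implied by the trait's
    icc and ``config.icc_scale``; draws below a trait's physical lower
    bound are re-drawn (truncation, which is why extreme sd/mean ratios
    slightly perturb the realized correlation).
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 101)))
    per_subject: list[dict[str, float]] = [dict() for _ in range(2 * config.n_subjects)]
    for name, spec in config.traits.items():
        icc = config.true_icc if spec.icc is None else spec.icc
        c = _pair_correlation(icc, config.icc_scale)
        cov = np.array([[1.0, c], [c, 1.0]]) * spec.sd**2
        vals = rng.multivariate_normal([spec.mean, spec.mean], cov, size=config.n_subjects)
        bad = ((vals < spec.lower) | (vals > spec.upper)).any(axis=1)
        while bad.any():
            vals[bad] = rng.multivariate_normal([spec.mean, spec.mean], cov, size=int(bad.sum()))
            bad = ((vals < spec.lower) | (vals > spec.upper)).any(axis=1)
        for i in range(config.n_subjects):
            per_subject[2 * i][name] = float(vals[i, 0])
            per_subject[2 * i + 1][name] = float(vals[i, 1])
    cohort = []
    for i in range(config.n_subjects):
        sid = f"S{i + 1:03d}"
        cohort.append(SubjectTraits(sid, 1, per_subject[2 * i]))
        cohort.append(SubjectTraits(sid, 2, per_subject[2 * i + 1]))
    return cohort


def cohort_table(cohort: list[SubjectTraits], trait: str) -> np.ndarray:
    """n x 2 (session1, session2) matrix of one latent trait."""
    by_subject: dict[str, dict[int, float]] = {}
    for st in cohort:
        by_subject.setdefault(st.subject_id, {})[st.session] = st.values[trait]
    return np.array([[v[1], v[2]] for v in by_subject.values()])


# ---------------------------------------------------------------------------
# event-level trial synthesis


def _saccade_duration_ms(amplitude_deg: float) -> float:
    """Main-sequence approximation: 2.2 ms/deg x amplitude + 21 ms."""
    return 2.2 * amplitude_deg + 21.0


def generate_trial_events(
    traits: SubjectTraits,
    layout: TrialLayout,
    instruction: str,
    seed: int | np.random.Generator = 0,
    config: SimulationConfig | None = None,
) -> TrialEvents:
    """Synthesize one trial's fixations, saccades and clicks.

    For each target in sequence order the trial contains a planted number
    of searching fixations on other targets (Poisson with the subject's
    rate, or ``config.fixed_search_count``), exactly one guiding fixation
    within reach of the current target, and a click at guiding-fixation
    onset + the subject's eye-hand lag (+ Gaussian noise).  The accuracy
    instruction halves click dispersion and lengthens the lag.

    Construction invariants that make the planted quantities exactly
    recoverable by the scorer: a searching fixation's object is never the
    current target at its onset, consecutive fixations always have
    different objects, and a guiding fixation's onset always falls after
    the previous target's correct click.
    """
    if instruction not in ("speed", "accuracy"):
        raise ValueError("instruction must be 'speed' or 'accuracy'")
    cfg = config or SimulationConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    lag = traits.values["eye_hand_lag_ms"]
    dispersion = traits.values["click_dispersion_deg"]
    if instruction == "accuracy":
        lag = lag * cfg.accuracy_lag_scale
        dispersion = dispersion * cfg.accuracy_dispersion_scale
    rate = traits.values["search_rate"]
    dur_mean = traits.values["fix_dur_mean_ms"]
    speed_factor = traits.values.get("speed_factor", 1.0)
    skip_prob = traits.values.get("guide_skip_prob", 0.0)

    pos = layout.positions()
    n_targets = pos.shape[0]
    radius = layout.targets[0].radius

    def fix_duration() -> float:
        # Gamma, shape 40 => cv ~ 0.16; floor keeps events above the 50 ms filter
        d = rng.gamma(40.0, dur_mean / 40.0) / speed_factor
        return float(max(80.0, round(d)))

    def jitter_point(center: np.ndarray) -> np.ndarray:
        if cfg.fix_pos_jitter_deg <= 0:
            return center.copy()
        ang = rng.uniform(0, 2 * np.pi)
        r = cfg.fix_pos_jitter_deg * np.sqrt(rng.uniform())
        return center + r * np.array([np.cos(ang), np.sin(ang)])

    fixations: list[dict] = []
    clicks: list[dict] = []
    click_times: list[tuple[int, float]] = []  # (target seq, correct click t)

    def current_at(t: float) -> int:
        cur = 1
        for seq, ct in click_times:
            if ct < t:
                cur = seq + 1
        return cur

    t = 0.0  # trial-start click on the fixation cross at time 0
    prev_xy = np.zeros(2)
    prev_obj = -1
    spans: list[float] = []

    for target in range(1, n_targets + 1):
        k = cfg.fixed_search_count if cfg.fixed_search_count is not None else int(rng.poisson(rate))
        for _ in range(k):
            for _attempt in range(100):
                if cfg.search_locality_deg:
                    # gaze prefers nearby objects while scanning
                    d = np.hypot(pos[:, 0] - prev_xy[0], pos[:, 1] - prev_xy[1])
                    w = np.exp(-d / cfg.search_locality_deg)
                    obj = int(rng.choice(n_targets, p=w / w.sum())) + 1
                else:
                    obj = int(rng.integers(1, n_targets + 1))
                # never the current or upcoming target (the upcoming target's
                # guiding fixation may directly follow this one, and
                # consecutive fixations must sit on different objects)
                if obj == target or obj == target + 1 or obj == prev_obj:
                    continue
                xy = jitter_point(pos[obj - 1])
                amp = float(np.hypot(*(xy - prev_xy)))
                onset = t + round(_saccade_duration_ms(amp))
                if obj != current_at(onset):
                    break
            else:  # pragma: no cover - 100 draws over 25 targets cannot all collide
                raise RuntimeError("could not place searching fixation")
            dur = fix_duration()
            fixations.append(
                dict(onset_ms=onset, offset_ms=onset + dur, cx=xy[0], cy=xy[1], object=obj, role="searching")
            )
            t, prev_xy, prev_obj = onset + dur, xy, obj

        # guiding fixation on the current target (occasionally skipped:
        # the subject clicks without a final guiding look)
        guided = rng.uniform() >= skip_prob
        if guided:
            xy = jitter_point(pos[target - 1])
            amp = float(np.hypot(*(xy - prev_xy)))
            onset = t + round(_saccade_duration_ms(amp))
            if click_times and onset <= click_times[-1][1]:
                # wait out the pending click by dwelling on the previous fixation
                shift = click_times[-1][1] + 1.0 - onset
                if fixations:
                    fixations[-1]["offset_ms"] += shift
                onset += shift
            dur = fix_duration()
            fixations.append(
                dict(onset_ms=onset, offset_ms=onset + dur, cx=xy[0], cy=xy[1], object=target, role="guiding")
            )
            t, prev_xy, prev_obj = onset + dur, xy, target
        else:
            onset = t  # click is timed from the current stream position

        # click: eye-hand lag after guiding onset, Gaussian around the center
        click_t = onset + lag
        if cfg.lag_noise_sd_ms > 0:
            click_t += rng.normal(0, cfg.lag_noise_sd_ms)
        click_t = round(max(click_t, onset + 1.0, (click_times[-1][1] + 10.0) if click_times else 1.0))
        for _attempt in range(10):
            cxy = pos[target - 1] + rng.normal(0, dispersion, size=2) if dispersion > 0 else pos[target - 1].copy()
            hit = float(np.hypot(*(cxy - pos[target - 1]))) <= radius
            clicks.append(dict(t_ms=click_t, x=float(cxy[0]), y=float(cxy[1])))
            if hit:
                break
            click_t = click_t + 150.0  # re-click after a miss
        else:
            clicks.append(dict(t_ms=click_t + 150.0, x=float(pos[target - 1, 0]), y=float(pos[target - 1, 1])))
            click_t += 150.0
        click_times.append((target, click_t))
        if guided:
            spans.append(click_t - onset)

    fix = pd.DataFrame(fixations)
    fix["duration_ms"] = fix["offset_ms"] - fix["onset_ms"]
    clk = pd.DataFrame(clicks)
    sacc = _saccades_between(fix)

    centers = fix[["cx", "cy"]].to_numpy()
    gt = TrialGroundTruth(
        n_fixations=len(fix),
        n_guiding=int((fix["role"] == "guiding").sum()),
        n_searching=int((fix["role"] == "searching").sum()),
        eye_hand_span_ms=float(np.median(spans)) if spans else math.nan,
        scanpath_length_deg=float(np.hypot(np.diff(centers[:, 0]), np.diff(centers[:, 1])).sum()),
        completion_time_s=click_times[-1][1] / 1000.0,
        median_fixation_duration_ms=float(fix["duration_ms"].median()),
        lag_ms=float(lag),
    )
    return TrialEvents(fixations=fix, saccades=sacc, clicks=clk, ground_truth=gt)


def _saccades_between(fix: pd.DataFrame) -> pd.DataFrame:
    """Saccade records implied by consecutive fixations."""
    rows = []
    for a, b in zip(fix.itertuples(), fix.iloc[1:].itertuples()):
        rows.append(
            dict(
                onset_ms=a.offset_ms,
                offset_ms=b.onset_ms,
                x0=a.cx, y0=a.cy, x1=b.cx, y1=b.cy,
                amplitude_deg=float(np.hypot(b.cx - a.cx, b.cy - a.cy)),
            )
        )
    return pd.DataFrame(rows, columns=["onset_ms", "offset_ms", "x0", "y0", "x1", "y1", "amplitude_deg"])


# ---------------------------------------------------------------------------
# raw-sample rendering


def generate_raw_samples(
    fixations: pd.DataFrame,
    rate_hz: float = 1000.0,
    jitter_deg: float = 0.0,
    seed: int | np.random.Generator = 0,
    blinks: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Render a degree-space gaze trace from a fixation timeline.

    Fixations become centroid + Gaussian jitter; the gap between
    consecutive fixations becomes a raised-cosine position ramp (whose
    peak velocity exceeds the 30 deg/s detection threshold for amplitudes
    >= 0.5 deg at main-sequence durations); optional blink windows are
    rendered as invalid samples.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fx = fixations.sort_values("onset_ms").reset_index(drop=True)
    if ((fx["offset_ms"] - fx["onset_ms"]) <= 0).any():
        raise ValueError("fixation durations must be positive")
    if (fx["onset_ms"].iloc[1:].to_numpy() < fx["offset_ms"].iloc[:-1].to_numpy()).any():
        raise ValueError("fixation events overlap")

    dt = 1000.0 / rate_hz
    t0 = float(fx["onset_ms"].iloc[0])
    t1 = float(fx["offset_ms"].iloc[-1])
    t = np.arange(t0, t1, dt)
    x = np.empty_like(t)
    y = np.empty_like(t)

    def idx(ms: float) -> int:
        return int(round((ms - t0) / dt))

    for i, r in enumerate(fx.itertuples()):
        a, b = idx(r.onset_ms), idx(r.offset_ms)
        x[a:b], y[a:b] = r.cx, r.cy
        if i + 1 < len(fx):
            nxt = fx.iloc[i + 1]
            c, d = b, idx(nxt["onset_ms"])
            m = d - c
            if m > 0:
                frac = (1 - np.cos(np.pi * (np.arange(m) + 0.5) / m)) / 2
                x[c:d] = r.cx + (nxt["cx"] - r.cx) * frac
                y[c:d] = r.cy + (nxt["cy"] - r.cy) * frac
    if jitter_deg > 0:
        x = x + rng.normal(0, jitter_deg, size=x.size)
        y = y + rng.normal(0, jitter_deg, size=y.size)

    valid = np.ones(t.size, dtype=bool)
    if blinks is not None and len(blinks):
        for b in blinks.itertuples():
            a, z = max(0, idx(b.onset_ms)), min(t.size, idx(b.offset_ms))
            valid[a:z] = False
            x[a:z] = np.nan
            y[a:z] = np.nan
    out = pd.DataFrame({"t_ms": t, "x": x, "y": y, "valid": valid})
    out.attrs["unit"] = "deg"
    return out


# ---------------------------------------------------------------------------
# full-design datasets


@dataclass(frozen=True)
class Dataset:
    """A full two-session design: subjects x sessions x parts x
    instructions x trials, with per-trial ground truth."""

    config: SimulationConfig
    cohort: list[SubjectTraits]
    layouts: dict[tuple[str, str, int], TrialLayout]  # (subject, part+instr, trial)
    trials: pd.DataFrame  # KEY_COLUMNS + ground-truth columns
    fixations: pd.DataFrame  # KEY_COLUMNS + event columns
    saccades: pd.DataFrame
    clicks: pd.DataFrame

    def trial_keys(self) -> list[tuple]:
        return [tuple(r) for r in self.trials[KEY_COLUMNS].itertuples(index=False)]

    def trial_events(self, key: tuple) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, TrialLayout]:
        sel = dict(zip(KEY_COLUMNS, key))

        def pick(df: pd.DataFrame) -> pd.DataFrame:
            m = np.ones(len(df), dtype=bool)
            for c, v in sel.items():
                m &= df[c] == v
            return df[m].drop(columns=KEY_COLUMNS).reset_index(drop=True)

        layout = self.layouts[(sel["subject"], sel["part"] + sel["instruction"], sel["trial"])]
        return pick(self.fixations), pick(self.saccades), pick(self.clicks), layout


def generate_dataset(config: SimulationConfig) -> Dataset:
    """Generate the whole design: every subject completes, per session,
    ``trials_per_condition`` trials of each part x instruction cell, with
    layouts identical across the two sessions of a subject."""
    cohort = generate_cohort(config)
    by_subject: dict[str, dict[int, SubjectTraits]] = {}
    for st in cohort:
        by_subject.setdefault(st.subject_id, {})[st.session] = st

    layouts: dict[tuple[str, str, int], TrialLayout] = {}
    trial_rows, fix_rows, sacc_rows, clk_rows = [], [], [], []
    for si, (sid, sessions) in enumerate(sorted(by_subject.items())):
        for part in ("A", "B"):
            for instruction in ("speed", "accuracy"):
                for trial in range(1, config.trials_per_condition + 1):
                    lay_rng = np.random.default_rng(
                        np.random.SeedSequence((config.seed, 7, si, ord(part), len(instruction), trial))
                    )
                    layout = generate_layout(part, config.geometry, lay_rng)
                    layouts[(sid, part + instruction, trial)] = layout
                    for session in (1, 2):
                        ev_rng = np.random.default_rng(
                            np.random.SeedSequence(
                                (config.seed, 11, si, session, ord(part), len(instruction), trial)
                            )
                        )
                        ev = generate_trial_events(sessions[session], layout, instruction, ev_rng, config)
                        key = dict(subject=sid, session=session, part=part, instruction=instruction, trial=trial)
                        trial_rows.append({**key, **ev.ground_truth.__dict__})
                        fix_rows.append(ev.fixations.assign(**key))
                        sacc_rows.append(ev.saccades.assign(**key))
                        clk_rows.append(ev.clicks.assign(**key))

    def cat(frames: list[pd.DataFrame]) -> pd.DataFrame:
        df = pd.concat(frames, ignore_index=True)
        return df[KEY_COLUMNS + [c for c in df.columns if c not in KEY_COLUMNS]]

    return Dataset(
        config=config,
        cohort=cohort,
        layouts=layouts,
        trials=pd.DataFrame(trial_rows),
        fixations=cat(fix_rows),
        saccades=cat(sacc_rows),
        clicks=cat(clk_rows),
    )


def score_dataset(dataset: Dataset, apply_filters: bool = True) -> pd.DataFrame:
    """Score every trial of a dataset; returns the long trial-scores frame."""
    from .events import filter_events
    from .scores import Trial, score_trial

    rows = []
    for key in dataset.trial_keys():
        fix, sacc, clk, layout = dataset.trial_events(key)
        if apply_filters:
            fix, sacc = filter_events(fix, sacc)
        trial = Trial(layout=layout, clicks=clk, fixations=fix, saccades=sacc, start_ms=0.0)
        rows.append({**dict(zip(KEY_COLUMNS, key)), **score_trial(trial).as_dict()})
    return pd.DataFrame(rows)
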