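"""The nine per-trial test scores and their aggregation to condition tables.

Scores per trial (all computed on filtered events in degree space):

1.  completion time (s) — trial-start click to first correct click on the
    last target.
2.  speed-accuracy slope — OLS slope of log-odds click accuracy on
    per-target reaction time (log odd accuracy ~ rt).
3.  median fixation duration (ms)
4.  number of fixations (all, including unassigned)
5.  number of guiding fixations (on the current target at fixation onset)
6.  number of searching fixations (on any other target)
7.  median saccade amplitude (deg)
8.  eye-hand span (ms) — median over targets of click time minus onset of
    the first guiding fixation on that target; positive = eyes lead hand.
9.  scanpath length (deg) — summed distance between consecutive fixation
    centroids.

Undefined scores (e.g. the last target was never hit) are carried as NaN,
never silently zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy import stats as sps

from .layout import TrialLayout

logger = logging.getLogger(__name__)

__all__ = [
    "Trial",
    "TrialScores",
    "SCORE_NAMES",
    "click_accuracy",
    "completion_time",
    "per_target_reaction_times",
    "speed_accuracy_slope",
    "assign_fixations",
    "count_fixation_types",
    "summary_stats",
    "scanpath_length",
    "eye_hand_span",
    "score_trial",
    "aggregate_condition",
    "condition_tables",
]

#: Radius within which a fixation counts as falling on a target.
OBJECT_RADIUS_DEG = 3.25
#: Log-odds clipping bound for click accuracies of exactly 0 or 1.
LOGODDS_EPS = 0.01

SCORE_NAMES = [
    "completion_time",
    "speed_accuracy_slope",
    "median_fixation_duration",
    "n_fixations",
    "n_guiding",
    "n_searching",
    "median_saccade_amplitude",
    "eye_hand_span",
    "scanpath_length",
]


@dataclass(frozen=True)
class TrialScores:
    completion_time: float = math.nan  # s
    speed_accuracy_slope: float = math.nan  # log-odds per ms
    median_fixation_duration: float = math.nan  # ms
    n_fixations: float = math.nan
    n_guiding: float = math.nan
    n_searching: float = math.nan
    median_saccade_amplitude: float = math.nan  # deg
    eye_hand_span: float = math.nan  # ms
    scanpath_length: float = math.nan  # deg

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class Trial:
    """One scored trial: layout, clicks, filtered events, start time."""

    layout: TrialLayout
    clicks: pd.DataFrame  # t_ms, x, y (degrees)
    fixations: pd.DataFrame
    saccades: pd.DataFrame
    start_ms: float = 0.0  # time of the trial-initiating click on the fixation cross


# ---------------------------------------------------------------------------
# click bookkeeping


def click_accuracy(distance_deg: float, radius_deg: float) -> float:
    """Relative click accuracy in [0, 1]: 1 at the center, 0 at or beyond
    the circumcircle, linear in between (max(0, 1 - d/r))."""
    return max(0.0, 1.0 - distance_deg / radius_deg)


def resolve_clicks(clicks: pd.DataFrame, layout: TrialLayout) -> pd.DataFrame:
    """Annotate a raw click stream with the current-target timeline.

    Adds columns ``target`` (seq_index of the current, lowest un-hit
    target when the click occurred), ``correct`` (click within that
    target's circumcircle), and ``accuracy``.
    """
    rows = []
    current = 1
    n_targets = len(layout.targets)
    for r in clicks.sort_values("t_ms").itertuples():
        if current > n_targets:
            rows.append((r.t_ms, r.x, r.y, np.nan, False, np.nan))
            continue
        tgt = layout.target(current)
        d = float(np.hypot(r.x - tgt.x, r.y - tgt.y))
        correct = d <= tgt.radius
        rows.append((r.t_ms, r.x, r.y, current, correct, click_accuracy(d, tgt.radius)))
        if correct:
            current += 1
    return pd.DataFrame(rows, columns=["t_ms", "x", "y", "target", "correct", "accuracy"])


def _correct_click_times(resolved: pd.DataFrame) -> dict[int, float]:
    """seq_index -> time of the first correct click on that target."""
    hits = resolved[resolved["correct"]]
    return {int(r.target): float(r.t_ms) for r in hits.itertuples()}


def completion_time(trial: Trial, resolved: pd.DataFrame | None = None) -> float:
    """Seconds from the trial-start click to the first correct click on the
    last target; NaN (with a log record) if the last target was never hit."""
    if resolved is None:
        resolved = resolve_clicks(trial.clicks, trial.layout)
    hits = _correct_click_times(resolved)
    last = len(trial.layout.targets)
    if last not in hits:
        logger.warning("completion_time undefined: last target never hit")
        return math.nan
    return (hits[last] - trial.start_ms) / 1000.0


def per_target_reaction_times(resolved: pd.DataFrame, start_ms: float) -> pd.DataFrame:
    """Per-target reaction time and accuracy of the first correct click.

    Reaction time is the inter-correct-click interval (trial start for
    target 1); error clicks do not reset the clock.
    """
    hits = resolved[resolved["correct"]].sort_values("t_ms")
    prev = start_ms
    rows = []
    for r in hits.itertuples():
        rows.append((int(r.target), r.t_ms - prev, r.accuracy))
        prev = r.t_ms
    return pd.DataFrame(rows, columns=["target", "rt_ms", "accuracy"])


def speed_accuracy_slope(trial: Trial, eps: float = LOGODDS_EPS, resolved: pd.DataFrame | None = None) -> float:
    """OLS slope of log-odds click accuracy on per-target reaction time.

    Accuracies are clipped to [eps, 1-eps] before the logit transform.
    Undefined (NaN) with fewer than 3 usable targets or zero RT variance.
    """
    if resolved is None:
        resolved = resolve_clicks(trial.clicks, trial.layout)
    pt = per_target_reaction_times(resolved, trial.start_ms)
    if len(pt) < 3:
        logger.warning("speed_accuracy_slope undefined: %d usable targets", len(pt))
        return math.nan
    acc = np.clip(pt["accuracy"].to_numpy(), eps, 1 - eps)
    logodds = np.log(acc / (1 - acc))
    rt = pt["rt_ms"].to_numpy()
    if np.allclose(rt.var(), 0):
        logger.warning("speed_accuracy_slope undefined: zero RT variance")
        return math.nan
    if np.allclose(logodds.var(), 0):
        return 0.0  # constant response after clipping
    return float(sps.linregress(rt, logodds).slope)


# ---------------------------------------------------------------------------
# fixation labeling and gaze scores


def assign_fixations(
    fixations: pd.DataFrame,
    layout: TrialLayout,
    clicks: pd.DataFrame,
    object_radius: float = OBJECT_RADIUS_DEG,
    resolved: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Label fixations guiding / searching / unassigned.

    A fixation falls on the target nearest its centroid if that distance is
    within ``object_radius`` (exact ties break to the lower seq_index); it
    is *guiding* if that target is the current (lowest un-hit) target at
    fixation onset, *searching* if it is any other target, and
    *unassigned* if no target is within reach.
    """
    out = fixations.copy()
    if not len(out):
        out["label"] = pd.Series(dtype=object)
        out["object"] = pd.Series(dtype=float)
        return out
    if resolved is None:
        resolved = resolve_clicks(clicks, layout)
    hits = sorted(_correct_click_times(resolved).items())  # [(seq, t)] ascending

    pos = layout.positions()  # ordered by seq_index
    cent = out[["cx", "cy"]].to_numpy()
    d = np.hypot(cent[:, 0:1] - pos[None, :, 0], cent[:, 1:2] - pos[None, :, 1])
    nearest = d.argmin(axis=1)  # lower index wins ties via argmin
    within = d[np.arange(len(out)), nearest] <= object_radius

    def current_at(t: float) -> int:
        cur = 1
        for seq, ht in hits:
            if ht < t:
                cur = seq + 1
            else:
                break
        return cur

    labels, objects = [], []
    for i, r in enumerate(out.itertuples()):
        if not within[i]:
            labels.append("unassigned")
            objects.append(np.nan)
            continue
        obj = int(nearest[i]) + 1
        objects.append(obj)
        labels.append("guiding" if obj == current_at(r.onset_ms) else "searching")
    out["label"] = labels
    out["object"] = objects
    return out


def count_fixation_types(labeled: pd.DataFrame) -> tuple[int, int, int]:
    """(n_fixations, n_guiding, n_searching); the total counts all
    fixations including unassigned ones."""
    if not len(labeled):
        return 0, 0, 0
    return (
        int(len(labeled)),
        int((labeled["label"] == "guiding").sum()),
        int((labeled["label"] == "searching").sum()),
    )


def summary_stats(fixations: pd.DataFrame, saccades: pd.DataFrame) -> tuple[float, float]:
    """(median fixation duration ms, median saccade amplitude deg);
    NaN for empty event lists.  Even counts use the central midpoint."""
    mfd = float(fixations["duration_ms"].median()) if len(fixations) else math.nan
    msa = float(saccades["amplitude_deg"].median()) if len(saccades) else math.nan
    return mfd, msa


def scanpath_length(fixations: pd.DataFrame) -> float:
    """Total degrees covered: sum of consecutive centroid distances."""
    if not len(fixations):
        return math.nan
    c = fixations.sort_values("onset_ms")[["cx", "cy"]].to_numpy()
    return float(np.hypot(np.diff(c[:, 0]), np.diff(c[:, 1])).sum())


def eye_hand_span(
    labeled: pd.DataFrame,
    clicks: pd.DataFrame,
    layout: TrialLayout,
    which: str = "first",
    resolved: pd.DataFrame | None = None,
) -> float:
    """Median over targets of (correct click time) - (onset of the first
    guiding fixation on that target).  Positive = eyes led the hand.

    A target's guiding fixations are the fixations falling on it from the
    moment it became the current target onward; this includes a look that
    begins just *after* the click (the hand led the eye), which yields a
    negative span.  ``which='last'`` uses the last such onset before the
    click instead.  Targets without a guiding fixation are skipped; NaN if
    no target qualifies.
    """
    if which not in ("first", "last"):
        raise ValueError("which must be 'first' or 'last'")
    if resolved is None:
        resolved = resolve_clicks(clicks, layout)
    hits = _correct_click_times(resolved)
    spans = []
    for seq, click_t in hits.items():
        became_current = hits.get(seq - 1, -math.inf) if seq > 1 else -math.inf
        g = labeled[(labeled["object"] == seq) & (labeled["onset_ms"] > became_current)]
        if which == "last":
            g = g[g["onset_ms"] < click_t]
        if not len(g):
            continue
        onset = g["onset_ms"].min() if which == "first" else g["onset_ms"].max()
        spans.append(click_t - onset)
    if not spans:
        logger.warning("eye_hand_span undefined: no target with guiding fixation and click")
        return math.nan
    return float(np.median(spans))


def score_trial(trial: Trial, eps: float = LOGODDS_EPS, span_which: str = "first") -> TrialScores:
    """Compute all nine scores for one trial; undefined scores are NaN."""
    resolved = resolve_clicks(trial.clicks, trial.layout)
    labeled = assign_fixations(trial.fixations, trial.layout, trial.clicks, resolved=resolved)
    n_fix, n_guid, n_search = count_fixation_types(labeled)
    mfd, msa = summary_stats(trial.fixations, trial.saccades)
    return TrialScores(
        completion_time=completion_time(trial, resolved=resolved),
        speed_accuracy_slope=speed_accuracy_slope(trial, eps=eps, resolved=resolved),
        median_fixation_duration=mfd,
        n_fixations=float(n_fix),
        n_guiding=float(n_guid),
        n_searching=float(n_search),
        median_saccade_amplitude=msa,
        eye_hand_span=eye_hand_span(labeled, trial.clicks, trial.layout, which=span_which, resolved=resolved),
        scanpath_length=scanpath_length(trial.fixations),
    )


# ---------------------------------------------------------------------------
# aggregation


def aggregate_condition(scores: pd.DataFrame, score: str) -> pd.DataFrame:
    """Build the n_subjects x 2 session table for one score and condition.

    Parameters
    ----------
    scores
        Long frame with columns ``subject``, ``session`` (1/2), trial-level
        score columns; already restricted to one part x instruction cell.
    score
        Which score column to tabulate.

    Cell values are means over the (default 2) trials in the cell; a cell
    with one valid trial keeps that trial's value.  Subjects missing a
    session entirely are dropped (listwise), with a logged count.
    """
    cell = scores.groupby(["subject", "session"])[score].mean().unstack("session")
    if cell.shape[1] < 2:
        raise ValueError("both sessions required to tabulate a condition")
    complete = cell.dropna()
    dropped = len(cell) - len(complete)
    if dropped:
        logger.info("aggregate_condition(%s): dropped %d incomplete subjects", score, dropped)
    if not len(complete):
        raise ValueError(f"no analyzable data for score {score!r}")
    out = complete.rename(columns={1: "session1", 2: "session2"})
    out.attrs["score"] = score
    return out


def condition_tables(scores: pd.DataFrame, score_names=SCORE_NAMES) -> dict:
    """All (score, part, instruction) -> n x 2 table mappings from a long
    trial-scores frame with columns subject, session, part, instruction,
    trial, and one column per score."""
    tables = {}
    for (part, instruction), chunk in scores.groupby(["part", "instruction"]):
        for name in score_names:
            try:
                tables[(name, part, instruction)] = aggregate_condition(chunk, name)
            except ValueError:
                logger.warning("no table for %s / %s / %s", name, part, instruction)
    return tables
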