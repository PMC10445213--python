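"""End-to-end orchestration: simulate -> detect -> score -> reliability/precision.

Each stage reads and writes the delimited-text artifacts of :mod:`.io`
under one output directory, so stages can be re-run individually and a
rerun with the same configuration is byte-identical.  Every output file
carries a metadata header with package version, seed, and a hash of the
stage parameters.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tgio
from .events import detect_events, filter_events
from .geometry import DEFAULT_GEOMETRY, ScreenGeometry, degrees_to_pixels, pixels_to_degrees
from .layout import TrialLayout
from .precision import PAPER_GRID, precision_table
from .reliability import reliability_report
from .scores import SCORE_NAMES, Trial, condition_tables, score_trial
from .synth import KEY_COLUMNS, Dataset, SimulationConfig, generate_dataset, generate_raw_samples

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

ALL_STAGES = ("simulate", "detect", "score", "reliability", "precision")


@dataclass
class RunConfig:
    outdir: str = "trailgaze_out"
    stages: tuple[str, ...] = ("simulate", "score", "reliability")
    seed: int = 0
    n_subjects: int = 31
    true_icc: float = 0.6
    trials_per_condition: int = 2
    icc_scale: str = "average"
    include_raw_samples: bool = False
    geometry: ScreenGeometry = field(default_factory=lambda: DEFAULT_GEOMETRY)
    # detection parameters
    rate_hz: float = 1000.0
    velocity_threshold: float = 30.0
    accel_threshold: float = 8000.0
    smooth_window: int = 5
    # precision-stage parameters
    precision_reps: int = 1000
    precision_population: int = 100_000
    precision_grid: tuple = tuple(PAPER_GRID)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "geometry" in raw:
            raw["geometry"] = ScreenGeometry(**raw["geometry"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "precision_grid" in raw:
            raw["precision_grid"] = tuple(tuple(g) for g in raw["precision_grid"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["geometry"] = asdict(self.geometry)
        raw["stages"] = list(self.stages)
        raw["precision_grid"] = [list(g) for g in self.precision_grid]
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)

    def metadata(self) -> dict:
        params = asdict(self)
        params["geometry"] = asdict(self.geometry)
        return {"seed": self.seed, "params_sha": tgio.parameter_hash(params)}


def _events_long(dataset_fix: pd.DataFrame, dataset_sacc: pd.DataFrame) -> pd.DataFrame:
    fix = dataset_fix.rename(columns={"cx": "x_deg", "cy": "y_deg"}).assign(kind="fix", amplitude_deg=math.nan)
    sacc = dataset_sacc.rename(columns={"x0": "x_deg", "y0": "y_deg"}).assign(kind="sacc")
    cols = tgio.EVENTS_COLUMNS
    both = pd.concat([fix[cols], sacc[cols]], ignore_index=True)
    return both.sort_values(KEY_COLUMNS + ["onset_ms", "kind"], kind="stable").reset_index(drop=True)


def _stage_simulate(cfg: RunConfig, out: Path) -> None:
    sim = SimulationConfig(
        n_subjects=cfg.n_subjects,
        true_icc=cfg.true_icc,
        trials_per_condition=cfg.trials_per_condition,
        seed=cfg.seed,
        icc_scale=cfg.icc_scale,
        geometry=cfg.geometry,
        rate_hz=cfg.rate_hz,
    )
    ds = generate_dataset(sim)
    meta = cfg.metadata()

    clicks_px = ds.clicks.copy()
    clicks_px["x_px"] = cfg.geometry.x_deg_to_px(clicks_px.pop("x"))
    clicks_px["y_px"] = cfg.geometry.y_deg_to_px(clicks_px.pop("y"))
    tgio.write_table(clicks_px[tgio.CLICKS_COLUMNS], out / "clicks.csv", meta)

    lay_rows = []
    for (sid, partinstr, trial), layout in sorted(ds.layouts.items()):
        part, instruction = partinstr[0], partinstr[1:]
        lf = layout.to_frame().assign(subject=sid, part=part, instruction=instruction, trial=trial)
        lay_rows.append(lf[tgio.LAYOUT_COLUMNS])
    tgio.write_table(pd.concat(lay_rows, ignore_index=True), out / "layout.csv", meta)

    tgio.write_table(_events_long(ds.fixations, ds.saccades), out / "events.csv", meta)
    tgio.write_table(ds.trials, out / "ground_truth.csv", meta)

    if cfg.include_raw_samples:
        chunks = []
        for key in ds.trial_keys():
            fix, _, _, _ = ds.trial_events(key)
            tr = generate_raw_samples(fix, rate_hz=cfg.rate_hz, seed=np.random.default_rng((cfg.seed, 13)))
            tr = degrees_to_pixels(tr)
            tr = tr.rename(columns={"x": "x_px", "y": "y_px"}).assign(**dict(zip(KEY_COLUMNS, key)))
            chunks.append(tr[tgio.SAMPLES_COLUMNS])
        tgio.write_table(pd.concat(chunks, ignore_index=True), out / "samples.csv.gz", meta)


def _stage_detect(cfg: RunConfig, out: Path) -> bool:
    path = out / "samples.csv.gz"
    if not path.exists():
        path = out / "samples.csv"
    if not path.exists():
        logger.info("detect: no raw samples file, stage skipped (event-level input assumed)")
        return False
    samples = tgio.read_samples(path)
    rows = []
    for key, chunk in samples.groupby(KEY_COLUMNS, sort=False):
        deg = chunk.rename(columns={"x_px": "x", "y_px": "y"})[["t_ms", "x", "y", "valid"]]
        deg.attrs["unit"] = "px"
        deg = pixels_to_degrees(deg, cfg.geometry)
        fix, sacc, blk = detect_events(
            deg,
            rate_hz=cfg.rate_hz,
            velocity_threshold=cfg.velocity_threshold,
            accel_threshold=cfg.accel_threshold,
            smooth_window=cfg.smooth_window,
        )
        keyd = dict(zip(KEY_COLUMNS, key))
        rows.append(_events_long(fix.assign(**keyd), sacc.assign(**keyd)))
        if len(blk):
            b = blk.assign(kind="blink", x_deg=math.nan, y_deg=math.nan, amplitude_deg=math.nan, **keyd)
            rows.append(b[tgio.EVENTS_COLUMNS])
    tgio.write_table(pd.concat(rows, ignore_index=True), out / "events.csv", cfg.metadata())
    return True


def _stage_score(cfg: RunConfig, out: Path) -> None:
    events = tgio.read_events(out / "events.csv")
    clicks = tgio.read_clicks(out / "clicks.csv")
    layouts = tgio.read_layout(out / "layout.csv")
    clicks = clicks.assign(
        x=cfg.geometry.x_px_to_deg(clicks["x_px"]), y=cfg.geometry.y_px_to_deg(clicks["y_px"])
    )

    rows = []
    for key, ev in events.groupby(KEY_COLUMNS, sort=False):
        sid, session, part, instruction, trial = key
        fix = ev[ev["kind"] == "fix"].rename(columns={"x_deg": "cx", "y_deg": "cy"})
        fix = fix.assign(duration_ms=fix["offset_ms"] - fix["onset_ms"])[
            ["onset_ms", "offset_ms", "cx", "cy", "duration_ms"]
        ].reset_index(drop=True)
        sacc = ev[ev["kind"] == "sacc"][["onset_ms", "offset_ms", "amplitude_deg"]].reset_index(drop=True)
        fix, sacc = filter_events(fix, sacc)
        lsel = layouts[
            (layouts["subject"] == sid) & (layouts["part"] == part)
            & (layouts["instruction"] == instruction) & (layouts["trial"] == trial)
        ]
        layout = TrialLayout.from_frame(lsel, part=part)
        csel = clicks[
            (clicks["subject"] == sid) & (clicks["session"] == session) & (clicks["part"] == part)
            & (clicks["instruction"] == instruction) & (clicks["trial"] == trial)
        ]
        trial_obj = Trial(layout=layout, clicks=csel, fixations=fix, saccades=sacc, start_ms=0.0)
        rows.append({**dict(zip(KEY_COLUMNS, key)), **score_trial(trial_obj).as_dict()})
    tgio.write_table(pd.DataFrame(rows), out / "scores.csv", cfg.metadata())


def _stage_reliability(cfg: RunConfig, out: Path) -> None:
    scores = tgio.read_scores(out / "scores.csv")
    tables = condition_tables(scores, SCORE_NAMES)
    report = reliability_report(tables)
    tgio.write_table(report, out / "report.tsv", cfg.metadata(), sep="\t")


def _stage_precision(cfg: RunConfig, out: Path) -> None:
    table = precision_table(
        grid=list(cfg.precision_grid),
        reps=cfg.precision_reps,
        population_size=cfg.precision_population,
        seed=cfg.seed,
    )
    tgio.write_table(table, out / "precision.tsv", cfg.metadata(), sep="\t")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the selected stages in canonical order; returns the output dir.

    Any stage failure is re-raised with the stage name attached.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    runners = {
        "simulate": _stage_simulate,
        "detect": _stage_detect,
        "score": _stage_score,
        "reliability": _stage_reliability,
        "precision": _stage_precision,
    }
    unknown = set(config.stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        try:
            runners[stage](config, out)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
        logger.info("stage %s finished in %.1f s", stage, time.perf_counter() - t0)
    return out
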