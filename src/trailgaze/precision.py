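"""Monte-Carlo precision of ICC(A,2) confidence intervals at given sample sizes.

Answers the planning question "how wide a 95% CI for the test-retest ICC
should we expect at our sample size?": simulate a large population of
paired session scores with a predefined intraclass correlation, repeatedly
subsample n individuals, compute the F-based 95% CI of ICC(A,2) per
subsample, and aggregate the bounds across replicates.

The population is bivariate normal with equal means and variances and pair
correlation equal to the predefined "true ICC".  Note that with k = 2 the
*average-measures* coefficient estimated by ICC(A,2) then converges to the
Spearman-Brown value 2*rho/(1+rho), not rho itself; the reported intervals
are the expected output of the standard analysis pipeline when run on data
whose single-measures reliability is rho, which is what the sample-size
planning question asks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reliability import _icc_a2_core

__all__ = [
    "PrecisionConfig",
    "PrecisionResult",
    "simulate_population",
    "precision_ci",
    "precision_table",
    "PAPER_GRID",
]

#: The (true ICC, n) grid of the published precision table.
PAPER_GRID = [(0.4, 31), (0.4, 34), (0.6, 31), (0.6, 34), (0.8, 31), (0.8, 34)]


@dataclass(frozen=True)
class PrecisionConfig:
    true_icc: float
    n: int
    population_size: int = 100_000
    reps: int = 10_000
    seed: int = 0
    aggregation: str = "mean_bounds"  # mean_bounds | median_bounds | percentile_of_estimates

    def __post_init__(self) -> None:
        if not 0 <= self.true_icc < 1:
            raise ValueError("true_icc must be in [0, 1)")
        if self.n > self.population_size:
            raise ValueError("n cannot exceed population_size")
        if self.n < 3:
            raise ValueError("n must be at least 3")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.aggregation not in ("mean_bounds", "median_bounds", "percentile_of_estimates"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")


@dataclass(frozen=True)
class PrecisionResult:
    true_icc: float
    n: int
    ci_low: float
    ci_high: float
    reps_used: int
    mean_estimate: float = field(default=float("nan"))


def simulate_population(true_icc: float, size: int = 100_000, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw ``size`` paired session scores with pair correlation ``true_icc``.

    Returns a (size, 2) array from a bivariate standard normal with equal
    means and variances.
    """
    if not 0 <= true_icc < 1:
        raise ValueError("true_icc must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cov = np.array([[1.0, true_icc], [true_icc, 1.0]])
    return rng.multivariate_normal(np.zeros(2), cov, size=size, method="cholesky")


def _sample_indices(rng: np.random.Generator, reps: int, pop_n: int, n: int) -> np.ndarray:
    """(reps, n) index array, without replacement within each row."""
    idx = rng.integers(0, pop_n, size=(reps, n))
    while True:
        bad = (np.diff(np.sort(idx, axis=1), axis=1) == 0).any(axis=1)
        if not bad.any():
            return idx
        idx[bad] = rng.integers(0, pop_n, size=(int(bad.sum()), n))


def precision_ci(config: PrecisionConfig, population: np.ndarray | None = None) -> PrecisionResult:
    """Expected 95% CI bounds of ICC(A,2) at sample size ``config.n``.

    Per replicate, ``n`` individuals are drawn without replacement from the
    population and the F-based CI of ICC(A,2) is computed; bounds are then
    aggregated per ``config.aggregation`` (default: mean lower bound, mean
    upper bound).  Replicates whose subsample is degenerate (non-finite
    interval) are redrawn.
    """
    rng = np.random.default_rng(config.seed)
    if population is None:
        population = simulate_population(config.true_icc, config.population_size, rng)
    pop_n = population.shape[0]

    lows = np.empty(config.reps)
    highs = np.empty(config.reps)
    ests = np.empty(config.reps)
    filled = 0
    redrawn = 0
    while filled < config.reps:
        todo = config.reps - filled
        idx = _sample_indices(rng, todo, pop_n, config.n)
        X = population[idx]
        est, lo, hi = _icc_a2_core(X)
        ok = np.isfinite(est) & np.isfinite(lo) & np.isfinite(hi)
        kept = int(ok.sum())
        lows[filled : filled + kept] = lo[ok]
        highs[filled : filled + kept] = hi[ok]
        ests[filled : filled + kept] = est[ok]
        redrawn += todo - kept
        filled += kept
    if redrawn:
        import logging

        logging.getLogger(__name__).warning("redrew %d degenerate subsamples", redrawn)

    if config.aggregation == "mean_bounds":
        lo, hi = lows.mean(), highs.mean()
    elif config.aggregation == "median_bounds":
        lo, hi = np.median(lows), np.median(highs)
    else:  # percentile_of_estimates
        lo, hi = np.percentile(ests, [2.5, 97.5])
    return PrecisionResult(config.true_icc, config.n, float(lo), float(hi), config.reps, float(ests.mean()))


def precision_table(
    grid=PAPER_GRID,
    reps: int = 10_000,
    population_size: int = 100_000,
    seed: int = 0,
    aggregation: str = "mean_bounds",
) -> pd.DataFrame:
    """Run :func:`precision_ci` over a (true_icc, n) grid.

    One population per distinct true ICC is shared by all its sample
    sizes, mirroring the simulate-once / subsample-many design.
    """
    rows = []
    by_icc: dict[float, np.ndarray] = {}
    for i, (icc, n) in enumerate(grid):
        if icc not in by_icc:
            by_icc[icc] = simulate_population(icc, population_size, np.random.default_rng((seed, round(icc * 1000))))
        cfg = PrecisionConfig(
            true_icc=icc, n=n, population_size=population_size, reps=reps,
            seed=int(np.random.SeedSequence((seed, i)).generate_state(1)[0] % (2**31)),
            aggregation=aggregation,
        )
        res = precision_ci(cfg, population=by_icc[icc])
        rows.append({"true_icc": icc, "n": n, "ci_low": res.ci_low, "ci_high": res.ci_high, "reps": res.reps_used})
    return pd.DataFrame(rows)
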