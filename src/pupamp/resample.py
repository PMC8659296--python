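"""Subsample-without-replacement resampling of ZINB stage coefficients.

Per-pupa CFU datasets (one genotype x bacterium combination spanning both
stages) are repeatedly subsampled — 60 rows without replacement per cycle,
4000 cycles by default — and a ZINB regression of count on stage is fitted to
each subset.  The per-cycle stage coefficients of the count component
(``beta1``) and of the zero component (``gamma1``) form sampling
distributions whose location and spread summarise whether bacterial loads
rise or fall between pupariation (P0) and the pharate adult stage.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from pupamp.config import RunConfig
from pupamp.zinb import fit_zinb

REDRAW_CAP_FACTOR = 50


@dataclasses.dataclass(frozen=True)
class ResampleResult:
    """Per-cycle stage coefficients plus redraw bookkeeping."""

    count_coeffs: np.ndarray  # beta1 per cycle
    zero_coeffs: np.ndarray  # gamma1 per cycle
    n_redraws: int
    seeds: np.ndarray  # (cycle, attempt) pairs actually used
    config: RunConfig

    def __post_init__(self) -> None:
        if len(self.count_coeffs) != self.config.n_iterations:
            raise ValueError("count_coeffs length must equal n_iterations")
        if len(self.zero_coeffs) != self.config.n_iterations:
            raise ValueError("zero_coeffs length must equal n_iterations")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(self.config.n_iterations),
                "attempt": self.seeds[:, 1],
                "beta1": self.count_coeffs,
                "gamma1": self.zero_coeffs,
            }
        )


def _substream(seed: int, cycle: int, attempt: int) -> np.random.Generator:
    """Counter-based substream: redraws never shift later cycles."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(cycle, attempt))
    return np.random.Generator(np.random.PCG64(ss))


def draw_subset(n_rows: int, subset_size: int, substream: np.random.Generator):
    """A uniformly distributed ``subset_size``-combination of row indices.

    Returned sorted: the draw is a set, and a canonical order makes the
    downstream fit independent of the generator's internal ordering.
    """
    if subset_size > n_rows:
        raise ValueError(f"subset_size {subset_size} exceeds n_rows {n_rows}")
    return np.sort(substream.choice(n_rows, size=subset_size, replace=False))


def _subset_degenerate(y: np.ndarray, stage: np.ndarray) -> bool:
    """True when a subset cannot identify the ZINB: a stage absent, no zeros
    overall, or a stage without a positive count (stage mean unidentified)."""
    if len(np.unique(stage)) < 2:
        return True
    if not (y == 0).any():
        return True
    for s in (0.0, 1.0):
        if not (y[stage == s] > 0).any():
            return True
    return False


def resample_coefficients(data: pd.DataFrame, config: RunConfig) -> ResampleResult:
    """Run the full resampling procedure on one genotype x bacterium dataset.

    Each cycle draws ``config.subset_size`` rows without replacement (rows
    are replaced between cycles), fits the ZINB, and stores the two stage
    coefficients.  Cycles whose subset is degenerate or whose fit fails to
    converge are redrawn from a fresh substream keyed by (seed, cycle,
    attempt); total draws are capped at 50x ``n_iterations``.
    """
    if "cfu_per_pupa" in data.columns:
        y_all = np.asarray(data["cfu_per_pupa"], dtype=float)
    else:
        y_all = np.asarray(data["colonies"], dtype=float)
    stage_all = np.asarray(data["stage"].astype(str) == "pharate", dtype=float)
    n = len(data)
    if n < config.subset_size:
        raise ValueError(
            f"dataset has {n} rows, fewer than subset_size {config.subset_size}"
        )
    if len(np.unique(stage_all)) < 2:
        raise ValueError("dataset must contain both stages")

    count_coeffs = np.empty(config.n_iterations)
    zero_coeffs = np.empty(config.n_iterations)
    seeds = np.empty((config.n_iterations, 2), dtype=int)
    n_redraws = 0
    total_draws = 0
    cap = REDRAW_CAP_FACTOR * config.n_iterations

    for cycle in range(config.n_iterations):
        attempt = 0
        while True:
            if total_draws >= cap:
                raise RuntimeError(
                    f"redraw cap exceeded after {total_draws} draws: dataset too "
                    "degenerate for the resampling procedure"
                )
            total_draws += 1
            rng = _substream(config.seed, cycle, attempt)
            idx = draw_subset(n, config.subset_size, rng)
            y, stage = y_all[idx], stage_all[idx]
            if _subset_degenerate(y, stage):
                n_redraws += 1
                attempt += 1
                continue
            fit = fit_zinb(data.iloc[idx])
            if not fit.converged:
                n_redraws += 1
                attempt += 1
                continue
            count_coeffs[cycle] = fit.params.beta[1]
            zero_coeffs[cycle] = fit.params.gamma[1]
            seeds[cycle] = (cycle, attempt)
            break

    return ResampleResult(
        count_coeffs=count_coeffs,
        zero_coeffs=zero_coeffs,
        n_redraws=n_redraws,
        seeds=seeds,
        config=config,
    )
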