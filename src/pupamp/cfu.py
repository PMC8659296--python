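"""CFU scaling, log-decade binning, and coefficient-distribution summaries.

Plate colony counts become per-pupa loads via the maceration dilution (300 uL
homogenate, 50 uL plated: factor 6).  Loads are reported in five log-decade
categories (0-10, 10-10^2, ..., >10^4), and resampled regression coefficients
are summarised by median, IQR, 0.05/0.95 quantiles, and a one-sample
Wilcoxon signed-rank test with effect size r = |z| / sqrt(n).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

CFU_CATEGORIES = ("0-10", "10-10^2", "10^2-10^3", "10^3-10^4", ">10^4")
_BIN_EDGES = np.array([10.0, 100.0, 1000.0, 10000.0])


@dataclasses.dataclass(frozen=True)
class CoefficientSummary:
    median: float
    q25: float
    q75: float
    q05: float
    q95: float
    mean: float
    wilcoxon_statistic: float | None = None
    z_value: float | None = None
    p_value: float | None = None
    effect_size_r: float | None = None
    alternative: str | None = None
    n_used: int | None = None

    def __post_init__(self) -> None:
        if not self.q05 <= self.q25 <= self.median <= self.q75 <= self.q95:
            raise ValueError("quantiles must be ordered q05<=q25<=median<=q75<=q95")


def scale_to_per_pupa(colonies, dilution_factor: float = 6.0):
    """Per-pupa CFU from a plate colony count: ``colonies * dilution_factor``."""
    colonies = np.asarray(colonies)
    if np.any(colonies < 0):
        raise ValueError("colony counts must be non-negative")
    if dilution_factor <= 0:
        raise ValueError("dilution_factor must be positive")
    scaled = colonies * dilution_factor
    if colonies.ndim == 0:
        return scaled.item()
    return scaled


def bin_cfu(cfu) -> str | np.ndarray:
    """Log-decade category of a per-pupa CFU load.

    Bins are upper-inclusive — [0,10], (10,10^2], (10^2,10^3], (10^3,10^4],
    (10^4, inf) — so every load maps to exactly one class and a load of
    exactly 10 falls in "0-10".
    """
    arr = np.asarray(cfu, dtype=float)
    if np.any(arr < 0):
        raise ValueError("CFU must be non-negative")
    # searchsorted with side="left": value equal to an edge stays in the lower bin
    idx = np.searchsorted(_BIN_EDGES, arr, side="left")
    labels = np.asarray(CFU_CATEGORIES, dtype=object)[idx]
    if arr.ndim == 0:
        return str(labels)
    return labels


def category_proportions(data: pd.DataFrame, dilution_factor: float = 6.0) -> pd.DataFrame:
    """Per-stage counts and proportions of individuals in each CFU category.

    Uses ``cfu_per_pupa`` when present, otherwise scales ``colonies`` by the
    dilution factor.  Returns a tidy frame with columns ``stage``,
    ``category``, ``count``, ``proportion``; proportions sum to one within
    each stage.
    """
    if "cfu_per_pupa" in data.columns:
        cfu = np.asarray(data["cfu_per_pupa"], dtype=float)
    else:
        cfu = scale_to_per_pupa(np.asarray(data["colonies"], dtype=float), dilution_factor)
    stages = data["stage"].astype(str)
    rows = []
    for stage in stages.unique():
        mask = (stages == stage).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"stage {stage!r} is empty")
        cats = bin_cfu(cfu[mask])
        n = mask.sum()
        for cat in CFU_CATEGORIES:
            count = int((cats == cat).sum())
            rows.append(
                {"stage": stage, "category": cat, "count": count, "proportion": count / n}
            )
    return pd.DataFrame(rows)


def coefficient_quantiles(values) -> CoefficientSummary:
    """Location/spread summary of a coefficient sampling distribution.

    Quantiles use linear interpolation of order statistics with plotting
    position (k-1)/(n-1), so on 1..100 the 0.05 quantile is 5.95.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    q05, q25, med, q75, q95 = np.quantile(values, [0.05, 0.25, 0.5, 0.75, 0.95])
    return CoefficientSummary(
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        q05=float(q05),
        q95=float(q95),
        mean=float(values.mean()),
    )


def wilcoxon_one_sample(
    values, mu0: float = 0.0, alternative: str = "less"
) -> CoefficientSummary:
    """One-sample Wilcoxon signed-rank test of central tendency against mu0.

    Differences equal to zero are dropped; ties get average ranks.  The test
    uses the normal approximation with tie correction and a continuity
    correction, appropriate at the resampling sample sizes in play (n in the
    thousands).  Effect size r = |z| / sqrt(n_used); when every difference
    has the same sign and there are no rank ties, r approaches
    sqrt(3(n+1) / (2(2n+1))) ~ 0.866.
    """
    if alternative not in ("less", "greater", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    values = np.asarray(values, dtype=float)
    d = values - mu0
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("all values equal mu0: test undefined")
    if n < 10:
        raise ValueError(f"need >= 10 nonzero differences, got {n}")

    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mean_w = n * (n + 1) / 4.0
    # tie correction on the variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / 48.0
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var_w <= 0:
        raise ValueError("degenerate rank variance")
    sd_w = np.sqrt(var_w)

    dev = w_plus - mean_w
    # continuity correction shrinks |W - E[W]| by 1/2
    if alternative == "greater":
        z = (dev - 0.5) / sd_w
        p = stats.norm.sf(z)
    elif alternative == "less":
        z = (dev + 0.5) / sd_w
        p = stats.norm.cdf(z)
    else:
        z = (dev - np.sign(dev) * 0.5) / sd_w
        p = 2.0 * stats.norm.sf(abs(z))
    p = float(min(max(p, np.nextafter(0, 1)), 1.0))
    r = float(abs(z) / np.sqrt(n))

    base = coefficient_quantiles(values) if values.size >= 2 else None
    return CoefficientSummary(
        median=base.median,
        q25=base.q25,
        q75=base.q75,
        q05=base.q05,
        q95=base.q95,
        mean=base.mean,
        wilcoxon_statistic=w_plus,
        z_value=float(z),
        p_value=p,
        effect_size_r=min(r, 1.0),
        alternative=alternative,
        n_used=int(n),
    )


def summarize_coefficients(
    coeffs: pd.DataFrame, mu0: float = 0.0
) -> pd.DataFrame:
    """Summarise a resampling coefficient table (columns beta1, gamma1).

    The one-sided alternative is chosen by the sign of the median, mirroring
    how directional hypotheses are phrased for each genotype (loads fall:
    median < 0; loads rise: median > 0).
    """
    rows = []
    for component, col in (("count", "beta1"), ("zero", "gamma1")):
        vals = coeffs[col].to_numpy()
        alt = "less" if np.median(vals) < mu0 else "greater"
        s = wilcoxon_one_sample(vals, mu0=mu0, alternative=alt)
        rows.append(
            {
                "component": component,
                "median": s.median,
                "q25": s.q25,
                "q75": s.q75,
                "q05": s.q05,
                "q95": s.q95,
                "mean": s.mean,
                "wilcoxon_statistic": s.wilcoxon_statistic,
                "z_value": s.z_value,
                "p_value": s.p_value,
                "effect_size_r": s.effect_size_r,
                "alternative": s.alternative,
                "n_used": s.n_used,
            }
        )
    return pd.DataFrame(rows)
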