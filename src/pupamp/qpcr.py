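"""Relative qPCR quantification (ddCT) and the factorial contrast machinery.

Fold-changes are computed by the ddCT method against a housekeeping gene
(*rpl32* by convention) with control-L3 samples as calibrator, then analysed
on the natural-log scale with a full Genotype x Stage x Gene factorial linear
model.  Estimated-marginal-mean pairwise contrasts within conditioning
families (e.g. between stages within each genotype) use the pooled residual
variance, Tukey adjustment per family, and compact-letter-display groups.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

FACTORS = ("genotype", "stage", "gene")


@dataclasses.dataclass(frozen=True)
class FactorialFit:
    """OLS fit of log fold-change on the full factorial design."""

    cell_means: pd.DataFrame  # columns: genotype, stage, gene, mean, n
    residual_variance: float
    residual_df: int
    n_obs: int

    def cell_mean(self, genotype: str, stage: str, gene: str) -> float:
        m = self.cell_means
        row = m[
            (m["genotype"] == genotype) & (m["stage"] == stage) & (m["gene"] == gene)
        ]
        if row.empty:
            raise KeyError(f"no cell ({genotype}, {stage}, {gene}) in the design")
        return float(row["mean"].iloc[0])


def delta_delta_ct(
    ct: pd.DataFrame,
    reference_gene: str = "rpl32",
    calibrator: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Per-sample ddCT fold-changes for every target gene.

    For each biological sample and target gene, technical CT replicates are
    averaged, dCT = mean CT(target) - mean CT(reference); ddCT subtracts the
    mean dCT of the calibrator cell (control genotype at L3 unless given
    explicitly); fold-change = 2^-ddCT.

    Returns a tidy frame with columns ``sample_id, genotype, stage, gene,
    delta_ct, delta_delta_ct, foldchange``.
    """
    df = ct.copy()
    df["stage"] = df["stage"].astype(str)
    mean_ct = (
        df.groupby(["sample_id", "genotype", "stage", "gene"], observed=True)["ct"]
        .mean()
        .reset_index()
    )
    ref = mean_ct[mean_ct["gene"] == reference_gene][["sample_id", "ct"]].rename(
        columns={"ct": "ref_ct"}
    )
    targets = mean_ct[mean_ct["gene"] != reference_gene]
    if targets.empty:
        raise ValueError("CT table contains no target genes besides the reference")
    merged = targets.merge(ref, on="sample_id", how="left")
    if merged["ref_ct"].isna().any():
        missing = merged.loc[merged["ref_ct"].isna(), "sample_id"].iloc[0]
        raise ValueError(f"sample {missing!r} is missing the reference gene")
    merged["delta_ct"] = merged["ct"] - merged["ref_ct"]

    if calibrator is None:
        genotypes = sorted(merged["genotype"].unique())
        calibrator = (genotypes[0], "L3")
    cal_geno, cal_stage = calibrator
    cal = merged[(merged["genotype"] == cal_geno) & (merged["stage"] == cal_stage)]
    if cal.empty:
        raise ValueError(f"empty calibrator cell ({cal_geno}, {cal_stage})")
    cal_means = cal.groupby("gene", observed=True)["delta_ct"].mean()

    missing_genes = set(merged["gene"]) - set(cal_means.index)
    if missing_genes:
        raise ValueError(
            f"calibrator cell lacks gene(s): {', '.join(sorted(missing_genes))}"
        )
    merged["delta_delta_ct"] = merged["delta_ct"] - merged["gene"].map(cal_means)
    merged["foldchange"] = 2.0 ** (-merged["delta_delta_ct"])
    return merged[
        ["sample_id", "genotype", "stage", "gene", "delta_ct", "delta_delta_ct", "foldchange"]
    ]


def fit_factorial_loglinear(fc: pd.DataFrame) -> FactorialFit:
    """OLS of natural-log fold-change on the Genotype x Stage x Gene factorial.

    Equivalent to the saturated cell-means model: returns per-cell means of
    log fold-change, pooled residual variance and residual degrees of
    freedom.  Requires fold-changes > 0 and at least two factor levels
    overall (otherwise no contrast is estimable).
    """
    df = fc.copy()
    if (df["foldchange"] <= 0).any():
        raise ValueError("fold-changes must be positive to take logs")
    for f in FACTORS:
        df[f] = df[f].astype(str)
    if all(df[f].nunique() == 1 for f in FACTORS):
        raise ValueError("all factors have a single level: no contrast possible")
    df["log_fc"] = np.log(df["foldchange"])

    terms = " * ".join(f"C({f})" for f in FACTORS if df[f].nunique() > 1)
    model = smf.ols(f"log_fc ~ {terms}", data=df).fit()
    if model.df_resid <= 0:
        raise ValueError("zero residual degrees of freedom: saturated without replication")

    cells = (
        df.groupby(list(FACTORS), observed=True)["log_fc"]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"size": "n"})
    )
    return FactorialFit(
        cell_means=cells,
        residual_variance=float(model.mse_resid),
        residual_df=int(model.df_resid),
        n_obs=int(model.nobs),
    )


def _compact_letter_display(
    labels: list[str], pmat: np.ndarray, alpha: float
) -> dict[str, str]:
    """Insert-and-absorb compact letter display: cells sharing a letter are
    not significantly different at alpha."""
    k = len(labels)
    # insert-absorb: start with one all-inclusive group; every significant
    # pair splits the groups containing both members, then proper subsets
    # and duplicates are absorbed
    groups: list[frozenset[int]] = [frozenset(range(k))]
    for i, j in itertools.combinations(range(k), 2):
        if pmat[i, j] < alpha:
            expanded: list[frozenset[int]] = []
            for g in groups:
                if i in g and j in g:
                    expanded.extend((g - {i}, g - {j}))
                else:
                    expanded.append(g)
            groups = [
                g
                for g in expanded
                if g and not any(g < h for h in expanded)
            ]
            groups = list(dict.fromkeys(groups))
    # assign letters in order of the smallest member index
    groups = sorted(groups, key=lambda g: min(g))
    letters = {lab: "" for lab in labels}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for letter, g in zip(alphabet, groups):
        for idx in sorted(g):
            letters[labels[idx]] += letter
    return letters


def pairwise_contrasts(
    fit: FactorialFit,
    by: str | tuple[str, ...],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All pairwise differences of cell means within each conditioning family.

    ``by`` names the conditioning factor(s); the remaining factors are
    crossed to form the compared cells, emulating
    ``lsmeans(pairwise ~ <compared> | <by>)``.  Standard errors use the
    pooled residual variance; p-values are Tukey-adjusted per family via the
    studentized range distribution, and compact letter groups are reported
    at ``alpha``.

    Returns a tidy frame: one row per ordered contrast with columns
    ``family, label, cell_a, cell_b, estimate, se, t_value, p_adjusted,
    letters_a, letters_b``.
    """
    if isinstance(by, str):
        by = (by,)
    unknown = set(by) - set(FACTORS)
    if unknown:
        raise ValueError(f"conditioning factor(s) not in the design: {sorted(unknown)}")
    compared = [f for f in FACTORS if f not in by]
    cells = fit.cell_means
    compared = [f for f in compared if cells[f].nunique() > 1 or len(compared) == 1]
    if not compared:
        raise ValueError("no factor left to compare within the conditioning family")

    s2 = fit.residual_variance
    df_resid = fit.residual_df
    rows = []
    for family_key, sub in cells.groupby(list(by), observed=True):
        if not isinstance(family_key, tuple):
            family_key = (family_key,)
        family = ", ".join(f"{f}={v}" for f, v in zip(by, family_key))
        sub = sub.reset_index(drop=True)
        labels = ["/".join(str(sub[f][i]) for f in compared) for i in range(len(sub))]
        k = len(sub)
        pmat = np.ones((k, k))
        stats_rows = []
        for i, j in itertools.combinations(range(k), 2):
            est = float(sub["mean"][i] - sub["mean"][j])
            se = float(np.sqrt(s2 * (1.0 / sub["n"][i] + 1.0 / sub["n"][j])))
            if se == 0:
                t = 0.0 if est == 0 else np.inf * np.sign(est)
            else:
                t = est / se
            # Tukey: compare |t|*sqrt(2) with the studentized range over k means
            if k > 1 and np.isfinite(t):
                p = float(stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df_resid))
            else:
                p = 0.0 if np.isinf(t) else 1.0
            p = min(max(p, 0.0), 1.0)
            pmat[i, j] = pmat[j, i] = p
            stats_rows.append((i, j, est, se, t, p))
        letters = _compact_letter_display(labels, pmat, alpha)
        for i, j, est, se, t, p in stats_rows:
            label = f"pairwise~{'*'.join(compared)}|{family}"
            rows.append(
                {
                    "family": family,
                    "label": label,
                    "cell_a": labels[i],
                    "cell_b": labels[j],
                    "estimate": est,
                    "se": se,
                    "t_value": t,
                    "p_adjusted": p,
                    "letters_a": letters[labels[i]],
                    "letters_b": letters[labels[j]],
                }
            )
    return pd.DataFrame(rows)


def amp_peak_share(
    rpkm: pd.DataFrame, focal: list[str] | set[str], stage: str
) -> float:
    """Percentage of total AMP expression contributed by focal transcripts.

    ``rpkm`` is a transcripts x stages table (index: transcript names).
    Returns ``100 * sum(focal RPKM at stage) / sum(all RPKM at stage)``.
    """
    if stage not in rpkm.columns:
        raise KeyError(f"stage {stage!r} not in table columns")
    focal = list(focal)
    missing = [t for t in focal if t not in rpkm.index]
    if missing:
        raise KeyError(f"focal transcript(s) not in table: {missing}")
    col = rpkm[stage].astype(float)
    if (col < 0).any():
        raise ValueError("RPKM values must be non-negative")
    total = col.sum()
    if total == 0:
        raise ValueError(f"all-zero expression at stage {stage!r}")
    return float(100.0 * col.loc[focal].sum() / total)
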