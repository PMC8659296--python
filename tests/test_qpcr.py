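import itertools

import numpy as np
import pandas as pd
import pytest

from pupamp.datasets import AMP_FOCAL_TOP3, load_amp_rpkm
from pupamp.qpcr import (
    amp_peak_share,
    delta_delta_ct,
    fit_factorial_loglinear,
    pairwise_contrasts,
)
from pupamp.synthetic import CtSimSpec, simulate_ct_dataset


def ct_table(rows):
    """rows: (sample_id, genotype, stage, gene, ct)"""
    return pd.DataFrame(
        [
            {"sample_id": s, "genotype": g, "stage": st, "gene": gene, "ct": ct,
             "replicate": 1}
            for (s, g, st, gene, ct) in rows
        ]
    )


def fc_table(cells, rng=None):
    """cells: dict (genotype, stage, gene) -> list of foldchange values."""
    rows = []
    for (g, st, gene), values in cells.items():
        for i, v in enumerate(values):
            rows.append(
                {"sample_id": f"{g}_{st}_{i}", "genotype": g, "stage": st,
                 "gene": gene, "foldchange": v}
            )
    return pd.DataFrame(rows)


class TestDeltaDeltaCt:
    def test_hand_evaluation(self):
        # sample dCT 5 vs calibrator mean dCT 8 -> ddCT -3, foldchange 8
        rows = [
            ("cal1", "control", "L3", "rpl32", 20.0),
            ("cal1", "control", "L3", "drs", 28.0),  # dCT 8
            ("s1", "control", "P0", "rpl32", 20.0),
            ("s1", "control", "P0", "drs", 25.0),  # dCT 5
        ]
        fc = delta_delta_ct(ct_table(rows))
        s1 = fc[fc.sample_id == "s1"].iloc[0]
        assert s1.delta_delta_ct == pytest.approx(-3.0)
        assert s1.foldchange == pytest.approx(8.0)

    def test_calibrator_sample_at_calibrator_mean_gives_unit_foldchange(self):
        rows = [
            ("cal1", "control", "L3", "rpl32", 20.0),
            ("cal1", "control", "L3", "drs", 28.0),
            ("s1", "control", "P0", "rpl32", 19.0),
            ("s1", "control", "P0", "drs", 27.0),
        ]
        fc = delta_delta_ct(ct_table(rows))
        cal = fc[fc.sample_id == "cal1"].iloc[0]
        assert cal.foldchange == pytest.approx(1.0)

    def test_calibrator_cell_log_mean_zero(self):
        spec = CtSimSpec(noise_sd=0.3, samples_per_cell=6,
                         effects={("control", "P0", "drs"): 4.0})
        fc = delta_delta_ct(simulate_ct_dataset(spec, seed=5))
        cal = fc[(fc.genotype == "control") & (fc.stage == "L3")]
        assert np.log(cal["foldchange"]).mean() == pytest.approx(0.0, abs=1e-12)

    def test_foldchange_is_exact_inverse_power(self):
        spec = CtSimSpec(noise_sd=0.5, effects={("control", "P0", "drs"): 2.0})
        fc = delta_delta_ct(simulate_ct_dataset(spec, seed=9))
        np.testing.assert_allclose(fc["foldchange"], 2.0 ** (-fc["delta_delta_ct"]))

    def test_zero_noise_planted_effect(self):
        spec = CtSimSpec(noise_sd=0.0, effects={("control", "P0", "drs"): 3.0})
        fc = delta_delta_ct(simulate_ct_dataset(spec, seed=0))
        np.testing.assert_allclose(fc[fc.stage == "P0"]["foldchange"], 8.0)

    def test_empty_calibrator_rejected(self):
        rows = [
            ("s1", "control", "P0", "rpl32", 20.0),
            ("s1", "control", "P0", "drs", 25.0),
        ]
        with pytest.raises(ValueError, match="calibrator"):
            delta_delta_ct(ct_table(rows), calibrator=("control", "L3"))


class TestFactorialFit:
    def test_balanced_two_cell_design(self):
        e = np.exp(1.0)
        cells = {
            ("c", "L3", "drs"): [e, e],
            ("c", "P0", "drs"): [np.exp(3.0), np.exp(3.0)],
        }
        fit = fit_factorial_loglinear(fc_table(cells))
        assert fit.cell_mean("c", "L3", "drs") == pytest.approx(1.0)
        assert fit.cell_mean("c", "P0", "drs") == pytest.approx(3.0)
        assert fit.residual_variance == pytest.approx(0.0, abs=1e-20)

    def test_cell_mean_recovery_with_noise(self):
        rng = np.random.default_rng(3)
        true = {("c", "L3", "drs"): 0.0, ("c", "P0", "drs"): 2.0,
                ("m", "L3", "drs"): 0.5, ("m", "P0", "drs"): 0.7}
        cells = {
            k: list(np.exp(v + rng.normal(0, 0.1, 5))) for k, v in true.items()
        }
        fit = fit_factorial_loglinear(fc_table(cells))
        for (g, st, gene), v in true.items():
            assert fit.cell_mean(g, st, gene) == pytest.approx(v, abs=3 * 0.1 / np.sqrt(5))

    def test_matches_normal_equations_oracle(self):
        """Cell means equal the direct least-squares solution of the
        saturated dummy design to near machine precision."""
        rng = np.random.default_rng(11)
        genos, stages, genes = ["c", "m"], ["L3", "P0"], ["drs", "drsl2"]
        cells = {
            k: list(np.exp(rng.normal(0, 1, 4)))
            for k in itertools.product(genos, stages, genes)
        }
        fc = fc_table(cells)
        fit = fit_factorial_loglinear(fc)
        # oracle: one dummy column per cell; betahat = (X'X)^-1 X'y
        labels = [f"{g}|{s}|{gene}" for g, s, gene in
                  zip(fc.genotype, fc.stage, fc.gene)]
        uniq = sorted(set(labels))
        X = np.array([[1.0 if lab == u else 0.0 for u in uniq] for lab in labels])
        y = np.log(fc["foldchange"].to_numpy())
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        for u, b in zip(uniq, beta):
            g, s, gene = u.split("|")
            assert fit.cell_mean(g, s, gene) == pytest.approx(b, abs=1e-10)

    def test_saturated_fit_reproduces_observations(self):
        cells = {("c", st, gene): [float(v)]
                 for (st, gene), v in zip(
                     itertools.product(["L3", "P0"], ["drs", "drsl2"]), [1.5, 2.5, 0.5, 4.0])}
        fc = fc_table(cells)
        with pytest.raises(ValueError, match="residual"):
            fit_factorial_loglinear(fc)  # one obs/cell leaves no residual df

    def test_single_level_everywhere_rejected(self):
        fc = fc_table({("c", "L3", "drs"): [1.0, 2.0]})
        with pytest.raises(ValueError, match="single level"):
            fit_factorial_loglinear(fc)

    def test_nonpositive_foldchange_rejected(self):
        fc = fc_table({("c", "L3", "drs"): [1.0, -2.0], ("c", "P0", "drs"): [1.0, 2.0]})
        with pytest.raises(ValueError, match="positive"):
            fit_factorial_loglinear(fc)


class TestPairwiseContrasts:
    def test_identical_cells_share_letter(self):
        rng = np.random.default_rng(5)
        noise = rng.normal(0, 0.1, 6)
        cells = {
            ("c", "L3", "drs"): list(np.exp(noise)),
            ("c", "P0", "drs"): list(np.exp(noise)),  # identical values
        }
        tab = pairwise_contrasts(fit_factorial_loglinear(fc_table(cells)), by="genotype")
        row = tab.iloc[0]
        assert row.estimate == pytest.approx(0.0, abs=1e-12)
        assert row.p_adjusted > 0.99
        assert row.letters_a == row.letters_b

    def test_outlier_cell_gets_distinct_letter(self):
        rng = np.random.default_rng(8)

        def draws(mean):
            x = rng.normal(0, 0.1, 5)
            return list(np.exp(x - x.mean() + mean))  # exact cell mean

        cells = {
            ("a", "L3", "drs"): draws(0.0),
            ("b", "L3", "drs"): draws(0.0),
            ("c", "L3", "drs"): draws(5.0),
        }
        tab = pairwise_contrasts(fit_factorial_loglinear(fc_table(cells)),
                                 by=("stage", "gene"))
        letters = {r.cell_a: r.letters_a for _, r in tab.iterrows()}
        letters.update({r.cell_b: r.letters_b for _, r in tab.iterrows()})
        assert letters["a"] == letters["b"]
        assert letters["c"] != letters["a"]

    def test_antisymmetry_and_adjustment_direction(self):
        rng = np.random.default_rng(2)
        cells = {
            ("c", "L3", "drs"): list(np.exp(rng.normal(0, 0.5, 5))),
            ("c", "P0", "drs"): list(np.exp(rng.normal(1, 0.5, 5))),
            ("m", "L3", "drs"): list(np.exp(rng.normal(0, 0.5, 5))),
            ("m", "P0", "drs"): list(np.exp(rng.normal(0.2, 0.5, 5))),
        }
        fit = fit_factorial_loglinear(fc_table(cells))
        tab = pairwise_contrasts(fit, by="genotype")
        for _, row in tab.iterrows():
            a = fit.cell_mean(row.family.split("=")[1], row.cell_a, "drs")
            b = fit.cell_mean(row.family.split("=")[1], row.cell_b, "drs")
            assert row.estimate == pytest.approx(a - b, abs=1e-12)
        # Tukey-adjusted p is never below the unadjusted two-sided p
        from scipy import stats

        for _, row in tab.iterrows():
            p_unadj = 2 * stats.t.sf(abs(row.t_value), fit.residual_df)
            assert row.p_adjusted >= p_unadj - 1e-12

    def test_stage_effect_pattern_with_planted_expression_peak(self):
        # pupariation induction in both conventional and germ-free flies:
        # strong stage effect within each genotype, no genotype effect at P0
        spec = CtSimSpec(
            genotypes=("conventional", "germfree"),
            noise_sd=0.3,
            samples_per_cell=5,
            effects={
                ("conventional", "P0", "drs"): 6.0,
                ("germfree", "P0", "drs"): 6.0,
            },
        )
        fc = delta_delta_ct(simulate_ct_dataset(spec, seed=19),
                            calibrator=("conventional", "L3"))
        fit = fit_factorial_loglinear(fc)
        within = pairwise_contrasts(fit, by="genotype")
        assert (within["p_adjusted"] < 1e-4).all()
        between = pairwise_contrasts(fit, by=("stage", "gene"))
        at_p0 = between[between.family.str.contains("stage=P0")]
        assert (at_p0["p_adjusted"] > 0.05).all()

    def test_unknown_conditioning_factor_rejected(self):
        fit = fit_factorial_loglinear(
            fc_table({("c", "L3", "drs"): [1.0, 1.1], ("c", "P0", "drs"): [2.0, 2.1]})
        )
        with pytest.raises(ValueError, match="not in the design"):
            pairwise_contrasts(fit, by="treatment")


class TestAmpPeakShare:
    def test_single_nonzero_transcript_is_everything(self):
        table = pd.DataFrame({"P0": [50.0, 0.0, 0.0]},
                             index=["drs", "drsl2", "drsl5"])
        assert amp_peak_share(table, ["drs"], "P0") == pytest.approx(100.0)

    def test_toy_hand_sum(self):
        # drs 50 + drsl2 30 + drsl5 15 = 95 of a 100 total
        table = pd.DataFrame(
            {"P0": [50.0, 30.0, 15.0, 2.0, 2.0, 1.0]},
            index=["drs", "drsl2", "drsl5", "AttA", "Def", "Mtk"],
        )
        assert amp_peak_share(table, AMP_FOCAL_TOP3, "P0") == pytest.approx(95.0)

    def test_packaged_table_reproduces_peak_structure(self):
        rpkm = load_amp_rpkm()
        assert amp_peak_share(rpkm, AMP_FOCAL_TOP3, "P0") == pytest.approx(95.0, abs=1.0)
        assert amp_peak_share(rpkm, ["drs", "drsl2"], "P0") == pytest.approx(70.0, abs=1.0)

    def test_unknown_stage_and_transcripts_rejected(self):
        table = pd.DataFrame({"P0": [1.0]}, index=["drs"])
        with pytest.raises(KeyError):
            amp_peak_share(table, ["drs"], "L3")
        with pytest.raises(KeyError):
            amp_peak_share(table, ["nope"], "P0")

    def test_all_zero_stage_rejected(self):
        table = pd.DataFrame({"P0": [0.0, 0.0]}, index=["drs", "drsl2"])
        with pytest.raises(ValueError, match="all-zero"):
            amp_peak_share(table, ["drs"], "P0")
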