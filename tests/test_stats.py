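import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_hyp

import coclaims as cc
from coclaims.stats import ConfusionMatrix, FitError


class TestConfusion:
    def test_perfect_agreement_has_no_off_diagonal(self):
        flags = [True, False, True, True]
        cm = cc.confusion(flags, flags)
        assert (cm.fp, cm.fn) == (0, 0)
        assert (cm.tp, cm.tn) == (3, 1)

    def test_all_four_cells(self):
        cm = cc.confusion([True, True, False, False],
                          [True, False, True, False])
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (1, 1, 1, 1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cc.confusion([True], [True, False])

    def test_matches_pandas_crosstab_on_random_data(self):
        rng = np.random.default_rng(8)
        idx = rng.random(500) < 0.4
        ref = rng.random(500) < 0.6
        cm = cc.confusion(idx, ref)
        tab = pd.crosstab(pd.Series(idx), pd.Series(ref))
        assert cm.tp == tab.loc[True, True]
        assert cm.tn == tab.loc[False, False]
        assert cm.fp == tab.loc[True, False]
        assert cm.fn == tab.loc[False, True]


class TestAccuracy:
    def test_perfect_agreement(self):
        rep = cc.accuracy(ConfusionMatrix(tp=50, fp=0, fn=0, tn=50))
        assert rep.sensitivity.estimate == 1.0
        assert rep.specificity.estimate == 1.0
        assert rep.kappa.estimate == pytest.approx(1.0)

    def test_published_shape_counts_round_to_printed_values(self):
        # cells chosen to mirror the published accuracy table's third row
        rep = cc.accuracy(ConfusionMatrix(tp=9036, fn=6543, fp=18823,
                                          tn=20742))
        assert round(rep.sensitivity.estimate, 2) == 0.58
        assert round(rep.specificity.estimate, 2) == 0.52
        assert rep.sensitivity.ci_low < rep.sensitivity.estimate \
            < rep.sensitivity.ci_high

    def test_sensitivity_margin_identity(self):
        cm = ConfusionMatrix(tp=13, fp=4, fn=7, tn=11)
        rep = cc.accuracy(cm)
        from fractions import Fraction
        assert Fraction(cm.tp, cm.tp + cm.fn) * (cm.tp + cm.fn) == cm.tp
        assert rep.sensitivity.estimate == pytest.approx(13 / 20)
        assert rep.ppv.estimate == pytest.approx(13 / 17)

    def test_zero_margin_reported_undefined(self):
        rep = cc.accuracy(ConfusionMatrix(tp=0, fp=0, fn=0, tn=10))
        assert rep.sensitivity.estimate is None
        assert rep.ppv.estimate is None
        assert rep.specificity.estimate == 1.0

    def test_kappa_near_zero_under_independence(self):
        rng = np.random.default_rng(2024)
        kappas = []
        for _ in range(200):
            idx = rng.random(400) < 0.5
            ref = rng.random(400) < 0.5
            kappas.append(cc.accuracy(cc.confusion(idx, ref)).kappa.estimate)
        # mean kappa ~ N(0, (1/sqrt(400))/sqrt(200)): 4 sigma ~ 0.014
        assert abs(float(np.mean(kappas))) < 0.015

    def test_kappa_ci_contains_estimate_and_is_clipped(self):
        rep = cc.accuracy(ConfusionMatrix(tp=40, fp=5, fn=5, tn=50))
        k = rep.kappa
        assert k.ci_low <= k.estimate <= k.ci_high
        assert -1 <= k.ci_low and k.ci_high <= 1


class TestOddsRatio:
    def test_equal_proportions_give_unity(self):
        eff = cc.odds_ratio_2x2(20, 100, 40, 200)
        assert eff.or_point == pytest.approx(1.0)
        assert eff.ci_low < 1 < eff.ci_high

    def test_row_and_column_swap_invariance(self):
        a, b, c, d = 30, 70, 20, 80  # events/nonevents by group
        eff = cc.odds_ratio_2x2(a, a + b, c, c + d)
        # swapping both rows and both columns leaves the OR unchanged
        swapped = cc.odds_ratio_2x2(d, d + c, b, b + a)
        assert swapped.or_point == pytest.approx(eff.or_point)
        # relabelling the exposure inverts the OR
        inv = cc.odds_ratio_2x2(c, c + d, a, a + b)
        assert inv.or_point == pytest.approx(1 / eff.or_point)
        assert inv.ci_low == pytest.approx(1 / eff.ci_high)

    def test_haldane_correction_on_zero_cell(self):
        eff = cc.odds_ratio_2x2(10, 10, 5, 10)
        assert eff.corrected
        assert math.isfinite(eff.or_point)

    def test_matches_statsmodels_table2x2(self):
        from statsmodels.stats.contingency_tables import Table2x2
        t = Table2x2([[30, 70], [20, 80]])
        eff = cc.odds_ratio_2x2(30, 100, 20, 100)
        assert eff.or_point == pytest.approx(t.oddsratio)
        lo, hi = t.oddsratio_confint()
        assert eff.ci_low == pytest.approx(lo)
        assert eff.ci_high == pytest.approx(hi)


class TestVif:
    def test_orthogonal_columns_all_near_one(self):
        rng = np.random.default_rng(0)
        design = pd.DataFrame(rng.standard_normal((500, 4)),
                              columns=["e", "x1", "x2", "x3"])
        kept, dropped = cc.vif_screen(design, exposure="e")
        assert dropped == []
        assert set(kept) == set(design.columns)

    def test_duplicated_column_dropped_with_infinite_vif(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(200)
        design = pd.DataFrame({"e": rng.standard_normal(200),
                               "x": x, "x_copy": x})
        kept, dropped = cc.vif_screen(design, exposure="e")
        assert len(dropped) == 1
        assert dropped[0][1] == math.inf
        assert len(kept) == 2

    def test_constructed_r2_gives_known_vif(self):
        # x3 = x1 + x2 + noise with var chosen for R^2 = 0.9 -> VIF = 10
        rng = np.random.default_rng(2)
        n = 200_000
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        noise = rng.standard_normal(n) * math.sqrt(2 / 9)
        design = pd.DataFrame({"e": rng.standard_normal(n),
                               "x1": x1, "x2": x2, "x3": x1 + x2 + noise})
        from coclaims.stats import _vif_one
        vif3 = _vif_one(design.to_numpy(float), 3)
        assert vif3 == pytest.approx(10.0, rel=0.05)
        kept, dropped = cc.vif_screen(design, exposure="e")
        assert len(dropped) == 1  # one of the trio resolves the cluster
        X = design[kept].to_numpy(float)
        assert all(_vif_one(X, j) <= 2.5 for j in range(X.shape[1]))

    def test_exposure_never_dropped(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(300)
        design = pd.DataFrame({"e": x, "x_dup": x + 1e-9})
        kept, dropped = cc.vif_screen(design, exposure="e")
        assert "e" in kept
        assert dropped[0][0] == "x_dup"


class TestLogistic:
    def test_saturated_model_equals_2x2_or(self):
        rng = np.random.default_rng(4)
        exposure = rng.random(2000) < 0.5
        p = np.where(exposure, 0.6, 0.45)
        y = rng.random(2000) < p
        fit = cc.fit_logistic(y, pd.DataFrame({"e": exposure.astype(int)}),
                              "e")
        eff = cc.odds_ratio_2x2(int((exposure & y).sum()),
                                int(exposure.sum()),
                                int((~exposure & y).sum()),
                                int((~exposure).sum()))
        assert fit.effect.or_point == pytest.approx(eff.or_point, rel=1e-6)
        assert fit.effect.ci_low == pytest.approx(eff.ci_low, rel=1e-4)

    def test_separation_raises(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        design = pd.DataFrame({"e": [0, 0, 0, 1, 1, 1]})
        with pytest.raises(FitError):
            cc.fit_logistic(y, design, "e")


class TestAuroc:
    def test_perfect_separation(self):
        assert cc.auroc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_constant_scores_all_ties(self):
        assert cc.auroc([0.5] * 10, [1, 0] * 5) == 0.5

    def test_small_case_matches_pair_counting(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.65, 0.35]
        y = [0, 0, 1, 1, 0, 1]
        pairs = [(s1, s0) for s1, o1 in zip(scores, y) if o1
                 for s0, o0 in zip(scores, y) if not o0]
        expected = np.mean([1.0 if a > b else 0.5 if a == b else 0.0
                            for a, b in pairs])
        assert cc.auroc(scores, y) == pytest.approx(expected)

    def test_matches_sklearn_on_random_scores(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(5)
        y = rng.random(300) < 0.4
        s = rng.random(300) + 0.5 * y
        assert cc.auroc(s, y) == pytest.approx(roc_auc_score(y, s))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cc.auroc([0.1, 0.2], [1, 1])


class TestDeLong:
    def _paired(self, n=400, seed=6):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        y = rng.random(n) < 1 / (1 + np.exp(-x))
        a = x + rng.standard_normal(n)
        b = x + rng.standard_normal(n) * 1.5
        return a, b, y

    def test_identical_models_give_p_one(self):
        a, _, y = self._paired()
        res = cc.delong_compare(a, a, y)
        assert res.delta == 0.0
        assert res.p_value == 1.0

    def test_antisymmetry(self):
        a, b, y = self._paired()
        ab = cc.delong_compare(a, b, y)
        ba = cc.delong_compare(b, a, y)
        assert ab.delta == pytest.approx(-ba.delta)
        assert ab.p_value == pytest.approx(ba.p_value)
        assert ab.chi2 == pytest.approx(ba.chi2)
        assert ab.chi2 == pytest.approx(ab.delta ** 2 / ab.variance_delta)

    def test_auroc_components_match_estimator(self):
        a, b, y = self._paired()
        res = cc.delong_compare(a, b, y)
        assert res.auroc_a == pytest.approx(cc.auroc(a, y))
        assert res.auroc_b == pytest.approx(cc.auroc(b, y))

    def test_matches_r_proc_delong(self, tmp_path):
        import shutil
        import subprocess
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not on PATH")
        a, b, y = self._paired(n=120, seed=9)
        df = pd.DataFrame({"y": y.astype(int), "a": a, "b": b})
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "dl.R"
        script.write_text(
            'suppressMessages(library(pROC));'
            f'd <- read.csv("{csv}");'
            'r <- roc.test(roc(d$y, d$a, quiet=TRUE),'
            ' roc(d$y, d$b, quiet=TRUE), method="delong", paired=TRUE);'
            'cat(r$statistic^2, r$p.value)\n')
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=120)
        if out.returncode != 0:
            pytest.skip(f"pROC unavailable: {out.stderr[:200]}")
        chi2_r, p_r = map(float, out.stdout.split())
        res = cc.delong_compare(a, b, y)
        assert res.chi2 == pytest.approx(chi2_r, rel=1e-6)
        assert res.p_value == pytest.approx(p_r, rel=1e-6)
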