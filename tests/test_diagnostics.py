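"""DANP cutoffs, classification, confusion metrics, Welch t, ROC/AUC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pibgm import (CohortTable, auc_grade, classify, confusion_metrics,
                   danp_cutoff, danp_sweep, make_profile_cohort, roc_auc,
                   sweep_frame, welch_ttest)
from pibgm.errors import ConfigError


class TestDanpCutoff:
    def test_order_statistic_definition(self):
        values = np.arange(1.0, 101.0)
        cutoff = danp_cutoff(values, 0.95)
        assert cutoff == 95.0
        assert np.count_nonzero(values <= cutoff) == 95

    def test_danp_one_gives_max_and_full_specificity(self, rng):
        values = rng.random(37)
        cutoff = danp_cutoff(values, 1.0)
        assert cutoff == values.max()
        assert not classify(values, cutoff).any()

    def test_all_tied_normals(self):
        values = np.full(20, 1.5)
        cutoff = danp_cutoff(values, 0.6)
        assert cutoff == 1.5
        assert not classify(values, cutoff).any()

    def test_empty_or_bad_danp_rejected(self):
        with pytest.raises(ConfigError):
            danp_cutoff([], 0.95)
        with pytest.raises(ConfigError):
            danp_cutoff([1.0], 0.0)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**32 - 1), st.floats(0.05, 1.0))
    def test_specificity_at_least_danp_by_construction(self, seed, danp):
        values = np.random.default_rng(seed).random(50)
        cutoff = danp_cutoff(values, danp)
        spec = np.mean(values <= cutoff)
        assert spec >= danp - 1e-12


class TestClassify:
    def test_strictness_at_cutoff(self):
        assert not classify([2.0], 2.0)[0]
        assert classify([2.0 + 1e-12], 2.0)[0]

    def test_all_below_cutoff(self):
        assert not classify([0.1, 0.2, 0.3], 1.0).any()

    def test_monotone_transform_invariance(self, rng):
        values = rng.random(30)
        cutoff = 0.5
        a = classify(values, cutoff)
        b = classify(np.exp(values), np.exp(cutoff))
        assert np.array_equal(a, b)


class TestConfusion:
    def test_worked_sensitivity_and_ppv(self):
        """43 of 67 diseased detected with 3 false alarms among 108 normals."""
        truth = np.r_[np.ones(67, bool), np.zeros(108, bool)]
        pred = np.r_[np.ones(43, bool), np.zeros(24, bool),
                     np.ones(3, bool), np.zeros(105, bool)]
        rep = confusion_metrics(pred, truth)
        assert round(100 * rep.sensitivity, 2) == 64.18
        assert round(100 * rep.ppv, 2) == 93.48
        assert rep.total == 175

    def test_perfect_prediction(self):
        truth = np.array([1, 1, 0, 0], bool)
        rep = confusion_metrics(truth, truth)
        assert (rep.sensitivity, rep.specificity, rep.ppv, rep.npv,
                rep.accuracy) == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_undefined_rates_reported_absent(self):
        truth = np.array([1, 1, 1], bool)
        pred = np.zeros(3, bool)
        rep = confusion_metrics(pred, truth)
        assert rep.ppv is None and rep.specificity is None
        assert rep.sensitivity == 0.0

    def test_accuracy_identity(self, rng):
        pred = rng.random(40) > 0.5
        truth = rng.random(40) > 0.5
        rep = confusion_metrics(pred, truth)
        assert rep.accuracy == (rep.tp + rep.tn) / 40

    def test_length_mismatch(self):
        with pytest.raises(ConfigError):
            confusion_metrics([True], [True, False])


def _welch_by_hand(a, b):
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (np.mean(a) - np.mean(b)) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    from scipy.stats import t as tdist
    return t, 2 * tdist.sf(abs(t), df)


class TestWelch:
    def test_identical_samples(self):
        t, p = welch_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_shifted_sample_matches_hand_formula(self):
        a, b = [1.0, 2.0, 3.0], [11.0, 12.0, 13.0]
        t, p = welch_ttest(a, b)
        th, ph = _welch_by_hand(a, b)
        assert t == pytest.approx(th, abs=1e-12)
        assert p == pytest.approx(ph, abs=1e-12)

    def test_antisymmetry(self, rng):
        a, b = rng.random(10), rng.random(12) + 0.3
        t1, p1 = welch_ttest(a, b)
        t2, p2 = welch_ttest(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_agrees_with_direct_transcription(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.normal(0, 1, 8), r.normal(0.4, 1.7, 13)
        t, p = welch_ttest(a, b)
        th, ph = _welch_by_hand(a, b)
        assert abs(t - th) < 1e-10 and abs(p - ph) < 1e-10

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ConfigError):
            welch_ttest([1.0], [1.0, 2.0])
        with pytest.raises(ConfigError):
            welch_ttest([2.0, 2.0], [3.0, 3.0])


def _concordance_auc(scores, truth):
    """Oracle: tie-corrected pairwise concordance probability."""
    pos = scores[truth]
    neg = scores[~truth]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        roc = roc_auc([0.1, 0.2, 0.8, 0.9], [False, False, True, True])
        assert roc.auc == pytest.approx(1.0)

    def test_all_equal_scores(self):
        roc = roc_auc(np.ones(10), np.r_[np.ones(5, bool), np.zeros(5, bool)])
        assert roc.auc == pytest.approx(0.5)

    def test_curve_endpoints_and_bounds(self, rng):
        roc = roc_auc(rng.random(30), rng.random(30) > 0.5)
        assert tuple(roc.points[0]) == (0.0, 0.0)
        assert tuple(roc.points[-1]) == (1.0, 1.0)
        assert 0.0 <= roc.auc <= 1.0

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_concordance_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(6, 50))
        scores = np.round(r.random(n), 1)  # rounding forces ties
        truth = r.random(n) > 0.5
        if truth.all() or not truth.any():
            truth[0] = ~truth[0]
        roc = roc_auc(scores, truth)
        assert roc.auc == pytest.approx(_concordance_auc(scores, truth), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ConfigError):
            roc_auc([0.1, 0.5], [True, True])

    @pytest.mark.parametrize("auc,grade", [
        (0.95, "Excellent"), (0.84, "Good"), (0.75, "Worthless"),
        (0.65, "Not good"), (0.5, "Fail"), (1.0, "Excellent"),
    ])
    def test_grading_bands(self, auc, grade):
        assert auc_grade(auc) == grade


class TestSweep:
    @staticmethod
    def table(n_normal=40, n_fuo=30, seed=0, **kw):
        records = make_profile_cohort(
            {"normal": n_normal, "inflammatory": n_fuo // 3,
             "infection": n_fuo // 3, "neoplasm": n_fuo - 2 * (n_fuo // 3)},
            seed=seed, **kw)
        return CohortTable.from_profiles(records)

    def test_specificity_constant_when_values_distinct(self):
        table = self.table(n_normal=100, n_fuo=60, seed=11)
        reports = danp_sweep(table, danp_grid=(0.95,))
        specs = {r.specificity for r in reports}
        assert specs == {0.95}

    def test_sensitivity_grows_as_danp_drops_under_dominance(self):
        table = self.table(seed=3)
        reports = danp_sweep(table, danp_grid=(0.99, 0.9, 0.8, 0.6),
                             t_grid=[1.2])
        sens = [r.sensitivity for r in reports]
        assert all(a <= b + 1e-12 for a, b in zip(sens, sens[1:]))

    def test_null_cohort_sensitivity_matches_exchangeability(self):
        """Identical distributions: mean sensitivity ~ 1 - danp over seeds."""
        loc = {g: 1.0 for g in ("normal", "inflammatory", "infection", "neoplasm")}
        sens = []
        for seed in range(30):
            table = self.table(seed=seed, group_loc=loc)
            rep = danp_sweep(table, danp_grid=(0.8,), t_grid=[1.0])[0]
            sens.append(rep.sensitivity)
        assert abs(np.mean(sens) - 0.2) < 0.06

    def test_per_etiology_rates_present_and_bounded(self):
        table = self.table(seed=5)
        rep = danp_sweep(table, danp_grid=(0.95,), t_grid=[1.2])[0]
        assert set(rep.per_etiology) == {"inflammatory", "infection", "neoplasm"}
        assert all(0.0 <= v <= 1.0 for v in rep.per_etiology.values())

    def test_sweep_frame_shape(self):
        table = self.table(seed=5)
        frame = sweep_frame(danp_sweep(table, danp_grid=(0.95, 0.9)))
        assert len(frame) == 2 * len(table.t_values("cortex", "bw"))
        assert {"danp", "t", "cutoff", "sensitivity", "specificity"} <= set(frame.columns)

    def test_needs_normals_and_fuo(self):
        records = make_profile_cohort({"normal": 10}, seed=0)
        with pytest.raises(ConfigError):
            danp_sweep(CohortTable.from_profiles(records))
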