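"""Peak extraction, behavioral scoring, and inferential statistics."""

import numpy as np
import pandas as pd
import pytest

from semtrf import stats as st
from semtrf.trf import LagSpec, TRFModel


def make_trf(weights_by_feature, ch_names, rate=250.0):
    names = list(weights_by_feature)
    lags = LagSpec(-100.0, 1000.0, rate)
    W = np.stack([weights_by_feature[f] for f in names])
    return TRFModel(
        weights=W,
        lags=lags,
        lam=1.0,
        feature_names=names,
        ch_names=ch_names,
        intercept=np.zeros(W.shape[2]),
    )


def gauss(t, center, width, amp):
    return amp * np.exp(-0.5 * ((t - center) / width) ** 2)


class TestRoiWaveform:
    def test_single_channel_roi(self):
        t = LagSpec(-100, 1000, 250.0).times_ms
        w = np.stack([gauss(t, 200, 40, 1.0), gauss(t, 300, 40, -1.0)], axis=1)
        trf = make_trf({"envelope": w}, ["Fz", "Cz"])
        _, wave = st.roi_waveform(trf, "envelope", ["Cz"])
        np.testing.assert_array_equal(wave, w[:, 1])

    def test_opposite_kernels_cancel(self):
        t = LagSpec(-100, 1000, 250.0).times_ms
        k = gauss(t, 200, 40, 1.0)
        trf = make_trf({"envelope": np.stack([k, -k], axis=1)}, ["Fz", "Cz"])
        _, wave = st.roi_waveform(trf, "envelope", ["Fz", "Cz"])
        assert np.max(np.abs(wave)) < 1e-12

    def test_three_channel_hand_mean(self):
        t = LagSpec(-100, 1000, 250.0).times_ms
        w = np.stack([np.full_like(t, 1.0), np.full_like(t, 2.0), np.full_like(t, 6.0)], axis=1)
        trf = make_trf({"envelope": w}, ["a", "b", "c"])
        _, wave = st.roi_waveform(trf, "envelope", ["a", "b", "c"])
        np.testing.assert_allclose(wave, 3.0)

    def test_empty_roi_rejected(self):
        t = LagSpec(-100, 1000, 250.0).times_ms
        trf = make_trf({"envelope": np.zeros((len(t), 1))}, ["Fz"])
        with pytest.raises(ValueError):
            st.roi_waveform(trf, "envelope", [])


class TestSensoryPeaks:
    def test_constructed_extrema(self):
        t = LagSpec(-100, 1000, 250.0).times_ms
        wave = gauss(t, 100, 20, -2.0) + gauss(t, 200, 25, 3.0)
        peaks = st.extract_sensory_peaks(wave, t)
        assert abs(peaks["N1"].latency_ms - 100) <= 4
        assert abs(peaks["P2"].latency_ms - 200) <= 4
        assert peaks["n1p2"] == pytest.approx(5.0, rel=0.01)

    def test_flat_waveform_tie_break(self):
        t = LagSpec(-100, 1000, 250.0).times_ms
        peaks = st.extract_sensory_peaks(np.zeros_like(t), t)
        assert peaks["N1"].amplitude == 0.0 and peaks["n1p2"] == 0.0
        assert peaks["N1"].latency_ms == 52.0  # first sample inside 50-150 ms

    def test_amplitude_scaling_latency_invariance(self):
        t = LagSpec(-100, 1000, 250.0).times_ms
        wave = gauss(t, 120, 25, -1.0) + gauss(t, 210, 25, 1.5)
        p1 = st.extract_sensory_peaks(wave, t)
        p2 = st.extract_sensory_peaks(5.0 * wave, t)
        assert p1["N1"].latency_ms == p2["N1"].latency_ms
        assert p2["n1p2"] == pytest.approx(5 * p1["n1p2"], rel=1e-9)

    def test_window_outside_axis_rejected(self):
        t = np.arange(0, 40.0, 4.0)
        with pytest.raises(ValueError):
            st.extract_sensory_peaks(np.zeros_like(t), t)


class TestN400:
    def roi_models(self, e45_wave, ctl_wave):
        W_e = np.stack([e45_wave, e45_wave], axis=1)
        W_c = np.stack([ctl_wave, ctl_wave], axis=1)
        chans = ["CPz", "Pz"]
        return (
            make_trf({"word_surprisal": W_e}, chans),
            make_trf({"word_surprisal": W_c}, chans),
        )

    def test_identical_conditions_zero(self):
        t = LagSpec(-100, 1000, 250.0).times_ms
        wave = gauss(t, 400, 60, -1.0)
        e45, ctl = self.roi_models(wave, wave)
        pk = st.extract_n400(e45, ctl, ["CPz", "Pz"])
        assert pk.amplitude == 0.0

    def test_injected_gaussian_latency_and_window_mean(self):
        """Gaussian dip at 500 ms: latency exact, amplitude = 20 ms window mean."""
        t = LagSpec(-100, 1000, 250.0).times_ms
        base = gauss(t, 350, 80, -0.3)
        bump = gauss(t, 500, 40, -1.2)
        e45, ctl = self.roi_models(base + bump, base)
        pk = st.extract_n400(e45, ctl, ["CPz", "Pz"])
        assert abs(pk.latency_ms - 500) <= 4
        mask = np.abs(t - pk.latency_ms) <= 10
        assert pk.amplitude == pytest.approx(bump[mask].mean(), rel=0.02)

    def test_equal_minima_earlier_wins(self):
        t = LagSpec(-100, 1000, 250.0).times_ms
        diff = np.zeros_like(t)
        diff[np.argmin(np.abs(t - 400))] = -1.0
        diff[np.argmin(np.abs(t - 700))] = -1.0
        e45, ctl = self.roi_models(diff, np.zeros_like(t))
        pk = st.extract_n400(e45, ctl, ["CPz", "Pz"])
        assert pk.latency_ms == pytest.approx(400, abs=4)


class TestBehavioralScoring:
    def full_design(self, n_recalled):
        """Loads 2-6, three blocks each: 60 presented words total."""
        trials = []
        k = 0
        for load in (2, 3, 4, 5, 6):
            for _ in range(3):
                presented = [f"word{k + i}" for i in range(load)]
                k += load
                trials.append(
                    {"presented": presented, "recalled": [], "judgments": [True] * load}
                )
        flat = [w for tr in trials for w in tr["presented"]]
        assert len(flat) == 60
        for w in flat[:n_recalled]:
            for tr in trials:
                if w in tr["presented"]:
                    tr["recalled"].append(w.upper())  # case-insensitive match
                    break
        return trials

    def test_half_recall_is_fifty_pct(self):
        scores = st.score_listening_span(self.full_design(30))
        assert scores.recall_pct == pytest.approx(50.0)
        assert scores.judgment_pct == pytest.approx(100.0)

    def test_empty_recall_zero(self):
        scores = st.score_listening_span(self.full_design(0))
        assert scores.recall_pct == 0.0

    def test_duplicate_recall_counted_once(self):
        trials = [{"presented": ["cat", "dog"], "recalled": ["cat", "cat", "cat"],
                   "judgments": [True, False]}]
        scores = st.score_listening_span(trials)
        assert scores.recall_pct == pytest.approx(50.0)
        assert scores.judgment_pct == pytest.approx(50.0)

    def test_ssq_domain_means(self):
        items = [("speech", 4.0)] * 14 + [("spatial", 8.0)] * 17 + [("quality", 8.0)] * 18
        scores = st.score_ssq(items)
        assert scores.ssq_speech == 4.0
        assert scores.ssq_spatial == 8.0
        assert scores.ssq_all == pytest.approx((4 * 14 + 8 * 35) / 49)

    def test_ssq_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            st.score_ssq([("speech", 11.0)])


class TestWelch:
    def test_identical_samples(self):
        r = st.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0 and r.p == pytest.approx(1.0)

    def test_textbook_hand_formula(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0])
        r = st.welch_t(a, b)
        se = np.sqrt(a.var(ddof=1) / 3 + b.var(ddof=1) / 3)
        t_hand = (a.mean() - b.mean()) / se
        assert r.statistic == pytest.approx(t_hand, rel=1e-12)
        assert r.df == pytest.approx(4.0)
        assert r.effect == pytest.approx(-1.0)

    def test_antisymmetry(self, rng):
        a, b = rng.standard_normal(12), rng.standard_normal(15) + 0.5
        r1, r2 = st.welch_t(a, b), st.welch_t(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p == pytest.approx(r2.p)

    def test_reduces_to_pooled_t_when_balanced(self, rng):
        """Equal n and equal variance: Welch equals the classical pooled t."""
        a = rng.standard_normal(20)
        b = rng.standard_normal(20) + 0.3
        b = (b - b.mean()) / b.std(ddof=1) * a.std(ddof=1) + b.mean()  # match variance
        from scipy.stats import ttest_ind

        r = st.welch_t(a, b)
        pooled = ttest_ind(a, b, equal_var=True)
        assert r.statistic == pytest.approx(pooled.statistic, abs=1e-10)
        assert r.p == pytest.approx(pooled.pvalue, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            st.welch_t([1.0, 1.0], [2.0, 2.0])


class TestWilcoxon:
    def test_six_positive_diffs_exact(self):
        r = st.wilcoxon_signed_rank(np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6]), "greater")
        assert r.p == pytest.approx(1 / 64)

    def test_symmetric_pairs_half(self, rng):
        d = np.concatenate([np.arange(1, 11.0), -np.arange(1, 11.0)])
        r = st.wilcoxon_signed_rank(d, "greater")
        assert 0.4 < r.p < 0.6

    def test_sign_flip_symmetry(self):
        d = np.array([0.3, -0.1, 0.5, 0.2, -0.4, 0.6, 0.15])
        p_greater = st.wilcoxon_signed_rank(d, "greater").p
        p_less = st.wilcoxon_signed_rank(-d, "less").p
        assert p_greater == pytest.approx(p_less)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            st.wilcoxon_signed_rank(np.zeros(6))


class TestMixedAnova:
    def build(self, rng, n_per_group=6, group_shift=0.0, model_shift=0.0):
        rows = []
        for s in range(2 * n_per_group):
            g = "CI" if s < n_per_group else "NH"
            for m in ("acoustic", "full"):
                for c in ("Control", "E45"):
                    y = rng.normal(
                        (group_shift if g == "CI" else 0)
                        + (model_shift if m == "full" else 0),
                        1.0,
                    )
                    rows.append(
                        {"subject": s, "group": g, "model": m, "condition": c, "y": y}
                    )
        return pd.DataFrame(rows)

    def test_identical_everything_f_near_zero(self):
        rows = [
            {"subject": s, "group": "CI" if s < 3 else "NH", "model": m,
             "condition": c, "y": 1.0}
            for s in range(6) for m in ("a", "f") for c in ("x", "y")
        ]
        out = st.mixed_anova(pd.DataFrame(rows), "y", "subject", "group",
                             ["model", "condition"])
        assert np.allclose(out["F"].fillna(0.0), 0.0)

    def test_brute_force_two_way_reduction(self, rng):
        """Collapsing one factor matches pingouin's 2-way mixed ANOVA."""
        pg = pytest.importorskip("pingouin")
        df = self.build(rng, model_shift=0.5, group_shift=0.4)
        two = df.groupby(["subject", "group", "model"], as_index=False)["y"].mean()
        ours = st.mixed_anova(two, "y", "subject", "group", ["model"])
        ref = pg.mixed_anova(two, dv="y", within="model", subject="subject", between="group")
        ref_f = dict(zip(ref["Source"], ref["F"]))
        got = dict(zip(ours["effect"], ours["F"]))
        assert got["group"] == pytest.approx(ref_f["group"], rel=1e-9)
        assert got["model"] == pytest.approx(ref_f["model"], rel=1e-9)
        assert got["model:group"] == pytest.approx(ref_f["Interaction"], rel=1e-9)

    def test_location_invariance(self, rng):
        df = self.build(rng, model_shift=0.3)
        a = st.mixed_anova(df, "y", "subject", "group", ["model", "condition"])
        b = st.mixed_anova(df.assign(y=df["y"] + 1000.0), "y", "subject", "group",
                           ["model", "condition"])
        np.testing.assert_allclose(a["F"], b["F"], rtol=1e-8)

    def test_model_effect_detected(self, rng):
        df = self.build(rng, n_per_group=10, model_shift=1.5)
        out = st.mixed_anova(df, "y", "subject", "group", ["model", "condition"])
        row = out[out["effect"] == "model"].iloc[0]
        assert row["p"] < 0.01

    def test_missing_cell_rejected(self, rng):
        df = self.build(rng).iloc[:-1]
        with pytest.raises(ValueError):
            st.mixed_anova(df, "y", "subject", "group", ["model", "condition"])


class TestSpearmanFdr:
    def test_monotone_transform_rho_one(self):
        x = np.arange(10.0)
        out = st.spearman_fdr([("exp", x, np.exp(x))])
        assert out["rho"][0] == pytest.approx(1.0)

    def test_bh_hand_family(self, rng):
        """q-values for p = (.01,.02,.03,.04) all equal .04 by BH step-up."""
        from statsmodels.stats.multitest import multipletests

        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(q, 0.04)
        # and the same family run through spearman_fdr keeps q >= p, monotone
        pairs = []
        x = np.arange(30.0)
        for k, noise in enumerate((0.1, 2.0, 8.0, 30.0)):
            y = x + noise * rng.standard_normal(30)
            pairs.append((f"pair{k}", x, y))
        out = st.spearman_fdr(pairs)
        assert (out["q"] >= out["p"] - 1e-12).all()
        srt = out.sort_values("p")
        assert srt["q"].is_monotonic_increasing

    def test_independent_rho_near_zero(self, rng):
        x = rng.standard_normal(100)
        out = st.spearman_fdr([("null", x, rng.permutation(x))])
        assert abs(out["rho"][0]) < 0.2

    def test_constant_variable_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            st.spearman_fdr([("flat", np.ones(10), np.arange(10.0))])

    def test_pairwise_missing_dropped(self):
        x = np.array([1, 2, 3, 4, 5, np.nan, 7.0])
        y = np.array([2, 1, 4, 3, 6, 5, np.nan])
        out = st.spearman_fdr([("m", x, y)])
        assert out["n"][0] == 5


class TestChiSquare:
    def test_printed_sex_table(self):
        r = st.chi_square_2x2([[12, 9], [11, 10]], continuity=True)
        assert round(r.statistic, 2) == 0.00 and r.p == pytest.approx(1.0)

    def test_proportional_table_zero(self):
        r = st.chi_square_2x2([[10, 20], [30, 60]], continuity=False)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_table_uncorrected(self):
        r = st.chi_square_2x2([[10, 0], [0, 10]], continuity=False)
        assert r.statistic == pytest.approx(20.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            st.chi_square_2x2([[0, 0], [5, 5]])


class TestSensitivity:
    def test_power_approaching_alpha_shrinks_d(self):
        d_small = st.min_detectable_effect(21, 21, alpha=0.05, power=0.051, tails=1)
        assert d_small < 0.05

    def test_monotone_in_power(self):
        d80 = st.min_detectable_effect(21, 21, power=0.80, tails=1)
        d95 = st.min_detectable_effect(21, 21, power=0.95, tails=1)
        assert d95 > d80

    def test_monte_carlo_power_at_returned_d(self, rng):
        """Simulated two-sample t at the returned d attains ~80% power."""
        d = st.min_detectable_effect(21, 21, alpha=0.05, power=0.80, tails=1)
        from scipy.stats import ttest_ind

        n_rep = 4000
        a = rng.standard_normal((n_rep, 21)) + d
        b = rng.standard_normal((n_rep, 21))
        t, p = ttest_ind(a, b, axis=1)
        hits = ((p / 2 < 0.05) & (t > 0)).mean()
        assert hits == pytest.approx(0.80, abs=0.02)

    def test_degenerate_power_rejected(self):
        with pytest.raises(ValueError):
            st.min_detectable_effect(21, 21, alpha=0.05, power=0.04)
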