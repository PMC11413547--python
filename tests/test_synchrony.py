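"""Tests for per-user synchrony metrics and the group-level tests."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from affsync import synchrony as sy
from affsync import wavelet_core as wc
from affsync.synthetic_data import simulate_pair
from _oracles import rm_anova_f, paired_t


def _constructed_cross(n=64, n_sig=10):
    """CrossSpectrum with a hand-built significance mask for count oracles."""
    grid = wc.WaveletGrid.for_length(n)
    rng = np.random.default_rng(0)
    sp = wc.morlet_cwt(rng.standard_normal(n), grid)
    cross = wc.xwt(sp, wc.morlet_cwt(rng.standard_normal(n), grid))
    rel = wc.reliable_mask(grid, cross.coi)
    mask = np.zeros_like(rel)
    idx = np.argwhere(rel)[:n_sig]
    mask[idx[:, 0], idx[:, 1]] = True
    cross.sig_power = mask
    cross.sig_coherence = mask.copy()
    return cross, rel


class TestFractions:
    def test_all_false_mask_gives_zero(self):
        cross, _ = _constructed_cross(n_sig=0)
        assert sy.common_power_fraction(cross) == 0.0
        assert sy.coherence_fraction(cross) == 0.0

    def test_all_reliable_significant_gives_one(self):
        cross, rel = _constructed_cross()
        cross.sig_power = rel.copy()
        assert sy.common_power_fraction(cross) == 1.0

    def test_fraction_equals_direct_count(self):
        cross, rel = _constructed_cross(n_sig=17)
        expected = 17 / rel.sum()
        assert sy.common_power_fraction(cross) == pytest.approx(expected)

    def test_missing_mask_rejected(self):
        cross, _ = _constructed_cross()
        cross.sig_power = None
        with pytest.raises(ValueError):
            sy.common_power_fraction(cross)


class TestCircularMean:
    def test_symmetric_pair_averages_to_zero(self):
        assert sy.circular_mean_deg(np.radians([10, -10])) == pytest.approx(0.0)

    def test_wraparound_at_antiphase(self):
        assert abs(sy.circular_mean_deg(np.radians([170, -170]))) == pytest.approx(180.0)

    @given(st.floats(-170, 170))
    def test_rotation_equivariant(self, theta):
        base = np.radians(np.array([20.0, -40.0, 55.0, 10.0]))
        m0 = sy.circular_mean_deg(base)
        m1 = sy.circular_mean_deg(base + np.radians(theta))
        diff = (m1 - m0 - theta + 180) % 360 - 180
        assert abs(diff) < 1e-6


class TestMeanRpAngle:
    def test_no_significant_points_is_missing(self):
        cross, _ = _constructed_cross(n_sig=0)
        assert np.isnan(sy.mean_rp_angle(cross))

    def test_quarter_period_lead_recovered(self):
        u = simulate_pair(512, 0.9, np.pi / 2, 24, 0.3, 0.3, 0.0, seed=3)
        m, _ = sy.analyze_pair(u.self_sentiment, u.peer_sentiment, compute_wtc=False)
        assert 75 < m.rp_angle_deg < 105


class TestBandFractions:
    def test_all_false_mask(self):
        cross, _ = _constructed_cross(n=128, n_sig=0)
        out = sy.band_fractions(cross)
        assert all(v == 0.0 for v in out.values())

    def test_band_isolation_at_period_24(self):
        cross, rel = _constructed_cross(n=128, n_sig=0)
        periods = cross.grid.periods
        row = np.argmin(np.abs(periods - 24))
        mask = np.zeros_like(rel)
        mask[row] = rel[row]
        cross.sig_power = mask
        out = sy.band_fractions(cross)
        assert out["low"] > 0
        assert out["medium"] == 0.0 and out["high"] == 0.0

    def test_band_without_rows_rejected(self):
        cross, _ = _constructed_cross(n=64)
        bands = sy.BandDefinition(low=(500.0, 600.0))
        with pytest.raises(ValueError, match="no rows"):
            sy.band_fractions(cross, bands)

    def test_simulated_low_band_coupling_dominates(self):
        wins = 0
        for s in range(8):
            u = simulate_pair(300, 0.8, 0.0, 24, 0.3, 0.5, 0.0, seed=s)
            m, _ = sy.analyze_pair(u.self_sentiment, u.peer_sentiment, compute_wtc=False)
            wins += m.band_common_power["low"] > m.band_common_power["high"]
        assert wins >= 7


class TestShuffledBaseline:
    def test_metrics_in_range_and_reduced(self):
        u = simulate_pair(300, 0.8, 0.0, 24, 0.3, 0.5, 0.0, seed=1)
        real, _ = sy.analyze_pair(u.self_sentiment, u.peer_sentiment, compute_wtc=False)
        shuf, _ = sy.shuffled_baseline(u, seed=2, compute_wtc=False)
        assert 0 <= shuf.common_power_frac <= 1
        assert shuf.common_power_frac < real.common_power_frac

    def test_coupled_cohort_real_exceeds_shuffled(self):
        wins = 0
        for s in range(10):
            u = simulate_pair(256, 0.8, 0.0, 24, 0.3, 0.5, 0.0, seed=100 + s)
            real, _ = sy.analyze_pair(u.self_sentiment, u.peer_sentiment, compute_wtc=False)
            shuf, _ = sy.shuffled_baseline(u, seed=200 + s, compute_wtc=False)
            wins += real.common_power_frac > shuf.common_power_frac
        assert wins >= 9

    def test_unknown_strategy_rejected(self):
        u = simulate_pair(128, 0.5, 0.0, 24, 0.3, 0.5, 0.0, seed=1)
        with pytest.raises(ValueError):
            sy.shuffled_baseline(u, seed=0, strategy="bogus")


class TestCouplingMonotonicity:
    def test_mean_coherence_fraction_nondecreasing_in_coupling(self):
        # shared Monte Carlo thresholds (same n, same generating AR
        # coefficient) applied across all three coupling cohorts
        n = 256
        grid = wc.WaveletGrid.for_length(n)
        crit = wc.wtc_significance_mc(0.3, 0.3, n, grid, nsim=100, seed=50)
        means = []
        for coupling in (0.0, 0.4, 0.8):
            fracs = []
            for s in range(30):
                u = simulate_pair(n, coupling, 0.0, 24.0, 0.3, 0.5, 0.0, seed=300 + s)
                m, _ = sy.analyze_pair(
                    u.self_sentiment, u.peer_sentiment,
                    grid=grid, compute_wtc=True, wtc_crit=crit,
                )
                fracs.append(m.coherence_frac)
            means.append(np.mean(fracs))
        assert means[0] <= means[1] <= means[2]
        assert means[2] > means[0]


class TestPairedSynchronyTest:
    def test_identical_vectors_rejected_zero_variance(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError):
            sy.paired_synchrony_test(x, x)

    def test_null_difference_gives_t_zero(self, rng):
        a = rng.standard_normal(30)
        shift = rng.standard_normal(30)
        res = sy.paired_synchrony_test(a + shift - shift.mean() * 0, a)
        # same data re-centred: t is finite and p in [0,1]
        assert 0.0 <= res.p <= 1.0

    def test_one_sd_shift_gives_unit_dz(self, rng):
        base = rng.standard_normal(199)
        noise = rng.standard_normal(199)
        diff = noise / noise.std(ddof=1) + 1.0  # mean 1, sd 1 in expectation
        res = sy.paired_synchrony_test(base + diff, base)
        assert res.d_z == pytest.approx(diff.mean() / diff.std(ddof=1), abs=1e-12)
        assert res.t == pytest.approx(res.d_z * np.sqrt(199), rel=1e-10)

    def test_matches_textbook_formulas(self, rng):
        a, b = rng.standard_normal(40), rng.standard_normal(40)
        res = sy.paired_synchrony_test(a, b)
        t_ref, p_ref = paired_t(a, b)
        assert res.t == pytest.approx(t_ref, abs=1e-10)
        assert res.p == pytest.approx(p_ref, abs=1e-10)
        assert res.df == 39
        d_av_ref = (a - b).mean() / ((a.std(ddof=1) + b.std(ddof=1)) / 2)
        assert res.d_av == pytest.approx(d_av_ref, abs=1e-12)


class TestBandAnova:
    def test_identical_band_values_give_f_zero(self):
        y = np.tile(np.random.default_rng(1).standard_normal(10)[:, None], (1, 3))
        res = sy.band_anova(y)
        assert res.F == 0.0
        assert res.p == 1.0

    def test_shifted_low_band_detected(self):
        rng = np.random.default_rng(77)
        y = rng.standard_normal((40, 3))
        y[:, 0] += 1.0
        res = sy.band_anova(y, ("low", "medium", "high"))
        assert res.p < 0.01
        t_lh, p_lh = res.pairwise[("low", "high")]
        assert p_lh < 0.01 and t_lh > 0

    def test_matches_bruteforce_ss(self, rng):
        y = rng.standard_normal((25, 3))
        res = sy.band_anova(y)
        f_ref, df1, df2 = rm_anova_f(y)
        assert res.F == pytest.approx(f_ref, abs=1e-8)
        assert (res.df1, res.df2) == (df1, df2)

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        y = rng.standard_normal((20, 3))
        res = sy.band_anova(y)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(20), 3),
                "band": np.tile(["low", "med", "high"], 20),
                "value": y.ravel(),
            }
        )
        ref = pg.rm_anova(data=long, dv="value", within="band", subject="subject")
        assert res.F == pytest.approx(float(ref["F"].iloc[0]), rel=1e-6)
        assert res.p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            sy.band_anova(np.ones((2, 3)))
        with pytest.raises(ValueError):
            sy.band_anova(np.full((5, 3), np.nan))


class TestCorrelateMetrics:
    def test_self_correlation_is_one(self, rng):
        import pandas as pd

        df = pd.DataFrame({"a": rng.standard_normal(30)})
        df["b"] = df["a"]
        out = sy.correlate_metrics(df)
        assert out.loc[("a", "r"), "b"] == pytest.approx(1.0)

    def test_matches_reference_correlation(self, rng):
        import pandas as pd
        from scipy.stats import pearsonr

        df = pd.DataFrame(rng.standard_normal((50, 3)), columns=["x", "y", "z"])
        out = sy.correlate_metrics(df)
        for a in df.columns:
            for b in df.columns:
                if a != b:
                    r_ref, p_ref = pearsonr(df[a], df[b])
                    assert out.loc[(a, "r"), b] == pytest.approx(r_ref, abs=1e-12)
                    assert out.loc[(a, "p"), b] == pytest.approx(p_ref, abs=1e-12)

    def test_listwise_deletion_minimum(self):
        import pandas as pd

        df = pd.DataFrame({"a": [1.0, np.nan, 2.0], "b": [1.0, 2.0, np.nan]})
        with pytest.raises(ValueError):
            sy.correlate_metrics(df)
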