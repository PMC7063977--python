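"""Michaelis–Menten fitting, efficiency/fold arithmetic and half-life estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flexistab import synthetic as syn
from flexistab.kinetics import (
    LN2,
    FirstOrderDecay,
    InactivationSeries,
    KineticDataset,
    MichaelisMentenRegressor,
    catalytic_efficiency,
    estimate_half_life,
    fit_michaelis_menten,
    fold_change,
    read_inactivation_csv,
    read_kinetics_csv,
    residual_activity_gain,
)
from flexistab.synthetic import SUBSTRATE_DOUBLING_SERIES_MM, TIME_GRID_60C_MIN


def mm_rates(vmax, km, s):
    s = np.asarray(s, dtype=float)
    return vmax * s / (km + s)


def grid_search_halflife(t, r, k_lo=1e-4, k_hi=1.0, n=20000):
    """Independent oracle: dense grid over k, free intercept, log-space SSE."""
    t, r = np.asarray(t, float), np.asarray(r, float)
    keep = r > 0
    t, logr = t[keep], np.log(r[keep])
    ks = np.linspace(k_lo, k_hi, n)
    best_k, best_sse = None, np.inf
    for k in ks:
        intercept = np.mean(logr + k * t)
        sse = np.sum((logr - (intercept - k * t)) ** 2)
        if sse < best_sse:
            best_k, best_sse = k, sse
    return LN2 / best_k


class TestMichaelisMentenFit:
    def test_exact_data_recovers_parameters(self):
        s = SUBSTRATE_DOUBLING_SERIES_MM
        assert s[0] == 10.0 and s[-1] == 0.078125  # the standard dilution endpoints
        v = mm_rates(714.29, 0.36, s)
        for method in ("lineweaver-burk", "nonlinear"):
            ds = KineticDataset("wt", np.array(s), v)
            fit = fit_michaelis_menten(ds, method=method)
            assert fit.vmax_U_per_mg == pytest.approx(714.29, rel=1e-6)
            assert fit.km_mM == pytest.approx(0.36, rel=1e-6)
            assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    @settings(deadline=None, max_examples=50)
    @given(
        vmax=st.floats(1.0, 5000.0),
        km=st.floats(0.01, 50.0),
    )
    def test_lb_exact_for_any_positive_parameters(self, vmax, km):
        s = np.array(SUBSTRATE_DOUBLING_SERIES_MM)
        est = MichaelisMentenRegressor("lineweaver-burk").fit(s, mm_rates(vmax, km, s))
        assert est.vmax_ == pytest.approx(vmax, rel=1e-8)
        assert est.km_ == pytest.approx(km, rel=1e-8)

    def test_zero_rate_raises(self):
        s = np.array([0.1, 1.0, 10.0])
        with pytest.raises(ValueError, match="reciprocal undefined"):
            MichaelisMentenRegressor().fit(s, np.array([0.0, 5.0, 9.0]))

    def test_non_hyperbolic_raises(self):
        s = np.array([1.0, 2.0, 4.0])
        v = np.array([1.0, 4.0, 16.0])  # superlinear -> negative 1/Vmax intercept
        with pytest.raises(ValueError, match="not hyperbolic"):
            MichaelisMentenRegressor().fit(s, v)

    def test_noisy_replicates_km_recovery(self):
        """2% multiplicative noise: median Km error < 10%, LB ~ nonlinear oracle."""
        km_err, disagreement = [], []
        for seed in range(100):
            df, truth = syn.gen_kinetics(seed=seed, noise_cv=0.02)
            s = df["substrate_mM"].to_numpy()
            v = df["rate_U_per_mg"].to_numpy()
            lb = MichaelisMentenRegressor("lineweaver-burk").fit(s, v)
            nl = MichaelisMentenRegressor("nonlinear").fit(s, v)
            km_err.append(abs(lb.km_ - truth["km_mM"]) / truth["km_mM"])
            disagreement.append(abs(lb.km_ - nl.km_) / nl.km_)
        assert np.median(km_err) < 0.10
        assert np.median(disagreement) < 0.10

    def test_predict_reproduces_hyperbola(self):
        s = np.array(SUBSTRATE_DOUBLING_SERIES_MM)
        est = MichaelisMentenRegressor().fit(s, mm_rates(500.0, 0.45, s))
        assert np.allclose(est.predict(s), mm_rates(500.0, 0.45, s), rtol=1e-8)

    def test_derived_kcat_labelled(self):
        s = np.array(SUBSTRATE_DOUBLING_SERIES_MM)
        ds = KineticDataset("wt", s, mm_rates(714.29, 0.36, s))
        fit = fit_michaelis_menten(ds, molar_mass_kDa=39.5)
        assert fit.kcat_source == "derived"
        assert fit.kcat_per_s == pytest.approx(714.29 * 39.5 / 60.0, rel=1e-6)
        fit2 = fit_michaelis_menten(ds, kcat_per_s=188.10)
        assert fit2.kcat_source == "supplied"
        assert fit2.efficiency_per_s_per_mM == pytest.approx(188.10 / fit2.km_mM)

    def test_dataset_validation(self):
        with pytest.raises(ValueError):
            KineticDataset("x", [1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            KineticDataset("x", [1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            KineticDataset("x", [0.0, 1.0, 2.0], [1.0, 2.0, 3.0])


class TestEfficiencyAndFolds:
    @pytest.mark.parametrize(
        "kcat,km,expected",
        [(188.10, 0.36, 522.5), (184.86, 0.29, 637.45), (187.95, 0.29, 648.1)],
    )
    def test_published_table_rows(self, kcat, km, expected):
        assert catalytic_efficiency(kcat, km) == pytest.approx(expected, abs=0.5)

    def test_zero_kcat(self):
        assert catalytic_efficiency(0.0, 1.0) == 0.0

    def test_invalid_km_raises(self):
        with pytest.raises(ValueError, match="invalid Km"):
            catalytic_efficiency(100.0, 0.0)

    @pytest.mark.parametrize(
        "mut,wt,expected",
        [(637.45, 522.50, 1.22), (648.10, 522.50, 1.24), (0.45, 0.36, 1.25)],
    )
    def test_published_fold_changes(self, mut, wt, expected):
        assert round(fold_change(mut, wt), 2) == expected

    def test_fold_identity_and_reciprocal(self):
        assert fold_change(7.0, 7.0) == 1.0
        assert fold_change(3.0, 5.0) * fold_change(5.0, 3.0) == pytest.approx(1.0)

    def test_zero_denominator_raises(self):
        with pytest.raises(ValueError, match="undefined ratio"):
            fold_change(1.0, 0.0)


class TestHalfLife:
    def test_exact_exponential(self):
        t = np.array(TIME_GRID_60C_MIN, dtype=float)
        series = InactivationSeries("wt", 60.0, t, 100 * np.exp(-LN2 / 30 * t))
        est = estimate_half_life(series, method="first-order-fit")
        assert est.t_half_min == pytest.approx(30.0, rel=1e-9)
        assert est.t_half_min == pytest.approx(LN2 / est.k_per_min, rel=1e-12)

    def test_nearest_timepoint_reads_off_published_course(self):
        # 60 C wild-type course: 53.28% at 25 min is the closest point to 50%
        t = np.array([1, 3, 6, 10, 15, 20, 25, 30, 35, 45, 60, 75, 90], float)
        r = 100 * np.exp(-LN2 / 27.0 * t)
        r[t == 25] = 53.28
        series = InactivationSeries("wt", 60.0, t, r)
        est = estimate_half_life(series, method="nearest-timepoint")
        assert est.t_half_min == 25.0

    def test_nearest_timepoint_tie_takes_earlier(self):
        series = InactivationSeries("e", 60.0, np.array([10.0, 20.0]),
                                    np.array([55.0, 45.0]))
        assert estimate_half_life(series, "nearest-timepoint").t_half_min == 10.0

    def test_no_decay_raises(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="no decay"):
            estimate_half_life(InactivationSeries("e", 50.0, t, np.array([90, 95, 99, 104.0])))

    def test_all_nonpositive_residuals_raise(self):
        t = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="invalid series"):
            estimate_half_life(InactivationSeries("e", 50.0, t, np.zeros(3)))

    def test_noisy_decays_match_grid_search_oracle(self):
        rel_err = []
        for seed in range(50):
            df, truth = syn.gen_decay(seed=seed, noise_cv=0.02,
                                      k_per_min=LN2 / 40.0, temperature_C=60.0)
            series = InactivationSeries("e", 60.0, df["time_min"].to_numpy(),
                                        df["residual_pct"].to_numpy())
            est = estimate_half_life(series)
            oracle = grid_search_halflife(series.time_min, series.residual_pct,
                                          k_lo=0.001, k_hi=0.1, n=5000)
            assert est.t_half_min == pytest.approx(oracle, rel=2e-2)
            rel_err.append(abs(est.t_half_min - truth["t_half_min"]) / truth["t_half_min"])
        assert np.median(rel_err) < 0.05

    def test_series_validation(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            InactivationSeries("e", 50.0, np.array([5.0, 5.0]), np.array([90.0, 80.0]))
        with pytest.warns(UserWarning, match="110"):
            InactivationSeries("e", 50.0, np.array([5.0]), np.array([120.0]))


class TestResidualGain:
    def _series(self, residual_120):
        t = np.array([5.0, 120.0])
        return InactivationSeries("e", 50.0, t, np.array([95.0, residual_120]))

    @pytest.mark.parametrize("mut,wt,expected", [(66.12, 28.24, 37.88),
                                                 (76.44, 28.24, 48.20)])
    def test_published_gains(self, mut, wt, expected):
        gain = residual_activity_gain(self._series(mut), self._series(wt), 120.0)
        assert gain == pytest.approx(expected, abs=1e-9)

    def test_identical_series_zero_gain(self):
        s = self._series(40.0)
        assert residual_activity_gain(s, s, 120.0) == 0.0

    def test_unsampled_time_raises(self):
        with pytest.raises(ValueError, match="time not sampled"):
            residual_activity_gain(self._series(40.0), self._series(30.0), 60.0)


def test_csv_readers_round_trip(tmp_path):
    kdf, _ = syn.gen_kinetics(seed=4, enzyme_id="wt")
    kpath = tmp_path / "kinetics.csv"
    kdf.to_csv(kpath, index=False)
    (ds,) = read_kinetics_csv(kpath)
    assert ds.enzyme_id == "wt" and ds.substrate_mM.size == 8

    ddf, _ = syn.gen_decay(seed=4, enzyme_id="wt", temperature_C=60.0)
    dpath = tmp_path / "decay.csv"
    ddf.to_csv(dpath, index=False)
    (series,) = read_inactivation_csv(dpath)
    assert series.temperature_C == 60.0
    assert series.time_min.size == len(TIME_GRID_60C_MIN)


def test_decay_estimator_consistency_as_noise_shrinks():
    errs = []
    for cv in (0.10, 0.02, 0.0):
        df, truth = syn.gen_decay(seed=77, noise_cv=cv, k_per_min=LN2 / 30.0)
        est = FirstOrderDecay().fit(df["time_min"], df["residual_pct"])
        errs.append(abs(est.t_half_ - 30.0))
    assert errs[-1] < 1e-9
    assert errs[2] <= errs[1] <= errs[0] + 1e-12
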