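"""Isotherm model evaluation, fitting, and diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bindkit import isotherm as iso
from bindkit import synthetic as syn
from bindkit.datasets import AdsorptionDataset
from bindkit.isotherm import IsothermParams


class TestEval:
    @pytest.mark.parametrize("model,params,F,expected", [
        ("one_site", IsothermParams(4.34, 8.69), 8.69, 2.17),
        ("langmuir_freundlich", IsothermParams(4.80, 6.90, m=0.77), 6.90, 2.40),
        ("one_site", IsothermParams(4.34, 8.69), 0.0, 0.0),
        ("two_site", IsothermParams(4.14, 13.68, 0.42, 0.13), 0.0, 0.0),
        ("langmuir_freundlich", IsothermParams(4.80, 6.90, m=0.77), 0.0, 0.0),
    ])
    def test_known_values(self, model, params, F, expected):
        assert iso.eval_isotherm(model, params, F) == pytest.approx(expected)

    def test_errors(self):
        p = IsothermParams(4.0, 8.0)
        with pytest.raises(ValueError):
            iso.eval_isotherm("one_site", p, -1.0)
        with pytest.raises(ValueError):
            iso.eval_isotherm("bet", p, 1.0)
        with pytest.raises(ValueError):
            iso.eval_isotherm("langmuir_freundlich", p, 1.0)  # missing m

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        n_max=st.floats(0.5, 10.0), K_d=st.floats(0.1, 100.0),
        m=st.floats(0.2, 2.0),
        model=st.sampled_from(iso.MODELS),
    )
    def test_monotone_and_bounded(self, n_max, K_d, m, model):
        params = IsothermParams(n_max, K_d, n_max_2=0.3 * n_max,
                                K_d_2=0.1 * K_d, m=m)
        F = np.geomspace(1e-3, 1e4, 100)
        B = iso.eval_isotherm(model, params, F)
        assert np.all(np.diff(B) >= -1e-12)
        assert np.all(B < params.total_capacity() + 1e-9)


class TestFit:
    @pytest.mark.parametrize("model,params", [
        ("one_site", IsothermParams(3.32, 10.55)),
        ("two_site", IsothermParams(4.14, 13.68, 0.42, 0.13)),
        ("langmuir_freundlich", IsothermParams(4.80, 6.90, m=0.77)),
    ])
    def test_noiseless_round_trip(self, model, params):
        d = syn.gen_isotherm(
            syn.IsothermGenConfig(model_id=model, params=params, noise_sd=0.0)
        )
        r = iso.fit_isotherm(d, model)
        assert r.converged
        for name in ("n_max", "K_d", "n_max_2", "K_d_2", "m"):
            truth = getattr(params, name)
            if truth is None:
                continue
            assert getattr(r.params, name) == pytest.approx(truth, rel=1e-4)

    def test_nested_model_rmse(self):
        d = syn.gen_isotherm(
            syn.IsothermGenConfig(params=IsothermParams(4.34, 8.69),
                                  noise_sd=0.1, seed=2)
        )
        r1 = iso.fit_isotherm(d, "one_site")
        r2 = iso.fit_isotherm(d, "two_site")
        assert r2.rmse <= r1.rmse + 1e-9

    def test_non_identifiable_inputs(self):
        with pytest.raises(ValueError, match="non-identifiable"):
            iso.fit_isotherm(
                AdsorptionDataset(np.linspace(1, 10, 10), np.zeros(10)), "one_site"
            )
        with pytest.raises(ValueError, match="non-identifiable"):
            iso.fit_isotherm(
                AdsorptionDataset(np.linspace(1, 10, 10), np.full(10, 2.0)),
                "one_site",
            )

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            iso.fit_isotherm(
                AdsorptionDataset([1.0, 2.0, 3.0], [0.1, 0.2, 0.3]), "one_site"
            )

    def test_sklearn_interface(self):
        est = iso.IsothermRegressor(model="one_site")
        assert est.get_params()["model"] == "one_site"
        d = syn.gen_isotherm(
            syn.IsothermGenConfig(params=IsothermParams(4.0, 10.0), noise_sd=0.0)
        )
        est.fit(d.free, d.bound)
        pred = est.predict([10.0])
        assert pred[0] == pytest.approx(2.0, rel=1e-3)


class TestPartitionCoefficient:
    # low-concentration grid so the through-origin slope sits in the
    # linear region (the estimator's relative bias is ~F/(K_d + F))
    _grid = tuple(np.linspace(0.01, 0.1, 8)) + (1.0, 10.0, 100.0)

    def test_low_concentration_limit(self):
        d = syn.gen_isotherm(
            syn.IsothermGenConfig(params=IsothermParams(4.34, 8.69),
                                  free_grid=self._grid, noise_sd=0.0)
        )
        res = iso.partition_coefficient(d, max_free=0.1)
        assert res["slope"] == pytest.approx(4.34 / 8.69, rel=0.03)

    def test_slope_converges_to_nmax_over_kd(self):
        # partition coefficient -> n_max/K_d as max_free -> 0
        grid = tuple(np.geomspace(1e-3, 5.0, 40))
        d = syn.gen_isotherm(
            syn.IsothermGenConfig(params=IsothermParams(4.34, 8.69),
                                  free_grid=grid, noise_sd=0.0)
        )
        errs = [
            abs(iso.partition_coefficient(d, mf)["slope"] - 4.34 / 8.69)
            for mf in (5.0, 0.5, 0.05)
        ]
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 0.003

    def test_substrate_ordering(self):
        # cellulose I one-site slope exceeds cellulose III: reduced binding
        dI = syn.gen_isotherm(
            syn.IsothermGenConfig(params=IsothermParams(4.34, 8.69),
                                  free_grid=self._grid, noise_sd=0.0)
        )
        dIII = syn.gen_isotherm(
            syn.IsothermGenConfig(params=IsothermParams(3.32, 10.55),
                                  free_grid=self._grid, noise_sd=0.0)
        )
        sI = iso.partition_coefficient(dI, 0.1)["slope"]
        sIII = iso.partition_coefficient(dIII, 0.1)["slope"]
        assert sI == pytest.approx(0.499, abs=0.01)
        assert sIII == pytest.approx(0.315, abs=0.01)
        assert sI > sIII

    def test_empty_region(self):
        d = AdsorptionDataset([10.0, 20.0, 30.0, 40.0], [1, 2, 3, 4])
        with pytest.raises(ValueError):
            iso.partition_coefficient(d, max_free=1.0)


class TestTruncation:
    def test_cutoff_beyond_max_is_full_fit(self):
        d = syn.gen_isotherm(
            syn.IsothermGenConfig(params=IsothermParams(4.0, 10.0),
                                  noise_sd=0.05, seed=4)
        )
        full, again = iso.truncate_and_fit(d, [1e6], "one_site")
        assert again.params.K_d == pytest.approx(full.params.K_d, rel=1e-9)
        assert again.n_points == full.n_points

    def test_truncation_inflates_kd_standard_error(self):
        d = syn.gen_isotherm(
            syn.IsothermGenConfig(params=IsothermParams(4.0, 10.0),
                                  noise_sd=0.1, seed=5)
        )
        full, trunc = iso.truncate_and_fit(d, [3.0], "one_site")
        assert trunc.std_errors["K_d"] > full.std_errors["K_d"]

    def test_nmax_decreases_with_tighter_truncation(self):
        # one-site refits of multi-site data lose apparent capacity as the
        # high-concentration tail is trimmed (truncation-sensitivity signature)
        params = IsothermParams(4.14, 13.68, 0.42, 0.13)
        d = syn.gen_isotherm(
            syn.IsothermGenConfig(model_id="two_site", params=params, noise_sd=0.0)
        )
        full, at50, at15 = iso.truncate_and_fit(d, [50.0, 15.0], "one_site")
        assert full.params.n_max > at50.params.n_max > at15.params.n_max
        # ~1.3- to 1.8-fold reduction range
        assert 1.2 < full.params.n_max / at15.params.n_max < 2.0

    def test_bad_cutoff(self):
        d = syn.gen_isotherm(
            syn.IsothermGenConfig(params=IsothermParams(4.0, 10.0), noise_sd=0.0)
        )
        with pytest.raises(ValueError):
            iso.truncate_and_fit(d, [-1.0], "one_site")
        with pytest.raises(ValueError):
            iso.truncate_and_fit(d, [1e-6], "one_site")  # excludes all points


class TestScatchard:
    def test_one_site_is_linear(self):
        d = syn.gen_isotherm(
            syn.IsothermGenConfig(params=IsothermParams(4.34, 8.69), noise_sd=0.0)
        )
        res = iso.scatchard_diagnostic(d)
        assert res["curvature_sign"] == 0

    def test_two_site_concave_up(self):
        params = IsothermParams(4.14, 13.68, 0.42, 0.13)
        d = syn.gen_isotherm(
            syn.IsothermGenConfig(model_id="two_site", params=params, noise_sd=0.0)
        )
        res = iso.scatchard_diagnostic(d)
        assert res["quadratic_coef"] > 0
        assert res["curvature_sign"] == 1

    def test_zero_free_excluded_with_warning(self):
        d = AdsorptionDataset([0.0, 1, 2, 4, 8, 16],
                              [0.0, 0.4, 0.7, 1.1, 1.5, 1.8])
        with pytest.warns(UserWarning):
            res = iso.scatchard_diagnostic(d)
        assert res["points"].shape[0] == 5


class TestAffinityFoldChange:
    def _fit(self, model, params):
        return iso.IsothermFitResult(model_id=model, params=params, converged=True)

    def test_one_site_fold(self):
        a = self._fit("one_site", IsothermParams(4.34, 8.69))
        b = self._fit("one_site", IsothermParams(3.32, 10.55))
        assert iso.affinity_fold_change(a, b) == pytest.approx(1.214, abs=0.001)

    def test_two_site_high_affinity_fold(self):
        a = self._fit("two_site", IsothermParams(4.14, 13.68, 0.42, 0.13))
        b = self._fit("two_site", IsothermParams(2.81, 25.06, 0.75, 0.92))
        assert iso.affinity_fold_change(a, b, site="high_affinity") == pytest.approx(
            7.08, abs=0.01
        )

    def test_identity_and_mismatch(self):
        a = self._fit("one_site", IsothermParams(4.0, 8.0))
        assert iso.affinity_fold_change(a, a) == 1.0
        b = self._fit("two_site", IsothermParams(4.0, 8.0, 0.4, 0.1))
        with pytest.raises(ValueError):
            iso.affinity_fold_change(a, b)


def test_noisy_recovery_within_reported_se():
    # one-site estimates fall within 3 reported SE of truth in >= 90% of seeds
    p = IsothermParams(4.34, 8.69)
    ok = 0
    n_seeds = 25
    for seed in range(n_seeds):
        d = syn.gen_isotherm(
            syn.IsothermGenConfig(params=p, noise_sd=0.1, seed=seed)
        )
        r = iso.fit_isotherm(d, "one_site")
        ok += (
            r.converged
            and abs(r.params.n_max - p.n_max) <= 3 * r.std_errors["n_max"]
            and abs(r.params.K_d - p.K_d) <= 3 * r.std_errors["K_d"]
        )
    assert ok >= 0.9 * n_seeds
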