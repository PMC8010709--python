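"""Generator-level checks: determinism, closed-form moments, model anchors."""

import numpy as np
import pytest

from bindkit import synthetic as syn
from bindkit.isotherm import IsothermParams


class TestMotilityTraceGen:
    def test_pure_forward_velocity_matches_renewal_rate(self):
        # noiseless, no back-steps: net velocity -> E[step]/dwell_mean
        cfg = syn.TraceGenConfig(
            dwell_mean=0.5, back_step_prob=0.0, noise_sd=0.0,
            duration=400.0, sample_rate=100.0, seed=11,
        )
        tr = syn.gen_motility_trace(cfg)
        v = (tr.position[-1] - tr.position[0]) / tr.duration
        # MC SE of the renewal rate: sqrt(E[s^2] / (dwell * T))
        se = np.sqrt(1.0 / (0.5 * 400.0))
        assert v == pytest.approx(1.0 / 0.5, abs=3 * se)

    def test_backstep_velocity_closed_form(self):
        # (1 - 2p) * step / dwell = (1 - 0.7) / 0.75 = 0.40 nm/s
        n_rep, T = 20, 100.0
        vs = []
        for seed in range(n_rep):
            cfg = syn.TraceGenConfig(
                dwell_mean=0.75, back_step_prob=0.35, noise_sd=0.0,
                duration=T, sample_rate=100.0, seed=seed,
            )
            tr = syn.gen_motility_trace(cfg)
            vs.append((tr.position[-1] - tr.position[0]) / tr.duration)
        se = np.sqrt(1.0 / (0.75 * T * n_rep))  # E[s^2]=1
        assert np.mean(vs) == pytest.approx((1 - 2 * 0.35) * 1.0 / 0.75, abs=3 * se)

    def test_seed_determinism(self):
        cfg = syn.TraceGenConfig(duration=5.0, seed=42)
        a = syn.gen_motility_trace(cfg)
        b = syn.gen_motility_trace(cfg)
        np.testing.assert_array_equal(a.position, b.position)
        c = syn.gen_motility_trace(syn.TraceGenConfig(duration=5.0, seed=43))
        assert not np.array_equal(a.position, c.position)

    def test_spikes_return_to_baseline(self):
        cfg = syn.TraceGenConfig(duration=20.0, n_spikes=2, noise_sd=0.0,
                                 back_step_prob=0.0, seed=5)
        tr = syn.gen_motility_trace(cfg)
        assert np.max(np.abs(tr.position)) >= 80.0  # ~100 nm excursions
        # baseline restored after the spike window
        i = int(2 * 2 * 0.5 * cfg.sample_rate) + 1
        assert abs(tr.position[i]) < 5.0

    @pytest.mark.parametrize("kwargs", [
        {"dwell_mean": 0.0}, {"sample_rate": 0.0}, {"back_step_prob": 1.5},
        {"step_sizes": ((1.0, 0.5), (2.0, 0.2))},
    ])
    def test_invalid_config(self, kwargs):
        with pytest.raises(ValueError):
            syn.TraceGenConfig(**kwargs)


class TestRuptureGen:
    def test_zero_force_mean_lifetime_is_tau0(self):
        cfg = syn.RuptureGenConfig(
            modes=((2.0, 0.4, 1.0),), force_range=(0.0, 0.0),
            n_events=4000, seed=1,
        )
        ev = syn.gen_rupture_events(cfg)
        se = 2.0 / np.sqrt(4000)
        assert ev.lifetime.mean() == pytest.approx(2.0, abs=3 * se)
        assert np.all(ev.force == 0)

    def test_zero_xdagger_force_independent(self):
        # with x_dagger = 0 the lifetime law does not depend on force
        n_sig = 0
        for seed in range(10):
            cfg = syn.RuptureGenConfig(modes=((1.5, 0.0, 1.0),),
                                       n_events=1000, seed=seed)
            ev = syn.gen_rupture_events(cfg)
            med = np.median(ev.force)
            lo = ev.lifetime[ev.force < med]
            hi = ev.lifetime[ev.force >= med]
            from scipy.stats import mannwhitneyu
            p = mannwhitneyu(lo, hi).pvalue
            n_sig += p < 0.05
        assert n_sig <= 1  # non-significant in >= 90% of runs

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            syn.RuptureGenConfig(n_events=0)
        with pytest.raises(ValueError):
            syn.RuptureGenConfig(modes=((1.0, 0.1, 0.6), (2.0, 0.1, 0.6)))


class TestIsothermGen:
    def test_half_saturation_noiseless(self):
        cfg = syn.IsothermGenConfig(
            params=IsothermParams(4.34, 8.69), free_grid=(8.69,), noise_sd=0.0
        )
        d = syn.gen_isotherm(cfg)
        assert d.bound[0] == pytest.approx(2.17)

    def test_zero_free_gives_zero_bound(self):
        for model, p in [
            ("one_site", IsothermParams(4.0, 8.0)),
            ("two_site", IsothermParams(4.0, 8.0, 0.4, 0.1)),
            ("langmuir_freundlich", IsothermParams(4.0, 8.0, m=0.8)),
        ]:
            cfg = syn.IsothermGenConfig(model_id=model, params=p,
                                        free_grid=(0.0,), noise_sd=0.0)
            assert syn.gen_isotherm(cfg).bound[0] == 0.0

    def test_replicate_mean_clt(self):
        cfg = syn.IsothermGenConfig(
            params=IsothermParams(4.34, 8.69), free_grid=(50.0,),
            noise_sd=0.2, replicates=200, seed=9,
        )
        d = syn.gen_isotherm(cfg)
        truth = 4.34 * 50 / (8.69 + 50)
        se = 0.2 / np.sqrt(200)
        assert d.bound.mean() == pytest.approx(truth, abs=3 * se)

    def test_unknown_model(self):
        with pytest.raises(ValueError):
            syn.IsothermGenConfig(model_id="bet", params=IsothermParams(1, 1))


class TestFrapGen:
    def test_anchor_and_asymptote(self):
        c = syn.gen_frap_curve(0.1, 0.6, baseline=0.2, noise_sd=0.0,
                               t_grid=np.array([0.0, 1e4]))
        assert c.signal[0] == pytest.approx(0.2)
        assert c.signal[1] == pytest.approx(0.8, rel=1e-9)

    def test_half_recovery_time(self):
        k = 0.1
        t = np.linspace(0, 60, 60001)
        c = syn.gen_frap_curve(k, 0.6, baseline=0.2, noise_sd=0.0, t_grid=t)
        span_half = 0.2 + 0.3
        t_half = t[np.argmax(c.signal >= span_half)]
        assert t_half == pytest.approx(np.log(2) / k, abs=2e-3)

    def test_invalid(self):
        with pytest.raises(ValueError):
            syn.gen_frap_curve(0.0, 0.5)
        with pytest.raises(ValueError):
            syn.gen_frap_curve(0.1, 0.5, noise_sd=-1.0)


class TestQcmdGen:
    def test_steady_state_and_rinse_decay(self):
        k_on, k_off, A = 0.13, 4.6e-3, 1e12
        s = syn.gen_qcmd_sensorgram(k_on, k_off, A, phase_times=(300.0, 900.0))
        from bindkit.kinetics import sauerbrey_mass, mass_to_molecules
        gamma = mass_to_molecules(
            sauerbrey_mass(s.signal, overtone=3), area=1.0, molar_mass=45000.0
        )
        g_eq = A * k_on / (k_on + k_off)
        i_pre = np.argmax(s.time >= 299.0)
        assert gamma[i_pre] == pytest.approx(g_eq, rel=1e-6)
        # rinse is a pure exponential at k_off
        rinse = s.time >= 300.0
        tr = s.time[rinse] - 300.0
        slope = np.polyfit(tr, np.log(gamma[rinse]), 1)[0]
        assert -slope == pytest.approx(k_off, rel=1e-6)

    def test_adsorption_relaxation_rate(self):
        # log(Gamma_eq - Gamma(t)) decays linearly at rate k_on* + k_off
        k_on, k_off, A = 0.05, 0.01, 1e12
        s = syn.gen_qcmd_sensorgram(k_on, k_off, A, phase_times=(200.0, 300.0))
        g_eq = A * k_on / (k_on + k_off)
        f_eq = -3 * (g_eq * 45000.0 / 6.02214076e23 * 1e9) / 17.7
        ads = s.time < 60.0
        slope = np.polyfit(s.time[ads], np.log(s.signal[ads] - f_eq), 1)[0]
        assert -slope == pytest.approx(k_on + k_off, rel=1e-6)

    def test_phase_order_error(self):
        with pytest.raises(ValueError):
            syn.gen_qcmd_sensorgram(0.1, 0.01, 1e12, phase_times=(500.0, 400.0))


class TestXrdGen:
    def test_single_peak_position(self):
        p = syn.gen_xrd_pattern([(23.0, 100.0, 0.9)], amorphous=(18.0, 0.0, 8.0))
        assert p.two_theta[np.argmax(p.intensity)] == pytest.approx(23.0, abs=0.02)

    def test_fwhm_round_trip(self):
        from bindkit.xrd import estimate_fwhm
        p = syn.gen_xrd_pattern([(23.0, 100.0, 0.9)], amorphous=(18.0, 0.0, 8.0))
        assert estimate_fwhm(p, 23.0) == pytest.approx(0.9, rel=0.01)

    def test_determinism_and_peak_outside_grid(self):
        a = syn.gen_xrd_pattern([(20.0, 10.0, 1.0)], noise_sd=0.5, seed=3)
        b = syn.gen_xrd_pattern([(20.0, 10.0, 1.0)], noise_sd=0.5, seed=3)
        np.testing.assert_array_equal(a.intensity, b.intensity)
        with pytest.raises(ValueError):
            syn.gen_xrd_pattern([(99.0, 10.0, 1.0)])


def test_streams_are_independent():
    # same master seed, different streams -> different draws
    r1 = syn.stream_rng(7, "trace")
    r2 = syn.stream_rng(7, "rupture")
    assert r1.random() != r2.random()
    # same stream twice -> identical
    assert syn.stream_rng(7, "trace").random() == syn.stream_rng(7, "trace").random()
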