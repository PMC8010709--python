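"""Step detection, dwell/step fitting, velocity, and commitment labels."""

import numpy as np
import pytest

from bindkit import motility as mot
from bindkit import synthetic as syn
from bindkit.datasets import MotilityTrace

from conftest import true_steps_of


def _staircase(step_indices, step_sizes, n, fs=1000.0, noise=0.0, rng=None):
    pos = np.zeros(n)
    for i, s in zip(step_indices, step_sizes):
        pos[i:] += s
    if noise > 0:
        pos = pos + rng.normal(0, noise, n)
    return MotilityTrace(np.arange(n) / fs, pos, fs)


class TestDetectSteps:
    def test_noiseless_staircase_exact(self):
        # 10 steps of +1 nm, 1-s dwells, recovered exactly
        idx = 1000 * np.arange(1, 11)
        tr = _staircase(idx, np.ones(10), 12000)
        s = mot.detect_steps(tr)
        assert s.n_steps == 10
        np.testing.assert_allclose(s.step_sizes, 1.0, atol=1e-9)
        np.testing.assert_allclose(s.dwell_times, 1.0, atol=1e-9)
        np.testing.assert_allclose(
            s.step_times, idx / 1000.0, atol=1.5e-3
        )

    def test_noisy_recall_and_size_error(self):
        matched, total, errs = 0, 0, []
        for seed in (21, 22, 23, 24, 25):
            cfg = syn.TraceGenConfig(dwell_mean=0.75, back_step_prob=0.35,
                                     noise_sd=0.3, duration=40.0, seed=seed)
            tr = syn.gen_motility_trace(cfg)
            true_idx, true_sizes = true_steps_of(cfg)
            s = mot.detect_steps(tr)
            det_idx = np.round(
                (s.step_times - tr.time[0]) * tr.sample_rate
            ).astype(int)
            used = set()
            for ti, tsz in zip(true_idx, true_sizes):
                total += 1
                j = int(np.argmin(np.abs(det_idx - ti)))
                if (abs(det_idx[j] - ti) <= 25 and j not in used
                        and np.sign(s.step_sizes[j]) == np.sign(tsz)):
                    matched += 1
                    used.add(j)
                    errs.append(abs(s.step_sizes[j] - tsz))
        assert matched / total >= 0.9
        assert np.mean(errs) <= 0.1

    def test_flat_noise_false_positive_rate(self):
        # < 1 false step per 100 s of featureless trace
        total_steps = 0
        for seed in range(3):
            rng = np.random.default_rng(seed)
            tr = MotilityTrace(np.arange(100_000) / 1000.0,
                               rng.normal(0, 0.3, 100_000), 1000.0)
            total_steps += mot.detect_steps(tr).n_steps
        assert total_steps < 3

    def test_step_conservation(self, rng):
        cfg = syn.TraceGenConfig(noise_sd=0.3, duration=20.0, seed=8)
        tr = syn.gen_motility_trace(cfg)
        s = mot.detect_steps(tr)
        net_plateau = s.plateau_levels[-1] - s.plateau_levels[0]
        assert s.net_displacement() == pytest.approx(net_plateau, abs=1e-9)

    def test_short_trace_error(self):
        tr = MotilityTrace([0.0, 1e-3, 2e-3], [0.0, 0.0, 0.0], 1000.0)
        with pytest.raises(ValueError):
            mot.detect_steps(tr, min_dwell=0.5)


class TestStepSizeMixture:
    def test_single_gaussian_recovery(self, rng):
        steps = rng.normal(1.0, 0.2, 1000)
        res = mot.fit_step_sizes(steps)
        assert res["forward"]["mu"] == pytest.approx(1.0, abs=0.05)
        assert res["forward"]["weights"][1] < 0.1
        assert res["reverse_fraction"] == 0.0

    def test_two_component_weights(self, rng):
        steps = np.concatenate([
            rng.normal(1.0, 0.15, 800), rng.normal(2.0, 0.2, 200)
        ])
        res = mot.fit_step_sizes(steps)
        assert res["forward"]["weights"][1] == pytest.approx(0.2, abs=0.05)
        assert res["forward"]["mu"] == pytest.approx(1.0, abs=0.05)

    def test_reverse_fraction_counting(self, rng):
        steps = np.concatenate([np.full(65, 1.0), np.full(35, -1.0)])
        rng.shuffle(steps)
        steps = steps + rng.normal(0, 0.05, 100)
        res = mot.fit_step_sizes(steps)
        assert res["reverse_fraction"] == pytest.approx(0.35, abs=0.01)

    def test_too_few_steps(self):
        with pytest.raises(ValueError):
            mot.fit_step_sizes(np.ones(10))


class TestDwellTimes:
    def test_mle_consistency(self, rng):
        d = rng.exponential(0.75, 10_000)
        res = mot.fit_dwell_times(d)
        assert res["tau"] == pytest.approx(0.75, abs=0.02)
        assert res["se"] == pytest.approx(0.75 / 100.0, rel=0.05)

    def test_identical_dwells(self):
        res = mot.fit_dwell_times(np.full(20, 0.6))
        assert res["tau"] == pytest.approx(0.6)

    def test_censoring_corrects_bias(self, rng):
        tau = 1.86  # ~20% of mass beyond a 3-s censor limit
        raw = rng.exponential(tau, 2000)
        obs = np.minimum(raw, 3.0)
        cens = mot.fit_dwell_times(obs, censor_limit=3.0)
        assert abs(cens["tau"] - tau) <= 3 * cens["se"]
        naive = float(np.mean(obs))
        assert naive < tau - 3 * cens["se"]  # naive mean biased low

    def test_histogram_mode(self, rng):
        d = rng.exponential(0.75, 5000)
        res = mot.fit_dwell_times(d, method="histogram")
        assert res["tau"] == pytest.approx(0.75, rel=0.15)

    def test_empty_and_small(self):
        with pytest.raises(ValueError):
            mot.fit_dwell_times([])
        with pytest.raises(ValueError):
            mot.fit_dwell_times([0.1] * 5)


class TestVelocity:
    def test_deterministic_ramp(self):
        t = np.arange(1000) / 100.0
        tr = MotilityTrace(t, 0.25 * t, 100.0)
        assert mot.trace_velocity(tr)["v"] == pytest.approx(0.25, abs=1e-12)

    def test_generated_trace_velocity(self):
        # expected (1 - 2*0.35)/0.75 = 0.40 nm/s
        vs = []
        for seed in range(10):
            cfg = syn.TraceGenConfig(dwell_mean=0.75, back_step_prob=0.35,
                                     noise_sd=0.3, duration=60.0, seed=seed)
            vs.append(mot.trace_velocity(syn.gen_motility_trace(cfg))["v"])
        se = np.sqrt(1.0 / (0.75 * 60.0 * len(vs)))
        assert np.mean(vs) == pytest.approx(0.40, abs=3 * se)


class TestCommitment:
    def test_long_staircase_committed(self):
        cfg = syn.TraceGenConfig(duration=120.0, seed=2, back_step_prob=0.0)
        lab = mot.classify_commitment(syn.gen_motility_trace(cfg))
        assert lab.state == "committed"
        assert lab.motile_duration >= 10.0

    def test_spikes_then_motility_unstable(self):
        cfg = syn.TraceGenConfig(duration=120.0, n_spikes=2, seed=3,
                                 back_step_prob=0.0)
        lab = mot.classify_commitment(syn.gen_motility_trace(cfg))
        assert lab.state == "unstable"
        assert lab.max_excursion >= 50.0

    def test_flat_trace_no_binding(self):
        tr = MotilityTrace(np.arange(20_000) / 1000.0, np.zeros(20_000), 1000.0)
        assert mot.classify_commitment(tr).state == "no_binding"

    def test_offset_invariance(self):
        cfg = syn.TraceGenConfig(duration=60.0, seed=4)
        tr = syn.gen_motility_trace(cfg)
        shifted = MotilityTrace(tr.time, tr.position + 500.0, tr.sample_rate)
        a = mot.classify_commitment(tr)
        b = mot.classify_commitment(shifted)
        assert a.state == b.state
        assert a.motile_duration == pytest.approx(b.motile_duration)


class TestInstabilitySummary:
    def _labels(self, n_unstable, n_committed, n_nobind=0):
        out = [mot.CommitmentLabel("unstable", 0.0, 100.0)] * n_unstable
        out += [mot.CommitmentLabel("committed", 60.0, 5.0)] * n_committed
        out += [mot.CommitmentLabel("no_binding", 0.0, 0.0)] * n_nobind
        return out

    def test_printed_fractions(self):
        # 2/17 -> 11.8% and 3/13 -> 23.1%
        r = mot.instability_summary(self._labels(2, 15))
        assert r["fraction_unstable"] * 100 == pytest.approx(11.76, abs=0.01)
        r = mot.instability_summary(self._labels(3, 10))
        assert r["fraction_unstable"] * 100 == pytest.approx(23.08, abs=0.01)

    def test_zero_and_empty(self):
        assert mot.instability_summary(self._labels(0, 5))["fraction_unstable"] == 0.0
        with pytest.raises(ValueError):
            mot.instability_summary([])

    def test_no_binding_excluded(self):
        r = mot.instability_summary(self._labels(1, 1, n_nobind=8))
        assert r["n"] == 2
        assert r["fraction_unstable"] == 0.5


def test_dwell_and_step_recovery_end_to_end():
    """Detector -> dwell/step fits recover generator truth within 3 SE."""
    all_steps, all_dwells = [], []
    for seed in range(8):
        cfg = syn.TraceGenConfig(dwell_mean=0.75, back_step_prob=0.35,
                                 noise_sd=0.3, duration=40.0, seed=100 + seed)
        s = mot.detect_steps(syn.gen_motility_trace(cfg))
        all_steps.extend(s.step_sizes)
        all_dwells.extend(s.dwell_times)
    dwell = mot.fit_dwell_times(all_dwells)
    # merged short dwells bias tau up slightly; allow 3 SE + merge bias bound
    assert dwell["tau"] == pytest.approx(0.75, abs=3 * dwell["se"] + 0.08)
    steps = mot.fit_step_sizes(all_steps)
    assert steps["forward"]["mu"] == pytest.approx(1.0, abs=0.1)
    n = len(all_steps)
    se_frac = np.sqrt(0.35 * 0.65 / n)
    assert steps["reverse_fraction"] == pytest.approx(0.35, abs=3 * se_frac + 0.03)
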