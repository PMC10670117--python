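"""Synapse kernel, connectivity, drives, and scaling transformation."""

import numpy as np
import pytest

from ca3gamma import (
    ScalingCondition,
    apply_scaling,
    build_connectivity,
    default_config,
    double_exp_kernel,
    double_exp_peak_time,
    ms_theta_drive,
    poisson_events,
)

# (tau1, tau2) pairs used by the synapse and background tables
KINETIC_PAIRS = [(0.05, 5.3), (15.0, 150.0), (0.07, 9.1), (0.2, 20.0),
                 (20.0, 40.0)]


class TestDoubleExpKernel:
    def test_zero_at_onset_and_infinity(self):
        assert double_exp_kernel(0.0, 0.05, 5.3) == pytest.approx(0.0)
        assert double_exp_kernel(1e6, 0.05, 5.3) == pytest.approx(0.0)

    def test_zero_before_onset(self):
        assert np.all(double_exp_kernel([-5.0, -0.1], 0.05, 5.3) == 0.0)

    def test_ampa_peak_time(self):
        # analytic peak t* = tau1·tau2/(tau2−tau1)·ln(tau2/tau1) ≈ 0.235 ms
        tp = double_exp_peak_time(0.05, 5.3)
        assert tp == pytest.approx(0.2355, abs=5e-4)
        t = np.linspace(0, 3, 30001)
        k = double_exp_kernel(t, 0.05, 5.3)
        assert t[np.argmax(k)] == pytest.approx(tp, abs=1e-3)

    @pytest.mark.parametrize("tau1,tau2", KINETIC_PAIRS)
    def test_peak_normalization(self, tau1, tau2):
        tp = double_exp_peak_time(tau1, tau2)
        assert double_exp_kernel(tp, tau1, tau2) == pytest.approx(
            1.0, abs=1e-9
        )
        t = np.linspace(0, 20 * tau2, 5000)
        k = double_exp_kernel(t, tau1, tau2)
        assert np.all(k >= 0)
        assert k.max() <= 1 + 1e-9

    def test_invalid_taus_raise(self):
        with pytest.raises(ValueError):
            double_exp_kernel(1.0, 5.3, 0.05)
        with pytest.raises(ValueError):
            double_exp_kernel(1.0, 2.0, 2.0)


class TestConnectivity:
    def test_zero_convergence_empty(self):
        conn = build_connectivity({"a": 5, "b": 5}, {"a->b": 0},
                                  np.random.default_rng(0))
        assert conn["a->b"].shape == (0, 2)

    def test_all_to_all_without_autapses(self):
        conn = build_connectivity({"a": 6}, {"a->a": 5},
                                  np.random.default_rng(0))
        edges = conn["a->a"]
        assert len(edges) == 30
        assert not np.any(edges[:, 0] == edges[:, 1])
        for post in range(6):
            pres = set(edges[edges[:, 1] == post, 0])
            assert pres == set(range(6)) - {post}

    def test_exact_in_degree_without_replacement(self):
        conn = build_connectivity({"a": 10, "b": 7}, {"a->b": 4},
                                  np.random.default_rng(1))
        edges = conn["a->b"]
        for post in range(7):
            pres = edges[edges[:, 1] == post, 0]
            assert len(pres) == 4
            assert len(set(pres)) == 4  # sampled without replacement

    def test_out_degree_matches_sampling_model(self):
        # each of N pre cells is chosen with prob C/N per post cell, so the
        # mean out-degree is n_post*C/N; check against binomial expectation
        rng = np.random.default_rng(7)
        conn = build_connectivity({"a": 10, "b": 200}, {"a->b": 4}, rng)
        out_deg = np.bincount(conn["a->b"][:, 0], minlength=10)
        assert out_deg.sum() == 800
        expected = 200 * 4 / 10
        sd = np.sqrt(200 * 0.4 * 0.6)
        assert np.all(np.abs(out_deg - expected) < 5 * sd)

    def test_reproducible_and_order_invariant(self):
        pops = {"a": 20, "b": 10}
        t1 = {"a->b": 3, "b->a": 2, "a->a": 4}
        t2 = {"b->a": 2, "a->a": 4, "a->b": 3}  # different insertion order
        c1 = build_connectivity(pops, t1, np.random.default_rng(5))
        c2 = build_connectivity(pops, t2, np.random.default_rng(5))
        for key in t1:
            np.testing.assert_array_equal(c1[key], c2[key])

    def test_convergence_exceeding_pool_raises(self):
        with pytest.raises(ValueError):
            build_connectivity({"a": 5}, {"a->a": 5},
                               np.random.default_rng(0))


class TestPoissonEvents:
    def test_zero_rate(self):
        assert poisson_events(0.0, 1000.0, np.random.default_rng(0)).size == 0

    def test_mean_count(self):
        rng = np.random.default_rng(11)
        counts = [poisson_events(1000.0, 4000.0, rng).size
                  for _ in range(50)]
        assert np.mean(counts) == pytest.approx(4000, rel=0.02)

    def test_sorted_in_range(self):
        ev = poisson_events(500.0, 2000.0, np.random.default_rng(3))
        assert np.all(np.diff(ev) >= 0)
        assert ev.min() >= 0 and ev.max() < 2000.0

    def test_count_distribution_poisson(self):
        from scipy import stats

        rng = np.random.default_rng(23)
        lam = 5.0  # rate 5 Hz × 1 s
        counts = np.array(
            [poisson_events(5.0, 1000.0, rng).size for _ in range(1000)]
        )
        kmax = int(counts.max())
        observed = np.bincount(counts, minlength=kmax + 1)
        probs = stats.poisson.pmf(np.arange(kmax + 1), lam)
        # pool tail bins so expected counts stay reasonable
        keep = probs * 1000 >= 5
        obs = np.append(observed[keep], observed[~keep].sum())
        exp = np.append(probs[keep], probs[~keep].sum()) * 1000
        stat, p = stats.chisquare(obs, exp * obs.sum() / exp.sum())
        assert p > 0.01


class TestMsThetaDrive:
    def test_event_count_7s(self):
        ev = ms_theta_drive(7000.0)
        assert ev.size == 47  # floor(7000/150)+1
        np.testing.assert_allclose(np.diff(ev), 150.0)

    def test_rising_phase(self):
        k = double_exp_kernel(np.array([2.0, 20.0]), 20.0, 40.0)
        assert k[1] > k[0]

    def test_bad_duration(self):
        with pytest.raises(ValueError):
            ms_theta_drive(0.0)


class TestApplyScaling:
    def test_identity_at_control(self):
        cfg = default_config()
        out = apply_scaling(cfg, ScalingCondition(1.0, 1.0))
        assert out.to_dict() == cfg.to_dict()

    def test_kext_arithmetic(self):
        cfg = default_config()
        out = apply_scaling(cfg, ScalingCondition(krec=1.0, kext=1.75))
        soma_ampa = [b for b in out.background
                     if b.post == "pyr" and b.compartment == "soma"
                     and b.receptor == "AMPA"]
        assert soma_ampa[0].g == pytest.approx(0.05 * 1.75)

    def test_krec_arithmetic(self):
        cfg = default_config()
        out = apply_scaling(cfg, ScalingCondition(krec=37.0, kext=1.0))
        pp = [s for s in out.synapses
              if s.pre == "pyr" and s.post == "pyr" and s.receptor == "AMPA"]
        assert pp[0].g == pytest.approx(0.74)

    def test_only_ampa_on_pyramidal_touched(self):
        cfg = default_config()
        out = apply_scaling(cfg, ScalingCondition(krec=2.0, kext=3.0))
        for s0, s1 in zip(cfg.synapses, out.synapses):
            if not (s0.pre == "pyr" and s0.post == "pyr"
                    and s0.receptor == "AMPA"):
                assert s0.g == s1.g
        for b0, b1 in zip(cfg.background, out.background):
            if not (b0.post == "pyr" and b0.receptor == "AMPA"):
                assert b0.g == b1.g

    def test_multiplicative_composition(self):
        cfg = default_config()
        once = apply_scaling(cfg, ScalingCondition(krec=6.0, kext=1.5))
        twice = apply_scaling(
            apply_scaling(cfg, ScalingCondition(krec=2.0, kext=1.5)),
            ScalingCondition(krec=3.0, kext=1.0),
        )
        assert once.to_dict() == twice.to_dict()

    def test_purity(self):
        cfg = default_config()
        before = cfg.to_dict()
        apply_scaling(cfg, ScalingCondition(krec=5.0, kext=5.0))
        assert cfg.to_dict() == before

    def test_negative_factor_raises(self):
        with pytest.raises(ValueError):
            ScalingCondition(krec=-1.0, kext=1.0)
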