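import numpy as np
import pytest
from scipy.stats import norm

from survldm import SimConfig, SimDesign, simulate_replicate
from survldm.simulate import (causal_score, draw_counts, draw_survival,
                              make_baseline, make_confounded_pair,
                              subject_frequencies)
from survldm.io import CountTable


class TestBaseline:
    def test_harmonic_normalization(self):
        cfg = SimConfig(J=4, gamma=1.0, n_confounded=2)
        pi = make_baseline(cfg)
        np.testing.assert_allclose(pi, [0.48, 0.24, 0.16, 0.12])

    def test_sums_to_one_and_sorted(self):
        cfg = SimConfig(J=300, gamma=0.8, n_confounded=100)
        pi = make_baseline(cfg)
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)
        assert (np.diff(pi) <= 0).all()

    def test_file_input_normalized_and_sorted(self, tmp_path):
        p = tmp_path / "freqs.txt"
        p.write_text("0.2\n0.5\n0.3\n")
        cfg = SimConfig(J=3, baseline_file=str(p), n_confounded=2)
        np.testing.assert_allclose(make_baseline(cfg), [0.5, 0.3, 0.2])

    def test_nonpositive_frequencies_rejected(self, tmp_path):
        p = tmp_path / "freqs.txt"
        p.write_text("0.5\n0\n0.5\n")
        cfg = SimConfig(J=3, baseline_file=str(p), n_confounded=2)
        with pytest.raises(ValueError, match="positive"):
            make_baseline(cfg)


class TestConfoundedPair:
    def test_frequency_multiset_conserved(self):
        rng = np.random.default_rng(0)
        pi1 = make_baseline(SimConfig(J=50, n_confounded=20))
        pi2, idx = make_confounded_pair(pi1, 20, rng)
        np.testing.assert_allclose(np.sort(pi1), np.sort(pi2))
        assert pi2.sum() == pytest.approx(1.0)

    def test_untouched_outside_selected_set(self):
        rng = np.random.default_rng(1)
        pi1 = make_baseline(SimConfig(J=50, n_confounded=20))
        pi2, idx = make_confounded_pair(pi1, 20, rng)
        outside = np.setdiff1d(np.arange(50), idx)
        np.testing.assert_array_equal(pi1[outside], pi2[outside])

    def test_zero_confounded_identity(self):
        rng = np.random.default_rng(2)
        pi1 = make_baseline(SimConfig(J=20, n_confounded=5))
        pi2, idx = make_confounded_pair(pi1, 0, rng)
        np.testing.assert_array_equal(pi1, pi2)
        assert idx.size == 0


class TestSubjectFrequencies:
    def test_group_zero_gets_baseline(self):
        pi1 = np.array([0.6, 0.4])
        pi2 = np.array([0.4, 0.6])
        P = subject_frequencies(pi1, pi2, 0.8, np.array([0, 1]))
        np.testing.assert_allclose(P[0], pi1)

    def test_full_mixture(self):
        pi1 = np.array([0.6, 0.4])
        pi2 = np.array([0.4, 0.6])
        P = subject_frequencies(pi1, pi2, 1.0, np.array([1]))
        np.testing.assert_allclose(P[0], pi2)

    def test_no_confounding_effect(self):
        pi1 = np.array([0.6, 0.4])
        pi2 = np.array([0.4, 0.6])
        P = subject_frequencies(pi1, pi2, 0.0, np.array([0, 1, 1]))
        np.testing.assert_allclose(P, np.tile(pi1, (3, 1)))


class TestDrawCounts:
    def test_degenerate_frequency_all_reads_on_one_taxon(self):
        cfg = SimConfig(n=4, J=3, n_confounded=0, theta=0.0)
        P = np.tile([1.0, 0.0, 0.0], (4, 1))
        rng = np.random.default_rng(3)
        t = draw_counts(P, 0.0, cfg, rng)
        assert (t.counts[:, 0] == t.library_sizes).all()

    def test_dm_mean_matches_target(self):
        cfg = SimConfig(n=3000, J=5, n_confounded=0, theta=0.02)
        pi = np.array([0.4, 0.3, 0.15, 0.1, 0.05])
        P = np.tile(pi, (3000, 1))
        rng = np.random.default_rng(4)
        t = draw_counts(P, 0.02, cfg, rng)
        freqs = t.counts / t.library_sizes[:, None]
        # DM marginal sd per subject ~ sqrt(pi (1-pi) (1 + theta(L-1)) / L)
        sd = np.sqrt(pi * (1 - pi) * (1 + 0.02 * 9999) / 10000)
        se = sd / np.sqrt(3000)
        assert (np.abs(freqs.mean(axis=0) - pi) < 4 * se).all()

    def test_library_sizes_truncated_normal(self):
        cfg = SimConfig(n=2000, J=2, n_confounded=0)
        P = np.tile([0.5, 0.5], (2000, 1))
        rng = np.random.default_rng(5)
        t = draw_counts(P, 0.02, cfg, rng)
        assert t.library_sizes.min() >= 1000
        assert abs(t.library_sizes.mean() - 10000) < 4 * 10000 / 3 / np.sqrt(2000)


class TestCausalScore:
    def test_presence_score_zero_when_absent(self):
        t = CountTable(["a", "b"], ["t1", "t2"], np.array([[5, 0], [5, 0]]))
        S = causal_score(t, "M2", np.array([1]), np.array([1.0]))
        np.testing.assert_array_equal(S, [0.0, 0.0])

    def test_ratio_score_constant_for_identical_subjects(self):
        t = CountTable(["a", "b"], ["t1", "t2"], np.array([[3, 7], [3, 7]]))
        S = causal_score(t, "M1", np.array([0, 1]), np.array([1.0, -1.0]))
        np.testing.assert_allclose(S, [0.0, 0.0])  # 1 - 1 per subject

    def test_hand_computed_ratio_score(self):
        counts = np.array([[2, 2, 6], [0, 5, 5], [4, 2, 4]])
        t = CountTable(["a", "b", "c"], ["t1", "t2", "t3"], counts)
        # frequencies: t1 = (0.2, 0, 0.4), mean 0.2; t2 = (0.2, 0.5, 0.2), mean 0.3
        S = causal_score(t, "M1", np.array([0, 1]), np.array([1.0, -1.0]))
        expected = np.array([0.2 / 0.2 - 0.2 / 0.3,
                             0.0 / 0.2 - 0.5 / 0.3,
                             0.4 / 0.2 - 0.2 / 0.3])
        np.testing.assert_allclose(S, expected)


class TestDrawSurvival:
    def test_weibull_median_closed_form(self):
        rng = np.random.default_rng(6)
        n = 100_000
        S = np.zeros(n)
        X = np.zeros(n)
        out, T, C = draw_survival(S, X, 0.0, 0.0, "cox-weibull", 0.0, rng)
        assert abs(np.median(T) - 10.0 * np.sqrt(np.log(2.0))) < 0.01 * 8.33

    def test_no_censoring_all_events(self):
        rng = np.random.default_rng(7)
        out, _, C = draw_survival(np.zeros(50), np.zeros(50), 0.0, 0.0,
                                  "cox-weibull", 0.0, rng)
        assert out.event.all()
        assert np.isinf(C).all()

    def test_ah_crossing_survival_curves(self):
        # closed form: S(t | B) = (1 - Phi(log(B t)))^(1/B); curves for
        # B = e and B = 1/e must cross (proportional hazards violated)
        t = np.linspace(0.05, 5.0, 200)

        def surv(B):
            return (1.0 - norm.cdf(np.log(B * t))) ** (1.0 / B)

        diff = surv(np.e) - surv(np.exp(-1.0))
        assert (diff > 0).any() and (diff < 0).any()

    def test_ah_matches_closed_form_survival(self):
        rng = np.random.default_rng(8)
        n = 60_000
        out, T, _ = draw_survival(np.zeros(n), np.zeros(n), 0.0, 0.0,
                                  "ah-lognormal", 0.0, rng)
        # B = 1: T is standard lognormal
        emp = (T <= 1.0).mean()
        assert abs(emp - 0.5) < 4 * 0.5 / np.sqrt(n)


class TestSimulateReplicate:
    def test_deterministic(self, sim_config):
        a = simulate_replicate(sim_config, 3)
        b = simulate_replicate(sim_config, 3)
        np.testing.assert_array_equal(a.table.counts, b.table.counts)
        np.testing.assert_array_equal(a.outcome.time, b.outcome.time)

    def test_balanced_groups(self, sim_config):
        rep = simulate_replicate(sim_config, 1)
        assert rep.X.sum() == sim_config.n // 2

    def test_confounded_taxa_differ_between_groups(self):
        cfg = SimConfig(n=2000, J=60, n_confounded=30, beta_XZ=0.8, seed=9,
                        censor_rate=0.0)
        design = SimDesign(cfg)
        rep = simulate_replicate(design, 1)
        freqs = rep.table.counts / rep.table.library_sizes[:, None]
        g0, g1 = freqs[rep.X == 0], freqs[rep.X == 1]
        diff = np.abs(g0.mean(axis=0) - g1.mean(axis=0))
        conf = np.zeros(60, dtype=bool)
        conf[design.confounded] = True
        # permuted frequencies genuinely moved for most confounded taxa
        moved = np.abs(design.pi1 - design.pi2) > 1e-9
        assert diff[conf & moved].max() > 10 * diff[~conf].mean()

    def test_censoring_rate_ah_model(self):
        cfg = SimConfig(n=100, J=50, n_confounded=25, seed=10,
                        hazard="ah-lognormal", censor_rate=0.5)
        design = SimDesign(cfg)
        cens = np.mean([simulate_replicate(design, r + 1).censored_fraction
                        for r in range(200)])
        assert abs(cens - 0.5) < 0.05

    def test_m2_causal_taxa_in_rank_band(self):
        cfg = SimConfig(n=50, J=120, n_confounded=60, model="M2", seed=11)
        design = SimDesign(cfg)
        assert ((design.causal >= 10) & (design.causal < 100)).all()
        assert design.causal.size == 10

    def test_custom_causal_set(self):
        cfg = SimConfig(n=50, J=120, n_confounded=60, model="custom",
                        causal_taxa=[10], seed=12)
        design = SimDesign(cfg)
        np.testing.assert_array_equal(design.causal, [10])
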