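"""Wright-Fisher simulator: moments, absorbing states, exact Markov oracle."""

import numpy as np
import pytest
from scipy.stats import binom

import isodrift as iso
from isodrift.wright_fisher import SimConfig, selection_update


def markov_transition_matrix(ne: int, s: float = 0.0, h: float | None = None) -> np.ndarray:
    """Exact (2Ne+1)-state transition matrix of the Wright-Fisher chain."""
    k = 2 * ne
    states = np.arange(k + 1)
    p_sel = selection_update(states / k, s, h)
    return binom.pmf(states[None, :], k, p_sel[:, None])


class TestWfStep:
    def test_absorbing_states(self):
        rng = np.random.default_rng(0)
        p = np.concatenate([np.zeros(50), np.ones(50)])
        out = iso.wf_step(p, ne=100, s=0.05, rng=rng)
        np.testing.assert_array_equal(out, p)

    def test_neutral_mean_preserved(self):
        """E[p'] = p under neutrality: mean of 100,000 draws within 3 SE."""
        rng = np.random.default_rng(1)
        ne, p0, n = 2471, 0.3, 100_000
        out = iso.wf_step(np.full(n, p0), ne=ne, s=0.0, rng=rng)
        se = np.sqrt(p0 * (1 - p0) / (2 * ne) / n)
        assert abs(out.mean() - p0) < 3 * se

    def test_selection_update_direct_evaluation(self):
        """Genic update at s=0.01, p=0.47 equals 0.47*1.01/1.0047."""
        assert selection_update(np.array([0.47]), 0.01)[0] == pytest.approx(
            0.47 * 1.01 / 1.0047, rel=1e-12
        )

    def test_dominance_schemes_exact_diploid_formula(self):
        """Recessive (h=0) and dominant (h=1) updates match the diploid
        fitness-weighted formula evaluated by hand at p=0.5."""
        p = np.array([0.5])
        s = 0.02
        rec = selection_update(p, s, h=0.0)[0]  # fitnesses 1,1,1+s
        dom = selection_update(p, s, h=1.0)[0]  # fitnesses 1,1+s,1+s
        w_rec = 0.25 * (1 + s) + 0.5 + 0.25
        assert rec == pytest.approx((0.25 * (1 + s) + 0.25) / w_rec, rel=1e-12)
        w_dom = 0.25 * (1 + s) + 0.5 * (1 + s) + 0.25
        assert dom == pytest.approx((0.25 * (1 + s) + 0.25 * (1 + s)) / w_dom, rel=1e-12)


class TestRunEnsemble:
    def test_identical_seed_identical_ensemble(self):
        cfg = SimConfig(ne=50, p0=0.4, n_generations=100, record_interval=10,
                        n_replicates=200, seed=7)
        e1, e2 = iso.run_ensemble(cfg), iso.run_ensemble(cfg)
        np.testing.assert_array_equal(e1.frequencies, e2.frequencies)

    def test_absorbed_trajectories_stay_absorbed(self):
        cfg = SimConfig(ne=10, p0=0.5, n_generations=200, record_interval=10,
                        n_replicates=500, seed=8)
        ens = iso.run_ensemble(cfg)
        f = ens.frequencies
        for col in range(1, f.shape[1]):
            fixed0 = f[:, col - 1] == 0.0
            fixed1 = f[:, col - 1] == 1.0
            assert np.all(f[fixed0, col] == 0.0)
            assert np.all(f[fixed1, col] == 1.0)
        assert f.min() >= 0 and f.max() <= 1

    def test_neutral_heterozygosity_decay(self):
        """Mean p(1-p) decays as (1 - 1/(2Ne))^t from p0(1-p0)."""
        ne, p0, t = 30, 0.5, 60
        cfg = SimConfig(ne=ne, p0=p0, n_generations=t, record_interval=10,
                        n_replicates=60_000, seed=9)
        ens = iso.run_ensemble(cfg)
        for col, gen in enumerate(ens.generations):
            h = (ens.frequencies[:, col] * (1 - ens.frequencies[:, col])).mean()
            expected = p0 * (1 - p0) * (1 - 1 / (2 * ne)) ** gen
            assert h == pytest.approx(expected, rel=0.03)

    def test_fixation_probability_matches_exact_markov_chain(self):
        """Small-Ne neutral ensemble vs exact transition-matrix propagation."""
        ne, p0, t = 10, 0.5, 200
        cfg = SimConfig(ne=ne, p0=p0, n_generations=t, record_interval=t,
                        n_replicates=100_000, seed=10)
        ens = iso.run_ensemble(cfg)
        P = markov_transition_matrix(ne)
        dist = np.zeros(2 * ne + 1)
        dist[int(round(p0 * 2 * ne))] = 1.0
        dist = dist @ np.linalg.matrix_power(P, t)
        terminal_counts = np.round(ens.frequencies[:, -1] * 2 * ne).astype(int)
        empirical = np.bincount(terminal_counts, minlength=2 * ne + 1) / cfg.n_replicates
        tv = 0.5 * np.abs(empirical - dist).sum()
        assert tv < 0.02
        assert ens.summary["fraction_fixed_derived"] == pytest.approx(dist[-1], abs=0.01)

    def test_selected_terminal_distribution_matches_markov_chain(self):
        """The exact-chain check also holds with selection switched on."""
        ne, p0, t, s = 8, 0.25, 100, 0.05
        cfg = SimConfig(ne=ne, p0=p0, s=s, n_generations=t, record_interval=t,
                        n_replicates=100_000, seed=11)
        ens = iso.run_ensemble(cfg)
        P = markov_transition_matrix(ne, s=s)
        dist = np.zeros(2 * ne + 1)
        dist[int(round(p0 * 2 * ne))] = 1.0
        dist = dist @ np.linalg.matrix_power(P, t)
        terminal_counts = np.round(ens.frequencies[:, -1] * 2 * ne).astype(int)
        empirical = np.bincount(terminal_counts, minlength=2 * ne + 1) / cfg.n_replicates
        assert 0.5 * np.abs(empirical - dist).sum() < 0.02

    def test_threshold_attainment_monotone_in_s(self):
        """Stronger selection never lowers the threshold-attainment percentage."""
        rates = []
        for i, s in enumerate((0.0, 0.005, 0.01, 0.02)):
            cfg = SimConfig(ne=500, p0=0.3, s=s, threshold=0.6, n_generations=200,
                            record_interval=50, n_replicates=10_000, seed=12 + i)
            ens = iso.run_ensemble(cfg)
            rates.append(ens.summary["fraction_terminal_at_threshold"])
        assert all(a <= b + 0.01 for a, b in zip(rates, rates[1:]))
        assert rates[-1] > rates[0]

    def test_record_interval_must_divide(self):
        with pytest.raises(ValueError):
            SimConfig(n_generations=500, record_interval=33)


class TestScenarios:
    def test_lct_all_ancestral_when_derived_absent(self):
        ens = iso.scenario_lct(p0=0.0, n_replicates=100, seed=1)
        assert ens.summary["percent_ancestral_fixed"] == 100.0

    def test_lct_small_ne_fixes_often(self):
        """At Ne=10 the ancestral allele fixes in a large share of replicates."""
        ens = iso.scenario_lct(ne=10, n_replicates=2000, seed=2)
        assert ens.summary["percent_ancestral_fixed"] > 20.0

    def test_actn3_zero_threshold_always_met(self):
        arms = iso.scenario_actn3(seed=3, threshold=0.0, n_replicates=100)
        for ens in arms.values():
            assert ens.summary["percent_terminal_at_threshold"] == 100.0

    def test_actn3_selected_arm_beats_neutral(self):
        arms = iso.scenario_actn3(seed=4, n_replicates=500)
        assert (
            arms["selected"].summary["percent_terminal_at_threshold"]
            > arms["neutral"].summary["percent_terminal_at_threshold"] + 50
        )
        # neutral drift from 0.47 essentially never gains 0.46 in 500 generations
        assert arms["neutral"].summary["percent_terminal_at_threshold"] < 1.0
        # "ever reached" can only exceed the terminal criterion
        for ens in arms.values():
            assert (
                ens.summary["percent_ever_at_threshold"]
                >= ens.summary["percent_terminal_at_threshold"]
            )
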