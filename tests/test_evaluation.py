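import numpy as np
import pytest

from mocu_design.evaluation import (
    StudyConfig,
    Trial,
    batch_study,
    computational_gain,
    generate_random_network,
    sample_uncertain_positions,
    sequential_evaluation,
)


class TestGenerator:
    def test_three_predictors_per_gene_no_self_loops(self, rng):
        R = generate_random_network(7, rng=rng)
        assert ((R != 0).sum(axis=1) == 3).all()
        assert (np.diag(R) == 0).all()
        assert np.isin(R, (-1, 0, 1)).all()

    def test_reproducible_under_seed(self):
        a = generate_random_network(7, rng=123)
        b = generate_random_network(7, rng=123)
        c = generate_random_network(7, rng=124)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_too_small_n(self):
        with pytest.raises(ValueError):
            generate_random_network(3)


class TestUncertainPositions:
    def test_all_positions_when_k_equals_total(self, rng):
        R = generate_random_network(5, rng=rng)
        pos = sample_uncertain_positions(R, 15, rng)
        assert len(pos) == 15

    def test_positions_index_nonzero_entries(self, rng):
        R = generate_random_network(6, rng=rng)
        for _ in range(20):
            for i, j in sample_uncertain_positions(R, 4, rng):
                assert R[i - 1, j - 1] != 0

    def test_uniformity_chi_square(self, rng):
        from scipy.stats import chisquare

        R = generate_random_network(5, rng=rng)
        counts = {}
        for _ in range(4000):
            for pos in sample_uncertain_positions(R, 1, rng):
                counts[pos] = counts.get(pos, 0) + 1
        stat, pval = chisquare(list(counts.values()))
        assert pval > 1e-4  # uniform draw over the 15 regulations

    def test_k_too_large(self, rng):
        R = generate_random_network(5, rng=rng)
        with pytest.raises(ValueError):
            sample_uncertain_positions(R, 16, rng)


class TestComputationalGain:
    @pytest.mark.parametrize(
        "n,p,s,digits,expected",
        [(15, 2, 0, 1, 0.7), (15, 3, 0, 1, 1.4), (15, 2, 3, 2, 1.16), (15, 1, 13, 2, 8.0)],
    )
    def test_printed_values(self, n, p, s, digits, expected):
        assert round(computational_gain(n, p, s), digits) == pytest.approx(expected)

    def test_infeasible_arguments(self):
        with pytest.raises(ValueError):
            computational_gain(5, 5, 0)
        with pytest.raises(ValueError):
            computational_gain(5, 0, 0)


class TestTrialGains:
    def test_gain_zero_when_chosen_equals_random(self):
        ss = np.random.SeedSequence(5)
        t = Trial(ss.spawn(1)[0], n=5, k=2, p=0.01)
        assert t.gain(t.random_experiment) == 0.0

    def test_k1_gain_always_zero(self):
        ss = np.random.SeedSequence(6)
        t = Trial(ss.spawn(1)[0], n=5, k=1, p=0.01)
        assert t.gain(t.optimal_selection()) == 0.0

    def test_gain_matches_recomputation_from_cached_tables(self):
        ss = np.random.SeedSequence(7)
        t = Trial(ss.spawn(1)[0], n=5, k=2, p=0.01)
        ens = t.ensemble
        chosen = t.optimal_selection()
        rho = t.gain(chosen)

        def err_after(i):
            mask = ens.condition(i, t.mu[i - 1])
            w = ens.weights[mask] / ens.weights[mask].sum()
            avg = np.tensordot(w, ens.errors[mask], axes=1)
            flat = int(np.argmin(avg))
            u, v = flat // avg.shape[1], flat % avg.shape[1]
            return ens.errors[t.true_index][u, v]

        expected = (
            0.0
            if chosen == t.random_experiment
            else err_after(t.random_experiment) - err_after(chosen)
        )
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_induced_gain_with_no_reduction_path(self):
        # substituting induced robust interventions reproduces the exact
        # gain whenever the induced interventions coincide
        ss = np.random.SeedSequence(8)
        t = Trial(ss.spawn(1)[0], n=5, k=2, p=0.01)
        chosen = t.optimal_selection()
        rho_ind = t.induced_gain(chosen, (3,))
        assert np.isfinite(rho_ind)
        assert t.induced_gain(t.random_experiment, (3,)) == 0.0

    def test_controllability_in_range(self):
        ss = np.random.SeedSequence(9)
        t = Trial(ss.spawn(1)[0], n=5, k=2, p=0.01)
        assert 0.0 <= t.controllability() <= 100.0


class TestSequential:
    def test_final_step_gain_is_zero_and_trace_matches(self):
        ss = np.random.SeedSequence(11)
        t = Trial(ss.spawn(1)[0], n=4, k=2, p=0.01)
        gains = sequential_evaluation(t, rng=3)
        assert len(gains) == 2
        assert gains[-1] == pytest.approx(0.0, abs=1e-12)

    def test_fully_revealed_class_recovers_true_optimum(self):
        ss = np.random.SeedSequence(12)
        t = Trial(ss.spawn(1)[0], n=4, k=2, p=0.01)
        ens = t.ensemble
        mask = np.ones(ens.m, dtype=bool)
        for i in (1, 2):
            mask &= ens.condition(i, t.mu[i - 1])
        psi, err = ens.robust(mask)
        assert err == pytest.approx(ens.opt_errors[t.true_index], abs=1e-12)


class TestBatchStudy:
    def test_zero_reps_is_empty_but_valid(self):
        df, summary = batch_study(StudyConfig(n=5, k=2, reps=0, seed=1))
        assert len(df) == 0
        assert summary["reps"] == 0

    def test_summary_means_match_trial_records(self):
        cfg = StudyConfig(n=5, k=2, reps=8, seed=3)
        df, summary = batch_study(cfg)
        assert summary["mean_rho_optimal"] == pytest.approx(df["rho_optimal"].mean())
        assert summary["agreement_min_pct"] == pytest.approx(df["agree_min"].mean() * 100)

    def test_bitwise_reproducibility(self):
        cfg = StudyConfig(n=5, k=2, reps=6, seed=42)
        df1, s1 = batch_study(cfg)
        df2, s2 = batch_study(StudyConfig(n=5, k=2, reps=6, seed=42))
        assert df1.equals(df2)
        assert s1 == s2

    def test_per_rank_gains_recorded(self):
        cfg = StudyConfig(n=5, k=2, reps=5, seed=4, per_rank=True)
        df, summary = batch_study(cfg)
        assert len(summary["mean_rho_by_rank"]) == 4  # 4 candidate genes

    def test_controllability_strata(self):
        cfg = StudyConfig(n=5, k=2, reps=5, seed=5, delta_thresholds=(0.0, 40.0))
        _, summary = batch_study(cfg)
        strata = summary["controllability_strata"]
        assert strata["0.0"]["count"] >= strata["40.0"]["count"]
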