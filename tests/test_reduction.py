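import itertools

import numpy as np
import pytest

from mocu_design.design import ExperimentDesign
from mocu_design.intervention import Intervention, robust_intervention
from mocu_design.network import BooleanNetwork
from mocu_design.reduction import (
    ReducedEnsemble,
    completion_table,
    deletion_cost,
    deletion_cost_table,
    induce_intervention,
    induce_optimal_intervention,
    induce_robust_intervention,
    reduce_many,
    reduce_network,
    select_deletion,
)
from mocu_design.uncertainty import UncertaintyClass, optimal_experiment

from conftest import random_class, random_model


class TestReduceNetwork:
    def test_hand_collapsing_example(self):
        # n=2, delete gene 2, pi = (0.1, 0.2, 0.3, 0.4): both reduced
        # states take their rule from the gene-2=1 parent (larger mass)
        m = BooleanNetwork(np.array([3, 0, 1, 2]), p=0.01)
        pi = np.array([0.1, 0.2, 0.3, 0.4])
        rm = reduce_network(m, 2, pi)
        assert rm.network.truth_table.tolist() == [0 >> 1, 2 >> 1]
        assert rm.genes == (1,) and rm.deleted == (2,)

    def test_tie_takes_zero_parent(self):
        # equal parent masses: the strict > rule falls to the 0-parent
        m = BooleanNetwork(np.array([3, 0, 1, 2]), p=0.01)
        pi = np.full(4, 0.25)
        rm = reduce_network(m, 2, pi)
        # parents of reduced 0 are states 0 (F=3) and 1 (F=0); 0-parent wins
        assert rm.network.truth_table[0] == 3 >> 1

    def test_projection_equality_is_tie_proof(self):
        # when both parents' successors project identically the tie rule
        # cannot matter
        m = BooleanNetwork(np.array([0, 1, 2, 3]), p=0.01)  # identity
        for pi in (np.array([0.4, 0.1, 0.1, 0.4]), np.full(4, 0.25)):
            rm = reduce_network(m, 2, pi)
            assert rm.network.truth_table.tolist() == [0, 1]

    def test_totality_and_target_protection(self, rng):
        m = random_model(rng, n=4, p=0.01)
        rm = reduce_network(m, 3)
        assert len(rm.network.truth_table) == 8
        with pytest.raises(ValueError):
            reduce_network(m, 1)  # target
        with pytest.raises(ValueError):
            reduce_network(m, 5)


class TestReduceMany:
    def test_empty_deletion_is_identity(self, rng):
        m = random_model(rng, n=3, p=0.01)
        rm = reduce_many(m, ())
        assert np.array_equal(rm.network.truth_table, m.truth_table)

    def test_orders_give_well_formed_tables(self, rng):
        m = random_model(rng, n=4, p=0.01)
        for order in ((2, 3), (3, 2)):
            rm = reduce_many(m, order)
            t = rm.network.truth_table
            assert len(t) == 4 and t.min() >= 0 and t.max() < 4

    def test_intermediate_ssd_balance(self, rng):
        m = random_model(rng, n=4, p=0.01)
        rm1 = reduce_network(m, 2)
        pi1 = rm1.network.ssd
        assert np.abs(pi1 @ rm1.network.tpm - pi1).max() < 1e-10
        rm2 = reduce_many(m, (2, 3))
        pi2 = rm2.network.ssd
        assert np.abs(pi2 @ rm2.network.tpm - pi2).max() < 1e-10

    def test_duplicate_genes_rejected(self, rng):
        m = random_model(rng, n=4, p=0.01)
        with pytest.raises(ValueError):
            reduce_many(m, (2, 2))


class TestInducedInterventions:
    def test_tie_prefers_one_completion(self, rng):
        # equal full-state masses: the >= rule completes with bit 1
        m = random_model(rng, n=3, p=0.01)
        rm = reduce_network(m, 3)
        pi = np.full(8, 1 / 8)
        psi = induce_intervention((0, 1), pi, rm.genes, rm.deleted, 3)
        assert psi.u % 2 == 1 and psi.v % 2 == 1  # gene-3 bit set

    def test_round_trip_projection(self, rng):
        for _ in range(10):
            m = random_model(rng, n=4, p=0.01)
            rm = reduce_many(m, (2, 4))
            u, v = rng.integers(0, 4, size=2)
            psi = induce_optimal_intervention(Intervention(int(u), int(v)), rm)
            comp = completion_table(rm.deleted, 4)
            # dropping the deleted bits must recover the reduced pair
            assert psi.u in comp[int(u)] and psi.v in comp[int(v)]

    def test_two_gene_completion_matches_exhaustive_argmax(self, rng):
        for _ in range(10):
            m = random_model(rng, n=4, p=0.01)
            rm = reduce_many(m, (3, 4))
            pi = m.ssd
            comp = completion_table((3, 4), 4)
            for s in range(4):
                got = induce_intervention((s, s), pi, rm.genes, rm.deleted, 4).u
                cand = comp[s]
                best = cand[pi[cand] == pi[cand].max()].max()
                assert got == best

    def test_algorithm_trace_on_two_network_class(self, rng):
        # induced robust via the expected SSD, followed line by line
        uc = random_class(rng, n=3, k=1, p=0.01)
        ens = uc.ensemble
        red = ReducedEnsemble(ens, (2,))
        mask = np.ones(2, dtype=bool)
        psi, err = red.induced_robust(mask)
        # line-by-line: average reduced tables, argmin, complete by the
        # prior-expected SSD with >= preferring the 1-completion
        avg = 0.5 * red.red_errors[0] + 0.5 * red.red_errors[1]
        flat = int(np.argmin(avg))
        u_hat, v_hat = flat // 4, flat % 4
        epi = 0.5 * ens.ssds[0] + 0.5 * ens.ssds[1]
        comp = completion_table((2,), 3)

        def complete(s):
            c0, c1 = comp[s]
            return c1 if epi[c1] >= epi[c0] else c0

        assert psi == Intervention(complete(u_hat), complete(v_hat))

    def test_singleton_class_robust_equals_optimal_inducement(self, rng):
        uc = random_class(rng, n=3, k=0, p=0.01)
        ens = uc.ensemble
        red = ReducedEnsemble(ens, (2,))
        psi, _ = red.induced_robust(np.ones(1, dtype=bool))
        flat = int(np.argmin(red.red_errors[0]))
        psi_opt = induce_optimal_intervention(
            Intervention(flat // 4, flat % 4), red.reduced[0], ens.ssds[0]
        )
        assert psi == psi_opt

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            induce_intervention((0, 1), np.ones(8) / 8, (1, 2), (3,), 4)


class TestDeletionCost:
    def test_costs_nonnegative(self, rng):
        for _ in range(5):
            uc = random_class(rng, n=4, k=2, p=0.01)
            for g in (2, 3, 4):
                assert deletion_cost(uc, (g,)) >= 0.0

    def test_argmin_equivalence_of_both_forms(self, rng):
        # surrogate form and ranking-disruption form rank identically
        for _ in range(8):
            uc = random_class(rng, n=4, k=2, p=0.01)
            sur = {g: deletion_cost(uc, (g,), form="surrogate") for g in (2, 3, 4)}
            dis = {g: deletion_cost(uc, (g,), form="ranking-disruption") for g in (2, 3, 4)}
            assert min(sur, key=sur.get) == min(dis, key=dis.get)

    def test_induced_robust_never_beats_exact_robust(self, rng):
        # expected induced-robust error >= expected robust error, per
        # conditional class
        for _ in range(8):
            uc = random_class(rng, n=4, k=2, p=0.01)
            ens = uc.ensemble
            cond = ens.conditional
            for g in (2, 3, 4):
                red = ReducedEnsemble(ens, (g,))
                assert (red.cond_err >= cond["robust_err"] - 1e-10).all()

    def test_symmetric_genes_get_equal_cost(self):
        # genes 2 and 3 play interchangeable roles
        R = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]])
        uc = UncertaintyClass(R, ((2, 1), (3, 1)), p=0.01)
        c2 = deletion_cost(uc, (2,))
        c3 = deletion_cost(uc, (3,))
        assert c2 == pytest.approx(c3, abs=1e-10)

    def test_target_cannot_be_deleted(self, rng):
        uc = random_class(rng, n=4, k=2, p=0.01)
        with pytest.raises(ValueError):
            deletion_cost(uc, (1,))


class TestSelectDeletion:
    def test_single_candidate_returned_directly(self, rng):
        uc = random_class(rng, n=4, k=2, p=0.01)
        got = select_deletion(uc, 1, excluded=(2, 3))
        assert got == (4,)

    def test_ranking_matches_exhaustive_recomputation(self, rng):
        uc = random_class(rng, n=4, k=2, p=0.01)
        table = deletion_cost_table(uc, 1)
        recomputed = {g: deletion_cost(uc, (g,)) for g in (2, 3, 4)}
        for genes, cost in table:
            assert cost == pytest.approx(recomputed[genes[0]], abs=1e-12)
        best = min(recomputed, key=lambda g: (recomputed[g], g))
        assert select_deletion(uc, 1) == (best,)

    def test_excluded_genes_never_selected(self, rng):
        for _ in range(5):
            uc = random_class(rng, n=5, k=2, p=0.01)
            got = select_deletion(uc, 2, excluded=(3,))
            assert 3 not in got and 1 not in got

    def test_infeasible_combination_raises(self, rng):
        uc = random_class(rng, n=4, k=2, p=0.01)
        with pytest.raises(ValueError):
            select_deletion(uc, 4)  # only 3 non-target genes exist


class TestApproximateDesign:
    def test_no_reduction_equals_optimal(self, rng):
        uc = random_class(rng, n=4, k=2, p=0.01)
        res_opt = ExperimentDesign(uc).fit(method="optimal")
        res_app = ExperimentDesign(uc).fit(method="approximate", n_delete=0)
        assert res_app.selected_experiment == res_opt.selected_experiment
        assert np.allclose(res_app.scores, res_opt.scores)

    def test_straight_line_recomputation_n3_k2_p1(self, rng):
        # every intermediate of the approximate pipeline recomputed naively
        for _ in range(5):
            uc = random_class(rng, n=3, k=2, p=0.02)
            ens = uc.ensemble
            cond = ens.conditional
            # naive cost per gene
            naive_cost = {}
            for g in (2, 3):
                red = ReducedEnsemble(ens, (g,))
                total = 0.0
                for i in (1, 2):
                    for phi in (-1, 1):
                        mask = ens.condition(i, phi)
                        w = ens.weights[mask] / ens.weights[mask].sum()
                        psi_red, _ = robust_intervention(red.red_errors[mask], w)
                        epi = w @ ens.ssds[mask]
                        psi = induce_robust_intervention(
                            psi_red, epi, red.reduced[int(np.flatnonzero(mask)[0])]
                        )
                        h = float(w @ ens.errors[mask][:, psi.u, psi.v])
                        assert h == pytest.approx(
                            red.conditional_h(i, phi), abs=1e-12
                        )
                        total += 0.5 * h
                naive_cost[g] = total
                assert total == pytest.approx(red.cost(), abs=1e-12)
            g_star = min(naive_cost, key=lambda g: (naive_cost[g], g))
            res = ExperimentDesign(uc).fit(method="approximate", n_delete=1)
            assert res.deleted_genes == (g_star,)
            assert 1 <= res.selected_experiment <= 2

    def test_selected_experiment_in_range(self, rng):
        for _ in range(5):
            uc = random_class(rng, n=4, k=3, p=0.01)
            res = ExperimentDesign(uc).fit(method="approximate", n_delete=1)
            assert 1 <= res.selected_experiment <= 3

    def test_summary_mentions_selection(self, rng):
        uc = random_class(rng, n=4, k=2, p=0.01)
        res = ExperimentDesign(uc).fit(method="approximate", n_delete=1)
        text = res.summary()
        assert f"E{res.selected_experiment}" in text
        assert "deleted genes" in text
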