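"""Objective-based network reduction and the approximate design method.

Deleting gene g collapses every pair of states differing only in gene g;
the collapsed state inherits the transition rule of the parent with the
larger steady-state probability.  Interventions found on the reduced
network are lifted back ("induced") to the full network by completing the
deleted bits with the completion of maximal (expected) steady-state
probability.

The cost of deleting a gene set g is the total expected error of the
induced robust interventions across all conditional classes,

    c(g) = sum_i E_{theta_i} E_{theta | theta_i}[ xi_theta(psi_IBR^ind(Theta_{i,theta_i}; g)) ],

which ranks candidate deletions identically to the ranking-disruption form
sum_i |M^g(Theta, i) - M(Theta, i)|.  The approximate design deletes the
minimum-cost set and ranks experiments by expected remaining MOCU with
both the per-network optimal and the robust interventions replaced by
their induced counterparts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .intervention import Intervention, robust_intervention
from .network import BooleanNetwork, bits_to_state, state_to_bits
from .uncertainty import ClassEnsemble, UncertaintyClass

__all__ = [
    "ReducedModel",
    "reduce_network",
    "reduce_many",
    "induce_intervention",
    "induce_optimal_intervention",
    "induce_robust_intervention",
    "ReducedEnsemble",
    "deletion_cost",
    "deletion_cost_table",
    "select_deletion",
    "approximate_scores",
]


def _remove_bit(values: np.ndarray, b: int) -> np.ndarray:
    """Drop the bit at LSB-position b from each value."""
    high = values >> (b + 1)
    low = values & ((1 << b) - 1)
    return (high << b) | low


def _insert_bit(values: np.ndarray, b: int, bit: int) -> np.ndarray:
    """Insert a bit at LSB-position b into each value."""
    high = values >> b
    low = values & ((1 << b) - 1)
    return (high << (b + 1)) | (bit << b) | low


@dataclass
class ReducedModel:
    """A reduced BNp plus the bookkeeping to map states back to the parent.

    ``genes`` lists the surviving original gene labels in their original
    order (so reduced bit 0..m-1, MSB-first, corresponds to ``genes``);
    ``deleted`` lists the removed labels in deletion order.
    """

    network: BooleanNetwork
    parent: BooleanNetwork
    genes: tuple[int, ...]
    deleted: tuple[int, ...]


def _collapse_once(
    table: np.ndarray, pi: np.ndarray, genes: tuple[int, ...], g: int
) -> tuple[np.ndarray, tuple[int, ...]]:
    """Collapse gene g out of a truth table using the current SSD.

    For each reduced state the two parents differ only in gene g; the rule
    of the strictly higher-probability parent wins (ties keep the
    0-parent, per the strict inequality in the collapsing rule).
    """
    m = len(genes)
    b = (m - 1) - genes.index(g)  # LSB position of gene g
    reduced = np.arange(2 ** (m - 1))
    s0 = _insert_bit(reduced, b, 0)
    s1 = _insert_bit(reduced, b, 1)
    src = np.where(pi[s1] > pi[s0], s1, s0)
    new_table = _remove_bit(table[src], b)
    new_genes = tuple(x for x in genes if x != g)
    return new_table, new_genes


def reduce_network(
    model: BooleanNetwork, g: int, pi: np.ndarray | None = None
) -> ReducedModel:
    """Delete one gene from a BNp by SSD-guided state collapsing."""
    if g == model.target:
        raise ValueError("the target gene cannot be deleted")
    if not 1 <= g <= model.n:
        raise ValueError(f"gene {g} out of range for n={model.n}")
    if pi is None:
        pi = model.ssd
    genes = tuple(range(1, model.n + 1))
    new_table, new_genes = _collapse_once(model.truth_table, pi, genes, g)
    # target keeps its positional index among the survivors
    new_target = new_genes.index(model.target) + 1
    red = BooleanNetwork(new_table, p=model.p, target=new_target)
    return ReducedModel(red, model, new_genes, (g,))


def reduce_many(
    model: BooleanNetwork, genes_to_delete, pi: np.ndarray | None = None
) -> ReducedModel:
    """Delete several genes by sequential single-gene collapses.

    Genes are collapsed in the given order; the SSD steering each collapse
    is recomputed on the current (already reduced) network, starting from
    the full network's SSD.
    """
    genes_to_delete = tuple(genes_to_delete)
    if len(set(genes_to_delete)) != len(genes_to_delete):
        raise ValueError("genes to delete must be distinct")
    if model.target in genes_to_delete:
        raise ValueError("the target gene cannot be deleted")
    for g in genes_to_delete:
        if not 1 <= g <= model.n:
            raise ValueError(f"gene {g} out of range for n={model.n}")
    if pi is None:
        pi = model.ssd
    table = model.truth_table
    genes = tuple(range(1, model.n + 1))
    current_pi = pi
    current = model
    for step, g in enumerate(genes_to_delete):
        table, genes = _collapse_once(table, current_pi, genes, g)
        new_target = genes.index(model.target) + 1
        current = BooleanNetwork(table, p=model.p, target=new_target)
        if step < len(genes_to_delete) - 1:
            current_pi = current.ssd
    return ReducedModel(current, model, genes, genes_to_delete)


def _completions(state: int, genes: tuple[int, ...], deleted: tuple[int, ...], n: int) -> np.ndarray:
    """All full states projecting to ``state`` on the surviving genes."""
    m = len(genes)
    bits_r = state_to_bits(np.asarray(state), m)
    surviving_idx = np.array([g - 1 for g in genes])
    deleted_idx = np.array(sorted(g - 1 for g in deleted))
    p = len(deleted_idx)
    out = np.empty(2**p, dtype=np.int64)
    for a, assignment in enumerate(itertools.product((0, 1), repeat=p)):
        bits = np.zeros(n, dtype=np.int64)
        bits[surviving_idx] = bits_r
        bits[deleted_idx] = assignment
        out[a] = bits_to_state(bits)
    return out


def induce_intervention(
    psi_red: Intervention | tuple[int, int],
    pi_full: np.ndarray,
    genes: tuple[int, ...],
    deleted: tuple[int, ...],
    n: int,
) -> Intervention:
    """Lift a reduced-network intervention to the full state space.

    Each endpoint is completed to the full state of maximal probability
    under ``pi_full`` among the ``2**p`` completions of the deleted bits;
    exact ties prefer 1-bits (the numerically larger full state), which
    for a single deleted gene is exactly the >= completion rule.
    """
    if len(genes) + len(deleted) != n:
        raise ValueError("gene bookkeeping does not match full network size")
    out = []
    for s in psi_red:
        cand = _completions(int(s), genes, deleted, n)
        vals = pi_full[cand]
        best = cand[vals == vals.max()].max()
        out.append(int(best))
    return Intervention(*out)


def completion_table(deleted: tuple[int, ...], n: int) -> np.ndarray:
    """All full-state completions of every reduced state, ``(2**m, 2**p)``.

    Row s lists the full states that project to reduced state s when the
    ``deleted`` genes are dropped; used to look completions up in bulk.
    """
    p = len(deleted)
    m = n - p
    positions = sorted(n - g for g in deleted)  # LSB bit positions, ascending
    reduced = np.arange(2**m)
    comp = np.empty((2**m, 2**p), dtype=np.int64)
    for a in range(2**p):
        v = reduced
        for idx, b in enumerate(positions):
            v = _insert_bit(v, b, (a >> idx) & 1)
        comp[:, a] = v
    return comp


def induce_optimal_intervention(
    psi_red, reduced: ReducedModel, pi_full: np.ndarray | None = None
) -> Intervention:
    """Induced optimal intervention: completion by the network's own SSD."""
    if pi_full is None:
        pi_full = reduced.parent.ssd
    return induce_intervention(
        psi_red, pi_full, reduced.genes, reduced.deleted, reduced.parent.n
    )


def induce_robust_intervention(
    psi_red, expected_pi: np.ndarray, reduced: ReducedModel
) -> Intervention:
    """Induced robust intervention: completion by the class-expected SSD."""
    return induce_intervention(
        psi_red, expected_pi, reduced.genes, reduced.deleted, reduced.parent.n
    )


class ReducedEnsemble:
    """Per-member reduced networks and caches for one deletion set.

    Built once per candidate gene set and reused by both the deletion-cost
    evaluation and the final approximate ranking.  The per-conditional-
    class induced robust interventions are computed in one batched pass
    over the class's conditional weight matrix.
    """

    def __init__(self, ensemble: ClassEnsemble, genes_to_delete):
        from .intervention import batch_error_tables

        self.ensemble = ensemble
        self.deleted = tuple(genes_to_delete)
        self.reduced: list[ReducedModel] = [
            reduce_many(net, self.deleted, pi=ensemble.ssds[idx])
            for idx, net in enumerate(ensemble.networks)
        ]
        proto = self.reduced[0]
        tables = np.stack([rm.network.truth_table for rm in self.reduced])
        self.red_errors, _, _ = batch_error_tables(
            tables, proto.network.p, proto.network.target
        )
        m, Sr, _ = self.red_errors.shape
        self._comp = completion_table(self.deleted, proto.parent.n)
        # induced optimal intervention per member and its full-network error
        flat = np.argmin(self.red_errors.reshape(m, -1), axis=1)
        self.induced_opt_errors = np.empty(m)
        for idx in range(m):
            u = self._induce_state(int(flat[idx]) // Sr, ensemble.ssds[idx])
            v = self._induce_state(int(flat[idx]) % Sr, ensemble.ssds[idx])
            self.induced_opt_errors[idx] = ensemble.errors[idx][u, v]
        # batched induced robust interventions for every conditional class
        cond = ensemble.conditional
        W = cond["W"]
        avg_red = W @ self.red_errors.reshape(m, -1)
        flat_r = np.argmin(avg_red, axis=1)
        expected_full = W @ ensemble.ssds  # conditional expected SSDs
        self.cond_psi = np.empty((len(flat_r), 2), dtype=np.int64)
        self.cond_err = np.empty(len(flat_r))
        for r, fr in enumerate(flat_r):
            u = self._induce_state(int(fr) // Sr, expected_full[r])
            v = self._induce_state(int(fr) % Sr, expected_full[r])
            self.cond_psi[r] = (u, v)
            self.cond_err[r] = float(W[r] @ ensemble.errors[:, u, v])

    def _induce_state(self, s: int, pi_full: np.ndarray) -> int:
        """Maximal-probability completion of a reduced state (ties -> 1-bits)."""
        cand = self._comp[s]
        vals = pi_full[cand]
        return int(cand[vals == vals.max()].max())

    def induced_robust(self, mask: np.ndarray) -> tuple[Intervention, float]:
        """Induced robust intervention for an arbitrary member subset, and
        its expected full-network error under the conditional prior."""
        w = self.ensemble.subset_weights(mask)
        psi_red, _ = robust_intervention(self.red_errors[mask], w)
        expected_pi = self.ensemble.expected_ssd(mask)
        psi = Intervention(
            self._induce_state(psi_red.u, expected_pi),
            self._induce_state(psi_red.v, expected_pi),
        )
        idxs = np.flatnonzero(mask)
        err = float(w @ self.ensemble.errors[idxs, psi.u, psi.v])
        return psi, err

    def conditional_h(self, i: int, phi: int) -> float:
        """h_g(theta_i): expected induced-robust error over Theta_{i,phi}."""
        cond = self.ensemble.conditional
        return float(self.cond_err[cond["index"][(i, phi)]])

    def cost(self) -> float:
        """Deletion cost: sum over experiments of the marginal-averaged
        expected induced-robust error."""
        cond = self.ensemble.conditional
        return float(cond["marginal"] @ self.cond_err)

    def ranking_disruption_cost(self) -> float:
        """Equivalent ranking-disruption form: sum_i |M^g(Theta,i) - M(Theta,i)|,
        with M^g using each member's true optimal intervention."""
        uc = self.ensemble.uc
        cond = self.ensemble.conditional
        total = 0.0
        for i in range(1, uc.k + 1):
            mg = 0.0
            m_exact = 0.0
            for phi, w in zip(uc.domain, uc.marginal(i)):
                if w > 0:
                    r = cond["index"][(i, phi)]
                    mg += w * (self.cond_err[r] - float(cond["W"][r] @ self.ensemble.opt_errors))
                    m_exact += w * cond["remaining_mocu"][r]
            total += abs(mg - m_exact)
        return total

    def approximate_scores(self) -> np.ndarray:
        """Expected remaining MOCU per experiment with induced interventions.

        Both terms of the MOCU are approximated: the robust intervention of
        each conditional class by its induced robust intervention, and each
        member's optimal intervention by its induced optimal intervention.
        """
        uc = self.ensemble.uc
        cond = self.ensemble.conditional
        cond_induced_opt = cond["W"] @ self.induced_opt_errors
        scores = np.empty(uc.k)
        for i in range(1, uc.k + 1):
            val = 0.0
            for phi, w in zip(uc.domain, uc.marginal(i)):
                if w > 0:
                    r = cond["index"][(i, phi)]
                    val += w * (self.cond_err[r] - cond_induced_opt[r])
            scores[i - 1] = val
        return scores


def deletion_cost(
    uc: UncertaintyClass, genes, form: str = "surrogate"
) -> float:
    """Cost of deleting a candidate gene set.

    ``form="surrogate"`` is the expected-induced-robust-error sum used for
    the argmin; ``form="ranking-disruption"`` is the absolute-difference
    form it is equivalent to.
    """
    genes = tuple(genes)
    if uc.target in genes:
        raise ValueError("the target gene cannot be deleted")
    re = ReducedEnsemble(uc.ensemble, genes)
    if form == "surrogate":
        return re.cost()
    if form == "ranking-disruption":
        return re.ranking_disruption_cost()
    raise ValueError(f"unknown cost form {form!r}")


def _candidate_sets(uc: UncertaintyClass, n_delete: int, excluded) -> list[tuple[int, ...]]:
    pool = [
        g
        for g in range(1, uc.n + 1)
        if g != uc.target and g not in set(excluded)
    ]
    if n_delete < 1 or len(pool) < n_delete:
        raise ValueError(
            f"search space of {len(pool)} genes cannot support deleting {n_delete}"
        )
    return list(itertools.combinations(pool, n_delete))


def deletion_cost_table(
    uc: UncertaintyClass,
    n_delete: int = 1,
    excluded=(),
    _cache: dict | None = None,
) -> list[tuple[tuple[int, ...], float]]:
    """Deletion cost of every candidate set, in lexicographic set order."""
    ens = uc.ensemble
    out = []
    for genes in _candidate_sets(uc, n_delete, excluded):
        re = ReducedEnsemble(ens, genes) if _cache is None else _cache.setdefault(
            genes, ReducedEnsemble(ens, genes)
        )
        out.append((genes, re.cost()))
    return out


def select_deletion(
    uc: UncertaintyClass, n_delete: int, excluded=()
) -> tuple[int, ...]:
    """Minimum-cost deletion set (ties -> lexicographically smallest set)."""
    table = deletion_cost_table(uc, n_delete, excluded)
    best = min(table, key=lambda t: (t[1], t[0]))
    return best[0]


def approximate_scores(uc: UncertaintyClass, genes) -> np.ndarray:
    """Per-experiment approximate expected remaining MOCU after deleting
    the given gene set."""
    return ReducedEnsemble(uc.ensemble, tuple(genes)).approximate_scores()
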