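"""Independent straight-line oracles used by the test suite.

Everything here deliberately avoids the package's fast paths: steady
states come from a dense null-space solve on an explicitly modified
transition matrix, and the design quantities are recomputed by literal
enumeration.  These implementations are kept naive so they can serve as
ground truth for the closed-form and cached implementations.
"""

from __future__ import annotations

import itertools

import numpy as np


def oracle_tpm(truth_table, p):
    """Transition matrix by explicit enumeration of flip events."""
    S = len(truth_table)
    n = int(np.log2(S))
    P = np.zeros((S, S))
    for x in range(S):
        for y in range(S):
            h = bin(x ^ y).count("1")
            if h >= 1:
                P[x, y] += p**h * (1 - p) ** (n - h)
        P[x, truth_table[x]] += (1 - p) ** n
    return P


def oracle_ssd(P):
    """Stationary vector via eigen-decomposition (independent method)."""
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, i])
    return v / v.sum()


def modified_tpm(model, u, v):
    """TPM after rewiring F(u) = v: exactly two entries change."""
    P = model.tpm.copy()
    q = (1 - model.p) ** model.n
    w = int(model.truth_table[u])
    P[u, w] -= q
    P[u, v] += q
    return P


def direct_intervention_error(model, u, v):
    """Undesirable mass after (u, v) via the modified TPM's own SSD."""
    pi = oracle_ssd(modified_tpm(model, u, v))
    return float(pi[model.undesirable_states].sum())


def brute_optimal_intervention(model):
    """Exhaustive search with direct SSD recomputation per candidate."""
    best = None
    for u in range(model.n_states):
        for v in range(model.n_states):
            err = direct_intervention_error(model, u, v)
            if best is None or err < best[1] - 1e-14:
                best = ((u, v), err)
    return best


def enumerate_networks(uc):
    """(theta, error table, optimal error) per member, via direct SSDs."""
    from mocu_design.network import BooleanNetwork, truth_table_from_matrix

    out = []
    for theta in itertools.product(uc.domain, repeat=uc.k):
        R = uc.R.copy()
        for (i, j), val in zip(uc.positions, theta):
            R[i - 1, j - 1] = val
        model = BooleanNetwork(
            truth_table_from_matrix(R), p=uc.p, target=uc.target
        )
        S = model.n_states
        E = np.array(
            [
                [direct_intervention_error(model, u, v) for v in range(S)]
                for u in range(S)
            ]
        )
        out.append((theta, E, E.min()))
    return out


def straight_line_design(uc):
    """Literal recomputation of the MOCU experiment ranking.

    Enumerates the class with direct-SSD error tables, forms each
    conditional class, finds its robust intervention by averaging errors,
    and returns (selected experiment, expected remaining MOCU scores).
    """
    members = enumerate_networks(uc)
    thetas = [t for t, _, _ in members]
    weights = []
    for theta in thetas:
        w = 1.0
        for i, val in enumerate(theta, start=1):
            w *= uc.marginal(i)[uc.domain.index(val)]
        weights.append(w)
    weights = np.array(weights)

    def mocu_of(indices):
        w = weights[indices]
        w = w / w.sum()
        avg = sum(wi * members[i][1] for wi, i in zip(w, indices))
        robust_err = avg.min()
        opt = sum(wi * members[i][2] for wi, i in zip(w, indices))
        return robust_err - opt

    scores = []
    for i in range(1, uc.k + 1):
        total = 0.0
        for phi, mw in zip(uc.domain, uc.marginal(i)):
            idx = [j for j, t in enumerate(thetas) if t[i - 1] == phi]
            if mw > 0:
                total += mw * mocu_of(idx)
        scores.append(total)
    scores = np.array(scores)
    return int(np.argmin(scores)) + 1, scores
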