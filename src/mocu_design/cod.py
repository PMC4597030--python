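"""Coefficient of determination (CoD) and CoD-based gene exclusion.

The CoD of a binary target Y relative to a predictor gene set X is the
relative reduction in optimal (Bayes) prediction error:

    CoD_X(Y) = (eps_Y - eps_{X,Y}) / eps_Y,

with eps_Y = min(P(Y=0), P(Y=1)) and eps_{X,Y} the expected minimum of the
two conditional target probabilities given X.  Here the joint law of
(X, Y) is read off the network's steady-state distribution: predictor and
target values are taken from the same state at equilibrium, so the CoD
measures how strongly a gene set pins down the target gene in the long
run.  Genes strongly tied to the target (large expected CoD over the
uncertainty class) are excluded from the deletion search space.
"""

from __future__ import annotations

import itertools

import numpy as np

from .network import BooleanNetwork, state_to_bits
from .uncertainty import UncertaintyClass

__all__ = ["cod", "network_cod", "expected_cod", "exclusion_set", "cod_table"]


def cod(joint: np.ndarray) -> float:
    """CoD from a joint pmf over (X, Y), shape ``(2**m, 2)``.

    Row j holds P(X=j, Y=0), P(X=j, Y=1).  A degenerate target
    (eps_Y = 0) yields CoD 0: a constant gene cannot be better predicted.
    """
    joint = np.asarray(joint, dtype=float)
    if joint.ndim != 2 or joint.shape[1] != 2:
        raise ValueError("joint must have shape (2**m, 2)")
    if (joint < -1e-12).any() or abs(joint.sum() - 1.0) > 1e-9:
        raise ValueError("joint must be a probability mass function")
    py = joint.sum(axis=0)
    eps_y = min(py[0], py[1])
    if eps_y <= 0.0:
        return 0.0
    eps_xy = joint.min(axis=1).sum()
    return float((eps_y - eps_xy) / eps_y)


def network_cod(model: BooleanNetwork, X, Y: int | None = None) -> float:
    """CoD of the target gene given predictor genes, under the model's SSD."""
    X = tuple(X)
    if Y is None:
        Y = model.target
    if not X:
        raise ValueError("predictor set must be nonempty")
    if Y in X:
        raise ValueError("target gene cannot be its own predictor")
    pi = model.ssd
    bits = state_to_bits(np.arange(model.n_states), model.n)  # (S, n)
    xbits = bits[:, [g - 1 for g in X]]
    xidx = xbits @ (1 << np.arange(len(X) - 1, -1, -1))
    ybit = bits[:, Y - 1]
    joint = np.zeros((2 ** len(X), 2))
    np.add.at(joint, (xidx, ybit), pi)
    return cod(joint)


def expected_cod(uc: UncertaintyClass, X, Y: int | None = None) -> float:
    """Prior-expected CoD over the uncertainty class."""
    ens = uc.ensemble
    vals = np.array([network_cod(net, X, Y) for net in ens.networks])
    return float(ens.weights @ vals)


def cod_table(uc: UncertaintyClass, block: int = 3):
    """Expected CoD of every predictor combination, ranked (TSV-ready).

    One row per ``block``-gene combination with the class-expected CoD and
    each member gene's expected individual CoD.
    """
    import pandas as pd

    pool = [g for g in range(1, uc.n + 1) if g != uc.target]
    indiv = {g: expected_cod(uc, (g,)) for g in pool}
    rows = []
    for combo in itertools.combinations(pool, block):
        rows.append(
            {
                "combination": ",".join(map(str, combo)),
                "expected_cod": expected_cod(uc, combo),
                "individual_cods": ",".join(f"{indiv[g]:.6g}" for g in combo),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["expected_cod", "combination"], ascending=[False, True]
    )
    return df.reset_index(drop=True)


def exclusion_set(uc: UncertaintyClass, s: int, block: int = 3) -> tuple[int, ...]:
    """Genes to exclude from the deletion search, by multivariate CoD.

    Ranks all ``block``-gene predictor combinations (target never a
    predictor) by expected CoD; walks the ranking from the top, taking the
    unseen genes of each combination in descending order of expected
    individual CoD, until ``s`` genes are collected.  All ties break
    toward the lower gene index.
    """
    n = uc.n
    if not 1 <= s <= n - 2:
        raise ValueError(f"cannot exclude {s} genes from an {n}-gene network")
    pool = [g for g in range(1, n + 1) if g != uc.target]
    if len(pool) < block:
        raise ValueError("not enough genes to form predictor combinations")
    combos = list(itertools.combinations(pool, block))
    combo_scores = [expected_cod(uc, c) for c in combos]
    # stable sort: descending score, ties toward the lexicographically
    # smaller combination
    order = sorted(range(len(combos)), key=lambda i: (-combo_scores[i], combos[i]))
    indiv = {g: expected_cod(uc, (g,)) for g in pool}
    chosen: list[int] = []
    for ci in order:
        members = [g for g in combos[ci] if g not in chosen]
        members.sort(key=lambda g: (-indiv[g], g))
        for g in members:
            chosen.append(g)
            if len(chosen) == s:
                return tuple(chosen)
    raise RuntimeError("ran out of combinations before excluding s genes")
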