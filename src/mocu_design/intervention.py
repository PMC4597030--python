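"""Single-gene structural interventions and their steady-state effect.

An intervention ``(u, v)`` rewires the deterministic rule at a single
state: after intervention ``F(u) = v`` while every other state keeps its
successor.  Only two TPM entries change, and the perturbed SSD has a
closed form in the fundamental matrix Z:

    pi~_i(u, v) = pi_i + (1-p)^n pi_u (z_vi - z_wi)
                  / (1 - (1-p)^n (z_vu - z_wu)),   w = F(u).

The intervention error is the undesirable steady-state mass after the
rewiring; the optimal intervention minimises it over all ``2**n x 2**n``
state pairs (the no-op ``(u, F(u))`` is in the search space, so the
optimum never exceeds the unintervened mass).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .network import BooleanNetwork

__all__ = [
    "Intervention",
    "perturbed_ssd",
    "intervention_error",
    "error_table",
    "batch_error_tables",
    "optimal_intervention",
    "robust_intervention",
    "controllability",
    "intervention_to_strings",
]

#: Denominators of the closed form closer to zero than this are treated as
#: infeasible pairs and excluded from argmin searches.
DENOM_TOL = 1e-12


class Intervention(NamedTuple):
    """A structural intervention redefining ``F(u) = v``."""

    u: int
    v: int


def perturbed_ssd(model: BooleanNetwork, psi: Intervention | tuple[int, int]) -> np.ndarray:
    """SSD after intervention ``(u, v)`` via the fundamental-matrix closed form."""
    u, v = psi
    if not (0 <= u < model.n_states and 0 <= v < model.n_states):
        raise ValueError(f"intervention ({u}, {v}) out of state range")
    pi, Z = model.ssd, model.fundamental
    w = int(model.truth_table[u])
    q = (1.0 - model.p) ** model.n
    denom = 1.0 - q * (Z[v, u] - Z[w, u])
    if abs(denom) < DENOM_TOL:
        raise ArithmeticError(f"infeasible intervention ({u}, {v}): zero denominator")
    return pi + q * pi[u] * (Z[v] - Z[w]) / denom


def intervention_error(model: BooleanNetwork, psi: Intervention | tuple[int, int]) -> float:
    """Undesirable steady-state mass after applying the intervention."""
    pit = perturbed_ssd(model, psi)
    return float(pit[model.undesirable_states].sum())


def batch_error_tables(
    truth_tables: np.ndarray, p: float, target: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Intervention error tables for a batch of BNps sharing n, p, target.

    Parameters
    ----------
    truth_tables : array, shape (m, 2**n)
        Deterministic rules of the m networks.
    p, target :
        Shared perturbation probability and 1-based target gene.

    Returns ``(errors, ssds, pi_u)``: per-network error tables
    ``(m, 2**n, 2**n)``, steady-state distributions and unintervened
    undesirable masses.  Entry ``errors[t, u, v]`` is the undesirable mass
    after rewiring ``F(u) = v`` in network t, computed from the
    fundamental-matrix closed form via the undesirable column sums
    ``S_v = sum_{i in U} z_vi``.  Infeasible pairs (vanishing denominator)
    are ``+inf`` so argmin searches skip them.  All chain quantities are
    computed with batched LAPACK calls.
    """
    from .network import build_tpm  # local import to avoid a cycle at import time

    tables = np.atleast_2d(np.asarray(truth_tables, dtype=np.int64))
    m, S = tables.shape
    n = int(np.log2(S))
    q = (1.0 - p) ** n
    kernel = build_tpm(np.arange(S), p)
    kernel[np.arange(S), np.arange(S)] -= q  # bare flip kernel
    P = np.empty((m, S, S))
    P[:] = kernel
    P[np.arange(m)[:, None], np.arange(S)[None, :], tables] += q
    # batched SSD: replace the last balance equation by normalisation
    A = np.transpose(P, (0, 2, 1)) - np.eye(S)
    A[:, -1, :] = 1.0
    b = np.zeros(S)
    b[-1] = 1.0
    try:
        pi = np.linalg.solve(A, np.broadcast_to(b[:, None], (m, S, 1)))[..., 0]
    except np.linalg.LinAlgError as exc:  # pragma: no cover - p>0 prevents this
        raise ArithmeticError(f"singular balance system: {exc}") from exc
    resid = np.abs(np.einsum("ms,msv->mv", pi, P) - pi).max()
    if resid > 1e-8:
        raise ArithmeticError(f"steady-state residual {resid:.2e} too large")
    # batched fundamental matrix Z = (I - P + e pi^T)^-1
    try:
        Z = np.linalg.inv(np.eye(S) - P + pi[:, None, :])
    except np.linalg.LinAlgError as exc:
        raise ArithmeticError(f"fundamental matrix is singular: {exc}") from exc
    states = np.arange(S)
    U = (states >> (n - target)) & 1 == 1
    pi_u = pi[:, U].sum(axis=1)
    Svec = Z @ U.astype(float)  # (m, S): S_v = sum_{i in U} z_vi
    Zw_u = Z[np.arange(m)[:, None], tables, np.arange(S)[None, :]]  # z_{w(u),u}
    Sw = np.take_along_axis(Svec, tables, axis=1)  # S_{w(u)}
    # in-place assembly to keep the (m, S, S) temporaries to a minimum
    denom = np.subtract(np.transpose(Z, (0, 2, 1)), Zw_u[:, :, None])  # z_vu - z_wu
    denom *= -q
    denom += 1.0
    E = np.subtract(Svec[:, None, :], Sw[:, :, None])
    E *= (q * pi)[:, :, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        E /= denom
    E += pi_u[:, None, None]
    E[np.abs(denom) < DENOM_TOL] = np.inf
    return E, pi, pi_u


def error_table(model: BooleanNetwork) -> np.ndarray:
    """Errors of every candidate intervention, as a ``(2**n, 2**n)`` array.

    Entry ``[u, v]`` is the undesirable mass after intervention ``(u, v)``;
    infeasible pairs (vanishing closed-form denominator) are ``+inf``.
    """
    E, _, _ = batch_error_tables(model.truth_table[None, :], model.p, model.target)
    return E[0]


def _argmin_pair(E: np.ndarray) -> tuple[Intervention, float]:
    """Lexicographically-first minimiser of an error table (ties -> smallest (u, v))."""
    flat = int(np.argmin(E))
    m = E.shape[1]
    return Intervention(flat // m, flat % m), float(E.flat[flat])


def optimal_intervention(
    model: BooleanNetwork, errors: np.ndarray | None = None
) -> tuple[Intervention, float]:
    """Exhaustive-search optimal intervention and its error.

    Ties are broken by the lexicographically smallest ``(u, v)``.  A
    precomputed ``error_table`` may be passed to avoid recomputation.
    """
    if errors is None:
        errors = error_table(model)
    return _argmin_pair(errors)


def robust_intervention(
    errors: np.ndarray, weights: np.ndarray
) -> tuple[Intervention, float]:
    """Intrinsically Bayesian robust intervention over an uncertainty class.

    Parameters
    ----------
    errors : array, shape (m, 2**n, 2**n)
        Per-network intervention error tables.
    weights : array, shape (m,)
        Prior weights of the class members (must sum to 1).

    Returns the intervention minimising the prior-expected error, and that
    expected error.  A pair infeasible for any member is excluded (inf
    propagates through the average).
    """
    errors = np.asarray(errors)
    weights = np.asarray(weights, dtype=float)
    if errors.ndim != 3 or len(weights) != errors.shape[0]:
        raise ValueError("need one error table per class member")
    if len(weights) == 0:
        raise ValueError("empty uncertainty class")
    avg = np.tensordot(weights, errors, axes=1)
    return _argmin_pair(avg)


def controllability(model: BooleanNetwork, errors: np.ndarray | None = None) -> float:
    """Percentage decrease of undesirable mass under the optimal intervention.

    ``Delta = (pi_U - pi~_U) / pi_U * 100``; 0 for an uncontrollable
    network (no-op optimal), at most 100.
    """
    _, best = optimal_intervention(model, errors)
    return (model.pi_u - best) / model.pi_u * 100.0


def intervention_to_strings(psi: Intervention | tuple[int, int], n: int) -> tuple[str, str]:
    """Render an intervention as binary gene-value strings, gene 1 leftmost."""
    u, v = psi
    return format(u, f"0{n}b"), format(v, f"0{n}b")
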