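"""Boolean networks with perturbation (BNp) and their Markov-chain quantities.

A BNp on ``n`` genes is a deterministic Boolean update rule ``F`` over the
``2**n`` gene activity profiles, plus an independent per-gene flip
probability ``p``.  With probability ``(1-p)**n`` the state follows ``F``;
otherwise at least one gene flips.  For ``p > 0`` the chain is ergodic and
has a unique steady-state distribution (SSD) ``pi`` with
``pi.T @ P = pi.T``.

State encoding: gene 1 is the most significant bit, so for ``n = 11`` the
states with gene 1 up-regulated are ``{1024, ..., 2047}``.  Gene indices
are 1-based throughout the public API, matching the field's convention of
naming the intervention target "gene 1".
"""

from __future__ import annotations

from functools import cached_property

import numpy as np
import scipy.linalg

__all__ = [
    "RegulatoryMatrix",
    "BooleanNetwork",
    "majority_vote_next",
    "truth_table_from_matrix",
    "build_tpm",
    "steady_state",
    "fundamental_matrix",
    "undesirable_mass",
    "state_to_bits",
    "bits_to_state",
]

DEFAULT_P = 0.001


def validate_regulatory_matrix(R: np.ndarray) -> np.ndarray:
    """Validate a signed regulatory matrix and return it as an int array.

    Entry ``(i, j)`` is +1 if gene j activates gene i, -1 if it suppresses
    it and 0 for no regulation.
    """
    R = np.asarray(R)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError(f"regulatory matrix must be square, got shape {R.shape}")
    if R.shape[0] < 2:
        raise ValueError("need at least 2 genes (target plus one regulator)")
    if not np.isin(R, (-1, 0, 1)).all():
        raise ValueError("regulatory matrix entries must be in {-1, 0, +1}")
    return R.astype(np.int8)


# alias used in type hints: an n x n signed integer matrix
RegulatoryMatrix = np.ndarray


def state_to_bits(state: int | np.ndarray, n: int) -> np.ndarray:
    """Decode state index(es) into gene bit vectors, gene 1 first (MSB)."""
    state = np.asarray(state)
    shifts = np.arange(n - 1, -1, -1)
    return (state[..., None] >> shifts) & 1


def bits_to_state(bits: np.ndarray) -> np.ndarray | int:
    """Pack gene bit vectors (gene 1 first) into state indexes."""
    bits = np.asarray(bits)
    n = bits.shape[-1]
    weights = 1 << np.arange(n - 1, -1, -1)
    out = bits @ weights
    return out


def majority_vote_next(R: RegulatoryMatrix, state: int) -> int:
    """One synchronous majority-vote update of a single state.

    Gene i turns ON when its active activators outnumber its active
    suppressors (``sum_j R[i, j] * X_j > 0``), OFF when they are
    outnumbered, and keeps its value on a tie.
    """
    R = validate_regulatory_matrix(R)
    n = R.shape[0]
    if not 0 <= state < 2**n:
        raise ValueError(f"state {state} out of range for n={n}")
    bits = state_to_bits(state, n)
    score = R @ bits
    nxt = np.where(score > 0, 1, np.where(score < 0, 0, bits))
    return int(bits_to_state(nxt))


def truth_table_from_matrix(R: RegulatoryMatrix) -> np.ndarray:
    """Tabulate the majority-vote rule over all ``2**n`` states."""
    R = validate_regulatory_matrix(R)
    n = R.shape[0]
    states = np.arange(2**n)
    bits = state_to_bits(states, n)  # (2^n, n)
    score = bits @ R.T.astype(np.int64)  # (2^n, n), column i = input to gene i
    nxt = np.where(score > 0, 1, np.where(score < 0, 0, bits))
    return bits_to_state(nxt).astype(np.int64)


def _perturbation_kernel(n: int, p: float) -> np.ndarray:
    """Hamming-distance flip kernel: mass of moving x -> y by perturbation.

    Entry (x, y) is ``p**H * (1-p)**(n-H)`` for Hamming distance
    ``H(x, y) >= 1`` and 0 on the diagonal (no flip means F applies).
    """
    states = np.arange(2**n)
    xor = states[:, None] ^ states[None, :]
    # popcount via uint8 view of the xor table
    ham = np.zeros(xor.shape, dtype=np.int64)
    v = xor.copy()
    while v.any():
        ham += v & 1
        v >>= 1
    K = (p**ham) * ((1.0 - p) ** (n - ham))
    np.fill_diagonal(K, 0.0)
    return K


_KERNEL_CACHE: dict[tuple[int, float], np.ndarray] = {}


def build_tpm(truth_table: np.ndarray, p: float) -> np.ndarray:
    """Transition probability matrix of the BNp.

    ``P[x, y]`` sums the probability of reaching y by a perturbation event
    (each gene flips independently with probability p, at least one flip)
    and, when ``y == F(x)``, the no-flip probability ``(1-p)**n``.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("perturbation probability must be in (0, 1)")
    table = np.asarray(truth_table)
    n = int(np.log2(len(table)))
    if 2**n != len(table):
        raise ValueError("truth table length must be a power of two")
    key = (n, float(p))
    if key not in _KERNEL_CACHE:
        _KERNEL_CACHE[key] = _perturbation_kernel(n, p)
    P = _KERNEL_CACHE[key].copy()
    P[np.arange(2**n), table] += (1.0 - p) ** n
    return P


def steady_state(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of an ergodic chain by direct linear solve.

    Solves ``pi.T (P - I) = 0`` with one balance equation replaced by the
    normalisation ``sum(pi) = 1``; deterministic and exact to solver
    precision, unlike power iteration.
    """
    P = np.asarray(P, dtype=float)
    m = P.shape[0]
    A = P.T - np.eye(m)
    A[-1, :] = 1.0
    b = np.zeros(m)
    b[-1] = 1.0
    try:
        pi = scipy.linalg.solve(A, b)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - p>0 prevents this
        raise ArithmeticError(f"singular balance system: {exc}") from exc
    resid = np.abs(pi @ P - pi).max()
    if resid > 1e-8:
        raise ArithmeticError(f"steady-state residual {resid:.2e} too large")
    return pi


def fundamental_matrix(P: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Fundamental matrix ``Z = (I - P + e pi.T)**-1`` of the chain.

    The identity here is full state-space dimensional (``2**n``); the
    closed-form effect of a single-state rule change on the SSD is a ratio
    of its entries.
    """
    m = P.shape[0]
    A = np.eye(m) - P + np.outer(np.ones(m), pi)
    try:
        return scipy.linalg.inv(A)
    except scipy.linalg.LinAlgError as exc:
        raise ArithmeticError(f"fundamental matrix is singular: {exc}") from exc


def undesirable_mass(pi: np.ndarray, target: int, n: int) -> float:
    """Steady-state mass of states whose target gene is up-regulated."""
    if not 1 <= target <= n:
        raise ValueError(f"target gene {target} out of range for n={n}")
    states = np.arange(len(pi))
    mask = (states >> (n - target)) & 1 == 1
    return float(pi[mask].sum())


class BooleanNetwork:
    """An n-gene Boolean network with perturbation.

    Parameters
    ----------
    truth_table : array of length 2**n
        Successor state of every state under the deterministic rule F.
    p : float
        Per-gene perturbation probability, in (0, 1).
    target : int
        1-based index of the target gene; states with this gene ON are
        the undesirable ones.
    R : array, optional
        The signed regulatory matrix the rule was derived from, if any.

    TPM, SSD, fundamental matrix and undesirable mass are computed lazily
    and cached on the instance.
    """

    def __init__(
        self,
        truth_table: np.ndarray,
        p: float = DEFAULT_P,
        target: int = 1,
        R: RegulatoryMatrix | None = None,
    ):
        table = np.asarray(truth_table, dtype=np.int64)
        n = int(np.log2(len(table)))
        if 2**n != len(table):
            raise ValueError("truth table length must be a power of two")
        if table.min() < 0 or table.max() >= 2**n:
            raise ValueError("truth table entries out of state range")
        if not 0.0 < p < 1.0:
            raise ValueError("perturbation probability must be in (0, 1)")
        if not 1 <= target <= n:
            raise ValueError(f"target gene {target} out of range for n={n}")
        self.truth_table = table
        self.n = n
        self.n_states = 2**n
        self.p = float(p)
        self.target = int(target)
        self.R = None if R is None else validate_regulatory_matrix(R)

    @classmethod
    def from_regulatory_matrix(
        cls, R: RegulatoryMatrix, p: float = DEFAULT_P, target: int = 1
    ) -> "BooleanNetwork":
        """Build the majority-vote BNp defined by a signed regulatory matrix."""
        R = validate_regulatory_matrix(R)
        return cls(truth_table_from_matrix(R), p=p, target=target, R=R)

    @cached_property
    def tpm(self) -> np.ndarray:
        return build_tpm(self.truth_table, self.p)

    @cached_property
    def ssd(self) -> np.ndarray:
        return steady_state(self.tpm)

    @cached_property
    def fundamental(self) -> np.ndarray:
        return fundamental_matrix(self.tpm, self.ssd)

    @cached_property
    def undesirable_states(self) -> np.ndarray:
        states = np.arange(self.n_states)
        return (states >> (self.n - self.target)) & 1 == 1

    @cached_property
    def pi_u(self) -> float:
        """Undesirable steady-state mass before intervention."""
        return float(self.ssd[self.undesirable_states].sum())

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"BooleanNetwork(n={self.n}, p={self.p}, target={self.target})"
        )
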