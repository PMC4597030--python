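"""Uncertainty classes over regulatory networks and MOCU quantities.

An uncertainty class fixes a regulatory matrix except at ``k`` designated
positions whose regulation sign is unknown; each uncertain parameter
``theta_i`` takes a value in ``{-1, +1}`` with an independent prior
(uniform by default), so the class enumerates ``2**k`` concrete majority-
vote BNps.

The mean objective cost of uncertainty (MOCU) is the prior-expected excess
error of the robust intervention over each member network's own optimum:

    M(Theta) = E_theta[ xi_theta(psi_IBR(Theta)) - xi_theta(psi(theta)) ] >= 0.

An experiment E_i reveals theta_i exactly.  The design criterion is the
expected remaining MOCU after the experiment, averaged over the marginal
prior of theta_i; the optimal experiment minimises it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .intervention import batch_error_tables, robust_intervention
from .network import DEFAULT_P, BooleanNetwork, validate_regulatory_matrix

__all__ = [
    "UncertaintyClass",
    "ClassEnsemble",
    "enumerate_class",
    "mocu",
    "remaining_mocu",
    "expected_remaining_mocu",
    "optimal_experiment",
]

#: Enumeration safety cap: classes larger than this raise a CapacityError.
DEFAULT_MAX_NETWORKS = 2**12


class CapacityError(RuntimeError):
    """Raised when a class is too large for exhaustive enumeration."""


@dataclass(frozen=True)
class UncertaintyClass:
    """A base regulatory matrix with k sign-uncertain regulation positions.

    Parameters
    ----------
    R : array
        Signed base matrix; the values stored at uncertain positions are
        ignored during enumeration (they are overwritten by each theta).
    positions : sequence of (i, j)
        1-based (regulated, regulator) coordinates of the uncertain
        regulations; must be distinct regulation sites.
    p, target :
        BNp perturbation probability and 1-based target gene.
    marginals : array (k, 2), optional
        Per-parameter prior P(theta_i = -1), P(theta_i = +1); uniform by
        default.  The joint prior is the product of marginals.
    """

    R: np.ndarray
    positions: tuple[tuple[int, int], ...]
    p: float = DEFAULT_P
    target: int = 1
    marginals: np.ndarray | None = None
    domain: tuple[int, ...] = (-1, 1)
    max_networks: int = DEFAULT_MAX_NETWORKS

    def __post_init__(self):
        R = validate_regulatory_matrix(self.R)
        object.__setattr__(self, "R", R)
        pos = tuple((int(i), int(j)) for i, j in self.positions)
        if len(set(pos)) != len(pos):
            raise ValueError("uncertain positions must be distinct")
        n = R.shape[0]
        for i, j in pos:
            if not (1 <= i <= n and 1 <= j <= n):
                raise ValueError(f"position {(i, j)} out of range for n={n}")
        object.__setattr__(self, "positions", pos)
        if self.marginals is not None:
            m = np.asarray(self.marginals, dtype=float)
            if m.shape != (len(pos), len(self.domain)):
                raise ValueError("marginals must be (k, l)")
            if (m < 0).any() or not np.allclose(m.sum(axis=1), 1.0):
                raise ValueError("marginals must be probability rows")
            object.__setattr__(self, "marginals", m)

    @property
    def n(self) -> int:
        return self.R.shape[0]

    @property
    def k(self) -> int:
        return len(self.positions)

    def marginal(self, i: int) -> np.ndarray:
        """Prior marginal of parameter i (1-based), over the domain order."""
        if self.marginals is None:
            return np.full(len(self.domain), 1.0 / len(self.domain))
        return self.marginals[i - 1]

    def network_for(self, theta: tuple[int, ...]) -> BooleanNetwork:
        """The concrete majority-vote BNp for one joint assignment."""
        R = self.R.copy()
        for (gi, gj), val in zip(self.positions, theta):
            R[gi - 1, gj - 1] = val
        return BooleanNetwork.from_regulatory_matrix(R, p=self.p, target=self.target)

    @cached_property
    def ensemble(self) -> "ClassEnsemble":
        """Enumerated members with cached error tables (built on demand)."""
        return ClassEnsemble.from_class(self)


def enumerate_class(uc: UncertaintyClass):
    """Enumerate (theta, model, weight) triples in lexicographic theta order.

    Weights are products of the per-parameter marginals and sum to 1.
    """
    l = len(uc.domain)
    if l**uc.k > uc.max_networks:
        raise CapacityError(
            f"class of {l}**{uc.k} networks exceeds cap {uc.max_networks}"
        )
    out = []
    for theta in itertools.product(uc.domain, repeat=uc.k):
        w = 1.0
        for i, val in enumerate(theta, start=1):
            w *= uc.marginal(i)[uc.domain.index(val)]
        out.append((theta, uc.network_for(theta), w))
    return out


@dataclass
class ClassEnsemble:
    """Cached per-member quantities for one uncertainty class.

    Holds, for each joint assignment theta (lexicographic order): the
    concrete network, its prior weight, full intervention error table,
    per-network optimal error, and SSD.  All MOCU quantities are weighted
    reductions over these caches; robust interventions reuse the same
    tables ("finding robust interventions does not require additional
    calculations").
    """

    uc: UncertaintyClass
    thetas: np.ndarray  # (m, k)
    weights: np.ndarray  # (m,)
    networks: list = field(repr=False)
    errors: np.ndarray = field(repr=False)  # (m, S, S)
    opt_errors: np.ndarray = None  # (m,)
    ssds: np.ndarray = field(default=None, repr=False)  # (m, S)
    pi_u: np.ndarray = field(default=None, repr=False)  # (m,)

    @classmethod
    def from_class(cls, uc: UncertaintyClass) -> "ClassEnsemble":
        triples = enumerate_class(uc)
        thetas = np.array([t for t, _, _ in triples])
        weights = np.array([w for _, _, w in triples])
        networks = [m for _, m, _ in triples]
        tables = np.stack([m.truth_table for m in networks])
        errors, ssds, pi_u = batch_error_tables(tables, uc.p, uc.target)
        opt_errors = errors.reshape(len(networks), -1).min(axis=1)
        ens = cls(uc, thetas, weights, networks, errors, opt_errors, ssds)
        ens.pi_u = pi_u
        # seed the member caches so later SSD access reuses the batch solve
        for net, pi in zip(networks, ssds):
            net.__dict__["ssd"] = pi
        return ens

    @property
    def m(self) -> int:
        return len(self.weights)

    def condition(self, i: int, phi: int) -> np.ndarray:
        """Boolean member mask of the remaining class with theta_i = phi."""
        if not 1 <= i <= self.uc.k:
            raise ValueError(f"experiment index {i} out of range")
        if phi not in self.uc.domain:
            raise ValueError(f"outcome {phi} not in parameter domain")
        return self.thetas[:, i - 1] == phi

    def subset_weights(self, mask: np.ndarray) -> np.ndarray:
        """Renormalised conditional prior over a member subset."""
        w = self.weights[mask]
        total = w.sum()
        if total <= 0:
            raise ValueError("conditioning on a zero-probability outcome")
        return w / total

    def robust(self, mask: np.ndarray | None = None):
        """IBR intervention and its expected error over a member subset."""
        if mask is None:
            mask = np.ones(self.m, dtype=bool)
        return robust_intervention(self.errors[mask], self.subset_weights(mask))

    def mocu_of(self, mask: np.ndarray | None = None) -> float:
        """MOCU of the (sub)class selected by the mask."""
        if mask is None:
            mask = np.ones(self.m, dtype=bool)
        w = self.subset_weights(mask)
        _, robust_err = self.robust(mask)
        return robust_err - float(w @ self.opt_errors[mask])

    def expected_ssd(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Prior-expected SSD over a member subset (Algorithm-3 input)."""
        if mask is None:
            mask = np.ones(self.m, dtype=bool)
        return self.subset_weights(mask) @ self.ssds[mask]

    @cached_property
    def conditional(self) -> dict:
        """Batched per-(experiment, outcome) conditional-class quantities.

        One row per (i, phi) with positive marginal prior: the member
        mask, the renormalised conditional weights (zero off-mask), the
        row's marginal weight, the conditional robust intervention and its
        expected error, and the remaining MOCU.  Shared by the exact
        design, the deletion-cost evaluation and the approximate ranking.
        """
        uc = self.uc
        index: dict[tuple[int, int], int] = {}
        masks, W, marg = [], [], []
        for i in range(1, uc.k + 1):
            for phi, mw in zip(uc.domain, uc.marginal(i)):
                if mw <= 0:
                    continue
                mask = self.condition(i, phi)
                w = np.where(mask, self.weights, 0.0)
                w /= w.sum()
                index[(i, phi)] = len(masks)
                masks.append(mask)
                W.append(w)
                marg.append(mw)
        masks = np.array(masks, dtype=bool).reshape(len(masks), self.m)
        W = np.array(W, dtype=float).reshape(len(W), self.m)
        marg = np.array(marg)
        avg = W @ self.errors.reshape(self.m, -1)  # (rows, S*S)
        flat = np.argmin(avg, axis=1)
        S = self.errors.shape[1]
        robust_psi = np.stack([flat // S, flat % S], axis=1)
        robust_err = avg[np.arange(len(flat)), flat]
        remaining = robust_err - W @ self.opt_errors
        return {
            "index": index,
            "masks": masks,
            "W": W,
            "marginal": marg,
            "robust_psi": robust_psi,
            "robust_err": robust_err,
            "remaining_mocu": remaining,
        }


def mocu(uc: UncertaintyClass) -> float:
    """MOCU of the full class: expected robust-minus-optimal error gap."""
    return uc.ensemble.mocu_of()


def remaining_mocu(uc: UncertaintyClass, i: int, phi: int) -> float:
    """MOCU remaining once experiment i reveals theta_i = phi."""
    ens = uc.ensemble
    return ens.mocu_of(ens.condition(i, phi))


def expected_remaining_mocu(uc: UncertaintyClass, i: int) -> float:
    """Design criterion: marginal-prior average of the remaining MOCU."""
    if not 1 <= i <= uc.k:
        raise ValueError(f"experiment index {i} out of range")
    cond = uc.ensemble.conditional
    total = 0.0
    for phi, w in zip(uc.domain, uc.marginal(i)):
        if w > 0:
            total += w * cond["remaining_mocu"][cond["index"][(i, phi)]]
    return float(total)


def optimal_experiment(uc: UncertaintyClass) -> tuple[int, np.ndarray]:
    """Optimal first experiment: argmin of expected remaining MOCU.

    Returns the 1-based experiment index (ties -> lowest index) and the
    full vector of per-experiment scores.
    """
    if uc.k < 1:
        raise ValueError("need at least one uncertain parameter")
    scores = np.array([expected_remaining_mocu(uc, i) for i in range(1, uc.k + 1)])
    return int(np.argmin(scores)) + 1, scores
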