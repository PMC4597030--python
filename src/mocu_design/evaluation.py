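"""Synthetic-network studies: random BNp generation, experiment gains,
sequential designs, controllability stratification and computational gain.

The study protocol generates random majority-vote networks (3 signed
predictors per gene, perturbation probability 0.001, gene 1 the target),
hides the signs of k randomly chosen regulations, runs a design method to
pick the first experiment, and scores it against a uniformly random
experiment by the gain

    rho = xi_mu(psi_IBR(Theta_{rnd, mu_rnd})) - xi_mu(psi_IBR(Theta_{i*, mu_i*})),

evaluated on the ground-truth network mu.  Positive rho means the designed
experiment led to a better robust intervention than the random one.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .intervention import controllability as _controllability
from .network import DEFAULT_P, validate_regulatory_matrix
from .reduction import ReducedEnsemble
from .uncertainty import CapacityError, UncertaintyClass

__all__ = [
    "generate_random_network",
    "sample_uncertain_positions",
    "computational_gain",
    "Trial",
    "StudyConfig",
    "batch_study",
    "sequential_evaluation",
]


def generate_random_network(
    n: int,
    predictors_per_gene: int = 3,
    rng: np.random.Generator | int | None = None,
    allow_self_loops: bool = False,
) -> np.ndarray:
    """Random signed regulatory matrix: each gene gets ``predictors_per_gene``
    distinct regulators (no self-loops by default), each activating or
    suppressive with probability 1/2."""
    if n < predictors_per_gene + 1:
        raise ValueError(
            f"n={n} too small for {predictors_per_gene} distinct non-self predictors"
        )
    rng = np.random.default_rng(rng)
    R = np.zeros((n, n), dtype=np.int8)
    for i in range(n):
        pool = [j for j in range(n) if allow_self_loops or j != i]
        preds = rng.choice(pool, size=predictors_per_gene, replace=False)
        signs = rng.choice([-1, 1], size=predictors_per_gene)
        R[i, preds] = signs
    return R


def sample_uncertain_positions(
    R: np.ndarray, k: int, rng: np.random.Generator | int | None = None
) -> tuple[tuple[int, int], ...]:
    """k distinct nonzero positions of R, uniform without replacement.

    Returned 1-based and sorted, so experiment indices are reproducible
    for a given draw.
    """
    R = validate_regulatory_matrix(R)
    nz = np.argwhere(R != 0)
    if k > len(nz):
        raise ValueError(f"k={k} exceeds the {len(nz)} regulations present")
    rng = np.random.default_rng(rng)
    idx = rng.choice(len(nz), size=k, replace=False)
    chosen = sorted((int(i) + 1, int(j) + 1) for i, j in nz[idx])
    return tuple(chosen)


def computational_gain(n: int, p: int, s: int = 0) -> float:
    """Complexity ratio of the exact to the approximate design method.

    ``lambda = 2**(3p) / C(n - s - 1, p)``: the per-network intervention
    search shrinks eight-fold per deleted gene, while the cost function
    must be evaluated for every candidate deletion set.
    """
    if s < 0 or p < 1 or p > n - s - 1:
        raise ValueError(f"infeasible arguments n={n}, p={p}, s={s}")
    return 2 ** (3 * p) / comb(n - s - 1, p)


class Trial:
    """One seeded study trial: a ground-truth network with hidden signs.

    Uses named substreams of the master seed (network topology/signs,
    uncertain positions, random-experiment baseline) so that records are
    bitwise reproducible.  Error tables and reduced ensembles are cached
    and shared between the methods evaluated on the trial.
    """

    def __init__(
        self,
        seed_seq: np.random.SeedSequence,
        n: int = 7,
        k: int = 5,
        p: float = DEFAULT_P,
        predictors_per_gene: int = 3,
    ):
        ss_net, ss_pos, ss_exp = seed_seq.spawn(3)
        self.R_true = generate_random_network(
            n, predictors_per_gene, np.random.default_rng(ss_net)
        )
        self.positions = sample_uncertain_positions(
            self.R_true, k, np.random.default_rng(ss_pos)
        )
        self.mu = tuple(int(self.R_true[i - 1, j - 1]) for i, j in self.positions)
        self.uc = UncertaintyClass(self.R_true, self.positions, p=p)
        self.random_experiment = int(
            np.random.default_rng(ss_exp).integers(1, k + 1)
        )
        self._reduced: dict[tuple[int, ...], ReducedEnsemble] = {}

    # -- cached pieces ---------------------------------------------------
    @property
    def ensemble(self):
        return self.uc.ensemble

    @property
    def true_index(self) -> int:
        """Row of the ground-truth assignment mu in the enumerated class."""
        match = np.flatnonzero((self.ensemble.thetas == self.mu).all(axis=1))
        return int(match[0])

    def reduced(self, genes) -> ReducedEnsemble:
        genes = tuple(genes)
        if genes not in self._reduced:
            self._reduced[genes] = ReducedEnsemble(self.ensemble, genes)
        return self._reduced[genes]

    def cost_ranking(self, n_delete: int = 1, excluded=()) -> list[tuple[tuple[int, ...], float]]:
        """Candidate deletion sets sorted by ascending cost (ties lexicographic)."""
        import itertools

        pool = [
            g
            for g in range(1, self.uc.n + 1)
            if g != self.uc.target and g not in set(excluded)
        ]
        table = [
            (genes, self.reduced(genes).cost())
            for genes in itertools.combinations(pool, n_delete)
        ]
        return sorted(table, key=lambda t: (t[1], t[0]))

    # -- designs ---------------------------------------------------------
    def optimal_selection(self) -> int:
        from .uncertainty import optimal_experiment

        sel, _ = optimal_experiment(self.uc)
        return sel

    def approximate_selection(self, genes) -> int:
        scores = self.reduced(genes).approximate_scores()
        return int(np.argmin(scores)) + 1

    # -- scoring ---------------------------------------------------------
    def robust_error_on_truth(self, i: int) -> float:
        """Error on the true network of the robust intervention obtained
        after experiment i reveals mu_i."""
        ens = self.ensemble
        mask = ens.condition(i, self.mu[i - 1])
        psi, _ = ens.robust(mask)
        return float(ens.errors[self.true_index][psi.u, psi.v])

    def induced_robust_error_on_truth(self, i: int, genes) -> float:
        ens = self.ensemble
        mask = ens.condition(i, self.mu[i - 1])
        psi, _ = self.reduced(genes).induced_robust(mask)
        return float(ens.errors[self.true_index][psi.u, psi.v])

    def gain(self, chosen: int) -> float:
        """rho of the chosen experiment over this trial's random baseline."""
        if chosen == self.random_experiment:
            return 0.0
        return self.robust_error_on_truth(self.random_experiment) - self.robust_error_on_truth(chosen)

    def induced_gain(self, chosen: int, genes) -> float:
        """rho with both robust interventions replaced by induced ones
        (the large-network variant where exact robust design is infeasible)."""
        if chosen == self.random_experiment:
            return 0.0
        return self.induced_robust_error_on_truth(
            self.random_experiment, genes
        ) - self.induced_robust_error_on_truth(chosen, genes)

    def controllability(self) -> float:
        """Controllability Delta of the ground-truth network (percent)."""
        ens = self.ensemble
        return _controllability(ens.networks[self.true_index], ens.errors[self.true_index])


def sequential_evaluation(trial: Trial, method: str = "optimal", genes=None, rng=None):
    """Gains of a designed experiment sequence over a random sequence.

    Conducts experiments until every uncertain parameter is revealed.  At
    each step the designed branch picks the experiment minimising expected
    remaining MOCU within the current conditional class (approximate:
    induced interventions through ``genes``); the random branch draws a
    fresh uniformly random unrevealed experiment.  The step gain is the
    error difference, on the true network, of the robust interventions
    implied by the two branches' revealed classes.  The final step gain is
    0 by construction (the network is then fully known on both branches).
    """
    ens = trial.ensemble
    uc = trial.uc
    rng = np.random.default_rng(rng)
    red = trial.reduced(genes) if genes else None

    def design_step(mask, remaining):
        best, best_score = None, None
        for i in remaining:
            score = 0.0
            for phi, w in zip(uc.domain, uc.marginal(i)):
                if w > 0:
                    sub = mask & ens.condition(i, phi)
                    if method == "optimal" or red is None:
                        m = ens.mocu_of(sub)
                    else:
                        _, h = red.induced_robust(sub)
                        cw = ens.subset_weights(sub)
                        m = h - float(cw @ red.induced_opt_errors[sub])
                    score += w * m
            if best_score is None or score < best_score:
                best, best_score = i, score
        return best

    def robust_err(mask):
        psi, _ = ens.robust(mask)
        return float(ens.errors[trial.true_index][psi.u, psi.v])

    mask_d = np.ones(ens.m, dtype=bool)
    mask_r = np.ones(ens.m, dtype=bool)
    remaining_d = list(range(1, uc.k + 1))
    remaining_r = list(range(1, uc.k + 1))
    gains = []
    for _ in range(uc.k):
        i_d = design_step(mask_d, remaining_d)
        i_r = int(rng.choice(remaining_r))
        remaining_d.remove(i_d)
        remaining_r.remove(i_r)
        mask_d = mask_d & ens.condition(i_d, trial.mu[i_d - 1])
        mask_r = mask_r & ens.condition(i_r, trial.mu[i_r - 1])
        gains.append(robust_err(mask_r) - robust_err(mask_d))
    return np.array(gains)


@dataclass
class StudyConfig:
    """Parameters of a batch study over random networks."""

    n: int = 7
    k: int = 5
    reps: int = 100
    seed: int = 0
    p: float = DEFAULT_P
    n_delete: int = 1
    n_exclude: int = 0
    methods: tuple[str, ...] = ("optimal", "approx_min", "approx_max")
    per_rank: bool = False
    delta_thresholds: tuple[float, ...] = ()

    def validate(self) -> "StudyConfig":
        if self.reps < 0 or self.n < 4 or self.k < 1:
            raise ValueError("invalid study configuration")
        return self


def batch_study(config: StudyConfig) -> tuple[pd.DataFrame, dict]:
    """Run seeded trials and summarise gains and agreement percentages.

    Returns the per-trial records and a summary with mean rho per method,
    agreement-with-optimal percentages, per-deletion-rank mean gains
    (``per_rank``) and controllability-thresholded means.
    """
    config.validate()
    master = np.random.SeedSequence(config.seed)
    records = []
    per_rank_gains: list[np.ndarray] = []
    for t, ss in enumerate(master.spawn(config.reps)):
        try:
            trial = Trial(ss, n=config.n, k=config.k, p=config.p)
            rec = {"trial": t, "random_experiment": trial.random_experiment}
            i_opt = None
            if "optimal" in config.methods or any(
                m.startswith("approx") for m in config.methods
            ):
                i_opt = trial.optimal_selection()
                rec["optimal_selection"] = i_opt
                rec["rho_optimal"] = trial.gain(i_opt)
            ranking = None
            if any(m.startswith("approx") for m in config.methods) or config.per_rank:
                from .cod import exclusion_set

                excluded = (
                    exclusion_set(trial.uc, config.n_exclude)
                    if config.n_exclude > 0
                    else ()
                )
                ranking = trial.cost_ranking(config.n_delete, excluded)
                rec["excluded"] = excluded
            if "approx_min" in config.methods:
                genes = ranking[0][0]
                sel = trial.approximate_selection(genes)
                rec["approx_min_selection"] = sel
                rec["rho_approx_min"] = trial.gain(sel)
                rec["agree_min"] = int(sel == i_opt)
                rec["deleted_min"] = genes
            if "approx_max" in config.methods:
                genes = ranking[-1][0]
                sel = trial.approximate_selection(genes)
                rec["approx_max_selection"] = sel
                rec["rho_approx_max"] = trial.gain(sel)
                rec["agree_max"] = int(sel == i_opt)
                rec["deleted_max"] = genes
            if config.per_rank:
                gains = []
                for genes, _cost in ranking:
                    sel = trial.approximate_selection(genes)
                    gains.append(trial.gain(sel))
                per_rank_gains.append(np.array(gains))
            if config.delta_thresholds:
                rec["controllability"] = trial.controllability()
            records.append(rec)
        except (CapacityError, ArithmeticError) as exc:
            records.append({"trial": t, "error": str(exc)})
    df = pd.DataFrame.from_records(records)
    summary: dict = {"reps": config.reps, "seed": config.seed, "n": config.n, "k": config.k}
    if config.reps == 0:
        return df, summary
    ok = df[~df.get("error", pd.Series(index=df.index, dtype=object)).notna()] if "error" in df else df
    for col, name in [
        ("rho_optimal", "mean_rho_optimal"),
        ("rho_approx_min", "mean_rho_approx_min"),
        ("rho_approx_max", "mean_rho_approx_max"),
    ]:
        if col in ok:
            summary[name] = float(ok[col].mean())
    for col, name in [
        ("agree_min", "agreement_min_pct"),
        ("agree_max", "agreement_max_pct"),
    ]:
        if col in ok:
            summary[name] = float(ok[col].mean() * 100.0)
    if per_rank_gains:
        ranks = np.stack(per_rank_gains)
        summary["mean_rho_by_rank"] = [float(x) for x in ranks.mean(axis=0)]
    if config.delta_thresholds and "controllability" in ok:
        strat = {}
        for thr in config.delta_thresholds:
            sub = ok[ok["controllability"] >= thr]
            strat[str(thr)] = {
                "count": int(len(sub)),
                "mean_rho_optimal": float(sub["rho_optimal"].mean()) if len(sub) else None,
            }
        summary["controllability_strata"] = strat
    return df, summary
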