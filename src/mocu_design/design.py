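"""Model/Results facade for MOCU-based experimental design.

``ExperimentDesign`` wraps an uncertainty class the way a statistical
model wraps its data: ``fit()`` runs either the exact design (rank
experiments by expected remaining MOCU) or the approximate design
(CoD-based exclusion, minimum-cost gene deletion, induced interventions)
and returns a ``DesignResults`` with the per-experiment scores, the chosen
experiment and a printable summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cod as _cod
from . import reduction as _reduction
from .uncertainty import UncertaintyClass, mocu, optimal_experiment

__all__ = ["ExperimentDesign", "DesignResults"]


@dataclass
class DesignResults:
    """Outcome of one experimental-design run.

    Attributes
    ----------
    scores : array, shape (k,)
        Expected remaining MOCU per experiment (approximated via induced
        interventions for the approximate method).
    selected_experiment : int
        1-based index of the experiment to conduct first (argmin of the
        scores; ties -> lowest index).
    method : str
        ``"optimal"`` or ``"approximate"``.
    deleted_genes, excluded_genes : tuples
        Reduction provenance (empty for the optimal method).
    deletion_costs : list of (gene set, cost) or None
        Cost of every candidate deletion set, when the approximate path
        evaluated them.
    mocu : float
        MOCU of the full class before any experiment.
    """

    uc: UncertaintyClass
    scores: np.ndarray
    selected_experiment: int
    method: str
    deleted_genes: tuple[int, ...] = ()
    excluded_genes: tuple[int, ...] = ()
    deletion_costs: list | None = None
    mocu: float = np.nan

    def summary(self) -> str:
        lines = [
            "MOCU experimental design results",
            "=" * 40,
            f"method:              {self.method}",
            f"genes (n):           {self.uc.n}",
            f"uncertain params (k): {self.uc.k}",
            f"MOCU of full class:  {self.mocu:.6g}",
        ]
        if self.method == "approximate":
            lines.append(f"excluded genes (s):  {self.excluded_genes or '-'}")
            lines.append(f"deleted genes (p):   {self.deleted_genes or '-'}")
        lines.append("")
        lines.append(self.score_frame().to_string(index=False))
        lines.append("")
        lines.append(f"selected experiment: E{self.selected_experiment}")
        return "\n".join(lines)

    def score_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "experiment": [f"E{i}" for i in range(1, self.uc.k + 1)],
                "position": [str(p) for p in self.uc.positions],
                "expected_remaining_mocu": self.scores,
            }
        )
        df["selected"] = [
            "*" if i == self.selected_experiment else "" for i in range(1, self.uc.k + 1)
        ]
        return df

    def deletion_cost_frame(self) -> pd.DataFrame | None:
        """Candidate deletion sets with their costs and ranks (TSV-ready)."""
        if self.deletion_costs is None:
            return None
        rows = sorted(self.deletion_costs, key=lambda t: (t[1], t[0]))
        return pd.DataFrame(
            {
                "genes": [",".join(map(str, g)) for g, _ in rows],
                "cost": [c for _, c in rows],
                "rank": range(1, len(rows) + 1),
            }
        )

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "selected_experiment": self.selected_experiment,
            "expected_remaining_mocu": [float(s) for s in self.scores],
            "positions": [list(p) for p in self.uc.positions],
            "deleted_genes": list(self.deleted_genes),
            "excluded_genes": list(self.excluded_genes),
            "deletion_costs": None
            if self.deletion_costs is None
            else [[list(g), float(c)] for g, c in self.deletion_costs],
            "mocu": float(self.mocu),
        }


class ExperimentDesign:
    """Experimental-design model over an uncertainty class of BNps."""

    def __init__(self, uncertainty_class: UncertaintyClass):
        self.uc = uncertainty_class

    def fit(
        self,
        method: str = "optimal",
        n_delete: int = 0,
        n_exclude: int = 0,
        deleted_genes=None,
        excluded_genes=None,
    ) -> DesignResults:
        """Run the design and return the ranked experiments.

        Parameters
        ----------
        method : {"optimal", "approximate"}
            Exact expected-remaining-MOCU ranking, or the reduced-network
            approximation.  ``approximate`` with ``n_delete=0`` and
            ``n_exclude=0`` degenerates to the optimal method.
        n_delete : int
            Number of genes to delete (approximate method); the minimum
            deletion-cost set is chosen unless ``deleted_genes`` is given.
        n_exclude : int
            Number of genes to remove from the deletion search space via
            the CoD procedure, unless ``excluded_genes`` is given.
        """
        uc = self.uc
        if method not in ("optimal", "approximate"):
            raise ValueError(f"unknown method {method!r}")
        full_mocu = mocu(uc)
        if method == "optimal" or (n_delete == 0 and not deleted_genes):
            sel, scores = optimal_experiment(uc)
            return DesignResults(
                uc, scores, sel, "optimal" if method == "optimal" else "approximate",
                mocu=full_mocu,
            )
        if excluded_genes is not None:
            excluded = tuple(excluded_genes)
        elif n_exclude > 0:
            excluded = _cod.exclusion_set(uc, n_exclude)
        else:
            excluded = ()
        costs = None
        if deleted_genes is not None:
            deleted = tuple(deleted_genes)
        else:
            costs = _reduction.deletion_cost_table(uc, n_delete, excluded)
            deleted = min(costs, key=lambda t: (t[1], t[0]))[0]
        scores = _reduction.approximate_scores(uc, deleted)
        sel = int(np.argmin(scores)) + 1
        return DesignResults(
            uc,
            scores,
            sel,
            "approximate",
            deleted_genes=deleted,
            excluded_genes=excluded,
            deletion_costs=costs,
            mocu=full_mocu,
        )
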