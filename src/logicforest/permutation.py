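"""Permutation p-values for prime implicants.

The null distribution of an importance score is built by refitting whole
forests to data whose outcome vector has been randomly permuted.  The
p-value of prime implicant ``X_j`` is the proportion of permuted-outcome
forests in which its importance is as large as or larger than the
importance observed in the original model.  A prime implicant that appears
in no tree of a permuted forest contributes importance 0 there — absence
is the null's strongest statement.

Refits use a shorter annealing schedule by default so that hundreds of
forest refits stay tractable; this is recorded in the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_model import Dataset
from .logic_forest import LogicForestModel, fit_forest, vi_frequency, vi_permutation
from .logic_tree import AnnealingSchedule, PrimeImplicant

logger = logging.getLogger(__name__)


@dataclass
class PermutationResult:
    """Observed importances and their permutation null exceedance counts."""

    importance_measure: str
    n_perm: int
    observed: dict[PrimeImplicant, float]
    exceed_counts: dict[PrimeImplicant, int]
    seed: int | None = None
    schedule_n_iter: int | None = None
    plus_one: bool = False
    selection_adjusted: bool = False

    def p_value(self, pi: PrimeImplicant) -> float:
        c = self.exceed_counts[pi]
        if self.plus_one:
            return (c + 1) / (self.n_perm + 1)
        return c / self.n_perm

    def p_display(self, pi: PrimeImplicant) -> str:
        c = self.exceed_counts[pi]
        if c == 0 and not self.plus_one:
            return f"< {1 / self.n_perm:g}"
        return f"{self.p_value(pi):g}"

    def as_dict(self) -> dict[PrimeImplicant, tuple[float, int, int, float]]:
        return {
            pi: (self.observed[pi], self.exceed_counts[pi], self.n_perm, self.p_value(pi))
            for pi in self.observed
        }


def _importance(model, W, pi, measure: str, rng) -> float:
    present = any(pi in set(dnf) for dnf in model.tree_dnfs())
    if not present:
        return 0.0
    if measure == "vi1":
        return vi_permutation(model, W, pi, rng=rng)
    if measure == "vi2":
        return vi_frequency(model, pi)
    raise ValueError(f"unknown importance measure {measure!r}")


def permutation_pvalues(
    W: Dataset,
    model: LogicForestModel,
    target_pis: list[PrimeImplicant],
    n_perm: int = 500,
    B: int | None = None,
    importance: str = "vi1",
    rng=None,
    schedule: AnnealingSchedule | None = None,
    max_leaves: int = 8,
    plus_one: bool = False,
    selection_adjusted: bool = False,
) -> PermutationResult:
    """Permutation p-values for ``target_pis`` by outcome-permuted forest refits.

    For each of ``n_perm`` permutations the outcome is shuffled uniformly,
    a forest of ``B`` trees (default: the original model's B) is refit, and
    the chosen importance of each target prime implicant in the permuted
    forest is compared against its observed value (exceedance means >=).
    Deterministic under a fixed ``rng``.  ``plus_one`` applies the
    (count+1)/(n_perm+1) small-sample correction; off by default, matching
    the plain proportion definition.

    By default the null importance is identity-matched: each permuted
    forest is searched for the *same* prime implicant (canonical literal
    set), contributing 0 when absent.  That is the right null for a
    pre-specified implicant, but it is anti-conservative for an implicant
    chosen *because* it topped the observed ranking — the observed value
    is a maximum over hundreds of candidates, while specific junk
    conjunctions essentially never recur in a permuted refit.
    ``selection_adjusted=True`` instead compares the observed value
    against the maximum importance over all prime implicants of each
    permuted forest (a max-statistic null), which is calibrated for
    top-ranked implicants and conservative for the rest.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    seed = rng if isinstance(rng, int) else None
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    B = B if B is not None else model.B
    schedule = schedule or AnnealingSchedule.fast()

    model_pis = set(model.unique_prime_implicants())
    for pi in target_pis:
        if pi not in model_pis:
            raise ValueError(f"target prime implicant {pi} does not occur in the fitted model")

    observed = {pi: _importance(model, W, pi, importance, rng) for pi in target_pis}
    exceed = {pi: 0 for pi in target_pis}
    for r in range(n_perm):
        y_perm = rng.permutation(W.y)
        W_perm = Dataset(W.X, y_perm, W.descriptors, list(W.subject_ids))
        null_model = fit_forest(W_perm, B=B, max_leaves=max_leaves, schedule=schedule, rng=rng)
        if selection_adjusted:
            null_val = _max_importance(null_model, W_perm, importance, rng)
            for pi in target_pis:
                if null_val >= observed[pi]:
                    exceed[pi] += 1
        else:
            for pi in target_pis:
                if _importance(null_model, W_perm, pi, importance, rng) >= observed[pi]:
                    exceed[pi] += 1
    return PermutationResult(
        importance_measure=importance,
        n_perm=n_perm,
        observed=observed,
        exceed_counts=exceed,
        seed=seed,
        schedule_n_iter=schedule.n_iter,
        plus_one=plus_one,
        selection_adjusted=selection_adjusted,
    )


def _max_importance(null_model, W_perm, measure: str, rng) -> float:
    """Maximum importance over every prime implicant of a permuted forest."""
    vals = [0.0]
    for pi in null_model.unique_prime_implicants():
        if measure == "vi1":
            vals.append(vi_permutation(null_model, W_perm, pi, rng=rng))
        else:
            vals.append(vi_frequency(null_model, pi))
    return max(vals)
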