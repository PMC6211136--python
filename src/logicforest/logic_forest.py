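"""Logic Forest: a bagged ensemble of logic trees with prime-implicant importance.

The forest fits ``B`` logic trees to ``B`` bootstrap samples of the
dataset.  Each tree's out-of-bag (OOB) set — the subjects absent from its
bootstrap draw — provides unbiased error estimates:

* the forest OOB prediction for subject *i* is the majority vote (>= 0.5)
  over the trees for which *i* is OOB;
* the forest OOB misclassification rate is the mean squared difference of
  outcome and OOB prediction, which for binary values is the mismatch
  fraction;
* a tree's own OOB misclassification restricts that mismatch to its OOB
  rows.

Two importance measures are computed for every prime implicant ``X_j``
found in the forest:

* **VI1** (permutation importance): the sum over trees containing ``X_j``
  of the increase in that tree's OOB misclassification when the
  implicant's 0/1 indicator is replaced by a randomly permuted copy,
  divided by ``B``.  Trees not containing the implicant contribute exactly
  0.  Ranges -1 to 1; positive values indicate association with the
  outcome.
* **VI2** (frequency importance): the fraction of trees whose DNF contains
  ``X_j`` (canonical literal-set identity).
"""

from __future__ import annotations

import json
import hashlib
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .data_model import Dataset
from .logic_tree import (
    AnnealingSchedule,
    LogicTree,
    PrimeImplicant,
    fit_tree,
    to_dnf,
)

logger = logging.getLogger(__name__)


def _dataset_fingerprint(W: Dataset) -> str:
    h = hashlib.sha256()
    h.update(W.X.tobytes())
    h.update(W.y.tobytes())
    return h.hexdigest()[:16]


@dataclass
class LogicForestModel:
    """B fitted trees with their bootstrap/OOB index sets."""

    trees: list[LogicTree]
    bootstrap_indices: list[np.ndarray]
    oob_indices: list[np.ndarray]
    dataset_fingerprint: str = ""
    seed: int | None = None

    @property
    def B(self) -> int:
        return len(self.trees)

    def tree_dnfs(self) -> list[list[PrimeImplicant]]:
        if not hasattr(self, "_dnfs"):
            self._dnfs = [to_dnf(t) for t in self.trees]
        return self._dnfs

    def unique_prime_implicants(self) -> dict[PrimeImplicant, int]:
        """Unique PIs across trees -> number of trees containing them."""
        counts: dict[PrimeImplicant, int] = {}
        for dnf in self.tree_dnfs():
            for pi in set(dnf):
                counts[pi] = counts.get(pi, 0) + 1
        return counts

    # -- persistence -------------------------------------------------------

    def to_json(self) -> dict:
        return {
            "trees": [t.to_json() for t in self.trees],
            "bootstrap_indices": [b.tolist() for b in self.bootstrap_indices],
            "dataset_fingerprint": self.dataset_fingerprint,
            "seed": self.seed,
        }

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh)

    @classmethod
    def from_json(cls, obj: dict, n: int) -> "LogicForestModel":
        trees = [LogicTree.from_json(t) for t in obj["trees"]]
        boots = [np.asarray(b, dtype=np.int64) for b in obj["bootstrap_indices"]]
        oobs = [_oob_from_bootstrap(b, n) for b in boots]
        return cls(trees, boots, oobs, obj.get("dataset_fingerprint", ""), obj.get("seed"))

    @classmethod
    def load(cls, path: str, n: int) -> "LogicForestModel":
        with open(path) as fh:
            return cls.from_json(json.load(fh), n)


def _oob_from_bootstrap(boot: np.ndarray, n: int) -> np.ndarray:
    inbag = np.zeros(n, dtype=bool)
    inbag[boot] = True
    return np.flatnonzero(~inbag)


def fit_forest(
    W: Dataset,
    B: int = 200,
    max_leaves: int = 8,
    schedule: AnnealingSchedule | None = None,
    rng=None,
) -> LogicForestModel:
    """Fit a Logic Forest: B bootstrap draws, one annealed tree per draw.

    Bootstrap draws are uniform with replacement of size n; a draw whose
    OOB set is empty (possible only at tiny n) is redrawn.  With a fixed
    ``rng`` the model is reproducible.
    """
    if W.n < 10:
        raise ValueError("need at least 10 subjects to fit a forest")
    if W.p < 1:
        raise ValueError("need at least one predictor")
    seed = None
    if not isinstance(rng, np.random.Generator):
        seed = rng if isinstance(rng, int) else None
        rng = np.random.default_rng(rng)
    trees, boots, oobs = [], [], []
    for b in range(B):
        while True:
            boot = rng.integers(0, W.n, size=W.n)
            oob = _oob_from_bootstrap(boot, W.n)
            if oob.size:
                break
            logger.info("bootstrap draw %d had an empty OOB set; redrawn", b)
        Wb = Dataset(W.X[boot], W.y[boot], W.descriptors,
                     [W.subject_ids[i] for i in boot])
        trees.append(fit_tree(Wb, max_leaves=max_leaves, schedule=schedule, rng=rng))
        boots.append(np.asarray(boot, dtype=np.int64))
        oobs.append(oob)
    return LogicForestModel(trees, boots, oobs, _dataset_fingerprint(W), seed)


# ---------------------------------------------------------------------------
# OOB machinery


def _vote_matrix(model: LogicForestModel, X: np.ndarray) -> np.ndarray:
    """B x n matrix of per-tree 0/1 predictions."""
    return np.stack([t.evaluate(X) for t in model.trees])


def _oob_mask(model: LogicForestModel, n: int) -> np.ndarray:
    """B x n boolean: tree b's OOB set contains subject i."""
    mask = np.zeros((model.B, n), dtype=bool)
    for b, oob in enumerate(model.oob_indices):
        mask[b, oob] = True
    return mask


def oob_predict(model: LogicForestModel, W: Dataset) -> np.ndarray:
    """Forest OOB prediction per subject: vote share >= 0.5 over OOB trees.

    Subjects that are OOB in zero trees get prediction -1 (excluded from
    OOB metrics) and are logged.
    """
    votes = _vote_matrix(model, W.X)
    mask = _oob_mask(model, W.n)
    counts = mask.sum(axis=0)
    share = np.divide(
        (votes * mask).sum(axis=0), counts,
        out=np.zeros(W.n, dtype=float), where=counts > 0,
    )
    pred = (share >= 0.5).astype(np.int8)
    never = counts == 0
    if never.any():
        logger.warning("%d subjects were OOB in no tree; excluded from OOB metrics",
                       int(never.sum()))
        pred[never] = -1
    return pred


def oob_misclassification(model: LogicForestModel, W: Dataset) -> float:
    """Forest OOB misclassification: mean (y - yhat_OOB)^2 over voted subjects."""
    pred = oob_predict(model, W)
    voted = pred >= 0
    return float(np.mean((W.y[voted].astype(int) - pred[voted].astype(int)) ** 2))


def tree_oob_misclassification(
    model: LogicForestModel, b: int, W: Dataset, X_override: np.ndarray | None = None
) -> float:
    """Tree b's misclassification on its own OOB rows (optionally on permuted X)."""
    X = W.X if X_override is None else X_override
    oob = model.oob_indices[b]
    yhat = model.trees[b].evaluate(X[oob])
    return float(np.mean((W.y[oob].astype(int) - yhat.astype(int)) ** 2))


# ---------------------------------------------------------------------------
# importance


def vi_permutation(
    model: LogicForestModel,
    W: Dataset,
    pi: PrimeImplicant,
    rng=None,
    n_reps: int = 1,
    mode: str = "implicant",
) -> float:
    """VI1: mean over all B trees of the OOB error increase after permuting ``pi``.

    In the default ``implicant`` mode the prime implicant is treated as a
    variable in its own right: within each tree whose DNF contains ``pi``
    (canonical literal-set identity), the implicant's 0/1 indicator is
    replaced by a randomly permuted copy over that tree's OOB rows, the
    tree's OOB misclassification recomputed, and the increase summed over
    trees and divided by B.  Trees that do not contain the implicant are
    unaffected and contribute exactly 0 — so rarely-found implicants
    cannot accrue large importance, and the measure pairs naturally with
    the frequency measure VI2.

    ``columns`` mode instead permutes the constituent predictor columns of
    ``pi`` in the full data matrix by one shared row permutation
    (preserving their joint pattern) and re-scores every tree that uses
    any of those predictors.  This reading rewards supersets of an
    informative implicant and is provided for comparison only.

    ``n_reps`` independent permutations are averaged.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if mode == "columns":
        return _vi_permutation_columns(model, W, pi, rng, n_reps)
    if mode != "implicant":
        raise ValueError(f"unknown vi_permutation mode {mode!r}")
    total = 0.0
    for b, dnf in enumerate(model.tree_dnfs()):
        if pi not in set(dnf):
            continue
        oob = model.oob_indices[b]
        Xo = W.X[oob]
        yo = W.y[oob].astype(bool)
        others = [q.indicator(Xo).astype(bool) for q in dnf if q != pi]
        rest = np.logical_or.reduce(others) if others else np.zeros(oob.size, dtype=bool)
        ind = pi.indicator(Xo).astype(bool)
        base = float(np.mean(yo != (rest | ind)))
        delta = 0.0
        for _ in range(n_reps):
            perm_ind = ind[rng.permutation(oob.size)]
            delta += float(np.mean(yo != (rest | perm_ind))) - base
        total += delta / n_reps
    return float(total / model.B)


def _vi_permutation_columns(model, W, pi, rng, n_reps: int) -> float:
    idxs = sorted(pi.predictor_indices)
    touched = [b for b in range(model.B)
               if model.trees[b].predictor_indices & pi.predictor_indices]
    if not touched:
        return 0.0
    base = {b: tree_oob_misclassification(model, b, W) for b in touched}
    total = 0.0
    for _ in range(n_reps):
        perm = rng.permutation(W.n)
        Xp = W.X.copy()
        Xp[:, idxs] = W.X[perm][:, idxs]
        delta = sum(
            tree_oob_misclassification(model, b, W, X_override=Xp) - base[b]
            for b in touched
        )
        total += delta / model.B
    return float(total / n_reps)


def vi_frequency(model: LogicForestModel, pi: PrimeImplicant) -> float:
    """VI2: fraction of trees whose DNF contains ``pi``."""
    return sum(pi in set(dnf) for dnf in model.tree_dnfs()) / model.B


@dataclass
class ImportanceRecord:
    prime_implicant: PrimeImplicant
    vi1: float
    vi2: float
    tree_count: int
    normalized_vi1: float = float("nan")
    perm_p: float | None = None
    perm_p_display: str | None = None


def _normalise(records: list[ImportanceRecord]) -> None:
    m = max((abs(r.vi1) for r in records), default=0.0)
    for r in records:
        r.normalized_vi1 = r.vi1 / m if m > 0 else 0.0


def aggregate(
    model: LogicForestModel,
    W: Dataset,
    rng=None,
    n_reps: int = 1,
) -> tuple[list[ImportanceRecord], list[ImportanceRecord]]:
    """Importance records for every unique PI and for every used predictor.

    A predictor "occurs" in a tree when any prime implicant of that tree
    contains it.  VI1 is max-absolute normalised within each table
    independently (a reporting convention for frequency-vs-importance
    plots, not part of inference).  Both tables are sorted by (vi1, vi2)
    descending.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    pi_counts = model.unique_prime_implicants()
    pi_records = []
    for pi, count in pi_counts.items():
        vi1 = vi_permutation(model, W, pi, rng=rng, n_reps=n_reps)
        pi_records.append(ImportanceRecord(pi, vi1, count / model.B, count))
    _normalise(pi_records)
    pi_records.sort(key=lambda r: (-r.vi1, -r.vi2, r.prime_implicant.canonical_key))

    pred_tree_counts: dict[int, int] = {}
    for dnf in model.tree_dnfs():
        used = set()
        for pi in dnf:
            used |= pi.predictor_indices
        for j in used:
            pred_tree_counts[j] = pred_tree_counts.get(j, 0) + 1
    pred_records = []
    from .logic_tree import Literal

    for j, count in pred_tree_counts.items():
        single = PrimeImplicant((Literal(j, False),))
        # an individual predictor is permuted as a data column, affecting
        # every tree that uses it in any literal
        vi1 = vi_permutation(model, W, single, rng=rng, n_reps=n_reps, mode="columns")
        pred_records.append(ImportanceRecord(single, vi1, count / model.B, count))
    _normalise(pred_records)
    pred_records.sort(key=lambda r: (-r.vi1, -r.vi2, r.prime_implicant.canonical_key))
    return pi_records, pred_records


def records_to_frame(records: list[ImportanceRecord], descriptors=None) -> pd.DataFrame:
    rows = []
    for rank, r in enumerate(records, start=1):
        rows.append(
            dict(
                rank=rank,
                prime_implicant=r.prime_implicant.render(descriptors),
                literals=r.prime_implicant.render(None),
                tree_count=r.tree_count,
                vi2=r.vi2,
                vi1=r.vi1,
                normalized_vi1=r.normalized_vi1,
                perm_p=np.nan if r.perm_p is None else r.perm_p,
                perm_p_display="" if r.perm_p_display is None else r.perm_p_display,
            )
        )
    return pd.DataFrame.from_records(rows)


# ---------------------------------------------------------------------------
# prediction / discrimination


def predict(model: LogicForestModel, X_new, names: list[str] | None = None):
    """Vote share over all B trees and the >= 0.5 label for new subjects.

    ``X_new`` may be an array with the model's column layout or a DataFrame
    carrying the predictor names used at fit time.
    """
    if isinstance(X_new, pd.DataFrame):
        if names is None:
            raise ValueError("names of the model's predictor columns are required")
        missing = [n for n in names if n not in X_new.columns]
        if missing:
            raise KeyError(f"missing predictor column(s): {', '.join(missing)}")
        X_new = X_new[names].to_numpy(dtype=np.uint8)
    X_new = np.asarray(X_new, dtype=np.uint8)
    share = _vote_matrix(model, X_new).mean(axis=0)
    return share, (share >= 0.5).astype(np.uint8)


def oob_vote_shares(model: LogicForestModel, W: Dataset) -> np.ndarray:
    votes = _vote_matrix(model, W.X)
    mask = _oob_mask(model, W.n)
    counts = mask.sum(axis=0)
    return np.divide((votes * mask).sum(axis=0), counts,
                     out=np.full(W.n, np.nan), where=counts > 0)


def roc_auc(scores: np.ndarray, y: np.ndarray):
    """ROC curve (threshold sweep) and trapezoid AUC of scores against y.

    Equivalent to the Mann-Whitney rank statistic under ties.  Returns
    (fpr, tpr, auc).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    ok = ~np.isnan(scores)
    scores, y = scores[ok], y[ok]
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present to compute a ROC curve")
    fpr, tpr, _ = _sk_roc_curve(y, scores)
    return fpr, tpr, float(_sk_auc(fpr, tpr))
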