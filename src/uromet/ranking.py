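"""Stage 2 — random-forest importance ranking of screened metabolites.

The screen says which metabolites differ; the forest says how much each one
contributes to telling cases from controls when all of them are available
at once.  Importance is Breiman's out-of-bag permutation importance (mean
decrease in OOB accuracy when a feature's values are shuffled), which is
comparable across features with very different scales — essential here,
where fold-changes span two orders of magnitude.

Trees are scikit-learn ``DecisionTreeClassifier``s; the stratified
bootstrap, out-of-bag bookkeeping and permutation importance are computed
in this module, since the library's permutation importance is not
out-of-bag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .data import (
    IntensityMatrix,
    MetaboliteAnnotation,
    SampleMetadata,
    ValidationError,
)

__all__ = ["RankingResult", "RankEntry", "rank_importance", "select_candidates"]


@dataclass(frozen=True)
class RankEntry:
    metabolite_id: str
    importance: float
    rank: int


@dataclass
class RankingResult:
    entries: list[RankEntry]  # rank order, 1..n, importance non-increasing
    n_trees: int
    max_features: str | int
    seed: int
    oob_error: float

    def top(self, k: int) -> list[RankEntry]:
        return self.entries[:k]

    def rank_of(self, metabolite_id: str) -> int:
        for e in self.entries:
            if e.metabolite_id == metabolite_id:
                return e.rank
        raise KeyError(metabolite_id)


def _stratified_bootstrap(
    labels: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Bootstrap indices drawn within each class, preserving class counts."""
    parts = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        parts.append(rng.choice(idx, size=idx.size, replace=True))
    return np.concatenate(parts)


def rank_importance(
    matrix: IntensityMatrix,
    metadata: Sequence[SampleMetadata],
    metabolite_ids: Sequence[str] | None = None,
    n_trees: int = 500,
    max_features: str | int = "sqrt",
    seed: int = 0,
) -> RankingResult:
    """Rank metabolites by out-of-bag permutation importance.

    ``metabolite_ids`` restricts the feature set (normally the screened,
    non-exogenous metabolites).  Features are canonicalized to lexicographic
    metabolite-id order before fitting and the RNG is seeded once, so the
    ranking is invariant to the column order of the input matrix.  Ties in
    importance are broken by metabolite id.
    """
    if metabolite_ids is None:
        metabolite_ids = matrix.metabolite_ids
    if len(metabolite_ids) == 0:
        raise ValidationError("empty feature set")
    feature_ids = sorted(metabolite_ids)
    sub = matrix.subset(metabolite_ids=feature_ids)

    lookup = {m.sample_id: m.group for m in metadata}
    missing = [s for s in sub.sample_ids if s not in lookup]
    if missing:
        raise ValidationError(f"samples without metadata: {missing}")
    y = np.array([1 if lookup[s] == "case" else 0 for s in sub.sample_ids])
    if np.unique(y).size < 2 or min(np.bincount(y)) < 2:
        raise ValidationError("need at least two samples per class")

    X = sub.values
    if np.isnan(X).any():
        raise ValidationError("ranking requires complete data (impute nondetects first)")
    n, p = X.shape

    rng = np.random.default_rng(seed)
    importance_sum = np.zeros(p)
    importance_trees = np.zeros(p, dtype=int)
    oob_votes = np.zeros((n, 2))

    for _ in range(n_trees):
        boot = _stratified_bootstrap(y, rng)
        oob = np.setdiff1d(np.arange(n), boot)
        tree = DecisionTreeClassifier(
            max_features=max_features,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[boot], y[boot])
        if oob.size == 0 or np.unique(y[oob]).size == 0:
            continue
        X_oob = X[oob]
        pred = tree.predict(X_oob)
        oob_votes[oob, pred] += 1
        acc_base = float(np.mean(pred == y[oob]))

        # One batched predict per tree: stack the p single-feature-permuted
        # copies of the OOB block.
        perm_rows = np.repeat(X_oob[None, :, :], p, axis=0)  # (p, n_oob, p)
        for j in range(p):
            perm_rows[j, :, j] = X_oob[rng.permutation(oob.size), j]
        pred_perm = tree.predict(perm_rows.reshape(p * oob.size, p))
        acc_perm = (pred_perm.reshape(p, oob.size) == y[oob]).mean(axis=1)
        importance_sum += acc_base - acc_perm
        importance_trees += 1

    if importance_trees.max() == 0:
        raise ValidationError("no tree produced out-of-bag samples")
    importance = importance_sum / np.maximum(importance_trees, 1)

    voted = oob_votes.sum(axis=1) > 0
    oob_pred = oob_votes.argmax(axis=1)
    oob_error = float(np.mean(oob_pred[voted] != y[voted])) if voted.any() else float("nan")

    order = sorted(range(p), key=lambda j: (-importance[j], feature_ids[j]))
    entries = [
        RankEntry(feature_ids[j], float(importance[j]), r + 1)
        for r, j in enumerate(order)
    ]
    return RankingResult(entries, n_trees, max_features, seed, oob_error)


def select_candidates(
    ranking: RankingResult,
    annotations: Sequence[MetaboliteAnnotation],
    k: int = 30,
) -> list[RankEntry]:
    """Top-``k`` ranked metabolites with unknown-structure features excluded.

    A feature without an identified structure cannot become a clinical
    marker, so it is dropped after ranking; survivors keep their original
    ranks (the published candidate table shows rank gaps for the same
    reason).
    """
    if k > len(ranking.entries):
        raise ValidationError(
            f"k={k} exceeds ranking length {len(ranking.entries)}"
        )
    lookup = {a.metabolite_id: a.structure_known for a in annotations}
    top = ranking.entries[:k]
    missing = [e.metabolite_id for e in top if e.metabolite_id not in lookup]
    if missing:
        raise ValidationError(f"unannotated metabolites: {missing[:5]}")
    return [e for e in top if lookup[e.metabolite_id]]
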