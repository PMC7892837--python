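"""Stage 3 — pathway-constrained marker-combination search and scoring.

Within one metabolic pathway the candidate markers rise and fall together,
so a panel drawn from a single pathway adds little information beyond its
best member.  The search therefore enumerates small marker subsets drawing
at most one metabolite per sub-pathway, fits an OPLS-DA model for each, and
ranks combinations by false negatives on the pretreatment cases first, then
cross-validated Q², then R²Y.  Exhaustive enumeration replaces manual trial
and error: with ~19 candidates there are at most C(19,3) = 969 fits.

Scoring applies the predictive-value equation — the dot product of the
model coefficients with the standardized intensities — with its cutoff at
0: a strictly positive value calls the sample high-risk.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .data import (
    IntensityMatrix,
    MetaboliteAnnotation,
    SampleMetadata,
    ValidationError,
)
from .oplsda import OplsdaModel, fit_marker_model
from .screening import pretreatment_split

__all__ = [
    "Combination",
    "ScoreRecord",
    "predictive_value",
    "score_samples",
    "evaluate_combination",
    "search_combinations",
]


@dataclass(frozen=True)
class ScoreRecord:
    sample_id: str
    predictive_value: float
    call: str  # "positive" iff predictive_value > 0

    def __post_init__(self) -> None:
        expected = "positive" if self.predictive_value > 0 else "negative"
        if self.call != expected:
            raise ValidationError(
                f"sample {self.sample_id!r}: call {self.call!r} contradicts score"
            )


@dataclass(frozen=True)
class Combination:
    marker_ids: tuple[str, ...]
    sub_pathways: tuple[str, ...]
    fn_count: int
    r2y: float
    q2: float

    @property
    def sort_key(self) -> tuple:
        return (self.fn_count, -self.q2, -self.r2y, self.marker_ids)


def predictive_value(
    coefficients: Sequence[float], standardized_intensities: Sequence[float]
) -> float:
    """Predictive value = Σ coefficient_i × standardized intensity_i.

    The caller guarantees the intensities were standardized with the
    fitting-cohort statistics.
    """
    c = np.asarray(coefficients, dtype=float)
    z = np.asarray(standardized_intensities, dtype=float)
    if c.shape != z.shape or c.ndim != 1:
        raise ValidationError(
            f"coefficient/intensity length mismatch: {c.shape} vs {z.shape}"
        )
    return float(c @ z)


def score_samples(
    model: OplsdaModel,
    matrix: IntensityMatrix,
    sample_ids: Sequence[str] | None = None,
) -> list[ScoreRecord]:
    """Score samples with a frozen model; positive call iff score > 0.

    New samples are standardized with the stats stored at fit time — never
    refit — and projected through the model coefficients.  A value of
    exactly 0 sits on the cutoff and is called negative (positive means
    strictly high-risk).
    """
    if model.stats is None:
        raise ValidationError("model carries no standardization stats")
    if not matrix.normalized:
        raise ValidationError("scoring requires an osmolality-normalized matrix")
    sub = matrix.subset(sample_ids=sample_ids, metabolite_ids=model.marker_ids)
    Z = model.stats.transform(sub.values, model.marker_ids)
    scores = model.predict_scores(Z)
    return [
        ScoreRecord(sid, float(s), "positive" if s > 0 else "negative")
        for sid, s in zip(sub.sample_ids, scores)
    ]


def evaluate_combination(
    marker_ids: Sequence[str],
    matrix: IntensityMatrix,
    metadata: Sequence[SampleMetadata],
    annotations: Sequence[MetaboliteAnnotation] | None = None,
    k_ortho: int = 1,
    folds: int = 7,
    seed: int = 0,
    fn_mode: str = "resubstitution",
) -> Combination:
    """Fit a model on one marker subset and measure (FN count, R²Y, Q²).

    ``fn_mode="resubstitution"`` counts pretreatment cases the fitted model
    itself fails to call positive; ``"cv"`` counts them from held-out
    cross-validation scores instead.
    """
    if fn_mode not in ("resubstitution", "cv"):
        raise ValidationError(f"unknown fn_mode {fn_mode!r}")
    model = fit_marker_model(
        matrix, metadata, list(marker_ids), k_ortho=k_ortho, folds=folds, seed=seed
    )
    cases, _ = pretreatment_split(matrix, metadata)
    if fn_mode == "resubstitution":
        records = score_samples(model, matrix, sample_ids=cases)
        fn = sum(1 for r in records if r.call == "negative")
    else:
        fn = _cv_false_negatives(matrix, metadata, list(marker_ids), k_ortho, folds, seed)
    pathways = ()
    if annotations is not None:
        lookup = {a.metabolite_id: a.sub_pathway for a in annotations}
        pathways = tuple(lookup.get(m, "") for m in marker_ids)
    assert model.q2 is not None
    return Combination(tuple(marker_ids), pathways, fn, model.r2y, model.q2)


def _cv_false_negatives(
    matrix: IntensityMatrix,
    metadata: Sequence[SampleMetadata],
    marker_ids: list[str],
    k_ortho: int,
    folds: int,
    seed: int,
) -> int:
    from .oplsda import _fold_assignment, encode_labels, fit_oplsda, standardize

    cases, controls = pretreatment_split(matrix, metadata)
    sample_ids = cases + controls
    groups = ["case"] * len(cases) + ["control"] * len(controls)
    sub = matrix.subset(sample_ids=sample_ids, metabolite_ids=marker_ids)
    assignment = _fold_assignment(groups, sample_ids, folds, seed)
    fn = 0
    for f in range(folds):
        test = assignment == f
        train = ~test
        stats_f = standardize(sub.values[train], marker_ids)
        y_train = encode_labels([g for g, tr in zip(groups, train) if tr])
        model = fit_oplsda(stats_f, y_train, k_ortho=k_ortho)
        scores = model.predict_scores(stats_f.transform(sub.values[test], marker_ids))
        for g, s in zip([g for g, te in zip(groups, test) if te], scores):
            if g == "case" and not s > 0:
                fn += 1
    return fn


def search_combinations(
    candidates: Sequence[str],
    matrix: IntensityMatrix,
    metadata: Sequence[SampleMetadata],
    annotations: Sequence[MetaboliteAnnotation],
    size: int = 3,
    pathway_constraint: bool = True,
    exclude_ids: Sequence[str] = (),
    k_ortho: int = 1,
    folds: int = 7,
    seed: int = 0,
    fn_mode: str = "resubstitution",
) -> list[Combination]:
    """Exhaustive constrained search over marker subsets of ``size``.

    Honors the one-marker-per-sub-pathway constraint when enabled, skips
    ``exclude_ids`` (e.g. the established clinical markers, searched
    separately for comparison), and returns combinations sorted by
    (FN ascending, Q² descending, R²Y descending, marker ids) — a total
    order, so the ranking is deterministic.
    """
    pool = [c for c in candidates if c not in set(exclude_ids)]
    if len(pool) < size:
        raise ValidationError(f"need at least {size} candidates, have {len(pool)}")
    lookup = {a.metabolite_id: a.sub_pathway for a in annotations}
    missing = [c for c in pool if c not in lookup]
    if missing:
        raise ValidationError(f"unannotated candidates: {missing[:5]}")
    if pathway_constraint and len({lookup[c] for c in pool}) < size:
        raise ValidationError(
            f"pathway constraint unsatisfiable: fewer than {size} distinct sub-pathways"
        )
    results: list[Combination] = []
    for subset in combinations(sorted(pool), size):
        pathways = [lookup[m] for m in subset]
        if pathway_constraint and len(set(pathways)) < size:
            continue
        results.append(
            evaluate_combination(
                subset, matrix, metadata, annotations, k_ortho, folds, seed, fn_mode
            )
        )
    results.sort(key=lambda c: c.sort_key)
    return results
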