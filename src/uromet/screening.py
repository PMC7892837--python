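"""Stage 1 — per-metabolite nonparametric screening.

Intensities in urine are so heavy-tailed that parametric normalization
fails, so group differences are screened with the two-sided Wilcoxon
rank-sum (Mann–Whitney) test on the raw normalized intensities, without log
transformation and — deliberately — without multiple-testing correction:
the screen is a refinement step, not a final inference, and the later
stages (forest ranking, cross-validated OPLS-DA, permutation test) carry
the error control.  Exogenous metabolites such as drugs and their
conjugates are removed after the test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .data import (
    IntensityMatrix,
    MetaboliteAnnotation,
    SampleMetadata,
    ValidationError,
)

__all__ = [
    "ScreenRecord",
    "wilcoxon_rank_sum",
    "fold_change",
    "screen",
    "exclude_exogenous",
    "pretreatment_split",
]

logger = logging.getLogger(__name__)

#: Largest combined sample size at which the tie-free null is enumerated
#: exactly; beyond it (or with ties) the normal approximation with
#: tie-corrected variance and continuity correction is used.
EXACT_LIMIT = 12


@dataclass(frozen=True)
class ScreenRecord:
    metabolite_id: str
    w_statistic: float  # rank-sum of the case group
    p_value: float
    fold_change: float  # case median / control median
    direction: str  # "increase" iff fold_change > 1
    passed: bool


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of ``x`` (cases) vs ``y`` (controls).

    Returns ``(w, p)`` where ``w`` is the rank-sum of ``x`` using midranks.
    ``mode`` selects the null: ``"exact"`` enumerates the tie-free
    distribution, ``"normal"`` uses the tie-corrected normal approximation
    with continuity correction, ``"auto"`` picks exact when the combined
    sample size is at most 12 and the pooled values are tie-free.

    Degenerate input with every value identical across both groups carries
    no ordering information; p = 1 by convention (logged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    if mode not in ("auto", "exact", "normal"):
        raise ValidationError(f"unknown mode {mode!r}")

    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    w = float(ranks[: x.size].sum())

    if np.all(pooled == pooled[0]):
        logger.debug("degenerate rank-sum input: all %d values identical", pooled.size)
        return w, 1.0

    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        mode = "exact" if (pooled.size <= EXACT_LIMIT and not has_ties) else "normal"
    if mode == "exact" and has_ties:
        mode = "normal"  # exact enumeration assumes a tie-free null

    method = "exact" if mode == "exact" else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return w, float(min(res.pvalue, 1.0))


def fold_change(x_case: Sequence[float], y_control: Sequence[float]) -> tuple[float, str]:
    """Case-over-control ratio of medians and its direction."""
    x = np.asarray(x_case, dtype=float)
    y = np.asarray(y_control, dtype=float)
    med_y = float(np.median(y))
    if not med_y > 0:
        raise ValidationError("control median must be positive (impute nondetects first)")
    fold = float(np.median(x)) / med_y
    return fold, ("increase" if fold > 1 else "decrease")


def pretreatment_split(
    matrix: IntensityMatrix, metadata: Sequence[SampleMetadata]
) -> tuple[list[str], list[str]]:
    """Pretreatment sample ids (one per subject) for cases and controls.

    Follow-up samples are reserved for evaluation; keeping one pretreatment
    sample per subject avoids pseudo-replication in the screen and the fit.
    """
    lookup = {m.sample_id: m for m in metadata}
    missing = [s for s in matrix.sample_ids if s not in lookup]
    if missing:
        raise ValidationError(f"samples without metadata: {missing}")
    cases: list[str] = []
    controls: list[str] = []
    seen_subjects: set[str] = set()
    for sid in matrix.sample_ids:
        rec = lookup[sid]
        if rec.timepoint != "pretreatment" or rec.subject_id in seen_subjects:
            continue
        seen_subjects.add(rec.subject_id)
        (cases if rec.group == "case" else controls).append(sid)
    return cases, controls


def screen(
    matrix: IntensityMatrix,
    metadata: Sequence[SampleMetadata],
    alpha: float = 0.05,
    mode: str = "auto",
) -> list[ScreenRecord]:
    """Per-metabolite Wilcoxon screen at significance level ``alpha``.

    No multiple-testing correction is applied: a metabolite passes iff its
    two-sided p-value is below ``alpha``.  Records come back in the
    matrix's metabolite order.
    """
    if not matrix.normalized:
        raise ValidationError("screen requires an osmolality-normalized matrix")
    if np.isnan(matrix.values).any():
        raise ValidationError("screen requires complete data (impute nondetects first)")
    cases, controls = pretreatment_split(matrix, metadata)
    if len(cases) < 2 or len(controls) < 2:
        raise ValidationError("need at least two pretreatment samples per group")

    frame = matrix.to_frame()
    x_block = frame.loc[cases].to_numpy()
    y_block = frame.loc[controls].to_numpy()

    records: list[ScreenRecord] = []
    for j, mid in enumerate(matrix.metabolite_ids):
        w, p = wilcoxon_rank_sum(x_block[:, j], y_block[:, j], mode=mode)
        fold, direction = fold_change(x_block[:, j], y_block[:, j])
        records.append(ScreenRecord(mid, w, p, fold, direction, bool(p < alpha)))
    n_passed = sum(r.passed for r in records)
    logger.info(
        "screen: %d of %d metabolites significant at alpha=%g",
        n_passed,
        len(records),
        alpha,
    )
    return records


def exclude_exogenous(
    records: Sequence[ScreenRecord], annotations: Sequence[MetaboliteAnnotation]
) -> list[ScreenRecord]:
    """Drop records for metabolites annotated exogenous (drugs, conjugates)."""
    lookup = {a.metabolite_id: a.exogenous for a in annotations}
    missing = [r.metabolite_id for r in records if r.metabolite_id not in lookup]
    if missing:
        raise ValidationError(f"unannotated metabolites: {missing[:5]}")
    kept = [r for r in records if not lookup[r.metabolite_id]]
    n_dropped = len(records) - len(kept)
    logger.info("exogenous exclusion: %d dropped, %d remain", n_dropped, len(kept))
    if not kept:
        logger.warning("every screened metabolite was exogenous")
    return kept
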