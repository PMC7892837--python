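"""Stage 4 — follow-up evaluation against residual-tumour truth.

During/after-treatment samples are scored with the model frozen on the
pretreatment cohort and cross-tabulated against the residual-tumour label
(imaging truth) in a 2×2 contingency table.  Sensitivity and specificity
are computed with exact rational arithmetic and reported to three decimals;
an undefined ratio (empty denominator) is flagged, never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from .data import SampleMetadata, ValidationError
from .selection import ScoreRecord

__all__ = [
    "ContingencyTable",
    "ComparisonReport",
    "build_contingency",
    "sensitivity_specificity",
    "compare_marker_sets",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Calls vs residual-tumour truth: tp, fp, fn, tn."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity_defined(self) -> bool:
        return self.tp + self.fn > 0

    @property
    def specificity_defined(self) -> bool:
        return self.tn + self.fp > 0

    @property
    def sensitivity(self) -> Fraction | None:
        if not self.sensitivity_defined:
            return None
        return Fraction(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> Fraction | None:
        if not self.specificity_defined:
            return None
        return Fraction(self.tn, self.tn + self.fp)


def build_contingency(
    calls: Sequence[ScoreRecord], metadata: Sequence[SampleMetadata]
) -> ContingencyTable:
    """Cross-tabulate positive/negative calls against residual-tumour truth.

    Every scored sample must carry a positive or negative residual-tumour
    label; an unknown label cannot serve as evaluation truth.
    """
    truth = {m.sample_id: m.residual_tumour for m in metadata}
    tp = fp = fn = tn = 0
    for rec in calls:
        if rec.sample_id not in truth:
            raise ValidationError(f"no metadata for scored sample {rec.sample_id!r}")
        status = truth[rec.sample_id]
        if status not in ("positive", "negative"):
            raise ValidationError(
                f"sample {rec.sample_id!r}: residual_tumour is {status!r}, "
                "need positive/negative for evaluation"
            )
        if rec.call == "positive":
            if status == "positive":
                tp += 1
            else:
                fp += 1
        else:
            if status == "positive":
                fn += 1
            else:
                tn += 1
    return ContingencyTable(tp, fp, fn, tn)


def sensitivity_specificity(
    table: ContingencyTable, decimals: int = 3
) -> tuple[float | None, float | None]:
    """Sensitivity tp/(tp+fn) and specificity tn/(tn+fp), rounded for report.

    Exact rationals are formed first and rounded only at the end; an
    undefined ratio comes back as None.
    """
    sens = table.sensitivity
    spec = table.specificity
    return (
        None if sens is None else round(float(sens), decimals),
        None if spec is None else round(float(spec), decimals),
    )


@dataclass
class ComparisonReport:
    """Two marker panels evaluated on the same samples, side by side."""

    table_a: ContingencyTable
    table_b: ContingencyTable
    discordant: list[tuple[str, str, str]]  # (sample_id, call_a, call_b)

    @property
    def n_discordant(self) -> int:
        return len(self.discordant)


def compare_marker_sets(
    calls_a: Sequence[ScoreRecord],
    calls_b: Sequence[ScoreRecord],
    metadata: Sequence[SampleMetadata],
) -> ComparisonReport:
    """Side-by-side contingency tables plus the discordant-sample list.

    The discordant list is where one panel catches what the other misses —
    e.g. residual-positive samples negative under the established markers
    but positive under the new panel.
    """
    ids_a = [r.sample_id for r in calls_a]
    ids_b = [r.sample_id for r in calls_b]
    if sorted(ids_a) != sorted(ids_b):
        raise ValidationError("marker sets were scored on different samples")
    by_id_b = {r.sample_id: r for r in calls_b}
    discordant = [
        (r.sample_id, r.call, by_id_b[r.sample_id].call)
        for r in calls_a
        if r.call != by_id_b[r.sample_id].call
    ]
    return ComparisonReport(
        build_contingency(calls_a, metadata),
        build_contingency(calls_b, metadata),
        discordant,
    )
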