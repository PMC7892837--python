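"""Core data model and table I/O for the urinary-metabolomics pipeline.

Three delimited tables drive every stage: a sample × metabolite relative
intensity matrix, per-sample metadata (group, timepoint, residual-tumour
status, ...) and per-metabolite annotations (pathway membership, exogenous
and structure-known flags).  Urine concentration varies widely between
voids, so intensities are divided by a per-sample osmolality before any
statistics are computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TableFormatError",
    "ValidationError",
    "IntensityMatrix",
    "SampleMetadata",
    "MetaboliteAnnotation",
    "Osmolality",
    "read_intensity_table",
    "write_intensity_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_annotations",
    "write_annotations",
    "read_osmolality",
    "write_osmolality",
    "normalize_osmolality",
    "impute_missing",
    "validate_join",
]

GROUPS = ("case", "control")
SEXES = ("male", "female")
STAGES = ("2A", "3", "4", "none")
TIMEPOINTS = ("pretreatment", "during_after")
RESIDUAL_STATUSES = ("positive", "negative", "unknown")
PRIMARY_SITES = ("adrenal", "mediastinum", "retroperitoneum", "none")

METADATA_COLUMNS = (
    "sample_id",
    "subject_id",
    "group",
    "age_years",
    "sex",
    "stage",
    "timepoint",
    "residual_tumour",
    "primary_site",
)
ANNOTATION_COLUMNS = (
    "metabolite_id",
    "name",
    "super_pathway",
    "sub_pathway",
    "exogenous",
    "structure_known",
)


class TableFormatError(ValueError):
    """Malformed input table (duplicate ids, ragged rows, missing columns)."""


class ValidationError(ValueError):
    """Well-formed table whose content violates a pipeline invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for token in ids:
        if token in seen:
            raise TableFormatError(f"duplicate {what} id: {token!r}")
        seen.add(token)


@dataclass
class IntensityMatrix:
    """Samples × metabolites relative-intensity matrix.

    ``values`` holds non-negative relative intensities (arbitrary units);
    missing measurements are NaN, never zero.  ``normalized`` records whether
    osmolality normalization has been applied — it is applied at most once.
    """

    sample_ids: list[str]
    metabolite_ids: list[str]
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.metabolite_ids)):
            raise TableFormatError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.metabolite_ids)} metabolites"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.metabolite_ids, "metabolite")
        present = self.values[~np.isnan(self.values)]
        if present.size and present.min() < 0:
            raise ValidationError("negative intensity value encountered")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.metabolite_ids
        )

    def column(self, metabolite_id: str) -> np.ndarray:
        try:
            j = self.metabolite_ids.index(metabolite_id)
        except ValueError:
            raise KeyError(f"metabolite {metabolite_id!r} not in matrix") from None
        return self.values[:, j]

    def subset(
        self,
        sample_ids: Sequence[str] | None = None,
        metabolite_ids: Sequence[str] | None = None,
    ) -> "IntensityMatrix":
        """Row/column subset in the order given, preserving the normalized flag."""
        frame = self.to_frame()
        if sample_ids is not None:
            missing = [s for s in sample_ids if s not in frame.index]
            if missing:
                raise ValidationError(f"samples not in matrix: {missing}")
            frame = frame.loc[list(sample_ids)]
        if metabolite_ids is not None:
            missing = [m for m in metabolite_ids if m not in frame.columns]
            if missing:
                raise ValidationError(f"metabolites not in matrix: {missing}")
            frame = frame[list(metabolite_ids)]
        return IntensityMatrix(
            list(frame.index), list(frame.columns), frame.to_numpy(), self.normalized
        )


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    subject_id: str
    group: str
    age_years: float
    sex: str
    stage: str = "none"
    timepoint: str = "pretreatment"
    residual_tumour: str = "unknown"
    primary_site: str = "none"

    def __post_init__(self) -> None:
        for name, value, allowed in (
            ("group", self.group, GROUPS),
            ("sex", self.sex, SEXES),
            ("stage", self.stage, STAGES),
            ("timepoint", self.timepoint, TIMEPOINTS),
            ("residual_tumour", self.residual_tumour, RESIDUAL_STATUSES),
            ("primary_site", self.primary_site, PRIMARY_SITES),
        ):
            if value not in allowed:
                raise ValidationError(
                    f"sample {self.sample_id!r}: {name}={value!r} not one of {allowed}"
                )
        if self.age_years < 0 or not math.isfinite(self.age_years):
            raise ValidationError(f"sample {self.sample_id!r}: invalid age")
        if self.group == "control":
            if self.stage != "none":
                raise ValidationError(
                    f"control sample {self.sample_id!r} must have stage 'none'"
                )
            if self.residual_tumour != "unknown":
                raise ValidationError(
                    f"control sample {self.sample_id!r} must have residual_tumour 'unknown'"
                )
        if self.timepoint == "during_after" and self.residual_tumour == "unknown":
            raise ValidationError(
                f"during/after-treatment sample {self.sample_id!r} needs a "
                "positive/negative residual_tumour label (it is the evaluation truth)"
            )


@dataclass(frozen=True)
class MetaboliteAnnotation:
    metabolite_id: str
    name: str
    super_pathway: str
    sub_pathway: str
    exogenous: bool
    structure_known: bool

    def __post_init__(self) -> None:
        if self.structure_known and not self.sub_pathway:
            raise ValidationError(
                f"metabolite {self.metabolite_id!r}: structure-known metabolites "
                "need a sub_pathway"
            )


@dataclass(frozen=True)
class Osmolality:
    sample_id: str
    osmolality: float

    def __post_init__(self) -> None:
        if not (self.osmolality > 0 and math.isfinite(self.osmolality)):
            raise ValidationError(
                f"sample {self.sample_id!r}: osmolality must be positive"
            )


# ---------------------------------------------------------------------------
# readers / writers


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_intensity_table(path: str | Path) -> IntensityMatrix:
    """Read a delimited intensity table (rows samples, columns metabolites).

    The first column holds sample ids, the header row metabolite ids.  Empty
    cells are read as missing (NaN), never as zero.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    _check_unique(header[1:], "metabolite")
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:  # ragged rows and friends
        raise TableFormatError(f"malformed intensity table {path}: {exc}") from exc
    if not all(np.issubdtype(d, np.number) for d in frame.dtypes):
        raise TableFormatError(f"non-numeric intensity values in {path}")
    return IntensityMatrix(
        [str(s) for s in frame.index],
        [str(m) for m in frame.columns],
        frame.to_numpy(dtype=float),
        normalized=False,
    )


def write_intensity_table(matrix: IntensityMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    sep = _sniff_sep(path)
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required columns {missing}")
    return frame


def _parse_bool(token: str, where: str) -> bool:
    low = token.strip().lower()
    if low in ("true", "1", "yes"):
        return True
    if low in ("false", "0", "no"):
        return False
    raise ValidationError(f"{where}: cannot parse boolean {token!r}")


def read_sample_metadata(path: str | Path) -> list[SampleMetadata]:
    frame = _read_table(path, METADATA_COLUMNS)
    records = [
        SampleMetadata(
            sample_id=row.sample_id,
            subject_id=row.subject_id,
            group=row.group,
            age_years=float(row.age_years),
            sex=row.sex,
            stage=row.stage,
            timepoint=row.timepoint,
            residual_tumour=row.residual_tumour,
            primary_site=row.primary_site,
        )
        for row in frame.itertuples(index=False)
    ]
    _check_unique([r.sample_id for r in records], "sample")
    return records


def write_sample_metadata(records: Iterable[SampleMetadata], path: str | Path) -> None:
    pd.DataFrame([vars(r) for r in records], columns=METADATA_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_annotations(path: str | Path) -> list[MetaboliteAnnotation]:
    frame = _read_table(path, ANNOTATION_COLUMNS)
    records = [
        MetaboliteAnnotation(
            metabolite_id=row.metabolite_id,
            name=row.name,
            super_pathway=row.super_pathway,
            sub_pathway=row.sub_pathway,
            exogenous=_parse_bool(row.exogenous, f"metabolite {row.metabolite_id}"),
            structure_known=_parse_bool(
                row.structure_known, f"metabolite {row.metabolite_id}"
            ),
        )
        for row in frame.itertuples(index=False)
    ]
    _check_unique([r.metabolite_id for r in records], "metabolite")
    return records


def write_annotations(records: Iterable[MetaboliteAnnotation], path: str | Path) -> None:
    pd.DataFrame([vars(r) for r in records], columns=ANNOTATION_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_osmolality(path: str | Path) -> list[Osmolality]:
    frame = _read_table(path, ("sample_id", "osmolality"))
    records = [
        Osmolality(sample_id=row.sample_id, osmolality=float(row.osmolality))
        for row in frame.itertuples(index=False)
    ]
    _check_unique([r.sample_id for r in records], "sample")
    return records


def write_osmolality(records: Iterable[Osmolality], path: str | Path) -> None:
    pd.DataFrame([vars(r) for r in records], columns=["sample_id", "osmolality"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# transforms


def normalize_osmolality(
    matrix: IntensityMatrix, osmo: Sequence[Osmolality]
) -> IntensityMatrix:
    """Divide each sample row by its osmolality, rescaled to the cohort median.

    The rescaling keeps normalized intensities on the same magnitude as the
    raw ones; relative comparisons between samples are unaffected.  A matrix
    already flagged normalized is rejected rather than silently re-scaled.
    """
    if matrix.normalized:
        raise ValidationError("matrix is already osmolality-normalized")
    lookup = {o.sample_id: o.osmolality for o in osmo}
    missing = [s for s in matrix.sample_ids if s not in lookup]
    if missing:
        raise ValidationError(f"no osmolality for samples: {missing}")
    factors = np.array([lookup[s] for s in matrix.sample_ids])
    scale = float(np.median(factors))
    values = matrix.values * (scale / factors)[:, None]
    return IntensityMatrix(
        list(matrix.sample_ids), list(matrix.metabolite_ids), values, normalized=True
    )


def impute_missing(
    matrix: IntensityMatrix, fraction: float = 0.5
) -> tuple[IntensityMatrix, int]:
    """Fill nondetects with ``fraction`` × the per-metabolite observed minimum.

    Metabolomics tables report nondetects as missing; half the observed
    minimum is the conventional stand-in for "below detection".  Returns the
    imputed matrix and the number of cells filled.  A metabolite with no
    observed value at all cannot be imputed and is an error.
    """
    values = matrix.values.copy()
    mask = np.isnan(values)
    n_imputed = int(mask.sum())
    if n_imputed:
        all_missing = mask.all(axis=0)
        if all_missing.any():
            bad = [m for m, b in zip(matrix.metabolite_ids, all_missing) if b]
            raise ValidationError(f"metabolites with no observed values: {bad}")
        fill = fraction * np.nanmin(values, axis=0)
        values[mask] = np.broadcast_to(fill, values.shape)[mask]
    return (
        IntensityMatrix(
            list(matrix.sample_ids),
            list(matrix.metabolite_ids),
            values,
            matrix.normalized,
        ),
        n_imputed,
    )


def validate_join(
    matrix: IntensityMatrix,
    metadata: Sequence[SampleMetadata] | None = None,
    annotations: Sequence[MetaboliteAnnotation] | None = None,
) -> None:
    """Check id consistency across the three tables before any computation."""
    if metadata is not None:
        meta_ids = {r.sample_id for r in metadata}
        unmatched = [s for s in matrix.sample_ids if s not in meta_ids]
        if unmatched:
            raise ValidationError(f"samples without metadata: {unmatched}")
    if annotations is not None:
        anno_ids = {r.metabolite_id for r in annotations}
        unmatched = [m for m in matrix.metabolite_ids if m not in anno_ids]
        if unmatched:
            raise ValidationError(
                f"metabolites without annotation: {unmatched[:5]}"
                + ("..." if len(unmatched) > 5 else "")
            )
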