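"""Synthetic urinary-metabolomics cohorts with stored ground truth.

The generator emulates the statistical structure the downstream pipeline
assumes: ~1000 metabolites with heavy-tailed (log-normal) relative
intensities, a small case group carrying large planted fold-changes on a
handful of disease markers, exogenous (drug) metabolites elevated in treated
cases, strong-effect features without identified structures, and a wide
per-sample dilution range undone by osmolality normalization.  Every planted
effect is recorded in a :class:`GroundTruth` so recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import (
    IntensityMatrix,
    MetaboliteAnnotation,
    Osmolality,
    SampleMetadata,
    ValidationError,
)

__all__ = [
    "PlantedMarker",
    "DISEASE_MARKERS",
    "THREE_MARKER_PANEL",
    "KNOWN_MARKER_PANEL",
    "CohortConfig",
    "GroundTruth",
    "Cohort",
    "generate_cohort",
    "generate_followup",
]


@dataclass(frozen=True)
class PlantedMarker:
    """A metabolite planted with a case-vs-control fold-change.

    ``fold_change`` multiplies case intensities; values below 1 encode a
    decrease.  ``known_marker`` flags the established clinical markers
    (HVA/VMA analogues) that the combination search deliberately sets aside.
    """

    name: str
    super_pathway: str
    sub_pathway: str
    fold_change: float
    known_marker: bool = False

    def __post_init__(self) -> None:
        if not self.fold_change > 0:
            raise ValidationError(f"marker {self.name!r}: fold_change must be > 0")


# The 19 structure-identified top-ranked metabolites of the motivating cohort,
# with their reported neuroblastoma/control fold-changes and pathways.
DISEASE_MARKERS: tuple[PlantedMarker, ...] = (
    PlantedMarker("homovanillate (HVA)", "Amino acid", "Tyrosine metabolism", 17.0, True),
    PlantedMarker("3-methoxytyramine sulfate", "Amino acid", "Tyrosine metabolism", 12.0),
    PlantedMarker("vanillylmandelate (VMA)", "Amino acid", "Tyrosine metabolism", 27.0, True),
    PlantedMarker("vanillactate", "Amino acid", "Tyrosine metabolism", 31.0),
    PlantedMarker("3-methoxy-4-hydroxyphenylglycol", "Amino acid", "Tyrosine metabolism", 19.0),
    PlantedMarker("cystathionine", "Amino acid", "Methionine metabolism", 11.0),
    PlantedMarker("3,4-dihydroxyphenylacetate", "Amino acid", "Tyrosine metabolism", 19.0),
    PlantedMarker("3,4-dihydroxyphenylacetate sulfate", "Amino acid", "Tyrosine metabolism", 9.3),
    PlantedMarker("dopamine 3-O-sulfate", "Amino acid", "Tyrosine metabolism", 7.8),
    PlantedMarker("dehydroascorbate", "Cofactors", "Ascorbate metabolism", 0.29),
    PlantedMarker("3-methoxytyrosine", "Amino acid", "Tyrosine metabolism", 13.0),
    PlantedMarker("alpha-hydroxyisovalerate", "Amino acid", "Leucine metabolism", 3.6),
    PlantedMarker("N2,N5-diacetylornithine", "Amino acid", "Arginine metabolism", 0.56),
    PlantedMarker("urea", "Amino acid", "Arginine metabolism", 0.77),
    PlantedMarker("cortisol", "Lipid", "Corticosteroids", 10.0),
    PlantedMarker("3-methoxytyramine", "Amino acid", "Tyrosine metabolism", 10.0),
    PlantedMarker("homocitrulline", "Amino acid", "Arginine metabolism", 0.33),
    PlantedMarker("tiglyl carnitine (C5)", "Amino acid", "Leucine metabolism", 0.77),
    PlantedMarker("xanthurenate", "Cofactors", "Tryptophan metabolism", 0.49),
)

#: The selected three-marker panel: one representative each from tyrosine
#: metabolism, methionine metabolism and corticosteroids.
THREE_MARKER_PANEL = ("3-methoxytyramine sulfate", "cystathionine", "cortisol")
#: The established clinical comparator panel.
KNOWN_MARKER_PANEL = ("homovanillate (HVA)", "vanillylmandelate (VMA)")

_SUPER_POOL = ("Amino acid", "Lipid", "Carbohydrate", "Nucleotide", "Cofactors", "Energy")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic pretreatment cohort."""

    n_cases: int = 15
    n_controls: int = 39
    n_metabolites: int = 998
    planted_markers: tuple[PlantedMarker, ...] = DISEASE_MARKERS
    n_exogenous: int = 64
    n_unknown_structure: int = 11
    log_noise_sd: float = 0.5
    osmolality_range: tuple[float, float] = (0.5, 2.0)
    baseline_log_mean: float = 3.0
    baseline_log_spread: float = 1.0
    drug_fold_range: tuple[float, float] = (3.0, 15.0)
    drug_case_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValidationError("need at least one case and one control")
        planted = len(self.planted_markers) + self.n_unknown_structure
        if planted + self.n_exogenous > self.n_metabolites:
            raise ValidationError(
                "planted + unknown + exogenous metabolites exceed n_metabolites"
            )
        if not self.log_noise_sd > 0:
            raise ValidationError("log_noise_sd must be positive")
        lo, hi = self.osmolality_range
        if not (0 < lo <= hi):
            raise ValidationError("osmolality_range must satisfy 0 < low <= high")

    def null(self) -> "CohortConfig":
        """Same cohort geometry with every planted effect removed."""
        return CohortConfig(
            n_cases=self.n_cases,
            n_controls=self.n_controls,
            n_metabolites=self.n_metabolites,
            planted_markers=(),
            n_exogenous=0,
            n_unknown_structure=0,
            log_noise_sd=self.log_noise_sd,
            osmolality_range=self.osmolality_range,
            baseline_log_mean=self.baseline_log_mean,
            baseline_log_spread=self.baseline_log_spread,
            seed=self.seed,
        )


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream recovery tests."""

    marker_folds: dict[str, float]  # metabolite_id -> planted case fold
    marker_names: dict[str, str]  # metabolite_id -> display name
    known_marker_ids: tuple[str, ...]
    exogenous_ids: tuple[str, ...]
    unknown_ids: tuple[str, ...]
    unknown_folds: dict[str, float]
    dilution: dict[str, float]  # sample_id -> applied dilution factor
    baseline_log_mean: dict[str, float] = field(default_factory=dict)

    def marker_id(self, name: str) -> str:
        for mid, n in self.marker_names.items():
            if n == name:
                return mid
        raise KeyError(f"no planted marker named {name!r}")

    def panel_ids(self, names: Sequence[str]) -> list[str]:
        return [self.marker_id(n) for n in names]


@dataclass
class Cohort:
    matrix: IntensityMatrix  # raw (un-normalized) intensities
    metadata: list[SampleMetadata]
    annotations: list[MetaboliteAnnotation]
    osmolality: list[Osmolality]
    truth: GroundTruth


def _case_metadata(config: CohortConfig, rng: np.random.Generator) -> list[SampleMetadata]:
    n = config.n_cases
    sexes = ["male"] * ((n + 1) // 2) + ["female"] * (n // 2)
    rng.shuffle(sexes)
    # Stage mix of the motivating cohort: mostly stage 4, one 2A, one 3.
    stages = ["4"] * n
    if n >= 2:
        stages[n // 2] = "2A"
        stages[n // 2 + 1 if n // 2 + 1 < n else 0] = "3"
    sites = (["adrenal"] * max(1, (2 * n) // 3) + ["mediastinum"] * max(1, n // 5))
    sites += ["retroperitoneum"] * (n - len(sites)) if len(sites) < n else []
    sites = sites[:n]
    rng.shuffle(sites)
    ages = np.clip(rng.normal(1.8, 1.75, size=n), 0.1, None)
    return [
        SampleMetadata(
            sample_id=f"P{i + 1:02d}-pre",
            subject_id=f"P{i + 1:02d}",
            group="case",
            age_years=round(float(ages[i]), 2),
            sex=sexes[i],
            stage=stages[i],
            timepoint="pretreatment",
            residual_tumour="positive",
            primary_site=sites[i],
        )
        for i in range(n)
    ]


def _control_metadata(config: CohortConfig, rng: np.random.Generator) -> list[SampleMetadata]:
    n = config.n_controls
    sexes = ["male"] * (n // 2) + ["female"] * ((n + 1) // 2)
    rng.shuffle(sexes)
    ages = np.clip(rng.normal(2.9, 2.05, size=n), 0.1, None)
    return [
        SampleMetadata(
            sample_id=f"C{i + 1:02d}-pre",
            subject_id=f"C{i + 1:02d}",
            group="control",
            age_years=round(float(ages[i]), 2),
            sex=sexes[i],
        )
        for i in range(n)
    ]


def generate_cohort(config: CohortConfig = CohortConfig()) -> Cohort:
    """Generate one pretreatment cohort (one sample per subject).

    Per metabolite a log-location is drawn once; intensities are log-normal
    around it.  Case rows of planted markers are multiplied by the configured
    fold-change.  Exogenous metabolites are elevated in a random subset of
    case samples — but only when disease markers are planted, since treatment
    follows diagnosis; a cohort with no planted markers is a clean null.
    Finally every sample is scaled by a dilution factor recorded as its
    osmolality, so the raw matrix requires normalization.  Deterministic
    under a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_samples = config.n_cases + config.n_controls
    p = config.n_metabolites

    metabolite_ids = [f"met{j + 1:04d}" for j in range(p)]
    special = rng.choice(
        p,
        size=len(config.planted_markers) + config.n_unknown_structure + config.n_exogenous,
        replace=False,
    )
    k = len(config.planted_markers)
    marker_idx = special[:k]
    unknown_idx = special[k : k + config.n_unknown_structure]
    exo_idx = special[k + config.n_unknown_structure :]

    mu = rng.normal(config.baseline_log_mean, config.baseline_log_spread, size=p)
    log_values = mu[None, :] + config.log_noise_sd * rng.standard_normal((n_samples, p))
    values = np.exp(log_values)

    case_rows = slice(0, config.n_cases)
    for idx, marker in zip(marker_idx, config.planted_markers):
        values[case_rows, idx] *= marker.fold_change

    # Strong-effect features without identified structures compete with the
    # named markers for the top ranks, exercising the top-K exclusion.
    unknown_folds: dict[str, float] = {}
    for idx in unknown_idx:
        if rng.random() < 0.7:
            fold = float(np.exp(rng.uniform(np.log(3.0), np.log(20.0))))
        else:
            fold = float(rng.uniform(0.3, 0.8))
        values[case_rows, idx] *= fold
        unknown_folds[metabolite_ids[idx]] = fold

    if len(config.planted_markers) > 0:
        lo, hi = config.drug_fold_range
        for idx in exo_idx:
            fold = rng.uniform(lo, hi)
            treated = rng.random(config.n_cases) < config.drug_case_fraction
            values[case_rows, idx][treated] *= fold

    dilution = rng.uniform(*config.osmolality_range, size=n_samples)
    values *= dilution[:, None]

    metadata = _case_metadata(config, rng) + _control_metadata(config, rng)
    sample_ids = [m.sample_id for m in metadata]

    annotations: list[MetaboliteAnnotation] = []
    marker_lookup = {int(i): m for i, m in zip(marker_idx, config.planted_markers)}
    unknown_set = set(int(i) for i in unknown_idx)
    exo_set = set(int(i) for i in exo_idx)
    for j, mid in enumerate(metabolite_ids):
        if j in marker_lookup:
            m = marker_lookup[j]
            annotations.append(
                MetaboliteAnnotation(mid, m.name, m.super_pathway, m.sub_pathway, False, True)
            )
        elif j in unknown_set:
            annotations.append(
                MetaboliteAnnotation(mid, f"X-{10000 + j}", "", "", False, False)
            )
        elif j in exo_set:
            annotations.append(
                MetaboliteAnnotation(
                    mid, f"drug conjugate {j}", "Xenobiotics", "Drug metabolism", True, True
                )
            )
        else:
            annotations.append(
                MetaboliteAnnotation(
                    mid,
                    mid,
                    _SUPER_POOL[j % len(_SUPER_POOL)],
                    f"background pathway {j % 40}",
                    False,
                    True,
                )
            )

    osmolality = [Osmolality(s, float(d)) for s, d in zip(sample_ids, dilution)]
    truth = GroundTruth(
        marker_folds={
            metabolite_ids[i]: m.fold_change for i, m in zip(marker_idx, config.planted_markers)
        },
        marker_names={
            metabolite_ids[i]: m.name for i, m in zip(marker_idx, config.planted_markers)
        },
        known_marker_ids=tuple(
            metabolite_ids[i]
            for i, m in zip(marker_idx, config.planted_markers)
            if m.known_marker
        ),
        exogenous_ids=tuple(metabolite_ids[i] for i in exo_idx),
        unknown_ids=tuple(metabolite_ids[i] for i in unknown_idx),
        unknown_folds=unknown_folds,
        dilution=dict(zip(sample_ids, (float(d) for d in dilution))),
        baseline_log_mean=dict(zip(metabolite_ids, (float(m) for m in mu))),
    )
    matrix = IntensityMatrix(sample_ids, metabolite_ids, values, normalized=False)
    return Cohort(matrix, metadata, annotations, osmolality, truth)


def generate_followup(
    config: CohortConfig,
    truth: GroundTruth,
    n_subjects: int = 13,
    n_samples: int = 33,
    residual_counts: tuple[int, int] = (13, 20),
    attenuation: float = 1.0,
    seed: int | None = None,
) -> tuple[IntensityMatrix, list[SampleMetadata], list[Osmolality]]:
    """Generate during/after-treatment samples for a subset of case subjects.

    Samples labelled residual-tumour positive retain the planted marker
    fold-changes, geometrically attenuated (``fold ** attenuation``);
    negative samples revert to the control distribution.  Exogenous (drug)
    metabolites stay elevated regardless of residual status — every subject
    is under treatment.  Metabolite baselines come from the pretreatment
    ``truth`` so a model frozen on the pretreatment cohort applies directly.
    """
    n_pos, n_neg = residual_counts
    if n_pos < 0 or n_neg < 0 or n_pos + n_neg != n_samples:
        raise ValidationError("residual_counts must be non-negative and sum to n_samples")
    if not 1 <= n_subjects <= config.n_cases:
        raise ValidationError("n_subjects must be between 1 and n_cases")
    if n_samples < n_subjects:
        raise ValidationError("need at least one sample per subject")
    if not 0 <= attenuation <= 1:
        raise ValidationError("attenuation must be in [0, 1]")

    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    p = config.n_metabolites
    metabolite_ids = [f"met{j + 1:04d}" for j in range(p)]
    mu = np.array([truth.baseline_log_mean[m] for m in metabolite_ids])

    subjects = [f"P{i + 1:02d}" for i in range(n_subjects)]
    owner = subjects * (n_samples // n_subjects) + subjects[: n_samples % n_subjects]
    status = ["positive"] * n_pos + ["negative"] * n_neg
    rng.shuffle(status)

    values = np.exp(
        mu[None, :] + config.log_noise_sd * rng.standard_normal((n_samples, p))
    )
    marker_cols = {m: metabolite_ids.index(m) for m in truth.marker_folds}
    for i, st in enumerate(status):
        if st == "positive":
            for mid, fold in truth.marker_folds.items():
                values[i, marker_cols[mid]] *= fold**attenuation
    if truth.exogenous_ids:
        lo, hi = config.drug_fold_range
        exo_cols = [metabolite_ids.index(m) for m in truth.exogenous_ids]
        for j in exo_cols:
            fold = rng.uniform(lo, hi)
            treated = rng.random(n_samples) < config.drug_case_fraction
            values[treated, j] *= fold

    dilution = rng.uniform(*config.osmolality_range, size=n_samples)
    values *= dilution[:, None]

    counter: dict[str, int] = {}
    metadata: list[SampleMetadata] = []
    sample_ids: list[str] = []
    for subj, st in zip(owner, status):
        counter[subj] = counter.get(subj, 0) + 1
        sid = f"{subj}-fu{counter[subj]}"
        sample_ids.append(sid)
        metadata.append(
            SampleMetadata(
                sample_id=sid,
                subject_id=subj,
                group="case",
                age_years=2.0,
                sex="male",
                stage="4",
                timepoint="during_after",
                residual_tumour=st,
                primary_site="adrenal",
            )
        )
    osmolality = [Osmolality(s, float(d)) for s, d in zip(sample_ids, dilution)]
    matrix = IntensityMatrix(sample_ids, metabolite_ids, values, normalized=False)
    return matrix, metadata, osmolality
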