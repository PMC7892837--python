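"""Shared configuration for the analysis drivers.

Every driver regenerates the same seeded synthetic cohort through the
uromet package rather than reading intermediate files, so each one is
runnable on its own and the whole chain stays deterministic.
"""

from pathlib import Path

import uromet as u

SEED = 20210218
RESULTS = Path(__file__).resolve().parent.parent / "results"

COHORT_CONFIG = u.CohortConfig(seed=SEED)

# Follow-up scenario: during/after-treatment samples from 13 case subjects,
# 13 residual-positive / 20 residual-negative, with marker elevation
# attenuated to 80% on the log scale in residual-positive samples (partial
# response to therapy).
FOLLOWUP_ATTENUATION = 0.8


def pretreatment_cohort():
    cohort = u.generate_cohort(COHORT_CONFIG)
    normalized = u.normalize_osmolality(cohort.matrix, cohort.osmolality)
    return cohort, normalized


def screened_candidate_ids(cohort, normalized, n_trees=500, k=30):
    """Screen → exogenous exclusion → forest ranking → top-k structure-known."""
    records = u.screen(normalized, cohort.metadata, alpha=0.05)
    passed = [r for r in records if r.passed]
    kept = u.exclude_exogenous(passed, cohort.annotations)
    ranking = u.rank_importance(
        normalized,
        cohort.metadata,
        [r.metabolite_id for r in kept],
        n_trees=n_trees,
        seed=SEED,
    )
    candidates = u.select_candidates(ranking, cohort.annotations, k=k)
    return records, kept, ranking, candidates
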