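"""Generate the synthetic study cohort and report its composition.

Emulates the study design: 54 pretreatment urine samples (15 neuroblastoma
cases, 39 controls), 998 metabolites with 19 disease markers planted at the
published fold-changes, 64 exogenous (drug) metabolites elevated in treated
cases, 11 strong-effect features without identified structures, and a
follow-up set of 33 during/after-treatment samples from 13 case subjects.
Writes the cohort composition summary to results/cohort_summary.json.
"""

import json

import uromet as u
from common import COHORT_CONFIG, FOLLOWUP_ATTENUATION, RESULTS, pretreatment_cohort


def main():
    cohort, _ = pretreatment_cohort()
    followup_matrix, followup_meta, _ = u.generate_followup(
        COHORT_CONFIG, cohort.truth, attenuation=FOLLOWUP_ATTENUATION
    )

    summary = {
        "seed": COHORT_CONFIG.seed,
        "pretreatment_samples": len(cohort.metadata),
        "cases": sum(m.group == "case" for m in cohort.metadata),
        "controls": sum(m.group == "control" for m in cohort.metadata),
        "metabolites": cohort.matrix.shape[1],
        "planted_markers": len(cohort.truth.marker_folds),
        "exogenous_metabolites": len(cohort.truth.exogenous_ids),
        "unknown_structure_features": len(cohort.truth.unknown_ids),
        "followup_samples": followup_matrix.shape[0],
        "followup_subjects": len({m.subject_id for m in followup_meta}),
        "followup_residual_positive": sum(
            m.residual_tumour == "positive" for m in followup_meta
        ),
        "planted_marker_table": [
            {
                "metabolite_id": mid,
                "name": cohort.truth.marker_names[mid],
                "fold_change": fold,
            }
            for mid, fold in sorted(cohort.truth.marker_folds.items())
        ],
    }
    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "cohort_summary.json"
    out.write_text(json.dumps(summary, indent=2) + "\n")
    print(
        f"cohort: {summary['cases']} cases / {summary['controls']} controls, "
        f"{summary['metabolites']} metabolites "
        f"({summary['planted_markers']} planted markers, "
        f"{summary['exogenous_metabolites']} exogenous, "
        f"{summary['unknown_structure_features']} unknown-structure)"
    )
    print(
        f"follow-up: {summary['followup_samples']} samples from "
        f"{summary['followup_subjects']} subjects, "
        f"{summary['followup_residual_positive']} residual-positive"
    )
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
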