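"""Stage 5: follow-up evaluation against residual-tumour status.

Scores the 33 during/after-treatment samples with the models frozen on the
pretreatment cohort, cross-tabulates calls against the residual-tumour
labels, and compares the new three-marker panel with the established pair.
Writes results/followup_evaluation.json.
"""

import json

import uromet as u
from common import (
    COHORT_CONFIG,
    FOLLOWUP_ATTENUATION,
    RESULTS,
    SEED,
    pretreatment_cohort,
)


def table_dict(table):
    sens, spec = u.sensitivity_specificity(table)
    return {
        "tp": table.tp, "fp": table.fp, "fn": table.fn, "tn": table.tn,
        "sensitivity": sens, "specificity": spec,
    }


def main():
    cohort, normalized = pretreatment_cohort()
    panel = cohort.truth.panel_ids(u.THREE_MARKER_PANEL)
    known = cohort.truth.panel_ids(u.KNOWN_MARKER_PANEL)
    new_model = u.fit_marker_model(normalized, cohort.metadata, panel, seed=SEED)
    known_model = u.fit_marker_model(normalized, cohort.metadata, known, seed=SEED)

    fu_matrix, fu_meta, fu_osmo = u.generate_followup(
        COHORT_CONFIG, cohort.truth, attenuation=FOLLOWUP_ATTENUATION
    )
    fu_norm = u.normalize_osmolality(fu_matrix, fu_osmo)

    new_calls = u.score_samples(new_model, fu_norm)
    known_calls = u.score_samples(known_model, fu_norm)
    report = u.compare_marker_sets(new_calls, known_calls, fu_meta)

    out = {
        "attenuation": FOLLOWUP_ATTENUATION,
        "three_marker": table_dict(report.table_a),
        "known_markers": table_dict(report.table_b),
        "discordant_samples": [
            {"sample_id": s, "three_marker": a, "known_markers": b}
            for s, a, b in report.discordant
        ],
    }
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "followup_evaluation.json").write_text(json.dumps(out, indent=2) + "\n")

    for label in ("three_marker", "known_markers"):
        t = out[label]
        print(
            f"{label}: tp={t['tp']} fp={t['fp']} fn={t['fn']} tn={t['tn']} "
            f"sensitivity={t['sensitivity']} specificity={t['specificity']}"
        )
    print(f"discordant samples: {len(out['discordant_samples'])}")


if __name__ == "__main__":
    main()
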