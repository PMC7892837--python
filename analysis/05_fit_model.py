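"""Stage 4: OPLS-DA predictive-value models with validation.

Fits the selected three-marker panel (tyrosine / methionine / corticosteroid
representatives) and, for comparison, the established two-marker panel
(HVA/VMA analogues), on the pretreatment cohort: per-marker constants, R2Y,
7-fold cross-validated Q2, and a 100-permutation significance test.  Writes
model summaries to results/model_*.json and per-sample predictive values to
results/scores_pretreatment.tsv.
"""

import json

import pandas as pd

import uromet as u
from common import RESULTS, SEED, pretreatment_cohort


def summarize(model, names):
    return {
        "markers": [names[m] for m in model.marker_ids],
        "constants": [round(float(c), 3) for c in model.coefficients],
        "r2y": round(model.r2y, 3),
        "q2": round(model.q2, 3),
        "cv_folds": model.cv_folds,
        "k_ortho": model.k_ortho,
        "permutation_p_q2": round(model.permutation.p_q2, 4),
        "n_permutations": len(model.permutation.permuted),
    }


def main():
    cohort, normalized = pretreatment_cohort()
    names = {a.metabolite_id: a.name for a in cohort.annotations}
    panel = cohort.truth.panel_ids(u.THREE_MARKER_PANEL)
    known = cohort.truth.panel_ids(u.KNOWN_MARKER_PANEL)

    models = {}
    for label, marker_ids in (("three_marker", panel), ("known_markers", known)):
        model = u.fit_marker_model(
            normalized, cohort.metadata, marker_ids, k_ortho=1, folds=7,
            n_perm=100, seed=SEED,
        )
        models[label] = model
        summary = summarize(model, names)
        RESULTS.mkdir(exist_ok=True)
        (RESULTS / f"model_{label}.json").write_text(
            json.dumps(summary, indent=2) + "\n"
        )
        consts = ", ".join(
            f"{n}={c}" for n, c in zip(summary["markers"], summary["constants"])
        )
        print(
            f"{label}: R2Y={summary['r2y']} Q2={summary['q2']} "
            f"(7-fold CV), permutation p={summary['permutation_p_q2']}"
        )
        print(f"  constants: {consts}")

    group = {m.sample_id: m.group for m in cohort.metadata}
    rows = []
    for label, model in models.items():
        for r in u.score_samples(model, normalized):
            rows.append(
                {
                    "model": label,
                    "sample_id": r.sample_id,
                    "group": group[r.sample_id],
                    "predictive_value": round(r.predictive_value, 4),
                    "call": r.call,
                }
            )
    pd.DataFrame(rows).to_csv(RESULTS / "scores_pretreatment.tsv", sep="\t", index=False)

    for label, model in models.items():
        recs = u.score_samples(model, normalized)
        pos_cases = sum(
            r.call == "positive" for r in recs if group[r.sample_id] == "case"
        )
        fp = sum(r.call == "positive" for r in recs if group[r.sample_id] == "control")
        print(f"{label}: {pos_cases}/15 cases positive, {fp} control false positives")


if __name__ == "__main__":
    main()
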