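"""Stage 2: random-forest importance ranking and candidate selection.

Ranks the screened non-exogenous metabolites by out-of-bag permutation
importance, takes the top 30 and drops features without identified
structures.  Writes results/ranking_top30.tsv (with structure flags and
planted ground truth) and results/candidates.tsv.
"""

import pandas as pd

import uromet as u
from common import RESULTS, pretreatment_cohort, screened_candidate_ids


def main():
    cohort, normalized = pretreatment_cohort()
    _, kept, ranking, candidates = screened_candidate_ids(cohort, normalized)

    anno = {a.metabolite_id: a for a in cohort.annotations}
    marker_ids = set(cohort.truth.marker_folds)

    def row(entry):
        a = anno[entry.metabolite_id]
        return {
            "rank": entry.rank,
            "metabolite_id": entry.metabolite_id,
            "name": a.name,
            "importance": round(entry.importance, 5),
            "sub_pathway": a.sub_pathway,
            "structure_known": a.structure_known,
            "planted_marker": entry.metabolite_id in marker_ids,
        }

    RESULTS.mkdir(exist_ok=True)
    top30 = ranking.top(30)
    pd.DataFrame([row(e) for e in top30]).to_csv(
        RESULTS / "ranking_top30.tsv", sep="\t", index=False
    )
    pd.DataFrame([row(e) for e in candidates]).to_csv(
        RESULTS / "candidates.tsv", sep="\t", index=False
    )

    n_unknown = sum(1 for e in top30 if not anno[e.metabolite_id].structure_known)
    n_planted = sum(1 for e in top30 if e.metabolite_id in marker_ids)
    print(
        f"ranked {len(ranking.entries)} screened metabolites "
        f"(forest OOB error {ranking.oob_error:.3f})"
    )
    print(
        f"top 30: {n_planted} planted markers, {n_unknown} unknown-structure "
        f"features excluded -> {len(candidates)} candidates"
    )


if __name__ == "__main__":
    main()
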