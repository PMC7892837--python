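"""Stage 3: pathway-constrained search over three-marker combinations.

Enumerates every size-3 subset of the candidates drawing at most one
metabolite per sub-pathway, with the established clinical markers (HVA/VMA
analogues) excluded from the search, and ranks combinations by false
negatives, then cross-validated Q2, then R2Y.  Writes the ranked list to
results/combinations.tsv.
"""

import pandas as pd

import uromet as u
from common import RESULTS, SEED, pretreatment_cohort, screened_candidate_ids


def main():
    cohort, normalized = pretreatment_cohort()
    _, _, _, candidates = screened_candidate_ids(cohort, normalized)
    candidate_ids = [e.metabolite_id for e in candidates]

    combos = u.search_combinations(
        candidate_ids,
        normalized,
        cohort.metadata,
        cohort.annotations,
        size=3,
        pathway_constraint=True,
        exclude_ids=cohort.truth.known_marker_ids,
        seed=SEED,
    )

    names = {a.metabolite_id: a.name for a in cohort.annotations}
    frame = pd.DataFrame(
        [
            {
                "rank": i + 1,
                "markers": " + ".join(names[m] for m in c.marker_ids),
                "sub_pathways": " / ".join(c.sub_pathways),
                "false_negatives": c.fn_count,
                "q2": round(c.q2, 3),
                "r2y": round(c.r2y, 3),
            }
            for i, c in enumerate(combos)
        ]
    )
    RESULTS.mkdir(exist_ok=True)
    frame.to_csv(RESULTS / "combinations.tsv", sep="\t", index=False)

    top = combos[0]
    print(
        f"searched {len(combos)} pathway-constrained three-marker combinations "
        f"from {len(candidate_ids)} candidates "
        f"({len(cohort.truth.known_marker_ids)} known markers excluded)"
    )
    print(
        f"best: {' + '.join(names[m] for m in top.marker_ids)} "
        f"(FN={top.fn_count}, Q2={top.q2:.3f}, R2Y={top.r2y:.3f})"
    )
    print(f"pathways: {' / '.join(top.sub_pathways)}")


if __name__ == "__main__":
    main()
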