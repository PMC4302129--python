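"""Parentage hypotheses by haplotype sharing.

For each trio hypothesis, a fragment is consistent when the offspring's
two haplotypes split into one exactly matching each proposed parent.
The default run checks the clementine (willowleaf x sweet orange) and
lemon (sour orange x citron) trios, the taxon-level F1 hypothesis for
sour orange, and the bergamot rejection case."""

import importlib

import pandas as pd

common = importlib.import_module("00_common")


def main() -> None:
    results, _ = common.outdirs()
    res = common.study_run()
    rows = []
    for h in res.parentage:
        verdict = "supported" if (
            h.n_informative and h.consistency == 1.0
        ) else "rejected" if h.n_inconsistent else "equivocal"
        rows.append(
            {
                "offspring": h.offspring,
                "parent1": h.parent1,
                "parent2": h.parent2,
                "consistent": h.n_consistent,
                "inconsistent": h.n_inconsistent,
                "uninformative": h.n_uninformative,
                "verdict": verdict,
            }
        )
        print(f"{h.offspring} = {h.parent1} x {h.parent2}: "
              f"{h.n_consistent} consistent / {h.n_inconsistent} inconsistent"
              f" / {h.n_uninformative} uninformative -> {verdict}")
    pd.DataFrame(rows).to_csv(results / "parentage.tsv", sep="\t", index=False)
    detail = pd.concat(
        [h.verdicts.assign(offspring=h.offspring) for h in res.parentage],
        ignore_index=True,
    )
    detail.to_csv(results / "parentage_fragments.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
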