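"""Paint chromosome 2: per-accession genotypic ancestry classes along the
fragment map, a BED export for genome-browser display, and an optional
matrix figure."""

import importlib

common = importlib.import_module("00_common")

from haplopaint import admixture, pipeline


def main() -> None:
    results, _ = common.outdirs()
    res = common.study_run()
    res.painting.to_csv(results / "painting.tsv", sep="\t")
    res.painting_bed.to_csv(results / "painting.bed", sep="\t", index=False)

    switches = {
        acc: admixture.class_switches(res.painting.loc[acc])
        for acc in res.painting.index
    }
    concord = pipeline.painting_concordance(
        res.painting, res.truth, res.coverage, res.config.depth_threshold
    )
    print(f"painted {len(res.painting)} accessions over "
          f"{res.painting.shape[1]} fragments")
    print(f"track vs simulated truth on well-covered amplicons: "
          f"{concord['concordance_pct']}% of {concord['n_compared']}")
    mosaics = sorted(switches, key=switches.get, reverse=True)[:5]
    print("most mosaic tracks (ancestry-class switches):",
          {m: switches[m] for m in mosaics})

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        classes = sorted(set(res.painting.values.ravel()))
        lut = {c: i for i, c in enumerate(classes)}
        img = res.painting.map(lut.get).to_numpy(dtype=float)
        fig, ax = plt.subplots(figsize=(8, 10))
        ax.imshow(img, aspect="auto", cmap="tab20", interpolation="nearest")
        ax.set_xticks(range(res.painting.shape[1]))
        ax.set_xticklabels(res.painting.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(len(res.painting)))
        ax.set_yticklabels(res.painting.index, fontsize=5)
        ax.set_title("Genotypic ancestry classes along the chromosome")
        fig.tight_layout()
        fig.savefig(results / "painting.png", dpi=150)
        print("wrote results/painting.png")
    except Exception as exc:  # plotting is decorative
        print(f"figure skipped: {exc}")


if __name__ == "__main__":
    main()
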