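"""Filter, demultiplex and bin the reads; account for coverage.

Reproduces the run-level bookkeeping: short primer-dimer reads discarded,
reads sorted by barcode and gene-specific primer into 768 amplicon bins,
and the below-threshold fraction that motivates a second sequencing
round."""

import importlib
import json

common = importlib.import_module("00_common")


def main() -> None:
    results, _ = common.outdirs()
    res = common.study_run()
    res.coverage.to_csv(results / "coverage.tsv", sep="\t", index=False)
    report = {**res.preprocess_report, **res.coverage_summary,
              "n_unassigned": len(res.unassigned)}
    (results / "read_accounting.json").write_text(json.dumps(report, indent=2))
    print(f"{report['total_reads']:,} raw reads; "
          f"{report['discarded_short']:,} short reads discarded "
          f"({report['discard_fraction']:.0%}); "
          f"{report['total_assigned_reads']:,} binned")
    print(f"combined coverage: mean {report['mean_depth']} reads/amplicon, "
          f"{report['pct_below_threshold']}% of the 768 amplicons below "
          f"{report['threshold']} reads")


if __name__ == "__main__":
    main()
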