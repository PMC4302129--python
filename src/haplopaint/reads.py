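"""Read filtering, demultiplexing and per-amplicon binning.

Raw amplicon reads are decorated as ``barcode + gene-specific primer +
insert``. Processing removes short (primer-dimer) reads, assigns each
surviving read to an accession by exact barcode match and to a fragment by
primer match (tolerating up to two mismatches), trims the decoration, and
bins reads per accession x fragment with depth accounting against the
50-read confident-calling threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .panel import ReferencePanel

DEFAULT_MIN_LENGTH = 150
DEFAULT_DEPTH_THRESHOLD = 50


@dataclass
class ReadRecord:
    id: str
    sequence: str
    quality: str
    barcode_call: str | None = None
    fragment_call: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")


@dataclass
class AmpliconBin:
    accession: str
    fragment: str
    reads: list[ReadRecord] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.reads)

    def passes_threshold(self, threshold: int = DEFAULT_DEPTH_THRESHOLD) -> bool:
        return self.depth >= threshold


def parse_fastq(path: str | Path) -> list[ReadRecord]:
    records = []
    try:
        with open(path) as fh:
            for title, seq, qual in FastqGeneralIterator(fh):
                records.append(ReadRecord(title.split()[0], seq, qual))
    except ValueError as exc:
        where = records[-1].id if records else "first record"
        raise ValueError(f"malformed FASTQ near record after {where!r}: {exc}") from exc
    return records


def preprocess_reads(
    reads: list[ReadRecord] | str | Path,
    min_length: int = DEFAULT_MIN_LENGTH,
    decoration_length: int = 0,
) -> tuple[list[ReadRecord], dict]:
    """Drop short (primer-dimer style) reads.

    Length is judged on the insert, i.e. after discounting
    ``decoration_length`` bases of barcode + primer decoration.
    """
    if isinstance(reads, (str, Path)):
        reads = parse_fastq(reads)
    kept = [r for r in reads if len(r.sequence) - decoration_length >= min_length]
    n_total = len(reads)
    n_discarded = n_total - len(kept)
    report = {
        "total_reads": n_total,
        "kept_reads": len(kept),
        "discarded_short": n_discarded,
        "discard_fraction": (n_discarded / n_total) if n_total else 0.0,
    }
    return kept, report


def _hamming_str(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex_and_bin(
    reads: list[ReadRecord],
    sample_sheet: pd.DataFrame,
    panel: ReferencePanel,
    barcode_length: int | None = None,
    max_primer_mismatches: int = 2,
    search_reverse_complement: bool = False,
) -> tuple[dict[tuple[str, str], AmpliconBin], list[ReadRecord]]:
    """Assign reads to accession x fragment bins; trim decoration.

    Barcodes are matched exactly at the read start (the barcode set is
    constructed with pairwise Hamming distance >= 3, so exact matching is
    well posed). The gene-specific primer that follows is matched against
    the panel allowing up to ``max_primer_mismatches`` substitutions.
    """
    barcodes = sample_sheet["barcode"].tolist()
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcode in sample sheet")
    if barcode_length is None:
        lengths = {len(b) for b in barcodes}
        if len(lengths) != 1:
            raise ValueError("mixed barcode lengths; pass barcode_length explicitly")
        barcode_length = lengths.pop()
    bc_to_acc = dict(zip(sample_sheet["barcode"], sample_sheet["accession"]))

    primers = {f.primer: f.name for f in panel.fragments.values()}
    primer_len = len(next(iter(primers)))

    bins: dict[tuple[str, str], AmpliconBin] = {
        (acc, frag): AmpliconBin(acc, frag)
        for acc in sample_sheet["accession"]
        for frag in panel.fragment_names
    }
    unassigned: list[ReadRecord] = []

    def primer_call(segment: str) -> str | None:
        frag = primers.get(segment)
        if frag is not None:
            return frag
        best, best_d = None, max_primer_mismatches + 1
        for p, name in primers.items():
            d = _hamming_str(segment, p)
            if d < best_d:
                best, best_d = name, d
        return best

    for read in reads:
        candidates = [read.sequence]
        quals = [read.quality]
        if search_reverse_complement:
            comp = str.maketrans("ACGTN", "TGCAN")
            candidates.append(read.sequence.translate(comp)[::-1])
            quals.append(read.quality[::-1])
        placed = False
        for seq, qual in zip(candidates, quals):
            acc = bc_to_acc.get(seq[:barcode_length])
            if acc is None:
                continue
            frag = primer_call(seq[barcode_length : barcode_length + primer_len])
            if frag is None:
                continue
            cut = barcode_length + primer_len
            trimmed = ReadRecord(read.id, seq[cut:], qual[cut:], acc, frag)
            bins[(acc, frag)].reads.append(trimmed)
            placed = True
            break
        if not placed:
            unassigned.append(read)
    return bins, unassigned


def coverage_summary(
    bins: dict[tuple[str, str], AmpliconBin],
    threshold: int = DEFAULT_DEPTH_THRESHOLD,
) -> tuple[pd.DataFrame, dict]:
    """Per-amplicon depth table (zeros retained) and run-level accounting."""
    table = pd.DataFrame(
        [
            {
                "accession": b.accession,
                "fragment": b.fragment,
                "depth": b.depth,
                "pass": b.passes_threshold(threshold),
            }
            for b in bins.values()
        ]
    )
    n_amplicons = len(table)
    n_below = int((~table["pass"]).sum())
    summary = {
        "n_amplicons": n_amplicons,
        "total_assigned_reads": int(table["depth"].sum()),
        "mean_depth": mean_reads_per_amplicon(int(table["depth"].sum()), n_amplicons),
        "n_below_threshold": n_below,
        "pct_below_threshold": below_threshold_percent(n_below, n_amplicons),
        "threshold": threshold,
    }
    return table, summary


# ----------------------------------------------------------------- accounting
def mean_reads_per_amplicon(total_reads: int, n_amplicons: int) -> int:
    """Run-summary mean depth, reported to the nearest read."""
    if n_amplicons <= 0:
        raise ValueError("n_amplicons must be positive")
    return int(round(total_reads / n_amplicons))


def below_threshold_percent(n_below: int, n_amplicons: int) -> int:
    """Percentage of amplicons under the depth threshold, nearest integer."""
    if n_amplicons <= 0:
        raise ValueError("n_amplicons must be positive")
    return int(round(100.0 * n_below / n_amplicons))
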