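"""Reference panel: per-fragment references, region annotation, map positions.

A *fragment* is one targeted gene amplicon (~450-550 bp) on the studied
chromosome. Each fragment carries a reference sequence, a gene-specific
primer used for read-to-fragment identification, an intron/exon/UTR span
annotation, and a map position ordering the fragments along the chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import seqs


@dataclass
class Region:
    """Annotated span on a fragment reference; 1-based inclusive coordinates."""

    label: str  # "intron" / "exon" / "utr3"
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Fragment:
    name: str
    reference: "seqs.np.ndarray"  # uint8 codes
    primer: str
    map_position: int  # chromosome coordinate of the fragment start (1-based)
    regions: list[Region] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.reference)

    @property
    def reference_str(self) -> str:
        return seqs.decode(self.reference)

    def region_at(self, position: int) -> str:
        """Region label covering a 1-based fragment position."""
        for r in self.regions:
            if r.start <= position <= r.end:
                return r.label
        return "unannotated"


@dataclass
class ReferencePanel:
    """All fragments of the targeted chromosome, ordered by map position."""

    fragments: dict[str, Fragment]

    def __post_init__(self) -> None:
        ordered = sorted(self.fragments.values(), key=lambda f: f.map_position)
        self.fragments = {f.name: f for f in ordered}

    @property
    def fragment_names(self) -> list[str]:
        return list(self.fragments)

    def __len__(self) -> int:
        return len(self.fragments)

    def __getitem__(self, name: str) -> Fragment:
        return self.fragments[name]

    # ---------------------------------------------------------------- I/O
    def write(self, outdir: str | Path, prefix: str = "panel") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        records = [
            SeqRecord(Seq(f.reference_str), id=f.name, description="")
            for f in self.fragments.values()
        ]
        SeqIO.write(records, outdir / f"{prefix}.fasta", "fasta")
        self.regions_table().to_csv(outdir / "regions.tsv", sep="\t", index=False)
        self.primer_table().to_csv(outdir / "primers.tsv", sep="\t", index=False)
        self.map_table().to_csv(outdir / "fragment_map.tsv", sep="\t", index=False)

    def regions_table(self) -> pd.DataFrame:
        rows = [
            {"fragment": f.name, "region": r.label, "start": r.start, "end": r.end}
            for f in self.fragments.values()
            for r in f.regions
        ]
        return pd.DataFrame(rows, columns=["fragment", "region", "start", "end"])

    def primer_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"fragment": f.name, "primer": f.primer} for f in self.fragments.values()]
        )

    def map_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"fragment": f.name, "map_position": f.map_position, "length": f.length}
                for f in self.fragments.values()
            ]
        )

    @classmethod
    def read(cls, outdir: str | Path, prefix: str = "panel") -> "ReferencePanel":
        outdir = Path(outdir)
        refs = {
            rec.id: seqs.encode(str(rec.seq))
            for rec in SeqIO.parse(outdir / f"{prefix}.fasta", "fasta")
        }
        regions = pd.read_csv(outdir / "regions.tsv", sep="\t")
        primers = pd.read_csv(outdir / "primers.tsv", sep="\t").set_index("fragment")["primer"]
        fmap = pd.read_csv(outdir / "fragment_map.tsv", sep="\t").set_index("fragment")
        fragments = {}
        for name, ref in refs.items():
            sub = regions[regions["fragment"] == name]
            fragments[name] = Fragment(
                name=name,
                reference=ref,
                primer=str(primers[name]),
                map_position=int(fmap.loc[name, "map_position"]),
                regions=[
                    Region(row.region, int(row.start), int(row.end))
                    for row in sub.itertuples()
                ],
            )
        return cls(fragments)
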