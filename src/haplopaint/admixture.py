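"""Chromosome ancestry painting, censuses, diagnostic SNPs and parentage.

Once each haplotype is assigned to an ancestral taxon (or indeterminate),
an accession's genotype at a fragment reduces to an unordered pair of
taxon labels — its genotypic ancestry class (e.g. re/re homozygous
reticulata, re/ma interspecific heterozygosity). Laying the classes out
along the fragment map paints the chromosome mosaic; haplotype sharing
between an offspring and two candidate parents tests parentage hypotheses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo import INDETERMINATE, HaplotypeCatalog, short_label

MISSING_CLASS = "missing"


# ------------------------------------------------------------------ painting
@dataclass
class PaintingTrack:
    accession: str
    fragments: list[str]
    classes: list[str]  # per fragment, e.g. "re/ma", "re/ind", "missing"

    def as_series(self) -> pd.Series:
        return pd.Series(self.classes, index=self.fragments, name=self.accession)


def genotypic_class(
    assign1: str | None, assign2: str | None, taxon_short: dict[str, str] | None = None
) -> str:
    """Unordered pair of short taxon labels; symmetric by construction."""
    if assign1 is None or assign2 is None:
        return MISSING_CLASS
    labels = sorted(
        ("ind" if a == INDETERMINATE else short_label(a, taxon_short))
        for a in (assign1, assign2)
    )
    return "/".join(labels)


def paint_chromosome(
    catalog: HaplotypeCatalog,
    phased: dict,
    panel,
    taxon_short: dict[str, str] | None = None,
    collapse_identical: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-accession genotypic ancestry classes along the chromosome.

    Returns (matrix, bed): ``matrix`` is accessions x fragments (map
    order) of class strings; ``bed`` is a BED-like table (chrom, start,
    end, accession, class) with 1-based inclusive fragment coordinates.
    ``collapse_identical`` keeps one representative per identical track.
    """
    fragments = panel.fragment_names  # already map-ordered
    accessions = sorted({acc for (acc, _f) in phased})
    rows = {}
    for acc in accessions:
        classes = []
        for frag in fragments:
            pg = phased.get((acc, frag))
            if pg is None or pg.status != "called":
                classes.append(MISSING_CLASS)
                continue
            e1 = catalog.entry_of(acc, frag, 0)
            e2 = catalog.entry_of(acc, frag, 1)
            classes.append(
                genotypic_class(
                    e1.assignment if e1 else None,
                    e2.assignment if e2 else None,
                    taxon_short,
                )
            )
        rows[acc] = classes
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=fragments)
    if collapse_identical:
        matrix = matrix[~matrix.duplicated(keep="first")]
    bed_rows = []
    for acc in matrix.index:
        for frag in fragments:
            f = panel[frag]
            bed_rows.append(
                {
                    "chrom": "chr",
                    "start": f.map_position,
                    "end": f.map_position + f.length - 1,
                    "accession": acc,
                    "class": matrix.loc[acc, frag],
                }
            )
    return matrix, pd.DataFrame(bed_rows)


def class_switches(track: pd.Series) -> int:
    """Number of ancestry-class changes along a painted track (missing
    fragments skipped); a coarse lower bound on historical recombination."""
    classes = [c for c in track if c != MISSING_CLASS]
    return sum(1 for a, b in zip(classes, classes[1:]) if a != b)


# -------------------------------------------------------------------- census
def haplotype_census(
    catalog: HaplotypeCatalog, class_order: list[str] | None = None
) -> pd.DataFrame:
    """Distinct-haplotype counts per fragment by assigned class, with a
    TOTAL row; the grand total is the sum of class totals."""
    counts: dict[str, dict[str, int]] = {}
    classes: set[str] = set()
    for frag, entries in catalog.entries.items():
        row: dict[str, int] = {}
        for e in entries:
            row[e.assignment] = row.get(e.assignment, 0) + 1
        counts[frag] = row
        classes.update(row)
    if class_order is None:
        class_order = sorted(classes - {INDETERMINATE}) + (
            [INDETERMINATE] if INDETERMINATE in classes else []
        )
    table = pd.DataFrame(
        [
            {cls: counts.get(frag, {}).get(cls, 0) for cls in class_order}
            for frag in catalog.entries
        ],
        index=list(catalog.entries),
        columns=class_order,
        dtype=int,
    )
    table.loc["TOTAL"] = table.sum()
    return table


def census_grand_total(census: pd.DataFrame) -> int:
    """Grand total of the census: sum of the per-class totals row."""
    row = census.loc["TOTAL"] if "TOTAL" in census.index else census.sum()
    return int(row.sum())


# ------------------------------------------------------------ diagnostic SNPs
def diagnostic_snp_counts(
    gst_tables: dict[str, pd.Series],
    loci: pd.DataFrame | None = None,
    high_threshold: float = 0.8,
    average_within_fragment: bool = False,
) -> pd.DataFrame:
    """Per-taxon counts of diagnostic SNPs: G_ST above the high threshold
    and totally discriminant (G_ST = 1).

    With ``average_within_fragment`` each SNP's value is replaced by the
    mean G_ST of its fragment before thresholding (requires ``loci`` with a
    fragment column indexed by locus).
    """
    rows = []
    for taxon, gst in gst_tables.items():
        vals = gst.dropna()
        if average_within_fragment:
            if loci is None:
                raise ValueError("average mode requires locus metadata")
            frag = loci.loc[vals.index, "fragment"]
            vals = vals.groupby(frag).transform("mean")
        rows.append(
            {
                "taxon": taxon,
                f"gst_gt_{high_threshold}": int((vals > high_threshold).sum()),
                "gst_eq_1": int(np.isclose(vals, 1.0).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("taxon")


def mask_introgressed(gm, introgressions: pd.DataFrame, loci: pd.DataFrame):
    """Set an accession's genotypes missing at loci on fragments where one
    of its haplotypes was purged as introgressed (region removal)."""
    gt = gm.genotypes.copy()
    for row in introgressions.itertuples():
        frag_loci = loci.index[loci["fragment"] == row.fragment]
        gt.loc[row.accession, frag_loci] = np.nan
    from .popgen import GenotypeMatrix

    return GenotypeMatrix(gt, gm.loci.copy(), gm.groups.copy())


# ----------------------------------------------------------------- parentage
@dataclass
class ParentageHypothesis:
    offspring: str
    parent1: str
    parent2: str
    verdicts: pd.DataFrame = field(default_factory=pd.DataFrame)
    n_consistent: int = 0
    n_inconsistent: int = 0
    n_uninformative: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def n_informative(self) -> int:
        return self.n_consistent + self.n_inconsistent

    @property
    def consistency(self) -> float:
        return self.n_consistent / self.n_informative if self.n_informative else np.nan


def _party_haplotypes(
    catalog: HaplotypeCatalog, accession: str, fragment: str
) -> list | None:
    entries = [catalog.entry_of(accession, fragment, h) for h in (0, 1)]
    if any(e is None for e in entries):
        return None
    return entries


def parentage_consistency(
    offspring: str,
    parent1: str,
    parent2: str,
    catalog: HaplotypeCatalog,
) -> ParentageHypothesis:
    """Trio haplotype-sharing test.

    A fragment is consistent iff the offspring's two haplotypes can be
    partitioned with one exactly matching a parent-1 haplotype and the
    other a parent-2 haplotype (identity over the fragment's called
    variant loci). A parent given as a taxon label instead of an accession
    name tests assignment of the gamete to that taxon's pool (the
    "direct F1 of two taxa" hypothesis). Fragments with any party missing
    are uninformative, as are failed matches where an offspring haplotype
    is of indeterminate origin (non-evidence rather than contradiction).
    """
    result = ParentageHypothesis(offspring, parent1, parent2)
    rows = []
    identical_to: dict[str, int] = {parent1: 0, parent2: 0}
    n_shared_frags = 0
    for fragment in catalog.entries:
        off = _party_haplotypes(catalog, offspring, fragment)
        if off is None:
            rows.append({"fragment": fragment, "verdict": "uninformative"})
            result.n_uninformative += 1
            continue

        def gamete_ok(entry, parent_spec: str) -> bool:
            parent_entries = _party_haplotypes(catalog, parent_spec, fragment)
            if parent_entries is not None:  # named accession
                return any(entry.alleles == p.alleles for p in parent_entries)
            return entry.assignment == parent_spec  # taxon-pool membership

        p1_named = _party_haplotypes(catalog, parent1, fragment) is not None
        p2_named = _party_haplotypes(catalog, parent2, fragment) is not None
        # a named parent with no called haplotypes here -> uninformative
        if (not p1_named and not _looks_like_taxon(parent1, catalog)) or (
            not p2_named and not _looks_like_taxon(parent2, catalog)
        ):
            rows.append({"fragment": fragment, "verdict": "uninformative"})
            result.n_uninformative += 1
            continue

        ok = (gamete_ok(off[0], parent1) and gamete_ok(off[1], parent2)) or (
            gamete_ok(off[0], parent2) and gamete_ok(off[1], parent1)
        )
        if ok:
            verdict = "consistent"
            result.n_consistent += 1
        elif any(e.assignment == INDETERMINATE for e in off):
            verdict = "uninformative"
            result.n_uninformative += 1
        else:
            verdict = "inconsistent"
            result.n_inconsistent += 1
        rows.append({"fragment": fragment, "verdict": verdict})

        n_shared_frags += 1
        for parent_spec in (parent1, parent2):
            pe = _party_haplotypes(catalog, parent_spec, fragment)
            if pe is not None and {e.alleles for e in off} == {
                e.alleles for e in pe
            }:
                identical_to[parent_spec] += 1
    for parent_spec, n_same in identical_to.items():
        if n_shared_frags and n_same == n_shared_frags:
            result.warnings.append(
                f"offspring {offspring!r} is identical to {parent_spec!r} at "
                "every compared fragment (clonal, not offspring)"
            )
    result.verdicts = pd.DataFrame(rows, columns=["fragment", "verdict"])
    return result


def _looks_like_taxon(label: str, catalog: HaplotypeCatalog) -> bool:
    assignments = {
        e.assignment for entries in catalog.entries.values() for e in entries
    }
    return label in assignments
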