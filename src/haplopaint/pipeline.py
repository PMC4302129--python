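"""End-to-end orchestration: simulate -> process -> call -> stats -> assign
-> refine -> paint -> parentage, with one global seed and full accounting.

Every stage is a pure function of its inputs and the configuration; the
global seed deterministically spawns per-stage seeds, so reruns with the
same configuration produce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import admixture, calling, phylo, popgen, reads as readsmod, seqs, simulate
from .panel import ReferencePanel


@dataclass
class PipelineConfig:
    simulation: simulate.SimulationConfig = field(
        default_factory=simulate.SimulationConfig
    )
    depth_threshold: int = 50
    min_read_length: int = 150
    min_identity: float = calling.MIN_IDENTITY
    min_minor_fraction: float = calling.MIN_MINOR_FRACTION
    min_minor_reads: int = calling.MIN_MINOR_READS
    min_phased_fraction: float = calling.MIN_PHASED_FRACTION
    assign_delta: float | None = None  # None -> fragment-level default
    assign_cap: float | None = None
    max_refine_iter: int = 10
    ld_permutations: int = 200
    parentage_trios: list[tuple[str, str, str]] = field(
        default_factory=lambda: [
            ("clementine_01", "willowleaf", "sweet_orange_01"),
            ("lemon_eureka", "sour_orange_01", "citron_01"),
            ("sour_orange_01", "maxima", "reticulata"),
            ("bergamot", "sour_orange_01", "citron_01"),
        ]
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.simulation.seed = self.seed


@dataclass
class PipelineResult:
    config: PipelineConfig
    panel: ReferencePanel
    pools: simulate.TaxonPools
    cohort: simulate.Cohort
    truth: simulate.TruthSet
    run: simulate.SimulatedRun
    preprocess_report: dict
    bins: dict
    unassigned: list
    coverage: pd.DataFrame
    coverage_summary: dict
    phased: dict
    gm: popgen.GenotypeMatrix
    gm_snp: popgen.GenotypeMatrix
    variants: pd.DataFrame
    catalog: phylo.HaplotypeCatalog
    refinement: phylo.RefinementResult
    painting: pd.DataFrame
    painting_bed: pd.DataFrame
    census: pd.DataFrame
    diagnostics_before: pd.DataFrame
    diagnostics_after: pd.DataFrame
    parentage: list
    summary: dict


# ------------------------------------------------------------------ calling
def process_reads(run, panel, config: PipelineConfig):
    decoration = (
        config.simulation.barcode_length + config.simulation.primer_length
    )
    read_records = [
        readsmod.ReadRecord(rid, seq, qual) for rid, seq, qual in run.reads
    ]
    kept, report = readsmod.preprocess_reads(
        read_records, config.min_read_length, decoration_length=decoration
    )
    bins, unassigned = readsmod.demultiplex_and_bin(
        kept, run.sample_sheet, panel,
        barcode_length=config.simulation.barcode_length,
    )
    coverage, cov_summary = readsmod.coverage_summary(bins, config.depth_threshold)
    return report, bins, unassigned, coverage, cov_summary


def call_cohort(bins, panel, config: PipelineConfig) -> dict:
    """(accession, fragment) -> PhasedGenotype for every amplicon bin."""
    phased = {}
    for (acc, frag), amplicon in bins.items():
        phased[(acc, frag)] = calling.call_and_phase(
            amplicon,
            panel[frag],
            depth_threshold=config.depth_threshold,
            min_identity=config.min_identity,
            min_minor_fraction=config.min_minor_fraction,
            min_minor_reads=config.min_minor_reads,
            min_phased_fraction=config.min_phased_fraction,
        )
    return phased


def build_genotype_matrix(
    phased: dict, panel: ReferencePanel, groups: pd.Series
) -> tuple[popgen.GenotypeMatrix, pd.DataFrame]:
    """Population-level genotype matrix and variant table from phased calls.

    Loci are the union over accessions of called variant positions; every
    accession's called genotype (including homozygous-reference) enters the
    matrix at those loci, with missing entries for low-coverage or failed
    amplicons. A locus is kind="indel" when a gap allele segregates.
    """
    accessions = sorted({acc for acc, _ in phased})
    loci_rows = []
    data: dict[str, dict[str, str]] = {}
    for fragment in panel.fragment_names:
        positions = phylo.population_variant_positions(phased, fragment)
        frag_obj = panel[fragment]
        for pos in positions:
            locus = f"{fragment}:{pos:04d}"
            alleles: set[str] = set()
            column: dict[str, str] = {}
            for acc in accessions:
                pg = phased.get((acc, fragment))
                if pg is None or pg.status != "called":
                    continue
                g = pg.genotype[:, pos - 1]
                a = seqs.decode(np.array([g[0]], np.uint8))
                b = seqs.decode(np.array([g[1]], np.uint8))
                column[acc] = f"{a}/{b}"
                alleles.update((a, b))
            kind = "indel" if "-" in alleles else "SNP"
            loci_rows.append(
                {
                    "locus": locus,
                    "fragment": fragment,
                    "position": pos,
                    "region": frag_obj.region_at(pos),
                    "kind": kind,
                    "n_alleles": len(alleles),
                    "alleles": "".join(sorted(alleles)),
                }
            )
            data[locus] = column
    loci = pd.DataFrame(loci_rows).set_index("locus")
    gt = pd.DataFrame(
        {locus: pd.Series(col) for locus, col in data.items()},
        index=accessions,
    )
    gm = popgen.GenotypeMatrix(gt, loci, groups.loc[accessions])
    variants = loci.reset_index()[["locus", "fragment", "position", "kind", "region"]]
    return gm, variants


def haplotype_allele_matrix(
    catalog: phylo.HaplotypeCatalog, snp_loci: pd.DataFrame
) -> pd.DataFrame:
    """Phased haplotype x SNP-locus allele table (for LD and NJ input)."""
    rows = {}
    for frag, entries in catalog.entries.items():
        positions = catalog.positions[frag]
        locus_names = [f"{frag}:{p:04d}" for p in positions]
        for e in entries:
            for acc, hap in e.carriers:
                key = f"{acc}|h{hap + 1}"
                rows.setdefault(key, {}).update(
                    dict(zip(locus_names, e.alleles))
                )
    mat = pd.DataFrame.from_dict(rows, orient="index")
    keep = [c for c in mat.columns if c in set(snp_loci.index)]
    return mat[keep]


# --------------------------------------------------------------- evaluation
def truth_class_short(truth, acc, frag, taxon_short=None) -> str:
    o1, o2 = truth.origins[(acc, frag)]
    return "/".join(sorted(phylo.short_label(t, taxon_short) for t in (o1, o2)))


def painting_concordance(
    painting: pd.DataFrame, truth, coverage: pd.DataFrame, threshold: int = 50
) -> dict:
    """Fraction of painted classes matching the simulator's record, over
    amplicons at or above the depth threshold."""
    deep = {
        (r.accession, r.fragment)
        for r in coverage.itertuples()
        if r.depth >= threshold
    }
    n_match = n_total = 0
    for acc in painting.index:
        for frag in painting.columns:
            if (acc, frag) not in deep:
                continue
            painted = painting.loc[acc, frag]
            if painted == admixture.MISSING_CLASS:
                continue
            n_total += 1
            if painted == truth_class_short(truth, acc, frag):
                n_match += 1
    return {
        "n_compared": n_total,
        "n_matching": n_match,
        "concordance_pct": round(100.0 * n_match / n_total, 2) if n_total else np.nan,
    }


def genotype_discordance_vs_truth(
    phased: dict, truth, coverage: pd.DataFrame, threshold: int = 50
) -> calling.Discordance:
    """Called genotypes vs true genotypes on amplicons with depth >= 50."""
    deep = {
        (r.accession, r.fragment)
        for r in coverage.itertuples()
        if r.depth >= threshold
    }
    calls = {
        key: pg.genotype
        for key, pg in phased.items()
        if key in deep and pg.status == "called" and pg.genotype is not None
    }
    truths = {
        key: np.vstack([np.minimum(h1, h2), np.maximum(h1, h2)])
        for key, (h1, h2) in truth.haplotypes.items()
        if key in calls
    }
    return calling.genotype_error_rate(calls, truths)


def assignment_accuracy(
    pools: simulate.TaxonPools,
    delta: float | None = None,
    cap: float | None = None,
) -> dict:
    """Assign every pool haplotype against the taxon panels and score it.

    Haplotypes are reduced to allele tuples over the positions that vary
    anywhere in the pools (the analogue of called variant loci). Returns
    counts of correct, indeterminate and cross-taxon assignments.
    """
    taxa = sorted(pools.haplotypes)
    fragments = list(next(iter(pools.haplotypes.values())))
    n = n_correct = n_indet = n_cross = 0
    for frag in fragments:
        stacked = np.vstack([pools.haplotypes[t][frag] for t in taxa])
        varying = np.flatnonzero((stacked != stacked[0]).any(axis=0))
        panels = {
            t: [
                tuple(seqs.decode(h[varying]))
                for h in pools.haplotypes[t][frag]
            ]
            for t in taxa
        }
        for taxon in taxa:
            for hap in panels[taxon]:
                assignment, _m, _nearest, _d = phylo.assign_haplotype(
                    hap, panels, delta, cap
                )
                n += 1
                if assignment == taxon:
                    n_correct += 1
                elif assignment == phylo.INDETERMINATE:
                    n_indet += 1
                else:
                    n_cross += 1
    return {
        "n_haplotypes": n,
        "n_correct": n_correct,
        "n_indeterminate": n_indet,
        "n_cross_taxon": n_cross,
        "accuracy_pct": round(100.0 * n_correct / n, 2),
    }


# --------------------------------------------------------------------- run
def run_pipeline(
    config: PipelineConfig, outdir: str | Path | None = None
) -> PipelineResult:
    panel, pools, cohort, truth, run = simulate.simulate_run(config.simulation)
    report, bins, unassigned, coverage, cov_summary = process_reads(
        run, panel, config
    )
    phased = call_cohort(bins, panel, config)

    groups = pd.Series(
        {n: cohort[n].nominal_taxon for n in cohort.names}, name="group"
    )
    gm, variants = build_genotype_matrix(phased, panel, groups)
    snp_loci = gm.loci[gm.loci["kind"] == "SNP"]
    gm_snp = popgen.GenotypeMatrix(
        gm.genotypes[snp_loci.index], snp_loci.copy(), gm.groups
    )

    basal_taxa = list(config.simulation.taxa)
    basal_accessions = {
        t: [n for n in cohort.names if cohort[n].nominal_taxon == t]
        for t in basal_taxa
    }

    catalog = phylo.build_catalog(phased, panel)
    fragment_lengths = {f: panel[f].length for f in panel.fragment_names}
    refinement = phylo.refine_reference_panels(
        catalog,
        basal_accessions,
        fragment_lengths,
        delta=config.assign_delta,
        cap=config.assign_cap,
        max_iter=config.max_refine_iter,
    )
    phylo.assign_catalog(
        catalog, refinement.panels, config.assign_delta, config.assign_cap
    )
    painting, painting_bed = admixture.paint_chromosome(catalog, phased, panel)
    census = admixture.haplotype_census(catalog)

    # diagnostic scans run over the basal (species-group) accessions only:
    # hybrids carry the focal taxon's alleles and would cap G_ST below 1
    basal_all = [a for accs in basal_accessions.values() for a in accs]
    gm_basal = popgen.GenotypeMatrix(
        gm_snp.genotypes.loc[basal_all], gm_snp.loci.copy(),
        gm_snp.groups.loc[basal_all],
    )
    gst_before = {t: popgen.gst_scan(gm_basal, t) for t in basal_taxa}
    gm_masked = admixture.mask_introgressed(
        gm_basal, refinement.introgressions, gm_basal.loci
    )
    gst_after = {t: popgen.gst_scan(gm_masked, t) for t in basal_taxa}
    diagnostics_before = admixture.diagnostic_snp_counts(gst_before)
    diagnostics_after = admixture.diagnostic_snp_counts(gst_after)

    parentage = [
        admixture.parentage_consistency(o, p1, p2, catalog)
        for (o, p1, p2) in config.parentage_trios
    ]

    n_triallelic = int((gm_snp.loci["n_alleles"] >= 3).sum())
    n_snps = len(gm_snp.loci)
    discord = genotype_discordance_vs_truth(
        phased, truth, coverage, config.depth_threshold
    )
    concord = painting_concordance(
        painting, truth, coverage, config.depth_threshold
    )
    r1 = list(truth.coverage_round1.values())
    round1_summary = {
        "mean_depth": readsmod.mean_reads_per_amplicon(int(np.sum(r1)), len(r1)),
        "pct_below_threshold": readsmod.below_threshold_percent(
            int(np.sum(np.array(r1) < config.depth_threshold)), len(r1)
        ),
    } if r1 else {}
    summary = {
        "reads": {**report, "n_unassigned": len(unassigned)},
        "coverage_round1_true": round1_summary,
        "coverage": cov_summary,
        "snps": {
            "n_loci": n_snps,
            "n_indel_loci": int((gm.loci["kind"] == "indel").sum()),
            "n_triallelic": n_triallelic,
            "triallelic_pct": popgen.triallelic_percent(n_triallelic, n_snps)
            if n_snps
            else 0,
        },
        "census_total": admixture.census_grand_total(census),
        "introgressions_purged": int(len(refinement.introgressions)),
        "genotype_discordance_pct": discord.percent,
        "painting_concordance_pct": concord["concordance_pct"],
        "parentage": {
            f"{h.offspring}={h.parent1}x{h.parent2}": {
                "consistent": h.n_consistent,
                "inconsistent": h.n_inconsistent,
                "uninformative": h.n_uninformative,
            }
            for h in parentage
        },
    }

    result = PipelineResult(
        config=config,
        panel=panel,
        pools=pools,
        cohort=cohort,
        truth=truth,
        run=run,
        preprocess_report=report,
        bins=bins,
        unassigned=unassigned,
        coverage=coverage,
        coverage_summary=cov_summary,
        phased=phased,
        gm=gm,
        gm_snp=gm_snp,
        variants=variants,
        catalog=catalog,
        refinement=refinement,
        painting=painting,
        painting_bed=painting_bed,
        census=census,
        diagnostics_before=diagnostics_before,
        diagnostics_after=diagnostics_after,
        parentage=parentage,
        summary=summary,
    )
    if outdir is not None:
        write_outputs(result, Path(outdir))
    return result


def write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.panel.write(outdir)
    result.run.write_fastq(outdir / "reads.fastq")
    result.run.sample_sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)
    result.truth.write(outdir / "truth.tsv")
    result.config.simulation.write_yaml(outdir / "config.yaml")
    result.coverage.to_csv(outdir / "coverage.tsv", sep="\t", index=False)
    result.variants.to_csv(outdir / "variants.tsv", sep="\t", index=False)
    result.gm.genotypes.to_csv(outdir / "genotypes.tsv", sep="\t")
    _write_haplotypes_fasta(result.phased, outdir / "haplotypes.fasta")
    _write_phasing_report(result.phased, outdir / "phasing_report.tsv")
    result.catalog.table().to_csv(outdir / "catalog.tsv", sep="\t", index=False)
    result.refinement.introgressions.to_csv(
        outdir / "introgression_report.tsv", sep="\t", index=False
    )
    result.refinement.revised_density.to_csv(
        outdir / "revised_dissimilarity.tsv", sep="\t"
    )
    result.refinement.initial_density.to_csv(
        outdir / "initial_dissimilarity.tsv", sep="\t"
    )
    result.painting.to_csv(outdir / "painting.tsv", sep="\t")
    result.painting_bed.to_csv(outdir / "painting.bed", sep="\t", index=False)
    result.census.to_csv(outdir / "census.tsv", sep="\t")
    pd.concat(
        [
            result.diagnostics_before.add_prefix("before_"),
            result.diagnostics_after.add_prefix("after_"),
        ],
        axis=1,
    ).to_csv(outdir / "diagnostics.tsv", sep="\t")
    pd.concat(
        [h.verdicts.assign(offspring=h.offspring, parent1=h.parent1,
                           parent2=h.parent2) for h in result.parentage],
        ignore_index=True,
    ).to_csv(outdir / "parentage.tsv", sep="\t", index=False)
    trees_dir = outdir / "trees"
    trees_dir.mkdir(exist_ok=True)
    _write_fragment_trees(result, trees_dir)
    (outdir / "summary.json").write_text(json.dumps(result.summary, indent=2))
    manifest = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(outdir.iterdir())
        if p.is_file()
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _write_haplotypes_fasta(phased: dict, path: Path) -> None:
    with open(path, "w") as fh:
        for (acc, frag), pg in sorted(phased.items()):
            for i, hap in enumerate(pg.haplotypes):
                fh.write(f">{acc}|{frag}|h{i + 1}\n{seqs.decode(hap, drop_gaps=True)}\n")


def _write_phasing_report(phased: dict, path: Path) -> None:
    rows = []
    for (acc, frag), pg in sorted(phased.items()):
        rows.append(
            {
                "accession": acc,
                "fragment": frag,
                "status": pg.status,
                "n_haplotypes": pg.n_haplotypes,
                "support": ",".join(map(str, pg.support)),
                "n_excluded": pg.n_excluded,
                "n_het_positions": len(pg.het_positions),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_fragment_trees(result: PipelineResult, trees_dir: Path) -> None:
    """Per-fragment NJ tree over deduplicated haplotypes (audit aid)."""
    for frag, entries in result.catalog.entries.items():
        named = [e for e in entries if len(e.alleles) > 0]
        if len(named) < 3:
            continue
        names = [e.name for e in named]
        d = pd.DataFrame(0.0, index=names, columns=names)
        for (i, a), (j, b) in itertools.combinations(enumerate(named), 2):
            val = sum(x != y for x, y in zip(a.alleles, b.alleles)) / len(a.alleles)
            d.iloc[i, j] = d.iloc[j, i] = val
        tree = phylo.neighbor_joining(d)
        (trees_dir / f"{frag}.nwk").write_text(tree.newick + "\n")
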