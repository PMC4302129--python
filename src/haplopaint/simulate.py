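"""Synthetic amplicon-sequencing study generator.

Emulates the study design the pipeline targets: four divergent ancestral
citrus gene pools (C. reticulata, C. maxima, C. medica, C. micrantha), a
48-accession diploid cohort containing pure representatives, interspecific
F1s, mosaics and fragment-level introgressions, and 454-style barcoded
long-amplicon reads over 16 gene fragments with skewed per-amplicon
coverage and per-base substitution error. Every stochastic choice is
recorded in a :class:`TruthSet` so downstream stages can be scored exactly.

Divergence model
----------------
Taxon consensus sequences are generated star-wise from a shared root: each
taxon receives a per-fragment branch mutation count ``b_i`` obtained by
non-negative least squares on ``b_i + b_j = d_ij * L / 1000`` where
``d_ij`` is the requested inter-taxon divergence in SNP/kb. Within-taxon
haplotypes mutate from their taxon consensus at half the requested
intra-taxon SNP/kb, so two pool members differ at approximately the
requested rate. Two taxa mutating the same site yields triallelic loci
naturally.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import nnls

from . import seqs
from .panel import Fragment, ReferencePanel, Region

DEFAULT_TAXA = ("reticulata", "maxima", "medica", "micrantha")

# Average pairwise SNP/kb between varietal groups observed in the targeted
# chromosome study (mandarins->reticulata, pummelos->maxima, citrons->medica).
DEFAULT_INTER = {
    ("reticulata", "maxima"): 10.41,
    ("reticulata", "medica"): 14.56,
    ("reticulata", "micrantha"): 13.49,
    ("maxima", "medica"): 11.21,
    ("maxima", "micrantha"): 10.61,
    ("medica", "micrantha"): 12.24,
}

# Within-group SNP/kb; the single-accession micrantha pool has no printed
# value and defaults to the low (citron-like) end of the observed range.
DEFAULT_INTRA = {
    "reticulata": 3.93,
    "maxima": 2.06,
    "medica": 1.26,
    "micrantha": 1.26,
}


def inter_matrix(taxa: tuple[str, ...], table: dict | None = None) -> np.ndarray:
    """Build a symmetric SNP/kb divergence matrix from a pair table."""
    table = dict(DEFAULT_INTER if table is None else table)
    m = np.zeros((len(taxa), len(taxa)))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i == j:
                continue
            key = (a, b) if (a, b) in table else (b, a)
            m[i, j] = table[key]
    return m


@dataclass
class CoverageModel:
    """Reads-per-amplicon distribution over one or more sequencing rounds.

    ``lognormal`` (default) reproduces the strongly right-skewed coverage of
    the study protocol: per-fragment representation factors (persistent
    across rounds, ``fragment_sigma``) plus residual amplicon noise
    (``sigma``). With one round at mean 75 roughly 35-40% of amplicons fall
    below the 50-read calling threshold; the default second round (mean
    133, the ratio of the study's two runs) rescues most of them while
    chronically under-represented fragments stay shallow.
    ``negative_binomial`` and ``constant`` (exactly ``round_means[0]`` reads
    everywhere) are available alternatives.
    """

    family: str = "lognormal"
    round_means: tuple[float, ...] = (75.0, 133.0)
    fragment_sigma: float = 0.55  # fragment representation spread
    sigma: float = 0.30  # residual amplicon-level spread
    dispersion: float = 2.0  # negative binomial k

    @property
    def mean(self) -> float:
        """Expected total reads per amplicon across rounds."""
        return float(sum(self.round_means))

    def draw_rounds(
        self, n_accessions: int, n_fragments: int, rng: np.random.Generator
    ) -> np.ndarray:
        """(n_rounds, n_accessions * n_fragments) depths, amplicons ordered
        accession-major (all fragments of accession 1, then accession 2...).
        """
        n = n_accessions * n_fragments
        if self.family == "constant":
            out = np.zeros((len(self.round_means), n), dtype=int)
            out[0] = int(round(self.round_means[0]))
            return out
        if self.family == "negative_binomial":
            k = self.dispersion
            return np.vstack(
                [
                    rng.negative_binomial(k, k / (k + m), size=n)
                    for m in self.round_means
                ]
            )
        if self.family == "lognormal":
            sf, sr = self.fragment_sigma, self.sigma
            frag_factor = rng.lognormal(-sf * sf / 2.0, sf, size=n_fragments)
            ff = np.tile(frag_factor, n_accessions)
            rows = []
            for m in self.round_means:
                mu = np.log(m * ff) - sr * sr / 2.0
                rows.append(
                    np.maximum(np.rint(rng.lognormal(mu, sr)), 0).astype(int)
                )
            return np.vstack(rows)
        raise ValueError(f"unknown coverage model family: {self.family}")

    def draw(
        self, n_accessions: int, n_fragments: int, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        """(total depth, round-1 depth) per amplicon."""
        rounds = self.draw_rounds(n_accessions, n_fragments, rng)
        return rounds.sum(axis=0), rounds[0]


@dataclass(frozen=True)
class HapOrigin:
    """Provenance of one haplotype of an accession at one fragment."""

    kind: str  # "pool" | "clone" | "novel"
    taxon: str | None = None
    accession: str | None = None
    hap: int | None = None  # pool index, clone haplotype index, or None=random


def pool(taxon: str, hap: int | None = None) -> HapOrigin:
    return HapOrigin("pool", taxon=taxon, hap=hap)


def clone(accession: str, hap: int | None = None) -> HapOrigin:
    return HapOrigin("clone", accession=accession, hap=hap)


def novel(taxon: str) -> HapOrigin:
    return HapOrigin("novel", taxon=taxon)


@dataclass
class AccessionSpec:
    """Design of one diploid accession: exactly two origins per fragment."""

    name: str
    nominal_taxon: str
    origins: list[tuple[HapOrigin, HapOrigin]]
    private_alleles: int = 0  # heterozygous alleles absent from all basal pools


def pure_design(name: str, taxon: str, n_fragments: int) -> AccessionSpec:
    return AccessionSpec(name, taxon, [(pool(taxon), pool(taxon))] * n_fragments)


def f1_design(name: str, taxon_a: str, taxon_b: str, n_fragments: int,
              nominal: str | None = None) -> AccessionSpec:
    return AccessionSpec(
        name, nominal or taxon_a, [(pool(taxon_a), pool(taxon_b))] * n_fragments
    )


def introgressed_design(
    name: str,
    base_taxon: str,
    donor_taxon: str,
    fragments: dict[int, str],
    n_fragments: int,
) -> AccessionSpec:
    """Pure ``base_taxon`` background with donor fragments.

    ``fragments`` maps fragment index -> "het" (one donor haplotype) or
    "hom" (both haplotypes from the donor pool).
    """
    origins = []
    for i in range(n_fragments):
        mode = fragments.get(i)
        if mode is None:
            origins.append((pool(base_taxon), pool(base_taxon)))
        elif mode == "het":
            origins.append((pool(base_taxon), pool(donor_taxon)))
        elif mode == "hom":
            origins.append((pool(donor_taxon), pool(donor_taxon)))
        else:
            raise ValueError(f"unknown introgression mode {mode!r}")
    return AccessionSpec(name, base_taxon, origins)


def mosaic_design(name: str, classes: list[tuple[str, str]], nominal: str) -> AccessionSpec:
    """Explicit per-fragment (taxonA, taxonB) genotypic classes."""
    return AccessionSpec(name, nominal, [(pool(a), pool(b)) for a, b in classes])


def offspring_design(name: str, parent_a: str, parent_b: str, n_fragments: int,
                     nominal: str) -> AccessionSpec:
    """F1 of two named accessions: one random gamete from each per fragment."""
    return AccessionSpec(
        name, nominal, [(clone(parent_a), clone(parent_b))] * n_fragments
    )


def backcross_design(
    name: str,
    recurrent: str,
    donor_parent: str,
    switch_fragments: list[int],
    n_fragments: int,
    nominal: str,
) -> AccessionSpec:
    """Recurrent-taxon background; the gamete from the hybrid parent switches
    origin between ``donor_parent`` taxon and ``recurrent`` taxon at the
    stated fragment boundaries (recombinant gamete)."""
    origins = []
    donor_on = False
    switches = set(switch_fragments)
    for i in range(n_fragments):
        if i in switches:
            donor_on = not donor_on
        gamete = pool(donor_parent) if donor_on else pool(recurrent)
        origins.append((pool(recurrent), gamete))
    return AccessionSpec(name, recurrent, origins)


@dataclass
class SimulationConfig:
    n_fragments: int = 16
    fragment_length_bp: int = 500
    taxa: tuple[str, ...] = DEFAULT_TAXA
    inter_taxon_divergence: np.ndarray | None = None  # SNP/kb, symmetric
    intra_taxon_diversity: dict[str, float] | None = None  # SNP/kb
    haplotypes_per_taxon: int = 10
    cohort_design: list[AccessionSpec] | None = None  # None -> default cohort
    coverage_model: CoverageModel = field(default_factory=CoverageModel)
    per_base_error_rate: float = 0.01
    homopolymer_indel_rate: float = 0.0
    exonic_indel_fraction: float = 0.0
    short_read_fraction: float = 0.11  # primer-dimer junk reads in the raw run
    barcode_length: int = 10
    primer_length: int = 20
    intron_fraction: float = 0.3  # tail of each fragment annotated as intron
    fragment_spacing_bp: int = 2_000_000  # chromosome map spacing
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inter_taxon_divergence is None:
            self.inter_taxon_divergence = inter_matrix(self.taxa)
        self.inter_taxon_divergence = np.asarray(self.inter_taxon_divergence, float)
        if self.intra_taxon_diversity is None:
            self.intra_taxon_diversity = {
                t: DEFAULT_INTRA.get(t, 2.0) for t in self.taxa
            }
        self.validate()

    def validate(self) -> None:
        m = self.inter_taxon_divergence
        k = len(self.taxa)
        if m.shape != (k, k):
            raise ValueError("divergence matrix shape must match taxa")
        if not np.allclose(m, m.T):
            raise ValueError("divergence matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("divergence matrix diagonal must be zero")
        if np.any(m < 0):
            raise ValueError("divergences must be non-negative")
        for name, rate in [
            ("per_base_error_rate", self.per_base_error_rate),
            ("homopolymer_indel_rate", self.homopolymer_indel_rate),
            ("short_read_fraction", self.short_read_fraction),
            ("exonic_indel_fraction", self.exonic_indel_fraction),
        ]:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.fragment_length_bp < 150:
            raise ValueError("fragment_length_bp must be >= 150")
        L = self.fragment_length_bp
        if np.any(m * L / 1000.0 > L):
            raise ValueError(
                "requested inter-taxon divergence exceeds fragment capacity "
                f"({m.max():.1f} SNP/kb over {L} bp)"
            )
        if self.cohort_design is not None:
            taxa = set(self.taxa)
            for spec in self.cohort_design:
                if len(spec.origins) != self.n_fragments:
                    raise ValueError(
                        f"accession {spec.name!r} specifies {len(spec.origins)} "
                        f"fragments, expected {self.n_fragments}"
                    )
                for pair in spec.origins:
                    if len(pair) != 2:
                        raise ValueError(
                            f"accession {spec.name!r} must name exactly 2 origins"
                        )
                    for o in pair:
                        if o.kind in ("pool", "novel") and o.taxon not in taxa:
                            raise ValueError(
                                f"accession {spec.name!r} references unknown "
                                f"taxon {o.taxon!r}"
                            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["inter_taxon_divergence"] = self.inter_taxon_divergence.tolist()
        d["taxa"] = list(self.taxa)
        d["cohort_design"] = (
            None
            if self.cohort_design is None
            else [spec.name for spec in self.cohort_design]
        )
        return d

    def write_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


# --------------------------------------------------------------------------
# Panel and haplotype pools
# --------------------------------------------------------------------------


@dataclass
class TaxonPools:
    """Taxon consensus sequences and within-taxon haplotype pools."""

    consensus: dict[str, dict[str, np.ndarray]]  # taxon -> fragment -> codes
    haplotypes: dict[str, dict[str, np.ndarray]]  # taxon -> fragment -> (n, L)

    def pool(self, taxon: str, fragment: str) -> np.ndarray:
        return self.haplotypes[taxon][fragment]


def _branch_counts(config: SimulationConfig) -> np.ndarray:
    """Per-taxon star-tree branch lengths (expected substitutions/fragment).

    The requested inter-taxon SNP/kb is a *pairwise haplotype* density, to
    which within-taxon spread also contributes (each haplotype sits about
    intra/2 from its taxon consensus), so the consensus-level target is
    d_ij - (intra_i + intra_j)/2, floored at zero.
    """
    k = len(config.taxa)
    L = config.fragment_length_bp
    intra = np.array([config.intra_taxon_diversity[t] for t in config.taxa])
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    A = np.zeros((len(pairs), k))
    d = np.zeros(len(pairs))
    for row, (i, j) in enumerate(pairs):
        A[row, i] = 1.0
        A[row, j] = 1.0
        target = max(
            config.inter_taxon_divergence[i, j] - (intra[i] + intra[j]) / 2.0, 0.0
        )
        d[row] = target * L / 1000.0
    b, _ = nnls(A, d)
    if np.any(b > L):
        raise ValueError("requested divergence exceeds fragment capacity")
    return b


def _integer_count(expected: float, rng: np.random.Generator) -> int:
    base = int(np.floor(expected))
    return base + int(rng.random() < expected - base)


def simulate_panel(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[ReferencePanel, TaxonPools]:
    """Generate fragment references, taxon consensuses and haplotype pools."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    L = config.fragment_length_bp
    branch = _branch_counts(config)

    fragments: dict[str, Fragment] = {}
    consensus: dict[str, dict[str, np.ndarray]] = {t: {} for t in config.taxa}
    pools: dict[str, dict[str, np.ndarray]] = {t: {} for t in config.taxa}

    exon_end = max(1, int(round(L * (1.0 - config.intron_fraction))))
    for fi in range(config.n_fragments):
        name = f"frag{fi + 1:02d}"
        root = seqs.random_sequence(L, rng)
        primer = seqs.decode(seqs.random_sequence(config.primer_length, rng))
        regions = [Region("exon", 1, exon_end)]
        if exon_end < L:
            regions.append(Region("intron", exon_end + 1, L))
        fragments[name] = Fragment(
            name=name,
            reference=root,
            primer=primer,
            map_position=1 + fi * config.fragment_spacing_bp,
            regions=regions,
        )
        for ti, taxon in enumerate(config.taxa):
            n_mut = min(_integer_count(branch[ti], rng), L)
            positions = rng.choice(L, size=n_mut, replace=False)
            cons = seqs.mutate(root, positions, rng)
            consensus[taxon][name] = cons
            lam = config.intra_taxon_diversity[taxon] / 2.0 * L / 1000.0
            haps = np.empty((config.haplotypes_per_taxon, L), dtype=np.uint8)
            for h in range(config.haplotypes_per_taxon):
                n_inner = min(int(rng.poisson(lam)), L)
                ppos = rng.choice(L, size=n_inner, replace=False)
                haps[h] = seqs.mutate(cons, ppos, rng)
            pools[taxon][name] = haps
        if config.exonic_indel_fraction > 0:
            _plant_exonic_indels(fragments[name], pools, config, rng)

    return ReferencePanel(fragments), TaxonPools(consensus, pools)


def _plant_exonic_indels(fragment, pools, config, rng) -> None:
    """Give random pool haplotypes a 1-bp deletion at exonic positions.

    Sites inside reference homopolymer runs (>= 3) are avoided so planted
    indels stay distinguishable from the pyrosequencing error mode that the
    caller normalizes away."""
    exon = next((r for r in fragment.regions if r.label == "exon"), None)
    if exon is None:
        return
    n_sites = int(round(config.exonic_indel_fraction * exon.length))
    ref = fragment.reference
    candidates = [
        p
        for p in range(exon.start - 1, exon.end)
        if _homopolymer_run(ref, p) < 3
    ]
    rng.shuffle(candidates)
    for pos in candidates[:n_sites]:
        taxon = config.taxa[int(rng.integers(len(config.taxa)))]
        haps = pools[taxon][fragment.name]
        haps[int(rng.integers(len(haps))), pos] = seqs.GAP


def _homopolymer_run(ref, pos: int) -> int:
    base = ref[pos]
    run = 1
    i = pos - 1
    while i >= 0 and ref[i] == base:
        run += 1
        i -= 1
    i = pos + 1
    while i < len(ref) and ref[i] == base:
        run += 1
        i += 1
    return run


# --------------------------------------------------------------------------
# Cohort
# --------------------------------------------------------------------------


def default_cohort_design(n_fragments: int = 16) -> list[AccessionSpec]:
    """48-accession cohort emulating the studied germplasm.

    14 mandarins (10 carrying a C. maxima introgression), 10 pummelos, 6
    citrons, one micrantha, and 17 interspecific hybrids (sweet/sour orange,
    clementine, grapefruit, lemons, lime, alemow, bergamot) including true
    trios for parentage checking and 19 planted hybrid-private alleles.
    """
    n = n_fragments
    re, ma, me, mi = "reticulata", "maxima", "medica", "micrantha"
    specs: list[AccessionSpec] = []

    # -- basal taxa representatives -------------------------------------
    specs.append(introgressed_design("willowleaf", re, ma, {n - 1: "het"}, n))
    specs.append(
        introgressed_design("ponkan", re, ma, {2 % n: "hom", 3 % n: "het"}, n)
    )
    for i in range(8):  # eight more singly-introgressed mandarins
        frag = (4 + i) % n
        specs.append(
            introgressed_design(f"mandarin_{i + 3:02d}", re, ma, {frag: "het"}, n)
        )
    for name in ("cleopatra", "sunki", "sun_chu_sha", "nanfengmiju"):
        specs.append(pure_design(name, re, n))
    for i in range(10):
        specs.append(pure_design(f"pummelo_{i + 1:02d}", ma, n))
    for i in range(6):
        specs.append(pure_design(f"citron_{i + 1:02d}", me, n))
    specs.append(pure_design("micrantha_01", mi, n))

    # -- secondary (hybrid) accessions ----------------------------------
    def sweet_orange_classes() -> list[tuple[str, str]]:
        cls = []
        for i in range(n):
            if i < 2:
                cls.append((re, re))
            elif i >= n - 2:
                cls.append((ma, ma))
            else:
                cls.append((ma, re))
        return cls

    specs.append(mosaic_design("sweet_orange_01", sweet_orange_classes(), "sweet_orange"))
    specs.append(
        AccessionSpec("sweet_orange_02", "sweet_orange",
                      [(clone("sweet_orange_01", 0), clone("sweet_orange_01", 1))] * n)
    )
    specs.append(
        AccessionSpec("sweet_orange_03", "sweet_orange",
                      [(clone("sweet_orange_01", 0), clone("sweet_orange_01", 1))] * n)
    )
    so1 = f1_design("sour_orange_01", ma, re, n, nominal="sour_orange")
    so1.private_alleles = 4
    specs.append(so1)
    specs.append(f1_design("sour_orange_02", ma, re, n, nominal="sour_orange"))
    specs.append(offspring_design("clementine_01", "willowleaf", "sweet_orange_01", n, "clementine"))
    specs.append(
        AccessionSpec("clementine_02", "clementine",
                      [(clone("clementine_01", 0), clone("clementine_01", 1))] * n)
    )
    gf = offspring_design("grapefruit_01", "pummelo_01", "sweet_orange_01", n, "grapefruit")
    gf.private_alleles = 1
    specs.append(gf)
    specs.append(
        AccessionSpec("grapefruit_02", "grapefruit",
                      [(clone("grapefruit_01", 0), clone("grapefruit_01", 1))] * n)
    )
    specs.append(offspring_design("lemon_eureka", "sour_orange_01", "citron_01", n, "lemon"))
    specs.append(
        AccessionSpec("lemon_lisbon", "lemon",
                      [(clone("lemon_eureka", 0), clone("lemon_eureka", 1))] * n)
    )
    specs.append(
        AccessionSpec("lemon_sweet", "lemon",
                      [(clone("lemon_eureka", 0), clone("lemon_eureka", 1))] * n)
    )
    meyer = [(ma, me) if i < n // 2 else (re, me) for i in range(n)]
    meyer[3] = (re, re)
    meyer[n - 3] = (re, re)
    specs.append(mosaic_design("lemon_meyer", meyer, "lemon"))
    vk = f1_design("lemon_volkamer", re, me, n, nominal="lemon")
    vk.private_alleles = 1
    specs.append(vk)
    lime = offspring_design("mexican_lime", "micrantha_01", "citron_01", n, "lime")
    lime.private_alleles = 1
    specs.append(lime)
    al = f1_design("alemow", me, mi, n, nominal="alemow")
    al.private_alleles = 9
    specs.append(al)
    berg_origins: list[tuple[HapOrigin, HapOrigin]] = []
    for i in range(n):
        if i in (5 % n, 9 % n):
            berg_origins.append((pool(me), novel(me)))
        elif i % 2 == 0:
            berg_origins.append((pool(me), pool(re)))
        else:
            berg_origins.append((pool(me), pool(ma)))
    berg = AccessionSpec("bergamot", "bergamot", berg_origins, private_alleles=3)
    specs.append(berg)

    assert len(specs) == 48
    return specs


BASAL_NOMINAL_GROUPS = {
    "reticulata": "mandarin",
    "maxima": "pummelo",
    "medica": "citron",
    "micrantha": "micrantha",
}

N_NOVEL_SUBSTITUTIONS = 4  # extra substitutions carried by a "novel" haplotype


@dataclass
class Accession:
    name: str
    nominal_taxon: str
    haplotypes: dict[str, tuple[np.ndarray, np.ndarray]]  # fragment -> (h1, h2)


@dataclass
class Cohort:
    accessions: dict[str, Accession]
    panel: ReferencePanel

    @property
    def names(self) -> list[str]:
        return list(self.accessions)

    def __getitem__(self, name: str) -> Accession:
        return self.accessions[name]


@dataclass
class TruthSet:
    """Ground truth for every simulated accession x fragment and read."""

    origins: dict[tuple[str, str], tuple[str, str]] = field(default_factory=dict)
    haplotypes: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )
    novel_flags: dict[tuple[str, str], tuple[bool, bool]] = field(default_factory=dict)
    private_alleles: list[dict] = field(default_factory=list)
    coverage: dict[tuple[str, str], int] = field(default_factory=dict)
    coverage_round1: dict[tuple[str, str], int] = field(default_factory=dict)
    reads: list[dict] = field(default_factory=list)

    def genotype_class(self, accession: str, fragment: str) -> frozenset[str]:
        """True genotypic ancestry class: unordered pair of origin taxa."""
        return frozenset(self.origins[(accession, fragment)])

    def table(self) -> pd.DataFrame:
        rows = []
        for (acc, frag), (o1, o2) in self.origins.items():
            h1, h2 = self.haplotypes[(acc, frag)]
            rows.append(
                {
                    "accession": acc,
                    "fragment": frag,
                    "origin1": o1,
                    "origin2": o2,
                    "class": "/".join(sorted((o1, o2))),
                    "hap1": seqs.decode(h1),
                    "hap2": seqs.decode(h2),
                    "true_depth": self.coverage.get((acc, frag), 0),
                }
            )
        return pd.DataFrame(rows)

    def read_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.reads)

    def write(self, path: str | Path) -> None:
        self.table().to_csv(path, sep="\t", index=False)


def _resolve_origin(
    origin: HapOrigin,
    fragment: str,
    pools: TaxonPools,
    built: dict[str, Accession],
    basal_allele_sets: dict[str, list[set[int]]] | None,
    rng: np.random.Generator,
) -> tuple[np.ndarray, str, bool]:
    """Materialize one haplotype; returns (sequence, origin taxon, novel?)."""
    if origin.kind == "pool":
        hp = pools.pool(origin.taxon, fragment)
        idx = origin.hap if origin.hap is not None else int(rng.integers(len(hp)))
        return hp[idx].copy(), origin.taxon, False
    if origin.kind == "clone":
        if origin.accession not in built:
            raise ValueError(
                f"clone origin references accession {origin.accession!r} "
                "not yet simulated (order the design parents-first)"
            )
        parent = built[origin.accession]
        idx = origin.hap if origin.hap is not None else int(rng.integers(2))
        seq = parent.haplotypes[fragment][idx].copy()
        # origin taxon is inherited from the parent's truth, resolved later
        return seq, f"@{origin.accession}:{idx}", False
    if origin.kind == "novel":
        hp = pools.pool(origin.taxon, fragment)
        base = hp[int(rng.integers(len(hp)))].copy()
        positions = rng.choice(len(base), size=N_NOVEL_SUBSTITUTIONS, replace=False)
        forbidden = None
        if basal_allele_sets is not None:
            forbidden = {int(p): basal_allele_sets[fragment][int(p)] for p in positions}
        return seqs.mutate(base, positions, rng, forbidden=forbidden), origin.taxon, True
    raise ValueError(f"unknown origin kind {origin.kind!r}")


def _basal_allele_sets(
    config: SimulationConfig, pools: TaxonPools, panel: ReferencePanel
) -> dict[str, list[set[int]]]:
    """Per fragment, per position: set of allele codes present in any pool."""
    out: dict[str, list[set[int]]] = {}
    for frag in panel.fragment_names:
        stacked = np.vstack([pools.pool(t, frag) for t in config.taxa])
        out[frag] = [set(np.unique(stacked[:, p]).tolist()) for p in range(stacked.shape[1])]
    return out


def simulate_cohort(
    config: SimulationConfig,
    panel: ReferencePanel,
    pools: TaxonPools,
    rng: np.random.Generator | None = None,
) -> tuple[Cohort, TruthSet]:
    """Materialize the diploid cohort and its ground-truth record."""
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    if config.cohort_design is not None and len(config.cohort_design) == 0:
        raise ValueError("cohort design names zero accessions")
    design = (
        config.cohort_design
        if config.cohort_design is not None
        else default_cohort_design(config.n_fragments)
    )
    frag_names = panel.fragment_names
    if any(len(spec.origins) != len(frag_names) for spec in design):
        raise ValueError("cohort design fragment count does not match panel")

    allele_sets = _basal_allele_sets(config, pools, panel)
    planted_positions: set[tuple[str, int]] = set()
    built: dict[str, Accession] = {}
    truth = TruthSet()
    deferred: dict[tuple[str, str, int], str] = {}  # clone refs to resolve

    for spec in design:
        haps: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for frag, origin_pair in zip(frag_names, spec.origins):
            resolved = []
            labels = []
            flags = []
            for slot, origin in enumerate(origin_pair):
                seq, label, is_novel = _resolve_origin(
                    origin, frag, pools, built, allele_sets, rng
                )
                resolved.append(seq)
                labels.append(label)
                flags.append(is_novel)
                if label.startswith("@"):
                    deferred[(spec.name, frag, slot)] = label
            haps[frag] = (resolved[0], resolved[1])
            truth.origins[(spec.name, frag)] = (labels[0], labels[1])
            truth.haplotypes[(spec.name, frag)] = haps[frag]
            truth.novel_flags[(spec.name, frag)] = (flags[0], flags[1])
        acc = Accession(spec.name, spec.nominal_taxon, haps)

        # plant hybrid-private alleles: heterozygous substitutions to bases
        # absent from every basal pool at that site
        # private alleles are planted at distinct sites cohort-wide, so k
        # plantings yield exactly k rare-allele loci
        for _ in range(spec.private_alleles):
            for _attempt in range(100):
                frag = frag_names[int(rng.integers(len(frag_names)))]
                pos = int(rng.integers(panel[frag].length))
                if (frag, pos) in planted_positions:
                    continue
                slot = int(rng.integers(2))
                hap = acc.haplotypes[frag][slot]
                try:
                    hap[:] = seqs.mutate(
                        hap, [pos], rng, forbidden={pos: allele_sets[frag][pos]}
                    )
                    planted_positions.add((frag, pos))
                    break
                except ValueError:
                    continue
            else:
                raise RuntimeError("could not place a private allele")
            truth.private_alleles.append(
                {
                    "accession": spec.name,
                    "fragment": frag,
                    "position": pos + 1,
                    "allele": seqs.decode(hap[pos : pos + 1]),
                }
            )
        built[spec.name] = acc

    # resolve clone origin labels to the parent's true origin taxon
    for (acc_name, frag, slot), label in deferred.items():
        parent, idx = label[1:].split(":")
        parent_label = truth.origins[(parent, frag)][int(idx)]
        while parent_label.startswith("@"):
            p2, i2 = parent_label[1:].split(":")
            parent_label = truth.origins[(p2, frag)][int(i2)]
        o = list(truth.origins[(acc_name, frag)])
        o[slot] = parent_label
        truth.origins[(acc_name, frag)] = (o[0], o[1])

    return Cohort(built, panel), truth


# Clone-origin gametes must copy a *specific* parent haplotype; when the
# design leaves the index random the draw above already fixed it, so the
# emitted TruthSet always names concrete origin taxa.


# --------------------------------------------------------------------------
# Reads
# --------------------------------------------------------------------------


def make_barcodes(
    n: int, length: int, rng: np.random.Generator, min_distance: int = 3
) -> list[str]:
    """Random barcodes pairwise Hamming >= ``min_distance`` apart."""
    chosen: list[np.ndarray] = []
    attempts = 0
    while len(chosen) < n:
        cand = seqs.random_sequence(length, rng)
        if all(seqs.hamming(cand, c) >= min_distance for c in chosen):
            chosen.append(cand)
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError("cannot place barcodes at the requested distance")
    return [seqs.decode(c) for c in chosen]


def _apply_errors(
    hap: np.ndarray, rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    if rate <= 0:
        return hap, 0
    n_err = int(rng.binomial(len(hap), rate))
    if n_err == 0:
        return hap, 0
    candidates = np.flatnonzero(hap != seqs.GAP)
    n_err = min(n_err, len(candidates))
    positions = rng.choice(candidates, size=n_err, replace=False)
    return seqs.mutate(hap, positions, rng), n_err


def _apply_homopolymer_indels(
    seq: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Insert/delete one base in homopolymer runs of length >= 3."""
    if rate <= 0:
        return seq
    out: list[int] = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        run = list(seq[i:j])
        if j - i >= 3 and rng.random() < rate:
            if rng.random() < 0.5:
                run.append(seq[i])
            else:
                run.pop()
        out.extend(run)
        i = j
    return np.array(out, dtype=np.uint8)


@dataclass
class SimulatedRun:
    """One simulated sequencing run plus all the files a real run would ship."""

    reads: list[tuple[str, str, str]]  # (id, sequence, quality)
    sample_sheet: pd.DataFrame  # barcode, accession, nominal_taxon
    n_short_reads: int

    def write_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rid, seq, qual in self.reads:
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def simulate_reads(
    cohort: Cohort,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    truth: TruthSet | None = None,
) -> SimulatedRun:
    """Emit barcoded, primered, error-bearing reads for every amplicon."""
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    panel = cohort.panel
    names = cohort.names
    barcodes = make_barcodes(len(names), config.barcode_length, rng)
    sheet = pd.DataFrame(
        {
            "barcode": barcodes,
            "accession": names,
            "nominal_taxon": [cohort[n].nominal_taxon for n in names],
        }
    )
    bc_of = dict(zip(names, barcodes))

    amplicons = [(acc, frag) for acc in names for frag in panel.fragment_names]
    depths, round1 = config.coverage_model.draw(
        len(names), len(panel.fragment_names), rng
    )

    reads: list[tuple[str, str, str]] = []
    counter = 0
    for (acc, frag), depth, d1 in zip(amplicons, depths, round1):
        if truth is not None:
            truth.coverage[(acc, frag)] = int(depth)
            truth.coverage_round1[(acc, frag)] = int(d1)
        haps = cohort[acc].haplotypes[frag]
        prefix = bc_of[acc] + panel[frag].primer
        for _ in range(int(depth)):
            hap_idx = int(rng.integers(2))
            insert, n_err = _apply_errors(
                haps[hap_idx], config.per_base_error_rate, rng
            )
            insert = _apply_homopolymer_indels(
                insert, config.homopolymer_indel_rate, rng
            )
            rid = f"r{counter:07d}"
            counter += 1
            seq = prefix + seqs.decode(insert, drop_gaps=True)
            qual = seqs.phred_string(rng.integers(30, 41, size=len(seq)))
            reads.append((rid, seq, qual))
            if truth is not None:
                truth.reads.append(
                    {
                        "read_id": rid,
                        "accession": acc,
                        "fragment": frag,
                        "hap_index": hap_idx,
                        "n_errors": n_err,
                    }
                )

    # primer-dimer style junk: short inserts that fail the length filter
    f = config.short_read_fraction
    n_junk = int(round(f / (1.0 - f) * len(reads))) if f > 0 else 0
    for _ in range(n_junk):
        acc = names[int(rng.integers(len(names)))]
        frag = panel.fragment_names[int(rng.integers(len(panel)))]
        ins_len = int(rng.integers(10, 120))
        seq = (
            bc_of[acc]
            + panel[frag].primer
            + seqs.decode(seqs.random_sequence(ins_len, rng))
        )
        rid = f"r{counter:07d}"
        counter += 1
        qual = seqs.phred_string(rng.integers(30, 41, size=len(seq)))
        reads.append((rid, seq, qual))

    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    return SimulatedRun(reads=reads, sample_sheet=sheet, n_short_reads=n_junk)


def simulate_run(
    config: SimulationConfig,
) -> tuple[ReferencePanel, TaxonPools, Cohort, TruthSet, SimulatedRun]:
    """Panel -> cohort -> reads, all seeded from ``config.seed``."""
    root = np.random.SeedSequence(config.seed)
    r_panel, r_cohort, r_reads = [np.random.default_rng(s) for s in root.spawn(3)]
    panel, pools = simulate_panel(config, r_panel)
    cohort, truth = simulate_cohort(config, panel, pools, r_cohort)
    run = simulate_reads(cohort, config, r_reads, truth)
    return panel, pools, cohort, truth, run


def perfect_phased_calls(cohort: Cohort, truth: TruthSet, panel: ReferencePanel) -> dict:
    """Noise-free PhasedGenotype records derived directly from the truth.

    Lets catalog/assignment/painting/parentage stages be exercised with
    full coverage and exact calls, independent of read simulation.
    """
    from .calling import PhasedGenotype, VariantCall

    out = {}
    for acc in cohort.names:
        for frag in panel.fragment_names:
            h1, h2 = truth.haplotypes[(acc, frag)]
            ref = panel[frag].reference
            genotype = np.vstack([np.minimum(h1, h2), np.maximum(h1, h2)])
            variants = []
            for p in np.flatnonzero((genotype[0] != ref) | (genotype[1] != ref)):
                alleles = sorted({int(genotype[0][p]), int(genotype[1][p])})
                variants.append(
                    VariantCall(
                        fragment=frag,
                        position=int(p) + 1,
                        kind="indel" if seqs.GAP in alleles else "SNP",
                        ref=seqs.decode(ref[p : p + 1]),
                        alleles=[
                            seqs.decode(np.array([a], np.uint8)) for a in alleles
                        ],
                        genotype=(
                            seqs.decode(np.array([genotype[0][p]], np.uint8)),
                            seqs.decode(np.array([genotype[1][p]], np.uint8)),
                        ),
                        region=panel[frag].region_at(int(p) + 1),
                    )
                )
            het = np.flatnonzero(genotype[0] != genotype[1])
            identical = bool(len(het) == 0)
            out[(acc, frag)] = PhasedGenotype(
                accession=acc,
                fragment=frag,
                status="called",
                haplotypes=[h1.copy()] if identical else [h1.copy(), h2.copy()],
                support=[2] if identical else [1, 1],
                het_positions=het.tolist(),
                variants=variants,
                genotype=genotype,
            )
    return out


def realized_divergence(
    pools: TaxonPools, taxa: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Realized mean pairwise SNP/kb between and within taxon pools."""
    taxa = tuple(pools.haplotypes) if taxa is None else taxa
    rows = []
    frags = list(next(iter(pools.haplotypes.values())))
    total_bp = sum(pools.haplotypes[taxa[0]][f].shape[1] for f in frags)
    for i, a in enumerate(taxa):
        for b in taxa[i:]:
            diffs = []
            for f in frags:
                ha, hb = pools.haplotypes[a][f], pools.haplotypes[b][f]
                if a == b:
                    n = len(ha)
                    d = [
                        seqs.hamming(ha[x], ha[y])
                        for x in range(n)
                        for y in range(x + 1, n)
                    ]
                else:
                    d = [seqs.hamming(x, y) for x in ha for y in hb]
                diffs.append(np.mean(d) if d else 0.0)
            rows.append(
                {
                    "taxon_a": a,
                    "taxon_b": b,
                    "snp_per_kb": 1000.0 * float(np.sum(diffs)) / total_bp,
                    "kind": "intra" if a == b else "inter",
                }
            )
    return pd.DataFrame(rows)
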