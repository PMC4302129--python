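"""Per-amplicon alignment, variant calling and within-amplicon phasing.

Long amplicon reads cover a whole gene fragment, so each read is a direct
observation of one parental haplotype and phasing reduces to grouping reads
by their allele vector over the accession's heterozygous positions. An
amplicon yields one haplotype (homozygous fragment) or two (heterozygous),
with per-haplotype supporting read counts; reads matching neither vector
(sequencing error, putative chimeras) are excluded and counted.

Coordinates are 1-based on the fragment reference in all outputs; internal
arithmetic is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import seqs
from .panel import Fragment
from .reads import AmpliconBin, ReadRecord

MIN_IDENTITY = 0.80
SEED_SIZE = 12
MIN_MINOR_FRACTION = 0.20
MIN_MINOR_READS = 10
MIN_PHASED_FRACTION = 0.70


@dataclass
class VariantCall:
    fragment: str
    position: int  # 1-based on the fragment reference
    kind: str  # "SNP" | "indel"
    ref: str
    alleles: list[str]
    genotype: tuple[str, str]
    region: str


@dataclass
class PhasedGenotype:
    accession: str
    fragment: str
    status: str  # "called" | "low-coverage" | "failed"
    haplotypes: list[np.ndarray] = field(default_factory=list)  # code arrays
    support: list[int] = field(default_factory=list)
    n_excluded: int = 0
    het_positions: list[int] = field(default_factory=list)  # 0-based
    variants: list[VariantCall] = field(default_factory=list)
    genotype: np.ndarray | None = None  # (2, L) sorted allele codes

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def haplotype_strings(self) -> list[str]:
        return [seqs.decode(h, drop_gaps=True) for h in self.haplotypes]


# ----------------------------------------------------------------- alignment
def align_read(
    read: ReadRecord | str,
    fragment: Fragment,
    min_identity: float = MIN_IDENTITY,
    seed_size: int = SEED_SIZE,
) -> np.ndarray | None:
    """Project one read onto fragment coordinates.

    Returns a length-L observation array (base codes; gap code at deleted
    reference positions; N where the read does not cover), or ``None`` when
    the read fails the identity floor or shares no exact seed k-mer with
    the reference. Equal-length reads take a fast mismatch-count path;
    length-changed reads are globally aligned.
    """
    seq = read.sequence if isinstance(read, ReadRecord) else read
    if not seq:
        raise ValueError("empty read")
    codes = seqs.encode(seq)
    ref = fragment.reference
    L = len(ref)
    if len(codes) == L:
        identity = 1.0 - seqs.hamming(codes, ref) / L
        return codes if identity >= min_identity else None

    if not _shares_seed(seq, fragment.reference_str, seed_size):
        return None
    import edlib

    res = edlib.align(seq, fragment.reference_str, mode="NW", task="path")
    aln_len = max(len(seq), L)
    identity = 1.0 - res["editDistance"] / aln_len
    if identity < min_identity:
        return None
    obs = np.full(L, seqs.N_CODE, dtype=np.uint8)
    qi = ri = 0
    for n_str, op in _iter_cigar(res["cigar"]):
        n = int(n_str)
        if op in ("=", "X", "M"):
            obs[ri : ri + n] = codes[qi : qi + n]
            qi += n
            ri += n
        elif op == "D":  # gap in query -> deletion at reference positions
            obs[ri : ri + n] = seqs.GAP
            ri += n
        elif op == "I":  # insertion in query: not representable on ref axis
            qi += n
    _collapse_homopolymer_deletions(obs, ref)
    return obs


def _iter_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield num, ch
            num = ""


def _shares_seed(read: str, ref: str, k: int) -> bool:
    kmers = {ref[i : i + k] for i in range(0, len(ref) - k + 1, k)}
    return any(read[i : i + k] in kmers for i in range(len(read) - k + 1))


def _collapse_homopolymer_deletions(obs: np.ndarray, ref: np.ndarray) -> None:
    """Normalize the dominant pyrosequencing error mode: a single-base
    deletion inside a reference homopolymer run (>= 3) is restored to the
    reference base before calling."""
    gap_pos = np.flatnonzero(obs == seqs.GAP)
    for p in gap_pos:
        base = ref[p]
        run = 1
        i = p - 1
        while i >= 0 and ref[i] == base:
            run += 1
            i -= 1
        i = p + 1
        while i < len(ref) and ref[i] == base:
            run += 1
            i += 1
        if run >= 3:
            obs[p] = base


def align_bin(
    amplicon: AmpliconBin,
    fragment: Fragment,
    min_identity: float = MIN_IDENTITY,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Align every read in a bin; returns (obs matrix, quality matrix,
    number of reads excluded by the identity filter)."""
    L = fragment.length
    obs_rows, qual_rows = [], []
    n_excluded = 0
    for read in amplicon.reads:
        obs = align_read(read, fragment, min_identity)
        if obs is None:
            n_excluded += 1
            continue
        obs_rows.append(obs)
        q = np.frombuffer(read.quality.encode(), dtype=np.uint8).astype(np.int32) - 33
        qrow = np.zeros(L, dtype=np.int32)
        n = min(L, len(q))
        qrow[:n] = q[:n]
        qual_rows.append(qrow)
    if not obs_rows:
        return (
            np.empty((0, L), dtype=np.uint8),
            np.empty((0, L), dtype=np.int32),
            n_excluded,
        )
    return np.vstack(obs_rows), np.vstack(qual_rows), n_excluded


# ------------------------------------------------------------------- calling
def _allele_counts(obs: np.ndarray) -> np.ndarray:
    """(5, L) observation counts for codes A,C,G,T,gap (N ignored)."""
    return np.stack([(obs == c).sum(axis=0) for c in range(5)])


def call_variants(
    obs: np.ndarray,
    fragment: Fragment,
    min_minor_fraction: float = MIN_MINOR_FRACTION,
    min_minor_reads: int = MIN_MINOR_READS,
) -> tuple[np.ndarray, list[VariantCall]]:
    """Diploid genotype per reference position from pooled observations.

    A position is heterozygous iff the minor allele reaches both the
    fraction and absolute-read floors; otherwise the majority allele is
    called homozygous. Returns a (2, L) sorted-code genotype array and the
    variant list (positions whose genotype differs from homozygous
    reference); gap alleles are recorded as kind="indel".
    """
    counts = _allele_counts(obs)
    L = counts.shape[1]
    totals = counts.sum(axis=0)
    top = counts.argmax(axis=0)  # ties -> lowest code (alphabetical)
    top_count = counts[top, np.arange(L)]
    minor_counts = counts.copy()
    minor_counts[top, np.arange(L)] = -1
    minor = minor_counts.argmax(axis=0)
    minor_count = minor_counts[minor, np.arange(L)]
    with np.errstate(invalid="ignore", divide="ignore"):
        minor_frac = np.where(totals > 0, minor_count / np.maximum(totals, 1), 0.0)
    het = (minor_count >= min_minor_reads) & (minor_frac >= min_minor_fraction)
    g_lo = np.where(het, np.minimum(top, minor), top).astype(np.uint8)
    g_hi = np.where(het, np.maximum(top, minor), top).astype(np.uint8)
    uncovered = totals == 0
    g_lo[uncovered] = fragment.reference[uncovered]
    g_hi[uncovered] = fragment.reference[uncovered]
    genotype = np.vstack([g_lo, g_hi])

    variants: list[VariantCall] = []
    ref = fragment.reference
    diff = (g_lo != ref) | (g_hi != ref)
    for p in np.flatnonzero(diff):
        alleles = sorted({int(g_lo[p]), int(g_hi[p])})
        kind = "indel" if seqs.GAP in alleles else "SNP"
        variants.append(
            VariantCall(
                fragment=fragment.name,
                position=int(p) + 1,
                kind=kind,
                ref=seqs.decode(ref[p : p + 1]),
                alleles=[seqs.decode(np.array([a], np.uint8)) for a in alleles],
                genotype=(
                    seqs.decode(np.array([g_lo[p]], np.uint8)),
                    seqs.decode(np.array([g_hi[p]], np.uint8)),
                ),
                region=fragment.region_at(int(p) + 1),
            )
        )
    return genotype, variants


def _consensus(obs: np.ndarray, quals: np.ndarray) -> np.ndarray:
    """Column-wise majority base; ties broken by total quality then by
    alphabetical base (lowest code), giving deterministic output."""
    counts = _allele_counts(obs).astype(np.int64)
    qsum = np.stack(
        [np.where(obs == c, quals, 0).sum(axis=0) for c in range(5)]
    ).astype(np.int64)
    code_pref = np.arange(4, -1, -1, dtype=np.int64)[:, None]  # prefer low codes
    score = counts * 10_000_000 + qsum * 10 + code_pref
    return score.argmax(axis=0).astype(np.uint8)


def phase_amplicon(
    accession: str,
    fragment: Fragment,
    obs: np.ndarray,
    quals: np.ndarray,
    genotype: np.ndarray,
    variants: list[VariantCall],
    min_phased_fraction: float = MIN_PHASED_FRACTION,
) -> PhasedGenotype:
    """Partition reads into allele classes and emit 1 or 2 haplotypes."""
    het_pos = np.flatnonzero(genotype[0] != genotype[1])
    result = PhasedGenotype(
        accession=accession,
        fragment=fragment.name,
        status="called",
        het_positions=het_pos.tolist(),
        variants=variants,
        genotype=genotype,
    )
    n_reads = obs.shape[0]
    if n_reads == 0:
        result.status = "failed"
        return result
    if len(het_pos) == 0:
        result.haplotypes = [_consensus(obs, quals)]
        result.support = [n_reads]
        return result

    vectors = obs[:, het_pos]
    uniq, inverse, counts = np.unique(
        vectors, axis=0, return_inverse=True, return_counts=True
    )
    # two largest groups; ties resolved by vector byte order (np.unique sorts)
    order = np.argsort(-counts, kind="stable")
    top2 = order[:2]
    members = [np.flatnonzero(inverse == g) for g in top2]
    in_top = counts[top2].sum()
    result.n_excluded = int(n_reads - in_top)
    if in_top / n_reads < min_phased_fraction:
        result.status = "failed"
        return result
    haps = [_consensus(obs[m], quals[m]) for m in members]
    # deterministic haplotype order: lexicographic on the het-allele vector
    if seqs.decode(haps[0][het_pos]) > seqs.decode(haps[1][het_pos]):
        haps.reverse()
        members.reverse()
    result.haplotypes = haps
    result.support = [int(len(m)) for m in members]
    return result


def call_and_phase(
    amplicon: AmpliconBin,
    fragment: Fragment,
    depth_threshold: int = 50,
    min_identity: float = MIN_IDENTITY,
    min_minor_fraction: float = MIN_MINOR_FRACTION,
    min_minor_reads: int = MIN_MINOR_READS,
    min_phased_fraction: float = MIN_PHASED_FRACTION,
    force: bool = False,
) -> PhasedGenotype:
    """Full per-amplicon path: align -> call -> phase.

    Bins under the depth threshold are reported as status "low-coverage"
    with no calls (the study's recourse for these was Sanger completion),
    unless ``force`` is set.
    """
    if amplicon.depth < depth_threshold and not force:
        return PhasedGenotype(
            accession=amplicon.accession,
            fragment=fragment.name,
            status="low-coverage",
        )
    obs, quals, _ = align_bin(amplicon, fragment, min_identity)
    if obs.shape[0] == 0:
        return PhasedGenotype(
            accession=amplicon.accession, fragment=fragment.name, status="failed"
        )
    genotype, variants = call_variants(
        obs, fragment, min_minor_fraction, min_minor_reads
    )
    return phase_amplicon(
        amplicon.accession, fragment, obs, quals, genotype, variants,
        min_phased_fraction,
    )


# --------------------------------------------------------------- concordance
@dataclass
class Discordance:
    n_discordant: int
    n_compared: int

    @property
    def percent(self) -> float:
        return discordance_percent(self.n_discordant, self.n_compared)


def discordance_percent(n_discordant: int, n_compared: int) -> float:
    """Discordance as a percentage of compared bases, 2 decimals."""
    if n_compared <= 0:
        raise ValueError("no compared bases")
    return round(100.0 * n_discordant / n_compared, 2)


def genotype_error_rate(
    calls_a: dict[tuple[str, str], np.ndarray],
    calls_b: dict[tuple[str, str], np.ndarray],
) -> Discordance:
    """Per-base discordance between two genotype call sets.

    Each call set maps (accession, fragment) -> (2, L) sorted allele-code
    arrays; all reference positions of amplicons present in both sets are
    compared as unordered allele pairs.
    """
    shared = sorted(set(calls_a) & set(calls_b))
    if not shared:
        raise ValueError("call sets share no amplicons")
    n_disc = 0
    n_comp = 0
    for key in shared:
        ga, gb = calls_a[key], calls_b[key]
        if ga.shape != gb.shape:
            raise ValueError(f"genotype shapes differ for {key}")
        n_comp += ga.shape[1]
        n_disc += int(np.count_nonzero((ga != gb).any(axis=0)))
    return Discordance(n_disc, n_comp)


def truth_genotypes(truth, panel) -> dict[tuple[str, str], np.ndarray]:
    """Sorted-code (2, L) genotype arrays from a simulator TruthSet."""
    out = {}
    for (acc, frag), (h1, h2) in truth.haplotypes.items():
        g = np.vstack([np.minimum(h1, h2), np.maximum(h1, h2)])
        out[(acc, frag)] = g
    return out
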