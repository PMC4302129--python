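# Methods

## The problem setting

Cultivated citrus arose from hybridization among four sexually compatible
but anciently diverged taxa — *C. reticulata*, *C. maxima*, *C. medica* and
*C. micrantha* — followed by apomictic propagation that froze interspecific
heterozygosity in place. A variety's genome is therefore a mosaic of
chromosome segments, each homozygous for one ancestral taxon or
heterozygous between two. Long amplicons (~450–550 bp) sequenced deeply on
single molecules let both haplotypes of each targeted gene fragment be read
without cloning; assigning each haplotype to an ancestral gene pool then
paints the mosaic and supports explicit parentage tests.

## Synthetic study generator

The simulator's defaults reproduce the study conditions end to end; they
are the conditions every test and the acceptance script run under.

**Divergence model.** A random root sequence per fragment; taxon consensus
sequences mutate star-wise from the root. The requested inter-taxon
divergence matrix (defaults, SNP/kb: re–ma 10.41, re–me 14.56, re–mi 13.49,
ma–me 11.21, ma–mi 10.61, me–mi 12.24) is a *pairwise haplotype* quantity
to which within-taxon spread also contributes, so the consensus-level
branch targets solve `b_i + b_j = (d_ij − (intra_i + intra_j)/2) · L/1000`
by non-negative least squares. Within-taxon pools (10 haplotypes/taxon by
default) mutate from their consensus at Poisson(intra/2 per kb) so two pool
members differ at about the requested intra rate (defaults: re 3.93, ma
2.06, me 1.26 SNP/kb; the single-accession micrantha pool has no observable
intra value and defaults to the citron-like 1.26). Substitutions are
uniform over the three alternative bases; two taxa mutating the same site
produce triallelic loci without any special mechanism. Realized densities
land within ~5% (inter) and ~20% (intra) of the request at these sizes.
A configurable fraction of exonic positions (default 0) receives 1-bp
deletions in random pool haplotypes, placed outside homopolymer runs so
planted indels stay distinguishable from the sequencing error mode that
calling normalizes away.

**Cohort.** The default design is 48 accessions: 14 mandarins (nominally
*C. reticulata*) of which 10 carry a *C. maxima* introgression — one
heterozygous fragment each, except 'Ponkan' which carries one homozygous
and one heterozygous donor fragment; 10 pummelos, 6 citrons, 1 micrantha;
and 17 hybrids. Hybrids include true trios built by copying concrete
parental haplotypes (clementine = willowleaf × sweet orange; lemons =
sour orange × citron; grapefruit = pummelo × sweet orange; Mexican lime =
micrantha × citron), F1 designs drawn from pools (sour orange = ma × re,
alemow = me × mi, Volkamer lemon = re × me), mosaics (sweet orange, Meyer
lemon) and a bergamot that carries novel haplotypes (pool members plus four
extra substitutions) on two fragments so that parentage rejection is
testable. Nineteen hybrid-private alleles — heterozygous substitutions to
bases absent from every basal pool, at distinct sites — are planted on the
hybrids (alemow 9, sour orange 4, bergamot 3, Volkamer 1, lime 1,
grapefruit 1).

**Reads and coverage.** A read is `barcode + gene-specific primer +
haplotype copy`; substitution errors hit the insert at the per-base rate
(default 1%), with an optional homopolymer length-error mode (default off,
as the real per-read error profile of the platform runs is not published;
1% substitution is a modeling choice). Barcodes are pairwise Hamming ≥ 3 by
construction, so exact-match demultiplexing is well posed. Qualities are
uniform Phred 30–40 (Sanger +33). Coverage follows the study protocol: two
sequencing rounds (means 75 and 133 reads/amplicon — the observed ratio of
the two runs), sharing per-fragment representation factors
(log-normal, σ_f = 0.55) plus residual amplicon noise (σ = 0.30). One round
leaves roughly 28–40% of amplicons under the 50-read threshold depending on
the fragment-factor draw; the combined rounds rescue most of them, with
chronically under-represented fragments persisting. Eleven percent of the
raw read count is planted as short primer-dimer junk. Everything an
emitted file would carry (haplotypes, origins, per-read error counts,
per-round coverage) is recorded in the `TruthSet`.

**What the simulator does not model:** recombination within a fragment,
PCR chimeras, flowgram-level signal, quality-correlated errors, and
coalescent genealogies (pools are star-shaped around a consensus). Passing
tests therefore demonstrate correctness of the pipeline's logic under
realistic divergence/coverage/error regimes, not robustness to every
artifact of real libraries.

## Read processing

Reads shorter than 150 bases after barcode/primer trimming are discarded as
primer-dimer material (the length is judged on the insert; the discard
fraction is reported). Barcodes are matched exactly at the read start;
the following gene-specific primer is matched with ≤ 2 substitutions
(no indels) — enough to tolerate sequencing error without cross-fragment
misassignment at these primer distances. Reads failing either match go to
an unassigned pool; binning is exhaustive and disjoint. Amplicons with zero
reads are retained in all summaries so percentages are over all 768
accession × fragment cells. Reads are not orientation-flipped by default
(the simulator emits forward reads); a reverse-complement search flag
exists for real data.

## Alignment, calling, phasing

Equal-length reads take a fast mismatch-count path; length-changed reads
are globally aligned (edlib, Needleman–Wunsch) after a shared exact 12-mer
seed check. Reads under 80% identity to the fragment reference are excluded
from calling. Single-base deletions inside reference homopolymer runs ≥ 3
are restored to the reference base before calling — the dominant
pyrosequencing error mode — so only length changes outside homopolymers can
become indel calls.

A position is called heterozygous iff the minor allele reaches both a
fraction ≥ 0.20 and an absolute count ≥ 10; otherwise the majority allele
is homozygous. The two floors together make an error-driven false
heterozygote (10+ identical wrong bases at one site) vanishingly improbable
at 1% error and 50–500× depth, while a true 50/50 heterozygote essentially
never misses both. Gap alleles are called by the same rule, recorded as
`kind=indel`, and excluded from SNP/kb densities. Bins under the 50-read
threshold are reported as `low-coverage` with no calls — the study's
recourse for these was Sanger completion, which is out of scope here, so
missing stays missing and is never imputed.

Phasing reduces each aligned read to its allele vector over the
heterozygous positions and groups identical vectors; the two largest groups
define the haplotypes (full-length majority consensus within each group;
ties broken by total base quality, then alphabetically — output is
deterministic and invariant to read order). Reads matching neither vector
are excluded and counted; if the two top groups hold < 70% of the reads the
amplicon is `failed` (ambiguous phasing). Zero heterozygous positions yield
a single consensus haplotype carried twice. Positions are 1-based on the
fragment reference in all outputs; internal arithmetic is 0-based.

## Statistics

The genotype matrix holds unordered allele pairs over the population-level
variant loci (the union of called variant positions); missing entries
reduce n locus-wise. Group means of H_o, unbiased H_e and F_W run over all
loci the group has data for — every matrix locus is a population-level SNP,
so loci fixed within a group contribute zeros, matching the study's
per-group tables; F_W is undefined (null) where H_e = 0. Confidence
intervals are the normal approximation mean ± 1.96·SD/√loci at α = 0.05,
with the SD taken across loci.

Population pairs use the Weir–Cockerham (1984) θ estimator, combined over
loci by the ratio-of-sums rule, with the SD across per-locus estimates and
monomorphic loci skipped and counted. (Which F_ST estimator the study's
software used is not stated; θ is the field default, and the per-SNP
diagnostic scans use Nei's G_ST as named there.) G_ST compares the focal
group with the pooled others: H_S is the sample-size-weighted mean
within-group 1−Σp², H_T uses pooled (sample-size-weighted) frequencies.
Diagnostic scans in the pipeline run over the basal accessions only:
hybrids carry the focal taxon's alleles, which would cap G_ST below 1 and
hide totally discriminant SNPs.

Simple-matching dissimilarity is mismatch fraction over shared loci
(haplotypic) or 1 − mean shared-allele similarity with per-locus values in
{0, 0.5, 1} (genotypic); pairs with zero compared loci are flagged missing.
LD r² is computed from phased two-locus haplotype frequencies, maximized
over allele dichotomizations for multi-allelic loci, with a label
permutation p-value. Note that phase *between* fragments is unknown (only
within-amplicon phase is observed), so cross-fragment r² is attenuated for
interspecific heterozygotes; structure-driven LD remains strong at common
SNPs. The rare-allele scan lists alleles absent from every basal accession
with their carriers, and the genotype matrix can mask them so diversity
tables can be computed without hybrid-private variation.

All of these agree with naive first-principles oracles to 1e-12 on small
matrices (see the test suite).

## Trees, assignment, refinement

Neighbor joining is the classic Q-criterion agglomeration with
deterministic tie-breaking (lexicographically smallest pair name) and
negative branch lengths clamped to zero with the deficit shifted to the
sister edge, preserving the joined pair's path length. On additive
distances it recovers topology and lengths exactly (verified against
exhaustive topology search up to 8 leaves, and against scikit-bio on
arbitrary matrices); trees are emitted as newick per fragment as an audit
aid.

The study assigned haplotypes to taxa by visual cluster membership in those
trees; this package operationalizes the rule: a haplotype joins the taxon
whose reference panel it is closest to by mean simple-matching
dissimilarity, provided the margin to the second-nearest panel is strictly
positive and ≥ δ, and the nearest distance is ≤ a cap. Defaults per
fragment: δ = half the pooled mean within-panel dissimilarity; cap =
midpoint of the mean within- and between-panel dissimilarities. Both are
tunable — the study states no numeric criterion for its indeterminate
class, so these defaults are this package's explicit surrogate. At the
default divergences ~97–99% of pool haplotypes assign to their true taxon,
errors fall exclusively to *indeterminate* (never cross-taxon), and the
few percent of indeterminate haplotypes mirrors the real study's 16 of 210.

Panel refinement starts from the nominal basal groups (every basal
accession contributes both haplotypes, carrier-level, so pool composition
reflects variety frequencies) and iteratively removes haplotypes that
assign to a different taxon — or are indeterminate with a cross-taxon
nearest panel — recording each as an introgression; the purged set grows
monotonically to a fixed point. Purging is only possible for amplicons deep
enough to call: an introgressed fragment that fell under the coverage
threshold is invisible to refinement (the study filled such gaps by Sanger
sequencing). Intra/inter dissimilarity tables (mean pairwise haplotype
differences per kb over the surveyed length) are emitted before and after
purging; purging lowers the focal taxon's intra-group density and raises
its totally-discriminant (G_ST = 1) diagnostic-SNP count.

## Painting and parentage

An accession's class at a fragment is the unordered pair of its two
haplotype assignments, rendered with two-letter labels (re/ma ≡ ma/re;
`ind` for indeterminate components; `missing` for uncalled amplicons);
identical tracks may be collapsed to one representative. Exports are a
matrix TSV and a BED-like table with 1-based inclusive map coordinates.
Class-switch counts along a track are reported as a coarse lower bound on
historical recombination, without claiming crossover counts (which depend
on fragment spacing).

Parentage: a fragment is consistent iff the offspring's two haplotypes
split into one exactly matching a parent-1 haplotype and the other a
parent-2 haplotype, where haplotype identity means exact match over the
fragment's called variant loci (isolated errors outside variant sites
cannot break a match). A parent given as a taxon label tests assignment of
the gamete to that taxon's pool ("direct F1 of two taxa"). Fragments with
any party uncalled are uninformative, as are failed matches involving an
indeterminate offspring haplotype (non-evidence, not contradiction). An
offspring identical to a parent at every compared fragment is flagged as
clonal. The test is symmetric in parent order.

## Problem sizes and determinism

The test suite and the acceptance script run the full default study — 48
accessions × 16 fragments, ~200k reads, ~450 SNP loci — once per seed
(about a minute), plus a 1,024-haplotype assignment study and exhaustive
tree searches to 8 leaves; smaller cohorts (4–8 fragments, constant
coverage) back the unit tests. One global seed deterministically spawns
per-stage generators, so a rerun with the same configuration is
byte-identical, including the FASTQ.

## Known limitations

- The micrantha panel rests on a single accession; at fragments where its
  amplicon is uncalled, micrantha-derived gametes in hybrids can only be
  indeterminate.
- Indeterminate assignments are counted as non-matches in painting
  concordance, so concordance against truth runs ~96–99% across seeds at
  the default conditions, driven by a handful of margin-boundary
  haplotypes per run.
- Group labels, not ancestry proportions, drive all statistics; model-based
  clustering and ordination are intentionally out of scope.
- Indel genotyping is limited to single-base events at non-homopolymer
  sites; homopolymer-length variation is normalized away by design.
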