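"""Diversity and differentiation statistics over called SNP genotypes.

Implements the statistics used to characterize the cohort: observed and
unbiased expected heterozygosity with Wright's fixation index F_W = 1 -
Ho/He, Weir-Cockerham theta for population pairs, Nei's G_ST for per-SNP
diagnostic scans of one taxon against the pooled rest, simple-matching
dissimilarity (haplotypic and genotypic), SNP/kb densities by gene region,
haplotype-based linkage disequilibrium r^2, and the scan for alleles absent
from all basal-taxon accessions.

Genotypes are held in a :class:`GenotypeMatrix`: accessions x SNP loci with
unordered allele-pair entries ("A/G") or missing (NaN); missing entries are
excluded locus-wise from every frequency denominator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = None


@dataclass
class GenotypeMatrix:
    genotypes: pd.DataFrame  # accessions x loci, entries "A/G" or NaN
    loci: pd.DataFrame  # index=locus, columns fragment, position, region
    groups: pd.Series  # accession -> group label

    def __post_init__(self) -> None:
        self.loci = self.loci.loc[self.genotypes.columns]
        self.groups = self.groups.loc[self.genotypes.index]

    @property
    def accessions(self) -> list[str]:
        return list(self.genotypes.index)

    @property
    def locus_names(self) -> list[str]:
        return list(self.genotypes.columns)

    def group_members(self, group: str | list[str]) -> list[str]:
        wanted = {group} if isinstance(group, str) else set(group)
        return [a for a in self.accessions if self.groups[a] in wanted]

    def alleles_at(self, locus: str, accessions: list[str] | None = None) -> list[str]:
        col = self.genotypes[locus]
        if accessions is not None:
            col = col.loc[accessions]
        out: set[str] = set()
        for g in col.dropna():
            out.update(g.split("/"))
        return sorted(out)

    def allele_counts(
        self, locus: str, accessions: list[str] | None = None
    ) -> tuple[dict[str, int], int]:
        """Allele count dict and number of non-missing diploid genotypes."""
        col = self.genotypes[locus]
        if accessions is not None:
            col = col.loc[accessions]
        counts: dict[str, int] = {}
        n = 0
        for g in col.dropna():
            a, b = g.split("/")
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
            n += 1
        return counts, n

    def mask_alleles(self, flagged: pd.DataFrame) -> "GenotypeMatrix":
        """Return a copy with flagged (locus, allele) carriers set missing."""
        gt = self.genotypes.copy()
        for row in flagged.itertuples():
            col = gt[row.locus]
            for acc in gt.index:
                g = col[acc]
                if isinstance(g, str) and row.allele in g.split("/"):
                    gt.loc[acc, row.locus] = np.nan
        return GenotypeMatrix(gt, self.loci.copy(), self.groups.copy())


# ------------------------------------------------------------------ Ho/He/Fw
def _locus_hetero(genotype: str) -> bool:
    a, b = genotype.split("/")
    return a != b


def unbiased_he(allele_counts: dict[str, int], n: int) -> float:
    """Nei's unbiased expected heterozygosity (2n/(2n-1)) (1 - sum p^2)."""
    total = sum(allele_counts.values())
    if total == 0 or n == 0:
        return 0.0
    p2 = sum((c / total) ** 2 for c in allele_counts.values())
    return (2.0 * n) / (2.0 * n - 1.0) * (1.0 - p2) if n > 0 else 0.0


@dataclass
class DiversitySummary:
    per_locus: pd.DataFrame
    per_fragment: pd.DataFrame
    overall: dict


def locus_diversity(gm: GenotypeMatrix, group: str | list[str]) -> DiversitySummary:
    """Ho, unbiased He and F_W per locus, with per-fragment and global means.

    Every locus in the matrix is a population-level SNP, so group means are
    unweighted averages over all loci the group has data for (loci fixed
    within the group contribute zeros, as in the study's per-group tables);
    F_W is null where He = 0 and its mean runs over defined values. The SD
    is taken across loci and the confidence interval is the normal
    approximation mean +/- 1.96 SD / sqrt(loci) at alpha = 0.05.
    """
    members = gm.group_members(group)
    if not members:
        raise ValueError(f"empty group {group!r}")
    rows = []
    for locus in gm.locus_names:
        col = gm.genotypes.loc[members, locus].dropna()
        n = len(col)
        if n == 0:
            continue
        counts, _ = gm.allele_counts(locus, members)
        ho = float(np.mean([_locus_hetero(g) for g in col]))
        he = unbiased_he(counts, n)
        fw = (1.0 - ho / he) if he > 0 else np.nan
        rows.append(
            {
                "locus": locus,
                "fragment": gm.loci.loc[locus, "fragment"],
                "n": n,
                "Ho": ho,
                "He": he,
                "Fw": fw,
                "polymorphic": he > 0,
            }
        )
    per_locus = pd.DataFrame(rows).set_index("locus")

    def summarize(df: pd.DataFrame) -> dict:
        out = {}
        for stat in ("Ho", "He", "Fw"):
            vals = df[stat].dropna().to_numpy(float)
            if len(vals) == 0:
                out[stat], out[f"{stat}_sd"], out[f"{stat}_ci"] = 0.0, 0.0, 0.0
                continue
            out[stat] = float(np.mean(vals))
            out[f"{stat}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            out[f"{stat}_ci"] = 1.96 * out[f"{stat}_sd"] / np.sqrt(len(vals))
        out["n_polymorphic_loci"] = int(df["polymorphic"].sum())
        return out

    frag_rows = []
    for frag, sub in per_locus.groupby("fragment"):
        frag_rows.append({"fragment": frag, **summarize(sub)})
    return DiversitySummary(
        per_locus=per_locus,
        per_fragment=pd.DataFrame(frag_rows).set_index("fragment"),
        overall=summarize(per_locus),
    )


# ---------------------------------------------------------------------- F_ST
def _wc_components(
    gm: GenotypeMatrix, locus: str, pops: list[list[str]]
) -> tuple[float, float, float] | None:
    """Weir-Cockerham (1984) variance components (a, b, c) for one locus,
    summed over alleles; None when the locus is monomorphic across pops or
    data are insufficient."""
    r = len(pops)
    per_pop = []
    for members in pops:
        col = gm.genotypes.loc[members, locus].dropna()
        n_i = len(col)
        if n_i == 0:
            return None
        counts: dict[str, int] = {}
        het: dict[str, int] = {}
        for g in col:
            x, y = g.split("/")
            counts[x] = counts.get(x, 0) + 1
            counts[y] = counts.get(y, 0) + 1
            if x != y:
                het[x] = het.get(x, 0) + 1
                het[y] = het.get(y, 0) + 1
        per_pop.append((n_i, counts, het))
    alleles = sorted({a for _, c, _ in per_pop for a in c})
    if len(alleles) < 2:
        return None
    n = np.array([p[0] for p in per_pop], float)
    nbar = n.mean()
    if nbar <= 1:
        return None
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    a_sum = b_sum = c_sum = 0.0
    for allele in alleles:
        p = np.array([c.get(allele, 0) / (2 * ni) for ni, c, _ in per_pop])
        h = np.array([ht.get(allele, 0) / ni for ni, _, ht in per_pop])
        pbar = (n * p).sum() / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n * h).sum() / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


@dataclass
class FstResult:
    theta: float
    sd: float
    n_loci: int
    n_skipped_monomorphic: int
    per_locus: pd.Series


def pairwise_fst(
    gm: GenotypeMatrix, group_a: str | list[str], group_b: str | list[str]
) -> FstResult:
    """Multi-locus Weir-Cockerham theta between two groups.

    Loci are combined by the ratio-of-sums rule; the SD is taken across
    per-locus theta estimates. Loci monomorphic across both groups are
    skipped and counted.
    """
    pops = [gm.group_members(group_a), gm.group_members(group_b)]
    if not all(pops):
        raise ValueError("both groups must be non-empty")
    a_tot = bc_tot = 0.0
    per_locus = {}
    n_skipped = 0
    for locus in gm.locus_names:
        comp = _wc_components(gm, locus, pops)
        if comp is None:
            n_skipped += 1
            continue
        a, b, c = comp
        denom = a + b + c
        a_tot += a
        bc_tot += denom
        if denom != 0:
            per_locus[locus] = a / denom
    if not per_locus:
        raise ValueError("no shared polymorphic loci between groups")
    series = pd.Series(per_locus)
    return FstResult(
        theta=float(a_tot / bc_tot),
        sd=float(series.std(ddof=1)) if len(series) > 1 else 0.0,
        n_loci=len(series),
        n_skipped_monomorphic=n_skipped,
        per_locus=series,
    )


# ---------------------------------------------------------------------- G_ST
def gst_locus(gm: GenotypeMatrix, locus: str, focal_members: list[str],
              rest_members: list[str]) -> float:
    """Nei's G_ST = (H_T - H_S)/H_T for {focal, pooled rest} at one SNP.

    H_S is the sample-size-weighted mean within-group expected
    heterozygosity (1 - sum p^2); H_T uses pooled allele frequencies. NaN
    when H_T = 0.
    """
    def freqs(members):
        counts, n = gm.allele_counts(locus, members)
        total = sum(counts.values())
        return counts, total, n

    cf, tf, nf = freqs(focal_members)
    cr, tr, nr = freqs(rest_members)
    if nf == 0 or nr == 0:
        return np.nan
    hs_f = 1.0 - sum((c / tf) ** 2 for c in cf.values())
    hs_r = 1.0 - sum((c / tr) ** 2 for c in cr.values())
    hs = (nf * hs_f + nr * hs_r) / (nf + nr)
    alleles = set(cf) | set(cr)
    # pooled frequencies weighted by sample size
    pooled = {
        a: (nf * cf.get(a, 0) / tf + nr * cr.get(a, 0) / tr) / (nf + nr)
        for a in alleles
    }
    ht = 1.0 - sum(p**2 for p in pooled.values())
    if ht <= 0:
        return np.nan
    return (ht - hs) / ht


def gst_scan(gm: GenotypeMatrix, focal_group: str | list[str]) -> pd.Series:
    """Per-SNP G_ST of the focal group against all other accessions pooled."""
    focal = gm.group_members(focal_group)
    rest = [a for a in gm.accessions if a not in set(focal)]
    if not focal or not rest:
        raise ValueError("focal and complement groups must be non-empty")
    return pd.Series(
        {loc: gst_locus(gm, loc, focal, rest) for loc in gm.locus_names},
        name="Gst",
    )


# ------------------------------------------------------- simple matching
def simple_matching_dissimilarity(
    items: pd.DataFrame, mode: str = "haplotypic"
) -> pd.DataFrame:
    """Simple-matching dissimilarity matrix over shared loci.

    ``items``: rows = haplotypes or accessions, columns = loci. Haplotypic
    mode entries are single alleles; d = mismatching loci / compared loci.
    Genotypic mode entries are "A/G" pairs; per-locus similarity counts
    shared alleles with multiplicity (0, 0.5 or 1) and d = 1 - mean
    similarity. Missing entries are excluded pairwise; a pair with zero
    compared loci gets NaN.
    """
    if mode not in ("haplotypic", "genotypic"):
        raise ValueError(f"unknown mode {mode!r}")
    names = list(items.index)
    d = pd.DataFrame(0.0, index=names, columns=names)
    vals = items.to_numpy(object)
    for i, j in itertools.combinations(range(len(names)), 2):
        sims = []
        for a, b in zip(vals[i], vals[j]):
            if pd.isna(a) or pd.isna(b):
                continue
            if mode == "haplotypic":
                sims.append(1.0 if a == b else 0.0)
            else:
                sims.append(_genotype_similarity(a, b))
        if not sims:
            d.iloc[i, j] = d.iloc[j, i] = np.nan
        else:
            val = 1.0 - float(np.mean(sims))
            d.iloc[i, j] = d.iloc[j, i] = val
    return d


def _genotype_similarity(a: str, b: str) -> float:
    """Shared alleles counting multiplicity, halved: AA~AA=1, AA~AT=0.5."""
    xa = sorted(a.split("/"))
    xb = sorted(b.split("/"))
    shared = 0
    pool = list(xb)
    for allele in xa:
        if allele in pool:
            pool.remove(allele)
            shared += 1
    return shared / 2.0


# ----------------------------------------------------------- SNP densities
def snp_density_by_region(
    variants: pd.DataFrame, regions: pd.DataFrame
) -> pd.DataFrame:
    """SNP/kb per fragment x region plus pooled totals (2 decimals).

    ``variants``: columns fragment, position, kind, region (one row per
    population-level SNP locus; indels excluded from densities).
    ``regions``: columns fragment, region, start, end (1-based inclusive).
    """
    if (regions["end"] < regions["start"]).any():
        raise ValueError("zero or negative length region")
    snps = variants[variants["kind"] == "SNP"]
    rows = []
    for (frag, region), sub in regions.groupby(["fragment", "region"]):
        length = int((sub["end"] - sub["start"] + 1).sum())
        if length <= 0:
            raise ValueError(f"zero-length region {region} on {frag}")
        count = int(
            ((snps["fragment"] == frag) & (snps["region"] == region)).sum()
        )
        rows.append(
            {
                "fragment": frag,
                "region": region,
                "length_bp": length,
                "n_snps": count,
                "snp_per_kb": snp_density(count, length),
            }
        )
    table = pd.DataFrame(rows)
    totals = []
    for region, sub in table.groupby("region"):
        length = int(sub["length_bp"].sum())
        count = int(sub["n_snps"].sum())
        totals.append(
            {
                "fragment": "TOTAL",
                "region": region,
                "length_bp": length,
                "n_snps": count,
                "snp_per_kb": snp_density(count, length),
            }
        )
    return pd.concat([table, pd.DataFrame(totals)], ignore_index=True)


def triallelic_percent(n_triallelic: int, n_loci: int) -> int:
    """Share of SNP loci with three alleles, nearest whole percent."""
    if n_loci <= 0:
        raise ValueError("n_loci must be positive")
    return int(round(100.0 * n_triallelic / n_loci))


def snp_density(n_snps: int, length_bp: int) -> float:
    """SNPs per kilobase, reported to 2 decimals."""
    if length_bp <= 0:
        raise ValueError("length must be positive")
    return round(1000.0 * n_snps / length_bp, 2)


# ------------------------------------------------------------------------ LD
def pairwise_ld(
    haplotypes: pd.DataFrame,
    locus_a: str,
    locus_b: str,
    n_permutations: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Haplotype-based r^2 between two loci with a permutation p-value.

    ``haplotypes``: rows = phased haplotypes, columns = loci, single-allele
    entries. Multi-allelic loci are handled by taking the maximum r^2 over
    allele dichotomizations. The p-value permutes one locus's labels.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    sub = haplotypes[[locus_a, locus_b]].dropna()
    a = sub[locus_a].to_numpy(object)
    b = sub[locus_b].to_numpy(object)
    r2 = _r2_max(a, b)
    if np.isnan(r2):
        return np.nan, np.nan
    count = 0
    for _ in range(n_permutations):
        if _r2_max(a, rng.permutation(b)) >= r2 - 1e-12:
            count += 1
    return r2, (count + 1) / (n_permutations + 1)


def _r2_max(a: np.ndarray, b: np.ndarray) -> float:
    al_a = sorted(set(a))
    al_b = sorted(set(b))
    if len(al_a) < 2 or len(al_b) < 2:
        return np.nan
    best = 0.0
    n = len(a)
    for x in al_a:
        pa = np.mean(a == x)
        for y in al_b:
            pb = np.mean(b == y)
            pab = np.mean((a == x) & (b == y))
            denom = pa * (1 - pa) * pb * (1 - pb)
            if denom <= 0:
                continue
            d = pab - pa * pb
            best = max(best, d * d / denom)
    return best


# ------------------------------------------------------------ rare alleles
def rare_allele_scan(
    gm: GenotypeMatrix, basal_groups: list[str]
) -> pd.DataFrame:
    """Alleles absent from every basal-group accession, with their carriers.

    These are the hybrid-private alleles the diversity tables are computed
    without; the returned frame feeds :meth:`GenotypeMatrix.mask_alleles`.
    """
    basal = set(gm.group_members(basal_groups))
    rows = []
    for locus in gm.locus_names:
        basal_alleles = set(gm.alleles_at(locus, sorted(basal)))
        col = gm.genotypes[locus]
        carriers: dict[str, list[str]] = {}
        for acc in gm.accessions:
            if acc in basal:
                continue
            g = col[acc]
            if not isinstance(g, str):
                continue
            for allele in g.split("/"):
                if allele not in basal_alleles:
                    carriers.setdefault(allele, []).append(acc)
        for allele, who in sorted(carriers.items()):
            rows.append({"locus": locus, "allele": allele, "carriers": ",".join(who)})
    return pd.DataFrame(rows, columns=["locus", "allele", "carriers"])
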