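"""Neighbor-joining trees, haplotype cataloguing and taxon assignment.

Each fragment's deduplicated haplotypes are placed on a neighbor-joining
tree (for audit) and assigned to an ancestral taxon by a nearest-panel rule
with an explicit margin: a haplotype joins the taxon whose reference panel
it is closest to (mean simple-matching dissimilarity) provided the
second-nearest panel is at least ``delta`` farther and the nearest distance
does not exceed ``cap``; otherwise it is "indeterminate". Panels of basal
accessions are then iteratively purged of haplotypes that assign away from
their carrier's nominal taxon, which is how fragment-level introgressions
are discovered.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

INDETERMINATE = "indeterminate"


# ------------------------------------------------------------------------ NJ
@dataclass
class TreeResult:
    newick: str
    leaf_names: list[str]

    @property
    def tree(self) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.newick, schema="newick")


class _Node:
    __slots__ = ("name", "children", "lengths")

    def __init__(self, name, children=None, lengths=None):
        self.name = name
        self.children = children or []
        self.lengths = lengths or []

    def newick(self) -> str:
        if not self.children:
            return self.name
        parts = [
            f"{c.newick()}:{l:.10g}" for c, l in zip(self.children, self.lengths)
        ]
        return "(" + ",".join(parts) + ")"


def neighbor_joining(d: pd.DataFrame) -> TreeResult:
    """Classic agglomerative neighbor joining (Saitou-Nei Q criterion).

    Deterministic: Q ties are broken by the lexicographically smallest
    sorted pair of node names. Negative branch lengths are clamped to zero
    with the deficit shifted onto the sister edge, preserving the joined
    pair's path length.
    """
    names = list(d.index)
    if len(names) < 3:
        raise ValueError("neighbor joining requires >= 3 items")
    arr = d.to_numpy(float)
    if np.isnan(arr).any():
        raise ValueError("distance matrix contains missing cells")
    dist: dict[frozenset, float] = {}
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            dist[frozenset((a, names[j]))] = float(arr[i, j])
    nodes: dict[str, _Node] = {n: _Node(n) for n in names}
    active = list(names)
    counter = 0

    def dget(a: str, b: str) -> float:
        return dist[frozenset((a, b))]

    while len(active) > 3:
        n = len(active)
        r = {a: sum(dget(a, b) for b in active if b != a) for a in active}
        best_q = np.inf
        best_pair: tuple[str, str] | None = None
        for a, b in itertools.combinations(sorted(active), 2):
            q = (n - 2) * dget(a, b) - r[a] - r[b]
            if q < best_q - 1e-12:
                best_q, best_pair = q, (a, b)
        a, b = best_pair
        dab = dget(a, b)
        la = dab / 2.0 + (r[a] - r[b]) / (2.0 * (n - 2))
        lb = dab - la
        la, lb = _clamp_pair(la, lb)
        new_name = f"__internal{counter}"
        counter += 1
        nodes[new_name] = _Node(new_name, [nodes[a], nodes[b]], [la, lb])
        for c in active:
            if c in (a, b):
                continue
            dist[frozenset((new_name, c))] = (dget(a, c) + dget(b, c) - dab) / 2.0
        active = [c for c in active if c not in (a, b)] + [new_name]

    # final unrooted trifurcation solved by the three-point formulas
    a, b, c = sorted(active)
    la = (dget(a, b) + dget(a, c) - dget(b, c)) / 2.0
    lb = dget(a, b) - la
    lc = dget(a, c) - la
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    root = _Node(
        "__root", [nodes[a], nodes[b], nodes[c]], [la, lb, lc]
    )
    return TreeResult(newick=root.newick() + ";", leaf_names=names)


def _clamp_pair(la: float, lb: float) -> tuple[float, float]:
    if la < 0:
        lb += la
        la = 0.0
    if lb < 0:
        la = max(la + lb, 0.0)
        lb = 0.0
    return la, lb


# ------------------------------------------------------------------- catalog
@dataclass
class CatalogEntry:
    fragment: str
    alleles: tuple[str, ...]  # over the fragment's population variant loci
    carriers: list[tuple[str, int]] = field(default_factory=list)
    name: str = ""
    assignment: str = ""
    margin: float = np.nan
    nearest: str = ""
    distances: dict[str, float] = field(default_factory=dict)


@dataclass
class HaplotypeCatalog:
    """Deduplicated haplotypes per fragment with taxon assignments."""

    entries: dict[str, list[CatalogEntry]]  # fragment -> entries
    positions: dict[str, list[int]]  # fragment -> 1-based variant positions

    def entry_of(self, accession: str, fragment: str, hap: int) -> CatalogEntry | None:
        for e in self.entries.get(fragment, []):
            if (accession, hap) in e.carriers:
                return e
        return None

    def table(self) -> pd.DataFrame:
        rows = []
        for frag, entries in self.entries.items():
            for e in entries:
                rows.append(
                    {
                        "fragment": frag,
                        "name": e.name,
                        "alleles": "".join(e.alleles),
                        "assignment": e.assignment,
                        "margin": e.margin,
                        "carriers": ",".join(f"{a}|h{h + 1}" for a, h in e.carriers),
                    }
                )
        return pd.DataFrame(
            rows, columns=["fragment", "name", "alleles", "assignment", "margin", "carriers"]
        )


def population_variant_positions(phased: dict, fragment: str) -> list[int]:
    """Sorted union of called variant positions (1-based) on a fragment."""
    positions: set[int] = set()
    for (acc, frag), pg in phased.items():
        if frag != fragment or pg.status != "called":
            continue
        positions.update(v.position for v in pg.variants)
    return sorted(positions)


def build_catalog(phased: dict, panel) -> HaplotypeCatalog:
    """Deduplicate called haplotypes per fragment.

    ``phased`` maps (accession, fragment) -> PhasedGenotype. A homozygous
    amplicon contributes the same entry as both carrier haplotypes.
    """
    entries: dict[str, list[CatalogEntry]] = {}
    positions: dict[str, list[int]] = {}
    for fragment in panel.fragment_names:
        pos = population_variant_positions(phased, fragment)
        positions[fragment] = pos
        idx = np.array(pos, dtype=int) - 1
        by_alleles: dict[tuple[str, ...], CatalogEntry] = {}
        for (acc, frag), pg in phased.items():
            if frag != fragment or pg.status != "called":
                continue
            haps = pg.haplotypes if len(pg.haplotypes) == 2 else pg.haplotypes * 2
            for hap_i, hap in enumerate(haps):
                from . import seqs

                alleles = tuple(seqs.decode(hap[idx])) if len(idx) else ()
                entry = by_alleles.get(alleles)
                if entry is None:
                    entry = CatalogEntry(fragment=fragment, alleles=alleles)
                    by_alleles[alleles] = entry
                entry.carriers.append((acc, hap_i))
        entries[fragment] = list(by_alleles.values())
    return HaplotypeCatalog(entries=entries, positions=positions)


# ---------------------------------------------------------------- assignment
def _dissim(a: tuple[str, ...], b: tuple[str, ...]) -> float:
    if len(a) != len(b):
        raise ValueError("haplotypes compared over different locus sets")
    if not a:
        return 0.0
    return sum(x != y for x, y in zip(a, b)) / len(a)


def _mean_panel_distance(hap: tuple[str, ...], panel_haps: list[tuple[str, ...]]) -> float:
    return float(np.mean([_dissim(hap, p) for p in panel_haps]))


def panel_thresholds(
    panels: dict[str, list[tuple[str, ...]]]
) -> tuple[float, float]:
    """Fragment-level defaults for the assignment rule.

    delta = half the pooled mean within-panel dissimilarity; cap = midpoint
    of the mean within-panel and mean between-panel dissimilarities.
    """
    intra = [
        _dissim(a, b)
        for haps in panels.values()
        for a, b in itertools.combinations(haps, 2)
    ]
    inter = [
        _dissim(a, b)
        for (ta, tb) in itertools.combinations(sorted(panels), 2)
        for a in panels[ta]
        for b in panels[tb]
    ]
    mean_intra = float(np.mean(intra)) if intra else 0.0
    mean_inter = float(np.mean(inter)) if inter else 1.0
    return mean_intra / 2.0, (mean_intra + mean_inter) / 2.0


def assign_haplotype(
    hap: tuple[str, ...],
    panels: dict[str, list[tuple[str, ...]]],
    delta: float | None = None,
    cap: float | None = None,
) -> tuple[str, float, str, dict[str, float]]:
    """Nearest-panel-with-margin assignment.

    Returns (assignment, margin, nearest taxon, per-taxon distances). Empty
    panels make that taxon unavailable. Assignment requires a strictly
    positive margin of at least ``delta`` and a nearest distance <= cap.
    """
    usable = {t: h for t, h in panels.items() if h}
    if not usable:
        raise ValueError("no non-empty reference panel")
    if delta is None or cap is None:
        d0, c0 = panel_thresholds(usable)
        delta = d0 if delta is None else delta
        cap = c0 if cap is None else cap
    distances = {t: _mean_panel_distance(hap, h) for t, h in usable.items()}
    ordered = sorted(distances.items(), key=lambda kv: (kv[1], kv[0]))
    nearest_taxon, nearest = ordered[0]
    second = ordered[1][1] if len(ordered) > 1 else np.inf
    margin = second - nearest
    if margin > 0 and margin >= delta and nearest <= cap:
        return nearest_taxon, margin, nearest_taxon, distances
    return INDETERMINATE, margin, nearest_taxon, distances


def assign_catalog(
    catalog: HaplotypeCatalog,
    panels: dict[str, dict[str, list[tuple[str, ...]]]],
    delta: float | None = None,
    cap: float | None = None,
    taxon_short: dict[str, str] | None = None,
) -> None:
    """Assign every catalog entry in place and give figure-style short names
    (taxon prefix + discovery-order index, e.g. re1, ma2; x1 for
    indeterminate)."""
    for fragment, entries in catalog.entries.items():
        frag_panels = {t: p.get(fragment, []) for t, p in panels.items()}
        frag_panels = {t: h for t, h in frag_panels.items() if h}
        counters: dict[str, int] = {}
        for e in entries:
            if not frag_panels:
                e.assignment, e.margin, e.nearest = INDETERMINATE, np.nan, ""
            else:
                e.assignment, e.margin, e.nearest, e.distances = assign_haplotype(
                    e.alleles, frag_panels, delta, cap
                )
            short = short_label(e.assignment, taxon_short)
            counters[short] = counters.get(short, 0) + 1
            e.name = f"{short}{counters[short]}"


def short_label(taxon: str, taxon_short: dict[str, str] | None = None) -> str:
    if taxon_short and taxon in taxon_short:
        return taxon_short[taxon]
    if taxon == INDETERMINATE:
        return "x"
    return taxon[:2]


# ---------------------------------------------------------------- refinement
@dataclass
class RefinementResult:
    panels: dict[str, dict[str, list[tuple[str, ...]]]]
    introgressions: pd.DataFrame
    n_iterations: int
    initial_density: pd.DataFrame
    revised_density: pd.DataFrame


class PanelEmptiedError(RuntimeError):
    def __init__(self, taxon: str, fragment: str, report: pd.DataFrame):
        super().__init__(
            f"reference panel for {taxon!r} on {fragment!r} emptied during "
            "refinement (degenerate configuration)"
        )
        self.report = report


def initial_panels(
    catalog: HaplotypeCatalog,
    nominal_taxon: pd.Series,
    basal_accessions: dict[str, list[str]],
) -> dict[str, dict[str, list[tuple[str, ...]]]]:
    """taxon -> fragment -> haplotype allele tuples of nominal basal carriers.

    Carrier-level: each basal accession contributes both of its haplotypes,
    so pool composition reflects variety frequencies.
    """
    panels: dict[str, dict[str, list[tuple[str, ...]]]] = {
        t: {f: [] for f in catalog.entries} for t in basal_accessions
    }
    members = {
        acc: taxon for taxon, accs in basal_accessions.items() for acc in accs
    }
    for fragment, entries in catalog.entries.items():
        for e in entries:
            for acc, _hap in e.carriers:
                taxon = members.get(acc)
                if taxon is not None:
                    panels[taxon][fragment].append(e.alleles)
    return panels


def refine_reference_panels(
    catalog: HaplotypeCatalog,
    basal_accessions: dict[str, list[str]],
    fragment_lengths: dict[str, int],
    delta: float | None = None,
    cap: float | None = None,
    max_iter: int = 10,
) -> RefinementResult:
    """Iteratively purge cross-taxon (introgressed) haplotypes from the
    basal reference panels until a fixed point.

    A basal accession's haplotype is purged from its nominal panel when it
    assigns to a different taxon, or is indeterminate with a cross-taxon
    nearest panel. The purged set grows monotonically; termination within
    ``max_iter`` is guaranteed.
    """
    members = {
        acc: taxon for taxon, accs in basal_accessions.items() for acc in accs
    }
    # carrier-level records: (fragment, accession, hap, alleles)
    records = [
        (frag, acc, hap, e.alleles)
        for frag, entries in catalog.entries.items()
        for e in entries
        for acc, hap in e.carriers
        if acc in members
    ]
    purged: set[tuple[str, str, int]] = set()
    intro_rows: list[dict] = []
    initial = _panels_from_records(records, members, purged, basal_accessions)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        panels = _panels_from_records(records, members, purged, basal_accessions)
        new_purges = 0
        for frag, acc, hap, alleles in records:
            key = (frag, acc, hap)
            if key in purged:
                continue
            frag_panels = {
                t: p[frag] for t, p in panels.items() if p.get(frag)
            }
            if not frag_panels:
                continue
            assignment, margin, nearest, _ = assign_haplotype(
                alleles, frag_panels, delta, cap
            )
            nominal = members[acc]
            cross = (
                assignment not in (nominal, INDETERMINATE)
                or (assignment == INDETERMINATE and nearest != nominal)
            )
            if cross:
                purged.add(key)
                new_purges += 1
                intro_rows.append(
                    {
                        "accession": acc,
                        "fragment": frag,
                        "haplotype": hap,
                        "nominal_taxon": nominal,
                        "assigned": assignment,
                        "nearest": nearest,
                        "iteration": n_iter,
                    }
                )
        if new_purges == 0:
            break
    report = pd.DataFrame(
        intro_rows,
        columns=[
            "accession", "fragment", "haplotype", "nominal_taxon",
            "assigned", "nearest", "iteration",
        ],
    )
    final = _panels_from_records(records, members, purged, basal_accessions)
    for taxon, per_frag in final.items():
        for frag, haps in per_frag.items():
            if not haps and initial[taxon][frag]:
                raise PanelEmptiedError(taxon, frag, report)
    return RefinementResult(
        panels=final,
        introgressions=report,
        n_iterations=n_iter,
        initial_density=panel_density_table(initial, fragment_lengths),
        revised_density=panel_density_table(final, fragment_lengths),
    )


def _panels_from_records(records, members, purged, basal_accessions):
    panels: dict[str, dict[str, list[tuple[str, ...]]]] = {
        t: {} for t in basal_accessions
    }
    for frag, acc, hap, alleles in records:
        if (frag, acc, hap) in purged:
            continue
        panels[members[acc]].setdefault(frag, []).append(alleles)
    return panels


def panel_density_table(
    panels: dict[str, dict[str, list[tuple[str, ...]]]],
    fragment_lengths: dict[str, int],
) -> pd.DataFrame:
    """Mean pairwise SNP/kb within and between taxon panels.

    Pairwise haplotype differences (over called variant loci) are summed
    per fragment and divided by the total surveyed length, mirroring the
    intra/inter varietal-group dissimilarity tables.
    """
    taxa = sorted(panels)
    total_kb = sum(fragment_lengths.values()) / 1000.0
    out = pd.DataFrame(np.nan, index=taxa, columns=taxa)
    for i, a in enumerate(taxa):
        for b in taxa[i:]:
            per_frag = []
            for frag in fragment_lengths:
                ha = panels[a].get(frag, [])
                hb = panels[b].get(frag, [])
                if a == b:
                    pairs = [
                        sum(x != y for x, y in zip(p, q))
                        for p, q in itertools.combinations(ha, 2)
                    ]
                else:
                    pairs = [
                        sum(x != y for x, y in zip(p, q))
                        for p in ha
                        for q in hb
                    ]
                if pairs:
                    per_frag.append(float(np.mean(pairs)))
                else:
                    per_frag.append(0.0)
            out.loc[a, b] = out.loc[b, a] = round(sum(per_frag) / total_kb, 2)
    return out
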