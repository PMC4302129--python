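"""Synthetic-study generator: divergence targeting, cohort designs, reads."""

import numpy as np
import pytest

from haplopaint import seqs, simulate

from conftest import small_cohort_config


def _flat_config(**overrides):
    taxa = ("alpha", "beta")
    base = dict(
        n_fragments=4,
        fragment_length_bp=300,
        taxa=taxa,
        inter_taxon_divergence=np.zeros((2, 2)),
        intra_taxon_diversity={t: 0.0 for t in taxa},
        haplotypes_per_taxon=3,
        cohort_design=[simulate.pure_design("a1", "alpha", 4)],
        seed=5,
    )
    base.update(overrides)
    return simulate.SimulationConfig(**base)


class TestPanel:
    def test_zero_divergence_gives_identical_consensuses(self):
        cfg = _flat_config()
        panel, pools = simulate.simulate_panel(cfg)
        for frag in panel.fragment_names:
            assert np.array_equal(
                pools.consensus["alpha"][frag], pools.consensus["beta"][frag]
            )

    def test_realized_densities_hit_requested_rates(self):
        # inter 12 SNP/kb, intra 2 SNP/kb over 16 x 500 bp, 10 haplotypes/taxon
        m = np.full((4, 4), 12.0)
        np.fill_diagonal(m, 0.0)
        cfg = simulate.SimulationConfig(
            inter_taxon_divergence=m,
            intra_taxon_diversity={t: 2.0 for t in simulate.DEFAULT_TAXA},
            seed=3,
        )
        _, pools = simulate.simulate_panel(cfg)
        realized = simulate.realized_divergence(pools)
        inter = realized[realized["kind"] == "inter"]["snp_per_kb"]
        intra = realized[realized["kind"] == "intra"]["snp_per_kb"]
        assert (abs(inter - 12.0) / 12.0 <= 0.15).all()
        assert (abs(intra - 2.0) / 2.0 <= 0.30).all()

    def test_same_seed_reproduces_panel_exactly(self):
        cfg = small_cohort_config()
        p1, h1 = simulate.simulate_panel(cfg)
        p2, h2 = simulate.simulate_panel(cfg)
        for frag in p1.fragment_names:
            assert p1[frag].reference_str == p2[frag].reference_str
            for t in cfg.taxa:
                assert np.array_equal(h1.haplotypes[t][frag], h2.haplotypes[t][frag])

    def test_unreachable_divergence_rejected(self):
        m = np.full((2, 2), 1500.0)
        np.fill_diagonal(m, 0.0)
        with pytest.raises(ValueError, match="exceeds fragment capacity"):
            _flat_config(inter_taxon_divergence=m)

    def test_regions_annotated(self):
        cfg = small_cohort_config()
        panel, _ = simulate.simulate_panel(cfg)
        table = panel.regions_table()
        assert set(table["region"]) == {"exon", "intron"}
        frag = panel[panel.fragment_names[0]]
        assert frag.region_at(1) == "exon"
        assert frag.region_at(frag.length) == "intron"


class TestConfigValidation:
    def test_asymmetric_matrix_rejected(self):
        m = np.array([[0.0, 3.0], [5.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            _flat_config(inter_taxon_divergence=m)

    def test_rates_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="per_base_error_rate"):
            _flat_config(per_base_error_rate=1.5)

    def test_short_fragment_rejected(self):
        with pytest.raises(ValueError, match="fragment_length_bp"):
            _flat_config(fragment_length_bp=100)

    def test_unknown_taxon_in_design_rejected(self):
        with pytest.raises(ValueError, match="unknown\\s+taxon"):
            _flat_config(cohort_design=[simulate.pure_design("x", "gamma", 4)])

    def test_wrong_fragment_count_in_design_rejected(self):
        with pytest.raises(ValueError, match="fragments"):
            _flat_config(cohort_design=[simulate.pure_design("x", "alpha", 7)])

    def test_empty_cohort_design_rejected(self):
        cfg = _flat_config()
        cfg.cohort_design = []
        panel, pools = simulate.simulate_panel(cfg)
        with pytest.raises(ValueError, match="zero accessions"):
            simulate.simulate_cohort(cfg, panel, pools)


class TestCohort:
    def test_truth_classes_follow_designs(self):
        n = 8
        design = [
            simulate.pure_design("pureA", "reticulata", n),
            simulate.f1_design("f1ab", "reticulata", "maxima", n, nominal="hybrid"),
            simulate.introgressed_design(
                "intro", "reticulata", "maxima", {3: "hom", 4: "hom", 5: "hom"}, n
            ),
            simulate.backcross_design(
                "bc", "reticulata", "maxima", [2, 6], n, nominal="hybrid"
            ),
        ]
        cfg = small_cohort_config(n_fragments=n, cohort_design=design)
        panel, pools = simulate.simulate_panel(cfg)
        cohort, truth = simulate.simulate_cohort(cfg, panel, pools)
        frags = panel.fragment_names
        for i, frag in enumerate(frags):
            assert truth.genotype_class("pureA", frag) == {"reticulata"}
            assert truth.genotype_class("f1ab", frag) == {"reticulata", "maxima"}
            expected = {"maxima"} if i in (3, 4, 5) else {"reticulata"}
            assert truth.genotype_class("intro", frag) == expected
            bc_expected = (
                {"reticulata", "maxima"} if 2 <= i < 6 else {"reticulata"}
            )
            assert truth.genotype_class("bc", frag) == bc_expected

    def test_pure_haplotypes_drawn_from_own_pool(self):
        cfg = small_cohort_config()
        panel, pools = simulate.simulate_panel(cfg)
        cohort, truth = simulate.simulate_cohort(cfg, panel, pools)
        for frag in panel.fragment_names:
            h1, h2 = cohort["reA"].haplotypes[frag]
            pool_rows = [tuple(h) for h in pools.pool("reticulata", frag)]
            assert tuple(h1) in pool_rows and tuple(h2) in pool_rows

    def test_offspring_inherits_one_haplotype_from_each_parent(self):
        cfg = small_cohort_config()
        panel, pools = simulate.simulate_panel(cfg)
        cohort, truth = simulate.simulate_cohort(cfg, panel, pools)
        for frag in panel.fragment_names:
            child = {tuple(h) for h in cohort["child"].haplotypes[frag]}
            pa = {tuple(h) for h in cohort["reA"].haplotypes[frag]}
            pb = {tuple(h) for h in cohort["maA"].haplotypes[frag]}
            assert any(c in pa for c in child) and any(c in pb for c in child)

    def test_default_cohort_shape(self):
        design = simulate.default_cohort_design(16)
        assert len(design) == 48
        nominal = [d.nominal_taxon for d in design]
        assert nominal.count("reticulata") == 14
        assert nominal.count("maxima") == 10
        assert nominal.count("medica") == 6
        assert nominal.count("micrantha") == 1
        assert sum(d.private_alleles for d in design) == 19
        introgressed = [
            d.name
            for d in design
            if d.nominal_taxon == "reticulata"
            and any(
                o.taxon == "maxima" for pair in d.origins for o in pair
            )
        ]
        assert len(introgressed) == 10


class TestReads:
    def test_error_free_reads_equal_their_source_haplotype(self, small_run):
        (panel, pools, cohort, truth, run), cfg0 = small_run
        cfg = small_cohort_config(per_base_error_rate=0.0)
        panel, pools = simulate.simulate_panel(cfg)
        cohort, truth = simulate.simulate_cohort(cfg, panel, pools)
        run = simulate.simulate_reads(cohort, cfg, truth=truth)
        cut = cfg.barcode_length + cfg.primer_length
        by_id = {r["read_id"]: r for r in truth.reads}
        for rid, seq, _q in run.reads[:500]:
            r = by_id[rid]
            hap = truth.haplotypes[(r["accession"], r["fragment"])][r["hap_index"]]
            assert seq[cut:] == seqs.decode(hap, drop_gaps=True)

    def test_constant_coverage_gives_exact_depth_everywhere(self, small_run):
        (panel, pools, cohort, truth, run), cfg = small_run
        assert set(truth.coverage.values()) == {60}
        assert len(truth.coverage) == len(cohort.names) * len(panel)

    def test_planted_substitutions_within_binomial_bounds(self):
        from scipy.stats import binom

        cfg = small_cohort_config(per_base_error_rate=0.01, seed=23)
        panel, pools = simulate.simulate_panel(cfg)
        cohort, truth = simulate.simulate_cohort(cfg, panel, pools)
        simulate.simulate_reads(cohort, cfg, truth=truth)
        n_bases = sum(
            panel[r["fragment"]].length for r in truth.reads
        )
        planted = sum(r["n_errors"] for r in truth.reads)
        assert n_bases >= 10_000
        lo = binom.ppf(0.005, n_bases, 0.01)
        hi = binom.ppf(0.995, n_bases, 0.01)
        assert lo <= planted <= hi

    def test_barcodes_sheet_complete_and_separated(self, small_run):
        (panel, pools, cohort, truth, run), cfg = small_run
        sheet = run.sample_sheet
        barcodes = sheet["barcode"].tolist()
        for i, a in enumerate(barcodes):
            for b in barcodes[i + 1 :]:
                assert sum(x != y for x, y in zip(a, b)) >= 3
        valid = set(barcodes)
        for _rid, seq, _q in run.reads:
            assert seq[: cfg.barcode_length] in valid

    def test_seeded_run_is_byte_identical(self):
        cfg = small_cohort_config(seed=9)
        runs = []
        for _ in range(2):
            *_, run = simulate.simulate_run(small_cohort_config(seed=9))
            runs.append(run.reads)
        assert runs[0] == runs[1]
        *_, other = simulate.simulate_run(small_cohort_config(seed=10))
        assert other.reads != runs[0]

    def test_short_read_fraction_plants_junk(self):
        cfg = small_cohort_config(short_read_fraction=0.11)
        *_, truth, run = simulate.simulate_run(cfg)
        n_good = len(run.reads) - run.n_short_reads
        assert run.n_short_reads == int(round(0.11 / 0.89 * n_good))

    def test_homopolymer_indels_change_read_lengths(self):
        cfg = small_cohort_config(homopolymer_indel_rate=0.5, seed=2)
        panel, pools = simulate.simulate_panel(cfg)
        cohort, truth = simulate.simulate_cohort(cfg, panel, pools)
        run = simulate.simulate_reads(cohort, cfg, truth=truth)
        cut = cfg.barcode_length + cfg.primer_length
        lengths = {len(seq) - cut for _rid, seq, _q in run.reads}
        assert len(lengths) > 1  # insertions and deletions occurred

    def test_exonic_indels_plant_gaps_in_pools(self):
        cfg = small_cohort_config(exonic_indel_fraction=0.02, seed=5)
        panel, pools = simulate.simulate_panel(cfg)
        n_gaps = sum(
            int((pools.haplotypes[t][f] == seqs.GAP).sum())
            for t in cfg.taxa
            for f in panel.fragment_names
        )
        assert n_gaps > 0

    def test_coverage_below_threshold_fraction_is_configurable(self):
        rng = np.random.default_rng(0)
        skewed = simulate.CoverageModel(
            "lognormal", round_means=(75.0,), fragment_sigma=0.55, sigma=0.30
        )
        deep = simulate.CoverageModel(
            "lognormal", round_means=(500.0,), fragment_sigma=0.1, sigma=0.1
        )
        d_skew, _ = skewed.draw(48, 16, rng)
        d_deep, _ = deep.draw(48, 16, rng)
        assert (d_skew < 50).mean() > 0.20
        assert (d_deep < 50).mean() == 0.0
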