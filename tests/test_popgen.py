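"""Diversity/differentiation statistics against hand arithmetic and
first-principles oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from haplopaint import popgen
from haplopaint.popgen import GenotypeMatrix

import _oracles as oracle


def _gm(columns: dict, groups: dict, fragment="f1") -> GenotypeMatrix:
    gt = pd.DataFrame(columns)
    gt.index = list(groups)
    loci = pd.DataFrame(
        {
            "fragment": [fragment] * len(columns),
            "position": list(range(1, len(columns) + 1)),
            "region": ["exon"] * len(columns),
        },
        index=list(columns),
    )
    return GenotypeMatrix(gt, loci, pd.Series(groups))


class TestDiversity:
    def test_hand_worked_locus(self):
        # genotypes {AA, AT, TT, AT}: p=0.5, n=4, unbiased factor 8/7
        gm = _gm({"L": ["A/A", "A/T", "T/T", "A/T"]},
                 {f"a{i}": "G" for i in range(4)})
        div = popgen.locus_diversity(gm, "G")
        row = div.per_locus.iloc[0]
        assert row["Ho"] == pytest.approx(0.5)
        assert row["He"] == pytest.approx(8 / 7 * 0.5, abs=1e-12)
        assert row["Fw"] == pytest.approx(1 - 0.5 / (8 / 7 * 0.5), abs=1e-12)
        assert row["Fw"] == pytest.approx(0.125, abs=1e-4)

    def test_monomorphic_locus(self):
        gm = _gm({"L": ["A/A", "A/A"]}, {"a": "G", "b": "G"})
        row = popgen.locus_diversity(gm, "G").per_locus.iloc[0]
        assert row["Ho"] == 0.0 and row["He"] == 0.0 and np.isnan(row["Fw"])

    def test_single_heterozygote_unbiased_he_is_one(self):
        # n=1: factor 2/1 times (1 - 0.5) = 1; the lone-accession case
        gm = _gm({"L": ["A/T"]}, {"solo": "G"})
        row = popgen.locus_diversity(gm, "G").per_locus.iloc[0]
        assert row["Ho"] == 1.0
        assert row["He"] == pytest.approx(1.0, abs=1e-12)
        assert row["Fw"] == pytest.approx(0.0, abs=1e-12)

    def test_empty_group_rejected(self, toy_gm):
        with pytest.raises(ValueError, match="empty group"):
            popgen.locus_diversity(toy_gm, "nope")

    def test_matches_first_principles_on_toy_matrix(self, toy_gm):
        div = popgen.locus_diversity(toy_gm, "P")
        members = ["p1", "p2", "p3"]
        for locus in toy_gm.locus_names:
            gens = toy_gm.genotypes.loc[members, locus].dropna().tolist()
            if not gens:
                continue
            row = div.per_locus.loc[locus]
            assert row["Ho"] == pytest.approx(oracle.naive_ho(gens), abs=1e-12)
            assert row["He"] == pytest.approx(
                oracle.naive_unbiased_he(gens), abs=1e-12
            )


class TestFst:
    def test_complete_fixation_gives_theta_one(self):
        gm = _gm(
            {"L1": ["A/A", "A/A", "T/T", "T/T"],
             "L2": ["C/C", "C/C", "G/G", "G/G"]},
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        res = popgen.pairwise_fst(gm, "A", "B")
        assert res.theta == pytest.approx(1.0)
        assert res.n_loci == 2

    def test_panmictic_pool_gives_theta_near_zero(self):
        rng = np.random.default_rng(17)
        n, n_loci = 60, 100
        cols = {}
        for j in range(n_loci):
            p = rng.uniform(0.2, 0.8)
            draws = rng.random((n, 2)) < p
            cols[f"L{j}"] = ["/".join(sorted("AT"[int(x)] for x in d)) for d in draws]
        groups = {f"s{i}": ("A" if i < 30 else "B") for i in range(n)}
        res = popgen.pairwise_fst(_gm(cols, groups), "A", "B")
        assert abs(res.theta) < 0.05

    def test_matches_naive_transcription(self, toy_gm):
        res = popgen.pairwise_fst(toy_gm, "P", "Q")
        loci = []
        for locus in toy_gm.locus_names:
            pa = toy_gm.genotypes.loc[["p1", "p2", "p3"], locus].dropna().tolist()
            pb = toy_gm.genotypes.loc[["q1", "q2"], locus].dropna().tolist()
            loci.append((pa, pb))
        assert res.theta == pytest.approx(oracle.naive_theta(loci), abs=1e-12)

    def test_monomorphic_loci_skipped_and_counted(self, toy_gm):
        res = popgen.pairwise_fst(toy_gm, "P", "Q")
        assert res.n_skipped_monomorphic >= 1  # L4 is monomorphic
        assert "L4" not in res.per_locus.index

    def test_no_shared_polymorphic_loci_rejected(self):
        gm = _gm({"L": ["A/A", "A/A"]}, {"a": "A", "b": "B"})
        with pytest.raises(ValueError, match="polymorphic"):
            popgen.pairwise_fst(gm, "A", "B")


class TestGst:
    def test_fixed_difference_is_totally_discriminant(self):
        gm = _gm({"L": ["A/A", "A/A", "T/T", "T/T"]},
                 {"f1": "F", "f2": "F", "r1": "R", "r2": "R"})
        assert popgen.gst_scan(gm, "F")["L"] == pytest.approx(1.0)

    def test_identical_frequencies_give_zero(self):
        gm = _gm({"L": ["A/T", "A/T", "A/T", "A/T"]},
                 {"f1": "F", "f2": "F", "r1": "R", "r2": "R"})
        assert popgen.gst_scan(gm, "F")["L"] == pytest.approx(0.0)

    def test_hand_worked_example(self):
        # focal n=4 fixed 'a'; rest n=12 at p(a)=0.5:
        # H_S = (4*0 + 12*0.5)/16 = 0.375; pooled p(a) = 0.625,
        # H_T = 1 - (0.625^2 + 0.375^2) = 0.46875; G_ST = 0.09375/0.46875 = 0.2
        col = ["A/A"] * 4 + ["A/T"] * 6 + ["A/A"] * 3 + ["T/T"] * 3
        groups = {f"f{i}": "F" for i in range(4)}
        groups.update({f"r{i}": "R" for i in range(12)})
        gm = _gm({"L": col}, groups)
        # rest has 12 A and 12 T alleles -> p(a)=0.5 as in the worked case
        assert popgen.gst_scan(gm, "F")["L"] == pytest.approx(0.2, abs=1e-12)

    def test_matches_first_principles_and_relabeling_invariance(self, toy_gm):
        scan = popgen.gst_scan(toy_gm, "P")
        # allele bijection A->G, T->C, G->T applied to every genotype string
        relabeled = toy_gm.genotypes.replace(
            {"A/A": "G/G", "A/T": "G/C", "T/T": "C/C", "A/G": "G/T", "G/T": "T/C"}
        )
        gm2 = GenotypeMatrix(relabeled, toy_gm.loci.copy(), toy_gm.groups.copy())
        scan2 = popgen.gst_scan(gm2, "P")
        for locus in toy_gm.locus_names:
            focal = toy_gm.genotypes.loc[["p1", "p2", "p3"], locus].dropna().tolist()
            rest = toy_gm.genotypes.loc[["q1", "q2"], locus].dropna().tolist()
            expected = oracle.naive_gst(focal, rest)
            if np.isnan(expected):
                assert np.isnan(scan[locus])
            else:
                assert scan[locus] == pytest.approx(expected, abs=1e-12)
                assert scan2[locus] == pytest.approx(expected, abs=1e-12)


class TestSimpleMatching:
    def test_identity_and_direct_count(self):
        items = pd.DataFrame(
            [list("AAAAAAAAAA"), list("AAAAAAAAAA"), list("AAAAAAAATT")],
            index=["h1", "h2", "h3"],
        )
        d = popgen.simple_matching_dissimilarity(items, "haplotypic")
        assert d.loc["h1", "h2"] == 0.0
        assert d.loc["h1", "h3"] == pytest.approx(0.2)
        assert np.allclose(d.values, d.values.T)
        assert np.all(np.diag(d.values) == 0)

    def test_genotypic_shared_allele_counting(self):
        items = pd.DataFrame({"L": ["A/A", "A/T", "T/T"]}, index=["x", "y", "z"])
        d = popgen.simple_matching_dissimilarity(items, "genotypic")
        assert d.loc["x", "y"] == pytest.approx(0.5)
        assert d.loc["x", "z"] == pytest.approx(1.0)

    def test_pair_with_no_shared_loci_flagged_missing(self):
        items = pd.DataFrame(
            {"L1": ["A", np.nan], "L2": [np.nan, "T"]}, index=["a", "b"]
        )
        d = popgen.simple_matching_dissimilarity(items, "haplotypic")
        assert np.isnan(d.loc["a", "b"])

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.permutations(list(range(6))))
    def test_invariant_to_locus_order(self, perm):
        rng = np.random.default_rng(4)
        items = pd.DataFrame(
            rng.choice(list("ACGT"), size=(4, 6)),
            index=list("wxyz"),
            columns=[f"L{i}" for i in range(6)],
        )
        d1 = popgen.simple_matching_dissimilarity(items, "haplotypic")
        d2 = popgen.simple_matching_dissimilarity(
            items[[f"L{i}" for i in perm]], "haplotypic"
        )
        assert np.allclose(d1.values, d2.values)

    def test_matches_naive_oracle(self, toy_gm):
        d = popgen.simple_matching_dissimilarity(toy_gm.genotypes, "genotypic")
        for a, b in itertools.combinations(toy_gm.accessions, 2):
            expected = oracle.naive_simple_matching(
                toy_gm.genotypes.loc[a], toy_gm.genotypes.loc[b], "genotypic"
            )
            assert d.loc[a, b] == pytest.approx(expected, abs=1e-12)


class TestDensity:
    def test_totals_match_printed_arithmetic(self):
        assert popgen.snp_density(60, 1120) == 53.57
        assert popgen.snp_density(14, 352) == 39.77
        assert popgen.snp_density(0, 999) == 0.0

    def test_table_pools_lengths_and_counts(self):
        variants = pd.DataFrame(
            {
                "fragment": ["f1", "f1", "f2"],
                "position": [5, 20, 8],
                "kind": ["SNP", "indel", "SNP"],
                "region": ["exon", "exon", "intron"],
            }
        )
        regions = pd.DataFrame(
            {
                "fragment": ["f1", "f1", "f2"],
                "region": ["exon", "intron", "intron"],
                "start": [1, 201, 1],
                "end": [200, 300, 250],
            }
        )
        table = popgen.snp_density_by_region(variants, regions)
        f1_exon = table[(table.fragment == "f1") & (table.region == "exon")]
        assert f1_exon["n_snps"].iloc[0] == 1  # indel excluded
        total_intron = table[
            (table.fragment == "TOTAL") & (table.region == "intron")
        ].iloc[0]
        assert total_intron["length_bp"] == 350
        assert total_intron["snp_per_kb"] == popgen.snp_density(1, 350)

    def test_zero_length_region_rejected(self):
        regions = pd.DataFrame(
            {"fragment": ["f1"], "region": ["exon"], "start": [10], "end": [5]}
        )
        with pytest.raises(ValueError):
            popgen.snp_density_by_region(
                pd.DataFrame(columns=["fragment", "position", "kind", "region"]),
                regions,
            )

    def test_triallelic_share(self):
        assert popgen.triallelic_percent(7, 318) == 2


class TestLd:
    def test_perfect_co_inheritance(self):
        haps = pd.DataFrame(
            {"A": ["A"] * 20 + ["T"] * 20, "B": ["C"] * 20 + ["G"] * 20}
        )
        r2, p = popgen.pairwise_ld(haps, "A", "B", n_permutations=200)
        assert r2 == pytest.approx(1.0)
        assert p < 0.05

    def test_hand_counted_table(self):
        # haplotype counts 40/10/10/40 -> D = 0.4 - 0.25 = 0.15, r^2 = 0.36
        rows = (
            [("A", "C")] * 40 + [("A", "G")] * 10 + [("T", "C")] * 10 + [("T", "G")] * 40
        )
        haps = pd.DataFrame(rows, columns=["A", "B"])
        r2, _p = popgen.pairwise_ld(haps, "A", "B", n_permutations=100)
        assert r2 == pytest.approx(0.36, abs=1e-12)

    def test_monomorphic_locus_gives_null(self):
        haps = pd.DataFrame({"A": ["A"] * 10, "B": ["C"] * 5 + ["G"] * 5})
        r2, p = popgen.pairwise_ld(haps, "A", "B")
        assert np.isnan(r2) and np.isnan(p)

    def test_independent_loci_not_significant(self):
        rng = np.random.default_rng(23)
        haps = pd.DataFrame(
            {
                "A": rng.choice(["A", "T"], 200),
                "B": rng.choice(["C", "G"], 200),
            }
        )
        r2, p = popgen.pairwise_ld(
            haps, "A", "B", n_permutations=500, rng=np.random.default_rng(1)
        )
        assert r2 < 0.05
        assert p > 0.01


class TestRareAlleles:
    def test_hybrid_private_allele_flagged_basal_allele_not(self):
        gm = _gm(
            {"L1": ["A/A", "A/T", "A/G"], "L2": ["C/C", "C/C", "C/C"]},
            {"basal1": "B", "basal2": "B", "hyb": "H"},
        )
        flagged = popgen.rare_allele_scan(gm, ["B"])
        assert len(flagged) == 1
        assert flagged.iloc[0]["locus"] == "L1"
        assert flagged.iloc[0]["allele"] == "G"
        assert flagged.iloc[0]["carriers"] == "hyb"

    def test_masking_removes_carrier_genotypes(self):
        gm = _gm(
            {"L1": ["A/A", "A/T", "A/G"]},
            {"basal1": "B", "basal2": "B", "hyb": "H"},
        )
        flagged = popgen.rare_allele_scan(gm, ["B"])
        masked = gm.mask_alleles(flagged)
        assert pd.isna(masked.genotypes.loc["hyb", "L1"])
        assert masked.genotypes.loc["basal2", "L1"] == "A/T"

    def test_planted_private_alleles_recovered_exactly(self):
        # controlled cohort: every pool haplotype is carried by a basal
        # accession, so the only hybrid-novel alleles are the planted ones
        from haplopaint import pipeline, simulate

        n = 4
        design = []
        for taxon in simulate.DEFAULT_TAXA:
            for h in range(2):
                design.append(
                    simulate.AccessionSpec(
                        f"{taxon[:2]}{h}", taxon,
                        [(simulate.pool(taxon, 2 * h),
                          simulate.pool(taxon, 2 * h + 1))] * n,
                    )
                )
        hybrids = [
            ("hybA", 9), ("hybB", 4), ("hybC", 3),
            ("hybD", 1), ("hybE", 1), ("hybF", 1),
        ]
        for name, k in hybrids:
            spec = simulate.AccessionSpec(
                name, "hybrid",
                [(simulate.clone("re0"), simulate.clone("ma0"))] * n,
                private_alleles=k,
            )
            design.append(spec)
        cfg = simulate.SimulationConfig(
            n_fragments=n,
            fragment_length_bp=300,
            haplotypes_per_taxon=4,
            cohort_design=design,
            coverage_model=simulate.CoverageModel("constant", round_means=(60.0,)),
            short_read_fraction=0.0,
            per_base_error_rate=0.0,
            seed=31,
        )
        panel, pools, cohort, truth, run = simulate.simulate_run(cfg)
        assert len(truth.private_alleles) == 19
        phased = simulate.perfect_phased_calls(cohort, truth, panel)
        groups = pd.Series({a: cohort[a].nominal_taxon for a in cohort.names})
        gm, _ = pipeline.build_genotype_matrix(phased, panel, groups)
        flagged = popgen.rare_allele_scan(gm, list(simulate.DEFAULT_TAXA))
        assert len(flagged) == 19


class TestRangeInvariants:
    def test_statistics_stay_in_unit_ranges_on_simulated_matrix(self, toy_gm):
        div = popgen.locus_diversity(toy_gm, ["P", "Q"])
        assert ((div.per_locus["Ho"] >= 0) & (div.per_locus["Ho"] <= 1)).all()
        assert ((div.per_locus["He"] >= 0) & (div.per_locus["He"] <= 1)).all()
        scan = popgen.gst_scan(toy_gm, "P").dropna()
        assert ((scan >= 0) & (scan <= 1)).all()
        theta = popgen.pairwise_fst(toy_gm, "P", "Q").theta
        assert -0.1 <= theta <= 1.0
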