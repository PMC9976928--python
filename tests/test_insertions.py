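"""Random loci, feature assignment, profiles, enrichment and target-site matrix."""
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy import stats as sps

from passerpipe import (GeneModel, InsertionSite, StateSegment, assign_feature,
                        chromatin_state_enrichment, expression_binned_frequency,
                        feature_distribution, fisher_exact, gene_body_decile,
                        generate_random_loci, palindrome_score, stars,
                        target_site_matrix, ta_positions, tss_profile)
from conftest import random_dna


def _fisher_oracle(a, b, c, d):
    """Independent exact two-sided Fisher p via the column-margin decomposition."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if n == 0 or row1 in (0, n) or col1 in (0, n):
        return Fraction(1)
    denom = comb(n, row1)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    pmf = {k: Fraction(comb(col1, k) * comb(n - col1, row1 - k), denom)
           for k in range(lo, hi + 1)}
    p_obs = pmf[a]
    return min(Fraction(1), sum(p for p in pmf.values() if p <= p_obs))


class TestFisher:
    def test_symmetric_table(self):
        assert fisher_exact(5, 5, 5, 5) == 1.0

    def test_zero_margin(self):
        assert fisher_exact(0, 0, 3, 7) == 1.0

    def test_matches_enumeration_small_tables(self):
        for a in range(0, 8):
            for b in range(0, 8):
                for c in range(0, 8):
                    for d in range(0, 8):
                        p = fisher_exact(a, b, c, d)
                        assert abs(p - float(_fisher_oracle(a, b, c, d))) <= 1e-12

    def test_large_table_fallback_consistent(self):
        p = fisher_exact(300, 700, 250, 750)
        assert p == pytest.approx(
            sps.fisher_exact([[300, 700], [250, 750]])[1], rel=1e-9)

    def test_negative_count_raises(self):
        with pytest.raises(ValueError):
            fisher_exact(-1, 2, 3, 4)

    def test_star_mapping(self):
        assert stars(0.005) == "**"
        assert stars(1e-4) == "****"
        assert stars(5e-4) == "***"
        assert stars(0.05) == "*"
        assert stars(0.051) == "ns"


class TestRandomLoci:
    def test_deterministic_under_seed(self):
        sizes = {"c1": 10_000, "c2": 5_000}
        a = generate_random_loci(sizes, n=500, seed=1)
        b = generate_random_loci(sizes, n=500, seed=1)
        assert a == b

    def test_length_proportional_sampling(self):
        """Two contigs at a 90/10 length split get counts within binomial bounds."""
        sizes = {"big": 90_000, "small": 10_000}
        loci = generate_random_loci(sizes, n=100_000, seed=2)
        n_big = sum(s.chrom == "big" for s in loci)
        lo, hi = sps.binom.ppf([0.005, 0.995], 100_000, 0.9)
        assert lo <= n_big <= hi

    def test_ta_matched_mode(self):
        genome = {"c": "TATATATA"}
        loci = generate_random_loci({"c": 8}, n=200, seed=3, mode="ta_matched",
                                    genome=genome)
        for s in loci:
            assert genome["c"][s.position:s.position + 2] == "TA"

    def test_ta_matched_requires_ta(self):
        with pytest.raises(ValueError, match="no TA"):
            generate_random_loci({"c": 8}, n=10, mode="ta_matched",
                                 genome={"c": "GGGGCCCC"})


GENES = [
    GeneModel("c", 10_000, 20_000, "+", "gA",
              exons=[(10_000, 12_000), (15_000, 20_000)], expression=5.0),
    GeneModel("c", 30_000, 36_000, "-", "gB",
              exons=[(30_000, 32_000), (34_000, 36_000)], expression=1.0),
]


class TestAssignFeature:
    def test_promoter_window_plus_strand(self):
        ann = assign_feature(InsertionSite("c", 9_500), GENES)
        assert ann.category == "promoter" and ann.gene_name == "gA"

    def test_promoter_window_minus_strand(self):
        ann = assign_feature(InsertionSite("c", 36_500), GENES)
        assert ann.category == "promoter" and ann.gene_name == "gB"

    def test_exon_intron_downstream_intergenic(self):
        assert assign_feature(InsertionSite("c", 11_000), GENES).category == "exon"
        assert assign_feature(InsertionSite("c", 13_000), GENES).category == "intron"
        assert assign_feature(InsertionSite("c", 20_500), GENES).category == "downstream"
        assert assign_feature(InsertionSite("c", 50_000), GENES).category == "intergenic"

    def test_promoter_precedence_over_exon(self):
        genes = GENES + [GeneModel("c", 8_000, 11_500, "+", "gC",
                                   exons=[(8_000, 11_500)])]
        # inside gC's exon but also within gA's promoter window
        ann = assign_feature(InsertionSite("c", 9_500), genes)
        assert ann.category == "promoter"

    def test_counts_match_independent_scan(self):
        """Category counts equal a per-site brute-force reimplementation."""
        rng = np.random.default_rng(60)
        sites = [InsertionSite("c", int(p))
                 for p in rng.integers(0, 40_000, size=500)]
        got = {}
        for s in sites:
            got[assign_feature(s, GENES).category] = \
                got.get(assign_feature(s, GENES).category, 0) + 1
        exp = {}
        for s in sites:
            cats = []
            for g in GENES:
                if g.strand == "+":
                    prom = range(g.start - 1000, g.start)
                    down = range(g.end, g.end + 1000)
                else:
                    prom = range(g.end, g.end + 1000)
                    down = range(g.start - 1000, g.start)
                if s.position in prom:
                    cats.append("promoter")
                elif g.start <= s.position < g.end:
                    in_ex = any(a <= s.position < b for a, b in g.exons)
                    cats.append("exon" if in_ex else "intron")
                elif s.position in down:
                    cats.append("downstream")
            order = ["promoter", "exon", "intron", "downstream"]
            cat = min(cats, key=order.index) if cats else "intergenic"
            exp[cat] = exp.get(cat, 0) + 1
        assert got == exp


class TestFeatureDistribution:
    def test_background_against_itself_is_null(self):
        rng = np.random.default_rng(61)
        sites = [InsertionSite("c", int(p), sample_label="PS")
                 for p in rng.integers(0, 40_000, size=400)]
        df = feature_distribution({"PS": sites, "random": sites}, GENES)
        ps = df[df["sample"] == "PS"]
        for _, row in ps.iterrows():
            if row["count"] > 0:
                assert row["fold"] == pytest.approx(1.0)
                assert row["p_value"] == pytest.approx(1.0)

    def test_fractions_partition(self):
        rng = np.random.default_rng(62)
        sites = [InsertionSite("c", int(p))
                 for p in rng.integers(0, 40_000, size=300)]
        df = feature_distribution({"sites": sites, "random": sites}, GENES)
        for label, grp in df.groupby("sample"):
            assert grp["fraction"].sum() == pytest.approx(1.0)

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError, match="empty"):
            feature_distribution({"PS": [], "random": [InsertionSite("c", 5)]},
                                 GENES)


class TestGeneBodyDecile:
    def test_midpoint_and_last_nucleotide(self):
        gene = GeneModel("c", 0, 1000, "+", "g")
        frac, _ = gene_body_decile([InsertionSite("c", 500)], [gene])
        assert frac[5] == 1.0
        frac, _ = gene_body_decile([InsertionSite("c", 999)], [gene])
        assert frac[9] == 1.0

    def test_minus_strand_orientation(self):
        gene = GeneModel("c", 0, 1000, "-", "g")
        frac, _ = gene_body_decile([InsertionSite("c", 999)], [gene])
        assert frac[0] == 1.0  # TSS-proximal end on the minus strand

    def test_uniform_sites_near_uniform_bins(self):
        gene = GeneModel("c", 0, 100_000, "+", "g")
        rng = np.random.default_rng(63)
        sites = [InsertionSite("c", int(p))
                 for p in rng.integers(0, 100_000, size=20_000)]
        frac, skipped = gene_body_decile(sites, [gene])
        assert skipped == 0
        lo, hi = sps.binom.ppf([0.0005, 0.9995], 20_000, 0.1) / 20_000
        assert ((frac >= lo) & (frac <= hi)).all()

    def test_sites_outside_genes_skipped(self):
        gene = GeneModel("c", 0, 1000, "+", "g")
        _, skipped = gene_body_decile([InsertionSite("c", 5000)], [gene])
        assert skipped == 1


class TestTssProfile:
    def test_site_at_tss(self):
        gene = GeneModel("c", 5000, 9000, "+", "g")
        edges, counts = tss_profile([InsertionSite("c", 5000)], [gene])
        assert counts[np.searchsorted(edges, 0)] == 1

    def test_out_of_window_excluded(self):
        gene = GeneModel("c", 5000, 9000, "+", "g")
        _, counts = tss_profile([InsertionSite("c", 5000 + 3001)], [gene])
        assert counts.sum() == 0

    def test_minus_strand_sign(self):
        gene = GeneModel("c", 5000, 9000, "-", "g")
        edges, counts = tss_profile([InsertionSite("c", 8999 - 200)], [gene])
        # 200 bp downstream of a minus-strand TSS is a +200 offset
        assert counts[np.searchsorted(edges, 200)] == 1


class TestExpressionGroups:
    def _genes(self, n=16, length=10_000):
        return [GeneModel("c", i * 20_000, i * 20_000 + length, "+", f"g{i}",
                          expression=float(i + 1)) for i in range(n)]

    def test_uniform_sites_equal_frequencies(self):
        genes = self._genes()
        rng = np.random.default_rng(64)
        sites = []
        for g in genes:
            sites += [InsertionSite("c", int(p)) for p in
                      rng.integers(g.start, g.end, size=50)]
        df = expression_binned_frequency(sites, genes, n_groups=8)
        assert len(df) == 8
        assert df.insertions.sum() == len(sites)
        assert df.insertions_per_mb.max() <= 2 * df.insertions_per_mb.min()

    def test_length_normalization_is_linear(self):
        genes1 = self._genes(length=10_000)
        genes2 = self._genes(length=20_000)
        sites = [InsertionSite("c", g.start + 10) for g in genes1 for _ in range(5)]
        f1 = expression_binned_frequency(sites, genes1, n_groups=8)
        f2 = expression_binned_frequency(sites, genes2, n_groups=8)
        np.testing.assert_allclose(f2.insertions_per_mb, f1.insertions_per_mb / 2)

    def test_groups_ordered_by_expression(self):
        df = expression_binned_frequency(
            [InsertionSite("c", 10)], self._genes(), n_groups=8)
        assert df.mean_expression.is_monotonic_increasing

    def test_too_few_genes_raises(self):
        with pytest.raises(ValueError):
            expression_binned_frequency([], self._genes(n=4), n_groups=8)


SEGMENTS = [StateSegment("c", 0, 10_000, "active"),
            StateSegment("c", 10_000, 100_000, "quiet")]


class TestChromatinEnrichment:
    def test_planted_state_fold_matches_closed_form(self):
        """All sites in a state covering 10% of the genome give fold ~= 10."""
        rng = np.random.default_rng(65)
        obs = [InsertionSite("c", int(p)) for p in rng.integers(0, 10_000, 400)]
        bg = [InsertionSite("c", int(p)) for p in rng.integers(0, 100_000, 20_000)]
        res = {r.label: r for r in chromatin_state_enrichment(obs, SEGMENTS, bg)}
        assert res["active"].fold == pytest.approx(10.0, rel=0.05)
        assert res["active"].stars == "****"

    def test_background_against_itself_fold_one(self):
        rng = np.random.default_rng(66)
        bg = [InsertionSite("c", int(p)) for p in rng.integers(0, 100_000, 5_000)]
        for r in chromatin_state_enrichment(bg, SEGMENTS, bg):
            assert r.fold == pytest.approx(1.0)
            assert r.stars == "ns"

    def test_conflicting_overlap_raises(self):
        segs = SEGMENTS + [StateSegment("c", 5_000, 15_000, "other")]
        with pytest.raises(ValueError, match="conflicting"):
            chromatin_state_enrichment([InsertionSite("c", 1)], segs,
                                       [InsertionSite("c", 2)])

    def test_state_absent_from_background_reported_not_fabricated(self):
        obs = [InsertionSite("c", 5)]
        bg = [InsertionSite("c", 50_000)]
        res = {r.label: r for r in chromatin_state_enrichment(obs, SEGMENTS, bg)}
        assert res["active"].fold is None


class TestTargetSiteMatrix:
    def test_palindrome_score_of_palindrome(self):
        assert palindrome_score("AAGTACTT") == 1.0
        assert palindrome_score("AAAAAAAA") == 0.0

    def test_planted_context_recovered(self):
        rng = np.random.default_rng(67)
        core = "AAGTACTT"
        chunks = []
        positions = []
        pos = 0
        for _ in range(60):
            pad = random_dna(rng, 40)
            chunks.append(pad + core)
            positions.append(pos + 40 + 3)  # TA at core positions 3-4
            pos += 48
        genome = {"c": "".join(chunks)}
        sites = [InsertionSite("c", p, "+") for p in positions]
        tsm = target_site_matrix(sites, genome, halfwidth=10)
        assert tsm.consensus[7:15] == core
        assert tsm.palindrome_score == 1.0
        assert tsm.n_sites == 60

    def test_counts_sum_to_sites(self):
        genome = {"c": "G" * 30 + "TA" + "G" * 30}
        sites = [InsertionSite("c", 30, "+")] * 5
        tsm = target_site_matrix(sites, genome)
        assert (tsm.counts.sum(axis=1) == 5).all()

    def test_non_ta_sites_excluded_by_default(self):
        genome = {"c": "G" * 30 + "TA" + "G" * 30}
        sites = [InsertionSite("c", 30, "+"), InsertionSite("c", 10, "+")]
        tsm = target_site_matrix(sites, genome)
        assert tsm.n_sites == 1

    def test_minus_strand_orientation(self):
        genome = {"c": "C" * 20 + "TA" + "G" * 20}
        plus = target_site_matrix([InsertionSite("c", 20, "+")], genome, halfwidth=3)
        minus = target_site_matrix([InsertionSite("c", 20, "-")], genome, halfwidth=3)
        assert plus.consensus == "CCCTAGGG"
        assert minus.consensus == "CCCTAGGG"  # revcomp of the window is itself here
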