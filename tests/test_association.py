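import itertools
import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protosex.association import (
    AssocResult,
    CountTable2x2,
    DegenerateTableWarning,
    apply_marker_filters,
    associate,
    bonferroni,
    build_table,
    fisher_exact,
    major_allele,
    permutation_correction,
    recessive_discordance,
)
from protosex.data_model import GenotypeMatrix, Individual, Marker


def make_matrix(genotypes_by_sex, alleles=("C", "G"), marker_id="m1"):
    """genotypes_by_sex: list of (sex, genotype-or-None)."""
    marker = Marker(marker_id, "c", 1, "snp", frozenset(alleles))
    inds, rows = [], []
    for i, (sex, g) in enumerate(genotypes_by_sex):
        inds.append(Individual(f"i{i}", sex))
        rows.append([g])
    return GenotypeMatrix(inds, [marker], rows)


class TestFilters:
    def test_maf_boundary_strict(self):
        # 10 individuals, exactly 2 minor alleles of 20 -> MAF 0.10 -> filtered
        rows = [("female", ("C", "G"))] * 2 + [("female", ("C", "C"))] * 8
        res = apply_marker_filters(make_matrix(rows))["m1"]
        assert res.maf == pytest.approx(0.10)
        assert not res.passed and "maf" in res.reason

    def test_call_rate_104_of_105_retained(self):
        rows = [("female", ("C", "G"))] * 52 + [("male", ("C", "C"))] * 52
        rows.append(("male", None))
        res = apply_marker_filters(make_matrix(rows))["m1"]
        assert res.call_rate == pytest.approx(104 / 105)
        assert res.passed

    def test_snp7271_maf_from_printed_counts(self, wild):
        res = apply_marker_filters(wild)["SNP7271"]
        assert res.maf == pytest.approx(47 / 210)
        assert res.passed

    def test_monomorphic_filtered_not_error(self):
        rows = [("female", ("C", "C"))] * 10
        res = apply_marker_filters(make_matrix(rows))["m1"]
        assert res.maf == 0.0 and not res.passed


class TestBuildTable:
    def test_snp7271_genotypic(self, wild):
        t = build_table(wild, "SNP7271", "genotypic_2x2")
        assert (t.a, t.b, t.c, t.d) == (58, 0, 0, 47)

    def test_snp7412_genotypic_excludes_undetermined(self, wild):
        t = build_table(wild, "SNP7412", "genotypic_2x2")
        assert (t.a, t.b, t.c, t.d) == (53, 5, 4, 42)
        assert t.total == 104

    def test_snp7271_allelic(self, wild):
        t = build_table(wild, "SNP7271", "allelic")
        assert (t.a, t.b, t.c, t.d) == (116, 0, 47, 47)

    def test_major_allele_tie_lexicographic(self):
        rows = [("female", ("C", "G")), ("male", ("C", "G"))]
        assert major_allele(make_matrix(rows), "m1") == "C"


class TestFisherExact:
    def test_perfect_split_reproduces_printed_value(self):
        p = fisher_exact(CountTable2x2(58, 0, 0, 47), "two_sided")
        assert p == pytest.approx(5.6e-31, rel=0.01)
        # perfect split: two-sided equals 1 / C(105, 58)
        assert p == pytest.approx(1 / math.comb(105, 58), rel=1e-10)

    def test_snp7412_reproduces_printed_value(self):
        p = fisher_exact(CountTable2x2(53, 5, 4, 42), "two_sided")
        assert p == pytest.approx(9.9e-19, rel=0.01)

    def test_one_sided_smaller_than_two_sided_7412(self):
        p1 = fisher_exact(CountTable2x2(53, 5, 4, 42), "one_sided")
        p2 = fisher_exact(CountTable2x2(53, 5, 4, 42), "two_sided")
        assert p1 == pytest.approx(7.7e-19, rel=0.01)
        assert p1 < p2

    def test_trivial_half(self):
        assert fisher_exact(CountTable2x2(1, 0, 0, 1), "one_sided") == pytest.approx(0.5)

    def test_degenerate_margins_p1_flagged(self):
        with pytest.warns(DegenerateTableWarning):
            assert fisher_exact(CountTable2x2(3, 0, 2, 0)) == 1.0

    def test_matches_oracle_random_small_tables(self, fisher_bruteforce):
        rng = np.random.default_rng(42)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 13, size=4)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            t = CountTable2x2(int(a), int(b), int(c), int(d))
            for alt in ("one_sided", "two_sided"):
                assert fisher_exact(t, alt) == pytest.approx(
                    fisher_bruteforce(int(a), int(b), int(c), int(d), alt),
                    rel=1e-9,
                ), (a, b, c, d, alt)

    @given(
        st.integers(0, 10), st.integers(0, 10),
        st.integers(0, 10), st.integers(0, 10),
    )
    @settings(max_examples=200, deadline=None)
    def test_two_sided_geq_one_sided(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        t = CountTable2x2(a, b, c, d)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateTableWarning)
            assert (
                fisher_exact(t, "two_sided")
                >= fisher_exact(t, "one_sided") - 1e-12
            )


class TestRecessiveDiscordance:
    def test_snp7412_nine_discordant(self, wild):
        discordant, excluded = recessive_discordance(wild, "SNP7412")
        assert len(discordant) == 9
        assert len(excluded) == 1
        # 5 CG females + 4 GG males
        assert sum(d.startswith("F") for d in discordant) == 5
        assert sum(d.startswith("M") for d in discordant) == 4

    def test_snp7271_zero_discordant(self, wild):
        discordant, excluded = recessive_discordance(wild, "SNP7271")
        assert discordant == [] and excluded == []

    def test_all_missing_marker(self):
        marker = Marker("m1", "c", 1, "snp", frozenset({"C", "G"}))
        m2 = Marker("m2", "c", 2, "snp", frozenset({"A", "T"}))
        inds = [Individual(f"i{k}", "female") for k in range(5)]
        gm = GenotypeMatrix(
            inds, [marker, m2], [[None, ("A", "A")] for _ in range(5)]
        )
        with pytest.raises(ValueError, match="no genotyped"):
            recessive_discordance(gm, "m1")

    def test_zero_discordance_iff_diagonal_table(self, wild):
        t = build_table(wild, "SNP7271", "genotypic_2x2")
        d, _ = recessive_discordance(wild, "SNP7271")
        assert (t.b == 0 and t.c == 0) == (len(d) == 0)
        t2 = build_table(wild, "SNP7412", "genotypic_2x2")
        d2, _ = recessive_discordance(wild, "SNP7412")
        assert len(d2) == t2.b + t2.c


class TestBonferroni:
    def test_threshold_13_markers(self):
        adjusted, threshold = bonferroni([1e-5] * 13)
        assert threshold == pytest.approx(0.05 / 13)
        assert -np.log10(threshold) == pytest.approx(2.415, abs=0.01)

    def test_single_test_identity(self):
        adjusted, _ = bonferroni([0.03])
        assert adjusted == [0.03]

    def test_p_one_stays_one(self):
        adjusted, _ = bonferroni([1.0, 0.5])
        assert adjusted[0] == 1.0


class TestPermutation:
    def _null_matrix(self, rng, n=20, m=3):
        markers = [
            Marker(f"m{j}", "c", j + 1, "snp", frozenset({"A", "C"}))
            for j in range(m)
        ]
        inds = [
            Individual(f"i{k}", "female" if k < n // 2 else "male")
            for k in range(n)
        ]
        rows = []
        for _ in range(n):
            row = []
            for _j in range(m):
                g = tuple(sorted(rng.choice(["A", "C"], size=2)))
                row.append(g)
            rows.append(row)
        return GenotypeMatrix(inds, markers, rows)

    def test_lower_bound_add_one(self):
        rng = np.random.default_rng(0)
        gm = self._null_matrix(rng)
        corrected = permutation_correction(gm, ["m0", "m1", "m2"], 99, seed=1)
        assert all(p >= 1 / 100 for p in corrected.values())
        assert all(p <= 1.0 for p in corrected.values())

    def test_matches_exhaustive_small(self, fisher_bruteforce):
        # 6 individuals, 1 marker: exhaustively enumerate sex relabelings
        marker = Marker("m0", "c", 1, "snp", frozenset({"A", "C"}))
        gts = [("A", "A"), ("A", "A"), ("A", "C"), ("A", "C"), ("A", "C"), ("C", "C")]
        sexes = ["female", "female", "female", "male", "male", "male"]
        inds = [Individual(f"i{k}", s) for k, s in enumerate(sexes)]
        gm = GenotypeMatrix(inds, [marker], [[g] for g in gts])

        hom = [g == ("A", "A") for g in gts]
        def p_for(assign):
            a = sum(h for h, s in zip(hom, assign) if s)
            b = sum((not h) for h, s in zip(hom, assign) if s)
            c = sum(h for h, s in zip(hom, assign) if not s)
            d = sum((not h) for h, s in zip(hom, assign) if not s)
            return fisher_bruteforce(a, b, c, d, "two_sided")

        observed = p_for([s == "female" for s in sexes])
        # exhaustive over equally likely permutations of the label vector:
        # fraction of 3-female subsets achieving p <= observed
        hits = total = 0
        for fem in itertools.combinations(range(6), 3):
            assign = [k in fem for k in range(6)]
            total += 1
            hits += p_for(assign) <= observed + 1e-12
        exhaustive = hits / total

        corrected = permutation_correction(gm, ["m0"], 4000, seed=5)["m0"]
        sigma = math.sqrt(exhaustive * (1 - exhaustive) / 4000)
        assert abs(corrected - exhaustive) <= 3 * sigma + 1 / 4001

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        gm = self._null_matrix(rng)
        c1 = permutation_correction(gm, ["m0", "m1"], 200, seed=9)
        c2 = permutation_correction(gm, ["m0", "m1"], 200, seed=9)
        assert c1 == c2

    def test_too_few_per_sex(self):
        marker = Marker("m0", "c", 1, "snp", frozenset({"A", "C"}))
        inds = [Individual("a", "female"), Individual("b", "male")]
        gm = GenotypeMatrix(inds, [marker], [[("A", "A")], [("A", "C")]])
        with pytest.raises(ValueError, match="each sex"):
            permutation_correction(gm, ["m0"], 10, seed=0)


class TestAssociatePipeline:
    def test_wild_panel_end_to_end(self, wild):
        results = associate(wild, maf_min=0.1, call_rate_min=0.9)
        by_id = {r.marker_id: r for r in results}
        assert by_id["SNP7271"].p_two_sided == pytest.approx(5.6e-31, rel=0.01)
        assert by_id["SNP7412"].p_two_sided == pytest.approx(9.9e-19, rel=0.01)
        assert by_id["SNP7271"].p_bonferroni == pytest.approx(2 * 5.62e-31, rel=0.01)

    def test_filtered_markers_carry_reason(self, wild):
        # default call-rate filter removes SNP7412 (104/105 < 0.99? no: 0.9905 > 0.99)
        results = associate(wild)
        by_id = {r.marker_id: r for r in results}
        assert not by_id["SNP7412"].filtered  # 104/105 = 0.9905 passes
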