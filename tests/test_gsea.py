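"""Running-sum enrichment score, permutation null, NES and screening."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from chemscreen.dataio import GeneSet
from chemscreen.errors import ValidationError
from chemscreen.gsea import (EnrichmentConfig, enrichment_score,
                             normalize_and_test, permutation_null, run_gsea)
from chemscreen.scoring import GeneScoreTable

from conftest import es_bruteforce, random_score_table


class TestEnrichmentScore:
    def test_worked_example_top_and_third(self, five_gene_table):
        es, curve = enrichment_score(five_gene_table, {"g1", "g3"}, p=1.0)
        np.testing.assert_allclose(
            curve, [0.625, 0.625 - 1 / 3, 0.625 - 1 / 3 + 0.375,
                    1.0 - 2 / 3, 0.0], atol=1e-12)
        assert es == pytest.approx(2 / 3, abs=1e-12)

    def test_bottom_concentrated_set_scores_zero(self, five_gene_table):
        es, _ = enrichment_score(five_gene_table, {"g4", "g5"}, p=1.0)
        assert es == 0.0

    def test_single_top_gene_scores_one(self, five_gene_table):
        es, _ = enrichment_score(five_gene_table, {"g1"}, p=1.0)
        assert es == pytest.approx(1.0, abs=1e-12)

    def test_full_universe_set_rejected(self, five_gene_table):
        with pytest.raises(ValidationError, match="N_H = N"):
            enrichment_score(five_gene_table, {"g1", "g2", "g3", "g4", "g5"})

    def test_no_overlap_rejected(self, five_gene_table):
        with pytest.raises(ValidationError, match="no overlap"):
            enrichment_score(five_gene_table, {"absent"})

    def test_zero_score_mass_rejected(self):
        t = GeneScoreTable.from_scores(["a", "b", "c"], [1.0, 0.0, 0.0], "s")
        with pytest.raises(ValidationError, match="N_R"):
            enrichment_score(t, {"b", "c"}, p=1.0)

    def test_accepts_gene_set_object(self, five_gene_table):
        s = GeneSet("chem", "X:1", frozenset({"g1", "g3"}))
        es, _ = enrichment_score(five_gene_table, s, p=1.0)
        assert es == pytest.approx(2 / 3, abs=1e-12)

    def test_exponent_zero_is_unweighted(self, five_gene_table):
        # with p=0 every hit contributes 1/N_H regardless of score
        es, _ = enrichment_score(five_gene_table, {"g1", "g3"}, p=0.0)
        assert es == pytest.approx(0.5 + 1 / 2 - 1 / 3, abs=1e-12)

    @given(st.integers(0, 5_000))
    def test_matches_bruteforce_oracle(self, case):
        rng = np.random.default_rng(case)
        n = int(rng.integers(3, 30))
        t = random_score_table(rng, n)
        k = int(rng.integers(1, n))
        members = set(rng.choice(t.gene_ids, size=k, replace=False))
        p = float(rng.choice([0.0, 0.5, 1.0, 2.0]))
        try:
            es, _ = enrichment_score(t, members, p=p)
        except ValidationError:
            return  # degenerate N_R = 0 draw
        assert es == pytest.approx(max(es_bruteforce(t, members, p), 0.0),
                                   abs=1e-12)

    @given(st.integers(0, 2_000))
    def test_range_invariant(self, case):
        rng = np.random.default_rng(case)
        n = int(rng.integers(3, 60))
        t = random_score_table(rng, n)
        k = int(rng.integers(1, n))
        members = set(rng.choice(t.gene_ids, size=k, replace=False))
        es, _ = enrichment_score(t, members)
        assert 0.0 <= es <= 1.0 + 1e-12

    @given(st.integers(0, 1_000))
    def test_promoting_a_member_never_decreases_unweighted_es(self, case):
        # monotone only for the unweighted (p=0) statistic: with p>0 a
        # promotion inflates N_R and can dilute an earlier-hit maximum
        rng = np.random.default_rng(case)
        n = int(rng.integers(5, 40))
        t = random_score_table(rng, n)
        ids = t.gene_ids
        k = int(rng.integers(1, n - 1))
        member_pos = sorted(rng.choice(n, size=k, replace=False).tolist())
        members = {ids[i] for i in member_pos}
        non_member_pos = [i for i in range(n) if i not in set(member_pos)]
        lowest_member = member_pos[-1]
        better = [i for i in non_member_pos if i < lowest_member]
        if not better:
            return
        swap_in = int(rng.choice(better))
        promoted = (members - {ids[lowest_member]}) | {ids[swap_in]}
        es_before, _ = enrichment_score(t, members, p=0.0)
        es_after, _ = enrichment_score(t, promoted, p=0.0)
        assert es_after >= es_before - 1e-12

    def test_two_sided_variant_sees_bottom_sets(self, five_gene_table):
        es, _ = enrichment_score(five_gene_table, {"g4", "g5"}, p=1.0,
                                 two_sided=True)
        assert es == pytest.approx(-1.0, abs=1e-12)  # deepest excursion at j=3


class TestPermutationNull:
    def test_deterministic_given_seed(self, rng):
        t = random_score_table(rng, 100)
        a = permutation_null(t, 10, n_perm=50, seed=42)
        b = permutation_null(t, 10, n_perm=50, seed=42)
        np.testing.assert_array_equal(a, b)
        c = permutation_null(t, 10, n_perm=50, seed=43)
        assert not np.array_equal(a, c)

    def test_single_permutation(self, rng):
        t = random_score_table(rng, 20)
        assert permutation_null(t, 5, n_perm=1, seed=0).shape == (1,)

    def test_nulls_match_single_pass_scorer(self, rng):
        # the fast hit-position kernel must agree with enrichment_score
        t = random_score_table(rng, 40)
        nulls = permutation_null(t, 7, n_perm=20, seed=9)
        rng2 = np.random.default_rng(np.random.SeedSequence(9))
        ids = t.gene_ids
        for i in range(20):
            keys = rng2.random((1, 40))
            pos = np.argpartition(keys, 6, axis=1)[:, :7][0]
            es, _ = enrichment_score(t, {ids[j] for j in pos})
            assert nulls[i] == pytest.approx(es, abs=1e-12)

    def test_constant_scores_es_depends_only_on_positions(self):
        # with equal scores the hit increment is uniform 1/N_H, so any two
        # sets occupying the same rank positions share one ES
        t1 = GeneScoreTable.from_scores([f"a{i}" for i in range(10)],
                                        [2.0] * 10, "s")
        t2 = GeneScoreTable.from_scores([f"b{i}" for i in range(10)],
                                        [7.0] * 10, "s")
        for pos in [(0, 1), (3, 8), (9,), (2, 4, 6)]:
            es1, _ = enrichment_score(t1, {t1.gene_ids[i] for i in pos})
            es2, _ = enrichment_score(t2, {t2.gene_ids[i] for i in pos})
            assert es1 == pytest.approx(es2, abs=1e-12)

    def test_set_size_bounds(self, rng):
        t = random_score_table(rng, 10)
        with pytest.raises(ValidationError):
            permutation_null(t, 10, n_perm=5, seed=0)
        with pytest.raises(ValidationError):
            permutation_null(t, 5, n_perm=0, seed=0)


class TestNormalizeAndTest:
    def test_nes_arithmetic(self):
        null = np.array([0.1, 0.2, 0.3])  # mean 0.2
        null = 0.2 + (null - null.mean()) * (0.1 / null.std(ddof=1))  # SD 0.1
        nes, _ = normalize_and_test(0.6, null)
        assert nes == pytest.approx(4.0, abs=1e-9)

    def test_add_one_empirical_p(self):
        nes, p = normalize_and_test(0.35, [0.1, 0.2, 0.3, 0.4])
        assert p == pytest.approx(2 / 5)

    def test_observed_equal_to_every_null_gives_p_one(self):
        _, p = normalize_and_test(0.25, [0.25] * 10)
        assert p == 1.0

    def test_constant_null_reports_zero_nes(self):
        nes, p = normalize_and_test(0.5, [0.25] * 10)
        assert nes == 0.0 and p == pytest.approx(1 / 11)

    def test_empty_null_rejected(self):
        with pytest.raises(ValidationError):
            normalize_and_test(0.5, [])


class TestRunGsea:
    def test_size_filters_and_sorting(self, rng):
        t = random_score_table(rng, 100)
        ids = t.gene_ids
        sets = [
            GeneSet("tiny", "S:1", frozenset(ids[:2])),          # N_H=2 < 5
            GeneSet("planted", "S:2", frozenset(ids[:10])),      # top-loaded
            GeneSet("random", "S:3", frozenset(
                rng.choice(ids, size=10, replace=False))),
        ]
        cfg = EnrichmentConfig(n_permutations=99, min_set_size=5, seed=1)
        res = run_gsea(t, sets, cfg)
        assert {r.chemical_name for r in res} == {"planted", "random"}
        assert res[0].chemical_name == "planted"
        assert res[0].p_empirical == pytest.approx(1 / 100)
        assert [r.p_empirical for r in res] == sorted(r.p_empirical for r in res)
        assert all(r.significant == (r.p_empirical < cfg.alpha) for r in res)
        assert all(r.p_empirical >= 1 / (cfg.n_permutations + 1) for r in res)

    def test_no_surviving_set_returns_empty(self, rng):
        t = random_score_table(rng, 20)
        sets = [GeneSet("alien", "S:1", frozenset({"x", "y", "z"}))]
        assert run_gsea(t, sets, EnrichmentConfig(n_permutations=10)) == []

    def test_reproducible_results_table(self, rng, tmp_path):
        from chemscreen.dataio import write_results_table

        t = random_score_table(rng, 200)
        sets = [GeneSet(f"c{i}", "S", frozenset(
            np.random.default_rng(i).choice(t.gene_ids, 20, replace=False)))
            for i in range(10)]
        cfg = EnrichmentConfig(n_permutations=100, seed=7)
        for name in ("a.tsv", "b.tsv"):
            write_results_table(run_gsea(t, sets, cfg), tmp_path / name)
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_equal_sizes_share_one_null(self, rng):
        # two disjoint same-size sets with identical member positions in two
        # runs must face the same null: identical ES implies identical p
        t = GeneScoreTable.from_scores([f"g{i:03d}" for i in range(50)],
                                       [1.0] * 50, "s")
        ids = t.gene_ids
        sets = [GeneSet("u", "S", frozenset(ids[5:15])),
                GeneSet("v", "S", frozenset(ids[5:15]) - {ids[5]} | {ids[4]})]
        res = run_gsea(t, sets, EnrichmentConfig(n_permutations=200, seed=0))
        by_name = {r.chemical_name: r for r in res}
        # constant scores: ES depends only on positions; nearly equal sets
        # with one member promoted by one rank differ by at most one step
        assert abs(by_name["u"].es - by_name["v"].es) <= 1 / 10 + 1e-12
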