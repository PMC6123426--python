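import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lateralyzer.gsea import (
    GeneSet,
    GeneSetCollection,
    RankedList,
    enrichment_score,
    gsea_preranked,
    read_gmt,
    read_rnk,
    _normalize,
)

from oracles import brute_force_es, brute_force_rank_es


def _ranked(scores, genes=None):
    scores = np.asarray(scores, dtype=float)
    genes = genes or [f"g{i:02d}" for i in range(len(scores))]
    return RankedList.from_scores(genes, scores)


class TestRankedList:
    def test_sorted_descending(self):
        rl = _ranked([1.0, 3.0, 2.0])
        assert list(rl.scores) == [3.0, 2.0, 1.0]

    def test_tie_break_lexicographic(self):
        rl = RankedList.from_scores(["B", "A"], np.array([1.0, 1.0]))
        assert rl.genes == ["A", "B"]

    def test_duplicate_genes_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            RankedList.from_scores(["A", "A"], np.array([1.0, 2.0]))

    def test_rnk_roundtrip(self, tmp_path):
        rl = _ranked([2.5, -1.25, 0.0])
        path = tmp_path / "x.rnk"
        rl.write_rnk(path)
        back = read_rnk(path)
        assert back.genes == rl.genes
        np.testing.assert_array_equal(back.scores, rl.scores)


class TestGmtRnkIO:
    def test_gmt_dedup(self, tmp_path):
        path = tmp_path / "x.gmt"
        path.write_text("S1\tdesc\tA\tB\tA\n")
        coll = read_gmt(path)
        assert coll["S1"].genes == ["A", "B"]

    def test_duplicate_set_names_rejected(self, tmp_path):
        path = tmp_path / "x.gmt"
        path.write_text("S1\td\tA\nS1\td\tB\n")
        with pytest.raises(ValueError, match="duplicate set names"):
            read_gmt(path)

    def test_empty_gmt(self, tmp_path):
        path = tmp_path / "x.gmt"
        path.write_text("")
        assert len(read_gmt(path)) == 0

    def test_empty_rnk(self, tmp_path):
        path = tmp_path / "x.rnk"
        path.write_text("")
        assert len(read_rnk(path)) == 0

    def test_non_numeric_score_rejected(self, tmp_path):
        path = tmp_path / "x.rnk"
        path.write_text("A\tfoo\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_rnk(path)


class TestEnrichmentScore:
    def test_top_k_set_front_loaded(self):
        rl = _ranked(np.linspace(5, 1, 10))
        es, running, lead = enrichment_score(rl, rl.genes[:3])
        assert es > 0
        assert int(np.argmax(np.abs(running))) == 2  # extremum at position k
        assert lead == rl.genes[:3]

    def test_whole_list_set(self):
        rl = _ranked([5.0, 4.0, 3.0, 2.0, 1.0])
        es, running, _ = enrichment_score(rl, rl.genes)
        # all hits: running sum climbs monotonically to 1
        assert es == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(running, np.cumsum([5, 4, 3, 2, 1]) / 15.0)

    def test_reversal_negates(self):
        rng = np.random.default_rng(0)
        scores = np.sort(rng.normal(size=12))[::-1]
        rl = _ranked(scores)
        members = [rl.genes[i] for i in (0, 3, 4, 9)]
        es, _, _ = enrichment_score(rl, members)
        flipped = RankedList.from_scores(rl.genes, -rl.scores)
        es2, _, _ = enrichment_score(flipped, members)
        assert es2 == pytest.approx(-es, abs=1e-12)

    def test_es_bounded(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = rng.integers(3, 30)
            scores = rng.normal(size=n)
            rl = _ranked(scores, genes=[f"x{i:03d}" for i in range(n)])
            k = int(rng.integers(1, n + 1))
            members = list(rng.choice(rl.genes, size=k, replace=False))
            es, _, _ = enrichment_score(rl, members)
            assert -1.0 <= es <= 1.0

    def test_zero_member_scores_rejected(self):
        rl = _ranked([3.0, 2.0, 0.0, 0.0, -1.0])
        zero_genes = [g for g, s in zip(rl.genes, rl.scores) if s == 0.0]
        with pytest.raises(ValueError, match="zero"):
            enrichment_score(rl, zero_genes, weight_p=1.0)

    def test_no_overlap_rejected(self):
        rl = _ranked([1.0, 2.0])
        with pytest.raises(ValueError, match="no genes"):
            enrichment_score(rl, ["absent"])

    def test_exhaustive_oracle_small_lists(self):
        """Exact match with the brute-force oracle over all subsets."""
        rng = np.random.default_rng(2)
        for n, trial in itertools.product([4, 6, 8], range(3)):
            scores = np.round(rng.normal(size=n), 3)
            scores[scores == 0] = 0.5
            rl = _ranked(scores, genes=[f"x{i:02d}" for i in range(n)])
            for k in range(1, n + 1):
                for members in itertools.combinations(rl.genes, k):
                    es, _, _ = enrichment_score(rl, list(members))
                    ref = brute_force_es(rl.genes, rl.scores, set(members))
                    assert es == pytest.approx(ref, abs=1e-12)

    def test_p_zero_rank_only(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=15)
        rl = _ranked(scores)
        members = list(rng.choice(rl.genes, size=5, replace=False))
        es, _, _ = enrichment_score(rl, members, weight_p=0.0)
        ref = brute_force_rank_es(rl.genes, set(members))
        assert es == pytest.approx(ref, abs=1e-12)
        # independent of magnitudes: rescaling scores changes nothing
        rl2 = RankedList(rl.genes, rl.scores * 37.0)
        es2, _, _ = enrichment_score(rl2, members, weight_p=0.0)
        assert es2 == pytest.approx(es, abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_oracle_property_random(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 20))
        scores = rng.normal(size=n)
        rl = _ranked(scores, genes=[f"x{i:02d}" for i in range(n)])
        k = int(rng.integers(1, min(10, n) + 1))
        members = set(rng.choice(rl.genes, size=k, replace=False))
        es, _, _ = enrichment_score(rl, list(members))
        assert es == pytest.approx(brute_force_es(rl.genes, rl.scores, members),
                                   abs=1e-12)


def _collection(sets):
    return GeneSetCollection([GeneSet(n, "d", g) for n, g in sets])


class TestGseaPreranked:
    def test_size_filter(self):
        rl = _ranked(np.linspace(3, -3, 40))
        coll = _collection([
            ("small", rl.genes[:10]),
            ("ok", rl.genes[:16]),
        ])
        results = gsea_preranked(rl, coll, n_perm=50, min_size=15, max_size=500,
                                 seed=0)
        assert [r.name for r in results] == ["ok"]
        assert results.filtered == ["small"]

    def test_no_surviving_sets_warns(self):
        rl = _ranked([1.0, 2.0, 3.0])
        coll = _collection([("s", ["g0"])])
        with pytest.warns(UserWarning, match="no gene sets"):
            out = gsea_preranked(rl, coll, n_perm=10, min_size=15, seed=0)
        assert list(out) == []

    def test_extreme_set_fwer_zero(self):
        """Top-k positive-score set: no null draw can strictly exceed it."""
        scores = np.concatenate([[9.0, 8.0, 7.0], np.linspace(1.0, -3.0, 17)])
        rl = _ranked(scores)
        coll = _collection([("top", rl.genes[:3])])
        results = gsea_preranked(rl, coll, n_perm=1000, min_size=2, max_size=500,
                                 seed=1)
        assert results[0].fwer == 0.0
        assert results[0].p == 0.0
        assert results[0].nes > 0

    def test_determinism(self):
        rng = np.random.default_rng(4)
        rl = _ranked(rng.normal(size=100))
        coll = _collection([
            (f"s{i}", list(rng.choice(rl.genes, size=20, replace=False)))
            for i in range(5)
        ])
        a = gsea_preranked(rl, coll, n_perm=100, min_size=5, seed=7)
        b = gsea_preranked(rl, coll, n_perm=100, min_size=5, seed=7)
        for x, y in zip(a, b):
            assert (x.es, x.nes, x.p, x.fwer, x.fdr) == (y.es, y.nes, y.p, y.fwer, y.fdr)

    def test_fwer_at_least_nominal_p(self):
        rng = np.random.default_rng(5)
        rl = _ranked(rng.normal(size=200))
        coll = _collection([
            (f"s{i}", list(rng.choice(rl.genes, size=rng.integers(15, 40),
                                      replace=False)))
            for i in range(8)
        ])
        results = gsea_preranked(rl, coll, n_perm=200, seed=2, min_size=10)
        for r in results:
            assert r.fwer >= r.p - 1e-12
            assert np.sign(r.nes) == np.sign(r.es)

    def test_nes_invariant_to_duplicating_nulls(self):
        rng = np.random.default_rng(6)
        obs = rng.normal(size=5)
        null = rng.normal(size=(5, 40))
        nes1, _ = _normalize(obs, null)
        nes2, _ = _normalize(obs, np.concatenate([null, null], axis=1))
        np.testing.assert_allclose(nes1, nes2, atol=1e-12)

    def test_nominal_p_uniform_under_null(self):
        """Random sets on exchangeable scores: nominal p ~ U(0,1)."""
        rng = np.random.default_rng(8)
        rl = _ranked(rng.normal(size=300))
        pvals = []
        for rep in range(200):
            members = list(rng.choice(rl.genes, size=20, replace=False))
            coll = _collection([("s", members)])
            res = gsea_preranked(rl, coll, n_perm=200, min_size=5, seed=rep)
            pvals.append(res[0].p)
        stat, ks_p = stats.kstest(pvals, "uniform")
        assert ks_p > 0.01

    def test_fdr_within_bounds(self):
        rng = np.random.default_rng(9)
        rl = _ranked(rng.normal(size=150))
        coll = _collection([
            (f"s{i}", list(rng.choice(rl.genes, size=20, replace=False)))
            for i in range(10)
        ])
        results = gsea_preranked(rl, coll, n_perm=100, min_size=5, seed=3)
        for r in results:
            assert 0.0 <= r.fdr <= 1.0
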