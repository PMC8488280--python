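import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pairsig import io_cohorts as io
from pairsig import pair_features as pf


class TestEnumeratePairs:
    def test_three_genes(self):
        assert pf.enumerate_pairs(["A", "B", "C"]) == [
            pf.GenePair("A", "B"),
            pf.GenePair("A", "C"),
            pf.GenePair("B", "C"),
        ]

    def test_two_genes(self):
        assert len(pf.enumerate_pairs(["B", "A"])) == 1

    @pytest.mark.parametrize("g", [2, 3, 7, 20, 50])
    def test_count_law_vs_brute_force(self, g):
        genes = [f"g{i:02d}" for i in range(g)]
        pairs = pf.enumerate_pairs(genes)
        brute = {
            frozenset((a, b)) for a in genes for b in genes if a != b
        }
        assert len(pairs) == g * (g - 1) // 2 == len(brute)
        assert {frozenset(p) for p in pairs} == brute

    def test_too_few_genes(self):
        with pytest.raises(ValueError):
            pf.enumerate_pairs(["A", "A"])

    def test_canonical_order(self):
        assert all(p.gene1 < p.gene2 for p in pf.enumerate_pairs(["z", "m", "a"]))


class TestPairScore:
    @pytest.mark.parametrize(
        "e1,e2,expected", [(5.0, 3.0, 0), (3.0, 5.0, 1), (4.0, 4.0, 1)]
    )
    def test_rule_including_tie(self, e1, e2, expected):
        assert pf.pair_score(e1, e2) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            pf.pair_score(np.nan, 1.0)


def random_expr(rng, n_genes=10, n_samples=20, cohort="c"):
    genes = [f"g{i:02d}" for i in range(n_genes)]
    return io.ExpressionMatrix(
        cohort,
        pd.DataFrame(
            rng.random((n_genes, n_samples)) * 100,
            index=genes,
            columns=[f"{cohort}-s{j}" for j in range(n_samples)],
        ),
    )


class TestBuildPairMatrix:
    def test_single_pair_single_sample(self):
        em = io.ExpressionMatrix(
            "c", pd.DataFrame({"s": [1.0, 2.0]}, index=["g1", "g2"])
        )
        pm = pf.build_pair_matrix(em, [pf.GenePair("g1", "g2")])
        assert pm.scores[0, 0] == 1

    def test_matches_elementwise_brute_force(self, rng):
        em = random_expr(rng)
        pairs = pf.enumerate_pairs(em.gene_ids)
        pm = pf.build_pair_matrix(em, pairs)
        for k, p in enumerate(pairs):
            for s, sid in enumerate(em.sample_ids):
                expected = pf.pair_score(
                    em.data.loc[p.gene1, sid], em.data.loc[p.gene2, sid]
                )
                assert pm.scores[k, s] == expected

    def test_missing_gene_named(self, rng):
        em = random_expr(rng)
        with pytest.raises(KeyError, match="zz"):
            pf.build_pair_matrix(em, [pf.GenePair("g00", "zz")])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_monotone_invariance(self, seed):
        """The load-bearing property: any strictly increasing per-sample
        transform leaves the pair matrix unchanged."""
        rng = np.random.default_rng(seed)
        em = random_expr(rng, n_genes=6, n_samples=5)
        pairs = pf.enumerate_pairs(em.gene_ids)
        base = pf.build_pair_matrix(em, pairs)
        transforms = [
            lambda v: 2.0 * v + 3.0,
            np.log1p,
            lambda v: v**1.7,
            lambda v: np.exp(v / 50.0),
        ]
        f = transforms[int(rng.integers(len(transforms)))]
        em2 = io.ExpressionMatrix("c", pd.DataFrame(
            f(em.values), index=em.data.index, columns=em.data.columns))
        assert np.array_equal(pf.build_pair_matrix(em2, pairs).scores, base.scores)


def pm_from_scores(scores, cohorts):
    scores = np.asarray(scores)
    pairs = [pf.GenePair(f"a{i:02d}", f"b{i:02d}") for i in range(scores.shape[0])]
    samples = [f"s{j}" for j in range(scores.shape[1])]
    return pf.PairMatrix(pairs, samples, np.array(cohorts, dtype=object), scores)


class TestFilterInformativePairs:
    def test_constant_in_one_cohort_excluded(self):
        pm = pm_from_scores(
            [[1, 1, 0, 1], [0, 1, 0, 1]], ["c1", "c1", "c2", "c2"]
        )
        kept = pf.filter_informative_pairs(pm)
        assert kept == [pm.pairs[1]]

    def test_mixed_everywhere_retained(self):
        pm = pm_from_scores([[0, 1, 1, 0]], ["c1", "c1", "c2", "c2"])
        assert pf.filter_informative_pairs(pm) == pm.pairs

    def test_planted_constants_match_brute_force(self, rng):
        n_pairs, cohorts = 40, np.repeat(["c1", "c2", "c3"], 30)
        scores = (rng.random((n_pairs, 90)) < 0.5).astype(np.uint8)
        planted = rng.choice(n_pairs, size=6, replace=False)
        for i, j in enumerate(planted):
            scores[j] = 0 if i % 2 else 1  # constant everywhere
        pm = pm_from_scores(scores, cohorts)
        kept = set(pf.filter_informative_pairs(pm))
        brute = set()
        for k, p in enumerate(pm.pairs):
            ok = True
            for c in ("c1", "c2", "c3"):
                col = scores[k, cohorts == c]
                if col.min() == col.max():
                    ok = False
            if ok:
                brute.add(p)
        assert kept == brute
        assert all(pm.pairs[j] not in kept for j in planted)

    def test_idempotent(self, rng):
        scores = (rng.random((20, 40)) < 0.3).astype(np.uint8)
        pm = pm_from_scores(scores, ["c1"] * 20 + ["c2"] * 20)
        once = pf.filter_informative_pairs(pm)
        again = pf.filter_informative_pairs(pm.select(once))
        assert once == again

    def test_pooled_mode_is_lenient(self):
        pm = pm_from_scores([[1, 1, 0, 1]], ["c1", "c1", "c2", "c2"])
        assert pf.filter_informative_pairs(pm, mode="pooled") == pm.pairs
        assert pf.filter_informative_pairs(pm, mode="per_cohort") == []

    def test_minority_frequency_option(self):
        pm = pm_from_scores(
            [[1, 0, 0, 0, 0, 1, 0, 0, 0, 0]], ["c1"] * 5 + ["c2"] * 5
        )
        assert pf.filter_informative_pairs(pm) == pm.pairs
        assert pf.filter_informative_pairs(pm, min_minority_freq=0.3) == []

    def test_tiny_cohort_error(self):
        pm = pm_from_scores([[1, 0, 1]], ["c1", "c1", "c2"])
        with pytest.raises(ValueError, match="constancy"):
            pf.filter_informative_pairs(pm)


def test_pair_matrix_tsv_round_trip(tmp_path, rng):
    scores = (rng.random((5, 8)) < 0.5).astype(np.uint8)
    pm = pm_from_scores(scores, ["c1"] * 4 + ["c2"] * 4)
    pf.write_pair_matrix(pm, tmp_path / "pm.tsv")
    back = pf.read_pair_matrix(tmp_path / "pm.tsv", pm.cohort_labels)
    assert back.pairs == pm.pairs
    assert np.array_equal(back.scores, pm.scores)
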