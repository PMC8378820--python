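"""Gene-set enrichment: exact running-sum oracle, permutation statistics,
restoration classification and GMT round trips."""

import itertools
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rescue_seq import (
    GeneSet,
    classify_restored,
    enrichment_score,
    nes_and_fdr,
    rank_genes,
    read_gmt,
    write_gmt,
)

def es_oracle(ranked_genes, scores, members, weight=1):
    """Exact rational running-sum ES; +x / -x ties resolve positive.

    Scores must be given in thousandths so the arithmetic stays exact.
    """
    hits = [g in members for g in ranked_genes]
    n, k = len(ranked_genes), sum(hits)
    assert 0 < k < n
    w = [abs(Fraction(s).limit_denominator(10 ** 6)) ** weight for s in scores]
    total = sum(wi for wi, h in zip(w, hits) if h)
    run = Fraction(0)
    best = Fraction(0)
    for h, wi in zip(hits, w):
        if h:
            run += (wi / total) if total > 0 else Fraction(1, k)
        else:
            run -= Fraction(1, n - k)
        if abs(run) > abs(best) or (abs(run) == abs(best) and run > best):
            best = run
    return float(best)


def _ranked(scores, genes=None):
    genes = genes or [f"g{i}" for i in range(len(scores))]
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], genes[i]))
    return pd.Series([scores[i] for i in order], index=[genes[i] for i in order])


class TestEnrichmentScore:
    def test_single_member_first_is_one(self):
        ranked = _ranked([3.0, 2.0, 1.0, 0.5])
        es, _ = enrichment_score(ranked, GeneSet("s", "", (ranked.index[0],)), weight=0)
        assert es == pytest.approx(1.0, abs=1e-12)

    def test_single_member_last_oracle_value(self):
        # frozen from the exact oracle: misses walk to -1 before the hit
        ranked = _ranked([3.0, 2.0, 1.0, 0.5])
        members = (ranked.index[-1],)
        es, _ = enrichment_score(ranked, GeneSet("s", "", members), weight=0)
        assert es_oracle(list(ranked.index), [1] * 4, set(members), weight=0) == -1.0
        assert es == pytest.approx(-1.0, abs=1e-12)

    def test_exhaustive_small_lists_match_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            n = int(rng.integers(4, 13))
            scores = [round(float(s), 3) for s in rng.normal(size=n)]
            ranked = _ranked(scores)
            genes = list(ranked.index)
            for size in range(1, min(4, n - 1) + 1):
                for members in itertools.combinations(genes, size):
                    es, _ = enrichment_score(ranked, GeneSet("s", "", members))
                    expect = es_oracle(genes, list(ranked.values), set(members))
                    assert es == pytest.approx(expect, abs=1e-9)

    @settings(max_examples=60, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(5, 40), st.integers(1, 4))
    def test_es_bounded(self, seed, n, size):
        rng = np.random.default_rng(seed)
        ranked = _ranked([round(float(s), 3) for s in rng.normal(size=n)])
        members = tuple(rng.choice(ranked.index, size=size, replace=False))
        es, running = enrichment_score(ranked, GeneSet("s", "", members))
        assert -1.0 - 1e-12 <= es <= 1.0 + 1e-12
        assert abs(running[-1]) < 1e-9  # the walk returns to zero

    def test_no_member_rejected(self):
        ranked = _ranked([1.0, 0.5])
        with pytest.raises(ValueError):
            enrichment_score(ranked, GeneSet("s", "", ("absent",)))

    def test_whole_list_rejected(self):
        ranked = _ranked([1.0, 0.5])
        with pytest.raises(ValueError):
            enrichment_score(ranked, GeneSet("s", "", tuple(ranked.index)))


class TestRankGenes:
    def _posthoc(self, genes, diffs, ps):
        return pd.DataFrame({"gene_id": genes, "class_a": "disease",
                             "class_b": "control", "mean_diff_log2": diffs,
                             "p_posthoc": ps})

    def test_score_formula(self):
        post = self._posthoc(["a", "b"], [1.0, 0.5], [0.01, 0.1])
        ranked = rank_genes(None, ("disease", "control"), posthoc_all=post)
        assert ranked["a"] == pytest.approx(2.0)
        assert ranked["b"] == pytest.approx(1.0)
        assert list(ranked.index) == ["a", "b"]

    def test_all_ties_sort_lexicographically(self):
        post = self._posthoc(["z", "m", "a"], [0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        ranked = rank_genes(None, ("disease", "control"), posthoc_all=post)
        assert list(ranked.index) == ["a", "m", "z"]
        assert (ranked == 0).all()

    def test_mirrored_contrast_flips_scores(self):
        post = self._posthoc(["a", "b"], [1.0, -0.5], [0.01, 0.2])
        fwd = rank_genes(None, ("disease", "control"), posthoc_all=post)
        rev = rank_genes(None, ("control", "disease"), posthoc_all=post)
        for g in ("a", "b"):
            assert fwd[g] == pytest.approx(-rev[g])

    def test_zero_p_is_finite(self):
        post = self._posthoc(["a"], [1.0], [0.0])
        ranked = rank_genes(None, ("disease", "control"), posthoc_all=post)
        assert np.isfinite(ranked["a"]) and ranked["a"] > 300


class TestNesAndFdr:
    def _null_inputs(self, seed=5, n=300, n_sets=12):
        rng = np.random.default_rng(seed)
        ranked = _ranked([round(float(s), 3) for s in rng.normal(size=n)],
                         genes=[f"g{i:03d}" for i in range(n)])
        sets = [GeneSet(f"s{i}", "", tuple(rng.choice(ranked.index, 15, replace=False)))
                for i in range(n_sets)]
        return ranked, sets

    def test_nperm_floor_enforced(self):
        ranked, sets = self._null_inputs()
        with pytest.raises(ValueError):
            nes_and_fdr(ranked, sets, n_perm=50)

    def test_nes_sign_and_p_floor(self):
        ranked, sets = self._null_inputs()
        res = nes_and_fdr(ranked, sets, n_perm=200, seed=1)
        assert (np.sign(res["NES"]) == np.sign(res["ES"])).all()
        assert (res["p_perm"] >= 1.0 / 201.0).all()
        assert res["q_fdr"].between(0, 1).all()

    def test_deterministic_and_order_invariant(self):
        ranked, sets = self._null_inputs()
        a = nes_and_fdr(ranked, sets, n_perm=150, seed=3)
        b = nes_and_fdr(ranked, sets[::-1], n_perm=150, seed=3)
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())


class TestClassifyRestored:
    def _table(self, nes, sig):
        return pd.DataFrame({"ES": np.sign(nes), "NES": nes, "p_perm": 0.01,
                             "q_fdr": 0.01, "significant": sig},
                            index=[f"s{i}" for i in range(len(nes))])

    def test_opposite_sign_significant_is_restored(self):
        dis = self._table([-2.0], [True])
        trt = self._table([1.8], [True])
        out = classify_restored(dis, trt)
        assert bool(out["restored"].iloc[0])
        assert out.attrs["summary"]["down"]["fraction_restored"] == 1.0

    def test_same_sign_not_restored(self):
        out = classify_restored(self._table([-2.0], [True]), self._table([-1.8], [True]))
        assert not out["restored"].iloc[0]

    def test_nonsignificant_treatment_not_restored(self):
        out = classify_restored(self._table([-2.0], [True]), self._table([1.8], [False]))
        assert not out["restored"].iloc[0]

    def test_mismatched_collections_rejected(self):
        dis = self._table([-2.0, 1.0], [True, False])
        trt = self._table([1.8], [True]).rename(index={"s0": "other"})
        with pytest.raises(ValueError):
            classify_restored(dis, trt.iloc[:1])


class TestGmt:
    def test_round_trip(self, tmp_path):
        sets = [GeneSet("alpha", "first", ("g1", "g2")),
                GeneSet("beta", "second", ("g3",))]
        path = tmp_path / "sets.gmt"
        write_gmt(sets, path)
        loaded = read_gmt(path)
        assert loaded == sets

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("name_only\tdesc\n")
        with pytest.raises(ValueError):
            read_gmt(path)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            GeneSet("s", "", ())

    def test_duplicate_members_rejected(self):
        with pytest.raises(ValueError):
            GeneSet("s", "", ("g1", "g1"))
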