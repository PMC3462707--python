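"""Rescoring arithmetic and the multiple-template selection stages."""

import math

import numpy as np
import pytest

from tbmcore import synth
from tbmcore.structio import HitRecord
from tbmcore.template_select import (
    SelectionParams, SimilarityMatrix, WeightSchedule, background_pool,
    final_top_filter, pool_filter, rescore, select_templates,
    similarity_matrix, split_rankers, weight_factor, zscore,
)


def hit(tid, seq=0.0, ss=0.0, p=50.0, pairs=()):
    return HitRecord(tid, seq, ss, p, frozenset(pairs))


def rescored_hits(scores, probs=None):
    """HitRecords with preset rescored values, in the given rank order."""
    out = []
    for i, s in enumerate(scores):
        h = hit(f"t{i}", p=probs[i] if probs else 50.0)
        h.rescored = s
        out.append(h)
    return out


class TestZscore:
    def test_direct_arithmetic(self):
        z = zscore([10.0, 8.0, 6.0])
        expect = 2.0 / math.sqrt(8.0 / 3.0)  # population std of (10,8,6)
        np.testing.assert_allclose(z, [expect, 0.0, -expect], atol=1e-9)
        assert z[0] == pytest.approx(1.2247, abs=1e-4)

    def test_constant_input_maps_to_zeros(self):
        np.testing.assert_array_equal(zscore([5.0, 5.0, 5.0]), [0, 0, 0])

    def test_normalization_identity(self):
        rng = np.random.default_rng(0)
        v = rng.normal(3.0, 2.0, 25)
        z = zscore(v)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0, abs=1e-12)

    def test_too_short(self):
        with pytest.raises(ValueError):
            zscore([1.0])


class TestWeightFactor:
    @pytest.mark.parametrize("p,expected", [
        (95.0, 1.0), (90.0, 1.0),   # boundary inclusive: p >= 90
        (89.99, 1.5), (85.0, 1.5), (80.0, 1.5),
        (79.99, 2.0), (70.0, 2.0), (60.0, 2.0),
        (59.9, 2.6), (30.0, 2.6), (0.0, 2.6),
    ])
    def test_schedule_bins(self, p, expected):
        assert weight_factor(p) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            weight_factor(101.0)
        with pytest.raises(ValueError):
            weight_factor(-0.1)

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            WeightSchedule(bins=((90.0, 2.0), (80.0, 1.0), (-math.inf, 3.0)))


class TestRescore:
    def test_equal_scores_keep_order(self):
        hits = [hit("a", 5, 5, 95), hit("b", 5, 5, 90)]
        out = rescore(hits)
        assert [h.template_id for h in out] == ["a", "b"]
        assert all(h.rescored == 0.0 for h in out)

    def test_ss_channel_reverses_ranking_for_hard_target(self):
        # z_seq = (1, -1), z_ss = (-1, 1); top-ranker p = 50 -> w = 2.6
        hits = [hit("a", seq=2.0, ss=0.0, p=50.0),
                hit("b", seq=0.0, ss=2.0, p=40.0)]
        out = rescore(hits)
        s = {h.template_id: h.rescored for h in out}
        assert s["a"] == pytest.approx(1 - 2.6)
        assert s["b"] == pytest.approx(-1 + 2.6)
        assert [h.template_id for h in out] == ["b", "a"]

    def test_weight_from_original_top_ranker_probability(self):
        # same scores, easy top ranker -> w = 1.0, sequence channel wins
        hits = [hit("a", seq=2.0, ss=0.0, p=95.0),
                hit("b", seq=0.0, ss=1.5, p=40.0)]
        out = rescore(hits)
        assert [h.template_id for h in out] == ["a", "b"]

    def test_needs_two_hits(self):
        with pytest.raises(ValueError):
            rescore([hit("a")])


class TestSplitAndPool:
    def test_split_at_95_percent_threshold(self):
        ranked = rescored_hits([10.0, 9.6, 9.4, 5.0])
        high, low = split_rankers(ranked)
        assert high == {"t0", "t1"}
        assert low == {"t2", "t3"}

    def test_all_equal_all_high(self):
        high, low = split_rankers(rescored_hits([3.0, 3.0, 3.0]))
        assert high == {"t0", "t1", "t2"} and low == set()

    def test_single_hit(self):
        high, low = split_rankers(rescored_hits([1.0]))
        assert high == {"t0"} and low == set()

    def test_nonpositive_top_score_degenerates(self):
        high, _ = split_rankers(rescored_hits([-0.5, -1.0, -2.0]))
        assert high == {"t0"}

    def test_pool_is_high_or_top3_whichever_greater(self):
        ranked = rescored_hits([10, 9, 8, 7, 6])
        assert background_pool({"t0", "t1"}, ranked) == {"t0", "t1", "t2"}
        assert background_pool({"t0", "t1", "t2", "t3"}, ranked) == {
            "t0", "t1", "t2", "t3"}

    def test_pool_with_fewer_than_three_candidates(self):
        ranked = rescored_hits([10, 9])
        assert background_pool({"t0"}, ranked) == {"t0", "t1"}


def pool_filter_oracle(candidates, pool, sims, ranked):
    """Independent step-by-step transcription of the removal rule."""
    s = {h.template_id: h.rescored for h in ranked}
    top = ranked[0].template_id
    thr = 0.95 * s[top]
    high = ({c.template_id for c in ranked if c.rescored >= thr}
            if s[top] > 0 else {top})
    high.add(top)

    def mean_tm(c):
        others = [q for q in pool if q != c]
        return (sum(sims.value(c, q) for q in others) / len(others)
                if others else 1.0)

    vals = [mean_tm(q) for q in pool]
    m = sum(vals) / len(vals)
    sd = math.sqrt(sum((v - m) ** 2 for v in vals) / len(vals))
    kept = []
    for c in candidates:
        if c == top:
            kept.append(c)
            continue
        alpha = 1.0 if c in high else min(1.0, max(0.0, s[c] / s[top] if s[top] > 0 else 0.0))
        if mean_tm(c) >= m - alpha * sd:
            kept.append(c)
    return kept


def random_instance(rng, n):
    scores = np.sort(rng.normal(0, 2, n))[::-1]
    ranked = rescored_hits(list(scores))
    ids = [h.template_id for h in ranked]
    base = rng.uniform(0.2, 1.0, (n, n))
    tm = np.clip((base + base.T) / 2, 0.01, 1.0)
    np.fill_diagonal(tm, 1.0)
    sims = SimilarityMatrix(ids, tm)
    high, _ = split_rankers(ranked)
    pool = background_pool(high, ranked)
    return ids, pool, sims, ranked


class TestPoolFilter:
    def test_identical_structures_all_retained(self):
        ranked = rescored_hits([5, 4, 3, 2])
        ids = [h.template_id for h in ranked]
        sims = SimilarityMatrix(ids, np.ones((4, 4)))
        kept = pool_filter(ids, {"t0", "t1", "t2"}, sims, ranked)
        assert kept == ids  # sigma = 0, cutoff = 1, nothing strictly below

    def test_outlier_removed(self):
        # hand evaluation: pool sims ~0.9 +- 0.02, outlier ~0.3
        ranked = rescored_hits([10.0, 9.9, 9.8, 9.7])
        ids = [h.template_id for h in ranked]
        # pool member mean-sims: (0.90, 0.90, 0.92); m = 0.9067,
        # sigma = 0.0094, cutoff = 0.8972 -> pool kept, outlier 0.30 removed
        tm = np.array([[1.00, 0.88, 0.92, 0.30],
                       [0.88, 1.00, 0.92, 0.30],
                       [0.92, 0.92, 1.00, 0.30],
                       [0.30, 0.30, 0.30, 1.00]])
        sims = SimilarityMatrix(ids, tm)
        kept = pool_filter(ids, {"t0", "t1", "t2"}, sims, ranked)
        assert kept == ["t0", "t1", "t2"]

    def test_low_ranker_with_top_score_ratio_one(self):
        # a low-ranker whose S equals the top score gets alpha = 1,
        # i.e. the same cutoff as a high-ranker would
        ranked = rescored_hits([10.0, 10.0, 9.0, 2.0])
        ids = [h.template_id for h in ranked]
        rng = np.random.default_rng(4)
        base = rng.uniform(0.5, 1.0, (4, 4))
        tm = np.clip((base + base.T) / 2, 0, 1)
        np.fill_diagonal(tm, 1.0)
        sims = SimilarityMatrix(ids, tm)
        pool = {"t0", "t1", "t2"}
        kept = pool_filter(ids, pool, sims, ranked)
        assert kept == pool_filter_oracle(ids, pool, sims, ranked)

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = int(rng.integers(3, 9))
            ids, pool, sims, ranked = random_instance(rng, n)
            assert pool_filter(ids, pool, sims, ranked) == \
                pool_filter_oracle(ids, pool, sims, ranked)

    def test_empty_pool_rejected(self):
        ranked = rescored_hits([1.0, 0.5])
        sims = SimilarityMatrix(["t0", "t1"], np.ones((2, 2)))
        with pytest.raises(ValueError):
            pool_filter(["t0", "t1"], set(), sims, ranked)


class TestFinalTopFilter:
    def test_strict_cutoff_boundary(self):
        kept = final_top_filter(["top", "a", "b"],
                                {"top": 1.0, "a": 0.50, "b": 0.49})
        assert kept == ["top", "a"]  # 0.50 retained, 0.49 removed

    def test_top_ranker_always_retained(self):
        assert final_top_filter(["top"], {"top": 1.0}) == ["top"]

    def test_missing_tm_value(self):
        with pytest.raises(KeyError):
            final_top_filter(["top", "a"], {"top": 1.0})


class TestSelectTemplates:
    def test_unrelated_decoys_excluded(self, family):
        spec, native, templates, tm_truth = family
        order = sorted(templates, key=lambda t: -tm_truth[t])
        hits = synth.make_hits(spec, order)
        selected = select_templates(hits, templates, spec.target_length)
        assert selected
        assert "decoy00" not in selected and "decoy01" not in selected
        assert selected[0] == order[0]

    def test_single_hit_passthrough(self, family):
        spec, _, templates, _ = family
        h = hit("tmpl00", 10, 5, 90, [(i, i) for i in range(1, 10)])
        assert select_templates([h], templates, spec.target_length) == ["tmpl00"]

    def test_order_invariance_for_equal_scores(self, family):
        spec, _, templates, _ = family
        pairs = [(i, i) for i in range(1, spec.target_length + 1)]
        a = [hit("tmpl00", 5, 5, 95, pairs), hit("tmpl01", 5, 5, 95, pairs),
             hit("tmpl02", 3, 3, 90, pairs)]
        b = [a[1], a[0], a[2]]  # swap the two equal-score hits
        sa = select_templates(a, templates, spec.target_length)
        sb = select_templates(b, templates, spec.target_length)
        assert set(sa) == set(sb)

    def test_output_subset_of_top_candidates_and_monotone_cutoff(self, family):
        spec, _, templates, tm_truth = family
        order = sorted(templates, key=lambda t: -tm_truth[t])
        hits = synth.make_hits(spec, order)
        loose = select_templates(hits, templates, spec.target_length,
                                 SelectionParams(final_tm_cutoff=0.3))
        strict = select_templates(hits, templates, spec.target_length,
                                  SelectionParams(final_tm_cutoff=0.7))
        assert set(strict) <= set(loose) <= set(templates)

    def test_top_hit_survives_random_tables(self, family):
        spec, _, templates, _ = family
        ids = list(templates)
        pairs = [(i, i) for i in range(1, spec.target_length + 1)]
        rng = np.random.default_rng(7)
        for _ in range(25):
            hits = [hit(t, rng.normal(50, 10), rng.normal(25, 5),
                        float(rng.uniform(5, 100)), pairs) for t in ids]
            hits[0].probability = float(rng.uniform(20, 100))
            selected = select_templates(hits, templates, spec.target_length)
            top = rescore(hits)[0].template_id
            assert top in selected and selected[0] == top
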