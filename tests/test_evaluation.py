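import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _oracles as oracle
from bclr import (
    EdgeStandard,
    ScoreMatrix,
    aupr,
    feo_ratio,
    mae,
    mean_ci,
    pr_curve,
    welch_ttest,
)


def score_matrix(gene_ids, triu):
    n = len(gene_ids)
    m = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    m[iu] = triu
    m += m.T
    return ScoreMatrix(gene_ids, m)


def random_scores(rng, n=5):
    return score_matrix(
        [f"g{i}" for i in range(n)], rng.uniform(size=n * (n - 1) // 2)
    )


class TestMAE:
    def test_identity_is_zero(self, rng):
        a = random_scores(rng)
        assert mae(a, a) == 0.0

    def test_uniform_shift_returns_the_shift(self, rng):
        a = random_scores(rng)
        shifted = ScoreMatrix(
            a.gene_ids, np.where(np.eye(a.n_genes, dtype=bool), 0.0, a.scores + 0.25)
        )
        assert mae(a, shifted) == pytest.approx(0.25, abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_scores(rng), random_scores(rng)
        assert mae(a, b) == pytest.approx(
            oracle.upper_mae(a.scores, b.scores), abs=1e-12
        )

    def test_gene_set_mismatch_lists_symmetric_difference(self, rng):
        a = random_scores(rng, 4)
        b = score_matrix(["g0", "g1", "g2", "gX"], rng.uniform(size=6))
        with pytest.raises(ValueError, match="g3.*gX|gX.*g3"):
            mae(a, b)

    def test_is_a_metric_on_random_triples(self, rng):
        a, b, c = (random_scores(rng) for _ in range(3))
        assert mae(a, b) == pytest.approx(mae(b, a), abs=1e-15)
        assert mae(a, c) <= mae(a, b) + mae(b, c) + 1e-12
        assert mae(a, b) > 0


def standard(positives, negatives):
    return EdgeStandard(frozenset(positives), frozenset(negatives))


class TestPRCurve:
    def test_perfect_ranking_geometry(self):
        sm = score_matrix(list("abcd"), [0.9, 0.8, 0.1, 0.2, 0.3, 0.05])
        # positives get the two top-scoring pairs (a,b)=0.9 and (a,c)=0.8
        std = standard(
            [("a", "b"), ("a", "c")],
            [("a", "d"), ("b", "c"), ("b", "d"), ("c", "d")],
        )
        curve = pr_curve(sm, std)
        assert curve.precision[0] == 1.0
        assert curve.recall[-1] == 1.0
        assert curve.precision[-1] == pytest.approx(curve.prevalence)
        assert aupr(sm, std) == 1.0

    def test_all_tied_scores_collapse_to_one_threshold(self):
        sm = score_matrix(list("abc"), [0.5, 0.5, 0.5])
        std = standard([("a", "b")], [("a", "c"), ("b", "c")])
        curve = pr_curve(sm, std)
        assert len(curve.thresholds) == 1
        assert curve.recall[0] == 1.0
        assert curve.precision[0] == pytest.approx(1 / 3)
        assert aupr(sm, std) == pytest.approx(curve.prevalence)

    def test_masked_pairs_are_ignored(self, rng):
        sm = random_scores(rng, 4)
        std = standard([("g0", "g1")], [("g0", "g2")])
        curve = pr_curve(sm, std)
        assert curve.n_evaluated == 2  # the other 4 pairs stay masked

    def test_recall_is_nondecreasing(self, rng):
        sm = random_scores(rng, 6)
        std = standard(
            [("g0", "g1"), ("g2", "g3")], [("g0", "g2"), ("g1", "g4"), ("g3", "g5")]
        )
        curve = pr_curve(sm, std)
        assert np.all(np.diff(curve.recall) >= 0)

    def test_needs_positives_and_negatives(self, rng):
        sm = random_scores(rng, 3)
        with pytest.raises(ValueError, match="positive"):
            pr_curve(sm, standard([], []))
        with pytest.raises(ValueError, match="negative"):
            pr_curve(sm, standard([("g0", "g1")], []))

    def test_directed_pairs_share_the_undirected_score(self, rng):
        sm = random_scores(rng, 3)
        both = standard([("g0", "g1")], [("g1", "g0")])
        curve = pr_curve(sm, both)
        # both orientations evaluated, same score -> single tied threshold
        assert curve.n_evaluated == 2
        assert len(curve.thresholds) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_threshold_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        sm = random_scores(rng, 4)
        std = standard(
            [("g0", "g1"), ("g2", "g3")],
            [("g0", "g2"), ("g0", "g3"), ("g1", "g2"), ("g1", "g3")],
        )
        pairs = sorted(std.positives) + sorted(std.negatives)
        scores = [sm.pair_score(*p) for p in pairs]
        labels = [1, 1, 0, 0, 0, 0]
        expected = oracle.pr_points(scores, labels)
        curve = pr_curve(sm, std)
        got = list(zip(curve.precision, curve.recall))
        assert got == pytest.approx(expected, abs=1e-12)
        assert aupr(sm, std) == pytest.approx(oracle.aupr(scores, labels), abs=1e-12)


class TestAUPRProperties:
    def test_agrees_with_sklearn_average_precision(self, rng):
        # sklearn's AP is the same tie-grouped rectangular sum
        from sklearn.metrics import average_precision_score

        sm = random_scores(rng, 6)
        std = standard(
            [("g0", "g1"), ("g2", "g3"), ("g1", "g5")],
            [("g0", "g2"), ("g1", "g4"), ("g3", "g5"), ("g4", "g5"), ("g0", "g3")],
        )
        pairs = sorted(std.positives) + sorted(std.negatives)
        y = [1] * 3 + [0] * 5
        s = [sm.pair_score(*p) for p in pairs]
        assert aupr(sm, std) == pytest.approx(
            average_precision_score(y, s), abs=1e-12
        )

    @pytest.mark.parametrize(
        "transform", [lambda s: s**3, lambda s: np.log1p(s)]
    )
    def test_invariant_under_monotone_transforms(self, rng, transform):
        sm = random_scores(rng, 6)
        std = standard(
            [("g0", "g1"), ("g2", "g3")],
            [("g0", "g2"), ("g1", "g4"), ("g3", "g5"), ("g4", "g5")],
        )
        transformed = ScoreMatrix(
            sm.gene_ids,
            np.where(np.eye(6, dtype=bool), 0.0, transform(sm.scores)),
        )
        assert aupr(transformed, std) == pytest.approx(aupr(sm, std), abs=1e-12)

    def test_random_ranking_concentrates_near_prevalence(self):
        # an uninformative ranking scores close to the prevalence; the
        # rectangular AUPR has a small positive bias at finite size
        # (early lucky positives earn high precision), so the check is
        # an envelope above and a hard floor below
        rng = np.random.default_rng(42)
        genes = [f"g{i}" for i in range(26)]
        pairs = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1:]]
        std = standard(pairs[:60], pairs[60:325])
        prev = 60 / 325
        n_pairs = len(pairs)
        vals = []
        for _ in range(200):
            sm = score_matrix(genes, rng.permutation(n_pairs) / n_pairs)
            vals.append(aupr(sm, std))
        vals = np.array(vals)
        assert prev - 0.01 < vals.mean() < prev + 0.05


class TestFEORatio:
    def test_all_edges_in_one_category_is_one(self):
        ann = {"a": {"K"}, "b": {"K"}, "c": {"K"}}
        assert feo_ratio([("a", "b"), ("b", "c")], ann) == 1.0

    def test_no_same_category_edges_is_zero(self):
        ann = {"a": {"K1"}, "b": {"K2"}}
        assert feo_ratio([("a", "b")], ann) == 0.0

    def test_unannotated_endpoints_are_ignored(self):
        # 5 edges, one involving an unannotated gene; 2 of the 4
        # remaining edges link a shared category -> 0.5
        ann = {"a": {"K1"}, "b": {"K1"}, "c": {"K2"}, "d": {"K1", "K2"}, "e": {"K3"}}
        edges = [("a", "b"), ("c", "d"), ("a", "e"), ("b", "e"), ("a", "x")]
        assert feo_ratio(edges, ann) == 0.5

    def test_undefined_when_no_annotated_edges(self):
        assert feo_ratio([("a", "b")], {"a": {"K"}}) is None

    def test_empty_edge_set_is_an_error(self):
        with pytest.raises(ValueError):
            feo_ratio([], {"a": {"K"}})

    def test_adding_same_category_edge_never_decreases(self, rng):
        ann = {f"g{i}": {f"K{rng.integers(3)}"} for i in range(10)}
        edges = [(f"g{i}", f"g{j}") for i in range(10) for j in range(i + 1, 10)]
        rng.shuffle(edges)
        subset = edges[:10]
        base = oracle.feo(subset, ann)
        same = [
            e for e in edges[10:]
            if ann[e[0]] & ann[e[1]]
        ]
        if base is not None and same:
            grown = feo_ratio(subset + [same[0]], ann)
            assert grown >= base


class TestWelch:
    def test_identical_samples_give_t0_p1(self):
        r = welch_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0 and r.pvalue == 1.0

    def test_separated_means_are_significant(self):
        r = welch_ttest([1.0, 2.0, 3.0], [101.0, 102.0, 103.0])
        assert r.pvalue < 0.01

    def test_matches_numerically_integrated_formulas(self, rng):
        xs = rng.normal(0, 1, 5)
        ys = rng.normal(0.8, 2, 5)
        t, df, p = oracle.welch(xs, ys)
        r = welch_ttest(xs, ys)
        assert r.statistic == pytest.approx(t, abs=1e-10)
        assert r.df == pytest.approx(df, abs=1e-10)
        assert r.pvalue == pytest.approx(p, abs=1e-8)

    def test_sample_of_one_is_a_hard_error(self):
        with pytest.raises(ValueError, match="2"):
            welch_ttest([1.0], [1.0, 2.0, 3.0])


class TestMeanCI:
    def test_constant_samples_give_zero_width(self):
        s = mean_ci([2.0, 2.0, 2.0, 2.0])
        assert s.ci_lower == s.mean == s.ci_upper == 2.0

    def test_matches_hand_computed_t_interval(self):
        rng = np.random.default_rng(99)
        x = rng.standard_normal(10)
        s = mean_ci(x, level=0.99)
        q = oracle.t_quantile(0.995, 9)
        half = q * x.std(ddof=1) / np.sqrt(10)
        assert s.ci_lower == pytest.approx(x.mean() - half, abs=1e-9)
        assert s.ci_upper == pytest.approx(x.mean() + half, abs=1e-9)

    def test_intervals_nest_with_level(self, rng):
        x = rng.standard_normal(8)
        narrow = mean_ci(x, level=0.5)
        wide = mean_ci(x, level=0.99)
        assert wide.ci_lower < narrow.ci_lower <= narrow.ci_upper < wide.ci_upper

    def test_fewer_than_two_samples_is_an_error(self):
        with pytest.raises(ValueError):
            mean_ci([1.0])


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.lists(st.floats(0, 10, allow_nan=False), min_size=3, max_size=15))
def test_mae_zero_iff_equal(triu):
    n = next(k for k in range(3, 20) if k * (k - 1) // 2 >= len(triu))
    triu = (triu + [0.0] * (n * (n - 1) // 2))[: n * (n - 1) // 2]
    genes = [f"g{i}" for i in range(n)]
    a = score_matrix(genes, triu)
    assert mae(a, a) == 0.0
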