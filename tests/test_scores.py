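import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sigmatch.scores import (
    DEFAULT_CHANGE_THRESHOLD,
    METHODS,
    POLARITY,
    ScoreError,
    ScoreSpec,
    correlation,
    ks_statistic,
    kraskov_mi,
    lp_distance,
    mutual_information,
    score_all,
    score_pair,
    set_overlap,
)
from sigmatch.mine import mine_stats

from conftest import toy_cube

vec = st.lists(st.floats(-10, 10, allow_nan=False), min_size=3, max_size=30)


class TestLpNorms:
    def test_hand_arithmetic(self):
        x, y = np.array([1.0, 2.0]), np.array([4.0, 6.0])
        assert lp_distance(x, y, 1) == pytest.approx(7.0)
        assert lp_distance(x, y, 2) == pytest.approx(5.0)
        assert lp_distance(x, y, np.inf) == pytest.approx(4.0)

    def test_identity_zero(self, rng):
        x = rng.normal(size=20)
        for p in (1, 2, np.inf):
            assert lp_distance(x, x, p) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(pair=st.tuples(vec, vec).filter(lambda t: len(t[0]) == len(t[1])))
    def test_norm_ordering(self, pair):
        x, y = np.asarray(pair[0]), np.asarray(pair[1])
        l1 = lp_distance(x, y, 1)
        l2 = lp_distance(x, y, 2)
        linf = lp_distance(x, y, np.inf)
        assert linf <= l2 + 1e-12
        assert l2 <= l1 + 1e-12

    def test_empty_errors(self):
        with pytest.raises(ScoreError):
            lp_distance(np.array([]), np.array([]), 2)


class TestCorrelation:
    def test_pearson_printed_example(self):
        assert correlation([1, 2, 3, 4], [1, 3, 2, 4], "pearson") == pytest.approx(0.8)

    def test_perfect_monotone_linear(self, rng):
        x = rng.normal(size=30)
        y = 2 * x + 1
        for m in ("pearson", "spearman", "bicor"):
            assert correlation(x, y, m) == pytest.approx(1.0)

    def test_centered_cosine_is_pearson(self, rng):
        x, y = rng.normal(size=40), rng.normal(size=40)
        assert correlation(x, y, "cosine", center=True) == pytest.approx(
            correlation(x, y, "pearson"), abs=1e-12
        )

    def test_degenerate_variance_missing(self, caplog):
        with caplog.at_level(logging.WARNING, logger="sigmatch"):
            v = correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], "pearson")
        assert np.isnan(v)
        assert "degenerate" in caplog.text

    def test_gini_forms(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        g1 = correlation(x, y, "gini", form="xy")
        g2 = correlation(x, y, "gini", form="yx")
        gm = correlation(x, y, "gini", form="mean")
        assert gm == pytest.approx((g1 + g2) / 2)
        assert correlation(x, 2 * x + 3, "gini") == pytest.approx(1.0)

    def test_needs_three_genes(self):
        with pytest.raises(ScoreError):
            correlation([1.0, 2.0], [1.0, 2.0], "pearson")


class TestKS:
    def test_same_multiset_zero(self):
        assert ks_statistic([3, 1, 2], [1, 2, 3]) == 0.0

    def test_full_separation_one(self):
        assert ks_statistic([1, 2, 3], [10, 11, 12]) == 1.0

    def test_printed_example(self):
        assert ks_statistic([1, 2, 3], [1, 2, 9]) == pytest.approx(1 / 3)


class TestSetOverlap:
    # genes: g1 changed only in x, g2 in both, g3 only in y
    X = np.array([1.0, 1.0, 0.0])
    Y = np.array([0.0, 1.0, 1.0])

    def test_printed_jaccard(self):
        assert set_overlap(self.X, self.Y, 0.5, "any") == pytest.approx(1 / 3)
        assert set_overlap(self.X, self.Y, 0.5, "any", normalize=False) == 1.0

    def test_self_same_direction_full(self):
        assert set_overlap(self.X, self.X, 0.5, "same") == 1.0
        assert set_overlap(self.X, self.X, 0.5, "opposite") == 0.0

    def test_union_empty_missing(self, caplog):
        with caplog.at_level(logging.WARNING, logger="sigmatch"):
            v = set_overlap(self.X, self.Y, change_threshold=10.0)
        assert np.isnan(v)
        assert "threshold" in caplog.text

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(pair=st.tuples(vec, vec).filter(lambda t: len(t[0]) == len(t[1])))
    def test_direction_decomposition(self, pair):
        x, y = np.asarray(pair[0]), np.asarray(pair[1])
        thr = DEFAULT_CHANGE_THRESHOLD
        j_any = set_overlap(x, y, thr, "any", normalize=False)
        j_same = set_overlap(x, y, thr, "same", normalize=False)
        j_opp = set_overlap(x, y, thr, "opposite", normalize=False)
        assert j_any >= j_same and j_any >= j_opp
        # partition: sign() comparisons split the matched set exactly
        assert j_same + j_opp == j_any


class TestMutualInformation:
    def test_independent_near_null(self, rng):
        x, y = rng.normal(size=500), rng.normal(size=500)
        mi = kraskov_mi(x, y)
        null = [kraskov_mi(x, rng.permutation(y)) for _ in range(200)]
        assert mi <= np.mean(null) + 3 * np.std(null) + 1e-9

    def test_mic_of_identity_is_one(self, rng):
        x = rng.normal(size=50)  # even n: the 2x2 grid is exact
        assert mine_stats(x, x)["mic"] == pytest.approx(1.0)

    def test_monotone_transform_invariance(self, rng):
        x, y = rng.normal(size=500), rng.normal(size=500)
        y = 0.7 * x + y
        base = kraskov_mi(x, y)
        warped = kraskov_mi(np.exp(x), y**3)
        assert warped == pytest.approx(base, abs=0.05)

    def test_constant_input_zero(self):
        x = np.ones(50)
        y = np.arange(50.0)
        assert mutual_information(x, y, "mic") == 0.0
        assert kraskov_mi(x, y) == 0.0


class TestScoreSpec:
    def test_unknown_method_lists_valid(self):
        with pytest.raises(ScoreError, match="pearson"):
            ScoreSpec("nonsense")

    def test_polarity_table(self):
        for m in ("l1", "l2", "linf", "ks"):
            assert POLARITY[m] == "distance"
        assert ScoreSpec("pearson").polarity == "similarity"

    def test_param_validation(self):
        with pytest.raises(ScoreError):
            ScoreSpec("jaccard", params={"direction": "sideways"})
        with pytest.raises(ScoreError):
            ScoreSpec("knn_mi", params={"k": 0})


class TestScoreAll:
    def test_self_exclusion(self, small_cube):
        res = score_all(small_cube, small_cube.instances[0], ScoreSpec("pearson"))
        assert len(res) == small_cube.n_instances - 1
        assert all(r.candidate != small_cube.instances[0] for r in res)

    def test_duplicate_column_attains_optimum(self):
        fc = [1.0, -2.0, 0.5, 0.0]
        cube = toy_cube({"a": fc, "dup": fc, "c": [0.2, 0.3, -1.0, 2.0]},
                        drug_of={"a": "D1", "dup": "D1", "c": "D2"})
        res_p = score_all(cube, cube.instances[0], ScoreSpec("pearson"))
        res_d = score_all(cube, cube.instances[0], ScoreSpec("l2"))
        by_cand_p = {r.candidate.cell_line + r.candidate.drug_id: r.value for r in res_p}
        assert max(r.value for r in res_p) == pytest.approx(1.0)
        dup = [r for r in res_p if r.candidate.drug_id == "D1"][0]
        assert dup.value == pytest.approx(1.0)
        dup2 = [r for r in res_d if r.candidate.drug_id == "D1"][0]
        assert dup2.value == pytest.approx(0.0, abs=1e-12)

    def test_candidate_order_invariance(self, rng):
        cols = {f"i{k}": rng.normal(size=8) for k in range(5)}
        cube = toy_cube(cols)
        perm_names = ["i3", "i0", "i4", "i2", "i1"]
        cube_p = toy_cube({n: cols[n] for n in perm_names},
                          drug_of={n: f"D{int(n[1:])}" for n in perm_names})
        q = cube.instances[0]
        res_a = {r.candidate.drug_id: r.value
                 for r in score_all(cube, q, ScoreSpec("spearman"))}
        qp = [k for k in cube_p.instances if k.drug_id == "D0"][0]
        res_b = {r.candidate.drug_id: r.value
                 for r in score_all(cube_p, qp, ScoreSpec("spearman"))}
        assert res_a == pytest.approx(res_b)


@pytest.mark.parametrize("method", [m for m in METHODS
                                    if m not in ("knn_mi", "mic", "gmic", "mev")])
def test_symmetry(method, rng):
    """score(x, y) == score(y, x) for every unfiltered method."""
    x, y = rng.normal(size=40), rng.normal(size=40)
    spec = ScoreSpec(method)
    assert score_pair(x, y, spec) == pytest.approx(score_pair(y, x, spec), abs=1e-12)


def test_symmetry_information_methods(rng):
    # separate: MINE/KSG are costlier, one pair suffices
    x, y = rng.normal(size=60), rng.normal(size=60)
    for method in ("knn_mi", "mic", "gmic", "mev"):
        spec = ScoreSpec(method)
        assert score_pair(x, y, spec) == pytest.approx(
            score_pair(y, x, spec), abs=1e-12)
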