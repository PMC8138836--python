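import numpy as np
import pandas as pd
import pytest

from sigmatch import SimConfig, simulate_effect_cube, simulate_network
from sigmatch.filters import (
    FilterError,
    FilterSpec,
    GeneNetwork,
    focus_filter,
    landmark_filter,
    top_n_filter,
    tune_focus_to_n,
)

from conftest import toy_cube


class TestGeneNetwork:
    def test_canonical_storage(self):
        net = GeneNetwork.from_edge_list(
            [("g2", "g1", 0.95), ("g1", "g2", 0.92), ("g3", "g4", 0.91)]
        )
        assert net.n_edges == 2  # reversed duplicate collapsed
        assert (net.edges["gene_a"] <= net.edges["gene_b"]).all()

    def test_self_loop_rejected(self):
        with pytest.raises(FilterError, match="self-loop"):
            GeneNetwork.from_edge_list([("g1", "g1", 0.95)])

    def test_weight_bounds(self):
        with pytest.raises(FilterError, match="weight"):
            GeneNetwork.from_edge_list([("g1", "g2", 1.5)])


class TestTopN:
    def test_abs_fc_example(self):
        cube = toy_cube({"a": [0.1, -2.0, 1.5]})
        out = top_n_filter(cube, cube.instances[0], "abs_fc", 2)
        assert list(out) == ["g1", "g2"]  # |-2.0| then |1.5|

    def test_n_exceeding_gene_count(self):
        cube = toy_cube({"a": [0.1, -2.0, 1.5]})
        out = top_n_filter(cube, cube.instances[0], "abs_fc", 99)
        assert list(out) == ["g1", "g2", "g0"]

    @pytest.mark.parametrize("criterion", ["abundance", "abs_fc", "abs_z", "p_value"])
    def test_nesting(self, small_cube, criterion):
        inst = small_cube.instances[0]
        top5 = set(top_n_filter(small_cube, inst, criterion, 5))
        top10 = set(top_n_filter(small_cube, inst, criterion, 10))
        assert top5 <= top10

    def test_tie_break_by_gene_id(self):
        cube = toy_cube({"a": [1.0, 1.0, 1.0, 2.0]})
        out = top_n_filter(cube, cube.instances[0], "abs_fc", 3)
        assert list(out) == ["g3", "g0", "g1"]

    def test_unknown_criterion(self, small_cube):
        with pytest.raises(FilterError):
            top_n_filter(small_cube, small_cube.instances[0], "magic", 5)


class TestLandmark:
    def test_superset_is_identity(self, small_cube):
        out = landmark_filter(small_cube, list(small_cube.gene_ids) + ["extra"])
        assert list(out) == list(small_cube.gene_ids)

    def test_single_gene(self, small_cube):
        g = str(small_cube.gene_ids[7])
        assert list(landmark_filter(small_cube, [g])) == [g]

    def test_empty_intersection_errors(self, small_cube):
        with pytest.raises(FilterError, match="empty intersection"):
            landmark_filter(small_cube, ["not-a-gene"])

    def test_instance_independence(self):
        for seed in (1, 2, 3):
            cube, _ = simulate_effect_cube(
                SimConfig(seed=seed, n_drugs=4, n_genes=50))
            spec = FilterSpec(method="landmark",
                              gene_set=[str(g) for g in cube.gene_ids[::3]])
            outs = {tuple(spec.select(cube, inst)) for inst in cube.instances}
            assert len(outs) == 1


class TestFocus:
    def _series(self, vals):
        return pd.Series(vals, index=[f"g{i}" for i in range(len(vals))])

    def test_node_criterion_alone(self):
        net = GeneNetwork(pd.DataFrame(columns=["gene_a", "gene_b", "weight"]))
        out = focus_filter(net, self._series([0.6, 0.1]), self._series([0.0, 0.0]),
                           fc_threshold=0.5, expr_threshold=np.inf, link_threshold=1.0)
        assert list(out) == ["g0"]

    def test_zero_thresholds_keep_all(self):
        net = GeneNetwork.from_edge_list([("g0", "g1", 0.95)])
        out = focus_filter(net, self._series([0.6, 0.1, 0.0]),
                           self._series([0.0, 0.0, 0.0]),
                           fc_threshold=0.0, expr_threshold=0.0, link_threshold=0.0)
        assert list(out) == ["g0", "g1", "g2"]

    def test_two_edge_toy_hand_enumerated(self):
        # edges (g0,g1) |0.8+0.4|=1.2 >= 1.0 keeps both; (g2,g3) |0.3-0.5|=0.2 < 1.0
        net = GeneNetwork.from_edge_list([("g0", "g1", 0.95), ("g2", "g3", 0.95)])
        logfc = self._series([0.8, 0.4, 0.3, -0.5, 0.05])
        out = focus_filter(net, logfc, self._series([0.0] * 5),
                           fc_threshold=np.inf, expr_threshold=np.inf,
                           link_threshold=1.0)
        assert list(out) == ["g0", "g1"]

    def test_missing_gene_error(self):
        net = GeneNetwork.from_edge_list([("g0", "gZ", 0.95)])
        with pytest.raises(FilterError, match="gZ"):
            focus_filter(net, self._series([0.1, 0.2]), self._series([0.0, 0.0]),
                         0.5, 0.5, 0.5)

    def test_edge_permutation_and_swap_invariance(self, rng):
        genes = [f"g{i}" for i in range(20)]
        triples = [(genes[i], genes[j], 0.95)
                   for i in range(20) for j in range(i + 1, 20)
                   if rng.random() < 0.2]
        logfc = pd.Series(rng.normal(size=20), index=genes)
        ad = pd.Series(rng.normal(size=20), index=genes)
        base = focus_filter(GeneNetwork.from_edge_list(triples), logfc, ad,
                            0.8, 1.0, 1.2)
        shuffled = [triples[i] for i in rng.permutation(len(triples))]
        swapped = [(b, a, w) for a, b, w in shuffled]
        other = focus_filter(GeneNetwork.from_edge_list(swapped), logfc, ad,
                             0.8, 1.0, 1.2)
        assert list(base) == list(other)


class TestTuner:
    def _inputs(self, n=500, seed=5):
        rng = np.random.default_rng(seed)
        genes = [f"g{i:05d}" for i in range(n)]
        logfc = pd.Series(rng.normal(scale=0.8, size=n), index=genes)
        ad = pd.Series(rng.normal(scale=2.0, size=n), index=genes)
        net = simulate_network(n, 0.01, seed=seed, gene_ids=genes)
        return net, logfc, ad

    def test_target_all_genes(self):
        net, logfc, ad = self._inputs(50)
        th, count = tune_focus_to_n(net, logfc, ad, target_n=50)
        assert count == 50
        assert th["scale"] == pytest.approx(0.0, abs=1e-9)

    def test_kept_count_monotone_in_scale(self):
        net, logfc, ad = self._inputs(100, seed=11)
        counts = []
        for scale in np.linspace(0, 1.05, 12):
            counts.append(len(focus_filter(
                net, logfc, ad,
                fc_threshold=scale * logfc.abs().max(),
                expr_threshold=scale * ad.abs().max(),
                link_threshold=scale * 2 * logfc.abs().max(),
            )))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_target_100_of_500_within_5pct(self):
        net, logfc, ad = self._inputs(500)
        th, count = tune_focus_to_n(net, logfc, ad, target_n=100, tolerance=0.05)
        assert 95 <= count <= 105


class TestFilterSpec:
    def test_validation(self):
        with pytest.raises(FilterError):
            FilterSpec(method="fc_top")  # n missing
        with pytest.raises(FilterError):
            FilterSpec(method="landmark")  # gene_set missing
        with pytest.raises(FilterError):
            FilterSpec(method="focus", n=10)  # network missing
        with pytest.raises(FilterError):
            FilterSpec(method="bogus")

    def test_purity_and_containment(self, small_cube):
        spec = FilterSpec(method="fc_top", n=20)
        inst = small_cube.instances[3]
        a = spec.select(small_cube, inst)
        b = spec.select(small_cube, inst)
        assert list(a) == list(b)
        assert len(set(a)) == len(a)
        assert set(a) <= set(small_cube.gene_ids)

    def test_focus_spec_reaches_target(self, small_cube):
        net = simulate_network(small_cube.n_genes, 0.02, seed=3,
                               gene_ids=list(small_cube.gene_ids))
        spec = FilterSpec(method="focus", n=30, network=net)
        out = spec.select(small_cube, small_cube.instances[0])
        assert 20 <= len(out) <= 40
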