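"""Co-expression graph construction and BFS leveling."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from togcn import ConfigError, ValidationError
from togcn.network import (
    CoexpressionCutoff,
    assign_levels_bfs,
    build_gcn,
    determine_cutoff,
    level_profiles,
    pairwise_pcc,
    suggest_seed,
)


def _textbook_pcc(x, y):
    """Independent oracle: the raw-sums correlation formula."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx, syy, sxy = sum(a * a for a in x), sum(b * b for b in y), sum(
        a * b for a, b in zip(x, y)
    )
    return (n * sxy - sx * sy) / math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))


class TestPairwisePcc:
    def test_duplicate_and_negated_profiles(self):
        df = pd.DataFrame(
            {"t1": [1, 1, -1], "t2": [3, 3, -3], "t3": [2, 2, -2], "t4": [5, 5, -5]},
            index=["a", "a_copy", "a_neg"], dtype=float,
        )
        pcc = pairwise_pcc(df)
        assert pcc.loc["a", "a_copy"] == pytest.approx(1.0)
        assert pcc.loc["a", "a_neg"] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        x, y = [1, 2, 3, 4, 5], [2, 1, 4, 3, 6]
        pcc = pairwise_pcc(pd.DataFrame([x, y], index=["x", "y"], dtype=float))
        assert pcc.loc["x", "y"] == pytest.approx(_textbook_pcc(x, y), abs=1e-12)

    def test_symmetric_with_unit_diagonal(self, rng):
        pcc = pairwise_pcc(pd.DataFrame(rng.random((8, 5))))
        arr = pcc.to_numpy()
        np.testing.assert_allclose(arr, arr.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(arr), 1.0)
        assert (arr >= -1).all() and (arr <= 1).all()

    def test_too_few_columns_rejected(self):
        with pytest.raises(ValidationError, match=">= 3"):
            pairwise_pcc(pd.DataFrame([[1.0, 2.0], [2.0, 1.0]]))

    def test_zero_variance_gene_excluded(self):
        df = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "ok"])
        with pytest.warns(UserWarning, match="flat"):
            pcc = pairwise_pcc(df)
        assert list(pcc.index) == ["ok"]


class TestDetermineCutoff:
    def test_fixed_mode_passthrough(self):
        cut = CoexpressionCutoff.fixed(0.92)
        assert cut.pcc_threshold == 0.92
        assert cut.method == "fixed"

    def test_reproducible_and_alpha_monotone(self, rng):
        profiles = pd.DataFrame(rng.normal(size=(30, 5)))
        a = determine_cutoff(profiles, alpha=0.05, n_permutations=3000, rng_seed=1)
        b = determine_cutoff(profiles, alpha=0.05, n_permutations=3000, rng_seed=1)
        assert a.pcc_threshold == b.pcc_threshold
        strict = determine_cutoff(profiles, alpha=0.01, n_permutations=3000, rng_seed=1)
        assert strict.pcc_threshold > a.pcc_threshold

    def test_alpha_one_gives_null_minimum(self, rng):
        profiles = pd.DataFrame(rng.normal(size=(10, 5)))
        with pytest.warns(UserWarning, match="degenerate"):
            cut = determine_cutoff(profiles, alpha=1.0, n_permutations=500, rng_seed=0)
        assert cut.pcc_threshold == pytest.approx(float(cut.null_sample.min()))

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValidationError, match=">= 2"):
            determine_cutoff(pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0]]))


class TestBuildGcn:
    def test_threshold_just_below_max_gives_one_edge(self, rng):
        pcc = pairwise_pcc(pd.DataFrame(rng.random((6, 5))))
        arr = pcc.to_numpy().copy()
        np.fill_diagonal(arr, -np.inf)
        top = arr.max()
        gcn = build_gcn(pcc, CoexpressionCutoff.fixed(top - 1e-9))
        assert gcn.graph.number_of_edges() == 1
        assert len(gcn.nodes) == 6  # isolated nodes retained

    def test_lowering_threshold_only_adds_edges(self, rng):
        pcc = pairwise_pcc(pd.DataFrame(rng.random((10, 5))))
        loose = build_gcn(pcc, CoexpressionCutoff.fixed(0.3))
        tight = build_gcn(pcc, CoexpressionCutoff.fixed(0.7))
        assert set(tight.graph.edges) <= set(loose.graph.edges)

    def test_positive_threshold_required(self, rng):
        pcc = pairwise_pcc(pd.DataFrame(rng.random((4, 5))))
        # a degenerate calibrated threshold may be <= 0, but co-expression
        # edges are only ever defined by positive correlation
        for bad in (0.0, -0.5):
            with pytest.raises(ConfigError, match="positive"):
                build_gcn(pcc, CoexpressionCutoff.fixed(bad))

    def test_no_self_edges(self, rng):
        pcc = pairwise_pcc(pd.DataFrame(rng.random((6, 5))))
        gcn = build_gcn(pcc, CoexpressionCutoff.fixed(0.1))
        assert all(a != b for a, b in gcn.graph.edges)


def _gcn_from_graph(g: nx.Graph):
    from togcn.network import GCN

    return GCN(
        graph=nx.relabel_nodes(g, {n: str(n) for n in g.nodes}),
        cutoff=CoexpressionCutoff.fixed(0.5),
    )


class TestBfsLevels:
    def test_path_graph(self):
        togcn = assign_levels_bfs(_gcn_from_graph(nx.path_graph(4)), "0")
        assert togcn.level_of == {"0": 1, "1": 2, "2": 3, "3": 4}
        assert togcn.n_levels == 4

    def test_star_graph(self):
        togcn = assign_levels_bfs(_gcn_from_graph(nx.star_graph(5)), "0")
        assert togcn.level_of["0"] == 1
        assert all(togcn.level_of[str(i)] == 2 for i in range(1, 6))

    def test_unreachable_nodes_reported_not_dropped(self):
        g = nx.Graph([("a", "b")])
        g.add_node("lonely")
        togcn = assign_levels_bfs(_gcn_from_graph(g), "a")
        assert togcn.excluded == {"lonely"}
        assert "lonely" not in togcn.level_of

    def test_missing_seed_rejected(self):
        with pytest.raises(ValidationError, match="seed"):
            assign_levels_bfs(_gcn_from_graph(nx.path_graph(3)), "99")

    def test_levels_equal_shortest_path_distance_plus_one(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 40))
            g = nx.gnp_random_graph(n, 0.15, seed=int(rng.integers(1 << 30)))
            togcn = assign_levels_bfs(_gcn_from_graph(g), "0")
            oracle = nx.single_source_shortest_path_length(g, 0)
            assert togcn.level_of == {str(k): v + 1 for k, v in oracle.items()}

    def test_invariant_under_relabeling(self, rng):
        g = nx.gnp_random_graph(20, 0.2, seed=3)
        togcn = assign_levels_bfs(_gcn_from_graph(g), "0")
        perm = {str(i): f"x{i}" for i in g.nodes}
        relabeled = _gcn_from_graph(nx.relabel_nodes(g, {i: f"x{i}" for i in g.nodes}))
        togcn2 = assign_levels_bfs(relabeled, "x0")
        assert togcn2.level_of == {perm[k]: v for k, v in togcn.level_of.items()}


class TestSuggestSeed:
    def test_earliest_peak_ranked_first(self):
        t = np.arange(5, dtype=float)
        rows = {"late1": np.exp(-((t - 4) ** 2)), "late2": np.exp(-((t - 3.5) ** 2)),
                "early": np.exp(-(t ** 2))}
        ranked = suggest_seed(pd.DataFrame(rows).T)
        assert ranked[0] == "early"

    def test_identical_profiles_tie_break_lexicographic(self):
        df = pd.DataFrame([[3.0, 2.0, 1.0]] * 2 + [[1.0, 2.0, 3.0]],
                          index=["b_gene", "a_gene", "later"])
        assert suggest_seed(df)[:2] == ["a_gene", "b_gene"]


class TestLevelProfiles:
    def _togcn(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("b", "d")])
        return assign_levels_bfs(_gcn_from_graph(g), "a")

    def test_single_member_level_equals_row(self):
        togcn = self._togcn()
        z = pd.DataFrame(
            [[1.0, -1.0], [0.5, -0.5], [2.0, 0.0], [0.0, 2.0]],
            index=["a", "b", "c", "d"],
        )
        lp = level_profiles(togcn, z)
        np.testing.assert_allclose(lp.profiles.loc[1], z.loc["a"])
        assert lp.counts == {1: 1, 2: 1, 3: 2}

    def test_opposite_profiles_cancel(self):
        togcn = self._togcn()
        z = pd.DataFrame(
            [[0.0, 0.0], [0.0, 0.0], [1.0, -2.0], [-1.0, 2.0]],
            index=["a", "b", "c", "d"],
        )
        np.testing.assert_allclose(level_profiles(togcn, z).profiles.loc[3], 0.0)

    def test_matches_group_by_mean_oracle(self, rng):
        g = nx.gnp_random_graph(20, 0.3, seed=11)
        togcn = assign_levels_bfs(_gcn_from_graph(g), "0")
        z = pd.DataFrame(rng.normal(size=(20, 5)), index=[str(i) for i in range(20)])
        lp = level_profiles(togcn, z)
        frame = pd.DataFrame({"level": pd.Series(togcn.level_of)})
        oracle = z.loc[frame.index].groupby(frame["level"]).mean()
        pd.testing.assert_frame_equal(lp.profiles, oracle, check_names=False)
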