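import json
from pathlib import Path

import numpy as np
import pytest

from evofoodweb import snapshot
from evofoodweb.analysis import (
    avalanche_statistics,
    compute_metrics,
    composition_fractions,
    count_chains,
    cutoff_max_attack,
    cutoff_relative_to_average,
    degree_statistics,
    flow_based_trophic_levels,
    global_structure,
    max_similarity,
    short_weighted_trophic_levels,
)
from evofoodweb.fixtures import four_species_community, random_community

from conftest import make_snapshot, web_from_edges

DATA = Path(__file__).parent / "data"


class TestAverageCutoff:
    def test_dominant_link_only(self):
        # contributions (10, 1, 1): mean 4, threshold 3 -> keep the 10-link
        snap = make_snapshot([[10.0, 1.0, 1.0, 0.0]] + [[0.0] * 4] * 2)
        web = cutoff_relative_to_average(snap, fraction=0.75)
        assert web.adjacency[1].tolist() == [True, False, False, False]

    def test_single_prey_always_kept(self):
        snap = make_snapshot([[0.0, 7.0]])
        web = cutoff_relative_to_average(snap)
        assert web.adjacency[1, 1]

    def test_equal_contributions_all_kept(self):
        snap = make_snapshot([[2.0, 2.0, 2.0, 2.0]] + [[0.0] * 4] * 2)
        web = cutoff_relative_to_average(snap)
        assert web.adjacency[1].sum() == 4

    def test_starving_consumer_has_no_links(self):
        snap = make_snapshot([[0.0, 0.0]])
        web = cutoff_relative_to_average(snap)
        assert web.n_links == 0


class TestMaxAttackCutoff:
    def test_printed_arithmetic(self):
        # rates (1.0, 0.2, 0.1), threshold 15% of max -> drop the 0.1 link
        snap = make_snapshot(
            flows=[[1.0, 0.2, 0.1, 0.0]] + [[0.0] * 4] * 2,
            attack=[[1.0, 0.2, 0.1, 0.0]] + [[0.0] * 4] * 2,
        )
        web = cutoff_max_attack(snap, fraction=0.15, reference="realized_max")
        assert web.adjacency[1].tolist() == [True, True, False, False]

    def test_all_rates_equal_all_kept(self):
        snap = make_snapshot([[0.3, 0.3, 0.3, 0.3]] + [[0.0] * 4] * 2)
        web = cutoff_max_attack(snap, reference="realized_max")
        assert web.adjacency[1].sum() == 4

    def test_all_rates_zero_empty_web(self):
        snap = make_snapshot([[0.0, 0.0]])
        web = cutoff_max_attack(snap, reference="realized_max")
        assert web.n_links == 0

    def test_kernel_peak_reference_on_real_snapshot(self):
        # the potential maximum disregards which prey are present: a
        # consumer whose centre matches no live prey still keeps only
        # links close to its kernel peak
        snap = snapshot(four_species_community())
        web = cutoff_max_attack(snap, fraction=0.15, reference="kernel_peak")
        edges = sorted(map(tuple, np.argwhere(web.adjacency).tolist()))
        assert edges == [(1, 0), (2, 0), (3, 1), (3, 2)]


class TestTrophicLevels:
    def test_chain_levels(self):
        web = web_from_edges(3, [(1, 0), (2, 1)])
        np.testing.assert_allclose(flow_based_trophic_levels(web=web), [1, 2, 3])
        np.testing.assert_allclose(short_weighted_trophic_levels(web), [1, 2, 3])

    def test_fifty_fifty_omnivore(self):
        web = web_from_edges(
            3,
            [(1, 0), (2, 0), (2, 1)],
            flows=[[1.0, 0, 0], [0.5, 0.5, 0]],
        )
        tl = flow_based_trophic_levels(web=web)
        assert tl[2] == pytest.approx(2.5)
        swtl = short_weighted_trophic_levels(web)
        assert swtl[2] == pytest.approx(2.25)  # shortest 2, prey-averaged 2.5

    @pytest.mark.parametrize("q", [0.1, 0.5, 0.9])
    def test_cannibal_closed_form_and_iteration(self, q):
        web = web_from_edges(
            2, [(1, 0), (1, 1)], flows=[[1 - q, q]]
        )
        tl = flow_based_trophic_levels(web=web)
        assert tl[1] == pytest.approx((2 - q) / (1 - q), rel=1e-12)
        # fixed-point iteration oracle
        lvl = 1.0
        for _ in range(2000):
            lvl = 1 + (1 - q) * 1.0 + q * lvl
        assert tl[1] == pytest.approx(lvl, rel=1e-9)

    def test_pure_self_diet_is_singular(self):
        web = web_from_edges(2, [(1, 1)], flows=[[0.0, 1.0]])
        with pytest.raises(ValueError, match="singular"):
            flow_based_trophic_levels(web=web)

    def test_disconnected_node_reported_as_nan(self):
        web = web_from_edges(3, [(1, 0)])
        swtl = short_weighted_trophic_levels(web)
        assert np.isnan(swtl[2])
        assert swtl[1] == pytest.approx(2.0)

    def test_levels_at_least_one_and_solve_equals_relaxation(self, assembly_run):
        snap = assembly_run.snapshots[-1]
        web = cutoff_relative_to_average(snap)
        tl = flow_based_trophic_levels(web=web)
        assert tl[0] == pytest.approx(1.0)
        assert np.all(tl >= 1.0 - 1e-12)
        # iterative relaxation oracle on the same diet matrix
        w = web.flows * web.adjacency[1:, :]
        n = web.n_nodes - 1
        D = np.zeros((n + 1, n + 1))
        tot = w.sum(axis=1)
        D[1:][tot > 0] = w[tot > 0] / tot[tot > 0, None]
        lvl = np.ones(n + 1)
        for _ in range(10_000):
            lvl = 1 + D @ lvl
        np.testing.assert_allclose(tl, lvl, atol=1e-10)


class TestDegreeStatistics:
    def test_chain_degrees(self):
        web = web_from_edges(3, [(1, 0), (2, 1)])
        df = degree_statistics(web)
        assert df["generality"].tolist() == [0, 1, 1]
        assert df["vulnerability"].tolist() == [1, 1, 0]

    def test_mean_degree_identity(self):
        # mean generality = mean vulnerability = L/S exactly, any web
        rng = np.random.default_rng(0)
        for _ in range(5):
            n = rng.integers(4, 12)
            adj = rng.random((n, n)) < 0.3
            adj[0] = False
            web = web_from_edges(n, list(map(tuple, np.argwhere(adj))))
            df = degree_statistics(web)
            ls = web.n_links / web.n_nodes
            assert df["generality"].mean() == pytest.approx(ls)
            assert df["vulnerability"].mean() == pytest.approx(ls)

    def test_matches_bruteforce_row_column_sums(self):
        rng = np.random.default_rng(1)
        adj = rng.random((6, 6)) < 0.4
        adj[0] = False
        web = web_from_edges(6, list(map(tuple, np.argwhere(adj))))
        df = degree_statistics(web)
        np.testing.assert_array_equal(df["generality"], web.adjacency.sum(axis=1))
        np.testing.assert_array_equal(df["vulnerability"], web.adjacency.sum(axis=0))


class TestComposition:
    def test_chain_fractions(self):
        web = web_from_edges(3, [(1, 0), (2, 1)])
        frac = composition_fractions(web)
        assert frac["top"] == pytest.approx(0.5)
        assert frac["herbivore"] == pytest.approx(0.5)
        assert frac["omnivore"] == 0.0
        assert frac["loop"] == 0.0

    def test_omnivore_spans_two_levels(self):
        # A eats the resource and B; B eats the resource -> A omnivorous
        web = web_from_edges(3, [(1, 0), (1, 2), (2, 0)])
        frac = composition_fractions(web)
        assert frac["omnivore"] == pytest.approx(0.5)

    def test_mutual_predation_counts_as_loop(self):
        web = web_from_edges(3, [(1, 0), (1, 2), (2, 1)])
        frac = composition_fractions(web)
        assert frac["loop"] == pytest.approx(1.0)

    def test_cannibal_detected(self):
        web = web_from_edges(2, [(1, 0), (1, 1)])
        assert composition_fractions(web)["cannibal"] == pytest.approx(1.0)


class TestGlobalStructure:
    def test_chain_has_one_chain(self):
        web = web_from_edges(3, [(1, 0), (2, 1)])
        g = global_structure(web)
        assert g["n_chains"] == 1
        assert g["connectance"] == pytest.approx(2 / 9)

    def test_identical_consumers_have_similarity_one(self):
        web = web_from_edges(4, [(1, 0), (2, 0), (3, 1), (3, 2)])
        # species 1 and 2 share prey {0} and predator {3}
        assert max_similarity(web) == pytest.approx((1 + 1 + 0) / 3)

    def test_chain_count_matches_bruteforce_dfs(self):
        rng = np.random.default_rng(2)
        # random DAG: consumer i may eat any node with smaller index
        n = 8
        edges = [
            (i, j) for i in range(1, n) for j in range(i) if rng.random() < 0.45
        ]
        web = web_from_edges(n, edges)
        adj = web.adjacency

        def dfs_paths(node):
            if node == 0:
                return 1
            return sum(dfs_paths(j) for j in np.nonzero(adj[node])[0])

        tops = [i for i in range(1, n) if not adj[:, i].any()]
        expected = sum(dfs_paths(t) for t in tops)
        assert count_chains(web) == expected


class TestCutoffInvariants:
    def test_trimming_never_adds_links(self, assembly_run):
        snap = assembly_run.snapshots[-1]
        for web in (cutoff_relative_to_average(snap), cutoff_max_attack(snap)):
            kept = web.adjacency[1:, :]
            assert np.all(snap.flow[kept] > 0)

    def test_link_count_monotone_in_cutoff_fraction(self, assembly_run):
        snap = assembly_run.snapshots[-1]
        for cutoff in (cutoff_relative_to_average, cutoff_max_attack):
            counts = [cutoff(snap, fraction=f).n_links for f in np.linspace(0.05, 2.0, 12)]
            assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_connectance_in_unit_interval(self, assembly_run):
        web = cutoff_relative_to_average(assembly_run.snapshots[-1])
        assert 0 < web.n_links / web.n_nodes**2 <= 1


class TestAvalancheStatistics:
    def test_recovers_generating_exponent(self):
        rng = np.random.default_rng(0)
        s = np.arange(1, 101)
        p = s**-2.0
        sizes = rng.choice(s, size=100_000, p=p / p.sum())
        stats = avalanche_statistics(sizes)
        assert stats["exponent"] == pytest.approx(2.0, abs=0.1)

    def test_single_size_has_undefined_exponent(self):
        assert np.isnan(avalanche_statistics([1] * 50)["exponent"])

    def test_two_point_regression_arithmetic(self):
        # counts (8, 1) at sizes (1, 2): slope -3 on the log2 scale
        stats = avalanche_statistics([1] * 8 + [2], binning="none")
        assert stats["exponent"] == pytest.approx(3.0, rel=1e-12)


class TestGoldenFourSpeciesMetrics:
    def test_metrics_match_hand_computed_values(self):
        snap = snapshot(four_species_community())
        web = cutoff_relative_to_average(snap)
        report = compute_metrics(web)
        golden = json.loads((DATA / "four_species_metrics.json").read_text())
        for key, expected in golden.items():
            if key.startswith("_"):
                continue
            assert getattr(report, key) == pytest.approx(expected, abs=1e-9), key
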