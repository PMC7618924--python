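"""Tracking: mixture fitting, Bures–Wasserstein costs, optimal transport,
link semantics, lineage assembly, TrackMate round-trip."""

import networkx as nx
import numpy as np
import pytest

from blastotrack.core import ConfigError, LabelVolume
from blastotrack.lineage import LineageForest
from blastotrack.track import (COV_EIGENVALUE_FLOOR, GaussianComponent,
                               TransportPlan, build_lineage, cost_matrix,
                               fit_gaussian_mixture, gmmot_plan, link_frames,
                               nuclei_counts, track_movie, w2_gaussian)
from blastotrack.trackmate import export_trackmate, read_trackmate

from conftest import random_mixture, random_spd


def gauss(mean, cov, weight=1.0, label=1):
    return GaussianComponent(weight=weight, mean=np.asarray(mean, float),
                             covariance=np.asarray(cov, float),
                             source_label=label)


def lp_oracle(a, b, c, weight_scale=10**9, cost_scale=10**12):
    """Independent balanced-transport oracle: integer min-cost flow by
    network simplex (networkx), evaluated on the exact cost matrix."""
    n, m = c.shape
    ai = [int(round(x * weight_scale)) for x in a]
    ai[int(np.argmax(ai))] += weight_scale - sum(ai)
    bi = [int(round(x * weight_scale)) for x in b]
    bi[int(np.argmax(bi))] += weight_scale - sum(bi)
    ci = np.round(c / c.max() * cost_scale).astype(object)
    G = nx.DiGraph()
    for i in range(n):
        G.add_node(("s", i), demand=-ai[i])
    for j in range(m):
        G.add_node(("t", j), demand=bi[j])
    for i in range(n):
        for j in range(m):
            G.add_edge(("s", i), ("t", j), weight=int(ci[i, j]))
    _, flow = nx.network_simplex(G)
    plan = np.zeros((n, m))
    for i in range(n):
        for j, f in flow[("s", i)].items():
            plan[i, j[1]] = f / weight_scale
    return float(np.sum(plan * c))


class TestFitMixture:
    def test_equal_volumes_get_equal_weights(self):
        labels = np.zeros((4, 4, 8), np.int32)
        labels[:, :, :3] = 1
        labels[:, :, 5:] = 2
        lv = LabelVolume(labels=labels, spacing=np.array([1.0, 1.0, 1.0]))
        comps = fit_gaussian_mixture(lv)
        assert [c.weight for c in comps] == [0.5, 0.5]
        assert sum(c.weight for c in comps) == pytest.approx(1.0)

    def test_ellipsoid_covariance_eigenvalues(self):
        """Second central moment of a solid ellipsoid: lambda_k = axis_k^2/5."""
        from test_segment import ellipsoid_volume
        semi = (5.0, 6.0, 8.0)
        lv = ellipsoid_volume(semi, shape=(30, 30, 30))
        comp = fit_gaussian_mixture(lv)[0]
        w = np.sort(np.linalg.eigvalsh(comp.covariance))
        expected = np.sort(np.array(semi)**2 / 5.0)
        assert np.allclose(w, expected, rtol=0.05)

    def test_single_voxel_gets_floor_covariance(self):
        labels = np.zeros((3, 3, 3), np.int32)
        labels[1, 1, 1] = 1
        lv = LabelVolume(labels=labels, spacing=np.array([1.0, 1.0, 1.0]))
        comp = fit_gaussian_mixture(lv)[0]
        assert np.allclose(comp.covariance, COV_EIGENVALUE_FLOOR * np.eye(3))

    def test_empty_volume_gives_empty_mixture(self):
        lv = LabelVolume(labels=np.zeros((3, 3, 3), np.int32),
                         spacing=np.array([1.0, 1.0, 1.0]))
        assert fit_gaussian_mixture(lv) == []


class TestBures:
    def test_identical_components_cost_zero(self):
        g = gauss([1, 2, 3], random_spd(np.random.default_rng(0)))
        assert w2_gaussian(g, g) == pytest.approx(0.0, abs=1e-9)

    def test_equal_covariance_reduces_to_squared_distance(self):
        cov = random_spd(np.random.default_rng(1))
        g1 = gauss([0, 0, 0], cov)
        g2 = gauss([0, 3, 0], cov)
        assert w2_gaussian(g1, g2) == pytest.approx(9.0, abs=1e-9)

    def test_commuting_diagonal_closed_form(self):
        g1 = gauss([0, 0, 0], np.diag([1.0, 1.0, 1.0]))
        g2 = gauss([0, 0, 0], np.diag([4.0, 1.0, 1.0]))
        # sum_k (sigma1_k - sigma2_k)^2 = (1 - 2)^2 = 1
        assert w2_gaussian(g1, g2) == pytest.approx(1.0, abs=1e-9)

    def test_metric_properties_on_random_triples(self):
        """Symmetry, identity of indiscernibles, triangle inequality."""
        rng = np.random.default_rng(7)
        for _ in range(500):
            g = [gauss(rng.uniform(-5, 5, 3), random_spd(rng)) for _ in range(3)]
            d01 = np.sqrt(w2_gaussian(g[0], g[1]))
            d10 = np.sqrt(w2_gaussian(g[1], g[0]))
            d12 = np.sqrt(w2_gaussian(g[1], g[2]))
            d02 = np.sqrt(w2_gaussian(g[0], g[2]))
            assert d01 == pytest.approx(d10, abs=1e-8)
            assert d02 <= d01 + d12 + 1e-8


class TestGMMOTPlan:
    def test_one_by_one_is_trivial(self):
        g1 = gauss([0, 0, 0], np.eye(3))
        g2 = gauss([9, 9, 9], np.eye(3))
        plan = gmmot_plan([g1], [g2], epsilon=0.0)
        assert plan.coupling == pytest.approx(np.array([[1.0]]))

    def test_obvious_assignment(self):
        cov = np.eye(3)
        src = [gauss([0, 0, 0], cov, 0.5, 1), gauss([20, 0, 0], cov, 0.5, 2)]
        dst = [gauss([1, 0, 0], cov, 0.5, 1), gauss([21, 0, 0], cov, 0.5, 2)]
        plan = gmmot_plan(src, dst, epsilon=0.0)
        assert np.allclose(plan.coupling, np.diag([0.5, 0.5]), atol=1e-9)

    @pytest.mark.parametrize("shape", [(3, 4), (5, 5), (2, 5)])
    def test_lp_matches_network_simplex_oracle(self, shape):
        rng = np.random.default_rng(sum(shape))
        src = random_mixture(rng, shape[0])
        dst = random_mixture(rng, shape[1])
        plan = gmmot_plan(src, dst, epsilon=0.0)
        a = np.array([g.weight for g in src])
        b = np.array([g.weight for g in dst])
        oracle = lp_oracle(a, b, plan.cost_matrix)
        assert plan.total_cost == pytest.approx(oracle, rel=1e-6, abs=1e-9)

    def test_marginals_conserved(self):
        rng = np.random.default_rng(5)
        src, dst = random_mixture(rng, 4), random_mixture(rng, 6)
        for eps in (0.0, "auto"):
            plan = gmmot_plan(src, dst, epsilon=eps)
            a = np.array([g.weight for g in src])
            b = np.array([g.weight for g in dst])
            assert np.abs(plan.coupling.sum(axis=1) - a).max() < 1e-6
            assert np.abs(plan.coupling.sum(axis=0) - b).max() < 1e-6
            assert plan.coupling.min() >= -1e-12

    def test_entropic_cost_decreases_toward_lp_optimum(self):
        rng = np.random.default_rng(9)
        src, dst = random_mixture(rng, 3, spread=6.0), random_mixture(rng, 4, spread=6.0)
        lp = gmmot_plan(src, dst, epsilon=0.0).total_cost
        costs = [gmmot_plan(src, dst, epsilon=e).total_cost
                 for e in (50.0, 20.0, 5.0)]
        assert costs[-1] == pytest.approx(lp, rel=1e-3)
        assert all(c >= lp - 1e-9 for c in costs)
        assert np.all(np.diff(costs) <= 1e-9)  # monotone in epsilon

    def test_empty_mixture_rejected(self):
        with pytest.raises(ConfigError):
            gmmot_plan([], [gauss([0, 0, 0], np.eye(3))])

    def test_displacement_penalty_inflates_far_costs(self):
        g0 = gauss([0, 0, 0], np.eye(3))
        g_far = gauss([30, 0, 0], np.eye(3))
        c0 = cost_matrix([g0], [g_far], lambda_disp=0.0)[0, 0]
        c1 = cost_matrix([g0], [g_far], lambda_disp=0.01)[0, 0]
        assert c1 == pytest.approx(c0 * (1 + 0.01 * 900), rel=1e-9)


def make_plan(coupling, src_labels=None, dst_labels=None):
    coupling = np.asarray(coupling, float)
    n, m = coupling.shape
    return TransportPlan(coupling=coupling, cost_matrix=np.zeros((n, m)),
                         total_cost=0.0,
                         src_labels=np.array(src_labels or range(1, n + 1)),
                         dst_labels=np.array(dst_labels or range(1, m + 1)))


class TestLinkFrames:
    def test_diagonal_coupling_is_all_continuations(self):
        edges, events = link_frames(make_plan(np.diag([0.5, 0.5])))
        assert edges == [(1, 1, "continuation"), (2, 2, "continuation")]
        assert not events["appearance"] and not events["disappearance"]

    def test_even_split_is_division(self):
        edges, _ = link_frames(make_plan([[0.25, 0.25]]))
        assert edges == [(1, 1, "division"), (1, 2, "division")]

    def test_small_split_below_threshold_is_continuation(self):
        edges, events = link_frames(make_plan([[0.9, 0.1]]),
                                    min_daughter_fraction=0.2)
        assert edges == [(1, 1, "continuation")]
        assert events["appearance"] == [2]

    def test_contested_target_goes_to_biggest_sender(self):
        # both sources claim target 1; source 2 sends more mass
        coupling = np.array([[0.2, 0.0], [0.3, 0.5]])
        edges, events = link_frames(make_plan(coupling))
        assert (2, 1, "division") in edges and (2, 2, "division") in edges
        assert events["disappearance"] == [1]


class TestBuildLineage:
    def test_parallel_tracks(self):
        ids = [np.arange(1, 11)] * 5
        edge_sets = [[(i, i, "continuation") for i in range(1, 11)]] * 4
        forest = build_lineage(edge_sets, labels_per_frame=ids)
        assert len(forest.tracks()) == 10
        assert all(len(t) == 5 for t in forest.tracks())

    def test_division_becomes_branch_point(self):
        ids = [[1], [1], [1], [2, 3], [2, 3]]
        edge_sets = [[(1, 1, "continuation")], [(1, 1, "continuation")],
                     [(1, 2, "division"), (1, 3, "division")],
                     [(2, 2, "continuation"), (3, 3, "continuation")]]
        forest = build_lineage(edge_sets, labels_per_frame=ids)
        assert forest.division_nodes() == [(2, 1)]
        assert len(forest.leaves()) == 2

    def test_counts_step_at_division(self):
        ids = [[1], [2, 3]]
        forest = build_lineage([[(1, 2, "division"), (1, 3, "division")]],
                               labels_per_frame=ids)
        assert list(forest.counts()) == [1, 2]


class TestTrackingRecovery:
    def test_default_movie_tracked_exactly(self, default_truth, default_labels,
                                           default_truth_forest):
        from blastotrack.validate import division_recall, edge_accuracy
        forest = track_movie(default_labels)
        assert edge_accuracy(forest, default_truth_forest) >= 0.95
        assert division_recall(forest, default_truth_forest) == 1.0
        # per-frame counts equal the generator's live-nuclei series exactly
        assert np.array_equal(nuclei_counts(forest).to_numpy(),
                              default_truth.live_counts())

    def test_micronucleus_follows_its_daughter_track(self):
        """A sub-30-um^3 micronucleus shed at division stays linked to the
        same daughter's neighbourhood track across the division."""
        from blastotrack import synth
        truth = synth.make_blastocyst(n_outer=8, n_inner=0, n_frames=10,
                                      division_schedule=[4], n_micronuclei=1,
                                      kappa=0.5, seed=21)
        labels = synth.rasterize_labels(truth)
        forest = track_movie(labels)
        micro = next(n for n in truth.nuclei if n.is_micronucleus)
        chain = [(f, micro.id) for f in range(micro.birth_frame,
                                              micro.death_frame + 1)]
        for u, v in zip(chain, chain[1:]):
            assert forest.graph.has_edge(u, v)


class TestTrackMate:
    def test_empty_forest_roundtrip(self, tmp_path):
        forest = LineageForest(n_frames=0)
        path = tmp_path / "empty.xml"
        export_trackmate(forest, path=path)
        back, _ = read_trackmate(path)
        assert back.graph.number_of_nodes() == 0

    def test_chain_spots_edges_tracks(self, tmp_path):
        forest = LineageForest(n_frames=3)
        for f in range(3):
            forest.add_node(f, 1)
        forest.add_edge((0, 1), (1, 1))
        forest.add_edge((1, 1), (2, 1))
        tree = export_trackmate(forest, path=tmp_path / "chain.xml")
        root = tree.getroot()
        assert len(root.findall(".//Spot")) == 3
        assert len(root.findall(".//Edge")) == 2
        assert len(root.findall(".//Track")) == 1

    def test_roundtrip_is_exact(self, tmp_path, default_labels):
        forest = track_movie(default_labels[:6])
        path = tmp_path / "forest.xml"
        export_trackmate(forest, path=path)
        back, spots = read_trackmate(path)
        assert back == forest
        # spot ids unique by construction; check the file agrees
        from lxml import etree
        ids = [s.get("ID") for s in etree.parse(str(path)).iter("Spot")]
        assert len(ids) == len(set(ids))
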