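"""Phantom generation: network, FODs, simulators, electrodes, coherence."""

from dataclasses import replace

import numpy as np
import pytest

from quadconn import structural as st
from quadconn.errors import ConfigError, PlacementError
from quadconn.grid import VolumeGrid
from quadconn.network import Edge, GroundTruthNetwork, Node, generate_network
from quadconn.phantom import (
    PhantomConfig,
    build_masks,
    build_phantom,
    place_electrodes,
    render_fod_field,
)
from quadconn.simulate import simulate_ccep, simulate_des_fmri, simulate_rsfmri


@pytest.fixture()
def grid36():
    return VolumeGrid((36, 36, 36))


class TestGenerateNetwork:
    def test_minimal_two_node_graph(self, grid36):
        rng = np.random.default_rng(7)
        net = generate_network(2, 1, (0.2, 0.9), grid36, rng)
        assert len(net.nodes) == 2
        assert len(net.edges) == 1
        e = net.edges[0]
        assert 0.2 <= e.weight <= 0.9
        # bundle endpoints inside the two patches
        assert net.node_containing(e.bundle[0]) == e.node_a
        assert net.node_containing(e.bundle[-1]) == e.node_b

    def test_zero_edges_still_places_nodes(self, grid36):
        net = generate_network(4, 0, (0.3, 0.9), grid36, np.random.default_rng(1))
        assert len(net.nodes) == 4 and net.edges == []

    def test_reproducible_and_seed_sensitive(self, grid36):
        a = generate_network(6, 8, (0.3, 0.9), grid36, np.random.default_rng(1))
        b = generate_network(6, 8, (0.3, 0.9), grid36, np.random.default_rng(1))
        c = generate_network(6, 8, (0.3, 0.9), grid36, np.random.default_rng(2))
        assert a.to_json() == b.to_json()
        assert a.to_json() != c.to_json()

    def test_patches_disjoint_and_bundles_avoid_patches(self, grid36):
        net = generate_network(7, 10, (0.3, 0.9), grid36, np.random.default_rng(3))
        for a in net.nodes:
            for b in net.nodes:
                if a.node_id < b.node_id:
                    gap = np.abs(np.subtract(a.center, b.center)).max()
                    assert gap > a.radius + b.radius
        for e in net.edges:
            for m in net.nodes:
                if m.node_id in (e.node_a, e.node_b):
                    continue
                assert (np.abs(e.bundle - np.asarray(m.center)).max(axis=1)
                        > m.radius).all()

    def test_grid_too_small_names_failing_node(self):
        small = VolumeGrid((8, 8, 8))
        with pytest.raises(PlacementError, match="node 1"):
            generate_network(3, 2, (0.3, 0.9), small, np.random.default_rng(0))

    def test_path_strength_takes_best_route(self):
        nodes = [Node(0, (2, 2, 2), 0), Node(1, (4, 2, 2), 0), Node(2, (6, 2, 2), 0)]
        line = np.array([[2, 2, 2], [3, 2, 2], [4, 2, 2]])
        edges = [
            Edge(0, 1, 0.9, line),
            Edge(1, 2, 0.9, line + [2, 0, 0]),
            Edge(0, 2, 0.5, np.array([[2, 2, 2], [3, 2, 2], [4, 2, 2], [5, 2, 2], [6, 2, 2]])),
        ]
        net = GroundTruthNetwork(nodes, edges)
        # two-hop 0.81 beats direct 0.5
        assert net.path_strength(0, 2) == pytest.approx(0.81)
        assert net.path_hops(0, 2) == 2


class TestRenderFOD:
    def straight_net(self, w=0.8):
        bundle = np.array([[x, 8, 8] for x in range(4, 13)])
        return GroundTruthNetwork(
            [Node(0, (4, 8, 8), 1), Node(1, (12, 8, 8), 1)], [Edge(0, 1, w, bundle)]
        )

    def test_high_concentration_mass_on_axis_pair(self, small_grid=None):
        grid = VolumeGrid((16, 16, 16))
        fod = render_fod_field(self.straight_net(1.0), grid, kappa=1e4)
        amp = fod.amplitudes[8, 8, 8]
        d = int(np.flatnonzero((st.OFFSETS == (1, 0, 0)).all(axis=1))[0])
        assert amp[d] + amp[st.OPPOSITE[d]] == pytest.approx(1.0, abs=1e-8)

    def test_zero_concentration_is_isotropic(self):
        grid = VolumeGrid((16, 16, 16))
        fod = render_fod_field(self.straight_net(0.9), grid, kappa=0.0)
        iso = st.isotropic_amplitudes(grid.voxel_size)
        np.testing.assert_allclose(fod.amplitudes[8, 8, 8], iso, atol=1e-12)
        np.testing.assert_allclose(fod.amplitudes[2, 2, 2], iso, atol=1e-12)

    def test_crossing_bundles_mix_by_weight(self):
        # numeric check: in the shared voxel, lobe mass along each axis pair
        # matches the w-weighted mixture of the two single-bundle lobes
        grid = VolumeGrid((16, 16, 16))
        bx = np.array([[x, 8, 8] for x in range(4, 13)])
        by = np.array([[8, y, 8] for y in range(4, 13)])
        w1, w2 = 0.9, 0.3
        net = GroundTruthNetwork(
            [Node(0, (4, 8, 8), 0), Node(1, (12, 8, 8), 0),
             Node(2, (8, 4, 8), 0), Node(3, (8, 12, 8), 0)],
            [Edge(0, 1, w1, bx), Edge(2, 3, w2, by)],
        )
        kappa = 30.0
        fod = render_fod_field(net, grid, kappa)
        only_x = render_fod_field(
            GroundTruthNetwork(net.nodes[:2], [net.edges[0]]), grid, kappa
        ).amplitudes[8, 8, 8]
        only_y = render_fod_field(
            GroundTruthNetwork(net.nodes[2:], [net.edges[1]]), grid, kappa
        ).amplitudes[8, 8, 8]
        expected = (w1 * only_x + w2 * only_y) / (w1 + w2)
        np.testing.assert_allclose(fod.amplitudes[8, 8, 8], expected, atol=1e-12)
        # lobe mass ratio equals w1:w2 once the lobes are concentrated enough
        # that each one's mass sits in its own axis cells (no cross-leak)
        sharp = render_fod_field(net, grid, 150.0).amplitudes[8, 8, 8]
        dx = int(np.flatnonzero((st.OFFSETS == (1, 0, 0)).all(axis=1))[0])
        dy = int(np.flatnonzero((st.OFFSETS == (0, 1, 0)).all(axis=1))[0])
        mx = sharp[dx] + sharp[st.OPPOSITE[dx]]
        my = sharp[dy] + sharp[st.OPPOSITE[dy]]
        assert mx / my == pytest.approx(w1 / w2, rel=1e-6)

    def test_bundle_outside_grid_rejected(self):
        grid = VolumeGrid((6, 6, 6))
        bundle = np.array([[x, 3, 3] for x in range(3, 9)])
        net = GroundTruthNetwork(
            [Node(0, (3, 3, 3), 0), Node(1, (8, 3, 3), 0)], [Edge(0, 1, 0.5, bundle)]
        )
        with pytest.raises(ConfigError, match="leaves the grid"):
            render_fod_field(net, grid, 10.0)


class TestSimulators:
    def two_node(self, grid, w):
        nodes = [Node(0, (5, 8, 8), 1), Node(1, (11, 8, 8), 1)]
        edges = []
        if w > 0:
            edges = [Edge(0, 1, w, np.array([[x, 8, 8] for x in range(5, 12)]))]
        return GroundTruthNetwork(nodes, edges)

    def test_rsfmri_noise_free_full_coupling(self):
        grid = VolumeGrid((16, 16, 16))
        net = self.two_node(grid, 1.0)
        masks = build_masks(net, grid)
        cfg = replace(PhantomConfig(), shape=(16, 16, 16), sigma_bold=0.0)
        bold = simulate_rsfmri(net, grid, masks, cfg, np.random.default_rng(0))
        ma = bold.data[tuple(net.patch_voxels(0, grid).T)].mean(axis=0)
        mb = bold.data[tuple(net.patch_voxels(1, grid).T)].mean(axis=0)
        assert np.corrcoef(ma, mb)[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_rsfmri_no_edge_null_correlation(self):
        grid = VolumeGrid((16, 16, 16))
        net = self.two_node(grid, 0.0)
        masks = build_masks(net, grid)
        cfg = replace(PhantomConfig(), shape=(16, 16, 16), sigma_bold=0.1)
        rs = []
        for s in range(20):
            bold = simulate_rsfmri(net, grid, masks, cfg, np.random.default_rng(s))
            ma = bold.data[tuple(net.patch_voxels(0, grid).T)].mean(axis=0)
            mb = bold.data[tuple(net.patch_voxels(1, grid).T)].mean(axis=0)
            rs.append(np.corrcoef(ma, mb)[0, 1])
        assert np.mean(np.abs(rs)) < 4.0 / np.sqrt(cfg.rest_volumes)

    def test_rsfmri_strong_edge_beats_weak_edge(self):
        grid = VolumeGrid((16, 16, 16))
        nodes = [Node(0, (8, 8, 8), 1), Node(1, (8, 14, 8), 1), Node(2, (8, 2, 8), 1)]
        b1 = np.array([[8, y, 8] for y in range(8, 15)])
        b2 = np.array([[8, y, 8] for y in range(2, 9)][::-1])
        net = GroundTruthNetwork(nodes, [Edge(0, 1, 0.9, b1), Edge(0, 2, 0.2, b2)])
        masks = build_masks(net, grid)
        cfg = replace(PhantomConfig(), shape=(16, 16, 16), sigma_bold=0.1)
        wins = 0
        n_seeds = 100
        for s in range(n_seeds):
            bold = simulate_rsfmri(net, grid, masks, cfg, np.random.default_rng(s))
            m0 = bold.data[tuple(net.patch_voxels(0, grid).T)].mean(axis=0)
            r1 = np.corrcoef(m0, bold.data[tuple(net.patch_voxels(1, grid).T)].mean(axis=0))[0, 1]
            r2 = np.corrcoef(m0, bold.data[tuple(net.patch_voxels(2, grid).T)].mean(axis=0))[0, 1]
            wins += r1 > r2
        assert wins >= 95

    def test_des_noise_free_regression_recovers_amplitude(self):
        grid = VolumeGrid((16, 16, 16))
        net = self.two_node(grid, 0.75)
        masks = build_masks(net, grid)
        cfg = replace(PhantomConfig(), shape=(16, 16, 16), sigma_bold=0.0,
                      negative_fraction=0.0)
        bold, signs = simulate_des_fmri(net, grid, masks, 0, cfg,
                                        np.random.default_rng(0))
        from quadconn.desfmri import build_design

        d = build_design(cfg.block_s, cfg.tr_s, cfg.n_blocks, cfg.des_total_s)
        y = bold.data[11, 8, 8]
        X = d.matrix
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert beta[0] == pytest.approx(cfg.des_amp * 0.75, abs=1e-10)
        assert signs[1] == 1

    def test_des_negative_nodes_get_negative_response(self):
        grid = VolumeGrid((16, 16, 16))
        net = self.two_node(grid, 0.75)
        masks = build_masks(net, grid)
        cfg = replace(PhantomConfig(), shape=(16, 16, 16), sigma_bold=0.0,
                      negative_fraction=1.0)
        bold, signs = simulate_des_fmri(net, grid, masks, 0, cfg,
                                        np.random.default_rng(0))
        assert signs[1] == -1
        from quadconn.desfmri import build_design

        d = build_design(cfg.block_s, cfg.tr_s, cfg.n_blocks, cfg.des_total_s)
        beta = np.linalg.lstsq(d.matrix, bold.data[11, 8, 8], rcond=None)[0]
        assert beta[0] == pytest.approx(-cfg.des_amp * 0.75, abs=1e-10)

    def test_des_never_writes_into_csf(self, grid36):
        cfg = PhantomConfig(rng_seed=9)
        ph = build_phantom(cfg)
        assert ph.masks.csf.any()
        csf_series = ph.des_bold.data[ph.masks.csf]
        task = None
        from quadconn.desfmri import build_design

        task = build_design(cfg.block_s, cfg.tr_s, cfg.n_blocks, cfg.des_total_s).task
        # csf voxels contain only white noise: no task correlation above chance
        r = np.array([np.corrcoef(v, task)[0, 1] for v in csf_series])
        assert np.abs(r).max() < 0.5

    def test_ccep_unconnected_contact_artifact_only(self, grid36):
        cfg = replace(PhantomConfig(rng_seed=0), sigma_ccep=0.0, outlier_fraction=0.0)
        ph = build_phantom(cfg, with_signals=False)
        rng = np.random.default_rng(0)
        trials = simulate_ccep(ph.network, ph.electrodes,
                               tuple(c.contact_id for c in ph.electrodes.stim_pair),
                               cfg, rng)
        # a shell contact outside every patch records only the artifact
        for c in ph.electrodes.recording_contacts():
            if ph.network.node_containing(c.true_voxel) is None:
                ep = trials.contacts[c.contact_id]
                folded = ep.polarity[:, None] * ep.epochs
                assert np.abs(folded - folded[0]).max() < 1e-9
                break
        else:
            pytest.skip("no off-network contact in this phantom")

    def test_ccep_amplitude_ratio_tracks_path_strength(self):
        grid = VolumeGrid((16, 16, 16))
        nodes = [Node(0, (8, 8, 8), 1), Node(1, (8, 14, 8), 1), Node(2, (8, 2, 8), 1)]
        b1 = np.array([[8, y, 8] for y in range(8, 15)])
        b2 = np.array([[8, y, 8] for y in range(2, 9)][::-1])
        net = GroundTruthNetwork(nodes, [Edge(0, 1, 1.0, b1), Edge(0, 2, 0.5, b2)])
        masks = build_masks(net, grid)
        cfg = replace(PhantomConfig(), shape=(16, 16, 16), sigma_ccep=0.0,
                      outlier_fraction=0.0, n_contacts=4)
        table = place_electrodes(net, grid, 4, masks.gm, np.random.default_rng(0))
        trials = simulate_ccep(net, table,
                               tuple(c.contact_id for c in table.stim_pair),
                               cfg, np.random.default_rng(0))
        means = {}
        for c in table.recording_contacts():
            node = net.node_containing(c.true_voxel)
            if node in (1, 2):
                means[node] = trials.contacts[c.contact_id].epochs.mean(axis=0)
        peak1 = np.abs(means[1]).max()
        peak2 = np.abs(means[2]).max()
        assert peak2 / peak1 == pytest.approx(0.5, abs=1e-9)

    def test_ccep_outlier_bookkeeping_exact_count(self, grid36):
        cfg = replace(PhantomConfig(rng_seed=1), outlier_fraction=0.1, n_trials=40)
        ph = build_phantom(cfg)
        assert len(ph.ccep.provenance["corrupted_trials"]) == 4

    def test_ccep_unknown_stim_pair_rejected(self, grid36):
        cfg = PhantomConfig(rng_seed=2)
        ph = build_phantom(cfg, with_signals=False)
        with pytest.raises(KeyError, match="stim pair"):
            simulate_ccep(ph.network, ph.electrodes, ("Cxxx", "Cyyy"), cfg,
                          np.random.default_rng(0))


class TestMeasureOptions:
    def test_rsfmri_rectification_flag(self):
        from quadconn.workflow import MeasureParams, measure_rsfmri

        ph = build_phantom(PhantomConfig(rng_seed=21))
        signed, _ = measure_rsfmri(ph, MeasureParams())
        rect, _ = measure_rsfmri(ph, MeasureParams(rsfmri_rectify=True))
        finite = np.isfinite(signed)
        assert (signed[finite] < 0).any()  # some anticorrelation exists
        np.testing.assert_allclose(rect[finite], np.abs(signed[finite]), atol=1e-12)


class TestElectrodes:
    def test_no_jitter_recorded_equals_truth(self, grid36):
        ph = build_phantom(PhantomConfig(rng_seed=3), with_signals=False)
        for c in ph.electrodes.contacts:
            assert c.voxel == c.true_voxel

    def test_jitter_bound_in_voxels(self, grid36):
        cfg = replace(PhantomConfig(rng_seed=3), jitter_mm=5.0)
        ph = build_phantom(cfg, with_signals=False)
        for c in ph.electrodes.contacts:
            # 5 mm on a 2.5 mm grid: recorded index within 2 voxels of truth
            assert np.abs(np.subtract(c.voxel, c.true_voxel)).max() <= 2

    def test_every_node_patch_gets_a_contact(self, grid36):
        cfg = replace(PhantomConfig(rng_seed=4), n_contacts=130)
        ph = build_phantom(cfg, with_signals=False)
        covered = {
            ph.network.node_containing(c.true_voxel)
            for c in ph.electrodes.contacts
        }
        assert set(range(cfg.n_nodes)) <= covered

    def test_too_few_contacts_rejected(self, grid36):
        with pytest.raises(ConfigError):
            PhantomConfig(n_contacts=1)


class TestPhantomInvariants:
    def test_bit_identical_under_same_seed(self):
        a = build_phantom(PhantomConfig(rng_seed=12))
        b = build_phantom(PhantomConfig(rng_seed=12))
        assert np.array_equal(a.rest_bold.data, b.rest_bold.data)
        assert np.array_equal(a.des_bold.data, b.des_bold.data)
        assert a.network.to_json() == b.network.to_json()
        for k in a.ccep.contacts:
            assert np.array_equal(a.ccep.contacts[k].epochs, b.ccep.contacts[k].epochs)

    def test_masks_disjoint_and_patches_gray(self):
        ph = build_phantom(PhantomConfig(rng_seed=13), with_signals=False)
        assert not (ph.masks.gm & ph.masks.csf).any()
        assert not (ph.masks.wm & ph.masks.csf).any()
        for n in ph.network.nodes:
            vox = ph.network.patch_voxels(n.node_id, ph.grid)
            assert ph.masks.gm[tuple(vox.T)].all()

    def test_cross_modal_coherence_of_generating_amplitudes(self):
        """At zero noise every modality's generating signal ranks the target
        nodes exactly by ground-truth path strength."""
        cfg = replace(PhantomConfig(rng_seed=14), sigma_bold=0.0, sigma_ccep=0.0,
                      outlier_fraction=0.0, negative_fraction=0.0)
        ph = build_phantom(cfg)
        strengths = [ph.network.path_strength(0, i) for i in range(1, cfg.n_nodes)]
        order = np.argsort(strengths)

        # latent BOLD coupling: population correlation equals path strength
        from quadconn.simulate import _latent_factor

        r = _latent_factor(ph.network.strength_matrix())
        pop_corr = (r @ r.T)[0, 1:]
        np.testing.assert_allclose(pop_corr, strengths, atol=1e-6)

        # evoked peak amplitude per node contact
        peaks = []
        for i in range(1, cfg.n_nodes):
            cid = next(c.contact_id for c in ph.electrodes.recording_contacts()
                       if ph.network.node_containing(c.true_voxel) == i)
            peaks.append(np.abs(ph.ccep.contacts[cid].epochs.mean(axis=0)).max())
        assert (np.argsort(peaks) == order).all()

        # DES activation amplitude (noise-free, all-positive signs)
        from quadconn.desfmri import build_design

        task = build_design(cfg.block_s, cfg.tr_s, cfg.n_blocks, cfg.des_total_s).task
        amps = [
            np.linalg.lstsq(
                np.column_stack([task, np.ones_like(task)]),
                ph.des_bold.data[ph.network.nodes[i].center], rcond=None,
            )[0][0]
            for i in range(1, cfg.n_nodes)
        ]
        assert (np.argsort(amps) == order).all()

        # structural solver score at node centers
        trans = st.transition_probabilities(ph.fod, ph.masks.tracking)
        field = st.solve_connectivity(
            trans, np.array([c.true_voxel for c in ph.electrodes.stim_pair])
        )
        scores = [field.score[ph.network.nodes[i].center] for i in range(1, cfg.n_nodes)]
        assert (np.argsort(scores) == order).all()
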