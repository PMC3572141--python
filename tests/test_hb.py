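"""Hierarchical Bayesian solver: components, ReML, posterior mean."""

import numpy as np
import pytest
import scipy.sparse as sp

from megloc import hb
from megloc import priors as pr
from megloc import surface as sf
from megloc.parcellation import Parcellation
from tests.conftest import random_leadfield


@pytest.fixture(scope="module")
def kernel_and_parcellation():
    surf = sf.synth_cortex(150, rng_seed=19)
    adj = sf.build_adjacency(surf)
    W = pr.smoothness_kernel(pr.graph_laplacian(adj), 0.6)
    rng = np.random.default_rng(2)
    from megloc.parcellation import MSPScores, ddp

    scores = MSPScores(scores=rng.uniform(size=(surf.n_vertices, 2)))
    parc = ddp(surf, adj, scores, 3)
    return surf, adj, W, parc


class TestBuildComponents:
    def test_iid_single_component(self):
        cm = hb.build_components("IID", p=50)
        assert cm.n_components == 1
        assert (cm.source_components[0] != sp.identity(50)).nnz == 0

    def test_coh_two_components(self, kernel_and_parcellation):
        _, _, W, _ = kernel_and_parcellation
        cm = hb.build_components("COH", W=W)
        assert cm.n_components == 2
        assert np.array_equal(cm.source_components[1], W.psd_matrix)

    def test_coh_s_count_is_two_plus_k(self, kernel_and_parcellation):
        _, _, W, parc = kernel_and_parcellation
        cm = hb.build_components("COH-s", W=W, parcellation=parc)
        assert cm.n_components == 2 + parc.n_parcels

    def test_parcel_components_tile_block_support_of_w(self, kernel_and_parcellation):
        _, _, W, parc = kernel_and_parcellation
        cm = hb.build_components("COH-s", W=W, parcellation=parc)
        total = sum(Q.toarray() for Q in cm.source_components[2:])
        # by-parcel block-diagonal restriction of W, exactly
        expected = np.zeros_like(total)
        for k in range(1, parc.n_parcels + 1):
            idx = parc.parcel_vertices(k)
            expected[np.ix_(idx, idx)] = W.psd_matrix[np.ix_(idx, idx)]
        assert np.allclose(total, expected, atol=0)

    def test_coh_s_requires_parcellation(self, kernel_and_parcellation):
        _, _, W, _ = kernel_and_parcellation
        with pytest.raises(ValueError, match="parcellation"):
            hb.build_components("COH-s", W=W)

    def test_unknown_model(self):
        with pytest.raises(ValueError, match="unknown model"):
            hb.build_components("LORETA", p=10)


class TestReML:
    def test_isotropic_closed_form(self):
        # no source components: exp(lambda_eps) = trace(S)/q
        rng = np.random.default_rng(1)
        q = 12
        M = rng.normal(size=(q, 400)) * np.sqrt(2.0)
        cm = hb.CovarianceModel(source_components=[], component_names=[])
        fit, trace, conv = hb.reml_fit(M, np.zeros((q, 1)), cm, shrink_prior=None)
        S = M @ M.T / 400
        assert np.exp(fit.log_sensor) == pytest.approx(np.trace(S) / q, rel=1e-3)
        assert conv

    def test_two_component_recovery(self):
        # identifiable two-block fixture, true weights (3, 0.5)
        rng = np.random.default_rng(1)
        q, p, tau, eps = 40, 80, 500, 0.1
        G = np.eye(q, p)
        Q1 = sp.diags([1.0] * 15 + [0.0] * 65).tocsr()
        Q2 = sp.diags([0.0] * 15 + [1.0] * 15 + [0.0] * 50).tocsr()
        cm = hb.CovarianceModel([Q1, Q2], ["a", "b"])
        C = eps * np.eye(q) + 3 * (G @ Q1 @ G.T) + 0.5 * (G @ Q2 @ G.T)
        M = np.linalg.cholesky(C) @ rng.normal(size=(q, tau))
        fit, trace, conv = hb.reml_fit(M, G, cm)
        w = fit.weights()
        assert abs(w["a"] - 3) / 3 < 0.15
        assert abs(w["b"] - 0.5) / 0.5 < 0.15
        assert np.all(np.diff(trace) >= 0)  # monotone ascent

    def test_null_component_suppressed(self):
        rng = np.random.default_rng(1)
        q, p, tau, eps = 40, 80, 500, 0.1
        G = np.eye(q, p)
        Q1 = sp.diags([1.0] * 15 + [0.0] * 65).tocsr()
        Q2 = sp.diags([0.0] * 15 + [1.0] * 15 + [0.0] * 50).tocsr()
        cm = hb.CovarianceModel([Q1, Q2], ["a", "b"])
        C = eps * np.eye(q) + 3 * (G @ Q1 @ G.T)
        M = np.linalg.cholesky(C) @ rng.normal(size=(q, tau))
        w = hb.reml_fit(M, G, cm)[0].weights()
        assert w["b"] < 0.01 * w["a"]

    def test_rescaling_covariance(self):
        rng = np.random.default_rng(4)
        q, p = 10, 25
        G = random_leadfield(q, p, 4)
        cm = hb.build_components("IID", p=p)
        M = rng.normal(size=(q, 40))
        w1 = hb.reml_fit(M, G, cm)[0].weights()
        w10 = hb.reml_fit(10 * M, G, cm)[0].weights()
        for k in w1:
            assert w10[k] / w1[k] == pytest.approx(100.0, rel=1e-6)


class TestPosteriorMean:
    def test_zero_data(self):
        cm = hb.build_components("IID", p=20)
        J = hb.posterior_mean(random_leadfield(8, 20, 5), cm, np.zeros((8, 3)))
        assert np.all(J == 0)

    def test_matches_dense_tikhonov_oracle(self):
        rng = np.random.default_rng(6)
        q, p = 15, 60
        G = random_leadfield(q, p, 6)
        Qs = [sp.identity(p).tocsr(), sp.diags(rng.uniform(size=p)).tocsr()]
        cm = hb.CovarianceModel(
            Qs, ["i", "d"],
            log_sensor=float(np.log(0.3)),
            log_source=np.log(np.array([0.7, 1.3])),
        )
        M = rng.normal(size=(q, 4))
        J = hb.posterior_mean(G, cm, M)
        SJ = 0.7 * np.eye(p) + 1.3 * Qs[1].toarray()
        oracle = SJ @ G.T @ np.linalg.solve(G @ SJ @ G.T + 0.3 * np.eye(q), M)
        assert np.linalg.norm(J - oracle) / np.linalg.norm(oracle) < 1e-8

    def test_support_restricted_to_component(self):
        rng = np.random.default_rng(7)
        q, p = 10, 30
        G = random_leadfield(q, p, 7)
        support = np.zeros(p)
        support[5:12] = 1.0
        cm = hb.CovarianceModel(
            [sp.diags(support).tocsr()], ["patch"], log_sensor=0.0,
        )
        J = hb.posterior_mean(G, cm, rng.normal(size=(q, 2)))
        outside = np.ones(p, bool)
        outside[5:12] = False
        assert np.all(J[outside] == 0)


class TestLocalizeHB:
    @pytest.fixture(scope="class")
    def focal_simulation(self):
        from megloc import forward as fw
        from megloc import simulate as sm

        surf = sf.synth_cortex(400, rng_seed=23)
        adj = sf.build_adjacency(surf)
        sensors = fw.radial_sensor_cap(60, radius_mm=120.0)
        G = fw.spherical_lead_field(sensors, surf, sphere_radius=95.0)
        # pick a well-coupled superficial seed for a clean focal source
        gains = np.linalg.norm(G.matrix, axis=0)
        seed = int(np.argmax(gains))
        src = sm.make_extended_source(surf, adj, seed, 1)
        w = sm.spike_waveform()
        bank = sm.synth_background(60, n_trials=32,
                                   sensor_positions=sensors.positions, rng_seed=3)
        # quiet-noise regime: the property under test is clean focal
        # localization, not low-SNR robustness
        bank.scale = 0.3 * sm.calibrate_noise_scale(G, surf, adj, bank, waveform=w)
        ds = sm.simulate_dataset(G, src, w, bank, rng_seed=5)
        return surf, adj, G, ds, src, w

    def test_iid_localizes_focal_source(self, focal_simulation):
        surf, adj, G, ds, src, w = focal_simulation
        sol = hb.localize_hb(ds.M, G, "IID",
                             window=np.arange(w.peak_index - 10, w.peak_index + 11))
        J_peak = sol.J[:, 10]
        gmax = int(np.argmax(np.abs(J_peak)))
        d = sf.geodesic_from(surf, adj, src.vertices)
        assert d[gmax] <= 2 * 7.5  # within two edge lengths of the source

    def test_coh_no_rougher_than_iid(self, focal_simulation):
        # sensor-space projections of the identity and smoothness
        # components are nearly collinear, so ReML model selection often
        # favors the minimum-energy prior and COH ~ IID; the smoothness
        # prior must never make the solution rougher
        surf, adj, G, ds, src, w = focal_simulation
        W = pr.smoothness_kernel(pr.graph_laplacian(adj), 0.6)
        win = np.arange(w.peak_index - 10, w.peak_index + 11)
        J_iid = hb.localize_hb(ds.M, G, "IID", window=win).J[:, 10]
        J_coh = hb.localize_hb(ds.M, G, "COH", W=W, window=win).J[:, 10]
        L = pr.graph_laplacian(adj).toarray()

        def roughness(J):
            Jn = J / np.linalg.norm(J)
            return float(-Jn @ (L @ Jn))  # -J'LJ >= 0, larger = rougher

        assert roughness(J_coh) <= roughness(J_iid) * (1 + 1e-3)

    def test_model_results_summary(self, focal_simulation):
        surf, adj, G, ds, src, w = focal_simulation
        res = hb.HBModel(ds.M, G, "IID").fit(
            window=np.arange(w.peak_index - 3, w.peak_index + 4)
        )
        text = res.summary()
        assert "IID" in text and "ReML" in text
        assert res.J.shape == (surf.n_vertices, 7)

    def test_fitted_model_csv(self, focal_simulation, tmp_path):
        surf, adj, G, ds, src, w = focal_simulation
        sol = hb.localize_hb(ds.M, G, "IID", window=[w.peak_index])
        path = str(tmp_path / "weights.csv")
        sol.model.to_csv(path)
        lines = open(path).read().strip().splitlines()
        assert lines[0] == "component,weight"
        assert len(lines) == 3  # sensor + iid
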