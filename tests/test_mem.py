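"""Maximum Entropy on the Mean: dual optimization and reference measure."""

import numpy as np
import pytest

from megloc import mem
from megloc.parcellation import Parcellation, ActivationMap, EPS_ALPHA
from tests.conftest import random_leadfield


def toy_problem(q=20, p=60, n_parcels=6, seed=0):
    rng = np.random.default_rng(seed)
    G = random_leadfield(q, p, seed)
    labels = np.repeat(np.arange(1, n_parcels + 1), p // n_parcels)
    parc = Parcellation(labels=labels, scale=1,
                        seeds=np.arange(0, p, p // n_parcels))
    return rng, G, parc


class TestMNE:
    def test_zero_data(self):
        G = random_leadfield(8, 20, 1)
        assert np.all(mem.mne_estimate(np.zeros((8, 2)), G) == 0)

    def test_scalar_low_regularization_limit(self):
        # q = p = 1, G = 2: as snr_param grows, J -> m / 2
        J = mem.mne_estimate(np.array([[1.0]]), np.array([[2.0]]), snr_param=1e6)
        assert J[0, 0] == pytest.approx(0.5, rel=1e-9)

    def test_residual_monotone_in_snr_param(self):
        rng = np.random.default_rng(3)
        G = random_leadfield(10, 30, 3)
        m = rng.normal(size=(10, 1))
        resid = [
            np.linalg.norm(G @ mem.mne_estimate(m, G, snr_param=s) - m)
            for s in (0.5, 1, 2, 4, 8, 16)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(resid, resid[1:]))

    def test_invalid_snr_param(self):
        with pytest.raises(ValueError):
            mem.mne_estimate(np.zeros((2, 1)), np.eye(2), snr_param=0)


class TestInitReference:
    def test_eta_is_five_percent_of_parcel_energy(self):
        # hand-computed 3-parcel toy
        labels = np.array([1, 1, 2, 2, 3, 3])
        parc = Parcellation(labels=labels, scale=1, seeds=np.array([0, 2, 4]))
        mne_map = np.array([[1.0], [3.0], [2.0], [2.0], [0.0], [0.0]])
        act = ActivationMap(alpha=np.full((3, 1), 0.5))
        ref = mem.init_reference(parc, act, mne_map)
        assert ref.eta[0, 0] == pytest.approx(0.05 * (1 + 9) / 2)
        assert ref.eta[1, 0] == pytest.approx(0.05 * 4)
        # all-zero parcel floored at 1e-12 of global mean energy
        assert ref.eta[2, 0] == pytest.approx(1e-12 * np.mean(mne_map**2))

    def test_doubling_data_quadruples_eta(self):
        rng, G, parc = toy_problem(seed=5)
        m = rng.normal(size=(20, 1))
        act = ActivationMap(alpha=np.full((6, 1), 0.5))
        e1 = mem.init_reference(parc, act, mem.mne_estimate(m, G)).eta
        e2 = mem.init_reference(parc, act, mem.mne_estimate(2 * m, G)).eta
        assert np.allclose(e2, 4 * e1, rtol=1e-10)

    def test_coherent_requires_kernel(self):
        _, G, parc = toy_problem()
        act = ActivationMap(alpha=np.full((6, 1), 0.5))
        with pytest.raises(ValueError, match="smoothness kernel"):
            mem.init_reference(parc, act, np.ones((60, 1)), coherent=True)


class TestMEMDual:
    def _reference(self, parc, alpha, eta, tau=1):
        K = parc.n_parcels
        return mem.ParcelReference(
            parcellation=parc,
            alpha=np.full((K, tau), alpha),
            eta=np.full((K, tau), eta),
            cov_blocks=[None] * K,
            coherent=False,
        )

    def test_ridge_oracle_all_parcels_active(self):
        # alpha -> 1, identity C_k, common eta: MEM = regularized min norm
        rng, G, parc = toy_problem(seed=0)
        eta, sigma2 = 0.7, 0.5
        ref = self._reference(parc, 1 - EPS_ALPHA, eta)
        m = rng.normal(size=20)
        lam, J, gamma, info = mem.mem_fit_timepoint(m, G, ref, sigma2 * np.eye(20))
        oracle = eta * G.T @ np.linalg.solve(eta * G @ G.T + sigma2 * np.eye(20), m)
        assert np.linalg.norm(J - oracle) / np.linalg.norm(oracle) < 1e-5
        assert info["converged"]

    def test_gradient_matches_central_differences(self):
        rng, G, parc = toy_problem(seed=1)
        ref = self._reference(parc, 0.4, 0.9)
        m = rng.normal(size=20)
        prob = mem._DualProblem(m, G, ref, 0, 0.3 * np.eye(20))
        h = 1e-6
        for _ in range(10):
            lam0 = rng.normal(size=20) * 0.5
            _, g, _ = prob.value_grad(lam0)
            gfd = np.empty(20)
            for i in range(20):
                e = np.zeros(20)
                e[i] = h
                gfd[i] = (prob.value_grad(lam0 + e)[0] - prob.value_grad(lam0 - e)[0]) / (2 * h)
            assert np.abs(gfd - g).max() / np.abs(g).max() < 1e-5

    def test_dual_is_concave_on_random_chords(self):
        rng, G, parc = toy_problem(seed=2)
        ref = self._reference(parc, 0.3, 1.2)
        m = rng.normal(size=20)
        prob = mem._DualProblem(m, G, ref, 0, 0.2 * np.eye(20))
        for _ in range(20):
            l1, l2 = rng.normal(size=20), rng.normal(size=20)
            a = rng.uniform()
            D1 = prob.value_grad(l1)[0]
            D2 = prob.value_grad(l2)[0]
            Dm = prob.value_grad(a * l1 + (1 - a) * l2)[0]
            assert Dm >= a * D1 + (1 - a) * D2 - 1e-10

    def test_zero_data_stationary_at_origin(self):
        _, G, parc = toy_problem(seed=3)
        ref = self._reference(parc, 0.5, 1.0)
        lam, J, gamma, info = mem.mem_fit_timepoint(
            np.zeros(20), G, ref, np.eye(20)
        )
        assert np.all(lam == 0) and np.all(J == 0)
        assert info["converged"]

    def test_inactive_reference_shuts_solution_down(self):
        # alpha -> eps drives ||J|| -> 0 monotonically on fixed data
        rng, G, parc = toy_problem(seed=4)
        m = rng.normal(size=20)
        norms = []
        for alpha in (0.9, 0.5, 0.1, 1e-3, 1e-6):
            ref = self._reference(parc, alpha, 0.005)
            _, J, _, _ = mem.mem_fit_timepoint(m, G, ref, np.eye(20))
            norms.append(np.linalg.norm(J))
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-3 * norms[0]

    def test_non_psd_noise_rejected(self):
        _, G, parc = toy_problem(seed=5)
        ref = self._reference(parc, 0.5, 1.0)
        with pytest.raises(ValueError, match="positive semidefinite"):
            mem.mem_fit_timepoint(np.ones(20), G, ref, -np.eye(20))


class TestLocalizeMEM:
    def _inputs(self, seed=6, tau=5):
        rng, G, parc = toy_problem(seed=seed)
        M = rng.normal(size=(20, tau))
        act = ActivationMap(alpha=np.full((6, tau), 0.4))
        return rng, G, parc, M, act

    def test_single_timepoint_window_matches_direct_call(self):
        rng, G, parc, M, act = self._inputs()
        sol = mem.localize_mem(M, G, parc, act, Sigma_E=0.3 * np.eye(20), window=[2])
        mne_w = mem.mne_estimate(M[:, [2]], G)
        ref = mem.init_reference(parc, ActivationMap(alpha=act.alpha[:, [2]]), mne_w)
        _, J_direct, _, _ = mem.mem_fit_timepoint(M[:, 2], G, ref, 0.3 * np.eye(20))
        assert np.allclose(sol.J[:, 0], J_direct, rtol=1e-8, atol=1e-12)

    def test_rho_zero_makes_coherent_equal_plain(self):
        from megloc import priors as pr
        from megloc import surface as sf

        surf = sf.synth_cortex(120, rng_seed=30)
        adj = sf.build_adjacency(surf)
        W0 = pr.smoothness_kernel(pr.graph_laplacian(adj), 0.0)
        rng = np.random.default_rng(8)
        G = rng.normal(size=(15, surf.n_vertices))
        M = rng.normal(size=(15, 3))
        labels = np.ones(surf.n_vertices, dtype=np.int64)
        labels[surf.hemisphere == "right"] = 2
        parc = Parcellation(labels=labels, scale=1, seeds=np.array([0, 1]))
        act = ActivationMap(alpha=np.full((2, 3), 0.5))
        a = mem.localize_mem(M, G, parc, act, coherent=False,
                             Sigma_E=np.eye(15), window=[1])
        b = mem.localize_mem(M, G, parc, act, coherent=True, W=W0,
                             Sigma_E=np.eye(15), window=[1])
        assert np.allclose(a.J, b.J, rtol=1e-7, atol=1e-14)

    def test_invariant_to_parcel_reordering(self):
        rng, G, parc, M, act = self._inputs(seed=9)
        # relabel parcels in reverse order (same partition)
        labels2 = 7 - parc.labels
        parc2 = Parcellation(labels=labels2, scale=1, seeds=parc.seeds[::-1])
        act2 = ActivationMap(alpha=act.alpha[::-1])
        a = mem.localize_mem(M, G, parc, act, Sigma_E=np.eye(20), window=[0])
        b = mem.localize_mem(M, G, parc2, act2, Sigma_E=np.eye(20), window=[0])
        assert np.allclose(a.J, b.J, rtol=1e-6, atol=1e-12)

    def test_window_out_of_range(self):
        _, G, parc, M, act = self._inputs()
        with pytest.raises(IndexError):
            mem.localize_mem(M, G, parc, act, window=[99])


class TestMEMModelFrontend:
    def test_fit_returns_results_with_summary(self):
        rng, G, parc, M, act = TestLocalizeMEM()._inputs(seed=12)
        model = mem.MEMModel(M, G, parc, act, Sigma_E=np.eye(20))
        res = model.fit(window=[0, 1])
        assert res.J.shape == (60, 2)
        text = res.summary()
        assert "MEM-s" in text and "parcels: 6" in text

    def test_solution_serialization(self, tmp_path):
        rng, G, parc, M, act = TestLocalizeMEM()._inputs(seed=13)
        res = mem.MEMModel(M, G, parc, act, Sigma_E=np.eye(20)).fit(window=[0])
        res.save(str(tmp_path / "sol"))
        gamma = np.loadtxt(tmp_path / "sol_gamma.csv", delimiter=",", skiprows=1)
        assert gamma.shape == (6, 3)
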