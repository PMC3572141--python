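"""Maximum Entropy on the Mean (MEM) source localization.

The source intensity J is treated as a random variable with a reference
probability measure dnu built on the parcellation P(s): each parcel k is
either silent (a Dirac mass at zero, with probability 1 - alpha_k) or
active (a Gaussian N(mu_k, Sigma_k), probability alpha_k), independently
across parcels:

    dnu = prod_k [ (1 - alpha_k(t)) delta + alpha_k(t) N(mu_k, Sigma_k(t)) ]

Among all distributions dp that explain the data in the mean
(E_p[G J] = m, relaxed by Gaussian sensor noise Sigma_E), the MEM solution
maximizes the entropy relative to dnu.  By convex duality this reduces, at
each time sample, to maximizing the concave dual over lambda in R^q:

    D(lambda) = lambda' m - sum_k F*_k(G_k' lambda) - 1/2 lambda' Sigma_E lambda
    F*_k(xi)  = log[(1 - a_k) + a_k exp(mu_k' xi + 1/2 xi' Sigma_k xi)]

where F*_k is the log-partition (free energy) of parcel k's mixture.  At
the optimum the posterior activation is
``gamma_k = sigmoid(z_k + logit(a_k))`` with
``z_k = mu_k' xi_k + 1/2 xi_k' Sigma_k xi_k`` and the estimate restricted
to parcel k is ``gamma_k (mu_k + Sigma_k xi_k)`` with
``xi_k = G_k' lambda*``.

Two methods differ only through the active-state covariance:
``MEM-s`` uses ``Sigma_k = eta_k I`` (independent sources within a parcel)
and ``CMEM-s`` uses ``Sigma_k = eta_k W_k`` (locally coherent sources,
W_k the parcel block of the diffusion kernel).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .forward import LeadField
from .parcellation import Parcellation, ActivationMap, msp_scores, ddp, stapm
from .priors import SmoothnessKernel, parcel_block

__all__ = [
    "ParcelReference",
    "MEMSolution",
    "mne_estimate",
    "init_reference",
    "mem_fit_timepoint",
    "localize_mem",
    "MEMModel",
    "MEMResults",
]

ETA_INIT_FRACTION = 0.05  # reference covariance = 5% of parcel MNE energy
ETA_FLOOR_FRACTION = 1e-12


def _gain(G) -> np.ndarray:
    return G.matrix if isinstance(G, LeadField) else np.asarray(G, float)


def mne_estimate(M: np.ndarray, G, snr_param: float = 3.0) -> np.ndarray:
    """Regularized minimum-norm estimate ``G'(GG' + lam I)^-1 M``.

    The Tikhonov parameter is ``lam = trace(GG') / (q snr_param^2)`` — the
    usual SNR-based depth of regularization.
    """
    if snr_param <= 0:
        raise ValueError("snr_param must be positive")
    Gm = _gain(G)
    M = np.atleast_2d(np.asarray(M, float))
    if M.ndim == 1:
        M = M[:, None]
    q = Gm.shape[0]
    gram = Gm @ Gm.T
    lam = np.trace(gram) / (q * snr_param**2)
    try:
        sol = np.linalg.solve(gram + lam * np.eye(q), M)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular MNE system: {exc}") from exc
    return Gm.T @ sol


@dataclass
class ParcelReference:
    """MEM reference measure: per-parcel mixture parameters.

    ``alpha`` is K x tau (clipped to the open unit interval); ``eta`` is
    K x tau (active-state covariance scale per parcel per time);
    ``cov_blocks[k]`` is parcel k's n_k x n_k structure matrix C_k
    (None means the identity); ``mu`` is zero unless set.
    """

    parcellation: Parcellation
    alpha: np.ndarray
    eta: np.ndarray
    cov_blocks: list
    coherent: bool
    mu: list | None = None

    @property
    def n_parcels(self) -> int:
        return self.parcellation.n_parcels


@dataclass
class MEMSolution:
    """MEM estimate with dual variables and optimizer diagnostics."""

    J: np.ndarray
    lambdas: np.ndarray  # tau x q dual vectors
    gamma: np.ndarray  # K x tau posterior activation
    iterations: np.ndarray
    grad_norms: np.ndarray
    converged: np.ndarray


def init_reference(
    parcellation: Parcellation,
    activation: ActivationMap,
    mne: np.ndarray,
    coherent: bool = False,
    W: SmoothnessKernel | None = None,
) -> ParcelReference:
    """Initialize the reference measure from the activation map and MNE.

    * ``alpha`` comes from the stAPM;
    * ``mu_k = 0`` (MEM infers the mean, so the prior mean stays
      uninformative);
    * ``eta_k(t)`` = 5% of the mean squared MNE amplitude within the
      parcel, floored at 1e-12 of the global mean energy;
    * ``C_k`` = identity (MEM-s) or the parcel block W_k of the diffusion
      kernel (CMEM-s).
    """
    K = parcellation.n_parcels
    mne = np.atleast_2d(mne)
    if mne.ndim == 1:
        mne = mne[:, None]
    tau = mne.shape[1]
    if activation.alpha.shape != (K, tau):
        raise ValueError("activation map inconsistent with parcellation/window")
    global_energy = float(np.mean(mne**2))
    if global_energy == 0:
        warnings.warn("all-zero MNE: reference energies set to the floor")
        global_energy = 1.0
    floor = ETA_FLOOR_FRACTION * global_energy
    eta = np.empty((K, tau))
    blocks = []
    for k in range(1, K + 1):
        idx = parcellation.parcel_vertices(k)
        eta[k - 1] = np.maximum(
            ETA_INIT_FRACTION * np.mean(mne[idx] ** 2, axis=0), floor
        )
        if coherent:
            if W is None:
                raise ValueError("coherent reference requires a smoothness kernel W")
            blocks.append(parcel_block(W, parcellation, k))
        else:
            blocks.append(None)
    return ParcelReference(
        parcellation=parcellation,
        alpha=activation.alpha.copy(),
        eta=eta,
        cov_blocks=blocks,
        coherent=coherent,
    )


class _DualProblem:
    """Concave MEM dual at one time sample, on an internally scaled system."""

    def __init__(self, m, Gm, ref: ParcelReference, t: int, Sigma_E):
        self.ref = ref
        K = ref.n_parcels
        self.idx = [ref.parcellation.parcel_vertices(k) for k in range(1, K + 1)]
        self.Gk = [Gm[:, ix] for ix in self.idx]
        self.alpha = ref.alpha[:, t]
        self.logit_alpha = logit(self.alpha)
        self.eta = ref.eta[:, t]
        self.blocks = ref.cov_blocks
        self.m = m
        self.Sigma_E = Sigma_E
        self.p = Gm.shape[1]

    def _parcel_terms(self, lam):
        """Per-parcel xi, Sigma xi and z at the current dual point."""
        xis, sxis, zs = [], [], []
        for k in range(len(self.Gk)):
            xi = self.Gk[k].T @ lam
            if self.blocks[k] is None:
                sxi = self.eta[k] * xi
            else:
                sxi = self.eta[k] * (self.blocks[k] @ xi)
            z = 0.5 * float(xi @ sxi)
            xis.append(xi)
            sxis.append(sxi)
            zs.append(z)
        return xis, sxis, np.array(zs)

    def value_grad(self, lam):
        xis, sxis, zs = self._parcel_terms(lam)
        # F* = log((1-a) + a e^z) = logaddexp(log(1-a), log(a) + z)
        fstar = np.logaddexp(np.log1p(-self.alpha), np.log(self.alpha) + zs)
        sig_e_lam = self.Sigma_E @ lam
        D = float(lam @ self.m) - float(fstar.sum()) - 0.5 * float(lam @ sig_e_lam)
        gamma = expit(zs + self.logit_alpha)
        grad = self.m - sig_e_lam
        for k, (sxi, g) in enumerate(zip(sxis, gamma)):
            grad -= self.Gk[k] @ (g * sxi)
        return D, grad, gamma

    def primal(self, lam):
        """Moment-matching map: J restricted to parcel k = gamma_k Sigma_k xi_k."""
        xis, sxis, zs = self._parcel_terms(lam)
        gamma = expit(zs + self.logit_alpha)
        J = np.zeros(self.p)
        for k, ix in enumerate(self.idx):
            J[ix] = gamma[k] * sxis[k]
        return J, gamma


def mem_fit_timepoint(
    m: np.ndarray,
    G,
    ref: ParcelReference,
    Sigma_E: np.ndarray,
    t: int = 0,
    max_iter: int = 500,
    grad_rtol: float = 1e-8,
):
    """Solve the MEM dual at one time sample.

    Returns ``(lambda*, J_t, gamma, info)`` where ``info`` carries the
    iteration count, final gradient infinity-norm and a convergence flag
    (gradient inf-norm <= grad_rtol * ||m||, or ``m = 0``).
    """
    Gm = _gain(G)
    m = np.asarray(m, float).ravel()
    Sigma_E = np.asarray(Sigma_E, float)
    evals = np.linalg.eigvalsh(0.5 * (Sigma_E + Sigma_E.T))
    if evals.min() < -1e-10 * max(1.0, evals.max()):
        raise ValueError("Sigma_E is not positive semidefinite")

    m_norm = np.linalg.norm(m)
    if m_norm == 0:
        K = ref.n_parcels
        gamma0 = expit(logit(ref.alpha[:, t]))
        info = {"iterations": 0, "grad_norm": 0.0, "converged": True}
        return np.zeros(Gm.shape[0]), np.zeros(Gm.shape[1]), gamma0, info

    # internal scaling: solve in units where J ~ O(1) and m ~ O(1)
    u_j = np.sqrt(np.mean(ref.eta[:, t]) / ETA_INIT_FRACTION)
    if u_j == 0:
        u_j = 1.0
    u_m = m_norm
    Gs = Gm * (u_j / u_m)
    ref_s = ParcelReference(
        parcellation=ref.parcellation,
        alpha=ref.alpha,
        eta=ref.eta / u_j**2,
        cov_blocks=ref.cov_blocks,
        coherent=ref.coherent,
    )
    prob = _DualProblem(m / u_m, Gs, ref_s, t, Sigma_E / u_m**2)

    def fun(lam):
        D, grad, _ = prob.value_grad(lam)
        if not np.isfinite(D):
            raise FloatingPointError(
                f"NaN/inf in MEM dual objective at ||lambda|| = {np.linalg.norm(lam):.3g}"
            )
        return -D, -grad

    res = minimize(
        fun,
        np.zeros(len(m)),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-16, "gtol": 1e-14, "maxcor": 30},
    )
    lam = res.x
    _, grad, _ = prob.value_grad(lam)
    gnorm = np.abs(grad).max()
    target = grad_rtol * np.linalg.norm(prob.m)
    converged = bool(gnorm <= target)
    J_s, gamma = prob.primal(lam)
    info = {
        "iterations": int(res.nit),
        "grad_norm": float(gnorm),
        "converged": converged,
    }
    return lam, u_j * J_s, gamma, info


def localize_mem(
    M: np.ndarray,
    G,
    parcellation: Parcellation,
    activation: ActivationMap,
    coherent: bool = False,
    W: SmoothnessKernel | None = None,
    snr_param: float = 3.0,
    Sigma_E: np.ndarray | None = None,
    baseline: slice | None = None,
    window=None,
    max_iter: int = 500,
) -> MEMSolution:
    """MEM-s / CMEM-s localization over a time window.

    The reference measure is initialized once (from the stAPM and the MNE
    of the window) and the dual problem is solved independently at each
    sample.  ``Sigma_E`` defaults to ``sigma^2 I`` with ``sigma^2`` the
    mean per-sensor variance over ``baseline`` (default: the first quarter
    of the samples of ``M``).
    """
    Gm = _gain(G)
    M = np.atleast_2d(np.asarray(M, float))
    q, tau_full = M.shape
    if window is None:
        window = np.arange(tau_full)
    window = np.atleast_1d(np.asarray(window, int))
    if window.min() < 0 or window.max() >= tau_full:
        raise IndexError("window indices outside the data")
    if Sigma_E is None:
        if baseline is None:
            baseline = slice(0, max(1, tau_full // 4))
        sigma2 = float(np.mean(np.var(M[:, baseline], axis=1)))
        if sigma2 == 0:
            sigma2 = 1e-12 * float(np.mean(M**2) + 1e-300)
        Sigma_E = sigma2 * np.eye(q)

    Mw = M[:, window]
    mne = mne_estimate(Mw, Gm, snr_param=snr_param)
    ref = init_reference(
        parcellation,
        ActivationMap(alpha=activation.alpha[:, window]),
        mne,
        coherent=coherent,
        W=W,
    )
    nT = len(window)
    p = Gm.shape[1]
    K = parcellation.n_parcels
    J = np.zeros((p, nT))
    lambdas = np.zeros((nT, q))
    gamma = np.zeros((K, nT))
    iters = np.zeros(nT, int)
    gnorms = np.zeros(nT)
    conv = np.zeros(nT, bool)
    for j in range(nT):
        try:
            lam, Jt, gam, info = mem_fit_timepoint(
                Mw[:, j], Gm, ref, Sigma_E, t=j, max_iter=max_iter
            )
        except Exception as exc:
            raise RuntimeError(f"MEM failed at window sample {j}: {exc}") from exc
        J[:, j] = Jt
        lambdas[j] = lam
        gamma[:, j] = gam
        iters[j] = info["iterations"]
        gnorms[j] = info["grad_norm"]
        conv[j] = info["converged"]
    return MEMSolution(
        J=J, lambdas=lambdas, gamma=gamma, iterations=iters,
        grad_norms=gnorms, converged=conv,
    )


# ---------------------------------------------------------------------------
# Model / Results front-end
# ---------------------------------------------------------------------------

class MEMModel:
    """MEM source localization model bound to one dataset.

    Parameters
    ----------
    M : (q, tau) ndarray
        Sensor data (T).
    G : LeadField or ndarray
        Forward gain matrix.
    parcellation : Parcellation
        Cortical partition P(s) (use :meth:`from_data` to build it from
        the data's MSP scores).
    activation : ActivationMap
        Parcel activation probabilities alpha_k(t) over the full data.
    coherent : bool
        False -> MEM-s (identity parcel covariance); True -> CMEM-s
        (diffusion-kernel parcel covariance, requires ``W``).
    """

    def __init__(
        self,
        M,
        G,
        parcellation: Parcellation,
        activation: ActivationMap,
        coherent: bool = False,
        W: SmoothnessKernel | None = None,
        snr_param: float = 3.0,
        Sigma_E: np.ndarray | None = None,
        baseline: slice | None = None,
    ):
        self.M = np.atleast_2d(np.asarray(M, float))
        self.G = G
        self.parcellation = parcellation
        self.activation = activation
        self.coherent = coherent
        if coherent and W is None:
            raise ValueError("CMEM-s requires the smoothness kernel W")
        self.W = W
        self.snr_param = snr_param
        self.Sigma_E = Sigma_E
        self.baseline = baseline

    @classmethod
    def from_data(
        cls,
        M,
        G,
        surface,
        adjacency,
        scale: int = 5,
        coherent: bool = False,
        W: SmoothnessKernel | None = None,
        subspace_energy: float = 0.95,
        parcellize_on: np.ndarray | None = None,
        **kwargs,
    ) -> "MEMModel":
        """Build the model with a data-driven parcellation.

        ``parcellize_on`` optionally substitutes other sensor data (e.g. a
        background segment) for the MSP scoring that drives the
        parcellation — the activation map is still computed from ``M``.
        """
        score_data = M if parcellize_on is None else parcellize_on
        sc = msp_scores(score_data, G, subspace_energy=subspace_energy)
        parc = ddp(surface, adjacency, sc, scale)
        sc_m = sc if parcellize_on is None else msp_scores(M, G, subspace_energy)
        act = stapm(sc_m, parc)
        return cls(M, G, parc, act, coherent=coherent, W=W, **kwargs)

    def fit(self, window=None, max_iter: int = 500) -> "MEMResults":
        sol = localize_mem(
            self.M,
            self.G,
            self.parcellation,
            self.activation,
            coherent=self.coherent,
            W=self.W,
            snr_param=self.snr_param,
            Sigma_E=self.Sigma_E,
            baseline=self.baseline,
            window=window,
            max_iter=max_iter,
        )
        return MEMResults(self, sol, window)


class MEMResults:
    """Fitted MEM solution: current density, activations, diagnostics."""

    def __init__(self, model: MEMModel, solution: MEMSolution, window):
        self.model = model
        self.solution = solution
        self.window = window
        self.J = solution.J
        self.gamma = solution.gamma

    @property
    def method(self) -> str:
        return "CMEM-s" if self.model.coherent else "MEM-s"

    def summary(self) -> str:
        sol = self.solution
        K, nT = sol.gamma.shape
        lines = [
            f"{self.method} localization (scale s={self.model.parcellation.scale})",
            f"  parcels: {K}   time samples solved: {nT}",
            f"  converged: {int(sol.converged.sum())}/{nT}"
            f"   max final grad: {sol.grad_norms.max():.3e}",
            f"  median iterations: {np.median(sol.iterations):.0f}",
            f"  active parcels (gamma > 0.5) at last sample: "
            f"{int((sol.gamma[:, -1] > 0.5).sum())}",
            f"  ||J|| at last sample: {np.linalg.norm(sol.J[:, -1]):.3e} A.m",
        ]
        return "\n".join(lines)

    def save(self, prefix: str) -> None:
        np.savetxt(prefix + "_J.tsv", self.J, delimiter="\t")
        K, nT = self.gamma.shape
        with open(prefix + "_gamma.csv", "w") as fh:
            fh.write("parcel,t,gamma\n")
            for k in range(K):
                for t in range(nT):
                    fh.write(f"{k + 1},{t},{float(self.gamma[k, t])!r}\n")
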