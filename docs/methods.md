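# Methods

This note documents the models implemented in `megloc`, the choices made
where the design was genuinely open, and what the synthetic benchmark does
and does not establish.

## The inverse problem

MEG measurements follow the linear model `M = G J + E`, with `M` the q x
tau sensor data, `G` the q x p lead field, `J` the unknown dipole moment
amplitudes on the cortical surface (orientations fixed along the cortical
normal) and `E` additive noise.  With p >> q the problem is ill-posed and
every method here is a choice of spatial prior plus an estimation
framework.  Two families are implemented over identical spatial priors:

* **Maximum Entropy on the Mean (MEM)** — `MEM-s`, `CMEM-s`;
* **Hierarchical Bayesian covariance components + ReML** — `IID`, `COH`,
  `COH-s`.

## Spatial models

**Data-driven parcellization (DDP).**  The cortex is partitioned into K
non-overlapping connected parcels P(s) at neighborhood scale s.  Seeds are
chosen greedily at the highest multivariate source pre-localization (MSP)
score; each seed grows a ball of graph order s through still-unassigned
vertices.  The MSP score of dipole i is the squared projection of its
normalized forward field onto the signal subspace of the (normalized)
data, the subspace dimension chosen to capture 95% of data variance
(configurable); the score is modulated over time by the instantaneous data
energy.  Ties in seed selection break to the lowest vertex index, making
the partition fully deterministic.  The per-parcel aggregation of MSP
scores into activation probabilities alpha_k(t) (the stAPM) uses the
within-parcel median by default (mean and max are available); alpha is
clipped to [1e-6, 1 - 1e-6] so the MEM log-partition stays finite.

**Diffusion smoothness kernel.**  Local spatial coherence is encoded by
`W = sum_{i=0}^{8} (rho L)^i / i!`, the order-8 truncation of `exp(rho L)`
with `L = A - diag(degree)` the (negative semidefinite) graph Laplacian of
the mesh and `rho = 0.6` by default (range [0, 1)).  Because L annihilates
constants, W has unit row sums; the implementation quantizes entries to
the 2^-40 grid and sets the diagonal so the row sums are *exactly* 1.0 in
floating point (the adjustment is ~1e-13, far below the ~1e-8 truncation
error of the series).  The truncation can leave slightly negative
eigenvalues at large rho x degree; a separate eigenvalue-clipped copy
(`psd_matrix`) is used wherever W enters a covariance.  Entries of W
vanish exactly beyond graph distance 8.

## MEM solvers (MEM-s, CMEM-s)

The reference measure factorizes over parcels; parcel k is silent (Dirac
at 0) with probability `1 - alpha_k(t)` or active with Gaussian law
`N(0, eta_k(t) C_k)`, where `eta_k(t)` is initialized as 5% of the mean
squared minimum-norm amplitude within the parcel (floored at 1e-12 of the
global mean energy) and `C_k` is the identity (MEM-s) or the parcel block
`W_k` of the diffusion kernel (CMEM-s).  The MEM solution maximizes
entropy relative to this reference among distributions that explain the
data in the mean; the sensor-noise relaxation is Gaussian with covariance
`Sigma_E`.  By Fenchel duality this is an unconstrained concave problem in
R^q per time sample:

    D(lambda) = lambda'm - sum_k F*_k(G_k'lambda) - 1/2 lambda'Sigma_E lambda,
    F*_k(xi)  = log[(1 - a_k) + a_k exp(xi'Sigma_k xi / 2)],

solved by L-BFGS with the analytic gradient from a fixed start lambda = 0;
convergence is declared at gradient infinity-norm <= 1e-8 ||m|| (500
iteration cap, non-convergence flagged).  The problem is solved on an
internally rescaled system (data and source units normalized to O(1)) so
the optimizer never sees tesla-scale numbers; the rescaling is exact (the
MEM solution is covariant under these unit changes).  At the optimum,
parcel activations are `gamma_k = sigmoid(z_k + logit(a_k))` and the
estimate on parcel k is `gamma_k Sigma_k G_k' lambda*`.  Time samples are
solved independently with the same parcellation over the window.

A closed-form guard anchors the implementation: with every parcel active
(alpha -> 1), identity C_k, common eta and `Sigma_E = sigma^2 I`, the MEM
estimate equals the Tikhonov-regularized minimum norm
`eta G'(eta GG' + sigma^2 I)^{-1} m`; the test suite checks this to 1e-5
together with finite-difference gradient and concavity checks.

## Hierarchical Bayesian solvers (IID, COH, COH-s)

Sensor and source covariances are positively weighted sums of fixed
components, `Sigma_E = exp(l_eps) I_q` and
`Sigma_J = sum_i exp(l_i) Q_i`, with the component sets

* IID: `{I_p}` (minimum-norm prior);
* COH: `{I_p, W}`;
* COH-s: `{I_p, W, B_1..B_K}`, B_k holding parcel k's block of W.

The log-weights are estimated by ReML on the window sample covariance
`S = MM'/tau` under `C = exp(l_eps) I + sum_i exp(l_i) G Q_i G'`, by
Fisher scoring with step-halving (the restricted likelihood is
non-decreasing across accepted steps; the step is the Fisher direction,
uniformly rescaled when too long so ascent is preserved).  A weak Gaussian
prior on the source log-weights (mean -32, variance 256) gives ARD
behavior: components the data do not support are driven to zero weight.
The sensor log-weight is anchored by a prior (variance 4) at its
initialization from the smallest positive sample eigenvalues — at short
windows (tau < q) the sample covariance is rank-deficient and without the
anchor the noise floor can collapse, leaving the estimate effectively
unregularized.  Fitting runs on internally unit-normalized data and gain;
fitted weights are mapped back exactly (rescaling M by c rescales every
weight by c^2).  The estimate is the Gaussian posterior mean
`Sigma_J G'(G Sigma_J G' + Sigma_E)^{-1} M`.

Note that `G W G'` is close to `G G'` on a 7-mm mesh (neighboring forward
fields are nearly parallel), so ReML frequently selects the identity
component and COH reproduces IID — the model-selection behavior, not a
solver defect.

## Forward model

Dipoles in a homogeneous conducting sphere (the analytic Sarvas field),
sensors modeled as radial point magnetometers on a helmet-like cap
(Fibonacci lattice over the top 72% of a 110 mm sphere).  For radial
sensors the volume currents contribute no field, so the implementation is
cross-checked in tests against the plain Biot-Savart field of the primary
dipole.  Units: moments in A·m, fields in T; the simulator works in nA·m
and converts.

## Synthetic anatomy

Two disconnected, folded, closed ellipsoidal hemisphere meshes built from
a Fibonacci lattice (vertex count honored exactly), mirrored about the
midline, mean edge length targeted at 7 mm.  Two features matter for
realism:

* **Dipole orientations** are the outward envelope normal tilted toward a
  smooth random tangent direction by a smooth angular field (20-85
  degrees).  At 7-mm decimation real cortical normals (gyral crowns vs
  sulcal walls) deviate strongly from the smooth envelope; without the
  tilt a spherical MEG model silences every superficial crown source and
  the depth-sensitivity profile of the benchmark is wrong.
* **A minimum-eccentricity shell** (`r -> sqrt(r^2 + 30^2)` mm) keeps the
  surface away from the head center: real cortex bottoms out around
  30-40 mm (insular/mesial surfaces), and without the shell the generator
  produces physically impossible near-center sources that no method can
  see.

## Simulated spike datasets

An extended source is a region-grown patch (order s_e) with every vertex
at 9.5 nA·m, driven by a unit-peak spike time course built from three
Gamma-density kernels (sharp biphasic peak, < 100 ms FWHM, followed by a
slow wave; onset at 250 ms of a 700 ms record sampled at 600 Hz; kernel
parameters configurable).  The background bank holds 128 independent
trials of spatially correlated (Gaussian kernel over sensor positions,
60 mm length scale), temporally autocorrelated (AR(1), coefficient 0.95)
activity with a spatially white instrument-noise floor at 10% of the
variance, band-passed 0.3-70 Hz.  Each dataset averages 20 randomly chosen
trials (n_avg = 1 gives the single-spike condition) and adds them to the
noiseless projection.

**0 dB calibration.**  The bank is globally scaled once so that the peak
sensor amplitude of a superficial ~6 cm^2 reference patch (grown at the
highest-eccentricity seed) equals the *single-trial* background standard
deviation.  Averaging 20 trials then improves the effective ratio by about
sqrt(20) for that reference, and deep or unfavorably oriented sources
realize proportionally less — matching the intended regime in which the
single-spike condition is strictly harder than the averaged one.  A flag
(`against_average`) calibrates against the averaged background instead.

## Validation metrics

All metrics are evaluated at the spike peak on the normalized energy map
`E_i = J_i^2 / max_j J_j^2`.

* **Balanced AUC**: actives = source vertices (n_a).  AUC_close samples
  n_a fictive inactives from the inactive vertices within 2 neighborhood
  orders beyond the source; AUC_far samples them from the discrete local
  maxima of E at geodesic distance > 30 mm (padded with other far vertices
  when maxima are scarce).  Each variant averages the midrank
  (Mann-Whitney) AUC over 50 seeded draws; the final index is the mean of
  the two, and 0.8 is read as the good-accuracy threshold.  The pool
  widths, distance cutoff and draw count are package defaults, seeded and
  configurable.
* **MSE**: `||J_hat - J_theo||^2 / ||J_theo||^2` over the whole cortex
  (1 for an all-zero estimate).
* **Dmin**: geodesic distance from the global |J| maximum to the nearest
  source vertex; a wrong-hemisphere maximum yields an infinite sentinel,
  replaced by the batch's largest finite value only at aggregation.
* **Otsu mask**: display threshold maximizing between-class variance on a
  256-bin histogram of E.

## Pipeline choices

All solvers run on noise-prewhitened data: the whitener is the inverse
Cholesky factor of the shrinkage-regularized (10% toward the scaled
identity) baseline covariance, estimated from the pre-onset samples.
Whitening makes the white-sensor-noise assumption of both frameworks hold
by construction and is standard MEG practice.  The analysis window is 21
samples centered on the spike peak; ReML fits the window covariance, MEM
solves the peak sample (metrics are read only at the peak).  The MEM MNE
initialization uses snr_param = 3.

## Benchmark scale and runtime

The packaged benchmark uses ~2000 vertices (1000 per hemisphere), 100
sensors, 20 source configurations per extent order (2-6) and clustering
scale 5 (plus scales 3-6 at extent 4 for the scale-sensitivity checks).
These sizes keep a full benchmark run within a few minutes on one CPU while
preserving the source-to-sensor ratio of the full-scale problem.  The
factorial driver reproduces the full-scale design bookkeeping (4 scales x
5 extents x 100 configurations x 5 methods = 10,000 rows) in dry-run mode.

## What the synthetic benchmark does and does not show

The generator emulates: band-limited, spatially correlated, temporally
autocorrelated background with an instrument floor; extended sources of
controlled geodesic extent and depth; trial averaging; the 0 dB amplitude
regime.  It does not emulate: real cortical folding geometry (gyral
crowns/sulcal banks are statistical, not anatomical), realistic BEM volume
conduction (a sphere is used), gradiometer geometry, artifacts, or
non-stationary background (e.g. alpha bursts).  Passing benchmark
thresholds therefore demonstrates correct and well-behaved implementations
under controlled realistic-order conditions, not clinical performance; the
relative ordering of methods is the robust quantity, and absolute AUC
levels shift with sensor count and noise rank.

## Known limitations

* MEM activation probabilities come from a reconstructed stAPM
  (median-aggregated MSP scores); the original aggregation rule is not
  public, and alternatives (mean, max) are provided.
* ReML with many near-collinear components (COH-s at fine scales) relies
  on the ARD prior for selection; degenerate combinations are resolved by
  the prior, not the likelihood.
* The spherical forward model makes purely radial sources invisible;
  benchmark difficulty therefore depends on the synthetic orientation
  field, which is a modeling choice (documented above), not data.
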