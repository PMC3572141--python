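# megloc

Distributed MEG source localization of **spatially extended** cortical
generators, with an end-to-end simulation and validation workbench.

Clinical MEG localizes the generators of inter-ictal epileptic spikes on a
cortical surface model carrying thousands of normal-oriented current
dipoles.  The measurement model is linear,

    M = G J + E,

with `M` the q x tau sensor data, `G` the lead field and `J` the unknown
dipole amplitudes (p >> q, so priors decide everything).  Epileptogenic
generators are spatially *extended* (several cm^2), and most standard
inverse solutions either blur them or shrink them to points.  `megloc`
implements and compares two regularization families over identical
spatial models — a data-driven cortical parcellization P(s) and a
graph-Laplacian diffusion kernel `W = sum_{i<=8} (rho L)^i / i!`:

| method | framework | spatial prior |
|---|---|---|
| `IID`    | hierarchical Bayes + ReML | independent sources (minimum norm) |
| `COH`    | hierarchical Bayes + ReML | identity + global smoothness W |
| `COH-s`  | hierarchical Bayes + ReML | identity + W + one component per parcel |
| `MEM-s`  | maximum entropy on the mean | per-parcel activation mixture, identity parcel covariance |
| `CMEM-s` | maximum entropy on the mean | per-parcel activation mixture, smooth parcel covariance W_k |

In the MEM framework each parcel k is silent or active with probability
`alpha_k(t)` (from the MSP-based activation map), and the solution
maximizes entropy relative to that reference measure subject to
explaining the data in the mean — a concave dual problem in R^q solved
per time sample.  In the hierarchical Bayesian framework the source
covariance is a positively weighted sum of components whose weights are
estimated by ReML (Fisher scoring, ARD-like shrinkage prior).

Because real patient anatomy and recordings cannot ship with the code,
the package includes a synthetic two-hemisphere folded cortex, an
analytic spherical-conductor (Sarvas) lead field, a realistic
extended-source spike simulator (three-Gamma waveform, 9.5 nA·m per
dipole, 128-trial background bank calibrated to 0 dB, 20-trial
averaging) and an ROC-based evaluation workbench (balanced close/far
AUC, relative MSE, geodesic Dmin, Otsu display masks).

## Worked example

```python
from megloc import Workbench
from megloc.evaluate import energy_normalize, balanced_auc

wb = Workbench.synthetic(n_vertices_per_hemisphere=1000,
                         n_sensors=100, master_seed=42)
ds = wb.dataset(extent=3, config=5)      # ~10 cm^2 source, 20-trial average
print(f"source: seed {ds.source.seed}, {ds.source.area_cm2:.1f} cm^2, "
      f"eccentricity {ds.source.eccentricity_mm:.0f} mm, "
      f"realized SNR {ds.realized_snr:.1f}")

J_mem = wb.localize(ds, "MEM-s", scale=5)   # current map at the spike peak
J_iid = wb.localize(ds, "IID", scale=5)
for name, J in [("MEM-s", J_mem), ("IID", J_iid)]:
    auc, close, far = balanced_auc(energy_normalize(J), ds.source,
                                   wb.surface, wb.adjacency, rng_seed=0)
    print(f"{name}: balanced AUC {auc:.2f} (close {close:.2f}, far {far:.2f})")
```

prints

```
source: seed 1078, 12.2 cm^2, eccentricity 71 mm, realized SNR 13.2
MEM-s: balanced AUC 0.94 (close 0.89, far 1.00)
IID: balanced AUC 0.94 (close 0.93, far 0.96)
```

i.e. for this strongly coupled superficial source both methods detect the
generator, with the MEM map also suppressing all far spurious maxima
(`far 1.00`); on deeper or smaller sources the methods separate, which is
what the factorial benchmark quantifies.  The model-object API mirrors
the usual fit/results pattern: `MEMModel(...).fit()` and
`HBModel(...).fit()` return results objects with `.J`, diagnostics and a
`summary()` table.

## Command line

```sh
megloc synth-anatomy --n-vertices 1000 --seed 0 --out cortex.ply
megloc leadfield --surface cortex.ply --n-sensors 100 --out G.tsv
megloc simulate --extent 3 --config 0 --seed 0 --out ds.npz
megloc localize --method cmem-s --scale 5 --extent 3 --config 0 --seed 0 --out J.tsv
megloc evaluate --method mem-s --extent 3 --config 0 --seed 0
megloc grid --dry-run --out design.csv     # enumerate the factorial design
```

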