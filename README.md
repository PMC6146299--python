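# cohdics

Mapping oscillatory power and all-to-all cortico-cortical coherence from
epoched, multichannel oscillatory recordings (MEG-like data) with the
DICS beamformer — from cross-spectral density estimation to group-level
cluster-permutation statistics — exercised end-to-end on synthetic data
from an analytic spherical-conductor forward model.

## Who this is for

Researchers studying functional connectivity through oscillatory
synchrony: two brain regions are taken to interact when their band-
limited activity is coherent.  Dynamic Imaging of Coherent Sources
(DICS) estimates both the cortical origin of oscillatory power and the
coherence between any two source locations directly from sensor-level
cross-spectral density (CSD) matrices, with no need to reconstruct
source time series.  This package implements that pipeline on synthetic
data with known ground truth, so every stage — from wavelet CSDs to the
family-wise-corrected group test — can be validated quantitatively.

## The method

**CSD estimation.**  Signals are convolved with complex Morlet wavelets
m(f) whose temporal width is σ_t = n_o/(2πf) for a fixed number of
oscillations n_o (default 7).  The CSD between sensors i and j is the
time- and epoch-averaged product e_i(f,t)·e_j(f,t)*, giving a Hermitian
N_s×N_s matrix **C** per frequency; band CSDs average over frequencies.

**DICS power mapping.**  With diagonal loading λ = α·trace(**C**)/N_s
(α = 0.05 by default) and norm-normalized leadfields L̂(r), the filter
for each dipole is

    A(r) = L̂(r)ᵀ Ĉ⁻¹ / (L̂(r)ᵀ Ĉ⁻¹ L̂(r)),

and source power is P(r) = A **C** Aᴴ, summarized by its largest
singular value (max-power orientation) or trace.

**Canonical coherence.**  Each source is a two-dipole tangential
equivalent current dipole; the leadfield at in-plane angle θ is
L̂(r,θ) = sin θ·L̂(r₁) + cos θ·L̂(r₂).  Coherence between two source
points is maximized over a 50×50 grid of orientation angles:

    M(r₁,r₂) = max_{θ₁,θ₂} |L̂(r₁,θ₁)ᵀ Ĉ⁻¹ L̂(r₂,θ₂)|² /
               ([L̂(r₁,θ₁)ᵀ Ĉ⁻¹ L̂(r₁,θ₁)][L̂(r₂,θ₂)ᵀ Ĉ⁻¹ L̂(r₂,θ₂)])

evaluated for every source pair farther apart than 4 cm (field spread
makes nearby pairs trivially coherent).

**Group statistics.**  Per connection, a paired t statistic compares
coherence between two power-matched conditions across subjects.
Connections with |t| below a threshold (default 5) are pruned; the
survivors are clustered into *bundles* in the 6-D space of their
endpoint coordinates (cutoff 1 cm, separately for positive and negative
t), each bundle scoring the sum of its |t| values.  A max-statistic
permutation test (default 1000 label flips) yields family-wise-
corrected bundle p-values.  Significant connections are summarized as
vertex degree maps and parcel-level connectome tables.

## Worked example

```python
import numpy as np
import cohdics as cd

# Geometry: 96 radial sensors at 0.10 m around a 0.07 m source shell
sensors = cd.make_spherical_sensor_array(96, 0.10, 0.85)
src = cd.make_spherical_source_grid(100, 0.07)
fwd = cd.forward_to_tangential(cd.compute_forward(src, sensors))

# Two sources, 10.7 cm apart, coherence c^2 = 0.64, SNR 2
cfg = cd.SimulationConfig(active_sources=((2, 0.3), (50, 1.0)),
                          coupling=0.8, n_epochs=200, seed=0)
epochs, truth = cd.simulate_epochs(fwd, cfg)

# Alpha-band CSD and all-to-all canonical coherence
csds = cd.csd_morlet(epochs, [9, 10, 11], tmin=0, tmax=0.4)
band = cd.csd_band_mean(csds, 7, 13)
pairs = cd.all_to_all_connectivity_pairs(src, min_dist=0.04)
con = cd.dics_connectivity(pairs, fwd, band, reg=0.05, n_angles=50)

k = np.nonzero((pairs.pairs[:, 0] == 2) & (pairs.pairs[:, 1] == 50))[0][0]
rank = (con.coherence > con.coherence[k]).sum()
print(f"{pairs.n_pairs} pairs; true-pair coherence "
      f"{con.coherence[k]:.3f}, rank {rank}")
```

Output:

```
4577 pairs; true-pair coherence 0.519, rank 29
```

The estimated canonical coherence at the true pair (0.519 — the
simulated c² = 0.64 attenuated by sensor noise) ranks 29th of all 4577
distance-valid pairs, i.e. within the top 1%; the pairs ranking above
it bridge the immediate neighbourhoods of the two true sources.

The same study runs end to end from a JSON config via the CLI:

```bash
cohdics validate --config config.json
cohdics run --config config.json --out results/ --seed 1
```

which writes HDF5/CSV artifacts per stage and a manifest with content
hashes (reruns with the same config are bit-identical).

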