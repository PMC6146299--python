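# Methods

This note documents the models, parameters and design choices behind
`cohdics`: a frequency-domain beamforming pipeline that maps
oscillatory power and all-to-all cortico-cortical coherence and tests
condition differences with a bundle-based cluster-permutation
statistic, all exercised on synthetic data with known ground truth.

## Forward model

Neural currents are modelled as equivalent current dipoles (ECDs)
inside a homogeneous conducting sphere.  The magnetic field outside
such a conductor has a closed-form solution (the Sarvas formula); the
package evaluates it exactly, projected onto each sensor's sensing
direction.  Sensors are radial magnetometer-like point sensors placed
quasi-uniformly (Fibonacci lattice) on a spherical cap.

Two physical facts shape the pipeline and are asserted as invariants:
radial dipoles are externally silent, and therefore a free-orientation
(x/y/z) forward model can be reduced to two orthonormal dipoles
tangential to the sphere without losing measurable signal.  The
tangential basis is deterministic: e₁ = normalize(ẑ × r̂) (with x̂ × r̂
as the fallback on the polar axis), e₂ = r̂ × e₁.

**Standard geometry.**  96 sensors on a shell of radius 0.10 m covering
85% of the sphere, sources on a 0.07 m shell, SI units throughout.
The 3 cm standoff and near-complete coverage were chosen so that the
beamformer's point spread is narrower than the 4 cm pair-distance
threshold used in connectivity analysis.  This matters: with a 5 cm
standoff and an upper-cap-only array (a geometry we evaluated first),
sources near the rim of sensor coverage have nearly collinear
leadfields, and pairs of such sources show spurious canonical coherence
approaching 1 regardless of the data — an extreme form of field spread
that no analysis step downstream can undo.  A close-fitting,
well-covering array is the synthetic analogue of a whole-head system
with good scalp coverage.  One consequence is that the sensor-distance
source restriction (≤ 7 cm to the nearest sensor, kept at the
boundary), which discards poorly measured deep sources in helmet
geometries, retains nearly the whole synthetic grid here; the operation
is validated against brute force on random geometries instead.

## Synthetic data

Each active source is a unit-variance Gaussian process band-limited to
the carrier band (default 8–12 Hz) by a zero-phase 4th-order
Butterworth filter, fresh per epoch.  Coupling between sources is
imposed by mixing, with the coupled component taken in *quadrature*
(Hilbert transform of the driver):

    s₂ = c·quadrature(s₁) + √(1−c²)·independent,

renormalized to unit variance per epoch.  The expected band
magnitude-squared coherence is c².  The quadrature construction is
deliberate: mixing in phase would add an interference term
2c·(g₁·g₂)·var(s₁) to the sensor power, so conditions with different c
would differ in power and a coherence contrast would be confounded by a
power contrast.  With quadrature mixing the conditions are
power-matched by construction, which is the regime the group contrast
is designed for (and is asserted to hold within Monte-Carlo tolerance).

Sensor noise is white and Gaussian; `snr` is the ratio of the RMS
signal field to the RMS noise per sensor, averaged over sensors
(default 2).  With no active sources an absolute `noise_sigma` applies.
Subjects get independent signal/noise realizations from substreams of
one master seed, plus a small per-subject jitter of source orientation
(default 0.1 rad) shared between conditions.

What the generator does **not** emulate: 1/f background spectra,
artifacts, evoked transients, head-position differences, or
subject-specific anatomy.  Passing tests therefore demonstrate the
pipeline's correctness and calibration under its own assumptions, not
robustness to real-data violations of them.

## CSD estimation

Morlet wavelets with σ_t = n_o/(2πf), sampled on t ∈ [−5σ_t, 5σ_t] at
1/fs (odd length by construction), with the (σ_t π)^(−1/2) prefactor.
Default n_o = 7; the named bands are theta 3–7, alpha 7–13, low beta
13–17, high beta 17–25 and 25–31, low gamma 31–40 Hz, with wavelet
centre frequencies spaced 1 Hz across each band.  Epochs are demeaned
per sensor before convolution (the wavelet method assumes a zero-mean
signal).  The CSD entry is the mean of e_i·conj(e_j) over the analysis
window's time points — selected as tmin-anchored indices with stride
`decim` (default 20; after wavelet smoothing the full sampling rate is
redundant) — then averaged over epochs.  Per-frequency matrices are
stored individually; band averaging is a separate unweighted mean,
which equals the one-pass 1/(N_f·N_t) normalization because every
frequency uses the same time grid.  A window closer than 5σ_t to an
epoch edge triggers an edge-effect warning rather than an error.

## Beamforming

Diagonal loading λ = α·trace(Re C)/N_s with α = 0.05 by default
(typical useful range 0.01–0.1); inversion by Moore–Penrose
pseudoinverse, so α = 0 on a rank-deficient CSD degrades gracefully
(with a warning).  Leadfields are norm-normalized before filtering to
counter the depth bias.  Filters are computed per dipole — the
denominator L̂ᵀĈ⁻¹L̂ is then a scalar — never jointly per source,
avoiding the inversion of a rank-deficient source-level matrix.  Power
maps use the full (unrestricted) source space and the free-orientation
model; the max-power summary (largest singular value of P) is the
default, trace is available.  A "surface-normal" summary is not
implemented: the spherical synthetic cortex has no meaningful surface
normal distinct from the radial direction, which the tangential model
excludes by design.

## Canonical coherence

For each distance-valid pair the coherence ratio is maximized over a
50×50 grid of in-plane angles in [0, π) (the objective is π-periodic;
this is asserted).  Pairs at exactly the distance threshold are
excluded (strictly-greater rule).  Ties in the grid maximum resolve to
the lexicographically smallest angle pair.  Numerics: the ratio is
evaluated through per-source 2×2 quadratic forms of Ĉ⁻¹, vectorized
over pairs in memory-bounded chunks; the result is clipped to [0, 1]
against rounding.  Separate filters (separate regularized inverses) are
computed per condition, so orientation optimization adapts to each
condition rather than being biased toward the higher-SNR one.

Two properties are worth stating plainly.  First, the 50-point grid
resolves the coherence peak to within 10⁻³ of a dense 720×720 scan for
physically realizable problems (leadfields from the forward model, CSDs
from data); adversarially ill-conditioned random quadratic forms can
show a slightly coarser gap, which is a property of peak curvature, not
of the search.  Second, *raw* canonical coherence necessarily decays
with pair distance (leadfield overlap — field spread), so distance
independence cannot hold for raw values in any beamformer geometry;
under the null it holds for the condition **contrast**, which is the
quantity the group statistics consume.  This is exactly why the
pipeline tests condition differences between power-matched conditions
rather than absolute coherence.

## Group statistics

Paired t per connection (n−1 denominator); zero-variance differences
yield ±∞ sentinels (0 when the difference is identically zero), which
survive thresholding and contribute a capped |t| (10× the threshold) to
bundle sums.  Connections with |t| ≥ `cluster_threshold` (default 5)
survive.  Bundles are connected components of the graph linking
survivors whose 6-D endpoint-coordinate distance is ≤ `max_spread`
(default 1 cm) — single-linkage clustering cut at `max_spread`,
verified against brute force — computed separately for positive and
negative t.  The 6-D distance is flip-aware (minimum over the
endpoint-swapped ordering), since a connection and its reversal are the
same physical link.  The permutation null flips each subject's
condition labels independently with probability ½, re-runs the whole
prune-and-cluster pipeline (the standard max-statistic construction),
and records the maximum bundle statistic, 0 when nothing survives.
Bundle p-values use the add-one convention
p = (1 + #{null ≥ bundle_t})/(1 + n_permutations), compared as
p ≤ α (defaults: 1000 permutations, α = 0.05).

## Summaries

Degree maps count surviving connections per vertex; parcel connectomes
count them per parcel pair, within-parcel connections on the diagonal
counted once so that the unordered-pair total is conserved.  Degree-
bias correction divides by the corresponding counts in the
*pre-statistics* candidate pair list (the distance-thresholded set —
connections that could have survived), giving fractions in [0, 1];
0/0 is defined as 0.  The synthetic parcellation is a fixed-seed
k-means partition of the source coordinates.  The connectogram export
is a long-format CSV of the upper triangle including the diagonal;
circular-plot rendering is intentionally out of scope — the matrix is
the tested artifact.

## Pipeline and problem sizes

The `cohdics` CLI drives the stages from a JSON config; artifacts are
HDF5 (arrays) and CSV (tables), datasets written without timestamps so
identical content yields identical bytes, and a manifest records every
artifact's SHA-256.  Raw epochs are not persisted by default (they
dominate storage); the simulate and CSD steps run streamed per subject,
while `save_epochs`/`load_epochs` expose epoch serialization for
single-recording work.

Validation studies use deliberately desk-scale problem sizes: power
localization on a 500-vertex grid (10 seeds, SNR 2, 100 epochs);
coupled-pair recovery on a 100-vertex grid (~4.6k pairs, c = 0.8, 200
epochs); type-I calibration with 12 subjects, 40 vertices, 12 epochs,
200 permutations and 100 replicate datasets; detection power with 16
subjects, 60 vertices, 30 epochs and coupling 0.7 vs 0.2.  These sizes
keep the full suite at minutes on one CPU while leaving each effect
comfortably measurable.

## Known limitations

- The single-sphere analytic forward model has no skull/scalp layers,
  no gradiometers, and perfectly known geometry; co-registration and
  forward-model error, a major practical concern, are absent.
- Canonical coherence estimates are upward-biased by the orientation
  search (a maximum over ~2500 grid points); the bias is common to both
  conditions and cancels in the contrast, but absolute values should be
  read with that in mind.
- The permutation test's validity rests on exchangeability of condition
  labels within subject; designs with condition-dependent noise levels
  violate it.
- Coupling is specified between consecutive active sources only; richer
  coupling graphs (e.g., one driver with several followers at distinct
  coherences) need the generator to be extended.
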