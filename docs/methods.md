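# Methods

`morphocell` quantifies the three-dimensional morphodynamics of migrating
amoeboid cells (its defaults are tuned to effector T cells crawling through
collagen) from time series of closed triangulated surface meshes with a
manually placed uropod landmark. This note records the models, the numerical
choices, and what the synthetic validation does and does not establish.

## Shape representation

**Spherical-harmonic expansion.** Each genus-0 surface is mapped bijectively
to the unit sphere and the three Cartesian coordinate functions
x(θ,φ), y(θ,φ), z(θ,φ) are fitted in orthonormal complex spherical harmonics
Y_l^m (Condon–Shortley phase) up to `l_max = 15`. Only m ≥ 0 coefficients are
stored; the negative orders of a real-valued function are fixed by conjugate
symmetry, and their power is accounted for by double-counting the m > 0
terms. The fit is weighted least squares with per-vertex spherical
barycentric-area weights, approximating the continuous L² projection rather
than a vertex-density-biased one. With 642-vertex meshes and 256 basis
functions the discrete basis is mildly non-orthogonal: descriptors and full
reconstructions are unaffected, but partial sums (truncations of the joint
fit) are only near-projections, and reconstruction error is guaranteed
monotone in the truncation degree only on finer meshes (2562 vertices).

**Spherical parameterization.** The initial map is the radial (Gauss)
projection taken in *anisotropy-whitened* coordinates: vertices are
transformed by the inverse of a 3×3 normalization A before projection, and A
is iterated to self-consistency with the degree-1 linear map of the fitted
surface. The fixed point sends an exact ellipsoid to the parameterization in
which it is purely degree-1, so the l = 1 reconstruction of a 2:1 ellipsoid
recovers its semi-axes to ~1–2%. Residual area distortion is then relaxed by
a surplus-weighted tangential Laplacian flow with monotone accept/reject on
the mesh-area-weighted RMS log distortion, but only until the per-face
(mesh area)/(sphere area) spread falls to a ceiling (default 2.5). We
deliberately do **not** equalize area fully: constructing the exact
equal-area map of the (2,1,1) spheroid analytically shows that full
equalization intrinsically transfers elongation out of degree 1 (l = 1
semi-axes come out as 1.035, 1.035, 1.846), i.e. the more faithful spectral
representation and the equal-area property are in tension, and we favour
spectral fidelity. The whole construction uses only geometric quantities, so
it is exactly equivariant under rigid rotation, uniform scaling, and vertex
reindexing; measured descriptor changes under random rigid transforms are at
the 1e-15 level.

**Invariant descriptor.** The shape vector is {D_0 … D_15} with

    D_l = sqrt( Σ_{i∈{x,y,z}} [ |c_{l,i}^0|² + 2 Σ_{m>0} |c_{l,i}^m|² ] ),  l ≥ 1,

coefficients divided by V^{1/3} (volume from the signed-tetrahedron sum) for
scale invariance and l = 0 dropped for translation invariance. The square
root linearizes the descriptor in feature amplitude; without it essentially
all variance sits in the ellipsoid degree. Rotations act within each degree
and mix the three coordinate channels unitarily, so each D_l is exactly
invariant. The polarization term is

    D_0 = (√3/2) · ‖uropod − centroid‖ / V^{1/3},

restoring the front–rear information a rotational invariant discards; the
prefactor combines the three coordinate channels summed in quadrature (√3)
with the factor ½ from coefficients spanning twice their magnitude, and is
exposed as `d0_factor` since the convention is not universal.

**Ellipsoid axis.** The l = 1 coefficients define a linear map n ↦ M n of
the unit sphere; the major axis is the leading right-singular vector of M,
with the sign chosen to point away from the uropod. Shapes whose top two
singular values agree within 2% are flagged degenerate (a sphere has no
axis).

## Uropod uncertainty and τ_sig

The uropod is a diffuse region. Its label uncertainty is the chord of a 20°
arc on the local rear radius R = 1/H, where H is the cotangent-Laplacian
mean curvature averaged over the 15 mesh vertices nearest the label
(non-convex rears fall back to the uropod–centroid distance as R; an option
`chord_center='centroid'` uses that radius unconditionally, since "a 20°
rotational perturbation" can be read about either center). All vertices
within one chord of the label are alternative labels; the standard deviation
of their recomputed D_0 values is σ(D_0), and the uncertainty of PC k is
σ(D_0)·|loading_k[D_0]| — the cosine between the D_0 axis and the PC. This
is evaluated every 10 frames and averaged into one characteristic value per
dataset. Because cell rears lie roughly perpendicular to the uropod–centroid
axis, σ(D_0) is much smaller than the chord itself suggests.

τ_sig is the mean over start frames of the first time the uropod's
displacement from its start position exceeds twice the chord, capped at
100 s; datasets hitting the cap are flagged near-stationary and excluded
from quantitative speed analyses. Displacement is measured from the start
position (not path length): path length would accumulate label jitter and
make a stationary uropod look mobile.

## Kinematics and run/stop modes

Uropod and centroid positions are smoothed with centered running means of
width τ_sig (centered, with shrinking edge windows, to avoid phase lag in
downstream autocorrelations), differenced, and divided by dt·V^{1/3},
giving velocities in s⁻¹ (cell lengths per second). The scalar motion
variable is the uropod velocity projected on the unit vector from uropod to
centroid (positive = advancing). Mode labels come from the 150 s running
mean: run above 0.005 s⁻¹, stop below 0.0025 s⁻¹, transition between.
Bimodality across running-mean windows is quantified with Hartigan's dip
test; the statistic is computed by bisection on the minimax distance to a
convex-then-concave CDF (verified against a linear-programming oracle at
small n) with Monte-Carlo p-values from uniform null samples. Classifier
accuracy is scored on decisively labeled (run/stop) frames; frames inside a
blend window around a mode switch are labeled transition by construction
and carry no decision.

For axis-alignment diagnostics, positions are smoothed over 100 s and
frames are kept when the uropod moves faster than 0.0025 s⁻¹ (more than a
quarter cell length in 100 s) and the uropod and centroid velocities differ
by less than half the uropod speed.

## Time-series statistics

Series are detrended with an order-2 zero-phase Butterworth high-pass at
0.0025 Hz. The autocorrelation decay time τ_ACF is an exponential fitted to
the ACF's local maxima (prominence ≥ 0.05), which recovers the envelope of
oscillating ACFs; the fit stops at the first peak below 0.3 because beyond
that the sample ACF of a finite series is dominated by its noise floor
(correlated positive excursions of size ~√(τ/T) that bias the decay upward).
Series whose lag-1 autocorrelation sits inside the white-noise band are
flagged memoryless. Non-oscillatory series (fewer than two peaks) fall back
to a full-ACF fit. Spectra are Hann-windowed Welch periodograms whose
integral matches the series variance to a few per cent. PC channels enter
these analyses only when sd(signal)/σ_PC ≥ 2.5, and speed channels only from
datasets not flagged near-stationary.

A caution established during validation: estimating a 225 s decay time from
a single record is information-limited to a relative error of roughly
√(τ/T). At T ≈ 45·τ no estimator variant we tried (peak fits, restricted
peak fits, full damped-cosine fits) achieves 10% median error; the recovery
fixtures therefore use records of T ≈ 133·τ (n = 6000 at dt = 5 s), where
the measured median error is 4–8% across seed sets. Real datasets of a few
hundred frames support only coarse per-cell τ_ACF estimates; cross-cell
medians are the meaningful statistic at that scale.

## Behavioral mapping

Each PC series is convolved with two real wavelets — Mexican hat (even) and
first Gaussian derivative (odd); the pair captures symmetric and
antisymmetric local dynamics, and phase is deliberately kept (no complex
wavelets). Six equally spaced frequencies per wavelet run from the period
4·dt (half the Nyquist frequency — the "double the Nyquist limit" reading
that is physically realizable) down to the wavelet-specific frequency whose
*width of influence* reaches 150 s, the organization timescale seen in the
autocorrelations. The width of influence is measured operationally: convolve
the wavelet with a long unit square pulse and find where the edge response
has settled to within 1% of the interior plateau, doubled for both sides.
Kernels are sampled on exactly symmetric grids with L¹ normalization
(ψ(t/s)/s), so time-reversal symmetry is exact and tone responses are
comparable across scales; the library sampling of these kernels at
fractional scales would otherwise break the even/odd symmetry the two-wavelet
design relies on.

Spectrogram columns (channels variance-normalized) are embedded in 2D with
t-SNE (perplexity 30, learning rate 200, 1000 iterations, PCA
initialization, fixed seed). Stereotyped motifs are connected components of
the adaptive binarization of the KDE density on a 101×101 raster (padded
10%): a pixel is kept when its 8-bit value exceeds the mean over a
surrounding square (7 pixels) plus a bias (20; 15/50 for run-mode-only
maps). Adaptive rather than global thresholding separates peaks joined by
high-density "superhighways". Scott's bandwidth rule is calibrated for
unimodal densities and oversmooths these strongly multimodal maps, so the
pipeline default is a fixed KDE factor of 0.12 (exposed as
`kde_bandwidth`; `None` restores Scott). Each time point is assigned to the
nearest motif region, transitions are counted only on label changes (zero
diagonal) and never across dataset boundaries.

Markov-chain entropy over a 20×20 grid of the map, −Σ π_i p_ij log₂ p_ij
with π the stationary distribution (largest strongly connected component if
the chain is reducible), quantifies stereotypy: periodic dynamics trace
closed loops and score low; a deterministic cycle scores exactly 0. The
per-wavelet maximum widths can be perturbed over candidates ≤ 150 s to
minimize this entropy (ties go to the smallest width). Entropy comparisons
are meaningful at fixed sampling: with only a few hundred points most grid
cells are visited once and every channel looks spuriously deterministic, so
the per-channel comparisons here use 2000-point records.

## Synthetic data: what it emulates, and what it does not

`make_cell_sequence` builds star-shaped genus-0 surfaces as radial graphs
over a subdivided icosahedron: an ellipsoid body (default semi-axes 8.0,
3.5, 3.5 μm — an elongated migrating cell with a narrow rear) whose length
oscillates sinusoidally with period 100 s (volume-compensated width), a
front-widening oscillation in quadrature, 2–4 protrusive bumps on the front
hemisphere with Ornstein–Uhlenbeck height dynamics (τ = 30 s), a rear pole
carrying the uropod label with 0.2 μm Gaussian jitter, 0.05 μm vertex
noise, and rigid translation along the body axis. Speeds are scale-invariant
(multiplied by V^{1/3}): a two-state continuous-time Markov chain switches
between run (0.008 s⁻¹) and stop (0.001 s⁻¹) with 300 s mean dwell, and the
run speed is modulated at the shape-oscillation period with
cycle-to-cycle-varying amplitude (dips to near zero), matching the
observation that both modes contain near-zero-speed phases at short
timescales. The default cohort adds cell-to-cell lognormal spread (~25%) in
run speed and (~40%) in stop speed. These heterogeneity and
near-zero-phase properties are not decoration: the emergence of run/stop
bimodality *only* at long running-mean windows is a population statistic,
and with few, homogeneous cells the short-window histogram can already be
bimodal (an unlucky 8-cell cohort occasionally still is).

The generator does not simulate ECM fibres, forces, actin dynamics,
turning, mode-dependent shape (beyond what elongation oscillation
produces), segmentation artifacts, or imaging noise beyond isotropic vertex
jitter. Passing tests therefore establish that the *pipeline* recovers
planted structure of the kinds the study relies on — invariances,
low-dimensionality, timescales, bimodality, stereotypy, periodicity — not
that real cells behave like the generator.

`make_oscillatory_signal` is a phase-diffusion oscillator
(√2·cos(2πt/T + Brownian phase), rate 2/τ): its autocorrelation is exactly
exp(−lag/τ)·cos(2π·lag/T) at O(n) cost, with optional white noise.

`make_shape_population` draws static cells from exactly three independent
latent coordinates (length, width, protrusion height) with shared protrusion
sites and 1% vertex noise, for testing how many principal components the
descriptor population needs.

## Problem sizes and determinism

Validation runs use 642-vertex meshes (2562 for quadrature-sensitive
checks), cohorts of 8 cells × 240 frames at dt = 5 s, 60-cell shape
populations, 20-seed τ-recovery ensembles of n = 6000, five-repeat entropy
comparisons of n = 2000, and three 300-frame run-mode cells for the
periodicity check; one full pass takes a few minutes on one CPU. All
randomness flows from explicit seeds: the same seed regenerates meshes
byte-identically, and pipeline reruns reproduce descriptor tables
bit-identically and embeddings exactly.

## Known limitations

- The parameterization assumes star-shaped surfaces (true of the generator
  and of typical T-cell segmentations); strongly non-star-shaped cells fall
  back to Tutte smoothing to remove inversions and may distort more.
- The absolute scale of D_l for l ≥ 1 depends on the harmonic normalization
  convention; PCA structure is unchanged up to per-degree rescaling, but
  descriptors should not be compared across implementations without
  checking conventions (`double_count_m`, `d0_factor`).
- Mean-curvature-based chords degrade on very coarse meshes (< ~150
  vertices) where the 15-nearest-vertex patch spans a large area.
- The dip test's Monte-Carlo null uses uniform samples; for heavily tied
  data (quantized speeds) p-values would need a tie-aware null.
- t-SNE maps are reproducible only at fixed seed and sample; motif counts
  depend on the KDE bandwidth and binarization parameters, which is why
  those are config, not constants.
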