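# morphocell

Quantitative analysis of three-dimensional cell morphodynamics — the shape
dynamics of migrating amoeboid cells such as effector T cells crawling
through collagen — from time series of closed triangulated surface meshes
with a uropod (cell-rear) landmark.

Modern light-sheet microscopy delivers full 3D cell surfaces every few
seconds, but cells have no joints or limbs: the meaningful degrees of
freedom must be extracted from the surfaces themselves. `morphocell`
implements a complete pipeline for doing that:

1. **Invariant shape descriptor.** Each genus-0 surface is mapped to the
   unit sphere and its coordinate functions expanded in spherical harmonics
   Y_l^m up to l = 15. The per-degree power

   D_l = √( Σ_{i∈{x,y,z}} Σ_m |c_{l,i}^m|² ),  l ≥ 1

   (coefficients scaled by V^{-1/3}, l = 0 dropped) is exactly invariant to
   translation, scale and rotation. Because a rotational invariant is blind
   to front–rear polarization, the vector is augmented with
   D₀ = (√3/2)·‖uropod − centroid‖/V^{1/3}.
2. **Shape space.** PCA over the pooled 16-dimensional descriptors; a few
   components capture most shape variance. Label uncertainty (the uropod is
   a diffuse region, not a point) is quantified from rear curvature as the
   chord of a 20° arc and propagated to each PC.
3. **Scale-invariant kinematics.** Uropod/centroid velocities in units of
   cell lengths per second (s⁻¹); the motion variable is the uropod speed
   along the uropod–centroid axis. Long-window running means separate a fast
   *run* mode (> 0.005 s⁻¹) from a near-stationary *stop* mode
   (< 0.0025 s⁻¹); the emergence of this bimodality with window length is
   tested with Hartigan's dip statistic.
4. **Time-series structure.** Butterworth detrending, autocorrelation decay
   times τ_ACF fitted to ACF peaks (robust to oscillation), Welch spectra,
   and SNR gating against the propagated label uncertainty.
5. **Behavioral map.** Two-wavelet (Mexican hat + Gaussian derivative)
   multiscale spectrograms of the PC series, embedded to 2D with t-SNE;
   stereotyped motifs from KDE density + adaptive binarization; motif
   transition matrices; and grid Markov entropy −Σ πᵢ p_ij log₂ p_ij as a
   stereotypy measure that exposes periodic (loop-like) morphodynamics.

A first-class synthetic-data module generates polarized, oscillating,
run/stop-switching cell-surface sequences with full ground truth, so every
stage is testable without any imaging data. See `docs/methods.md` for the
models, defaults and caveats.

## Worked example

```python
from morphocell import RunConfig, SynthCellParams, make_cell_sequence
from morphocell.pipeline import run_pipeline

cfg = RunConfig(seed=1)
cells = [make_cell_sequence(SynthCellParams(seed=s), n_frames=120, dt=5.0,
                            dataset_id=f"cell{s}") for s in range(3)]
res = run_pipeline(cells, cfg, out_dir="out")

ev = res["shape_space"].explained_variance_ratio
print(f"top-3 shape variance: {ev[:3].sum():.1%}")
print(res["uncertainty_table"][["dataset_id", "chord_um", "tau_sig_s"]])
print(f"motifs: {res['map'].n_motifs}, entropy: {res['map'].entropy:.2f} bits")
```

prints

```
top-3 shape variance: 98.7%
  dataset_id  chord_um  tau_sig_s
0      cell0  0.905287  38.973214
1      cell1  0.911363  39.227273
2      cell2  0.910524  40.130435
motifs: 15, entropy: 1.00 bits
```

Here the three synthetic cells share one dominant shape mode (elongation +
polarization oscillating with a 100 s period), so the top PCs absorb nearly
all variance; the ~0.9 μm chord is the positional uncertainty implied by the
rear's radius of curvature, and τ_sig ≈ 40 s is the time the uropod needs to
move twice that uncertainty — the window used to smooth positions before
differentiating. The stages also write `descriptors.csv`,
`uncertainty.csv`, `kinematics.csv`, `stats.csv` and `map.npz` under
`out/`, plus a manifest recording the config hash and seeds.

## Analysis scripts

`analysis/01…06` run the full study on the default synthetic cohort
(8 heterogeneous cells × 240 frames at 5 s), writing summary tables under
`results/` and bulky intermediates under `scratch/`:

```bash
python analysis/01_simulate_cohort.py      # cohort generation + validation
python analysis/02_shape_space.py          # descriptors + PCA variance
python analysis/03_uropod_uncertainty.py   # chords, sigma(D0), sigma_PC, tau_sig
python analysis/04_kinematics_modes.py     # speeds, run/stop labels, dip tests
python analysis/05_timeseries_stats.py     # tau_ACF + spectra, recovery check
python analysis/06_behavior_map.py         # motifs, transitions, entropies
```

Each takes an optional integer seed argument (default 0).

There is also a small CLI (`morphocell ingest|synth|all`) for working with
OBJ/PLY mesh directories and landmark CSVs from the shell.

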