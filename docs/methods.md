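# Methods

## Model and procedure

`bandloc` treats probe localization as a correspondence problem between two
partitions of the electrode array: an electrophysiological partition
(clusters of electrodes with similar normalized LFP band-power profiles)
and an anatomical partition (atlas labels at the electrodes' stereotactic
positions). The method assumes that (i) distinct brain structures express
distinct stationary distributions of power across the canonical LFP bands,
(ii) the probe insertion is coronal (all electrodes share one AP slice),
and (iii) the user's stereotactic estimate is within a few hundred
micrometers of the true implant site, so a local exhaustive search over
placement offsets can recover the residual targeting error.

The processing chain is: zero-phase band-pass to 1–300 Hz → polyphase
resampling to 1,250 Hz → (optional) common average reference → Welch PSD
per electrode → band integration and normalization → per-shank local
outlier exclusion → per-shank spatial smoothing → z-scoring and PCA →
silhouette-selected hierarchical clustering → atlas placement, modal
cluster-region assignment, and exhaustive offset search.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| LFP band | 1–300 | Hz | passband of interest; also the band-power normalizer |
| common rate | 1,250 | Hz | shared rate across probe technologies; 4× the upper band edge |
| Welch window | 8,192 samples (≈6 s) | — | power of two closest to 6 s; trades low-frequency resolution against convergence speed |
| Welch overlap / taper | 50% / Hann | — | standard Welch averaging |
| band edges | δ 1–4, θ 4–8, α 8–12, β 12–30, γ 30–100, ripple 100–250 | Hz | canonical bands plus the ripple band |
| outlier window | 20 electrodes | — | ≈300 μm of shank on a two-column 30 μm-pitch layout: enough context for stable window statistics |
| z threshold | 2.5 (strict inequality) | — | ≈1% tail of a normal distribution; conservative so genuine anatomical contrast is not removed |
| smoothing window | 8 electrodes (centered, truncated at ends) | — | ≈120 μm effective vertical length |
| PCA retention | ≥95% cumulative explained variance | — | adapts dimensionality per dataset; ≤6 components |
| cluster range | k ∈ [3, 12], silhouette argmax, ties → smaller k | — | captures meaningful subdivisions without over-segmentation |
| search extent | ±8 coronal slices, ±600 μm ML/DV | — | matches the expected scale of stereotactic targeting error |
| search step | atlas voxel size (50 μm toy, 20 μm typical real atlas) | μm | finest meaningful granularity |
| CAR | disabled | — | removes shared physiological components and tends to split otherwise coherent clusters; enable only when common-mode contamination is suspected |

All scalars live in a single `PipelineConfig`; the CLI reads the same
fields from a JSON config file with flag overrides.

## Coordinate and atlas conventions

Volumes are stored (AP, DV, ML) with isotropic voxels. Bregma anchors at
atlas AP 5.4 mm from the volume front, DV index 0 (brain surface) and the
declared midsagittal ML index. Positive AP is anterior, positive ML is the
left hemisphere, deeper positions have more negative DV. The probe tip
(shank 0, z = 0) is aligned to the requested ML/DV; `z_um` increases from
tip to base, so electrodes above the tip map to shallower voxels. Label 0
always means "outside brain"; electrodes shifted past the volume edge read
label 0, so they can still match a cluster whose assigned region is
outside-brain (as happens when a probe's upper rows protrude from cortex).
Real atlas annotations are adapted by saving the label volume plus
metadata through the package's NPZ + JSON contract; `merge_labels`
consolidates over-fine parcellations (e.g. all cortical subareas into one
label) before matching.

During refinement the cluster→region modes are assigned once at the
initial placement and held fixed while the probe is shifted
(`reassign_modes=True` recomputes them at every candidate instead). Ties
in the match count resolve to the smallest offset norm, then the smallest
AP offset, so a refinement started at the optimum returns the zero offset.

## Synthetic data

The generator gives each atlas region a target profile of normalized band
powers (eight built-in templates, each dominated by a different band or
band pair; pairwise L1 separation ≥ 0.4 in the high-separation setting)
and synthesizes every electrode as a sum of independent band-limited noise
processes whose variances realize its region's profile, plus a broadband
1–300 Hz floor (5%), optional per-electrode white noise (2% variance), and
an optional common-mode component shared across channels. Electrodes
outside brain tissue receive the same construction scaled to 10⁻⁴ of the
in-tissue power. Band-limited noise is synthesized by brick-wall spectral
masking of white noise rather than IIR filtering: a 4th-order band-pass
leaks several percent of each component's power into neighboring bands,
which would bias the realized band fractions away from the targets; with
masking the measured normalized band powers match the profiles to within
0.05 per band at 30–60 s durations.

The toy atlas stacks named layers along DV inside a rectangular brain with
an outside margin. Optionally each internal boundary (and the bottom of
the deepest layer) carries AP and ML slopes (μm/mm), because a perfectly
plane-layered volume makes lateral placement offsets unobservable: moving
the probe within a laterally uniform slab changes no labels. The recovery
fixtures use three crossed boundaries with linearly independent
(AP-slope, ML-slope) orientations — including a steep ML "staircase"
boundary that crosses the four shanks at very different depths — plus a
block of above-surface electrodes whose outside-brain cluster pins the DV
axis. Slopes were chosen to maximize the worst-case visibility (total
boundary-depth residual beyond the 25 μm voxel-quantization blind zone) of
small offset vectors outside the acceptance tolerance.

What the generator does **not** emulate: volume conduction and spatial
correlation between electrodes, gradual (rather than stepwise) spectral
transitions across boundaries unless a blend is configured, state-dependent
nonstationarity of awake recordings, line noise, and electrode-impedance
heterogeneity. Passing tests therefore demonstrate the correctness of the
pipeline's decision rules and the identifiability of placement under clean
region-structured signals, not performance on real tissue.

## Numerical choices

- Filtering: 4th-order Butterworth band-pass applied forward–backward
  (`sosfiltfilt`) for zero phase; resampling by polyphase FIR with the
  rational factor closest to the requested rate.
- Band integration: exact integral of the piecewise-linear interpolant of
  the PSD between band edges (edge bins are interpolated, not snapped), so
  a flat spectrum yields band fractions exactly proportional to bandwidth
  (δ = 3/299 of the 1–300 Hz normalizer).
- Outlier windows tile the shank ("adjacent", non-overlapping); the last
  tile absorbs the remainder. Window statistics use the sample (n−1)
  denominator; zero-variance windows flag nothing; dead (zero-power)
  channels are excluded before z-scoring. An electrode flagged in any band
  is excluded from all bands, since the clustered feature vector must be
  complete.
- Smoothing covers positions i−4 … i+3 of the depth order, truncated at
  shank ends; excluded electrodes contribute nothing and receive the
  window mean of retained members for map display (their exclusion mask is
  preserved and they never enter clustering).
- The silhouette sweep updates the winner only on a strict improvement, so
  ties go to the smaller k. k-means uses 10 restarts from a fixed seed;
  HDBSCAN uses `min_cluster_size = max(5, 2% of electrodes)`.
- The convergence plateau is the mean of the final six time points plus
  three times their standard deviation (ddof = 1); prefix durations must
  cover at least one Welch window, so the default schedule starts at the
  first step multiple ≥ 6.6 s rather than at 5 s.
- Degenerate inputs raise: recordings shorter than one Welch window,
  all-identical feature vectors (silhouette undefined), reference maps
  with zero pixel variance (convergence normalizer), shanks with no
  retained electrodes (interpolation).

## Problem sizes used by the test suite

Unit and property tests run on a 64-electrode single-shank fixture with a
flat three-layer toy brain (30 s, 1,250 Hz). End-to-end cluster recovery
uses the 256-electrode single-shank device over three 1.3 mm layers (60 s);
placement recovery runs 20 seeded 20 s simulations on a 640-electrode
four-shank fixture with the tilted-boundary atlas; the decimation contrast
uses 24 × 150 μm versus 3 × 1.3 mm layers (30 s each); convergence tests
use 30 s recordings with 2.5 s steps. These sizes keep the full suite
within a few minutes on one CPU while leaving every statistical margin
(ARI, recovery rate, Parseval tolerance) comfortably resolved.

## Known limitations

- Only coronal (vertical, non-angled) insertions are modeled; a tilted
  probe violates the single-slice assumption.
- The frozen-mode refinement objective can be misled when the initial
  displacement is large enough to flip a small cluster's modal region;
  this mirrors the method's stated assumption that the initial estimate is
  close to the truth.
- With a layered anatomy, combinations of small AP/ML/DV offsets whose
  boundary-depth residuals all fall below the voxel size are mutually
  indistinguishable; at 50 μm voxels this limits worst-case recovery to
  about one voxel plus one search step per axis.
- On stationary synthetic signals the prefix-vs-full convergence metric
  decays smoothly toward zero instead of reaching an early noise floor, so
  the plateau rule crosses later than it does on real (slowly drifting)
  recordings; the full-duration difference is exactly zero by
  construction either way.
- Multi-probe recordings are refined per probe; joint refinement and
  deformable (subject-specific) atlas registration are out of scope.
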