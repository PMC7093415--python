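# Methods

## Phasor model

Each pixel of a TCSPC-FLIM image holds a decay histogram `I_k` over
`n_time_bins` bins spanning the laser repetition period `T` (defaults
256 bins, 12.5 ns). The phasor transform evaluates the normalized Fourier
coefficient at `ω = 2πn/T`:

    G = Σ_k I_k cos(ω t_k) / Σ_k I_k,   S = Σ_k I_k sin(ω t_k) / Σ_k I_k

with `t_k = (k + ½) T / n_time_bins` the bin-center time. Bin-center (rather
than bin-edge) sampling is a deliberate choice: for a pulse-train-wrapped
monoexponential decay the bin-center sum is the midpoint rule for the
periodic integral whose exact value is `1/(1 + iωτ)`, so discretization
error is `O((T/n)²)` — below 10⁻⁵ already at 256 bins — and the closed form
`G = 1/(1+(ωτ)²)`, `S = ωτ/(1+(ωτ)²)` can serve as an oracle. No background
subtraction is applied before the transform; backgrounds should be handled
upstream or via the intensity mask.

The transform is linear: the phasor of a summed decay is the
intensity-weighted mean of the summands' phasors. This exact identity is
what justifies both spatial binning (a 3×3 sum lifts ~300 photons/pixel
above the ~2500 needed for multi-component analysis) and the simulator's
phasor assignment.

Pixels with zero (or sub-threshold) intensity are masked, never
NaN-propagated. The default `min_photons` is 0 for reference images and
configurable for tissue; the default binning is sliding 3×3 so image size is
preserved.

## IRF calibration

The instrument response is corrected in phasor space, not by time-domain
deconvolution: the mean phasor of a measured reference of known lifetime
(fluorescein, 4.05 ns at pH 9) is compared with its theoretical semicircle
point, and the polar decomposition of the ratio gives a phase rotation and
modulation scaling applied to every pixel. Calibrating and then applying on
the same reference is exact by construction (the acceptance check recovers
4.05 ns to numerical precision), so residual error on tissue comes only from
the reference measurement itself.

## Multiexponential fits

`fit_decay` fits `I(t) = Σ a_i exp(−t/τ_i)` (1–3 components, optional IRF
convolution) by variable projection: amplitudes are solved by non-negative
least squares at each trial lifetime set, lifetimes refined by
Levenberg–Marquardt from a fixed multi-start grid over [0.1, 5] ns
(geometric, 8 nodes, all sorted combinations). The procedure is
deterministic; non-convergence returns a flagged fit with infinite residual
rather than raising.

## Reference clusters and the single-drug map

A cluster's center is the mean (G, S) of its unmasked pixels; its scalar
variance is the *mean* squared Euclidean distance of points to the center,
which equals the trace of the population covariance. The mean convention
(over sum) is an interpretation choice: it makes variance fractions
independent of how many pixels each reference image contributes.
Covariances use the sample (N−1) convention and are diagonally loaded
(+10⁻⁹) when the smallest eigenvalue falls below 10⁻¹², so collinear or
degenerate references cannot crash the distance computation.

The single-drug fraction is `D_endo / (D_endo + D_exo)` with Mahalanobis
distances to the two clusters. The complementary normalized form is chosen
because it meets the contract the method needs — 0 at the endogenous center,
1 at the exogenous center, bounded in [0, 1] for every input; no additional
clipping or renormalization is applied beyond these natural bounds.

## Multicomponent algorithm

Roles: topmost = largest S; of the rest, leftmost/rightmost by G. Ties are
broken deterministically (smaller G wins topmost, then input order) and
logged; realistic clusters never tie.

Augmentation multiplies the role coordinate by `(1 ± 0.25·v_i/Σv)`, where
`v_i` is cluster i's scalar variance — i.e. each center moves outward by 25%
of its *fraction of total variance* times its own coordinate. The fraction
reading (over raw variance) keeps the shift scale-free. Augmented centers
may leave the physical phasor domain (e.g. rightmost G above 1); they are
virtual anchors, not lifetimes. With zero total variance the augmentation is
the identity (warned, not an error).

Augmentation is computed once from the references and reused for every test
image, for reproducibility. Geometrically it expands the reference triangle
whenever the topmost center lies counterclockwise of the directed
leftmost→rightmost segment — the layout actual phasor clusters form; for
adversarial role geometries (nearly collinear centers with inverted
orientation) the outward shifts can shrink the triangle, so the property
tests assert expansion on the realistic orientation only.

Contributions to a pixel are `C_i = 1/D_i` (Euclidean distance to the
augmented centers — the covariance-weighted metric is reserved for the
two-reference method), normalized by `C_tot`. The map is continuous except
at the centers; a pixel within 10⁻¹² of a center is attributed entirely to
that component, which is the limit value of the singular `1/D`. RGB
rendering blends each component's display color by its contribution
(half-up rounding, clamped); applying the identical blend to phasor-plot
points yields a phasor colormap in 1:1 correspondence with the tissue image.

## Synthetic benchmark

`make_ground_truth` builds the three-component map from linear cone ramps
`max(0, 1 − d/r)`: two peaking at the opposite bottom corners (radius 1 in
unit coordinates) and one radial peaking at the top-middle pixel (radius
√½), normalized per pixel. The two printed anchors of the design — pure
single components at the extremes, near-equal thirds at the image center —
fix the radii: with r = 1 and √½ the central pixel is an *exact*
equal-thirds mixture and the corner/top-middle pixels are exactly pure.

Noise: per pixel and component, counts `k_i ~ Poisson(f_i · photon_scale)`
are drawn and renormalized; all-zero pixels are redrawn. The default
`photon_scale = 300` is the realistic single-frame photon budget per pixel.
Phasors are then assigned as fraction-weighted combinations of the three
cluster centers — the exact mixing algebra of the transform. The default
centers are the closed-form phasors of 1.4 ns (TAZ, leftmost), 0.45 ns
(MNC, rightmost) and 2.0 ns (AF, topmost) at T = 12.5 ns. Following the
generating convention, these anchors are taken to be the variance-adjusted
centers themselves (they carry no scatter), so the augmentation step is the
identity inside the benchmark; `simulate_reference_clusters` provides
scattered synthetic references (AF broad, σ = 0.03; drugs tight, σ = 0.01)
for exercising the augmentation path itself. `simulate_decays` extends the
simulation down to TCSPC cubes (wrapped monoexponential mixtures,
Poisson-drawn or deterministically rounded counts) so the transform stack
can be tested end to end.

### Error metric

"Mean squared percent error" is computed as the mean squared
contribution-fraction error expressed as a percent, `100 · mean(e²)`; RMSE
and MAE in percentage points are emitted alongside in every report, and
per-component RMSE over all pixels is reported separately. Pixels are
stratified by how many true fractions exceed the primary-component
threshold (default 0.1, exposed as a CLI flag): at 256×256 and 300
photons/pixel the benchmark yields ≈3% for the 1–2-component stratum and
≈5% for the 3-component stratum, stable across seeds.

Two measured properties of the estimator are worth knowing:

- *Model-mismatch floor.* With zero noise and exact phasors the
  inverse-distance reconstruction does not invert linear mixing; the
  residual bias floor on this geometry is ≈3%/≈4.8% (strata) — a property of
  the 1/D model, not a bug. Errors at finite photon budgets sit just above
  this floor.
- *Monotonicity.* The overall (pooled) error decreases monotonically in
  `photon_scale` (tested at 30/300/3000 over 5 seeds). The 3-component
  stratum by itself is *not* monotone: Poisson scatter partially offsets the
  deterministic bias there, so its error can decrease slightly at low photon
  budgets. The monotonicity claim is therefore asserted on the overall
  error.

Benchmarks default to 256×256 (the native FLIM frame size); a 64×64 variant
gives indistinguishable stratified errors and runs in milliseconds, and is
used where many repetitions are needed.

## I/O choices

The native container is a multi-page TIFF time-stack plus JSON sidecar
(portable and inspectable); HDF5 (`/counts` + JSON `meta` attribute) serves
single-file workflows. Counts are stored uint16 (sufficient at ~300
photons/pixel), real channels float32. Vendor `.sdt` reading sits behind a
lazy import of the optional `sdtfile` package so the core never depends on
it. Cluster models serialize to JSON (label, points, center, covariance,
variance, color, role) so references are reusable across runs. Every CLI
run writes a resolved-config snapshot and logs its seed, making each
artifact reproducible from snapshot + seed.

## Known limitations

- The multicomponent algorithm is stated for exactly three references (one
  endogenous + two exogenous); more components would need a different
  attribution model.
- The inverse-distance contributions are biased for mid-simplex mixtures
  (see the model-mismatch floor above); they are a visualization-oriented
  attribution, not a maximum-likelihood unmixing.
- The simulator emulates phasor-level statistics (mixing, Poisson photon
  noise), not tissue morphology, optical sectioning, scattering or detector
  afterpulsing — passing benchmarks show algorithmic correctness under the
  stated noise model, not performance on any particular tissue.
- Tissue-specific results (real uptake maps and their contribution maxima)
  require measured reference and sample images; only the statistics are
  implemented here.
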