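# phasormix

Phasor-domain analysis of fluorescence lifetime imaging (FLIM) data for
mapping topical drug uptake in tissue.

Two-photon FLIM records, at every pixel, a time-correlated single-photon
counting (TCSPC) decay histogram. Many fluorescent drugs — e.g. minocycline
(MNC, dried-form lifetime ~0.4–0.5 ns) and tazarotene (TAZ, ~1.4 ns) — have
lifetimes distinct from skin autofluorescence (AF, ~1.5–2.5 ns), so lifetime
contrast can localize them label-free. `phasormix` implements the full
analysis chain:

- **Phasor transform.** Each decay `I(t)` maps to
  `G = Σ I_k cos(ω t_k) / Σ I_k`, `S = Σ I_k sin(ω t_k) / Σ I_k` with
  `ω = 2πn/T` (harmonic `n`, laser repetition period `T`, bin-center times
  `t_k`). Monoexponential decays land on the universal semicircle
  `(G−½)² + S² = ¼`; mixtures are intensity-weighted means of their
  components' phasors. Instrument response is corrected in phasor space by a
  rotation/scaling derived from a reference fluorophore of known lifetime
  (fluorescein, 4.05 ns).
- **Reference clusters.** Phasor populations of a vehicle-treated tissue
  image (endogenous) and dried single-drug samples (exogenous), summarized
  by center, covariance, and scalar variance.
- **Single-drug maps.** Per-pixel drug fraction
  `f = D_endo / (D_endo + D_exo)` from Mahalanobis distances to the two
  clusters.
- **Multicomponent maps** (one AF + two drug references). Cluster centers
  are first pushed outward by 25% of each cluster's fraction of total
  variance (topmost center up, leftmost left, rightmost right), expanding
  the reference triangle and down-weighting the broad AF cloud; then each
  pixel's contributions are inverse distances `C_i = 1/D_i` to the augmented
  centers, normalized to sum to one, and rendered to RGB
  (AF yellow, TAZ cyan, MNC magenta).
- **Synthetic benchmark.** A gradient ground-truth tissue map with
  per-component Poisson noise and phasor assignment by linear mixing,
  scored by stratified mean squared percent error.

## Worked example

```python
import numpy as np
from phasormix import (
    make_ground_truth, add_noise, assign_phasors,
    AugmentedCenters, contribution_image, colorize, benchmark,
)

gt = make_ground_truth(256, 256)                 # 3-component gradient map
noisy = add_noise(gt, photon_scale=300, seed=0)  # Poisson noise at 300 photons/px
phasors = assign_phasors(noisy, gt.centers)      # linear phasor mixing
anchors = AugmentedCenters.from_points(gt.centers, gt.labels, gt.colors)
recon = contribution_image(phasors, anchors)     # inverse-distance unmixing
rgb = colorize(recon)                            # AF/TAZ/MNC color blend
report = benchmark(gt, recon)
print({k: round(v, 2) for k, v in report.error_by_stratum.items()})
```

prints

```
{'1-2_components': 3.04, '3_components': 4.74}
```

the mean squared percent error of the reconstructed contribution fractions,
split by whether a pixel's ground truth holds at most two primary components
(error ~3%) or mixes all three (error ~5%; three-way mixtures carry more
Poisson noise and sit in the flattest part of the inverse-distance map).

The same pipeline is available from the shell:

```bash
phasormix benchmark --size 256 --photon-scale 300 --seed 0 --out results/
phasormix simulate --size 64 --seed 1 --out sim/
phasormix multi --sample sim/phasor.tif --ref af.json --ref taz.json \
    --ref mnc.json --out maps/
```

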