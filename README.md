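# optiregen

Quantification pipeline for zebrafish optic-nerve regeneration studies.

Adult zebrafish regenerate retinal ganglion cell (RGC) axons after optic
nerve crush, and labs measure that recovery along four complementary axes:
how far GFP-labelled axons have regrown along the nerve, how completely
they reinnervate the retinorecipient layers (SO/SFGS) of the optic tectum,
how well vision has functionally recovered (the dorsal light response, in
which injured fish swim tilted, blind eye up), and what transcriptional
programs (e.g. the cholesterol/mevalonate pathway) accompany the regrowth.
`optiregen` implements the quantification machinery of that study design
as a tested, reusable library plus CLI, and ships synthetic phantom
generators with ground truth so every stage is verifiable without any
microscope or sequencing data.

## Core quantities

- **Regeneration index** — mean GFP intensity *F* in 50 μm bins from the
  injury site toward the optic chiasm, normalized as

  *index = (F − F₀) / (F_pre − F₀)*

  where *F_pre* is the mean of the 50 μm window just proximal to the
  injury and *F₀* the mean of the whole uninjured nerve. Index 1 means
  pre-injury brightness, 0 means background; values are not clipped.
- **Tectal reinnervation ΔF/F** — mean fluorescence of the segmented
  SO/SFGS band on the crushed side over the uninjured side, per
  dorsal/medial/ventral sector, resampled onto a normalized 0–100%
  rostro-caudal axis; groups compared by two-way ANOVA with Fisher's LSD
  per position.
- **DLR tilt angle** — principal-axis orientation of the binarized fish
  silhouette relative to the horizon (degrees, positive = blind-eye-up),
  averaged over ≥ 5 frames per fish and time point; recovery curves
  compared by repeated-measures two-way ANOVA with Bonferroni post hocs.
- **Puncta / density / colocalization** — Laplacian-of-Gaussian detection
  of cells and RNAscope puncta, nearest-centroid assignment of puncta to
  cells, nuclei density per calibrated area, and one-to-one colocalization
  fractions.
- **Enrichment workflow** — median-of-ratios size-factor normalization,
  a two-group permutation test on log₂ fold change with BH FDR
  (thresholds FDR < 0.05, |log₂FC| > 1), weighted Kolmogorov–Smirnov GSEA
  with a phenotype-permutation null (ES/NES/FDR), three-way |FC| > 1.5
  intersections, hypergeometric over-representation with the
  (k/n)/(m/N) enrichment ratio, and ΔΔCt qPCR quantification
  (fold = 2^(−ΔΔCt), *gapdh* reference).

## Worked example

```python
import numpy as np
from optiregen import phantoms, nerve, dlr

# A regenerating-nerve phantom: injury at 250 um, front 500 um distal.
spec = phantoms.NervePhantomSpec(seed=1)
image, truth = phantoms.make_nerve_phantom(spec)
profile = nerve.bin_intensity(image, injury_x_um=250, chiasm_x_um=1500,
                              px_per_um=1.0, f_0=spec.f0_level)
rip = nerve.regeneration_index(profile)
print(profile.F_pre, profile.F_0)        # 200.0 20.0
print(np.round(rip.index[8:12], 3))      # [0.946 0.717 0.283 0.054]
print(nerve.front_position(rip))         # 475.0

# A tilted-fish silhouette: true tilt 10 deg, 1 deg frame jitter.
frames, _ = phantoms.make_silhouette(
    phantoms.SilhouetteSpec(tilt_deg=10, jitter_deg=1, seed=2))
angles = [dlr.estimate_tilt(f) for f in frames]
print(round(dlr.mean_tilt(angles).mean_angle_deg, 2))   # 9.73
```

The index profile holds at 1 through the regenerated region, crosses 0.5
inside the bin containing the true front (500 μm distal → bin centre
475 μm), and decays to 0 beyond it; the behavioural estimator recovers the
10° tilt to within the frame jitter.

## Command-line pipeline

```sh
optiregen simulate --config cfg.yaml --out sim/ --seed 11
optiregen nerve    --config cfg.yaml --out run/
optiregen tectum   --config cfg.yaml --out run/
optiregen dlr      --config cfg.yaml --out run/
optiregen retina   --config cfg.yaml --out run/
optiregen enrich   --config cfg.yaml --out run/
optiregen report   --config cfg.yaml --out run/
```

Each stage reads a YAML config section, writes CSV/TSV/JSON outputs plus a
run log and a verbatim config echo, and exits with a distinct code for
config errors (2), missing inputs (3) and stage failures (4). Distances
are in μm, angles in degrees, image coordinates 0-based with the origin
top-left. All randomness is seeded.

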