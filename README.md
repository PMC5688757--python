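# retinamech

Image-analysis and tissue-mechanics tools for the zebrafish photoreceptor
mosaic, written for researchers quantifying confocal flat-mount imagery of
the retinal epithelium: selective projection of z-stacks at the outer
limiting membrane (OLM), watershed counting of reporter-positive apical
profiles, steerable-filter detection of Müller-glial bands, and strain
estimation from laser-ablation recoil. A synthetic-data module renders all
of these inputs with known ground truth, so every stage of the pipeline is
testable end to end.

## The science in brief

**Lattice mosaic.** Adult zebrafish cones pack into single-cell-width
columns repeating the motif R, B, R, G, U, G — successive Red cones
separated alternately by one Blue cone or a Green–UV–Green triplet — with
rows of alternating UV/Blue cones perpendicular to the columns and four
rods at the corners of each UV cone. Counting one repeat unit predicts the
ratio of Red-reporter-positive to negative apical profiles: **1:2** if
only cones are present and **1:4** once rods are included. `mosaic_model`
builds and validates these lattices and derives the ratios by counting.

**Selective OLM projection.** The OLM surface z(x, y) is reconstructed
from a junction channel by Gaussian smoothing of each pixel's z-profile
and sub-voxel peak localization, with interpolation across masked or
low-signal pixels, then any channel is projected within a thin band
around that surface; the fitted tilt plane corrects for sample
inclination (`surface_projection`).

**Profile counting.** Apical profiles are segmented by seeded watershed
on the boundary projection, mean reporter intensity is measured per
profile, and profiles are classified ± by exact two-cluster 1D k-means
(`profile_segmentation`).

**Glial ridges.** An order-4 steerable Gaussian-derivative filter (width
8 px) scores ridge-likeness and orientation per pixel; the column
direction θ_c comes from the image power spectrum (its peak direction is
perpendicular to the columns); ridges deviating more than 30° from θ_c or
shorter than 20 px are discarded, and repeating the filter at θ_c + 90°
serves as a negative control (`ridge_analysis`).

**Ablation strain.** From centroids r_i⁰ tracked to r_iᶠ after glial
ablation, the affine map minimizing Σ‖r_iᶠ − M r_i⁰ − b‖² is fitted in
closed form; the polar decomposition M = U·P splits off the rotation, and
the eigenvalues of P are the principal stretch ratios (>1 stretching,
<1 compression), assigned to the axes along (y) and across (x) the cone
columns. Welch and unequal-covariance Hotelling T² tests compare ablation
to control groups (`strain_mechanics`).

## Worked example

The full simulate → project → segment → classify chain on a noise-free
ideal lattice, from the shell:

```console
$ retinamech ratio --no-rods
measured ratio 1:2 (24 positive, 48 negative)
$ retinamech ratio --include-rods
measured ratio 1:4 (24 positive, 96 negative)
```

The measured ratios equal the lattice predictions exactly: with 3 columns
of 4 repeat units there are 24 Red cones against 48 other cones (1:2), or
against 48 cones + 48 rods (1:4) once rods occupy the UV-cone corners.

Strain recovery from a simulated recoil (true stretch λ = (1.0, 1.2)
across/along the columns, saturating with τ = 20 min; 20 tracked points,
positional noise 2% of the 5 µm spacing):

```python
>>> from retinamech.pipelines import strain_recovery_pipeline
>>> exp, results, table = strain_recovery_pipeline(
...     strain_true=(1.0, 1.2), noise_frac=0.02, seed=3)
>>> print(table.to_string(index=False))
 time_min    group  x_strain  y_strain  axis_deviation_deg  residual_fraction
      5.0 ABLATION  1.000129  1.042507            2.409401           0.032064
     15.0 ABLATION  1.003900  1.103611            0.011848           0.026893
     30.0 ABLATION  0.994769  1.153143            0.113380           0.027211
     60.0 ABLATION  0.999926  1.188788            0.581719           0.023262
```

The y-strain (along the columns) climbs toward the imposed 1.2 as the
recoil saturates while the x-strain stays at 1, the principal axis stays
within a degree or two of the column direction, and the residual fraction
(~3% of the neighbour distance) confirms the deformation is affine.

The CLI also exposes the individual stages — `retinamech simulate`,
`project`, `segment`, `ridges`, `strain` — each writing CSV/TIFF/JSON
outputs plus a manifest with parameters and input hashes; see
`retinamech --help`.

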