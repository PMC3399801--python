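# trabkit

Trabecular bone morphometry and locomotor-group discrimination for
comparative skeletal biology.

The spongy bone inside joint ends remodels under habitual loading, so its
architecture should — in principle — record how an animal moved. Testing
that idea across primates requires a long chain of quantitative steps:
extract a volume of interest (VOI) scaled to joint size from a microCT
scan, segment bone from marrow, measure the architectural suite
(bone volume fraction BV/TV, trabecular thickness Tb.Th, spacing Tb.Sp,
number Tb.N, connectivity density Conn.D, structure model index SMI, and
the mean-intercept-length degree of anisotropy DA), correct Tb.Th for
voxel-size dependence, remove body-size allometry, check for
phylogenetic signal, and finally ask whether the size-corrected suite
separates locomotor groups in a discriminant analysis. `trabkit`
implements that entire chain as a tested Python library with a thin CLI,
driven end-to-end by synthetic phantoms with analytic ground truth — so
every operator is verifiable without any scan archive.

Who it is for: researchers in skeletal functional morphology and
bone image analysis who want a transparent, scriptable reference
implementation of the standard morphometric operators and the
multivariate locomotor-classification workflow built on top of them.

## The quantities at the core

For a segmented spherical VOI of bone phase B:

- **Tb.Th / Tb.Sp** — volume-weighted mean of the sphere-fitting local
  thickness of the bone / marrow phase (the diameter of the largest
  inscribed sphere through each point).
- **Tb.N** — 1 / (mean spacing between trabecular mid-axes), mid-axes
  taken as distance-map ridges.
- **Conn.D** — β₁/V = (1 − χ)/V for the purged structure, with χ the
  26-connectivity Euler characteristic.
- **SMI** — 6·S′·V/S², S′ the surface-area derivative under infinitesimal
  outward dilation of the triangulated surface (plates → 0, rods → 3,
  spheres → 4).
- **DA** — mil₁/mil₃ from the ellipsoid fit 1/MIL²(ω) = ωᵀAω of
  directional mean intercept lengths.
- **Tb.Th.corr** — Tb.Th × (−4.4856·voxel + 1.0805), the published
  voxel-size correction (recalibratable via `calibrate_correction`).
- **Blomberg's K** — (MSE0/MSE) / E_BM[MSE0/MSE] on species means under
  the Brownian covariance C of a dated phylogeny.
- **Discriminant analysis** — eigenstructure of W⁻¹B with Wilks' Λ /
  Bartlett χ², pooled within-group structure matrix, Mahalanobis
  classification, stepwise Wilks selection (F-enter 3.84 / F-remove
  2.71), and pairwise group F-tests on Mahalanobis distances with
  DF = (p, n−g−p+1).

## Worked example

Generate a plate phantom with known architecture, degrade it to a
grayscale "scan", extract a spherical VOI and run the morphometric suite:

```python
import numpy as np
from trabkit import (PhantomSpec, make_plate_phantom, degrade,
                     extract_spherical_voi, summarize, MorphometryConfig,
                     VOISpec)

spec = PhantomSpec("plates", shape=(128, 128, 128), voxel_mm=0.025,
                   plate_thickness_mm=0.2, plate_spacing_mm=0.8)
vol, truth = make_plate_phantom(spec)
scan = degrade(vol, blur_sigma_mm=0.012, noise_sd=8, seed=1)

center = (np.array(scan.shape)[::-1] - 1) / 2 * scan.voxel_mm
voi = extract_spherical_voi(scan, VOISpec(center, 3.0))
s = summarize(voi, MorphometryConfig(seed=0))
```

Formatted field by field, the summary reads:

```
threshold    123.81
BV/TV         0.185   (truth 0.200)
Tb.Th         0.197   (truth 0.200 mm)
Tb.Th.corr    0.191
Tb.Sp         0.798   (truth 0.800 mm)
Tb.N          1.031   (truth 1.000 /mm)
Conn.D        0.000   (plates have no loops)
SMI           0.000   (plates -> 0)
DA            5.724   (plates are strongly anisotropic)
```

The isodata threshold lands between the 60/190 intensity plateaus; every
measured variable recovers the phantom's analytic truth (blur erodes
BV/TV slightly, by design of the degradation model), and the fabric
tensor correctly reports a strongly anisotropic, plate-like, loop-free
structure.

The statistical half runs from tables rather than volumes:

```python
from trabkit import CanonicalDiscriminant, simulate_groups
from trabkit.phantoms import locomotor_demo_centroids

cent = locomotor_demo_centroids(2.5)          # 7 locomotor groups, 5 traits
tab = simulate_groups(cent, np.eye(5), 15, seed=2024)
res = CanonicalDiscriminant(tab[cent.columns], tab["group"]).fit_stepwise()
print(res.summary())            # eigenvalues, Wilks' Λ, structure matrix
print(res.confusion().summary())  # classification table, % correct
```

A YAML-configured end-to-end demonstration (three phantom "taxa" →
morphometry → residuals → K → discriminant report) is available as
`trabkit all --config examples/demo.yaml`; see `trabkit --help` for the
per-stage subcommands (`simulate`, `voi`, `morph`, `calibrate`,
`residuals`, `physig`, `dfa`).

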