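# tactoidmc

Monte Carlo simulation and director-field analysis of **hard colloidal rods
confined to quasi-2D spindle-shaped (tactoid-like) containers**.

Lyotropic liquid crystals phase-separating from the isotropic phase form
spindle-shaped nematic droplets ("tactoids").  Microfabricated lens-shaped
chambers let one impose that geometry on a nematic of rod-like colloids
(e.g. fd virus) while varying the size and the aspect ratio independently.
At chamber sizes of only a few rod lengths, the competition between mutual
alignment and planar wall anchoring produces a family of director-field
patterns — homogeneous, bipolar, displaced-defect, wavy and multi-domain
states — many of which are long-lived metastable intermediates of distinct
relaxation pathways.  `tactoidmc` reproduces this system in silico: a
hard-spherocylinder Monte Carlo engine in the lens geometry plus the
order-parameter, defect-detection and pattern/pathway classification stack
used to analyze it.  It is written for soft-matter researchers who want a
compact, scriptable model of confined lyotropic nematics.

## The model

* **Container** — the cross-section of two overlapping circles of equal
  radius *R*, extruded to a shallow depth *h*.  Major axis *L<sub>y</sub>*
  (cusp to cusp), minor axis *L<sub>x</sub>*, cusp opening angle
  *α* = 4 arccot(*L<sub>y</sub>*/*L<sub>x</sub>*).  All lengths are in units
  of the rod diameter *d*.
* **Particles** — hard spherocylinders of length *L* and diameter *d*
  (default *L/d* = 20) interacting by steric exclusion only; the
  particle–wall interaction is also hard.  Default volume fraction
  *η* = 0.16, depth *h/d* = 6.
* **Dynamics** — standard single-particle Metropolis moves (joint random
  translation and rotation); MC sweeps serve as the time proxy.
* **Order fields** — the global tensor order parameter
  **Q** = ⟨3/2 **û**ᵢ⊗**û**ᵢ − ½𝟙⟩ (scalar order *S* = top eigenvalue,
  director **n** = its eigenvector) and its local version **Q**ᵏ on cuboidal
  sub-volumes, each rod weighted by the centerline length *l*ᵢᵏ inside
  sub-volume *k*.
* **Defects** — located by the nematic winding number on cell plaquettes
  (interior disclinations) and by the open-arc director rotation around
  boundary sites (surface boojums); an angular-deficit scalar
  δ = min∠(**n**₁,**n**₂) + min∠(**n**₃,**n**₄) over opposite neighbor
  pairs peaks at defect cores.  On the lens the detected charges sum to +1,
  the Euler characteristic of the domain.
* **Taxonomy** — patterns H, B, B∥, D\*, D\*\*, D<sub>h</sub>, S, S\*\*,
  M₄, M₆; relaxation pathways *melt* (six-defect central-droplet
  intermediate), *slide* (four-defect intermediate) and *turn* (rotating
  two-defect sequence).

## Worked example

```python
from tactoidmc import (make_spindle, fixture_spec, synth_field,
                       detect_defects, total_charge, classify_pattern)

geom = make_spindle(Ly=90.0, aspect=1.5, h=6.0)   # smallest study geometry
field = synth_field(fixture_spec("Bpar", geom), cell_size=10.0)
defects = detect_defects(field, geom)
for d in defects:
    print(f"charge {d.charge:+.1f} at ({d.position[0]:+.1f}, "
          f"{d.position[1]:+.1f}) [{d.locale}]")
print("total charge", total_charge(defects))
print("pattern:", classify_pattern(field, defects, L=20.0))
```

prints

```
charge +0.5 at (+0.0, -45.0) [boundary]
charge +0.5 at (+0.0, +45.0) [boundary]
total charge 1.0
pattern: Bpar
```

— the bipolar pattern's two +1/2 boojums sit exactly in the cusps at
(0, ±L<sub>y</sub>/2) and their charges sum to +1, as the topology of the
lens demands.  The `examples/` directory holds short narrative scripts for
each capability (geometry, simulation, defect detection, pattern
classification, a full relaxation experiment), and the `tactoidmc` console
command exposes `simulate` / `analyze` / `classify` / `pathways` /
`fixtures` subcommands over the same library.

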