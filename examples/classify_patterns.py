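"""Classifying the director-field pattern gallery.

Builds the analytic fixture for every pattern class at the container sizes
where each occurs (in units of the rod diameter d) and runs the classifier.
Every fixture must come back under its own label with total charge +1
(0 defects for the homogeneous H state).
"""

from tactoidmc import (classify_pattern, detect_defects, fixture_spec,
                       make_spindle, synth_field, total_charge)

GALLERY = [
    ("H", 400, 5.0), ("B", 300, 1.0), ("Bpar", 300, 1.5),
    ("Dstar", 270, 1.5), ("Dstarstar", 300, 1.5), ("Dh", 300, 1.5),
    ("S", 150, 1.5), ("Sstarstar", 300, 1.5), ("M4", 270, 1.5),
    ("M6", 240, 1.5),
]

for pattern, Ly, aspect in GALLERY:
    geom = make_spindle(Ly, aspect, 6.0)
    field = synth_field(fixture_spec(pattern, geom), cell_size=10.0)
    defects = detect_defects(field, geom)
    label = classify_pattern(field, defects, L=20.0)
    print(f"{pattern:10s} (Ly={Ly:3.0f}, aspect={aspect}): classified as "
          f"{label!s:10s} with {len(defects)} defects, "
          f"charge {total_charge(defects):+.1f}")
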