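"""Spindle-container geometry: sizes, opening angle, rod counts.

Builds the smallest container of the study conditions (Ly = 4.5 L at
aspect ratio 1.5) and prints its derived quantities.
"""

from tactoidmc import (alpha_from_aspect, aspect_from_alpha, count_rods,
                       lens_area, make_spindle)

geom = make_spindle(Ly=90.0, aspect=1.5, h=6.0)
print(f"container: Ly = {geom.Ly} d, Lx = {geom.Lx} d, depth h = {geom.h} d")
print(f"generating circles: radius R = {geom.R} d at x = +-{geom.c} d")
print(f"cusp opening angle alpha = {geom.alpha:.2f} degrees")
print(f"cross-section area = {lens_area(geom):.1f} d^2")

n = count_rods(geom, eta=0.16, L=20.0, d=1.0)
print(f"rods at volume fraction 0.16 (L/d = 20): N = {n}")

# the angle-aspect relation alpha = 4 arccot(Ly/Lx) and its inverse
print(f"alpha(aspect=1)    = {alpha_from_aspect(1.0):.1f} deg  (circle)")
print(f"aspect(alpha=30)   = {aspect_from_alpha(30.0):.4f}     (slender spindle)")
# A 30-degree cusp needs a ~7.6:1 spindle; alpha decreases as the
# container elongates, reaching 180 degrees for the circular case.
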