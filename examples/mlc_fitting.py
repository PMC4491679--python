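"""Fit a static MLC leaf bank to an aperture and quantify the scalloping.

Generate a random, gently irregular aperture outline, fit 0.5 cm leaves with
the midpoint rule (each leaf end's midpoint sits on the aperture line), and
measure the scalloping error — the area where the stepped leaf opening and
the smooth aperture disagree — for both leaf orientations and for
successively narrower leaves.
"""

from protonplan.mlc import aperture_area_error, fit_leaf_positions, orientation_variants
from protonplan.synthetic import gen_aperture

aperture = gen_aperture(seed=20, mean_radius=3.0, irregularity=0.15)
print(f"Aperture area: {aperture.area:.2f} cm^2")

both = orientation_variants(aperture, leaf_width=0.5)
print(f"Scalloping error, leaves stacked along y: {both.error_y:.3f} cm^2")
print(f"Scalloping error, leaves stacked along x: {both.error_x:.3f} cm^2")

print("\nError vs leaf width (y orientation):")
for width in (1.0, 0.5, 0.25, 0.125):
    bank = fit_leaf_positions(aperture, leaf_width=width)
    err = aperture_area_error(aperture, bank)
    print(f"  {width:5.3f} cm -> {err:.3f} cm^2 ({100 * err / aperture.area:.1f}% of aperture)")

print(
    "\nWith clinical 0.5 cm leaves the stepped opening differs from the custom\n"
    "aperture by a few percent of its area, concentrated at the field edge;\n"
    "halving the leaf width shrinks the scalloping roughly in proportion."
)
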