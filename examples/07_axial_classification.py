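"""Axial-coordination classification of a square-planar complex.

Square-planar d8 metal complexes can bind 0, 1 or 2 extra ligands at the
axial positions (square-planar / square-pyramidal / octahedral).  The
classifier fits the equatorial plane through the 4 bound ligand anchors and
counts solvent anchors inside a distance window and angular cone about the
plane normal.
"""

from solvshell.analysis import ComplexSpec, axial_state_classifier
from solvshell.fixtures import build_complex

spec = ComplexSpec(metal=0, equatorial=[1, 4, 7, 10], solvent_anchors="N",
                   r_min=2.4, r_max=3.6, cone_half_angle=35.0)

# a mock trajectory alternating ideal geometries 7:4
octahedral = build_complex("octahedral", metal="Pd", ligand="nitrile",
                           bond_length=(2.0, 3.0))
pyramid = build_complex("square-pyramidal", metal="Pd", ligand="nitrile",
                        bond_length=(2.0, 3.0))
trajectory = [octahedral] * 7 + [pyramid] * 4

states, fractions = axial_state_classifier(trajectory, spec)
print("per-frame states:", states)
print("fractions:", {k: round(v, 3) for k, v in fractions.items()})
ratio = fractions["octahedral"] / fractions["square-pyramidal"]
print(f"octahedral : square-pyramidal = {ratio:.2f} (constructed 7:4)")
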