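# Toy backbone parameters for the coarse synthetic fixtures.
# One threefold torsion over consecutive CA quadruples stands in for the
# backbone torsional stiffness; LJ/charges give the nonbonded terms a
# well-behaved signal. Not a calibrated force field.

DIHEDRAL CA CA CA CA  0.6 3 0.0

NONBONDED CA 0.055 2.000

CHARGE S* -0.69
CHARGE Fe  0.78
CHARGE S  -0.68
CHARGE C_B -0.04
CHARGE H   0.09
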