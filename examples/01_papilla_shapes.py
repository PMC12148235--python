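"""Build the analytic WT and ktn1-5 papilla surfaces and inspect them.

The papilla is a surface of revolution: an ellipsoidal head joined C2-
continuously to a shaft with a single neck constriction.  The two shaft
coefficients are solved from the measured neck position and width.
"""

from papillasim.io import default_shapes

shapes = default_shapes()
for genotype, shape in shapes.items():
    d = shape.descriptors
    print(f"{genotype}: Lhead={d.Lhead} um, Lneck={d.Lneck} um, "
          f"Whead={d.Whead} um, Wneck={d.Wneck} um")
    print(f"  shaft coefficients a1={shape.a1:.5f}, a2={shape.a2:.4f}")
    for z in (0.0, d.Lhead, d.Lneck, shape.z_base):
        R, R1, _ = shape.radius(z)
        print(f"  z={z:5.2f} um -> R={R:6.3f} um (dR/dz={R1:+.4f})")

# R(Lneck) equals half the measured neck width and has zero slope there:
# the neck is the narrowest point of the shaft, where geodesics coil.
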