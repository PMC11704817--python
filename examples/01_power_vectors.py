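"""Power-vector decomposition of keratometry and refraction.

Decomposes a keratometry reading and a manifest refraction into (EQ, C0,
C45), classifies the astigmatism orientation and computes the defocus
equivalent.
"""

from toricalc import (
    MeridionalPower,
    SpheroCylinder,
    classify_orientation,
    defocus_equivalent,
    meridional_to_powervector,
    spherocyl_to_powervector,
)

# keratometry: flat 42.5 D at 5 deg, steep 44.0 D (steep meridian at 95 deg)
k = meridional_to_powervector(MeridionalPower(42.5, 44.0, 5.0))
print(f"keratometry power vector: EQ={k.EQ:.3f}  C0={k.C0:.3f}  C45={k.C45:.3f} D")
print(f"orientation: {classify_orientation(k)}  (positive C0 = with-the-rule)")

# manifest refraction -0.50 / -0.75 x 170 (minus-cylinder notation)
ref = spherocyl_to_powervector(SpheroCylinder(-0.50, -0.75, 170.0))
print(f"refraction power vector:  EQ={ref.EQ:.3f}  C0={ref.C0:.3f}  C45={ref.C45:.3f} D")
print(f"defocus equivalent: {defocus_equivalent(ref):.3f} D")
print("DEQ is the scalar burden of the residual refractive error; every")
print("dioptre of it costs roughly two decimal lines of uncorrected acuity.")
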