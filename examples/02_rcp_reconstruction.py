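"""Back-calculating reconstructed corneal power (RCP) for one eye.

Builds a pseudophakic eye (Haigis effective lens position, toric IOL),
simulates its manifest refraction through the paraxial vergence model, then
reconstructs the corneal power from that refraction and the IOL data — the
two directions are exact inverses.
"""

from toricalc import (
    PowerVector,
    PseudophakicGeometry,
    TORBI709,
    haigis_elp,
    iol_to_spherocylinder,
    reconstruct_rcp,
    simulate_refraction,
)

al, acd = 23.9, 3.1  # axial length, anterior chamber depth (mm)
elp = haigis_elp(acd, al, TORBI709)
print(f"Haigis ELP = 0.912 + 0.4*{acd} + 0.1*{al} = {elp:.3f} mm")

cornea = PowerVector(43.0, 1.8, -0.4)  # total corneal power, right eye
geometry = PseudophakicGeometry(al, elp)
# 21.0 D equivalent toric IOL, 2.0 D cylinder, marked flat axis at 95 deg
iol = iol_to_spherocylinder(21.0, 2.0, 95.0)

ref = simulate_refraction(cornea, iol, geometry)
print(
    f"simulated refraction: {ref.sphere:+.3f} / {ref.cylinder:+.3f} x {ref.axis:.1f}"
)

rcp = reconstruct_rcp(ref, iol, geometry)
print(f"reconstructed corneal power: EQ={rcp.EQ:.6f} C0={rcp.C0:.6f} C45={rcp.C45:.6f}")
err = max(abs(rcp.EQ - cornea.EQ), abs(rcp.C0 - cornea.C0), abs(rcp.C45 - cornea.C45))
print(f"round-trip error vs the true cornea: {err:.2e} D (exact inverse)")
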