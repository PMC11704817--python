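"""Astigmatic vergence propagation and RCP back-calculation."""

import numpy as np
import pytest

from toricalc.powervector import (
    PowerVector,
    SpheroCylinder,
    spherocyl_to_powervector,
)
from toricalc.vergence import (
    LISA939,
    TORBI709,
    DegenerateVergenceError,
    EyeModelConstants,
    HaigisConstants,
    PseudophakicGeometry,
    haigis_elp,
    iol_to_spherocylinder,
    matrix_to_powervector,
    powervector_to_matrix,
    reconstruct_rcp,
    simulate_refraction,
    translate_vergence,
)

CONST = EyeModelConstants()


# ---------------------------------------------------------------- matrices
def test_powervector_matrix_cardinal_case():
    m = powervector_to_matrix(PowerVector(43.0, 2.0, 0.0))
    assert m == pytest.approx(np.array([[42.0, 0.0], [0.0, 44.0]]))
    # eigenvalues are the principal powers, half-trace the equivalent power
    assert sorted(np.linalg.eigvalsh(m)) == pytest.approx([42.0, 44.0])


def test_powervector_matrix_oblique_case():
    m = powervector_to_matrix(PowerVector(0.0, 0.0, 2.0))
    assert m == pytest.approx(np.array([[0.0, -1.0], [-1.0, 0.0]]))


def test_matrix_roundtrip_identity():
    rng = np.random.default_rng(0)
    for _ in range(200):
        pv = PowerVector(rng.normal(43, 3), rng.normal(0, 2), rng.normal(0, 1))
        back = matrix_to_powervector(powervector_to_matrix(pv))
        assert back.as_array() == pytest.approx(pv.as_array(), abs=1e-12)


# ------------------------------------------------------------- translation
def test_translate_scalar_vergence_formula():
    V = 10.0 * np.eye(2)
    out = translate_vergence(V, 0.01, 1.0, "forward")
    assert out == pytest.approx(10.0 / (1.0 - 0.1) * np.eye(2))


def test_translate_zero_distance_is_identity():
    V = powervector_to_matrix(PowerVector(5.0, 1.0, -0.5))
    assert translate_vergence(V, 0.0, 1.336, "forward") == pytest.approx(V)


def test_translate_forward_backward_inverse_pair():
    rng = np.random.default_rng(1)
    for _ in range(200):
        V = powervector_to_matrix(
            PowerVector(rng.normal(20, 10), rng.normal(0, 3), rng.normal(0, 3))
        )
        W = translate_vergence(V, 0.004, 1.336, "forward")
        back = translate_vergence(W, 0.004, 1.336, "backward")
        assert back == pytest.approx(V, abs=1e-10)
        assert W == pytest.approx(W.T)  # symmetry preserved


def test_translate_aligned_axes_act_like_scalar_meridians():
    pv = PowerVector(43.0, 4.0, 0.0)  # principal powers 41 and 45 on x/y
    out = translate_vergence(powervector_to_matrix(pv), 0.005, 1.336, "forward")
    tau = 0.005 / 1.336
    assert out[0, 0] == pytest.approx(41.0 / (1 - tau * 41.0))
    assert out[1, 1] == pytest.approx(45.0 / (1 - tau * 45.0))


def test_translate_degenerate_configuration_raises():
    V = 100.0 * np.eye(2)  # focuses at 10 mm; translate exactly 10 mm in n=1
    with pytest.raises(DegenerateVergenceError):
        translate_vergence(V, 0.01, 1.0, "forward")


# ------------------------------------------------------------------ Haigis
@pytest.mark.parametrize(
    "constants, expected",
    [(TORBI709, 4.512), (LISA939, 4.560), (HaigisConstants(1.5, 0, 0), 1.5)],
)
def test_haigis_elp_linear_formula(constants, expected):
    assert haigis_elp(3.0, 24.0, constants) == pytest.approx(expected)


def test_haigis_warns_on_implausible_biometry():
    with pytest.warns(UserWarning, match="plausible"):
        haigis_elp(0.5, 24.0, TORBI709)
    with pytest.raises(ValueError):
        haigis_elp(float("nan"), 24.0, TORBI709)


def test_geometry_requires_elp_inside_eye():
    with pytest.raises(ValueError):
        PseudophakicGeometry(23.0, 25.0)


# ---------------------------------------------------- forward/backward RCP
def _random_eye(rng):
    cornea = PowerVector(rng.uniform(39, 48), rng.normal(0, 2), rng.normal(0, 1))
    al = rng.uniform(21, 28)
    acd = rng.uniform(2.4, 4.0)
    elp = haigis_elp(acd, al, TORBI709 if rng.random() < 0.5 else LISA939)
    geometry = PseudophakicGeometry(al, elp)
    iol = iol_to_spherocylinder(
        rng.uniform(2, 32), rng.uniform(0, 6), rng.uniform(0, 180)
    )
    return cornea, iol, geometry


def test_reconstruction_inverts_simulation_on_random_eyes():
    """The central correctness property of the eye model."""
    rng = np.random.default_rng(2024)
    worst = 0.0
    for _ in range(1000):
        cornea, iol, geometry = _random_eye(rng)
        ref = simulate_refraction(cornea, iol, geometry, CONST)
        back = reconstruct_rcp(ref, iol, geometry, CONST)
        worst = max(worst, np.max(np.abs(back.as_array() - cornea.as_array())))
    assert worst < 1e-9


def test_rcp_invariant_under_refraction_transposition():
    rng = np.random.default_rng(7)
    cornea, iol, geometry = _random_eye(rng)
    ref = simulate_refraction(cornea, iol, geometry, CONST)
    a = reconstruct_rcp(ref, iol, geometry, CONST)
    b = reconstruct_rcp(ref.transposed(), iol, geometry, CONST)
    assert a.as_array() == pytest.approx(b.as_array(), abs=1e-10)


def _scalar_refraction(k, iol_power, geometry, const=CONST):
    """Independent scalar vergence chain for spherical eyes."""
    elp, al = geometry.elp / 1000, geometry.axial_length / 1000
    v = const.n_vitreous / (al - elp) - iol_power
    v = v / (1 + (elp / const.n_aqueous) * v)  # backward through ELP
    v = v - k
    v = v / (1 + const.vertex_distance * v)  # backward through vertex
    return v - const.object_vergence


def test_matrix_pipeline_matches_scalar_chain_for_spherical_eyes():
    rng = np.random.default_rng(3)
    for _ in range(100):
        k = rng.uniform(39, 48)
        p = rng.uniform(5, 30)
        geometry = PseudophakicGeometry(rng.uniform(21, 27), rng.uniform(3.8, 5.5))
        sc = simulate_refraction(
            PowerVector(k, 0, 0), SpheroCylinder(p, 0, 0), geometry, CONST
        )
        assert sc.cylinder == pytest.approx(0.0, abs=1e-10)
        assert sc.sphere == pytest.approx(_scalar_refraction(k, p, geometry), abs=1e-12)


def test_emmetropic_construction_yields_plano():
    """Solve the scalar chain for AL, then the full simulation must be plano."""
    from scipy.optimize import brentq

    k, p, elp = 43.0, 21.0, 4.5
    al = brentq(
        lambda a: _scalar_refraction(k, p, PseudophakicGeometry(a, elp)),
        20.0,
        30.0,
        xtol=1e-12,
    )
    sc = simulate_refraction(
        PowerVector(k, 0, 0), SpheroCylinder(p, 0, 0), PseudophakicGeometry(al, elp), CONST
    )
    assert sc.sphere == pytest.approx(0.0, abs=1e-9)
    assert sc.cylinder == pytest.approx(0.0, abs=1e-9)


def _compensating_iol(cornea_flat, cornea_steep, steep_axis, geometry):
    """Per-meridian IOL powers that null the refraction of each meridian."""
    from scipy.optimize import brentq

    def solve(k):
        return brentq(
            lambda p: _scalar_refraction(k, p, geometry), -20.0, 45.0, xtol=1e-13
        )

    p_flat, p_steep = solve(cornea_flat), solve(cornea_steep)
    # higher IOL power sits on the corneal flat meridian; IOL flat axis = corneal steep
    seq = 0.5 * (p_flat + p_steep)
    cyl = p_flat - p_steep
    return iol_to_spherocylinder(seq, cyl, steep_axis)


def test_compensating_toric_iol_nulls_residual_cylinder():
    geometry = PseudophakicGeometry(23.9, 4.512)
    cornea = spherocyl_to_powervector(SpheroCylinder(42.0, 2.0, 0.0))  # 2 D WTR
    iol = _compensating_iol(42.0, 44.0, 90.0, geometry)
    sc = simulate_refraction(cornea, iol, geometry, CONST)
    assert sc.cylinder == pytest.approx(0.0, abs=1e-9)
    assert sc.sphere == pytest.approx(0.0, abs=1e-9)


def test_misaligned_by_90_degrees_doubles_the_cylinder_effect():
    geometry = PseudophakicGeometry(23.9, 4.512)
    cornea = spherocyl_to_powervector(SpheroCylinder(42.0, 2.0, 0.0))
    good = _compensating_iol(42.0, 44.0, 90.0, geometry)
    rotated = SpheroCylinder(good.sphere, good.cylinder, good.axis + 90.0)
    sc = simulate_refraction(cornea, rotated, geometry, CONST).to_plus_cylinder()
    # corneal and IOL cylinder now add: residual is about twice either alone
    alone = simulate_refraction(
        cornea, SpheroCylinder(good.sphere + good.cylinder / 2, 0.0, 0.0), geometry, CONST
    ).to_plus_cylinder()
    assert sc.cylinder == pytest.approx(2 * alone.cylinder, rel=0.12)
    # orientation preserved: still a cardinal-axis cylinder
    assert min(sc.axis % 90.0, 90.0 - sc.axis % 90.0) < 1e-6
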