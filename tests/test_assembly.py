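import math

import numpy as np
import pytest

from betasyn.assembly import (
    FLAT,
    LHH,
    RHH,
    AssemblyError,
    AssemblyModel,
    ChargeModel,
    ClosureError,
    HelicalParams,
    ReferenceObservables,
    ToroidParams,
    arc_segment,
    clash_check,
    macrodipole,
    measure_pitch,
    ribbon_assemble,
    screw_assemble,
    substrate_height,
    toroid_assemble,
)
from betasyn.structures import StructureModel
from betasyn.synthetic import ParametricBetaHelixSpec, make_beta_helix


def _point_cloud(seed=0, n=12, spread=8.0, offset=(30.0, 0.0, 0.0)):
    """Small random rigid body with centroid off the z-axis."""
    rng = np.random.default_rng(seed)
    coords = rng.normal(0.0, spread, (n, 3)) + np.asarray(offset)
    return StructureModel.from_arrays(
        res_ids=np.arange(1, n + 1),
        res_names=["ALA"] * n,
        atom_names=["CA"] * n,
        coords=coords,
        elements=["C"] * n,
    )


@pytest.fixture(scope="module")
def monomer():
    return _point_cloud()


# ---------------------------------------------------------------------------
# screw assembly and pitch


def test_translational_stack_spacing(monomer):
    asm = screw_assemble(monomer, HelicalParams(rise=47.0, twist=0.0, n_subunits=3))
    c = asm.centroids()
    assert np.allclose(np.diff(c[:, 2]), 47.0, atol=1e-5)
    assert measure_pitch(asm) == (math.inf, FLAT)


def test_single_copy_is_identity(monomer):
    asm = screw_assemble(monomer, HelicalParams(rise=4.8, twist=-9.0, n_subunits=1))
    assert asm.n_copies == 1
    assert np.allclose(asm.copies[0].coords, monomer.coords)


def test_pitch_closed_form(monomer):
    """twist -9 deg at 4.8 A rise: pitch 4.8*360/9 = 192 A = 19.2 nm, LHH."""
    asm = screw_assemble(monomer, HelicalParams(rise=4.8, twist=-9.0, n_subunits=10))
    pitch, handed = measure_pitch(asm)
    assert handed == LHH
    assert pitch == pytest.approx(19.2, rel=1e-3)


@pytest.mark.parametrize("seed", range(6))
def test_pitch_roundtrip_randomized(monomer, seed):
    """measure_pitch recovers randomized screw parameters to 0.1%."""
    rng = np.random.default_rng(seed)
    twist = float(rng.uniform(2.0, 30.0) * rng.choice([-1.0, 1.0]))
    rise = float(rng.uniform(2.0, 10.0))
    n = int(rng.integers(5, 12))
    params = HelicalParams(rise=rise, twist=twist, n_subunits=n)
    pitch, handed = measure_pitch(screw_assemble(monomer, params))
    assert handed == (LHH if twist < 0 else RHH)
    assert pitch == pytest.approx(params.pitch / 10.0, rel=1e-3)


def test_mirror_image_flips_handedness(monomer):
    asm = screw_assemble(monomer, HelicalParams(rise=4.8, twist=-9.0, n_subunits=8))
    mirror = AssemblyModel(
        copies=[c.transformed(np.diag([-1.0, 1.0, 1.0]), np.zeros(3))
                for c in asm.copies],
        transforms=asm.transforms,
    )
    assert measure_pitch(asm)[1] == LHH
    assert measure_pitch(mirror)[1] == RHH


def test_screw_assembly_copies_follow_generator_powers(monomer):
    params = HelicalParams(rise=6.0, twist=15.0, n_subunits=5)
    asm = screw_assemble(monomer, params)
    for k, copy in enumerate(asm.copies):
        R, t = asm.transforms[k]
        expected = monomer.coords @ R.T + t
        assert np.allclose(copy.coords, expected, atol=1e-4)


def test_pitch_needs_three_subunits(monomer):
    asm = screw_assemble(monomer, HelicalParams(rise=4.8, twist=-9.0, n_subunits=2))
    with pytest.raises(AssemblyError):
        measure_pitch(asm)


# ---------------------------------------------------------------------------
# toroids


def test_hexamer_arc_closes_into_36mer(monomer):
    """Six 60-degree hexamer arc segments close into a toroidal 36-mer."""
    params = ToroidParams(subunits_per_segment=6, arc_per_segment=60.0,
                          n_segments=6, radius=120.0)
    toroid = toroid_assemble(monomer, params)
    assert toroid.n_copies == 36
    assert toroid.provenance["closure_rmsd"] < 0.5


def test_single_subunit_ring(monomer):
    toroid = toroid_assemble(
        monomer, ToroidParams(subunits_per_segment=1, arc_per_segment=90.0,
                              n_segments=4, radius=50.0)
    )
    assert toroid.n_copies == 4


def test_non_closing_arc_raises(monomer):
    with pytest.raises(ClosureError):
        toroid_assemble(
            monomer, ToroidParams(subunits_per_segment=6, arc_per_segment=61.0,
                                  n_segments=6, radius=120.0)
        )


def test_toroid_centroids_equidistant_from_axis(monomer):
    params = ToroidParams(subunits_per_segment=6, arc_per_segment=60.0,
                          n_segments=6, radius=120.0)
    toroid = toroid_assemble(monomer, params)
    c = toroid.centroids()
    radii = np.hypot(c[:, 0], c[:, 1])
    assert radii.max() - radii.min() < 1e-3


# ---------------------------------------------------------------------------
# clashes


def test_distant_copies_do_not_clash(monomer):
    far = monomer.transformed(np.eye(3), np.array([100.0, 0.0, 0.0]))
    asm = AssemblyModel(copies=[monomer, far], transforms=[])
    assert clash_check(asm) == 0


def test_duplicated_copy_counts_self_pairs():
    """Coincident copies clash once per atom (atoms well separated)."""
    cloud = _point_cloud(seed=1, n=10, spread=20.0)
    asm = AssemblyModel(copies=[cloud, cloud], transforms=[])
    assert clash_check(asm, cutoff=2.2) == 10


def test_clash_count_matches_brute_force(monomer):
    near = monomer.transformed(np.eye(3), np.array([2.0, 1.0, 0.0]))
    asm = AssemblyModel(copies=[monomer, near], transforms=[])
    brute = sum(
        1
        for a in monomer.coords
        for b in near.coords
        if np.linalg.norm(a - b) < 3.5
    )
    assert clash_check(asm, cutoff=3.5) == brute


# ---------------------------------------------------------------------------
# substrate height


def _box_cloud(nx=5, ny=7, nz=40, sx=20.0, sy=35.0, sz=200.0):
    xs = np.linspace(0, sx, nx)
    ys = np.linspace(0, sy, ny)
    zs = np.linspace(0, sz, nz)
    pts = np.array([[x, y, z] for x in xs for y in ys for z in zs])
    n = len(pts)
    return StructureModel.from_arrays(
        res_ids=np.arange(1, n + 1), res_names=["ALA"] * n,
        atom_names=["CA"] * n, coords=pts, elements=["C"] * n,
    )


def test_substrate_height_is_smallest_extent():
    assert substrate_height(_box_cloud()) == pytest.approx(2.0, rel=1e-6)


def test_substrate_height_rotation_invariant():
    from scipy.spatial.transform import Rotation

    box = _box_cloud()
    R = Rotation.from_euler("zyx", [0.7, 0.3, 1.9]).as_matrix()
    rotated = box.transformed(R, np.array([5.0, 6.0, 7.0]))
    assert substrate_height(rotated) == pytest.approx(
        substrate_height(box), rel=1e-5
    )


def test_fiber_height_matches_generator_cross_section():
    spec = ParametricBetaHelixSpec(n_coils=2)
    fiber = screw_assemble(
        make_beta_helix(spec, seed=0),
        HelicalParams(rise=2 * spec.rise_per_coil, twist=0.0, n_subunits=20),
    )
    expected_nm = spec.cross_section_diameter / 10.0
    assert substrate_height(fiber) == pytest.approx(expected_nm, rel=0.10)


# ---------------------------------------------------------------------------
# macrodipole


def _two_charges(d=1.0):
    return StructureModel.from_arrays(
        res_ids=np.array([1, 2]),
        res_names=["LYS", "ASP"],
        atom_names=["CB", "CB"],
        coords=np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]]),
        elements=["C", "C"],
    )


def test_unit_conversion_e_angstrom_to_debye():
    """+1 e and -1 e separated by 1 A give exactly 4.8032 Debye."""
    result = macrodipole(_two_charges(1.0), ChargeModel(include_termini=False))
    assert result.magnitude == pytest.approx(4.8032, abs=1e-9)
    assert result.total_charge == 0.0


def test_neutral_dipole_translation_invariant():
    charges = ChargeModel(include_termini=False)
    a = macrodipole(_two_charges(3.0), charges)
    moved = _two_charges(3.0).transformed(np.eye(3), np.array([100.0, -50.0, 7.0]))
    b = macrodipole(moved, charges)
    assert np.allclose(a.vector, b.vector, atol=1e-6)


def test_dipole_rotation_equivariance():
    from scipy.spatial.transform import Rotation

    charges = ChargeModel(include_termini=False)
    R = Rotation.from_euler("xyz", [0.2, 1.0, -0.5]).as_matrix()
    base = _two_charges(3.0)
    a = macrodipole(base, charges)
    b = macrodipole(base.transformed(R, np.zeros(3)), charges)
    assert np.allclose(R @ a.vector, b.vector, atol=1e-6)


def _charged_monomer():
    """Monomer with both axial (z) and transverse (x) dipole components."""
    return StructureModel.from_arrays(
        res_ids=np.array([1, 2, 3, 4]),
        res_names=["LYS", "ASP", "LYS", "ASP"],
        atom_names=["CB"] * 4,
        coords=np.array(
            [[8.0, 0.0, 0.0], [2.0, 0.0, 0.0],   # +x transverse pair
             [5.0, 0.0, 6.0], [5.0, 0.0, 0.0]]   # +z axial pair
        ),
        elements=["C"] * 4,
    )


@pytest.mark.parametrize("n", [2, 4, 8])
def test_antiparallel_ribbon_transverse_dipole_grows_with_n(n):
    """Antiparallel strands: axial components cancel pairwise, transverse add."""
    mono = _charged_monomer()
    charges = ChargeModel(include_termini=False)
    mono_dip = macrodipole(mono, charges)
    ribbon = ribbon_assemble(mono, n_per_strand=n, rise=12.0,
                             configuration="antiparallel")
    dip = macrodipole(ribbon, charges)
    assert dip.orthogonal == pytest.approx(2 * n * abs(mono_dip.vector[0]), rel=1e-4)
    assert abs(dip.axial) < 0.01 * 2 * n * abs(mono_dip.axial)


def test_parallel_ribbon_transverse_dipole_cancels():
    """Parallel strands oppose their transverse charges; axial adds."""
    mono = _charged_monomer()
    charges = ChargeModel(include_termini=False)
    mono_dip = macrodipole(mono, charges)
    ribbon = ribbon_assemble(mono, n_per_strand=4, rise=12.0,
                             configuration="parallel")
    dip = macrodipole(ribbon, charges)
    assert dip.orthogonal < 0.01 * 8 * abs(mono_dip.vector[0])
    assert dip.axial == pytest.approx(8 * mono_dip.axial, rel=1e-4)


def test_reference_observables_flagging():
    ref = ReferenceObservables()
    assert ref.in_lhh_band(100.0) and not ref.in_lhh_band(50.0)
    assert ref.near_rhh_pitch(45.0) and not ref.near_rhh_pitch(90.0)
    assert ref.in_nac_height_band(3.5) and not ref.in_nac_height_band(5.0)
    assert ref.in_annulus_bands(4.0, 50.0) and not ref.in_annulus_bands(10.0, 50.0)
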