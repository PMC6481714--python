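"""Supramolecular assembly geometry: fibers, toroids, heights and dipoles.

Fibrils are modeled as screw assemblies: copy *k* of a subunit is the
subunit rotated by ``k * twist`` about the fiber axis (+z by construction)
and translated by ``k * rise`` along it.  Negative twist gives a left-handed
helix (LHH), positive a right-handed one (RHH); the pitch is
``rise * 360 / |twist|``.  Annular pore models are rings of arc segments
rotated about the toroid axis; a ring closes when the segment arcs sum to a
full turn.  Macrodipoles are estimated from integer side-chain charges at
point sites, converted at 4.8032 Debye per unit-charge Angstrom.

Reference observables from fibril imaging literature (strand dimensions,
pitch bands, heights) are packaged for in/out-of-range flagging only -- they
are checks of qualitative consistency, not fit targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from betasyn.structures import StructureModel

E_ANGSTROM_TO_DEBYE = 4.8032  # 1 e*A in Debye

LHH = "LHH"
RHH = "RHH"
FLAT = "flat"


class AssemblyError(ValueError):
    pass


class ClosureError(AssemblyError):
    """A toroid's segments do not close into a full ring."""


@dataclass(frozen=True)
class HelicalParams:
    """Screw parameters: rise (A/subunit), signed twist (deg/subunit)."""

    rise: float
    twist: float
    n_subunits: int

    def __post_init__(self) -> None:
        if self.rise <= 0:
            raise AssemblyError("rise must be positive")
        if self.n_subunits < 1:
            raise AssemblyError("need at least one subunit")

    @property
    def pitch(self) -> float:
        """Pitch in Angstroms (undefined for a flat, untwisted stack)."""
        if self.twist == 0:
            return math.inf
        return self.rise * 360.0 / abs(self.twist)

    @property
    def handedness(self) -> str:
        if self.twist == 0:
            return FLAT
        return LHH if self.twist < 0 else RHH


@dataclass(frozen=True)
class ToroidParams:
    """Ring built from arc segments; closure needs n_segments*arc = 360."""

    subunits_per_segment: int
    arc_per_segment: float
    n_segments: int
    radius: float

    def __post_init__(self) -> None:
        if self.subunits_per_segment < 1 or self.n_segments < 1:
            raise AssemblyError("segment and subunit counts must be positive")
        if self.radius <= 0:
            raise AssemblyError("radius must be positive")


def _rot_z(deg: float) -> np.ndarray:
    t = math.radians(deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_x(deg: float) -> np.ndarray:
    t = math.radians(deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


_CHAIN_IDS = [chr(c) for c in range(ord("A"), ord("Z") + 1)] + [
    a + b
    for a in "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    for b in "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
]


@dataclass
class AssemblyModel:
    """Rigid copies of a subunit with their generating transforms."""

    copies: list[StructureModel]
    transforms: list[tuple[np.ndarray, np.ndarray]]
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    provenance: dict = field(default_factory=dict)

    @property
    def n_copies(self) -> int:
        return len(self.copies)

    def centroids(self) -> np.ndarray:
        return np.array([c.centroid() for c in self.copies])

    def combined(self) -> StructureModel:
        """All copies as one structure, chain IDs A, B, C, ..."""
        import biotite.structure as struc

        arrays = []
        for k, copy in enumerate(self.copies):
            arr = copy.atoms.copy()
            arr.chain_id = np.full(arr.array_length(), _CHAIN_IDS[k], dtype="U4")
            arrays.append(arr)
        return StructureModel(struc.concatenate(arrays))

    def write_pdb(self, path) -> None:
        self.combined().write_pdb(path)


# ---------------------------------------------------------------------------
# Builders

def screw_assemble(monomer: StructureModel, params: HelicalParams) -> AssemblyModel:
    """Stack copies by the screw operator (twist about z, rise along z)."""
    copies, transforms = [], []
    for k in range(params.n_subunits):
        R = _rot_z(k * params.twist)
        t = np.array([0.0, 0.0, k * params.rise])
        copies.append(monomer.transformed(R, t))
        transforms.append((R, t))
    return AssemblyModel(
        copies=copies,
        transforms=transforms,
        provenance={"kind": "screw", "params": params},
    )


def arc_segment(
    monomer: StructureModel,
    n_subunits: int,
    arc: float,
    radius: float,
) -> AssemblyModel:
    """Place subunits along an arc about the z-axis (toroid building block).

    The monomer is first translated so its centroid sits at ``radius`` on
    the +x axis, then copy k is rotated by ``k * arc / n_subunits`` about z.
    A 6-subunit segment over a 60 degree arc is the hexamer arc used for
    annular pore models.
    """
    if n_subunits < 1:
        raise AssemblyError("need at least one subunit")
    base = monomer.transformed(
        np.eye(3), np.array([radius, 0.0, 0.0]) - monomer.centroid()
    )
    step = arc / n_subunits
    copies, transforms = [], []
    for k in range(n_subunits):
        R = _rot_z(k * step)
        copies.append(base.transformed(R, np.zeros(3)))
        transforms.append((R, np.zeros(3)))
    return AssemblyModel(
        copies=copies,
        transforms=transforms,
        provenance={"kind": "arc", "arc": arc, "radius": radius},
    )


def toroid_assemble(
    segment: AssemblyModel | StructureModel,
    params: ToroidParams,
    closure_rmsd: float = 0.5,
) -> AssemblyModel:
    """Replicate an arc segment into a closed toroid.

    ``segment`` may be a ready arc :class:`AssemblyModel` or a monomer, in
    which case the arc is built from ``params`` first.  Closure is verified
    by the RMSD between the would-be segment ``n_segments`` (one past the
    last) and segment 0; above ``closure_rmsd`` Angstroms the ring does not
    close and a :class:`ClosureError` is raised.
    """
    if isinstance(segment, StructureModel):
        segment = arc_segment(
            segment, params.subunits_per_segment, params.arc_per_segment, params.radius
        )
    seg_atoms = segment.combined()

    wrap = seg_atoms.transformed(_rot_z(params.n_segments * params.arc_per_segment),
                                 np.zeros(3))
    rmsd = float(np.sqrt(np.mean(np.sum((wrap.coords - seg_atoms.coords) ** 2, axis=1))))
    if rmsd > closure_rmsd:
        raise ClosureError(
            f"{params.n_segments} segments x {params.arc_per_segment} deg = "
            f"{params.n_segments * params.arc_per_segment} deg does not close "
            f"(closure RMSD {rmsd:.2f} A > {closure_rmsd} A)"
        )

    copies, transforms = [], []
    for s in range(params.n_segments):
        R = _rot_z(s * params.arc_per_segment)
        for copy in segment.copies:
            copies.append(copy.transformed(R, np.zeros(3)))
            transforms.append((R, np.zeros(3)))
    return AssemblyModel(
        copies=copies,
        transforms=transforms,
        provenance={"kind": "toroid", "params": params, "closure_rmsd": rmsd},
    )


def ribbon_assemble(
    monomer: StructureModel,
    n_per_strand: int,
    rise: float,
    configuration: str = "antiparallel",
    strand_offset: float = 14.0,
) -> AssemblyModel:
    """Two-stranded ribbon: a translational stack plus its C2-related mate.

    Strand A is the monomer stacked along z at ``+strand_offset/2`` in x;
    strand B is strand A rotated 180 degrees about the fiber axis z
    (``parallel``, both strands point the same way along z, transverse
    charges diametrically opposed) or about x (``antiparallel``, strands
    point opposite ways along z).  These are the two strand configurations
    whose macrodipoles behave oppositely: antiparallel ribbons add their
    transverse dipole components while axial components cancel pairwise,
    parallel ribbons the reverse.
    """
    if configuration == "parallel":
        C2 = _rot_z(180.0)
    elif configuration == "antiparallel":
        C2 = _rot_x(180.0)
    else:
        raise AssemblyError("configuration must be 'parallel' or 'antiparallel'")
    shifted = monomer.transformed(np.eye(3), np.array([strand_offset / 2.0, 0.0, 0.0]))
    copies, transforms = [], []
    for k in range(n_per_strand):
        t = np.array([0.0, 0.0, k * rise])
        copies.append(shifted.transformed(np.eye(3), t))
        transforms.append((np.eye(3), t))
    for k in range(n_per_strand):
        t = np.array([0.0, 0.0, k * rise])
        copies.append(shifted.transformed(C2, np.zeros(3)).transformed(np.eye(3), t))
        transforms.append((C2, t))
    return AssemblyModel(
        copies=copies,
        transforms=transforms,
        provenance={"kind": "ribbon", "configuration": configuration},
    )


# ---------------------------------------------------------------------------
# Measurements

def measure_pitch(
    assembly: AssemblyModel, flat_tol_deg: float = 1e-4
) -> tuple[float, str]:
    """Fit a helix to subunit centroids; return (pitch in nm, handedness).

    The helix axis is recovered as the direction along which successive
    centroid displacements have constant projection (null vector of the
    second differences); the signed twist comes from the angular steps of
    the centroids about that axis.  Collinear centroids or negligible twist
    report ``(inf, "flat")``.
    """
    if assembly.n_copies < 3:
        raise AssemblyError("pitch needs at least 3 subunits")
    c = assembly.centroids()
    d = np.diff(c, axis=0)
    dd = np.diff(d, axis=0)
    scale = float(np.abs(d).max(initial=1.0))
    if float(np.abs(dd).max(initial=0.0)) < 1e-7 * scale:
        return math.inf, FLAT  # pure translation (or collinear)

    # axis: unit vector minimizing variation of d_k . a
    _, _, vt = np.linalg.svd(dd)
    axis = vt[-1]
    rise = float(np.mean(d @ axis))
    if rise < 0:
        axis, rise = -axis, -rise

    # project centroids onto the plane orthogonal to the axis
    proj = c - np.outer(c @ axis, axis)
    # circle center by algebraic (Kasa) fit in an in-plane basis
    u = np.linalg.svd(np.vstack([axis]))[2][-1]
    u = u - (u @ axis) * axis
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    pu, pv = proj @ u, proj @ v
    A = np.column_stack([2 * pu, 2 * pv, np.ones_like(pu)])
    b = pu**2 + pv**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cu, cv = sol[0], sol[1]
    if float(np.hypot(pu - cu, pv - cv).mean()) < 1e-4 * max(1.0, rise):
        return math.inf, FLAT  # centroids (nearly) on the axis: no visible twist
    ang = np.unwrap(np.arctan2(pv - cv, pu - cu))
    twist = math.degrees(float(np.mean(np.diff(ang))))
    if abs(twist) < flat_tol_deg:
        return math.inf, FLAT
    pitch_nm = rise * 360.0 / abs(twist) / 10.0
    return pitch_nm, (LHH if twist < 0 else RHH)


def clash_check(
    assembly: AssemblyModel, cutoff: float = 2.2, include_adjacent: bool = True
) -> int:
    """Count inter-copy heavy-atom pairs closer than ``cutoff`` Angstroms."""
    heavy = []
    for copy in assembly.copies:
        mask = copy.atoms.element != "H"
        heavy.append(copy.atoms.coord[mask])
    count = 0
    for i in range(len(heavy)):
        tree = cKDTree(heavy[i])
        for j in range(i + 1, len(heavy)):
            if not include_adjacent and j == i + 1:
                continue
            count += int(tree.query_ball_point(heavy[j], cutoff, return_length=True).sum())
    return count


def substrate_height(assembly: AssemblyModel | StructureModel) -> float:
    """Minimal slab thickness of the atom cloud, in nm.

    Thickness is the extent of the atom coordinates along each principal
    axis of the cloud; the smallest of the three is the height the assembly
    would present lying flat on a substrate (as in AFM of surface-grown
    fibrils).  Rotation invariant by construction.
    """
    model = assembly.combined() if isinstance(assembly, AssemblyModel) else assembly
    x = model.coords - model.coords.mean(axis=0)
    cov = np.cov(x.T)
    _, vecs = np.linalg.eigh(cov)
    extents = [float((x @ vecs[:, k]).max() - (x @ vecs[:, k]).min()) for k in range(3)]
    return min(extents) / 10.0


# ---------------------------------------------------------------------------
# Macrodipole

@dataclass(frozen=True)
class ChargeModel:
    """Integer point charges at side-chain sites.

    D/E carry -1, K/R +1, H is neutral by default (``his_charge=0.5``
    approximates partial protonation).  Terminal charges (+1 at each chain's
    N-terminus, -1 at its C-terminus) are on by default.  The charge site is
    CB (CA for glycine or CA-only models).
    """

    his_charge: float = 0.0
    include_termini: bool = True

    def residue_charge(self, res_name: str) -> float:
        return {
            "ASP": -1.0, "GLU": -1.0, "LYS": 1.0, "ARG": 1.0,
            "HIS": self.his_charge,
        }.get(res_name, 0.0)


def _charge_sites(model: StructureModel, charges: ChargeModel) -> tuple[np.ndarray, np.ndarray]:
    """(positions, charges) of all charged sites in a structure."""
    atoms = model.atoms
    positions, qs = [], []
    for chain in model.chains():
        cmask = atoms.chain_id == chain
        rids = np.unique(atoms.res_id[cmask])
        for rid in rids:
            rmask = cmask & (atoms.res_id == rid)
            name = str(atoms.res_name[rmask][0])
            q = charges.residue_charge(name)
            if q != 0.0:
                anames = atoms.atom_name[rmask]
                site = "CB" if "CB" in anames else ("CA" if "CA" in anames else anames[0])
                positions.append(atoms.coord[rmask][anames == site][0])
                qs.append(q)
        if charges.include_termini and len(rids) > 0:
            for rid, q, pref in ((rids.min(), 1.0, ("N", "CA")),
                                 (rids.max(), -1.0, ("OXT", "C", "CA"))):
                rmask = cmask & (atoms.res_id == rid)
                anames = atoms.atom_name[rmask]
                site = next((p for p in pref if p in anames), anames[0])
                positions.append(atoms.coord[rmask][anames == site][0])
                qs.append(q)
    if not positions:
        return np.zeros((0, 3)), np.zeros(0)
    return np.array(positions), np.array(qs)


@dataclass(frozen=True)
class DipoleResult:
    vector: np.ndarray          # Debye
    magnitude: float            # Debye
    axial: float                # component along the reference axis, Debye
    orthogonal: float           # in-plane magnitude, Debye
    total_charge: float         # e


def macrodipole(
    model: AssemblyModel | StructureModel,
    charges: ChargeModel | None = None,
    axis: np.ndarray | None = None,
) -> DipoleResult:
    """Dipole moment mu = sum q_i r_i in Debye (4.8032 D per e*A).

    The origin is the center of absolute charge, which makes the dipole of
    net-charged systems well defined (and reduces to the usual convention
    for neutral ones, where the dipole is origin independent).  ``axis``
    (default: the assembly's fiber axis, +z) selects the axial/orthogonal
    decomposition.
    """
    charges = charges or ChargeModel()
    if isinstance(model, AssemblyModel):
        if axis is None:
            axis = model.axis
        model = model.combined()
    if axis is None:
        axis = np.array([0.0, 0.0, 1.0])
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)

    positions, qs = _charge_sites(model, charges)
    if len(qs) == 0:
        return DipoleResult(np.zeros(3), 0.0, 0.0, 0.0, 0.0)
    origin = (np.abs(qs)[:, None] * positions).sum(axis=0) / np.abs(qs).sum()
    mu = E_ANGSTROM_TO_DEBYE * (qs[:, None] * (positions - origin)).sum(axis=0)
    axial = float(mu @ axis)
    orth = mu - axial * axis
    return DipoleResult(
        vector=mu,
        magnitude=float(np.linalg.norm(mu)),
        axial=axial,
        orthogonal=float(np.linalg.norm(orth)),
        total_charge=float(qs.sum()),
    )


# ---------------------------------------------------------------------------
# Reference observables (flagging only)

@dataclass(frozen=True)
class ReferenceObservables:
    """Published fibril-imaging observables, for in-range flagging only.

    Units: nm.  These bands describe what imaging studies report for
    alpha-synuclein fibrils and annuli; the package uses them to flag
    whether a measured model quantity falls in the observed range, never as
    a fit target.
    """

    ds_ribbon_strand: tuple[float, float] = (4.0, 5.5)     # strand cross-section
    inter_strand_gap: float = 1.4
    afm_ribbon_height: tuple[float, float] = (5.2, 6.6)
    lhh_pitch: tuple[float, float] = (81.0, 141.0)
    rhh_pitch: float = 45.0
    annulus_height: tuple[float, float] = (3.0, 6.0)
    annulus_diameter: tuple[float, float] = (24.0, 91.0)
    nac_fibril_height: float = 3.5
    nac_fibril_height_tol: float = 0.5

    def in_lhh_band(self, pitch_nm: float) -> bool:
        lo, hi = self.lhh_pitch
        return lo <= pitch_nm <= hi

    def near_rhh_pitch(self, pitch_nm: float, rel_tol: float = 0.25) -> bool:
        return abs(pitch_nm - self.rhh_pitch) <= rel_tol * self.rhh_pitch

    def in_nac_height_band(self, height_nm: float) -> bool:
        return abs(height_nm - self.nac_fibril_height) <= self.nac_fibril_height_tol

    def in_annulus_bands(self, height_nm: float, diameter_nm: float) -> bool:
        return (
            self.annulus_height[0] <= height_nm <= self.annulus_height[1]
            and self.annulus_diameter[0] <= diameter_nm <= self.annulus_diameter[1]
        )


REFERENCE = ReferenceObservables()
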