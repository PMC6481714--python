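"""Synthetic structural inputs with known ground truth.

Three generators cover the desk-scale inputs of the pipeline:

* ``make_beta_helix`` -- an idealized parametric beta-helix (solenoid):
  a CA trace on a gently triangular helical coil (18 residues per coil,
  4.8 Angstrom rise per coil by default, left-handed-beta-helix-like
  dimensions) plus one side-chain pseudo-atom per residue, named CB, placed
  along the inward (buried columns) or outward (exposed columns) normal.
  Residue i stacks exactly on residue i + residues_per_coil.

* ``make_stack_library`` -- a library of such solenoids threaded with
  sequences sampled so stacked-pair identities follow *planted* conditional
  frequencies per burial class; the ground truth for table derivation.

* ``make_restraint_set`` -- residue-pair restraints measured from a
  structure with a chosen number of satisfied and violated entries, the
  construction oracle for satisfaction statistics.

All generators are deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from betasyn.register import BURIED, EXPOSED
from betasyn.restraints import DistanceRestraint
from betasyn.sequences import ProteinSequence
from betasyn.structures import StructureModel, one_to_three


class SyntheticError(ValueError):
    pass


_DEFAULT_MOTIF = "AVGKELSTIVNDAQHKEF"  # 18 letters, mixed charges/sizes


@dataclass(frozen=True)
class ParametricBetaHelixSpec:
    """Geometry of an idealized solenoid.

    ``radius`` is the mean CA ring radius; ``tri_amplitude`` modulates it
    three-fold for a rounded-triangular cross-section.  Each residue carries
    one side-chain pseudo-atom (named CB; a side-chain envelope stand-in,
    not a literal C-beta bond): exposed columns (odd column indices by
    default) point it outward by ``cb_length``, buried columns (even
    indices) point it inward all the way to ``core_radius`` from the
    solenoid axis, emulating side chains packing the solenoid core.
    """

    residues_per_coil: int = 18
    n_coils: int = 4
    rise_per_coil: float = 4.8
    radius: float = 11.0
    tri_amplitude: float = 0.10
    cb_length: float = 3.0
    core_radius: float = 2.0
    sequence: str | None = None
    jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.residues_per_coil < 6:
            raise SyntheticError("need at least 6 residues per coil")
        if self.n_coils < 1:
            raise SyntheticError("need at least 1 coil")
        if self.rise_per_coil <= 0 or self.radius <= 0:
            raise SyntheticError("rise and radius must be positive")
        if not 0 < self.core_radius < self.radius * (1.0 - self.tri_amplitude):
            raise SyntheticError("core_radius must lie inside the CA ring")

    @property
    def n_residues(self) -> int:
        return self.residues_per_coil * self.n_coils

    @property
    def cross_section_diameter(self) -> float:
        """Nominal outer diameter (mean CA ring + exposed pseudo-atoms), A.

        The three-fold radius modulation averages out, so this is the
        diameter the solenoid presents lying on a substrate to within a few
        percent.
        """
        return 2.0 * (self.radius + self.cb_length)

    def burial_of_column(self, column: int) -> str:
        """Burial class of a stacked column (even inward, odd outward)."""
        return BURIED if column % 2 == 0 else EXPOSED


def _resolve_sequence(spec: ParametricBetaHelixSpec) -> tuple[str, int]:
    """(letters, first residue number) long enough for the solenoid."""
    if spec.sequence is None:
        reps = -(-spec.n_residues // len(_DEFAULT_MOTIF))
        return (_DEFAULT_MOTIF * reps)[: spec.n_residues], 1
    seq = spec.sequence
    first = 1
    if isinstance(seq, ProteinSequence):
        first = seq.first_residue_number
        seq = seq.residues
    if len(seq) < spec.residues_per_coil:
        raise SyntheticError(
            f"sequence of {len(seq)} residues is shorter than one coil "
            f"({spec.residues_per_coil})"
        )
    if len(seq) < spec.n_residues:
        raise SyntheticError(
            f"sequence of {len(seq)} residues cannot thread "
            f"{spec.n_coils} coils of {spec.residues_per_coil}"
        )
    return seq[: spec.n_residues], first


def make_beta_helix(spec: ParametricBetaHelixSpec, seed: int = 0) -> StructureModel:
    """Build the idealized solenoid as a CA + pseudo-CB structure.

    Residue i and residue i + residues_per_coil sit on consecutive coils of
    the same column, with CA-CA distance exactly ``rise_per_coil`` (up to
    ``jitter_sd`` coordinate noise, default 0).
    """
    letters, first = _resolve_sequence(spec)
    rng = np.random.default_rng(seed)
    rpc = spec.residues_per_coil
    rise_per_residue = spec.rise_per_coil / rpc

    res_ids, res_names, atom_names, coords = [], [], [], []
    for i in range(spec.n_residues):
        theta = 2.0 * math.pi * i / rpc
        r = spec.radius * (1.0 + spec.tri_amplitude * math.cos(3.0 * theta))
        radial = np.array([math.cos(theta), math.sin(theta), 0.0])
        ca = r * radial + np.array([0.0, 0.0, i * rise_per_residue])
        if spec.burial_of_column(i % rpc) == BURIED:
            cb = ca - (r - spec.core_radius) * radial  # pack to the core
        else:
            cb = ca + spec.cb_length * radial
        rid = first + i
        name3 = one_to_three(letters[i])
        for atom, xyz in (("CA", ca), ("CB", cb)):
            res_ids.append(rid)
            res_names.append(name3)
            atom_names.append(atom)
            coords.append(xyz)
    coords = np.array(coords)
    if spec.jitter_sd > 0:
        coords = coords + rng.normal(0.0, spec.jitter_sd, coords.shape)
    return StructureModel.from_arrays(
        res_ids=np.array(res_ids),
        res_names=res_names,
        atom_names=atom_names,
        coords=coords,
        elements=["C"] * len(atom_names),
    )


# ---------------------------------------------------------------------------
# Planted stack libraries

@dataclass(frozen=True)
class PlantedStackLibrarySpec:
    """Target conditional frequencies P(upper | lower, burial) to plant.

    ``frequencies`` maps (aa_lower, aa_upper, burial) to probabilities; for
    every (aa_lower, burial) present the values must sum to 1.  Sequences
    are threaded column-wise as Markov chains of these conditionals, so the
    realized stacked-pair statistics converge to the planted table.
    """

    frequencies: dict[tuple[str, str, str], float]
    n_structures: int = 200
    geometry: ParametricBetaHelixSpec = field(
        default_factory=lambda: ParametricBetaHelixSpec(n_coils=16, sequence=None)
    )

    def __post_init__(self) -> None:
        if not self.frequencies:
            raise SyntheticError("no planted frequencies given")
        rows: dict[tuple[str, str], float] = {}
        for (lo, up, b), p in self.frequencies.items():
            if p < 0:
                raise SyntheticError(f"negative frequency for ({lo},{up},{b})")
            rows[(lo, b)] = rows.get((lo, b), 0.0) + p
        for (lo, b), total in rows.items():
            if abs(total - 1.0) > 1e-9:
                raise SyntheticError(
                    f"frequencies for (lower={lo}, {b}) sum to {total}, not 1"
                )

    def lowers(self, burial: str) -> list[str]:
        return sorted({lo for (lo, _, b) in self.frequencies if b == burial})

    def conditional(self, lower: str, burial: str) -> tuple[list[str], list[float]]:
        items = [
            (up, p) for (lo, up, b), p in self.frequencies.items()
            if lo == lower and b == burial
        ]
        items.sort()
        return [u for u, _ in items], [p for _, p in items]

    @classmethod
    def default(cls, n_structures: int = 200) -> "PlantedStackLibrarySpec":
        """An asymmetric 4x4 transition table per burial class."""
        buried_aas = ["A", "I", "L", "V"]
        exposed_aas = ["E", "G", "K", "S"]
        buried_p = [
            [0.40, 0.30, 0.20, 0.10],
            [0.10, 0.40, 0.30, 0.20],
            [0.20, 0.10, 0.40, 0.30],
            [0.30, 0.20, 0.10, 0.40],
        ]
        exposed_p = [
            [0.55, 0.25, 0.15, 0.05],
            [0.05, 0.55, 0.25, 0.15],
            [0.15, 0.05, 0.55, 0.25],
            [0.25, 0.15, 0.05, 0.55],
        ]
        freqs: dict[tuple[str, str, str], float] = {}
        for aas, table, burial in (
            (buried_aas, buried_p, BURIED),
            (exposed_aas, exposed_p, EXPOSED),
        ):
            for i, lo in enumerate(aas):
                for j, up in enumerate(aas):
                    freqs[(lo, up, burial)] = table[i][j]
        return cls(frequencies=freqs, n_structures=n_structures)


def make_stack_library(
    spec: PlantedStackLibrarySpec, seed: int = 0
) -> tuple[list[StructureModel], pd.DataFrame]:
    """Generate solenoids whose stacked pairs follow the planted table.

    Each structure threads one sequence: for every stacked column the rung-0
    residue is drawn uniformly from the planted lower-residue alphabet of
    that column's burial class, and each next rung from the planted
    conditional given the residue below.  Returns the structures and the
    truth table (planted conditional percentages).
    """
    rng = np.random.default_rng(seed)
    geom = spec.geometry
    rpc = geom.residues_per_coil
    structures = []
    for s in range(spec.n_structures):
        letters = [[""] * rpc for _ in range(geom.n_coils)]
        for col in range(rpc):
            burial = geom.burial_of_column(col)
            lowers = spec.lowers(burial)
            current = lowers[rng.integers(len(lowers))]
            letters[0][col] = current
            for rung in range(1, geom.n_coils):
                uppers, probs = spec.conditional(current, burial)
                current = uppers[rng.choice(len(uppers), p=np.array(probs))]
                letters[rung][col] = current
        sequence = "".join("".join(row) for row in letters)
        geom_s = ParametricBetaHelixSpec(
            residues_per_coil=rpc,
            n_coils=geom.n_coils,
            rise_per_coil=geom.rise_per_coil,
            radius=geom.radius,
            tri_amplitude=geom.tri_amplitude,
            cb_length=geom.cb_length,
            sequence=sequence,
            jitter_sd=geom.jitter_sd,
        )
        structures.append(make_beta_helix(geom_s, seed=int(rng.integers(2**31))))
    truth = pd.DataFrame(
        [
            {"aa_lower": lo, "aa_upper": up, "burial": b, "percent": 100.0 * p}
            for (lo, up, b), p in sorted(spec.frequencies.items())
        ]
    )
    return structures, truth


# ---------------------------------------------------------------------------
# Planted restraint sets

def make_restraint_set(
    structure: StructureModel,
    n_satisfied: int,
    n_violated: int,
    bound: float = 6.0,
    atom_mode: str = "CA",
    min_separation: int = 2,
    seed: int = 0,
) -> tuple[list[DistanceRestraint], pd.DataFrame]:
    """Sample residue-pair restraints with a known satisfied fraction.

    Distances are measured from the structure itself, so by construction
    exactly ``n_satisfied`` of the returned restraints are within ``bound``
    and ``n_violated`` exceed it.  Raises when the structure cannot supply
    enough pairs of either kind.
    """
    from betasyn.restraints import min_distance

    rng = np.random.default_rng(seed)
    res_ids = structure.residue_numbers().astype(int)
    pairs = [
        (int(a), int(b))
        for ai, a in enumerate(res_ids)
        for b in res_ids[ai + 1 :]
        if b - a >= min_separation
    ]
    dists = {p: min_distance(structure, p[0], p[1], atom_mode) for p in pairs}
    satisfied_pool = [p for p in pairs if dists[p] <= bound]
    violated_pool = [p for p in pairs if dists[p] > bound]
    if len(satisfied_pool) < n_satisfied:
        raise SyntheticError(
            f"structure has only {len(satisfied_pool)} pairs within {bound} A, "
            f"need {n_satisfied}"
        )
    if len(violated_pool) < n_violated:
        raise SyntheticError(
            f"structure has only {len(violated_pool)} pairs beyond {bound} A, "
            f"need {n_violated}"
        )
    chosen: list[tuple[tuple[int, int], bool]] = []
    for pool, n, flag in ((satisfied_pool, n_satisfied, True),
                          (violated_pool, n_violated, False)):
        idx = rng.choice(len(pool), size=n, replace=False)
        chosen.extend((pool[i], flag) for i in idx)
    restraints = [
        DistanceRestraint(res_i=i, res_j=j, atom_mode=atom_mode, upper_bound=bound)
        for (i, j), _ in chosen
    ]
    truth = pd.DataFrame(
        [
            {"res_i": i, "res_j": j, "distance": dists[(i, j)], "satisfied": flag}
            for (i, j), flag in chosen
        ]
    )
    return restraints, truth
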