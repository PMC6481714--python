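"""Distance-restraint satisfaction statistics against atomic structures.

Solid-state NMR on amyloid fibrils yields upper bounds (here typically
<= 6 Angstroms) on inter-residue distances, without knowing which molecular
copy in the fibril each partner belongs to.  A candidate structure satisfies
a restraint when the *minimal* distance between the two residues -- over all
atoms in the selected mode and over all chain-copy combinations, intra- and
intermolecular -- is within the bound.  The fraction of a restraint list
satisfied by a structure ("coincident" restraints) is the statistic used to
compare fibril models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from betasyn.structures import StructureModel, StructureError

ATOM_MODES = ("heavy", "CA", "CB", "sidechain")


class RestraintError(ValueError):
    pass


@dataclass(frozen=True)
class DistanceRestraint:
    """Upper bound on the minimal distance between two residues."""

    res_i: int
    res_j: int
    atom_mode: str = "heavy"
    upper_bound: float = 6.0

    def __post_init__(self) -> None:
        if self.upper_bound <= 0:
            raise RestraintError(f"upper bound must be positive, got {self.upper_bound}")
        if self.atom_mode not in ATOM_MODES:
            raise RestraintError(f"atom_mode must be one of {ATOM_MODES}")
        if self.res_i == self.res_j and self.atom_mode in ("CA", "CB"):
            raise RestraintError(
                f"restraint {self.res_i}-{self.res_j}: identical residues need an "
                f"atom mode that distinguishes atoms"
            )


def min_distance(
    model: StructureModel,
    res_i: int,
    res_j: int,
    atom_mode: str = "heavy",
    intra_only: bool = False,
) -> float:
    """Minimal distance (Angstroms) between two residues.

    The minimum runs over all atom pairs in ``atom_mode`` and over all chain
    combinations (both residues may sit on any copy); ``intra_only=True``
    restricts to same-chain pairs.  Raises if either residue is absent from
    every chain.
    """
    chains = model.chains()
    coords_i = {}
    coords_j = {}
    for chain in chains:
        try:
            coords_i[chain] = model.atom_selection(res_i, atom_mode, chain)
        except StructureError:
            pass
        try:
            coords_j[chain] = model.atom_selection(res_j, atom_mode, chain)
        except StructureError:
            pass
    if not coords_i:
        raise StructureError(f"residue {res_i} absent from every chain")
    if not coords_j:
        raise StructureError(f"residue {res_j} absent from every chain")

    best = np.inf
    for ci, xi in coords_i.items():
        for cj, xj in coords_j.items():
            if intra_only and ci != cj:
                continue
            d = cdist(xi, xj)
            if res_i == res_j and ci == cj:
                # same residue on the same copy: ignore self atom pairs
                np.fill_diagonal(d, np.inf)
            best = min(best, float(d.min()))
    if not np.isfinite(best):
        raise StructureError(
            f"no valid atom pairs for restraint {res_i}-{res_j} (mode {atom_mode})"
        )
    return best


@dataclass
class SatisfactionReport:
    """Per-restraint minimal distances and the satisfied fraction."""

    records: list[dict] = field(default_factory=list)

    @property
    def n_restraints(self) -> int:
        return len(self.records)

    @property
    def n_satisfied(self) -> int:
        return sum(1 for r in self.records if r["satisfied"])

    @property
    def fraction(self) -> float:
        if not self.records:
            raise RestraintError("empty report has no satisfied fraction")
        return self.n_satisfied / self.n_restraints

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records,
            columns=["res_i", "res_j", "atom_mode", "upper_bound",
                     "min_distance", "satisfied", "missing"],
        )

    def summary(self) -> dict:
        return {
            "n_restraints": self.n_restraints,
            "n_satisfied": self.n_satisfied,
            "fraction": self.fraction,
        }


def restraint_satisfaction(
    model: StructureModel,
    restraints: list[DistanceRestraint],
    intra_only: bool = False,
    missing: str = "unsatisfied",
) -> SatisfactionReport:
    """Evaluate a restraint list against a structure.

    A restraint is satisfied iff its minimal distance is within the upper
    bound.  Restraints referencing residues absent from the model are
    counted unsatisfied and flagged (``missing="error"`` raises instead).
    """
    if not restraints:
        raise RestraintError("restraint list is empty")
    if missing not in ("unsatisfied", "error"):
        raise RestraintError("missing must be 'unsatisfied' or 'error'")
    records = []
    for r in restraints:
        try:
            d = min_distance(model, r.res_i, r.res_j, r.atom_mode, intra_only)
            absent = False
        except StructureError:
            if missing == "error":
                raise
            d, absent = np.nan, True
        records.append(
            {
                "res_i": r.res_i,
                "res_j": r.res_j,
                "atom_mode": r.atom_mode,
                "upper_bound": r.upper_bound,
                "min_distance": d,
                "satisfied": bool(not absent and d <= r.upper_bound),
                "missing": absent,
            }
        )
    return SatisfactionReport(records)


# ---------------------------------------------------------------------------
# Restraint list I/O (plain CSV: res_i,res_j,atom_mode,upper_bound)

def read_restraints(path: str | Path, default_bound: float = 6.0,
                    default_mode: str = "heavy") -> list[DistanceRestraint]:
    df = pd.read_csv(path, comment="#")
    required = {"res_i", "res_j"}
    if not required <= set(df.columns):
        raise RestraintError(f"restraint CSV must have columns {sorted(required)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            DistanceRestraint(
                res_i=int(row.res_i),
                res_j=int(row.res_j),
                atom_mode=str(getattr(row, "atom_mode", default_mode)),
                upper_bound=float(getattr(row, "upper_bound", default_bound)),
            )
        )
    return out


def write_restraints(path: str | Path, restraints: list[DistanceRestraint]) -> None:
    pd.DataFrame(
        [
            {"res_i": r.res_i, "res_j": r.res_j, "atom_mode": r.atom_mode,
             "upper_bound": r.upper_bound}
            for r in restraints
        ]
    ).to_csv(path, index=False)
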