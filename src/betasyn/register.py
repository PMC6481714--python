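"""The beta-helix register: faces, rungs, stacked pairs and burial states.

A *register* assigns sequence positions to the geometric features of a
beta-helix (solenoid) fold: which residues form each *face* of the solenoid
cross-section, how the chain is divided into *rungs* (full coils), and which
residue pairs on consecutive rungs *stack* on top of each other, either with
their side chains buried in the solenoid core or exposed to solvent.

The packaged NAC register encodes the beta-helical model of the
alpha-synuclein NAC domain: an amphipathic face (48-51 + 63-66 + 81-83), an
alkaline face (42-45 + 57-60 + 75-78 + 93-95), a hydrophobic face (37-40 +
54-56 + 69-72 + 87-92) plus NT/CT bases, with six annotated stacked pairs.
Amphipathic-face pairs stack buried, alkaline-face pairs stack exposed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from betasyn.sequences import ProteinSequence

BURIED = "buried"
EXPOSED = "exposed"
_BURIAL_STATES = (BURIED, EXPOSED)

FACE_NAMES = ("amphipathic", "alkaline", "hydrophobic", "NT_base", "CT_base")


class RegisterError(ValueError):
    """Raised when a register violates its structural invariants."""


@dataclass(frozen=True)
class Face:
    """A named face of the solenoid, as disjoint residue-number ranges."""

    name: str
    segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.name not in FACE_NAMES:
            raise RegisterError(f"unknown face name {self.name!r}; expected one of {FACE_NAMES}")
        for start, stop in self.segments:
            if stop < start:
                raise RegisterError(f"face {self.name}: segment {start}-{stop} reversed")
        spans = sorted(self.segments)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise RegisterError(
                    f"face {self.name}: overlapping segments {s1}-{e1} and {s2}-{e2}"
                )

    def contains(self, position: int) -> bool:
        return any(start <= position <= stop for start, stop in self.segments)

    @property
    def positions(self) -> list[int]:
        out: list[int] = []
        for start, stop in sorted(self.segments):
            out.extend(range(start, stop + 1))
        return out


@dataclass(frozen=True)
class StackedPair:
    """Two residues on consecutive rungs predicted to align vertically.

    ``pos_upper`` is the partner one rung toward the C-terminus, so
    ``pos_upper > pos_lower``.  ``burial`` states whether the stacked side
    chains point into the solenoid core or to solvent.
    """

    pos_lower: int
    pos_upper: int
    burial: str

    def __post_init__(self) -> None:
        if self.pos_upper <= self.pos_lower:
            raise RegisterError(
                f"stacked pair ({self.pos_lower},{self.pos_upper}): upper must exceed lower"
            )
        if self.burial not in _BURIAL_STATES:
            raise RegisterError(f"burial must be one of {_BURIAL_STATES}, got {self.burial!r}")


@dataclass(frozen=True)
class BetaHelixRegister:
    """Faces, rungs and stacked pairs of one beta-helix register.

    ``rungs`` is an optional ordered list of residue-number ranges, one per
    solenoid coil; when present, every stacked pair must span consecutive
    rungs.
    """

    faces: tuple[Face, ...] = field(default_factory=tuple)
    stacked_pairs: tuple[StackedPair, ...] = field(default_factory=tuple)
    rungs: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.validate()

    # -- queries ----------------------------------------------------------
    def face_of(self, position: int) -> Face | None:
        for face in self.faces:
            if face.contains(position):
                return face
        return None

    def rung_of(self, position: int) -> int | None:
        for k, (start, stop) in enumerate(self.rungs):
            if start <= position <= stop:
                return k
        return None

    # -- validation -------------------------------------------------------
    def validate(self, sequence: ProteinSequence | None = None) -> None:
        """Check all structural invariants; raise :class:`RegisterError`.

        With ``sequence`` given, additionally checks every face segment and
        stacked-pair position against the sequence bounds.
        """
        seen: dict[int, str] = {}
        for face in self.faces:
            for pos in face.positions:
                if pos in seen:
                    raise RegisterError(
                        f"residue {pos} assigned to both faces {seen[pos]!r} and {face.name!r}"
                    )
                seen[pos] = face.name

        lowers: set[int] = set()
        uppers: set[int] = set()
        burial_by_pos: dict[int, str] = {}
        for pair in self.stacked_pairs:
            for pos in (pair.pos_lower, pair.pos_upper):
                if self.faces and self.face_of(pos) is None:
                    raise RegisterError(
                        f"stacked-pair position {pos} lies outside every face segment"
                    )
            if pair.pos_lower in lowers:
                raise RegisterError(f"position {pair.pos_lower} is lower partner of two pairs")
            if pair.pos_upper in uppers:
                raise RegisterError(f"position {pair.pos_upper} is upper partner of two pairs")
            lowers.add(pair.pos_lower)
            uppers.add(pair.pos_upper)
            # burial constant within a stacked column: positions shared by
            # chained pairs must carry the same burial state
            for pos in (pair.pos_lower, pair.pos_upper):
                if pos in burial_by_pos and burial_by_pos[pos] != pair.burial:
                    raise RegisterError(
                        f"burial conflict at residue {pos}: "
                        f"{burial_by_pos[pos]} vs {pair.burial}"
                    )
                burial_by_pos[pos] = pair.burial
            if self.rungs:
                rl, ru = self.rung_of(pair.pos_lower), self.rung_of(pair.pos_upper)
                if rl is None or ru is None or ru != rl + 1:
                    raise RegisterError(
                        f"stacked pair ({pair.pos_lower},{pair.pos_upper}) does not span "
                        f"consecutive rungs (got rungs {rl} and {ru})"
                    )
        if sequence is not None:
            for face in self.faces:
                for start, stop in face.segments:
                    for pos in (start, stop):
                        if not sequence.contains(pos):
                            raise RegisterError(
                                f"face {face.name}: residue {pos} outside sequence "
                                f"{sequence.first_residue_number}-{sequence.last_residue_number}"
                            )
            for pair in self.stacked_pairs:
                for pos in (pair.pos_lower, pair.pos_upper):
                    if not sequence.contains(pos):
                        raise RegisterError(f"stacked-pair residue {pos} outside sequence")


# ---------------------------------------------------------------------------
# Serialization (JSON)

def _register_to_dict(register: BetaHelixRegister) -> dict:
    return {
        "faces": [
            {"name": f.name, "segments": [list(s) for s in f.segments]}
            for f in register.faces
        ],
        "stacked_pairs": [
            [p.pos_lower, p.pos_upper, p.burial] for p in register.stacked_pairs
        ],
        "rungs": [list(r) for r in register.rungs],
    }


def _register_from_dict(data: dict) -> BetaHelixRegister:
    faces = tuple(
        Face(name=f["name"], segments=tuple(tuple(s) for s in f["segments"]))
        for f in data.get("faces", [])
    )
    pairs = tuple(
        StackedPair(pos_lower=int(p[0]), pos_upper=int(p[1]), burial=str(p[2]))
        for p in data.get("stacked_pairs", [])
    )
    rungs = tuple(tuple(r) for r in data.get("rungs", []))
    return BetaHelixRegister(faces=faces, stacked_pairs=pairs, rungs=rungs)


def load_register(path: str | Path, sequence: ProteinSequence | None = None) -> BetaHelixRegister:
    """Load and validate a register from a JSON config file."""
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise RegisterError(f"cannot parse register config {path}: {exc}") from exc
    register = _register_from_dict(data)
    register.validate(sequence)
    return register


def save_register(register: BetaHelixRegister, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(_register_to_dict(register), fh, indent=1)
        fh.write("\n")


def stacked_residues(
    register: BetaHelixRegister, seq: ProteinSequence
) -> list[tuple[str, str, str]]:
    """Resolve residue identities of every stacked pair.

    Returns one ``(aa_lower, aa_upper, burial)`` tuple per pair, in register
    order.  Raises if a pair position falls outside the sequence.
    """
    return [
        (seq.residue_at(p.pos_lower), seq.residue_at(p.pos_upper), p.burial)
        for p in register.stacked_pairs
    ]


def _data_path(name: str) -> Path:
    return Path(resources.files("betasyn").joinpath("data", name))


def nac_register() -> BetaHelixRegister:
    """The packaged beta-helix register of the NAC domain (six stacked pairs)."""
    return load_register(_data_path("nac_register.json"))
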