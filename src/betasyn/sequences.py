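"""Protein sequences with full-length alpha-synuclein numbering, and mutations.

Residue numbering is 1-based full-length numbering throughout the package:
truncated constructs keep the numbers of the parent protein, so the NAC
construct (residues 30-99) still calls its first residue 30.  This matches
the conventional mutation nomenclature (K43D, A53T, ...) used for
alpha-synuclein.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


class SequenceError(ValueError):
    """Raised for invalid sequences, numbering, or mutations."""


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid sequence with an explicit numbering offset.

    Parameters
    ----------
    id : str
        Identifier (FASTA header).
    residues : str
        One-letter amino-acid string (canonical 20 letters).
    first_residue_number : int
        Number of the first residue in full-length numbering (default 1).
    """

    id: str
    residues: str
    first_residue_number: int = 1

    def __post_init__(self) -> None:
        bad = set(self.residues) - _AA_SET
        if bad:
            raise SequenceError(
                f"non-canonical residue letters in {self.id!r}: {sorted(bad)}"
            )
        if len(self.residues) == 0:
            raise SequenceError(f"empty sequence {self.id!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def last_residue_number(self) -> int:
        return self.first_residue_number + len(self.residues) - 1

    def index_of(self, position: int) -> int:
        """0-based index of residue number ``position``."""
        idx = position - self.first_residue_number
        if not 0 <= idx < len(self.residues):
            raise SequenceError(
                f"residue {position} outside {self.id!r} "
                f"({self.first_residue_number}-{self.last_residue_number})"
            )
        return idx

    def residue_at(self, position: int) -> str:
        return self.residues[self.index_of(position)]

    def contains(self, position: int) -> bool:
        return self.first_residue_number <= position <= self.last_residue_number

    def subsequence(self, start: int, stop: int, id: str | None = None) -> "ProteinSequence":
        """Slice by residue numbers (inclusive), keeping parent numbering."""
        i, j = self.index_of(start), self.index_of(stop)
        if j < i:
            raise SequenceError(f"stop {stop} precedes start {start}")
        return ProteinSequence(
            id=id or f"{self.id}_{start}-{stop}",
            residues=self.residues[i : j + 1],
            first_residue_number=start,
        )


@dataclass(frozen=True)
class Mutation:
    """A point substitution in conventional ``K43D`` notation."""

    position: int
    wildtype: str
    mutant: str

    @classmethod
    def parse(cls, token: str) -> "Mutation":
        m = _MUTATION_RE.match(token.strip())
        if not m:
            raise SequenceError(f"cannot parse mutation token {token!r}")
        wt, pos, mut = m.groups()
        if wt not in _AA_SET or mut not in _AA_SET:
            raise SequenceError(f"non-canonical letters in mutation {token!r}")
        return cls(position=int(pos), wildtype=wt, mutant=mut)

    def __str__(self) -> str:
        return f"{self.wildtype}{self.position}{self.mutant}"

    @property
    def inverse(self) -> "Mutation":
        return Mutation(self.position, self.mutant, self.wildtype)


@dataclass(frozen=True)
class MutationSet:
    """An ordered set of point mutations with unique positions."""

    mutations: tuple[Mutation, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        positions = [m.position for m in self.mutations]
        if len(positions) != len(set(positions)):
            raise SequenceError(f"duplicate positions in mutation set: {positions}")

    @classmethod
    def parse(cls, text: str) -> "MutationSet":
        """Parse ``"K43D;V48I"`` (``;``, ``,`` or whitespace separated)."""
        tokens = [t for t in re.split(r"[;,\s]+", text.strip()) if t]
        return cls(tuple(Mutation.parse(t) for t in tokens))

    def __iter__(self):
        return iter(self.mutations)

    def __len__(self) -> int:
        return len(self.mutations)

    @property
    def inverse(self) -> "MutationSet":
        return MutationSet(tuple(m.inverse for m in self.mutations))

    @property
    def positions(self) -> frozenset[int]:
        return frozenset(m.position for m in self.mutations)

    def __str__(self) -> str:
        return ";".join(str(m) for m in self.mutations)


def apply_mutations(seq: ProteinSequence, muts: MutationSet) -> ProteinSequence:
    """Return a new sequence with the substitutions applied.

    The stated wildtype letter of every mutation must match the sequence;
    a mismatch raises :class:`SequenceError` naming the position.
    """
    residues = list(seq.residues)
    for m in muts:
        idx = seq.index_of(m.position)
        if residues[idx] != m.wildtype:
            raise SequenceError(
                f"wildtype mismatch at {m.position}: sequence has "
                f"{residues[idx]}, mutation {m} expects {m.wildtype}"
            )
        residues[idx] = m.mutant
    new_id = seq.id if len(muts) == 0 else f"{seq.id}^{muts}"
    return ProteinSequence(
        id=new_id, residues="".join(residues),
        first_residue_number=seq.first_residue_number,
    )


# ---------------------------------------------------------------------------
# FASTA I/O

def read_fasta(path: str | Path, first_residue_number: int = 1) -> list[ProteinSequence]:
    """Read sequences from a FASTA file.

    A header suffix ``/start-stop`` (e.g. ``NAC/30-99``) overrides
    ``first_residue_number`` for that record.
    """
    import biotite.sequence.io.fasta as fasta

    records = []
    for header, seq in fasta.FastaFile.read(str(path)).items():
        start = first_residue_number
        m = re.search(r"/(\d+)-(\d+)\s*$", header)
        if m:
            start = int(m.group(1))
        records.append(
            ProteinSequence(id=header.split()[0], residues=str(seq).upper(),
                            first_residue_number=start)
        )
    return records


def write_fasta(path: str | Path, sequences: list[ProteinSequence]) -> None:
    import biotite.sequence.io.fasta as fasta

    f = fasta.FastaFile()
    for s in sequences:
        header = s.id
        if s.first_residue_number != 1 and "/" not in header:
            header = f"{s.id}/{s.first_residue_number}-{s.last_residue_number}"
        f[header] = s.residues
    f.write(str(path))


# ---------------------------------------------------------------------------
# Packaged fixtures

def _data_path(name: str) -> Path:
    return Path(resources.files("betasyn").joinpath("data", name))


def alpha_synuclein() -> ProteinSequence:
    """Full-length human alpha-synuclein (140 residues, UniProt P37840)."""
    (seq,) = read_fasta(_data_path("alpha_synuclein.fasta"))
    return seq


def nac_sequence() -> ProteinSequence:
    """The NAC construct: alpha-synuclein residues 30-99, parent numbering."""
    return alpha_synuclein().subsequence(30, 99, id="NAC")


DNAC_MUTATIONS = MutationSet.parse("K43D;V48I;K58P;V63R")


def dnac_sequence() -> ProteinSequence:
    """The designed quadruple mutant NAC(30-99) K43D/V48I/K58P/V63R."""
    return apply_mutations(nac_sequence(), DNAC_MUTATIONS)
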