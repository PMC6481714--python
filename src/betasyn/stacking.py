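"""Conditional stacking-propensity tables and register scoring.

In a beta-helix, residue *i* on one rung sits directly below residue *j* on
the next rung.  Surveys of solved beta-helix structures yield conditional
probabilities P(upper residue | lower residue, burial class) for such stacked
pairs -- the BETAWRAP-style propensities used here to score a register and to
design destabilizing mutations.  A register's score is the product of its
stacked-pair propensities (accumulated in log space), so the fold-change of a
mutation set is the product of the per-pair wildtype/mutant ratios; pairs the
mutations do not touch cancel exactly.

``derive_table`` re-derives such a table from a structure library: stacked
pairs are detected geometrically (``detect_stacks``), classified buried or
exposed by relative side-chain solvent accessibility, counted with a Laplace
pseudocount, and normalized to conditional percentages.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from betasyn.register import BURIED, EXPOSED, BetaHelixRegister, StackedPair
from betasyn.sequences import AMINO_ACIDS, MutationSet, ProteinSequence, apply_mutations
from betasyn.structures import StructureModel

_BURIALS = (BURIED, EXPOSED)
_AA_SET = frozenset(AMINO_ACIDS)


class StackingError(ValueError):
    pass


class MissingEntryWarning(UserWarning):
    """Emitted when a lookup falls back to the pseudocount floor."""


@dataclass
class StackingTable:
    """Directional stacking propensities keyed by (aa_lower, aa_upper, burial).

    Scores are positive reals in the units of their source ("published units"
    for the packaged exemplar table, percent for derived tables).  Missing
    entries resolve to the pseudocount floor
    ``pseudocount / (20 + total_count) * 100`` with a warning, so products
    over pairs stay strictly positive.
    """

    entries: dict[tuple[str, str, str], float]
    source: str = "unspecified"
    pseudocount: float = 1.0
    total_count: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (lo, up, burial), score in self.entries.items():
            if lo not in _AA_SET or up not in _AA_SET:
                raise StackingError(f"invalid amino-acid letters in entry ({lo},{up},{burial})")
            if burial not in _BURIALS:
                raise StackingError(f"invalid burial {burial!r} in table entry")
            if self.pseudocount > 0 and score <= 0:
                raise StackingError(
                    f"non-positive score {score} for ({lo},{up},{burial}) "
                    f"with pseudocount {self.pseudocount}"
                )

    @property
    def floor(self) -> float:
        return self.pseudocount / (20.0 + self.total_count) * 100.0

    def lookup(self, aa_lower: str, aa_upper: str, burial: str) -> float:
        """Score of one stacked pair; missing entries return the floor."""
        if aa_lower not in _AA_SET:
            raise StackingError(f"invalid amino-acid letter {aa_lower!r}")
        if aa_upper not in _AA_SET:
            raise StackingError(f"invalid amino-acid letter {aa_upper!r}")
        if burial not in _BURIALS:
            raise StackingError(f"invalid burial class {burial!r}")
        key = (aa_lower, aa_upper, burial)
        if key in self.entries:
            return self.entries[key]
        warnings.warn(
            f"no table entry for ({aa_lower},{aa_upper},{burial}); "
            f"using pseudocount floor {self.floor:g}",
            MissingEntryWarning,
            stacklevel=2,
        )
        return self.floor

    # -- serialization ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"aa_lower": lo, "aa_upper": up, "burial": b, "score": s}
            for (lo, up, b), s in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["aa_lower", "aa_upper", "burial", "score"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        import json

        payload = {
            "source": self.source,
            "pseudocount": self.pseudocount,
            "total_count": self.total_count,
            "entries": [
                {"aa_lower": lo, "aa_upper": up, "burial": b, "score": s}
                for (lo, up, b), s in sorted(self.entries.items())
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_tsv(cls, path: str | Path, source: str | None = None, **kwargs) -> "StackingTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        entries = {
            (r.aa_lower, r.aa_upper, r.burial): float(r.score)
            for r in df.itertuples(index=False)
        }
        return cls(entries=entries, source=source or str(path), **kwargs)

    @classmethod
    def from_json(cls, path: str | Path) -> "StackingTable":
        import json

        with open(path) as fh:
            payload = json.load(fh)
        entries = {
            (e["aa_lower"], e["aa_upper"], e["burial"]): float(e["score"])
            for e in payload["entries"]
        }
        return cls(
            entries=entries,
            source=payload.get("source", str(path)),
            pseudocount=payload.get("pseudocount", 1.0),
            total_count=payload.get("total_count", 0),
        )


def exemplar_table() -> StackingTable:
    """The packaged exemplar propensity table used for the DNAC design."""
    path = Path(resources.files("betasyn").joinpath("data", "stacking_table.tsv"))
    return StackingTable.from_tsv(path, source="packaged exemplar table")


# ---------------------------------------------------------------------------
# Register scoring

@dataclass(frozen=True)
class RegisterScore:
    """Product score of a register's stacked pairs, kept in log space."""

    log_score: float
    per_pair: tuple[tuple[StackedPair, float], ...]

    @property
    def score(self) -> float:
        return math.exp(self.log_score)


def score_register(
    table: StackingTable, seq: ProteinSequence, register: BetaHelixRegister
) -> RegisterScore:
    """Score = product over stacked pairs of the table lookups.

    An empty register scores 1 (empty product).  Accumulation is in log
    space so long registers cannot underflow.
    """
    register.validate(seq)
    log_score = 0.0
    per_pair: list[tuple[StackedPair, float]] = []
    for pair in register.stacked_pairs:
        contrib = table.lookup(
            seq.residue_at(pair.pos_lower), seq.residue_at(pair.pos_upper), pair.burial
        )
        per_pair.append((pair, contrib))
        log_score += math.log(contrib)
    return RegisterScore(log_score=log_score, per_pair=tuple(per_pair))


def mutation_fold_change(
    table: StackingTable,
    seq: ProteinSequence,
    register: BetaHelixRegister,
    muts: MutationSet,
) -> float:
    """Fold-reduction score(wildtype)/score(mutant) of a mutation set.

    Only stacked pairs touching a mutated position contribute; all other
    pairs cancel exactly, so unprinted table entries for untouched pairs are
    never queried.  Values > 1 mean the mutations destabilize the register.
    """
    mutant = apply_mutations(seq, muts)
    touched = muts.positions
    log_fold = 0.0
    for pair in register.stacked_pairs:
        if pair.pos_lower in touched or pair.pos_upper in touched:
            wt = table.lookup(
                seq.residue_at(pair.pos_lower), seq.residue_at(pair.pos_upper), pair.burial
            )
            mu = table.lookup(
                mutant.residue_at(pair.pos_lower),
                mutant.residue_at(pair.pos_upper),
                pair.burial,
            )
            log_fold += math.log(wt) - math.log(mu)
    return math.exp(log_fold)


def scan_mutations(
    table: StackingTable,
    seq: ProteinSequence,
    register: BetaHelixRegister,
    positions: list[int],
    alphabet: str = AMINO_ACIDS,
) -> pd.DataFrame:
    """Fold-change matrix of single substitutions (positions x alphabet).

    Entry (p, a) is ``mutation_fold_change`` for the lone substitution p->a;
    the wildtype letter scores exactly 1.  Values below 1 flag stabilizing
    substitutions (mutant more probable than wildtype), as for the familial
    mutations E46K/H50Q/G51D/A53T discussed in the package docs.
    """
    from betasyn.sequences import Mutation

    in_register = {p.pos_lower for p in register.stacked_pairs} | {
        p.pos_upper for p in register.stacked_pairs
    }
    rows = {}
    for pos in positions:
        if pos not in in_register:
            raise StackingError(f"position {pos} is not part of any stacked pair")
        wt = seq.residue_at(pos)
        row = {}
        for aa in alphabet:
            if aa == wt:
                row[aa] = 1.0
            else:
                muts = MutationSet((Mutation(pos, wt, aa),))
                row[aa] = mutation_fold_change(table, seq, register, muts)
        rows[pos] = row
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Geometric stack detection and table derivation

def detect_stacks(
    structure: StructureModel,
    ca_cutoff: float = 5.5,
    min_separation: int = 10,
    min_parallel_dot: float = 0.5,
) -> list[tuple[int, int]]:
    """Detect stacked residue pairs on consecutive solenoid rungs.

    A pair (i, j), i < j, is stacked when the CA-CA distance is at most
    ``ca_cutoff`` Angstroms, the sequence separation is at least
    ``min_separation`` residues, and the local backbone direction vectors
    CA(i+1)-CA(i-1) and CA(j+1)-CA(j-1) have a normalized dot product above
    ``min_parallel_dot`` (parallel strands).  Residues without a CA atom are
    skipped with a warning.
    """
    from scipy.spatial import cKDTree

    res_ids, coords = structure.ca_trace(warn_missing=True)
    if len(res_ids) == 0:
        return []
    order = np.argsort(res_ids)
    res_ids = res_ids[order]
    coords = coords[order]
    index_of = {rid: k for k, rid in enumerate(res_ids)}

    def direction(k: int) -> np.ndarray | None:
        # central difference where possible, one-sided at chain ends
        rid = res_ids[k]
        prev_k = index_of.get(rid - 1, k)
        next_k = index_of.get(rid + 1, k)
        if prev_k == next_k:
            return None  # isolated residue
        d = coords[next_k] - coords[prev_k]
        n = np.linalg.norm(d)
        return d / n if n > 0 else None

    tree = cKDTree(coords)
    pairs: list[tuple[int, int]] = []
    for ki, kj in sorted(tree.query_pairs(ca_cutoff)):
        ri, rj = int(res_ids[ki]), int(res_ids[kj])
        if abs(rj - ri) < min_separation:
            continue
        di, dj = direction(ki), direction(kj)
        if di is None or dj is None:
            continue
        if float(di @ dj) > min_parallel_dot:
            pairs.append((min(ri, rj), max(ri, rj)))
    return sorted(pairs)


def _relative_sidechain_sasa(structure: StructureModel, probe: float = 1.4,
                             point_number: int = 200) -> dict[int, float]:
    """Relative SASA of each residue's side-chain pseudo-atom (CB, else CA).

    Normalized by the surface of an isolated carbon sphere, so 1.0 means
    fully exposed.  Shrake-Rupley style with single-element radii.
    """
    import biotite.structure as struc

    atoms = structure.atoms
    sasa = struc.sasa(atoms, probe_radius=probe, vdw_radii="Single",
                      point_number=point_number)
    # reference: isolated carbon sphere (single radius 1.7 A)
    max_area = 4.0 * math.pi * (1.7 + probe) ** 2
    out: dict[int, float] = {}
    for rid in np.unique(atoms.res_id):
        mask = atoms.res_id == rid
        names = atoms.atom_name[mask]
        vals = sasa[mask]
        if "CB" in names:
            area = float(vals[names == "CB"][0])
        elif "CA" in names:
            area = float(vals[names == "CA"][0])
        else:
            continue
        out[int(rid)] = area / max_area
    return out


def derive_table(
    library: list[StructureModel],
    pseudocount: float = 1.0,
    sasa_threshold: float = 0.2,
    ca_cutoff: float = 5.5,
    min_separation: int = 10,
    min_parallel_dot: float = 0.5,
    sasa_points: int = 200,
) -> StackingTable:
    """Derive conditional stacking propensities from a structure library.

    For each structure, stacked pairs are detected geometrically, each pair
    is classified buried when the mean relative side-chain SASA of the two
    partners is below ``sasa_threshold``, and (aa_lower, aa_upper, burial)
    occurrences are counted.  Counts get a Laplace pseudocount over the
    20-letter alphabet and are normalized to conditional probabilities
    P(aa_upper | aa_lower, burial), reported in percent.
    """
    if not library:
        raise StackingError("cannot derive a table from an empty library")

    counts: dict[tuple[str, str, str], int] = {}
    total = 0
    for k, structure in enumerate(library):
        pairs = detect_stacks(structure, ca_cutoff, min_separation, min_parallel_dot)
        if not pairs:
            warnings.warn(f"structure {k}: no detectable rungs; skipped", stacklevel=2)
            continue
        rel_sasa = _relative_sidechain_sasa(structure, point_number=sasa_points)
        one_letter = structure.residue_letters()
        for ri, rj in pairs:
            if ri not in one_letter or rj not in one_letter:
                continue
            mean_sasa = 0.5 * (rel_sasa.get(ri, 1.0) + rel_sasa.get(rj, 1.0))
            burial = BURIED if mean_sasa < sasa_threshold else EXPOSED
            key = (one_letter[ri], one_letter[rj], burial)
            counts[key] = counts.get(key, 0) + 1
            total += 1

    if total == 0:
        raise StackingError("no stacked pairs detected anywhere in the library")

    entries: dict[tuple[str, str, str], float] = {}
    rows = {(lo, b) for (lo, _, b) in counts}
    for lo, b in rows:
        row_total = sum(c for (l2, _, b2), c in counts.items() if l2 == lo and b2 == b)
        denom = row_total + 20.0 * pseudocount
        for up in AMINO_ACIDS:
            c = counts.get((lo, up, b), 0)
            p = (c + pseudocount) / denom * 100.0
            if p > 0:
                entries[(lo, up, b)] = p
    return StackingTable(
        entries=entries,
        source=f"derived from {len(library)} structures",
        pseudocount=pseudocount,
        total_count=total,
        metadata={
            "sasa_threshold": sasa_threshold,
            "ca_cutoff": ca_cutoff,
            "min_separation": min_separation,
            "min_parallel_dot": min_parallel_dot,
        },
    )
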