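import numpy as np
import pytest

from betasyn.register import nac_register
from betasyn.sequences import alpha_synuclein, nac_sequence
from betasyn.stacking import derive_table, exemplar_table
from betasyn.synthetic import (
    ParametricBetaHelixSpec,
    PlantedStackLibrarySpec,
    make_beta_helix,
    make_stack_library,
)


@pytest.fixture(scope="session")
def asyn():
    return alpha_synuclein()


@pytest.fixture(scope="session")
def nac():
    return nac_sequence()


@pytest.fixture(scope="session")
def register():
    return nac_register()


@pytest.fixture(scope="session")
def table():
    return exemplar_table()


@pytest.fixture(scope="session")
def solenoid():
    """Default 4-coil idealized beta-helix (72 residues, CA + pseudo-CB)."""
    return make_beta_helix(ParametricBetaHelixSpec(), seed=11)


@pytest.fixture(scope="session")
def planted_recovery():
    """Derived-vs-planted table comparison on the 200-structure library.

    Computed once per session (it is the most expensive fixture) and shared
    between the synthetic-data tests and the acceptance suite.
    """
    spec = PlantedStackLibrarySpec.default(n_structures=200)
    library, truth = make_stack_library(spec, seed=7)
    derived = derive_table(library)
    errors = {}
    for row in truth.itertuples(index=False):
        key = (row.aa_lower, row.aa_upper, row.burial)
        errors[key] = derived.entries.get(key, 0.0) - row.percent
    return {"derived": derived, "truth": truth, "errors": errors}


def brute_force_min_distance(model, res_i, res_j, atom_mode="heavy"):
    """Independent double-loop oracle for minimal inter-residue distance."""
    best = np.inf
    for ci in model.chains():
        for cj in model.chains():
            try:
                xi = model.atom_selection(res_i, atom_mode, ci)
                xj = model.atom_selection(res_j, atom_mode, cj)
            except Exception:
                continue
            for a in xi:
                for b in xj:
                    if res_i == res_j and ci == cj and np.allclose(a, b):
                        continue
                    best = min(best, float(np.linalg.norm(a - b)))
    return best


def brute_force_stacks(structure, ca_cutoff=5.5, min_separation=10, min_dot=0.5):
    """All-pairs oracle for stack detection under the same three criteria."""
    res_ids, coords = structure.ca_trace()
    order = np.argsort(res_ids)
    res_ids, coords = res_ids[order], coords[order]
    idx = {int(r): k for k, r in enumerate(res_ids)}

    def direction(rid):
        prev_k = idx.get(rid - 1, idx[rid])
        next_k = idx.get(rid + 1, idx[rid])
        if prev_k == next_k:
            return None
        d = coords[next_k] - coords[prev_k]
        return d / np.linalg.norm(d)

    pairs = []
    for a in range(len(res_ids)):
        for b in range(a + 1, len(res_ids)):
            ri, rj = int(res_ids[a]), int(res_ids[b])
            if rj - ri < min_separation:
                continue
            if np.linalg.norm(coords[a] - coords[b]) > ca_cutoff:
                continue
            di, dj = direction(ri), direction(rj)
            if di is None or dj is None:
                continue
            if float(di @ dj) > min_dot:
                pairs.append((ri, rj))
    return sorted(pairs)
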