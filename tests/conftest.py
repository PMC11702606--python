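"""Shared fixtures: hand-built models, the study-scale toy complex, and
brute-force oracles kept deliberately independent of the library's
KD-tree code paths."""

from __future__ import annotations

import numpy as np
import pytest
import biotite.structure as struc

from mhcgroove.structure import StructureModel
from mhcgroove.synthetic import make_toy_complex, study_complex_spec


def build_model(atoms, model_id="test"):
    """Build a StructureModel from rows of
    (chain_id, res_id, res_name, atom_name, element, (x, y, z))."""
    n = len(atoms)
    arr = struc.AtomArray(n)
    arr._coord = np.array([a[5] for a in atoms], dtype=np.float64)
    arr.chain_id = np.array([a[0] for a in atoms])
    arr.res_id = np.array([a[1] for a in atoms])
    arr.ins_code = np.full(n, "")
    arr.res_name = np.array([a[2] for a in atoms])
    arr.atom_name = np.array([a[3] for a in atoms])
    arr.element = np.array([a[4] for a in atoms])
    arr.hetero = np.full(n, False)
    return StructureModel(id=model_id, atoms=arr)


def poly_ala_chain(chain_id, n_res, origin=(0.0, 0.0, 0.0), spacing=6.0,
                   start_res=1, axis=(1.0, 0.0, 0.0)):
    """Rows for an n-residue poly-alanine line of CA atoms."""
    origin = np.asarray(origin, float)
    axis = np.asarray(axis, float)
    rows = []
    for i in range(n_res):
        xyz = tuple(origin + i * spacing * axis)
        rows.append((chain_id, start_res + i, "ALA", "CA", "C", xyz))
    return rows


def random_two_chain_model(rng, n_a=20, n_b=20, box=12.0, min_dist=1.8):
    """Two chains of single-carbon residues scattered in adjacent boxes."""
    rows = []

    def sample(n, chain, offset):
        pts = []
        while len(pts) < n:
            p = rng.uniform(0, box, size=3) + offset
            if all(np.linalg.norm(p - q) >= min_dist for q in pts):
                pts.append(p)
        for i, p in enumerate(pts):
            rows.append((chain, i + 1, "ALA", "CA", "C", tuple(p)))

    sample(n_a, "A", np.zeros(3))
    sample(n_b, "B", np.array([box * 0.7, 0.0, 0.0]))
    return build_model(rows, model_id="random")


def brute_force_contact_pairs(model, roles, query_roles, target_roles,
                              cutoff):
    """All-pairs O(n^2) contact oracle on heavy protein atoms."""
    a = model.atoms
    aa_mask = struc.filter_amino_acids(a)
    query_idx = [
        i for i in range(a.array_length())
        if roles.get(str(a.chain_id[i])) in set(query_roles)
        and aa_mask[i] and not a.hetero[i] and str(a.element[i]) != "H"
    ]
    target_idx = [
        i for i in range(a.array_length())
        if roles.get(str(a.chain_id[i])) in set(target_roles)
        and aa_mask[i] and not a.hetero[i] and str(a.element[i]) != "H"
    ]
    hits = set()
    for j in target_idx:
        for i in query_idx:
            if np.linalg.norm(a.coord[i] - a.coord[j]) <= cutoff:
                hits.add((str(a.chain_id[j]), int(a.res_id[j]),
                          str(a.ins_code[j])))
                break
    return hits


@pytest.fixture(scope="session")
def study_complex():
    """The study-scale toy: model, ground truth, and role map."""
    model, truth = make_toy_complex(study_complex_spec())
    return model, truth, truth.roles


@pytest.fixture(scope="session")
def study_interface(study_complex):
    from mhcgroove.interface import compute_interface

    model, truth, roles = study_complex
    return compute_interface(model, roles)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
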