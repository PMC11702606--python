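"""Structure input/output and biological chain-role assignment.

A :class:`StructureModel` is a thin wrapper around a biotite ``AtomArray``
holding one model of one complex. Chains are mapped onto biological roles
(binder, MHC heavy chain, beta-2-microglobulin, displayed peptide,
crystallization chaperone) either from explicit hints or from size/contact
heuristics, so that downstream interface and geometry code can address
"the peptide" or "the MHC" without caring about deposition chain ids.

Conventions applied on read:

* only the first model of a multi-model file is kept;
* waters are dropped;
* alternate locations are resolved to the highest-occupancy conformer
  (ties resolve to altloc ``A``, the first in file order);
* hydrogens are kept (hydrogen-bond geometry can use them) but are excluded
  from all surface-area and contact computations downstream.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from biotite.structure.io.pdbx import CIFFile
from biotite.structure.io.pdbx import get_structure as _cif_get_structure
from biotite.structure.io.pdbx import set_structure as _cif_set_structure

from ._chem import WATER_NAMES
from .errors import RoleAssignmentError, SelectionError, StructureFormatError

__all__ = [
    "AtomRecord",
    "StructureModel",
    "ROLES",
    "read_structure",
    "write_structure",
    "assign_roles",
    "select_subset",
]

#: Recognised biological roles for chains.
ROLES = ("binder", "mhc_heavy", "b2m", "peptide", "chaperone", "other")

#: Chain length windows (in standard amino-acid residues) for the role
#: heuristics. MHC class I heavy chains run ~270-280 residues in crystal
#: constructs, beta-2-microglobulin ~99, class I peptides 8-13.
PEPTIDE_LENGTH_RANGE = (8, 13)
MHC_HEAVY_LENGTH_RANGE = (250, 299)
B2M_LENGTH_RANGE = (90, 109)


@dataclass(frozen=True)
class AtomRecord:
    """One atom with author numbering, as read from the deposition."""

    chain_id: str
    res_seq: int
    ins_code: str
    res_name: str
    atom_name: str
    element: str
    coords: tuple[float, float, float]
    is_hetero: bool


@dataclass
class StructureModel:
    """One model of one macromolecular complex."""

    id: str
    atoms: struc.AtomArray
    resolution: float | None = None

    def __post_init__(self) -> None:
        if self.atoms.array_length() == 0:
            raise StructureFormatError(f"structure {self.id!r}: empty model")
        # biotite stores coordinates as float32; docking-angle and
        # superposition reproducibility need double precision, so the
        # coordinate block is kept as float64 throughout.
        self.atoms._coord = np.asarray(self.atoms.coord, dtype=np.float64)
        if not np.all(np.isfinite(self.atoms.coord)):
            raise StructureFormatError(
                f"structure {self.id!r}: non-finite coordinates"
            )
        if np.any(self.atoms.element == ""):
            idx = int(np.flatnonzero(self.atoms.element == "")[0])
            raise StructureFormatError(
                f"structure {self.id!r}: atom index {idx} has empty element"
            )

    # -- basic accessors ---------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return self.atoms.array_length()

    def chain_ids(self) -> list[str]:
        """Chain identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for cid in self.atoms.chain_id:
            seen.setdefault(str(cid), None)
        return list(seen)

    def chain(self, chain_id: str) -> struc.AtomArray:
        return self.atoms[self.atoms.chain_id == chain_id]

    def chain_length(self, chain_id: str) -> int:
        """Number of standard amino-acid residues in a chain."""
        arr = self.chain(chain_id)
        arr = arr[struc.filter_amino_acids(arr) & ~arr.hetero]
        if arr.array_length() == 0:
            return 0
        return len(np.unique(_residue_uid(arr)))

    def atom_records(self) -> Iterator[AtomRecord]:
        a = self.atoms
        for i in range(a.array_length()):
            yield AtomRecord(
                chain_id=str(a.chain_id[i]),
                res_seq=int(a.res_id[i]),
                ins_code=str(a.ins_code[i]),
                res_name=str(a.res_name[i]),
                atom_name=str(a.atom_name[i]),
                element=str(a.element[i]),
                coords=tuple(float(x) for x in a.coord[i]),
                is_hetero=bool(a.hetero[i]),
            )


def _residue_uid(arr: struc.AtomArray) -> np.ndarray:
    """String key (chain|res_id|ins_code) identifying residues uniquely."""
    return np.char.add(
        np.char.add(arr.chain_id.astype("U8"), "|"),
        np.char.add(
            np.char.add(arr.res_id.astype("U8"), "|"), arr.ins_code.astype("U4")
        ),
    )


def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".pdb", ".ent"):
        return "pdb"
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    head = path.read_text(errors="replace")[:4096]
    if head.lstrip().startswith(("data_", "#")) or "_atom_site." in head:
        return "mmcif"
    return "pdb"


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"pdb"``, ``"mmcif"`` or ``"auto"`` (sniff from suffix/content).
    """
    path = Path(path)
    if not path.is_file():
        raise StructureFormatError(f"no such structure file: {path}")
    fmt = _sniff_format(path) if format == "auto" else format
    if fmt not in ("pdb", "mmcif"):
        raise StructureFormatError(f"unknown structure format {format!r}")
    try:
        if fmt == "pdb":
            pdb = PDBFile.read(str(path))
            atoms = pdb.get_structure(model=1, altloc="occupancy")
        else:
            cif = CIFFile.read(str(path))
            atoms = _cif_get_structure(cif, model=1, altloc="occupancy")
    except StructureFormatError:
        raise
    except Exception as exc:  # biotite raises various parse errors
        raise StructureFormatError(
            f"could not parse {path} as {fmt}: {exc}"
        ) from exc
    if atoms.array_length() == 0:
        raise StructureFormatError(f"{path}: file parsed to an empty model")
    # Drop waters; everything else (ions, glycans) is retained here and
    # filtered to amino acids by the interface layer.
    atoms = atoms[~np.isin(atoms.res_name, list(WATER_NAMES))]
    if atoms.array_length() == 0:
        raise StructureFormatError(f"{path}: model contains only water")
    model = StructureModel(id=path.stem, atoms=atoms)
    _check_unique_atoms(model, path)
    return model


def _check_unique_atoms(model: StructureModel, path: Path) -> None:
    a = model.atoms
    keys = np.char.add(
        np.char.add(_residue_uid(a), "|"), a.atom_name.astype("U8")
    )
    uniq, counts = np.unique(keys, return_counts=True)
    if np.any(counts > 1):
        raise StructureFormatError(
            f"{path}: duplicate atom records after altloc resolution: "
            f"{uniq[counts > 1][:5].tolist()}"
        )


def write_structure(model: StructureModel, path: str | Path,
                    format: str = "auto") -> None:
    """Write a model as PDB (default) or mmCIF, chosen by suffix."""
    path = Path(path)
    fmt = format
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    if fmt == "pdb":
        pdb = PDBFile()
        pdb.set_structure(model.atoms)
        pdb.write(str(path))
    elif fmt == "mmcif":
        cif = CIFFile()
        _cif_set_structure(cif, model.atoms)
        cif.write(str(path))
    else:
        raise StructureFormatError(f"unknown structure format {format!r}")


def transform_model(
    model: StructureModel,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
) -> StructureModel:
    """Rigidly transform a model (x' = R x + t) at double precision."""
    atoms = model.atoms.copy()
    xyz = np.asarray(model.atoms.coord, dtype=np.float64)
    if rotation is not None:
        xyz = xyz @ np.asarray(rotation, dtype=np.float64).T
    if translation is not None:
        xyz = xyz + np.asarray(translation, dtype=np.float64)
    atoms._coord = xyz
    return StructureModel(id=model.id, atoms=atoms,
                          resolution=model.resolution)


def structure_to_pdb_string(model: StructureModel) -> str:
    pdb = PDBFile()
    pdb.set_structure(model.atoms)
    buf = io.StringIO()
    pdb.write(buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Role assignment
# ---------------------------------------------------------------------------

def assign_roles(
    model: StructureModel,
    hints: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Map each chain id to a biological role.

    Without hints, sizes decide: a chain of 8-13 standard residues is the
    displayed peptide, ~270-280 residues the MHC heavy chain, ~99 residues
    beta-2-microglobulin. If exactly one chain remains it is the binder.
    When several candidate binder chains remain (e.g. a Fab or TCR plus a
    crystallization chaperone), chains whose heavy atoms come within 5 A of
    the peptide are binders and the rest are chaperones; if that still fails
    to separate them, an error lists the candidates and explicit ``hints``
    (chain id -> role) are required. Hints always override heuristics.
    """
    hints = dict(hints or {})
    for cid, role in hints.items():
        if role not in ROLES:
            raise RoleAssignmentError(f"unknown role {role!r} for chain {cid!r}")
        if cid not in model.chain_ids():
            raise RoleAssignmentError(f"hint for absent chain {cid!r}")

    roles: dict[str, str] = {}
    unassigned: list[str] = []
    windows: dict[str, list[tuple[str, int]]] = {
        "peptide": [], "mhc_heavy": [], "b2m": [],
    }
    for cid in model.chain_ids():
        if cid in hints:
            roles[cid] = hints[cid]
            continue
        n = model.chain_length(cid)
        if PEPTIDE_LENGTH_RANGE[0] <= n <= PEPTIDE_LENGTH_RANGE[1]:
            windows["peptide"].append((cid, n))
        elif MHC_HEAVY_LENGTH_RANGE[0] <= n <= MHC_HEAVY_LENGTH_RANGE[1]:
            windows["mhc_heavy"].append((cid, n))
        elif B2M_LENGTH_RANGE[0] <= n <= B2M_LENGTH_RANGE[1]:
            windows["b2m"].append((cid, n))
        else:
            unassigned.append(cid)

    if len(windows["peptide"]) > 1:
        raise RoleAssignmentError(
            "ambiguous 'peptide' assignment, candidates "
            f"{[c for c, _ in windows['peptide']]}; supply hints"
        )
    # For the larger chains, the closest to the canonical size takes the
    # role; other window members remain binder/chaperone candidates
    # (e.g. a ~100-residue designed binder next to beta-2-microglobulin).
    canonical = {"mhc_heavy": 276, "b2m": 99, "peptide": 9}
    for role in ("peptide", "mhc_heavy", "b2m"):
        cands = windows[role]
        if not cands:
            continue
        cands = sorted(cands, key=lambda cn: (abs(cn[1] - canonical[role]),
                                              cn[0]))
        roles[cands[0][0]] = role
        unassigned.extend(c for c, _ in cands[1:])

    for role in ("peptide", "mhc_heavy"):
        found = [c for c, r in roles.items() if r == role]
        if len(found) == 0:
            raise RoleAssignmentError(
                f"no chain assigned role {role!r}; supply hints "
                f"(chains: {model.chain_ids()})"
            )
        if len(found) > 1:
            raise RoleAssignmentError(
                f"ambiguous {role!r} assignment, candidates {found}; "
                "supply hints"
            )

    if len(unassigned) == 1:
        roles[unassigned[0]] = "binder"
    elif len(unassigned) > 1:
        roles.update(_split_binder_candidates(model, roles, unassigned))

    n_pep = model.chain_length(
        next(c for c, r in roles.items() if r == "peptide")
    )
    if not PEPTIDE_LENGTH_RANGE[0] <= n_pep <= PEPTIDE_LENGTH_RANGE[1]:
        raise RoleAssignmentError(
            f"peptide chain has {n_pep} residues, outside "
            f"{PEPTIDE_LENGTH_RANGE}"
        )
    return roles


def _split_binder_candidates(
    model: StructureModel, roles: dict[str, str], candidates: list[str]
) -> dict[str, str]:
    """Separate binder chains from chaperones by peptide proximity."""
    pep_chain = next(c for c, r in roles.items() if r == "peptide")
    pep = model.chain(pep_chain)
    pep_xyz = pep.coord[pep.element != "H"]
    out: dict[str, str] = {}
    from scipy.spatial import cKDTree

    tree = cKDTree(pep_xyz)
    for cid in candidates:
        arr = model.chain(cid)
        xyz = arr.coord[arr.element != "H"]
        d, _ = tree.query(xyz, k=1)
        out[cid] = "binder" if float(np.min(d)) <= 5.0 else "chaperone"
    if not any(r == "binder" for r in out.values()):
        raise RoleAssignmentError(
            f"cannot assign binder among candidate chains {candidates}; "
            "none contacts the peptide — supply hints"
        )
    return out


def select_subset(
    model: StructureModel,
    roles: Mapping[str, str],
    keep: set[str] | frozenset[str] | tuple[str, ...] | list[str],
) -> StructureModel:
    """Return a model containing only chains whose role is in ``keep``.

    Atom order is preserved. Raises if the selection is empty or names a
    role absent from the role map.
    """
    keep = set(keep)
    present = set(roles.values())
    missing = keep - present
    if missing:
        raise SelectionError(
            f"roles {sorted(missing)} not present in role map "
            f"(present: {sorted(present)})"
        )
    chain_ids = [c for c, r in roles.items() if r in keep]
    mask = np.isin(model.atoms.chain_id, chain_ids)
    if not np.any(mask):
        raise SelectionError(f"selection {sorted(keep)} matched no atoms")
    return StructureModel(
        id=f"{model.id}[{'+'.join(sorted(keep))}]",
        atoms=model.atoms[mask],
        resolution=model.resolution,
    )


def peptide_positions(model: StructureModel, roles: Mapping[str, str]
                      ) -> list[tuple[int, str, int]]:
    """Peptide residues renumbered 1..N in chain order.

    Returns ``(position, res_name, author_res_seq)`` triples, so hotspot
    addresses like "Met4, Trp5" work on any deposition regardless of the
    author numbering of the peptide chain.
    """
    pep_chain = next((c for c, r in roles.items() if r == "peptide"), None)
    if pep_chain is None:
        raise SelectionError("role map has no peptide chain")
    arr = model.chain(pep_chain)
    arr = arr[struc.filter_amino_acids(arr) & ~arr.hetero]
    out = []
    seen: dict[tuple[int, str], None] = {}
    for i in range(arr.array_length()):
        key = (int(arr.res_id[i]), str(arr.ins_code[i]))
        if key not in seen:
            seen[key] = None
            out.append((len(seen), str(arr.res_name[i]), key[0]))
    return out
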