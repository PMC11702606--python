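"""Interface quantification: buried surface area, footprints, H-bonds.

The central quantity is the solvent-accessible surface area lost when two
sides of a complex associate:

    BSA_total = SASA(A alone) + SASA(B alone) - SASA(A+B)

``interface_area`` is half of that two-sided loss (the convention used by
PISA-style servers); both numbers are always reported, because published
interface sizes use either convention without saying which.

Peptide-centric fractions quantify how peptide-focused a binder is:

* ``peptide_fraction`` — peptide share of the target-side buried area
  (peptide dSASA / dSASA of the whole pMHC side);
* ``peptide_burial_fraction`` — fraction of the groove-displayed peptide's
  exposed surface (its SASA within the pMHC alone) that the binder buries.

Contacts use a heavy-atom distance criterion (default 4.0 A); hydrogen
bonds use donor/acceptor heavy-atom distance plus an angle criterion, and
salt bridges pair standard basic and acidic side-chain atoms. All residues
are tagged with their chain role, so footprints from different depositions
of the same target are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy.spatial import cKDTree
import biotite.structure as struc

from . import _chem
from .errors import SelectionError
from .sasa import compute_sasa
from .structure import StructureModel

__all__ = [
    "ResidueTag",
    "AtomTag",
    "HBond",
    "SaltBridge",
    "ContactFootprint",
    "InterfaceReport",
    "compute_interface",
    "contact_residues",
    "peptide_contacting_residues",
    "detect_hbonds",
    "detect_salt_bridges",
    "compare_footprints",
    "diff_interfaces",
]

DEFAULT_TARGET_SIDE = ("mhc_heavy", "peptide", "b2m")


class ResidueTag(NamedTuple):
    role: str
    chain_id: str
    res_seq: int
    ins_code: str
    res_name: str

    @property
    def key(self) -> tuple[str, int, str]:
        """Role-based key used to match residues across depositions."""
        return (self.role, self.res_seq, self.ins_code)

    def label(self) -> str:
        return f"{self.res_name}{self.res_seq}{self.ins_code}({self.role})"


class AtomTag(NamedTuple):
    role: str
    chain_id: str
    res_seq: int
    ins_code: str
    res_name: str
    atom_name: str

    @property
    def residue(self) -> ResidueTag:
        return ResidueTag(self.role, self.chain_id, self.res_seq,
                          self.ins_code, self.res_name)


@dataclass(frozen=True)
class HBond:
    donor: AtomTag
    acceptor: AtomTag
    distance: float
    angle: float
    donor_side: str  # "a" or "b"

    @property
    def key(self) -> tuple:
        """Identity used when diffing reports: residues + atom names."""
        d, a = self.donor, self.acceptor
        return (d.role, d.res_seq, d.ins_code, d.atom_name,
                a.role, a.res_seq, a.ins_code, a.atom_name)


@dataclass(frozen=True)
class SaltBridge:
    basic: AtomTag
    acidic: AtomTag
    distance: float


@dataclass(frozen=True)
class ContactFootprint:
    """Set of target-side residues contacted by a query side."""

    residues: tuple[ResidueTag, ...]
    cutoff: float
    criterion: str  # "distance" or "dsasa"
    query_roles: tuple[str, ...]
    target_roles: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.residues)

    def keys(self) -> frozenset[tuple[str, int, str]]:
        return frozenset(r.key for r in self.residues)


@dataclass
class InterfaceReport:
    """Buried-surface-area statistics for one binder/target pair."""

    side_a: tuple[str, ...]
    side_b: tuple[str, ...]
    bsa_total: float
    interface_area: float
    per_residue_dsasa: dict[ResidueTag, float]
    peptide_fraction: float | None
    peptide_burial_fraction: float | None
    hbonds: list[HBond]
    salt_bridges: list[SaltBridge]
    binder_contact_residues: ContactFootprint
    target_contact_residues: ContactFootprint
    parameters: dict = field(default_factory=dict)

    def peptide_position_dsasa(self) -> dict[int, float]:
        """Buried area per peptide position (1..N in chain order)."""
        pep = sorted(
            ((t, v) for t, v in self.per_residue_dsasa.items()
             if t.role == "peptide"),
            key=lambda tv: (tv[0].res_seq, tv[0].ins_code),
        )
        return {i + 1: v for i, (_, v) in enumerate(pep)}


# ---------------------------------------------------------------------------
# Atom selection helpers
# ---------------------------------------------------------------------------

def _role_of(roles: Mapping[str, str], chain_id: str) -> str:
    return roles.get(chain_id, "other")


def _protein_atoms(model: StructureModel, roles: Mapping[str, str],
                   keep_roles: Iterable[str],
                   include_h: bool = False) -> struc.AtomArray:
    """Standard amino-acid atoms of chains with the requested roles."""
    keep = set(keep_roles)
    atoms = model.atoms
    chain_ids = [c for c in model.chain_ids() if _role_of(roles, c) in keep]
    mask = np.isin(atoms.chain_id, chain_ids)
    mask &= struc.filter_amino_acids(atoms) & ~atoms.hetero
    if not include_h:
        mask &= atoms.element != "H"
    sub = atoms[mask]
    if sub.array_length() == 0:
        raise SelectionError(
            f"no protein atoms for roles {sorted(keep)}"
        )
    return sub


def _atom_tags(arr: struc.AtomArray, roles: Mapping[str, str]) -> list[AtomTag]:
    return [
        AtomTag(
            role=_role_of(roles, str(arr.chain_id[i])),
            chain_id=str(arr.chain_id[i]),
            res_seq=int(arr.res_id[i]),
            ins_code=str(arr.ins_code[i]),
            res_name=str(arr.res_name[i]),
            atom_name=str(arr.atom_name[i]),
        )
        for i in range(arr.array_length())
    ]


def _check_sides(side_a: Sequence[str], side_b: Sequence[str]) -> None:
    if not side_a or not side_b:
        raise SelectionError("both interface sides must be non-empty")
    overlap = set(side_a) & set(side_b)
    if overlap:
        raise SelectionError(f"interface sides overlap: {sorted(overlap)}")


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------

def contact_residues(
    model: StructureModel,
    roles: Mapping[str, str],
    query_side: Sequence[str],
    target_side: Sequence[str],
    cutoff: float = 4.0,
) -> ContactFootprint:
    """Target-side residues with any heavy atom within ``cutoff`` of the
    query side (heavy-atom distance criterion)."""
    _check_sides(query_side, target_side)
    if cutoff <= 0:
        raise SelectionError(f"contact cutoff must be positive, got {cutoff}")
    query = _protein_atoms(model, roles, query_side)
    target = _protein_atoms(model, roles, target_side)
    tree = cKDTree(query.coord)
    d, _ = tree.query(target.coord, k=1, distance_upper_bound=cutoff)
    hit = np.isfinite(d) & (d <= cutoff)
    tags = _atom_tags(target[hit], roles)
    residues = sorted(
        {t.residue for t in tags},
        key=lambda r: (r.role, r.chain_id, r.res_seq, r.ins_code),
    )
    return ContactFootprint(
        residues=tuple(residues),
        cutoff=cutoff,
        criterion="distance",
        query_roles=tuple(query_side),
        target_roles=tuple(target_side),
    )


def peptide_contacting_residues(
    model: StructureModel,
    roles: Mapping[str, str],
    cutoff: float = 4.0,
    binder_roles: Sequence[str] = ("binder",),
) -> ContactFootprint:
    """Binder residues with any heavy atom within ``cutoff`` of the peptide."""
    if "peptide" not in set(roles.values()):
        raise SelectionError("role map has no peptide chain")
    return contact_residues(model, roles, ("peptide",), binder_roles, cutoff)


def footprint_from_dsasa(
    report: InterfaceReport,
    roles_subset: Sequence[str],
    threshold: float = 0.1,
) -> ContactFootprint:
    """Alternative footprint criterion: residues burying > threshold A^2."""
    residues = sorted(
        (t for t, v in report.per_residue_dsasa.items()
         if t.role in set(roles_subset) and v > threshold),
        key=lambda r: (r.role, r.chain_id, r.res_seq, r.ins_code),
    )
    return ContactFootprint(
        residues=tuple(residues),
        cutoff=threshold,
        criterion="dsasa",
        query_roles=tuple(report.side_a),
        target_roles=tuple(roles_subset),
    )


# ---------------------------------------------------------------------------
# Hydrogen bonds and salt bridges
# ---------------------------------------------------------------------------

def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    u = a - vertex
    v = b - vertex
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    c = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def _residue_atom_index(arr: struc.AtomArray) -> dict[tuple, dict[str, int]]:
    idx: dict[tuple, dict[str, int]] = {}
    for i in range(arr.array_length()):
        rkey = (str(arr.chain_id[i]), int(arr.res_id[i]), str(arr.ins_code[i]))
        idx.setdefault(rkey, {})[str(arr.atom_name[i])] = i
    return idx


def detect_hbonds(
    model: StructureModel,
    roles: Mapping[str, str],
    side_a: Sequence[str],
    side_b: Sequence[str],
    d_max: float = 3.5,
    angle_min: float = 90.0,
) -> list[HBond]:
    """Cross-interface hydrogen bonds on heavy-atom criteria.

    A donor/acceptor heavy-atom pair across the interface is a hydrogen
    bond if their distance is <= ``d_max`` and the angle at the donor
    between its antecedent atom and the acceptor is >= ``angle_min``
    (near-linear arrangements score ~180 deg). When explicit hydrogens
    bonded to the donor are present, the criterion D-H...A >= 120 deg is
    used instead.
    """
    _check_sides(side_a, side_b)
    if d_max <= 0:
        raise SelectionError(f"d_max must be positive, got {d_max}")
    arr_a = _protein_atoms(model, roles, side_a, include_h=True)
    arr_b = _protein_atoms(model, roles, side_b, include_h=True)
    bonds: list[HBond] = []
    for donor_arr, acc_arr, donor_side in ((arr_a, arr_b, "a"),
                                           (arr_b, arr_a, "b")):
        bonds.extend(
            _hbonds_one_direction(donor_arr, acc_arr, donor_side, roles,
                                  d_max, angle_min)
        )
    bonds.sort(key=lambda h: h.key)
    return bonds


def _hbonds_one_direction(
    donor_arr: struc.AtomArray,
    acc_arr: struc.AtomArray,
    donor_side: str,
    roles: Mapping[str, str],
    d_max: float,
    angle_min: float,
) -> list[HBond]:
    don_index = _residue_atom_index(donor_arr)
    donors: list[tuple[int, int]] = []  # (donor atom idx, antecedent idx)
    hydrogens: dict[int, list[int]] = {}
    for rkey, atom_map in don_index.items():
        res_name = str(donor_arr.res_name[next(iter(atom_map.values()))])
        for donor_name, ante_name in _chem.donor_atoms(res_name):
            di = atom_map.get(donor_name)
            ai = atom_map.get(ante_name)
            if di is None or ai is None:
                continue
            donors.append((di, ai))
            hs = [
                j for name, j in atom_map.items()
                if str(donor_arr.element[j]) == "H"
                and np.linalg.norm(donor_arr.coord[j] - donor_arr.coord[di])
                < 1.3
            ]
            if hs:
                hydrogens[di] = hs

    acceptors: list[int] = []
    acc_index = _residue_atom_index(acc_arr)
    for rkey, atom_map in acc_index.items():
        res_name = str(acc_arr.res_name[next(iter(atom_map.values()))])
        for name in _chem.acceptor_atoms(res_name):
            if name in atom_map:
                acceptors.append(atom_map[name])

    if not donors or not acceptors:
        return []

    donor_xyz = donor_arr.coord[[d for d, _ in donors]]
    acc_xyz = acc_arr.coord[acceptors]
    tree = cKDTree(acc_xyz)
    out: list[HBond] = []
    pairs = tree.query_ball_point(donor_xyz, r=d_max)
    for k, acc_hits in enumerate(pairs):
        di, anti = donors[k]
        for m in acc_hits:
            aj = acceptors[m]
            dist = float(np.linalg.norm(acc_arr.coord[aj]
                                        - donor_arr.coord[di]))
            if dist > d_max:
                continue
            if di in hydrogens:
                ang = max(
                    _angle_deg(donor_arr.coord[di], donor_arr.coord[h],
                               acc_arr.coord[aj])
                    for h in hydrogens[di]
                )
                ok = ang >= 120.0
            else:
                ang = _angle_deg(donor_arr.coord[anti], donor_arr.coord[di],
                                 acc_arr.coord[aj])
                ok = ang >= angle_min
            if ok:
                out.append(HBond(
                    donor=_atom_tags(donor_arr[di:di + 1], roles)[0],
                    acceptor=_atom_tags(acc_arr[aj:aj + 1], roles)[0],
                    distance=dist,
                    angle=ang,
                    donor_side=donor_side,
                ))
    return out


def detect_salt_bridges(
    model: StructureModel,
    roles: Mapping[str, str],
    side_a: Sequence[str],
    side_b: Sequence[str],
    d_max: float = 4.0,
) -> list[SaltBridge]:
    """Cross-interface Lys/Arg/His vs Asp/Glu charged-group pairs.

    One bridge is reported per (basic residue, acidic residue) pair, at
    the minimum atom-atom distance <= ``d_max``.
    """
    _check_sides(side_a, side_b)
    if d_max <= 0:
        raise SelectionError(f"d_max must be positive, got {d_max}")
    arr_a = _protein_atoms(model, roles, side_a)
    arr_b = _protein_atoms(model, roles, side_b)

    best: dict[tuple, SaltBridge] = {}
    for basic_arr, acid_arr in ((arr_a, arr_b), (arr_b, arr_a)):
        basic_idx = [
            i for i in range(basic_arr.array_length())
            if str(basic_arr.atom_name[i])
            in _chem.BASIC_ATOMS.get(str(basic_arr.res_name[i]), ())
        ]
        acid_idx = [
            i for i in range(acid_arr.array_length())
            if str(acid_arr.atom_name[i])
            in _chem.ACIDIC_ATOMS.get(str(acid_arr.res_name[i]), ())
        ]
        if not basic_idx or not acid_idx:
            continue
        acid_xyz = acid_arr.coord[acid_idx]
        tree = cKDTree(acid_xyz)
        hits = tree.query_ball_point(basic_arr.coord[basic_idx], r=d_max)
        for k, acc_hits in enumerate(hits):
            i = basic_idx[k]
            for m in acc_hits:
                j = acid_idx[m]
                dist = float(np.linalg.norm(acid_arr.coord[j]
                                            - basic_arr.coord[i]))
                if dist > d_max:
                    continue
                btag = _atom_tags(basic_arr[i:i + 1], roles)[0]
                atag = _atom_tags(acid_arr[j:j + 1], roles)[0]
                pair_key = (btag.residue, atag.residue)
                prev = best.get(pair_key)
                if prev is None or dist < prev.distance:
                    best[pair_key] = SaltBridge(basic=btag, acidic=atag,
                                                distance=dist)
    return sorted(best.values(),
                  key=lambda sb: (sb.basic.residue, sb.acidic.residue))


# ---------------------------------------------------------------------------
# Interface report
# ---------------------------------------------------------------------------

def compute_interface(
    model: StructureModel,
    roles: Mapping[str, str],
    side_a: Sequence[str] = ("binder",),
    side_b: Sequence[str] = DEFAULT_TARGET_SIDE,
    probe: float = _chem.PROBE_RADIUS,
    n_points: int = _chem.N_SPHERE_POINTS,
    contact_cutoff: float = 4.0,
    hbond_d_max: float = 3.5,
    hbond_angle_min: float = 90.0,
    salt_bridge_d_max: float = 4.0,
) -> InterfaceReport:
    """Full buried-surface-area report for a binder/target pair.

    ``side_b`` roles absent from the role map are silently dropped (a
    construct may lack beta-2-microglobulin); ``side_a`` roles must exist.
    """
    _check_sides(side_a, side_b)
    present = set(roles.values())
    side_b = tuple(r for r in side_b if r in present)
    if not side_b:
        raise SelectionError("no side_b role present in the role map")

    arr_a = _protein_atoms(model, roles, side_a)
    arr_b = _protein_atoms(model, roles, side_b)
    arr_ab = arr_a + arr_b
    # Concatenation downcasts coordinates to float32; restore the exact
    # values so per-atom areas of the complex and the isolated sides are
    # computed from identical positions.
    arr_ab._coord = np.concatenate(
        [np.asarray(arr_a.coord, dtype=np.float64),
         np.asarray(arr_b.coord, dtype=np.float64)]
    )

    sasa_ab = compute_sasa(arr_ab, probe=probe, n_points=n_points)
    sasa_a = compute_sasa(arr_a, probe=probe, n_points=n_points)
    sasa_b = compute_sasa(arr_b, probe=probe, n_points=n_points)

    n_a = arr_a.array_length()
    dsasa_a = sasa_a.per_atom_area - sasa_ab.per_atom_area[:n_a]
    dsasa_b = sasa_b.per_atom_area - sasa_ab.per_atom_area[n_a:]
    bsa_total = float(dsasa_a.sum() + dsasa_b.sum())

    per_res: dict[ResidueTag, float] = {}
    for arr, dsasa in ((arr_a, dsasa_a), (arr_b, dsasa_b)):
        tags = _atom_tags(arr, roles)
        for t, v in zip(tags, dsasa):
            rt = t.residue
            per_res[rt] = per_res.get(rt, 0.0) + float(v)

    pep_delta = sum(v for t, v in per_res.items() if t.role == "peptide")
    side_b_delta = float(dsasa_b.sum())
    if "peptide" in side_b and side_b_delta > 0:
        peptide_fraction: float | None = pep_delta / side_b_delta
    else:
        peptide_fraction = None

    peptide_burial_fraction: float | None = None
    if "peptide" in side_b:
        pep_free = sum(
            v for (cid, rid, ic), v in sasa_b.per_residue_area.items()
            if _role_of(roles, cid) == "peptide"
        )
        if pep_free > 0:
            peptide_burial_fraction = pep_delta / pep_free

    hbonds = detect_hbonds(model, roles, side_a, side_b,
                           d_max=hbond_d_max, angle_min=hbond_angle_min)
    bridges = detect_salt_bridges(model, roles, side_a, side_b,
                                  d_max=salt_bridge_d_max)
    target_fp = contact_residues(model, roles, side_a, side_b,
                                 cutoff=contact_cutoff)
    binder_fp = contact_residues(model, roles, side_b, side_a,
                                 cutoff=contact_cutoff)

    return InterfaceReport(
        side_a=tuple(side_a),
        side_b=side_b,
        bsa_total=bsa_total,
        interface_area=bsa_total / 2.0,
        per_residue_dsasa=per_res,
        peptide_fraction=peptide_fraction,
        peptide_burial_fraction=peptide_burial_fraction,
        hbonds=hbonds,
        salt_bridges=bridges,
        binder_contact_residues=binder_fp,
        target_contact_residues=target_fp,
        parameters={
            "probe": probe,
            "n_points": n_points,
            "contact_cutoff": contact_cutoff,
            "hbond_d_max": hbond_d_max,
            "hbond_angle_min": hbond_angle_min,
            "salt_bridge_d_max": salt_bridge_d_max,
        },
    )


# ---------------------------------------------------------------------------
# Cross-structure comparison
# ---------------------------------------------------------------------------

def compare_footprints(
    footprints: Sequence[ContactFootprint],
) -> tuple[ResidueTag, ...]:
    """Residues shared by all footprints, matched on (role, res_seq).

    All footprints must address the same target roles; residue names are
    taken from the first footprint.
    """
    if len(footprints) < 2:
        raise SelectionError("need at least two footprints to intersect")
    target_roles = {tuple(sorted(fp.target_roles)) for fp in footprints}
    if len(target_roles) > 1:
        raise SelectionError(
            f"footprints address different targets: {sorted(target_roles)}"
        )
    shared = footprints[0].keys()
    for fp in footprints[1:]:
        shared &= fp.keys()
    out = [r for r in footprints[0].residues if r.key in shared]
    return tuple(sorted(out, key=lambda r: (r.role, r.res_seq, r.ins_code)))


@dataclass
class InterfaceDiff:
    """Hydrogen bonds and buried-area changes between two reports."""

    hbonds_only_a: list[HBond]
    hbonds_only_b: list[HBond]
    dsasa_changes: list[tuple[tuple[str, int, str], float, float]]

    @property
    def n_hbond_changes(self) -> int:
        return len(self.hbonds_only_a) + len(self.hbonds_only_b)


def diff_interfaces(
    report_a: InterfaceReport,
    report_b: InterfaceReport,
    dsasa_threshold: float = 1.0,
) -> InterfaceDiff:
    """Structured difference between two interface reports.

    Hydrogen bonds are keyed by donor/acceptor residue (role + author
    number) and atom names; buried-area changes above ``dsasa_threshold``
    (A^2) are listed per residue key with both values.
    """
    keys_a = {h.key for h in report_a.hbonds}
    keys_b = {h.key for h in report_b.hbonds}
    only_a = [h for h in report_a.hbonds if h.key not in keys_b]
    only_b = [h for h in report_b.hbonds if h.key not in keys_a]

    da = {t.key: v for t, v in report_a.per_residue_dsasa.items()}
    db = {t.key: v for t, v in report_b.per_residue_dsasa.items()}
    changes = []
    for key in sorted(set(da) | set(db)):
        va = da.get(key, 0.0)
        vb = db.get(key, 0.0)
        if abs(va - vb) > dsasa_threshold:
            changes.append((key, va, vb))
    return InterfaceDiff(hbonds_only_a=only_a, hbonds_only_b=only_b,
                         dsasa_changes=changes)
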