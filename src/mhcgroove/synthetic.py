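"""Synthetic fixtures with properties known by construction.

Two generators:

* :func:`make_toy_complex` builds a geometric scaffold of an MHC-like
  target (helix residues in the canonical alpha-1/alpha-2 author ranges
  forming a plane, a displayed peptide along the groove, optionally a
  beta-2-microglobulin-sized chain) plus a binder chain whose interface
  residues lie along an axis at a chosen docking angle. Contacts,
  hydrogen bonds and salt bridges are planted at exact distances, and the
  generator verifies by brute force that no accidental cross-interface
  feature exists, so detector outputs are known exactly.

* :func:`make_synthetic_atlas` samples an immunopeptidome-like table of
  9-mers around a reference epitope, planting neighbours at exact Hamming
  distances (optionally preserving the hotspot motif) while rejecting
  background peptides that would come too close or match the motif by
  chance. The default specification mirrors a screen over an MS-detected
  HLA-A*02 9-mer atlas: 14,356 background peptides plus 5 planted
  distance-4 neighbours and 2 motif-preserving neighbours at distances 5
  and 6 (14,363 records in all).

These are scaffolds, not protein folds: bond lengths and sterics are not
physical, only the planted geometric relations are.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import biotite.structure as struc

from ._chem import CANONICAL_LETTERS, ONE_TO_THREE
from .errors import FixtureError
from .offtarget import PeptideRecord, hamming
from .structure import StructureModel, write_structure

__all__ = [
    "PlantedContact",
    "PlantedHBond",
    "PlantedSaltBridge",
    "ToyComplexSpec",
    "ToyGroundTruth",
    "make_toy_complex",
    "AtlasSpec",
    "AtlasGroundTruth",
    "make_synthetic_atlas",
    "study_complex_spec",
    "study_atlas_spec",
    "write_fixture_dir",
]

# Scaffold layout constants (Angstrom).
_SPACING = 5.5            # CA-CA spacing within target chains
_HELIX_Y = 5.5            # half-separation of the two groove helices
_BINDER_Z = 8.0           # height of binder interface C-alphas
_CORE_Z = 20.0            # height of non-interface binder residues
_PAD_Z = -12.0            # depth of non-helix MHC padding residues
_B2M_Z = -25.0
_BACKBONE = {"N": (-1.2, 0.6, 0.0), "CA": (0.0, 0.0, 0.0),
             "C": (1.2, 0.6, 0.0), "O": (1.2, 1.8, 0.0)}
_HELIX_RANGES = ((50, 84), (138, 180))
_CONTACT_ATOM_NAMES = ("CB", "CG", "CD1", "CD2")
_TARGET_ATOM_CYCLE = ("CA", "N", "C", "O")


@dataclass(frozen=True)
class PlantedContact:
    binder_res: int          # 1-based residue index in the binder chain
    target_role: str         # "peptide" or "mhc_heavy"
    target_res: int          # author residue number on the target chain
    gap: float = 3.6         # planted heavy-atom distance (A)


@dataclass(frozen=True)
class PlantedHBond:
    binder_res: int
    target_role: str
    target_res: int
    distance: float = 2.9    # donor-acceptor heavy-atom distance (A)
    angle: float = 150.0     # antecedent-donor-acceptor angle (deg)


@dataclass(frozen=True)
class PlantedSaltBridge:
    binder_res: int
    target_role: str
    target_res: int
    distance: float = 3.8    # inside the 4.0 A bridge cutoff, outside the
                             # 3.5 A H-bond cutoff


@dataclass(frozen=True)
class ToyComplexSpec:
    """Construction recipe for a toy binder/pMHC complex."""

    peptide_sequence: str = "SLLMWITQV"
    n_binder_residues: int = 40
    n_mhc_residues: int = 276
    include_b2m: bool = True
    binder_axis_angle: float = 40.0
    planted_contacts: tuple[PlantedContact, ...] = ()
    planted_hbonds: tuple[PlantedHBond, ...] = ()
    planted_salt_bridges: tuple[PlantedSaltBridge, ...] = ()
    seed: int = 0

    @property
    def peptide_length(self) -> int:
        return len(self.peptide_sequence)


@dataclass
class ToyGroundTruth:
    """Everything a detector should find in the fixture, by construction."""

    roles: dict[str, str]
    binder_axis_angle: float
    contact_pairs: list[tuple[int, str, int]]   # (binder_res, role, target)
    mhc_footprint: list[int]
    peptide_footprint: list[int]
    binder_peptide_residues: list[int]
    binder_interface_residues: list[int]
    hbond_pairs: list[tuple[int, str, int]]
    salt_bridge_pairs: list[tuple[int, str, int]]

    @property
    def n_hbonds(self) -> int:
        return len(self.hbond_pairs)

    @property
    def n_salt_bridges(self) -> int:
        return len(self.salt_bridge_pairs)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _validate_toy_spec(spec: ToyComplexSpec) -> None:
    if not 0.0 <= spec.binder_axis_angle <= 90.0:
        raise FixtureError(
            f"binder_axis_angle must be in [0, 90], got "
            f"{spec.binder_axis_angle}"
        )
    if not set(spec.peptide_sequence) <= CANONICAL_LETTERS:
        raise FixtureError(
            f"non-canonical peptide sequence {spec.peptide_sequence!r}"
        )
    if not 3 <= spec.peptide_length <= 13:
        raise FixtureError("peptide length must be 3..13")
    if spec.n_mhc_residues < _HELIX_RANGES[1][1]:
        raise FixtureError(
            f"n_mhc_residues must cover the helix ranges "
            f"(>= {_HELIX_RANGES[1][1]})"
        )
    plants = (list(spec.planted_contacts) + list(spec.planted_hbonds)
              + list(spec.planted_salt_bridges))
    special = [p.binder_res for p in spec.planted_hbonds] + \
              [p.binder_res for p in spec.planted_salt_bridges]
    if len(special) != len(set(special)):
        raise FixtureError(
            "each binder residue may carry at most one planted H-bond or "
            "salt bridge"
        )
    contact_binders = {p.binder_res for p in spec.planted_contacts}
    if contact_binders & set(special):
        raise FixtureError(
            "binder residues with planted H-bonds/bridges cannot also "
            "carry plain contacts"
        )
    for p in plants:
        if not 1 <= p.binder_res <= spec.n_binder_residues:
            raise FixtureError(f"binder residue {p.binder_res} out of range")
        if p.target_role not in ("peptide", "mhc_heavy"):
            raise FixtureError(
                f"plants must target peptide or mhc_heavy, got "
                f"{p.target_role!r}"
            )
        if p.target_role == "peptide":
            if not 1 <= p.target_res <= spec.peptide_length:
                raise FixtureError(
                    f"peptide position {p.target_res} out of range"
                )
        else:
            in_helix = any(lo <= p.target_res <= hi
                           for lo, hi in _HELIX_RANGES)
            if not in_helix:
                raise FixtureError(
                    f"MHC plants must hit helix residues "
                    f"{_HELIX_RANGES}, got {p.target_res}"
                )
    for p in spec.planted_contacts:
        if not 2.8 <= p.gap <= 3.95:
            raise FixtureError(
                f"planted contact gap {p.gap} outside the buildable "
                "window [2.8, 3.95]"
            )
    for p in spec.planted_hbonds:
        if not 2.5 <= p.distance <= 3.5:
            raise FixtureError(
                f"planted H-bond distance {p.distance} outside [2.5, 3.5]"
            )
        if not 95.0 <= p.angle <= 180.0:
            raise FixtureError(
                f"planted H-bond angle {p.angle} outside [95, 180]"
            )
    for p in spec.planted_salt_bridges:
        if not 3.0 <= p.distance <= 4.0:
            raise FixtureError(
                f"planted salt-bridge distance {p.distance} outside "
                "[3.0, 4.0]"
            )
    bridge_targets = [(p.target_role, p.target_res)
                      for p in spec.planted_salt_bridges]
    if len(bridge_targets) != len(set(bridge_targets)):
        raise FixtureError("one salt bridge per target residue")
    hbond_targets = [(p.target_role, p.target_res)
                     for p in spec.planted_hbonds]
    if len(hbond_targets) != len(set(hbond_targets)):
        raise FixtureError("one planted H-bond per target residue")
    # The backbone O of an H-bond target is reserved for the donor plant.
    from collections import Counter

    contact_counts = Counter((p.target_role, p.target_res)
                             for p in spec.planted_contacts)
    for tkey in hbond_targets:
        if contact_counts.get(tkey, 0) > len(_TARGET_ATOM_CYCLE) - 1:
            raise FixtureError(
                f"target residue {tkey} carries an H-bond plant; at most "
                f"{len(_TARGET_ATOM_CYCLE) - 1} contacts fit alongside"
            )


class _Builder:
    """Accumulates atoms for one chain at a time."""

    def __init__(self) -> None:
        self.chain_id: list[str] = []
        self.res_id: list[int] = []
        self.res_name: list[str] = []
        self.atom_name: list[str] = []
        self.element: list[str] = []
        self.coord: list[tuple[float, float, float]] = []

    def add_atom(self, chain: str, res: int, res_name: str, name: str,
                 element: str, xyz: np.ndarray | tuple) -> None:
        self.chain_id.append(chain)
        self.res_id.append(res)
        self.res_name.append(res_name)
        self.atom_name.append(name)
        self.element.append(element)
        self.coord.append(tuple(float(v) for v in xyz))

    def add_residue(self, chain: str, res: int, res_name: str,
                    ca: np.ndarray) -> None:
        for name, off in _BACKBONE.items():
            self.add_atom(chain, res, res_name, name, name[0],
                          ca + np.asarray(off))

    def to_array(self) -> struc.AtomArray:
        n = len(self.coord)
        arr = struc.AtomArray(n)
        arr._coord = np.asarray(self.coord, dtype=np.float64)
        arr.chain_id = np.asarray(self.chain_id)
        arr.res_id = np.asarray(self.res_id)
        arr.ins_code = np.full(n, "")
        arr.res_name = np.asarray(self.res_name)
        arr.atom_name = np.asarray(self.atom_name)
        arr.element = np.asarray(self.element)
        arr.hetero = np.full(n, False)
        return arr


def make_toy_complex(
    spec: ToyComplexSpec,
) -> tuple[StructureModel, ToyGroundTruth]:
    """Build a toy complex and its by-construction ground truth.

    Raises :class:`FixtureError` if the requested plants are infeasible
    (atom clash under 1 A) or if construction produced any accidental
    cross-interface contact, so a returned fixture is always exact.
    """
    _validate_toy_spec(spec)
    b = _Builder()
    pep_len = spec.peptide_length

    # --- target side -----------------------------------------------------
    # Peptide along +x at z=0, centered at the origin.
    pep_ca: dict[int, np.ndarray] = {}
    for i in range(pep_len):
        ca = np.array([(i - (pep_len - 1) / 2.0) * _SPACING, 0.0, 0.0])
        pep_ca[i + 1] = ca
        aa = ONE_TO_THREE[spec.peptide_sequence[i]]
        b.add_residue("C", i + 1, aa, ca)

    # MHC groove helices flank the peptide in the z=0 plane; all other MHC
    # residues pad the chain to full length well below the groove.
    mhc_ca: dict[int, np.ndarray] = {}
    bridge_targets = {(p.target_role, p.target_res): p
                      for p in spec.planted_salt_bridges}
    for res in range(1, spec.n_mhc_residues + 1):
        if _HELIX_RANGES[0][0] <= res <= _HELIX_RANGES[0][1]:
            k = res - (_HELIX_RANGES[0][0] + _HELIX_RANGES[0][1]) / 2.0
            ca = np.array([k * _SPACING, -_HELIX_Y, 0.0])
        elif _HELIX_RANGES[1][0] <= res <= _HELIX_RANGES[1][1]:
            k = res - (_HELIX_RANGES[1][0] + _HELIX_RANGES[1][1]) / 2.0
            ca = np.array([k * _SPACING, _HELIX_Y, 0.0])
        else:
            k = res - 1
            ca = np.array([(k % 40) * _SPACING - 100.0,
                           -30.0 - (k // 40) * _SPACING, _PAD_Z])
        mhc_ca[res] = ca
        res_name = "GLU" if ("mhc_heavy", res) in bridge_targets else "ALA"
        b.add_residue("A", res, res_name, ca)
        if res_name == "GLU":
            b.add_atom("A", res, "GLU", "OE1", "O",
                       ca + np.array([0.0, -1.6, 0.0]))

    # Peptide residues carrying a planted bridge also need the acid group.
    for (role, res), plant in bridge_targets.items():
        if role == "peptide":
            raise FixtureError(
                "salt-bridge plants on the peptide are not supported; "
                "target the MHC helices"
            )

    if spec.include_b2m:
        for res in range(1, 100):
            k = res - 1
            ca = np.array([(k % 40) * _SPACING - 100.0,
                           -30.0 - (k // 40) * _SPACING, _B2M_Z])
            b.add_residue("B", res, "ALA", ca)

    # --- binder ----------------------------------------------------------
    theta = np.radians(spec.binder_axis_angle)
    axis = np.array([np.cos(theta), np.sin(theta), 0.0])
    interface_res = sorted(
        {p.binder_res for p in spec.planted_contacts}
        | {p.binder_res for p in spec.planted_hbonds}
        | {p.binder_res for p in spec.planted_salt_bridges}
    )
    res_kind = {p.binder_res: "SER" for p in spec.planted_hbonds}
    res_kind.update({p.binder_res: "LYS"
                     for p in spec.planted_salt_bridges})

    binder_ca: dict[int, np.ndarray] = {}
    m = len(interface_res)
    for slot, res in enumerate(interface_res):
        t = (slot - (m - 1) / 2.0) * _SPACING
        binder_ca[res] = t * axis + np.array([0.0, 0.0, _BINDER_Z])
    core = [r for r in range(1, spec.n_binder_residues + 1)
            if r not in binder_ca]
    for k, res in enumerate(core):
        binder_ca[res] = np.array([(k % 20) * _SPACING - 50.0,
                                   40.0 + (k // 20) * _SPACING, _CORE_Z])
    for res in sorted(binder_ca):
        b.add_residue("D", res, res_kind.get(res, "ALA"), binder_ca[res])

    def target_atom_pos(role: str, res: int, name: str) -> np.ndarray:
        ca = pep_ca[res] if role == "peptide" else mhc_ca[res]
        return ca + np.asarray(_BACKBONE[name])

    # Planted plain contacts: a carbon pseudo-side-chain atom placed a
    # fixed gap above a target backbone atom; target atoms cycle so plants
    # sharing a target residue never coincide.
    used_target_atoms: dict[tuple[str, int], int] = {}
    used_binder_names: dict[int, int] = {}
    expected_pairs: set[tuple[int, str, int]] = set()
    hbond_target_keys = {(p.target_role, p.target_res)
                         for p in spec.planted_hbonds}
    for p in spec.planted_contacts:
        tkey = (p.target_role, p.target_res)
        cycle = _TARGET_ATOM_CYCLE
        if tkey in hbond_target_keys:  # backbone O reserved for the donor
            cycle = tuple(n for n in cycle if n != "O")
        idx = used_target_atoms.get(tkey, 0)
        if idx >= len(cycle):
            raise FixtureError(
                f"more than {len(cycle)} plants on target residue {tkey}"
            )
        used_target_atoms[tkey] = idx + 1
        tname = cycle[idx]
        nidx = used_binder_names.get(p.binder_res, 0)
        if nidx >= len(_CONTACT_ATOM_NAMES):
            raise FixtureError(
                f"more than {len(_CONTACT_ATOM_NAMES)} contacts on binder "
                f"residue {p.binder_res}"
            )
        used_binder_names[p.binder_res] = nidx + 1
        pos = target_atom_pos(p.target_role, p.target_res, tname) \
            + np.array([0.0, 0.0, p.gap])
        b.add_atom("D", p.binder_res, "ALA",
                   _CONTACT_ATOM_NAMES[nidx], "C", pos)
        expected_pairs.add((p.binder_res, p.target_role, p.target_res))

    # Planted H-bonds: serine OG donor above the target backbone O, with
    # CB placed to realise the requested antecedent-donor-acceptor angle.
    for p in spec.planted_hbonds:
        tkey = (p.target_role, p.target_res)
        acc = target_atom_pos(p.target_role, p.target_res, "O")
        og = acc + np.array([0.0, 0.0, p.distance])
        phi = np.radians(180.0 - p.angle)
        cb = og + 1.43 * np.array([np.sin(phi), 0.0, np.cos(phi)])
        b.add_atom("D", p.binder_res, "SER", "CB", "C", cb)
        b.add_atom("D", p.binder_res, "SER", "OG", "O", og)
        expected_pairs.add((p.binder_res, p.target_role, p.target_res))

    # Planted salt bridges: lysine NZ above the target glutamate OE1.
    for p in spec.planted_salt_bridges:
        acc = target_atom_pos(p.target_role, p.target_res, "CA") \
            + np.array([0.0, -1.6, 0.0])
        nz = acc + np.array([0.0, 0.0, p.distance])
        b.add_atom("D", p.binder_res, "LYS", "CE", "C",
                   nz + np.array([0.0, 0.0, 1.2]))
        b.add_atom("D", p.binder_res, "LYS", "NZ", "N", nz)
        expected_pairs.add((p.binder_res, p.target_role, p.target_res))

    arr = b.to_array()
    roles = {"A": "mhc_heavy", "C": "peptide", "D": "binder"}
    if spec.include_b2m:
        roles["B"] = "b2m"
    _verify_toy(arr, roles, expected_pairs)

    truth = ToyGroundTruth(
        roles=roles,
        binder_axis_angle=spec.binder_axis_angle,
        contact_pairs=sorted(expected_pairs),
        mhc_footprint=sorted({t for _, r, t in expected_pairs
                              if r == "mhc_heavy"}),
        peptide_footprint=sorted({t for _, r, t in expected_pairs
                                  if r == "peptide"}),
        binder_peptide_residues=sorted({bres for bres, r, _ in
                                        expected_pairs if r == "peptide"}),
        binder_interface_residues=interface_res,
        hbond_pairs=sorted((p.binder_res, p.target_role, p.target_res)
                           for p in spec.planted_hbonds),
        salt_bridge_pairs=sorted((p.binder_res, p.target_role, p.target_res)
                                 for p in spec.planted_salt_bridges),
    )
    model = StructureModel(id=f"toy-complex-{spec.seed}", atoms=arr)
    return model, truth


def _verify_toy(arr: struc.AtomArray, roles: dict[str, str],
                expected_pairs: set[tuple[int, str, int]],
                cutoff: float = 4.0) -> None:
    """Brute-force check: planted pairs exist, nothing else does."""
    coord = arr.coord
    # Global clash check.
    from scipy.spatial import cKDTree

    tree = cKDTree(coord)
    close = tree.query_pairs(r=1.0)
    clashes = [(i, j) for i, j in close
               if not (arr.chain_id[i] == arr.chain_id[j]
                       and arr.res_id[i] == arr.res_id[j])]
    if clashes:
        i, j = clashes[0]
        raise FixtureError(
            f"infeasible geometry: atoms closer than 1 A, e.g. "
            f"{arr.chain_id[i]}{arr.res_id[i]}/{arr.atom_name[i]} vs "
            f"{arr.chain_id[j]}{arr.res_id[j]}/{arr.atom_name[j]}"
        )

    binder = np.flatnonzero(arr.chain_id == "D")
    observed: set[tuple[int, str, int]] = set()
    for cid, role in roles.items():
        if role not in ("peptide", "mhc_heavy", "b2m"):
            continue
        tmask = np.flatnonzero(arr.chain_id == cid)
        d = np.linalg.norm(
            coord[binder][:, None, :] - coord[tmask][None, :, :], axis=2
        )
        for bi, ti in zip(*np.nonzero(d <= cutoff)):
            observed.add((
                int(arr.res_id[binder[bi]]),
                role,
                int(arr.res_id[tmask[ti]]),
            ))
    if observed != expected_pairs:
        extra = observed - expected_pairs
        missing = expected_pairs - observed
        raise FixtureError(
            f"fixture verification failed: accidental contacts {extra}, "
            f"missing plants {missing}"
        )


# ---------------------------------------------------------------------------
# Synthetic atlas
# ---------------------------------------------------------------------------

_AA = sorted(CANONICAL_LETTERS)


@dataclass(frozen=True)
class AtlasSpec:
    """Recipe for a synthetic immunopeptidome table.

    ``planted`` entries are (hamming distance, count, motif_preserving).
    Background peptides are sampled uniformly and rejected while they are
    closer than ``min_background_distance`` to the reference or happen to
    match the hotspot motif, so planted records are exactly the peptides
    a search can find.
    """

    reference: str = "SLLMWITQV"
    n_background: int = 14356
    planted: tuple[tuple[int, int, bool], ...] = (
        (4, 5, False), (5, 1, True), (6, 1, True),
    )
    motif_positions: tuple[int, ...] = (4, 5)
    min_background_distance: int = 5
    allele: str = "HLA-A*02:01"
    seed: int = 0


@dataclass
class AtlasGroundTruth:
    reference: str
    planted: list[dict]
    n_background: int
    motif_positions: tuple[int, ...]

    def to_json(self) -> str:
        return json.dumps(
            {
                "reference": self.reference,
                "planted": self.planted,
                "n_background": self.n_background,
                "motif_positions": list(self.motif_positions),
            },
            indent=2,
            sort_keys=True,
        )


def _mutate(rng: np.random.Generator, seq: str, positions: list[int]) -> str:
    out = list(seq)
    for pos in positions:
        choices = [a for a in _AA if a != seq[pos]]
        out[pos] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def make_synthetic_atlas(
    spec: AtlasSpec,
) -> tuple[list[PeptideRecord], AtlasGroundTruth]:
    """Sample an atlas with planted near-neighbours of the reference."""
    ref = spec.reference
    if not set(ref) <= CANONICAL_LETTERS:
        raise FixtureError(f"non-canonical reference {ref!r}")
    length = len(ref)
    motif = tuple(spec.motif_positions)
    for pos in motif:
        if not 1 <= pos <= length:
            raise FixtureError(f"motif position {pos} out of range")
    motif_idx = [p - 1 for p in motif]
    non_motif_idx = [i for i in range(length) if i not in motif_idx]

    rng = np.random.default_rng(spec.seed)
    planted_records: list[PeptideRecord] = []
    planted_truth: list[dict] = []
    seen: set[str] = {ref}
    for dist, count, preserve in spec.planted:
        if dist <= 0:
            raise FixtureError(
                f"cannot plant {count} records at Hamming distance {dist}"
            )
        if dist > length:
            raise FixtureError(f"planted distance {dist} exceeds length")
        if preserve and dist > len(non_motif_idx):
            raise FixtureError(
                f"cannot preserve motif {motif} at distance {dist}"
            )
        for _ in range(count):
            for _attempt in range(1000):
                if preserve:
                    pos = rng.choice(non_motif_idx, size=dist,
                                     replace=False).tolist()
                else:
                    # Always break the motif so motif-only searches find
                    # exactly the motif-preserving plants.
                    first = motif_idx[int(rng.integers(len(motif_idx)))] \
                        if motif_idx else int(rng.integers(length))
                    rest_pool = [i for i in range(length) if i != first]
                    pos = [first] + rng.choice(
                        rest_pool, size=dist - 1, replace=False
                    ).tolist()
                seq = _mutate(rng, ref, pos)
                if seq not in seen:
                    break
            else:
                raise FixtureError("could not plant a unique sequence")
            seen.add(seq)
            planted_records.append(PeptideRecord(
                sequence=seq, allele=spec.allele,
                source=f"planted:d{dist}"
                       + (":motif" if preserve else ""),
            ))
            planted_truth.append({
                "sequence": seq, "hamming": dist,
                "motif_preserving": bool(preserve),
            })

    background: list[PeptideRecord] = []
    while len(background) < spec.n_background:
        seq = "".join(_AA[i] for i in rng.integers(len(_AA), size=length))
        if hamming(seq, ref) < spec.min_background_distance:
            continue
        if motif_idx and all(seq[i] == ref[i] for i in motif_idx):
            continue
        if seq in seen:
            continue
        seen.add(seq)
        background.append(PeptideRecord(sequence=seq, allele=spec.allele,
                                        source="background"))

    records = planted_records + background
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    truth = AtlasGroundTruth(
        reference=ref,
        planted=planted_truth,
        n_background=spec.n_background,
        motif_positions=motif,
    )
    return records, truth


# ---------------------------------------------------------------------------
# Study-scale fixture specifications
# ---------------------------------------------------------------------------

def study_complex_spec(seed: int = 0) -> ToyComplexSpec:
    """Toy complex mirroring the study's headline interface structure.

    14 binder residues contact the peptide (11 plain contacts plus 3
    hydrogen bonds, concentrated on the up-facing hotspot positions 4 and
    5), 19 MHC helix residues are contacted (13 plain contacts, 5
    hydrogen bonds, 1 salt bridge — the classical TCR anchor residues
    among them), and the binder axis crosses the groove at 40 degrees.
    """
    pep_contacts = [4, 4, 4, 4, 5, 5, 5, 7, 8, 1, 3]
    mhc_contacts = [58, 62, 65, 66, 69, 72, 73, 76, 146, 150, 151, 155, 158]
    mhc_hbond_targets = [68, 75, 142, 154, 162]
    contacts = tuple(
        [PlantedContact(binder_res=i + 1, target_role="peptide",
                        target_res=t)
         for i, t in enumerate(pep_contacts)]
        + [PlantedContact(binder_res=i + 15, target_role="mhc_heavy",
                          target_res=t)
           for i, t in enumerate(mhc_contacts)]
    )
    hbonds = tuple(
        [PlantedHBond(binder_res=12, target_role="peptide", target_res=5),
         PlantedHBond(binder_res=13, target_role="peptide", target_res=7),
         PlantedHBond(binder_res=14, target_role="peptide", target_res=8)]
        + [PlantedHBond(binder_res=i + 28, target_role="mhc_heavy",
                        target_res=t)
           for i, t in enumerate(mhc_hbond_targets)]
    )
    bridges = (PlantedSaltBridge(binder_res=33, target_role="mhc_heavy",
                                 target_res=166),)
    return ToyComplexSpec(
        planted_contacts=contacts,
        planted_hbonds=hbonds,
        planted_salt_bridges=bridges,
        binder_axis_angle=40.0,
        seed=seed,
    )


def study_atlas_spec(seed: int = 0, n_background: int = 14356) -> AtlasSpec:
    """Atlas mirroring the structure of the MS-detected 9-mer screen."""
    return AtlasSpec(n_background=n_background, seed=seed)


def write_fixture_dir(
    outdir: str | Path,
    toy_spec: ToyComplexSpec | None = None,
    atlas_spec: AtlasSpec | None = None,
) -> dict[str, Path]:
    """Write a fixture directory: PDB complex, atlas TSV, truth JSONs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    toy_spec = toy_spec or study_complex_spec()
    atlas_spec = atlas_spec or AtlasSpec(n_background=1000,
                                         seed=toy_spec.seed)
    model, truth = make_toy_complex(toy_spec)
    records, atlas_truth = make_synthetic_atlas(atlas_spec)

    paths = {
        "complex": outdir / "complex.pdb",
        "complex_truth": outdir / "complex_truth.json",
        "atlas": outdir / "atlas.tsv",
        "atlas_truth": outdir / "atlas_truth.json",
    }
    write_structure(model, paths["complex"])
    paths["complex_truth"].write_text(truth.to_json() + "\n")
    with paths["atlas"].open("w") as fh:
        fh.write("sequence\tallele\tsource\n")
        for rec in records:
            fh.write(f"{rec.sequence}\t{rec.allele}\t{rec.source}\n")
    paths["atlas_truth"].write_text(atlas_truth.to_json() + "\n")
    return paths
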