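"""Docking geometry over the MHC groove and rigid-body superposition.

The groove frame is built from the class I MHC architecture: the alpha-1
and alpha-2 helices (author residues 50-84 and 138-180 by default) flank
the peptide, and a least-squares plane through their C-alpha atoms defines
the "top of the MHC". The peptide axis is the first principal component of
the peptide C-alpha coordinates, oriented N- to C-terminus and projected
into that plane. A binder's docking angle is then the in-plane angle
between its interface axis (first principal component of the C-alpha
atoms of its interface residues) and the peptide axis, folded into
[0, 90] degrees because the binder axis has no intrinsic sign. Natural
TCRs dock diagonally at roughly 30-70 degrees by comparable conventions.

Superposition uses the Kabsch algorithm (SVD of the cross-covariance,
with reflection correction), the standard least-squares optimal rigid
alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import biotite.structure as struc

from .errors import GeometryError
from .interface import contact_residues, peptide_contacting_residues
from .structure import StructureModel

__all__ = [
    "AxisFrame",
    "DockingGeometry",
    "SuperpositionResult",
    "fit_mhc_frame",
    "docking_angle",
    "kabsch_superpose",
    "align_pair",
    "DEFAULT_HELIX_RANGES",
]

#: Author-numbering ranges of the class I alpha-1 and alpha-2 helices.
DEFAULT_HELIX_RANGES = ((50, 84), (138, 180))


@dataclass(frozen=True)
class AxisFrame:
    """Groove coordinate frame: origin, plane normal, peptide axis."""

    origin: np.ndarray
    groove_plane_normal: np.ndarray
    peptide_axis: np.ndarray

    def project(self, v: np.ndarray) -> np.ndarray:
        """Project a vector into the groove plane."""
        n = self.groove_plane_normal
        return v - np.dot(v, n) * n


@dataclass(frozen=True)
class DockingGeometry:
    angle: float            # degrees, in [0, 90]
    binder_axis: np.ndarray  # unit vector, in the groove plane
    frame: AxisFrame
    n_interface_residues: int


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray     # 3x3, det = +1
    translation: np.ndarray  # applied after rotation
    rmsd: float
    n_atoms: int
    unmatched: tuple = ()


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GeometryError(f"degenerate {what}: zero-length vector")
    return v / n


def _principal_axis(points: np.ndarray) -> np.ndarray:
    """First principal component of a point cloud (unit vector)."""
    centered = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-9:
        raise GeometryError("degenerate axis fit: coincident points")
    return vt[0]


def _ca_coords(model: StructureModel, chain_id: str,
               res_range: tuple[int, int] | None = None) -> np.ndarray:
    arr = model.chain(chain_id)
    mask = (arr.atom_name == "CA") & ~arr.hetero
    mask &= struc.filter_amino_acids(arr)
    if res_range is not None:
        mask &= (arr.res_id >= res_range[0]) & (arr.res_id <= res_range[1])
    return arr.coord[mask]


def fit_mhc_frame(
    model: StructureModel,
    roles: Mapping[str, str],
    helix_ranges: Sequence[tuple[int, int]] = DEFAULT_HELIX_RANGES,
) -> AxisFrame:
    """Least-squares groove frame from the MHC helices and the peptide.

    The plane normal is oriented toward the peptide centroid side of the
    helix plane (i.e. "up", out of the groove); the peptide axis points
    from P1 to PN.
    """
    mhc_chain = next((c for c, r in roles.items() if r == "mhc_heavy"), None)
    pep_chain = next((c for c, r in roles.items() if r == "peptide"), None)
    if mhc_chain is None or pep_chain is None:
        raise GeometryError("role map must contain mhc_heavy and peptide")

    helix_ca = [
        _ca_coords(model, mhc_chain, res_range=rng) for rng in helix_ranges
    ]
    helix_ca = np.concatenate([h for h in helix_ca if len(h)], axis=0) \
        if any(len(h) for h in helix_ca) else np.empty((0, 3))
    if len(helix_ca) < 3:
        raise GeometryError(
            f"fewer than 3 helix C-alpha atoms in ranges {helix_ranges}"
        )

    centroid = helix_ca.mean(axis=0)
    centered = helix_ca - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9:
        raise GeometryError("collinear helix atoms: groove plane undefined")
    normal = vt[2]

    pep_ca = _ca_coords(model, pep_chain)
    if len(pep_ca) < 3:
        raise GeometryError(
            f"fewer than 3 peptide C-alpha atoms (found {len(pep_ca)})"
        )
    # Orient the normal out of the groove, toward the peptide.
    pep_centroid = pep_ca.mean(axis=0)
    if np.dot(pep_centroid - centroid, normal) < 0:
        normal = -normal

    axis = _principal_axis(pep_ca)
    # Orient P1 -> PN (chain order).
    if np.dot(pep_ca[-1] - pep_ca[0], axis) < 0:
        axis = -axis
    axis_in_plane = axis - np.dot(axis, normal) * normal
    axis_in_plane = _unit(axis_in_plane,
                          "peptide axis (parallel to plane normal)")
    return AxisFrame(
        origin=pep_centroid,
        groove_plane_normal=_unit(normal, "plane normal"),
        peptide_axis=axis_in_plane,
    )


def docking_angle(
    model: StructureModel,
    roles: Mapping[str, str],
    helix_ranges: Sequence[tuple[int, int]] = DEFAULT_HELIX_RANGES,
    contact_cutoff: float = 4.0,
    binder_roles: Sequence[str] = ("binder",),
) -> DockingGeometry:
    """In-plane angle between the binder interface axis and the peptide.

    Interface residues are binder residues contacting the peptide or the
    MHC heavy chain (heavy atoms within ``contact_cutoff``).
    """
    frame = fit_mhc_frame(model, roles, helix_ranges=helix_ranges)

    fp_pep = peptide_contacting_residues(model, roles, cutoff=contact_cutoff,
                                         binder_roles=binder_roles)
    fp_mhc = contact_residues(model, roles, ("mhc_heavy",), binder_roles,
                              cutoff=contact_cutoff)
    iface_keys = {(r.chain_id, r.res_seq, r.ins_code)
                  for r in fp_pep.residues + fp_mhc.residues}
    if len(iface_keys) < 3:
        raise GeometryError(
            f"only {len(iface_keys)} binder interface residues; "
            "need at least 3 for an axis"
        )

    atoms = model.atoms
    mask = np.zeros(atoms.array_length(), dtype=bool)
    for i in range(atoms.array_length()):
        if str(atoms.atom_name[i]) != "CA":
            continue
        key = (str(atoms.chain_id[i]), int(atoms.res_id[i]),
               str(atoms.ins_code[i]))
        if key in iface_keys:
            mask[i] = True
    ca = atoms.coord[mask]
    if len(ca) < 3:
        raise GeometryError("fewer than 3 interface C-alpha atoms")

    axis = _principal_axis(ca)
    axis_in_plane = frame.project(axis)
    axis_in_plane = _unit(axis_in_plane,
                          "binder axis (perpendicular to groove plane)")
    cosang = abs(float(np.dot(axis_in_plane, frame.peptide_axis)))
    angle = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
    return DockingGeometry(
        angle=angle,
        binder_axis=axis_in_plane,
        frame=frame,
        n_interface_residues=len(iface_keys),
    )


def kabsch_superpose(coords_a: np.ndarray,
                     coords_b: np.ndarray) -> SuperpositionResult:
    """Optimal rigid superposition of ``coords_b`` onto ``coords_a``.

    Correspondence is by row order. Returns the proper rotation R and
    translation t minimising ``|| coords_a - (coords_b R^T + t) ||`` and
    the post-fit RMSD.
    """
    a = np.asarray(coords_a, dtype=np.float64)
    b = np.asarray(coords_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise GeometryError(
            f"coordinate shapes must match and be (N, 3); got "
            f"{a.shape} and {b.shape}"
        )
    n = a.shape[0]
    if n < 3:
        raise GeometryError(f"need at least 3 atom pairs, got {n}")
    ca = a.mean(axis=0)
    cb = b.mean(axis=0)
    a0 = a - ca
    b0 = b - cb
    if np.linalg.matrix_rank(np.vstack([a0, b0]), tol=1e-9) < 2:
        raise GeometryError("degenerate (collinear/coincident) coordinates")
    h = b0.T @ a0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    b_fit = b0 @ rot.T
    rmsd = float(np.sqrt(((a0 - b_fit) ** 2).sum() / n))
    translation = ca - cb @ rot.T
    return SuperpositionResult(rotation=rot, translation=translation,
                               rmsd=rmsd, n_atoms=n)


def align_pair(
    model_a: StructureModel,
    model_b: StructureModel,
    roles_a: Mapping[str, str],
    roles_b: Mapping[str, str],
    role_subset: Sequence[str] = ("mhc_heavy", "peptide"),
    atom_selection: str = "ca",
) -> SuperpositionResult:
    """Superpose two models on residues matched by (role, res_seq).

    ``atom_selection`` is ``"ca"`` (C-alpha only) or ``"heavy"`` (all
    heavy atoms, additionally matched by atom name). Residues present in
    only one model are excluded and reported in ``unmatched``.
    """
    if atom_selection not in ("ca", "heavy"):
        raise GeometryError(f"unknown atom selection {atom_selection!r}")

    def collect(model: StructureModel, roles: Mapping[str, str]
                ) -> dict[tuple, np.ndarray]:
        out: dict[tuple, np.ndarray] = {}
        atoms = model.atoms
        role_by_chain = dict(roles)
        keep = set(role_subset)
        aa = struc.filter_amino_acids(atoms)
        for i in range(atoms.array_length()):
            role = role_by_chain.get(str(atoms.chain_id[i]), "other")
            if role not in keep or not aa[i] or atoms.hetero[i]:
                continue
            if str(atoms.element[i]) == "H":
                continue
            name = str(atoms.atom_name[i])
            if atom_selection == "ca" and name != "CA":
                continue
            key = (role, int(atoms.res_id[i]), str(atoms.ins_code[i]), name)
            out[key] = atoms.coord[i]
        return out

    map_a = collect(model_a, roles_a)
    map_b = collect(model_b, roles_b)
    shared = sorted(set(map_a) & set(map_b))
    unmatched_res = sorted(
        {k[:3] for k in set(map_a) ^ set(map_b)}
    )
    if len(shared) < 3:
        raise GeometryError(
            f"only {len(shared)} matched atoms between models; need >= 3"
        )
    coords_a = np.array([map_a[k] for k in shared])
    coords_b = np.array([map_b[k] for k in shared])
    result = kabsch_superpose(coords_a, coords_b)
    return SuperpositionResult(
        rotation=result.rotation,
        translation=result.translation,
        rmsd=result.rmsd,
        n_atoms=result.n_atoms,
        unmatched=tuple(unmatched_res),
    )
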