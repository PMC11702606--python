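"""Solvent-accessible surface area by the Shrake-Rupley method.

Each heavy atom is inflated by the probe radius and covered with a
deterministic Fibonacci (golden-spiral) point lattice; a point is
accessible if it lies outside every neighbouring inflated sphere. The
accessible fraction times the inflated-sphere area gives the per-atom
SASA. No randomness is involved: results are exactly reproducible for a
given point count.

Hydrogens and atoms of unknown element are handled explicitly: hydrogens
are silently excluded (X-ray depositions usually lack them, so heavy-atom
areas are the comparable quantity), while an element missing from the
radius table raises, because silently dropping it would corrupt areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
import biotite.structure as struc

from ._chem import N_SPHERE_POINTS, PROBE_RADIUS, VDW_RADII
from .errors import SasaError
from .structure import StructureModel

__all__ = ["SasaResult", "compute_sasa", "sphere_points"]

#: Residue key: (chain_id, res_seq, ins_code)
ResidueKey = tuple[str, int, str]


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral lattice of ``n`` unit vectors."""
    i = np.arange(n, dtype=np.float64)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack((r * np.cos(phi), r * np.sin(phi), z))


@dataclass
class SasaResult:
    """Per-atom and per-residue accessible surface areas (A^2)."""

    per_atom_area: np.ndarray          # aligned with the input atoms; 0 for H
    per_residue_area: dict[ResidueKey, float]
    total: float
    probe_radius: float
    n_points: int
    res_names: dict[ResidueKey, str] = field(default_factory=dict)


def _radii_for(atoms: struc.AtomArray) -> np.ndarray:
    radii = np.empty(atoms.array_length())
    for i, elem in enumerate(atoms.element):
        e = str(elem).upper()
        r = VDW_RADII.get(e)
        if r is None:
            raise SasaError(
                f"no van der Waals radius configured for element {e!r} "
                f"(atom {atoms.atom_name[i]!r}, residue "
                f"{atoms.res_name[i]}{atoms.res_id[i]})"
            )
        radii[i] = r
    return radii


def compute_sasa(
    model: StructureModel | struc.AtomArray,
    probe: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
) -> SasaResult:
    """Shrake-Rupley SASA of all heavy atoms of a model.

    Parameters
    ----------
    model:
        Structure (or bare ``AtomArray``); hydrogens are ignored.
    probe:
        Probe sphere radius in Angstrom (water: 1.4).
    n_points:
        Sphere sample points per atom; at least 92. Area resolution per
        atom is (inflated sphere area) / n_points.
    """
    atoms = model.atoms if isinstance(model, StructureModel) else model
    if n_points < 92:
        raise SasaError(f"n_points={n_points} too small (minimum 92)")
    if probe < 0:
        raise SasaError(f"probe radius must be non-negative, got {probe}")

    heavy = atoms.element != "H"
    sub = atoms[heavy]
    n = sub.array_length()
    if n == 0:
        raise SasaError("model has no heavy atoms")

    radii = _radii_for(sub) + probe
    xyz = sub.coord.astype(np.float64)
    unit = sphere_points(n_points)

    tree = cKDTree(xyz)
    max_r = float(radii.max())
    area_sub = np.empty(n)
    point_area = 4.0 * np.pi * radii**2 / n_points
    # Neighbour lists: atoms whose inflated spheres can intersect.
    neighbor_lists = tree.query_ball_point(xyz, r=radii + max_r)
    for i in range(n):
        nbrs = [j for j in neighbor_lists[i]
                if j != i
                and np.dot(xyz[j] - xyz[i], xyz[j] - xyz[i])
                < (radii[i] + radii[j]) ** 2]
        pts = xyz[i] + radii[i] * unit
        if nbrs:
            d2 = ((pts[:, None, :] - xyz[nbrs][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (radii[nbrs] ** 2)[None, :]).any(axis=1)
            n_acc = int((~buried).sum())
        else:
            n_acc = n_points
        area_sub[i] = n_acc * point_area[i]

    per_atom = np.zeros(atoms.array_length())
    per_atom[np.flatnonzero(heavy)] = area_sub

    per_res: dict[ResidueKey, float] = {}
    res_names: dict[ResidueKey, str] = {}
    for i in np.flatnonzero(heavy):
        key = (str(atoms.chain_id[i]), int(atoms.res_id[i]),
               str(atoms.ins_code[i]))
        per_res[key] = per_res.get(key, 0.0) + per_atom[i]
        res_names.setdefault(key, str(atoms.res_name[i]))

    return SasaResult(
        per_atom_area=per_atom,
        per_residue_area=per_res,
        total=float(per_atom.sum()),
        probe_radius=probe,
        n_points=n_points,
        res_names=res_names,
    )
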