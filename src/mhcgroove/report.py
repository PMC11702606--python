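"""Report assembly: machine-readable summaries of a full analysis.

Every report echoes the full run configuration and the package version,
so two runs with identical inputs and configuration produce byte-identical
files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .geometry import DEFAULT_HELIX_RANGES, docking_angle
from .interface import (
    InterfaceReport,
    compare_footprints,
    compute_interface,
)
from .structure import StructureModel, peptide_positions

__all__ = ["RunConfig", "analyze_structure", "compare_structures",
           "interface_to_dict", "dsasa_tsv", "write_json"]


@dataclass(frozen=True)
class RunConfig:
    """All tunable parameters of an analysis run."""

    probe: float = 1.4
    n_points: int = 960
    contact_cutoff: float = 4.0
    hbond_d_max: float = 3.5
    hbond_angle_min: float = 90.0
    salt_bridge_d_max: float = 4.0
    helix_ranges: tuple[tuple[int, int], ...] = DEFAULT_HELIX_RANGES
    scorer_backend: str = "blosum62"
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["helix_ranges"] = [list(r) for r in self.helix_ranges]
        return d


def _tag_dict(tag) -> dict:
    return {
        "role": tag.role,
        "chain_id": tag.chain_id,
        "res_seq": tag.res_seq,
        "ins_code": tag.ins_code,
        "res_name": tag.res_name,
    }


def interface_to_dict(report: InterfaceReport) -> dict:
    """JSON-serializable form of an interface report."""
    return {
        "side_a": list(report.side_a),
        "side_b": list(report.side_b),
        "bsa_total": round(report.bsa_total, 3),
        "interface_area": round(report.interface_area, 3),
        "peptide_fraction": None if report.peptide_fraction is None
        else round(report.peptide_fraction, 4),
        "peptide_burial_fraction":
            None if report.peptide_burial_fraction is None
            else round(report.peptide_burial_fraction, 4),
        "n_hbonds": len(report.hbonds),
        "n_salt_bridges": len(report.salt_bridges),
        "hbonds": [
            {
                "donor": {**_tag_dict(h.donor.residue),
                          "atom": h.donor.atom_name},
                "acceptor": {**_tag_dict(h.acceptor.residue),
                             "atom": h.acceptor.atom_name},
                "distance": round(h.distance, 3),
                "angle": round(h.angle, 1),
                "donor_side": h.donor_side,
            }
            for h in report.hbonds
        ],
        "salt_bridges": [
            {
                "basic": {**_tag_dict(sb.basic.residue),
                          "atom": sb.basic.atom_name},
                "acidic": {**_tag_dict(sb.acidic.residue),
                           "atom": sb.acidic.atom_name},
                "distance": round(sb.distance, 3),
            }
            for sb in report.salt_bridges
        ],
        "target_footprint": [_tag_dict(r) for r in
                             report.target_contact_residues.residues],
        "binder_footprint": [_tag_dict(r) for r in
                             report.binder_contact_residues.residues],
        "per_residue_dsasa": [
            {**_tag_dict(t), "dsasa": round(v, 3)}
            for t, v in sorted(report.per_residue_dsasa.items())
            if v > 1e-6
        ],
        "parameters": report.parameters,
    }


def dsasa_tsv(report: InterfaceReport) -> str:
    """Per-residue buried area as TSV (chain, number, name, dSASA)."""
    lines = ["chain\trole\tres_seq\tins_code\tres_name\tdsasa"]
    for t, v in sorted(report.per_residue_dsasa.items()):
        lines.append(
            f"{t.chain_id}\t{t.role}\t{t.res_seq}\t{t.ins_code}\t"
            f"{t.res_name}\t{v:.3f}"
        )
    return "\n".join(lines) + "\n"


def analyze_structure(
    model: StructureModel,
    roles: Mapping[str, str],
    config: RunConfig = RunConfig(),
) -> dict:
    """Full single-structure analysis: interface report + docking angle."""
    report = compute_interface(
        model, roles,
        probe=config.probe, n_points=config.n_points,
        contact_cutoff=config.contact_cutoff,
        hbond_d_max=config.hbond_d_max,
        hbond_angle_min=config.hbond_angle_min,
        salt_bridge_d_max=config.salt_bridge_d_max,
    )
    geo = docking_angle(model, roles, helix_ranges=config.helix_ranges,
                        contact_cutoff=config.contact_cutoff)
    mhc_fp = [r for r in report.target_contact_residues.residues
              if r.role == "mhc_heavy"]
    out = {
        "structure_id": model.id,
        "roles": dict(roles),
        "interface": interface_to_dict(report),
        "n_mhc_footprint": len(mhc_fp),
        "n_peptide_contacting_binder_residues": len(
            {(r.chain_id, r.res_seq, r.ins_code)
             for r in _peptide_contacting(model, roles, config).residues}
        ),
        "docking_angle_deg": round(geo.angle, 2),
        "n_interface_residues": geo.n_interface_residues,
        "frame": {
            "origin": [round(float(x), 3) for x in geo.frame.origin],
            "groove_plane_normal": [round(float(x), 6)
                                    for x in geo.frame.groove_plane_normal],
            "peptide_axis": [round(float(x), 6)
                             for x in geo.frame.peptide_axis],
            "binder_axis": [round(float(x), 6) for x in geo.binder_axis],
        },
        "peptide": [
            {"position": pos, "res_name": name, "author_res_seq": seq}
            for pos, name, seq in peptide_positions(model, roles)
        ],
        "config": config.to_dict(),
        "version": __version__,
    }
    return out


def _peptide_contacting(model, roles, config):
    from .interface import peptide_contacting_residues

    return peptide_contacting_residues(model, roles,
                                       cutoff=config.contact_cutoff)


def compare_structures(
    models_roles: Sequence[tuple[StructureModel, Mapping[str, str]]],
    config: RunConfig = RunConfig(),
) -> dict:
    """Side-by-side comparison of 2-3 binders on the same pMHC target.

    Rows carry per-structure footprint sizes, buried areas and docking
    angles; the shared footprint intersects the MHC-residue footprints
    across all structures (matched by author numbering).
    """
    from .interface import contact_residues

    rows = []
    mhc_footprints = []
    for model, roles in models_roles:
        summary = analyze_structure(model, roles, config)
        fp = contact_residues(model, roles, ("binder",), ("mhc_heavy",),
                              cutoff=config.contact_cutoff)
        mhc_footprints.append(fp)
        rows.append({
            "structure_id": model.id,
            "n_mhc_footprint": fp.size,
            "bsa_total": summary["interface"]["bsa_total"],
            "interface_area": summary["interface"]["interface_area"],
            "peptide_fraction": summary["interface"]["peptide_fraction"],
            "peptide_burial_fraction":
                summary["interface"]["peptide_burial_fraction"],
            "n_hbonds": summary["interface"]["n_hbonds"],
            "n_salt_bridges": summary["interface"]["n_salt_bridges"],
            "docking_angle_deg": summary["docking_angle_deg"],
        })
    shared = compare_footprints(mhc_footprints) if len(mhc_footprints) >= 2 \
        else ()
    return {
        "structures": rows,
        "shared_footprint": [_tag_dict(r) for r in shared],
        "n_shared_footprint": len(shared),
        "config": config.to_dict(),
        "version": __version__,
    }


def write_json(data: dict, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(data, indent=2, sort_keys=True) + "\n"
    )
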