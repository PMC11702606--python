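"""Buried surface area, contacts, hydrogen bonds and report diffs."""

import numpy as np
import pytest

from mhcgroove.errors import SelectionError
from mhcgroove.interface import (
    compare_footprints,
    compute_interface,
    contact_residues,
    detect_hbonds,
    detect_salt_bridges,
    diff_interfaces,
    peptide_contacting_residues,
)
from mhcgroove.sasa import compute_sasa
from mhcgroove.synthetic import (
    PlantedHBond,
    ToyComplexSpec,
    make_toy_complex,
    study_complex_spec,
)

from conftest import (
    build_model,
    brute_force_contact_pairs,
    random_two_chain_model,
)

AB_ROLES = {"A": "binder", "B": "peptide"}


def test_separated_chains_have_no_interface():
    rows = [("A", 1, "ALA", "CA", "C", (0.0, 0.0, 0.0)),
            ("A", 2, "ALA", "CA", "C", (6.0, 0.0, 0.0)),
            ("B", 1, "ALA", "CA", "C", (50.0, 0.0, 0.0)),
            ("B", 2, "ALA", "CA", "C", (56.0, 0.0, 0.0))]
    model = build_model(rows)
    rep = compute_interface(model, AB_ROLES, ("binder",), ("peptide",))
    assert rep.bsa_total == pytest.approx(0.0, abs=1e-9)
    assert rep.target_contact_residues.size == 0
    assert rep.hbonds == [] and rep.salt_bridges == []


@pytest.mark.parametrize("k", [1, 2, 3])
def test_exactly_k_target_residues_lose_area(k):
    # 5 isolated target residues 12 A apart; k binder atoms hover 4 A
    # above the first k, far outside occlusion range of the others.
    rows = [("B", i + 1, "ALA", "CA", "C", (i * 12.0, 0.0, 0.0))
            for i in range(5)]
    rows += [("A", j + 1, "ALA", "CA", "C", (j * 12.0, 0.0, 4.0))
             for j in range(k)]
    model = build_model(rows)
    rep = compute_interface(model, AB_ROLES, ("binder",), ("peptide",))
    support = {t.res_seq for t, v in rep.per_residue_dsasa.items()
               if t.role == "peptide" and v > 1e-6}
    assert support == set(range(1, k + 1))


def test_bsa_is_symmetric_and_subadditive(study_complex):
    model, _, roles = study_complex
    ab = compute_interface(model, roles, ("binder",), ("mhc_heavy",))
    ba = compute_interface(model, roles, ("mhc_heavy",), ("binder",))
    assert ab.bsa_total == pytest.approx(ba.bsa_total, abs=1e-6)
    assert ab.bsa_total >= 0
    # peptide fraction undefined when the peptide is not on side_b
    assert ba.peptide_fraction is None

    # SASA(A+B) <= SASA(A) + SASA(B)
    arr = model.atoms
    a = arr[arr.chain_id == "D"]
    b = arr[arr.chain_id == "C"]
    both = a + b
    assert compute_sasa(both).total <= (
        compute_sasa(a).total + compute_sasa(b).total + 1e-9
    )


def test_contact_cutoff_boundary():
    rows = [("A", 1, "ALA", "CA", "C", (0.0, 0.0, 0.0)),
            ("B", 1, "ALA", "CA", "C", (3.9, 0.0, 0.0))]
    model = build_model(rows)
    assert contact_residues(model, AB_ROLES, ("binder",), ("peptide",),
                            cutoff=4.0).size == 1
    rows[1] = ("B", 1, "ALA", "CA", "C", (4.1, 0.0, 0.0))
    model = build_model(rows)
    assert contact_residues(model, AB_ROLES, ("binder",), ("peptide",),
                            cutoff=4.0).size == 0
    with pytest.raises(SelectionError):
        contact_residues(model, AB_ROLES, ("binder",), ("peptide",),
                         cutoff=-1.0)
    with pytest.raises(SelectionError):
        contact_residues(model, AB_ROLES, ("binder",), ("binder",))


def test_footprint_monotone_in_cutoff(rng):
    model = random_two_chain_model(rng)
    prev = None
    for cutoff in (2.5, 3.5, 4.5, 6.0):
        fp = contact_residues(model, AB_ROLES, ("binder",), ("peptide",),
                              cutoff=cutoff)
        if prev is not None:
            assert prev.keys() <= fp.keys()
        prev = fp


def test_contacts_match_brute_force_oracle(rng, study_complex):
    for _ in range(3):
        model = random_two_chain_model(rng, n_a=40, n_b=40)
        fp = contact_residues(model, AB_ROLES, ("binder",), ("peptide",),
                              cutoff=4.0)
        oracle = brute_force_contact_pairs(model, AB_ROLES, ("binder",),
                                           ("peptide",), 4.0)
        assert {(r.chain_id, r.res_seq, r.ins_code)
                for r in fp.residues} == oracle

    model, truth, roles = study_complex
    fp = contact_residues(model, roles, ("binder",), ("mhc_heavy",))
    oracle = brute_force_contact_pairs(model, roles, ("binder",),
                                       ("mhc_heavy",), 4.0)
    assert {(r.chain_id, r.res_seq, r.ins_code)
            for r in fp.residues} == oracle
    assert sorted(r.res_seq for r in fp.residues) == truth.mhc_footprint


def test_peptide_contacting_residues_on_study_fixture(study_complex):
    model, truth, roles = study_complex
    fp = peptide_contacting_residues(model, roles)
    assert sorted(r.res_seq for r in fp.residues) \
        == truth.binder_peptide_residues
    assert fp.size == 14


def _hbond_model(distance, angle_deg):
    """Serine OG donor above an alanine backbone O acceptor."""
    og = np.array([0.0, 0.0, distance])
    phi = np.radians(180.0 - angle_deg)
    cb = og + 1.43 * np.array([np.sin(phi), 0.0, np.cos(phi)])
    rows = [
        ("B", 1, "ALA", "CA", "C", (-1.2, -1.8, 0.0)),
        ("B", 1, "ALA", "C", "C", (0.0, -1.2, 0.0)),
        ("B", 1, "ALA", "O", "O", (0.0, 0.0, 0.0)),
        ("A", 1, "SER", "CA", "C", tuple(cb + np.array([0.0, 0.0, 1.5]))),
        ("A", 1, "SER", "CB", "C", tuple(cb)),
        ("A", 1, "SER", "OG", "O", tuple(og)),
    ]
    return build_model(rows)


@pytest.mark.parametrize("distance,angle,expected", [
    (2.9, 150.0, 1),   # ideal geometry
    (3.8, 150.0, 0),   # beyond distance cutoff
    (2.9, 60.0, 0),    # angle criterion fails
    (3.4, 100.0, 1),   # loose but acceptable
])
def test_hbond_geometric_criteria(distance, angle, expected):
    model = _hbond_model(distance, angle)
    bonds = detect_hbonds(model, AB_ROLES, ("binder",), ("peptide",))
    assert len(bonds) == expected
    if expected:
        (bond,) = bonds
        assert bond.donor.atom_name == "OG"
        assert bond.acceptor.atom_name == "O"
        assert bond.distance == pytest.approx(distance, abs=1e-6)
        assert bond.angle == pytest.approx(angle, abs=0.5)
        assert bond.donor_side == "a"


def test_hbonds_on_study_fixture_match_ground_truth(study_complex):
    model, truth, roles = study_complex
    mhc = detect_hbonds(model, roles, ("binder",), ("mhc_heavy",))
    pep = detect_hbonds(model, roles, ("binder",), ("peptide",))
    assert len(mhc) == 5 and len(pep) == 3
    got = sorted((b.donor.res_seq, b.acceptor.role, b.acceptor.res_seq)
                 for b in mhc + pep)
    assert got == truth.hbond_pairs


@pytest.mark.parametrize("distance,expected", [(3.2, 1), (4.5, 0)])
def test_salt_bridge_distance_criterion(distance, expected):
    rows = [
        ("B", 1, "GLU", "CA", "C", (0.0, -1.6, 0.0)),
        ("B", 1, "GLU", "OE1", "O", (0.0, 0.0, 0.0)),
        ("A", 1, "LYS", "CA", "C", (0.0, 0.0, distance + 2.5)),
        ("A", 1, "LYS", "NZ", "N", (0.0, 0.0, distance)),
    ]
    model = build_model(rows)
    bridges = detect_salt_bridges(model, AB_ROLES, ("binder",),
                                  ("peptide",))
    assert len(bridges) == expected
    if expected:
        assert bridges[0].basic.atom_name == "NZ"
        assert bridges[0].acidic.atom_name == "OE1"
        assert bridges[0].distance == pytest.approx(distance, abs=1e-6)


def test_one_bridge_per_residue_pair():
    # Both OE1 and OE2 within range of NZ: still a single reported bridge.
    rows = [
        ("B", 1, "GLU", "OE1", "O", (0.0, 0.0, 0.0)),
        ("B", 1, "GLU", "OE2", "O", (1.0, 0.0, 0.0)),
        ("A", 1, "LYS", "NZ", "N", (0.5, 0.0, 3.0)),
    ]
    bridges = detect_salt_bridges(build_model(rows), AB_ROLES,
                                  ("binder",), ("peptide",))
    assert len(bridges) == 1


def test_study_interface_report(study_complex, study_interface):
    _, truth, _ = study_complex
    rep = study_interface
    assert rep.bsa_total == pytest.approx(2 * rep.interface_area)
    assert 0 <= rep.peptide_fraction <= 1
    assert 0 <= rep.peptide_burial_fraction <= 1
    assert len(rep.hbonds) == truth.n_hbonds
    assert len(rep.salt_bridges) == truth.n_salt_bridges
    mhc_fp = [r for r in rep.target_contact_residues.residues
              if r.role == "mhc_heavy"]
    assert sorted(r.res_seq for r in mhc_fp) == truth.mhc_footprint


def test_compare_footprints_identity_disjoint_and_mismatch(study_complex):
    model, _, roles = study_complex
    fp = contact_residues(model, roles, ("binder",), ("mhc_heavy",))
    assert compare_footprints([fp, fp]) == fp.residues

    fp_pep = contact_residues(model, roles, ("binder",), ("peptide",))
    with pytest.raises(SelectionError):
        compare_footprints([fp, fp_pep])  # different target roles

    empty = contact_residues(model, roles, ("b2m",), ("mhc_heavy",))
    assert compare_footprints([fp, empty]) == ()


def test_compare_footprints_across_structures():
    # Same target numbering, different binders: intersection by res_seq.
    spec1 = study_complex_spec()
    m1, t1 = make_toy_complex(spec1)
    spec2 = ToyComplexSpec(
        planted_contacts=tuple(
            c for c in spec1.planted_contacts
            if c.target_role == "mhc_heavy" and c.target_res < 150
        ),
        binder_axis_angle=70.0,
    )
    m2, t2 = make_toy_complex(spec2)
    fp1 = contact_residues(m1, t1.roles, ("binder",), ("mhc_heavy",))
    fp2 = contact_residues(m2, t2.roles, ("binder",), ("mhc_heavy",))
    shared = compare_footprints([fp1, fp2])
    expected = sorted(set(t1.mhc_footprint) & set(t2.mhc_footprint))
    assert sorted(r.res_seq for r in shared) == expected


def test_diff_interfaces_self_is_empty(study_interface):
    diff = diff_interfaces(study_interface, study_interface)
    assert diff.n_hbond_changes == 0
    assert diff.dsasa_changes == []


def test_diff_interfaces_three_planted_discrepancies():
    """Crystal-vs-prediction style diff: one bond lost, one gained, one
    donor keeping its residue but swapping acceptor."""
    common = [PlantedHBond(binder_res=54, target_role="peptide",
                           target_res=5)]
    crystal_only = [
        PlantedHBond(binder_res=80, target_role="peptide", target_res=7),
        PlantedHBond(binder_res=57, target_role="peptide", target_res=8),
    ]
    predicted_only = [
        PlantedHBond(binder_res=76, target_role="peptide", target_res=8),
        PlantedHBond(binder_res=57, target_role="peptide", target_res=6),
    ]

    def build(hbonds):
        spec = ToyComplexSpec(n_binder_residues=100,
                              planted_hbonds=tuple(hbonds))
        model, truth = make_toy_complex(spec)
        return compute_interface(model, truth.roles)

    crystal = build(common + crystal_only)
    predicted = build(common + predicted_only)
    diff = diff_interfaces(crystal, predicted)
    assert len(diff.hbonds_only_a) == 2
    assert len(diff.hbonds_only_b) == 2
    only_a = {(h.donor.res_seq, h.acceptor.res_seq)
              for h in diff.hbonds_only_a}
    only_b = {(h.donor.res_seq, h.acceptor.res_seq)
              for h in diff.hbonds_only_b}
    assert only_a == {(80, 7), (57, 8)}
    assert only_b == {(76, 8), (57, 6)}


def test_diff_interfaces_dsasa_changes():
    m1, t1 = make_toy_complex(study_complex_spec())
    spec2 = ToyComplexSpec(
        planted_contacts=study_complex_spec().planted_contacts[:5],
    )
    m2, t2 = make_toy_complex(spec2)
    rep1 = compute_interface(m1, t1.roles)
    rep2 = compute_interface(m2, t2.roles)
    diff = diff_interfaces(rep1, rep2, dsasa_threshold=5.0)
    assert diff.dsasa_changes  # removing plants changes burial
    for key, va, vb in diff.dsasa_changes:
        assert abs(va - vb) > 5.0
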