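"""Hamming search, scan variants, position weights and scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mhcgroove.errors import ScreenError
from mhcgroove.interface import InterfaceReport, ResidueTag
from mhcgroove.offtarget import (
    OffTargetCandidate,
    PeptideRecord,
    PositionWeights,
    WeightedSubstitutionScorer,
    alanine_scan,
    blosum62,
    derive_position_weights,
    generate_scan_variants,
    hamming,
    load_atlas,
    offtarget_score,
    rank_candidates,
    score_candidates,
    search_atlas,
)
from mhcgroove.synthetic import AtlasSpec, make_synthetic_atlas

REF = "SLLMWITQV"

peptides = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=9, max_size=9)


def fake_report(dsasa_by_position):
    """Minimal InterfaceReport carrying only a peptide dSASA profile."""
    per_res = {
        ResidueTag("peptide", "C", pos, "", "ALA"): v
        for pos, v in dsasa_by_position.items()
    }
    return InterfaceReport(
        side_a=("binder",), side_b=("peptide",),
        bsa_total=2 * sum(dsasa_by_position.values()),
        interface_area=sum(dsasa_by_position.values()),
        per_residue_dsasa=per_res, peptide_fraction=1.0,
        peptide_burial_fraction=None, hbonds=[], salt_bridges=[],
        binder_contact_residues=None, target_contact_residues=None,
    )


# ---------------------------------------------------------------------------
# Hamming distance
# ---------------------------------------------------------------------------

def test_hamming_basics():
    assert hamming("AAAAAAAAA", "AAAAAAAAA") == 0
    assert hamming("AAAAAAAAA", "AAAMWAAAA") == 2
    with pytest.raises(ScreenError):
        hamming("AAAA", "AAAAA")


def test_hamming_against_positionwise_oracle(rng):
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    for _ in range(1000):
        a = "".join(rng.choice(letters, size=9))
        b = "".join(rng.choice(letters, size=9))
        oracle = sum(1 for x, y in zip(a, b) if x != y)
        assert hamming(a, b) == oracle


@settings(deadline=None, max_examples=200, derandomize=True)
@given(peptides, peptides, peptides)
def test_hamming_metric_axioms(a, b, c):
    assert hamming(a, a) == 0
    assert (hamming(a, b) == 0) == (a == b)
    assert hamming(a, b) == hamming(b, a)
    assert hamming(a, c) <= hamming(a, b) + hamming(b, c)


# ---------------------------------------------------------------------------
# Scan variants
# ---------------------------------------------------------------------------

def test_scan_variant_naming_convention():
    variants = generate_scan_variants(REF, [(4, "A"), (5, "A"), (4, "L"),
                                            (5, "F")])
    assert [v.name for v in variants] == ["M4A", "W5A", "M4L", "W5F"]
    assert variants[0].sequence == "SLLAWITQV"
    assert variants[2].sequence == "SLLLWITQV"
    for v in variants:
        assert hamming(v.sequence, REF) == 1
        assert v.sequence[v.position - 1] == v.name[-1]


def test_scan_variant_edge_cases():
    assert generate_scan_variants(REF, []) == []
    with pytest.raises(ScreenError, match="no-op"):
        generate_scan_variants(REF, [(1, "S")])
    with pytest.raises(ScreenError):
        generate_scan_variants(REF, [(10, "A")])
    with pytest.raises(ScreenError):
        generate_scan_variants(REF, [(1, "X")])


def test_alanine_scan_covers_all_non_ala_positions():
    variants = alanine_scan("MWMWMWMWM")
    assert len(variants) == 9
    assert all(v.name.endswith("A") for v in variants)
    partial = alanine_scan("AALAWAAAA")
    assert [v.name for v in partial] == ["L3A", "W5A"]


# ---------------------------------------------------------------------------
# Atlas search
# ---------------------------------------------------------------------------

def test_reference_only_atlas_yields_nothing():
    cands, stats = search_atlas([PeptideRecord(REF)], REF, max_hamming=4)
    assert cands == []
    assert stats.n_reference_excluded == 1


def test_length_mismatches_are_skipped_not_aligned():
    atlas = [PeptideRecord("SLLMWITQ"), PeptideRecord("SLLMWITQVA"),
             PeptideRecord("ALLMWITQV")]
    cands, stats = search_atlas(atlas, REF, max_hamming=4)
    assert stats.n_skipped_length == 2
    assert [c.record.sequence for c in cands] == ["ALLMWITQV"]
    assert cands[0].hamming == 1


@pytest.mark.parametrize("seed", [0, 1, 7, 123])
def test_planted_atlas_recovery_is_exact(seed):
    spec = AtlasSpec(n_background=1000, seed=seed)
    records, truth = make_synthetic_atlas(spec)
    assert len(records) == 1007
    cands, _ = search_atlas(records, spec.reference, max_hamming=4,
                            motif_positions=spec.motif_positions)
    assert len(cands) == 7
    planted = {p["sequence"]: p for p in truth.planted}
    assert {c.record.sequence for c in cands} == set(planted)
    d4 = [c for c in cands if c.hamming <= 4]
    motif = [c for c in cands if c.motif_match]
    assert len(d4) == 5 and len(motif) == 2
    assert sorted(c.hamming for c in motif) == [5, 6]


def test_search_results_invariant_to_atlas_order(rng):
    records, _ = make_synthetic_atlas(AtlasSpec(n_background=500, seed=3))
    shuffled = list(records)
    rng.shuffle(shuffled)
    a, _ = search_atlas(records, REF, 4, motif_positions=(4, 5))
    b, _ = search_atlas(shuffled, REF, 4, motif_positions=(4, 5))
    assert [(c.record.sequence, c.hamming, c.motif_match) for c in a] \
        == [(c.record.sequence, c.hamming, c.motif_match) for c in b]


def test_empty_atlas_warns():
    with pytest.warns(UserWarning, match="empty atlas"):
        cands, _ = search_atlas([], REF, 4)
    assert cands == []


def test_load_atlas_tsv_and_csv(tmp_path):
    tsv = tmp_path / "a.tsv"
    tsv.write_text("sequence\tallele\nALLMWITQV\tHLA-A*02:01\n")
    csv = tmp_path / "a.csv"
    csv.write_text("sequence,allele,source\nALLMWITQV,HLA-A*02:01,GENE1\n")
    assert load_atlas(tsv)[0].sequence == "ALLMWITQV"
    rec = load_atlas(csv)[0]
    assert rec.allele == "HLA-A*02:01" and rec.source == "GENE1"
    bad = tmp_path / "bad.tsv"
    bad.write_text("peptide\tallele\nAAA\tx\n")
    with pytest.raises(ScreenError, match="sequence"):
        load_atlas(bad)


# ---------------------------------------------------------------------------
# Position weights
# ---------------------------------------------------------------------------

def test_uniform_dsasa_gives_uniform_weights():
    report = fake_report({i: 10.0 for i in range(1, 10)})
    w = derive_position_weights(report)
    assert w.weights == pytest.approx([1 / 9] * 9, abs=1e-12)


def test_concentrated_dsasa_dominates_weights():
    profile = {i: 1.0 for i in range(1, 10)}
    profile[4] = 50.0
    profile[5] = 40.0
    w = derive_position_weights(fake_report(profile))
    order = np.argsort(w.weights)[::-1] + 1
    assert set(order[:2]) == {4, 5}


def test_zero_interface_weights_error():
    with pytest.raises(ScreenError, match="weights undefined"):
        derive_position_weights(fake_report({i: 0.0 for i in range(1, 10)}))


def test_weight_normalization_contract():
    with pytest.raises(ScreenError):
        PositionWeights((0.5, 0.4))          # does not sum to 1
    with pytest.raises(ScreenError):
        PositionWeights.normalized([-1.0, 2.0])
    w = PositionWeights.normalized([2.0, 2.0])
    assert w.weights == (0.5, 0.5)


def test_study_fixture_weights_rank_hotspots_first(study_interface):
    w = derive_position_weights(study_interface)
    order = np.argsort(w.weights)[::-1] + 1
    assert set(order[:2]) == {4, 5}


# ---------------------------------------------------------------------------
# Scoring and ranking
# ---------------------------------------------------------------------------

def test_score_is_zero_for_reference_and_zero_weight_positions():
    w = PositionWeights.normalized([1, 0, 1, 1, 1, 1, 1, 1, 1])
    assert offtarget_score(REF, REF, w) == 0.0
    mutated_at_zero = REF[:1] + "A" + REF[2:]
    assert offtarget_score(mutated_at_zero, REF, w) == 0.0


def test_conservative_beats_radical_at_hotspot(study_interface):
    w = derive_position_weights(study_interface)
    m4l = offtarget_score("SLLLWITQV", REF, w)   # Met4 -> Leu
    m4d = offtarget_score("SLLDWITQV", REF, w)   # Met4 -> Asp
    assert 0 < m4l < m4d
    mat = blosum62()
    assert mat[("M", "L")] > mat[("M", "D")]  # the inequality behind it


def test_score_monotone_under_added_mismatches(rng):
    w = PositionWeights.uniform(9)
    letters = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(50):
        seq = list(REF)
        prev = 0.0
        positions = rng.permutation(9)
        for pos in positions[: rng.integers(1, 9)]:
            choices = [a for a in letters if a != REF[pos]]
            seq[pos] = choices[rng.integers(len(choices))]
            score = offtarget_score("".join(seq), REF, w)
            assert score >= prev - 1e-12
            prev = score


def test_scorer_length_checks():
    w = PositionWeights.uniform(9)
    with pytest.raises(ScreenError):
        offtarget_score("SLLM", REF, w)
    with pytest.raises(ScreenError):
        WeightedSubstitutionScorer("SLLM", w)


def test_rank_ties_break_deterministically():
    cands = [
        OffTargetCandidate(PeptideRecord("CLLMWITQV"), 1, False, 1.0),
        OffTargetCandidate(PeptideRecord("ALLMWITQV"), 1, False, 1.0),
        OffTargetCandidate(PeptideRecord("AALMWITQV"), 2, False, 1.0),
    ]
    ranked = rank_candidates(cands)
    assert [c.record.sequence for c in ranked] == [
        "ALLMWITQV", "CLLMWITQV", "AALMWITQV",
    ]
    with pytest.raises(ScreenError, match="no score"):
        rank_candidates([OffTargetCandidate(PeptideRecord(REF), 0, True)])


def test_hotspot_preserving_candidates_rank_first():
    """With burial concentrated on the motif, peptides keeping Met4-Trp5
    outrank all motif-breaking ones regardless of total distance."""
    w = PositionWeights.normalized([0.02, 0.02, 0.02, 0.42, 0.42,
                                    0.02, 0.02, 0.03, 0.03])
    keep_motif = ["ALAMWATQV", "SLAMWITAA"]
    break_motif = ["SLLDWITQV", "SLLMDITQV", "SLLAAITQV", "SLLKWITQV",
                   "SLLMPITQV"]
    cands = [
        OffTargetCandidate(PeptideRecord(s), hamming(s, REF),
                           s[3] == REF[3] and s[4] == REF[4])
        for s in keep_motif + break_motif
    ]
    scorer = WeightedSubstitutionScorer(REF, w)
    ranked = rank_candidates(score_candidates(cands, scorer))
    assert {c.record.sequence for c in ranked[:2]} == set(keep_motif)
    assert all(c.motif_match for c in ranked[:2])
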