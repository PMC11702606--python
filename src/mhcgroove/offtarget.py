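"""Structure-guided off-target peptide screening.

Given a binder whose crystal structure shows which peptide positions carry
the interface (the "hotspots"), cross-reactivity risk concentrates in
MS-detected peptides of the same length that are (a) few substitutions
away from the reference epitope, or (b) identical at the hotspot motif
even if globally more distant. The screen therefore combines:

1. a Hamming-distance search over an immunopeptidome atlas (no alignment
   — class I 9-mers are compared position by position);
2. an optional motif search returning every atlas peptide matching the
   reference exactly at the hotspot positions;
3. a reference-relative compatibility score. The default scorer is a
   position-weighted substitution score

       S(p) = sum_i w_i * ( m(ref_i, ref_i) - m(ref_i, p_i) )

   with weights w_i proportional to the per-position peptide buried
   surface area from the crystal interface and m a BLOSUM62 table.
   S(reference) = 0 exactly and larger scores predict worse fit, so any
   scorer that returns a candidate's negative log-likelihood minus the
   reference's can be plugged in unchanged (see :class:`PeptideScorer`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol, Sequence

import numpy as np
import pandas as pd

from ._chem import CANONICAL_LETTERS
from .errors import ScreenError
from .interface import InterfaceReport

__all__ = [
    "PeptideRecord",
    "ScanVariant",
    "PositionWeights",
    "OffTargetCandidate",
    "hamming",
    "generate_scan_variants",
    "alanine_scan",
    "load_atlas",
    "search_atlas",
    "SearchStats",
    "derive_position_weights",
    "blosum62",
    "offtarget_score",
    "score_candidates",
    "rank_candidates",
    "PeptideScorer",
    "WeightedSubstitutionScorer",
]


@dataclass(frozen=True)
class PeptideRecord:
    """One atlas entry: a presented peptide with its allele of origin."""

    sequence: str
    allele: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        _validate_sequence(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ScanVariant:
    """A single-position mutant, named original+position+mutation (M4A)."""

    name: str
    sequence: str
    position: int


@dataclass(frozen=True)
class PositionWeights:
    """Non-negative per-position weights summing to 1."""

    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ScreenError("position weights must be non-negative")
        total = float(w.sum())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ScreenError(
                f"position weights must sum to 1 (got {total:.6g}); "
                "use PositionWeights.normalized()"
            )

    @classmethod
    def normalized(cls, raw: Sequence[float]) -> "PositionWeights":
        w = np.asarray(raw, dtype=float)
        if np.any(w < 0):
            raise ScreenError("position weights must be non-negative")
        total = float(w.sum())
        if total <= 0:
            raise ScreenError("cannot normalize all-zero weights")
        return cls(tuple(float(x) for x in w / total))

    @classmethod
    def uniform(cls, length: int) -> "PositionWeights":
        return cls.normalized([1.0] * length)

    def __len__(self) -> int:
        return len(self.weights)


@dataclass
class OffTargetCandidate:
    record: PeptideRecord
    hamming: int
    motif_match: bool
    score: float | None = None


@dataclass
class SearchStats:
    """Bookkeeping for an atlas search (skipped/excluded record counts)."""

    n_records: int = 0
    n_skipped_length: int = 0
    n_reference_excluded: int = 0
    n_searched: int = 0


def _validate_sequence(seq: str) -> None:
    if not seq:
        raise ScreenError("empty peptide sequence")
    bad = sorted(set(seq) - CANONICAL_LETTERS)
    if bad:
        raise ScreenError(
            f"non-canonical letters {bad} in peptide {seq!r}"
        )


# ---------------------------------------------------------------------------
# Distance and variants
# ---------------------------------------------------------------------------

def hamming(a: str, b: str) -> int:
    """Number of positions at which two equal-length peptides differ.

    No alignment is attempted; a length mismatch is an error.
    """
    if len(a) != len(b):
        raise ScreenError(
            f"length mismatch: {len(a)} vs {len(b)} ({a!r} vs {b!r})"
        )
    return sum(x != y for x, y in zip(a, b))


def generate_scan_variants(
    reference: str,
    mutations: Sequence[tuple[int, str]],
) -> list[ScanVariant]:
    """Single-position variants of ``reference``.

    ``mutations`` is a list of (1-based position, replacement letter);
    each yields one variant named by the convention original residue,
    position, mutation (e.g. ``M4A``). Replacing a residue by itself is
    rejected as a no-op.
    """
    _validate_sequence(reference)
    out = []
    for pos, letter in mutations:
        if not 1 <= pos <= len(reference):
            raise ScreenError(
                f"position {pos} outside 1..{len(reference)}"
            )
        if letter not in CANONICAL_LETTERS:
            raise ScreenError(f"non-canonical replacement {letter!r}")
        orig = reference[pos - 1]
        if letter == orig:
            raise ScreenError(
                f"no-op mutation {orig}{pos}{letter}: replacement equals "
                "the reference residue"
            )
        seq = reference[:pos - 1] + letter + reference[pos:]
        out.append(ScanVariant(name=f"{orig}{pos}{letter}", sequence=seq,
                               position=pos))
    return out


def alanine_scan(reference: str) -> list[ScanVariant]:
    """Alanine variants at every non-alanine position."""
    _validate_sequence(reference)
    mutations = [
        (i + 1, "A") for i, letter in enumerate(reference) if letter != "A"
    ]
    return generate_scan_variants(reference, mutations)


# ---------------------------------------------------------------------------
# Atlas I/O and search
# ---------------------------------------------------------------------------

def load_atlas(path: str | Path) -> list[PeptideRecord]:
    """Read a peptide atlas from a delimited text table.

    The table must have a header with a ``sequence`` column; ``allele``
    and ``source`` columns are optional. The delimiter (tab or comma) is
    sniffed from the header line.
    """
    path = Path(path)
    if not path.is_file():
        raise ScreenError(f"no such atlas file: {path}")
    header = path.open().readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    df.columns = [c.strip().lower() for c in df.columns]
    if "sequence" not in df.columns:
        raise ScreenError(
            f"{path}: atlas table needs a 'sequence' column "
            f"(found {list(df.columns)})"
        )
    records = []
    for row in df.itertuples(index=False):
        records.append(PeptideRecord(
            sequence=str(getattr(row, "sequence")).strip().upper(),
            allele=str(getattr(row, "allele", "")),
            source=str(getattr(row, "source", "")),
        ))
    return records


def search_atlas(
    atlas: Iterable[PeptideRecord],
    reference: str,
    max_hamming: int,
    motif_positions: Sequence[int] | None = None,
) -> tuple[list[OffTargetCandidate], SearchStats]:
    """Similarity search of an atlas against a reference peptide.

    Returns candidates with Hamming distance <= ``max_hamming``, plus —
    when ``motif_positions`` (1-based) is given — every record matching
    the reference exactly at those positions regardless of total
    distance. Records of a different length are skipped and counted; the
    reference itself is excluded. Results are sorted by
    (hamming, sequence), so output is independent of atlas order.
    """
    _validate_sequence(reference)
    if max_hamming < 0:
        raise ScreenError(f"max_hamming must be >= 0, got {max_hamming}")
    motif = tuple(motif_positions or ())
    for pos in motif:
        if not 1 <= pos <= len(reference):
            raise ScreenError(
                f"motif position {pos} outside 1..{len(reference)}"
            )

    stats = SearchStats()
    best: dict[str, OffTargetCandidate] = {}
    for rec in atlas:
        stats.n_records += 1
        if rec.length != len(reference):
            stats.n_skipped_length += 1
            continue
        if rec.sequence == reference:
            stats.n_reference_excluded += 1
            continue
        stats.n_searched += 1
        d = hamming(rec.sequence, reference)
        is_motif = bool(motif) and all(
            rec.sequence[p - 1] == reference[p - 1] for p in motif
        )
        if d <= max_hamming or is_motif:
            if rec.sequence not in best:
                best[rec.sequence] = OffTargetCandidate(
                    record=rec, hamming=d, motif_match=is_motif
                )
    if stats.n_records == 0:
        warnings.warn("empty atlas: nothing to search", stacklevel=2)
    out = sorted(best.values(),
                 key=lambda c: (c.hamming, c.record.sequence))
    return out, stats


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def derive_position_weights(report: InterfaceReport) -> PositionWeights:
    """Per-position weights from the peptide buried-surface-area profile.

    Positions whose side chains carry more of the interface get more
    weight; weights are the per-position peptide dSASA normalized to sum
    to 1. An all-zero profile (no peptide interface) is an error.
    """
    profile = report.peptide_position_dsasa()
    if not profile:
        raise ScreenError("report has no peptide residues")
    raw = [profile[k] for k in sorted(profile)]
    if sum(raw) <= 0:
        raise ScreenError(
            "peptide buries no surface in this interface; weights undefined"
        )
    return PositionWeights.normalized(raw)


def blosum62() -> dict[tuple[str, str], float]:
    """BLOSUM62 as a symmetric dict over one-letter codes."""
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    out: dict[tuple[str, str], float] = {}
    for x in CANONICAL_LETTERS:
        for y in CANONICAL_LETTERS:
            out[(x, y)] = float(mat[x, y])
    return out


class PeptideScorer(Protocol):
    """Anything that maps a peptide sequence to a real-valued score.

    Scores are reference-relative: the reference peptide must score 0 and
    larger must mean worse predicted fit. A structure-conditioned
    log-likelihood backend fits this interface by returning each
    peptide's negative log-likelihood minus the reference's.
    """

    def __call__(self, candidate: str) -> float: ...


@dataclass
class WeightedSubstitutionScorer:
    """Default interpretable scorer: burial-weighted substitution cost."""

    reference: str
    weights: PositionWeights
    matrix: dict[tuple[str, str], float] = field(default_factory=blosum62)

    def __post_init__(self) -> None:
        _validate_sequence(self.reference)
        if len(self.weights) != len(self.reference):
            raise ScreenError(
                f"weights length {len(self.weights)} != reference length "
                f"{len(self.reference)}"
            )

    def __call__(self, candidate: str) -> float:
        return offtarget_score(candidate, self.reference, self.weights,
                               self.matrix)


def offtarget_score(
    candidate: str,
    reference: str,
    weights: PositionWeights,
    matrix: dict[tuple[str, str], float] | None = None,
) -> float:
    """Burial-weighted substitution cost of a candidate vs the reference.

    ``S(p) = sum_i w_i * (m(ref_i, ref_i) - m(ref_i, p_i))`` — exactly 0
    for the reference, and strictly larger for radical substitutions than
    for conservative ones at the same (positively weighted) position.
    """
    _validate_sequence(candidate)
    _validate_sequence(reference)
    if len(candidate) != len(reference):
        raise ScreenError(
            f"length mismatch: candidate {len(candidate)} vs reference "
            f"{len(reference)}"
        )
    if len(weights) != len(reference):
        raise ScreenError("weights length does not match peptides")
    m = blosum62() if matrix is None else matrix
    total = 0.0
    for i, (r, c) in enumerate(zip(reference, candidate)):
        total += weights.weights[i] * (m[(r, r)] - m[(r, c)])
    return total


def score_candidates(
    candidates: Sequence[OffTargetCandidate],
    scorer: PeptideScorer,
) -> list[OffTargetCandidate]:
    """Attach scores in place (and return the list for chaining)."""
    for cand in candidates:
        cand.score = float(scorer(cand.record.sequence))
    return list(candidates)


def rank_candidates(
    candidates: Sequence[OffTargetCandidate],
) -> list[OffTargetCandidate]:
    """Ascending by score (best predicted fit first).

    Ties break by (hamming, sequence), so ranking is deterministic and
    independent of input order.
    """
    for cand in candidates:
        if cand.score is None:
            raise ScreenError(
                f"candidate {cand.record.sequence} has no score; run "
                "score_candidates first"
            )
    return sorted(
        candidates,
        key=lambda c: (c.score, c.hamming, c.record.sequence),
    )
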