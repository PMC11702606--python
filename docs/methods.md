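# Methods

This note records the models, conventions and numerical choices behind
`mhcgroove`, and what its synthetic fixtures do and do not establish
about real structures.

## Structure model and chain roles

Structures are read with biotite (PDB and mmCIF); the first model is
kept, waters are dropped, and alternate locations resolve to the
highest-occupancy conformer (ties fall to altloc `A`, the first in file
order). Coordinates are held at double precision internally — the
underlying container stores float32, which would cap the
reproducibility of docking angles and superpositions near 1e-5
degrees — so a float64 coordinate block is maintained for all geometry.

Chains are mapped to biological roles. Size heuristics do most of the
work: 8–13 standard residues → displayed peptide, 250–299 → MHC class I
heavy chain, 90–109 → beta-2-microglobulin; when several chains fall in
one window, the chain closest to the canonical size (9/276/99) takes
the role. A single remaining chain is the binder. When several
candidate binder chains remain — a Fab or TCR contributes two, and
crystallization chaperones are common — chains whose heavy atoms come
within 5 Å of the peptide are binders and the rest chaperones; anything
still ambiguous is an error that lists the candidates, and explicit
hints (chain → role) always override. Chaperones are excluded from all
interface computations: they stabilise the crystal, not the studied
interface.

Author residue numbering is used verbatim for the MHC (so anchor
residues such as Arg65, Lys66 or Gln155 keep their conventional
addresses), while peptide residues are additionally renumbered 1..N in
chain order so hotspot positions ("Met4", "Trp5") work on any
deposition.

Hydrogens, when present, participate in hydrogen-bond geometry but
never in surface areas or contacts: X-ray depositions usually lack
them, so heavy-atom criteria are the comparable ones.

## Surface areas and buried surface

SASA uses the Shrake–Rupley sphere-point method with a deterministic
golden-spiral (Fibonacci) lattice — no random number generator is
involved, so areas are exactly reproducible for a given point count.
Defaults: probe 1.4 Å, 960 points per atom (single-atom closed-form
areas are exact; two-sphere overlaps agree with the analytic
spherical-cap formula to well under 2%, and totals move by <0.5% when
the lattice is refined to 3840 points). Radii are Bondi single-atom
values (C 1.70, N 1.55, O 1.52, S 1.80 Å, plus halogens/Se/P); an
element without a configured radius is an error rather than a silent
omission. biotite's independent Shrake–Rupley implementation, run with
the same radius set, serves as a cross-check oracle in the test suite
only.

Buried surface area is the two-sided SASA loss
`BSA = SASA(A) + SASA(B) − SASA(A∪B)`, computed per atom from identical
coordinates (the complex array is re-assembled at float64 so per-atom
differences are exactly non-negative). Published interface sizes use
either the two-sided total or half of it without always saying which,
so both are always reported: `bsa_total` and `interface_area =
bsa_total / 2`.

Two peptide-centric fractions are deliberately distinct quantities:

* `peptide_fraction` — peptide ΔSASA divided by the ΔSASA of the whole
  target side; "how much of the interface is peptide".
* `peptide_burial_fraction` — peptide ΔSASA divided by the peptide's
  SASA within the pMHC alone (binder removed); "how much of the
  displayed peptide surface the binder covers". The free state is the
  groove-displayed peptide, not an isolated peptide chain, because the
  groove already buries the anchor side; this is the quantity used when
  comparing how peptide-hungry different binders are.

## Contacts, hydrogen bonds, salt bridges

A target residue is in a binder's footprint iff any of its heavy atoms
lies within the cutoff (default 4.0 Å) of any binder heavy atom;
footprints at smaller cutoffs are subsets of those at larger ones, and
a ΔSASA > 0.1 Å² alternative criterion is available. Footprint residues
are tagged by role + author number, so footprints from different
depositions of the same target intersect meaningfully.

Hydrogen bonds pair donor and acceptor heavy atoms from standard
amino-acid chemistry tables (backbone N except proline, and Arg/Lys/
His/Trp/Asn/Gln/Ser/Thr/Tyr side chains as donors; backbone O and
Asp/Glu/Asn/Gln/Ser/Thr/Tyr/His side chains as acceptors) at distance
≤ 3.5 Å with an antecedent–donor–acceptor angle ≥ 90°; with explicit
hydrogens, D–H…A ≥ 120° replaces the angle test. Salt bridges pair
Lys NZ / Arg NH1,NH2,NE / His ND1,NE2 with Asp OD1,OD2 / Glu OE1,OE2 at
≤ 4.0 Å, one bridge per residue pair at the minimal atom distance. A
bridge closer than 3.5 Å generally also satisfies the hydrogen-bond
criteria and is then reported by both detectors, which is chemically
accurate.

All cutoffs and parameter values are configurable and echoed into every
report; the defaults are standard structural-biology criteria, chosen
because published contact and bond counts rarely state theirs.

## Docking geometry

There is no universal convention for a docking angle when the binder is
not a VαVβ heterodimer (the TCR-literature disulfide-vector convention
does not transfer to a monomeric helical bundle). The convention here:
the groove plane is the least-squares plane through the Cα atoms of the
α1/α2 helices (author ranges 50–84 and 138–180, configurable), with the
normal oriented toward the peptide; the peptide axis is the first
principal component of peptide Cα positions, oriented P1→PN and
projected into the plane; the binder axis is the first principal
component of the Cα positions of its interface residues (those
contacting peptide or MHC heavy chain), projected likewise. The angle
between the projected axes is folded into [0°, 90°] because the binder
axis has no intrinsic sign. The convention is deterministic, rigid-
motion invariant (to ~1e-6° at double precision), and recovers planted
axis angles on fixtures to well under 0.5°; absolute values for real
structures should be read with a ±10° mindset since other reasonable
conventions (footprint centroids, helix axes) differ by a few degrees.

Superposition is the Kabsch algorithm: SVD of the cross-covariance with
a reflection correction so the rotation determinant is +1; RMSD is
computed over the superposed pairs. Residues are matched across models
by (role, author number) — Cα only, or all heavy atoms additionally
matched by atom name — with unmatched residues excluded and reported.

## Off-target screen

The screen's search space is an atlas of MS-detected peptides (tabular
input with a `sequence` column), deliberately not the whole proteome:
presentation is gated by expression, processing and competition, and MS
detection is the practical threshold for "actually on the surface".
Peptides of a different length than the reference are skipped, never
aligned; class I 9-mers are compared position by position with Hamming
distance. The motif search returns every peptide identical to the
reference at the hotspot positions regardless of total distance, since
a binder that grips only the hotspot side chains can tolerate distant
mutations elsewhere.

The compatibility score is reference-relative by construction:
S(p) = Σ wᵢ·(m(refᵢ,refᵢ) − m(refᵢ,pᵢ)), with wᵢ ∝ per-position peptide
ΔSASA from the analysed interface and m = BLOSUM62 (via biopython).
S(reference) = 0 exactly; the score is non-decreasing as mismatches
accumulate at positively weighted positions; conservative substitutions
at hotspots (Met→Leu) score strictly better than radical ones
(Met→Asp). The scorer is a plain callable interface, so a
structure-conditioned likelihood model can replace the substitution
backend by returning each candidate's negative log-likelihood minus the
reference's — the interpretable default exists precisely so that the
screen is reproducible without any trained model. Ranking is ascending
by score with (distance, sequence) tie-breaks; all outputs are
deterministic and independent of atlas row order.

## Synthetic fixtures

The toy complex is a geometric scaffold, not a protein fold: residues
are compact backbone clusters on straight lines, the two "helices" and
the peptide define an exact groove plane, and binder interface residues
sit on an axis at the requested angle 8 Å above it. Contacts, hydrogen
bonds (serine OG donors at chosen distance/angle over backbone O
acceptors) and salt bridges (Lys NZ over Glu OE1, default 3.8 Å — inside
the bridge cutoff, outside the H-bond cutoff, so counts stay disjoint)
are planted at exact distances against distinct target atoms. After
construction the generator re-derives every cross-interface contact by
brute force and raises if anything accidental appeared or any atom pair
fell under 1 Å, so returned ground truth is exact, not approximate. The
default study-scale specification plants the headline structure of a
peptide-centric designed binder: 14 peptide-contacting binder residues
with burial concentrated on positions 4–5, 19 contacted MHC helix
residues including the classical anchors, 5 binder–MHC hydrogen bonds,
one salt bridge, and a 40° docking angle.

The synthetic atlas samples background 9-mers uniformly, rejecting any
that come within Hamming distance 5 of the reference or accidentally
match the hotspot motif, and plants neighbours at exact distances —
5 at distance 4 (each breaking the motif), plus motif-preserving ones
at distances 5 and 6. Recovery of exactly 5 + 2 is therefore a property
of the construction for every seed; the default size (14,363 records)
mirrors the scale of an MS-detected HLA-A\*02 9-mer catalogue. A single
seeded generator drives all sampling; identical seeds give byte-
identical fixture files.

What passing fixture tests show: the detectors, geometry and screen
implement their definitions exactly. What they do not show: performance
on real packing densities (real interfaces bury area through many
sub-cutoff near-misses, fixtures only through plants), real H-bond
geometry distributions, or the behaviour of the size heuristics on
unusual constructs — those are exercised only by the deposited-
structure tests, which require the PDB entries on disk.

## Problem sizes and defaults

The study-scale fixture has ~1,700 atoms and analyses in ~1–2 s at 960
sphere points; the synthetic atlas screen over 14,363 peptides runs in
well under a second. Property tests use 100 random fixtures for the
BSA/footprint invariants, 1,000 random triples for the metric axioms,
and 1,000 random rotations for Kabsch optimality. Real class I ternary
complexes (~3,000–4,000 heavy atoms per side selection) analyse in
tens of seconds at default settings.

## Known limitations

* No energetics: ΔSASA-based weights proxy importance by burial, which
  ignores electrostatics, water-mediated bonds and conformational
  strain.
* The docking-angle convention is one of several defensible choices;
  cross-paper comparisons of absolute angles need the convention
  stated.
* The off-target score treats positions independently; epistasis
  between peptide positions (register shifts, compensating mutations)
  is out of scope, as is MHC binding-affinity prediction — atlas
  membership is the presentation filter.
* Role heuristics target class I architecture; class II or single-chain
  constructs need explicit hints.
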