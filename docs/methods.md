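# Methods

## Disulfide torsions and their sign convention

A Cys–Cys bridge is parameterized by five torsions: χ₁ = N–Cα–Cβ–Sγ and
χ₂ = Cα–Cβ–Sγ–Sγ′ on the unprimed half-cystine, χ₃ = Cβ–Sγ–Sγ′–Cβ′
across the S–S bond, and the primed mirrors χ₂′ = Cα′–Cβ′–Sγ′–Sγ and
χ₁′ = N′–Cα′–Cβ′–Sγ′. Torsions follow the right-handed (IUPAC)
convention — looking down the central bond, clockwise rotation of the
far substituent relative to the near one is positive — and are reported
in degrees in (−180, 180], with exactly ±180 normalized to +180. The
implementation uses the atan2 form of the two-plane-normal construction,
which is invariant under rigid motion and under full point-order
reversal; agreement with biotite's torsion routine is asserted in the
test suite at that library's float32 precision (1e-4°).

Canonical ordering: the half-cystine with the lower (chain ID, residue
number) key is unprimed. For the QueF active-site bridge this makes
Cys55 unprimed and Cys99 primed, matching how the crystallographic
literature tabulates the angles. Swapping the residue order exchanges
primed/unprimed angles and leaves χ₃ and the energy unchanged.

## Configuration taxonomy

The sign quintuple places a bridge in a 20-class taxonomy:

* handedness from sign(χ₃): negative → LH, non-negative → RH;
* shape from the χ₂/χ₂′ signs relative to χ₃: both matching → Spiral,
  exactly one opposite → Hook, both opposite → Staple;
* a prefix from (sign χ₁, sign χ₁′): (−,−) → "−", (+,+) → "+", mixed →
  "−/+" or "+/−". Spiral and Staple are symmetric under the
  primed/unprimed exchange, so their two mixed prefixes are the same
  class and collapse to "−/+"; Hooks are asymmetric and keep both.

This yields 6 spiral + 6 staple + 8 hook = 20 classes, and maps the
(−,−,−,+,−) pattern of the oxidized QueF active site to −LHHook. The
rule set is anchored on that example plus the class count; exotic
patterns outside the anchored cases carry the usual caveat that naming
conventions differ slightly between published taxonomies. An angle
whose magnitude falls below the ambiguity threshold (default 0.5°)
leaves the best-call class in place but flags the record "ambiguous",
since the sign — and hence the class — sits on a knife edge.

## Dihedral strain energy

E = 8.37(1+cos 3χ₁) + 8.37(1+cos 3χ₁′) + 4.18(1+cos 3χ₂)
  + 4.18(1+cos 3χ₂′) + 14.64(1+cos 2χ₃) + 2.51(1+cos 3χ₃), in kJ/mol.

The three-fold terms vanish at the ±60/180° staggered rotamers; the χ₃
term mixes a dominant two-fold barrier (minima at ±90°) with a small
three-fold component. The function is non-negative with an analytic
maximum of 84.5 kJ/mol (all cosines at +1, i.e. every torsion eclipsed),
120°-periodic in χ₁/χ₁′/χ₂/χ₂′ and 360°-periodic in χ₃, and symmetric
under the primed/unprimed swap. The test suite pins the five published
QueF bridge quintuples to their published energies at ±0.005 kJ/mol.

## Bridge detection

Bridges are always recomputed from coordinates (SSBOND records are
parsed but only advisory): all unordered CYS pairs with Sγ–Sγ′ distance
≤ 2.30 Å are candidates, accepted greedily by ascending distance with
each Sγ used at most once. The 2.30 Å default covers crystallographic
S–S bonds (2.0–2.1 Å) with margin for coordinate error while excluding
adjacent free thiols (van der Waals S···S contacts start near 3.6 Å);
it is configurable. Cysteines lacking an Sγ atom are skipped with a
warning. HETATM records named CYS are retained so chemically modified
cysteines still participate.

PDB parsing is delegated to gemmi, with a fixed-column validation pass
on top (gemmi silently coerces malformed coordinate fields, and a parse
error naming the line is more useful). Alternate locations resolve to
the highest-occupancy conformer, ties to the alphabetically first tag —
dihedral math needs exactly one conformer, and this choice is
deterministic. Only the first MODEL of a multi-model file is read.
Author residue numbering is preserved throughout.

## Synthetic bridge geometry

The coordinate generator places the atom chain
N→Cα→Cβ→Sγ→Sγ′→Cβ′→Cα′→N′ by sequential natural-extension (NeRF)
internal-to-Cartesian construction, consuming exactly χ₁, χ₂, χ₃, χ₂′,
χ₁′ as the five placement torsions. Fixed internal geometry defaults to
standard cysteine stereochemistry — N–Cα 1.46 Å, Cα–Cβ 1.53 Å,
Cβ–Sγ 1.81 Å, angles N–Cα–Cβ 110.5°, Cα–Cβ–Sγ 114.0°, Cβ–Sγ–Sγ′ 104.0° —
all overridable; the S–S length defaults to 2.04 Å. The first three
atoms seed a canonical frame (origin / x-axis / xy-plane); the PDB
writer then applies a seeded random rigid motion per bridge plus a
30 Å per-chain offset so bridges cannot cross-link. Build → analyze
round-trips recover arbitrary torsion quintuples to better than 1e-6°
(the acceptance suite checks 1000 seeded draws); writing through the
PDB format adds only its 3-decimal coordinate quantization (~0.03°,
~0.015 kJ/mol on the published bridges).

What the generator does *not* emulate: full side-chain context, backbone
continuity beyond the four atoms each torsion needs, thermal
disorder/altlocs, or crystal packing. Passing tests therefore establish
the correctness of the torsion/energy/classification machinery, not
robustness to real-world structure pathology beyond what the parser
tests cover.

## Family census

Gating requires, simultaneously: C at the mapped catalytic-cysteine
position, D at the mapped aspartate, E at the mapped glutamate, and a
QueF-motif window E(S/L)K(S/A)hK(L/Y)(Y/F/W) that contains the mapped
motif-glutamate. The hydrophobic set for the motif's `h` position
defaults to {A,V,L,I,M,F,W,Y,C} (configurable; the motif literature
leaves it to convention). The leftmost motif match wins; all matches are
available programmatically. `X` is tolerated in input but never matches.

Landmark transfer uses pairwise global alignment of each query against
its subfamily reference (BLOSUM62, gap open −11 / extend −1, end gaps
free), rather than one multiple alignment of the whole input: pairwise
mapping is deterministic, incremental and testable per sequence. A
landmark aligned to a gap maps to nothing and the check fails. The
Cys53 "alternative backdoor" check is a mapped-sequence-position proxy
for structural inspection of the active-site loop.

Architecture: length < 200 → unimodular, ≥ 200 → bimodular. The family
definition leaves exactly 200 unassigned; the tie goes to the longer,
two-domain architecture so the rule is total.

Module splitting for bimodular sequences finds the two best
non-overlapping local alignments of the unimodular reference against
the query (each tandem T-fold module is homologous to a unimodular
subunit) and cuts at the midpoint of the inter-module gap, rounding an
odd gap toward the C module. On synthetic bimodular sequences this
locates the construction boundary to ±1 residue; `split_override` in
the census config fixes the cut exactly when the boundary is known.
The catalytic cysteine and the Cys236-equivalent backdoor land in the
C-terminal module. Concatenating the parts always reproduces the input.

Percentages are tallied per subfamily over gated QueF sequences only:
`pct_backdoor` counts the primary backdoor cysteine, `pct_any_backdoor`
(unimodular) counts primary or alternative, so it always dominates.
Percentages are undefined (null) for an empty subfamily rather than 0.

## Synthetic sequences

Subfamily references are not shipped as real database sequences; the
package generates deterministic synthetic stand-ins (fixed internal
seed) carrying the landmark residues at the literature positions —
unimodular: Cys53/Cys55/Asp62/motif-Glu78/Glu97/Cys99 on a 165-residue
background; bimodular: a 280-residue tandem of two diverged copies of
the unimodular module with motif-Glu94 in the N module and
Cys194/Asp201/Glu234/Cys236 in the C module, construction boundary at
residue 140. Real reference sequences can be supplied via a YAML config.

Query generation mutates the reference background at 8% point
substitutions (landmarks and the motif window protected), optionally
extends the N-terminus 0–4 residues (shifting all landmarks, which the
ground truth records) and grows or trims the C-terminal tail to the
requested length — unimodular 140–199, bimodular 240–320, bracketing
the family's ~160 and ~280 residue exemplars. Features are planted or
knocked out per category (C→S, D→N, E→Q; motif window → polyglycine),
and accidental motif matches elsewhere are erased so the planted call
is unambiguous. Composition counts use largest-remainder rounding
(ties to the earlier category), so a planted composition is recovered
by the census exactly, not statistically. Decoys are random background
sequences. The default composition — 61% primary backdoor, 22%
alternative-only, 17% neither among unimodular; 100% among bimodular —
mirrors the conservation pattern reported for the family; the
family-wide percentages themselves depend on a historical database
snapshot and are deliberately not a reproduction target. What the
generator does not emulate: realistic phylogenetic correlation between
sequences, domain shuffling, indels inside modules, or non-standard
residues; census tests therefore validate the pipeline's bookkeeping
and mapping, not alignment robustness on deeply diverged real families.

## Problem sizes and runtime

Tests run the census on planted sets of ≤ 260 sequences and the
geometry round trip on 1000 torsion quintuples; both complete in
seconds. The acceptance script analyzes five single-bridge structures.
These sizes exercise every code path; nothing in the method scales
worse than alignment cost × number of sequences.

## Known limitations

* Configuration names outside the anchored −LHHook case follow the rule
  set above; cross-check against the taxonomy literature before relying
  on exotic class names.
* The census maps landmarks by pairwise alignment; a query whose true
  homology is undetectable at BLOSUM62/−11/−1 will be gated out as
  non-QueF rather than flagged.
* mmCIF input, symmetry expansion and biological-assembly generation
  are out of scope; PDB is the supported dialect.
* No energy minimization, redox-potential estimation or bond-breaking
  prediction — the strain energy is a torsional estimate only.
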