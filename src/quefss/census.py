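"""QueF family gating and backdoor-cysteine conservation census.

The QueF nitrile reductase family is defined by the simultaneous presence
of four active-site features: the catalytic cysteine (Cys55 in
B. subtilis / Cys194 in V. cholerae numbering), the substrate-anchoring
aspartate (Asp62/201) and glutamate (Glu97/234), and the QueF motif
E(S/L)K(S/A)hK(L/Y)(Y/F/W) containing the NADPH-binding Glu78/94, where h
is a hydrophobic residue. Sequences lacking any feature are called
non-QueF and excluded.

Surviving sequences split into two architectures by length: unimodular
(< 200 residues, a single T-fold domain) and bimodular (>= 200 residues,
tandem T-folds). Each is then examined for the protective "backdoor"
cysteine that forms the intramolecular disulfide with the catalytic
cysteine under oxidative stress: Cys99 in unimodular sequences (with
Cys53 as an alternative candidate near the active-site loop) and Cys236
in bimodular ones. The census tallies, per subfamily, the percentage of
QueF sequences carrying the backdoor cysteine and (unimodular only) the
percentage carrying any potentially disulfide-forming cysteine.

Reference landmark positions are transferred to each query by pairwise
global alignment against a subfamily reference sequence (BLOSUM62, affine
gaps, free end gaps). The Cys53 check is a sequence-position proxy for
structural inspection of the active-site region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "CensusError",
    "CensusConfig",
    "ReferenceSpec",
    "ReferenceSet",
    "SequenceCall",
    "CensusResult",
    "DEFAULT_HYDROPHOBIC",
    "find_quef_motif",
    "find_all_quef_motifs",
    "map_landmark",
    "gate_family",
    "classify_modularity",
    "find_backdoor",
    "split_bimodular",
    "run_census",
    "load_references",
]

DEFAULT_HYDROPHOBIC = frozenset("AVLIMFWYC")

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

_LANDMARK_RESIDUE = {
    "catalytic_cys": "C",
    "asp": "D",
    "glu": "E",
    "motif_glu": "E",
    "backdoor_cys": "C",
    "alt_backdoor_cys": "C",
}


class CensusError(ValueError):
    """Invalid census input or usage."""


@dataclass(frozen=True)
class CensusConfig:
    """Alignment scoring and classification tunables.

    BLOSUM62 with gap open -11 / extend -1 is the standard protein
    scoring; end gaps are free so that domain-length references map into
    longer queries without penalty. `length_boundary` splits the
    subfamilies (sequences of exactly that length count as bimodular —
    ties favor the longer architecture). `split_override`, when set,
    fixes the bimodular module boundary instead of locating it by
    alignment.
    """

    substitution_matrix: str = "BLOSUM62"
    open_gap_score: float = -11.0
    extend_gap_score: float = -1.0
    hydrophobic_set: frozenset = DEFAULT_HYDROPHOBIC
    length_boundary: int = 200
    split_override: int | None = None

    def __post_init__(self) -> None:
        if self.length_boundary <= 0:
            raise CensusError("length_boundary must be positive")
        object.__setattr__(self, "hydrophobic_set", frozenset(self.hydrophobic_set))


@dataclass(frozen=True)
class ReferenceSpec:
    """A subfamily reference sequence plus its landmark residue positions.

    Landmark roles: catalytic_cys, asp, glu, motif_glu, backdoor_cys and
    (unimodular only) alt_backdoor_cys; positions are 1-based residue
    numbers in the reference. Construction validates that each landmark
    position actually holds the expected amino acid.
    """

    subfamily: str
    ref_sequence: str
    landmark_positions: dict[str, int]

    def __post_init__(self) -> None:
        if self.subfamily not in ("unimodular", "bimodular"):
            raise CensusError(f"unknown subfamily {self.subfamily!r}")
        for role, pos in self.landmark_positions.items():
            if not 1 <= pos <= len(self.ref_sequence):
                raise CensusError(
                    f"{self.subfamily} landmark {role} position {pos} outside "
                    f"reference of length {len(self.ref_sequence)}"
                )
            expected = _LANDMARK_RESIDUE.get(role)
            actual = self.ref_sequence[pos - 1]
            if expected is not None and actual != expected:
                raise CensusError(
                    f"{self.subfamily} landmark {role} expects {expected} at "
                    f"position {pos}, reference has {actual}"
                )


@dataclass(frozen=True)
class ReferenceSet:
    """Both subfamily references."""

    unimodular: ReferenceSpec
    bimodular: ReferenceSpec

    def for_subfamily(self, subfamily: str) -> ReferenceSpec:
        if subfamily == "unimodular":
            return self.unimodular
        if subfamily == "bimodular":
            return self.bimodular
        raise CensusError(f"unknown subfamily {subfamily!r}")


@dataclass
class SequenceCall:
    """Per-sequence census verdict."""

    seq_id: str
    length: int
    is_quef: bool
    failure_reasons: list[str] = field(default_factory=list)
    subfamily: str = "none"
    motif_span: tuple[int, int] | None = None
    backdoor: str = "none"  # primary_cys | alternative_cys | none


@dataclass
class CensusResult:
    """Aggregate conservation tallies (percentages are None when the
    subfamily has no QueF sequences)."""

    n_unimodular: int
    n_bimodular: int
    pct_backdoor_unimodular: float | None
    pct_backdoor_bimodular: float | None
    pct_any_backdoor_unimodular: float | None

    def to_dict(self) -> dict:
        return {
            "n_unimodular": self.n_unimodular,
            "n_bimodular": self.n_bimodular,
            "pct_backdoor_unimodular": self.pct_backdoor_unimodular,
            "pct_backdoor_bimodular": self.pct_backdoor_bimodular,
            "pct_any_backdoor_unimodular": self.pct_any_backdoor_unimodular,
        }


# ---------------------------------------------------------------------------
# Motif scan
# ---------------------------------------------------------------------------

def _motif_match(window: str, hydrophobic: frozenset) -> bool:
    return (
        len(window) == 8
        and window[0] == "E"
        and window[1] in "SL"
        and window[2] == "K"
        and window[3] in "SA"
        and window[4] in hydrophobic
        and window[5] == "K"
        and window[6] in "LY"
        and window[7] in "YFW"
    )


def find_all_quef_motifs(
    sequence: str, hydrophobic_set: frozenset = DEFAULT_HYDROPHOBIC
) -> list[tuple[int, int]]:
    """All QueF-motif windows, as 1-based inclusive (start, end) spans."""
    sequence = sequence.upper()
    hydro = frozenset(hydrophobic_set)
    spans = []
    for i in range(len(sequence) - 7):
        if _motif_match(sequence[i : i + 8], hydro):
            spans.append((i + 1, i + 8))
    return spans


def find_quef_motif(
    sequence: str, hydrophobic_set: frozenset = DEFAULT_HYDROPHOBIC
) -> tuple[int, int] | None:
    """Leftmost QueF-motif window E(S/L)K(S/A)hK(L/Y)(Y/F/W), or None.

    `X` is tolerated in the sequence but never matches a motif position.
    """
    spans = find_all_quef_motifs(sequence, hydrophobic_set)
    return spans[0] if spans else None


# ---------------------------------------------------------------------------
# Alignment-based landmark transfer
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _make_aligner(
    matrix: str, open_gap: float, extend_gap: float, mode: str
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    aligner.mode = "local" if mode == "local" else "global"
    if mode == "global":
        # free end gaps: map a domain-sized reference into longer queries
        try:
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        except AttributeError:  # older Biopython naming
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
    return aligner


def _align_pair(ref_seq: str, query: str, config: CensusConfig, mode: str = "global"):
    if not query:
        raise CensusError("empty query sequence")
    bad = set(query.upper()) - VALID_RESIDUES
    if bad:
        raise CensusError(f"invalid residue characters {sorted(bad)} in query")
    aligner = _make_aligner(
        config.substitution_matrix, config.open_gap_score,
        config.extend_gap_score, mode,
    )
    return aligner.align(ref_seq, query.upper())[0]


def map_landmark(
    query: str,
    ref: ReferenceSpec,
    role: str,
    config: CensusConfig | None = None,
    alignment=None,
) -> int | None:
    """Transfer a reference landmark onto the query by global alignment.

    Returns the 1-based query position aligned to the reference landmark
    column, or None when the landmark sits opposite a gap. A precomputed
    `alignment` (reference as target, query as query) may be supplied to
    avoid re-aligning for every role.
    """
    config = config or CensusConfig()
    if role not in ref.landmark_positions:
        raise CensusError(f"{ref.subfamily} reference has no landmark {role!r}")
    if alignment is None:
        alignment = _align_pair(ref.ref_sequence, query, config)
    ref_idx = ref.landmark_positions[role] - 1
    indices = alignment.indices  # 2 x n_columns, -1 marks a gap
    cols = (indices[0] == ref_idx).nonzero()[0]
    if len(cols) == 0:
        return None
    qpos = int(indices[1][cols[0]])
    return qpos + 1 if qpos >= 0 else None


def classify_modularity(sequence: str, config: CensusConfig | None = None) -> str:
    """Architecture call from length: < boundary -> unimodular, else bimodular.

    The boundary (default 200) itself counts as bimodular: the family's
    length split leaves the boundary unassigned, and ties favor the
    longer, two-domain architecture.
    """
    config = config or CensusConfig()
    return "unimodular" if len(sequence) < config.length_boundary else "bimodular"


def gate_family(
    query: str,
    refs: ReferenceSet,
    config: CensusConfig | None = None,
    seq_id: str = "",
) -> SequenceCall:
    """Family gate: all active-site landmarks plus the QueF motif.

    A sequence is QueF iff the alignment-mapped catalytic-cysteine
    position holds C, the mapped aspartate holds D, the mapped glutamate
    holds E, and a QueF-motif window exists that contains the mapped
    motif glutamate. `failure_reasons` lists every check that failed
    (catalytic_cys, asp, glu, motif).
    """
    config = config or CensusConfig()
    subfamily = classify_modularity(query, config)
    ref = refs.for_subfamily(subfamily)
    q = query.upper()
    alignment = _align_pair(ref.ref_sequence, q, config)

    reasons = []
    for role, expected in (("catalytic_cys", "C"), ("asp", "D"), ("glu", "E")):
        pos = map_landmark(q, ref, role, config, alignment=alignment)
        if pos is None or q[pos - 1] != expected:
            reasons.append(role)

    motif_span = find_quef_motif(q, config.hydrophobic_set)
    motif_glu = map_landmark(q, ref, "motif_glu", config, alignment=alignment)
    motif_ok = (
        motif_span is not None
        and motif_glu is not None
        and motif_span[0] <= motif_glu <= motif_span[1]
    )
    if not motif_ok:
        reasons.append("motif")

    is_quef = not reasons
    return SequenceCall(
        seq_id=seq_id,
        length=len(q),
        is_quef=is_quef,
        failure_reasons=reasons,
        subfamily=subfamily if is_quef else "none",
        motif_span=motif_span if is_quef else None,
    )


def find_backdoor(
    query: str,
    call: SequenceCall,
    refs: ReferenceSet,
    config: CensusConfig | None = None,
) -> str:
    """Backdoor-cysteine call for a gated QueF sequence.

    primary_cys when the mapped Cys99/Cys236-equivalent position holds C;
    otherwise (unimodular only) alternative_cys when the mapped
    Cys53-equivalent holds C; otherwise none. Requires a sequence that
    passed the family gate.
    """
    config = config or CensusConfig()
    if not call.is_quef:
        raise CensusError("find_backdoor requires a sequence that passed the gate")
    ref = refs.for_subfamily(call.subfamily)
    q = query.upper()
    alignment = _align_pair(ref.ref_sequence, q, config)
    pos = map_landmark(q, ref, "backdoor_cys", config, alignment=alignment)
    if pos is not None and q[pos - 1] == "C":
        return "primary_cys"
    if call.subfamily == "unimodular" and "alt_backdoor_cys" in ref.landmark_positions:
        alt = map_landmark(q, ref, "alt_backdoor_cys", config, alignment=alignment)
        if alt is not None and q[alt - 1] == "C":
            return "alternative_cys"
    return "none"


# ---------------------------------------------------------------------------
# Bimodular module splitting
# ---------------------------------------------------------------------------

def split_bimodular(
    query: str,
    refs: ReferenceSet,
    config: CensusConfig | None = None,
) -> tuple[str, str]:
    """Split a bimodular sequence into its N- and C-terminal modules.

    Each tandem T-fold module of a bimodular sequence is homologous to
    the unimodular reference, so the two best non-overlapping local
    alignments of the unimodular reference against the query locate the
    modules; the split point is the midpoint between the end of the
    earlier hit and the start of the later one. The catalytic cysteine
    and the Cys236-equivalent backdoor fall in the C-terminal module.
    `config.split_override` fixes the split position instead.

    Concatenating the two returned parts always reproduces the input.
    """
    config = config or CensusConfig()
    if classify_modularity(query, config) != "bimodular":
        raise CensusError("split_bimodular requires a bimodular-length sequence")
    q = query.upper()

    if config.split_override is not None:
        k = config.split_override
        if not 0 < k < len(q):
            raise CensusError(f"split_override {k} outside sequence of length {len(q)}")
        return q[:k], q[k:]

    uni = refs.unimodular.ref_sequence
    first = _align_pair(uni, q, config, mode="local")
    qa = first.aligned[1]
    if len(qa) == 0:
        raise CensusError("no local similarity to the unimodular reference")
    s1, e1 = int(qa[0][0]), int(qa[-1][1])  # 0-based, end exclusive

    best = None  # (score, start0, end0)
    for lo, hi in ((0, s1), (e1, len(q))):
        segment = q[lo:hi]
        if len(segment) < 20:
            continue
        aln = _align_pair(uni, segment, config, mode="local")
        sa = aln.aligned[1]
        if len(sa) == 0:
            continue
        cand = (float(aln.score), lo + int(sa[0][0]), lo + int(sa[-1][1]))
        if best is None or cand[0] > best[0]:
            best = cand
    if best is None:
        raise CensusError(
            "could not locate a second module; supply config.split_override"
        )
    _, s2, e2 = best
    # midpoint of the inter-module gap; an odd gap rounds toward the
    # C module so the gap's central residue stays with the N module
    if s2 >= e1:  # first hit is the N module
        k = (e1 + s2 + 1) // 2
    else:  # first hit is the C module
        k = (e2 + s1 + 1) // 2
    return q[:k], q[k:]


# ---------------------------------------------------------------------------
# The census driver
# ---------------------------------------------------------------------------

def _pct(numer: int, denom: int) -> float | None:
    return None if denom == 0 else 100.0 * numer / denom


def run_census(
    fasta_path: str,
    refs: ReferenceSet,
    config: CensusConfig | None = None,
) -> tuple[CensusResult, list[SequenceCall], list[dict]]:
    """Gate, classify and tally every sequence of a FASTA file.

    Returns the aggregate :class:`CensusResult`, the ordered per-sequence
    calls, and a rejects report (sequences with invalid residue
    characters, skipped with a warning). Raises :class:`CensusError` on
    an empty FASTA. Deterministic: identical input and config give
    identical output.
    """
    import warnings

    config = config or CensusConfig()
    records = list(SeqIO.parse(fasta_path, "fasta"))
    if not records:
        raise CensusError(f"{fasta_path}: no FASTA records found")

    calls: list[SequenceCall] = []
    rejects: list[dict] = []
    for rec in records:
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_RESIDUES
        if not seq or bad:
            reason = (
                "empty sequence" if not seq
                else f"invalid residue characters {''.join(sorted(bad))}"
            )
            warnings.warn(f"{rec.id}: {reason}; skipped", stacklevel=2)
            rejects.append({"seq_id": rec.id, "reason": reason})
            continue
        call = gate_family(seq, refs, config, seq_id=rec.id)
        if call.is_quef:
            call.backdoor = find_backdoor(seq, call, refs, config)
        calls.append(call)

    uni = [c for c in calls if c.is_quef and c.subfamily == "unimodular"]
    bim = [c for c in calls if c.is_quef and c.subfamily == "bimodular"]
    n_uni_primary = sum(c.backdoor == "primary_cys" for c in uni)
    n_uni_any = sum(c.backdoor in ("primary_cys", "alternative_cys") for c in uni)
    n_bim_primary = sum(c.backdoor == "primary_cys" for c in bim)

    result = CensusResult(
        n_unimodular=len(uni),
        n_bimodular=len(bim),
        pct_backdoor_unimodular=_pct(n_uni_primary, len(uni)),
        pct_backdoor_bimodular=_pct(n_bim_primary, len(bim)),
        pct_any_backdoor_unimodular=_pct(n_uni_any, len(uni)),
    )
    return result, calls, rejects


def load_references(config_path: str) -> ReferenceSet:
    """Load user-supplied subfamily references from a JSON/YAML config.

    The file maps each subfamily to {"sequence": ..., "landmarks":
    {role: position}} or {"fasta": path, "landmarks": ...} with the
    FASTA's first record used.
    """
    import yaml

    with open(config_path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise CensusError(f"{config_path}: expected a mapping of subfamilies")
    specs = {}
    for subfamily in ("unimodular", "bimodular"):
        if subfamily not in data:
            raise CensusError(f"{config_path}: missing {subfamily!r} reference")
        entry = data[subfamily]
        if "sequence" in entry:
            seq = entry["sequence"]
        elif "fasta" in entry:
            seq = str(next(SeqIO.parse(entry["fasta"], "fasta")).seq)
        else:
            raise CensusError(
                f"{config_path}: {subfamily} needs 'sequence' or 'fasta'"
            )
        specs[subfamily] = ReferenceSpec(
            subfamily=subfamily,
            ref_sequence=str(seq).upper(),
            landmark_positions={k: int(v) for k, v in entry["landmarks"].items()},
        )
    return ReferenceSet(**specs)
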