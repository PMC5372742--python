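"""Ground-truth synthetic inputs for both analysis strands.

Two generators live here:

* a cysteine-pair coordinate builder that places the eight backbone/side
  chain atoms (N, CA, CB, SG per half-cystine) by sequential
  internal-to-Cartesian construction so that the five disulfide torsions
  and the S-S bond length take prescribed values exactly — the geometric
  oracle for the dihedral analysis;
* a protein sequence-set generator that emits FASTA files with planted
  QueF-family composition (motif, active-site landmarks, backdoor
  cysteines, unimodular/bimodular architecture) plus a manifest recording
  every sequence's ground-truth category — the oracle for the census.

Synthetic reference sequences stand in for the B. subtilis / V. cholerae
QueF references in tests: they carry the landmark residues at the
literature positions (unimodular Cys55/Asp62/Glu97/motif-Glu78/Cys99/Cys53;
bimodular Cys194/Asp201/Glu234/motif-Glu94/Cys236) on a random background,
so no database download is needed. They are synthetic stand-ins, not real
QueF sequences.

Planted category counts use largest-remainder rounding, so a requested
composition is reproduced exactly by the census, not just in expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import gemmi
import numpy as np

from .census import ReferenceSpec, ReferenceSet, find_quef_motif, DEFAULT_HYDROPHOBIC
from .structure import ResidueRecord, StructureModel

__all__ = [
    "DisulfideGeometrySpec",
    "SequenceSetSpec",
    "SyntheticSpecError",
    "build_disulfide_coords",
    "coords_to_residues",
    "write_disulfide_pdb",
    "make_reference",
    "make_reference_set",
    "generate_quef_like",
    "generate_sequence_set",
    "largest_remainder_counts",
    "GLU97GLN_BRIDGES",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Dihedrals (chi1, chi2, chi3, chi2', chi1', degrees) and S-S bond lengths
# (A) reported for the five Cys55-Cys99 bridges in subunits A-E of the
# B. subtilis QueF Glu97Gln crystal structure (PDB 5UDG).
GLU97GLN_BRIDGES: dict[str, tuple[tuple[float, float, float, float, float], float]] = {
    "A": ((-59.85, -126.76, -105.12, 176.01, -66.90), 2.03),
    "B": ((-56.90, -123.68, -89.05, 171.20, -81.83), 2.03),
    "C": ((-59.70, -116.71, -102.91, 168.10, -63.57), 2.05),
    "D": ((-60.93, -127.32, -79.75, 173.65, -89.46), 2.07),
    "E": ((-55.16, -120.73, -94.72, 172.66, -72.34), 2.04),
}


class SyntheticSpecError(ValueError):
    """Invalid generator specification."""


@dataclass(frozen=True)
class DisulfideGeometrySpec:
    """Target internal coordinates for one synthetic Cys-Cys bridge.

    Bond lengths and bend angles default to standard cysteine
    stereochemistry; the five torsions and the S-S length are the
    quantities under test and have no defaults.
    """

    chi1: float
    chi2: float
    chi3: float
    chi2p: float
    chi1p: float
    ss_bond_length: float = 2.04
    n_ca: float = 1.46
    ca_cb: float = 1.53
    cb_sg: float = 1.81
    angle_n_ca_cb: float = 110.5
    angle_ca_cb_sg: float = 114.0
    angle_cb_sg_sg: float = 104.0

    def __post_init__(self) -> None:
        for name in ("ss_bond_length", "n_ca", "ca_cb", "cb_sg"):
            if getattr(self, name) <= 0:
                raise SyntheticSpecError(f"{name} must be > 0")
        for name in ("angle_n_ca_cb", "angle_ca_cb_sg", "angle_cb_sg_sg"):
            if not 0.0 < getattr(self, name) < 180.0:
                raise SyntheticSpecError(f"{name} must lie in (0, 180) degrees")


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Next atom D from frame (a, b, c): |CD|=bond, angle(BCD), torsion(ABCD).

    Standard natural-extension (NeRF) frame construction; the torsion sign
    follows the right-handed convention used by
    :func:`quefss.geometry.dihedral_angle`.
    """
    theta = math.radians(angle_deg)
    phi = math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = bond * (
        -math.cos(theta) * bc
        + math.sin(theta) * (math.cos(phi) * m + math.sin(phi) * n)
    )
    return c + d


def build_disulfide_coords(spec: DisulfideGeometrySpec) -> dict[str, np.ndarray]:
    """Eight labeled atom positions realizing the spec's internal coordinates.

    Atoms are placed along the chain N->CA->CB->SG->SG'->CB'->CA'->N',
    consuming the torsions chi1, chi2, chi3, chi2', chi1' in that order.
    Keys: N1/CA1/CB1/SG1 (unprimed residue) and N2/CA2/CB2/SG2 (primed).
    Recomputing the five torsions from the output recovers the spec's
    angles to numerical precision, and |SG1-SG2| equals ss_bond_length.
    """
    n1 = np.zeros(3)
    ca1 = np.array([spec.n_ca, 0.0, 0.0])
    th = math.radians(spec.angle_n_ca_cb)
    cb1 = ca1 + spec.ca_cb * np.array([-math.cos(th), math.sin(th), 0.0])

    sg1 = _place_atom(n1, ca1, cb1, spec.cb_sg, spec.angle_ca_cb_sg, spec.chi1)
    sg2 = _place_atom(ca1, cb1, sg1, spec.ss_bond_length, spec.angle_cb_sg_sg, spec.chi2)
    cb2 = _place_atom(cb1, sg1, sg2, spec.cb_sg, spec.angle_cb_sg_sg, spec.chi3)
    ca2 = _place_atom(sg1, sg2, cb2, spec.ca_cb, spec.angle_ca_cb_sg, spec.chi2p)
    n2 = _place_atom(sg2, cb2, ca2, spec.n_ca, spec.angle_n_ca_cb, spec.chi1p)

    return {
        "N1": n1, "CA1": ca1, "CB1": cb1, "SG1": sg1,
        "N2": n2, "CA2": ca2, "CB2": cb2, "SG2": sg2,
    }


_ELEMENTS = {"N": "N", "CA": "C", "CB": "C", "SG": "S"}


def coords_to_residues(
    coords: dict[str, np.ndarray],
    chain_id: str = "A",
    res_nums: tuple[int, int] = (55, 99),
) -> tuple[ResidueRecord, ResidueRecord]:
    """Package built coordinates as two CYS :class:`ResidueRecord` objects."""
    from .structure import AtomRecord

    out = []
    for idx, res_num in zip((1, 2), res_nums):
        rec = ResidueRecord(chain_id=chain_id, res_num=res_num, res_name="CYS")
        for name in ("N", "CA", "CB", "SG"):
            rec.atoms[name] = AtomRecord(
                name=name, element=_ELEMENTS[name], coords=coords[f"{name}{idx}"]
            )
        out.append(rec)
    return out[0], out[1]


def _random_rotation(rng: np.random.Generator):
    from scipy.spatial.transform import Rotation

    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q))


def rigid_transform_coords(
    coords: dict[str, np.ndarray], rng: np.random.Generator,
    translation_scale: float = 10.0,
) -> dict[str, np.ndarray]:
    """Apply one seeded random rotation + translation to all atoms."""
    rot = _random_rotation(rng)
    shift = rng.uniform(-translation_scale, translation_scale, size=3)
    return {k: rot.apply(v) + shift for k, v in coords.items()}


_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def write_disulfide_pdb(
    specs: list[DisulfideGeometrySpec],
    path: str,
    seed: int = 0,
    res_nums: tuple[int, int] = (55, 99),
    free_cysteines: int = 0,
) -> None:
    """Write synthetic bridges to a PDB file, one chain per bridge.

    Each bridge is built at its spec's internal coordinates, then placed
    by a seeded random rigid motion plus a per-chain offset so bridges do
    not collide. Residues are numbered 55 and 99 (mnemonic for the QueF
    pair). Optionally appends `free_cysteines` lone CYS residues (reduced
    thiols, no partner within bonding distance) as detection decoys. The
    output parses cleanly with :func:`quefss.structure.read_pdb`.
    """
    if len(specs) + (1 if free_cysteines else 0) > len(_CHAIN_IDS):
        raise SyntheticSpecError("too many chains for single-letter chain IDs")
    rng = np.random.default_rng(seed)

    st = gemmi.Structure()
    st.name = "SYNTH"
    model = gemmi.Model("1")

    def add_residue(chain, res_num, atom_coords):
        res = gemmi.Residue()
        res.name = "CYS"
        res.seqid = gemmi.SeqId(res_num, " ")
        for name in ("N", "CA", "CB", "SG"):
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(_ELEMENTS[name])
            atom.occ = 1.0
            xyz = atom_coords[name]
            atom.pos = gemmi.Position(*xyz)
            res.add_atom(atom)
        chain.add_residue(res)

    for i, spec in enumerate(specs):
        coords = rigid_transform_coords(build_disulfide_coords(spec), rng)
        offset = np.array([30.0 * i, 0.0, 0.0])
        chain = gemmi.Chain(_CHAIN_IDS[i])
        add_residue(
            chain, res_nums[0],
            {n: coords[f"{n}1"] + offset for n in ("N", "CA", "CB", "SG")},
        )
        add_residue(
            chain, res_nums[1],
            {n: coords[f"{n}2"] + offset for n in ("N", "CA", "CB", "SG")},
        )
        model.add_chain(chain)

    if free_cysteines:
        chain = gemmi.Chain(_CHAIN_IDS[len(specs)])
        for j in range(free_cysteines):
            base = DisulfideGeometrySpec(-60.0, -60.0, -90.0, -60.0, -60.0)
            coords = rigid_transform_coords(build_disulfide_coords(base), rng)
            offset = np.array([30.0 * (len(specs) + 1), 30.0 * j, 0.0])
            # keep only the unprimed half: a lone thiol, no partner sulfur
            add_residue(
                chain, j + 1,
                {n: coords[f"{n}1"] + offset for n in ("N", "CA", "CB", "SG")},
            )
        model.add_chain(chain)

    st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"TITLE     QUEFSS SYNTHETIC DISULFIDE FIXTURE (SEED {seed})\n")
        fh.write(doc)


# ---------------------------------------------------------------------------
# Sequence generators
# ---------------------------------------------------------------------------

_MOTIF_WINDOW = "ESKSLKLY"  # matches E(S/L)K(S/A)hK(L/Y)(Y/F/W)
_REF_BG_SEED = 20170316  # fixed: references must be identical across runs

_UNI_LANDMARKS = {
    "catalytic_cys": 55, "asp": 62, "glu": 97,
    "motif_glu": 78, "backdoor_cys": 99, "alt_backdoor_cys": 53,
}
_BIM_LANDMARKS = {
    "catalytic_cys": 194, "asp": 201, "glu": 234,
    "motif_glu": 94, "backdoor_cys": 236,
}
_LANDMARK_RESIDUE = {
    "catalytic_cys": "C", "asp": "D", "glu": "E",
    "motif_glu": "E", "backdoor_cys": "C", "alt_backdoor_cys": "C",
}

_UNI_REF_LEN = 165
_BIM_MODULE_BOUNDARY = 140  # N-module = 1..140, C-module = 141..280
_BIM_REF_LEN = 280


def _plant(seq: list[str], pos1: int, residue: str) -> None:
    seq[pos1 - 1] = residue


def _plant_motif(seq: list[str], start1: int) -> None:
    for k, aa in enumerate(_MOTIF_WINDOW):
        seq[start1 - 1 + k] = aa


def _scramble_motifs(seq: list[str], keep_start1: int | None) -> None:
    """Destroy accidental QueF-motif matches outside the planted window."""
    while True:
        span = find_quef_motif("".join(seq), DEFAULT_HYDROPHOBIC)
        if span is None or span[0] == keep_start1:
            break
        seq[span[0] - 1] = "G"  # G is not E: kills the match


def _uni_reference_seq() -> str:
    rng = np.random.default_rng(_REF_BG_SEED)
    seq = list(rng.choice(list(AMINO_ACIDS), size=_UNI_REF_LEN))
    for role, pos in _UNI_LANDMARKS.items():
        if role == "motif_glu":
            continue
        _plant(seq, pos, _LANDMARK_RESIDUE[role])
    _plant_motif(seq, _UNI_LANDMARKS["motif_glu"])
    _scramble_motifs(seq, keep_start1=_UNI_LANDMARKS["motif_glu"])
    return "".join(seq)


def _mutate(
    seq: list[str], rng: np.random.Generator, rate: float, protected: set[int]
) -> list[str]:
    """Point-substitute at `rate`, never touching protected 1-based positions."""
    out = list(seq)
    for i in range(len(out)):
        if (i + 1) in protected:
            continue
        if rng.random() < rate:
            choices = AMINO_ACIDS.replace(out[i], "")
            out[i] = choices[rng.integers(len(choices))]
    return out


def _bim_reference_seq() -> str:
    uni = _uni_reference_seq()
    template = list(uni[:_BIM_MODULE_BOUNDARY])
    rng = np.random.default_rng(_REF_BG_SEED + 1)

    # N-terminal module: diverged copy that lost the catalytic machinery
    # but carries the QueF motif (at position 94, V. cholerae-style).
    nmod = _mutate(template, rng, rate=0.30, protected=set())
    for pos in (53, 55, 62, 97, 99):
        _plant(nmod, pos, "A" if nmod[pos - 1] in "CDE" else nmod[pos - 1])
    for k in range(8):  # erase the template's motif window
        nmod[_UNI_LANDMARKS["motif_glu"] - 1 + k] = "G"
    _plant_motif(nmod, _BIM_LANDMARKS["motif_glu"])

    # C-terminal module: lightly diverged copy, shifted one position so the
    # catalytic Cys/Asp land at absolute positions 194/201, with the
    # Glu/backdoor pair overwritten at 234/236.
    cmod_full = _mutate(template, rng, rate=0.10, protected={55, 62})
    for k in range(8):
        cmod_full[_UNI_LANDMARKS["motif_glu"] - 1 + k] = "G"
    cmod = cmod_full[1:]  # module position = template position - 1
    cmod.append(AMINO_ACIDS[rng.integers(20)])  # pad to 140

    seq = nmod + cmod
    assert len(seq) == _BIM_REF_LEN
    for role, pos in _BIM_LANDMARKS.items():
        if role == "motif_glu":
            continue
        _plant(seq, pos, _LANDMARK_RESIDUE[role])
    _scramble_motifs(seq, keep_start1=_BIM_LANDMARKS["motif_glu"])
    return "".join(seq)


def make_reference(subfamily: str) -> ReferenceSpec:
    """Synthetic stand-in reference for one subfamily (deterministic)."""
    if subfamily == "unimodular":
        return ReferenceSpec(
            subfamily="unimodular",
            ref_sequence=_uni_reference_seq(),
            landmark_positions=dict(_UNI_LANDMARKS),
        )
    if subfamily == "bimodular":
        return ReferenceSpec(
            subfamily="bimodular",
            ref_sequence=_bim_reference_seq(),
            landmark_positions=dict(_BIM_LANDMARKS),
        )
    raise SyntheticSpecError(f"unknown subfamily {subfamily!r}")


def make_reference_set() -> ReferenceSet:
    """Both synthetic stand-in references."""
    return ReferenceSet(
        unimodular=make_reference("unimodular"),
        bimodular=make_reference("bimodular"),
    )


_UNI_LENGTH_RANGE = (140, 199)
_BIM_LENGTH_RANGE = (240, 320)

_KNOCKOUT = {"C": "S", "D": "N", "E": "Q"}

_DEFAULT_FEATURES = {
    "catalytic_cys": True, "asp": True, "glu": True, "motif": True,
    "backdoor_cys": True, "alt_backdoor_cys": False,
}


def generate_quef_like(
    subfamily: str,
    features: dict[str, bool] | None = None,
    length: int | None = None,
    seed: int = 0,
    mutation_rate: float = 0.08,
    n_term_ext: int | None = None,
) -> tuple[str, dict]:
    """One synthetic QueF-like sequence with controllable features.

    Starts from the subfamily's synthetic reference, applies background
    point substitutions, optionally extends the N-terminus (shifting all
    landmarks) and grows/trims the C-terminal tail to hit `length`, then
    plants or knocks out each feature per the feature map. Returns the
    sequence and a ground-truth dict (landmark positions as they ended up,
    module boundary for bimodular, applied features).
    """
    ref = make_reference(subfamily)
    feats = dict(_DEFAULT_FEATURES)
    feats.update(features or {})
    if subfamily == "bimodular":
        feats.pop("alt_backdoor_cys", None)
    lo, hi = _UNI_LENGTH_RANGE if subfamily == "unimodular" else _BIM_LENGTH_RANGE
    rng = np.random.default_rng(seed)
    if length is None:
        length = int(rng.integers(lo, hi + 1))
    if not lo <= length <= hi:
        raise SyntheticSpecError(
            f"{subfamily} length {length} outside legal range {lo}-{hi}"
        )
    if n_term_ext is None:
        n_term_ext = int(rng.integers(0, 5))

    last_landmark = max(ref.landmark_positions.values())
    if n_term_ext + last_landmark + 1 > length:
        raise SyntheticSpecError(
            f"length {length} cannot hold landmarks up to {last_landmark} "
            f"plus N-terminal extension {n_term_ext}"
        )

    landmarks = {k: v + n_term_ext for k, v in ref.landmark_positions.items()}
    motif_start = landmarks["motif_glu"]
    protected = set(landmarks.values()) | set(range(motif_start, motif_start + 8))

    seq = list(rng.choice(list(AMINO_ACIDS), size=n_term_ext)) + list(ref.ref_sequence)
    seq = _mutate(seq, rng, mutation_rate, protected)
    # tail adjustment: grow or trim at the C-terminus only
    if len(seq) < length:
        seq += list(rng.choice(list(AMINO_ACIDS), size=length - len(seq)))
    else:
        seq = seq[:length]

    for role in ("catalytic_cys", "asp", "glu", "backdoor_cys", "alt_backdoor_cys"):
        if role not in landmarks:
            continue
        target = _LANDMARK_RESIDUE[role]
        on = feats.get(role, role != "alt_backdoor_cys")
        _plant(seq, landmarks[role], target if on else _KNOCKOUT[target])
    if feats["motif"]:
        _plant_motif(seq, motif_start)
    else:
        for k in range(8):
            seq[motif_start - 1 + k] = "G"
    _scramble_motifs(seq, keep_start1=motif_start if feats["motif"] else None)

    truth = {
        "subfamily": subfamily,
        "features": feats,
        "landmarks": landmarks,
        "length": length,
        "n_term_ext": n_term_ext,
    }
    if subfamily == "bimodular":
        truth["module_boundary"] = _BIM_MODULE_BOUNDARY + n_term_ext
    return "".join(seq), truth


@dataclass(frozen=True)
class SequenceSetSpec:
    """Composition of a planted census input set.

    Unimodular fractions (primary backdoor / alternative-only / neither)
    must sum to 1; counts per category are fixed by largest-remainder
    rounding so the planted composition is exact. Defaults mirror the
    conservation pattern reported for the QueF family: 61% of unimodular
    sequences keep the Cys99-equivalent backdoor cysteine, a further 22%
    carry only the alternative Cys53, and every bimodular sequence keeps
    Cys236.
    """

    n_unimodular: int = 200
    n_bimodular: int = 50
    f_primary_backdoor: float = 0.61
    f_alt_backdoor: float = 0.22
    f_none: float = 0.17
    f_bimodular_backdoor: float = 1.0
    n_decoys: int = 10
    seed: int = 0
    unimodular_lengths: tuple[int, int] = _UNI_LENGTH_RANGE
    bimodular_lengths: tuple[int, int] = _BIM_LENGTH_RANGE

    def __post_init__(self) -> None:
        fr = (self.f_primary_backdoor, self.f_alt_backdoor, self.f_none)
        if any(not 0.0 <= f <= 1.0 for f in fr + (self.f_bimodular_backdoor,)):
            raise SyntheticSpecError("fractions must lie in [0, 1]")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise SyntheticSpecError(
                f"unimodular fractions must sum to 1 (got {sum(fr):g})"
            )
        if min(self.n_unimodular, self.n_bimodular, self.n_decoys) < 0:
            raise SyntheticSpecError("counts must be >= 0")


def largest_remainder_counts(total: int, fractions: list[float]) -> list[int]:
    """Apportion `total` into integer counts proportional to `fractions`.

    Largest-remainder (Hamilton) method; ties broken by category order.
    Deterministic, sums exactly to `total`.
    """
    quotas = [total * f for f in fractions]
    counts = [int(math.floor(q)) for q in quotas]
    short = total - sum(counts)
    order = sorted(
        range(len(fractions)), key=lambda i: (-(quotas[i] - counts[i]), i)
    )
    for i in order[:short]:
        counts[i] += 1
    return counts


_CATEGORY_FEATURES = {
    "uni_primary": ("unimodular", {"backdoor_cys": True, "alt_backdoor_cys": False}),
    "uni_alternative": ("unimodular", {"backdoor_cys": False, "alt_backdoor_cys": True}),
    "uni_none": ("unimodular", {"backdoor_cys": False, "alt_backdoor_cys": False}),
    "bim_backdoor": ("bimodular", {"backdoor_cys": True}),
    "bim_none": ("bimodular", {"backdoor_cys": False}),
}


def generate_sequence_set(
    spec: SequenceSetSpec, fasta_path: str, manifest_path: str | None = None
) -> list[dict]:
    """Write a planted FASTA set and its ground-truth manifest (TSV).

    Category counts are exact (largest-remainder). Decoys are random
    background sequences carrying none of the family features. The
    manifest records seq_id, subfamily, category and length per sequence;
    its header comment records the seed. Deterministic for a fixed spec.
    """
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    rng = np.random.default_rng(spec.seed)
    uni_counts = largest_remainder_counts(
        spec.n_unimodular,
        [spec.f_primary_backdoor, spec.f_alt_backdoor, spec.f_none],
    )
    bim_counts = largest_remainder_counts(
        spec.n_bimodular, [spec.f_bimodular_backdoor, 1.0 - spec.f_bimodular_backdoor]
    )
    plan = list(
        zip(
            ("uni_primary", "uni_alternative", "uni_none", "bim_backdoor", "bim_none"),
            uni_counts + bim_counts,
        )
    )

    records, manifest = [], []
    for category, count in plan:
        subfamily, features = _CATEGORY_FEATURES[category]
        lo, hi = (
            spec.unimodular_lengths if subfamily == "unimodular"
            else spec.bimodular_lengths
        )
        for k in range(count):
            seq_seed = int(rng.integers(0, 2**31 - 1))
            length = int(rng.integers(lo, hi + 1))
            seq, truth = generate_quef_like(
                subfamily, features=features, length=length, seed=seq_seed
            )
            seq_id = f"{category}_{k + 1:04d}"
            records.append(
                SeqRecord(Seq(seq), id=seq_id, description=f"synthetic {category}")
            )
            manifest.append(
                {
                    "seq_id": seq_id,
                    "subfamily": subfamily,
                    "category": category,
                    "length": len(seq),
                }
            )
    for k in range(spec.n_decoys):
        length = int(rng.integers(120, 321))
        seq = list(rng.choice(list(AMINO_ACIDS), size=length))
        _scramble_motifs(seq, keep_start1=None)
        seq_id = f"decoy_{k + 1:04d}"
        records.append(
            SeqRecord(Seq("".join(seq)), id=seq_id, description="synthetic decoy")
        )
        manifest.append(
            {"seq_id": seq_id, "subfamily": "none", "category": "decoy",
             "length": length}
        )

    with open(fasta_path, "w", encoding="utf-8") as fh:
        SeqIO.write(records, fh, "fasta")
    if manifest_path is not None:
        with open(manifest_path, "w", encoding="utf-8") as fh:
            fh.write(f"# quefss synthetic sequence set; seed={spec.seed}\n")
            fh.write("seq_id\tsubfamily\tcategory\tlength\n")
            for row in manifest:
                fh.write(
                    f"{row['seq_id']}\t{row['subfamily']}\t"
                    f"{row['category']}\t{row['length']}\n"
                )
    return manifest
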