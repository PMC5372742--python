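"""Disulfide bridge detection, stereochemistry and dihedral strain energy.

A disulfide bond between two cysteines is described by five torsion angles:

* chi1  = N-CA-CB-SG of the unprimed half-cystine,
* chi2  = CA-CB-SG-SG' of the unprimed half-cystine,
* chi3  = CB-SG-SG'-CB' across the S-S bond,
* chi2' = CA'-CB'-SG'-SG of the primed half-cystine,
* chi1' = N'-CA'-CB'-SG' of the primed half-cystine,

all signed per the right-handed (IUPAC) torsion convention and reported in
degrees in (-180, 180]. The residue with the lower (chain_id, res_num) is
the unprimed half; for B. subtilis QueF that makes Cys55 unprimed and
Cys99 primed, matching how the crystallographic literature tabulates them.

The sign pattern of the quintuple places the bond in a 20-class
configuration taxonomy (spirals, hooks, staples, each left- or
right-handed with a chi1/chi1' sign prefix); the magnitudes enter a
five-term cosine potential giving the dihedral strain energy (DSE) in
kJ/mol. Allosteric/regulatory disulfides characteristically adopt the
-LHHook class at moderate strain (roughly 10-20 kJ/mol), which is the
geometry observed in the oxidized QueF active site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import ResidueRecord, StructureModel, StructureError

__all__ = [
    "GeometryError",
    "GeometryConfig",
    "DisulfideRecord",
    "dihedral_angle",
    "chi_angles",
    "classify_configuration",
    "strain_energy",
    "detect_disulfides",
    "analyze_structure",
    "STRAIN_ENERGY_MAX",
]

# Analytic maximum of the strain-energy potential (all cosine terms at +1).
STRAIN_ENERGY_MAX = 2 * (8.37 + 4.18) * 2 + (14.64 + 2.51) * 2  # 84.5 kJ/mol

_CHI_ATOMS = ("N", "CA", "CB", "SG")


class GeometryError(ValueError):
    """Degenerate geometry (coincident or collinear points)."""


@dataclass(frozen=True)
class GeometryConfig:
    """Tunables for bridge detection and classification.

    detection_cutoff: maximum SG-SG' distance (A) to call a bridge.
        2.30 A covers crystallographic S-S bonds (2.0-2.1 A) with margin
        while excluding adjacent free thiols.
    ambiguous_angle_threshold: |angle| below this (degrees) makes the sign
        call ambiguous; the record is flagged but still classified.
    """

    detection_cutoff: float = 2.30
    ambiguous_angle_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.detection_cutoff <= 0:
            raise ValueError("detection_cutoff must be > 0")
        if self.ambiguous_angle_threshold < 0:
            raise ValueError("ambiguous_angle_threshold must be >= 0")


@dataclass
class DisulfideRecord:
    """One analyzed S-S bridge."""

    res1: tuple[str, int]
    res2: tuple[str, int]
    chi1: float
    chi2: float
    chi3: float
    chi2p: float
    chi1p: float
    ss_bond_length: float
    config_class: str
    sign_pattern: tuple[str, str, str, str, str]
    strain_energy: float
    flags: list[str] = field(default_factory=list)

    @property
    def angles(self) -> tuple[float, float, float, float, float]:
        return (self.chi1, self.chi2, self.chi3, self.chi2p, self.chi1p)


def _normalize_angle(deg: float) -> float:
    """Map to (-180, 180]; exactly -180 normalizes to +180."""
    a = ((deg + 180.0) % 360.0) - 180.0
    if a == -180.0:
        a = 180.0
    return a


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed torsion of p4 about the p2->p3 axis relative to p1, degrees.

    Right-handed (IUPAC) convention: looking down p2->p3, a clockwise
    rotation from the p1 side to the p4 side is positive. The value is
    invariant under rigid motion and under full point-order reversal.

    Raises :class:`GeometryError` for coincident consecutive points or a
    collinear triple (torsion undefined).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for b, pair in ((b1, "p1,p2"), (b2, "p2,p3"), (b3, "p3,p4")):
        if np.linalg.norm(b) < 1e-12:
            raise GeometryError(f"coincident points {pair}")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise GeometryError("collinear points: torsion undefined")
    b2u = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2u))
    return _normalize_angle(np.degrees(np.arctan2(y, x)))


def chi_angles(
    cys1: ResidueRecord, cys2: ResidueRecord
) -> tuple[float, float, float, float, float]:
    """The five disulfide torsions (chi1, chi2, chi3, chi2', chi1').

    Unprimed angles come from `cys1`, primed from `cys2`; chi3 is
    symmetric, so swapping the arguments exchanges the primed/unprimed
    angles and leaves chi3 unchanged. Both residues must carry N, CA, CB
    and SG atoms.
    """
    for res in (cys1, cys2):
        for name in _CHI_ATOMS:
            if name not in res.atoms:
                raise StructureError(
                    f"residue {res.chain_id}/{res.res_name}{res.res_num} "
                    f"is missing atom {name!r} required for chi angles"
                )
    n1, ca1, cb1, sg1 = (cys1.atom_coords(a) for a in _CHI_ATOMS)
    n2, ca2, cb2, sg2 = (cys2.atom_coords(a) for a in _CHI_ATOMS)
    chi1 = dihedral_angle(n1, ca1, cb1, sg1)
    chi2 = dihedral_angle(ca1, cb1, sg1, sg2)
    chi3 = dihedral_angle(cb1, sg1, sg2, cb2)
    chi2p = dihedral_angle(ca2, cb2, sg2, sg1)
    chi1p = dihedral_angle(n2, ca2, cb2, sg2)
    return (chi1, chi2, chi3, chi2p, chi1p)


def _sign(angle: float) -> str:
    return "-" if angle < 0 else "+"


def classify_configuration(
    chi1: float,
    chi2: float,
    chi3: float,
    chi2p: float,
    chi1p: float,
    threshold: float = 0.5,
) -> tuple[str, tuple[str, str, str, str, str], bool]:
    """Name the disulfide configuration class from the five torsion signs.

    Rules (20-class taxonomy):

    * handedness: chi3 < 0 -> LH, chi3 >= 0 -> RH;
    * shape from chi2/chi2' signs relative to chi3: both matching chi3 ->
      Spiral; exactly one opposite -> Hook; both opposite -> Staple;
    * prefix from (sign chi1, sign chi1'): (-,-) -> "-", (+,+) -> "+",
      mixed -> "-/+" or "+/-". Spiral and Staple are symmetric shapes, so
      their mixed prefixes collapse to "-/+"; Hooks keep the two mixed
      prefixes distinct.

    Returns (class name, sign pattern, ambiguous). `ambiguous` is True when
    any |angle| falls below `threshold` degrees, i.e. the sign call sits on
    the boundary; the best-call class is still returned.
    """
    angles = (chi1, chi2, chi3, chi2p, chi1p)
    pattern = tuple(_sign(a) for a in angles)
    s1, s2, s3, s2p, s1p = pattern

    hand = "LH" if s3 == "-" else "RH"
    n_opposite = (s2 != s3) + (s2p != s3)
    shape = {0: "Spiral", 1: "Hook", 2: "Staple"}[n_opposite]

    if s1 == s1p:
        prefix = s1
    elif shape == "Hook":
        prefix = f"{s1}/{s1p}"
    else:  # symmetric shapes: canonical ordering collapses mixed prefixes
        prefix = "-/+"

    ambiguous = any(abs(a) < threshold for a in angles)
    return f"{prefix}{hand}{shape}", pattern, ambiguous


def strain_energy(
    chi1: float, chi2: float, chi3: float, chi2p: float, chi1p: float
) -> float:
    """Dihedral strain energy of a disulfide, kJ/mol.

    Five-term cosine potential:

        E = 8.37 (1 + cos 3 chi1) + 8.37 (1 + cos 3 chi1')
          + 4.18 (1 + cos 3 chi2) + 4.18 (1 + cos 3 chi2')
          + 14.64 (1 + cos 2 chi3) + 2.51 (1 + cos 3 chi3)

    Nonnegative, bounded by 84.5 kJ/mol, 120-degree periodic in
    chi1/chi1'/chi2/chi2', mixed two- and three-fold periodic in chi3, and
    symmetric under the primed/unprimed swap.
    """
    c1, c2, c3, c2p, c1p = np.radians([chi1, chi2, chi3, chi2p, chi1p])
    return float(
        8.37 * (1 + np.cos(3 * c1))
        + 8.37 * (1 + np.cos(3 * c1p))
        + 4.18 * (1 + np.cos(3 * c2))
        + 4.18 * (1 + np.cos(3 * c2p))
        + 14.64 * (1 + np.cos(2 * c3))
        + 2.51 * (1 + np.cos(3 * c3))
    )


def _canonical_pair(
    r1: ResidueRecord, r2: ResidueRecord
) -> tuple[ResidueRecord, ResidueRecord]:
    """Lower (chain_id, res_num) is the unprimed half-cystine."""
    if (r1.chain_id, r1.res_num) <= (r2.chain_id, r2.res_num):
        return r1, r2
    return r2, r1


def detect_disulfides(
    model: StructureModel, config: GeometryConfig | None = None
) -> list[tuple[ResidueRecord, ResidueRecord]]:
    """Find S-S bridges from SG-SG' distances.

    All unordered CYS pairs within the cutoff are candidates; pairs are
    accepted greedily by ascending distance with each SG used at most
    once. Cysteines without an SG atom are skipped with a warning. Output
    pairs are canonically ordered (lower (chain, resnum) unprimed) and
    sorted by the unprimed key.
    """
    import warnings as _warnings

    config = config or GeometryConfig()
    cysteines = []
    for res in model.cysteines():
        if "SG" not in res.atoms:
            _warnings.warn(
                f"{model.structure_id}: CYS {res.chain_id}/{res.res_num} "
                "has no SG atom; skipped",
                stacklevel=2,
            )
            continue
        cysteines.append(res)

    candidates = []
    for i in range(len(cysteines)):
        for j in range(i + 1, len(cysteines)):
            d = float(
                np.linalg.norm(
                    cysteines[i].atom_coords("SG") - cysteines[j].atom_coords("SG")
                )
            )
            if d <= config.detection_cutoff:
                candidates.append((d, i, j))
    candidates.sort()

    used: set[int] = set()
    pairs = []
    for _, i, j in candidates:
        if i in used or j in used:
            continue
        used.update((i, j))
        pairs.append(_canonical_pair(cysteines[i], cysteines[j]))
    pairs.sort(key=lambda p: (p[0].chain_id, p[0].res_num, p[1].chain_id, p[1].res_num))
    return pairs


def analyze_structure(
    model: StructureModel, config: GeometryConfig | None = None
) -> list[DisulfideRecord]:
    """Full per-bridge report: torsions, bond length, class, strain energy."""
    config = config or GeometryConfig()
    records = []
    for cys1, cys2 in detect_disulfides(model, config):
        angles = chi_angles(cys1, cys2)
        cls, pattern, ambiguous = classify_configuration(
            *angles, threshold=config.ambiguous_angle_threshold
        )
        d = float(np.linalg.norm(cys1.atom_coords("SG") - cys2.atom_coords("SG")))
        records.append(
            DisulfideRecord(
                res1=(cys1.chain_id, cys1.res_num),
                res2=(cys2.chain_id, cys2.res_num),
                chi1=angles[0],
                chi2=angles[1],
                chi3=angles[2],
                chi2p=angles[3],
                chi1p=angles[4],
                ss_bond_length=d,
                config_class=cls,
                sign_pattern=pattern,
                strain_energy=strain_energy(*angles),
                flags=["ambiguous"] if ambiguous else [],
            )
        )
    return records
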