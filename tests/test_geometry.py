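"""Disulfide torsions, classification taxonomy and strain energy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quefss.geometry import (
    STRAIN_ENERGY_MAX,
    GeometryConfig,
    GeometryError,
    analyze_structure,
    chi_angles,
    classify_configuration,
    detect_disulfides,
    dihedral_angle,
    strain_energy,
)
from quefss.structure import StructureError, StructureModel
from quefss.synth import (
    DisulfideGeometrySpec,
    build_disulfide_coords,
    coords_to_residues,
    rigid_transform_coords,
)

angles_strategy = st.floats(
    min_value=-180.0, max_value=180.0, exclude_min=True,
    allow_nan=False, allow_infinity=False,
)


def _bridge(chis, ss=2.04, chain="A", res_nums=(55, 99)):
    spec = DisulfideGeometrySpec(*chis, ss_bond_length=ss)
    return coords_to_residues(
        build_disulfide_coords(spec), chain_id=chain, res_nums=res_nums
    )


class TestDihedralAngle:
    def test_anti_periplanar_is_180(self):
        assert dihedral_angle((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)) == pytest.approx(180.0)

    def test_syn_periplanar_is_0(self):
        assert dihedral_angle((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)) == pytest.approx(0.0)

    def test_perpendicular_sign_follows_right_handed_convention(self):
        # hand-computed: n1 = b1 x b2 = (0,0,1), n2 = b2 x b3 = (0,-1,0),
        # (n1 x n2).b2 = +1, n1.n2 = 0  ->  atan2(1, 0) = +90 degrees
        assert dihedral_angle((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 0, 1)) == pytest.approx(90.0)

    def test_matches_independent_oracle_on_random_points(self):
        struc = pytest.importorskip("biotite.structure")
        rng = np.random.default_rng(42)
        for _ in range(50):
            pts = rng.normal(size=(4, 3)) * 5
            expected = float(np.degrees(struc.dihedral(*pts)))
            # the oracle computes in float32; compare at its precision
            assert dihedral_angle(*pts) == pytest.approx(expected, abs=1e-4)

    def test_point_order_reversal_preserves_value(self):
        pts = [(0.3, 1.1, 0.2), (0, 0, 0), (1.4, 0.1, -0.2), (1.5, -0.8, 1.0)]
        assert dihedral_angle(*pts) == pytest.approx(
            dihedral_angle(*pts[::-1]), abs=1e-9
        )

    @pytest.mark.parametrize(
        "pts",
        [
            [(0, 0, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)],  # coincident
            [(2, 0, 0), (1, 0, 0), (0, 0, 0), (0, 1, 0)],  # collinear triple
        ],
    )
    def test_degenerate_input_raises(self, pts):
        with pytest.raises(GeometryError):
            dihedral_angle(*pts)


class TestChiAngles:
    def test_recovers_published_bridge_geometries(self, published_bridges):
        for row in published_bridges.values():
            r1, r2 = _bridge(row["chis"], ss=row["ss"])
            recovered = chi_angles(r1, r2)
            assert recovered == pytest.approx(row["chis"], abs=1e-6)

    def test_argument_swap_exchanges_primed_and_unprimed(self):
        r1, r2 = _bridge((-59.85, -126.76, -105.12, 176.01, -66.90))
        c1, c2, c3, c2p, c1p = chi_angles(r1, r2)
        assert chi_angles(r2, r1) == pytest.approx((c1p, c2p, c3, c2, c1), abs=1e-9)

    def test_missing_atom_names_residue_and_atom(self):
        r1, r2 = _bridge((-60, -60, -90, -60, -60))
        del r1.atoms["SG"]
        with pytest.raises(StructureError, match=r"CYS55.*'SG'"):
            chi_angles(r1, r2)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(chis=st.tuples(*([angles_strategy] * 5)))
    def test_round_trip_recovers_arbitrary_torsions(self, chis):
        r1, r2 = _bridge(chis)
        assert chi_angles(r1, r2) == pytest.approx(chis, abs=1e-6)

    def test_rigid_motion_leaves_torsions_unchanged(self):
        spec = DisulfideGeometrySpec(-59.85, -126.76, -105.12, 176.01, -66.90)
        coords = build_disulfide_coords(spec)
        before = chi_angles(*coords_to_residues(coords))
        rng = np.random.default_rng(7)
        for _ in range(10):
            moved = rigid_transform_coords(coords, rng)
            after = chi_angles(*coords_to_residues(moved))
            assert after == pytest.approx(before, abs=1e-9)

    def test_reflection_negates_all_torsions(self):
        chis = (-59.85, -126.76, -105.12, 176.01, -66.90)
        coords = build_disulfide_coords(DisulfideGeometrySpec(*chis))
        mirrored = {k: v * np.array([1.0, 1.0, -1.0]) for k, v in coords.items()}
        recovered = chi_angles(*coords_to_residues(mirrored))
        assert recovered == pytest.approx(tuple(-c for c in chis), abs=1e-6)


class TestClassification:
    @pytest.mark.parametrize(
        "chis,expected_class,expected_pattern",
        [
            # the oxidized QueF active-site geometry
            ((-59.85, -126.76, -105.12, 176.01, -66.90), "-LHHook",
             ("-", "-", "-", "+", "-")),
            # all-negative: both chi2 share chi3's sign -> spiral
            ((-60, -80, -85, -80, -60), "-LHSpiral", ("-", "-", "-", "-", "-")),
            ((-60, 100, 85, 100, -60), "-RHSpiral", ("-", "+", "+", "+", "-")),
            ((60, 100, 85, 100, 60), "+RHSpiral", ("+", "+", "+", "+", "+")),
            # both chi2 oppose chi3 -> staple
            ((-60, 100, -85, 100, -60), "-LHStaple", ("-", "+", "-", "+", "-")),
            # hooks keep mixed chi1 prefixes distinct
            ((-60, -80, -85, 100, 60), "-/+LHHook", ("-", "-", "-", "+", "+")),
            ((60, -80, -85, 100, -60), "+/-LHHook", ("+", "-", "-", "+", "-")),
            # symmetric shapes collapse mixed prefixes
            ((-60, -80, -85, -80, 60), "-/+LHSpiral", ("-", "-", "-", "-", "+")),
            ((60, -80, -85, -80, -60), "-/+LHSpiral", ("+", "-", "-", "-", "-")),
            ((-60, 100, -85, 100, 60), "-/+LHStaple", ("-", "+", "-", "+", "+")),
        ],
    )
    def test_rule_set(self, chis, expected_class, expected_pattern):
        cls, pattern, ambiguous = classify_configuration(*chis)
        assert cls == expected_class
        assert pattern == expected_pattern
        assert not ambiguous

    def test_taxonomy_has_twenty_classes(self):
        signs = (-60.0, 60.0)
        classes = set()
        for c1 in signs:
            for c2 in (-80.0, 100.0):
                for c3 in (-85.0, 85.0):
                    for c2p in (-80.0, 100.0):
                        for c1p in signs:
                            cls, _, _ = classify_configuration(c1, c2, c3, c2p, c1p)
                            classes.add(cls)
        assert len(classes) == 20

    def test_near_zero_angle_flags_ambiguous(self):
        cls, pattern, ambiguous = classify_configuration(-0.2, -80, -85, -80, -60)
        assert ambiguous
        assert pattern[0] == "-"
        cls2, _, amb2 = classify_configuration(-5, -80, -85, -80, -60)
        assert not amb2
        assert cls == cls2


class TestStrainEnergy:
    def test_published_energies(self, published_bridges):
        for row in published_bridges.values():
            assert strain_energy(*row["chis"]) == pytest.approx(
                row["energy"], abs=0.005
            )

    def test_analytic_minimum_of_threefold_terms(self):
        # chi1/chi2 terms vanish at -60, twofold chi3 term vanishes at -90;
        # only the threefold chi3 term survives: 2.51 * (1 + cos(-270)) = 2.51
        assert strain_energy(-60, -60, -90, -60, -60) == pytest.approx(2.51, abs=1e-9)

    def test_symmetric_under_primed_unprimed_swap(self):
        chis = (-59.85, -126.76, -105.12, 176.01, -66.90)
        swapped = (chis[4], chis[3], chis[2], chis[1], chis[0])
        assert strain_energy(*chis) == pytest.approx(strain_energy(*swapped))

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(chis=st.tuples(*([angles_strategy] * 5)))
    def test_bounded_and_nonnegative(self, chis):
        e = strain_energy(*chis)
        assert 0.0 <= e <= STRAIN_ENERGY_MAX + 1e-9

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(chis=st.tuples(*([angles_strategy] * 5)))
    def test_periodicity(self, chis):
        c1, c2, c3, c2p, c1p = chis
        e = strain_energy(*chis)
        assert strain_energy(c1 + 120, c2, c3, c2p, c1p) == pytest.approx(e, abs=1e-9)
        assert strain_energy(c1, c2 - 120, c3, c2p, c1p) == pytest.approx(e, abs=1e-9)
        # chi3 has mixed two- and three-fold terms: period 360
        assert strain_energy(c1, c2, c3 + 360, c2p, c1p) == pytest.approx(e, abs=1e-9)


class TestDetection:
    def test_bonded_pair_found_and_far_pair_ignored(self):
        r1, r2 = _bridge((-60, -60, -90, -60, -60), ss=2.05)
        model = StructureModel(structure_id="t", residues=[r1, r2])
        assert len(detect_disulfides(model)) == 1

        far1, far2 = _bridge((-60, -60, -90, -60, -60), ss=3.5)
        model_far = StructureModel(structure_id="t", residues=[far1, far2])
        assert detect_disulfides(model_far) == []

    def test_planted_bridges_with_free_cysteine_decoys(self, published_bridges):
        residues = []
        for chain, row in zip("ABCDE", published_bridges.values()):
            r1, r2 = _bridge(row["chis"], ss=row["ss"], chain=chain)
            shift = np.array([30.0 * ord(chain), 0.0, 0.0])
            for r in (r1, r2):
                for name, atom in list(r.atoms.items()):
                    r.atoms[name] = type(atom)(
                        name=atom.name, element=atom.element,
                        coords=atom.coords + shift,
                    )
                residues.append(r)
        # three lone thiols, far away from everything
        for j in range(3):
            lone, _ = _bridge((-60, -60, -90, -60, -60), chain="Z",
                              res_nums=(j + 1, 200 + j))
            for name, atom in list(lone.atoms.items()):
                lone.atoms[name] = type(atom)(
                    name=atom.name, element=atom.element,
                    coords=atom.coords + np.array([0.0, 500.0 + 30 * j, 0.0]),
                )
            residues.append(lone)
        model = StructureModel(structure_id="decamer", residues=residues)
        pairs = detect_disulfides(model)
        assert len(pairs) == 5
        assert all(p[0].chain_id == p[1].chain_id for p in pairs)
        assert [(p[0].res_num, p[1].res_num) for p in pairs] == [(55, 99)] * 5

    def test_canonical_ordering_lower_key_is_unprimed(self):
        r1, r2 = _bridge((-60, -60, -90, -60, -60))
        model = StructureModel(structure_id="t", residues=[r2, r1])
        (pair,) = detect_disulfides(model)
        assert (pair[0].res_num, pair[1].res_num) == (55, 99)

    def test_cysteine_without_sg_is_skipped_with_warning(self):
        r1, r2 = _bridge((-60, -60, -90, -60, -60))
        del r2.atoms["SG"]
        model = StructureModel(structure_id="t", residues=[r1, r2])
        with pytest.warns(UserWarning, match="no SG"):
            assert detect_disulfides(model) == []


class TestAnalyzeStructure:
    def test_full_record_for_one_planted_bridge(self, published_bridges):
        row = published_bridges["D"]
        r1, r2 = _bridge(row["chis"], ss=row["ss"])
        model = StructureModel(structure_id="t", residues=[r1, r2])
        (rec,) = analyze_structure(model)
        assert rec.strain_energy == pytest.approx(row["energy"], abs=0.005)
        assert rec.config_class == "-LHHook"
        assert rec.ss_bond_length == pytest.approx(row["ss"], abs=1e-9)
        assert rec.res1 == ("A", 55) and rec.res2 == ("A", 99)
        assert rec.flags == []

    def test_no_cysteines_gives_empty_report(self):
        model = StructureModel(structure_id="t", residues=[])
        assert analyze_structure(model) == []

    def test_swap_symmetry_of_analysis(self):
        chis = (-56.90, -123.68, -89.05, 171.20, -81.83)
        r1, r2 = _bridge(chis)
        fwd = analyze_structure(StructureModel(structure_id="t", residues=[r1, r2]))
        rev = analyze_structure(StructureModel(structure_id="t", residues=[r2, r1]))
        assert fwd[0].strain_energy == pytest.approx(rev[0].strain_energy, abs=1e-9)
        assert fwd[0].chi3 == pytest.approx(rev[0].chi3, abs=1e-9)
        assert fwd[0].angles == pytest.approx(rev[0].angles, abs=1e-9)

    def test_cutoff_is_configurable(self, published_bridges):
        row = published_bridges["A"]
        r1, r2 = _bridge(row["chis"], ss=row["ss"])
        model = StructureModel(structure_id="t", residues=[r1, r2])
        assert analyze_structure(model, GeometryConfig(detection_cutoff=1.0)) == []
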