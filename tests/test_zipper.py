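"""Sheet and steric-zipper assembly, class taxonomy, distance measures."""

import numpy as np
import pytest

from phosphozip import STRAND_E
from phosphozip.zipper import (
    ArrangementKind,
    BuildParams,
    ClashError,
    FibrilModel,
    SheetBuildError,
    StrandArrangement,
    average_cb_distance,
    build_class_zipper,
    build_ideal_strand,
    build_sheet,
    enumerate_zipper_classes,
    shifted_compatible_classes,
)
from phosphozip.zipper.builder import hbond_compatible
from phosphozip.zipper.geometry import Atom


class TestClassEnumeration:
    def test_exactly_eight_distinct_classes(self):
        classes = enumerate_zipper_classes()
        assert len(classes) == 8
        assert len({(c.strand_orientation, c.sheet_face_packing, c.sheet_polarity)
                    for c in classes}) == 8
        assert [c.class_id for c in classes] == list(range(1, 9))

    def test_half_are_antiparallel(self):
        classes = enumerate_zipper_classes()
        anti = [c for c in classes if c.strand_orientation == "antiparallel"]
        assert len(anti) == 4

    def test_shifted_arrangement_admits_classes_7_and_8(self):
        arr = StrandArrangement(ArrangementKind.ANTIPARALLEL_SHIFTED, -1)
        ids = {c.class_id for c in shifted_compatible_classes(arrangement=arr)}
        assert ids == {7, 8}

    def test_in_register_antiparallel_admits_5_and_6(self):
        arr = StrandArrangement(ArrangementKind.ANTIPARALLEL_IN_REGISTER, 0)
        ids = {c.class_id for c in shifted_compatible_classes(arrangement=arr)}
        assert ids == {5, 6}

    def test_parallel_admits_parallel_classes_only(self):
        arr = StrandArrangement(ArrangementKind.PARALLEL_IN_REGISTER, 0)
        out = shifted_compatible_classes(arrangement=arr)
        assert {c.class_id for c in out} == {1, 2, 3, 4}
        assert all(c.strand_orientation == "parallel" for c in out)


def _ca_x(model, chain, resi):
    (a,) = model.select(chain=chain, resi=resi, name="CA")
    return a.x


class TestSheetPairing:
    def test_parallel_stacks_residues_in_register(self):
        strand = build_ideal_strand(STRAND_E)
        sheet = build_sheet(strand, StrandArrangement(ArrangementKind.PARALLEL_IN_REGISTER, 0))
        for i in (1, 5, 13):
            assert _ca_x(sheet, "A", i) == pytest.approx(_ca_x(sheet, "B", i), abs=1e-9)

    def test_antiparallel_in_register_pairs_5_with_9(self):
        strand = build_ideal_strand(STRAND_E)
        sheet = build_sheet(
            strand, StrandArrangement(ArrangementKind.ANTIPARALLEL_IN_REGISTER, 0)
        )
        assert _ca_x(sheet, "A", 5) == pytest.approx(_ca_x(sheet, "B", 9), abs=0.5)
        assert _ca_x(sheet, "A", 7) == pytest.approx(_ca_x(sheet, "B", 7), abs=0.5)

    def test_shifted_default_pairs_5_with_8_and_9_with_4(self):
        strand = build_ideal_strand(STRAND_E)
        sheet = build_sheet(
            strand, StrandArrangement(ArrangementKind.ANTIPARALLEL_SHIFTED, -1)
        )
        assert _ca_x(sheet, "A", 5) == pytest.approx(_ca_x(sheet, "B", 8), abs=0.5)
        assert _ca_x(sheet, "A", 9) == pytest.approx(_ca_x(sheet, "B", 4), abs=0.5)

    def test_excessive_shift_rejected(self):
        strand = build_ideal_strand(STRAND_E)
        with pytest.raises(SheetBuildError, match="overlap"):
            build_sheet(
                strand, StrandArrangement(ArrangementKind.ANTIPARALLEL_SHIFTED, -10)
            )

    @pytest.mark.parametrize(
        "kind,shift",
        [
            (ArrangementKind.PARALLEL_IN_REGISTER, 0),
            (ArrangementKind.ANTIPARALLEL_IN_REGISTER, 0),
            (ArrangementKind.ANTIPARALLEL_SHIFTED, -1),
        ],
    )
    def test_sheets_are_hbond_compatible(self, kind, shift):
        strand = build_ideal_strand(STRAND_E)
        sheet = build_sheet(strand, StrandArrangement(kind, shift))
        assert hbond_compatible(sheet)

    def test_strand_count_and_spacing(self):
        strand = build_ideal_strand(STRAND_E)
        params = BuildParams(n_strands_per_sheet=6, intra_sheet_spacing=4.8)
        sheet = build_sheet(strand, StrandArrangement(), params)
        assert len(sheet.chains) == 6
        ys = [np.mean([a.y for a in sheet.select(chain=c, name="CA")])
              for c in sheet.chains]
        assert np.allclose(np.diff(ys), 4.8, atol=0.1)


class TestZipperBuilds:
    def test_all_eight_classes_build_without_clash(self):
        for cid in range(1, 9):
            model = build_class_zipper(STRAND_E, cid)
            assert len(model.chains) == 16
            assert model.provenance["zipper_class"].class_id == cid

    def test_doubling_separation_doubles_plane_gap(self):
        def gap(sep):
            m = build_class_zipper(STRAND_E, 7, params=BuildParams(inter_sheet_separation=sep))
            sheets = m.provenance["sheets"]
            z = {
                s: np.mean([a.z for a in m.atoms if a.chain in cs and a.name == "CA"])
                for s, cs in sheets.items()
            }
            return abs(z[2] - z[1])

        assert gap(24.0) == pytest.approx(2 * gap(12.0), rel=1e-9)

    def test_sheet_one_identical_between_class_7_and_8(self):
        m7 = build_class_zipper(STRAND_E, 7)
        m8 = build_class_zipper(STRAND_E, 8)
        s1_7 = [a for a in m7.atoms if a.chain in m7.provenance["sheets"][1]]
        s1_8 = [a for a in m8.atoms if a.chain in m8.provenance["sheets"][1]]
        assert s1_7 == s1_8

    def test_clash_detection(self):
        with pytest.raises(ClashError):
            build_class_zipper(
                STRAND_E, 7, params=BuildParams(inter_sheet_separation=3.0)
            )

    def test_arrangement_class_mismatch_rejected(self):
        arr = StrandArrangement(ArrangementKind.ANTIPARALLEL_SHIFTED, -1)
        with pytest.raises(SheetBuildError):
            build_class_zipper(STRAND_E, 1, arrangement=arr)


class TestAverageCbDistance:
    def test_single_pair_returns_its_distance(self):
        atoms = [
            Atom("A", 1, "ALA", "CA", 0, 0, 0),
            Atom("A", 1, "ALA", "CB", 0, 0, 1.5),
            Atom("B", 1, "ALA", "CA", 0, 0, 11.5),
            Atom("B", 1, "ALA", "CB", 0, 0, 10.0),
        ]
        m = FibrilModel(atoms, provenance={"sheets": {1: ("A",), 2: ("B",)}})
        assert average_cb_distance(m, 1) == pytest.approx(10.0 - 1.5)

    def test_missing_cb_rejected(self, class7_zipper):
        with pytest.raises(ValueError):
            average_cb_distance(class7_zipper, 99)

    def test_matches_brute_force_oracle(self, class7_zipper, class8_zipper):
        """Independent re-computation from raw atom records."""
        for model in (class7_zipper, class8_zipper):
            for pos in (5, 8, 9):
                assert average_cb_distance(model, pos) == pytest.approx(
                    _oracle_cb_distance(model, pos), abs=1e-9
                )

    def test_rigid_motion_invariance(self, class7_zipper):
        th = 0.6
        rz = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        rx = np.array(
            [[1, 0, 0], [0, np.cos(1.2), -np.sin(1.2)], [0, np.sin(1.2), np.cos(1.2)]]
        )
        moved = class7_zipper.transformed(rz @ rx, np.array([3.0, -8.0, 40.0]))
        moved.provenance = class7_zipper.provenance
        for pos in (5, 9):
            assert average_cb_distance(moved, pos) == pytest.approx(
                average_cb_distance(class7_zipper, pos), abs=1e-9
            )

    def test_positions_5_and_8_equal_by_pairing_symmetry(
        self, class7_zipper, class8_zipper
    ):
        for model in (class7_zipper, class8_zipper):
            d5 = average_cb_distance(model, 5)
            d8 = average_cb_distance(model, 8)
            assert abs(d5 - d8) < 0.5

    def test_class7_pattern_position9_far(self, class7_zipper):
        d5 = average_cb_distance(class7_zipper, 5)
        d8 = average_cb_distance(class7_zipper, 8)
        d9 = average_cb_distance(class7_zipper, 9)
        assert d9 > d5 + 3 and d9 > d8 + 3

    def test_class8_all_positions_comparable(self, class8_zipper):
        ds = [average_cb_distance(class8_zipper, p) for p in (5, 8, 9)]
        assert max(ds) - min(ds) < 1.5
        assert all(10.0 <= d <= 13.0 for d in ds)


def _oracle_cb_distance(model, pos):
    """Brute-force restatement: interface-facing CBs, nearest across sheets."""
    sheets = model.provenance["sheets"]
    cb, ca = {}, {}
    for a in model.atoms:
        if a.resi == pos and a.name == "CB":
            cb[a.chain] = np.array([a.x, a.y, a.z])
        if a.resi == pos and a.name == "CA":
            ca[a.chain] = np.array([a.x, a.y, a.z])
    cents = {}
    for s, cs in sheets.items():
        pts = [
            np.array([a.x, a.y, a.z])
            for a in model.atoms
            if a.chain in cs and a.name == "CA"
        ]
        cents[s] = np.mean(pts, axis=0)
    axis = cents[2] - cents[1]
    axis = axis / np.linalg.norm(axis)
    pools = {}
    for s, cs in sheets.items():
        toward = axis if s == 1 else -axis
        facing = [
            cb[c] for c in cs if np.dot(cb[c] - ca[c], toward) > 0
        ]
        pools[s] = facing if facing else [cb[c] for c in cs]
    dists = []
    for s, o in ((1, 2), (2, 1)):
        for xyz in pools[s]:
            dists.append(min(np.linalg.norm(xyz - q) for q in pools[o]))
    return float(np.mean(dists))
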