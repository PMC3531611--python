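"""Cross-beta sheet and steric-zipper assembly.

A steric zipper is a pair of beta-sheets whose side chains interdigitate
across a dry interface. Eight symmetry classes exist, generated by three
binary choices: strand orientation within a sheet (parallel/antiparallel),
which faces of the two sheets meet (face-to-face / face-to-back), and the
relative polarity of the sheets (up-up / up-down).

Coordinate convention: strand axis = x, sheet stacking (hydrogen-bond /
fibril axis) = y, sheet separation = z. Right-handed, angstroms, 1-based
residue indices. Chains A..H form sheet 1, I..P sheet 2.
"""

from __future__ import annotations

import dataclasses
import enum
import string

import numpy as np

from .geometry import Atom, FibrilModel, build_ideal_strand

__all__ = [
    "ArrangementKind",
    "StrandArrangement",
    "ZipperClassDescriptor",
    "BuildParams",
    "enumerate_zipper_classes",
    "shifted_compatible_classes",
    "build_sheet",
    "build_zipper",
    "build_class_zipper",
    "average_cb_distance",
    "hbond_partner",
    "SheetBuildError",
    "ClashError",
]


class ArrangementKind(str, enum.Enum):
    PARALLEL_IN_REGISTER = "parallel_in_register"
    ANTIPARALLEL_IN_REGISTER = "antiparallel_in_register"
    ANTIPARALLEL_SHIFTED = "antiparallel_shifted"


@dataclasses.dataclass(frozen=True)
class StrandArrangement:
    """Strand-strand organisation within one beta-sheet.

    ``registry_shift`` applies only to the shifted antiparallel arrangement:
    neighbouring strands pair residue i with residue (N+1)-i+s, where s is
    the shift. The default s = -1 places residue 5 opposite residue 8 of
    its antiparallel neighbour (and residue 9 opposite residue 4).
    """

    kind: ArrangementKind = ArrangementKind.ANTIPARALLEL_SHIFTED
    registry_shift: int = -1

    def __post_init__(self):
        if self.kind is not ArrangementKind.ANTIPARALLEL_SHIFTED:
            object.__setattr__(self, "registry_shift", 0)

    def pairing_offset(self, n_residues: int) -> int:
        """P such that residue i on one strand faces residue P - i on its
        neighbour (parallel arrangements face residue i itself)."""
        if self.kind is ArrangementKind.PARALLEL_IN_REGISTER:
            return 0  # sentinel: pairing is i <-> i
        return n_residues + 1 + self.registry_shift


@dataclasses.dataclass(frozen=True)
class ZipperClassDescriptor:
    class_id: int
    strand_orientation: str  # "parallel" | "antiparallel"
    sheet_face_packing: str  # "face_to_face" | "face_to_back"
    sheet_polarity: str      # "up_up" | "up_down"


def _class_table() -> dict[int, ZipperClassDescriptor]:
    # Steric-zipper taxonomy: classes 1-4 parallel, 5-8 antiparallel;
    # within each orientation the face and polarity choices alternate as
    # below. Classes 7 and 8 are the two antiparallel, up-down classes
    # compatible with a shifted strand registry; they differ in which
    # faces of the two sheets meet at the dry interface: in class 7 the
    # sheets present opposite faces (front packs against back), in class 8
    # the copy is turned over so equivalent faces meet.
    rows = [
        (1, "parallel", "face_to_face", "up_up"),
        (2, "parallel", "face_to_back", "up_up"),
        (3, "parallel", "face_to_face", "up_down"),
        (4, "parallel", "face_to_back", "up_down"),
        (5, "antiparallel", "face_to_face", "up_up"),
        (6, "antiparallel", "face_to_back", "up_up"),
        (7, "antiparallel", "face_to_back", "up_down"),
        (8, "antiparallel", "face_to_face", "up_down"),
    ]
    return {cid: ZipperClassDescriptor(cid, o, f, p) for cid, o, f, p in rows}


CLASS_TABLE = _class_table()

# Default sheet-2 slide along the strand axis, in units of the strand
# rise, per face packing. Equivalent-face packings (face_to_face) need a
# two-residue slide so the side chains of the two sheets interleave
# rather than meet tip-to-tip; opposite-face packings pack in register.
_DEFAULT_OFFSET_RISE = {
    "face_to_back": 0.0,
    "face_to_face": 2.0,
}


def enumerate_zipper_classes() -> list[ZipperClassDescriptor]:
    """The eight steric-zipper symmetry classes (full binary cross-product)."""
    return [CLASS_TABLE[i] for i in range(1, 9)]


def shifted_compatible_classes(
    classes: list[ZipperClassDescriptor] | None = None,
    arrangement: StrandArrangement | None = None,
) -> list[ZipperClassDescriptor]:
    """Filter zipper classes by the strand symmetry of a sheet arrangement.

    The shifted antiparallel sheet relates neighbouring strands by a
    two-fold axis perpendicular to the strand direction; only the two
    antiparallel up-down classes (7 and 8) possess that symmetry. The
    in-register antiparallel sheet maps to the up-up classes (5, 6), and
    parallel sheets to classes 1-4.
    """
    if classes is None:
        classes = enumerate_zipper_classes()
    if arrangement is None:
        arrangement = StrandArrangement()
    kind = arrangement.kind
    if kind is ArrangementKind.ANTIPARALLEL_SHIFTED:
        keep = {7, 8}
    elif kind is ArrangementKind.ANTIPARALLEL_IN_REGISTER:
        keep = {5, 6}
    else:
        keep = {1, 2, 3, 4}
    return [c for c in classes if c.class_id in keep]


@dataclasses.dataclass(frozen=True)
class BuildParams:
    """Geometry of an idealized 8x2 steric zipper.

    ``intra_sheet_spacing`` is the cross-beta hydrogen-bond stacking
    distance between neighbouring strands (4.8 A in essentially all
    amyloids); ``inter_sheet_separation`` is the distance between the mean
    CA planes of the two sheets (12 A). ``interface_offset`` slides sheet 2
    along the strand axis relative to sheet 1, emulating the side-chain
    interdigitation register of a real zipper; None selects the
    face-packing default (0 for opposite-face packing, two residues of
    rise for equivalent-face packing).
    """

    n_strands_per_sheet: int = 8
    n_sheets: int = 2
    intra_sheet_spacing: float = 4.8
    inter_sheet_separation: float = 12.0
    strand_rise: float | None = None  # None: use built-strand geometry
    interface_offset: float | None = None
    clash_cutoff: float = 2.2

    def __post_init__(self):
        if self.intra_sheet_spacing <= 0 or self.inter_sheet_separation <= 0:
            raise ValueError("spacings must be positive")
        if self.n_strands_per_sheet < 2:
            raise ValueError("need at least 2 strands per sheet")


class SheetBuildError(ValueError):
    pass


class ClashError(ValueError):
    def __init__(self, msg: str, pair: tuple[Atom, Atom] | None = None):
        super().__init__(msg)
        self.pair = pair


# --------------------------------------------------------------------------
# sheet construction
# --------------------------------------------------------------------------

_RZ180 = np.diag([-1.0, -1.0, 1.0])   # 180 deg about z (sheet normal)
_RY180 = np.diag([-1.0, 1.0, -1.0])   # 180 deg about y (stacking axis)
_RX180 = np.diag([1.0, -1.0, -1.0])   # 180 deg about x (strand axis)
_ID = np.eye(3)


def _mean_ca(model: FibrilModel, chains=None) -> np.ndarray:
    sel = model.select(name="CA", chains=chains)
    return np.array([(a.x, a.y, a.z) for a in sel]).mean(axis=0)


def _antiparallel_partner(
    strand: FibrilModel, pairing_offset: int, rise: float, flip_faces: bool
) -> FibrilModel:
    """Antiparallel copy of ``strand`` with residue i facing residue
    (pairing_offset - i) of the original.

    ``flip_faces`` chooses between the two C2 operations that reverse the
    strand direction: rotation about the stacking axis y (flips which face
    each side chain decorates; required for the shifted registry, where
    residues of opposite parity pair) or rotation about the sheet normal z
    (face-preserving; the in-register odd-with-odd pairing).
    """
    rot = _RY180 if flip_faces else _RZ180
    flipped = strand.transformed(rot, np.zeros(3))
    # x-translation aligning the pairing: original residue i CA sits near
    # (i-1)*rise; the rotated copy's residue j sits near -(j-1)*rise, so a
    # shift of (pairing_offset-2)*rise puts residue pairing_offset-i at the
    # x of residue i.
    dx = (pairing_offset - 2) * rise
    # re-center y and z onto the original strand's means
    m0 = _mean_ca(strand)
    m1 = _mean_ca(flipped)
    trans = np.array([dx, m0[1] - m1[1], m0[2] - m1[2]])
    return flipped.transformed(_ID, trans)


def build_sheet(
    strand: FibrilModel,
    arrangement: StrandArrangement | None = None,
    params: BuildParams | None = None,
) -> FibrilModel:
    """Stack ``n_strands_per_sheet`` copies of a strand into one beta-sheet.

    Strands are stacked along y at ``intra_sheet_spacing``; antiparallel
    arrangements alternate strand direction, and the shifted arrangement
    additionally offsets the registry (see StrandArrangement).
    """
    arrangement = arrangement or StrandArrangement()
    params = params or BuildParams()
    if len(strand.chains) != 1:
        raise SheetBuildError("build_sheet expects a single-strand model")
    seq = strand.sequence()
    n_res = len(seq)
    rise = params.strand_rise or strand.provenance.get("rise_per_residue")
    if not rise:
        raise SheetBuildError("strand rise unavailable")

    if arrangement.kind is ArrangementKind.PARALLEL_IN_REGISTER:
        partner = strand
    else:
        p_off = arrangement.pairing_offset(n_res)
        overlap = n_res - abs(n_res + 1 - p_off)
        if overlap < 4:
            raise SheetBuildError(
                f"registry shift {arrangement.registry_shift} leaves only "
                f"{overlap} residues of overlap"
            )
        flip_faces = arrangement.kind is ArrangementKind.ANTIPARALLEL_SHIFTED
        partner = _antiparallel_partner(strand, p_off, rise, flip_faces)

    chain_ids = string.ascii_uppercase
    atoms: list[Atom] = []
    for k in range(params.n_strands_per_sheet):
        template = strand if k % 2 == 0 else partner
        dy = k * params.intra_sheet_spacing
        cid = chain_ids[k]
        for a in template.atoms:
            atoms.append(Atom(cid, a.resi, a.resn, a.name, a.x, a.y + dy, a.z))
    model = FibrilModel(atoms)
    model.provenance = {
        "kind": "sheet",
        "sequence": seq,
        "arrangement": arrangement,
        "params": params,
        "rise_per_residue": rise,
    }
    return model


# --------------------------------------------------------------------------
# zipper construction
# --------------------------------------------------------------------------

def _sheet2_rotation(zclass: ZipperClassDescriptor) -> np.ndarray:
    """Rigid rotation applied to the copy of sheet 1 that becomes sheet 2.

    face_to_face presents the same face of each sheet to the interface
    (the copy is turned over about the strand axis); face_to_back stacks
    front against back (pure translation). For parallel sheets the
    up_down polarity additionally reverses the strand-axis sense of sheet
    2 (rotation about z composed with the face operation). Antiparallel
    sheets already contain strands of both senses, so their polarity
    label is realized by the *arrangement* of the sheet itself
    (in-register for up_up, shifted for up_down), not by an extra
    rotation of sheet 2.
    """
    flip_face = zclass.sheet_face_packing == "face_to_face"
    base = _RX180 if flip_face else _ID
    if (
        zclass.strand_orientation == "parallel"
        and zclass.sheet_polarity == "up_down"
    ):
        return _RZ180 @ base
    return base


def build_zipper(
    sheet: FibrilModel,
    zclass: ZipperClassDescriptor,
    params: BuildParams | None = None,
) -> FibrilModel:
    """Duplicate a sheet and pack the copy against it as sheet 2.

    The copy is rotated by the class's face/polarity operation, then
    translated so the two mean CA planes are ``inter_sheet_separation``
    apart along z, re-centred in x/y (plus any ``interface_offset`` along
    the strand axis). A cross-sheet clash check (< ``clash_cutoff``)
    rejects impossible packings.
    """
    params = params or BuildParams()
    arrangement = sheet.provenance.get("arrangement")
    if arrangement is not None:
        orient = (
            "parallel"
            if arrangement.kind is ArrangementKind.PARALLEL_IN_REGISTER
            else "antiparallel"
        )
        if orient != zclass.strand_orientation:
            raise SheetBuildError(
                f"sheet arrangement {arrangement.kind.value} is "
                f"{orient}, class {zclass.class_id} needs "
                f"{zclass.strand_orientation} strands"
            )

    n_chains = len(sheet.chains)
    rot = _sheet2_rotation(zclass)
    copy = sheet.transformed(rot, np.zeros(3))
    rise = sheet.provenance.get("rise_per_residue") or 3.4
    offset = params.interface_offset
    if offset is None:
        offset = _DEFAULT_OFFSET_RISE[zclass.sheet_face_packing] * rise
    m1 = _mean_ca(sheet)
    m2 = _mean_ca(copy)
    trans = np.array(
        [
            m1[0] - m2[0] + offset,
            m1[1] - m2[1],
            m1[2] - m2[2] + params.inter_sheet_separation,
        ]
    )
    copy = copy.transformed(_ID, trans)

    chain_ids = string.ascii_uppercase
    mapping = {
        old: chain_ids[n_chains + i] for i, old in enumerate(copy.chains)
    }
    copy = copy.with_chain_ids(mapping)

    atoms = list(sheet.atoms) + list(copy.atoms)
    model = FibrilModel(atoms)
    sheet1_chains = tuple(sheet.chains)
    sheet2_chains = tuple(mapping[c] for c in sheet.chains)
    model.provenance = {
        "kind": "zipper",
        "sequence": sheet.provenance.get("sequence"),
        "arrangement": arrangement,
        "zipper_class": zclass,
        "params": params,
        "sheets": {1: sheet1_chains, 2: sheet2_chains},
        "rise_per_residue": sheet.provenance.get("rise_per_residue"),
    }
    _check_clashes(model, params.clash_cutoff)
    return model


def _check_clashes(model: FibrilModel, cutoff: float) -> None:
    sheets = model.provenance["sheets"]
    s1 = set(sheets[1])
    a1 = [a for a in model.atoms if a.chain in s1]
    a2 = [a for a in model.atoms if a.chain not in s1]
    x1 = np.array([(a.x, a.y, a.z) for a in a1])
    x2 = np.array([(a.x, a.y, a.z) for a in a2])
    from scipy.spatial import cKDTree

    tree = cKDTree(x2)
    dist, idx = tree.query(x1, k=1)
    i = int(np.argmin(dist))
    if dist[i] < cutoff:
        raise ClashError(
            f"inter-sheet clash: {a1[i]} vs {a2[idx[i]]} at {dist[i]:.2f} A",
            pair=(a1[i], a2[idx[i]]),
        )


def build_class_zipper(
    sequence: str,
    class_id: int,
    arrangement: StrandArrangement | None = None,
    params: BuildParams | None = None,
) -> FibrilModel:
    """Convenience pipeline: strand -> sheet -> zipper for one class."""
    params = params or BuildParams()
    zclass = CLASS_TABLE[class_id]
    if arrangement is None:
        if zclass.strand_orientation == "parallel":
            arrangement = StrandArrangement(ArrangementKind.PARALLEL_IN_REGISTER)
        elif zclass.sheet_polarity == "up_down":
            arrangement = StrandArrangement(ArrangementKind.ANTIPARALLEL_SHIFTED)
        else:
            arrangement = StrandArrangement(
                ArrangementKind.ANTIPARALLEL_IN_REGISTER, 0
            )
    strand = build_ideal_strand(sequence)
    sheet = build_sheet(strand, arrangement, params)
    return build_zipper(sheet, zclass, params)


# --------------------------------------------------------------------------
# measurements
# --------------------------------------------------------------------------

def average_cb_distance(
    model: FibrilModel,
    residue_position: int,
    sheets: dict[int, tuple[str, ...]] | None = None,
) -> float:
    """Mean nearest cross-sheet CB-CB distance at one residue position.

    The quantity of interest is how close phosphate-bearing side chains
    at ``residue_position`` come across the dry inter-sheet interface, so
    the average runs over the chains whose CB at that position *faces the
    interface* (its CA->CB vector has a positive component along the
    sheet-to-sheet axis): for each such CB, the nearest interface-facing
    CB of the same position on the opposite sheet is found, and the mean
    of those nearest-pair distances is returned. If a sheet presents no
    interface-facing CB at the position (small or schematic models), all
    of its CBs at the position are used instead. The measure is invariant
    under rigid-body motion of the whole model.
    """
    sheets = sheets or model.provenance.get("sheets")
    if not sheets:
        raise ValueError("model has no sheet partition; pass `sheets`")
    chain_sheet = {c: s for s, cs in sheets.items() for c in cs}
    cb: dict[str, np.ndarray] = {}
    ca: dict[str, np.ndarray] = {}
    for a in model.atoms:
        if a.resi == residue_position:
            if a.name == "CB":
                cb[a.chain] = np.array([a.x, a.y, a.z])
            elif a.name == "CA":
                ca[a.chain] = np.array([a.x, a.y, a.z])
    missing = [c for c in chain_sheet if c not in cb]
    if missing:
        raise ValueError(
            f"no CB at position {residue_position} in chains {missing}"
        )
    # sheet centroids (all CA atoms, falling back to every atom)
    cents = {}
    for s, cs in sheets.items():
        sel = model.select(name="CA", chains=cs) or model.select(chains=cs)
        cents[s] = np.array([(a.x, a.y, a.z) for a in sel]).mean(axis=0)
    axis = cents[2] - cents[1]
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("sheet centroids coincide; cannot define interface")
    axis /= norm

    facing: dict[int, list[np.ndarray]] = {1: [], 2: []}
    everything: dict[int, list[np.ndarray]] = {1: [], 2: []}
    for c, xyz in cb.items():
        s = chain_sheet[c]
        toward = axis if s == 1 else -axis
        everything[s].append(xyz)
        if c in ca and float(np.dot(xyz - ca[c], toward)) > 0:
            facing[s].append(xyz)
    pools = {
        s: np.array(facing[s] if facing[s] else everything[s])
        for s in (1, 2)
    }
    dists = []
    for s, other in ((1, 2), (2, 1)):
        for xyz in pools[s]:
            d = np.linalg.norm(pools[other] - xyz, axis=1)
            dists.append(d.min())
    return float(np.mean(dists))


def hbond_compatible(
    model: FibrilModel,
    chains: tuple[str, str] | None = None,
    window: tuple[float, float] = (2.6, 3.4),
) -> bool:
    """Check cross-beta hydrogen-bond geometry between adjacent strands.

    In a beta-sheet each residue donates/accepts backbone hydrogen bonds
    to one of its two neighbouring strands, so along any adjacent strand
    pair alternate residues form N...O contacts near 2.9 A. The check
    passes when, for every adjacent chain pair (or the given pair), at
    least 40% of residues have a backbone N...O contact inside
    ``window``.
    """
    chain_list = model.chains
    pairs = (
        [chains]
        if chains is not None
        else list(zip(chain_list[:-1], chain_list[1:]))
    )
    for c1, c2 in pairs:
        at: dict[tuple[str, int, str], np.ndarray] = {}
        resis: set[int] = set()
        for a in model.atoms:
            if a.chain in (c1, c2) and a.name in ("N", "O"):
                at[(a.chain, a.resi, a.name)] = np.array([a.x, a.y, a.z])
                if a.chain == c1:
                    resis.add(a.resi)
        n_ok = 0
        for i in sorted(resis):
            best = np.inf
            ni = at.get((c1, i, "N"))
            oi = at.get((c1, i, "O"))
            for j in resis:
                oj = at.get((c2, j, "O"))
                nj = at.get((c2, j, "N"))
                if ni is not None and oj is not None:
                    best = min(best, float(np.linalg.norm(ni - oj)))
                if oi is not None and nj is not None:
                    best = min(best, float(np.linalg.norm(oi - nj)))
            if window[0] <= best <= window[1]:
                n_ok += 1
        if n_ok < 0.4 * len(resis):
            return False
    return True


def hbond_partner(position: int, arrangement: StrandArrangement, n_residues: int) -> int | None:
    """Residue of the neighbouring strand paired with ``position``.

    Returns None when the pairing falls outside the strand (shifted ends).
    """
    if arrangement.kind is ArrangementKind.PARALLEL_IN_REGISTER:
        return position
    q = arrangement.pairing_offset(n_residues) - position
    return q if 1 <= q <= n_residues else None
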