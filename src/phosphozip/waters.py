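"""Water penetration of the dry steric-zipper interface.

A stable steric zipper keeps the gap between its two beta-sheets free of
solvent. Dissolution shows up in a trajectory as water molecules
(counted by their oxygen positions) entering that gap. The interface is
operationalised as the slab between the two sheets' mean planes, inset
by a margin on each side, intersected with the prism over the convex
hull of the interface-facing CB atoms (dilated by 2 A). A model whose
per-frame interior water count stays below five is called stable —
fewer than five penetrating waters is the hallmark of the zippers that
survive simulation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import shapely
from shapely.geometry import MultiPoint

from .zipper import FibrilModel

__all__ = [
    "TrajectoryFrame",
    "InterfaceRegion",
    "PenetrationSeries",
    "RegionError",
    "define_interface_region",
    "count_interface_waters",
    "penetration_series",
    "DEFAULT_WATER_THRESHOLD",
]

DEFAULT_WATER_THRESHOLD = 5
FOOTPRINT_DILATION = 2.0


class RegionError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class TrajectoryFrame:
    """One frame: peptide coordinates plus water-oxygen and ion positions."""

    time_ns: float
    peptide: FibrilModel
    waters: np.ndarray  # (n, 3) water oxygen coordinates, A
    ions: np.ndarray = dataclasses.field(
        default_factory=lambda: np.empty((0, 3))
    )

    def __post_init__(self):
        w = np.asarray(self.waters, dtype=float).reshape(-1, 3)
        i = np.asarray(self.ions, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "waters", w)
        object.__setattr__(self, "ions", i)


@dataclasses.dataclass(frozen=True)
class InterfaceRegion:
    """Slab-and-footprint definition of the dry inter-sheet region.

    ``origin``/``axes`` define a local frame whose third axis points from
    sheet 1 to sheet 2; ``lo``/``hi`` bound the slab along that axis
    (already inset); ``footprint`` is a shapely polygon in the first two
    local coordinates. ``plane_gap`` is the uninset mean-plane distance.
    """

    origin: np.ndarray
    axes: np.ndarray  # rows u, v, w; orthonormal
    lo: float
    hi: float
    footprint: shapely.Geometry
    plane_gap: float

    def __post_init__(self):
        if not self.hi > self.lo:
            raise RegionError("degenerate slab: inset exceeds half the gap")
        if self.footprint.is_empty or self.footprint.area <= 0:
            raise RegionError("degenerate footprint")


class _RegionFrame:
    """Local/world coordinate transforms for an InterfaceRegion."""

    def __init__(self, region: InterfaceRegion):
        self.origin = region.origin
        self.axes = region.axes

    def to_local(self, xyz: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(xyz) - self.origin) @ self.axes.T

    def to_world(self, uv: np.ndarray, w: float) -> np.ndarray:
        return (
            self.origin
            + uv[0] * self.axes[0]
            + uv[1] * self.axes[1]
            + w * self.axes[2]
        )


def _region_frame(region: InterfaceRegion) -> _RegionFrame:
    return _RegionFrame(region)


def _sheet_partition(model: FibrilModel, sheets=None) -> dict[int, tuple[str, ...]]:
    sheets = sheets or model.provenance.get("sheets")
    if not sheets or set(sheets) != {1, 2}:
        raise RegionError(
            "model has no two-sheet partition; build provenance or an "
            "explicit chain mapping is required"
        )
    return sheets


def define_interface_region(
    model: FibrilModel,
    inset: float = 1.0,
    sheets: dict[int, tuple[str, ...]] | None = None,
) -> InterfaceRegion:
    """Construct the dry-interface region of a two-sheet model.

    The slab spans the space between the two sheets' mean CA planes,
    inset by ``inset`` on each side; the footprint is the convex hull of
    the CB atoms lying between the planes (the interface-decorating side
    chains), dilated by 2 A. Raises RegionError when the inset consumes
    the whole gap or the sheets cannot be separated.
    """
    sheets = _sheet_partition(model, sheets)
    cents = {}
    for s, cs in sheets.items():
        sel = model.select(name="CA", chains=cs) or model.select(chains=cs)
        if not sel:
            raise RegionError(f"sheet {s} has no atoms")
        cents[s] = np.array([(a.x, a.y, a.z) for a in sel]).mean(axis=0)
    w = cents[2] - cents[1]
    gap = float(np.linalg.norm(w))
    if gap < 1e-6:
        raise RegionError("sheets not separable: coincident centroids")
    w /= gap
    # orthonormal in-plane axes
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, w)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    u = seed - np.dot(seed, w) * w
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    origin = 0.5 * (cents[1] + cents[2])
    axes = np.array([u, v, w])

    lo_plane = float(np.dot(cents[1] - origin, w))   # = -gap/2
    hi_plane = float(np.dot(cents[2] - origin, w))   # = +gap/2
    lo, hi = lo_plane + inset, hi_plane - inset
    if not hi > lo:
        raise RegionError(
            f"degenerate slab: inset {inset} >= half the {gap:.2f} A gap"
        )

    cbs = [a for a in model.atoms if a.name == "CB"]
    if not cbs:
        raise RegionError("model has no CB atoms for a footprint")
    xyz = np.array([(a.x, a.y, a.z) for a in cbs])
    local = (xyz - origin) @ axes.T
    inside = (local[:, 2] > lo_plane) & (local[:, 2] < hi_plane)
    pts = local[inside][:, :2] if inside.any() else local[:, :2]
    footprint = MultiPoint(pts).convex_hull.buffer(FOOTPRINT_DILATION)
    return InterfaceRegion(
        origin=origin, axes=axes, lo=lo, hi=hi,
        footprint=footprint, plane_gap=gap,
    )


def count_interface_waters(
    frame: TrajectoryFrame, region: InterfaceRegion
) -> int:
    """Water oxygens strictly inside slab-and-footprint (boundary excluded)."""
    if frame.waters.size == 0:
        return 0
    local = (frame.waters - region.origin) @ region.axes.T
    in_slab = (local[:, 2] > region.lo) & (local[:, 2] < region.hi)
    if not in_slab.any():
        return 0
    pts = local[in_slab]
    hits = shapely.contains_xy(region.footprint, pts[:, 0], pts[:, 1])
    return int(np.count_nonzero(hits))


def _count_ions(frame: TrajectoryFrame, region: InterfaceRegion) -> int:
    if frame.ions.size == 0:
        return 0
    local = (frame.ions - region.origin) @ region.axes.T
    in_slab = (local[:, 2] > region.lo) & (local[:, 2] < region.hi)
    if not in_slab.any():
        return 0
    pts = local[in_slab]
    return int(
        np.count_nonzero(shapely.contains_xy(region.footprint, pts[:, 0], pts[:, 1]))
    )


@dataclasses.dataclass(frozen=True)
class PenetrationSeries:
    """Per-frame interior water counts and the stability verdict.

    ``verdict`` is "stable" when every frame count stays below
    ``threshold`` (default 5) and the sheets never drift beyond twice
    their initial separation; otherwise "dissolved".
    """

    times_ns: np.ndarray
    counts: np.ndarray
    ion_counts: np.ndarray
    threshold: int
    verdict: str
    collapsed: bool = False

    @property
    def max_count(self) -> int:
        return int(self.counts.max()) if len(self.counts) else 0


def penetration_series(
    frames: list[TrajectoryFrame],
    inset: float = 1.0,
    threshold: int = DEFAULT_WATER_THRESHOLD,
    sheets: dict[int, tuple[str, ...]] | None = None,
) -> PenetrationSeries:
    """Count interface waters frame by frame and classify stability.

    The region is recomputed from each frame's peptide coordinates, so
    sheet drift widens (or invalidates) the slab naturally. If the
    mean-plane gap exceeds twice its initial value the zipper is deemed
    structurally collapsed and the verdict is "dissolved" regardless of
    counts. Ions are counted with the same region but reported
    separately; only waters enter the criterion.
    """
    if not frames:
        raise ValueError("need at least one frame")
    times, counts, ion_counts = [], [], []
    initial_gap = None
    collapsed = False
    for i, frame in enumerate(frames):
        if not frame.peptide.atoms:
            raise ValueError(f"frame {i} has no peptide atoms")
        region = define_interface_region(frame.peptide, inset=inset, sheets=sheets)
        if initial_gap is None:
            initial_gap = region.plane_gap
        elif region.plane_gap > 2.0 * initial_gap:
            collapsed = True
        times.append(frame.time_ns)
        counts.append(count_interface_waters(frame, region))
        ion_counts.append(_count_ions(frame, region))
    counts_arr = np.array(counts, dtype=int)
    verdict = (
        "stable"
        if not collapsed and (counts_arr < threshold).all()
        else "dissolved"
    )
    return PenetrationSeries(
        times_ns=np.array(times, dtype=float),
        counts=counts_arr,
        ion_counts=np.array(ion_counts, dtype=int),
        threshold=threshold,
        verdict=verdict,
        collapsed=collapsed,
    )
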