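"""Synthetic inputs for every pipeline stage.

Nothing in the study is deposited as raw data, so the generators here
stand in for the wet-lab plates and the solvated trajectories:

* ``simulate_tht_replicates`` — 40-replicate sigmoidal ThT curve sets
  with per-well half-times, plateau scatter and white noise, plus a
  constant blank; ground-truth parameters are returned alongside so the
  t50 pipeline can be validated against known values.
* ``simulate_zipper_trajectory`` — multi-frame copies of a zipper model
  with a scheduled number of water oxygens planted strictly inside the
  dry inter-sheet interface (and decoys outside), for validating the
  water-penetration counter.
* ``study_outcome_fixture`` — the variant-by-pH aggregation outcome
  matrix transcribed from the study, the input to architecture
  inference.

All randomness flows through a single integer seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .inference import AggregationOutcomeMatrix, Outcome
from .kinetics import KineticCurve, ReplicateSet
from .waters import TrajectoryFrame, define_interface_region, _region_frame
from .zipper import FibrilModel, Atom

__all__ = [
    "ThTSimParams",
    "TrajSimParams",
    "SimTruth",
    "simulate_tht_replicates",
    "simulate_zipper_trajectory",
    "study_outcome_fixture",
]


@dataclasses.dataclass(frozen=True)
class ThTSimParams:
    """Ground-truth parameters of a synthetic replicate plate.

    Each well i follows blank + A_i * L(t; tau_i, k) + noise, with L a
    logistic (or Gompertz) sigmoid, tau_i ~ N(true_t50_mean,
    true_t50_sd) and A_i ~ N(plateau_mean, cv * mean). Defaults emulate a
    40-replicate condition with ~5% plateau scatter and 1% noise.
    """

    n_replicates: int = 40
    true_t50_mean: float = 10.0        # s
    true_t50_sd: float = 1.0           # s
    steepness: float = 2.0             # 1/s
    lag_shape: float = 1.0             # Gompertz asymmetry (mode="gompertz")
    plateau_mean: float = 100.0        # a.u.
    plateau_cv: float = 0.05
    noise_sd: float = 1.0              # a.u.
    blank_level: float = 5.0           # a.u.
    t_max: float = 30.0                # s
    n_points: int = 301
    mode: str = "logistic"             # or "gompertz"
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 5:
            raise ValueError("need at least 5 replicates")
        if self.plateau_mean < 0:
            raise ValueError("plateau must be non-negative")
        for name in ("true_t50_mean", "steepness", "t_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("true_t50_sd", "plateau_cv", "noise_sd", "blank_level"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclasses.dataclass(frozen=True)
class SimTruth:
    """Per-well ground truth of a simulated plate."""

    t50: np.ndarray       # tau_i, seconds
    plateau: np.ndarray   # A_i, a.u.


def _sigmoid(t: np.ndarray, tau: float, k: float, mode: str, lag_shape: float):
    if mode == "logistic":
        return 1.0 / (1.0 + np.exp(-k * (t - tau)))
    if mode == "gompertz":
        # asymmetric sigmoid; lag_shape scales the approach rate and the
        # ln(ln 2) shift keeps the half-maximum at tau
        return np.exp(-np.exp(-k * lag_shape * (t - tau) + np.log(np.log(2.0))))
    raise ValueError(f"unknown sigmoid mode {mode!r}")


def simulate_tht_replicates(
    params: ThTSimParams | None = None,
    variant: str = "synthetic",
    ph: float = 3.6,
) -> tuple[ReplicateSet, SimTruth]:
    """Simulate one condition's replicate curves plus blank.

    Returns the raw (blank-included) ReplicateSet and the per-well
    ground-truth half-times and plateaus. Identical seeds give
    bit-identical output.
    """
    p = params or ThTSimParams()
    rng = np.random.default_rng(p.seed)
    t = np.linspace(0.0, p.t_max, p.n_points)

    taus = rng.normal(p.true_t50_mean, p.true_t50_sd, size=p.n_replicates)
    taus = np.clip(taus, 1e-6, None)
    amps = rng.normal(p.plateau_mean, p.plateau_cv * p.plateau_mean,
                      size=p.n_replicates)
    amps = np.clip(amps, 0.0, None)

    curves = []
    for i in range(p.n_replicates):
        clean = amps[i] * _sigmoid(t, taus[i], p.steepness, p.mode, p.lag_shape)
        noise = rng.normal(0.0, p.noise_sd, size=t.shape) if p.noise_sd else 0.0
        curves.append(
            KineticCurve(t, p.blank_level + clean + noise, well_id=f"W{i+1:02d}")
        )
    blank = KineticCurve(t, np.full_like(t, p.blank_level), well_id="blank")
    return (
        ReplicateSet(tuple(curves), blank, variant=variant, ph=ph),
        SimTruth(t50=taus, plateau=amps),
    )


# --------------------------------------------------------------------------
# zipper trajectories
# --------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class TrajSimParams:
    """Schedule for a synthetic zipper trajectory.

    ``interior_counts``/``exterior_counts`` give, per frame, how many
    water oxygens to plant strictly inside / outside the inter-sheet
    interface region. ``jitter_sd`` adds isotropic Gaussian displacement
    to the peptide atoms before waters are placed (so planted counts stay
    exact). Waters respect a 2.8 A mutual exclusion distance.
    """

    base_model: FibrilModel
    interior_counts: tuple[int, ...]
    exterior_counts: tuple[int, ...] | None = None
    jitter_sd: float = 0.0
    inset: float = 1.0
    time_step_ns: float = 0.1
    n_ions: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        ext = self.exterior_counts
        if ext is not None and len(ext) != len(self.interior_counts):
            raise ValueError("schedules must have equal length")

    @property
    def n_frames(self) -> int:
        return len(self.interior_counts)


_WATER_EXCLUSION = 2.8


def _sample_points(
    rng: np.random.Generator,
    n: int,
    inside: bool,
    region,
    placed: list[np.ndarray],
    max_tries: int = 20000,
) -> list[np.ndarray]:
    """Rejection-sample points strictly inside/outside a region."""
    import shapely

    frame_r = _region_frame(region)
    lo2d = np.array(region.footprint.bounds[:2])
    hi2d = np.array(region.footprint.bounds[2:])
    pad = 8.0
    out: list[np.ndarray] = []
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                "could not place waters: region capacity exceeded at "
                f"{_WATER_EXCLUSION} A exclusion"
            )
        if inside:
            uv = rng.uniform(lo2d, hi2d)
            w = rng.uniform(region.lo, region.hi)
        else:
            uv = rng.uniform(lo2d - pad, hi2d + pad)
            w = rng.uniform(region.lo - pad, region.hi + pad)
        point_ok = shapely.contains_xy(region.footprint, uv[0], uv[1])
        slab_ok = region.lo < w < region.hi
        if inside != (point_ok and slab_ok):
            continue
        xyz = frame_r.to_world(uv, w)
        if any(np.linalg.norm(xyz - q) < _WATER_EXCLUSION for q in placed + out):
            continue
        out.append(xyz)
    return out


def simulate_zipper_trajectory(params: TrajSimParams) -> list[TrajectoryFrame]:
    """Frames of a jittered zipper with planted interface/exterior waters.

    Peptide atoms are jittered first and the interface region recomputed
    from the jittered coordinates, so the scheduled interior counts are
    exact by construction at any jitter level.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    ext = p.exterior_counts or tuple([0] * p.n_frames)
    frames: list[TrajectoryFrame] = []
    base_atoms = p.base_model.atoms
    xyz0 = p.base_model.coords()
    for f in range(p.n_frames):
        if p.jitter_sd > 0:
            xyz = xyz0 + rng.normal(0.0, p.jitter_sd, size=xyz0.shape)
        else:
            xyz = xyz0
        atoms = [
            Atom(a.chain, a.resi, a.resn, a.name, *xyz[i])
            for i, a in enumerate(base_atoms)
        ]
        peptide = FibrilModel(atoms, provenance=dict(p.base_model.provenance))
        region = define_interface_region(peptide, inset=p.inset)
        placed: list[np.ndarray] = []
        interior = _sample_points(rng, p.interior_counts[f], True, region, placed)
        placed += interior
        exterior = _sample_points(rng, ext[f], False, region, placed)
        waters = np.array(interior + exterior, dtype=float).reshape(-1, 3)
        ions = (
            np.array(
                _sample_points(rng, p.n_ions, False, region, placed + exterior),
                dtype=float,
            ).reshape(-1, 3)
            if p.n_ions
            else np.empty((0, 3))
        )
        frames.append(
            TrajectoryFrame(
                time_ns=f * p.time_step_ns,
                peptide=peptide,
                waters=waters,
                ions=ions,
            )
        )
    return frames


# --------------------------------------------------------------------------
# outcome fixture
# --------------------------------------------------------------------------

def study_outcome_fixture() -> AggregationOutcomeMatrix:
    """Variant-by-pH aggregation outcomes of the phospho-scanning study.

    At pH 1.1 (neutral phosphate) every variant forms fibrils; at pH 3.6
    (mono-anionic) p5Y, p8Y and the double variant p3S10T are inhibited
    while the rest aggregate; at pH 7.5 (di-anionic) only the
    non-phosphorylated control still assembles. Mean t50 values are
    attached where the study reports them; the double variant shows too
    broad a rate spread at pH 1.1 for a single t50.
    """
    variants = ["control", "p13T", "p10T", "p9Y", "p8Y", "p5Y", "p3S", "p3S10T"]
    t50 = {
        ("control", 1.1): 0.367,
        ("control", 3.6): 0.484,
        ("control", 7.5): 10.59,
        ("p9Y", 1.1): 2.90,
        ("p9Y", 3.6): 74.77,
    }
    entries: dict[tuple[str, float], Outcome] = {}
    for v in variants:
        entries[(v, 1.1)] = Outcome("fibrils", t50.get((v, 1.1)))
    aggregating_36 = {"control", "p13T", "p10T", "p9Y", "p3S"}
    for v in variants:
        if v in aggregating_36:
            entries[(v, 3.6)] = Outcome("fibrils", t50.get((v, 3.6)))
        else:
            entries[(v, 3.6)] = Outcome("no_fibrils")
    for v in variants:
        if v == "control":
            entries[(v, 7.5)] = Outcome("fibrils", t50.get((v, 7.5)))
        else:
            entries[(v, 7.5)] = Outcome("no_fibrils")
    return AggregationOutcomeMatrix(entries)
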