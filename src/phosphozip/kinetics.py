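"""ThT aggregation-kinetics processing.

Fibril formation is monitored as thioflavin-T fluorescence over time in
replicate wells (nominally 40 per condition). The pipeline is:

1. subtract the DMSO blank from every well,
2. normalise each curve to the mean of its end-point plateau,
3. extract t50 — the time at which the normalised signal first reaches
   50% of the plateau — by linear interpolation between the bracketing
   samples: t50 = t1 + (t2 - t1) * (0.5 - y1) / (y2 - y1),
4. histogram the replicate t50 values (10 bins) and fit a Gaussian to
   obtain a mean t50 and standard deviation per condition.

Wells whose plateau never rises above baseline noise are called
``no_fibrils`` and censored at the final observation time.

``ThTKineticsModel`` wraps the pipeline in a model/results pair:
``ThTKineticsModel(replicates).fit()`` returns a ``ThTKineticsResults``
carrying the per-well estimates, the Gaussian summary and the assembly
call, with a ``summary()`` table.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "KineticCurve",
    "ReplicateSet",
    "T50Estimate",
    "T50Summary",
    "AssemblyCall",
    "GridMismatchError",
    "NoCrossingError",
    "DegenerateStartError",
    "NonAggregatorError",
    "InsufficientReplicatesError",
    "subtract_blank",
    "normalize_to_plateau",
    "compute_t50",
    "summarize_t50",
    "classify_assembly",
    "ThTKineticsModel",
    "ThTKineticsResults",
]


class GridMismatchError(ValueError):
    pass


class NoCrossingError(ValueError):
    """Curve never reaches half-plateau: candidate non-aggregator."""


class DegenerateStartError(ValueError):
    """Curve already at/above half-plateau at the first sample."""


class NonAggregatorError(ValueError):
    """Plateau at or below zero: nothing to normalise against."""


class InsufficientReplicatesError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class KineticCurve:
    """One well's fluorescence time course (times in seconds)."""

    times: np.ndarray
    intensities: np.ndarray
    well_id: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if t.ndim != 1 or y.ndim != 1 or len(t) != len(y):
            raise ValueError("times and intensities must be equal-length 1-D")
        if len(t) < 2:
            raise ValueError("need at least 2 samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)


@dataclasses.dataclass(frozen=True)
class ReplicateSet:
    """Replicate curves for one (variant, pH) condition plus their blank."""

    curves: tuple[KineticCurve, ...]
    blank: KineticCurve
    variant: str = ""
    ph: float = float("nan")

    def __post_init__(self):
        object.__setattr__(self, "curves", tuple(self.curves))
        for c in self.curves:
            if len(c.times) != len(self.blank.times) or not np.allclose(
                c.times, self.blank.times
            ):
                raise GridMismatchError(
                    f"well {c.well_id!r} not on the blank's time grid"
                )


@dataclasses.dataclass(frozen=True)
class T50Estimate:
    """t50 with its bracketing samples (t1, y1) below and (t2, y2) above."""

    t50: float
    t1: float
    t2: float
    y1: float
    y2: float
    well_id: str = ""

    def __post_init__(self):
        if not (self.t1 < self.t50 <= self.t2):
            raise ValueError("t50 must lie in (t1, t2]")
        if not (self.y1 < 0.5 <= self.y2):
            raise ValueError("bracket must straddle 0.5")


@dataclasses.dataclass(frozen=True)
class T50Summary:
    mean_t50: float
    sd_t50: float
    n_bins: int
    bin_edges: np.ndarray
    counts: np.ndarray
    n_curves: int
    method: str = "gaussian_fit"  # or "sample_stats"


@dataclasses.dataclass(frozen=True)
class AssemblyCall:
    outcome: str  # "fibrils" | "no_fibrils"
    censored_at: float | None = None  # set iff no_fibrils

    def __post_init__(self):
        if self.outcome not in ("fibrils", "no_fibrils"):
            raise ValueError("outcome must be fibrils/no_fibrils")
        if (self.outcome == "no_fibrils") != (self.censored_at is not None):
            raise ValueError("censored_at present iff no_fibrils")


# --------------------------------------------------------------------------
# pipeline operations
# --------------------------------------------------------------------------

def average_blanks(blanks: Sequence[KineticCurve]) -> KineticCurve:
    """Pointwise mean of several blank wells (common time grid required)."""
    t0 = blanks[0].times
    for b in blanks[1:]:
        if not np.allclose(b.times, t0):
            raise GridMismatchError("blank wells not on a common time grid")
    mean = np.mean([b.intensities for b in blanks], axis=0)
    return KineticCurve(t0, mean, well_id="blank_mean")


def subtract_blank(replicates: ReplicateSet) -> ReplicateSet:
    """Subtract the blank's intensity from every curve, pointwise."""
    blank = replicates.blank
    curves = tuple(
        KineticCurve(c.times, c.intensities - blank.intensities, c.well_id)
        for c in replicates.curves
    )
    zero_blank = KineticCurve(
        blank.times, np.zeros_like(blank.intensities), blank.well_id
    )
    return ReplicateSet(curves, zero_blank, replicates.variant, replicates.ph)


def normalize_to_plateau(
    curve: KineticCurve, plateau_fraction: float = 0.1
) -> KineticCurve:
    """Divide by the mean of the final ``plateau_fraction`` of samples.

    After normalisation the plateau mean is exactly 1. A plateau mean at
    or below zero means the well never aggregated; such wells belong in
    classify_assembly, not here.
    """
    if not 0 < plateau_fraction <= 1:
        raise ValueError("plateau_fraction must be in (0, 1]")
    n = len(curve.intensities)
    k = max(1, int(round(plateau_fraction * n)))
    plateau = float(np.mean(curve.intensities[-k:]))
    if plateau <= 0:
        raise NonAggregatorError(
            f"well {curve.well_id!r}: plateau mean {plateau:.3g} <= 0"
        )
    return KineticCurve(curve.times, curve.intensities / plateau, curve.well_id)


def compute_t50(curve: KineticCurve) -> T50Estimate:
    """Interpolated time of the first upward crossing of half-plateau.

    The curve must be normalised (plateau ~ 1). To be robust to early
    noise spikes, the crossing searched is the first upward crossing of
    0.5 at or after the curve's global minimum. The crossing time is the
    linear interpolation t50 = t1 + (t2 - t1)(0.5 - y1)/(y2 - y1).
    """
    t, y = curve.times, curve.intensities
    start = int(np.argmin(y))
    if y[start] >= 0.5:
        raise DegenerateStartError(
            f"well {curve.well_id!r}: signal already >= 0.5 at its minimum"
        )
    seg = y[start:]
    above = np.nonzero(seg >= 0.5)[0]
    if len(above) == 0:
        raise NoCrossingError(
            f"well {curve.well_id!r}: signal never reaches 0.5"
        )
    i2 = start + above[0]
    i1 = i2 - 1
    t1, t2, y1, y2 = t[i1], t[i2], y[i1], y[i2]
    t50 = t1 + (t2 - t1) * (0.5 - y1) / (y2 - y1)
    return T50Estimate(
        t50=float(t50), t1=float(t1), t2=float(t2),
        y1=float(y1), y2=float(y2), well_id=curve.well_id,
    )


def _gauss(x, amp, mu, sigma):
    return amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def summarize_t50(
    t50s: Sequence[float], n_bins: int = 10
) -> T50Summary:
    """Histogram + Gaussian-fit summary of replicate t50 values.

    An equal-width ``n_bins`` histogram over [min, max] is least-squares
    fitted with amp*exp(-(x-mu)^2 / 2 sigma^2); mu and |sigma| become the
    condition's mean t50 and SD. When the fit fails, explains the counts
    poorly (R^2 < 0.5) or returns a sigma wider than the data range, the
    sample mean/SD are reported instead with a warning.
    """
    x = np.asarray(list(t50s), dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 5:
        raise ValueError("need at least 5 finite t50 values")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        edges = np.linspace(lo - 0.5, hi + 0.5, n_bins + 1)
        counts, _ = np.histogram(x, bins=edges)
        return T50Summary(lo, 0.0, n_bins, edges, counts, len(x), "degenerate")

    counts, edges = np.histogram(x, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    mu0, sd0 = float(x.mean()), float(x.std(ddof=1))
    try:
        popt, _ = curve_fit(
            _gauss, centers, counts,
            p0=(float(counts.max()), mu0, sd0 if sd0 > 0 else 1.0),
            maxfev=5000,
        )
        amp, mu, sigma = popt
        sigma = abs(float(sigma))
        resid = counts - _gauss(centers, *popt)
        ss_tot = float(np.sum((counts - counts.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
        ok = r2 >= 0.5 and sigma <= (hi - lo) and lo <= mu <= hi
    except (RuntimeError, ValueError):
        ok = False
    if not ok:
        warnings.warn(
            "Gaussian fit to the t50 histogram failed or fit poorly; "
            "falling back to sample statistics",
            stacklevel=2,
        )
        return T50Summary(mu0, sd0, n_bins, edges, counts, len(x), "sample_stats")
    return T50Summary(float(mu), sigma, n_bins, edges, counts, len(x), "gaussian_fit")


def classify_assembly(
    replicates: ReplicateSet,
    noise_k: float = 5.0,
    plateau_fraction: float = 0.1,
    baseline_fraction: float = 0.1,
) -> AssemblyCall:
    """Call fibrils / no_fibrils from blank-subtracted replicate curves.

    Fibrils are called when the median final-plateau signal across wells
    exceeds ``noise_k`` times the standard deviation of the early
    baseline; otherwise the condition is censored at the final time point
    (the ">4 days" style of call for non-aggregating variants).
    """
    if len(replicates.curves) < 3:
        raise InsufficientReplicatesError(
            f"need >= 3 replicate curves, got {len(replicates.curves)}"
        )
    plateaus, baselines = [], []
    for c in replicates.curves:
        n = len(c.intensities)
        kp = max(1, int(round(plateau_fraction * n)))
        kb = max(2, int(round(baseline_fraction * n)))
        plateaus.append(float(np.mean(c.intensities[-kp:])))
        baselines.append(c.intensities[:kb])
    noise_sd = float(np.std(np.concatenate(baselines)))
    threshold = noise_k * max(noise_sd, np.finfo(float).tiny)
    if float(np.median(plateaus)) > threshold:
        return AssemblyCall("fibrils")
    return AssemblyCall(
        "no_fibrils", censored_at=float(replicates.curves[0].times[-1])
    )


# --------------------------------------------------------------------------
# model / results wrappers
# --------------------------------------------------------------------------

@dataclasses.dataclass
class ThTKineticsResults:
    """Fitted summary of one replicate set.

    ``estimates`` holds the per-well t50 brackets for wells that crossed
    half-plateau; ``failed_wells`` the wells that could not be processed
    (no crossing / degenerate / non-aggregator).
    """

    variant: str
    ph: float
    call: AssemblyCall
    estimates: list[T50Estimate]
    summary_stats: T50Summary | None
    failed_wells: list[tuple[str, str]]

    @property
    def t50s(self) -> np.ndarray:
        return np.array([e.t50 for e in self.estimates])

    @property
    def mean_t50(self) -> float | None:
        return self.summary_stats.mean_t50 if self.summary_stats else None

    @property
    def sd_t50(self) -> float | None:
        return self.summary_stats.sd_t50 if self.summary_stats else None

    def summary(self) -> str:
        lines = [
            "ThT kinetics summary",
            "====================",
            f"variant:          {self.variant or '-'}",
            f"pH:               {self.ph}",
            f"assembly call:    {self.call.outcome}",
        ]
        if self.call.outcome == "no_fibrils":
            lines.append(f"censored at:      {self.call.censored_at:g} s")
        if self.summary_stats is not None:
            s = self.summary_stats
            lines += [
                f"wells used:       {s.n_curves}",
                f"mean t50:         {s.mean_t50:.4g} s",
                f"sd t50:           {s.sd_t50:.4g} s",
                f"summary method:   {s.method} ({s.n_bins} bins)",
            ]
        if self.failed_wells:
            lines.append(f"failed wells:     {len(self.failed_wells)}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Histogram of t50 values with the fitted Gaussian overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.summary_stats
        if s is None:
            raise ValueError("nothing to plot: no t50 summary")
        centers = 0.5 * (s.bin_edges[:-1] + s.bin_edges[1:])
        ax.bar(centers, s.counts, width=np.diff(s.bin_edges), alpha=0.6,
               edgecolor="k", label="t50 histogram")
        if s.method == "gaussian_fit" and s.sd_t50 > 0:
            xs = np.linspace(s.bin_edges[0], s.bin_edges[-1], 200)
            amp = s.counts.max()
            ax.plot(xs, _gauss(xs, amp, s.mean_t50, s.sd_t50), "k-",
                    label="Gaussian fit")
        ax.set_xlabel("t50 (s)")
        ax.set_ylabel("count")
        ax.legend()
        return ax


class ThTKineticsModel:
    """End-to-end t50 analysis of one replicate set.

    Parameters
    ----------
    replicates : raw replicate curves plus blank for one condition.
    plateau_fraction : final fraction of samples defining the plateau.
    n_bins : histogram bins for the t50 summary.
    noise_k : aggregation-call threshold multiplier.
    """

    def __init__(
        self,
        replicates: ReplicateSet,
        plateau_fraction: float = 0.1,
        n_bins: int = 10,
        noise_k: float = 5.0,
    ):
        self.replicates = replicates
        self.plateau_fraction = plateau_fraction
        self.n_bins = n_bins
        self.noise_k = noise_k

    def fit(self) -> ThTKineticsResults:
        sub = subtract_blank(self.replicates)
        call = classify_assembly(
            sub, noise_k=self.noise_k, plateau_fraction=self.plateau_fraction
        )
        estimates: list[T50Estimate] = []
        failed: list[tuple[str, str]] = []
        if call.outcome == "fibrils":
            for c in sub.curves:
                try:
                    norm = normalize_to_plateau(c, self.plateau_fraction)
                    estimates.append(compute_t50(norm))
                except (NoCrossingError, DegenerateStartError,
                        NonAggregatorError) as exc:
                    failed.append((c.well_id, type(exc).__name__))
        stats = (
            summarize_t50([e.t50 for e in estimates], self.n_bins)
            if len(estimates) >= 5
            else None
        )
        return ThTKineticsResults(
            variant=sub.variant,
            ph=sub.ph,
            call=call,
            estimates=estimates,
            summary_stats=stats,
            failed_wells=failed,
        )
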