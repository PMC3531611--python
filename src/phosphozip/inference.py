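"""Fibril-architecture inference from position-dependent aggregation.

The logic mirrors the phospho-scanning argument: assuming (i) that
electrostatic repulsion between nearby phosphate groups is what blocks
assembly and (ii) that all variants share a common fibril morphology,
the pattern of which phosphovariants can and cannot aggregate at the
mono-anionic pH constrains where phosphosites may sit relative to one
another in the fibril.

Two screens are applied in sequence:

1. *Strand arrangements* (schematic): within a beta-sheet, neighbouring
   strands pair residue i with residue i (parallel) or (N+1)-i+s
   (antiparallel, shift s). The phosphate-phosphate offset along the
   strand axis, in residues, is |p - q| (parallel) or |p + q - P|
   (antiparallel, P = N+1+s) minimised over phosphosite pairs (p, q). An
   arrangement is eliminated when some non-aggregating variant's
   phosphates are no closer than some aggregating variant's.
2. *Zipper classes* (geometric): for the two classes compatible with the
   surviving arrangement, 8x2 coordinate models are built and the
   cross-interface CB-CB separation at each variant's phosphosite is
   measured; a class survives only if every aggregating variant's
   separation exceeds every non-aggregating one's by a margin (3 A by
   default).

On the study's outcomes the chain contracts 3 arrangements -> 1
arrangement -> 2 classes -> class 7.
"""

from __future__ import annotations

import dataclasses
import io
from typing import Mapping

import pandas as pd

from .peptides import PeptideVariant, STRAND_E
from .zipper import (
    ArrangementKind,
    BuildParams,
    FibrilModel,
    StrandArrangement,
    ZipperClassDescriptor,
    average_cb_distance,
    build_class_zipper,
    enumerate_zipper_classes,
    shifted_compatible_classes,
)

__all__ = [
    "Outcome",
    "AggregationOutcomeMatrix",
    "ConsistencyReport",
    "InferenceResult",
    "phosphosite_separation",
    "screen_strand_arrangements",
    "screen_zipper_classes",
    "infer_architecture",
    "ArchitectureModel",
    "ArchitectureResults",
    "CANDIDATE_ARRANGEMENTS",
]

COMMON_MORPHOLOGY_ASSUMPTION = (
    "Assumes electrostatic phosphate-phosphate repulsion controls "
    "assembly and that all variants share a common fibril morphology."
)


@dataclasses.dataclass(frozen=True)
class Outcome:
    outcome: str  # "fibrils" | "no_fibrils"
    mean_t50: float | None = None

    def __post_init__(self):
        if self.outcome not in ("fibrils", "no_fibrils"):
            raise ValueError(f"bad outcome {self.outcome!r}")


@dataclasses.dataclass(frozen=True)
class AggregationOutcomeMatrix:
    """(variant, pH) -> aggregation outcome, with optional mean t50."""

    entries: Mapping[tuple[str, float], Outcome]

    def __post_init__(self):
        object.__setattr__(self, "entries", dict(self.entries))

    def at(self, variant: str, ph: float) -> Outcome:
        return self.entries[(variant, ph)]

    def variants(self) -> list[str]:
        seen: dict[str, None] = {}
        for v, _ in self.entries:
            seen.setdefault(v, None)
        return list(seen)

    def ph_values(self) -> list[float]:
        return sorted({ph for _, ph in self.entries})

    def outcomes_at(self, ph: float) -> dict[str, Outcome]:
        return {v: o for (v, p), o in self.entries.items() if p == ph}

    # -- I/O -------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"variant": v, "ph": p, "outcome": o.outcome, "t50": o.mean_t50}
            for (v, p), o in self.entries.items()
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path_or_buf) -> "AggregationOutcomeMatrix":
        df = pd.read_csv(path_or_buf, sep="\t")
        entries = {}
        for _, r in df.iterrows():
            t50 = r.get("t50")
            t50 = None if pd.isna(t50) else float(t50)
            entries[(str(r["variant"]), float(r["ph"]))] = Outcome(
                str(r["outcome"]), t50
            )
        return cls(entries)


@dataclasses.dataclass(frozen=True)
class ConsistencyReport:
    """Verdict for one candidate arrangement or zipper class."""

    candidate: str
    verdict: str  # "consistent" | "eliminated" | "indeterminate"
    reason: str = ""
    separations: Mapping[str, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if self.verdict == "eliminated" and not self.reason:
            raise ValueError("eliminated verdict requires a reason")


CANDIDATE_ARRANGEMENTS: tuple[StrandArrangement, ...] = (
    StrandArrangement(ArrangementKind.PARALLEL_IN_REGISTER, 0),
    StrandArrangement(ArrangementKind.ANTIPARALLEL_IN_REGISTER, 0),
    StrandArrangement(ArrangementKind.ANTIPARALLEL_SHIFTED, -1),
)


def phosphosite_separation(
    arrangement_or_model: StrandArrangement | FibrilModel,
    variant: PeptideVariant,
) -> float:
    """Phosphate-phosphate separation score for one variant.

    For a schematic StrandArrangement the score is the residue-offset of
    the closest phosphate pair on neighbouring strands (0 = directly
    opposed). For a built FibrilModel it is the cross-interface CB-CB
    distance in angstroms, minimised over the variant's phosphosites.
    """
    sites = sorted(variant.phosphosites)
    if not sites:
        raise ValueError(f"variant {variant.name!r} has no phosphosites")
    if isinstance(arrangement_or_model, StrandArrangement):
        arr = arrangement_or_model
        n = len(variant.sequence)
        if arr.kind is ArrangementKind.PARALLEL_IN_REGISTER:
            # residue q of the neighbour stacks at the axial position of
            # residue q, so the closest pair offset is min |p - q|
            return float(min(abs(p - q) for p in sites for q in sites))
        p_off = arr.pairing_offset(n)
        return float(min(abs(p + q - p_off) for p in sites for q in sites))
    model = arrangement_or_model
    return min(average_cb_distance(model, p) for p in sites)


def _split_outcomes(
    outcomes: AggregationOutcomeMatrix,
    ph: float,
    variants: Mapping[str, PeptideVariant],
    single_site_only: bool = False,
) -> tuple[list[PeptideVariant], list[PeptideVariant]]:
    agg, non = [], []
    for name, out in outcomes.outcomes_at(ph).items():
        v = variants.get(name)
        if v is None or v.is_control:
            continue  # no phosphate, no constraint
        if single_site_only and len(v.phosphosites) > 1:
            continue
        (agg if out.outcome == "fibrils" else non).append(v)
    return agg, non


def screen_strand_arrangements(
    outcomes: AggregationOutcomeMatrix,
    ph: float,
    variants: Mapping[str, PeptideVariant] | None = None,
    candidates: tuple[StrandArrangement, ...] = CANDIDATE_ARRANGEMENTS,
) -> list[ConsistencyReport]:
    """Screen the three in-sheet strand arrangements against outcomes.

    Repulsion monotonicity: an arrangement is eliminated when a
    non-aggregating variant's phosphosite separation is greater than or
    equal to an aggregating variant's (the blocked variant would have to
    be at least as repelled as one that assembles). When all variants
    behave alike no arrangement can be eliminated and every report is
    flagged indeterminate.
    """
    if variants is None:
        from .peptides import table1_variants

        variants = table1_variants()
    agg, non = _split_outcomes(outcomes, ph, variants)
    reports = []
    for arr in candidates:
        label = arr.kind.value
        seps = {
            v.name: phosphosite_separation(arr, v) for v in agg + non
        }
        if not agg or not non:
            reports.append(
                ConsistencyReport(
                    label,
                    "indeterminate",
                    "all outcomes identical: no constraint binds",
                    seps,
                )
            )
            continue
        violation = None
        for nv in non:
            for av in agg:
                if seps[nv.name] >= seps[av.name]:
                    violation = (nv, av)
                    break
            if violation:
                break
        if violation:
            nv, av = violation
            reports.append(
                ConsistencyReport(
                    label,
                    "eliminated",
                    f"non-aggregating {nv.name} has phosphosite separation "
                    f"{seps[nv.name]:g} >= aggregating {av.name}'s "
                    f"{seps[av.name]:g}",
                    seps,
                )
            )
        else:
            reports.append(ConsistencyReport(label, "consistent", "", seps))
    return reports


def screen_zipper_classes(
    outcomes: AggregationOutcomeMatrix,
    models: Mapping[int, FibrilModel],
    ph: float,
    margin: float = 3.0,
    variants: Mapping[str, PeptideVariant] | None = None,
) -> list[ConsistencyReport]:
    """Screen built zipper classes by cross-interface phosphosite distance.

    A class is consistent iff every aggregating variant's separation
    exceeds every non-aggregating variant's by at least ``margin``
    angstroms. Only single-phosphosite variants inform this screen: a
    multi-site variant can be blocked by intra-sheet pairing of its own
    sites, which the cross-sheet metric does not measure.
    """
    if variants is None:
        from .peptides import table1_variants

        variants = table1_variants()
    agg, non = _split_outcomes(outcomes, ph, variants, single_site_only=True)
    reports = []
    for cid in sorted(models):
        model = models[cid]
        if model is None:
            raise ValueError(f"missing model for class {cid}")
        label = f"class {cid}"
        seps = {
            v.name: phosphosite_separation(model, v) for v in agg + non
        }
        if not agg or not non:
            reports.append(
                ConsistencyReport(
                    label,
                    "indeterminate",
                    "all outcomes identical: no constraint binds",
                    seps,
                )
            )
            continue
        min_agg = min(seps[v.name] for v in agg)
        max_non = max(seps[v.name] for v in non)
        if min_agg >= max_non + margin:
            reports.append(ConsistencyReport(label, "consistent", "", seps))
        else:
            worst_a = min(agg, key=lambda v: seps[v.name])
            worst_n = max(non, key=lambda v: seps[v.name])
            reports.append(
                ConsistencyReport(
                    label,
                    "eliminated",
                    f"aggregating {worst_a.name} separation "
                    f"{seps[worst_a.name]:.1f} A does not exceed "
                    f"non-aggregating {worst_n.name}'s "
                    f"{seps[worst_n.name]:.1f} A by the {margin:g} A margin",
                    seps,
                )
            )
    return reports


@dataclasses.dataclass
class InferenceResult:
    """Full audit trail of the two-stage architecture screen."""

    arrangement_reports: list[ConsistencyReport]
    class_reports: list[ConsistencyReport]
    candidate_classes: list[ZipperClassDescriptor]
    winner: int | None
    ph: float
    margin: float
    assumption: str = COMMON_MORPHOLOGY_ASSUMPTION


def infer_architecture(
    outcomes: AggregationOutcomeMatrix,
    params: BuildParams | None = None,
    ph: float = 3.6,
    margin: float = 3.0,
    sequence: str = STRAND_E,
    variants: Mapping[str, PeptideVariant] | None = None,
) -> InferenceResult:
    """Run the complete screen: arrangements, then compatible classes.

    Returns the audit trail and the winning class id (None when no
    arrangement or class is uniquely consistent).
    """
    params = params or BuildParams()
    arr_reports = screen_strand_arrangements(outcomes, ph, variants)
    consistent_arrs = [
        a
        for a, r in zip(CANDIDATE_ARRANGEMENTS, arr_reports)
        if r.verdict == "consistent"
    ]
    if len(consistent_arrs) != 1:
        return InferenceResult(arr_reports, [], [], None, ph, margin)
    arrangement = consistent_arrs[0]
    candidates = shifted_compatible_classes(
        enumerate_zipper_classes(), arrangement
    )
    models = {
        c.class_id: build_class_zipper(sequence, c.class_id, arrangement, params)
        for c in candidates
    }
    cls_reports = screen_zipper_classes(outcomes, models, ph, margin, variants)
    winners = [
        r for r in cls_reports if r.verdict == "consistent"
    ]
    winner = (
        int(winners[0].candidate.split()[-1]) if len(winners) == 1 else None
    )
    return InferenceResult(arr_reports, cls_reports, candidates, winner, ph, margin)


# --------------------------------------------------------------------------
# model / results wrappers
# --------------------------------------------------------------------------

@dataclasses.dataclass
class ArchitectureResults:
    """Results object for ArchitectureModel.fit()."""

    result: InferenceResult

    @property
    def winner(self) -> int | None:
        return self.result.winner

    @property
    def audit_trail(self) -> list[ConsistencyReport]:
        return self.result.arrangement_reports + self.result.class_reports

    def summary(self) -> str:
        r = self.result
        buf = io.StringIO()
        print("Fibril architecture inference", file=buf)
        print("=============================", file=buf)
        print(r.assumption, file=buf)
        print(f"screen pH: {r.ph}   class margin: {r.margin:g} A", file=buf)
        print("", file=buf)
        print("Strand arrangements:", file=buf)
        for rep in r.arrangement_reports:
            line = f"  {rep.candidate:28s} {rep.verdict}"
            if rep.reason:
                line += f"  [{rep.reason}]"
            print(line, file=buf)
            if rep.separations:
                seps = ", ".join(
                    f"{k}={v:g}" for k, v in sorted(rep.separations.items())
                )
                print(f"      separations (residues): {seps}", file=buf)
        if r.class_reports:
            print("", file=buf)
            print("Zipper classes:", file=buf)
            for rep in r.class_reports:
                line = f"  {rep.candidate:28s} {rep.verdict}"
                if rep.reason:
                    line += f"  [{rep.reason}]"
                print(line, file=buf)
                if rep.separations:
                    seps = ", ".join(
                        f"{k}={v:.1f}A" for k, v in sorted(rep.separations.items())
                    )
                    print(f"      separations: {seps}", file=buf)
        print("", file=buf)
        if r.winner is not None:
            print(f"Winning architecture: class {r.winner} steric zipper", file=buf)
        else:
            print("Winning architecture: indeterminate", file=buf)
        return buf.getvalue()


class ArchitectureModel:
    """Architecture screen as a model over an outcome matrix.

    ``ArchitectureModel(outcomes).fit()`` runs both screens with default
    geometry and returns an ArchitectureResults.
    """

    def __init__(
        self,
        outcomes: AggregationOutcomeMatrix,
        sequence: str = STRAND_E,
        ph: float = 3.6,
        margin: float = 3.0,
        params: BuildParams | None = None,
        variants: Mapping[str, PeptideVariant] | None = None,
    ):
        self.outcomes = outcomes
        self.sequence = sequence
        self.ph = ph
        self.margin = margin
        self.params = params or BuildParams()
        self.variants = variants

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "ArchitectureModel":
        return cls(AggregationOutcomeMatrix.from_tsv(path), **kwargs)

    def fit(self) -> ArchitectureResults:
        return ArchitectureResults(
            infer_architecture(
                self.outcomes,
                params=self.params,
                ph=self.ph,
                margin=self.margin,
                sequence=self.sequence,
                variants=self.variants,
            )
        )
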