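"""Peptide variants and pH-dependent charge-state modelling.

The model peptide is strand E of beta-2-microglobulin (residues 59-71,
DWSFYLLYYTEFT), synthesised with an acetylated N terminus and an amidated
C terminus so the termini carry no charge. Phosphate groups can be placed
on any Ser/Thr/Tyr; a phosphomonoester titrates through three charge
states (0 / -1 / -2) across its two pKa values, which is what makes pH a
switch for aggregation.

Charges are computed per ionisable site, either as the dominant
Henderson-Hasselbalch species (integer) or as the fractional expectation.
"""

from __future__ import annotations

import dataclasses
import io
import re
from typing import Iterable, Mapping

import yaml

__all__ = [
    "STRAND_E",
    "PH_ACIDIC",
    "PH_INTERMEDIATE",
    "PH_NEUTRAL",
    "PeptideVariant",
    "ChargeModel",
    "ProtonationState",
    "InvalidVariantError",
    "count_phosphorylatable_sites",
    "net_charge",
    "phosphate_charge_state",
    "protonation_state",
    "parse_variant",
    "variants_from_yaml",
    "table1_variants",
]

STRAND_E = "DWSFYLLYYTEFT"

# The three pH regimes of the study: phosphate fully protonated,
# mono-anionic, and di-anionic.
PH_ACIDIC = 1.1
PH_INTERMEDIATE = 3.6
PH_NEUTRAL = 7.5

PHOSPHORYLATABLE = set("STY")
_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


class InvalidVariantError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class PeptideVariant:
    """A peptide sequence with zero or more phosphorylated S/T/Y residues.

    ``phosphosites`` are 1-based residue indices. Termini are capped
    (acetyl / amide) by default, matching the synthetic peptides, so they
    contribute no charge.
    """

    name: str
    sequence: str
    phosphosites: frozenset[int] = frozenset()
    n_term_acetylated: bool = True
    c_term_amidated: bool = True

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "phosphosites", frozenset(self.phosphosites))
        bad = sorted(set(seq) - _STANDARD_AA)
        if bad:
            raise InvalidVariantError(
                f"{self.name}: unknown residue letter(s) {bad!r}"
            )
        for i in self.phosphosites:
            if not 1 <= i <= len(seq):
                raise InvalidVariantError(
                    f"{self.name}: phosphosite {i} outside 1..{len(seq)}"
                )
            if seq[i - 1] not in PHOSPHORYLATABLE:
                raise InvalidVariantError(
                    f"{self.name}: phosphosite {i} is {seq[i-1]}, not S/T/Y"
                )

    @property
    def is_control(self) -> bool:
        return not self.phosphosites


@dataclasses.dataclass(frozen=True)
class ChargeModel:
    """Site pKa values used for the Henderson-Hasselbalch charge model.

    Asp/Glu carboxylates are taken as pKa ~ 4; the phosphomonoester pKa
    pair (2.1 / 6.7) makes the dominant phosphate species neutral at pH
    1.1, mono-anionic at pH 3.6 and di-anionic at pH 7.5. Basic and thiol
    side chains (absent from strand E) are covered by an extensible
    table. Unphosphorylated Ser/Thr/Tyr are treated as non-ionisable in
    the pH range of interest.
    """

    pka_asp: float = 4.0
    pka_glu: float = 4.0
    pka_phos1: float = 2.1
    pka_phos2: float = 6.7
    extra_site_pkas: Mapping[str, tuple[float, int]] = dataclasses.field(
        # residue -> (pKa, charge of protonated form)
        default_factory=lambda: {
            "K": (10.5, +1),
            "R": (12.5, +1),
            "H": (6.0, +1),
            "C": (8.3, 0),
        }
    )

    def __post_init__(self):
        import math

        for v in (self.pka_asp, self.pka_glu, self.pka_phos1, self.pka_phos2):
            if not math.isfinite(v):
                raise ValueError("pKa values must be finite")
        if not self.pka_phos1 < self.pka_phos2:
            raise ValueError("phosphate pKa1 must be below pKa2")

    # -- per-site charges ------------------------------------------------
    def acid_charge(self, pka: float, ph: float, mode: str) -> float:
        """Charge of a monoprotic acid site (0 protonated, -1 deprotonated).

        A tie at pH == pKa resolves toward the protonated species.
        """
        if mode == "dominant":
            return -1 if ph > pka else 0
        frac = 1.0 / (1.0 + 10.0 ** (pka - ph))
        return -frac

    def base_charge(self, pka: float, ph: float, mode: str) -> float:
        """Charge of a monoprotic basic site (+1 protonated, 0 neutral)."""
        if mode == "dominant":
            return 1 if ph <= pka else 0
        return 1.0 / (1.0 + 10.0 ** (ph - pka))

    def phosphate_charge(self, ph: float, mode: str = "dominant") -> float:
        """Charge of a phosphomonoester (diprotic: 0 / -1 / -2).

        Dominant mode picks the most populated species, with ties broken
        toward the more protonated one; fractional mode returns the
        Henderson-Hasselbalch expectation.
        """
        if mode == "dominant":
            if ph <= self.pka_phos1:
                return 0
            if ph <= self.pka_phos2:
                return -1
            return -2
        r1 = 10.0 ** (ph - self.pka_phos1)
        r2 = 10.0 ** (2 * ph - self.pka_phos1 - self.pka_phos2)
        denom = 1.0 + r1 + r2
        return -(r1 + 2.0 * r2) / denom


@dataclasses.dataclass(frozen=True)
class ProtonationState:
    """Integer charge assignment at a query pH.

    ``phosphate_charge`` is the dominant phosphate species (0/-1/-2);
    ``residue_charges`` maps 1-based residue indices to their dominant
    integer charges (phosphosites included).
    """

    ph: float
    phosphate_charge: int
    residue_charges: Mapping[int, int] = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if self.phosphate_charge not in (0, -1, -2):
            raise ValueError("phosphate charge must be 0, -1 or -2")


def count_phosphorylatable_sites(variant: PeptideVariant | str) -> int:
    """Number of Ser/Thr/Tyr residues in the sequence (strand E has 6)."""
    seq = variant.sequence if isinstance(variant, PeptideVariant) else variant
    seq = seq.upper()
    bad = sorted(set(seq) - _STANDARD_AA)
    if bad:
        raise InvalidVariantError(f"unknown residue letter(s) {bad!r}")
    return sum(1 for c in seq if c in PHOSPHORYLATABLE)


def _site_charges(
    variant: PeptideVariant, ph: float, model: ChargeModel, mode: str
) -> dict[int, float]:
    charges: dict[int, float] = {}
    for i, aa in enumerate(variant.sequence, start=1):
        if i in variant.phosphosites:
            charges[i] = model.phosphate_charge(ph, mode)
        elif aa == "D":
            charges[i] = model.acid_charge(model.pka_asp, ph, mode)
        elif aa == "E":
            charges[i] = model.acid_charge(model.pka_glu, ph, mode)
        elif aa in model.extra_site_pkas:
            pka, prot_charge = model.extra_site_pkas[aa]
            if prot_charge > 0:
                charges[i] = model.base_charge(pka, ph, mode)
            else:
                charges[i] = model.acid_charge(pka, ph, mode)
    return charges


def net_charge(
    variant: PeptideVariant,
    ph: float,
    model: ChargeModel | None = None,
    mode: str = "dominant",
) -> float:
    """Net peptide charge at the given pH.

    ``dominant`` sums integer dominant-species charges per ionisable site
    (the control peptide goes from 0 at pH 1.1 to -2 at pH 7.5 through
    its Asp and Glu); ``fractional`` sums Henderson-Hasselbalch
    expectations. Capped termini contribute nothing.
    """
    if not 0 < ph < 14:
        raise ValueError(f"pH {ph} outside (0, 14)")
    if mode not in ("dominant", "fractional"):
        raise ValueError(f"unknown mode {mode!r}")
    model = model or ChargeModel()
    total = sum(_site_charges(variant, ph, model, mode).values())
    # uncapped termini: alpha-amino ~9.0, alpha-carboxyl ~3.1
    if not variant.n_term_acetylated:
        total += model.base_charge(9.0, ph, mode)
    if not variant.c_term_amidated:
        total += model.acid_charge(3.1, ph, mode)
    if mode == "dominant":
        return int(round(total))
    return float(total)


def phosphate_charge_state(
    ph: float, model: ChargeModel | None = None
) -> ProtonationState:
    """Dominant phosphate protonation state at a pH (0 / -1 / -2)."""
    if not 0 < ph < 14:
        raise ValueError(f"pH {ph} outside (0, 14)")
    model = model or ChargeModel()
    return ProtonationState(
        ph=ph, phosphate_charge=int(model.phosphate_charge(ph, "dominant"))
    )


def protonation_state(
    variant: PeptideVariant, ph: float, model: ChargeModel | None = None
) -> ProtonationState:
    """Per-residue dominant charges of a variant at a pH."""
    model = model or ChargeModel()
    charges = {
        i: int(c) for i, c in _site_charges(variant, ph, model, "dominant").items()
    }
    return ProtonationState(
        ph=ph,
        phosphate_charge=int(model.phosphate_charge(ph, "dominant")),
        residue_charges=charges,
    )


# --------------------------------------------------------------------------
# variant definitions
# --------------------------------------------------------------------------

_VARIANT_RE = re.compile(
    r"^\s*(?P<name>[\w.+-]+)\s*=\s*(?P<seq>[A-Za-z]+)"
    r"(?:\s*;\s*phos\s*=\s*(?P<phos>[\d,\s]+))?\s*$"
)


def parse_variant(text: str) -> PeptideVariant:
    """Parse a ``NAME=SEQ;phos=3,10`` definition string."""
    m = _VARIANT_RE.match(text)
    if not m:
        raise InvalidVariantError(f"cannot parse variant definition {text!r}")
    phos = frozenset(
        int(tok) for tok in m.group("phos").split(",") if tok.strip()
    ) if m.group("phos") else frozenset()
    return PeptideVariant(m.group("name"), m.group("seq"), phos)


def variants_from_yaml(source: str | io.TextIOBase) -> list[PeptideVariant]:
    """Load variant definitions from YAML.

    Expected form::

        variants:
          - name: p9Y
            sequence: DWSFYLLYYTEFT
            phosphosites: [9]
    """
    data = yaml.safe_load(source if isinstance(source, str) else source.read())
    entries = data.get("variants", data) if isinstance(data, dict) else data
    out = []
    for e in entries:
        out.append(
            PeptideVariant(
                name=e["name"],
                sequence=e.get("sequence", STRAND_E),
                phosphosites=frozenset(e.get("phosphosites", [])),
                n_term_acetylated=e.get("n_term_acetylated", True),
                c_term_amidated=e.get("c_term_amidated", True),
            )
        )
    return out


def table1_variants() -> dict[str, PeptideVariant]:
    """The eight synthesised strand-E variants (control + 7 phosphoforms).

    Single-site variants are named pX by phosphorylated position; the
    double variant carries phosphates on Ser3 and Thr10.
    """
    defs: Iterable[tuple[str, frozenset[int]]] = [
        ("control", frozenset()),
        ("p13T", frozenset({13})),
        ("p10T", frozenset({10})),
        ("p9Y", frozenset({9})),
        ("p8Y", frozenset({8})),
        ("p5Y", frozenset({5})),
        ("p3S", frozenset({3})),
        ("p3S10T", frozenset({3, 10})),
    ]
    return {name: PeptideVariant(name, STRAND_E, sites) for name, sites in defs}
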