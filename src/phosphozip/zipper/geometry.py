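"""Idealized peptide-backbone geometry.

Builds extended beta-strands from internal coordinates (bond lengths, bond
angles, torsions) using the natural-extension reference frame construction.
Only backbone heavy atoms (N, CA, C, O) plus CB are generated; side chains
beyond CB are deliberately absent — all downstream distance metrics need
only CB, and fabricating rotamers without an energy model would add noise,
not information.

Coordinate convention for the canonical strand: strand axis along +x,
residue 1 CA at the origin, odd-residue CB atoms pointing toward +z.
Units are angstroms; residue indices are 1-based.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "Atom",
    "FibrilModel",
    "InvalidSequenceError",
    "build_ideal_strand",
    "AA3",
]

# Standard one-letter -> three-letter residue codes.
AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# Ideal covalent geometry (Engh & Huber style averages, angstroms / degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.530

ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_N_CA_CB = 110.5

OMEGA_TRANS = 180.0

# Default beta-strand dihedrals (degrees).
DEFAULT_PHI = -139.0
DEFAULT_PSI = 135.0


class InvalidSequenceError(ValueError):
    """Sequence contains a letter outside the 20 standard amino acids."""


class Atom(NamedTuple):
    chain: str
    resi: int
    resn: str
    name: str
    x: float
    y: float
    z: float


@dataclasses.dataclass
class FibrilModel:
    """Coordinate model of a strand, sheet or two-sheet steric zipper.

    ``atoms`` is a flat list; ``provenance`` records how the model was built
    (arrangement, zipper class, build parameters, chain->sheet mapping).
    """

    atoms: list[Atom]
    provenance: dict = dataclasses.field(default_factory=dict)

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    def coords(self) -> np.ndarray:
        return np.array([(a.x, a.y, a.z) for a in self.atoms], dtype=float)

    def select(
        self,
        chain: str | None = None,
        resi: int | None = None,
        name: str | None = None,
        chains: Iterable[str] | None = None,
    ) -> list[Atom]:
        chain_set = set(chains) if chains is not None else None
        out = []
        for a in self.atoms:
            if chain is not None and a.chain != chain:
                continue
            if chain_set is not None and a.chain not in chain_set:
                continue
            if resi is not None and a.resi != resi:
                continue
            if name is not None and a.name != name:
                continue
            out.append(a)
        return out

    def sequence(self, chain: str | None = None) -> str:
        ch = chain or self.chains[0]
        rev3 = {v: k for k, v in AA3.items()}
        resn_by_idx: dict[int, str] = {}
        for a in self.atoms:
            if a.chain == ch:
                resn_by_idx[a.resi] = a.resn
        return "".join(rev3[resn_by_idx[i]] for i in sorted(resn_by_idx))

    # -- geometry --------------------------------------------------------
    def transformed(self, rot: np.ndarray, trans: np.ndarray) -> "FibrilModel":
        """Return a copy with coordinates mapped x -> rot @ x + trans."""
        xyz = self.coords() @ np.asarray(rot, dtype=float).T + np.asarray(trans, dtype=float)
        atoms = [
            Atom(a.chain, a.resi, a.resn, a.name, *xyz[i])
            for i, a in enumerate(self.atoms)
        ]
        return FibrilModel(atoms, provenance=dict(self.provenance))

    def with_chain_ids(self, mapping: dict[str, str]) -> "FibrilModel":
        atoms = [
            Atom(mapping.get(a.chain, a.chain), a.resi, a.resn, a.name, a.x, a.y, a.z)
            for a in self.atoms
        ]
        return FibrilModel(atoms, provenance=dict(self.provenance))


def _place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Position atom d given three predecessors and internal coordinates.

    d is at distance ``bond`` from c, with angle b-c-d = ``angle_deg`` and
    torsion a-b-c-d = ``torsion_deg``.
    """
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _backbone(sequence: str, phi: float, psi: float) -> list[dict[str, np.ndarray]]:
    """Raw backbone + CB coordinates, one dict of atom name -> xyz per residue."""
    n_res = len(sequence)
    residues: list[dict[str, np.ndarray]] = []

    # Seed the first residue in an arbitrary frame; the strand is
    # re-oriented afterwards.
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = n0 + np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    residues.append({"N": n0, "CA": ca0, "C": c0})

    for i in range(1, n_res):
        prev = residues[-1]
        n_i = _place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psi)
        ca_i = _place_atom(prev["CA"], prev["C"], n_i, BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
        c_i = _place_atom(prev["C"], n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi)
        residues.append({"N": n_i, "CA": ca_i, "C": c_i})

    # Carbonyl O: in the peptide plane, anti to the next residue's N
    # (torsion N(i+1)-relative = psi + 180). Terminal O uses the same psi.
    for i, res in enumerate(residues):
        res["O"] = _place_atom(
            res["N"], res["CA"], res["C"], BOND_C_O, ANGLE_CA_C_O, psi + 180.0
        )

    # CB: tetrahedral branch off CA. Torsion C(i)-N(i)-CA(i)-CB set for
    # L-chirality (checked in tests via the N-C-CA-CB improper ~ +122.5 deg).
    for i, res in enumerate(residues):
        if sequence[i] != "G":
            res["CB"] = _place_atom(
                res["C"], res["N"], res["CA"], BOND_CA_CB, ANGLE_N_CA_CB, -122.5
            )
    return residues


def _canonical_frame(residues: list[dict[str, np.ndarray]]) -> tuple[np.ndarray, np.ndarray]:
    """Rotation + translation mapping the raw strand into the canonical frame.

    Strand axis (the two-residue repeat translation of CA atoms) -> +x;
    mean odd-residue CB deviation -> +z; residue 1 CA -> origin.
    """
    cas = np.array([r["CA"] for r in residues])
    if len(cas) >= 3:
        reps = cas[2:] - cas[:-2]
        axis = reps.mean(axis=0)
    else:
        axis = cas[-1] - cas[0]
    ex = axis / np.linalg.norm(axis)

    # Reference vector: average CB (or carbonyl O as fallback) offset of
    # odd residues, orthogonalised against the axis.
    offs = []
    for i, r in enumerate(residues):
        if i % 2 == 0 and "CB" in r:
            offs.append(r["CB"] - r["CA"])
    if not offs:
        offs = [residues[0]["O"] - residues[0]["C"]]
    ref = np.mean(offs, axis=0)
    ez = ref - np.dot(ref, ex) * ex
    ez /= np.linalg.norm(ez)
    ey = np.cross(ez, ex)
    rot = np.array([ex, ey, ez])  # rows: new basis -> rot @ v gives new coords
    trans = -rot @ residues[0]["CA"]
    return rot, trans


def build_ideal_strand(
    sequence: str,
    phi: float = DEFAULT_PHI,
    psi: float = DEFAULT_PSI,
    chain: str = "A",
) -> FibrilModel:
    """Build a single extended beta-strand with ideal covalent geometry.

    Parameters
    ----------
    sequence : one-letter amino-acid string.
    phi, psi : backbone dihedrals in degrees, defaults -139/+135
        (antiparallel beta-sheet region of the Ramachandran map).

    Returns
    -------
    FibrilModel in the canonical frame (axis along +x, residue 1 CA at the
    origin, odd-residue CB atoms toward +z). Glycine emits no CB.
    """
    sequence = sequence.upper()
    bad = [c for c in sequence if c not in AA3]
    if bad:
        raise InvalidSequenceError(f"unknown residue letter(s): {bad!r}")
    if not sequence:
        raise InvalidSequenceError("empty sequence")

    residues = _backbone(sequence, phi, psi)
    rot, trans = _canonical_frame(residues)

    atoms: list[Atom] = []
    order = ("N", "CA", "C", "O", "CB")
    for i, res in enumerate(residues):
        resn = AA3[sequence[i]]
        for name in order:
            if name not in res:
                continue
            xyz = rot @ res[name] + trans
            atoms.append(Atom(chain, i + 1, resn, name, *xyz))
    model = FibrilModel(atoms)
    model.provenance = {
        "kind": "strand",
        "sequence": sequence,
        "phi": phi,
        "psi": psi,
        "rise_per_residue": _rise(atoms),
    }
    return model


def _rise(atoms: Sequence[Atom]) -> float:
    cas = [a for a in atoms if a.name == "CA"]
    if len(cas) < 2:
        return 0.0
    return (cas[-1].x - cas[0].x) / (len(cas) - 1)
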