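"""PDB input/output for fibril models and multi-frame trajectories.

Writing produces standard v3.3 ATOM records with one TER per chain;
reading goes through Biopython's parser. Round-trips preserve coordinates
to the format's three decimals along with chain and residue identity.
"""

from __future__ import annotations

import warnings

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning

from .geometry import Atom, FibrilModel

__all__ = ["write_model", "read_model", "read_trajectory", "PDBFormatError", "PDBParseError"]

# PDB fixed-width coordinate field: %8.3f
_COORD_MIN, _COORD_MAX = -999.999, 9999.999

_WATER_RESNAMES = {"HOH", "WAT"}
_ION_RESNAMES = {"NA", "NA+", "SOD"}


class PDBFormatError(ValueError):
    """Model cannot be represented in fixed-width PDB fields."""


class PDBParseError(ValueError):
    def __init__(self, msg: str, line_number: int | None = None):
        super().__init__(msg)
        self.line_number = line_number


def _atom_record(serial: int, a: Atom) -> str:
    for v in (a.x, a.y, a.z):
        if not (_COORD_MIN <= v <= _COORD_MAX):
            raise PDBFormatError(
                f"coordinate {v:.3f} outside PDB fixed-width range "
                f"[{_COORD_MIN}, {_COORD_MAX}]"
            )
    element = a.name[0]
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    return (
        f"ATOM  {serial:5d} {name}{'':1s}{a.resn:>3s} {a.chain:1s}"
        f"{a.resi:4d}    {a.x:8.3f}{a.y:8.3f}{a.z:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}\n"
    )


def write_model(model: FibrilModel, path) -> None:
    """Write a FibrilModel as PDB ATOM records, TER-delimited per chain."""
    lines: list[str] = []
    serial = 1
    chains = model.chains
    by_chain: dict[str, list[Atom]] = {c: [] for c in chains}
    for a in model.atoms:
        by_chain[a.chain].append(a)
    for c in chains:
        last = None
        for a in by_chain[c]:
            lines.append(_atom_record(serial, a))
            serial += 1
            last = a
        if last is not None:
            lines.append(
                f"TER   {serial:5d}      {last.resn:>3s} {last.chain:1s}"
                f"{last.resi:4d}\n"
            )
            serial += 1
    lines.append("END\n")
    with open(path, "w") as fh:
        fh.writelines(lines)


def _prescan(path) -> None:
    """Cheap structural validation so parse errors carry line numbers."""
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise PDBParseError(
                        f"truncated ATOM record at line {ln}", line_number=ln
                    )
                try:
                    float(line[30:38]), float(line[38:46]), float(line[46:54])
                    int(line[22:26])
                except ValueError as exc:
                    raise PDBParseError(
                        f"malformed ATOM fields at line {ln}: {exc}",
                        line_number=ln,
                    ) from exc


def _structure(path):
    _prescan(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        try:
            return parser.get_structure("model", str(path))
        except PDBConstructionException as exc:  # pragma: no cover - rare
            raise PDBParseError(str(exc)) from exc


def _model_to_fibril(bio_model) -> tuple[FibrilModel, np.ndarray, np.ndarray]:
    atoms: list[Atom] = []
    waters: list[tuple[float, float, float]] = []
    ions: list[tuple[float, float, float]] = []
    for chain in bio_model:
        for res in chain:
            resn = res.get_resname().strip()
            if resn in _WATER_RESNAMES:
                for at in res:
                    if at.get_name().startswith(("O", "OW")):
                        waters.append(tuple(at.coord))
                continue
            if resn in _ION_RESNAMES:
                for at in res:
                    ions.append(tuple(at.coord))
                continue
            for at in res:
                x, y, z = at.coord
                atoms.append(
                    Atom(chain.id, res.id[1], resn, at.get_name(),
                         float(x), float(y), float(z))
                )
    return (
        FibrilModel(atoms),
        np.array(waters, dtype=float).reshape(-1, 3),
        np.array(ions, dtype=float).reshape(-1, 3),
    )


def read_model(path) -> FibrilModel:
    """Read the first model of a PDB file as a FibrilModel (waters/ions dropped)."""
    structure = _structure(path)
    bio_models = list(structure)
    if not bio_models:
        raise PDBParseError("no MODEL/ATOM content found")
    fib, _, _ = _model_to_fibril(bio_models[0])
    return fib


def read_trajectory(path) -> list[tuple[FibrilModel, np.ndarray, np.ndarray]]:
    """Read a multi-MODEL PDB; one (peptide, waters, ions) triple per frame.

    Waters are reduced to their oxygen coordinates (HOH/WAT residues);
    sodium ions (NA) are returned separately.
    """
    structure = _structure(path)
    frames = [_model_to_fibril(m) for m in structure]
    if not frames:
        raise PDBParseError("no MODEL/ATOM content found")
    return frames
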