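"""Plate-reader file handling.

Two tabular layouts are accepted:

* wide — first column is time in seconds, every other column one well;
* long — columns (well, time, intensity).

A plate map (YAML) assigns wells to conditions::

    wells:
      A1: {variant: control, ph: 1.1}
      A2: {variant: control, ph: 1.1}
      H12: {blank: true}

Wells marked ``blank: true`` are averaged into the blank curve shared by
every condition on the plate.
"""

from __future__ import annotations

import pandas as pd
import yaml

from .kinetics import KineticCurve, ReplicateSet, average_blanks

__all__ = [
    "read_plate_wide",
    "read_plate_long",
    "load_plate_map",
    "replicate_sets_from_plate",
]


def read_plate_wide(path_or_buf, sep: str | None = None) -> dict[str, KineticCurve]:
    """Read a wide-format plate file (time + one column per well)."""
    df = pd.read_csv(path_or_buf, sep=sep, engine="python")
    tcol = df.columns[0]
    t = df[tcol].to_numpy(dtype=float)
    return {
        str(c): KineticCurve(t, df[c].to_numpy(dtype=float), well_id=str(c))
        for c in df.columns[1:]
    }


def read_plate_long(path_or_buf, sep: str | None = None) -> dict[str, KineticCurve]:
    """Read a long-format plate file with columns (well, time, intensity)."""
    df = pd.read_csv(path_or_buf, sep=sep, engine="python")
    cols = {c.lower(): c for c in df.columns}
    need = [cols.get("well"), cols.get("time"), cols.get("intensity")]
    if any(c is None for c in need):
        raise ValueError("long format needs columns well, time, intensity")
    out = {}
    for well, grp in df.groupby(need[0]):
        grp = grp.sort_values(need[1])
        out[str(well)] = KineticCurve(
            grp[need[1]].to_numpy(dtype=float),
            grp[need[2]].to_numpy(dtype=float),
            well_id=str(well),
        )
    return out


def load_plate_map(source) -> dict[str, dict]:
    data = yaml.safe_load(source if isinstance(source, str) else source.read())
    wells = data.get("wells", data)
    if not isinstance(wells, dict):
        raise ValueError("plate map must map well ids to condition dicts")
    return {str(k): dict(v) for k, v in wells.items()}


def replicate_sets_from_plate(
    curves: dict[str, KineticCurve], plate_map: dict[str, dict]
) -> list[ReplicateSet]:
    """Group well curves into per-(variant, pH) replicate sets.

    Blank wells are averaged into one blank shared by all conditions.
    """
    blanks = [
        curves[w] for w, spec in plate_map.items()
        if spec.get("blank") and w in curves
    ]
    if not blanks:
        raise ValueError("plate map defines no blank wells")
    blank = average_blanks(blanks)
    groups: dict[tuple[str, float], list[KineticCurve]] = {}
    for w, spec in plate_map.items():
        if spec.get("blank") or w not in curves:
            continue
        key = (str(spec["variant"]), float(spec["ph"]))
        groups.setdefault(key, []).append(curves[w])
    return [
        ReplicateSet(tuple(cs), blank, variant=v, ph=p)
        for (v, p), cs in sorted(groups.items())
    ]
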