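"""Tape-method band measurements: phenotype codes, standardization, I/O.

The empirical protocol wraps a tape strip around the last whorl from the
suture to the umbilicus, marks each band's start and end, and measures the
marks with calipers.  Raw distances (mm) are standardized against the
total suture-to-umbilicus distance so shells of different sizes compare
directly; a band's *position* is the midpoint of its interval and its
*width* the interval length, both expressed in percent.

Banding phenotypes use the classical five-position notation read from the
suture downward: a digit marks a present band (``12345`` fully banded,
``00300`` mid-banded), ``0`` an absent band, ``.`` a band present only on
the last part of the shell (partial, e.g. ``1.345``), ``:`` a punctate
band, and parentheses enclose runs of fused bands (``123(45)``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BandState",
    "Phenotype",
    "PhenotypeError",
    "MeasurementRecord",
    "StandardizedBands",
    "parse_phenotype",
    "format_phenotype",
    "standardize",
    "standardize_table",
    "read_measurements",
    "write_standardized",
    "DEFAULT_COLUMNS",
]

N_POSITIONS = 5


class BandState(str, Enum):
    PRESENT = "present"
    ABSENT = "absent"
    PARTIAL = "partial"
    PUNCTATE = "punctate"


class PhenotypeError(ValueError):
    """Malformed banding code; carries the offending character offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


@dataclass(frozen=True)
class Phenotype:
    """Parsed five-position banding code with fusion groups."""

    states: tuple[BandState, ...]
    fusion_groups: tuple[frozenset[int], ...] = ()

    def __post_init__(self) -> None:
        if len(self.states) != N_POSITIONS:
            raise ValueError(f"phenotype needs exactly {N_POSITIONS} positions")
        for g in self.fusion_groups:
            idx = sorted(g)
            if len(idx) < 2 or idx != list(range(idx[0], idx[-1] + 1)):
                raise ValueError(f"fusion group {idx} must be >=2 adjacent bands")
            for i in idx:
                if self.states[i - 1] == BandState.ABSENT:
                    raise ValueError(f"fused band {i} cannot be absent")

    @property
    def present_bands(self) -> tuple[int, ...]:
        """1-based positions scored present, partial or punctate."""
        return tuple(
            i + 1 for i, s in enumerate(self.states) if s != BandState.ABSENT
        )

    @property
    def fused_bands(self) -> frozenset[int]:
        out: set[int] = set()
        for g in self.fusion_groups:
            out |= g
        return frozenset(out)

    @property
    def code(self) -> str:
        return format_phenotype(self)

    def __str__(self) -> str:
        return self.code


def parse_phenotype(code: str) -> Phenotype:
    """Parse a banding code such as ``12345``, ``00300``, ``1.345``,
    ``123(45)`` into a :class:`Phenotype`.

    Raises :class:`PhenotypeError` (with the character offset) for wrong
    length, a digit that disagrees with its position, or unbalanced
    parentheses.
    """
    if not code:
        raise PhenotypeError("empty phenotype code", 0)
    states: list[BandState] = []
    groups: list[frozenset[int]] = []
    group: Optional[list[int]] = None
    for off, ch in enumerate(code):
        if ch == "(":
            if group is not None:
                raise PhenotypeError("nested parenthesis", off)
            group = []
        elif ch == ")":
            if group is None:
                raise PhenotypeError("unmatched closing parenthesis", off)
            if len(group) < 2:
                raise PhenotypeError("fusion group needs at least 2 bands", off)
            groups.append(frozenset(group))
            group = None
        else:
            pos = len(states) + 1
            if pos > N_POSITIONS:
                raise PhenotypeError(f"more than {N_POSITIONS} positions", off)
            if ch == "0":
                states.append(BandState.ABSENT)
            elif ch == ".":
                states.append(BandState.PARTIAL)
            elif ch == ":":
                states.append(BandState.PUNCTATE)
            elif ch.isdigit():
                if int(ch) != pos:
                    raise PhenotypeError(
                        f"digit {ch} at band position {pos}", off
                    )
                states.append(BandState.PRESENT)
            else:
                raise PhenotypeError(f"unexpected character {ch!r}", off)
            if group is not None:
                group.append(pos)
    if group is not None:
        raise PhenotypeError("unclosed parenthesis", len(code))
    if len(states) != N_POSITIONS:
        raise PhenotypeError(
            f"expected {N_POSITIONS} positions, got {len(states)}", len(code)
        )
    try:
        return Phenotype(tuple(states), tuple(groups))
    except ValueError as exc:
        raise PhenotypeError(str(exc), 0) from exc


def format_phenotype(ph: Phenotype) -> str:
    """Inverse of :func:`parse_phenotype` on valid codes."""
    opens = {min(g) for g in ph.fusion_groups}
    closes = {max(g) for g in ph.fusion_groups}
    out = []
    for i, s in enumerate(ph.states, start=1):
        if i in opens:
            out.append("(")
        if s == BandState.ABSENT:
            out.append("0")
        elif s == BandState.PARTIAL:
            out.append(".")
        elif s == BandState.PUNCTATE:
            out.append(":")
        else:
            out.append(str(i))
        if i in closes:
            out.append(")")
    return "".join(out)


@dataclass
class MeasurementRecord:
    """One shell's tape measurements, phenotype and biometrics.

    ``band_marks_mm`` maps a 1-based band position to its (start, end)
    distances from the suture in mm; only measured bands appear.  The
    ``ill_defined`` flag marks shells whose band edges could not be scored
    reliably; fused bands are taken from the phenotype.
    """

    shell_id: str
    species: str
    population: str
    phenotype: Phenotype
    total_mm: float
    band_marks_mm: dict[int, tuple[float, float]]
    height_mm: float = np.nan
    width_mm: float = np.nan
    weight_g: float = np.nan
    ill_defined: bool = False

    def __post_init__(self) -> None:
        if self.species not in ("nemoralis", "hortensis"):
            raise ValueError(f"species must be nemoralis|hortensis, got {self.species!r}")
        if not self.total_mm > 0:
            raise ValueError("total suture-to-umbilicus distance must be positive")
        marks = self.marks_mm
        if len(marks) and not (
            np.all(np.diff(marks) > 0) and marks[0] > 0 and marks[-1] < self.total_mm
        ):
            raise ValueError(
                f"shell {self.shell_id}: marks must be strictly increasing "
                f"within (0, {self.total_mm})"
            )

    @property
    def marks_mm(self) -> np.ndarray:
        """All marks flattened in order along the strip."""
        out = []
        for i in sorted(self.band_marks_mm):
            out.extend(self.band_marks_mm[i])
        return np.asarray(out, dtype=float)

    @property
    def shape(self) -> float:
        """Shell shape as height/width (inverse available downstream)."""
        return self.height_mm / self.width_mm


@dataclass
class StandardizedBands:
    """Band/gap metrics in percent of the suture-to-umbilicus distance.

    Per band (1-based): position (interval midpoint, %) and width (%);
    per gap 1..B+1 along the measured strip: width (%).  Fused or
    ill-defined bands carry NaN for band-level metrics.  The *measured*
    band and gap percentages always partition 100.
    """

    shell_id: str
    positions_pct: dict[int, float]
    widths_pct: dict[int, float]
    gaps_pct: list[float]
    shape: float
    excluded: tuple[int, ...] = ()

    def region_percents(self) -> np.ndarray:
        """Interleaved gap/band/gap/... percentages (measured bands only)."""
        bands = [
            self.widths_pct[i]
            for i in sorted(self.widths_pct)
            if not np.isnan(self.widths_pct[i])
        ]
        out = []
        for g, b in zip(self.gaps_pct, bands + [None]):
            out.append(g)
            if b is not None:
                out.append(b)
        return np.asarray(out)


def standardize(record: MeasurementRecord, shape_inverse: bool = False) -> StandardizedBands:
    """Standardize one record's marks to percent of the strip length.

    Band i occupying ``[start, end]`` mm becomes position
    ``100 * (start + end) / (2 * total)`` and width
    ``100 * (end - start) / total``.  Gaps fill the complement, including
    the suture-side gap before the first measured band and the
    umbilicus-side gap after the last.  Bands belonging to a fusion group,
    or any band on an ill-defined shell, yield NaN metrics (such measures
    are not usable individually) but still shape the gap partition.

    ``shape_inverse=True`` reports width/height instead of height/width.
    """
    total = record.total_mm
    fused = record.phenotype.fused_bands
    positions: dict[int, float] = {}
    widths: dict[int, float] = {}
    gaps: list[float] = []
    prev_end = 0.0
    for i in sorted(record.band_marks_mm):
        start, end = record.band_marks_mm[i]
        gaps.append(100.0 * (start - prev_end) / total)
        if i in fused or record.ill_defined:
            positions[i] = np.nan
            widths[i] = np.nan
        else:
            positions[i] = 100.0 * 0.5 * (start + end) / total
            widths[i] = 100.0 * (end - start) / total
        prev_end = end
    gaps.append(100.0 * (total - prev_end) / total)
    shape = record.shape
    if shape_inverse:
        shape = 1.0 / shape
    excluded = tuple(i for i in positions if np.isnan(positions[i]))
    return StandardizedBands(
        shell_id=record.shell_id,
        positions_pct=positions,
        widths_pct=widths,
        gaps_pct=gaps,
        shape=shape,
        excluded=excluded,
    )


# -- CSV I/O ----------------------------------------------------------------

DEFAULT_COLUMNS = {
    "shell_id": "shell_id",
    "species": "species",
    "population": "population",
    "phenotype": "phenotype",
    "total_mm": "total_mm",
    "height_mm": "height_mm",
    "width_mm": "width_mm",
    "weight_g": "weight_g",
    "flags": "flags",
}

_MANDATORY = ("shell_id", "species", "population", "phenotype", "total_mm")


def read_measurements(
    path: str | Path,
    column_map: Optional[dict[str, str]] = None,
) -> tuple[list[MeasurementRecord], list[tuple[int, str]]]:
    """Read a measurement CSV into typed records.

    Band marks are taken from columns ``b{i}_start_mm`` / ``b{i}_end_mm``
    (blank for absent bands).  A *column_map* adapts files with different
    headers (maps canonical names to file columns).  Bad rows are skipped
    and reported as ``(row_number, message)`` pairs rather than raising.
    """
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    # read as strings: phenotype codes like "00300" must keep leading zeros
    frame = pd.read_csv(path, dtype=str)
    missing = [cmap[k] for k in _MANDATORY if cmap[k] not in frame.columns]
    if missing:
        raise ValueError(f"measurement file missing mandatory columns: {missing}")

    records: list[MeasurementRecord] = []
    errors: list[tuple[int, str]] = []
    for row_no, row in frame.iterrows():
        try:
            phenotype = parse_phenotype(str(row[cmap["phenotype"]]))
            marks: dict[int, tuple[float, float]] = {}
            for i in range(1, N_POSITIONS + 1):
                s_col, e_col = f"b{i}_start_mm", f"b{i}_end_mm"
                if s_col in frame.columns and not pd.isna(row.get(s_col)):
                    marks[i] = (float(row[s_col]), float(row[e_col]))
            flags = str(row.get(cmap["flags"], "") or "")
            records.append(
                MeasurementRecord(
                    shell_id=str(row[cmap["shell_id"]]),
                    species=str(row[cmap["species"]]),
                    population=str(row[cmap["population"]]),
                    phenotype=phenotype,
                    total_mm=float(row[cmap["total_mm"]]),
                    band_marks_mm=marks,
                    height_mm=float(row.get(cmap["height_mm"], np.nan)),
                    width_mm=float(row.get(cmap["width_mm"], np.nan)),
                    weight_g=float(row.get(cmap["weight_g"], np.nan)),
                    ill_defined="ill_defined" in flags,
                )
            )
        except (ValueError, KeyError, TypeError) as exc:
            errors.append((int(row_no), str(exc)))
    return records, errors


def write_measurements(records: Sequence[MeasurementRecord], path: str | Path) -> None:
    """Write records in the canonical CSV dialect."""
    rows = []
    for r in records:
        row = {
            "shell_id": r.shell_id,
            "species": r.species,
            "population": r.population,
            "phenotype": r.phenotype.code,
            "total_mm": r.total_mm,
            "height_mm": r.height_mm,
            "width_mm": r.width_mm,
            "weight_g": r.weight_g,
            "flags": "ill_defined" if r.ill_defined else "",
        }
        for i in range(1, N_POSITIONS + 1):
            start_end = r.band_marks_mm.get(i)
            row[f"b{i}_start_mm"] = start_end[0] if start_end else np.nan
            row[f"b{i}_end_mm"] = start_end[1] if start_end else np.nan
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def standardize_table(
    records: Iterable[MeasurementRecord], shape_inverse: bool = False
) -> pd.DataFrame:
    """Standardize many records into a wide analysis table.

    Columns: shell_id, species, population, phenotype, shape, height_mm,
    weight_g, b{i}_pos / b{i}_w (percent, NaN when absent or excluded) and
    g{j}_w for gaps 1..6 on fully measured five-banded shells (NaN
    otherwise, since gap identity is ambiguous with missing bands).
    """
    rows = []
    for r in records:
        st = standardize(r, shape_inverse=shape_inverse)
        row: dict[str, object] = {
            "shell_id": r.shell_id,
            "species": r.species,
            "population": r.population,
            "phenotype": r.phenotype.code,
            "shape": st.shape,
            "height_mm": r.height_mm,
            "weight_g": r.weight_g,
        }
        for i in range(1, N_POSITIONS + 1):
            row[f"b{i}_pos"] = st.positions_pct.get(i, np.nan)
            row[f"b{i}_w"] = st.widths_pct.get(i, np.nan)
        if len(r.band_marks_mm) == N_POSITIONS:
            for j, g in enumerate(st.gaps_pct, start=1):
                row[f"g{j}_w"] = g
        else:
            for j in range(1, N_POSITIONS + 2):
                row[f"g{j}_w"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def write_standardized(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)
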