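"""Readers and writers for the peak-list dialect and the alignment table.

The input dialect is a delimited text export in the style of ChromaTOF peak
tables: a header row naming the four required columns ``Name``, ``R.T. (s)``
(one cell holding ``"rt1 , rt2"`` in seconds), ``Area`` and ``Spectrum``
(whitespace-separated ``mz:intensity`` tokens). The output alignment table is
a CSV with one row per aligned group and per-sample rt1/rt2/area columns.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

from .model import (
    AlignedGroup,
    AlignmentTable,
    FormatError,
    MalformedSpectrumError,
    MassSpectrum,
    Peak,
    PeakList,
)

log = logging.getLogger("gcalign.io")

__all__ = [
    "Dialect",
    "parse_spectrum",
    "read_peak_list",
    "write_peak_list",
    "write_alignment_table",
    "read_alignment_table",
    "read_truth",
    "write_truth",
]


@dataclass(frozen=True)
class Dialect:
    """Column mapping and options of the peak-list export format.

    Defaults match common ChromaTOF CSV exports; every column name is
    configurable because vendors localise headers. ``round_mz`` collapses
    fragment m/z values to the nearest unit channel (TOF spectra are exported
    at unit resolution), which puts all spectra on a shared integer grid for
    Pearson correlation.
    """

    delimiter: str = ","
    name_col: str = "Name"
    rt_col: str = "R.T. (s)"
    area_col: str = "Area"
    spectrum_col: str = "Spectrum"
    round_mz: bool = True


def parse_spectrum(text: str, *, round_mz: bool = True, context: str = "") -> MassSpectrum:
    """Parse whitespace-separated ``mz:intensity`` tokens into a spectrum.

    Entries come back sorted by m/z with duplicate channels summed.
    Raises :class:`MalformedSpectrumError` on empty/blank input or any
    non-numeric token; ``context`` (e.g. a row number) is appended to the
    error message.
    """
    if text is None or not text.strip():
        raise MalformedSpectrumError(f"empty spectrum{context}")
    pairs: list[tuple[float, float]] = []
    for token in text.split():
        head, sep, tail = token.partition(":")
        if not sep:
            raise MalformedSpectrumError(f"malformed spectrum token {token!r}{context}")
        try:
            mz = float(head)
            inten = float(tail)
        except ValueError:
            raise MalformedSpectrumError(f"non-numeric spectrum token {token!r}{context}") from None
        if round_mz:
            mz = float(round(mz))
        pairs.append((mz, inten))
    return MassSpectrum.from_pairs(pairs)


def _parse_rt_cell(cell: str) -> tuple[float, float]:
    parts = cell.split(",")
    if len(parts) != 2:
        raise ValueError(f"retention-time cell {cell!r} is not 'rt1 , rt2'")
    return float(parts[0].strip()), float(parts[1].strip())


def read_peak_list(
    path: str | Path, dialect: Dialect = Dialect(), sample_id: str | None = None
) -> PeakList:
    """Read one sample's peak list from a delimited text file.

    One :class:`Peak` per well-formed data row, sorted by (rt1, rt2); each
    peak's ``source_ids`` holds its 0-based data-row index. Rows with
    non-positive area or retention time, or with unparseable numeric cells,
    are rejected with a logged warning. A missing required column raises
    :class:`FormatError`.
    """
    path = Path(path)
    sid = sample_id if sample_id is not None else path.stem
    peaks: list[Peak] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=dialect.delimiter)
        header = reader.fieldnames or []
        required = (dialect.name_col, dialect.rt_col, dialect.area_col, dialect.spectrum_col)
        missing = [c for c in required if c not in header]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        for idx, row in enumerate(reader):
            try:
                rt1, rt2 = _parse_rt_cell(row[dialect.rt_col])
                area = float(row[dialect.area_col])
                spectrum = parse_spectrum(
                    row[dialect.spectrum_col], round_mz=dialect.round_mz, context=f" (row {idx})"
                )
            except (ValueError, MalformedSpectrumError) as exc:
                log.warning("%s row %d rejected: %s", path, idx, exc)
                continue
            if rt1 <= 0 or rt2 <= 0 or area <= 0:
                log.warning(
                    "%s row %d rejected: non-positive rt/area (rt1=%g rt2=%g area=%g)",
                    path, idx, rt1, rt2, area,
                )
                continue
            name = (row[dialect.name_col] or "").strip()
            peaks.append(
                Peak(
                    name=name,
                    rt1=rt1,
                    rt2=rt2,
                    area=area,
                    spectrum=spectrum,
                    source_ids=(idx,),
                    uid=f"{sid}:{idx:04d}",
                )
            )
    return PeakList(sample_id=sid, peaks=peaks)


def write_peak_list(sample: PeakList, path: str | Path, dialect: Dialect = Dialect()) -> None:
    """Write a peak list in the input dialect (used by the simulator)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter)
        writer.writerow([dialect.name_col, dialect.rt_col, dialect.area_col, dialect.spectrum_col])
        for peak in sample.peaks:
            assert peak.spectrum is not None
            writer.writerow(
                [
                    peak.name,
                    f"{peak.rt1:.6f} , {peak.rt2:.6f}",
                    f"{peak.area:.6f}",
                    peak.spectrum.to_text(),
                ]
            )


def write_alignment_table(table: AlignmentTable, path: str | Path) -> None:
    """Write the alignment table as CSV.

    Columns: ``group_id, kind, consensus_name`` then per sample
    ``<sid>_rt1, <sid>_rt2, <sid>_area``, then per sample ``<sid>_rows``
    (semicolon-joined source row indices, so the table can be re-linked to a
    ground-truth file). Cells of absent members are empty.
    """
    table.validate()
    path = Path(path)
    header = ["group_id", "kind", "consensus_name"]
    for sid in table.samples:
        header += [f"{sid}_rt1", f"{sid}_rt2", f"{sid}_area"]
    header += [f"{sid}_rows" for sid in table.samples]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for gid, row in enumerate(table.rows):
            cells: list[str] = [str(gid), row.kind, row.consensus_name]
            for sid in table.samples:
                peak = row.members.get(sid)
                if peak is None:
                    cells += ["", "", ""]
                else:
                    cells += [f"{peak.rt1:.6f}", f"{peak.rt2:.6f}", f"{peak.area:.6f}"]
            for sid in table.samples:
                peak = row.members.get(sid)
                cells.append("" if peak is None else ";".join(str(i) for i in peak.source_ids))
            writer.writerow(cells)


def read_alignment_table(path: str | Path) -> AlignmentTable:
    """Read back a written alignment table.

    Member peaks are reconstructed with rt1/rt2/area and source row indices;
    spectra are not stored in the table and come back as ``None``.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        if header[:3] != ["group_id", "kind", "consensus_name"]:
            raise FormatError(f"{path}: not an alignment table")
        triplet_cols = [c for c in header[3:] if not c.endswith("_rows")]
        samples = [c[: -len("_rt1")] for c in triplet_cols[::3]]
        rows: list[AlignedGroup] = []
        for cells in reader:
            members: dict[str, Peak] = {}
            for k, sid in enumerate(samples):
                base = 3 + 3 * k
                if cells[base] == "":
                    continue
                rows_cell = cells[3 + 3 * len(samples) + k]
                source_ids = tuple(int(x) for x in rows_cell.split(";")) if rows_cell else (0,)
                members[sid] = Peak(
                    name=cells[2],
                    rt1=float(cells[base]),
                    rt2=float(cells[base + 1]),
                    area=float(cells[base + 2]),
                    spectrum=None,
                    source_ids=source_ids,
                    uid=f"{sid}:{min(source_ids):04d}",
                )
            rows.append(AlignedGroup(members=members, kind=cells[1], consensus_name=cells[2]))
    return AlignmentTable(rows=rows, samples=samples)


def read_truth(path: str | Path) -> dict[tuple[str, int], str]:
    """Read a ground-truth CSV (columns sample_id, peak_id, compound_id)."""
    truth: dict[tuple[str, int], str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"sample_id", "peak_id", "compound_id"}
        if not required.issubset(reader.fieldnames or []):
            raise FormatError(f"{path}: truth file must have columns {sorted(required)}")
        for row in reader:
            truth[(row["sample_id"], int(row["peak_id"]))] = row["compound_id"]
    return truth


def write_truth(truth: dict[tuple[str, int], str], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "peak_id", "compound_id"])
        for (sid, pid), cid in sorted(truth.items()):
            writer.writerow([sid, pid, cid])
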