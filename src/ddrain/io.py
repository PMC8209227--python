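"""Readers and writers for droplet amplitude tables and plate manifests.

Amplitude files follow the QuantaSoft-style CSV export: one row per
droplet with a ``Ch1 Amplitude`` and a ``Ch2 Amplitude`` column (header
matching is case-insensitive and tolerant of extra columns; an explicit
column mapping can override it).  A plate manifest is a CSV listing one
well per row: the amplitude file, the well's role, sample id, replicate
index and training flag.
"""

from __future__ import annotations

import csv
import os
import re
from typing import Mapping

import numpy as np
import pandas as pd

from .model import Plate, Well, WELL_ROLES

__all__ = [
    "AmplitudeFormatError",
    "ManifestError",
    "read_amplitude_csv",
    "write_amplitude_csv",
    "read_plate_manifest",
    "write_plate_manifest",
]


class AmplitudeFormatError(ValueError):
    """The amplitude CSV is malformed (columns missing or non-numeric)."""


class ManifestError(ValueError):
    """The plate manifest is malformed or references missing files."""


_CH_PATTERNS = {
    "ch1": re.compile(r"^\s*ch\.?\s*1\b.*amplitude|^\s*ch1\s*$", re.IGNORECASE),
    "ch2": re.compile(r"^\s*ch\.?\s*2\b.*amplitude|^\s*ch2\s*$", re.IGNORECASE),
}


def _find_column(columns: list[str], channel: str) -> str:
    pattern = _CH_PATTERNS[channel]
    hits = [c for c in columns if pattern.search(str(c))]
    if not hits:
        raise AmplitudeFormatError(
            f"no column matching {channel!r} amplitude among {list(columns)}"
        )
    if len(hits) > 1:
        raise AmplitudeFormatError(
            f"ambiguous {channel!r} amplitude columns: {hits}"
        )
    return hits[0]


def read_amplitude_csv(
    path: str | os.PathLike,
    *,
    well_id: str | None = None,
    role: str = "sample",
    sample_id: str = "",
    replicate_index: int = 0,
    is_training: bool = False,
    columns: Mapping[str, str] | None = None,
) -> Well:
    """Read one well's droplet amplitudes from a CSV export.

    Parameters
    ----------
    path:
        CSV file with a header row; amplitude columns are located by a
        case-insensitive match on ``Ch1 Amplitude`` / ``Ch2 Amplitude``
        (or bare ``ch1``/``ch2``) unless ``columns`` maps ``"ch1"`` and
        ``"ch2"`` to explicit header names.
    well_id:
        Defaults to the file's stem.

    Returns
    -------
    Well
        Droplets in file row order; the droplet count equals the number
        of data rows.

    Raises
    ------
    AmplitudeFormatError
        Missing/ambiguous amplitude columns, a non-numeric amplitude
        (reported with its data-row number), or an empty data section.
    """
    try:
        frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise AmplitudeFormatError(f"{path}: no droplets (empty file)") from None
    if frame.shape[0] == 0:
        raise AmplitudeFormatError(f"{path}: no droplets (empty data section)")

    cols = list(frame.columns)
    if columns:
        try:
            c1, c2 = columns["ch1"], columns["ch2"]
        except KeyError as exc:
            raise AmplitudeFormatError(f"column mapping must name {exc}") from None
        for c in (c1, c2):
            if c not in cols:
                raise AmplitudeFormatError(f"{path}: mapped column {c!r} not in header {cols}")
    else:
        c1 = _find_column(cols, "ch1")
        c2 = _find_column(cols, "ch2")

    amps = np.empty((frame.shape[0], 2), dtype=float)
    for j, col in enumerate((c1, c2)):
        try:
            # numpy's string parser is correctly rounded (round-trip exact)
            values = frame[col].to_numpy(dtype=np.float64)
        except (ValueError, TypeError):
            coerced = pd.to_numeric(frame[col], errors="coerce").to_numpy(dtype=float)
            bad = int(np.flatnonzero(~np.isfinite(coerced))[0])
            raise AmplitudeFormatError(
                f"{path}: non-numeric amplitude {frame[col].iloc[bad]!r} "
                f"in column {col!r}, data row {bad + 1}"
            ) from None
        bad_idx = np.flatnonzero(~np.isfinite(values))
        if bad_idx.size:
            row = int(bad_idx[0]) + 1  # 1-based data-row number
            raise AmplitudeFormatError(
                f"{path}: non-numeric amplitude {frame[col].iloc[bad_idx[0]]!r} "
                f"in column {col!r}, data row {row}"
            )
        amps[:, j] = values

    if well_id is None:
        well_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return Well(
        well_id=well_id,
        amplitudes=amps,
        role=role,
        sample_id=sample_id,
        replicate_index=replicate_index,
        is_training=is_training,
    )


def write_amplitude_csv(well: Well, path: str | os.PathLike) -> str:
    """Write a well's amplitudes as a two-column CSV.

    Amplitudes are written with 17 significant digits, so a
    read-back reproduces them bit-for-bit.
    """
    if well.n_droplets == 0:
        raise ValueError(f"well {well.well_id!r} has no droplets to write")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["Ch1 Amplitude", "Ch2 Amplitude"])
        for a, b in well.amplitudes:
            writer.writerow([format(a, ".17g"), format(b, ".17g")])
    return os.fspath(path)


_MANIFEST_COLUMNS = ["well_id", "file", "role", "sample_id", "replicate_index", "is_training"]


def read_plate_manifest(path: str | os.PathLike, *, plate_id: str | None = None) -> Plate:
    """Load a plate from a manifest CSV, reading every referenced well.

    The manifest has columns ``well_id, file, role, sample_id,
    replicate_index, is_training``; ``file`` paths are resolved relative
    to the manifest's directory.

    Raises
    ------
    ManifestError
        Duplicate well ids, an unknown role (the message lists the
        allowed roles), or a referenced amplitude file that does not
        exist (the message names the well).
    """
    base = os.path.dirname(os.path.abspath(os.fspath(path)))
    try:
        table = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ManifestError(f"{path}: empty manifest") from None
    missing_cols = [c for c in _MANIFEST_COLUMNS[:3] if c not in table.columns]
    if missing_cols:
        raise ManifestError(f"{path}: manifest lacks required columns {missing_cols}")

    wells: list[Well] = []
    seen: set[str] = set()
    for _, row in table.iterrows():
        wid = row["well_id"]
        if wid in seen:
            raise ManifestError(f"{path}: duplicate well_id {wid!r}")
        seen.add(wid)
        role = row["role"]
        if role not in WELL_ROLES:
            raise ManifestError(
                f"{path}: unknown role {role!r} for well {wid!r}; "
                f"allowed roles: {', '.join(WELL_ROLES)}"
            )
        fpath = row["file"]
        if not os.path.isabs(fpath):
            fpath = os.path.join(base, fpath)
        if not os.path.exists(fpath):
            raise ManifestError(
                f"{path}: amplitude file {row['file']!r} for well {wid!r} not found"
            )
        rep = row.get("replicate_index", "0")
        training = str(row.get("is_training", "")).strip().lower() in {"1", "true", "yes"}
        wells.append(
            read_amplitude_csv(
                fpath,
                well_id=wid,
                role=role,
                sample_id=row.get("sample_id", ""),
                replicate_index=int(rep) if str(rep).strip() else 0,
                is_training=training,
            )
        )
    if plate_id is None:
        plate_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return Plate(plate_id=plate_id, wells=tuple(wells))


def write_plate_manifest(plate: Plate, directory: str | os.PathLike) -> str:
    """Write a plate as one manifest CSV plus one amplitude CSV per well.

    Returns the manifest path (``<plate_id>.manifest.csv`` inside
    ``directory``).
    """
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    manifest_path = os.path.join(directory, f"{plate.plate_id}.manifest.csv")
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_MANIFEST_COLUMNS)
        for well in plate.wells:
            fname = f"{plate.plate_id}_{well.well_id}.csv"
            write_amplitude_csv(well, os.path.join(directory, fname))
            writer.writerow(
                [
                    well.well_id,
                    fname,
                    well.role,
                    well.sample_id,
                    well.replicate_index,
                    int(well.is_training),
                ]
            )
    return manifest_path
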