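"""Reading and writing pedigree tables.

Herdbook exports arrive as delimited text with one row per animal.  The
reader accepts configurable column names, tolerates the usual missing
codes (``""``, ``"0"``, ``"NA"``) and closes the pedigree by appending
phantom founder records for parents that never appear in the id column.
Full birth dates, when supplied, are converted to decimal years so that
generation intervals keep sub-year precision.
"""

from __future__ import annotations

import os
from typing import Mapping

import pandas as pd

from .errors import PedigreeError
from .pedigree import Pedigree

DEFAULT_COLUMNS: Mapping[str, str] = {
    "id": "id",
    "sire": "sire",
    "dam": "dam",
    "sex": "sex",
    "birth_date": "birth_date",
    "birth_year": "birth_year",
}


def _decimal_year(series: pd.Series) -> pd.Series:
    parsed = pd.to_datetime(series, errors="coerce", format="mixed")
    bad = series.notna() & (series.astype(str).str.strip() != "") & parsed.isna()
    if bad.any():
        rows = [int(i) + 2 for i in series.index[bad]]  # +2: header + 1-based
        raise PedigreeError(f"unparseable birth dates at file lines {rows}")
    start = parsed.dt.year.astype("float")
    frac = parsed.dt.dayofyear.astype("float") / 365.25
    return start + frac


def read_pedigree(
    path: str | os.PathLike,
    *,
    sep: str | None = None,
    columns: Mapping[str, str] | None = None,
) -> Pedigree:
    """Read a CSV/TSV pedigree file into a closed :class:`Pedigree`.

    Parameters
    ----------
    path
        Delimited text file with a header row.  The separator is inferred
        from the extension (``.csv`` -> comma, otherwise tab) unless
        ``sep`` is given.
    columns
        Mapping from the roles ``id``, ``sire``, ``dam`` (required) and
        ``sex``, ``birth_date``, ``birth_year`` (optional) to the actual
        column names in the file.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    if sep is None:
        sep = "," if str(path).lower().endswith(".csv") else "\t"

    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, na_values=[])
    raw.columns = [c.strip() for c in raw.columns]
    for role in ("id", "sire", "dam"):
        if colmap[role] not in raw.columns:
            raise PedigreeError(
                f"required column {colmap[role]!r} (role {role}) not found; "
                f"file has {list(raw.columns)}"
            )

    frame = pd.DataFrame(
        {
            "id": raw[colmap["id"]],
            "sire": raw[colmap["sire"]],
            "dam": raw[colmap["dam"]],
        }
    )
    if colmap["sex"] in raw.columns:
        frame["sex"] = raw[colmap["sex"]]
    if colmap["birth_year"] in raw.columns:
        years = raw[colmap["birth_year"]].str.strip().replace("", None)
        numeric = pd.to_numeric(years, errors="coerce")
        bad = years.notna() & numeric.isna()
        if bad.any():
            rows = [int(i) + 2 for i in years.index[bad]]
            raise PedigreeError(f"unparseable birth years at file lines {rows}")
        frame["birth_year"] = numeric
    elif colmap["birth_date"] in raw.columns:
        dates = raw[colmap["birth_date"]].str.strip().replace("", None)
        frame["birth_year"] = _decimal_year(dates)
    return Pedigree(frame)


def write_pedigree(ped: Pedigree, path: str | os.PathLike) -> None:
    """Write the normalized pedigree TSV with ``0`` for missing values."""
    frame = ped.to_frame().copy()
    for col in ("sire", "dam"):
        frame[col] = frame[col].fillna("0")
    def fmt_year(y) -> str:
        if pd.isna(y):
            return "0"
        return str(int(y)) if float(y).is_integer() else f"{float(y):.3f}"

    frame["birth_year"] = [fmt_year(y) for y in frame["birth_year"]]
    frame.to_csv(path, sep="\t", index=False)
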