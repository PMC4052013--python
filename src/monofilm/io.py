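"""Reading and writing delimited π–A isotherm files.

File dialect
------------
Plain text; lines starting with ``#`` carry metadata as ``key: value`` pairs
(recognised keys: ``components``, ``mole_fractions``, ``temperature_C``,
``label``; anything else is preserved verbatim in ``record.extra``).  The
first non-comment line may name the columns (``area_A2,pressure_mN_m``);
otherwise the first two numeric columns are taken as area and pressure.  The
delimiter is auto-detected among comma, tab, semicolon and whitespace, since
trough-software exports vary.

Areas may be declared in nm²/molecule (``area_unit="nm2"`` or a header column
named ``area_nm2``); they are converted to the internal Å²/molecule on read.
"""

from __future__ import annotations

import os
from typing import Optional, Union

from .errors import IsothermParseError, ValidationError
from .records import CompositionTriple, IsothermRecord

__all__ = ["read_isotherm", "write_isotherm"]

_META_KEYS = ("components", "mole_fractions", "temperature_C", "label")


def _detect_delimiter(line: str) -> Optional[str]:
    counts = {d: line.count(d) for d in (",", "\t", ";")}
    best = max(counts, key=counts.get)
    return best if counts[best] > 0 else None  # None → whitespace split


def _split(line: str, delim: Optional[str]) -> list[str]:
    parts = line.split(delim) if delim else line.split()
    return [p.strip() for p in parts if p.strip() != ""]


def read_isotherm(
    path: Union[str, os.PathLike],
    *,
    area_unit: str = "A2",
    area_column: Optional[int] = None,
    pressure_column: Optional[int] = None,
) -> IsothermRecord:
    """Read and canonicalize one isotherm file.

    Parameters
    ----------
    path : str or path-like
        Delimited text file with at least two numeric columns.
    area_unit : {"A2", "nm2"}
        Unit of the area column; nm²/molecule is multiplied by 100.
    area_column, pressure_column : int, optional
        Zero-based column indices, overriding header names / defaults (0, 1).

    Raises
    ------
    IsothermParseError
        On a non-numeric or short row; the message names the line number.
    ValidationError
        When the parsed points violate the isotherm invariants.
    """
    meta: dict[str, str] = {}
    data_lines: list[tuple[int, str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    meta[key.strip()] = value.strip()
                continue
            data_lines.append((lineno, line))

    if not data_lines:
        raise IsothermParseError(f"{path}: no data rows found")

    delim = _detect_delimiter(data_lines[0][1])

    # Optional header row naming the columns.
    header_tokens = _split(data_lines[0][1], delim)
    has_header = False
    try:
        [float(t) for t in header_tokens]
    except ValueError:
        has_header = True

    a_col, p_col = area_column, pressure_column
    if has_header:
        names = [t.lower() for t in header_tokens]
        for i, name in enumerate(names):
            if "area" in name and a_col is None:
                a_col = i
                if name.endswith("nm2"):
                    area_unit = "nm2"
            elif "pressure" in name and p_col is None:
                p_col = i
        data_lines = data_lines[1:]
    a_col = 0 if a_col is None else a_col
    p_col = 1 if p_col is None else p_col

    areas: list[float] = []
    pressures: list[float] = []
    for lineno, line in data_lines:
        tokens = _split(line, delim)
        if len(tokens) <= max(a_col, p_col):
            raise IsothermParseError(
                f"{path}: line {lineno}: expected at least {max(a_col, p_col) + 1} columns, got {len(tokens)}"
            )
        try:
            a = float(tokens[a_col])
            p = float(tokens[p_col])
        except ValueError as exc:
            raise IsothermParseError(f"{path}: line {lineno}: non-numeric value ({exc})") from None
        areas.append(a)
        pressures.append(p)

    if area_unit == "nm2":
        areas = [a * 100.0 for a in areas]
    elif area_unit != "A2":
        raise ValidationError(f"unknown area unit {area_unit!r}; use 'A2' or 'nm2'")

    composition = None
    if "mole_fractions" in meta:
        try:
            x1, x2, x3 = (float(v) for v in meta["mole_fractions"].replace(";", ",").split(","))
        except ValueError:
            raise IsothermParseError(f"{path}: malformed mole_fractions metadata {meta['mole_fractions']!r}")
        composition = CompositionTriple(x1, x2, x3)
    temperature = float(meta.get("temperature_C", 37.0))
    label = meta.get("label", "")
    extra = {k: v for k, v in meta.items() if k not in _META_KEYS}

    return IsothermRecord.from_points(
        areas,
        pressures,
        composition=composition,
        temperature_c=temperature,
        label=label,
        source=str(path),
        extra=extra,
    )


def write_isotherm(record: IsothermRecord, path: Union[str, os.PathLike]) -> str:
    """Write a record so that ``read_isotherm`` reproduces it.

    Points survive the round trip to better than 1e-9 (17 significant digits)
    and metadata exactly.
    """
    record.validate()
    lines = []
    lines.append("# components: cholesterol,POPC,APC")
    if record.composition is not None:
        c = record.composition
        lines.append(f"# mole_fractions: {c.x1!r},{c.x2!r},{c.x3!r}")
    lines.append(f"# temperature_C: {record.temperature_c!r}")
    if record.label:
        lines.append(f"# label: {record.label}")
    for key, value in record.extra.items():
        lines.append(f"# {key}: {value}")
    lines.append("area_A2,pressure_mN_m")
    for a, p in zip(record.area, record.pressure):
        lines.append(f"{float(a):.17g},{float(p):.17g}")
    text = "\n".join(lines) + "\n"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)
    return str(path)
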