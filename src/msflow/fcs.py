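"""Minimal reader for FCS 2.0 / 3.0 / 3.1 list-mode files.

Covers the subset of the Flow Cytometry Standard needed to ingest
exported cytometer data: the fixed-width ASCII header, the delimited
TEXT segment (with doubled-delimiter escaping), and list-mode DATA
segments of type ``F`` (float32), ``D`` (float64) or ``I`` (unsigned
integers of uniform 8/16/32/64-bit width), in either byte order.

Out of scope, by design: FCS writing, spectral compensation ($SPILLOVER
is read but not applied), gain/log amplification ($PnE is not applied),
and multi-dataset files (only the first dataset is read).
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np

__all__ = ["FCSFormatError", "parse_fcs", "channel_names"]

_SUPPORTED_VERSIONS = ("FCS2.0", "FCS3.0", "FCS3.1")


class FCSFormatError(ValueError):
    """Raised when a file cannot be parsed as a supported FCS version."""


def _read_offset(header: bytes, lo: int, hi: int) -> int:
    txt = header[lo:hi].decode("ascii", errors="replace").strip()
    if not txt:
        return 0
    try:
        return int(txt)
    except ValueError as exc:
        raise FCSFormatError(f"malformed header offset field {txt!r}") from exc


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    # first byte of the segment is the delimiter; doubled delimiters
    # inside a value are an escape for a literal delimiter
    if not raw:
        raise FCSFormatError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    tokens = body.split(delim)
    # re-join tokens emptied by the doubled-delimiter escape
    merged: list[str] = []
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        while i + 1 < len(tokens) and tokens[i + 1] == b"":
            # escaped delimiter: "" came from delim+delim inside a value
            if i + 2 < len(tokens):
                tok = tok + delim + tokens[i + 2]
                i += 2
            else:
                tok = tok + delim
                i += 1
        merged.append(tok.decode("utf-8", errors="replace"))
        i += 1
    if len(merged) % 2 != 0:
        merged.append("")
    keywords: dict[str, str] = {}
    for k, v in zip(merged[::2], merged[1::2]):
        keywords[k.strip().upper()] = v.strip()
    return keywords


def parse_fcs(path: str | os.PathLike) -> tuple[dict[str, str], np.ndarray]:
    """Parse an FCS file into (TEXT keywords, events matrix).

    The returned matrix has ``$TOT`` rows (events) and ``$PAR`` columns
    (channels), as float64 regardless of the on-disk datatype.
    """
    with open(path, "rb") as fh:
        blob = fh.read()
    if len(blob) < 58:
        raise FCSFormatError(f"{path}: too short to hold an FCS header")
    version = blob[0:6].decode("ascii", errors="replace")
    if version not in _SUPPORTED_VERSIONS:
        raise FCSFormatError(
            f"{path}: unsupported or missing FCS version marker {version!r}"
        )
    text_begin = _read_offset(blob, 10, 18)
    text_end = _read_offset(blob, 18, 26)
    data_begin = _read_offset(blob, 26, 34)
    data_end = _read_offset(blob, 34, 42)
    if text_begin <= 0 or text_end <= text_begin:
        raise FCSFormatError(f"{path}: invalid TEXT segment offsets")
    keywords = _parse_text_segment(blob[text_begin:text_end + 1])

    # FCS 3.x may put zero in the header and the real offsets in TEXT
    if data_begin == 0 and "$BEGINDATA" in keywords:
        data_begin = int(keywords["$BEGINDATA"])
    if data_end == 0 and "$ENDDATA" in keywords:
        data_end = int(keywords["$ENDDATA"])
    if data_begin <= 0 or data_end < data_begin:
        raise FCSFormatError(f"{path}: invalid DATA segment offsets")

    mode = keywords.get("$MODE", "L").upper()
    if mode != "L":
        raise FCSFormatError(f"{path}: only list mode ($MODE=L) is supported")
    try:
        n_par = int(keywords["$PAR"])
        n_tot = int(keywords["$TOT"])
        datatype = keywords["$DATATYPE"].upper()
    except KeyError as exc:
        raise FCSFormatError(f"{path}: missing required keyword {exc}") from exc

    byteord = keywords.get("$BYTEORD", "1,2,3,4")
    if byteord.startswith("1"):
        endian = "<"
    elif byteord.startswith("4") or byteord.startswith("2"):
        endian = ">"
    else:
        raise FCSFormatError(f"{path}: unsupported $BYTEORD {byteord!r}")

    if datatype == "F":
        dtype = np.dtype(endian + "f4")
    elif datatype == "D":
        dtype = np.dtype(endian + "f8")
    elif datatype == "I":
        bits = {int(keywords.get(f"$P{i}B", "16")) for i in range(1, n_par + 1)}
        if len(bits) != 1 or bits.pop() not in (8, 16, 32, 64):
            raise FCSFormatError(
                f"{path}: integer data requires one uniform $PnB of 8/16/32/64"
            )
        nbytes = int(keywords["$P1B"]) // 8
        dtype = np.dtype(f"{endian}u{nbytes}")
    else:
        raise FCSFormatError(f"{path}: unsupported $DATATYPE {datatype!r}")

    needed = n_par * n_tot * dtype.itemsize
    segment = blob[data_begin:data_begin + needed]
    if len(segment) < needed:
        raise FCSFormatError(
            f"{path}: DATA segment truncated ({len(segment)} < {needed} bytes)"
        )
    events = np.frombuffer(segment, dtype=dtype).reshape(n_tot, n_par)
    return keywords, events.astype(np.float64)


def channel_names(keywords: dict[str, str]) -> list[str]:
    """Channel names: marker name $PnS when present, else short name $PnN."""
    n_par = int(keywords["$PAR"])
    names = []
    for i in range(1, n_par + 1):
        name = keywords.get(f"$P{i}S") or keywords.get(f"$P{i}N") or f"P{i}"
        names.append(name)
    return names
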