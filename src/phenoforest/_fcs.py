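"""Minimal list-mode FCS 2.0/3.0/3.1 reader.

Reads the TEXT segment and the uncompensated, untransformed DATA segment
of list-mode files with float, double, or fixed-width integer events.
Deliberately small: no compensation, no transforms, no ANALYSIS segment,
no writing.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

__all__ = ["read_fcs"]


def _parse_text(raw: bytes) -> dict:
    if not raw:
        raise ValueError("empty TEXT segment")
    delim = raw[0:1]
    # delimiter-separated key/value pairs; doubled delimiters inside
    # values are rare and unsupported here
    parts = raw[1:].split(delim)
    if parts and parts[-1] == b"":
        parts = parts[:-1]
    kv = {}
    for i in range(0, len(parts) - 1, 2):
        key = parts[i].decode("latin-1").strip().upper()
        kv[key] = parts[i + 1].decode("latin-1").strip()
    return kv


def read_fcs(path):
    """Read an FCS file; returns (marker_names, values, text_keywords).

    Marker names prefer the stain keyword $PnS and fall back to the
    detector name $PnN; a collision between resolved names is an error.
    """
    path = Path(path)
    blob = path.read_bytes()
    version = blob[0:6].decode("latin-1", "replace")
    if not version.startswith("FCS"):
        raise ValueError(f"{path.name}: not an FCS file (header {version!r})")

    def _off(a, b):
        return int(blob[a:b].decode("latin-1").strip() or 0)

    t0, t1 = _off(10, 18), _off(18, 26)
    d0, d1 = _off(26, 34), _off(34, 42)
    text = _parse_text(blob[t0 : t1 + 1])
    if d0 == 0 and "$BEGINDATA" in text:
        d0 = int(text["$BEGINDATA"])
        d1 = int(text["$ENDDATA"])
    npar = int(text["$PAR"])
    tot = int(text["$TOT"])
    dtype_code = text.get("$DATATYPE", "F").upper()
    byteord = text.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")
    order = "<" if little else ">"
    if text.get("$MODE", "L").upper() != "L":
        raise ValueError(f"{path.name}: only list-mode FCS is supported")

    names = []
    for i in range(1, npar + 1):
        stain = text.get(f"$P{i}S", "").strip()
        detector = text.get(f"$P{i}N", "").strip()
        names.append(stain or detector or f"P{i}")
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(
            f"{path.name}: duplicate marker names after $PnS/$PnN "
            f"resolution: {dup}"
        )

    data = blob[d0 : d1 + 1]
    if dtype_code == "F":
        arr = np.frombuffer(data[: tot * npar * 4], dtype=order + "f4")
        values = arr.astype(np.float64).reshape(tot, npar)
    elif dtype_code == "D":
        arr = np.frombuffer(data[: tot * npar * 8], dtype=order + "f8")
        values = arr.astype(np.float64).reshape(tot, npar)
    elif dtype_code == "I":
        bits = {int(text[f"$P{i}B"]) for i in range(1, npar + 1)}
        if len(bits) != 1:
            raise ValueError(
                f"{path.name}: mixed integer widths are not supported"
            )
        nbytes = bits.pop() // 8
        code = {2: "u2", 4: "u4"}.get(nbytes)
        if code is None:
            raise ValueError(f"{path.name}: unsupported $PnB width")
        arr = np.frombuffer(data[: tot * npar * nbytes], dtype=order + code)
        values = arr.astype(np.float64).reshape(tot, npar)
    else:
        raise ValueError(f"{path.name}: unsupported $DATATYPE {dtype_code!r}")
    return names, values, text


def write_fcs_for_tests(path, markers, values):
    """Write a small FCS 3.0 float file (test fixture helper only)."""
    values = np.asarray(values, dtype="<f4")
    tot, npar = values.shape
    kv = {
        "$DATATYPE": "F",
        "$MODE": "L",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(npar),
        "$TOT": str(tot),
        "$NEXTDATA": "0",
    }
    for i, m in enumerate(markers, 1):
        kv[f"$P{i}N"] = f"FL{i}-A"
        kv[f"$P{i}S"] = m
        kv[f"$P{i}B"] = "32"
        kv[f"$P{i}E"] = "0,0"
        kv[f"$P{i}R"] = "262144"
    text = "/" + "/".join(f"{k}/{v}" for k, v in kv.items()) + "/"
    header_len = 58
    text_start = header_len
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + values.nbytes - 1
    header = (
        b"FCS3.0    "
        + f"{text_start:8d}".encode()
        + f"{text_end:8d}".encode()
        + f"{data_start:8d}".encode()
        + f"{data_end:8d}".encode()
        + f"{0:8d}".encode()
        + f"{0:8d}".encode()
    )
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text.encode("latin-1"))
        fh.write(values.tobytes())
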