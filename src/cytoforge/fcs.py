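"""Minimal FCS 3.0/3.1 list-mode reader and writer.

Supports the subset of the Flow Cytometry Standard that mass-cytometry
pipelines actually exchange: a single list-mode dataset per file, TEXT +
DATA segments, float (``$DATATYPE/F``), double (``/D``) or unsigned-integer
(``/I``, 16/32 bit) storage, and either byte order.  Channel names come from
``$PnS`` (stain name) falling back to ``$PnN`` (short name).  Writing always
emits FCS 3.1 little-endian float32 with both ``$PnN`` and ``$PnS`` set, and
is deterministic (no timestamps), so re-writing re-read data is
byte-identical.

Out of scope: FCS 2.0, multi-dataset files (``$NEXTDATA`` != 0 on read is an
error), ANALYSIS segments, bit-packed integers, and gating metadata.
"""

from __future__ import annotations

import numpy as np

from .errors import FormatError

_DELIM = b"/"


def _parse_text(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FormatError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    # trailing delimiter closes the last value
    if body.endswith(delim):
        body = body[:-1]
    parts = body.split(delim)
    if len(parts) % 2 != 0:
        raise FormatError("TEXT segment has an odd number of delimited tokens")
    out: dict[str, str] = {}
    for k, v in zip(parts[0::2], parts[1::2]):
        out[k.decode("utf-8", "replace").strip().upper()] = v.decode("utf-8", "replace").strip()
    return out


def _require(text: dict[str, str], key: str) -> str:
    try:
        return text[key]
    except KeyError:
        raise FormatError(f"required keyword {key} missing from TEXT segment") from None


def _int_kw(text: dict[str, str], key: str) -> int:
    val = _require(text, key)
    try:
        return int(val)
    except ValueError:
        raise FormatError(f"keyword {key} is not an integer: {val!r}") from None


def read_fcs(path) -> tuple[np.ndarray, list[str], dict[str, str]]:
    """Read an FCS file.

    Returns ``(values, names, text)`` where *values* is a float64 array of
    shape (events, parameters), *names* are per-channel names ($PnS falling
    back to $PnN), and *text* is the full TEXT keyword dictionary.
    """
    with open(path, "rb") as fh:
        blob = fh.read()
    if len(blob) < 58:
        raise FormatError("file too short to hold an FCS HEADER")
    version = blob[:6].decode("ascii", "replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FormatError(f"unsupported FCS version {version!r} (keyword: HEADER version)")

    def _offset(lo: int, hi: int, what: str) -> int:
        field = blob[lo:hi].decode("ascii", "replace").strip()
        if field == "":
            return 0
        try:
            return int(field)
        except ValueError:
            raise FormatError(f"non-numeric {what} offset in HEADER: {field!r}") from None

    text_start = _offset(10, 18, "TEXT start")
    text_end = _offset(18, 26, "TEXT end")
    data_start = _offset(26, 34, "DATA start")
    data_end = _offset(34, 42, "DATA end")
    if text_start <= 0 or text_end <= text_start:
        raise FormatError("invalid TEXT segment offsets in HEADER")
    text = _parse_text(blob[text_start : text_end + 1])

    if text.get("$NEXTDATA", "0") not in ("0", ""):
        raise FormatError("multi-dataset files ($NEXTDATA != 0) are not supported")
    mode = text.get("$MODE", "L")
    if mode != "L":
        raise FormatError(f"only list mode is supported ($MODE = {mode!r})")

    if data_start == 0 or data_end == 0:
        data_start = _int_kw(text, "$BEGINDATA")
        data_end = _int_kw(text, "$ENDDATA")
    n_par = _int_kw(text, "$PAR")
    n_tot = _int_kw(text, "$TOT")
    dtype_code = _require(text, "$DATATYPE")
    byteord = _require(text, "$BYTEORD")
    if byteord in ("1,2,3,4", "1,2"):
        endian = "<"
    elif byteord in ("4,3,2,1", "2,1"):
        endian = ">"
    else:
        raise FormatError(f"unsupported $BYTEORD {byteord!r}")

    bits = [_int_kw(text, f"$P{i}B") for i in range(1, n_par + 1)]
    if dtype_code == "F":
        if any(b != 32 for b in bits):
            raise FormatError("$DATATYPE/F requires $PnB/32 for every channel")
        np_dtype = np.dtype(endian + "f4")
    elif dtype_code == "D":
        if any(b != 64 for b in bits):
            raise FormatError("$DATATYPE/D requires $PnB/64 for every channel")
        np_dtype = np.dtype(endian + "f8")
    elif dtype_code == "I":
        if len(set(bits)) != 1 or bits[0] not in (16, 32):
            raise FormatError("$DATATYPE/I supported only with uniform $PnB of 16 or 32")
        np_dtype = np.dtype(endian + ("u2" if bits[0] == 16 else "u4"))
    else:
        raise FormatError(f"unsupported $DATATYPE {dtype_code!r}")

    expected = n_tot * n_par * np_dtype.itemsize
    raw = blob[data_start : data_end + 1]
    if len(raw) < expected:
        raise FormatError(
            f"DATA segment holds {len(raw)} bytes but $TOT*$PAR requires {expected}"
        )
    values = np.frombuffer(raw[:expected], dtype=np_dtype).reshape(n_tot, n_par).astype(np.float64)

    names = []
    for i in range(1, n_par + 1):
        name = text.get(f"$P{i}S") or text.get(f"$P{i}N")
        if not name:
            raise FormatError(f"channel {i} has neither $P{i}S nor $P{i}N")
        names.append(name.strip())
    return values, names, text


def write_fcs(path, values: np.ndarray, names: list[str], extra_text: dict[str, str] | None = None) -> None:
    """Write a single list-mode FCS 3.1 dataset (little-endian float32)."""
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2:
        raise FormatError("values must be a 2-D events x parameters array")
    n_tot, n_par = values.shape
    if n_par == 0:
        raise FormatError("cannot write an FCS file with zero parameters")
    if len(names) != n_par:
        raise FormatError(f"{len(names)} names for {n_par} parameters")
    data = values.astype("<f4").tobytes()

    kw: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
    }
    finite = values[np.isfinite(values)]
    top = float(finite.max()) if finite.size else 0.0
    rng = str(int(np.ceil(top)) + 1)
    for i, name in enumerate(names, start=1):
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}N"] = name
        kw[f"$P{i}S"] = name
        kw[f"$P{i}R"] = rng
    if extra_text:
        kw.update(extra_text)

    delim = _DELIM.decode()
    for k, v in kw.items():
        if delim in k or delim in v:
            raise FormatError(f"keyword {k!r} or its value contains the delimiter {delim!r}")
        if v == "":
            raise FormatError(f"keyword {k!r} has an empty value (not representable)")

    # Two-pass offset fill: fixed-width zero-padded offsets keep TEXT length stable.
    def render(begin_data: int, end_data: int) -> bytes:
        items = dict(kw)
        items["$BEGINDATA"] = f"{begin_data:010d}"
        items["$ENDDATA"] = f"{end_data:010d}"
        body = delim + delim.join(f"{k}{delim}{v}" for k, v in sorted(items.items())) + delim
        return body.encode("utf-8")

    text_start = 58
    probe = render(0, 0)
    text_end = text_start + len(probe) - 1
    begin_data = text_end + 1
    end_data = begin_data + len(data) - 1
    text_seg = render(begin_data, end_data)
    assert len(text_seg) == len(probe)

    def hfield(x: int) -> bytes:
        s = str(x)
        if len(s) > 8:
            s = "0"  # too large for HEADER; TEXT keywords carry the true offsets
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + hfield(text_start) + hfield(text_end)
    if end_data <= 99_999_999:
        header += hfield(begin_data) + hfield(end_data)
    else:
        header += hfield(0) + hfield(0)
    header += hfield(0) + hfield(0)
    assert len(header) == 58

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text_seg)
        fh.write(data)
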