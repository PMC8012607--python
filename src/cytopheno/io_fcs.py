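"""Minimal FCS 3.0 reader/writer.

This is the package's own small implementation covering the subset of the
flow-cytometry standard the pipeline needs: a single dataset, list mode,
little-endian float32 data, no analysis segment.  It exists for round-trip
export/import of simulated raw-scale intensities; files written by vendor
software with integer data types or multiple datasets are out of scope.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_DELIM = "/"


def write_fcs(path, data: pd.DataFrame) -> None:
    """Write a cells x channels table as a single-dataset FCS 3.0 file."""
    arr = np.ascontiguousarray(data.to_numpy(dtype=np.float32))
    n_cells, n_par = arr.shape
    kw = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_cells),
    }
    for i, name in enumerate(data.columns, start=1):
        if _DELIM in str(name):
            raise ValueError(f"channel name contains the delimiter {_DELIM!r}: {name}")
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}N"] = str(name)
        kw[f"$P{i}R"] = str(int(np.ceil(max(1.0, float(np.nanmax(arr[:, i - 1], initial=1.0))))))

    def render_text(begin_data: int, end_data: int) -> bytes:
        items = dict(kw)
        items["$BEGINDATA"] = str(begin_data)
        items["$ENDDATA"] = str(end_data)
        parts = [_DELIM]
        for k in sorted(items):
            parts.append(f"{k}{_DELIM}{items[k]}{_DELIM}")
        return "".join(parts).encode("ascii")

    header_len = 58  # "FCS3.0" + 4 spaces + 6 x 8-byte offsets
    text_start = header_len
    # text length depends on the data offsets it embeds; iterate to fixpoint
    begin_data = end_data = 0
    for _ in range(8):
        text = render_text(begin_data, end_data)
        new_begin = text_start + len(text)
        new_end = new_begin + arr.nbytes - 1
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end
    text = render_text(begin_data, end_data)
    text_end = text_start + len(text) - 1

    def off(x: int) -> bytes:
        s = str(x)
        if len(s) > 8:
            s = "0"  # exceeds header field width; reader falls back to TEXT keywords
        return s.rjust(8).encode("ascii")

    with open(path, "wb") as fh:
        fh.write(b"FCS3.0    ")
        fh.write(off(text_start) + off(text_end))
        fh.write(off(begin_data if begin_data <= 99999999 else 0))
        fh.write(off(end_data if end_data <= 99999999 else 0))
        fh.write(off(0) + off(0))
        fh.write(text)
        fh.write(arr.astype("<f4").tobytes())


def read_fcs(path) -> pd.DataFrame:
    """Read a single-dataset FCS 3.0/3.1 file written with float data."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if not raw[:6] in (b"FCS3.0", b"FCS3.1"):
        raise IOError(f"not an FCS 3.x file: {path}")
    text_start = int(raw[10:18])
    text_end = int(raw[18:26])
    text = raw[text_start : text_end + 1].decode("ascii", errors="replace")
    delim = text[0]
    fields = text[1:].split(delim)
    kw = {fields[i].strip(): fields[i + 1] for i in range(0, len(fields) - 1, 2)}
    if kw.get("$DATATYPE") != "F":
        raise IOError("only $DATATYPE/F (float) FCS files are supported")
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    begin = int(raw[26:34].strip() or 0) or int(kw["$BEGINDATA"])
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    dtype = "<f4" if byteord.startswith("1") else ">f4"
    arr = np.frombuffer(raw, dtype=dtype, count=n_par * n_tot, offset=begin)
    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    return pd.DataFrame(arr.reshape(n_tot, n_par).astype(float), columns=names)
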