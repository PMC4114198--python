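"""Minimal synthetic EDF writer, test-only.

Produces standards-conforming EDF files from a channels x samples matrix
so the reader can be exercised without real recordings.  16-bit digital
range, symmetric per-channel physical range (quantisation step =
full-scale / 2**15).
"""

from __future__ import annotations

import numpy as np


def _pad(s: str, n: int) -> bytes:
    b = s.encode("ascii")
    if len(b) > n:
        raise ValueError(f"field too long: {s!r}")
    return b + b" " * (n - len(b))


def write_edf(path, data: np.ndarray, fs: float, labels=None,
              record_s: float = 1.0, samples_per_record=None) -> np.ndarray:
    """Write ``data`` (C x T, microvolts) as EDF; returns the quantised
    physical values actually stored (C x T_written).

    ``samples_per_record`` may be a per-channel list to produce a
    (deliberately invalid for this toolbox) mixed-rate file.
    """
    data = np.asarray(data, dtype=float)
    C, T = data.shape
    if labels is None:
        labels = [f"EEG ch{i + 1}" for i in range(C)]
    if samples_per_record is None:
        spr = [int(round(fs * record_s))] * C
    else:
        spr = [int(s) for s in samples_per_record]
    n_records = T // max(spr)
    if n_records < 1:
        raise ValueError("not enough samples for one record")

    pmax = np.maximum(np.abs(data).max(axis=1), 1e-6)
    pmin = -pmax
    dmax, dmin = 32767, -32768
    scale = (pmax - pmin) / (dmax - dmin)

    header = b"".join([
        _pad("0", 8), _pad("X X X X", 80), _pad("Startdate 01-JAN-2024", 80),
        _pad("01.01.24", 8), _pad("00.00.00", 8),
        _pad(str(256 + C * 256), 8), _pad("", 44),
        _pad(str(n_records), 8), _pad(str(record_s), 8), _pad(str(C), 4),
    ])
    sig = b"".join([
        b"".join(_pad(l, 16) for l in labels),
        b"".join(_pad("AgAgCl electrode", 80) for _ in range(C)),
        b"".join(_pad("uV", 8) for _ in range(C)),
        b"".join(_pad(f"{pmin[i]:.6g}"[:8], 8) for i in range(C)),
        b"".join(_pad(f"{pmax[i]:.6g}"[:8], 8) for i in range(C)),
        b"".join(_pad(str(dmin), 8) for _ in range(C)),
        b"".join(_pad(str(dmax), 8) for _ in range(C)),
        b"".join(_pad("", 80) for _ in range(C)),
        b"".join(_pad(str(s), 8) for s in spr),
        b"".join(_pad("", 32) for _ in range(C)),
    ])

    digital = np.empty_like(data, dtype=np.int16)
    for i in range(C):
        d = np.round((data[i] - pmin[i]) / scale[i]) + dmin
        digital[i] = np.clip(d, dmin, dmax).astype(np.int16)

    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_records):
            for i in range(C):
                s = spr[i]
                seg = digital[i, r * s:(r + 1) * s]
                if len(seg) < s:
                    seg = np.pad(seg, (0, s - len(seg)))
                fh.write(seg.astype("<i2").tobytes())

    stored = (digital.astype(float) - dmin) * scale[:, None] + pmin[:, None]
    return stored[:, : n_records * max(spr)]
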