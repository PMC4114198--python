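"""Readers/writers for recordings, montages, annotations and models.

Native format: a delimited-text matrix ``<name>.dat`` (rows = channels,
columns = samples) plus a JSON sidecar ``<name>.json`` holding ``fs``,
``labels`` and optional ``positions``.  Annotation files are one record
per line, ``sample<TAB>tag``.  EDF reading is a convenience for real EEG
containers and goes through :mod:`mne`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import scipy.signal

from .core import (
    BeatAnnotations,
    ChannelSubset,
    EventSchedule,
    InferenceModel,
    Recording,
    ValidationError,
)

__all__ = [
    "read_recording",
    "write_recording",
    "read_montage",
    "write_montage",
    "read_beats",
    "write_beats",
    "read_schedule",
    "write_schedule",
    "read_model",
    "write_model",
    "read_edf",
    "highpass_1hz",
    "FormatError",
]


class FormatError(ValueError):
    """Raised when an on-disk artifact does not match its declared shape."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: Recording, path) -> None:
    """Write ``<path>.dat`` + ``<path>.json`` (lossless %.17g text)."""
    path = Path(path)
    if path.suffix != ".dat":
        path = path.with_suffix(".dat")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, rec.data, fmt="%.17g", delimiter="\t")
    sidecar = {"fs": rec.fs, "labels": list(rec.labels)}
    if rec.positions is not None:
        sidecar["positions"] = rec.positions.tolist()
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_recording(path, sidecar=None) -> Recording:
    """Read a matrix file + sidecar back into a validated Recording."""
    path = Path(path)
    if path.suffix != ".dat":
        path = path.with_suffix(".dat")
    sidecar = _sidecar_path(path) if sidecar is None else Path(sidecar)
    meta = json.loads(sidecar.read_text())
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    labels = meta.get("labels")
    if labels is not None and len(labels) != data.shape[0]:
        raise FormatError(
            f"sidecar lists {len(labels)} labels but matrix has "
            f"{data.shape[0]} rows ({path})"
        )
    positions = meta.get("positions")
    try:
        return Recording(
            data=data,
            fs=float(meta["fs"]),
            labels=labels,
            positions=np.asarray(positions, dtype=float)
            if positions is not None
            else None,
        )
    except ValidationError:
        raise


def write_montage(labels, positions, path) -> None:
    """Montage-only sidecar: labels + 2-D positions, same dialect."""
    path = Path(path)
    doc = {
        "labels": [str(l) for l in labels],
        "positions": np.asarray(positions, dtype=float).tolist(),
    }
    path.write_text(json.dumps(doc, indent=1))


def read_montage(path) -> tuple[list[str], np.ndarray]:
    doc = json.loads(Path(path).read_text())
    labels = [str(l) for l in doc["labels"]]
    positions = np.asarray(doc["positions"], dtype=float)
    if positions.ndim != 2 or positions.shape != (len(labels), 2):
        raise FormatError(
            f"montage positions must be ({len(labels)}, 2), "
            f"got {positions.shape}"
        )
    return labels, positions


def _write_events(pairs, path) -> None:
    lines = [f"{int(s)}\t{tag}" for s, tag in pairs]
    Path(path).write_text("\n".join(lines) + "\n")


def _read_events(path) -> list[tuple[int, str]]:
    out = []
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        sample, tag = ln.split("\t")
        out.append((int(sample), tag))
    return out


def write_beats(beats: BeatAnnotations, path) -> None:
    _write_events(((p, "R") for p in beats.r_peaks), path)


def read_beats(path, fs: float = 250.0) -> BeatAnnotations:
    return BeatAnnotations([s for s, _ in _read_events(path)], fs=fs)


def write_schedule(schedule: EventSchedule, path) -> None:
    _write_events(schedule.onsets, path)


def read_schedule(path) -> EventSchedule:
    return EventSchedule(_read_events(path))


def write_model(model: InferenceModel, path) -> None:
    """Inference model as ``<path>.dat`` (W_expanded) + JSON sidecar."""
    path = Path(path)
    if path.suffix != ".dat":
        path = path.with_suffix(".dat")
    np.savetxt(path, model.W_expanded, fmt="%.17g", delimiter="\t")
    sidecar = {
        "subset": list(model.subset.indices),
        "universe_size": model.subset.universe_size,
        "training_meta": model.training_meta,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_model(path) -> InferenceModel:
    path = Path(path)
    if path.suffix != ".dat":
        path = path.with_suffix(".dat")
    meta = json.loads(_sidecar_path(path).read_text())
    subset = ChannelSubset(meta["subset"], meta["universe_size"])
    W_expanded = np.loadtxt(path, delimiter="\t", ndmin=2)
    W = W_expanded[subset.complement().row_indices]
    return InferenceModel(
        subset=subset,
        W=W,
        W_expanded=W_expanded,
        training_meta=meta.get("training_meta", {}),
    )


def _edf_samples_per_record(path: Path) -> list[tuple[str, int]]:
    """Scan the fixed-layout EDF header for per-signal record lengths."""
    with open(path, "rb") as fh:
        header = fh.read(256)
        if len(header) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        ns = int(header[252:256].decode("ascii").strip())
        sig = fh.read(ns * 216 + ns * 8 + ns * 32)
    labels = [
        sig[i * 16:(i + 1) * 16].decode("ascii", "replace").strip()
        for i in range(ns)
    ]
    spr_off = ns * 216
    spr = [
        int(sig[spr_off + i * 8: spr_off + (i + 1) * 8].decode("ascii").strip())
        for i in range(ns)
    ]
    return list(zip(labels, spr))


def read_edf(path) -> Recording:
    """Read an EDF/EDF+ file into a Recording (microvolts, no resampling).

    Raises
    ------
    FormatError
        If the data channels carry mixed per-channel sampling rates;
        resampling is never performed implicitly.
    """
    import mne

    path = Path(path)
    sig_info = _edf_samples_per_record(path)
    rates = {
        spr for label, spr in sig_info if label != "EDF Annotations"
    }
    if len(rates) > 1:
        raise FormatError(
            f"{path}: mixed per-channel sampling rates {sorted(rates)} "
            "are unsupported (no implicit resampling)"
        )
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne loads SI volts; native unit is uV
    return Recording(data=data, fs=float(raw.info["sfreq"]),
                     labels=list(raw.ch_names))


class InsufficientLengthError(ValueError):
    """Signal too short for the requested zero-phase filter."""


def highpass_1hz(rec: Recording, cutoff: float = 1.0) -> Recording:
    """Zero-phase 4th-order Butterworth high-pass (forward-backward).

    Removes DC and slow drifts; the default 1 Hz cutoff is the standard
    pre-filter before heartbeat-synchronised averaging.
    """
    if rec.fs <= 2 * cutoff:
        raise ValidationError(
            f"fs={rec.fs} must exceed twice the cutoff {cutoff}"
        )
    sos = scipy.signal.butter(4, cutoff, btype="highpass", fs=rec.fs,
                              output="sos")
    # sosfiltfilt pads by 3x the section-implied impulse span
    ntaps = 2 * (sos.shape[0] * 2 + 1)
    padlen = 3 * ntaps
    if rec.n_samples <= padlen:
        raise InsufficientLengthError(
            f"need more than {padlen} samples for zero-phase filtering, "
            f"got {rec.n_samples}"
        )
    filtered = scipy.signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(filtered)
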