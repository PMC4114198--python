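"""Acquisition-stage artifact estimation and inference-matrix recalculation.

``estimate_bcg`` applies the trained linear map to insulated-channel
signals.  ``recalculate_inference`` re-estimates the map from
heartbeat-synchronised segment averages of 1-Hz high-passed data, in
which brain activity averages out while the beat-locked artifact
survives, correcting for between-session changes in the artifact's
spatial structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .core import (
    BeatAnnotations,
    ChannelSubset,
    InferenceModel,
    Recording,
    ValidationError,
)
from .io import highpass_1hz

__all__ = ["BeatAverage", "estimate_bcg", "beat_average",
           "recalculate_inference"]


@dataclass
class BeatAverage:
    """Per-channel heartbeat-synchronised segment averages."""

    templates: np.ndarray     # C x L
    L: int
    n_segments: int

    def __post_init__(self):
        if self.L <= 0 or self.templates.shape[1] != self.L:
            raise ValidationError("template length mismatch")
        if not np.all(np.isfinite(self.templates)):
            raise ValidationError("templates must be finite")


def estimate_bcg(model: InferenceModel, bcg_ins: Recording) -> Recording:
    """Artifact estimate on the non-insulated channels.

    ``bcg_ins`` rows must correspond to the model's insulated subset in
    model order; the output rows are labelled by the non-insulated
    channel indices.
    """
    k = len(model.subset)
    if bcg_ins.n_channels != k:
        raise ValidationError(
            f"expected {k} insulated rows, got {bcg_ins.n_channels}")
    est = model.W @ bcg_ins.data
    nins = model.nins_subset
    return Recording(data=est, fs=bcg_ins.fs,
                     labels=[str(i) for i in nins.indices])


def beat_average(rec: Recording, beats: BeatAnnotations,
                 beats_per_segment: int = 10) -> BeatAverage:
    """Average consecutive segments spanning a fixed number of heartbeats.

    Segments run from one R-peak to the peak ``beats_per_segment`` beats
    later; all segments are truncated to the shortest segment length, the
    incomplete trailing segment is dropped, and the per-channel mean over
    segments is returned.  The caller is expected to have 1-Hz
    high-passed the data (a DC check warns otherwise).
    """
    if beats_per_segment < 1:
        raise ValidationError("beats_per_segment must be >= 1")
    peaks = beats.row_indices
    n_segments = (len(peaks) - 1) // beats_per_segment
    if n_segments < 2:
        raise ValidationError(
            f"need >= 2 complete segments of {beats_per_segment} beats, "
            f"got {n_segments}")
    means = np.abs(rec.data.mean(axis=1))
    stds = rec.data.std(axis=1)
    if np.any(means > 0.1 * np.maximum(stds, 1e-12)):
        warnings.warn("input looks unfiltered (large DC component); "
                      "apply a 1-Hz high-pass before beat averaging",
                      RuntimeWarning)
    bounds = [peaks[i * beats_per_segment] for i in range(n_segments + 1)]
    lengths = np.diff(bounds)
    L = int(min(lengths))
    segs = np.stack([rec.data[:, b: b + L] for b in bounds[:-1]], axis=0)
    return BeatAverage(templates=segs.mean(axis=0), L=L,
                       n_segments=n_segments)


def recalculate_inference(Y_nins: Recording, bcg_ins: Recording,
                          beats: BeatAnnotations, subset: ChannelSubset,
                          beats_per_segment: int = 10,
                          highpass: bool = True) -> InferenceModel:
    """New inference matrix from heartbeat-synced segment averages.

    Both the contaminated non-insulated recordings and the artifact-only
    insulated recordings are (optionally) 1-Hz high-passed and
    beat-averaged; the insulated templates are then mapped to the
    non-insulated templates by (minimum-norm) least squares.  The
    returned model keeps the original subset.
    """
    if Y_nins.fs != bcg_ins.fs:
        raise ValidationError("sampling rates differ")
    k = len(subset)
    C = subset.universe_size
    if bcg_ins.n_channels != k:
        raise ValidationError(
            f"expected {k} insulated rows, got {bcg_ins.n_channels}")
    if Y_nins.n_channels != C - k:
        raise ValidationError(
            f"expected {C - k} non-insulated rows, got {Y_nins.n_channels}")
    if highpass:
        Y_nins = highpass_1hz(Y_nins)
        bcg_ins = highpass_1hz(bcg_ins)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        avg_nins = beat_average(Y_nins, beats, beats_per_segment)
        avg_ins = beat_average(bcg_ins, beats, beats_per_segment)
    L = min(avg_nins.L, avg_ins.L)
    T_ins = avg_ins.templates[:, :L]
    T_nins = avg_nins.templates[:, :L]
    Wt, *_ = scipy.linalg.lstsq(T_ins.T, T_nins.T, lapack_driver="gelsd")
    W = Wt.T
    W_expanded = np.zeros((C, k))
    W_expanded[subset.row_indices] = np.eye(k)
    W_expanded[subset.complement().row_indices] = W
    return InferenceModel(
        subset=subset, W=W, W_expanded=W_expanded,
        training_meta={"method": "recalculated",
                       "beats_per_segment": beats_per_segment,
                       "n_segments": avg_nins.n_segments})
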