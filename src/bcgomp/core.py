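"""Domain containers for multichannel recordings and artifact-inference models.

All containers validate on construction.  Channel labels are 1-based
everywhere a user sees them (files, logs, reports, ``ChannelSubset``);
array row indices are an internal detail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Recording",
    "ChannelSubset",
    "InferenceModel",
    "BeatAnnotations",
    "EventSchedule",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when a container's invariants are violated."""


def _as_float_matrix(data, name: str) -> np.ndarray:
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise ValidationError(f"{name} must be a 2-D matrix, got ndim={arr.ndim}")
    bad = ~np.isfinite(arr)
    if bad.any():
        ch, smp = np.argwhere(bad)[0]
        raise ValidationError(
            f"{name} contains a non-finite value at channel row {ch + 1}, "
            f"sample {smp + 1}"
        )
    return arr


@dataclass
class Recording:
    """A channels x samples multichannel recording.

    Parameters
    ----------
    data : ndarray, shape (C, T)
        Signal matrix in microvolts; row i is channel ``labels[i]``.
    fs : float
        Sampling rate in Hz.
    labels : sequence of str, optional
        Unique channel identifiers; defaults to "1".."C".
    positions : ndarray, shape (C, 2), optional
        Planar scalp coordinates, used for pattern construction and
        topographic reporting only.
    """

    data: np.ndarray
    fs: float = 250.0
    labels: Sequence[str] | None = None
    positions: np.ndarray | None = None

    def __post_init__(self):
        self.data = _as_float_matrix(self.data, "data")
        C, T = self.data.shape
        if C < 1 or T < 1:
            raise ValidationError(f"need C >= 1 and T >= 1, got shape {(C, T)}")
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.labels is None:
            self.labels = [str(i + 1) for i in range(C)]
        else:
            self.labels = [str(l) for l in self.labels]
            if len(self.labels) != C:
                raise ValidationError(
                    f"{len(self.labels)} labels for {C} channel rows"
                )
            if len(set(self.labels)) != C:
                raise ValidationError("channel labels must be unique")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape != (C, 2):
                raise ValidationError(
                    f"positions must be ({C}, 2), got {self.positions.shape}"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray, labels=None, positions="keep") -> "Recording":
        """New Recording sharing metadata, with replaced data (and labels)."""
        if positions == "keep":
            positions = self.positions if (
                labels is None and self.positions is not None
            ) else None
        return Recording(
            data=np.array(data, dtype=float),
            fs=self.fs,
            labels=list(self.labels) if labels is None else labels,
            positions=positions,
        )

    def pick(self, subset: "ChannelSubset") -> "Recording":
        """Restrict to the channels of ``subset`` in subset order (1-based)."""
        idx = subset.row_indices
        pos = self.positions[idx] if self.positions is not None else None
        return Recording(
            data=self.data[idx].copy(),
            fs=self.fs,
            labels=[self.labels[i] for i in idx],
            positions=pos,
        )


@dataclass
class ChannelSubset:
    """An ordered subset of 1-based channel indices out of ``universe_size``.

    Order is meaningful: greedy selection emits channels in selection order.
    """

    indices: Sequence[int]
    universe_size: int

    def __post_init__(self):
        self.indices = [int(i) for i in self.indices]
        if self.universe_size < 1:
            raise ValidationError("universe_size must be >= 1")
        seen = set()
        for i in self.indices:
            if not (1 <= i <= self.universe_size):
                raise ValidationError(
                    f"channel index {i} outside [1..{self.universe_size}]"
                )
            if i in seen:
                raise ValidationError(f"duplicate channel index {i}")
            seen.add(i)

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)

    @property
    def row_indices(self) -> np.ndarray:
        """0-based array row positions corresponding to ``indices``."""
        return np.asarray(self.indices, dtype=int) - 1

    def complement(self) -> "ChannelSubset":
        """The non-selected channels, in increasing index order."""
        inset = set(self.indices)
        rest = [i for i in range(1, self.universe_size + 1) if i not in inset]
        return ChannelSubset(rest, self.universe_size)


@dataclass
class InferenceModel:
    """Insulated subset plus the linear maps predicting full-scalp artifact.

    ``W_expanded`` (C x k) predicts every channel from the k insulated ones;
    its restriction to the insulated rows is the identity block when the
    training rows were linearly independent.  ``W`` is the restriction to
    the non-insulated rows, the map actually applied in acquisition.
    """

    subset: ChannelSubset
    W: np.ndarray
    W_expanded: np.ndarray
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        k = len(self.subset)
        C = self.subset.universe_size
        self.W = _as_float_matrix(self.W, "W")
        self.W_expanded = _as_float_matrix(self.W_expanded, "W_expanded")
        if self.W_expanded.shape != (C, k):
            raise ValidationError(
                f"W_expanded must be ({C}, {k}), got {self.W_expanded.shape}"
            )
        if self.W.shape != (C - k, k):
            raise ValidationError(
                f"W must be ({C - k}, {k}), got {self.W.shape}"
            )

    @property
    def nins_subset(self) -> ChannelSubset:
        return self.subset.complement()


@dataclass
class BeatAnnotations:
    """Strictly increasing R-peak sample indices (1-based) at rate ``fs``."""

    r_peaks: Sequence[int]
    fs: float = 250.0

    def __post_init__(self):
        self.r_peaks = [int(p) for p in self.r_peaks]
        if any(p < 1 for p in self.r_peaks):
            raise ValidationError("R-peak indices are 1-based and must be >= 1")
        diffs = np.diff(self.r_peaks)
        if len(diffs) and (diffs <= 0).any():
            raise ValidationError("R-peak indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.r_peaks)

    @property
    def row_indices(self) -> np.ndarray:
        return np.asarray(self.r_peaks, dtype=int) - 1

    def rr_intervals(self) -> np.ndarray:
        """RR intervals in samples."""
        return np.diff(np.asarray(self.r_peaks, dtype=int))


#: Recognised eyes-open / eyes-closed state tags.
EC, EO = "EC", "EO"


@dataclass
class EventSchedule:
    """Alternating eyes-closed/eyes-open block onsets, (sample, state)."""

    onsets: Sequence[tuple]

    def __post_init__(self):
        onsets = [(int(s), str(tag)) for s, tag in self.onsets]
        if not onsets:
            raise ValidationError("schedule must contain at least one onset")
        prev = 0
        prev_tag = None
        for s, tag in onsets:
            if tag not in (EC, EO):
                raise ValidationError(f"unknown state tag {tag!r}")
            if s <= prev:
                raise ValidationError("onsets must be strictly increasing")
            if tag == prev_tag:
                raise ValidationError("EC/EO states must alternate")
            prev, prev_tag = s, tag
        self.onsets = onsets

    def __len__(self) -> int:
        return len(self.onsets)

    def blocks(self, total_samples: int):
        """Yield (start, stop, state) half-open 1-based sample blocks."""
        for i, (s, tag) in enumerate(self.onsets):
            stop = (
                self.onsets[i + 1][0] if i + 1 < len(self.onsets)
                else total_samples + 1
            )
            yield s, stop, tag
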