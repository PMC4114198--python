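"""Metrics and experiment harnesses.

Normalised RMS error (nRMSE, %) against ground truth and its spatial
average; consistency error matrices across segments/sessions; random
insulation-pattern studies; the eyes-closed/eyes-open alpha-band
rank-sum analysis; and short-time spectral reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal
import scipy.stats

from .core import (
    ChannelSubset,
    EventSchedule,
    InferenceModel,
    Recording,
    ValidationError,
    EC,
    EO,
)

__all__ = [
    "nrmse",
    "ave_nrmse",
    "ErrorMap",
    "error_map",
    "ConsistencyMatrix",
    "consistency_matrix",
    "random_pattern_study",
    "RandomPatternStudy",
    "AlphaTestResult",
    "alpha_ec_eo_test",
    "spectrogram_report",
]


class UndefinedMetricError(ValidationError):
    """nRMSE against a zero-norm ground truth is undefined."""


def nrmse(truth, estimate) -> float:
    """100 * ||truth - estimate||_2 / ||truth||_2 (percent)."""
    truth = np.asarray(truth, dtype=float).ravel()
    estimate = np.asarray(estimate, dtype=float).ravel()
    denom = np.linalg.norm(truth)
    if denom == 0:
        raise UndefinedMetricError("ground truth has zero norm")
    return 100.0 * float(np.linalg.norm(truth - estimate)) / float(denom)


def _as_matrix(x) -> np.ndarray:
    return x.data if isinstance(x, Recording) else np.asarray(x, dtype=float)


def ave_nrmse(truth, estimate, subset: ChannelSubset | None = None) -> float:
    """Mean per-channel nRMSE (%) over ``subset`` (default: all rows)."""
    Xt, Xe = _as_matrix(truth), _as_matrix(estimate)
    if Xt.shape != Xe.shape:
        raise ValidationError(f"shape mismatch {Xt.shape} vs {Xe.shape}")
    rows = subset.row_indices if subset is not None else np.arange(Xt.shape[0])
    return float(np.mean([nrmse(Xt[i], Xe[i]) for i in rows]))


@dataclass
class ErrorMap:
    """Per-channel nRMSE (%) with labels and optional positions, ready
    for tabular or topographic display."""

    values: np.ndarray
    labels: list[str]
    positions: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValidationError("nRMSE values must be >= 0")

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame({"channel": self.labels,
                           "nrmse_pct": np.round(self.values, 2)})
        if self.positions is not None:
            df["x"], df["y"] = self.positions[:, 0], self.positions[:, 1]
        return df


def error_map(truth: Recording, estimate: Recording,
              subset: ChannelSubset | None = None) -> ErrorMap:
    rows = (subset.row_indices if subset is not None
            else np.arange(truth.n_channels))
    vals = [nrmse(truth.data[i], estimate.data[i]) for i in rows]
    labels = [truth.labels[i] for i in rows]
    pos = truth.positions[rows] if truth.positions is not None else None
    return ErrorMap(values=np.asarray(vals), labels=labels, positions=pos)


@dataclass
class ConsistencyMatrix:
    """E[i, j] = ave nRMSE (%) of segment j under the model of segment i."""

    E: np.ndarray
    mode: str = "full"

    def __post_init__(self):
        self.E = np.asarray(self.E, dtype=float)

    @property
    def diagonal_mean(self) -> float:
        return float(np.mean(np.diag(self.E)))

    @property
    def off_diagonal_mean(self) -> float:
        E = self.E
        mask = ~np.eye(E.shape[0], dtype=bool)
        return float(E[mask].mean())


def _segment_eval(model: InferenceModel, seg: np.ndarray) -> float:
    sub = model.subset
    pred = model.W @ seg[sub.row_indices]
    return ave_nrmse(seg[sub.complement().row_indices], pred)


def consistency_matrix(Xbcg, n_segments: int | None = None,
                       budget: int = 20, mode: str = "full",
                       fixed: InferenceModel | None = None,
                       beats_list=None) -> ConsistencyMatrix:
    """Cross-segment artifact-estimation error matrix.

    ``Xbcg`` is either a Recording split into ``n_segments`` contiguous
    equal parts, or an explicit list of artifact-only Recordings
    (segments/sessions).  Modes:

    * ``full`` — select + fit on segment i, evaluate on segment j.
    * ``fixed_subset`` — subset from segment i (or from ``fixed``), but
      the inference matrix refit optimally on segment j: tests whether
      the selected channels stay representative.
    * ``fixed_model`` — subset AND matrix from segment i (or ``fixed``)
      applied unchanged to segment j: the stale-model test.
    """
    from .estimators import OmpBcgInference

    if isinstance(Xbcg, Recording):
        if n_segments is None or n_segments < 2:
            raise ValidationError("need n_segments >= 2")
        seg_len = Xbcg.n_samples // n_segments
        segs = [Xbcg.data[:, k * seg_len: (k + 1) * seg_len]
                for k in range(n_segments)]
    else:
        segs = [_as_matrix(s) for s in Xbcg]
        if len(segs) < 2:
            raise ValidationError("need at least 2 segments")
    K = len(segs)
    if mode not in ("full", "fixed_subset", "fixed_model"):
        raise ValidationError(f"unknown mode {mode!r}")
    row_models = []
    for i in range(K):
        if fixed is not None:
            row_models.append(fixed)
        else:
            est = OmpBcgInference(budget=budget).fit(segs[i].T)
            row_models.append(est.to_model())
    E = np.empty((K, K))
    for i in range(K):
        model_i = row_models[i]
        for j in range(K):
            if mode == "fixed_subset":
                refit = OmpBcgInference(
                    subset=list(model_i.subset)).fit(segs[j].T).to_model()
                E[i, j] = _segment_eval(refit, segs[j])
            else:  # full / fixed_model: stale model applied as-is
                E[i, j] = _segment_eval(model_i, segs[j])
    return ConsistencyMatrix(E=E, mode=mode)


@dataclass
class RandomPatternStudy:
    errors: np.ndarray            # ave nRMSE (%) per realisation
    omp_error: float              # greedy pattern on the same split
    histogram: tuple = field(default=None)

    @property
    def mean(self) -> float:
        return float(self.errors.mean())

    @property
    def min(self) -> float:
        return float(self.errors.min())

    @property
    def max(self) -> float:
        return float(self.errors.max())


def random_pattern_study(Xbcg: Recording, budget: int = 20,
                         n_realizations: int = 500, seed: int = 0,
                         train_frac: float = 0.5) -> RandomPatternStudy:
    """Held-out estimation error of random insulation patterns.

    Each realisation draws a uniformly random subset, fits the inference
    matrix on the training split and evaluates ave nRMSE on the held-out
    split; the greedy selection's error on the same split is computed
    alongside for comparison.
    """
    from .estimators import OmpBcgInference
    from .selection import random_pattern

    if n_realizations < 1:
        raise ValidationError("n_realizations must be >= 1")
    T = Xbcg.n_samples
    n_train = max(int(T * train_frac), 1)
    tr, te = Xbcg.data[:, :n_train], Xbcg.data[:, n_train:]
    rng = np.random.default_rng(seed)
    errors = []
    for _ in range(n_realizations):
        sub = random_pattern(Xbcg.n_channels, budget,
                             seed=int(rng.integers(2**31)))
        model = OmpBcgInference(subset=list(sub)).fit(tr.T).to_model()
        errors.append(_segment_eval(model, te))
    omp_model = OmpBcgInference(budget=budget).fit(tr.T).to_model()
    omp_err = _segment_eval(omp_model, te)
    errors = np.asarray(errors)
    return RandomPatternStudy(errors=errors, omp_error=float(omp_err),
                              histogram=np.histogram(errors, bins=20))


class InsufficientDataError(ValidationError):
    """Too few epochs to run the rank-sum comparison."""


@dataclass
class AlphaTestResult:
    powers_ec: np.ndarray      # band power (uV^2) per EC epoch
    powers_eo: np.ndarray
    p_value: float
    significant: bool          # at the 0.05 level


def alpha_ec_eo_test(eeg: Recording, schedule: EventSchedule, channel,
                     band: tuple = (8.0, 10.0), epoch_s: float = 3.0,
                     guard_s: float = 3.0) -> AlphaTestResult:
    """Eyes-closed vs eyes-open alpha-band power comparison.

    Each block is cut into non-overlapping ``epoch_s`` epochs, omitting
    ``guard_s`` after the block onset and before the next onset; the
    alpha-band power per epoch is the periodogram power summed over the
    closed band, and EC vs EO epoch samples are compared with a
    two-sided Wilcoxon rank-sum test.
    """
    if isinstance(channel, (int, np.integer)):
        row = int(channel) - 1
    else:
        row = eeg.labels.index(str(channel))
    x = eeg.data[row]
    fs = eeg.fs
    n_ep = int(round(epoch_s * fs))
    guard = int(round(guard_s * fs))
    powers = {EC: [], EO: []}
    for start, stop, state in schedule.blocks(eeg.n_samples):
        a = (start - 1) + guard
        b = min(stop - 1, eeg.n_samples) - guard
        pos = a
        while pos + n_ep <= b:
            seg = x[pos: pos + n_ep]
            freqs, pxx = scipy.signal.periodogram(seg, fs=fs)
            in_band = (freqs >= band[0]) & (freqs <= band[1])
            df = freqs[1] - freqs[0]
            powers[state].append(float(pxx[in_band].sum() * df))
            pos += n_ep
    if len(powers[EC]) < 5 or len(powers[EO]) < 5:
        raise InsufficientDataError(
            f"need >= 5 epochs per state, got EC={len(powers[EC])}, "
            f"EO={len(powers[EO])}")
    stat = scipy.stats.ranksums(powers[EC], powers[EO])
    p = float(stat.pvalue)
    return AlphaTestResult(powers_ec=np.asarray(powers[EC]),
                           powers_eo=np.asarray(powers[EO]),
                           p_value=p, significant=p < 0.05)


def spectrogram_report(signal, fs: float, window: int = 256,
                       overlap: int = 200):
    """Short-time periodogram (Hamming window) in power units.

    Returns (freqs, times, Sxx) with Sxx in power spectral density;
    the number of time slices is floor((T - window)/(window-overlap)) + 1.
    """
    signal = np.asarray(signal, dtype=float).ravel()
    if len(signal) < window:
        raise ValidationError(
            f"signal length {len(signal)} shorter than window {window}")
    win = scipy.signal.get_window("hamming", window)
    return scipy.signal.spectrogram(signal, fs=fs, window=win,
                                    noverlap=overlap, detrend=False)
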