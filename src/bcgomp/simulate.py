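"""Synthetic BCG / EEG / contaminated-recording generators.

The generators reproduce the statistical structure the removal method
relies on, so every stage is testable without real recordings:

* BCG artifacts are spatially low-rank (``spatial_rank`` beat-locked
  sources mixed through smooth spatial profiles) and temporally
  non-stationary (RR-interval jitter, per-beat amplitude jitter, per-beat
  latency jitter, and a slow multiplicative amplitude drift per source
  emulating respiratory/vasomotor modulation of pulse amplitude).
* Clean EEG is a 1/f^beta background plus a posterior alpha rhythm whose
  amplitude follows an eyes-closed/eyes-open block schedule.
* Contaminated data are the additive superposition of both plus sensor
  noise.

Every generator is a pure function of its config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import BeatAnnotations, EventSchedule, Recording, ValidationError, EC, EO
from .montage import spherical_cap_montage

__all__ = [
    "BcgSimConfig",
    "EegSimConfig",
    "simulate_bcg",
    "simulate_eeg",
    "synthesize_contaminated",
    "perturb_mixing",
    "perturb_session",
    "make_schedule",
]


@dataclass
class BcgSimConfig:
    """Scene parameters for BCG-only generation.

    Defaults describe a desk-scale stand-in for a high-density cap:
    64 channels, 2 minutes at 250 Hz, four artifact sources, 60 bpm with
    5% RR jitter and 20% per-beat amplitude jitter.
    """

    C: int = 64
    T: int = 250 * 120
    fs: float = 250.0
    spatial_rank: int = 4
    heart_rate: float = 60.0
    rr_jitter: float = 0.05
    amp_jitter: float = 0.2
    latency_jitter_s: float = 0.020
    amp_drift: float = 0.5          # std of slow log-amplitude drift
    drift_tau_s: float = 20.0       # drift correlation time
    mixing_smoothness: float = 0.8  # spatial kernel width, montage units
    noise_std: float = 1.0          # sensor noise sigma, uV
    target_rms: float = 50.0        # mean channel RMS of the noiseless BCG, uV
    seed: int = 0

    def __post_init__(self):
        if not (1 <= self.spatial_rank <= self.C):
            raise ValidationError(
                f"spatial_rank must be in [1..C], got {self.spatial_rank}"
            )
        if self.rr_jitter < 0 or self.amp_jitter < 0:
            raise ValidationError("jitter fractions must be >= 0")


@dataclass
class EegSimConfig:
    """Clean-EEG generator parameters (microvolts)."""

    C: int = 64
    T: int = 250 * 120
    fs: float = 250.0
    alpha_freq: float = 9.0
    alpha_amp_ec: float = 10.0
    alpha_amp_eo: float = 7.5
    # waxing/waning knob for realism studies; default off because burst
    # correlation between contiguous epochs de-calibrates rank-sum epochs
    alpha_env_cv: float = 0.0
    alpha_env_tau_s: float = 1.0
    alpha_channels: list | None = None   # 1-based; default: posterior third
    background_exponent: float = 2.0     # power ~ 1/f^exponent
    background_amp: float = 10.0         # per-channel background RMS
    block_s: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if not (self.alpha_amp_ec > self.alpha_amp_eo >= 0):
            raise ValidationError(
                "need alpha_amp_ec > alpha_amp_eo >= 0, got "
                f"{self.alpha_amp_ec} / {self.alpha_amp_eo}"
            )


def _beat_times(cfg: BcgSimConfig, rng: np.random.Generator) -> np.ndarray:
    """R-peak times in seconds covering (0, T/fs)."""
    rr_mean = 60.0 / cfg.heart_rate
    duration = cfg.T / cfg.fs
    times = []
    t = rr_mean * (0.5 + 0.1 * rng.random())
    while t < duration:
        times.append(t)
        rr = rr_mean * float(np.clip(1 + cfg.rr_jitter * rng.standard_normal(),
                                     0.5, 1.5))
        t += rr
    return np.asarray(times)


def _source_templates(cfg: BcgSimConfig, rng: np.random.Generator):
    """Per-source analytic pulse shapes: sums of Gaussian derivatives."""
    rr_mean = 60.0 / cfg.heart_rate
    templates = []
    for _ in range(cfg.spatial_rank):
        n_bumps = rng.integers(2, 4)
        bumps = []
        for _ in range(n_bumps):
            center = rr_mean * (0.05 + 0.55 * rng.random())
            width = 0.03 + 0.05 * rng.random()
            amp = rng.choice([-1.0, 1.0]) * (0.5 + rng.random())
            order = int(rng.integers(1, 3))
            bumps.append((center, width, amp, 0.0, order))
        # damped oscillatory component: each pulse rings at 5-15 Hz, the
        # dominant spectral signature of cardiac-locked motion artifact
        for _ in range(2):
            center = rr_mean * (0.1 + 0.4 * rng.random())
            width = 0.08 + 0.04 * rng.random()
            f0 = 7.0 + 5.0 * rng.random()
            amp = rng.choice([-1.0, 1.0]) * (3.5 + 2.0 * rng.random())
            bumps.append((center, width, amp, f0, 0))
        templates.append(bumps)
    return templates


def _eval_template(bumps, t: np.ndarray) -> np.ndarray:
    out = np.zeros_like(t)
    for center, width, amp, f0, order in bumps:
        u = (t - center) / width
        g = np.exp(-0.5 * u * u)
        if f0 > 0:       # Gaussian-windowed oscillation (ringing)
            out += amp * np.cos(2 * np.pi * f0 * (t - center)) * g
        else:
            out += amp * (u * g if order == 1 else (u * u - 1) * g)
    return out


def _render_sources(cfg: BcgSimConfig, templates, beat_times,
                    rng: np.random.Generator) -> np.ndarray:
    """r x T source matrix with per-beat amplitude/latency jitter and
    slow amplitude drift."""
    r = cfg.spatial_rank
    sources = np.zeros((r, cfg.T))
    rr_mean = 60.0 / cfg.heart_rate
    span = 1.2 * rr_mean          # template support rendered per beat
    n_beats = len(beat_times)
    # slow log-amplitude drift, OU-sampled at beat times
    drift = np.zeros((r, n_beats))
    if cfg.amp_drift > 0 and n_beats:
        a = float(np.exp(-rr_mean / cfg.drift_tau_s))
        x = cfg.amp_drift * rng.standard_normal(r)
        for b in range(n_beats):
            drift[:, b] = x
            x = a * x + cfg.amp_drift * np.sqrt(1 - a * a) * \
                rng.standard_normal(r)
    gains = np.exp(drift)
    amp_jit = 1 + cfg.amp_jitter * rng.standard_normal((r, n_beats))
    lat_jit = cfg.latency_jitter_s * rng.standard_normal((r, n_beats))
    for b, t0 in enumerate(beat_times):
        i0 = max(int((t0 - 0.1 * rr_mean) * cfg.fs), 0)
        i1 = min(int((t0 + span) * cfg.fs), cfg.T)
        if i1 <= i0:
            continue
        t_rel = np.arange(i0, i1) / cfg.fs - t0
        for k in range(r):
            sources[k, i0:i1] += (
                gains[k, b] * amp_jit[k, b]
                * _eval_template(templates[k], t_rel - lat_jit[k, b])
            )
    return sources


def _smooth_columns(positions: np.ndarray, r: int, smoothness: float,
                    rng: np.random.Generator) -> np.ndarray:
    """C x r mixing with columns smooth over the montage (Gaussian kernels
    at random centers plus a broad offset), so adjacent channels mix
    similarly."""
    C = positions.shape[0]
    span = positions.max(0) - positions.min(0)
    cols = np.empty((C, r))
    for k in range(r):
        center = positions.min(0) + rng.random(2) * span
        d2 = ((positions - center) ** 2).sum(1)
        sign = rng.choice([-1.0, 1.0])
        # broad baseline: every channel picks up every source appreciably,
        # as for pulse-driven artifacts under a strong static field
        cols[:, k] = sign * (0.35 * np.exp(-d2 / (2 * smoothness ** 2))
                             + 0.8 + 0.2 * rng.random())
    return cols


def simulate_bcg(cfg: BcgSimConfig, positions: np.ndarray | None = None):
    """Generate a BCG-only full-scalp session.

    Returns
    -------
    rec : Recording
        C x T data = mixing @ sources + sensor noise, with montage
        positions attached.
    beats : BeatAnnotations
    mixing : ndarray (C, r)
    sources : ndarray (r, T)

    The noiseless part has exact matrix rank ``spatial_rank``.
    """
    rng = np.random.default_rng(cfg.seed)
    if positions is None:
        positions = spherical_cap_montage(cfg.C)
    beat_times = _beat_times(cfg, rng)
    if len(beat_times) < 2:
        raise ValidationError("recording too short for at least two beats")
    templates = _source_templates(cfg, rng)
    sources = _render_sources(cfg, templates, beat_times, rng)
    mixing = _smooth_columns(positions, cfg.spatial_rank,
                             cfg.mixing_smoothness, rng)
    clean = mixing @ sources
    rms = np.sqrt(np.mean(clean ** 2))
    if rms > 0 and cfg.target_rms:
        scale = cfg.target_rms / rms
        mixing = mixing * scale
        clean = clean * scale
    data = clean + cfg.noise_std * rng.standard_normal(clean.shape)
    rec = Recording(data=data, fs=cfg.fs, positions=positions)
    peaks = np.clip(np.round(beat_times * cfg.fs).astype(int) + 1, 1, cfg.T)
    return rec, BeatAnnotations(list(peaks), fs=cfg.fs), mixing, sources


def make_schedule(T: int, fs: float, block_s: float = 30.0,
                  start: str = EC) -> EventSchedule:
    """Alternating EC/EO blocks of ``block_s`` seconds covering [1..T]."""
    step = int(round(block_s * fs))
    onsets = []
    state = start
    for s in range(1, T + 1, step):
        onsets.append((s, state))
        state = EO if state == EC else EC
    return EventSchedule(onsets)


def _one_over_f(C: int, T: int, fs: float, exponent: float, amp: float,
                rng: np.random.Generator) -> np.ndarray:
    """FFT-shaped Gaussian noise with power ~ 1/f^exponent (flat below 1 Hz),
    scaled to per-channel RMS ``amp``."""
    freqs = np.fft.rfftfreq(T, d=1 / fs)
    shape = np.ones_like(freqs)
    nz = freqs >= 1.0
    shape[nz] = freqs[nz] ** (-exponent / 2)
    spec = (rng.standard_normal((C, len(freqs)))
            + 1j * rng.standard_normal((C, len(freqs)))) * shape
    spec[:, 0] = 0.0
    x = np.fft.irfft(spec, n=T, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return amp * x / sd


def simulate_eeg(cfg: EegSimConfig, schedule: EventSchedule) -> Recording:
    """Clean EEG: 1/f^beta background everywhere plus a block-modulated
    alpha rhythm (random phase per block) on the alpha channels."""
    if len(schedule) == 0:
        raise ValidationError("schedule must not be empty")
    rng = np.random.default_rng(cfg.seed)
    positions = spherical_cap_montage(cfg.C)
    data = _one_over_f(cfg.C, cfg.T, cfg.fs, cfg.background_exponent,
                       cfg.background_amp, rng) \
        if cfg.background_amp > 0 else np.zeros((cfg.C, cfg.T))
    if cfg.alpha_channels is None:
        # posterior third of the cap (most negative y)
        order = np.argsort(positions[:, 1])
        alpha_rows = np.sort(order[: max(cfg.C // 3, 1)])
    else:
        alpha_rows = np.asarray(cfg.alpha_channels, dtype=int) - 1
    t = np.arange(cfg.T) / cfg.fs
    # waxing/waning: lognormal AR(1) envelope per channel, unit mean power
    if cfg.alpha_env_cv > 0:
        import scipy.signal

        a = np.exp(-1.0 / (cfg.alpha_env_tau_s * cfg.fs))
        sigma = np.sqrt(np.log(1 + cfg.alpha_env_cv ** 2))
        w = rng.standard_normal((len(alpha_rows), cfg.T))
        x = scipy.signal.lfilter([np.sqrt(1 - a * a)], [1, -a], w, axis=1)
        env = np.exp(sigma * x - sigma ** 2)
    else:
        env = np.ones((len(alpha_rows), cfg.T))
    for start, stop, state in schedule.blocks(cfg.T):
        amp = cfg.alpha_amp_ec if state == EC else cfg.alpha_amp_eo
        sl = slice(start - 1, min(stop - 1, cfg.T))
        if amp == 0 or sl.start >= cfg.T:
            continue
        phases = 2 * np.pi * rng.random(len(alpha_rows))
        wave = np.sin(2 * np.pi * cfg.alpha_freq * t[sl][None, :]
                      + phases[:, None])
        data[alpha_rows, sl] += np.sqrt(2) * amp * env[:, sl] * wave
    return Recording(data=data, fs=cfg.fs, positions=positions)


def synthesize_contaminated(bcg: Recording, eeg: Recording,
                            noise_std: float = 2.0,
                            seed: int = 0) -> Recording:
    """Additive superposition: contaminated = BCG + EEG + sensor noise."""
    if bcg.data.shape != eeg.data.shape or bcg.fs != eeg.fs:
        raise ValidationError(
            f"BCG {bcg.data.shape}@{bcg.fs}Hz and EEG "
            f"{eeg.data.shape}@{eeg.fs}Hz do not match"
        )
    rng = np.random.default_rng(seed)
    noise = (noise_std * rng.standard_normal(bcg.data.shape)
             if noise_std > 0 else 0.0)
    return Recording(data=bcg.data + eeg.data + noise, fs=bcg.fs,
                     labels=list(bcg.labels), positions=bcg.positions)


def perturb_mixing(mixing: np.ndarray, mix_perturb: float, seed: int,
                   positions: np.ndarray | None = None,
                   smoothness: float = 0.8) -> np.ndarray:
    """Mixing matrix plus a smooth random perturbation with
    ||delta||_F = mix_perturb * ||mixing||_F exactly."""
    if mix_perturb < 0:
        raise ValidationError("mix_perturb must be >= 0")
    if mix_perturb == 0:
        return mixing.copy()
    rng = np.random.default_rng(seed)
    C, r = mixing.shape
    if positions is None:
        positions = spherical_cap_montage(C)
    delta = _smooth_columns(positions, r, smoothness, rng)
    delta -= delta.mean(axis=0, keepdims=True)
    nd = np.linalg.norm(delta)
    if nd == 0:
        raise ValidationError("degenerate zero perturbation")
    delta *= mix_perturb * np.linalg.norm(mixing) / nd
    return mixing + delta


def perturb_session(mixing: np.ndarray, sources: np.ndarray,
                    mix_perturb: float, seed: int,
                    cfg: BcgSimConfig | None = None,
                    positions: np.ndarray | None = None):
    """A follow-up session: perturbed spatial mixing, regenerated beats.

    When ``cfg`` is provided the source waveforms and beat sequence are
    re-simulated (fresh cardiac cycle realisation at the same statistics);
    otherwise the given sources are reused and only the mixing changes.
    ``mix_perturb = 0`` reproduces the original spatial relationships.

    Returns (Recording, BeatAnnotations, new_mixing).
    """
    rng = np.random.default_rng(seed)
    new_mixing = perturb_mixing(mixing, mix_perturb, int(rng.integers(2**31)),
                                positions=positions)
    if cfg is not None:
        cfg2 = replace(cfg, seed=int(rng.integers(2**31)))
        if positions is None:
            positions = spherical_cap_montage(cfg2.C)
        rng2 = np.random.default_rng(cfg2.seed)
        beat_times = _beat_times(cfg2, rng2)
        templates = _source_templates(cfg2, rng2)
        new_sources = _render_sources(cfg2, templates, beat_times, rng2)
        clean = new_mixing @ new_sources
        noise = cfg2.noise_std * rng2.standard_normal(clean.shape)
        fs, T = cfg2.fs, cfg2.T
        peaks = np.clip(np.round(beat_times * fs).astype(int) + 1, 1, T)
        beats = BeatAnnotations(list(peaks), fs=fs)
        rec = Recording(data=clean + noise, fs=fs, positions=positions)
    else:
        clean = new_mixing @ sources
        fs = 250.0
        rec = Recording(data=clean, fs=fs, positions=positions)
        beats = BeatAnnotations([1, clean.shape[1]], fs=fs)
    return rec, beats, new_mixing
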