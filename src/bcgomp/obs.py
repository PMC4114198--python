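"""Optimal-basis-set baseline: heartbeat-epoch template + PC regression.

The channel-wise comparison method: epoch the signal around each R-peak,
then regress the epoch-mean template and the top principal components of
the demeaned epoch matrix out of every epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import BeatAnnotations, Recording, ValidationError
from .estimators import ObsCleaner

__all__ = ["ObsConfig", "obs_clean"]


@dataclass
class ObsConfig:
    """n_pcs principal components; epoch window as (pre, post) fractions
    of the median RR interval around each R-peak (must sum to 1)."""

    n_pcs: int = 3
    window: tuple = (0.25, 0.75)

    def __post_init__(self):
        if self.n_pcs < 0:
            raise ValidationError("n_pcs must be >= 0")
        if abs(self.window[0] + self.window[1] - 1.0) > 1e-9:
            raise ValidationError("window fractions must sum to 1")


def obs_clean(Y: Recording, beats: BeatAnnotations,
              cfg: ObsConfig | None = None) -> Recording:
    """Clean every channel of ``Y``; samples outside any complete
    heartbeat epoch pass through unchanged."""
    cfg = cfg or ObsConfig()
    cleaner = ObsCleaner(n_pcs=cfg.n_pcs, window=cfg.window)
    return Y.copy_with(cleaner.clean(Y.data, beats))
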