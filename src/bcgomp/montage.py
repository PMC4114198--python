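"""Planar electrode layouts for synthetic scenes and pattern construction.

The default layout is a spherical-cap spiral (a stand-in for a high-density
geodesic cap) projected to the plane with an azimuthal-equidistant map, so
euclidean distance in the layout tracks along-scalp distance.
"""

from __future__ import annotations

import numpy as np

__all__ = ["spherical_cap_montage", "ten_twenty_subset", "TEN_TWENTY_2D"]


def spherical_cap_montage(n: int = 256, cap_deg: float = 100.0) -> np.ndarray:
    """n x 2 planar positions on a Fibonacci spiral over a spherical cap.

    ``cap_deg`` is the polar angle (degrees from vertex) the cap spans;
    100 degrees reaches below the ears like a full EEG cap.  Radius of the
    projected layout equals the polar angle in radians (unit sphere).
    """
    if n < 1:
        raise ValueError("montage needs at least one electrode")
    golden = (1 + 5 ** 0.5) / 2
    i = np.arange(n)
    theta_max = np.deg2rad(cap_deg)
    # equal-area spacing in cos(theta) over the cap
    z = 1 - (1 - np.cos(theta_max)) * (i + 0.5) / n
    theta = np.arccos(np.clip(z, -1, 1))
    phi = 2 * np.pi * i / golden
    r = theta  # azimuthal-equidistant projection
    return np.column_stack([r * np.cos(phi), r * np.sin(phi)])


#: Idealised 10-20 electrode positions in the same projection
#: (x towards the right ear, y towards the nasion; radians of polar angle).
TEN_TWENTY_2D = {
    "Fp1": (-0.35, 1.34), "Fp2": (0.35, 1.34),
    "F7": (-1.13, 0.83), "F3": (-0.56, 0.72), "Fz": (0.0, 0.70),
    "F4": (0.56, 0.72), "F8": (1.13, 0.83),
    "T7": (-1.40, 0.0), "C3": (-0.70, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.70, 0.0), "T8": (1.40, 0.0),
    "P7": (-1.13, -0.83), "P3": (-0.56, -0.72), "Pz": (0.0, -0.70),
    "P4": (0.56, -0.72), "P8": (1.13, -0.83),
    "O1": (-0.35, -1.34), "Oz": (0.0, -1.40), "O2": (0.35, -1.34),
}


def ten_twenty_subset(positions: np.ndarray) -> list[int]:
    """1-based indices of the montage channels nearest the 20 standard
    10-20 sites (a realistic 'unblocked' acquisition subset)."""
    out: list[int] = []
    taken: set[int] = set()
    for name, (x, y) in TEN_TWENTY_2D.items():
        d = np.hypot(positions[:, 0] - x, positions[:, 1] - y)
        order = np.argsort(d)
        for j in order:
            if int(j) not in taken:
                taken.add(int(j))
                out.append(int(j) + 1)
                break
    return out
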