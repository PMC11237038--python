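"""Color-space baseline dissimilarity models.

Two control models for color similarity structures: Euclidean distance in
8-bit sRGB space, and the CIEDE2000 color difference (Delta E 2000) in
CIELAB.  Stimuli enter as HEX codes; LAB coordinates are derived via the
standard sRGB path — IEC 61966-2-1 inverse companding, the sRGB RGB->XYZ
matrix, then XYZ->LAB under the D65 white point (2 degree observer).

CIEDE2000 is implemented from its published definition: the a*-axis chroma
rescaling (G term), lightness/chroma/hue differences with weighting
functions S_L, S_C, S_H, the hue rotation term R_T, and parametric factors
k_L = k_C = k_H = 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import DissimilarityMatrix

__all__ = [
    "ColorSet",
    "parse_hex",
    "srgb_to_lab",
    "ciede2000",
    "rgb_dissimilarity",
    "lab_dissimilarity",
    "read_color_list",
]

_HEX_RE = re.compile(r"^#?([0-9a-fA-F]{6})$")

# D65 reference white (2 degree observer), XYZ scaled to Y=100
_WHITE_D65 = np.array([95.047, 100.0, 108.883])

# sRGB (linear) -> XYZ, D65
_RGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)


def parse_hex(code: str) -> tuple[int, int, int]:
    """'#RRGGBB' or 'RRGGBB' (case-insensitive) -> 8-bit RGB triple."""
    m = _HEX_RE.match(code.strip())
    if m is None:
        raise ValueError(f"malformed hex color code: {code!r}")
    h = m.group(1)
    return tuple(int(h[i : i + 2], 16) for i in (0, 2, 4))


def srgb_to_lab(rgb: Sequence[float]) -> tuple[float, float, float]:
    """8-bit sRGB triple -> CIELAB (D65, 2 degree observer)."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape != (3,) or np.any(rgb < 0) or np.any(rgb > 255):
        raise ValueError(f"RGB channels must lie in [0, 255], got {rgb}")
    c = rgb / 255.0
    # IEC 61966-2-1 inverse companding
    linear = np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)
    xyz = _RGB_TO_XYZ @ linear * 100.0
    t = xyz / _WHITE_D65
    delta = 6.0 / 29.0
    f = np.where(t > delta**3, np.cbrt(t), t / (3 * delta**2) + 4.0 / 29.0)
    L = 116.0 * f[1] - 16.0
    a = 500.0 * (f[0] - f[1])
    b = 200.0 * (f[1] - f[2])
    return (float(L), float(a), float(b))


def ciede2000(lab1: Sequence[float], lab2: Sequence[float]) -> float:
    """CIEDE2000 color difference Delta E_00 between two LAB triples."""
    L1, a1, b1 = (float(x) for x in lab1)
    L2, a2, b2 = (float(x) for x in lab2)

    C1 = np.hypot(a1, b1)
    C2 = np.hypot(a2, b2)
    Cbar = (C1 + C2) / 2.0
    G = 0.5 * (1.0 - np.sqrt(Cbar**7 / (Cbar**7 + 25.0**7)))
    a1p = (1.0 + G) * a1
    a2p = (1.0 + G) * a2
    C1p = np.hypot(a1p, b1)
    C2p = np.hypot(a2p, b2)

    # hue angles in degrees, in [0, 360); undefined (set 0) when C'=0
    h1p = np.degrees(np.arctan2(b1, a1p)) % 360.0 if C1p > 0 else 0.0
    h2p = np.degrees(np.arctan2(b2, a2p)) % 360.0 if C2p > 0 else 0.0

    dLp = L2 - L1
    dCp = C2p - C1p

    if C1p * C2p == 0:
        dhp = 0.0
    else:
        diff = h2p - h1p
        if abs(diff) <= 180.0:
            dhp = diff
        elif diff > 180.0:
            dhp = diff - 360.0
        else:
            dhp = diff + 360.0
    dHp = 2.0 * np.sqrt(C1p * C2p) * np.sin(np.radians(dhp) / 2.0)

    Lbp = (L1 + L2) / 2.0
    Cbp = (C1p + C2p) / 2.0
    if C1p * C2p == 0:
        hbp = h1p + h2p
    else:
        s = h1p + h2p
        if abs(h1p - h2p) <= 180.0:
            hbp = s / 2.0
        elif s < 360.0:
            hbp = (s + 360.0) / 2.0
        else:
            hbp = (s - 360.0) / 2.0

    T = (
        1.0
        - 0.17 * np.cos(np.radians(hbp - 30.0))
        + 0.24 * np.cos(np.radians(2.0 * hbp))
        + 0.32 * np.cos(np.radians(3.0 * hbp + 6.0))
        - 0.20 * np.cos(np.radians(4.0 * hbp - 63.0))
    )
    d_theta = 30.0 * np.exp(-(((hbp - 275.0) / 25.0) ** 2))
    R_C = 2.0 * np.sqrt(Cbp**7 / (Cbp**7 + 25.0**7))
    S_L = 1.0 + 0.015 * (Lbp - 50.0) ** 2 / np.sqrt(20.0 + (Lbp - 50.0) ** 2)
    S_C = 1.0 + 0.045 * Cbp
    S_H = 1.0 + 0.015 * Cbp * T
    R_T = -np.sin(np.radians(2.0 * d_theta)) * R_C

    return float(
        np.sqrt(
            (dLp / S_L) ** 2
            + (dCp / S_C) ** 2
            + (dHp / S_H) ** 2
            + R_T * (dCp / S_C) * (dHp / S_H)
        )
    )


@dataclass(frozen=True)
class ColorSet:
    """A list of color stimuli with parsed RGB and derived LAB coordinates."""

    labels: tuple[str, ...]  # hex codes as given
    rgb: np.ndarray = field(repr=False)  # n x 3 ints in [0, 255]
    lab: np.ndarray = field(repr=False)  # n x 3 CIELAB

    @classmethod
    def from_hex(cls, codes: Iterable[str]) -> "ColorSet":
        codes = list(codes)
        rgb = np.array([parse_hex(c) for c in codes], dtype=int)
        lab = np.array([srgb_to_lab(row) for row in rgb])
        return cls(labels=tuple(codes), rgb=rgb, lab=lab)

    def __len__(self) -> int:
        return len(self.labels)


def rgb_dissimilarity(colors: ColorSet) -> DissimilarityMatrix:
    """Pairwise Euclidean distance in 8-bit RGB space."""
    if len(colors) < 2:
        raise ValueError("need at least 2 colors")
    rgb = colors.rgb.astype(float)
    diff = rgb[:, None, :] - rgb[None, :, :]
    values = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(values, 0.0)
    return DissimilarityMatrix(colors.labels, values)


def lab_dissimilarity(colors: ColorSet) -> DissimilarityMatrix:
    """Pairwise CIEDE2000 differences of the LAB coordinates."""
    if len(colors) < 2:
        raise ValueError("need at least 2 colors")
    n = len(colors)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = ciede2000(colors.lab[i], colors.lab[j])
            values[i, j] = values[j, i] = d
    return DissimilarityMatrix(colors.labels, values)


def read_color_list(path: str | Path) -> ColorSet:
    """Read colors from a text file (one hex code per line) or a CSV with a
    ``hex`` column (optionally ``label``)."""
    path = Path(path)
    text = path.read_text().strip()
    first = text.splitlines()[0]
    if "," in first:
        df = pd.read_csv(path)
        if "hex" not in df.columns:
            raise ValueError(f"CSV color list {path} needs a 'hex' column")
        return ColorSet.from_hex(df["hex"].astype(str))
    return ColorSet.from_hex(
        line.strip() for line in text.splitlines() if line.strip()
    )
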