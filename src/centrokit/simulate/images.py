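"""Synthetic multi-channel nucleus images with known radial ground truth.

Channel 0: nucleus disks (DNA-like); channel 1: Gaussian foci
(CENP-A-like); channel 2: background + a piecewise-constant radial
function of the distance to the nearest focus + Gaussian noise
(H3K9me3-like). Ground truth (nucleus label mask, focus table) is
returned alongside the pixel data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ImageSpec:
    shape: tuple[int, int]
    pixel_size: float  # um / px
    #: (center_y, center_x, radius) in px
    nuclei: Sequence[tuple[float, float, float]]
    #: (nucleus_index, center_y, center_x, amplitude, sigma_px)
    foci: Sequence[tuple[int, float, float, float, float]] = field(
        default_factory=tuple
    )
    #: piecewise radial intensity for channel 2: (upper_radius_um, value)
    #: pairs, sorted by radius; use math.inf for the tail. Radii beyond the
    #: last breakpoint score 0.
    radial_profile: Sequence[tuple[float, float]] = field(default_factory=tuple)
    nucleus_value: float = 1000.0
    background: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        for ni, cy, cx, amp, sigma in self.foci:
            if not 0 <= ni < len(self.nuclei):
                raise ValueError(f"focus references unknown nucleus {ni}")
            ny, nx, r = self.nuclei[ni]
            if math.hypot(cy - ny, cx - nx) > r:
                raise ValueError(
                    f"focus ({cy}, {cx}) lies outside nucleus {ni}"
                )
            if sigma <= 0:
                raise ValueError("focus sigma must be > 0")
        radii = [r for r, _ in self.radial_profile]
        if radii != sorted(radii):
            raise ValueError("radial_profile radii must be non-decreasing")


@dataclass
class SyntheticImage:
    channels: np.ndarray        # 3 x H x W float
    nucleus_labels: np.ndarray  # H x W int, 0 = background
    foci: pd.DataFrame          # nucleus, focus, y, x, amplitude, sigma

    @property
    def dna(self) -> np.ndarray:
        return self.channels[0]

    @property
    def focus_channel(self) -> np.ndarray:
        return self.channels[1]

    @property
    def measure_channel(self) -> np.ndarray:
        return self.channels[2]


def evaluate_radial(
    profile: Sequence[tuple[float, float]], r: np.ndarray | float
) -> np.ndarray | float:
    """Evaluate a piecewise-constant radial profile at radius r (um).

    Segment i covers (upper_{i-1}, upper_i]; r = 0 falls in the first
    segment. Radii beyond the last breakpoint give 0.
    """
    r = np.asarray(r, dtype=float)
    out = np.zeros_like(r)
    assigned = np.zeros(r.shape, dtype=bool)
    lower = 0.0
    for i, (upper, value) in enumerate(profile):
        if i == 0:
            sel = r <= upper
        else:
            sel = (r > lower) & (r <= upper)
        out[sel & ~assigned] = value
        assigned |= sel
        lower = upper
    return out if out.ndim else float(out)


def simulate_nucleus_image(spec: ImageSpec) -> SyntheticImage:
    """Render the three channels and ground truth. Deterministic under seed."""
    h, w = spec.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    labels = np.zeros((h, w), dtype=np.int32)
    for i, (cy, cx, r) in enumerate(spec.nuclei, start=1):
        labels[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = i
    dna = np.where(labels > 0, spec.nucleus_value, 0.0)

    focus_ch = np.zeros((h, w), dtype=float)
    for _, cy, cx, amp, sigma in spec.foci:
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        focus_ch += amp * np.exp(-d2 / (2 * sigma * sigma))

    measure = np.full((h, w), float(spec.background))
    if spec.foci and spec.radial_profile:
        d2min = np.full((h, w), np.inf)
        for _, cy, cx, _, _ in spec.foci:
            d2 = (yy - cy) ** 2 + (xx - cx) ** 2
            np.minimum(d2min, d2, out=d2min)
        r_um = np.sqrt(d2min) * spec.pixel_size
        measure += evaluate_radial(spec.radial_profile, r_um)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        measure = measure + rng.normal(0.0, spec.noise_sd, size=(h, w))

    foci_df = pd.DataFrame(
        [
            {
                "nucleus": ni + 1,
                "focus": fi,
                "y": cy,
                "x": cx,
                "amplitude": amp,
                "sigma": sigma,
            }
            for fi, (ni, cy, cx, amp, sigma) in enumerate(spec.foci)
        ],
        columns=["nucleus", "focus", "y", "x", "amplitude", "sigma"],
    )
    return SyntheticImage(np.stack([dna, focus_ch, measure]), labels, foci_df)
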