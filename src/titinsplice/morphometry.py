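"""Sarcomere morphometry from 1-D fluorescence line profiles.

Sarcomere lengths are measured as distances between successive Z-line
(α-actinin) fluorescence peaks along a line profile; length variability
between groups is compared by an F-test of sample variances; proximal-Ig
domain length is proxied by the positional difference between the Z-line
(or Z1Z2) epitope and the N2A epitope, which flank the proximal Ig
segment of titin's I-band spring.

Peak positions are refined to sub-pixel precision by a three-point
parabolic fit around each local maximum, since epitope distances are on
the nm scale while pixels are typically ~10 nm or coarser.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import find_peaks

__all__ = [
    "LineProfileSet",
    "SarcomereLengths",
    "VarianceTest",
    "detect_peaks",
    "sarcomere_lengths",
    "variance_test",
    "epitope_distance",
]


@dataclass
class LineProfileSet:
    """Named 1-D intensity channels on a shared axis with a pixel size in nm."""

    channels: dict[str, np.ndarray]
    pixel_size: float  # nm per pixel

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        lengths = {k: len(v) for k, v in self.channels.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"channels differ in length: {lengths}")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.channels)
        df.insert(0, "position", np.arange(len(df)))
        return df


@dataclass(frozen=True)
class SarcomereLengths:
    """Successive Z-peak spacings with a physiological-window validity mask."""

    lengths_nm: np.ndarray
    valid: np.ndarray  # True where inside the physiological window

    @property
    def valid_lengths_nm(self) -> np.ndarray:
        return self.lengths_nm[self.valid]

    @property
    def n_flagged(self) -> int:
        return int((~self.valid).sum())


@dataclass(frozen=True)
class VarianceTest:
    """Two-sided F-test of equality of variances.

    ``F`` preserves direction (variance a over variance b);
    ``F_larger_over_smaller`` is the conventional >= 1 form.
    """

    F: float
    df1: int
    df2: int
    p_value: float

    @property
    def F_larger_over_smaller(self) -> float:
        return self.F if self.F >= 1 else 1.0 / self.F


def detect_peaks(
    profile: np.ndarray,
    pixel_size: float,
    min_separation: float = 1000.0,
    min_prominence: float = 0.2,
) -> np.ndarray:
    """Peak positions (nm) along a 1-D intensity profile.

    Local maxima must be separated by at least ``min_separation`` nm and
    have prominence of at least ``min_prominence`` times the profile's
    dynamic range.  Each surviving maximum is refined by fitting a
    parabola through the three samples around it; a flat profile yields
    an empty result.
    """
    y = np.asarray(profile, dtype=float)
    if y.size < 3:
        raise ValueError("profile must have at least 3 samples")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    rng = float(np.ptp(y))
    if rng == 0:
        return np.empty(0)
    distance = max(1, int(round(min_separation / pixel_size)))
    idx, _ = find_peaks(y, prominence=min_prominence * rng, distance=distance)
    positions = []
    for i in idx:
        if 0 < i < y.size - 1:
            denom = y[i - 1] - 2 * y[i] + y[i + 1]
            delta = 0.0 if denom == 0 else 0.5 * (y[i - 1] - y[i + 1]) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        positions.append((i + delta) * pixel_size)
    return np.asarray(positions)


def sarcomere_lengths(
    z_peaks: np.ndarray,
    min_length: float = 1000.0,
    max_length: float = 5000.0,
) -> SarcomereLengths:
    """Successive Z-peak spacings in nm, flagging non-physiological values.

    Spacings outside [min_length, max_length] nm (default 1.0-5.0 µm)
    are flagged and excluded from summaries but retained in the result.
    """
    z = np.sort(np.asarray(z_peaks, dtype=float))
    if z.size < 2:
        warnings.warn("fewer than 2 Z peaks: no sarcomere lengths", stacklevel=2)
        return SarcomereLengths(np.empty(0), np.empty(0, dtype=bool))
    d = np.diff(z)
    valid = (d >= min_length) & (d <= max_length)
    return SarcomereLengths(d, valid)


def variance_test(lengths_a: np.ndarray, lengths_b: np.ndarray) -> VarianceTest:
    """Two-sided F-test comparing group variances, F = s2_a / s2_b.

    Degrees of freedom are (n_a - 1, n_b - 1); the two-sided p-value is
    twice the smaller tail of the F distribution.  Two groups with equal
    variance (including two identical noiseless samples) give F = 1,
    p = 1 exactly.
    """
    a = np.asarray(lengths_a, dtype=float)
    b = np.asarray(lengths_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    va = float(np.var(a, ddof=1))
    vb = float(np.var(b, ddof=1))
    df1, df2 = a.size - 1, b.size - 1
    if va == vb:
        return VarianceTest(1.0, df1, df2, 1.0)
    if vb == 0:
        return VarianceTest(math.inf, df1, df2, 0.0)
    F = va / vb
    p = 2.0 * min(stats.f.cdf(F, df1, df2), stats.f.sf(F, df1, df2))
    return VarianceTest(F, df1, df2, float(min(p, 1.0)))


def epitope_distance(
    z_peaks: np.ndarray,
    epitope_peaks: np.ndarray,
    max_half_sarcomere: float = 1500.0,
) -> np.ndarray:
    """Z-line to epitope distances, one per resolvable half-sarcomere (nm).

    For each Z peak the nearest epitope peak on each side within
    ``max_half_sarcomere`` nm contributes one distance.  Matching is
    greedy by increasing distance and each epitope peak may serve only
    one Z peak, so a peak between two Z lines is never double counted;
    unmatched sides are simply missing from the result.
    """
    z = np.sort(np.asarray(z_peaks, dtype=float))
    e = np.sort(np.asarray(epitope_peaks, dtype=float))
    if z.size == 0 or e.size == 0:
        return np.empty(0)
    candidates: list[tuple[float, int, int, int]] = []  # (dist, z index, side, e index)
    for zi, zpos in enumerate(z):
        left = np.searchsorted(e, zpos) - 1
        right = left + 1
        if left >= 0 and zpos - e[left] <= max_half_sarcomere:
            candidates.append((zpos - e[left], zi, -1, left))
        if right < e.size and e[right] - zpos <= max_half_sarcomere:
            candidates.append((e[right] - zpos, zi, +1, right))
    candidates.sort()
    used_e: set[int] = set()
    used_side: set[tuple[int, int]] = set()
    out: list[float] = []
    for dist, zi, side, ei in candidates:
        if ei in used_e or (zi, side) in used_side:
            continue
        used_e.add(ei)
        used_side.add((zi, side))
        out.append(dist)
    return np.asarray(out)
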