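"""Percent-spliced-in (PSI) analysis of exon junction read counts.

PSI estimator
-------------
An included cassette exon is supported by two junctions (upstream and
downstream inclusion junctions) while skipping is supported by one, so
inclusion evidence is halved before forming the ratio::

    PSI = (I / 2) / (I / 2 + S)

where ``I`` is the summed inclusion-junction read count and ``S`` the
skipping-junction count.  A raw ratio ``I / (I + S)`` is available via
``estimator='raw'``.  PSI is undefined (missing, never 0) when there is
no junction evidence at all.

Event-level analysis averages exon PSI over a contiguous exon range per
sample and compares groups by a two-sample t-test with samples as
replicates.  ``segment_event_by_similarity`` partitions a large range
into k contiguous segments of similar PSI by exact dynamic programming.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ValidationError

__all__ = [
    "JunctionCounts",
    "PsiTable",
    "compute_psi",
    "delta_psi",
    "aggregate_events",
    "segment_event_by_similarity",
]

Region = tuple[int, int]


@dataclass
class JunctionCounts:
    """Per exon x sample inclusion/skipping junction read counts.

    ``inclusion`` and ``skipping`` are integer DataFrames with identical
    exon index and sample columns; ``groups`` maps sample -> group label.
    """

    inclusion: pd.DataFrame
    skipping: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        if not self.inclusion.index.equals(self.skipping.index) or list(
            self.inclusion.columns
        ) != list(self.skipping.columns):
            raise ValidationError("inclusion and skipping tables must be aligned")
        for df in (self.inclusion, self.skipping):
            arr = df.to_numpy()
            if (arr < 0).any():
                raise ValidationError("junction counts must be non-negative")
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("junction counts must be integers")
        missing = [s for s in self.inclusion.columns if s not in self.groups]
        if missing:
            raise ConfigurationError(f"samples without a group label: {missing}")


@dataclass
class PsiTable:
    """Exon x sample PSI values in [0, 1] (NaN where evidence is absent)."""

    psi: pd.DataFrame
    groups: dict[str, str]

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.psi.columns if self.groups[s] == group]


def compute_psi(counts: JunctionCounts, estimator: str = "junction_normalized") -> PsiTable:
    """Estimate PSI per exon and sample from junction counts."""
    I = counts.inclusion.to_numpy(dtype=float)
    S = counts.skipping.to_numpy(dtype=float)
    if estimator == "junction_normalized":
        inc = I / 2.0
    elif estimator == "raw":
        inc = I
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    denom = inc + S
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(denom > 0, inc / denom, np.nan)
    return PsiTable(
        psi=pd.DataFrame(psi, index=counts.inclusion.index, columns=counts.inclusion.columns),
        groups=dict(counts.groups),
    )


def delta_psi(psi: PsiTable, group_a: str, group_b: str) -> pd.Series:
    """Per-exon ΔPSI = mean PSI(group_b) - mean PSI(group_a).

    NaN where either group has no sample with defined PSI at the exon.
    """
    a = psi.psi[psi.samples_in_group(group_a)].mean(axis=1, skipna=True)
    b = psi.psi[psi.samples_in_group(group_b)].mean(axis=1, skipna=True)
    return b - a


def event_psi(psi: PsiTable, event: Region) -> pd.DataFrame:
    """Per-sample mean PSI over the exons of one event (row-vector frame)."""
    lo, hi = event
    exons = [e for e in psi.psi.index if lo <= e <= hi]
    return psi.psi.loc[exons].mean(axis=0, skipna=True).to_frame().T


def aggregate_events(
    psi: PsiTable,
    events: Sequence[Region],
    group_a: str,
    group_b: str,
    equal_var: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample event PSI and a per-event group comparison.

    Each event's PSI in a sample is the mean over its member exons with
    defined PSI (missing when no member exon is defined).  Per event a
    classical two-sample t-test across samples compares the groups; no
    multiple-testing correction is applied across events (per-event
    p-values are reported).

    Returns
    -------
    (per_sample, tests)
        ``per_sample``: events x samples DataFrame of event PSI.
        ``tests``: one row per event with group means, delta_psi, t, p.
    """
    for i, (lo_i, hi_i) in enumerate(events):
        for lo_j, hi_j in events[i + 1 :]:
            if max(lo_i, lo_j) <= min(hi_i, hi_j):
                raise ConfigurationError("events must be non-overlapping")
    rows = []
    labels = []
    for lo, hi in events:
        exons = [e for e in psi.psi.index if lo <= e <= hi]
        rows.append(psi.psi.loc[exons].mean(axis=0, skipna=True))
        labels.append(f"{lo}-{hi}")
    per_sample = pd.DataFrame(rows, index=labels)

    test_rows = []
    for (lo, hi), label in zip(events, labels):
        a = per_sample.loc[label, psi.samples_in_group(group_a)].dropna().to_numpy(float)
        b = per_sample.loc[label, psi.samples_in_group(group_b)].dropna().to_numpy(float)
        mean_a = float(a.mean()) if a.size else math.nan
        mean_b = float(b.mean()) if b.size else math.nan
        if a.size >= 2 and b.size >= 2:
            t, p = stats.ttest_ind(b, a, equal_var=equal_var)
        else:
            t, p = math.nan, math.nan
        test_rows.append(
            {
                "event": label,
                "start_exon": lo,
                "end_exon": hi,
                "n_a": a.size,
                "n_b": b.size,
                "mean_psi_a": mean_a,
                "mean_psi_b": mean_b,
                "delta_psi": mean_b - mean_a,
                "t_statistic": float(t),
                "p_value": float(p),
            }
        )
    return per_sample, pd.DataFrame(test_rows).set_index("event")


def _segment_cost(prefix: np.ndarray, prefix_sq: np.ndarray, i: int, j: int) -> float:
    """Within-segment sum of squared deviations for values[i:j] (0-based, half-open)."""
    n = j - i
    s = prefix[j] - prefix[i]
    sq = prefix_sq[j] - prefix_sq[i]
    return max(sq - s * s / n, 0.0)


def segment_event_by_similarity(
    psi: PsiTable, exon_range: Region, k: int
) -> list[Region]:
    """Split a contiguous exon range into k segments of similar mean PSI.

    Minimizes the total within-segment sum of squared deviations of the
    per-exon mean PSI (averaged over all samples) by exact dynamic
    programming over contiguous partitions.  Ties break toward the
    earliest boundaries.

    Returns the partition as a list of inclusive genomic exon ranges.
    """
    lo, hi = exon_range
    exons = [e for e in psi.psi.index if lo <= e <= hi]
    n = len(exons)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    values = psi.psi.loc[exons].mean(axis=1, skipna=True).to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValidationError("exon(s) with no defined PSI inside the range")

    prefix = np.concatenate([[0.0], np.cumsum(values)])
    prefix_sq = np.concatenate([[0.0], np.cumsum(values**2)])

    # dp[j][i]: min cost of splitting values[i:] into j segments
    INF = math.inf
    dp = [[INF] * (n + 1) for _ in range(k + 1)]
    nxt = [[-1] * (n + 1) for _ in range(k + 1)]
    dp[0][n] = 0.0
    for j in range(1, k + 1):
        for i in range(n - 1, -1, -1):
            best, arg = INF, -1
            for m in range(i + 1, n + 1):  # segment values[i:m]
                rest = dp[j - 1][m]
                if rest == INF:
                    continue
                c = _segment_cost(prefix, prefix_sq, i, m) + rest
                if c < best:  # strict improvement keeps earliest boundary
                    best, arg = c, m
            dp[j][i], nxt[j][i] = best, arg

    bounds: list[Region] = []
    i, j = 0, k
    while j > 0:
        m = nxt[j][i]
        bounds.append((exons[i], exons[m - 1]))
        i, j = m, j - 1
    return bounds
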