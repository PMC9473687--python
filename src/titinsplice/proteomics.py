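"""Label-free LC-MS peptide quantification over titin exon regions.

The quantification convention:

1. peptides whose median peak area in the control group falls below a
   threshold (default 1.5e7 units) are excluded;
2. each remaining peak area is divided, per sample, by the mean peak
   area of peptides mapping entirely inside the constitutive region
   (exons 256-363, not alternatively spliced);
3. per peptide and group, the median normalized abundance across that
   group's samples is taken; a region's group mean/SD are computed over
   its member peptides' medians, and the percent difference is reported
   on this linear scale;
4. group comparison is a two-sample t-test on the natural log of the
   per-peptide group medians (log-normal peak areas), with a Bonferroni
   adjusted significance threshold alpha / n_regions_tested.

Peptides occurring at more than one locus in the protein (``n_loci > 1``;
titin's Ig/PEVK repeats guarantee some) are excluded from exon-specific
quantification by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, NormalizationError
from .exon_model import MappedPeptide

__all__ = [
    "PeptideTable",
    "RegionSummary",
    "GelLanes",
    "filter_low_abundance",
    "count_covered_exons",
    "normalize_to_constitutive",
    "summarize_region",
    "compare_region",
    "gel_isoform_fractions",
]

logger = logging.getLogger(__name__)

Region = tuple[int, int]


@dataclass
class PeptideTable:
    """Peptides x samples peak-area matrix with group labels.

    Attributes
    ----------
    peptides : list of MappedPeptide
        Row annotations, aligned with ``abundances.index``.
    abundances : DataFrame
        Non-negative peak areas (NaN = missing), indexed by unique
        peptide ids, one column per sample.
    groups : dict
        sample name -> group label; every sample column must be present.
    """

    peptides: list[MappedPeptide]
    abundances: pd.DataFrame
    groups: dict[str, str]
    normalized: bool = False

    def __post_init__(self) -> None:
        if len(self.peptides) != len(self.abundances):
            raise ValueError("peptides and abundance rows differ in length")
        if self.abundances.index.has_duplicates:
            raise ValueError("peptide identifiers must be unique")
        missing = [s for s in self.abundances.columns if s not in self.groups]
        if missing:
            raise ConfigurationError(f"samples without a group label: {missing}")
        if (self.abundances.to_numpy(dtype=float) < 0).any():
            raise ValueError("peak areas must be >= 0 or missing")

    @property
    def sample_names(self) -> list[str]:
        return list(self.abundances.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.abundances.columns if self.groups[s] == group]

    def exon_sets(self) -> pd.Series:
        return pd.Series(
            [p.exon_set for p in self.peptides], index=self.abundances.index
        )

    def subset(self, mask: np.ndarray | pd.Series) -> "PeptideTable":
        mask = np.asarray(mask, dtype=bool)
        return PeptideTable(
            peptides=[p for p, m in zip(self.peptides, mask) if m],
            abundances=self.abundances.loc[mask],
            groups=dict(self.groups),
            normalized=self.normalized,
        )

    def region_members(
        self,
        region: Region,
        membership: str = "strict",
        unique_only: bool = True,
    ) -> np.ndarray:
        """Boolean mask of peptides belonging to an inclusive exon range.

        ``membership='strict'`` requires every exon of the peptide to lie
        inside the range (no double counting across adjacent regions);
        ``'any'`` requires overlap.  ``unique_only`` drops peptides with
        ``n_loci > 1``.
        """
        lo, hi = region
        out = np.zeros(len(self.peptides), dtype=bool)
        for i, p in enumerate(self.peptides):
            if unique_only and p.n_loci > 1:
                continue
            if not p.exon_set:
                continue
            if membership == "strict":
                out[i] = all(lo <= e <= hi for e in p.exon_set)
            elif membership == "any":
                out[i] = any(lo <= e <= hi for e in p.exon_set)
            else:
                raise ValueError(f"unknown membership policy {membership!r}")
        return out


@dataclass
class RegionSummary:
    """Group-level summary of normalized peptide abundance in an exon region."""

    region: Region
    group_a: str
    group_b: str
    n_peptides_a: int
    n_peptides_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    percent_difference: float  # 100 * (mean_b - mean_a) / mean_a; NaN if undefined
    undefined_reference: bool = False
    t_statistic: float = math.nan
    p_value: float = math.nan
    alpha_adjusted: float = math.nan
    significant: bool | None = None
    n_excluded_nonpositive: int = 0

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["region"] = list(self.region)
        return d


@dataclass(frozen=True)
class GelLanes:
    """Densitometric band intensities per gel lane (long T1, short T1, T2)."""

    long_t1: Sequence[float]
    short_t1: Sequence[float]
    t2: Sequence[float]


def _group_medians(table: PeptideTable, group: str) -> pd.Series:
    samples = table.samples_in_group(group)
    if not samples:
        raise ConfigurationError(f"no samples in group {group!r}")
    return table.abundances[samples].median(axis=1, skipna=True)


def filter_low_abundance(
    table: PeptideTable, control_group: str, threshold: float = 1.5e7
) -> PeptideTable:
    """Drop peptides whose control-group median peak area is below ``threshold``.

    Values strictly less than the threshold are excluded; a median equal
    to the threshold is kept.  Missing values are ignored in the median;
    a peptide missing in every control sample counts as below threshold.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    med = _group_medians(table, control_group)
    keep = (med >= threshold).fillna(False).to_numpy()
    logger.info(
        "abundance filter: retained %d of %d peptides (threshold %.3g)",
        int(keep.sum()), len(keep), threshold,
    )
    return table.subset(keep)


def count_covered_exons(table: PeptideTable) -> int:
    """Number of distinct genomic exons covered by the table's peptides."""
    covered: set[int] = set()
    for p in table.peptides:
        covered |= p.exon_set
    return len(covered)


def normalize_to_constitutive(
    table: PeptideTable,
    constitutive_region: Region = (256, 363),
    unique_only: bool = True,
) -> PeptideTable:
    """Divide each sample's peak areas by that sample's mean constitutive peak area.

    The constitutive region (default exons 256-363) shows no evidence of
    alternative splicing, so its mean abundance serves as a per-sample
    loading/ionization reference; after the call the mean normalized
    abundance of constitutive peptides is 1 in every sample.

    Raises
    ------
    NormalizationError
        If some sample has no constitutive peptide with a value.
    """
    member = table.region_members(constitutive_region, "strict", unique_only)
    if not member.any():
        raise NormalizationError(
            f"no peptide maps entirely within constitutive region {constitutive_region}"
        )
    const = table.abundances.loc[member]
    denom = const.mean(axis=0, skipna=True)
    bad = [s for s in table.sample_names if not np.isfinite(denom[s]) or denom[s] <= 0]
    if bad:
        raise NormalizationError(f"no usable constitutive peptide value in sample(s) {bad}")
    out = table.abundances.div(denom, axis=1)
    return PeptideTable(
        peptides=list(table.peptides),
        abundances=out,
        groups=dict(table.groups),
        normalized=True,
    )


def summarize_region(
    table: PeptideTable,
    region: Region,
    group_a: str,
    group_b: str,
    membership: str = "strict",
    unique_only: bool = True,
) -> RegionSummary:
    """Mean/SD of per-peptide group-median normalized abundance in a region.

    ``percent_difference`` is 100 * (mean_b - mean_a) / mean_a on the
    linear normalized scale.  If the reference group has no detected
    member peptide the summary is returned with ``undefined_reference``
    set and a NaN percent difference.
    """
    lo, hi = region
    if hi < lo:
        raise ValueError(f"empty region {region}")
    member = table.region_members(region, membership, unique_only)
    med_a = _group_medians(table, group_a)[member]
    med_b = _group_medians(table, group_b)[member]
    med_a = med_a.dropna()
    med_b = med_b.dropna()

    mean_a = float(med_a.mean()) if len(med_a) else math.nan
    mean_b = float(med_b.mean()) if len(med_b) else math.nan
    undefined = len(med_a) == 0 or not (mean_a > 0)
    pct = math.nan if undefined else 100.0 * (mean_b - mean_a) / mean_a
    return RegionSummary(
        region=region,
        group_a=group_a,
        group_b=group_b,
        n_peptides_a=int(len(med_a)),
        n_peptides_b=int(len(med_b)),
        mean_a=mean_a,
        mean_b=mean_b,
        sd_a=float(med_a.std(ddof=1)) if len(med_a) > 1 else math.nan,
        sd_b=float(med_b.std(ddof=1)) if len(med_b) > 1 else math.nan,
        percent_difference=pct,
        undefined_reference=undefined,
    )


def compare_region(
    table: PeptideTable,
    region: Region,
    group_a: str,
    group_b: str,
    n_regions_tested: int = 2,
    alpha: float = 0.05,
    membership: str = "strict",
    unique_only: bool = True,
    equal_var: bool = True,
) -> RegionSummary:
    """Region summary plus a t-test on ln-transformed per-peptide group medians.

    Peptides are the replication unit (each peptide contributes its
    group-median normalized abundance).  Values <= 0 cannot be
    ln-transformed and are excluded with a logged count.  Significance is
    declared iff p < alpha / n_regions_tested (Bonferroni).
    """
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must be in (0, 1)")
    if n_regions_tested < 1:
        raise ConfigurationError("n_regions_tested must be >= 1")
    summary = summarize_region(table, region, group_a, group_b, membership, unique_only)
    member = table.region_members(region, membership, unique_only)
    a = _group_medians(table, group_a)[member].dropna()
    b = _group_medians(table, group_b)[member].dropna()
    n_bad = int((a <= 0).sum() + (b <= 0).sum())
    if n_bad:
        logger.warning("compare_region %s: excluded %d non-positive values", region, n_bad)
    a = np.log(a[a > 0].to_numpy())
    b = np.log(b[b > 0].to_numpy())

    summary.alpha_adjusted = alpha / n_regions_tested
    summary.n_excluded_nonpositive = n_bad
    if len(a) >= 2 and len(b) >= 2:
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
            t, p = 0.0, 1.0  # identical constant groups: no evidence of difference
        else:
            t, p = stats.ttest_ind(b, a, equal_var=equal_var)
        summary.t_statistic = float(t)
        summary.p_value = float(p)
        summary.significant = bool(p < summary.alpha_adjusted)
    return summary


def gel_isoform_fractions(lanes: GelLanes) -> pd.DataFrame:
    """Per-lane fractions of long T1, short T1 and T2 titin over total.

    Total titin is all bands combined; fractions sum to 1 per lane and
    the long:short T1 ratio is reported (inf when short T1 is 0).
    """
    arr = np.column_stack(
        [
            np.asarray(lanes.long_t1, dtype=float),
            np.asarray(lanes.short_t1, dtype=float),
            np.asarray(lanes.t2, dtype=float),
        ]
    )
    if (arr < 0).any():
        raise ValueError("band intensities must be >= 0")
    total = arr.sum(axis=1)
    if (total <= 0).any():
        raise ValueError("each lane needs at least one band > 0")
    frac = arr / total[:, None]
    with np.errstate(divide="ignore"):
        ratio = np.where(arr[:, 1] > 0, arr[:, 0] / arr[:, 1], np.inf)
    return pd.DataFrame(
        {
            "frac_long_t1": frac[:, 0],
            "frac_short_t1": frac[:, 1],
            "frac_t2": frac[:, 2],
            "long_to_short_ratio": ratio,
        }
    )
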