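"""End-to-end orchestration: config, staged runs, machine-readable reports.

Each ``run_*`` function executes one analysis arm on either preloaded
objects or the file paths named in the :class:`RunConfig`, logs
per-stage counts, and returns a JSON-serializable report that echoes the
configuration and package version, so identical config + seed give
bit-identical reports.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import __version__
from .errors import ConfigurationError
from .exon_model import ExonModel
from .io import (
    read_junction_counts,
    read_line_profiles,
    read_peptide_table,
    write_json_report,
)
from .morphometry import (
    LineProfileSet,
    detect_peaks,
    epitope_distance,
    sarcomere_lengths,
    variance_test,
)
from .proteomics import (
    PeptideTable,
    compare_region,
    count_covered_exons,
    filter_low_abundance,
    normalize_to_constitutive,
)
from .splicing import JunctionCounts, aggregate_events, compute_psi, delta_psi

__all__ = ["RunConfig", "run_proteomics", "run_splicing", "run_morphometry"]

logger = logging.getLogger(__name__)

Region = tuple[int, int]


@dataclass
class RunConfig:
    """Run parameters with the analysis defaults.

    Defaults: abundance filter threshold 1.5e7 peak-area units in the
    control group; constitutive normalization region exons 256-363;
    quantified regions / splicing events 52-69, 70-79, 80-88; alpha 0.05
    Bonferroni-adjusted over the 2 detected-in-both-groups regions.
    """

    group_a: str = "control"
    group_b: str = "knockout"
    filter_threshold: float = 1.5e7
    constitutive_region: Region = (256, 363)
    regions: list[Region] = field(default_factory=lambda: [(52, 69), (70, 79), (80, 88)])
    events: list[Region] = field(default_factory=lambda: [(52, 69), (70, 79), (80, 88)])
    alpha: float = 0.05
    n_regions_tested: int = 2
    membership: str = "strict"
    unique_only: bool = True
    psi_estimator: str = "junction_normalized"
    pixel_size_nm: float = 10.0
    z_channel: str = "actinin"
    epitope_channel: str = "epitope"
    z_min_separation_nm: float = 1000.0
    epitope_min_separation_nm: float = 200.0
    min_prominence: float = 0.2
    length_window_nm: tuple[float, float] = (1000.0, 5000.0)
    max_half_sarcomere_nm: float = 1500.0
    seed: int = 0
    # optional input paths (used when data are not passed in directly)
    peptide_table_path: str | None = None
    junction_counts_path: str | None = None
    profile_paths: dict[str, str] = field(default_factory=dict)  # group -> path
    groups_map: dict[str, str] = field(default_factory=dict)  # sample -> group
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        for lo, hi in [self.constitutive_region, *self.regions, *self.events]:
            if hi < lo or lo < 1:
                raise ConfigurationError(f"invalid exon range ({lo}, {hi})")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("constitutive_region", "length_window_nm"):
            if key in raw:
                raw[key] = tuple(raw[key])
        for key in ("regions", "events"):
            if key in raw:
                raw[key] = [tuple(r) for r in raw[key]]
        return cls(**raw)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["regions"] = [list(r) for r in self.regions]
        d["events"] = [list(r) for r in self.events]
        d["constitutive_region"] = list(self.constitutive_region)
        d["length_window_nm"] = list(self.length_window_nm)
        return d


def _report_shell(config: RunConfig, stage: str) -> dict:
    return {"stage": stage, "version": __version__, "config": config.echo()}


def run_proteomics(
    config: RunConfig,
    table: PeptideTable | None = None,
    model: ExonModel | None = None,
) -> dict:
    """Filter -> normalize -> summarize -> compare, over all configured regions."""
    if table is None:
        if not config.peptide_table_path:
            raise ConfigurationError("no peptide table given (object or path)")
        if not config.groups_map:
            raise ConfigurationError("groups_map required to read a peptide table")
        table = read_peptide_table(
            config.peptide_table_path, groups=config.groups_map, model=model
        )
    report = _report_shell(config, "proteomics")
    report["n_peptides_input"] = len(table.peptides)

    filtered = filter_low_abundance(table, config.group_a, config.filter_threshold)
    report["n_peptides_retained"] = len(filtered.peptides)
    report["n_exons_covered"] = count_covered_exons(filtered)

    normalized = normalize_to_constitutive(
        filtered, config.constitutive_region, config.unique_only
    )
    regions = {}
    for region in config.regions:
        summary = compare_region(
            normalized,
            region,
            config.group_a,
            config.group_b,
            n_regions_tested=config.n_regions_tested,
            alpha=config.alpha,
            membership=config.membership,
            unique_only=config.unique_only,
        )
        regions[f"{region[0]}-{region[1]}"] = summary.to_dict()
        logger.info(
            "region %s: %%diff=%.2f p=%.3g", region, summary.percent_difference, summary.p_value
        )
    report["regions"] = regions
    return report


def run_splicing(config: RunConfig, counts: JunctionCounts | None = None) -> dict:
    """PSI -> ΔPSI -> event aggregation and per-event group tests."""
    if counts is None:
        if not config.junction_counts_path:
            raise ConfigurationError("no junction counts given (object or path)")
        if not config.groups_map:
            raise ConfigurationError("groups_map required to read junction counts")
        counts = read_junction_counts(config.junction_counts_path, config.groups_map)
    report = _report_shell(config, "splicing")
    psi = compute_psi(counts, estimator=config.psi_estimator)
    report["n_exons"] = int(psi.psi.shape[0])
    report["n_exons_defined"] = int(psi.psi.notna().any(axis=1).sum())

    dpsi = delta_psi(psi, config.group_a, config.group_b)
    per_sample, tests = aggregate_events(psi, config.events, config.group_a, config.group_b)
    report["delta_psi_by_exon"] = {int(k): (None if np.isnan(v) else float(v)) for k, v in dpsi.items()}
    report["event_psi_per_sample"] = {
        e: {s: (None if np.isnan(v) else float(v)) for s, v in row.items()}
        for e, row in per_sample.iterrows()
    }
    report["event_tests"] = tests.reset_index().to_dict(orient="records")
    return report


def _measure_group(profiles: LineProfileSet, config: RunConfig) -> dict:
    z = detect_peaks(
        profiles.channels[config.z_channel],
        profiles.pixel_size,
        config.z_min_separation_nm,
        config.min_prominence,
    )
    lengths = sarcomere_lengths(z, *config.length_window_nm)
    out = {
        "n_z_peaks": int(z.size),
        "n_lengths": int(lengths.valid_lengths_nm.size),
        "n_flagged": lengths.n_flagged,
        "mean_length_um": float(np.mean(lengths.valid_lengths_nm) / 1000.0)
        if lengths.valid_lengths_nm.size
        else None,
        "sd_length_um": float(np.std(lengths.valid_lengths_nm, ddof=1) / 1000.0)
        if lengths.valid_lengths_nm.size > 1
        else None,
        "_lengths_nm": lengths.valid_lengths_nm,
    }
    if config.epitope_channel in profiles.channels:
        epi = detect_peaks(
            profiles.channels[config.epitope_channel],
            profiles.pixel_size,
            config.epitope_min_separation_nm,
            config.min_prominence,
        )
        dists = epitope_distance(z, epi, config.max_half_sarcomere_nm)
        out["n_epitope_peaks"] = int(epi.size)
        out["n_half_sarcomeres"] = int(dists.size)
        out["mean_proximal_ig_nm"] = float(dists.mean()) if dists.size else None
        out["sem_proximal_ig_nm"] = (
            float(np.std(dists, ddof=1) / np.sqrt(dists.size)) if dists.size > 1 else None
        )
    return out


def run_morphometry(
    config: RunConfig,
    profiles_by_group: Mapping[str, LineProfileSet] | None = None,
) -> dict:
    """Peak detection, sarcomere lengths, group F-test, epitope distances."""
    if profiles_by_group is None:
        if not config.profile_paths:
            raise ConfigurationError("no line profiles given (objects or paths)")
        profiles_by_group = {
            g: read_line_profiles(p, config.pixel_size_nm)
            for g, p in config.profile_paths.items()
        }
    report = _report_shell(config, "morphometry")
    per_group = {}
    lengths = {}
    for g, prof in profiles_by_group.items():
        res = _measure_group(prof, config)
        lengths[g] = res.pop("_lengths_nm")
        per_group[g] = res
    report["groups"] = per_group

    a, b = config.group_a, config.group_b
    if a in lengths and b in lengths and lengths[a].size >= 2 and lengths[b].size >= 2:
        vt = variance_test(lengths[a], lengths[b])
        report["variance_test"] = {
            "F": vt.F,
            "F_larger_over_smaller": vt.F_larger_over_smaller,
            "df1": vt.df1,
            "df2": vt.df2,
            "p_value": vt.p_value,
        }
    return report


def write_report(report: dict, config: RunConfig, name: str) -> None:
    if config.output_dir:
        write_json_report(report, Path(config.output_dir) / f"{name}.json")
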