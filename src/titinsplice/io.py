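"""Readers and writers for the pipeline's plain-text formats.

Formats
-------
* transcript / genomic exon sequences: FASTA (Biopython);
* exon boundary and mapping tables: CSV/TSV with columns
  ``index,start,end[,genomic_number]``;
* peptide tables: CSV/TSV with a peptide-sequence column plus one
  abundance column per sample; a column-mapping config adapts arbitrary
  exported layouts (including an optional precomputed exon column);
* junction counts: tidy TSV with ``exon,sample,inclusion_reads,skipping_reads``;
* line profiles: CSV/TSV with a position index column and one intensity
  column per channel;
* results: tidy TSV tables plus JSON reports.
"""

from __future__ import annotations

import json
import re
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import PeptideNotFoundError, ValidationError
from .exon_model import ExonModel, MappedPeptide, map_peptide_to_exons
from .morphometry import LineProfileSet
from .proteomics import PeptideTable
from .splicing import JunctionCounts

__all__ = [
    "read_fasta",
    "read_exon_boundaries",
    "read_exon_mapping",
    "read_peptide_table",
    "read_junction_counts",
    "read_line_profiles",
    "write_json_report",
]


def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file -> ordered dict of id -> uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_exon_boundaries(path: str | Path) -> pd.DataFrame:
    """Exon boundary table with 1-based inclusive ``start``/``end`` columns."""
    df = _read_table(path)
    df.columns = [c.lower() for c in df.columns]
    for col in ("start", "end"):
        if col not in df.columns:
            raise ValidationError(f"boundary table {path} lacks column {col!r}")
    return df


def read_exon_mapping(path: str | Path) -> dict[int, int]:
    """Explicit transcript-exon -> genomic-exon-number mapping table."""
    df = _read_table(path)
    df.columns = [c.lower() for c in df.columns]
    if "index" not in df.columns or "genomic_number" not in df.columns:
        raise ValidationError(
            f"mapping table {path} needs columns 'index' and 'genomic_number'"
        )
    return {int(r["index"]): int(r["genomic_number"]) for _, r in df.iterrows()}


def _parse_exon_field(value) -> frozenset[int]:
    """Parse exon annotations like '52', '52;53', '52-54' or '52,53'."""
    out: set[int] = set()
    for token in re.split(r"[;,\s]+", str(value).strip()):
        if not token:
            continue
        if "-" in token[1:]:
            a, b = token.split("-", 1)
            out.update(range(int(a), int(b) + 1))
        else:
            out.add(int(token))
    return frozenset(out)


def read_peptide_table(
    path: str | Path,
    groups: Mapping[str, str],
    model: ExonModel | None = None,
    sequence_column: str = "peptide_sequence",
    sample_columns: Mapping[str, str] | None = None,
    exon_column: str | None = None,
) -> PeptideTable:
    """Read an exported peptide-level LC-MS table.

    Parameters
    ----------
    groups : mapping
        sample name -> group label for every abundance column used.
    model : ExonModel, optional
        If given, peptides are mapped to genomic exons through the model
        (rows whose sequence is absent from the model protein are
        dropped with a warning).  Alternatively ``exon_column`` names a
        column carrying precomputed exon annotations.
    sample_columns : mapping, optional
        file column name -> canonical sample name; defaults to using the
        keys of ``groups`` as literal column names.
    """
    df = _read_table(path)
    if sequence_column not in df.columns:
        raise ValidationError(f"peptide table lacks sequence column {sequence_column!r}")
    colmap = dict(sample_columns) if sample_columns else {s: s for s in groups}
    missing = [c for c in colmap if c not in df.columns]
    if missing:
        raise ValidationError(f"peptide table lacks sample columns {missing}")

    peptides: list[MappedPeptide] = []
    keep_rows: list[int] = []
    n_unmapped = 0
    for i, row in df.iterrows():
        seq = str(row[sequence_column]).strip().upper()
        if model is not None:
            try:
                pep = map_peptide_to_exons(seq, model)
            except PeptideNotFoundError:
                n_unmapped += 1
                continue
        else:
            exons = (
                _parse_exon_field(row[exon_column])
                if exon_column and pd.notna(row.get(exon_column))
                else frozenset()
            )
            pep = MappedPeptide(seq, 0, 0, exons, 1)
        peptides.append(pep)
        keep_rows.append(i)
    if n_unmapped:
        warnings.warn(f"{n_unmapped} peptide(s) not found in the model protein; dropped")

    abund = df.loc[keep_rows, list(colmap)].astype(float)
    abund.columns = [colmap[c] for c in abund.columns]
    abund.index = [f"row{r}_{p.sequence[:12]}" for r, p in zip(keep_rows, peptides)]
    if abund.index.has_duplicates:
        abund.index = [f"{ix}_{k}" for k, ix in enumerate(abund.index)]
    return PeptideTable(peptides=peptides, abundances=abund, groups=dict(groups))


def read_junction_counts(path: str | Path, groups: Mapping[str, str]) -> JunctionCounts:
    """Tidy junction count table -> :class:`JunctionCounts`.

    Expected columns: ``exon, sample, inclusion_reads, skipping_reads``.
    Malformed rows raise :class:`ValidationError` naming the line.
    """
    df = _read_table(path)
    required = ["exon", "sample", "inclusion_reads", "skipping_reads"]
    for col in required:
        if col not in df.columns:
            raise ValidationError(f"junction table lacks column {col!r}")
    for i, row in df.iterrows():
        try:
            int(row["exon"])
            inc, skp = int(row["inclusion_reads"]), int(row["skipping_reads"])
            if inc < 0 or skp < 0:
                raise ValueError
        except (TypeError, ValueError):
            raise ValidationError(f"malformed junction count row at line {i + 2} of {path}")
    inc = df.pivot_table(index="exon", columns="sample", values="inclusion_reads").astype(int)
    skp = df.pivot_table(index="exon", columns="sample", values="skipping_reads").astype(int)
    skp = skp.loc[inc.index, inc.columns]
    inc.columns.name = skp.columns.name = None
    return JunctionCounts(inclusion=inc, skipping=skp, groups=dict(groups))


def read_line_profiles(path: str | Path, pixel_size: float) -> LineProfileSet:
    """Multichannel profile table (position column + one column per channel)."""
    df = _read_table(path)
    pos_cols = [c for c in df.columns if c.lower() in {"position", "pos", "index", "pixel"}]
    channels = {c: df[c].to_numpy(dtype=float) for c in df.columns if c not in pos_cols}
    if not channels:
        raise ValidationError(f"no intensity channels found in {path}")
    return LineProfileSet(channels=channels, pixel_size=pixel_size)


def write_json_report(report: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=1, default=_default))
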