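"""Exon-annotated protein model of a transcript.

Builds a translated protein from a transcript sequence plus an exon
boundary table, tracks which genomic exon(s) encode every residue,
renumbers transcript exons to the genomic numbering scheme, and maps
(tryptic) peptides back to genomic exons.

Conventions
-----------
* All nucleotide and residue coordinates are 1-based inclusive.
* A residue whose codon spans an exon junction is annotated with every
  exon its codon nucleotides touch.
* Translation stops at the first in-frame stop codon; trailing UTR is
  ignored and the stop position is recorded on the model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .errors import (
    AmbiguousMatchError,
    PeptideNotFoundError,
    StructuralError,
    UnmatchedExonError,
)

__all__ = [
    "TranscriptExon",
    "ExonModel",
    "MappedPeptide",
    "build_exon_model",
    "renumber_exons",
    "digest_tryptic",
    "map_peptide_to_exons",
]


@dataclass(frozen=True)
class TranscriptExon:
    """One exon in transcript coordinates (1-based inclusive)."""

    index_in_transcript: int
    start_nt: int
    end_nt: int
    sequence: str

    def __post_init__(self) -> None:
        if self.end_nt < self.start_nt:
            raise StructuralError(
                f"exon {self.index_in_transcript}: end {self.end_nt} < start {self.start_nt}"
            )
        if len(self.sequence) != self.end_nt - self.start_nt + 1:
            raise StructuralError(
                f"exon {self.index_in_transcript}: sequence length "
                f"{len(self.sequence)} != span {self.end_nt - self.start_nt + 1}"
            )


@dataclass
class ExonModel:
    """Transcript exons, genomic exon numbering, and per-residue exon annotation.

    Attributes
    ----------
    transcript_id : str
        Identifier of the source transcript.
    exons : list of TranscriptExon
    genomic_number : dict
        index_in_transcript -> genomic exon number (injective).
    protein : str
        Translated CDS, up to (excluding) the first in-frame stop.
    residue_exons : dict
        1-based residue position -> frozenset of genomic exon numbers
        touched by that residue's codon.
    cds_start : int
        1-based transcript position of the first CDS nucleotide.
    stop_codon_nt : int or None
        1-based position of the first nucleotide of the in-frame stop
        codon, if one was found before the transcript end.
    """

    transcript_id: str
    exons: list[TranscriptExon]
    genomic_number: dict[int, int]
    protein: str
    residue_exons: dict[int, frozenset[int]]
    cds_start: int = 1
    stop_codon_nt: int | None = None
    unmatched_exons: list[int] = field(default_factory=list)

    @property
    def genomic_exons_covered(self) -> frozenset[int]:
        """Genomic exon numbers touched by at least one CDS residue."""
        out: set[int] = set()
        for s in self.residue_exons.values():
            out |= s
        return frozenset(out)

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "transcript_id": self.transcript_id,
            "cds_start": self.cds_start,
            "stop_codon_nt": self.stop_codon_nt,
            "protein": self.protein,
            "exons": [
                {
                    "index_in_transcript": e.index_in_transcript,
                    "start_nt": e.start_nt,
                    "end_nt": e.end_nt,
                    "sequence": e.sequence,
                    "genomic_number": self.genomic_number[e.index_in_transcript],
                }
                for e in self.exons
            ],
            "residue_exons": {str(k): sorted(v) for k, v in self.residue_exons.items()},
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "ExonModel":
        exons = [
            TranscriptExon(e["index_in_transcript"], e["start_nt"], e["end_nt"], e["sequence"])
            for e in d["exons"]
        ]
        return cls(
            transcript_id=d["transcript_id"],
            exons=exons,
            genomic_number={e["index_in_transcript"]: e["genomic_number"] for e in d["exons"]},
            protein=d["protein"],
            residue_exons={
                int(k): frozenset(v) for k, v in d["residue_exons"].items()
            },
            cds_start=d["cds_start"],
            stop_codon_nt=d.get("stop_codon_nt"),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ExonModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class MappedPeptide:
    """A peptide located on the model protein with its genomic exon annotation.

    ``exon_set`` is the union of ``residue_exons`` over the peptide's
    residue span (over all loci when the sequence occurs more than once);
    ``n_loci`` counts distinct occurrences so downstream quantification
    can exclude non-unique peptides.
    """

    sequence: str
    start_res: int
    end_res: int
    exon_set: frozenset[int]
    n_loci: int = 1


def _normalize_boundaries(boundaries) -> list[tuple[int, int, int]]:
    """Accept a DataFrame (index/start/end columns) or iterable of (start, end)."""
    if isinstance(boundaries, pd.DataFrame):
        cols = {c.lower(): c for c in boundaries.columns}
        start_c = cols.get("start", cols.get("start_nt"))
        end_c = cols.get("end", cols.get("end_nt"))
        if start_c is None or end_c is None:
            raise StructuralError("boundary table needs 'start' and 'end' columns")
        idx_c = cols.get("index", cols.get("index_in_transcript"))
        rows = []
        for i, (_, r) in enumerate(boundaries.iterrows(), start=1):
            idx = int(r[idx_c]) if idx_c is not None else i
            rows.append((idx, int(r[start_c]), int(r[end_c])))
        return rows
    return [(i, int(s), int(e)) for i, (s, e) in enumerate(boundaries, start=1)]


_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"
# standard-code codon table, precomputed once (fast path for long CDSs)
_CODON_AA = {
    a + b + c: str(Seq(a + b + c).translate())
    for a in _BASES
    for b in _BASES
    for c in _BASES
}


def build_exon_model(
    transcript_seq: str,
    boundaries,
    cds_start: int = 1,
    transcript_id: str = "transcript",
) -> ExonModel:
    """Build an :class:`ExonModel` from a transcript sequence and exon boundaries.

    Parameters
    ----------
    transcript_seq : str
        Nucleotide sequence of the full transcript.
    boundaries : DataFrame or iterable of (start, end)
        Exon spans in 1-based inclusive transcript coordinates.  They must
        tile the transcript exactly (contiguous, non-overlapping, covering
        position 1 through the transcript end).  A DataFrame may carry a
        ``genomic_number`` column, used as the initial numbering;
        otherwise exons are numbered by transcript position.
    cds_start : int
        1-based transcript position where translation begins.

    Raises
    ------
    StructuralError
        If the boundaries do not tile the transcript or cds_start is
        outside the transcript, or the CDS is shorter than one codon.
    """
    seq = str(transcript_seq).upper().replace("U", "T")
    n = len(seq)
    rows = _normalize_boundaries(boundaries)
    rows.sort(key=lambda r: r[1])

    genomic_init: dict[int, int] = {}
    if isinstance(boundaries, pd.DataFrame) and "genomic_number" in {
        c.lower() for c in boundaries.columns
    }:
        bdf = boundaries.copy()
        bdf.columns = [c.lower() for c in bdf.columns]
        for idx, s, e in rows:
            match = bdf[(bdf["start"] == s) & (bdf["end"] == e)]
            if not match.empty and pd.notna(match.iloc[0]["genomic_number"]):
                genomic_init[idx] = int(match.iloc[0]["genomic_number"])

    pos = 1
    exons: list[TranscriptExon] = []
    for idx, s, e in rows:
        if s != pos:
            raise StructuralError(
                f"exon boundaries do not tile the transcript: expected start {pos}, got {s}"
            )
        if e > n:
            raise StructuralError(f"exon end {e} beyond transcript length {n}")
        exons.append(TranscriptExon(idx, s, e, seq[s - 1 : e]))
        pos = e + 1
    if pos != n + 1:
        raise StructuralError(
            f"exon boundaries do not tile the transcript: covered through {pos - 1}, length {n}"
        )
    if not 1 <= cds_start <= n:
        raise StructuralError(f"cds_start {cds_start} outside transcript of length {n}")
    if n - cds_start + 1 < 3:
        raise StructuralError("CDS shorter than one codon")

    genomic_number = {
        e.index_in_transcript: genomic_init.get(e.index_in_transcript, e.index_in_transcript)
        for e in exons
    }
    if len(set(genomic_number.values())) != len(genomic_number):
        raise StructuralError("genomic_number must be injective")

    # nucleotide position -> genomic exon number, for codon annotation
    nt_exon = [0] * (n + 1)
    for e in exons:
        g = genomic_number[e.index_in_transcript]
        for p in range(e.start_nt, e.end_nt + 1):
            nt_exon[p] = g

    protein_chars: list[str] = []
    residue_exons: dict[int, frozenset[int]] = {}
    stop_nt: int | None = None
    res = 0
    for codon_start in range(cds_start, n - 1, 3):
        codon = seq[codon_start - 1 : codon_start + 2]
        if codon in _STOPS:
            stop_nt = codon_start
            break
        aa = _CODON_AA.get(codon, "X")
        res += 1
        protein_chars.append(aa)
        residue_exons[res] = frozenset(
            nt_exon[p] for p in range(codon_start, codon_start + 3)
        )

    return ExonModel(
        transcript_id=transcript_id,
        exons=exons,
        genomic_number=genomic_number,
        protein="".join(protein_chars),
        residue_exons=residue_exons,
        cds_start=cds_start,
        stop_codon_nt=stop_nt,
    )


def renumber_exons(
    model: ExonModel,
    genomic_exon_seqs: Sequence[str] | None = None,
    mapping: Mapping[int, int] | None = None,
    allow_partial: bool = False,
) -> ExonModel:
    """Renumber transcript exons to the genomic exon numbering scheme.

    Either an explicit ``mapping`` (index_in_transcript -> genomic number;
    the primary path) or an ordered list of genomic exon sequences for
    exact-sequence matching must be given.  Genomic exons absent from the
    transcript simply have no preimage.

    Raises
    ------
    AmbiguousMatchError
        A transcript exon sequence equals >= 2 genomic exon sequences.
    UnmatchedExonError
        A transcript exon matches no genomic exon (suppressed when
        ``allow_partial``; unmatched exons keep their transcript number
        and are listed in ``model.unmatched_exons``).
    """
    if (genomic_exon_seqs is None) == (mapping is None):
        raise ValueError("give exactly one of genomic_exon_seqs or mapping")

    unmatched: list[int] = []
    if mapping is not None:
        missing = [e.index_in_transcript for e in model.exons if e.index_in_transcript not in mapping]
        if missing and not allow_partial:
            raise UnmatchedExonError(f"mapping table misses transcript exons {missing}")
        unmatched = missing
        new_numbers = {
            e.index_in_transcript: int(mapping.get(e.index_in_transcript, e.index_in_transcript))
            for e in model.exons
        }
    else:
        genomic = [str(s).upper().replace("U", "T") for s in genomic_exon_seqs]
        by_seq: dict[str, list[int]] = {}
        for g, s in enumerate(genomic, start=1):
            by_seq.setdefault(s, []).append(g)
        new_numbers = {}
        for e in model.exons:
            cands = by_seq.get(e.sequence, [])
            if len(cands) > 1:
                raise AmbiguousMatchError(
                    f"transcript exon {e.index_in_transcript} matches genomic exons {cands}"
                )
            if not cands:
                if not allow_partial:
                    raise UnmatchedExonError(
                        f"transcript exon {e.index_in_transcript} has no exact genomic match"
                    )
                unmatched.append(e.index_in_transcript)
                new_numbers[e.index_in_transcript] = e.index_in_transcript
            else:
                new_numbers[e.index_in_transcript] = cands[0]

    matched_vals = [v for k, v in new_numbers.items() if k not in unmatched]
    if len(set(matched_vals)) != len(matched_vals):
        raise AmbiguousMatchError("renumbering is not injective")

    old_to_new = {model.genomic_number[k]: v for k, v in new_numbers.items()}
    return ExonModel(
        transcript_id=model.transcript_id,
        exons=model.exons,
        genomic_number=new_numbers,
        protein=model.protein,
        residue_exons={
            r: frozenset(old_to_new[g] for g in s) for r, s in model.residue_exons.items()
        },
        cds_start=model.cds_start,
        stop_codon_nt=model.stop_codon_nt,
        unmatched_exons=unmatched,
    )


def _find_all(haystack: str, needle: str) -> list[int]:
    """0-based start offsets of all (possibly overlapping) occurrences."""
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def _exon_set_for_span(model: ExonModel, start_res: int, end_res: int) -> frozenset[int]:
    out: set[int] = set()
    for r in range(start_res, end_res + 1):
        out |= model.residue_exons[r]
    return frozenset(out)


def map_peptide_to_exons(seq: str, model: ExonModel) -> MappedPeptide:
    """Locate ``seq`` in the model protein and annotate it with genomic exons.

    When the sequence occurs at several loci, ``exon_set`` is the union
    over all loci and ``n_loci`` records the count so downstream
    quantification can exclude non-unique peptides.

    Raises
    ------
    PeptideNotFoundError
        If the sequence does not occur in the protein (identification
        vs. model mismatch).
    """
    if not seq:
        raise ValueError("empty peptide sequence")
    hits = _find_all(model.protein, seq)
    if not hits:
        raise PeptideNotFoundError(seq)
    exon_set: frozenset[int] = frozenset()
    for h in hits:
        exon_set |= _exon_set_for_span(model, h + 1, h + len(seq))
    return MappedPeptide(
        sequence=seq,
        start_res=hits[0] + 1,
        end_res=hits[0] + len(seq),
        exon_set=exon_set,
        n_loci=len(hits),
    )


def cleavage_sites(protein: str) -> list[int]:
    """0-based offsets after which trypsin cleaves (K/R not followed by P)."""
    return [
        i
        for i in range(len(protein) - 1)
        if protein[i] in "KR" and protein[i + 1] != "P"
    ]


def digest_tryptic(model: ExonModel, missed_cleavages: int = 0) -> list[MappedPeptide]:
    """In-silico tryptic digest of the model protein.

    Cleaves after K or R except when the next residue is P.  With
    ``missed_cleavages`` m, returns every run of 1..m+1 consecutive fully
    tryptic fragments.  Each peptide carries its genomic exon annotation
    and occurrence count (``n_loci``).
    """
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    protein = model.protein
    if not protein:
        raise ValueError("model protein is empty")
    sites = cleavage_sites(protein)
    # fragment boundaries as 0-based [start, end) pairs
    starts = [0] + [s + 1 for s in sites]
    ends = [s + 1 for s in sites] + [len(protein)]
    peptides: list[MappedPeptide] = []
    n_frag = len(starts)
    for i in range(n_frag):
        for j in range(i, min(i + missed_cleavages + 1, n_frag)):
            a, b = starts[i], ends[j]
            seq = protein[a:b]
            peptides.append(
                MappedPeptide(
                    sequence=seq,
                    start_res=a + 1,
                    end_res=b,
                    exon_set=_exon_set_for_span(model, a + 1, b),
                    n_loci=len(_find_all(protein, seq)),
                )
            )
    return peptides
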