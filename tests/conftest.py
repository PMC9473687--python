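import numpy as np
import pandas as pd
import pytest

from titinsplice.exon_model import ExonModel, MappedPeptide, build_exon_model
from titinsplice.proteomics import PeptideTable
from titinsplice.simulate import _AA_CODON, titin_like_model


def model_from_protein(protein: str) -> ExonModel:
    """Single-exon model encoding the given protein (for digestion toys)."""
    seq = "".join(_AA_CODON[a] for a in protein) + "TAA"
    return build_exon_model(seq, [(1, len(seq))])


def make_table(rows, groups) -> PeptideTable:
    """Build a PeptideTable from (peptide_id, exon_set, n_loci, {sample: value}) rows."""
    peptides = []
    data = {}
    for pid, exons, n_loci, values in rows:
        peptides.append(
            MappedPeptide(sequence=pid, start_res=1, end_res=1, exon_set=frozenset(exons), n_loci=n_loci)
        )
        data[pid] = values
    abund = pd.DataFrame(data).T
    abund = abund[sorted(abund.columns, key=list(groups).index)]
    return PeptideTable(peptides=peptides, abundances=abund, groups=dict(groups))


@pytest.fixture(scope="session")
def titin_model():
    """Synthetic 363-exon model shared across tests (digest memoized)."""
    return titin_like_model(seed=11)


@pytest.fixture
def toy_model():
    """12-nt toy: exons [1-6],[7-12], protein MAK with a trailing stop."""
    return build_exon_model("ATGGCTAAATAG", [(1, 6), (7, 12)])
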