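"""Shared fixtures: usage tables, the bundled eGFP ORF, random sequences."""

from pathlib import Path

import numpy as np
import pytest

from tapslivr.seq_core import (
    GENETIC_CODE,
    SENSE_CODONS,
    CodonUsageTable,
    ProteinRecord,
    human_codon_usage,
    read_fasta,
)

AA20 = sorted(set(GENETIC_CODE.values()) - {"*"})
SENSE = sorted(SENSE_CODONS)


@pytest.fixture(scope="session")
def usage() -> CodonUsageTable:
    return human_codon_usage()


@pytest.fixture(scope="session")
def uniform_usage() -> CodonUsageTable:
    return CodonUsageTable.uniform()


@pytest.fixture(scope="session")
def egfp_cds():
    path = Path(__file__).parents[1] / "src" / "tapslivr" / "data" / "egfp.fasta"
    return read_fasta(path, kind="nucleotide")[0]


def random_protein(rng: np.random.Generator, length: int, id_: str = "p") -> ProteinRecord:
    letters = rng.choice(AA20, size=length)
    return ProteinRecord(id=id_, residues="".join(letters))


def random_cds_seq(rng: np.random.Generator, n_codons: int) -> str:
    """A random CDS with no internal stop (uniform over sense codons)."""
    return "".join(rng.choice(SENSE, size=n_codons))
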