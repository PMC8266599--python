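"""Domain types and codon-class definitions for I34-tRNA decoding analysis.

Eukaryotic tRNAs carrying inosine at the wobble position (I34) decode the
U-, C- and A-ended codons of eight codon boxes, covering the amino acids
Thr, Ala, Pro, Ser, Leu, Ile, Val and Arg (TAPSLIVR).  This module fixes
those codon class sets, provides validated sequence record types, the
standard genetic code, and FASTA / TSV readers and writers used by every
downstream stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AMINO_ACIDS",
    "PROTEIN_ALPHABET",
    "GENETIC_CODE",
    "STOP_CODONS",
    "SENSE_CODONS",
    "TAPSLIVR_AA",
    "ADAT_CODONS",
    "TAPSLIVR_CODONS",
    "CodonClass",
    "codon_class",
    "ProteinRecord",
    "CodingRecord",
    "CodonUsageTable",
    "human_codon_usage",
    "translate",
    "read_fasta",
    "write_fasta",
    "read_tsv",
    "write_tsv",
]

#: The 20 canonical amino acids.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: Residue letters tolerated on input; 'X' is never counted as TAPSLIVR.
PROTEIN_ALPHABET = AMINO_ACIDS | frozenset("X")

#: The eight amino acids whose codon boxes are read by I34-tRNAs.
TAPSLIVR_AA = frozenset("TAPSLIVR")

# The eight I34-decoded codon boxes (first two codon positions).  An
# inosine-34 anticodon pairs with U, C and A at the codon third position,
# so each box contributes three ADAT-sensitive codons: 24 in total.
_I34_BOXES = ("AC", "GC", "CC", "TC", "CT", "AT", "GT", "CG")
ADAT_CODONS = frozenset(box + third for box in _I34_BOXES for third in "TCA")


def _build_genetic_code() -> dict:
    """Standard genetic code (translation table 1) as codon -> letter/'*'."""
    table = CodonTable.unambiguous_dna_by_id[1]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


#: Codon -> amino-acid letter, with '*' for the three stop codons.
GENETIC_CODE = _build_genetic_code()
STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")
SENSE_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa != "*")

#: All 37 sense codons encoding a TAPSLIVR amino acid.
TAPSLIVR_CODONS = frozenset(
    c for c in SENSE_CODONS if GENETIC_CODE[c] in TAPSLIVR_AA
)

# Sanity of the fixed class sets; these equalities define the analysis.
assert len(ADAT_CODONS) == 24
assert len(TAPSLIVR_CODONS) == 37
assert ADAT_CODONS < TAPSLIVR_CODONS


class CodonClass(str, Enum):
    """Classification of a codon with respect to I34-tRNA decoding."""

    ADAT = "ADAT"
    TAPSLIVR_NON_ADAT = "TAPSLIVR_NON_ADAT"
    OTHER = "OTHER"
    STOP = "STOP"


def codon_class(codon: str) -> CodonClass:
    """Classify a DNA codon as ADAT / TAPSLIVR_NON_ADAT / OTHER / STOP.

    ADAT codons are the 24 U-, C- or A-ended codons of the eight
    I34-decoded boxes; TAPSLIVR_NON_ADAT are the remaining 13 sense
    codons encoding Thr/Ala/Pro/Ser/Leu/Ile/Val/Arg.
    """
    codon = codon.upper().replace("U", "T")
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise ValueError(f"not an ACGT codon: {codon!r}")
    if codon in STOP_CODONS:
        return CodonClass.STOP
    if codon in ADAT_CODONS:
        return CodonClass.ADAT
    if codon in TAPSLIVR_CODONS:
        return CodonClass.TAPSLIVR_NON_ADAT
    return CodonClass.OTHER


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence (uppercase; 'X' tolerated)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("empty protein id")
        if not self.residues:
            raise ValueError(f"{self.id}: empty protein sequence")
        bad = set(self.residues) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"{self.id}: invalid residue letters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CodingRecord:
    """A coding DNA sequence; length divisible by 3, no internal stop.

    ``protein`` optionally links the record to the protein it encodes; the
    translation (minus a terminal stop) must then match its residues.
    """

    id: str
    nucleotides: str
    protein: Optional[ProteinRecord] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("empty coding-record id")
        seq = self.nucleotides
        bad = set(seq) - set("ACGT")
        if bad:
            raise ValueError(f"{self.id}: invalid nucleotides {sorted(bad)}")
        if len(seq) == 0 or len(seq) % 3:
            raise ValueError(
                f"{self.id}: CDS length {len(seq)} not a positive multiple of 3"
            )
        for i in range(0, len(seq) - 3, 3):
            if seq[i : i + 3] in STOP_CODONS:
                raise ValueError(
                    f"{self.id}: internal stop codon at codon index {i // 3}"
                )
        if self.protein is not None:
            tr = _translate_str(seq)
            if tr != self.protein.residues:
                raise ValueError(
                    f"{self.id}: translation does not match linked protein "
                    f"{self.protein.id}"
                )

    def codons(self) -> list[str]:
        """Codons of the CDS, excluding a terminal stop if present."""
        seq = self.nucleotides
        out = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if out and out[-1] in STOP_CODONS:
            out.pop()
        return out

    def __len__(self) -> int:
        return len(self.nucleotides)


def _translate_str(seq: str) -> str:
    aa = []
    n_codons = len(seq) // 3
    for i in range(n_codons):
        codon = seq[3 * i : 3 * i + 3]
        letter = GENETIC_CODE[codon]
        if letter == "*":
            if i == n_codons - 1:
                break  # single terminal stop, dropped
            raise ValueError(f"internal stop codon at codon index {i}")
        aa.append(letter)
    return "".join(aa)


def translate(cds: CodingRecord) -> ProteinRecord:
    """Translate a coding record under the standard code.

    A single terminal stop codon is dropped; an internal stop raises with
    the offending codon index.
    """
    return ProteinRecord(id=cds.id, residues=_translate_str(cds.nucleotides))


@dataclass
class CodonUsageTable:
    """Relative codon frequencies over the 61 sense codons.

    Values may be fractions or per-thousand counts; every statistic
    derived from the table is invariant to overall rescaling.
    """

    frequencies: dict = field(default_factory=dict)
    normalization: str = "per_thousand"

    def __post_init__(self) -> None:
        freqs = {
            k.upper().replace("U", "T"): float(v)
            for k, v in self.frequencies.items()
        }
        freqs = {k: v for k, v in freqs.items() if k not in STOP_CODONS}
        missing = SENSE_CODONS - set(freqs)
        if missing:
            raise ValueError(
                f"usage table missing {len(missing)} sense codons, "
                f"e.g. {sorted(missing)[:5]}"
            )
        if any(v < 0 for v in freqs.values()):
            raise ValueError("negative codon frequency")
        for aa in set(GENETIC_CODE.values()) - {"*"}:
            family = [c for c in SENSE_CODONS if GENETIC_CODE[c] == aa]
            if not any(freqs[c] > 0 for c in family):
                raise ValueError(f"synonymous family of {aa} has zero total usage")
        self.frequencies = freqs

    def __getitem__(self, codon: str) -> float:
        return self.frequencies[codon.upper().replace("U", "T")]

    @classmethod
    def uniform(cls) -> "CodonUsageTable":
        """Uniform usage over the 61 sense codons (the counting null)."""
        return cls({c: 1.0 for c in SENSE_CODONS}, normalization="uniform")

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "CodonUsageTable":
        """Read a two-column TSV (codon, frequency); '#' lines ignored."""
        df = read_tsv(path)
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected two columns (codon, frequency)")
        codon_col, freq_col = df.columns[0], df.columns[1]
        return cls(dict(zip(df[codon_col], df[freq_col])))

    def to_tsv(self, path: Union[str, Path], comments: Optional[list] = None) -> None:
        df = pd.DataFrame(
            sorted(self.frequencies.items()), columns=["codon", "frequency"]
        )
        write_tsv(df, path, comments=comments)


def human_codon_usage() -> CodonUsageTable:
    """The standard *H. sapiens* codon usage table bundled with the package."""
    path = Path(__file__).parent / "data" / "human_codon_usage.tsv"
    return CodonUsageTable.from_tsv(path)


# ---------------------------------------------------------------------------
# FASTA and TSV I/O


def read_fasta(
    path: Union[str, Path], kind: str = "protein"
) -> list:
    """Read a FASTA file into ProteinRecord or CodingRecord objects.

    IDs are the first whitespace-delimited token of each header; sequences
    are uppercased.  For ``kind='nucleotide'`` RNA input (U) is mapped to T.
    An empty file yields an empty list with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    with open(path) as handle:
        try:
            parsed = list(SeqIO.parse(handle, "fasta"))
        except ValueError as exc:
            raise ValueError(f"{path}: malformed FASTA: {exc}") from exc
        for rec in parsed:
            seq = str(rec.seq).upper()
            if kind == "protein":
                records.append(ProteinRecord(id=rec.id, residues=seq))
            elif kind == "nucleotide":
                records.append(
                    CodingRecord(id=rec.id, nucleotides=seq.replace("U", "T"))
                )
            else:
                raise ValueError(f"unknown FASTA kind: {kind!r}")
    if not records:
        # distinguish an empty file from a file SeqIO failed to parse
        text = path.read_text().strip()
        if text and not text.startswith(">"):
            first = text.splitlines()[0]
            raise ValueError(f"{path}: malformed FASTA, first line {first!r}")
        warnings.warn(f"{path}: empty FASTA, no records read")
    return records


def write_fasta(
    records: Iterable[Union[ProteinRecord, CodingRecord]],
    path: Union[str, Path],
    width: int = 60,
) -> None:
    """Write records to FASTA (fixed line width for byte-stable output)."""
    seqrecs = []
    for r in records:
        seq = r.residues if isinstance(r, ProteinRecord) else r.nucleotides
        seqrecs.append(SeqRecord(Seq(seq), id=r.id, description=""))
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seqrecs)


def read_tsv(path: Union[str, Path]) -> pd.DataFrame:
    """Read a TSV with a header row, skipping '#'-prefixed comment lines."""
    return pd.read_csv(path, sep="\t", comment="#")


def write_tsv(
    df: pd.DataFrame,
    path: Union[str, Path],
    comments: Optional[list] = None,
) -> None:
    """Write a TSV with optional '#' comment lines carrying run metadata."""
    with open(path, "w") as handle:
        for line in comments or []:
            handle.write(f"# {line}\n")
        df.to_csv(handle, sep="\t", index=False)
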