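"""Stage 2 — ADAT-codon enrichment, CAI/GC metrics and synonymous recoding.

The enrichment statistic is the percentage of ADAT-sensitive codons among
the TAPSLIVR codons of a coding region; a sequence counts as enriched when
that percentage exceeds the genome-expected fraction derived from codon
usage (65.743% for the human genome, the shipped default).  Recoding
rewrites every TAPSLIVR codon to a canonical C-ended (I34-sensitive) or
G-ended (I34-insensitive) synonym while preserving the protein, the
reporter-design logic for ADAT-sensitivity experiments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

from .seq_core import (
    ADAT_CODONS,
    GENETIC_CODE,
    SENSE_CODONS,
    TAPSLIVR_AA,
    TAPSLIVR_CODONS,
    CodingRecord,
    CodonUsageTable,
    translate,
)

__all__ = [
    "DEFAULT_ENRICHMENT_THRESHOLD",
    "EnrichmentScore",
    "adat_enrichment",
    "derive_threshold",
    "gc_percent",
    "cai",
    "RecodeReport",
    "recode_tapslivr",
    "C_ENDED_SYNONYMS",
    "G_ENDED_SYNONYMS",
]

#: Genome-expected ADAT percentage among human TAPSLIVR codons (default
#: enrichment threshold); derive_threshold() reproduces it from usage.
DEFAULT_ENRICHMENT_THRESHOLD = 65.743

#: Canonical C-ended synonym per TAPSLIVR amino acid (all ADAT-sensitive).
C_ENDED_SYNONYMS = {
    "T": "ACC",
    "A": "GCC",
    "P": "CCC",
    "S": "TCC",
    "L": "CTC",
    "I": "ATC",
    "V": "GTC",
    "R": "CGC",
}

#: Canonical G-ended synonym per TAPSLIVR amino acid.  Ile has no G-ended
#: codon; its handling is governed by the ``ile_fallback`` option.
G_ENDED_SYNONYMS = {
    "T": "ACG",
    "A": "GCG",
    "P": "CCG",
    "S": "TCG",
    "L": "CTG",
    "V": "GTG",
    "R": "CGG",
}


@dataclass(frozen=True)
class EnrichmentScore:
    """ADAT-codon share among the TAPSLIVR codons of a (sub)sequence."""

    cds_id: str
    n_tapslivr_codons: int
    n_adat_codons: int
    adat_percent: Optional[float]  # None when no TAPSLIVR codons
    threshold: float
    enriched: bool

    @property
    def undefined(self) -> bool:
        return self.adat_percent is None


def adat_enrichment(
    cds: CodingRecord,
    region: Optional[tuple[int, int]] = None,
    threshold: float = DEFAULT_ENRICHMENT_THRESHOLD,
) -> EnrichmentScore:
    """Score a CDS (or the codons of a residue interval) for ADAT enrichment.

    ``region`` is a 0-based half-open residue interval; the corresponding
    codons are scored.  With no TAPSLIVR codons the percentage is
    undefined and ``enriched`` is False.
    """
    codons = cds.codons()
    if region is not None:
        start, end = region
        if not (0 <= start < end <= len(codons)):
            raise ValueError(
                f"region {region} outside codon range [0, {len(codons)})"
            )
        codons = codons[start:end]
    n_taps = sum(1 for c in codons if c in TAPSLIVR_CODONS)
    n_adat = sum(1 for c in codons if c in ADAT_CODONS)
    if n_taps == 0:
        return EnrichmentScore(cds.id, 0, 0, None, threshold, False)
    percent = 100.0 * n_adat / n_taps
    return EnrichmentScore(
        cds.id, n_taps, n_adat, percent, threshold, percent > threshold
    )


def derive_threshold(usage: CodonUsageTable) -> float:
    """Genome-expected ADAT percentage among TAPSLIVR codons.

    100 x (usage mass on the 24 ADAT codons) / (usage mass on all 37
    TAPSLIVR codons); invariant to rescaling the table.
    """
    adat = sum(usage[c] for c in ADAT_CODONS)
    taps = sum(usage[c] for c in TAPSLIVR_CODONS)
    if taps == 0:
        raise ValueError("usage table has zero total TAPSLIVR mass")
    return 100.0 * adat / taps


def gc_percent(seq: str) -> float:
    """Percentage of G+C bases in an ACGT string."""
    seq = seq.upper().replace("U", "T")
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"invalid nucleotides {sorted(bad)}")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def cai(
    cds: CodingRecord,
    usage: CodonUsageTable,
    zero_floor: float = 0.01,
) -> float:
    """Codon Adaptation Index: geometric mean of relative adaptiveness.

    w(c) = usage(c) / max usage among c's synonyms.  Codons of
    single-codon families (Met, Trp) and stops are excluded; zero-usage
    codons contribute ``zero_floor`` instead of 0 to avoid log(0).
    """
    family_max: dict[str, float] = {}
    family_size: dict[str, int] = {}
    for c in SENSE_CODONS:
        aa = GENETIC_CODE[c]
        family_max[aa] = max(family_max.get(aa, 0.0), usage[c])
        family_size[aa] = family_size.get(aa, 0) + 1
    log_sum = 0.0
    n = 0
    for codon in cds.codons():
        aa = GENETIC_CODE[codon]
        if family_size[aa] == 1:
            continue
        w = usage[codon] / family_max[aa]
        if w <= 0:
            w = zero_floor
        log_sum += math.log(w)
        n += 1
    if n == 0:
        raise ValueError(f"{cds.id}: no codons contribute to CAI")
    return math.exp(log_sum / n)


@dataclass
class RecodeReport:
    """Provenance of a synonymous recoding run."""

    mode: str
    substitutions: list = field(default_factory=list)  # (index, old, new)
    n_changed: int = 0
    n_fallback: int = 0
    cai_before: Optional[float] = None
    cai_after: Optional[float] = None
    gc_before: float = 0.0
    gc_after: float = 0.0


def recode_tapslivr(
    cds: CodingRecord,
    mode: str,
    usage: Optional[CodonUsageTable] = None,
    ile_fallback: str = "ATC",
    c_synonyms: Optional[dict] = None,
    g_synonyms: Optional[dict] = None,
) -> tuple[CodingRecord, RecodeReport]:
    """Rewrite every TAPSLIVR codon to the mode's canonical synonym.

    ``mode`` is ``'C_ENDED'`` (all TAPSLIVR codons become ADAT-sensitive)
    or ``'G_ENDED'`` (all become I34-insensitive, except Ile which has no
    G-ended codon and is handled per ``ile_fallback`` in {'ATC', 'ATT',
    'keep'}).  Non-TAPSLIVR codons are untouched and translation is
    preserved.  When ``usage`` is given the report carries CAI before and
    after; GC percentages are always reported.
    """
    mode = mode.upper()
    if mode not in {"C_ENDED", "G_ENDED"}:
        raise ValueError(f"unknown recode mode: {mode!r}")
    if ile_fallback not in {"ATC", "ATT", "keep"}:
        raise ValueError(f"ile_fallback must be ATC, ATT or keep: {ile_fallback!r}")
    table = dict(c_synonyms or C_ENDED_SYNONYMS) if mode == "C_ENDED" else dict(
        g_synonyms or G_ENDED_SYNONYMS
    )
    report = RecodeReport(mode=mode)
    seq = cds.nucleotides
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for i, codon in enumerate(codons):
        aa = GENETIC_CODE[codon]
        if aa not in TAPSLIVR_AA:
            continue
        if mode == "G_ENDED" and aa == "I":
            # no G-ended Ile codon exists in the standard code
            new = codon if ile_fallback == "keep" else ile_fallback
            report.n_fallback += 1
            if report.n_fallback == 1:
                warnings.warn(
                    f"{cds.id}: Ile has no G-ended codon; using fallback "
                    f"{ile_fallback!r}"
                )
        else:
            new = table[aa]
        if new != codon:
            report.substitutions.append((i, codon, new))
            report.n_changed += 1
            codons[i] = new
    new_seq = "".join(codons)
    recoded = CodingRecord(id=f"{cds.id}|{mode}", nucleotides=new_seq)
    assert translate(recoded).residues == translate(cds).residues
    report.gc_before = gc_percent(seq)
    report.gc_after = gc_percent(new_seq)
    if usage is not None:
        report.cai_before = cai(cds, usage)
        report.cai_after = cai(recoded, usage)
    return recoded, report
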