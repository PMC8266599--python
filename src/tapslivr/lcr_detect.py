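"""Stage 1 — detection of low-complexity TAPSLIVR-rich regions.

A protein segment qualifies when a fixed-length running window (default
30 residues, step 1) contains at least 80% TAPSLIVR residues, in any
combination.  Overlapping or adjacent qualifying windows are merged by
coordinate union into maximal regions of >= 30 residues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .seq_core import (
    ADAT_CODONS,
    TAPSLIVR_AA,
    CodingRecord,
    ProteinRecord,
)

__all__ = [
    "ScanParams",
    "TapslivrRegion",
    "tapslivr_mask",
    "find_regions",
    "scan_proteome",
    "ScanSummary",
    "composition_profile",
]


@dataclass(frozen=True)
class ScanParams:
    """Running-window parameters: window length, minimum fraction, step."""

    window: int = 30
    min_fraction: float = 0.80
    step: int = 1

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError(f"window must be >= 1, got {self.window}")
        if not (0 < self.min_fraction <= 1):
            raise ValueError(
                f"min_fraction must be in (0, 1], got {self.min_fraction}"
            )
        if self.step < 1:
            raise ValueError(f"step must be >= 1, got {self.step}")

    @property
    def min_count(self) -> int:
        """Smallest TAPSLIVR count that satisfies count/window >= min_fraction."""
        # robust ceiling of min_fraction * window under float representation
        target = self.min_fraction * self.window
        k = int(np.ceil(target - 1e-9))
        return k


@dataclass(frozen=True)
class TapslivrRegion:
    """A merged run of qualifying windows; coordinates 0-based half-open."""

    protein_id: str
    start: int
    end: int
    tapslivr_fraction: float
    n_qualifying_windows: int

    @property
    def length(self) -> int:
        return self.end - self.start


def tapslivr_mask(protein: ProteinRecord) -> np.ndarray:
    """Boolean flag per residue: True iff the residue is T/A/P/S/L/I/V/R."""
    arr = np.array(list(protein.residues))
    return np.isin(arr, list(TAPSLIVR_AA))


def find_regions(
    protein: ProteinRecord, params: ScanParams = ScanParams()
) -> list[TapslivrRegion]:
    """Detect TAPSLIVR-rich regions by the running-window union rule.

    Slide a window of exactly ``params.window`` residues with
    ``params.step``; a window qualifies when its TAPSLIVR count is at
    least ``ceil(min_fraction * window)`` (24 of 30 at the defaults).
    Qualifying windows are merged by coordinate union into maximal
    regions, whose overall fraction is recomputed and reported.
    """
    n = len(protein)
    w = params.window
    if n < w:
        return []
    mask = tapslivr_mask(protein).astype(np.int64)
    csum = np.concatenate([[0], np.cumsum(mask)])
    starts = np.arange(0, n - w + 1, params.step)
    counts = csum[starts + w] - csum[starts]
    qualifying = starts[counts >= params.min_count]
    if qualifying.size == 0:
        return []

    regions: list[TapslivrRegion] = []
    run_start = int(qualifying[0])
    run_end = run_start + w
    n_windows = 1
    for s in qualifying[1:]:
        s = int(s)
        if s <= run_end:  # overlapping or adjacent window: extend the union
            run_end = s + w
            n_windows += 1
        else:
            regions.append(_make_region(protein, run_start, run_end, n_windows, csum))
            run_start, run_end, n_windows = s, s + w, 1
    regions.append(_make_region(protein, run_start, run_end, n_windows, csum))
    return regions


def _make_region(
    protein: ProteinRecord, start: int, end: int, n_windows: int, csum: np.ndarray
) -> TapslivrRegion:
    frac = float(csum[end] - csum[start]) / (end - start)
    return TapslivrRegion(
        protein_id=protein.id,
        start=start,
        end=end,
        tapslivr_fraction=frac,
        n_qualifying_windows=n_windows,
    )


@dataclass(frozen=True)
class ScanSummary:
    n_proteins: int
    n_proteins_with_region: int
    n_regions: int


def scan_proteome(
    records: Sequence[ProteinRecord], params: ScanParams = ScanParams()
) -> tuple[pd.DataFrame, ScanSummary]:
    """Scan a proteome; return a region table and summary counts.

    The table has one row per region (protein_id, start0, end0, length,
    tapslivr_fraction, n_windows).  Duplicate protein IDs are rejected.
    """
    ids = [r.id for r in records]
    dupes = sorted({i for i in ids if ids.count(i) > 1}) if len(set(ids)) != len(ids) else []
    if dupes:
        raise ValueError(f"duplicate protein IDs: {dupes}")
    rows = []
    n_with = 0
    for rec in records:
        regions = find_regions(rec, params)
        if regions:
            n_with += 1
        for reg in regions:
            rows.append(
                {
                    "protein_id": reg.protein_id,
                    "start0": reg.start,
                    "end0": reg.end,
                    "length": reg.length,
                    "tapslivr_fraction": reg.tapslivr_fraction,
                    "n_windows": reg.n_qualifying_windows,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "start0",
            "end0",
            "length",
            "tapslivr_fraction",
            "n_windows",
        ],
    )
    return table, ScanSummary(len(records), n_with, len(rows))


def brute_force_coverage(
    protein: ProteinRecord, params: ScanParams = ScanParams()
) -> set[int]:
    """Residues covered by any qualifying window, by direct enumeration.

    Independent oracle for ``find_regions``: checks every window of length
    exactly ``window`` by counting letters, with no cumulative sums or
    merging logic.
    """
    covered: set[int] = set()
    seq = protein.residues
    w = params.window
    for s in range(0, len(seq) - w + 1, params.step):
        count = sum(1 for a in seq[s : s + w] if a in TAPSLIVR_AA)
        if count / w >= params.min_fraction - 1e-12:
            covered.update(range(s, s + w))
    return covered


def composition_profile(
    protein: ProteinRecord,
    cds: Optional[CodingRecord] = None,
    window: int = 30,
) -> pd.DataFrame:
    """Centered moving TAPSLIVR and ADAT-codon fractions along a sequence.

    At residue i the TAPSLIVR fraction of residues (and, when a CDS is
    given, the fraction of ADAT codons among codons) in the window
    centered on i is reported; windows are truncated at the sequence
    edges.  Output has one row per residue.
    """
    n = len(protein)
    if cds is not None:
        codons = cds.codons()
        if len(codons) != n:
            raise ValueError(
                f"{cds.id}: {len(codons)} codons do not match protein length {n}"
            )
    if window > n:
        warnings.warn(
            f"{protein.id}: profile window {window} exceeds length {n}; "
            "reporting the full-sequence value at every position"
        )
    mask = tapslivr_mask(protein).astype(np.int64)
    csum = np.concatenate([[0], np.cumsum(mask)])
    if cds is not None:
        adat = np.array([c in ADAT_CODONS for c in codons], dtype=np.int64)
        asum = np.concatenate([[0], np.cumsum(adat)])
    half_lo = (window - 1) // 2
    half_hi = window // 2
    rows = []
    for i in range(n):
        lo = max(0, i - half_lo)
        hi = min(n, i + half_hi + 1)
        if window > n:
            lo, hi = 0, n
        size = hi - lo
        row = {
            "position": i,
            "tapslivr_fraction": (csum[hi] - csum[lo]) / size,
        }
        if cds is not None:
            row["adat_codon_fraction"] = (asum[hi] - asum[lo]) / size
        rows.append(row)
    return pd.DataFrame(rows)
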