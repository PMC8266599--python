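"""Stage 4 — enrichment statistics over translation-efficiency tables.

Consumes per-gene fold-change tables from an upstream differential
expression fit of polysome-profiling RNA-Seq (high-polysome vs total
RNA), classifies genes by the interaction fold-change thresholds,
tests enrichment of low-complexity-encoding genes by Fisher's exact
test, and runs the fixed-size permutation-proportion test whose p-value
is the fraction of random gene sets with a statistic at least as extreme
as observed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .homolog_stats import PermutationResult
from .seq_core import read_tsv

__all__ = [
    "GeneTERecord",
    "read_te_table",
    "classify_te",
    "fisher_enrichment",
    "permutation_proportion_test",
]

TE_COLUMNS = [
    "gene_id",
    "fc_hp_total_ctrl",
    "fc_hp_total_kd",
    "interaction_fc",
    "p",
    "encodes_lcr",
]


@dataclass(frozen=True)
class GeneTERecord:
    """Fold-changes and significance of one gene's translation efficiency.

    ``interaction_fc`` is the knockdown-vs-control ratio of HP/Total
    (values below 1 mean reduced translation efficiency after knockdown);
    ``encodes_lcr`` flags genes whose protein contains a TAPSLIVR-rich
    low-complexity region (from the Stage 1 detector).
    """

    gene_id: str
    fc_hp_total_ctrl: float
    fc_hp_total_kd: float
    interaction_fc: float
    p: float
    encodes_lcr: bool
    p_ctrl: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("fc_hp_total_ctrl", "fc_hp_total_kd", "interaction_fc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{self.gene_id}: {name} must be > 0")
        if not (0 <= self.p <= 1):
            raise ValueError(f"{self.gene_id}: p outside [0, 1]")


def read_te_table(path: Union[str, Path]) -> list[GeneTERecord]:
    """Read the TE table TSV (header per TE_COLUMNS; '#' comments allowed)."""
    df = read_tsv(path)
    missing = set(TE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        GeneTERecord(
            gene_id=str(r.gene_id),
            fc_hp_total_ctrl=float(r.fc_hp_total_ctrl),
            fc_hp_total_kd=float(r.fc_hp_total_kd),
            interaction_fc=float(r.interaction_fc),
            p=float(r.p),
            encodes_lcr=bool(r.encodes_lcr),
            p_ctrl=float(r.p_ctrl) if hasattr(r, "p_ctrl") else None,
        )
        for r in df.itertuples(index=False)
    ]


def classify_te(
    records: Sequence[GeneTERecord],
    fc_cut: float = 1.5,
    p_cut: float = 0.05,
    relaxed: bool = False,
) -> dict[str, set]:
    """Classify genes by the interaction fold-change thresholds.

    Threshold mode (default): impaired = interaction FC < ``fc_cut`` with
    p < ``p_cut``; increased symmetric (FC > cut, p < cut); the rest
    unchanged.  Highly-translated-in-control = control HP/Total FC >
    ``fc_cut``, with the control p applied when one is supplied.

    Relaxed mode classifies by FC sign only (log FC below/above 0),
    mirroring an unthresholded up/down split.
    """
    impaired, increased, unchanged, high_ctrl = set(), set(), set(), set()
    for r in records:
        if relaxed:
            if r.interaction_fc < 1:
                impaired.add(r.gene_id)
            elif r.interaction_fc > 1:
                increased.add(r.gene_id)
            else:
                unchanged.add(r.gene_id)
            if r.fc_hp_total_ctrl > 1:
                high_ctrl.add(r.gene_id)
            continue
        if r.interaction_fc < fc_cut and r.p < p_cut:
            impaired.add(r.gene_id)
        elif r.interaction_fc > fc_cut and r.p < p_cut:
            increased.add(r.gene_id)
        else:
            unchanged.add(r.gene_id)
        ctrl_ok = r.p_ctrl is None or r.p_ctrl < p_cut
        if r.fc_hp_total_ctrl > fc_cut and ctrl_ok:
            high_ctrl.add(r.gene_id)
    return {
        "impaired": impaired,
        "increased": increased,
        "unchanged": unchanged,
        "highly_translated_ctrl": high_ctrl,
    }


def fisher_enrichment(
    set_of_interest: set,
    annotation: Mapping[str, bool],
    universe: Sequence[str],
) -> tuple[np.ndarray, Optional[float], float]:
    """Fisher's exact test of annotation enrichment in a gene set.

    Rows: in/out of the set; columns: annotated/not.  Returns the raw
    2x2 table, the odds ratio (Haldane 0.5 correction only when a zero
    cell makes the raw ratio undefined), and the exact two-sided p.
    """
    universe = list(universe)
    if not universe:
        raise ValueError("empty universe")
    extra = set_of_interest - set(universe)
    if extra:
        raise ValueError(f"set_of_interest outside universe: {sorted(extra)[:5]}")
    a = sum(1 for g in universe if g in set_of_interest and annotation.get(g, False))
    b = sum(1 for g in universe if g in set_of_interest and not annotation.get(g, False))
    c = sum(1 for g in universe if g not in set_of_interest and annotation.get(g, False))
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if b * c == 0 and a * d != 0:
        odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    elif b * c == 0:
        odds = None if a * d == 0 else np.inf
    else:
        odds = a * d / (b * c)
    return table, odds, float(p)


def permutation_proportion_test(
    universe_annotations: Mapping[str, bool],
    set_size: int,
    observed_statistic: float,
    B: int = 10_000,
    seed: int = 0,
    inclusive: bool = True,
    smoothed: bool = False,
) -> PermutationResult:
    """Permutation test of an annotated proportion in fixed-size gene sets.

    The statistic of a random set of ``set_size`` genes drawn without
    replacement from the universe is the proportion carrying the
    annotation; the p-value is the fraction of the B permutations with a
    statistic at least as extreme as (>= by default) the observed one.
    ``smoothed`` applies the (r+1)/(B+1) correction.
    """
    if not (0 <= observed_statistic <= 1):
        raise ValueError("observed statistic must be a proportion in [0, 1]")
    genes = sorted(universe_annotations)
    if set_size > len(genes):
        raise ValueError("set_size exceeds universe")
    flags = np.array([bool(universe_annotations[g]) for g in genes])
    rng = np.random.default_rng(seed)
    null = np.empty(B)
    n = len(genes)
    for j in range(B):
        rows = rng.choice(n, size=set_size, replace=False)
        null[j] = flags[rows].mean()
    if inclusive:
        r = int(np.sum(null >= observed_statistic - 1e-12))
    else:
        r = int(np.sum(null > observed_statistic + 1e-12))
    p = (r + 1) / (B + 1) if smoothed else r / B
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    z = (observed_statistic - null_mean) / null_sd if null_sd > 0 else None
    return PermutationResult(
        observed=observed_statistic,
        null_mean=null_mean,
        null_sd=null_sd,
        z=z,
        p=float(p),
        p_empirical=float(p),
        B=B,
        set_size=set_size,
        seed=seed,
        degenerate=null_sd == 0,
    )
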