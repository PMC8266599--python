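"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure each stage assumes:
proteomes with planted TAPSLIVR-rich regions at known coordinates,
coding sequences sampled from a codon-usage table with a controllable
ADAT-codon fraction, homolog hit tables with group-specific Poisson hit
rates, species A34-tRNA gene counts monotonically linked to planted
homolog abundance, and per-gene TE fold-change tables with a planted
impaired subset.  Every generator is fully determined by its seed and
emits a truth object alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .seq_core import (
    ADAT_CODONS,
    GENETIC_CODE,
    SENSE_CODONS,
    TAPSLIVR_AA,
    CodingRecord,
    CodonUsageTable,
    ProteinRecord,
)
from .te_enrichment import GeneTERecord

__all__ = [
    "ProteomeTruth",
    "gen_proteome",
    "gen_cds",
    "HomologTruth",
    "gen_homolog_data",
    "TETruth",
    "gen_te_table",
]

_TAPSLIVR_LETTERS = sorted(TAPSLIVR_AA)
_NON_TAPSLIVR_LETTERS = sorted(set("ACDEFGHIKLMNPQRSTVWY") - TAPSLIVR_AA)

_SYNONYMS: dict[str, list[str]] = {}
for _c in sorted(SENSE_CODONS):
    _SYNONYMS.setdefault(GENETIC_CODE[_c], []).append(_c)


# ---------------------------------------------------------------------------
# Proteomes with planted regions


@dataclass(frozen=True)
class PlantedRegion:
    protein_id: str
    start: int
    end: int
    target_fraction: float


@dataclass
class ProteomeTruth:
    """Planted-region coordinates and parameters of a synthetic proteome."""

    regions: dict[str, list[PlantedRegion]] = field(default_factory=dict)
    background_rate: float = 0.0
    seed: int = 0


def _background(rng: np.random.Generator, n: int, rate: float) -> list[str]:
    """Residues that are TAPSLIVR with probability ``rate``."""
    out = []
    taps = rng.random(n) < rate
    t_idx = rng.integers(0, len(_TAPSLIVR_LETTERS), size=n)
    n_idx = rng.integers(0, len(_NON_TAPSLIVR_LETTERS), size=n)
    for i in range(n):
        out.append(
            _TAPSLIVR_LETTERS[t_idx[i]] if taps[i] else _NON_TAPSLIVR_LETTERS[n_idx[i]]
        )
    return out


def _region_block(rng: np.random.Generator, length: int, fraction: float) -> list[str]:
    """A region with an exact TAPSLIVR count of round(fraction * length)."""
    k = int(round(fraction * length))
    letters = [
        _TAPSLIVR_LETTERS[i] for i in rng.integers(0, len(_TAPSLIVR_LETTERS), size=k)
    ] + [
        _NON_TAPSLIVR_LETTERS[i]
        for i in rng.integers(0, len(_NON_TAPSLIVR_LETTERS), size=length - k)
    ]
    rng.shuffle(letters)
    return letters


def gen_proteome(
    n_proteins: int,
    n_regions: int = 1,
    region_length: tuple[int, int] = (35, 60),
    region_fraction: tuple[float, float] = (0.85, 1.0),
    background_rate: float = 0.2,
    flank_length: int = 60,
    seed: int = 0,
    window: int = 30,
) -> tuple[list[ProteinRecord], ProteomeTruth]:
    """Synthetic proteome with planted TAPSLIVR-rich regions.

    Each protein carries ``n_regions`` planted regions (length uniform in
    ``region_length``, TAPSLIVR fraction uniform in ``region_fraction``),
    separated and flanked by non-TAPSLIVR-only spacers of at least
    ``2 * window`` residues so planted regions never merge and recovery
    against the truth coordinates is exact; the remaining background is
    sampled at ``background_rate``.
    """
    spacer = max(flank_length, 2 * window)
    rng = np.random.default_rng(seed)
    truth = ProteomeTruth(background_rate=background_rate, seed=seed)
    records = []
    for i in range(n_proteins):
        pid = f"synp{i:04d}"
        parts: list[str] = []
        planted = []
        # non-TAPSLIVR spacer guarantees planted coordinates are exact
        spacer_block = [
            _NON_TAPSLIVR_LETTERS[j]
            for j in rng.integers(0, len(_NON_TAPSLIVR_LETTERS), size=spacer)
        ]
        parts.extend(spacer_block)
        for _ in range(n_regions):
            length = int(rng.integers(region_length[0], region_length[1] + 1))
            fraction = float(rng.uniform(*region_fraction))
            start = len(parts)
            parts.extend(_region_block(rng, length, fraction))
            planted.append(PlantedRegion(pid, start, start + length, fraction))
            parts.extend(
                _NON_TAPSLIVR_LETTERS[j]
                for j in rng.integers(0, len(_NON_TAPSLIVR_LETTERS), size=spacer)
            )
        if n_regions == 0:
            parts.extend(_background(rng, 200, background_rate))
        records.append(ProteinRecord(id=pid, residues="".join(parts)))
        truth.regions[pid] = planted
    return records, truth


# ---------------------------------------------------------------------------
# Coding sequences


def gen_cds(
    protein: ProteinRecord,
    usage: Optional[CodonUsageTable] = None,
    adat_bias: Optional[list[tuple[int, int, float]]] = None,
    seed: int = 0,
) -> CodingRecord:
    """Sample a CDS for a protein from a codon-usage table.

    Codons are drawn among synonyms proportionally to usage.  Inside each
    ``(start, end, target)`` interval of ``adat_bias`` (0-based half-open
    residue coordinates) TAPSLIVR codons are instead drawn ADAT-sensitive
    with probability ``target`` (choice within the ADAT / non-ADAT
    synonyms remains usage-proportional).  Ile, which has no non-ADAT
    synonym, always yields an ADAT codon.
    """
    usage = usage or CodonUsageTable.uniform()
    rng = np.random.default_rng(seed)
    bias = np.full(len(protein), np.nan)
    for start, end, target in adat_bias or []:
        if not (0 <= start < end <= len(protein)):
            raise ValueError(f"bias interval ({start}, {end}) out of bounds")
        bias[start:end] = target
    codons = []
    for i, aa in enumerate(protein.residues):
        if aa == "X":
            raise ValueError(f"{protein.id}: cannot back-translate residue 'X'")
        syns = _SYNONYMS[aa]
        if not np.isnan(bias[i]) and aa in TAPSLIVR_AA:
            adat_syns = [c for c in syns if c in ADAT_CODONS]
            other_syns = [c for c in syns if c not in ADAT_CODONS]
            if not other_syns:  # Ile: every synonym is ADAT-sensitive
                pool = adat_syns
            else:
                pool = adat_syns if rng.random() < bias[i] else other_syns
            syns = pool
        weights = np.array([usage[c] for c in syns], dtype=float)
        if weights.sum() == 0:
            weights = np.ones(len(syns))
        codons.append(syns[rng.choice(len(syns), p=weights / weights.sum())])
    return CodingRecord(
        id=protein.id, nucleotides="".join(codons), protein=protein
    )


# ---------------------------------------------------------------------------
# Homolog hit data


@dataclass
class HomologTruth:
    """Planted rates and links of a synthetic homolog-hit data set."""

    rates: dict = field(default_factory=dict)  # (query_class, group) -> lambda
    query_set: list = field(default_factory=list)
    planted_abundance: dict = field(default_factory=dict)  # species -> float
    seed: int = 0


def gen_homolog_data(
    n_queries: int = 50,
    n_background: int = 200,
    species_groups: Optional[Sequence[dict]] = None,
    rate_query: Optional[Mapping[str, float]] = None,
    rate_background: Optional[Mapping[str, float]] = None,
    fail_fraction: float = 0.2,
    a34_slope: float = 10.0,
    a34_noise: float = 0.0,
    seed: int = 0,
):
    """Synthetic homolog hits plus species metadata with planted structure.

    ``species_groups`` lists dicts with keys domain, phylum,
    multicellularity, count.  Hit counts per (query, species) are
    Poisson with the group's rate — ``rate_query`` applies to the
    ``n_queries`` focal queries, ``rate_background`` to the background
    queries; rates are keyed by 'prokaryote'/'eukaryote' or by
    multicellularity class.  A ``fail_fraction`` of emitted hits gets an
    e-value/coverage failing the standard filters (to exercise
    filtering).  Eukaryote A34-tRNA gene counts increase strictly with
    the species' planted hit abundance (``a34_slope`` genes per dense
    abundance rank, Gaussian noise ``a34_noise``).

    Returns (hits, meta, truth) where hits are HomologHit records, meta
    is {species_id: SpeciesMeta} and truth records the planted rates.
    """
    from .homolog_stats import HomologHit, SpeciesMeta

    if species_groups is None:
        species_groups = [
            {"domain": "Bacteria", "phylum": "Proteobacteria", "count": 20},
            {"domain": "Archaea", "phylum": "Euryarchaeota", "count": 5},
            {
                "domain": "Eukarya",
                "phylum": "Chordata",
                "multicellularity": "multicellular",
                "count": 15,
            },
            {
                "domain": "Eukarya",
                "phylum": "Ascomycota",
                "multicellularity": "unicellular",
                "count": 10,
            },
        ]
    rate_query = dict(rate_query or {"prokaryote": 0.1, "eukaryote": 5.0})
    rate_background = dict(rate_background or {"prokaryote": 1.0, "eukaryote": 1.0})
    rng = np.random.default_rng(seed)

    meta: dict[str, SpeciesMeta] = {}
    species_order = []
    for g, grp in enumerate(species_groups):
        for j in range(grp["count"]):
            sid = f"sp{g}_{j:03d}"
            species_order.append((sid, grp))
    queries = [f"q{i:04d}" for i in range(n_queries)] + [
        f"bg{i:04d}" for i in range(n_background)
    ]
    truth = HomologTruth(
        rates={"query": rate_query, "background": rate_background},
        query_set=[q for q in queries if q.startswith("q")],
        seed=seed,
    )

    hits = []
    abundance: dict[str, float] = {}
    for sid, grp in species_order:
        is_euk = grp["domain"] == "Eukarya"
        group_key = "eukaryote" if is_euk else "prokaryote"
        mc = grp.get("multicellularity")
        total = 0
        for q in queries:
            rates = rate_query if q.startswith("q") else rate_background
            lam = rates.get(mc, rates.get(group_key, 0.0)) if mc else rates.get(
                group_key, 0.0
            )
            k = int(rng.poisson(lam))
            total += k
            for h in range(k):
                failing = rng.random() < fail_fraction
                if failing:
                    # fails either the e-value or the coverage filter
                    if rng.random() < 0.5:
                        ev, cov = float(rng.uniform(0.02, 1.0)), float(
                            rng.uniform(0.3, 1.0)
                        )
                    else:
                        ev, cov = float(rng.uniform(1e-30, 1e-3)), float(
                            rng.uniform(0.0, 0.15)
                        )
                else:
                    ev = float(rng.uniform(1e-30, 1e-3))
                    cov = float(rng.uniform(0.3, 1.0))
                hits.append(
                    HomologHit(
                        query_id=q,
                        subject_id=f"{sid}|{q}_h{h}",
                        species_id=sid,
                        evalue=max(ev, 1e-300),
                        overlap_fraction=cov,
                    )
                )
        abundance[sid] = total

    # A34 gene counts: a strictly increasing function of planted abundance
    # (dense rank), so equal abundances tie in both variables and the
    # noise-free Spearman correlation is exactly 1 by construction.
    euk_totals = sorted(
        {abundance[sid] for sid, grp in species_order if grp["domain"] == "Eukarya"}
    )
    rank_of = {t: i for i, t in enumerate(euk_totals)}
    for sid, grp in species_order:
        is_euk = grp["domain"] == "Eukarya"
        if is_euk:
            noise = rng.normal(0, a34_noise) if a34_noise > 0 else 0.0
            n_a34 = max(1, int(round(10 + a34_slope * rank_of[abundance[sid]] + noise)))
            diversity = 8
        else:
            n_a34, diversity = 0, 0
        meta[sid] = SpeciesMeta(
            species_id=sid,
            domain=grp["domain"],
            phylum=grp["phylum"],
            multicellularity=grp.get("multicellularity"),
            n_A34_genes=n_a34,
            a34_diversity=diversity,
        )
    truth.planted_abundance = abundance
    return hits, meta, truth


# ---------------------------------------------------------------------------
# TE tables


@dataclass
class TETruth:
    """Planted impaired subset and noise model of a synthetic TE table."""

    impaired_genes: list = field(default_factory=list)
    delta: float = 0.0
    sigma: float = 0.0
    seed: int = 0


def gen_te_table(
    n_genes: int = 1000,
    fraction_annotated: float = 0.1,
    n_impaired: int = 31,
    delta: float = 1.0,
    sigma: float = 0.3,
    impaired_annotated_fraction: float = 1.0,
    seed: int = 0,
) -> tuple[list[GeneTERecord], TETruth]:
    """Synthetic per-gene TE table with a planted impaired subset.

    Background log2 interaction fold-changes are Normal(0, sigma); the
    ``n_impaired`` planted genes are Normal(-delta, sigma).  P-values are
    the two-sided normal tail of the corresponding z statistic.  A
    ``fraction_annotated`` of background genes (and
    ``impaired_annotated_fraction`` of planted ones) carry the
    low-complexity annotation.
    """
    if n_impaired > n_genes:
        raise ValueError(f"n_impaired {n_impaired} exceeds n_genes {n_genes}")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    impaired = list(rng.choice(genes, size=n_impaired, replace=False))
    impaired_set = set(impaired)
    records = []
    for g in genes:
        mu = -delta if g in impaired_set else 0.0
        log2_fc = rng.normal(mu, sigma)
        z = log2_fc / sigma
        p = float(2 * stats.norm.sf(abs(z)))
        if g in impaired_set:
            annotated = rng.random() < impaired_annotated_fraction
        else:
            annotated = rng.random() < fraction_annotated
        ctrl_fc = float(2 ** rng.normal(1.0, sigma))  # mostly > 1.5
        records.append(
            GeneTERecord(
                gene_id=g,
                fc_hp_total_ctrl=ctrl_fc,
                fc_hp_total_kd=float(2 ** rng.normal(0.0, sigma)),
                interaction_fc=float(2**log2_fc),
                p=p,
                encodes_lcr=bool(annotated),
            )
        )
    truth = TETruth(impaired_genes=impaired, delta=delta, sigma=sigma, seed=seed)
    return records, truth
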