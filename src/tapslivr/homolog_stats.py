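"""Stage 3 — cross-domain homolog-distribution statistics.

Consumes BLAST-style tabular hits against a panel of genomes, filters
them (e-value <= 0.01, query coverage >= 20%, 10 000-hit cap), and
computes the comparative statistics: per-genome average hit rates per
species group and their ratio, a permutation test of that ratio over
random query sets with a z-score p-value, presence screening of homologs
for TAPSLIVR-rich regions, phylum-normalized presence fractions, the
unicellular-vs-multicellular comparison (median fold-change plus
Mann-Whitney U), and the Spearman correlation with A34-tRNA gene counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .lcr_detect import ScanParams, find_regions
from .seq_core import ProteinRecord, read_tsv

__all__ = [
    "HomologHit",
    "SpeciesMeta",
    "PermutationResult",
    "read_blast_tab",
    "read_species_meta",
    "filter_hits",
    "species_hit_matrix",
    "group_average_ratio",
    "permutation_ratio_test",
    "presence_screen",
    "phylum_normalize",
    "multicellular_compare",
    "trna_spearman",
]


@dataclass(frozen=True)
class HomologHit:
    """One filtered homology hit of a query protein in a target species."""

    query_id: str
    subject_id: str
    species_id: str
    evalue: float
    overlap_fraction: float

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError("evalue must be > 0")
        if not (0 <= self.overlap_fraction <= 1):
            raise ValueError("overlap_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SpeciesMeta:
    """Taxonomy, multicellularity and A34-tRNA gene content of a species."""

    species_id: str
    domain: str  # Archaea | Bacteria | Eukarya
    phylum: str
    multicellularity: Optional[str] = None  # unicellular | multicellular
    n_A34_genes: int = 0
    a34_diversity: int = 0

    def __post_init__(self) -> None:
        if self.domain not in {"Archaea", "Bacteria", "Eukarya"}:
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.multicellularity not in {None, "unicellular", "multicellular"}:
            raise ValueError(f"bad multicellularity {self.multicellularity!r}")
        if not (0 <= self.a34_diversity <= 8):
            raise ValueError("a34_diversity must be 0-8")
        if self.a34_diversity == 0 and self.n_A34_genes != 0:
            raise ValueError("a34_diversity 0 requires n_A34_genes 0")


@dataclass(frozen=True)
class PermutationResult:
    """Observed statistic against a resampled null, with z-score p-value."""

    observed: float
    null_mean: float
    null_sd: float
    z: Optional[float]
    p: Optional[float]
    p_empirical: float
    B: int
    set_size: int
    seed: int
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Input


def read_blast_tab(
    path: Union[str, Path],
    query_lengths: Optional[Mapping[str, int]] = None,
    species_from_subject: bool = True,
) -> list[HomologHit]:
    """Read BLAST outfmt-6 hits into HomologHit records.

    The 12 standard columns are expected; a 13th column, when present, is
    taken as the query length (the ``qlen`` output token).  Otherwise
    ``query_lengths`` must supply lengths so query coverage can be
    computed as alignment length / query length.  Subject IDs of the form
    ``species|protein`` carry the species; otherwise a ``species``
    14th column is required.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] < 12:
        raise ValueError(f"{path}: expected >= 12 BLAST outfmt-6 columns")
    hits = []
    for row in df.itertuples(index=False):
        qid, sid = str(row[0]), str(row[1])
        aln_len = int(row[3])
        evalue = float(row[10])
        if df.shape[1] >= 13 and query_lengths is None:
            qlen = int(row[12])
        elif query_lengths is not None:
            qlen = int(query_lengths[qid])
        else:
            raise ValueError(
                f"{path}: no qlen column and no query_lengths supplied"
            )
        if df.shape[1] >= 14:
            species = str(row[13])
        elif species_from_subject and "|" in sid:
            species = sid.split("|", 1)[0]
        else:
            raise ValueError(
                f"{path}: cannot infer species for subject {sid!r}"
            )
        hits.append(
            HomologHit(
                query_id=qid,
                subject_id=sid,
                species_id=species,
                evalue=max(evalue, 1e-300),
                overlap_fraction=min(1.0, aln_len / qlen),
            )
        )
    return hits


def read_species_meta(path: Union[str, Path]) -> dict[str, SpeciesMeta]:
    """Read the species metadata TSV keyed by species_id."""
    df = read_tsv(path)
    meta = {}
    for row in df.itertuples(index=False):
        mc = getattr(row, "multicellularity", None)
        if isinstance(mc, float) and np.isnan(mc):
            mc = None
        meta[str(row.species_id)] = SpeciesMeta(
            species_id=str(row.species_id),
            domain=str(row.domain),
            phylum=str(row.phylum),
            multicellularity=mc,
            n_A34_genes=int(getattr(row, "n_A34_genes", 0)),
            a34_diversity=int(getattr(row, "a34_diversity", 0)),
        )
    return meta


# ---------------------------------------------------------------------------
# Filtering and the hit matrix


def filter_hits(
    hits: Sequence[HomologHit],
    evalue_max: float = 0.01,
    overlap_min: float = 0.20,
    max_hits_per_query: int = 10_000,
) -> list[HomologHit]:
    """Apply the hit-acceptance cap and the e-value / coverage filters.

    The per-query cap (best ``max_hits_per_query`` hits by e-value) is
    applied first, mirroring a search tool's accepted-hits limit, then
    hits with e-value above ``evalue_max`` or query coverage below
    ``overlap_min`` are dropped.
    """
    by_query: dict[str, list[HomologHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    kept = []
    for qid, qhits in by_query.items():
        qhits = sorted(qhits, key=lambda h: h.evalue)[:max_hits_per_query]
        kept.extend(
            h
            for h in qhits
            if h.evalue <= evalue_max and h.overlap_fraction >= overlap_min
        )
    return kept


def species_hit_matrix(
    hits: Sequence[HomologHit], meta: Mapping[str, SpeciesMeta]
) -> pd.DataFrame:
    """Query x species matrix of hit counts (distinct subjects per query).

    Duplicate (query, subject) pairs — e.g. multiple HSPs — count once.
    Every species in ``meta`` gets a column; missing combinations are 0.
    """
    unknown = sorted({h.species_id for h in hits} - set(meta))
    if unknown:
        raise ValueError(f"hits reference unknown species: {unknown}")
    pairs = {(h.query_id, h.subject_id, h.species_id) for h in hits}
    queries = sorted({q for q, _, _ in pairs})
    matrix = pd.DataFrame(
        0, index=queries, columns=sorted(meta), dtype=np.int64
    )
    for q, _, s in pairs:
        matrix.loc[q, s] += 1
    matrix.index.name = "query_id"
    return matrix


# ---------------------------------------------------------------------------
# Group averages and the permutation scheme


def _group_columns(
    matrix: pd.DataFrame, meta: Mapping[str, SpeciesMeta], group: str
) -> list[str]:
    """Species columns belonging to a named group.

    Group names: 'prokaryote' (Archaea + Bacteria), a domain name, or a
    multicellularity class.
    """
    def in_group(m: SpeciesMeta) -> bool:
        if group == "prokaryote":
            return m.domain in {"Archaea", "Bacteria"}
        if group == "eukaryote":
            return m.domain == "Eukarya"
        if group in {"Archaea", "Bacteria", "Eukarya"}:
            return m.domain == group
        if group in {"unicellular", "multicellular"}:
            return m.multicellularity == group
        raise ValueError(f"unknown species group {group!r}")

    return [s for s in matrix.columns if s in meta and in_group(meta[s])]


def group_average_ratio(
    matrix: pd.DataFrame,
    meta: Mapping[str, SpeciesMeta],
    group_a: str = "prokaryote",
    group_b: str = "eukaryote",
    queries: Optional[Sequence[str]] = None,
) -> tuple[float, float, Optional[float]]:
    """Per-genome average hit rates of two groups and their ratio a/b.

    For each query the hit rate in a group is (total hits in the group's
    genomes) / (number of genomes in the group); the group average is the
    mean of these rates over queries, and the 'average ratio' divides the
    two averages.  A zero group-b average yields a flagged None ratio.
    """
    cols_a = _group_columns(matrix, meta, group_a)
    cols_b = _group_columns(matrix, meta, group_b)
    if not cols_a or not cols_b:
        raise ValueError(f"empty species group: {group_a if not cols_a else group_b}")
    sub = matrix.loc[list(queries)] if queries is not None else matrix
    rate_a = sub[cols_a].sum(axis=1) / len(cols_a)
    rate_b = sub[cols_b].sum(axis=1) / len(cols_b)
    avg_a = float(rate_a.mean())
    avg_b = float(rate_b.mean())
    if avg_b == 0:
        warnings.warn("group-b average hit rate is 0; ratio undefined")
        return avg_a, avg_b, None
    return avg_a, avg_b, avg_a / avg_b


def permutation_ratio_test(
    matrix: pd.DataFrame,
    meta: Mapping[str, SpeciesMeta],
    query_set: Sequence[str],
    group_a: str = "prokaryote",
    group_b: str = "eukaryote",
    B: int = 5000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test of the average ratio for a query set.

    The null resamples B query sets of the same size uniformly without
    replacement from all queries of the matrix; the z-score of the
    observed ratio against the null mean/sd gives a one-sided normal
    p-value in the direction of the observed deviation, reported next to
    the empirical tail proportion.
    """
    query_set = list(query_set)
    missing = sorted(set(query_set) - set(matrix.index))
    if missing:
        raise ValueError(f"query_set not in matrix: {missing[:5]}")
    cols_a = _group_columns(matrix, meta, group_a)
    cols_b = _group_columns(matrix, meta, group_b)
    if not cols_a or not cols_b:
        raise ValueError("empty species group")

    # per-query group rates once; set-level averages are means over rows
    rate_a = (matrix[cols_a].sum(axis=1) / len(cols_a)).to_numpy(float)
    rate_b = (matrix[cols_b].sum(axis=1) / len(cols_b)).to_numpy(float)
    idx = {q: i for i, q in enumerate(matrix.index)}
    obs_rows = np.array([idx[q] for q in query_set])

    def ratio(rows: np.ndarray) -> float:
        b = rate_b[rows].mean()
        return rate_a[rows].mean() / b if b > 0 else np.nan

    observed = ratio(obs_rows)
    rng = np.random.default_rng(seed)
    n, k = len(matrix), len(query_set)
    null = np.empty(B)
    for j in range(B):
        null[j] = ratio(rng.choice(n, size=k, replace=False))
    null = null[~np.isnan(null)]
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if len(null) > 1 else 0.0
    p_emp = float(
        np.mean(null >= observed)
        if observed >= null_mean
        else np.mean(null <= observed)
    )
    if null_sd == 0:
        z = 0.0 if observed == null_mean else None
        p = 0.5 if z == 0.0 else None
        return PermutationResult(
            observed, null_mean, null_sd, z, p, p_emp, B, k, seed, degenerate=True
        )
    z = (observed - null_mean) / null_sd
    p = float(stats.norm.sf(abs(z)))
    return PermutationResult(observed, null_mean, null_sd, z, p, p_emp, B, k, seed)


# ---------------------------------------------------------------------------
# Presence screening, normalization, group comparisons


def presence_screen(
    subject_records: Mapping[str, Mapping[str, Sequence[ProteinRecord]]],
    params: ScanParams = ScanParams(),
) -> pd.DataFrame:
    """Species x query presence of TAPSLIVR-rich homologs.

    ``subject_records[species][query]`` holds the homologous protein
    sequences of a query found in a species; presence requires at least
    one homolog that itself contains a TAPSLIVR-rich region (the Stage 1
    detector is reused).
    """
    species_ids = sorted(subject_records)
    queries = sorted({q for sp in subject_records.values() for q in sp})
    table = pd.DataFrame(False, index=species_ids, columns=queries)
    for sp, by_query in subject_records.items():
        for q, homologs in by_query.items():
            table.loc[sp, q] = any(
                find_regions(h, params) for h in homologs
            )
    table.index.name = "species_id"
    return table


def phylum_normalize(
    presence: pd.DataFrame, meta: Mapping[str, SpeciesMeta]
) -> pd.DataFrame:
    """Fraction of a phylum's species with a qualifying homolog, per query.

    Long-format output (phylum, query_id, fraction), heatmap-ready.
    """
    unknown = sorted(set(presence.index) - set(meta))
    if unknown:
        raise ValueError(f"presence table references unknown species: {unknown}")
    phyla = pd.Series({s: meta[s].phylum for s in presence.index})
    rows = []
    for phylum, species in phyla.groupby(phyla).groups.items():
        n = len(species)
        if n == 0:
            warnings.warn(f"phylum {phylum!r} has no species; excluded")
            continue
        frac = presence.loc[list(species)].mean(axis=0)
        for q, f in frac.items():
            rows.append({"phylum": phylum, "query_id": q, "fraction": float(f)})
    return pd.DataFrame(rows, columns=["phylum", "query_id", "fraction"])


def multicellular_compare(
    per_species_counts: Mapping[str, int],
    meta: Mapping[str, SpeciesMeta],
    matrix: Optional[pd.DataFrame] = None,
    query_set: Optional[Sequence[str]] = None,
    B: int = 5000,
    seed: int = 0,
) -> dict:
    """Compare qualifying-homolog abundance in uni- vs multicellular species.

    Returns the median fold-change multicellular/unicellular, a two-sided
    Mann-Whitney U p-value (tie-corrected), and — when a hit matrix and
    query set are supplied — the average-ratio permutation test with
    groups unicellular vs multicellular.
    """
    uni = [
        per_species_counts[s]
        for s in per_species_counts
        if meta[s].multicellularity == "unicellular"
    ]
    multi = [
        per_species_counts[s]
        for s in per_species_counts
        if meta[s].multicellularity == "multicellular"
    ]
    if not uni or not multi:
        raise ValueError("both multicellularity groups must be non-empty")
    med_uni = float(np.median(uni))
    med_multi = float(np.median(multi))
    if med_uni == 0:
        warnings.warn("unicellular median is 0; fold-change undefined")
        fc = None
    else:
        fc = med_multi / med_uni
    mw = stats.mannwhitneyu(multi, uni, alternative="two-sided")
    out = {
        "median_unicellular": med_uni,
        "median_multicellular": med_multi,
        "median_fold_change": fc,
        "mannwhitney_U": float(mw.statistic),
        "mannwhitney_p": float(mw.pvalue),
        "permutation": None,
    }
    if matrix is not None and query_set is not None:
        out["permutation"] = permutation_ratio_test(
            matrix,
            meta,
            query_set,
            group_a="unicellular",
            group_b="multicellular",
            B=B,
            seed=seed,
        )
    return out


def trna_spearman(
    per_species_counts: Mapping[str, int],
    meta: Mapping[str, SpeciesMeta],
    exclude_above: int = 400,
) -> dict:
    """Spearman correlation of homolog abundance with A34-tRNA gene counts.

    Species with more than ``exclude_above`` A34-tRNA genes are excluded
    and listed (the paper's rule for genomes with unusual tRNA gene
    amplifications).  A34 diversity (0-8) is carried as an annotation.
    """
    species = sorted(per_species_counts)
    excluded = [s for s in species if meta[s].n_A34_genes > exclude_above]
    used = [s for s in species if s not in set(excluded)]
    if len(used) < 3:
        raise ValueError("fewer than 3 species after exclusion")
    x = np.array([meta[s].n_A34_genes for s in used], dtype=float)
    y = np.array([per_species_counts[s] for s in used], dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant vector; Spearman rho undefined")
        rho, p = None, None
    else:
        res = stats.spearmanr(x, y)
        rho, p = float(res.statistic), float(res.pvalue)
    return {
        "rho": rho,
        "p": p,
        "n_used": len(used),
        "excluded_species": excluded,
        "a34_diversity": {s: meta[s].a34_diversity for s in used},
    }
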