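# tapslivr

Detection and codon-level analysis of **low-complexity TAPSLIVR-rich
protein regions** and their dependence on **inosine-34 tRNA decoding**.

Eukaryotic tRNAs for Thr, Ala, Pro, Ser, Leu, Ile, Val and Arg
(**TAPSLIVR**) carry inosine at the anticodon wobble position (I34,
produced from A34 by the ADAT2/ADAT3 deaminase). An I34 anticodon pairs
with U-, C- and A-ended codons, so the 24 U/C/A-ended codons of the
eight I34-decoded codon boxes ("ADAT codons") are translated by
I34-tRNAs, while their G-ended synonyms are not. Proteins whose
sequences contain long low-complexity regions made almost entirely of
TAPSLIVR — mucin-like domains, syndecans, dystroglycan — place an
exceptional demand on this tRNA pool. This package implements the
computational pipeline for studying that demand:

1. **`lcr_detect`** — running-window detection of TAPSLIVR-rich regions:
   a window of *w* = 30 residues qualifies when at least 80% of its
   residues are TAPSLIVR; overlapping qualifying windows are merged by
   coordinate union into maximal regions. Per-position composition
   profiles (TAPSLIVR fraction of residues, ADAT fraction of codons).
2. **`codon_metrics`** — ADAT-codon enrichment of a coding region
   (percentage of ADAT codons among its TAPSLIVR codons, compared with
   the genome-expected 65.743% derived from human codon usage), GC
   content, Codon Adaptation Index, and synonymous recoding of every
   TAPSLIVR codon to C-ended (I34-sensitive) or G-ended
   (I34-insensitive) triplets — the reporter-design logic.
3. **`homolog_stats`** — comparative statistics over homology-hit
   tables: e-value/coverage filtering, per-genome average hit rates per
   species group and their "average ratio", a permutation test of that
   ratio over random query sets (z-score p-value), presence screening of
   homologs for TAPSLIVR regions, phylum-normalized presence fractions,
   unicellular-vs-multicellular comparison (median fold-change +
   Mann-Whitney U), and the Spearman correlation with A34-tRNA gene
   counts (species with > 400 such genes excluded).
4. **`te_enrichment`** — statistics over translation-efficiency tables
   from polysome profiling: interaction fold-change classification
   (FC < 1.5, p < 0.05), Fisher exact enrichment of
   low-complexity-encoding genes, and a fixed-size permutation test
   whose p-value is the proportion of random gene sets with a statistic
   at least as extreme as observed.

**`synthetic_data`** generates seeded inputs with ground truth for every
stage (planted regions, codon-usage-sampled CDS with controllable ADAT
fraction, Poisson homolog-hit tables with group-specific rates, TE
tables with a planted impaired subset), so the full pipeline is testable
without downloads.

## Worked example

```bash
$ tapslivr simulate proteome --n 5 --seed 11 --out prot.fasta --truth truth.tsv
5 proteins -> prot.fasta; truth -> truth.tsv
$ tapslivr scan --fasta prot.fasta --out regions.tsv
5 proteins scanned; 5 with >=1 region; 5 regions -> regions.tsv
$ head -5 regions.tsv
# tapslivr 0.1.0 scan window=30 min_fraction=0.8
# n_proteins=5 n_with_region=5 n_regions=5
protein_id	start0	end0	length	tapslivr_fraction	n_windows
synp0000	57	119	62	0.7903225806451613	33
synp0001	54	113	59	0.7966101694915254	30
```

Each detected region is the union of its qualifying 30-residue windows;
`tapslivr_fraction` is recomputed over the merged span (it may fall
slightly below 0.80 because the union includes window flanks).

```bash
$ tapslivr simulate cds --fasta prot.fasta --seed 3 --out cds.fasta
$ tapslivr enrich --cds cds.fasta --out enr.tsv
$ head -4 enr.tsv
# threshold=65.743
cds_id	n_tapslivr_codons	n_adat_codons	adat_percent	enriched	undefined
synp0000	49	37	75.51020408163265	True	False
synp0001	47	34	72.34042553191489	True	False
```

`adat_percent` is the share of ADAT codons among TAPSLIVR codons;
`enriched` compares it against the human genome-wide expectation of
65.743%. Here the usage-sampled coding sequences of TAPSLIVR-rich
synthetic proteins land above the threshold, as expected for sequences
dominated by amino acids whose preferred human codons are U/C/A-ended.

The same operations are available as library calls
(`tapslivr.find_regions`, `tapslivr.adat_enrichment`,
`tapslivr.recode_tapslivr`, ...), and `tapslivr run --config run.yaml`
chains stages with a manifest of parameters, seeds and input checksums.

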