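# Methods

## Codon classes

The analysis rests on two fixed codon sets built from the standard
genetic code (translation table 1). The eight I34-decoded codon boxes
are ACN (Thr), GCN (Ala), CCN (Pro), TCN (Ser), CTN (Leu), ATN (Ile),
GTN (Val) and CGN (Arg); an inosine-34 anticodon pairs with U, C and A
at the codon third position, so each box contributes three
**ADAT codons** — 24 in total. The **TAPSLIVR codons** are all 37 sense
codons encoding Thr/Ala/Pro/Ser/Leu/Ile/Val/Arg; the 13 that are not
ADAT codons are the G-ended members of the eight boxes plus the
out-of-box synonyms (TTA/TTG for Leu, AGT/AGC for Ser, AGA/AGG for
Arg). These sets partition the 64 codons into ADAT (24),
TAPSLIVR-non-ADAT (13), other sense (24) and stop (3). The ADAT set is
reconstructed from the eight I34 substrate tRNAs and the wobble rule;
it is a module constant, and the canonical recoding synonym tables are
override-able arguments should a different reconstruction be needed.

## Region detection

A low-complexity TAPSLIVR-rich region is operationalized by a running
window: a window of exactly `window` residues (default 30) slid with
step 1 qualifies when its TAPSLIVR count is at least
`ceil(min_fraction × window)` — 24 of 30 at the default 80%, with the
ceiling computed robustly against float representation. Overlapping or
adjacent qualifying windows are merged by coordinate union into maximal
regions, which therefore always span ≥ 30 residues. The merged region's
overall fraction is recomputed and reported but not re-filtered: regions
are defined by their qualifying windows, and the union can dilute the
fraction slightly below the window threshold (flanks of up to
`floor((1−min_fraction)×window)` = 6 residues can enter at the ends).
'X' residues are tolerated on input and never counted as TAPSLIVR
(conservative detection). Coordinates are 0-based half-open internally.

Two consequences of this formalization are worth knowing. First, it is
monotone in `min_fraction` (lowering the threshold only grows coverage)
but **not** in `window`: a residue covered at window 30 can be uncovered
at window 25 when the misses are packed into one end (the test suite
carries an explicit counterexample). Second, a fully saturated planted
region bounded by non-TAPSLIVR flanks is detected with exactly 6 extra
residues on each side. The detector is verified exhaustively against a
brute-force oracle that re-counts every window by direct enumeration.

## Enrichment threshold and codon metrics

A coding region's ADAT enrichment is the percentage of ADAT codons
**among its TAPSLIVR codons** (not among all codons); a region with no
TAPSLIVR codons gets an undefined, flagged score. The region counts as
enriched when the percentage strictly exceeds the threshold. The
genome-expected threshold is derived from a codon-usage table as
100 × (usage mass on ADAT codons)/(usage mass on TAPSLIVR codons):
uniform usage gives 100 × 24/37 = 64.865%, and the bundled human table
(the standard CUTG per-1000 frequencies) gives 65.76%, consistent with
the shipped default of 65.743%. The TAPSLIVR-only denominator was
chosen because it is the only reading under which the uniform-usage
value and the published human threshold are mutually consistent. The
derivation is invariant to rescaling the table.

CAI is the geometric mean of per-codon relative adaptiveness
w(c) = usage(c)/max(usage over c's synonyms), excluding stops and the
single-codon families (Met, Trp); zero-usage codons contribute a
configurable floor (default 0.01) instead of log(0). GC content is the
plain G+C percentage.

## Synonymous recoding

`recode_tapslivr` rewrites every TAPSLIVR codon to one canonical
synonym per amino acid: C-ended ACC/GCC/CCC/TCC/CTC/ATC/GTC/CGC
(all ADAT-sensitive) or G-ended ACG/GCG/CCG/TCG/CTG/GTG/CGG. Ile has no
G-ended codon; the default fallback keeps the ATC codon in G-mode
(options: ATT or keep the original), counts the position in
`n_fallback`, and warns. Because each C/G canonical pair differs only
at the third position and the Ile fallback is shared, the two recoded
variants of any CDS have identical GC content — mirroring the
equal-GC design requirement for reporter pairs. Translation invariance
is asserted at run time. The canonical synonym tables are a
reconstruction (published constructs do not list their per-position
choices); applied to the bundled canonical eGFP ORF they give CAI 0.876
(C-mode) and 0.784 (G-mode) under the bundled usage table, so a
construct designer wanting CAI-balanced variants should override the
tables with usage-matched choices.

## Homolog-distribution statistics

Hits are accepted per query up to a cap (default 10 000, applied before
the other filters, mirroring a search tool's accepted-hit limit), then
filtered by e-value ≤ 0.01 and query coverage ≥ 0.20 (aligned query
length / query length; subject coverage ignored). One hit means one
distinct subject protein per query — duplicate HSPs collapse.

For a set of query proteins, each group's per-genome hit rate is
(total hits in the group)/(number of genomes in the group), averaged
over queries; the **average ratio** divides the two group averages
(ratio of means, not mean of per-query ratios, which would be undefined
whenever a query has no hits in the denominator group). The permutation
test draws B (default 5000) query sets of the same size uniformly
without replacement from the whole query universe, computes the null
mean and SD of the average ratio, and reports
z = (observed − mean)/SD with p = Φ̄(|z|), the one-sided normal tail in
the observed direction — this is the approximation that can report
extreme bounds (p < 1e−10) beyond the resolution of B draws; the
empirical tail proportion is reported alongside. When the query set is
the whole universe the null is degenerate and z = 0, p = 0.5 is
returned with a flag. Note the folded p is uniform on (0, 0.5) under
the null; calibration checks therefore evaluate the fixed-direction
tail Φ(z), which is uniform on (0, 1).

Presence screening asks, per species and query, whether any homolog of
the query in that species itself contains a TAPSLIVR-rich region
(reusing the Stage 1 detector); phylum normalization divides the number
of positive species by the phylum's size. The
unicellular/multicellular comparison reports the fold-change of group
medians and a two-sided, tie-corrected Mann-Whitney U (scipy; verified
against exact enumeration for small groups). The A34 correlation is a
Spearman rank correlation between per-species qualifying-homolog counts
and A34-tRNA gene counts, excluding species with more than 400 such
genes (genomes with unusual tRNA gene amplifications) and listing them.

## Translation-efficiency enrichment

The pipeline consumes per-gene fold-change tables from an upstream
differential-expression fit (it never fits the model itself). Threshold
classification marks a gene translationally impaired when the
interaction fold-change (knockdown vs control of the high-polysome/total
ratio) is < 1.5 with p < 0.05, on the linear fold-change scale as those
cuts are conventionally printed; a relaxed mode classifies by fold-change
sign only. "Highly translated in control" means control HP/Total FC
> 1.5, with the control p-value applied when one is supplied.
Enrichment of low-complexity-encoding genes is Fisher's exact test on
the 2×2 table (in/out of set × annotated/not), with a Haldane 0.5
correction of the odds ratio only when a zero cell would make it
undefined (the raw table is always reported). The fixed-size
permutation test draws B = 10 000 gene sets of size n (= 31 in the
reference analysis) without replacement and reports the proportion of
sets whose annotated fraction is ≥ the observed one (inclusive
comparison, the conservative convention; strict and (r+1)/(B+1)
smoothed variants are flags). As B → ∞ this converges to the
hypergeometric upper tail, which the tests verify.

## Synthetic data

The generators produce the statistical structure each stage assumes,
with truth tables, under a single seed (outputs are byte-identical
across runs):

- **Proteomes**: planted regions of length U[35, 60] and TAPSLIVR
  fraction U[0.85, 1.0] (an exact count of TAPSLIVR letters, shuffled),
  separated and flanked by ≥ 2 × window non-TAPSLIVR-only spacers so
  regions never merge; background residues are TAPSLIVR with
  probability 0.2 — far enough below the 0.8 threshold that false
  positive windows are vanishingly rare at window 30.
- **CDS**: codons sampled among synonyms proportional to a usage table;
  inside bias intervals TAPSLIVR codons are drawn ADAT with the target
  probability (Ile, all of whose synonyms are ADAT, always yields one).
- **Homolog hits**: counts per (query, species) are Poisson with
  group-specific rates (the simplest count model for per-species
  averages; overdispersion can be emulated by mixing rates); a
  configurable fraction of hits gets a failing e-value or coverage to
  exercise the filters; eukaryote A34 gene counts increase strictly
  with the species' planted hit abundance (genes per dense abundance
  rank plus optional Gaussian noise), so the noise-free Spearman
  correlation is exactly 1.
- **TE tables**: background log2 interaction fold-changes are
  N(0, σ = 0.3), the planted impaired subset N(−δ, σ) with δ = 1 by
  default (δ = 2 in recovery tests); p-values are the exact two-sided
  normal tails of the corresponding z, so under δ = 0 the p < 0.05 rate
  is 5% by construction.

What the synthetic data does **not** emulate: homology and phylogenetic
correlation between species (hits are independent Poisson draws),
realistic protein length and composition distributions, BLAST score
statistics, or correlated replicate noise in TE estimates. Passing the
recovery tests therefore shows the statistics are implemented and wired
correctly and detect effects of the planted size under idealized
sampling — not that they are robust to the dependence structures of
real comparative or expression data.

## Problem sizes and numerical choices

The test suite and the acceptance script use scaled-down but fully
powered designs chosen as the smallest sizes with unambiguous expected
outcomes: 1000 random proteins (≤ 200 aa) for the detector oracle, 1000
random CDS for recoding invariants, 500 repetitions for null
calibration (3σ binomial band on the 5% rate), B = 200–1000 for
permutation nulls inside calibration loops and B = 10 000 for the
hypergeometric cross-check, 40 planted + 160 background queries over 50
genomes for ratio recovery, and 1000-gene TE tables with a 31-gene
planted subset. Window qualification uses an epsilon-robust ceiling;
e-values are floored at 1e−300; empty families, zero denominators,
constant vectors and degenerate nulls return flagged results rather
than NaNs. Full-scale replications (the 2218-protein human proteome
scan and the published reporter constructs) run against user-supplied
files under `data/external/`, as described there.
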