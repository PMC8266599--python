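# External inputs (not redistributed)

Two replication tests in `tests/test_acceptance.py` need inputs that are
too large or not licensed for redistribution. Place them here to run
those tests; in their absence the tests fail with instructions.

- `CCDS_protein.faa` — Human CCDS release 22 protein sequences
  (14 June 2018). Download `CCDS_protein.current.faa.gz` from the NCBI
  CCDS archive for release 22 and decompress it here. Scanning it with
  window 30 and minimum fraction 0.80 should flag 2218 proteins with at
  least one TAPSLIVR-rich region.
- `egfp_supplementary.fasta` — the published eGFP ADAT / eGFP nonADAT
  reporter coding sequences (supplementary material of the source
  article); two records whose IDs contain `ADAT` and `nonADAT`.
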