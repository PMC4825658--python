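# barscreen

Analysis pipeline for pooled FACS reporter screens read out by molecular
barcode sequencing, plus a full synthetic-screen simulator.

A barcoded knockout pool carrying a fluorescent pathway reporter is sorted
by FACS into fluorescence gates (two uninduced pools, three induced pools),
each sorted pool is regrown and its strain barcodes are PCR-amplified and
sequenced. `barscreen` covers the dry half of that experiment:

- **`barcode_io`** — barcode catalog TSVs (primary + resequenced lists with
  conflict-aware merging), FASTQ read/write, and an N-spacered concatenated
  barcode reference (FASTA) for cross-validation with external aligners.
- **`screen_sim`** — synthetic data: per-phenotype-class log-normal GFP
  mixtures, gate derivation from control draws, FACS sorting, regrowth with
  fitness and bottleneck drift, PCR efficiency noise, and read generation
  with multiplex tags and substitution errors, all seeded and
  bit-reproducible, with an analytic ground-truth table.
- **`demux_count`** — multiplex-tag demultiplexing, primer-anchored barcode
  extraction, minimal-Hamming-distance matching against the catalog
  (pigeonhole-indexed, oracle-equivalent to brute force), count tables with
  exact read ledgers, the ≥50-reads-in-control (UPTAG and/or DNTAG)
  inclusion filter, and tag-preserving table merging.
- **`enrichment`** — median-of-ratios size factors, method-of-moments NB
  dispersions with a parametric mean-dispersion trend, a conditioned
  two-sided NB exact test of each sorted pool against the presorted
  library, Benjamini–Hochberg adjustment, deterministic ranking, and a
  decision-table phenotype classifier (pathway-null / non-inducer /
  high-basal / hyper-inducer).
- **`cat_analysis`** — concordance-at-the-top curves for two ranked gene
  lists with an analytic hypergeometric null band (default 99.9% critical
  region) and an indistinguishable/distinguishable verdict.
- **`facs_summary`** — median fold changes between fluorescence samples and
  bimodal-subpopulation detection via a hand-rolled 1D Gaussian-mixture EM
  with penalized-likelihood model selection.

## CLI

```sh
barscreen simulate --outdir demo --seed 1 --genes 300        # synthetic screen
barscreen count --catalog demo/catalog.tsv \
    --sample-sheet demo/sample_sheet.tsv --outdir demo/counts
barscreen test --counts-up demo/counts/counts_up.tsv \
    --counts-dn demo/counts/counts_dn.tsv \
    --sample-sheet demo/sample_sheet.tsv --outdir demo/results
barscreen classify --results-dir demo/results --out demo/results/calls.tsv
barscreen run-all --seed 1 --genes 300 --outdir demo   # all of the above
barscreen cat --list-a a.tsv --list-b b.tsv --out cat.tsv
barscreen facs --sample cells.tsv --reference wt.tsv
```

All options can also be set in a YAML config (`--config`); CLI flags
override config keys. Output TSVs carry `# key: value` provenance headers
(read them back with `pandas.read_csv(..., comment='#')`).

Real FACS data enters via single-column TSVs of per-cell log10
fluorescence (`facs` subcommand); FCS binary parsing is out of scope —
export with any standard FCS tool first. Real sequencing data enters as
FASTQ plus a sample sheet TSV (`sample`, `pool`, `replicate`, `bar_tag`,
`multiplex_tag`, `fastq` columns).

## Acceptance

Acceptance is property-based (matching-oracle equivalence, ledger
conservation, exact-test enumeration checks, type-I calibration,
closed-loop recovery of planted mutant classes, the minimum-read rule,
CAT-band coverage, fold-change and bimodality recovery); it lives in
`tests/test_acceptance.py`. The report script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs an end-to-end smoke check and writes an (intentionally empty) JSON
object: this artifact has no numeric point targets, as the source study's
printed values depend on its deposited sequencing data and external
annotation databases.
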