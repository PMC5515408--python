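# eboxscape

Analysis toolkit for E-box DNA-binding specificity of bHLHZ dimer pairs
(a MYC:MAX-style heterodimer vs a MAX:MAX-style homodimer), covering four
workflows end to end, exercisable entirely on synthetic data with known
ground truth:

- **PBM analysis** (`eboxscape.pbm_analysis`) — design of a custom
  protein-binding-microarray probe library (4096 core-register hexamer probes
  `tgaNNNNNNgta`, 64 + 64 flank-substitution probes, 518 multi-point mutants,
  100 random null probes), triplicate-intensity normalization, empirical-null
  thresholding against the random probes (95% / 80% quantiles), motif
  ranking, common and high-confidence motif sets, score correlation, and
  position weight matrices (rank slices and flank quartiles).
- **Motif genomics** (`eboxscape.motif_genomics`) — exact two-strand motif
  scanning, peak summits (apex ±100 bp), top-fraction and fold-enrichment
  strata, genome-normalized motif frequency, motif co-occurrence Venn cells,
  promoter/intragenic/intergenic annotation, condition (dose) fold changes,
  spatial offset histograms and top-k motif coverage of summits.
- **Competition modelling** (`eboxscape.emsa_model`) — full mass-balance
  equilibrium of a labeled probe and an unlabeled competitor for limited
  protein, least-squares estimation of competitor dissociation constants,
  non-binding detection, and relative-affinity summary tables normalized to a
  reference sequence.
- **Synthetic data** (`eboxscape.synthetic_data`) — seeded generators for
  genomes, planted motif sites with tiered affinities, gene models,
  dose-dependent peak calls driven by a mass-action occupancy model, PBM
  intensities with multiplicative noise, and competition curves — all with
  ground truth for parameter-recovery tests.

File formats, configuration and the CLI live in `eboxscape.io_cli`
(FASTA/BED/TSV/XLSX/YAML; coordinates are 0-based half-open everywhere).

## Tests

```sh
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py` with one test per acceptance
criterion (library counts; brute-force scanning oracles on 100 random
genomes; partition laws on 1000 random fixtures; normalized-frequency hand
counts; competition-fit parameter recovery for K-ratios {5, 20, 33} over
seeds 1–100; synthetic end-to-end motif recovery over seeds 1–100). Two
acceptance tests are data-gated and skip unless external inputs are provided:

- the published probe/score workbook at `data/S1_table.xlsx` or
  `$EBOXSCAPE_S1_TABLE`;
- externally derived ChIP-seq peak tables and genome via
  `$EBOXSCAPE_GENOME`, `$EBOXSCAPE_PEAKS_HIGH`, `$EBOXSCAPE_PEAKS_LOW`
  (peak tables are 8-column TSV: chrom, start, end, apex, height, pvalue,
  condition, id).

## CLI

```sh
eboxscape --seed 1 run --mode synthetic --out report/        # full pipeline
eboxscape design --out lib/                                  # probe library
eboxscape scan --genome g.fa --motifs CACGTG,AACGTT --out hits.bed
eboxscape enrich --genome g.fa --peaks peaks.tsv --motifs CACGTG,AACGTT --out enr.tsv
eboxscape venn --genome g.fa --peaks peaks.tsv --out venn.json
eboxscape annotate --peaks peaks.tsv --genes genes.bed --out ann.tsv
eboxscape compare-conditions --genome g.fa --peaks-high h.tsv --peaks-low l.tsv --out fc.tsv
eboxscape coverage --genome g.fa --peaks peaks.tsv --motifs CACGTG,AACGTT
eboxscape emsa-fit --curves curves.tsv --reference NE --kl-anchor CME --out fits.tsv
```

Global options: `--config config.yaml` (see `eboxscape.io_cli.AnalysisConfig`
for keys and defaults), `--seed`, `--log-level`. Synthetic runs are byte-for-
byte reproducible for a fixed config and seed.

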