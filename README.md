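# pkat

Comparative sequence analyses for the PMEL/GPNMB/TMEM130 ("PKAT") protein
family, packaged as a tested pipeline:

- **`pkat.seq_io`** — FASTA, gene-order TSV, exon-table TSV and Newick
  readers/writers; the canonical `SeqRecord`.
- **`pkat.simulate`** — synthetic data with ground truth for every stage:
  imperfect tandem-repeat arrays with planted T/S / D/E ladders, full
  PKAT-style proteins with planted domain spans, paralogon gene
  neighborhoods with known shared-gene counts, ortholog exon tables with
  controlled jitter, and sequence families evolved along a known tree.
- **`pkat.architecture`** — domain annotation from explicit heuristics:
  signal peptide (charged residue within 1–13 of Met, ≥8 uncharged run,
  7–33 aa total), PKD motifs (`WDFGDGS` with mismatch budget,
  `[LI][HY]DP`), six-cysteine Kringle-like domain against a spacing
  template, ≥90%-nonpolar transmembrane window, C-terminal `[DE]XXXL[LI]`
  dileucine signal, and variant-position → domain mapping.
- **`pkat.repeats`** — tandem-repeat period detection (pair-normalized
  self-similarity with harmonic suppression), unit segmentation with
  bounded length drift, progressive unit alignment with the ≥50%/X
  consensus rule, T/S and D/E ladder columns, and degenerate/paired motif
  censuses.
- **`pkat.align`** — affine-gap global alignment (BLOSUM62 defaults) and
  percent identity over the full alignment length.
- **`pkat.exons`** — protein-domain → exon mapping and the ±5%
  exon-length conservation statistic reported as `"153 bp (7/10)"`.
- **`pkat.synteny`** — ±100-gene neighborhoods, shared-symbol counts
  against reference paralogon groups, half-up one-decimal ratios and an
  inparalog classification.
- **`pkat.phylo`** — p-distance, deterministic neighbor joining,
  bootstrap support and monophyly checks.
- **`pkat.reporting` / `pkat.cli`** — a `pkat` command with one
  subcommand per stage plus a config-driven panel report.

## CLI

```sh
pkat annotate --in proteins.fasta --out arch.tsv --json
pkat repeats --in seq.fasta --pmin 8 --pmax 40 --ladder-threshold 0.7 --out report.tsv
pkat identity --a a.fasta --b b.fasta --out id.tsv
pkat exons --tables exons.tsv --tol 0.05 --out exoncons.tsv
pkat synteny --focal-table lamprey.tsv --focal-gene gpnmb \
    --ref-tables human.tsv,chicken.tsv,skate.tsv \
    --ref-genes-a GPNMB --ref-genes-b PMEL --window 100 --out synteny.tsv
pkat phylo --msa aln.fasta --bootstrap 1000 --seed 42 --outgroup Trichoplax_tmem130 --out tree.nwk
pkat simulate --kind rpt --seed 1 --out-dir sim/
pkat run --config panel.cfg
```

`panel.cfg` is a flat `key = value` file (`proteins`, `out_dir`,
`ladder_threshold`, `pmin`, `pmax`, `kld_mode`, `motifs`, `seed`); every
effective value is echoed into the report's provenance block.

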