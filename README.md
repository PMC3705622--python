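# ervkit

Toolkit for analysing a family of near-identical LTR-retroelement loci:

- **`ervkit.core`** — coordinate conventions (0-based half-open internally,
  1-based inclusive display spans), FASTA/primer-TSV IO, reverse complement.
- **`ervkit.catalog`** — repeat-table parsing (UCSC rmsk TSV and
  RepeatMasker `.out` dialects), family-name filtering, fragment-length
  histograms, aggregate fragment statistics, and clustering of fragments
  into element calls (solo LTR vs provirus vs internal-only).
- **`ervkit.intersect`** — orientation-aware intersection of loci with gene
  models (GTF/BED), intergenic/intragenic classification with
  opposite-direction double counting, and summary tables.
- **`ervkit.assign`** — assignment of cDNA clones to their locus of origin
  among ~99%-identical paralogs by local-alignment identity, with a
  two-key score (integer match count, then percent identity) and a strict
  tie→ambiguous rule; diagnostic-site extraction across candidates.
- **`ervkit.splice`** — splice-junction inference by best split placement
  against a proviral model, donor classification (canonical / GT major /
  U12-type minor / non-canonical), type I/II classification via the 292-bp
  pol–env boundary segment, and in-silico amplicon size prediction.
- **`ervkit.quant`** — ΔCt fold-change arithmetic, housekeeping
  normalization, and R-region copy correction giving the solo-LTR
  transcript excess.
- **`ervkit.synth`** — seeded synthetic-data generator: toy genome with
  planted proviruses/solo LTRs (target-site duplications, type I
  deletions, breakage-style fragmentation), gene models, strand-specific
  unspliced/spliced transcripts, in-silico PCR, clone sampling, and Ct
  simulation — all with a full truth table.
- **`ervkit.cli`** — `ervkit` command-line tool and the end-to-end
  recovery harness.

## CLI

```sh
ervkit catalog rmsk.tsv --dialect ucsc_rmsk_tsv --window 200 --out-dir catalog_out
ervkit intersect genes.gtf loci.bed --out-dir intersect_out
ervkit assign loci.fa clones.fa --min-identity 99 --out assignments.tsv
ervkit splice model.fa landmarks.json cdnas.fa --out junctions.tsv
ervkit qpcr ct.tsv --reference-amplicon q-int --target-amplicon q-ltr --out fold.tsv
ervkit simulate --seed 42 --out-dir sim_out
ervkit end-to-end --seed 42 --out report.json
```

`simulate` writes a genome FASTA, an rmsk-dialect fragment table, a GTF,
locus/transcript/clone FASTAs, a Ct TSV and a `truth.json` ground-truth
table. `end-to-end` runs simulate → assign → splice → quant and reports
truth recovery (mis-assignment counts, recovered splice offsets, ΔCt).

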