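# clipflow

An iCLIP crosslink-site analysis pipeline for small (prokaryote-scale)
genomes, built as a tested, reusable package:

- **preprocess** — composite 9-nt barcode handling (3 random + 4
  experimental + 2 random), first-base trim, two-step quality filtering,
  PCR-duplicate collapsing on the full read (random barcode included),
  3' adapter clipping (`TGAGATCGGA`, partial terminal matches ≥ 5 nt) and
  exact-match demultiplexing.
- **map** — internal unique-best ungapped seed-and-extend mapper; reads
  whose best score ties at two or more locations are *ambiguous* and
  excluded (the multimapper/MAPQ filter); stranded bedGraph coverage.
- **circdetect** — circular-RNA junction detection in unmapped reads via a
  two-pass permuted-fragment search (primary fragment ≥ 20 nt, secondary
  fragment ≥ 12 nt in the unaligned flank, same strand, ≤ 4000 nt apart,
  single-positional), with candidate filtering (≥ 10 reads in ≥ 3 eligible
  libraries).
- **taildetect** — non-templated 3' attachments: perfectly matching 5'
  anchor at a unique location, maximal templated extension, minimal
  non-templated suffix; per-position and overall base composition
  profiles (tails analyzed up to 40 nt).
- **profile** — crosslink sites from cDNA truncation (the crosslinked
  base is one nt 5' of the read start), per-biotype/orientation decile
  metagenes, artificial operon units, ±100-nt boundary profiles around
  gene starts/ends, and ±10-nt motif-window extraction.
- **content / enrich / igr-polya** — per-CDS A/AG content and longest
  poly(A) runs, TPM normalization, per-position iCLIP/RNA-Seq coverage
  ratios (type-7 quartiles), 2-fold peak-enrichment calls (including the
  zero-RNA-Seq rule), and ranked intergenic poly(A) runs.
- **simulate** — a synthetic-data generator that plants circles, A-rich
  tails (default 73% A), crosslink intensity profiles, PCR duplicates and
  per-gene RNA-Seq abundances with fully known, per-read ground truth;
  every stage is tested against it.

## CLI

Everything is reachable through one entry point:

```sh
clipflow simulate   --seed 3 --out-dir sim
clipflow preprocess --fastq sim/iclip_raw.fastq --barcodes sim/barcodes.tsv --out-dir pre
clipflow map        --genome sim/genome.fa --fastq pre/target_1.fastq --out-prefix map/target_1
clipflow circdetect --genome sim/genome.fa --unmapped target_1=map/target_1.unmapped.fastq ... --out-prefix circ
clipflow taildetect --genome sim/genome.fa --unmapped map/target_1.unmapped.fastq \
                    --exclude-junctions circ.junction_reads.tsv --out-prefix tails
clipflow profile    --genome sim/genome.fa --bed map/target_1.bed --gff sim/annotation.gff3 \
                    --operons sim/operons.tsv --out-dir profile
clipflow content    --genome genome.fna --gff annotation.gff --out content.tsv
clipflow enrich     --genome sim/genome.fa --iclip s1=a.bedgraph --rnaseq r.bedgraph \
                    --loci loci.bed --out enrich.tsv
clipflow igr-polya  --genome genome.fna --gff annotation.gff --out igr.tsv
```

All internal coordinates are 0-based half-open on the plus strand;
conversions to GFF3/bedGraph conventions happen only in `io_formats`.

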