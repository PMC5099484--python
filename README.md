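# mitokit

Comparative plant mitochondrial genome analysis as a reusable, tested
pipeline: organelle genome assembly from contig graphs, repeat landscapes
(SSR / tandem / dispersed DR+IR), conserved gene clusters, organellar DNA
transfer and synteny, conservation-scored C→U RNA-editing prediction,
NG86 Ka/Ks, and neighbor-joining phylogenies — all exercisable on synthetic
genomes with planted, machine-readable truth.

## Package layout

| module | purpose |
|---|---|
| `mitokit.seqio` | FASTA/GenBank/GFF3/BED/TSV/GFA I/O, `GenomeRecord`/`Feature`/`ContigGraph` data model. Internal coordinates are 0-based half-open everywhere; format conventions are converted at the boundary only. |
| `mitokit.simulate` | Synthetic genomes with planted genes, SSRs, tandem and dispersed repeats; nuclear chromosomes with transferred blocks; sheared contig graphs with repeat-depth multiplicities; CDS sets with planted C→U edits and reference protein panels. Deterministic per seed. |
| `mitokit.align` | Seeded, gapped local alignment (exact word seeding, windowed optimal extension, ungapped X-drop fast path for long single-diagonal repeats), Karlin–Altschul E-values, identity/coverage/E-value hit filtering. |
| `mitokit.repeats` | SSR scanner (MISA-style thresholds 8,4,4,3,3,3 for unit lengths 1–6), lag-autocorrelation tandem-repeat scanner (unit ≥ 7 bp), dispersed repeat family builder with DR/IR/DR-IR typing, genomic-context labelling. |
| `mitokit.stats` | Composition report, start/stop-codon survey (ACG-start / CGA-stop / unknown flags), cis/trans intron census, grouped gene inventory. |
| `mitokit.clusters` | Conserved gene-cluster detection across annotated genomes; signed junction intervals. |
| `mitokit.transfer` | cp→mt and mt→nucleus gene/tRNA transfer detection (identity ≥ 80 %, E ≤ 1e-10, coverage ≥ 50 %; tRNA copies at > 90 %), syntenic block chaining (≥ 10 kb, ≥ 99.5 %), coding-SNP ledger. |
| `mitokit.editing` | C→U RNA-editing prediction by protein-conservation support with cutoff 0.6; per-codon joint edit enumeration capped at 3. |
| `mitokit.evolution` | NG86 Ka/Ks with Jukes–Cantor correction, concatenation with complete deletion, JC distances, Saitou–Nei NJ, bootstrap support, outgroup rooting. |
| `mitokit.assembly` | Depth-window filtering ([15, 50] default with reference-confirmed graph-essential rescue), reference selection, edge pruning, circular path walking with repeat-contig reuse, read-based gap filling and validation. |
| `mitokit.pipeline` / `mitokit.cli` | Orchestration, fixtures, and the `mitokit` command-line interface. |

## CLI

```bash
mitokit simulate --seed 1 --out-dir simdata          # synthetic bundle + truth
mitokit ssr genome.fasta                             # SSRs (TSV to stdout)
mitokit tandem genome.fasta
mitokit repeats genome.fasta                         # dispersed families
mitokit stats genome.gb                              # composition/codons/introns
mitokit clusters genomeA.gb genomeB.gb
mitokit transfer genes.fasta target.fasta --transfer-class "mt->nuc gene"
mitokit synteny mt.fasta chr1.fasta
mitokit editing cds.fasta panel.fasta --cutoff 0.6
mitokit kaks aligned_pair.fasta
mitokit nj alignment.fasta --bootstrap 1000 --outgroup M_polymorpha
mitokit assemble graph.gfa --depth-tsv depth.tsv --depth-window 15 50
```

Alignment TSV output is BLAST-outfmt-6-like:
`qstart qend sstart send strand length identity score evalue`
(coordinates 0-based half-open; `strand -` means the subject interval is on
the reverse strand).

## Conventions and caveats

- Junction intervals between clustered genes use one signed formula for
  both gap and overlap cases: `start2 − end1 − 1` on 1-based inclusive
  coordinates (equivalently `start2 − end1` half-open). Published tables
  that use `start2 − end1` for overlaps will print overlaps one base
  smaller in magnitude than this tool (−73 here vs −72 there).
- The SSR scanner reports each simple SSR separately (no compound-SSR
  merging); compound merging is version-dependent in MISA and is the main
  source of possible count divergence against published totals.
- Gap scoring in `align`: a gap of length k costs `Q + k·R` (defaults
  Q=R=3). E-value constants (λ solved from the scoring scheme, K=0.711)
  are exposed on `AlignParams`.
- Maximum-likelihood tree building is out of scope; the NJ companion
  analysis is the implemented path.
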