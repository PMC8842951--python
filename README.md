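# gametephase

Reconstruction of chromosome-scale parental haplotypes from single haploid
gamete cells, and trio-free partitioning of the cells' reads into two
parental pools for downstream diploid assembly.

Sequencing a few dozen gamete cells of one individual gives direct access
to phase: each cell is a single recombinant haplotype. This package
implements the computational core of that idea as a tested library + CLI:

- **`simulate`** (`gametephase.simulate`) — synthetic diploid genomes,
  meiosis with Poisson crossovers, genotype observations with
  amplification-bias dropout/error, and error-free reads — all with a full
  truth record, so every downstream stage is verifiable at desk scale.
- **`snp_qc`** — SNP filtering (biallelic, QUAL ≥ 20, pooled allele
  fraction in [0.3, 0.7], ≥ 5 bp from InDels), the cells × loci genotype
  matrix (depth < 5 and heterozygous calls demoted to missing), and cell
  exclusion (het rate > 5%, missing rate outside [30%, 70%]).
- **`phasing`** — majority-vote chaining of adjacent-SNP linkage across
  cells into two complementary consensus haplotypes, with phase-set breaks
  at ties and an exhaustive max-agreement oracle for testing.
- **`blocks`** — per-cell haplotype blocks and crossover intervals from a
  two-state HMM (per-SNP error rate ε, distance-scaled transitions)
  decoded by Viterbi.
- **`partition`** — reads assigned to a parental pool only when fully
  contained in one of their own cell's blocks, then two-pass k-mer-depth
  normalization of the merged pools (keep probability
  `min(1, target/median_kmer_depth)`).
- **`evaluation`** — hapmer (haplotype-specific k-mer) PPV of pools and
  contigs, switch error / Hamming accuracy of consensus haplotypes, and
  crossover precision/recall against simulation truth.
- **`cli_io` / `pipeline`** — format adapters (VCF, FASTA/FASTQ, BED-like
  TSV; gzip transparent) and the end-to-end driver with a JSON run report.

Coordinates are 0-based half-open internally and 1-based only in VCF.

## CLI

```sh
# one-command synthetic end-to-end run (writes every stage output + report)
gametephase run --simulate --seed 7 --outdir out/

# individual stages compose on files:
gametephase simulate --config cfg.json --outdir sim/ --fastq
gametephase filter-snps cells/*.vcf --out panel.vcf
gametephase qc-cells --panel panel.vcf --cell-vcf c1.vcf --cell-vcf c2.vcf \
    --out-prefix qc
gametephase phase --matrix qc.matrix.tsv --out hap
gametephase call-blocks --matrix qc.matrix.tsv --haplotypes hap.tsv \
    --chrom-length chr1=1000000 --out-prefix calls
gametephase partition --placements placements.tsv --blocks calls.blocks.tsv \
    --out-prefix pools
gametephase normalize pool_A.fastq --k 31 --target-depth 40 --seed 1 \
    --out pool_A.norm.fastq
gametephase evaluate --hap1 hapA.fasta --hap2 hapB.fasta \
    --pool pool_A.fastq --pool pool_B.fastq --out scores.json
```

Config files are JSON or flat `key=value`; unknown keys are rejected and
every effective parameter is echoed into the run report.

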