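# scdnasim

Synthetic single-cell DNA sequencing (scDNA-seq) data with complete ground
truth, for developing and benchmarking single-cell variant and CNV callers.

Benchmarking callers on real scDNA-seq is hard: the truth is unknown, and
public datasets are small. `scdnasim` generates, from one parameter
configuration, a whole batch of single cells with

- **per-cell variant ground truth**: SNPs (drawn from a SNP database, with a
  batch-shared core), de novo SNVs, and 4–10 bp indels, all with HET/HOM
  genotypes;
- **per-cell mutated diploid genomes** (two haplotype FASTAs per cell);
- **per-cell FASTQ reads** (SE or PE) whose depth tracks copy number;
- **CNV ground truth**: a cells × bins integer copy-number matrix in clean
  and noisy forms, subclone cell labels, segment breakpoints (TSV) and
  segments (BED).

A bundled synthetic-reference and synthetic-dbSNP generator makes the whole
pipeline runnable with no downloads.

## The model

**Point variants.** Each cell carries `snp_no` SNPs from the database; a
fraction `shared_snp_frac` (default 0.80) of the sites form a core set
sampled once and present — with identical genotypes — in every cell of the
batch, while the remaining private sites are disjoint across cells, so the
shared fraction is exact. SNVs are uniform random non-N reference sites,
private to each cell; indels are insertions/deletions of length uniform on
{4,…,10}, placed with a 10 bp exclusion buffer so every variant round-trips
unambiguously. Each variant is heterozygous with probability `het_rate`
(default 0.5) and is applied to one or both haplotypes accordingly.

**Copy number.** Each contig is tiled with `bin_len` bins (default 500 kb)
and cut into `seg_no` segments by `seg_no − 1` uniformly drawn bin
boundaries. Cells are `normal` (CN = 2 everywhere; exactly
`round(normal_frac · cell_no)` of them) or belong to one of `cluster_no`
tumor subclones; a clone assigns each segment CN = 2 with probability
`p_neutral`, otherwise a copy number uniform on {0,1} ∪ {3,…,max_cn}.
Noise perturbs each matrix entry independently by ±1 with probability
`noise_rate` (clipped to [0, max_cn]).

**Reads.** Per bin with copy number *c*, the number of sequenced templates
is Poisson with mean

    λ = coverage · bin_width / bases_per_template · c / 2,

so a CN = 2 region is covered at `coverage`× and depth is exactly linear in
copy number — the signal CNV callers segment on. Substitution errors occur
per base with probability `error_rate`; qualities are a constant Phred
score. Read names carry truth tags
`cell|haplotype|contig|start|serial` (PE mates add `/1`/`/2`), where
`start` is the 1-based position of the read (for PE, of the fragment) on
the named haplotype, so every read can be traced to its origin.

Everything is driven by one global seed through named, per-cell random
streams: identical configurations reproduce byte-identical outputs, and
adding cells never changes the draws of existing cells.

## Worked example

Generate a 2 Mb synthetic reference plus a 5000-record SNP database, then a
10-cell SNP dataset and a 100-cell CNV dataset:

```bash
scdnasim fixture --out-dir fixture --contig-len 2000000 --dbsnp-records 5000 --seed 7
scdnasim snp --ref fixture/reference.fa --dbsnp fixture/dbsnp.tsv \
    --out-dir snp_run --cells 10 --snp-no 1000 --coverage 1 --seed 7
scdnasim verify --run-dir snp_run
```

`verify` re-derives every ground-truth record from the written profiles and
haplotype FASTAs and prints:

```
class	cells	average_generating_accuracy
snp	10	100.00%
```

i.e. all 10 × 1000 simulated SNPs are verifiably present in the generated
genomes (the generating-accuracy; the command exits non-zero if any class
averages below 100%).

```bash
scdnasim cnv --ref fixture/reference.fa --out-dir cnv_run --cells 100 \
    --cluster-no 4 --normal-frac 0.2 --seg-no 7 --bin-len 100000 \
    --noise-rate 0.1 --coverage 0.1 --seed 7
```

This writes `cnv_run/cnv/` with the clean and noisy 100 × 20 CNV matrices,
`clusters.csv`, `breakpoints.tsv` (six breakpoints for seven segments —
always `seg_no − 1`) and `segments.bed`:

```
$ head -4 cnv_run/cnv/breakpoints.tsv
chrom	pos
sim1	400000
sim1	800000
sim1	1400000

$ cut -d, -f2 cnv_run/cnv/clusters.csv | tail -n +2 | sort | uniq -c
     21 clone1
     24 clone2
     19 clone3
     16 clone4
     20 normal
```

Exactly 20 of 100 cells are normal (`normal_frac 0.2`) and the four tumor
subclones are all non-empty; per-cell FASTQs in `cnv_run/fastq/` have
per-bin depth proportional to the noisy matrix row of that cell. Every run
directory also contains `manifest.json` (parameter snapshot plus SHA-256 of
every output file; byte-identical across reruns with the same seed) and
`run.log`.

The same pipeline is available as a library (`scdnasim.simulate_snp_profiles`,
`scdnasim.build_cell_genome`, `scdnasim.simulate_cell_reads`, …); see the
module docstrings and `docs/methods.md`.

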