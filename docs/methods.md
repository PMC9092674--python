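# Methods

`scdnasim` simulates single-cell DNA sequencing batches with complete
ground truth. This note records the generative model, the parameters that
matter, the numerical choices, and what the synthetic setting does and does
not establish about real data.

## Generative model

A batch is defined by one immutable `SimulationParams` object. Every source
of randomness derives from the single global `seed` through named streams
(`numpy.random.SeedSequence` spawn keys on `(seed, stream-name, cell-index)`),
so the pipeline is reproducible byte-for-byte and enlarging a batch never
reshuffles the draws of cells that already exist.

### SNPs

SNPs are drawn from a SNP database (the bundled 5-column TSV dialect:
chrom, 1-based pos, rsid, ref, alt). With `n_shared = round(shared_snp_frac
· snp_no)` (rounding half away from zero), one permutation of the database
is drawn per batch; the first `n_shared` records form the shared core
present in every cell, and cell *c* takes the next disjoint slice of
`snp_no − n_shared` records as private sites. Sharing is therefore an exact
batch property, not an expectation: every pair of cells shares precisely
the core set. Shared genotypes are drawn once (so shared sites look
identical across cells); private genotypes come from per-cell streams.
Whether shared sites should also share genotype is a modelling choice —
fixing them at the batch level makes the shared block of any profile
heatmap strictly constant, which is the cleanest benchmarking target.

### SNVs and indels

SNVs are `snv_no` distinct uniform non-N reference positions per cell,
sampled independently across cells (no sharing rule); the alternative base
is uniform over the three non-reference bases. Indels are `indel_no` events
per cell: insertion or deletion with probability 1/2, length uniform on
{4,…,10}, inserted bases i.i.d. uniform ACGT. Indel anchors are placed by
rejection sampling so that the event span padded by 10 bp on each side (the
maximum indel length) avoids every other variant in the cell; sampling
aborts with an error after 200 attempts per requested indel. The buffer is
what makes the round-trip verification below exact — no two edits can
interact. Substitution sites themselves are only required to be distinct:
two substitutions commute regardless of spacing, and a tiny genome must
remain exhaustively mutable.

Deletion semantics: `pos` is the **first deleted base** (a length-5
deletion removes `pos..pos+4`). Insertions place their sequence immediately
**after** the anchor base `pos`. These profiles are deliberately not VCF
(VCF anchors before the event); the BED output alone is 0-based half-open.

### Diploid genome construction

Each cell's genome is two explicit haplotypes. HOM variants are applied to
both; each HET variant lands on haplotype A or B by a fair coin (one draw
per variant, in genome order). Sequences are built in a single ascending
pass per haplotype; a `CoordMap` per (haplotype, contig) translates
reference to haplotype coordinates (undefined inside deletions). The length
identity `len(hap) = ref_len + Σ ins − Σ del` holds by construction and is
asserted in tests.

Copy number is **not** materialised in the FASTA: duplicating or dropping
segments would shift every downstream coordinate and make point-variant
verification ambiguous. Depth is instead realised at read-sampling time,
which reproduces the depth-steps-at-breakpoints signal callers consume
while keeping coordinates stable.

### Generating-accuracy

`generating_accuracy` is the round-trip metric: the fraction of
ground-truth variants verifiably present in the haplotype sequences. It
works from sequences alone — phase is re-inferred, never read back from the
builder — so it is an independent check of the construction path. Per
contig, variants are scanned in ascending order while per-haplotype indel
offsets accumulate. A HOM variant verifies iff both haplotypes carry the
expected content at the mapped position; a HET variant iff exactly one
haplotype carries it and the other shows the reference continuation.

Indel checks compare windows extended by 10 reference bases past the event
— exactly the placement buffer, so the extension is guaranteed unedited.
The extension is what disambiguates tandem repeats: deleting one copy of a
duplicated k-mer leaves a sequence locally identical to the unedited one
over any window of only k bases, and without the extension the HET carrier
would be unidentifiable (and the running offsets would then corrupt every
downstream check). With it, ambiguity would require a repeat run longer
than the event plus 10 bp, which the i.i.d. fixture essentially never
produces. When neither exact interpretation fits (possible only on
corrupted input), the carrier used for offset bookkeeping is chosen by
Hamming distance, ties to haplotype A; in the residual degenerate case
where both interpretations fit exactly, the variant is counted as verified,
since the sequences are genuinely indistinguishable from correct. An empty
profile scores 1.0.

### Copy-number matrix

Bins tile each contig (`ceil(len / bin_len)` bins; the last bin may be
short). Segments are per-contig: `seg_no − 1` interior bin boundaries drawn
uniformly without replacement, so a breakpoint coordinate — defined as the
inclusive end of the upstream segment's last bin — is always a multiple of
`bin_len`, and the contig end (the short bin's end) is never a breakpoint.
`SegmentSet` also accepts an explicit boundary list, for benchmarks that
need fixed breakpoints rather than seeded draws.

The first `round(normal_frac · cell_no)` cell indices are normal — a stable
labelling that keeps cell identity comparable across configurations — and
each tumor clone receives one cell before the remainder are assigned
uniformly, so no clone is empty. Clone profiles draw CN = 2 per segment
with probability `p_neutral`, else uniform on {0,1} ∪ {3,…,max_cn};
all-neutral profiles and duplicates are redrawn (1000 attempts, then an
error — e.g. one segment cannot support nine distinct clones). Noise
perturbs each entry independently by ±1 with probability `noise_rate`; a
step that would leave `[0, max_cn]` flips direction, so a perturbed entry
always differs from the clean one and stays a valid integer copy number.
With `cluster_no = 0` every cell is normal regardless of `normal_frac`.

### Read sampling

Per bin at copy number *c* the template count is Poisson with mean
`coverage · bin_width / bases_per_template · c/2`, where
`bases_per_template` is `read_len` (SE) or `2 · read_len` (PE). Templates
choose haplotype A/B with probability 1/2 independent of copy number
(allelic imbalance is out of scope), and start uniformly within the
haplotype-mapped bin extent so that the whole template fits; templates
never straddle bin boundaries, which keeps per-bin counts exactly Poisson
and depth steps at breakpoints sharp. PE fragment lengths are
Normal(`insert_mean`, `insert_sd`) rounded, truncated to
`[2 · read_len, extent]`; mate 2 is the reverse complement of the fragment
end. Substitution errors are i.i.d. per base with probability `error_rate`,
uniform over the three other bases; qualities are the constant
`base_quality` (Phred+33). A bin whose mapped extent is shorter than one
template is skipped with a logged warning.

This sampler intentionally models amplification as uniform: no GC bias, no
allele dropout, no MALBAC/DOP-PCR protocol artifacts, no chimeras, no
duplicate structure. It is the cleanest possible depth-∝-CN signal, which
is the property the CNV ground truth is meant to exercise; protocol-level
realism is a separate concern and out of scope.

## Parameters

| name | default | unit | role |
|---|---|---|---|
| `cell_no` | 10 | cells | batch size |
| `snp_no` / `snv_no` / `indel_no` | 1000 / 100 / 100 | per cell | variant counts |
| `shared_snp_frac` | 0.80 | fraction | batch-shared SNP core (exact) |
| `het_rate` | 0.5 | prob. | P(variant is HET); 0/1 force HOM/HET-only batches |
| `cluster_no` | 2 | clones | tumor subclones (0 = all normal) |
| `seg_no` | 5 | per chrom | CNV segments; breakpoints = `seg_no − 1` |
| `normal_frac` | 0.2 | fraction | normal cells = round(·cell_no), half away from zero |
| `p_neutral` | 0.5 | prob. | per-segment chance a clone stays CN = 2 |
| `noise_rate` | 0.1 | fraction | perturbed matrix entries |
| `bin_len` | 500000 | bp | CNV bin width |
| `max_cn` | 8 | copies | copy-number ceiling |
| `coverage` | 1.0 | × | depth of a CN = 2 region |
| `read_len` | 100 | bp | read length |
| `layout` | SE | — | SE or PE |
| `insert_mean` / `insert_sd` | 300 / 30 | bp | PE fragment model |
| `error_rate` | 0.002 | per base | substitution errors |
| `base_quality` | 30 | Phred | constant quality score |
| `seed` | 0 | — | drives every stream |

Defaults for the read model (coverage, read length, error rate, insert
geometry) are this package's own declared values, chosen as typical Illumina
short-read settings. The feasibility invariant
`round(normal_frac · cell_no) + cluster_no ≤ cell_no` is enforced whenever
`cluster_no > 0`; the point-variant CLI commands default `cluster_no` to 0
because subclone structure is meaningful only to the CNV simulator.

## Synthetic fixtures and what the tests show

`generate_synthetic_reference` emits i.i.d. bases at a chosen GC content
(no N runs, no repeats, no chromosome-scale structure);
`generate_synthetic_dbsnp` samples uniform distinct sites from it. These
fixtures make every pipeline property testable hermetically, and all
sequence-level guarantees (round trips, coordinate maps, Poisson counts,
error rates) are composition-independent, so they transfer to real
references. What the passing tests do **not** show is robustness to
real-genome structure: repeats and low-complexity regions would make
alignment-based downstream evaluation harder (reads here are traced by
truth tags, not by alignment), N gaps shrink usable bin extents, and real
dbSNP density is non-uniform. Users benchmarking callers should run the
same pipeline on a real reference FASTA.

## Problem sizes

The test suite and acceptance script run at desk scale by choice: a 2 Mb
single-contig reference for sequence-level checks ( 30 mutated genomes are
built and verified in under a second), 10 000 pooled indels for the length
law, a 100 × 103 matrix (a chr22-like tiling) for noise recovery, and
coverage 5 with 100 kb bins for the depth-recovery property. All statistical
assertions use 3σ bands of the exact sampling distribution (binomial,
multinomial, Poisson, or delta-method for the depth ratio) so they are
seed-stable; the indel length law uses a χ² goodness-of-fit at α = 0.01.

## Known limitations

- No evolutionary model: subclones are unrelated profiles, not a phylogeny,
  and point mutations carry no lineage structure.
- No allele-specific copy number, no whole-genome doubling, no SVs beyond
  short indels and the CNV depth model.
- Uniform amplification only (see read sampling above); FASTQ only, no BAM.
- One parameter set applies genome-wide (no per-chromosome overrides).
- `verify` infers HET phase from sequence; in pathological repeat contexts
  an indel's placement can be genuinely ambiguous (counted as verified when
  both interpretations match exactly).
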