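# hlavb — HLA diplotype typing by variational Bayesian read assignment

HLA genes (chromosome 6p21.3) are the most polymorphic region of the
human genome: thousands of registered allele sequences differ from one
another by as little as a single base. Short sequencing reads from an
HLA locus therefore align acceptably to many alleles at once, and naive
best-hit counting cannot decide which two alleles an individual actually
carries. `hlavb` resolves this multi-mapping ambiguity probabilistically
and calls a diplotype (the allele pair) per locus at up to full 8-digit
nomenclature resolution (e.g. `A*01:01:01:01`), for whole-genome or
targeted short-read data, without any population allele-frequency prior.

## Model

Each read pair *Rₙ* originates from exactly one allele *t* of the panel
(indicator *Zₙₜ*), with relative abundance **θ** and a symmetric
Dirichlet prior

P(**θ**) = (1/C) ∏ₜ θₜ^(α₀−1),  ∑ₜ θₜ = 1,

while gapped alignments give fixed likelihoods P(*Rₙ*|*t*) under a
per-base error model (substitutions, insertions, deletions,
soft-clipping). Mean-field variational Bayes with
q(**θ**) = Dirichlet(**α̂**) alternates

- **VBE**: resp(n,t) ∝ P(*Rₙ*|*t*)·exp(ψ(α̂ₜ) − ψ(∑α̂)), r̂ₜ = ∑ₙ resp(n,t)
- **VBM**: α̂ₜ = α₀ + r̂ₜ, E[θₜ] = α̂ₜ/∑α̂

until the expected read counts r̂ stop moving; α₀ is chosen from a small
grid by maximising the evidence lower bound (ELBO). Expected counts
become per-allele depths of coverage, depth(t) = r̂ₜ·(bases per
pair)/length(t), and each locus is called by threshold rules: alleles
below 20% of the sample's mean coverage are ignored; a lone passing
allele at ≥ 2× the threshold is homozygous; among several passing
alleles the top one is homozygous only if it exceeds twice the
runner-up, otherwise the top two form the diplotype.

The core estimator `DirichletMultinomialVB` follows the scikit-learn
convention (`fit` on a sparse read × allele log-likelihood matrix;
fitted attributes `theta_`, `r_`, `responsibilities_`, `elbo_`, ...).
A built-in k-mer seed-and-extend aligner produces the multi-hit
alignments at panel scale, or a report-all SAM/BAM from an external
aligner (e.g. `bwa mem -a`) can be ingested directly. A simulator
generates benchmark cohorts: diplotypes drawn uniformly from the panel,
1 SNP/kb of individual variation, 100 bp paired-end reads with
N(300, 40²) fragment lengths and 0.1% substitution/deletion/insertion
errors — plus fully synthetic hierarchical allele panels so nothing
needs downloading.

## Worked example

Simulate one individual at 30× on a synthetic panel, type it, and score
the calls:

```bash
hlavb simulate --n-individuals 1 --coverage 30 --seed 7 --out-dir demo
hlavb type --panel demo/panel.fasta \
    --fastq1 demo/ind0_1.fastq --fastq2 demo/ind0_2.fastq \
    --mean-depth 30 --individual ind0 --out-dir demo/typed
hlavb evaluate --calls demo/typed/calls.tsv --truth demo/truth.tsv \
    --out demo/eval.tsv
```

`demo/typed/calls.tsv` (excerpt):

```
individual  locus  allele1         allele2         zygosity      depth1   depth2   threshold
ind0        L1     L1*01:02:01:02  L1*03:01:01:02  heterozygous  31.2     28.2     6
ind0        L2     L2*01:02:01:01  L2*01:01:01:01  heterozygous  34.3552  27.8448  6
ind0        L5     L5*03:02:01:01  L5*03:01:01:01  heterozygous  31.9996  27.0004  6
```

Each row is one locus: the two called alleles, their zygosity, their
estimated depths of coverage (here ~30× split ~15× per haplotype copy,
doubled because both copies of a heterozygote pass), and the calling
threshold 6× = 20% of the 30× mean depth. The run log records that the
1,800 read pairs were assigned over 72 alleles with α₀ = 0.1 selected by
ELBO in 33 iterations. `demo/eval.tsv` then shows all 12 allele slots
(6 loci × 2) matching the simulated truth at every resolution:

```
resolution  locus  true_positives  total  accuracy
2           ALL    12              12     1
8           ALL    12              12     1
```

The same pipeline is available as library calls (`type_read_pairs`,
`type_sam`, `run_benchmark`) returning dataclasses and DataFrames.

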