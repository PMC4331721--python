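# Methods

## Problem setting

HLA allele reference sequences within a locus are highly homologous:
protein-level (4-digit) groups differ at tens of positions, while
full-resolution (8-digit) siblings may differ by one or two non-coding
bases. A 100 bp read therefore rarely identifies a single allele, and
the typing problem is to distribute read pairs over the panel so that
the two alleles the individual carries absorb the reads, while their
near-identical neighbours do not.

## Generative model and inference

Let T be the number of panel alleles and N the number of read pairs with
at least one alignment to the panel. Read pair n carries a latent
indicator Z_nt (1 iff it originated from allele t), the abundance vector
θ lies on the T-simplex, and

    P(θ) = (1/C) ∏_t θ_t^(α0−1),        P(R_n | Z_nt = 1) = P(R_n | t),

with P(R_n | t) fixed by the alignment stage (below). The posterior over
(Z, θ) is approximated by a mean-field product q(Z) q(θ) with
q(θ) = Dirichlet(α̂); coordinate ascent gives the familiar updates

    VBE:  resp(n,t) ∝ P(R_n|t) · exp(ψ(α̂_t) − ψ(∑_u α̂_u)),
          r̂_t = ∑_n resp(n,t)
    VBM:  α̂_t = α0 + r̂_t,   E[θ_t] = α̂_t / ∑_u α̂_u

where ψ is the digamma function. The ELBO

    E_q[log p(R,Z,θ)] − E_q[log q(Z,θ)]
      = ∑_{n,t} resp·[log P(R_n|t) + ψ(α̂_t) − ψ(∑α̂)]
        − ∑_{n,t} resp·log resp − KL(Dirichlet(α̂) ‖ Dirichlet(α0·1))

is evaluated after every VBE/VBM pair; both steps are coordinate ascent,
so it is non-decreasing (the test suite enforces ≥ −1e−8 per step).
Small α0 (< 1) favours sparse abundance vectors — the rich-get-richer
dynamics that concentrate shared reads onto the supported allele — and
α0 is selected from the grid {0.01, 0.1, 0.2, 0.5, 1.0} as the
maximiser of the final ELBO, ties going to the smaller value.

Numerical choices:

- responsibilities are computed in log space with per-read max
  subtraction; a NaN anywhere raises rather than propagates;
- initialisation splits each read equally over its hit alleles
  (deterministic, no seed);
- convergence: max_t |r̂_t change| < 0.01 reads (the quantity the
  stopping criterion names is the expected read count), capped at 1000
  iterations with a warning, not an exception;
- reads with no alignment to any panel allele are dropped before
  inference and counted in the run log. No explicit "off-panel noise"
  mixture component is modelled; dropping zero-hit reads plays that
  role. The matrix keeps one row per retained read pair.

The sklearn estimator shape (`DirichletMultinomialVB.fit`) was chosen
because the inference genuinely is a fit-shaped decomposition of a
sparse matrix; the surrounding pipeline (alignment, calling, simulation)
remains ordinary functions and a CLI.

## Read-given-allele likelihoods

The alignment stage supplies, for each mate and allele,
match/mismatch/indel/soft-clip counts; then

    log P(mate | t) = matches·log(1−ε_s) + mismatches·log(ε_s/3)
                    + opens·log(ε_g) + extends·log(ε_e)
                    + soft_clipped·log(1/4)

with defaults ε_s = 0.01, ε_g = 0.002, ε_e = 0.1; a gap run of length L
counts one open and L−1 extends. Mismatches spread uniformly over the
three wrong bases; soft clips are priced at the random-sequence rate so
clipping cannot inflate a likelihood. Base qualities are ignored (flat
ε_s): simulated data uses uniform error rates and SAM input may lack
qualities. For a read pair, log P(R_n|t) sums the two mates; a mate
with no hit on t contributes read_len·log(1/4), the likelihood of a
random sequence, so alleles supported by both mates dominate alleles
supported by one.

Alignments come from either source:

- **SAM/BAM ingestion** (pysam): primary and secondary records;
  mismatches = NM − inserted − deleted bases, falling back to =/X CIGAR
  operations, then to the MD tag; both absent is an error.
- **Built-in aligner**: exact k-mer seeding (default k = 25) over an
  index of all panel sequences, vote per (allele, diagonal), ungapped
  verification at the best diagonal, and an edlib infix alignment on a
  ±8 bp window when more than 5 ungapped mismatches suggest an indel.
  Hits score matches − 3·mismatches − 4·indel bases; all alleles within
  0.9× the read's best score are reported (capped at max_hits = 100).
  This is a panel-scale aligner for reads already near the HLA region,
  not a genome aligner; k = 25 keeps seeding specific between loci yet
  robust to ~0.2%/bp divergence (several seed positions per 100 bp
  read).

## Diplotype calling

depth(t) = r̂_t × bases_per_fragment / length(t), with
bases_per_fragment the sequenced bases per pair (200 for 2×100 bp;
inferred from observed read lengths when not given). The calling
threshold is 20% of the experiment's genome-wide mean depth, which is a
required input (e.g. 6× for a 30× genome); a fallback estimate from the
panel reads alone would conflate locus dropout with low coverage, so it
is not silently substituted. Per locus:

1. no allele ≥ threshold → no call;
2. exactly one ≥ threshold → homozygous if its depth ≥ 2× threshold,
   else a single heterozygous allele (reported with one empty slot);
3. two or more → sort by depth descending (exact ties broken by allele
   name for determinism); top depth strictly > 2× second → homozygous
   of the top, else heterozygous of the top two.

Inference always runs jointly over the full panel (one matrix, all
loci); only the calling step is per-locus, so cross-locus homology
competes for reads exactly as it does in the data.

Accuracy is the fraction of true alleles recovered: per individual and
locus, the ≤ 2 called alleles are matched to the 2 true alleles
(order-free, best pairing) under name agreement at the chosen digit
resolution; empty slots are misses. A name with fewer fields than the
resolution requests matches on the fields it has (so a 6-digit truth
can be fully credited at "8-digit" scoring); expression suffixes such
as `N` are compared verbatim. A heterozygous-single call can therefore
earn at most one of a homozygous truth's two slots — a deliberate,
conservative convention.

## Simulator

The benchmark generator emulates the evaluation protocol: per
individual, one diplotype per locus drawn uniformly with replacement
from the panel; each haplotype copy independently mutated at
1 SNP/kb (per-base Bernoulli(0.001) — a rate, not a fixed count, so
positions stay independent); read pairs at the configured mean coverage
(pairs = round(coverage × total haplotype length / (2 × read_len))),
fragment lengths from N(300, 40²) truncated to [read_len, haplotype
length], uniform starts, mate 2 reverse-complemented from the far end;
sequencing errors applied per base at 0.1% each for substitution,
deletion (drops the base, pulling sequence from downstream) and
insertion (adds a uniform base). Read names encode the source haplotype,
start and fragment length for diagnostics; FASTQ qualities are constant
"I". One root seed spawns independent child streams per individual, so
any individual is reproducible in isolation.

Not emulated: quality-score error profiles, PCR duplicates, off-target
genomic background reads, coverage bias, and structural variation
beyond SNPs. Passing benchmarks therefore demonstrate correct
multi-mapping resolution and calling under idealised error structure,
not robustness to real instrument artefacts or to reads leaking in from
unmodelled paralogous regions.

### Synthetic panels

To avoid external database downloads, `generate_synthetic_panel` builds
panels whose sequence distances respect the naming hierarchy. Defaults:
6 loci × 12 alleles of 1,000 bp, branching (3 serological groups × 2
proteins × 1 × 2 full-resolution siblings), divergence 0.02. Substitution
counts per level — 20 (2-digit), 5 (4-digit), 3 (6-digit), 1 (8-digit) at
the defaults — are drawn from disjoint position pools, so 2-digit groups
differ by ≥ 40 positions while 8-digit siblings differ by exactly 2, and
all sequences are distinct by construction. The 1 kb allele length is a
deliberate scale-down from ~3 kb genomic HLA alleles (it keeps the
benchmark cohorts fast on one CPU) while the 2-base sibling separation
is, if anything, harder than typical real 8-digit pairs; locus sequences
are independent, so cross-locus multi-mapping — present between real
paralogues and pseudogenes — only enters via a user-supplied real panel.
Benchmarks reported by `scripts/acceptance.py` use 20 individuals
(noiseless check) and 50 individuals (noisy protocol at 5× and 30×) on
this default panel.

## Known limitations

- The likelihood treats the two mates as independent given the allele
  and ignores fragment-length consistency and orientation of the pair.
- The depth threshold assumes the experiment's mean coverage is known;
  badly mis-stated coverage shifts calls toward no-call (too high) or
  spurious heterozygotes (too low).
- The built-in aligner's k-mer index is held in memory; for
  database-scale panels (10⁴ alleles) use an external report-all
  aligner and the SAM path instead.
- Very low coverage (< ~3×) leaves single-allele depths near the
  threshold, where the heterozygous-single and no-call branches absorb
  most of the loss of accuracy.
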