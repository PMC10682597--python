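# Methods

`cubkit` quantifies codon usage bias (CUB) in parasite coding sequences and
its co-adaptation to a host's codon usage. This note records the models
implemented, the conventions and numerical choices behind them, and what
the synthetic data used in the test suite does and does not establish.

## Sequence model and conventions

All statistics assume the standard nuclear genetic code (NCBI table 1).
Setting aside Met (ATG) and Trp (TGG), the 59 remaining sense codons
partition into 18 synonymous families: nine two-fold, one three-fold (Ile),
five four-fold (Val, Pro, Thr, Ala, Gly) and three six-fold (Leu, Ser,
Arg). Six-fold families are treated as single k=6 families everywhere —
never split 4+2 — so ENc, RSCU and every per-family statistic share one
convention. Stop codons are carried in count tables but never enter
synonymous-family statistics (a stop has no synonymous family).

Validation policy: sequences are upper-cased; a trailing 1–2 nt partial
codon is dropped with a warning; any non-ACGT character rejects the record
(rejection is a reported QC outcome, not an exception) — this keeps all
downstream count denominators exact rather than masking codons. In-frame
internal stops are kept but flagged. Length filtering is inclusive and
expressed in amino acids (codons); the workflow default bounds of
100–4000 aa suit typical viral proteomes.

## Composition diagnostics

- GC content: gc_k = fraction of G/C at codon position k; GC12 = (GC1+GC2)/2.
- PR2: x = G3/(G3+C3), y = A3/(A3+T3). With `fold4_only` (the default for
  plots) the tally is restricted to third positions of the five four-fold
  families, where the third base is free of protein-level constraint; the
  four-fold sub-boxes of six-fold families are excluded as the conservative
  reading of "four-fold degenerate site". (0.5, 0.5) is the parity origin.
- Neutrality regression: OLS of per-gene GC12 on GC3 (scipy `linregress`).
  Slope near 1 is consistent with mutation pressure acting on all positions,
  near 0 with selective constraint at positions 1–2. The plot annotates the
  slope equation, R, R² and the two-sided p-value of the slope t-statistic
  (both R and R² are shown because conventions differ across the
  literature). A constant GC3 vector leaves the slope undefined and is an
  error; n ≥ 3 is required.

## Gene-level indices

Let n_c be the count of codon c in a gene, n_a = Σ_{c∈a} n_c its amino-acid
total, f = n_c/n_a the gene's within-family frequencies and g the
reference's.

- **ENc (Wright)**: per amino acid with n_a ≥ 2, homozygosity
  F_a = (n_a Σf² − 1)/(n_a − 1); class averages F̄_k over amino acids of
  degeneracy k give ENc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, capped at 61.
  Amino acids with n_a < 2 are dropped from their class; an empty
  three-fold class is replaced by (F̄₂+F̄₄)/2; an empty (or zero-valued)
  two-, four- or six-fold class leaves plain ENc undefined for that gene.
- **ENc (modified)**: homozygosity from pseudocounted frequencies
  p̃_i = (n_i+1)/(n_a+k), every family contributing (absent families become
  uniform), same aggregation and cap. Defined for any non-empty gene; it
  approaches Wright's value from above as counts grow.
- **MILC**: Σ_a M_a / L − C with M_a = 2 Σ_c n_c ln(f_c/g_c),
  L = total family-codon count and C = Σ_a(k_a−1)/L − 0.5 over amino acids
  present in the gene. Note C < 0 for long genes, so the exact-identity
  gene scores −C, typically near 0.5 — the familiar scale of this index.
- **B (Karlin–Mrázek)**: Σ_a (n_a/L) Σ_c |f_c − g_c| ∈ [0, 2].
- **MCB (Urrutia–Hurst)**: B_a = Σ_c (f_c−g_c)²/g_c over families with
  n_a ≥ 2; gene value Σ_a B_a log₁₀(n_a) / Σ_a n_a ( ≥ 0, zero at identity).
- **CAI (Sharp–Li)**: reference weights w_c = n_c/max over family; gene CAI
  is the count-weighted geometric mean of w over family codons, in (0, 1].
- **FOP**: fraction of family codons that are the reference's family-most-
  frequent codon (ties: all tied codons optimal, logged).
- **MELP** = MILC(gene | organism background) / MILC(gene | host);
  **E** = B(gene | background) / B(gene | host). Values above 1 indicate
  host-reference-like (putatively highly expressed) usage. E of a gene
  identical to both usages is defined as 1; a zero host-side denominator
  with a nonzero numerator is NaN and flagged.
- **RSCU**: n_c/((1/k)Σ_family n); nonzero families sum to k, absent
  families report 0 for all members.

MILC, B and MCB run host-free against the organism's own pooled codon
counts (pooled rather than per-gene self-reference, so single genes carry
signal), or against the pooled host counts when a host is supplied. CAI,
MELP, FOP and E require the host and refuse to run without it.

**Pseudocount policy** (one rule everywhere): whenever any codon of a
family has a zero reference count, 1 is added to every codon of that family
in the reference, and the event is logged. Consequences worth knowing: the
"maximally deviant" B of exactly 2 is approached but not attained, and CAI
weights are strictly positive by construction.

## Host co-adaptation

- **SiD** = (1 − R)/2 with R the cosine between the organism-mean parasite
  RSCU vector and the host RSCU vector; range [0, 0.5]. Computed per
  organism by default (one summary point per parasite), per sequence behind
  a flag. Identical vectors return exactly 0 (the cosine is clamped at 1 to
  keep floating-point noise out of the bound).
- **RCDI** = Σ_c (CiF_a(c)/CiF_h(c)) n_c / N over family codons, where
  CiF are within-family relative frequencies in the gene and host
  respectively; 1 at host-matched usage, larger with deoptimization,
  invariant to gene duplication. Host frequencies come from the pooled host
  counts under the same pseudocount policy. The index is defined on
  frequencies only; no ENc input is involved.

## Dinucleotide representation tests

For each gene, observed overlapping dinucleotide counts (all three frames)
are compared to permutation nulls: base shuffle/resample, codon
shuffle/resample (frame-preserving) and synonymous-codon randomization
(protein-preserving). z = (obs − mean)/sd over the permutation replicates,
sd with the n−1 denominator; degenerate cells (sd = 0, e.g. homopolymers
under base shuffling) are NaN, never 0. The statistic is count-based.
Synonymous randomization without replacement permutes the gene's own codons
within each family (an exact conditional null); with replacement each codon
is drawn uniformly from its family. Defaults are 100 permutations without
replacement. Each record gets an RNG stream keyed by (seed, organism, id),
so outputs are independent of collection order and bit-reproducible.

## Multivariate analysis

PCA runs on the organism-mean RSCU matrix (parasites plus host; rows are
single points per organism) after dropping the excluded codons
(default ATG + stops + TGG). The matrix is centered but not scaled — RSCU
is already family-normalized, and scaling would overweight rare families; a
scale flag exists. Component signs are fixed by forcing the
largest-magnitude loading positive, making scores backend-independent.
Clustering operates on the first `rank` score dimensions: kmeans (10
restarts, seeded) or hierarchical clustering accepting the R linkage names
— "ward.D2" is Ward on Euclidean distances, "ward.D" Ward on squared
distances. Heatmap matrices optionally collapse to organism means; NaN
cells are excluded pairwise from distances and all-NaN rows dropped.

## Synthetic data generator

`cubkit.simulate` draws proteins (template or random over the 18 degenerate
amino acids) and encodes them codon-by-codon from per-family weight
profiles; `gc3_bias` builds a profile giving every G/C-ending codon weight
s and every A/T-ending codon 1−s. A JSON sidecar records the normalised
family frequencies and expected GC3 for recovery tests. Defaults — 30
sequences of 150–450 aa per organism — emulate the scale of a viral CDS
study (influenza- to coronavirus-sized proteins).

What the generator does *not* emulate: amino-acid composition bias linked
to protein function, position-dependent codon usage, dinucleotide
constraints beyond those induced by codon choice (e.g. CpG suppression
acting across codon boundaries), gene-expression covariates, and
phylogenetic correlation among sequences. Tests passing on this generator
therefore establish the correctness and calibration of the statistics, not
biological conclusions about real parasites.

## Problem sizes and determinism

Test-suite simulations use desk-scale inputs chosen as the package's own
study conditions: index fuzzing over 1,000 random count tables; permutation
calibration with 500 replicates of a 300-residue protein at 100
permutations; neutrality recovery with 200 genes per slope; the end-to-end
workflow on two 8-sequence organisms plus a 12-sequence host. All
randomness is seeded; the CLI's tables are byte-identical across runs with
the same configuration and seed (floats are written with %.10g, SVG ids
are salted deterministically).

## Known limitations

- Only the standard genetic code; no alternative translation tables.
- Non-ACGT records are rejected outright rather than codon-masked.
- Karlin's odds-ratio dinucleotide statistics, tAI, codon-pair bias and
  correspondence analysis are out of scope.
- The host-free reference for MILC/B/MCB is the organism's pooled usage; a
  gene is therefore never compared against itself alone.
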