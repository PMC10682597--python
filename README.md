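# cubkit

Codon usage bias (CUB) analysis for parasite coding sequences and their
co-adaptation to a host, aimed at molecular evolution studies of viruses
and other intracellular parasites. Given one multi-FASTA of coding
sequences per parasite and a single host reference set (ideally highly
expressed genes), `cubkit` computes:

- **composition diagnostics** — GC content by codon position, parity-rule-2
  (PR2) coordinates at (four-fold degenerate) third positions, and the
  neutrality regression of GC12 on GC3;
- **gene-level CUB indices** — the effective number of codons in Wright's
  form (ENc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, range 20–61) and a
  pseudocounted modified form, MILC, Karlin–Mrázek B, MCB, CAI
  (geometric mean of Sharp–Li weights w_c = n_c/max_family), MELP, FOP and
  the expression measure E;
- **codon-level statistics** — RSCU profiles, the parasite–host similarity
  index SiD = (1 − cos(RSCU_p, RSCU_h))/2 ∈ [0, 0.5], and the relative
  codon deoptimization index RCDI (1 = host-matched usage);
- **dinucleotide representation** — permutation z-scores for the 16
  dinucleotides under base-, codon- and synonymous-codon-randomization
  nulls;
- **multivariate views** — PCA of organism-mean RSCU profiles, clustering
  on the scores, clustered heatmaps, and the standard diagnostic plots
  (QC/GC boxplots, ENc–GC3 with the expected curve
  ENc\*(s) = 2 + s + 29/(s² + (1−s)²), PR2, neutrality).

A deterministic synthetic CDS generator (`cubkit.simulate`) supports
testing and method calibration without any downloads.

See `docs/methods.md` for formulas, conventions (family structure,
pseudocount policy, null models) and limitations.

## Worked example

```python
from cubkit.simulate import GeneratorSpec, generate_collection, generate_host
from cubkit.cub_indices import enc_table, cai_table
from cubkit.host_adapt import sid_table, rcdi_table

virus, _ = generate_collection(GeneratorSpec(
    name="virusA", n_sequences=30, gc3_bias=0.3, seed=1))
host, _ = generate_host(GeneratorSpec(
    name="host", n_sequences=50, gc3_bias=0.6, seed=2))

enc = enc_table([virus], modified=True)
cai = cai_table([virus], host)
print(enc.head(3).to_string(index=False))
print("mean ENc:", round(enc["value"].mean(), 2))
print("mean CAI:", round(cai["value"].mean(), 3))
print(sid_table([virus], host).to_string(index=False))
print("mean RCDI:", round(rcdi_table([virus], host)["rcdi"].mean(), 3))
```

prints

```
organism          id     value reference_used
  virusA virusA_0000 51.247720           none
  virusA virusA_0001 50.267353           none
  virusA virusA_0002 51.985440           none
mean ENc: 51.26
mean CAI: 0.74
organism     sid
  virusA 0.08059
mean RCDI: 1.517
```

The simulated virus prefers A/T-ending codons (GC3 bias 0.3) while the
host prefers G/C-ending ones (0.6): the mean modified ENc of ~51 shows
moderate within-gene bias, the CAI of 0.74 and RCDI of 1.52 quantify how
far the virus sits from the host's preferred codons (CAI = 1 and RCDI = 1
would be fully host-optimized usage), and the organism-level SiD of 0.08
summarises the same divergence on the RSCU profiles.

## Command line

```sh
cubkit all -p fluA.fasta -p fluB.fasta --host human.fasta \
    --min-aa 100 --max-aa 4000 --permutations 100 --seed 42 -o results/
```

writes the full artifact tree: `qc/` (validation report, lengths), `gc/`
(GC metrics, PR2 points, neutrality fits), `dinuc/` (z-score tables per
null model), `indices/` (nine index tables), `rscu/`, `adapt/` (SiD,
RCDI), `pca/` and `plots/` (PNG + SVG + the tidy table behind each
figure), plus the resolved configuration and a log. Subcommands (`qc`,
`gc`, `dinuc`, `indices`, `rscu`, `adapt`, `pca`, `plots`) run branches
individually and reuse tables already present in the output directory.
Indices that need the reference set (CAI, MELP, E, FOP — and SiD/RCDI in
`adapt`) refuse to run without `--host` and say so. Identical
configuration and seed give byte-identical tables.

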