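# cnvassoc

Case-control association testing for **copy-number variation (CNV)** from
SNP-array intensities.

Genome-wide association studies genotype hundreds of thousands of SNPs in
thousands of cases and controls, but the standard genotype tests see only
the three diploid genotypes. CNVs — deletions and amplifications of DNA
segments spanning many consecutive SNPs — distort the allele-intensity
clusters those tests rely on, and their risk signal is invisible to them.
`cnvassoc` implements an integrated strategy for finding disease-associated
CNV loci directly from the array signal, for statistical geneticists working
with case-control intensity data (or with copy-number calls from any
source):

1. **Signal transformation.** Raw A/B allele intensities become the Log R
   Ratio, LRR = log2(r / r_expected(θ)) with r = x + y and
   θ = (2/π)·arctan(y/x), and the B-allele frequency (BAF), the
   piecewise-linear rescaling of θ that pins the AA/AB/BB cluster centres
   to 0, 0.5, 1. Cluster centres are 90% trimmed means over the cohort.
2. **Copy-number calling.** A six-state hidden Markov model along each
   chromosome (total copy numbers 0, 1, 2, 2-LOH, 3, 4) decodes integer
   copy numbers from the (LRR, BAF) series, with a self-training loop that
   refits all emission and transition parameters until every parameter
   changes by less than 1e-4.
3. **Site-based testing.** Each SNP is tested under triple null hypotheses
   — deletion (*Loss*, CN < 2), amplification (*Gain*, CN > 2), either
   (*Abnm*, CN ≠ 2) — by the 1-df chi-squared test
   X² = Σ (n_ij − e_ij)²/e_ij, replaced by the two-sided Fisher exact test
   whenever an expected count falls below 5; plus a Cochran-Armitage trend
   test over copy-number categories.
4. **Window-based testing.** Around each candidate site, the 41-SNP
   copy-number vectors of all samples are clustered by complete linkage
   under Euclidean distance; every dendrogram node is tested as a 2×2
   in-node/out-of-node table, and the minimum node P — the **first class
   P value** — is the window's statistic.
5. **Permutation FDR.** Both levels control multiple testing by case/control
   label permutation: FDR(P\*) = (mean permuted #{P ≤ P\*}) / (observed
   #{P ≤ P\*}). Candidates pass at FDR < 0.05 per hypothesis; final windows
   at fewer than one expected false positive; neighbouring significant
   sites merge into loci.

A seeded synthetic-cohort generator (genotype clusters in intensity space,
planted multi-SNP CNV regions with group-specific frequencies, Gaussian
noise, full ground truth) makes every stage testable without any external
data. See `docs/methods.md` for the model details and design decisions.

## Worked example

Simulate a cohort of 500 cases and 500 controls over 300 SNPs with an
8-SNP hemizygous deletion carried by 20% of cases and 5% of controls, then
run the full pipeline:

```sh
cnvassoc simulate --out demo/fx --seed 7
cnvassoc run-all \
    --intensities demo/fx/intensities.tsv \
    --snp-map     demo/fx/snp_map.tsv \
    --phenotypes  demo/fx/phenotypes.tsv \
    --out demo/out --site-perms 200 --window-perms 500 --seed 7
```

The run prints the stage counts and writes per-stage tables; the resulting
`demo/out/loci.tsv` is:

```
 Chr      Landmark  Start    End       P_loss       P_abnm  P_gain     P_window  n_members
   1 chr1_snp00140 141000 149000 8.139970e-12 8.139970e-12     1.0 6.307365e-13          9
```

Reading it: of 300 sites tested, 9 passed the site-level FDR gate, all 9
survived the window-level gate, and they merge into one locus. Its landmark
SNP sits at the planted deletion (map positions 141–149 kb); the deletion
hypothesis and the combined hypothesis are both overwhelmingly significant
(P ≈ 8×10⁻¹²) while the amplification hypothesis is null (P = 1), and the
window-based clustering confirms the carrier pattern (first class
P ≈ 6×10⁻¹³). The two label-neutral background CNV regions in the simulated
cohort are correctly absent.

The same stages are available in-library (`cnvassoc.signals_from_raw`,
`cnvassoc.train`, `cnvassoc.decode_cohort`, `cnvassoc.run_cohort`) and as
separate subcommands (`train`, `call`, `site-test`, `window-test`, `fdr`).

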