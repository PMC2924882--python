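# Methods

`cnvassoc` tests whether copy-number variation (CNV) at and around SNP-array
sites differs between cases and controls. The computation has four stages:
signal transformation, hidden-Markov copy-number calling, two-pass
association testing (per-site, then window-based pattern clustering), and
label-permutation control of multiple testing. This note documents the model
at each stage, the tunable parameters and their defaults, the numerical
choices, what the synthetic-data generator does and does not emulate, and the
known limitations.

## Signal transformation

Each SNP assay yields two fluorescence intensities, `x` (A allele) and `y`
(B allele). These are summarized as the allelic angle
`theta = (2/pi)·arctan(y/x)` in `[0, 1]` and the intensity sum `r = x + y`.
Per SNP, the canonical genotype clusters AA/AB/BB are located in
`(theta, r)` space as 90% trimmed means over the cohort (discard
`floor(0.05·n)` values per tail). Two derived signals follow:

- **Log R Ratio (LRR)** = `log2(r / r_expected(theta))`, where `r_expected`
  interpolates linearly through the three cluster centres and clamps beyond
  the homozygous clusters. LRR is a proxy for total copy number: 0 at
  diploid, about −0.66 at one copy, about +0.4 at three.
- **B-allele frequency (BAF)**: the piecewise-linear rescaling of `theta`
  that pins the cluster centres to 0, 0.5 and 1. BAF is a proxy for allelic
  composition. When the AA and AB centres coincide (degenerate clusters),
  the branch order resolves `theta == theta_AB` upward to 0.5, preserving
  monotonicity.

When no genotype calls accompany the intensities, samples are assigned to
clusters by **exact 1-D 3-means on theta**: the optimal clusters of sorted
1-D data are contiguous, so the globally SSE-minimal assignment is found by
enumerating the two break points (on weighted quantile bins above 200
distinct values). Seeded Lloyd iterations were rejected: with skewed allele
frequencies the median-percentile seed falls inside the major homozygote
cloud and converges to a split-cluster local optimum that corrupts the het
centre by up to 0.4. The exact assignment has no seeds and no local optima.

Empty clusters are imputed and flagged: a missing AB centre takes the
midpoint of AA and BB; a missing homozygote mirrors the present one around
`theta = 0.5`. Dead probes (`x = y = 0`) are masked, never imputed.

Cross-cohort quantile normalization (for aligning a training cohort to a
study cohort) is rank-based substitution against the reference's pooled
empirical distribution, with both intensity channels pooled into one
distribution. It preserves training-set ranks and is idempotent against a
fixed reference.

## Copy-number HMM

Six hidden states along each chromosome, with total copy numbers
(0, 1, 2, 2, 3, 4); the second CN2 state is copy-neutral loss of
heterozygosity (LOH). Emissions at a SNP with population B-allele frequency
`pB` combine:

- a Gaussian on LRR with state-specific mean and one **shared** standard
  deviation (noise is assumed state-independent);
- a mixture on BAF over allelic compositions: for copy number `c`,
  components at `b/c` for `b = 0..c` B alleles, weighted `Binomial(c, pB)`.
  The LOH state has components only at 0 and 1 with weights `(1−pB, pB)`
  (one haplotype duplicated). CN0 has no allelic composition and uses a
  uniform density on `[0, 1]`. Homozygous components collapse their Gaussian
  mass beyond `[0, 1]` onto the boundaries as point masses, matching the
  clamping of BAF by construction;
- a small uniform outlier component (`outlier_weight`, default 0.01) so no
  single artifact dominates a path.

Masked signal points contribute emission probability 1 in every state; the
transition model still spans them. Viterbi decoding breaks exact ties toward
the lowest state index. Decoded copy-number runs `!= 2` spanning at least 3
SNPs are reported as CNV segments; shorter runs are treated as noise.

### Self-training

Training iterates: decode → reset sub-threshold segments to the normal
state → refit LRR means/sd → refit BAF components → update transitions →
set the initial distribution to the stationary distribution of the updated
transition matrix. It stops when every scalar parameter moves by less than
`1e-4` (cap 50 iterations, flagged if hit).

- **LRR refit**: copy numbers with at least `min_state_count` called points
  (default 500; configurable, and smaller for small cohorts) get direct
  means; the rest are filled from the least-squares line of mean LRR against
  copy number over the well-populated copy numbers. The sd comes from
  CN2-called points only. Both CN2 states share one LRR mean. Barely
  populated extreme states (CN4 at the default threshold's edge) are subject
  to truncation bias — the state absorbs only the favorable noise tail — so
  the direct-mean threshold should not be set low on small cohorts.
- **BAF refit**: values called in a state are assigned to its nearest
  component; component means/sds are the assigned moments (sd floored at
  1e-3). Components or states with no support keep their previous values
  and are flagged; such parameters retain their initialization and are
  excluded from any initialization-independence comparison.
- **Transition refit (default: filtered-path counts).** Free Baum-Welch
  expected-count updates are implemented (`baum_welch_transitions`, scaled
  forward-backward, chromosome-weighted mean with SNP-count weights) and
  verified against exhaustive posterior enumeration, but they are unstable
  as the in-loop update on cohorts without real LOH: at every homozygous SNP
  the LOH state carries roughly twice the per-site BAF likelihood of the
  normal state (`(1−pB)` vs `(1−pB)²` at BAF 0), so any soft off-diagonal
  normal→LOH mass lowers the switching cost and feeds itself; in practice
  the normal state's self-transition decayed from 0.998 to 0.83 over
  iterations with no convergence. The default update therefore counts
  transitions along the **noise-filtered Viterbi paths** (Viterbi training):
  per chromosome, hard adjacent-pair counts plus a 0.5 pseudocount per cell,
  row-normalized, then averaged across chromosomes with SNP-count weights.
  The segment filter operates on hidden-**state** runs, not copy-number
  runs, so isolated LOH calls (CN 2) are filtered like any other isolated
  CNV call. Rows with fewer than 10 observed transitions are data-starved
  and fall back to the flat pseudocount row, which keeps never-visited
  states' rows deterministic and initialization-independent. With this
  update, training converges in 3–5 iterations and two perturbed
  initializations agree on the data-informed parameters to a few 1e-4;
  off-diagonal entries of rows resting on a few hundred transitions have
  count resolution ~2e-3 and can differ at that scale when the two runs'
  converged call sets differ by a boundary site.

Default initialization (config-exposed): LRR means
`(−3.5, −0.66, 0, 0, 0.4, 0.68)`, LRR sd 0.2, BAF component sd 0.03,
transition diagonal 0.999 with the off-diagonal mass spread evenly, initial
distribution stationary. Transitions are distance-independent: one matrix
regardless of inter-SNP spacing.

## Site-based testing

At each SNP, three null hypotheses are tested with 2×2 case-control tables:
**Loss** (variant class CN < 2), **Gain** (CN > 2) and **Abnm** (CN ≠ 2).
The complement class is *all remaining samples* — the Loss complement
includes gains and vice versa (an alternative complement-is-CN2-only rule is
config-exposed). The test is the uncorrected chi-squared statistic
`X² = Σ (n_ij − e_ij)²/e_ij` on 1 df when every expected count is ≥ 5, and
the two-sided Fisher exact test otherwise (sum of hypergeometric
probabilities of all tables with the observed margins at most as probable as
the observed table; float ties within relative 1e-7). A zero margin carries
no information and reports P = 1. The expected-count trigger was chosen over
the observed-count reading; with it, the choice of test depends only on the
margins — which are invariant under label permutation, the key to the
permutation engines below. A Cochran-Armitage trend test over the ordered
copy-number categories (scores 0..4) complements the three dichotomous
hypotheses.

Note on asymptotics: the worst-case gap between the min-likelihood two-sided
exact P and the chi-squared P is of the order of the modal hypergeometric
probability mass, roughly `1/(σ√2π)` with σ the hypergeometric sd. Expected
counts ≥ 5 (or even ≥ 50) do not by themselves bound the gap below 0.01;
agreement at 0.01 absolute requires σ ≳ 40 (cell counts in the thousands).

## Window-based testing

For each candidate SNP, the copy-number vectors of all samples over a
41-SNP window centred on the site (truncated and flagged at chromosome ends;
masked entries imputed as diploid for distances) are clustered
agglomeratively with **complete linkage** under Euclidean distance.
Deterministic tie-breaking: the candidate pair whose union has the lowest
smallest sample index merges first. Identical vectors — overwhelmingly the
all-diploid vector — are collapsed into weighted leaves before clustering;
zero-distance merges happen first under complete linkage, so the memberships
of nodes separating distinct patterns are unchanged (verified against
uncollapsed runs and a naive O(S³) reference agglomerator).

Every non-root node (leaves included) yields a 2×2 table — cases/controls
inside vs outside the node — tested exactly as at the site level. The
minimum P over nodes is the **first class P value**, the window's statistic.
Ties prefer the *smaller* node, then the lower node id: the root's two
children always carry identical tables (complementary rows), so a carrier
cluster directly under the root ties with its complement, and the smaller of
the two is the CNV-pattern cluster itself. The P value is tie-invariant;
only the reported node identity depends on this rule.

## Multiple testing

Both levels estimate FDR by label permutation (copy numbers fixed):

    FDR(P*) = (mean over permutations of #{permuted P ≤ P*}) / #{observed P ≤ P*}

with ties counted on both sides and the raw (possibly non-monotone) curve
used by default; a running-minimum monotonized curve is available behind a
flag.

- **Site gate** (default B = 1000): one FDR curve per hypothesis over all
  sites; a SNP is a candidate when any hypothesis P value is at or below
  that hypothesis's largest boundary with FDR < 0.05. Pooling the three
  hypotheses into one curve is available behind a flag.
- **Window gate** (default B = 25000): the boundary is the largest observed
  P* with `#{observed ≤ P*} × FDR(P*) < 1` — fewer than one expected false
  window.

Because margins are permutation-invariant, the P value at a site (or node)
is a precomputed function of a single count — case carriers `k` for fixed
variant margin, or cases-in-node `k` for fixed node size — so each
permutation reduces to one matrix multiplication plus table lookups. The
window-level engine re-scores cached node member sets; dendrograms are never
recomputed (they depend only on the vectors). Site- and window-level
permutations use independent seeded streams keyed `(seed, b)`; a full run is
reproducible from one master seed.

Significant sites merge into **loci**: sites on one chromosome whose
map-index gap is at most `(n−1)/2` (half a window; the span over which
window tests share SNPs) merge transitively. The landmark is the member with
the smallest window P, ties to the smallest position. Because all sites of
one CNV region typically tie on window P, and a decoded segment boundary can
smear one SNP beyond the true region in a minority of carriers, the landmark
can land one SNP outside the generating span; localization should be read at
±1 SNP.

### Behaviour under a global null

The two-stage design has a structural property worth knowing: windows
centred on the sites of one CNV region share their pattern, so when a null
region fluctuates past the site gate its ~10–15 windows pass or fail the
window gate together. Measured over 60 independent null cohorts (300/300
samples, 300 SNPs, B = 200/200), the site gate passed in ~7% of runs and
every pass produced one full bundle: ~0.97 false windows per run on average
— at the design bound of 1 — but only ~0.07 false *loci* per run. The
per-window expected-FP bound should be interpreted at the locus level when
windows are strongly correlated; the gate's own estimate does not account
for the site-stage selection of which windows get tested.

## Synthetic cohorts

The generator draws, per planted region, Bernoulli carrier status at
group-specific frequencies; builds true copy-number paths; samples allelic
compositions binomially in a per-SNP `pB ~ U(0.2, 0.8)`; and emits raw
`(x, y)` intensities from the genotype-cluster geometry (theta centres
0.08/0.5/0.92, r = 2) at the copy-number-scaled intensity sum, with Gaussian
noise applied in (LRR, theta) space. A shortcut mode emits (LRR, BAF)
directly for fast tests. Copy-neutral LOH regions (homozygous compositions
at CN 2) are an optional region type. Everything is bit-reproducible from
one seed, and ground truth (per-sample paths, carrier lists, generating
parameters) accompanies every cohort.

Reference conditions used by the test suite and the verification script,
chosen once as realistic desk-scale analogues:

- **Power**: 500 cases / 500 controls, one chromosome of 300 SNPs, an 8-SNP
  hemizygous deletion at case frequency 0.20 vs control 0.05, plus two
  label-neutral background regions; B = 200 (site) / 500 (window).
- **Training**: 200 samples, two chromosomes × 200 SNPs, four neutral CNV
  regions of 8–12 SNPs at frequencies 0.15–0.20; direct-mean threshold 50.
- **Null calibration**: 500/500 samples with an independently drawn
  single-SNP common CNV (frequency 0.25–0.45) at each of 2100 sites. Sites
  of one multi-SNP region share carriers and are perfectly correlated, which
  violates the independence premise of a binomial envelope without changing
  per-site calibration; hence single-SNP regions for this check.
- **Null end-to-end**: 300/300 samples, 300 SNPs, multi-SNP neutral regions.

What the generator does **not** emulate: probe-level artifacts, GC waves,
plate/batch structure, linkage disequilibrium (genotypes are independent
across SNPs, so runs of homozygosity are short — one reason the free-EM LOH
instability manifests so readily), distance-dependent CNV breakpoints, and
sex chromosomes. Passing tests on these cohorts demonstrate correctness of
the statistical machinery and calibration under the stated noise model, not
robustness to real-array artifacts.

## Defaults that matter

| Parameter | Default | Meaning |
| --- | --- | --- |
| window size n | 41 SNPs | span of pattern clustering, brackets most CNVs |
| site FDR bound | 0.05 | candidate gate, per hypothesis |
| expected-FP bound | 1 window | final window gate |
| permutations | 1000 / 25000 | site / window level (200/500 in test profiles) |
| min segment | 3 SNPs | shorter CNV runs treated as noise |
| training tolerance | 1e-4 | max per-parameter change at convergence |
| fisher trigger | expected < 5 | observed-count rule behind a flag |
| outlier weight | 0.01 | uniform emission mass |

The CLI exposes the pipeline (`cnvassoc simulate|train|call|site-test|`
`window-test|fdr|run-all`); `--threads` is accepted for interface
compatibility but results never depend on it — all heavy paths are
vectorized in-process, which keeps run output bit-identical by construction.

## Known limitations

- Transitions are distance-independent; dense and sparse SNP panels get the
  same persistence.
- The LOH state is weakly identified per-site; only run length separates it
  from chance homozygosity. Free Baum-Welch transition training is provided
  but not the default for this reason.
- The window-level FDR inherits a selection effect: permutations re-score
  only the windows the site gate selected. Under strong inter-window
  correlation the expected-FP guarantee is effectively a per-locus one.
- Fisher/chi-squared agreement is asymptotic; near the trigger boundary the
  two can differ by several hundredths in the mid-P range.
- Sex chromosomes are excluded by default (different copy-number baselines).
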