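# Methods

This note documents the models, numerical choices and limitations behind
`finestrat`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from external runs.

## Genotype model and I/O

Genotypes are diploid SNP dosages in {0, 1, 2, missing}, counting copies of
the BIM A1 allele (PLINK convention). The BED codec implements the
SNP-major 2-bit encoding exactly (00 → 2 copies of A1, 01 → missing,
10 → 1, 11 → 0, little-endian within each byte, 4 genotypes per byte);
round trips are bit-exact, which the suite asserts on random fixtures.
Individual-major BED is refused explicitly rather than mis-read.

## Quality control

The seven filters run in a fixed order — founders, autosomes, LD pruning,
HWE, sample call rate, SNP missingness, MAF — with all statistics
recomputed on the current dataset at each step. This order applies LD
pruning before the marker-quality filters, which differs from much common
practice but is the order this pipeline is specified to follow; because
each filter recomputes from the surviving data, order matters (e.g. a SNP
can pass the MAF filter only after a low-call-rate sample is removed, and
the suite pins that case).

Boundary conventions: the call-rate and missingness filters remove
strictly-greater-than fractions; MAF and HWE remove strictly-less-than
values. So a sample with exactly 5% missingness, a SNP with MAF exactly
0.05 or HWE p exactly 0.001 all survive.

*LD pruning* is greedy within sliding windows of 50 SNPs advanced by 5 per
chromosome: while any retained in-window pair exceeds r² = 0.2 (squared
Pearson correlation of dosages on pairwise-complete entries; zero-variance
pairs score 0), one SNP of the worst pair is removed — the one with the
smaller MAF, or the later in map order on a tie. The guaranteed contract
is that no surviving in-window pair exceeds the threshold; the exact pruned
set is a dialect choice and is not promised to match any other
implementation SNP-for-SNP.

*HWE* uses the two-sided exact conditional test: the probability, given the
observed allele counts, of all heterozygote configurations no more probable
than the observed one, evaluated by full enumeration in log space. The
suite cross-checks it against an independent exact-rational enumeration.

*Imputation* replaces each missing entry with the SNP's modal non-missing
dosage, ties breaking to the smaller dosage for determinism. A SNP with no
observed genotypes is an error (the missingness filter removes such SNPs
first in any sane configuration).

## Hudson F<sub>ST</sub>

Per SNP, with sample frequencies p₁, p₂ from n₁, n₂ observed chromosomes:

    N = (p1 − p2)² − p1(1 − p1)/(n1 − 1) − p2(1 − p2)/(n2 − 1)
    D = p1(1 − p2) + p2(1 − p1)

aggregated as mean(N)/mean(D) over SNPs with D > 0 (ratio of averages, not
average of ratios — the latter is dominated by low-information SNPs, and a
two-SNP test case pins the distinction). Chromosome counts are twice the
non-missing genotype counts per SNP per group, so missingness shrinks the
small-sample correction per SNP; counting individuals instead would only
rescale that correction. Negative values are kept: near zero divergence
the estimator is unbiased around 0, and the clustering gate simply treats
them as below threshold.

Under the generator below, two populations drawn independently at drift F
from a shared ancestor satisfy E[N] = 2F·p(1−p) and E[D] = 2p(1−p), so the
estimator's expectation is F itself; the acceptance run verifies ≤ 10%
relative error of the 20-replicate mean at F ∈ {0.001, 0.01, 0.1} with
10,000 SNPs and 100+100 chromosomes.

## The clustering engine

At each node: standardize (drop SNPs monomorphic within the node, center,
scale by √(2p̂(1−p̂))), eigendecompose (via the n×n Gram matrix when
n ≤ m), then:

1. **RubikClust peeling, before the stopping rule.** Outlier separation is
   a robustification step, not a structure decision, so it is not gated by
   the spectral statistic: a node whose spectrum looks flat can still shed
   a gross outlier. The 3-D cloud of PC1–3 scores is rotated by all
   pairwise-axis rotations on a 10° grid; each axis projection is scanned
   for internal gaps larger than `gap_factor` (default 3) times the
   interquartile range of the gap's *majority side*. Using the majority
   side's IQR rather than the global IQR means a balanced two-cloud
   separation qualifies (the global IQR would span the gap itself) while a
   few stragglers on the minority side cannot inflate the spread. The
   single widest qualifying gap selects the projection; the node is then
   cut at every qualifying gap of that projection, so several outliers
   strung along one direction peel in one call. On an isotropic Gaussian
   cloud (n = 200) the false-split rate is zero across the seeded suite.

2. **EigenFit stop.** The statistic is the largest consecutive
   log₁₀ gap among the leading `n_eigs_fit` (default 10) positive
   eigenvalues; a flat spectrum scores 0, a spectrum (100, 1, 1, …) scores
   2. The engine feeds it only *group-supported* components: a component
   whose inverse participation ratio implies an effective support below 5
   samples (the same bound that defines an outlier group) is an outlier
   direction, not group structure. This matters quantitatively: a single
   outlying individual's eigenvalue spike is bounded by ≈ 1.4× the
   Marchenko–Pastur bulk edge at n ≈ 700, m = 20,000 — big enough to sit
   mid-gap and smear the structure-to-bulk drop below any usable
   threshold, yet far too small ever to clear a 1.5× gap itself. Filtering
   such spikes restores the clean drop (measured ≈ 0.27 on the preset's
   structured nodes vs ≈ 0.003 on homogeneous nodes, against the default
   threshold 0.18 ≈ a 1.5× eigenvalue ratio).

3. **Mixture split.** A full-covariance 2-component Gaussian mixture on
   the top 3 PC scores, k-means-initialized and seeded, accepted only when
   its BIC beats the 1-component fit; EM degeneracy or an empty component
   means no separation. Attempted only on nodes of at least
   2·`min_in_group` samples.

4. **FST gate.** Any proposed split (rubik or mixture) is accepted only if
   the average Hudson F<sub>ST</sub> between its two largest children is at
   least `min_fst` = 0.0008; a second-largest child of a single sample is a
   peeled outlier and skips the gate (no n−1 correction exists for n = 1).
   This gate, not the spectral rule, is what guarantees a panmictic cloud
   is never split by an over-eager proposer.

Children smaller than `min_in_group` (default 20) become terminal
immediately; terminal groups smaller than 5 are reported as outlier groups
(the two bounds are deliberately distinct: `min_in_group` bars *splitting*,
5 defines *outlier reporting*). Accepted groups are numbered depth-first
with children ordered by smallest member index, so the numbering is a
deterministic function of (data, parameters, seed). Every split strictly
shrinks the largest part, so the recursion terminates.

The engine is exposed as a scikit-learn estimator
(`IterativePCAClustering`: `fit`, `fit_predict`, `labels_`, `outlier_`,
`tree_`, `n_groups_`) and composes with sklearn model-selection tooling;
`ipcaps(dataset, params)` is the dataset-level wrapper that returns the
cluster tree and the per-sample assignment table.

Per-node seeds are derived as CRC32(seed, node path), keeping every source
of randomness reproducible and below 2³¹.

## Discriminator SNPs and the uniqueness test

Per accepted-group pair, per-SNP Hudson ratios are ranked (SNPs
monomorphic across both groups rank below everything); the cutoff is the
value at rank ⌈0.999·m⌉ of the ascending sort and all SNPs at or above it
are selected. For tie-free values this yields exactly m − ⌈0.999·m⌉ + 1
SNPs — 139 for m = 138,111 — and a tied block at the cutoff is always
taken whole (ties can only enlarge the selection under this rule, never
shrink it).

Uniqueness is a reproducibility test: each of `n_permutations` rounds draws
a `subsample_fraction` (default ½) cohort of every group without
replacement, the resampled individuals keeping their assigned labels,
recomputes the top set, and compares it with the observed set via a
bootstrap Jaccard/Tanimoto test. Under independent membership with
marginals π_A, π_B over m SNPs the expected Jaccard index is
π_Aπ_B/(π_A+π_B−π_Aπ_B); the null is B multinomial resamples of
independent membership indicators, and the two-sided p is add-one-smoothed
(never exactly 0). The *maximum* p over rounds summarizes the pair: a
genuine discriminator set reproduces in every half-cohort, so every round
is maximally significant and max p ≈ 1/(B+1); a noise set fails to
reproduce in at least some rounds, pushing max p toward 1.

The alternative construction — permuting group labels over the pooled pair
and testing the permuted top set against the observed one — was examined
and rejected: under label exchange the permuted top set is noise, and it
is disjoint from the observed set for structured *and* panmictic pairs
alike (overlap ≈ 0 measured in 98/100 rounds at F = 0.05, 50+50, 20k
SNPs), while disjointness of two sparse sets is the *null* of the Jaccard
test. That construction therefore cannot distinguish a real discriminator
set from noise at these study conditions; label-preserving subsampling
can, and its full-scale max p for a genuine pair, 1/(B+1) ≈ 0.001 at
B = 1000, is the value such an analysis prints.

## The synthetic generator

Populations evolve from a shared ancestral frequency pool
(Uniform(0.05, 0.95), wide enough that the MAF filter does not dominate
fixtures) along a tree whose branches apply Balding–Nichols drift:
p → Beta(p(1−F)/F, (1−p)(1−F)/F), mean p, variance F·p(1−p). Genotypes
are Binomial(2, p) draws; admixed individuals use
p_eff = Σ_k Q_k p_k with per-individual mixing proportions. All output is
deterministic per seed, down to BED bytes.

No linkage disequilibrium is simulated — drift acts independently per SNP
— so LD-pruning behavior is exercised through explicitly planted
duplicated/correlated SNPs (`NoiseSpec`), not through background LD.
Consequently, passing tests demonstrate correctness of the pruning
algorithm, not performance on realistic LD block structure. Real-data
features the generator also does not emulate: genotyping batch effects,
non-random missingness, relatedness beyond the founder filter, and
selection.

### The `western_africa_like` preset

The preset instantiates the study design the pipeline targets, with every
planted feature resolvable at the default threshold 0.18 (the spike-margin
arithmetic below is the design rationale, fixed before any end-to-end
run):

* 6 closely related populations × 85 samples, branch F 0.0090–0.0105
  (pairwise Hudson F<sub>ST</sub> ≈ 0.009–0.0105). With 20,000 SNPs this
  puts each population-contrast eigenvalue ≈ 2.3–2.5× the bulk edge;
  weaker drift (or many fewer samples) would drop the weakest contrast
  below the 1.5× ratio the 0.18 threshold demands, making the design
  unresolvable *by construction* rather than by algorithmic failure.
* 1 strongly diverged population × 55, branch F 0.28 — two independent
  drifts of 0.28 and ≈ 0.01 give pairwise F<sub>ST</sub> ≈ 0.145 ≥ 0.14,
  the scale of a highly endogamous nomadic group against everyone else.
* 2 admixed diaspora-like groups × 75: own local lineages at F = 0.014
  plus a per-individual Uniform(0.05, 0.15) ancestry fraction from an
  out-group at F = 0.30 — admixture both spreads the groups in PC space
  (their top-PC dispersion exceeds every unadmixed group's, which the
  suite asserts) and shifts them off the unadmixed cluster manifold.
* 5 singleton outliers, each the sole member of its own lineage at
  F = 0.95. A singleton's PCA spike cannot exceed ≈ 1.4× the bulk edge
  regardless of divergence, so outliers must be near-fixated to be
  peelable at all; F = 0.95 puts them at the detectability ceiling, which
  is precisely what "planted outlier" must mean for a PCA-based method.

Total 720 samples. Truth labels ride along as `population_label` and in
the sidecar labels TSV; the clustering engine never reads them.

## Problem sizes and defaults

Defaults follow the protocol the pipeline implements: threshold 0.18,
min_in_group 20, min_fst 0.0008, percentile 0.999, 10,000 resampling
rounds, B = 1000. The acceptance script scales the resampling test to 100
rounds with B = 200 and runs recovery simulations at 10,000 SNPs with
100–720 samples; at these sizes the full acceptance run completes in
about half a minute on a single CPU, and the statistical conclusions are
unchanged from the full-scale settings (the max-p statistic only becomes
more extreme with more rounds).

## Known limitations

* The EigenFit statistic and RubikClust schedule are calibrated stand-ins
  for the original iterative-pruning heuristics, specified fully above;
  bit-exact agreement with other implementations is not claimed, only the
  documented contracts.
* Covariate adjustment of the PCA is not implemented (no covariates in the
  supported protocol), and only the 'mix' method order (rubik first,
  mixture fallback) exists.
* The min_fst gate is applied uniformly to every proposed split with a
  computable sibling F<sub>ST</sub>; whether it should exempt rotation
  splits is undecidable from the protocol and the uniform choice is the
  conservative one.
* Balanced splits rely on the Gaussian mixture proposer; heavily
  imbalanced fine-scale splits below `min_in_group` are invisible by
  design.
* `pairwise_group_fst` is quadratic in the number of groups and the
  uniqueness test is linear in rounds × SNPs; both are intended for the
  dozens-of-groups regime, not thousands.
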