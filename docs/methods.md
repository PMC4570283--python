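# Methods

This note documents the models behind each module, the defaults and why
they were chosen, what the synthetic-data generators do and do not emulate,
and the numerical conventions.  Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Drift model and the divergence-time transform

All tree-based analyses assume pure drift: after `t` generations at
constant diploid effective size `Ne`, allele frequencies disperse around
their ancestral value with drift coefficient

    F = 1 − exp(−t / (2·Ne)) ≈ 1 − (1 − 1/(2Ne))^t,

and F composes along a path as `F_path = 1 − Π(1 − F_branch)`.  Hudson's
per-SNP F<sub>ST</sub> between two populations whose lineages carry drift
F_A and F_B below their common ancestor has expectation `(F_A + F_B)/2`
under a uniform ancestral spectrum, which is what the transform

    T = log(1 − FST) / log(1 − 1/(2·Ne))

converts back into a branch length in generations.  The transform is the
exact inverse of `FST(T) = 1 − (1 − 1/(2Ne))^T` (verified to 1e-10 relative
error); it recovers the generating `t` exactly when both lineages drift at
the same `Ne`, and returns an `Ne`-weighted equivalent time otherwise.
F<sub>ST</sub> is clamped to `[0, 1 − 1e-6]` before the log so fixed
differences give large finite T rather than infinity; negative estimator
values map to T = 0.

**Estimator choice.** Hudson's estimator (Bhatia-style, with the
`p(1−p)/(n−1)` sample-size correction) is the default because it is robust
to the strongly unequal sample sizes typical of isolate studies (tens of
focal samples vs. large reference panels).  Weir–Cockerham is available via
`estimator="weir_cockerham"`.  Per-SNP scans use single-SNP ratios; the
genome-wide F<sub>ST</sub> used for divergence dating is the
ratio-of-averages form, which is the stable convention for genome-wide
values.

**Ne in the scan.** The transform needs the effective size of the drifting
population.  The scan applies one `Ne` (default 2,471, the LD-based
estimate for the focal isolate; CI presets 2,319/2,603) to all three
pairwise T values, overridable per pair via `ne_per_pair` — only the focal
population's Ne is usually estimated in such studies, and PBS is rank-based
so a shared monotone rescaling of T changes little.

**Outliers** use the nearest-rank empirical percentile (threshold = the
`ceil(q·N)`-th smallest PBS); ties at the threshold are all flagged, and
negative PBS values are retained since calling is rank-based.

## f3 statistics and the block jackknife

Outgroup f3(O; A, B) is the plain mean of `(o−a)(o−b)` over SNPs with
defined frequencies in all three populations; no bias correction is applied
because the A/B slots routinely hold single pseudo-diploid (n=2) genomes
whose heterozygosity correction would be enormous and is unnecessary for a
ranking statistic.  Admixture f3(C; A, B) subtracts the target's
finite-sample bias `c(1−c)/(n_c−1)` so that an unadmixed target is centred
at or above zero.

Standard errors come from a weighted delete-one-block jackknife (Busing
delete-m_j form) over contiguous physical blocks, default 5 Mb — large
enough to exceed LD range in human-like data; configurable.  Fewer than two
blocks yields an undefined SE (and no Z).  Note the jackknife SE estimates
the sampling error of the statistic for the given data: it shrinks as the
genome grows (~1/√blocks at fixed block size), not as a fixed genome is cut
into more blocks.

## LD-based Ne and divergence dating

Pairs of variants (MAF ≥ 0.05, same chromosome) are binned by genetic
distance; 25 logarithmic bins over [0.0005, 0.25] Morgans, minimum 50 pairs
per bin.  The composite (Rogers–Huff) r² of each pair, minus the sample
inflation `1/n` (n diploids) and floored at 1e-6, is averaged per bin and
inverted through Sved's relation `E[r²] = 1/(2 + 4·Ne·c)`:

    Ne(bin) = (1/r²_adj − 2) / (4·c),   dated t = 1/(2c) generations ago.

Bin distance in Morgans is used directly as the recombination fraction `c`;
at the largest bins (c ~ 0.2) this overstates the true recombination
fraction by ~10–20% (Haldane), which is inside the method's intrinsic
factor-level accuracy.  `r²_adj ≥ 0.5` would give non-positive Ne and is
reported as undefined.

Pairwise divergence times apply the T transform to genome-wide
ratio-of-averages F<sub>ST</sub> with `Ne_pair` the harmonic mean of the
two populations' recent sizes (drift accrues at 1/(2Ne) per lineage; the
harmonic mean is the conservative symmetric choice, configurable).  The 95%
CI is a delete-one-chromosome jackknife on F<sub>ST</sub>, transformed to
time; years use a generation time of 25 by default (28 is a common
alternative; the conversion is linear).  UPGMA (average linkage via scipy)
clusters the dated matrix; node height is half the merged distance, taxa
are pre-sorted lexicographically for deterministic tie-breaking, and the
output Newick is ultrametric by construction.

## Wright–Fisher simulator

Each generation applies a deterministic fitness update then binomial
resampling of `2·Ne` copies; 0 and 1 are absorbing, there is no mutation,
migration or size change.  The generic default is genic selection
(`p* = p(1+s)/(1+sp)`, genotype fitnesses 1 : 1+s : (1+s)²); a dominance
coefficient `h` switches to 1 : 1+hs : 1+s.

**ACTN3 scenario fitness.**  The selected arm defaults to a *recessive*
advantage of the derived stop-gain allele (h = 0, fitnesses 1 : 1 : 1+s).
Two observations force this choice over the genic default.  First, genic
s = 0.01 from p0 = 0.47 crosses the 0.93 threshold deterministically by
generation ~270 and ends at ≥ 0.93 in essentially every replicate, leaving
no drift-vs-selection contrast on a 500-generation horizon; the recessive
scheme crosses deterministically around generation ~376 and leaves a
substantial minority of replicates below threshold, the regime the scenario
is meant to probe.  Second, the biology: the variant removes α-actinin-3
only in derived homozygotes, so a homozygote-only fitness effect is the
natural single-parameter model.  `dominance=None` restores the genic
scheme.  "Achieved the observed frequency after 500 generations" is scored
as terminal frequency ≥ threshold at generation 500; the more permissive
"ever reached" count is always reported alongside.

The recording grid is {0, 50, …, 500} (1,000 replicates by default);
threshold attainment is tracked every generation, not just at recorded
points.  Small-Ne ensembles are validated against exact `(2Ne+1)`-state
Markov-chain propagation (total-variation distance < 0.02 at 1e5
replicates), and neutral runs against the closed-form heterozygosity decay
`E[p(1−p)]_t = p0(1−p0)(1 − 1/(2Ne))^t`.

## QC conventions

LD pruning is PLINK-style greedy: sliding windows (default 50 variants,
step 5) per chromosome, left-to-right pair scan, the lower-MAF member of a
violating pair (r² > 0.4) is dropped, ties drop the larger index; rescanning
a pruned panel finds no violations.  PI_HAT is the method-of-moments
IBS→IBD solution using pooled allele frequencies (per-population
frequencies are configurable by subsetting); PLINK's small-sample
allele-frequency corrections are omitted — with ≥ 100 samples' worth of
frequency information and thousands of SNPs the omitted terms are well
below the 0.05 decision margins used here.  The relatedness filter
iteratively removes the individual in the most PI_HAT > 0.6 pairs (ties:
later sample id) until none remains.

Missing dosages use a dedicated sentinel (−1); every statistic uses
pairwise-complete samples.

## Synthetic data: what it does and does not emulate

`generate_tree_genotypes` draws unlinked loci: a root frequency from
Uniform(0.05, 0.95) (chip-like, few monomorphic sites; configurable), one
Balding–Nichols Beta step per branch, binomial diploid genotypes at the
leaves, and a variant map spreading loci at 50 kb spacing (1 cM/Mb) over 22
chromosomes so physical-block and chromosome-block jackknives are
exercised.  Because loci are unlinked, jackknife SEs on these data are
honest but do not test robustness to real LD; chip ascertainment bias,
genotyping error and missingness patterns are also not modelled.
`spike_selected_loci` moves leaf frequencies below one branch toward
fixation and redraws those genotypes — positives for the scan, not a model
of a selective sweep's haplotype structure.

`simulate_ld_haplotypes` is a discrete-locus forward Wright–Fisher
population with per-interval crossover probabilities from the inverse
Haldane map and symmetric mutation, burned in for ≥ 4·Ne generations from a
random start.  It produces the Sved-type r² decay needed to validate the Ne
inversion at desk scale (Ne ≤ ~1,000); it does not model recombination
hotspots, gene conversion or demographic change.

## Problem sizes and numerical choices

Default test and example scales — 8,000–25,000 unlinked loci, 20–25
diploids per population, Ne = 200 / 4,000 loci / 50 cM for the LD recovery,
50 replicates for CI coverage, 1e5 replicates for Markov-chain validation —
were chosen as the smallest sizes at which the Monte-Carlo tolerances in
the tests are comfortably resolved.  Beta sampling degenerates gracefully:
F = 0 passes frequencies through unchanged, fixed frequencies stay fixed,
F ≥ 1 is rejected.  Composite r² returns NaN for monomorphic pairs, and
callers exclude NaN explicitly.  All generators take explicit integer seeds
and are byte-reproducible under a fixed seed.

## Known limitations

- The T transform reports drift-equivalent time at the supplied Ne; if the
  two lineages' true sizes differ and only one is known, the result is a
  weighted compromise, not either lineage's wall-clock time.
- Sved inversion inherits the approximations of composite r² and the
  constant-2 denominator; estimates are factor-level, not percent-level.
- The admixture f3 test loses power when the target has drifted strongly
  after mixing; a non-negative f3 does not prove isolation, it only fails
  to reject it.
- Single-locus simulation ignores linked selection and interference.
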