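# Methods

`poolscan` analyses pooled-sequencing (Poolseq) surveys of structured
metapopulations: many demes, one pooled DNA library per deme, read counts
standing in for allele frequencies. It was built around the study design of
vernal-pool clam-shrimp surveys — 11 natural pools, 100 diploids per pool,
~70x coverage per pool, roughly one SNP per 85 bp over a ~120-Mb genome —
and every default below is that design's working point. This note records
the models, the numerical choices, and what the synthetic generator does
and does not emulate.

## Generative model (synthetic_data)

The generator produces every input the pipeline consumes, plus ground
truth.

**Allele frequencies.** Per SNP an ancestral frequency `pi` is drawn from
Beta(0.8, 0.8), clipped to [0.01, 0.99]; population frequencies are

    p ~ MVN(pi * 1, pi (1 - pi) * Omega),   truncated to [0, 1],

where `Omega` is the covariance of standardized frequencies (relatedness
matrix). This is exactly the shared-ancestry null the covariance-corrected
scan assumes, which makes the generator the natural calibration
instrument. `Omega` may be given explicitly, as `("identity", c)`, or as a
newick tree whose branch lengths are drift amounts (covariance = shared
root path). Truncation (not a logit transform) keeps the moments simple;
its cost is variance loss for `pi` near the boundaries, so moment-recovery
tests condition on mid-frequency SNPs. The `Omega = 0` limit (all demes at
the ancestral frequency) is accepted: the spec of a PSD matrix is enough
for generation.

**Spiked regions.** A configurable number of regions (widths drawn from
1–2,600 bp) displace the frequencies of a random subset of populations by
a fixed effect (clamped), or — in covariate mode — displace every
population proportionally to a standardized covariate. Every spiked region
is guaranteed to hold at least `spike_min_snps` SNPs; since a 1-bp region
cannot contain 5 distinct sites, a drawn width is widened minimally to
`spike_min_snps` bp and extra SNP positions are injected where the uniform
draw left too few.

**Pooled reads.** Per site and pool: realized pool frequency
`Binomial(2N, p) / 2N` for `N` diploids; depth `Poisson(coverage x
anomaly multiplier)` (Gamma-mixed when `depth_overdispersion > 0`;
Poisson is the default because the anomaly multipliers, not global
overdispersion, are what produce the overcovered regions of interest);
alternate reads `Binomial(depth, p')` with `p' = p(1-e) + (1-p)e` for
symmetric per-base error `e`. Site qualities are drawn with a deliberate
low-quality tail so the quality filter has work to do.

**Read pairs for LD.** A haplotype pool of `2 Ne_sim` chromosomes per
short window is simulated with msprime (neutral, single population, no
demography) at per-bp recombination `r = rho / (4 Ne_sim)`, and `depth`
reads covering each SNP pair <= 400 bp apart are drawn with replacement
from the pool, yielding the four two-site gamete-class counts. The
coalescent simulator was chosen over a hand-rolled forward simulation
because it gives exact control of the population-scaled `rho` with far
less machinery.

**What the generator does not emulate.** SNPs in the frequency model are
independent (no LD along the genome — LD lives only in the dedicated
read-pair windows); the site-frequency spectrum is a Beta prior, not a
neutral coalescent SFS, so absolute diversity levels are not meaningful in
the genome-wide table (the diversity estimators are instead calibrated
against a separate coalescent oracle); there are no indels, no paralogy,
no mapping artifacts, and reference base context is ignored when placing
SNPs. Passing tests therefore demonstrate estimator correctness under the
assumed models, not robustness to real-data pathologies.

## Filtering and frequencies (pooldata)

Biallelic records only (multiallelics dropped and counted, never split —
the two-allele count model requires it). Filtering keeps sites with
quality >= 30 and depth >= 10 in *every* population; it is idempotent and
reports per-criterion removal counts. Positions are 1-based internally
(VCF convention); BED exports are 0-based half-open. Sync rows carry no
quality, so reads assign a configurable default (60).

## 4-fold degenerate sites (degeneracy)

A genomic site is emitted iff every transcript whose CDS covers it places
it on the third position of a codon whose amino acid is invariant to all
four bases (standard genetic code; a hook accepts other tables). Reverse
strands are handled by reverse complement; GFF phase is honoured;
transcripts whose phase-adjusted CDS is not a multiple of three are
excluded from both the covering and the qualifying role (conservative:
they neither emit nor block). Coverage means CDS coverage only — a site
under a UTR of one transcript and a CDS of another is judged by the CDS
transcripts alone. Correctness is pinned to a brute-force
substitute-and-translate oracle in the tests.

## Pooled diversity (diversity)

Reads resample pool chromosomes with replacement, so `c` reads represent

    n_e = n (1 - (1 - 1/n)^c)

distinct chromosomes out of `n`. Per 10-kb window (the survey preset):

    theta_w = S / (a(round(mean n_e)) * L),      a(n) = sum_{i<n} 1/i
    pi      = (1/L) sum_sites 2 p (1-p) * c/(c-1) * n_e/(n_e-1)

both conditioned on the ascertained SNP set. The harmonic factor needs an
integer argument, hence the rounding; sensitivity to it is covered by the
depth-duplication test. A `naive` mode evaluates `a()` at the full pool
size and drops the chromosome-resampling inflation — kept because surveys
often report both an error-controlling and a plain windowed estimate, and
the two can differ severalfold on ascertained SNP sets. The ratio
`theta/pi` is the neutrality diagnostic; it is undefined at `pi = 0`.

## LD, rho, and the map chain (linkage_map)

Per SNP pair, within-read phasing gives gamete counts; `r^2` is estimated
directly from haplotype frequencies, or by an EM maximum-likelihood fit
when a symmetric per-base error is modelled (the EM fixed point at zero
error equals the direct estimate to 1e-10; convergence tolerance 1e-12,
cap 2,000 iterations). Pairs with fewer than 10 double-covering reads are
dropped — below that the estimate is sampling noise.

Distance bins (25 bp up to 400 bp) summarize LD as the sigma_d^2 form,

    sum_pairs D^2 / sum_pairs p_A(1-p_A) p_B(1-p_B),

rather than a plain mean of per-pair `r^2`: sigma_d^2 is the
ratio-of-expectations quantity whose drift expectation is the Hill–Weir
curve fitted next, while the mean of ratios sits far below that curve at
short distances and would bias `rho` upward severalfold. The fit is
weighted least squares of

    E[r^2](d) = (10 + C) / (22 + 13 C + C^2) + 1/n,   C = rho_bp * d,

with `n` the effective number of chromosomes behind each estimate; it is
exactly self-consistent on noise-free curves. The bin bootstrap gives a
fit-level CI; for simulation recovery the tests use a window-block
bootstrap, since pairs within a window share genealogy.

The chain `Ne = theta / (4 mu)` (default `mu = 2.8e-9` per bp per gamete
per generation, the Drosophila point estimate), `r = rho / (4 Ne)`,
`map = r x genome x 100 cM`, and — when a fraction `f` of the population
is a non-recombining heterogametic class —
`recombining-class map = sex-averaged map / (1 - f)` (default `f = 0.8`
amphigenics) completes the recombination analysis.

## Pooled F_ST and IBD (differentiation)

Identity-probability estimator for pool-seq: within-pool identity `Q1` is
recovered from the identity of two distinct reads after removing the
`1/n` chance they resample one chromosome; between-pool identity `Q2` is
the cross-pool read product. `F_ST = (Q1bar - Q2bar) / (1 - Q2bar)`,
aggregated across SNPs as a ratio of sums — unbiased under variable depth
and invariant to duplicating the SNP set; the mean-of-ratios alternative
is kept only as a contrast. A pool tested against an independent
re-sequencing of itself centers on zero up to an O(1/n) term (reads of
the two libraries share chromosomes, which `Q2` rightly does not correct
between genuinely distinct pools).

Isolation by distance is OLS of pairwise F_ST on great-circle (haversine,
6,371-km sphere) distance in km, with an option to drop one population
(for a geographic outlier) from all pairs.

## Covariance-corrected scan (covariance_scan)

Standardized deviations `z = (p - pibar) / sqrt(pibar (1 - pibar))` (depth-
weighted mean across pools; fixed sites skipped) over putatively neutral
SNPs — the 4-fold degenerate set — give the moment estimate
`Omega = (1/S) sum z z^T`, ridge-regularized to PD only if needed (delta
recorded). Greedy basepair thinning (e.g. 100 kb) is available as an
LD-robustness check, with `matrix_correlation` (Pearson over the upper
triangle including the diagonal) to compare the results.

Per-SNP differentiation is `XtX = z^T Omega^{-1} z`, chi-square with
`npop` degrees of freedom under the exact null `z ~ MVN(0, Omega)`. In
practice `z` uses a data-estimated mean frequency, which removes roughly
one degree of freedom and shrinks the genome-wide mean slightly below
`npop`; with a moment-estimated `Omega` from the same SNPs the mean is
`npop` by construction. Covariate association is the closed-form
conjugate-normal Bayes factor after whitening by the Cholesky factor of
`Omega`:

    BF = (1 + v x^T x)^{-1/2} exp( v (x^T y)^2 / (2 (1 + v x^T x)) )

with `y = L^{-1} z`, `x = L^{-1} c`, prior effect variance `v = 1` on
standardized scales. Populations missing a covariate are dropped from `z`
and `Omega` for that scan; covariates observed in fewer than 3
populations are dropped outright. These are deterministic analogs of the
MCMC machinery usually used for such scans: same model, no
posterior-sampling treatment of binomial read noise, in exchange for
reproducibility and analytic nulls — they will not reproduce an MCMC
tool's numbers SNP-for-SNP. Highly correlated covariates are collapsed by
single linkage on `|r| >= 0.8` (a judgment call; the threshold is a
parameter), the first member representing each group, and one 0/1 dummy
per population is appended so population-specific scans can run through
the same interface. The decision preset for "significant" BF tracks is
deliberately extreme (1e20), reflecting how heavy-tailed these tracks
are; it is a config value, not a hard-coded rule.

## Region calling (region_caller)

Two-state Gaussian HMM over the SNP-ordered statistic track, one contig
at a time; steps are SNP-ordinal, so inter-SNP basepair distance does not
enter the transition model (a documented simplification — sparse and
dense stretches are treated alike). Transition probability 0.001 per step
both ways (stationary initial distribution is then uniform), Viterbi in
log space, ties broken toward background (conservative). Emission
presets: background N(20, 9) vs differentiated N(100, 200) for XtX-like
tracks; N(0.24, 0.36) vs N(0.8, 1.6) for F_ST-like tracks. Emissions can
instead be fitted by Baum–Welch with transitions held fixed, initialized
from a 95th-percentile split (background below); the log-likelihood trace
is monotone and degenerate fits fall back to the preset with a warning.

Runs of the differentiated state become intervals `[first_pos,
last_pos + 1]` — width `end - start`, so a single-SNP region has width 1
— and intervals on a contig are merged when the gap between them
(next start minus previous end) is at most 100 bp. Regions are annotated
with genes whose span intersects the region ±5 kb (boundary inclusive);
a missing annotation yields null counts, distinct from zero.

## Coverage outliers and power (coverage_power)

Depth is summarized in 550-bp tiles (the average called-region size),
each population normalized to its own genome-wide mean tile coverage.
The overcoverage test Bonferroni-corrects at `n_tests = populations x
regions` (e.g. 11 x 19 = 209, per-test alpha 0.05/209; a
`paper_rounding` preset uses the 0.9997 percentile instead of the exact
division) and flags a region for a population when its mean normalized
coverage over overlapping tiles exceeds that population's empirical tail
quantile. Partially overlapping tiles count fully (a simplification that
slightly smooths region boundaries). Because the threshold is a per-tile
quantile while the region statistic is a mean over covered tiles, exact
family-wise calibration holds for single-tile regions; means over several
tiles are stochastically smaller, making multi-tile tests conservative.
Flags are invariant to rescaling any one population's raw depth.

The power analysis keeps an exact uniform subsample of `round(f x n)`
markers per replicate, re-runs the identical HMM and merging, and scores
a full-density region as recovered when any re-called region overlaps it
by >= 1 bp (no overlap fraction is imposed; single-SNP regions make any
stricter rule degenerate). Fraction 1.0 is a deterministic identical
re-run, hence exactly 100% recovery; mean recovery is monotone
non-increasing in expectation as density drops.

## Problem sizes

Test and acceptance workloads are sized for a single CPU: the headline
downsampling analysis uses a 10-Mb track (~117k SNPs, 19 spiked regions,
20 replicates); diversity calibration uses 100 independent 10-kb
coalescent windows at theta 0.005 with 200-chromosome pools at 70x; the
F_ST calibration uses 4,000 Balding–Nichols SNPs across 11 pools; LD
recovery uses 20 five-kb windows of a 200-chromosome deme; the
family-wise-error check uses 20,000 tiles x 11 populations x 300
replicates. These are the package's chosen reference conditions; scaling
any of them up changes only Monte-Carlo precision.

## Known limitations

- The scan statistics are moment/closed-form analogs, not MCMC
  posteriors; they inherit the Gaussian allele-frequency approximation
  and ignore binomial read noise in `z` beyond depth weighting.
- `rho` from short-range LD extrapolates poorly to long-range maps; the
  map-length chain inherits every upstream uncertainty multiplicatively.
- The HMM ignores physical inter-SNP distance and supports exactly two
  states; no per-region significance is attached to calls.
- The generator's truncated-Gaussian frequencies misbehave for ancestral
  frequencies near 0/1 (variance loss), which is why neutral-SNP moment
  checks condition away from the boundary.
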