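# Methods

`lofsel` estimates the fitness cost of losing one copy of a gene — the
heterozygous selection coefficient hs — from the aggregate frequency of
loss-of-function (LOF) alleles in a large population sample, and builds
distributions of fitness effects (DFEs) over sets of LOF mutations from the
per-gene posteriors. This note records the model, the numerical choices, and
what the synthetic-data experiments do and do not establish.

## Model

A gene is a single non-recombining biallelic locus in a panmictic diploid
Wright-Fisher population. Forward mutation to the LOF class occurs at a
per-gene rate μ per transmission, only on backgrounds free of other LOF
variants; back mutation occurs at 0.01μ. Genotype fitnesses are 1, 1−hs and
1−s (wildtype, heterozygote, homozygote); compound heterozygotes are
implicitly treated as homozygotes because all LOF alleles in a gene are
assumed equivalent. Each generation applies, in order: selection on parents
(fertility selection), mutation in transmission, and binomial resampling of
2N allele copies at the next generation's diploid size N. The model is not
meant for fully recessive genes (2Nhs ≪ 1 with 2Ns ≫ 1), where the
aggregate frequency carries little information about hs.

On the non-PAR X chromosome the two sexes are tracked separately (fixed sex
ratio 0.5, no sex difference in demography or reproductive variance).
Females carry genotype fitnesses 1, 1−hs, 1−s; hemizygous males 1, 1−s.
Sex-specific mutation rates derive from the sex-averaged rate μ and the
male-to-female ratio α (default 3.5): μ_m = 3μα/(2+α), μ_f = 3μ/(2+α),
so 2μ_f + μ_m = 3μ for every α — the male bias redistributes but never
changes the total X-linked mutational input. By default, mutation is applied
to transmitted gametes, so a new paternal-germline mutation is first exposed
to selection as a heterozygous daughter and a maternal-germline mutation
mostly as a hemizygous son — the viability-selection approximation. The
alternative (`x_parental_mutation=True`) mutates parents before selection,
reproducing a strict fertility-selection reading; the two differ only at
order μ·s per generation, and a simulation test confirms the difference is
below Monte-Carlo noise at default parameters.

### Demography

Histories are piecewise-constant diploid sizes indexed in generations before
present, preceded by a 10N-generation burn-in (N = 14,448 by default) so the
population enters the epoch era at mutation-selection-drift equilibrium.
Selection acts during burn-in by default (`burnin_with_selection=True`);
a flag disables it for comparison. The packaged European model keeps the
ancestral size 14,448 until 124 generations before present, then N_e =
613,285 ("standard"); the "modified" variant replaces the last 50
generations with N_e = 5,000,000. These are the documented sizes of the
underlying published history; its intermediate epochs are not reproduced —
exploratory runs showed that inserting plausible bottleneck-shaped
intermediate epochs degrades the model's agreement with the documented
neutral frequency-spectrum behaviour (see "Demography calibration" below),
so the default table deliberately contains only the documented values.
Any analysis accepts a user-supplied epoch table (TSV: start_gen, end_gen,
size) instead.

### Simulation engine

The simulator operates on allele counts, not individuals: with one
biallelic locus the count is a sufficient state, the per-generation update
is one binomial draw (a multinomial over female genotypes plus a binomial
for males on the X), and the chain is exact for the stated model. While the
locus is monomorphic only mutation can move it, so the waiting time to the
next polymorphic state is geometric; the kernels draw that waiting time
directly and jump, which accelerates the long burn-in by one to two orders
of magnitude without any approximation. Population size changes resample
the standing count binomially at the new size. The final sample of 2n
chromosomes is drawn binomially from the final population frequency
(sex-stratified 2:1 female:male on the X when individual sex counts are not
given). Kernels are numba-compiled and deterministic given a seed.

## Inference

Priors: h ~ U(0,1) and log10 s ~ U(−6,0), independent. Only hs is
identifiable from autosomal data; sampling h and s separately keeps the same
hs prior on autosomes and the X, where s enters on its own through males.
Closed forms under this prior: P(hs > t) = (−log10 t − (1−t)/ln 10)/6, so
P(hs > 1%) ≈ 26% and the prior median hs ≈ 3.7×10⁻⁴ (0.04%).

The ABC-SMC sampler accumulates, at each tolerance ε of the schedule
[10/2n, 5/2n, 2/2n, 0], a fixed number of particles (default 50,000) whose
simulated sample frequency q_i satisfies |q_i − q| ≤ ε. Stage 0 proposes
from the prior; later stages resample the previous particles by weight and
perturb with a component-wise uniform kernel on (log10 s, h) of width half
the previous particle range, reflecting at the prior bounds; importance
weights are prior density over the kernel mixture. ε = 0 means exact
equality of sampled allele counts, so an off-grid observed frequency is
snapped to the nearest count/2n with a logged warning.

Two implementation details matter:

- On autosomes/PAR the terminal sampling stage is integrated out
  analytically: the sample count given the final population frequency q_pop
  is Binomial(2n, q_pop), so a proposal is accepted with probability
  P(|count − c_obs| ≤ band | q_pop)/M, with M the maximum of that
  probability over q_pop. This targets exactly the same posterior as
  simulating the count, but keeps acceptance workable when the observed
  count is large. The plain rejection-ABC implementation retains literal
  count simulation, and a test verifies the two posteriors are
  indistinguishable (two-sample KS), which also validates the analytic
  kernel. On the X the count is a sum of two binomials and is simulated
  literally.
- Acceptance counts, the ε schedule, and the burn-in length are all
  configurable so that desk-scale runs (hundreds of acceptances, shortened
  schedules) remain exact samplers of their stated targets.

Summaries: the MAP is the mode of a weighted Gaussian KDE (Silverman
bandwidth) of log10(hs) evaluated on a 512-point grid over the prior
support, clipped into the credible interval; the 95% CI is the weighted
2.5/97.5 percentile of hs; exceedance probabilities are weighted particle
fractions. X-linked genes additionally report the sex-averaged cost
(hs + s)/2 of losing one copy in a random carrier.

### Neutral screen

Genes whose observed LOF frequency is at or above the 90th percentile
(order statistic of rank ceil(0.9·reps), ties flagging) of their own
neutral (hs = 0) simulated distribution are flagged as model-misspecified
(mutation-rate error, balancing selection, annotation error) and excluded
from inference. By construction ~10% of truly neutral genes are flagged;
the discreteness of the count grid can push the realized rate slightly
above 10% because the comparison is inclusive.

## DFEs and cohort comparisons

A DFE is the mixture of per-gene hs posteriors weighted by each gene's
share of a mutation set: mutational opportunities for the genome-wide DFE,
observed counts for a cohort. Exceedance probabilities P(hs > t) are always
computed from pooled weighted particles; the KDE is used for display only.
A cohort is tested against chance by drawing B (default 1000) null cohorts
of the same size from the opportunity weights and ranking the observed
cohort-DFE mean hs among the null means; p = r/(B+1) with r the rank from
the top, never 0. Two DFEs are compared by bootstrapping B (default 500)
mutation-resamples of each, computing the posterior mass in (0.1, 1] (open
at 0.1) per resample, and applying a two-sample Kolmogorov-Smirnov test to
the two sets of areas. The mean used by the rank test is the mean of hs
(not of log10 hs), configurable in principle but fixed here. The causal
probability of a strongly deleterious de-novo mutation in an enriched
cohort is 1 − p_pop/p_cohort; carrier rates follow from the per-person DNM
count, the fraction of DNMs that are LOF, and the deleterious fraction of
the DFE.

## Allele ages

Ages of alleles segregating at present are simulated with at most one
mutation in the locus at a time: while the locus is monomorphic wildtype, a
single-copy mutation arises with probability min(1, 2Nμ) per generation
(μ = 10⁻⁶ by default, a typical per-gene LOF rate); no recurrent or back
mutation acts while it segregates; fixation is absorbing and discarded.
Conditional on 0 < count < 2N at present, the age is the number of
generations since the locus was last invariant, so a newly arisen allele
has age 1. Deterministic injection of one mutation per invariant generation
was considered and rejected: it overweights young alleles relative to the
mutational process and roughly doubles the median age at hs = 1% under the
modified model by saturating arrivals in the large recent epochs. For
hs ≥ 10⁻³ the run starts 5,000 generations before present (surviving
excursions at that strength are far shorter); `window=0` forces the full
history. Under the modified European model the median age is ~60
generations at hs = 1% and ~3 at hs = 10% — strongly selected variants seen
segregating today are almost always new.

## Demography calibration

The singleton fraction among segregating neutral sites (per-site rate
3.8×10⁻⁹, the non-CpG transversion rate; 113,710 sampled chromosomes)
summarizes how well the recent demography reproduces the rare-variant-heavy
spectrum of large exome samples. With 4×10⁵ forward replicates the packaged
modified model yields ≈ 0.65 and the standard model ≈ 0.38 (asymptotically
0.648 and 0.382 at 10⁶ replicates). An independent coalescent computation
(msprime branch-length frequency spectra on the same epoch tables) agrees
with the forward simulator for small sample fractions and slightly
overestimates the singleton fraction when ~9% of the population is sampled,
where the forward simulator is the more faithful computation.

## Synthetic data

The generator draws per-gene rates (log-normal, median 10⁻⁶, σ = 1 on the
natural-log scale), true (h, s) (from the prior or an explicit list), and
opportunity counts (proportional to μ at one opportunity per 2×10⁻⁹ of
rate, with Poisson noise), then produces observed frequencies by running
the same forward simulator used in inference. DNM cohorts mix a causal
component (genes with true hs above a cutoff, drawn by opportunity) with an
opportunity-weighted background. Truth tables are returned separately and
never enter panel files. What passing recovery tests show is therefore
internal calibration — the inference machinery inverts its own generative
model at realistic parameter scales; they do not certify robustness to
mutation-rate misspecification, annotation error, population structure, or
frequency-dependent selection in real exome data.

### Problem sizes in the shipped tests

The recovery experiment uses 50 genes with true hs log-spaced over
[10⁻⁴, 0.3] (h = 0.5), μ = 10⁻⁵ per gene (the high end of real per-gene
LOF rates, keeping allele counts informative at this sample size), a
scaled demography (ancestral N = 3,000 with a 10,000-generation burn-in,
growth to 100,000 then 10⁶ over the last 174 generations), 15,000 sampled
chromosomes, 120 acceptances per gene and a two-stage tolerance schedule
[10/2n, 0]. Under these conditions the 95% CI covers the true hs for about
95% of genes (within binomial noise) and the Spearman rank correlation
between true and MAP hs exceeds 0.8. Weakly selected genes whose observed counts drift into the hundreds
dominate the runtime; the analytic sampling kernel keeps them tractable.
Other stochastic tests use constant-size models of N = 1,000-20,000 with
short epochs, sized so that three-Monte-Carlo-SE assertions are sharp.

## Known limitations

- The intermediate epochs of the European history are deliberately absent
  from the packaged table; analyses sensitive to variation older than ~124
  generations should supply a full epoch table.
- hs is fixed through time and across carriers; changing environments and
  variable penetrance are outside the model.
- The X implementation assumes equal sex ratios and equal reproductive
  variance; dosage compensation enters only through the interpretation of h.
- Exact-count matching (ε = 0) against a single aggregate frequency is the
  paper-faithful distance but is expensive for weakly selected genes in
  very large samples; the analytic kernel mitigates, not removes, this.
- Posterior tails near s = 1 are prior-limited: dominant-lethal genes are
  hard to distinguish from hs ≈ 0.3-0.5 with frequency data alone.
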