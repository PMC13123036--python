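# Methods

`upcycle` simulates a closed pig nucleus under genomic selection in which a
fixed share of the sow capacity is diverted to "upcycling" layers: archived
boars chosen as *diversity donors* are mated to elite sows, and their
descendants are backcrossed toward elite performance over up to four layers
before competing for elite selection.  This note records the model, the
parameters that matter, and the design choices made where the underlying
program design was open.

## Genome and trait model

The genome has `n_chromosomes` (default 18) autosomes of `chrom_length_cm`
(default 100 cM) each.  Loci (default 65,000) are placed uniformly at
random and sorted; `n_qtl` (default 6,000) loci are flagged as purely
additive QTL, and the genotyping chip (default 20,000 SNPs) consists of the
non-QTL loci with the highest founder minor allele frequency — the usual
commercial-array ascertainment — with MAF ties broken by locus index so
chip construction is deterministic.

QTL effects are i.i.d. standard normal; each effect is stored for the
*beneficial* allele (the trait-increasing direction), so all stored effects
are non-negative and the true breeding value is the beneficial-allele dose
times the effect, summed over QTL.  The residual variance is solved from
the realised base-generation TBV variance so that heritability is exactly
`h2` (default 0.3) at the base: `sigma2_e = Var(TBV) (1-h2)/h2`.

Meiosis follows a Poisson crossover process without interference
(Haldane), no sex-specific maps.  The batched engine uses the equivalent
marker-transmission Markov chain (switch probability `(1-exp(-2d))/2` per
marker interval), which has exactly the same marker-level transmission law
as explicit crossover sampling; the two implementations are cross-checked
in the tests.  Every haplotype carries per-locus founder labels, so
identity-by-descent relative to the founder generation is known exactly —
this is what the "true kinship" metrics use.

## Founder history

Founders are produced by a neutral Wright–Fisher history: per-locus initial
allele frequencies are drawn uniformly from `init_freq` and a population of
`history_ne` diploids mates at random for `history_generations`
generations, creating a drift-shaped frequency spectrum and
recombination-limited LD.  The defaults (U(0.13, 0.87), Ne 175, 30
generations) were calibrated once so that, at the reduced scale used for
desk runs, about 5–6% of QTL are fixed for the unfavourable allele by the
end of burn-in; they are configuration knobs, not fitted quantities.  This
generator reproduces the *summary* behaviour a realistic founder
population needs here (allele-frequency spectrum, LD decay over cM,
initial beneficial-allele loss); it does not model mutation,
population-size history, or sequence-level ascertainment, so absolute
LD levels and rare-variant tails of real pig populations are out of its
scope — conclusions from desk runs are about program *comparisons*, not
absolute diversity levels.

## Breeding program

Each generation, 400 sows (desk scale: 100) produce litters of 6; every
sow is inseminated by a single boar.  Ten burn-in generations select
`burnin_sires` males (40; desk 10) and all sows by GEBV truncation with
random mating.  Generation 0 denotes the last burn-in cohort; scenario
generations are 1..T.

Post burn-in, the selection order within a generation is: elite dams
(GEBV), elite sires (OCS), layer-1 dams (next-best GEBV), then layer dams
from the highest layer down (layer 4 by GEBV from layer-1–3-born females;
layers 3 and 2 by the strategy's diversity criterion, layer 3 ignoring
layer-1-born females), and donors last.  Criterion-based choices use as
reference everything already selected that generation, so donors avoid
genetics that already contribute.  When an eligibility pool runs short
(e.g. no layer-born females exist yet in generation 0), the shortfall is
filled with the next-best remaining females and logged.  The 13 strategies
(donor counts 3/10/25 per criterion, the 3-layer/2-layer reductions, the
8+4+5 mixed scheme, and the control) are encoded as data and scale
proportionally to the configured sow count.

Donors are boars selected as elite sires within the last 10 generations
(5 for the rare-beneficial part of the mixed strategy); each donor
inseminates exactly one layer-1 sow.  Layer-2–4 sows are served by the
OCS-selected elite boars, sampled in proportion to their optimised
contributions, and these matings count against the dose cap.

## Genomic evaluation

Breeding values come from single-trait GBLUP (`y = 1 mu + g + e`,
`Var(g) = G sigma2_g`) with a method-1 VanRaden GRM.  The training window
is the current plus previous five generations, all with own phenotypes;
reference allele frequencies for centring are the observed training
frequencies.  Marker effects are obtained by backsolving the animal
solutions and provide indirect predictions for archived boars outside the
window.  Internally the closed loop solves the model in marker dimension
via the Woodbury identity with per-cohort cached cross-products —
algebraically identical to the animal-model solve (tested), but linear
instead of cubic in the training size.

Variance components are re-estimated every 3 generations by REML
(eigendecomposition profile likelihood, the rrBLUP-style parametrisation)
on a random sample of 3,000 animals (desk 750) from the current and last
three elite generations, using that sample's allele frequencies for its
GRM; estimates are frozen between updates.  Three different reference-
frequency policies therefore co-exist deliberately (training population
for GBLUP, VCE sample for variance components, old elite frequencies for
OCS), mirroring the relationship-definition inconsistencies of practical
programs.

Numerical choices: reference frequencies are clamped to [0.001, 0.999];
loci monomorphic in the reference are zeroed outright so they carry no
effect; a 1e-8 ridge stabilises every GRM solve; REML is bounded away from
the h2 = 0/1 edges by 1e-6.

## Optimum contribution selection

Sire contributions maximise `c'g` subject to the expected offspring mean
kinship `x'Kx <= f + (1-f) * 0.01` (kinship = half the VanRaden GRM built
with elite allele frequencies from 5 generations earlier, or the oldest
available), fixed equal dam shares summing to 0.5, a 30-dose cap (desk 8)
and a sum-to-0.5 equality.  The current mean kinship `f` is the mean of K
over the candidate-and-dam set, and the constraint is applied to the
expected offspring cohort, consistent with the one-generation kinship
recursion.  The solver is an exact active-set method: on the current free
set the KKT conditions confine the solution to a line in the Lagrange
parameter, along which the quadratic constraint is a scalar quadratic
solved in closed form; box violators are clamped, multipliers are checked
for release, and a final bisection toward the kinship-minimising feasible
point guarantees the bound to 1e-6.  Boars whose optimised contribution is
below one mating are iteratively fixed to zero and the problem re-solved.
If the bound is unattainable the kinship-minimising feasible vector is
returned and flagged (`infeasible-relaxed`) so the program proceeds rather
than aborting.  Contributions become matings by largest-remainder rounding
followed by a seeded dam shuffle.

## Diversity criteria

*Rare beneficial haplotypes*: chromosomes are split into windows of 44
chip SNPs (about 4 cM at default densities) advancing by 20% of the window
(9 SNPs); a trailing partial window is kept if it covers at least half a
window, otherwise merged into the previous one.  A haplotype's window
value is the sum of backsolved SNP effects times alleles; donors are
selected greedily to maximise the summed per-window maximum, the winner's
haplotypes joining the reference each round.

*Rare (unique) haplotypes*: chromosomes are tiled with half-open 1 cM
segments; a segment's diversity is the number of distinct allele strings
among the haplotypes.  Donor selection greedily maximises added distinct
strings; the operational criterion uses chip loci, while the reported
elite-population count is also computed on all loci.

*Low average kinship*: segment-based IBD kinship — the genome fraction (in
cM, averaged over the four haplotype pairs) covered by maximal runs of
literally identical alleles of at least 4 cM **and** at least 20
consecutive SNPs; runs may span monomorphic stretches.  Donors are the
candidates with the lowest mean kinship to the reference.  The run scan is
a numba kernel with an equivalent vectorised numpy fallback; both paths
are compared in the tests.

## Reported statistics

Per generation, on the elite-born cohort only: mean TBV (reported in gSD —
the square root of generation-0 genic variance — with generation 0 centred
to zero), genic variance `sum 2 p (1-p) alpha^2`, founder-IBD mean kinship
(computed from per-locus founder-label frequency spectra, identical to
averaging the pairwise matrix), the selection limit (2 alpha summed over
QTL whose beneficial allele survives), unique-haplotype counts (all-loci
and chip), the share of beneficial alleles lost, and selected-animal
counts by origin.  Conversion efficiencies divide the cumulative gain by
the diversity lost over the same span, from unrounded accumulators.
Scenario contrasts use paired t-tests on seed-matched replicates.  Donor
ancestry is traced up to 10 generations with donor-terminated paths
contributing `2^-length`.

The per-generation haplotype/kinship diversity metrics are recorded from
generation 0 onward by default (`full_metrics_from`); burn-in rows carry
the cheap statistics only.

## Scales

`SimConfig.full()` reproduces the program sizes above.  `SimConfig.desk()`
is the reduced configuration used by the test suite and worked examples:
100 dams, 5,000 loci, 1,000 QTL, 1,500-SNP chip, 10 burn-in sires, dose
cap 8, VCE sample 750 — all program sizes scaled by the dam ratio or the
locus ratio.  Donor counts scale the same way (3/10/25 become 1/3/6).
Because the desk population is smaller, absolute drift and inbreeding
rates exceed the full-scale program's; desk runs are therefore read
directionally (scenario versus scenario), and the packaged comparisons are
the control versus the low-kinship upcycling programs at three resource
shares over 10 post-burn-in generations with 10 seed-paired replicates
sharing burn-in.

## Randomness

All randomness derives from one master seed per replicate through named
substreams (map, history, effects, per-generation breeding/mating/VCE
streams), so adding a consumer never perturbs existing draws, identical
seeds give identical runs, and scenario comparisons are exactly paired
through burn-in.

## Known limitations

Discrete generations; single trait; no mutation, no sex chromosomes, no
non-additive gene action; no mate-allocation optimisation; donor semen is
assumed unlimited within one-sow-per-donor; the OCS mean-kinship reference
set is the candidate-and-dam set rather than the whole cohort.  The
worked single-locus retention formula `[(1-(1-p)^(2Ne))^g]^L` is exposed
as printed; note that evaluating it at p = 0.05, Ne = 50, 10 generations
and 45 loci yields about 0.069, not the round 10% sometimes quoted for
that example — the formula, not the rounded prose value, is implemented.
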