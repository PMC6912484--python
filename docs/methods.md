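# Methods

This note documents the statistical machinery, the conventions chosen
where the literature leaves room, and what the synthetic pedigrees do
and do not emulate.

## Pedigree model

A pedigree is a closed, acyclic table of animals with optional sire/dam
links, sex and birth year. *Closed* means every referenced parent id has
a record: ids that appear only in a parent column are appended as
phantom founders (unknown sex and year). Phantom parents count as known
parents of their offspring but as founders for every ancestry-based
statistic — consistent with the definition of a founder as an animal
with both parents unknown. Animals with exactly one known parent are
not founders; their unrecorded half-genome is tracked as
*pseudo-founder* mass (below). Missing parents are accepted on input as
`""`, `"0"`, `"NA"` (and similar) and written as `"0"`.

Topological ordering (parents before offspring) underlies every
recursion. Ties are broken deterministically by ascending birth year
(unknown years last) then id, so row order never affects any result;
cycles — including self-parenting — are reported by `validate()` and
refuse analysis. Birth dates, when given as full dates, become decimal
years (year + day-of-year/365.25), preserving the sub-year precision
generation intervals need.

## Completeness

For animal *i* and depth *n*, each of the `2^n` ancestor slots is known
or unknown; an ancestor reached via several paths fills several slots.

* `equiGen = Σ_slots (1/2)^n` — each known ancestor weighted by its
  expected genomic contribution; computed by the recursion
  `equi(i) = ½(1 + equi(sire)) + ½(1 + equi(dam))` with missing parents
  contributing 0, which the tests verify equals the explicit slot sum.
* `maxGen` — longest known ancestral path; `fullGen` — deepest
  generation with *all* slots known. `fullGen ≤ equiGen ≤ maxGen`
  always.
* `PCI = 4·Cs·Cd/(Cs+Cd)` over a horizon of `d` generations
  (default 5), with `C_line = (1/d)·Σ_{i≤d} g_i` and `g_i` the known
  proportion of generation *i*. Each generation's proportion is taken
  over all `2^i` slots, so one line contributes at most 0.5 and the
  harmonic-mean form is bounded by 1; under the alternative per-line
  normalization the index could reach 2. `PCI = 0` whenever either
  parental line is entirely unknown, which is exactly its purpose:
  flagging animals whose inbreeding cannot be estimated.
* Pedigree content reports the mean known proportion per generation
  1..5, overall (`2^k` slots) and per line (`2^(k−1)` slots). Breed-level
  `P_CONT` is the first-generation overall content over **all** animals;
  over a both-parents-known reference it would be identically 100%.

## Inbreeding and relatedness

`F_i` is the probability that the two alleles of animal *i* at a locus
are identical by descent. It is computed by the ancestral-path
(Meuwissen–Luo-style) recursion on the factorization `A = T D T'` of
the additive relationship matrix: tracing the gene-flow row `L_i`
upward with weights halved per link gives `a_ii = Σ_j L_ij² D_j`, where
`D_j` is the Mendelian sampling variance (`½ − ¼(F_s + F_d)` with both
parents known, `¾ − ¼F_p` with one, 1 for founders), and
`F_i = a_ii − 1`. No matrix is materialized; animals sharing a
(sire, dam) pair share the computation, so pedigrees of hundreds of
thousands of animals are feasible. A dense tabular `A` (bounded at
2 000 animals by default) serves as the independent oracle; the suite
checks agreement below 1e-10 on 50 random simulated pedigrees.

`AR_i` is half the mean of row *i* of `A`: the probability that an
allele drawn at random from the population (itself included) descends
from *i*. It is computed in two linear passes — descendant totals
`v = T'1` by a reverse sweep, then row sums `s = T(Dv)` forward — and
reported as a percentage. The probability scale means a lone founder
has AR 50% and founders in a large unrelated population approach
`1/(2N)`; the alternative convention (the full row mean) would double
every value.

TMI ("true mean inbreeding") averages `F` over animals with
`fullGen ≥ 3` (strict), limiting the downward bias of shallow records;
on incomplete pedigrees TMI ≥ mean F, which the suite reproduces on
heavily missing simulated data. Per-generation trends bin animals by
`floor(equiGen)` by default (`maxGen` optional) and report the classical
`ΔF_t = (F̄_t − F̄_{t−1})/(1 − F̄_{t−1})`; bins under 5 animals are
flagged rather than dropped.

## Effective population size

The realized `Ne` comes from the unweighted OLS regression (free
intercept) of individual `F` on individual `equiGen` over the
reference population: `ΔF = b`, `Ne = 1/(2b)`. Using equivalent
generations as the time axis compensates for uneven pedigree depth.
A non-positive slope leaves `Ne` undefined (NaN) with the slope and its
standard error still reported; a constant-`equiGen` reference raises.
The reference defaults to animals with both parents known — the common
convention when none is stated — with an optional birth-year window.

## Gene-origin statistics

Founder contributions `q_k` are obtained by propagating each reference
animal's genome upward, half to each known parent; mass meeting an
unrecorded link stays with the animal holding it as pseudo-founder
mass, so `Σq = 1` under any missingness (this inflates founder counts
on shallow pedigrees — a known caveat, not a bug). `fe = 1/Σq²`.

Ancestors (founders or not) are selected greedily: each round scores
every candidate — any animal with recorded progeny — by its *marginal*
contribution, i.e. its upward arrival mass with absorption at already
selected ancestors, discounted by the fraction of its own genome the
selected set explains. Ties break by earlier birth year then id.
Selection stops when contributions are exhausted (marginal < 1e-9 or
cumulative ≥ 1) or at `max_ancestors`. `fa = 1/Σp²`; unknown-parent
mass of the reference animals themselves enters the denominator as
pseudo-ancestor contributions, mirroring the `fe` convention, so
incomplete recording cannot inflate `fa`. `ANC_50` is the count of top
ancestors whose cumulative marginal contribution reaches 0.5 (with a
1e-9 slack against float error at exactly one half).

`fe/fa` reads as a bottleneck index: 1 for balanced contributions,
larger when a few ancestors funnel the gene pool. One caveat: the
greedy marginal partition is not mathematically guaranteed to be at
least as concentrated as the founder partition, so on virtually
bottleneck-free pedigrees the ratio can dip a fraction of a percent
below 1 (0.999 observed); this is a property of the greedy algorithm,
not an error, and disappears under any real bottleneck. Truncating via
`max_ancestors` biases `fa` downward because unexplained mass falls
into the pseudo-ancestor residual.

## Demography

Generation intervals average the parent's age at progeny birth per
pathway (father–son, father–daughter, mother–son, mother–daughter; the
total pools all pairs, i.e. is progeny-weighted). The
`reproductive_progeny` measure keeps only progeny that themselves left
recorded offspring. Progeny of unknown sex belong to no pathway and
are excluded. SDs are per-pair sample SDs.

Close-relative matings are classified on distinct (sire, dam) pairs
with both parents of the progeny recorded, classes mutually exclusive
with precedence parent–offspring > full-sib > half-sib; full sibs share
both (known) parents, half sibs exactly one known parent. Pairs with
missing parentage are classified from known links only, which can only
under-count. A repeated mating counts once; the `progeny` unit weights
pairs by offspring number instead (the two interpretations of
"animals involved in matings").

Census statistics use birth-year cohorts (the only per-animal date):
`APSR = mean[(N_y/N_{y+1})·100 − 100]` over consecutive years in range
and `APSSD` the sample SD of the same terms. The ratio orientation is
implemented as printed in the source convention — a shrinking
population gives positive APSR — with an explicit `orientation="growth"`
flag for the reversed reading, since published growing-population
values appear with positive sign. Years with an empty following cohort
are skipped and counted.

## Breed-parameter PCA

The ten breed-level parameters (AVG_F, TMI, AR, Ne, fe/fa, ANC_50,
P_CONT, APSR, APSSD, GI) span four orders of magnitude, so the PCA
z-scores each column (sample SD, `ddof=1`, exposed as a flag) and
eigendecomposes the correlation matrix — a covariance PCA would load
almost everything on the largest-scale column. Percent variance is
reported over all variables (sums to 100); loadings are sign-fixed so
each vector's largest-magnitude entry is positive; GI is the total
all-progeny interval. On the bundled eight-breed table this yields
49.78% on PC1 and 75.32% on PC1+PC2.

## Synthetic pedigrees

The simulator breeds discrete generations: every offspring of
generation *g* draws parents from generation *g−1*, with two
deliberate exceptions — a planned parent–offspring mating pairs a dam
with her own sire (generation *g−2*), since under strictly discrete
generations such matings cannot exist, and imported parents are created
on the fly as new founders. Mating classes (parent–offspring, full-sib,
half-sib, random) are drawn per offspring from the configured target
rates and pairs of the requested class are sampled from the previous
cohort's sibling structure, falling back to random mating when no such
pair exists (notably in generation 1). Family sizes are Poisson per
dam; sex is Bernoulli(½); a dominant-sire option concentrates paternity.
Birth years advance from the later-born recorded parent by a
truncated-normal age draw (mean `gi_mean_years`, minimum 2 years), so
progeny always postdate both parents; generation intervals emerge from
these draws rather than from overlapping breeding. Record-missingness
erases each recorded parent link independently with the configured
probability, after the fact — erasure can only remove information and
can never create cycles. All randomness flows from a single seeded
generator; identical configs give byte-identical pedigrees.

Because generations are discrete with Poisson family sizes, the drift
of an unstructured constant-size configuration follows the idealized
expectation `Ne = 4·Nm·Nf/(Nm+Nf)` with cohort mean
`F_t ≈ 1 − (1 − 1/(2Ne))^(t−1)` — the one-generation offset being the
classical delay of populations with separate sexes, where offspring of
unrelated founders cannot be inbred. The suite verifies this over 20
seeds with Nm = Nf = 25 (Ne = 50, tested at ±30% for the regression
estimate and ±25% per cohort for the curve), sizes chosen to keep the
whole simulation battery under a few minutes.

Archetype presets reproduce the broad regimes of the motivating
populations at default scale 1: `tuscan` (~1 000 animals, 9
generations, half-sib/parent–offspring mating rates of 10%/8%, 3% link
missingness → mean PCI ≈ 0.6, mean F ≈ 5–7%), `sardinian` (~15 000
animals, 45% link missingness → mean equiGen < 2 and TMI well above
mean F), `cosmopolitan` (~8 000 animals, 25% imported-founder rate →
mean F < 0.1%). The presets are calibrated only to published
breed-level summary ranges; they do not emulate herd structure,
selection on phenotypes, overlapping generations or non-random
culling, so passing tests demonstrate correctness of the estimators
under the stated model, not fidelity to any particular herdbook.

## Numerical choices and limitations

* Recursive F/AR vs dense oracle agreement is asserted at 1e-10; the
  founder-contribution sum at 1e-9 (raising, not warning, on failure).
* The dense relationship matrix refuses pedigrees above 2 000 animals
  (configurable); it exists as an oracle, not a workhorse.
* The ΔF–Ne identity `delta_f_from_ne(ne_from_delta_f(x)) = x` is exact
  by construction.
* Published-table reproduction: the bundled eight-breed parameter
  table carries values at printed precision; quantities derived from
  them (the PCA variance split) inherit that rounding, and the PC1+PC2
  share is sensitive to it at the level of a few points.
* No genomic layer: marker-based relationship matrices, LD-based Ne
  and ancestral-inbreeding decompositions are out of scope, as are
  herd/farm spatial structure and any imputation of missing ancestry.
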