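# pedimetrics

Pedigree-based population-structure and genetic-diversity analysis for
livestock conservation genetics.

Small local breeds — the package's motivating case is Italian beef
cattle, from a few hundred animals in endangered Tuscan herdbooks to
hundreds of thousands in cosmopolitan Charolais/Limousine registers —
are monitored almost entirely through their genealogy. `pedimetrics`
turns a plain pedigree table (one row per animal: id, sire, dam, sex,
birth year) into the standard toolkit used to judge a breed's
conservation status:

* **Pedigree completeness** — equivalent complete generations
  `equiGen = Σ (1/2)^n` over known-ancestor slots, maximum and full
  generations, and the completeness index
  `PCI = 4·Cs·Cd / (Cs + Cd)` with per-line completeness
  `C = (1/d)·Σ g_i`, `g_i` the proportion of known ancestors in
  generation `i`.
* **Inbreeding and relatedness** — per-animal `F` by the
  Meuwissen–Luo ancestral-path recursion (verified against the dense
  tabular relationship matrix), true mean inbreeding (TMI) over animals
  with ≥ 3 fully recorded generations, and average relatedness `AR`
  (half the mean relationship-matrix row, on a probability scale).
* **Effective population size** — realized `Ne = 1/(2b)` where `b` is
  the OLS slope of individual `F` on individual `equiGen` over a
  reference population; `ΔF = b` per generation.
* **Gene origin** — effective number of founders `fe = 1/Σ q_k²`,
  effective number of ancestors `fa` from greedy marginal contributions,
  and `ANC_50`, the number of top ancestors explaining half of the
  reference gene pool; `fe/fa > 1` flags a bottleneck.
* **Demography** — generation intervals over the four parent–offspring
  pathways, close-relative mating rates (parent–offspring, full-sib,
  half-sib), per-generation sex ratios and census-trajectory statistics
  (APSR/APSSD).
* **Breed comparison** — a populations × parameters table fed into a
  z-scored (correlation) PCA with biplot output.

A forward-in-time simulator (`pedimetrics.simulate`) generates
pedigrees with controllable depth, size trajectory, close-mating rates
and record-missingness, including presets that emulate the three broad
population types above (`tuscan`, `sardinian`, `cosmopolitan`).

## Worked example

```python
from pedimetrics import PedigreeAnalysis, make_archetype

ped = make_archetype("tuscan", scale=0.5, seed=42)   # 595 animals
res = PedigreeAnalysis(ped).fit()
print(res.summary())
```

prints

```
Pedigree population-structure analysis
======================================================
Animals: 595   founders: 34   reference: 531 (both_parents_known)

Completeness (means over all animals)
  equiGen    4.252   maxGen   4.81   fullGen   2.75   PCI  66.19%

Inbreeding and relatedness
  mean F   6.484%   TMI   9.641% (fullGen >= 3, n=329)   mean AR   4.711%

Effective population size (F on equiGen regression)
  b = 0.01125 (SE 0.00149, n=531)   Ne = 44.46   dF = 1.125%/generation

Gene origin
  fe = 14.34   fa = 14.35   fe/fa = 1.00   ANC_50 = 5

Close-relative matings (502 matings)
  parent_offspring      34    6.77%
  full_sib               0    0.00%
  half_sib              62   12.35%
...
```

Read it as a conservation report: the herd descends from 34 founders
but only ~14 effective ones, and five ancestors already explain half of
the current gene pool; inbreeding averages 6.5% (9.6% among animals
whose pedigree is deep enough to measure it reliably — TMI exceeds mean
F whenever records are incomplete); the realized effective size of ~44
is below the usual Ne = 50 alarm threshold; and more than one mating in
six involves close relatives, dominated by half-sib and sire–daughter
pairings. Every number is exposed programmatically
(`res.effective_size`, `res.gene_origin`, `res.parameter_row()`, …).

The same pipeline runs from the shell:

```sh
pedimetrics simulate --archetype tuscan --scale 0.5 --seed 42 --out sim/
pedimetrics analyze  --pedigree sim/pedigree.tsv --out results/
pedimetrics pca      --table params.tsv --out pca/
```

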