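# Methods

`surrosim` simulates a two-part pig breeding program in order to compare
dissemination strategies for elite genetics: conventional multiplication
of selected nucleus males versus a surrogate-sire strategy in which a
small number of elite donor males, identified by multi-stage testing, are
disseminated through germline-ablated surrogate sires.  All comparisons
are expressed in years' worth of genetic gain (YGG) relative to a
conventional reference program.

## Population and genome model

The nucleus is simulated by gene drop over 42 discrete, non-overlapping
generations, indexed −22…20.  Generation −22 is the founder cohort;
generations −21…0 represent historical genomic selection (burn-in) and
generations 1…20 the future phase in which strategies are compared.  One
nucleus generation equals one calendar year.

Founders draw chromosome haplotypes (with replacement, independently per
chromosome) from a panel of 400 base haplotypes.  The genome has 10
chromosomes of 1 Morgan each.  Panel alleles are biallelic (0/1): each
locus receives an allele frequency from a configurable spectrum —
`neutral-sfs` (density ∝ 1/x on the grid i/n, the default), `uniform`, or
`beta(a,b)` — and haplotype alleles are independent Bernoulli draws at
that frequency; loci that come out monomorphic are redrawn.  This is a
deliberately simple stand-in for coalescent-simulated haplotypes: it
reproduces a realistic U-shaped frequency spectrum but carries no base
linkage disequilibrium between panel loci.  Phased haplotype panels
produced by other simulators can be imported instead (0/1 matrix with a
genetic-map file, or phased VCF at 1 cM/Mb).

Meiosis follows a count-location model without interference: the number
of crossovers per chromosome is Poisson with mean equal to the map length
in Morgans, crossover positions are i.i.d. uniform, and the starting
strand is chosen at random.  Internally, gametes for whole cohorts are
formed in one vectorised pass (crossovers are scattered into locus bins
and the strand at each locus is the parity of the cumulative crossover
count).

## Quantitative trait

The trait is purely additive.  At full scale, 1,000 causal loci per
chromosome (10,000 total) are sampled uniformly without replacement;
allele-substitution effects are i.i.d. Normal with standard deviation
1/√n_causal (0.01 at 10,000 causal loci).  The true breeding value (TBV)
of an animal is the sum of effects times its count of the "1" allele.  No
phenotypes are simulated.

Reported merit is standardized by the *base scale* — the mean and
standard deviation (n−1 denominator) of TBVs in the founder cohort,
frozen at generation −22.

## Testing and selection

Breeding-value estimation is never modelled explicitly.  A test with
accuracy r (correlation between estimated and true breeding value) is
emulated as a pseudo-EBV: ebv = tbv + e with e ~ Normal(0,
σ²_A (1 − r²)/r²), where σ²_A is the TBV variance of the candidate group,
so the expected correlation within that group is r.  Progeny tests with n
progeny get the classical sire-model accuracy r = √(n / (n + (4 − h²)/h²))
with h² = 0.25 by default.

Each generation, the 50 best males by a fresh genomic pseudo-EBV (at
accuracy 0.5, 0.7, or 0.9) and all females are selected as parents.
Every female is mated once to a sire drawn uniformly at random from the
selected males and contributes cohort_size / n_females offspring; sexes
alternate so every cohort is exactly half male.  Cohort sizes are 1,000
(small program) or 5,000 (big program).

## Dissemination strategies

**Conventional multiplication** takes the top 50, 200, or 500 nucleus
males per generation (ranked by an independent genomic pseudo-EBV at the
nucleus accuracy).  Their mean TBV passes through two rounds of
multiplication (lag 3.5 years) and is diluted by the lagged, unselected
females of the multiplier layer:

    diluted(t) = 0.5·a(t) + 0.5·Σᵢ wᵢ·a(t − i),   w = (0.5, 0.25, …, 0.015625)

The weights — the relationship between a commercial sire and his maternal
male ancestor i generations back — are applied exactly as printed; they
sum to 0.984375 and are not renormalised.  Because the leftover 0.0078125
multiplies absolute merit, the recursion's year-equivalent depends on the
merit origin; we apply it to merit expressed as deviation from the
generation-0 nucleus mean (the point at which the multiplier pyramid is
anchored), which makes the steady-state extra lag ≈ 1.05 years,
consistent with an analysis that anchors merit at the start of the
comparison program rather than at the founder generation.

**Surrogate sires** identify one or five elite donors per male cohort by
multi-stage testing under a fixed budget of 14,000 test progeny:
a genomic screen (S0) followed by one progeny test (S1; two-stage, lag
3.5 years) or two (S1 + S2; three-stage, lag 4.5 years).  Each stage is
ranked on its own test alone.  The donors' own mean TBV reaches the
commercial layer undiluted.  Stage allocations follow the study grid
(two-stage: 14×1000 … 448×31; three-stage: S1 budgets 2,000/4,000/6,000
across 100/200/400 candidates, S2 with 10 or 20 candidates and the
complementary budget).  Progeny-per-candidate counts are whole animals,
so the two printed cells 224×63 and 448×31 deviate from the exact budget
by the rounding of 62.5 and 31.25.

## Years' worth of genetic gain

A strategy's commercial-sire merit at comparison year t is converted to
years by inverting the reference trajectory (conventional top-50): YGG is
the mean of t*(merit) − t over the window of source generations 11–20,
where t* is found by linear interpolation on the reference (linear
extrapolation with the reference's fitted slope beyond its observed
range).  Sampled reference trajectories are first made non-decreasing by
a pool-adjacent-violators fit (a minimal perturbation that removes
Monte-Carlo downticks which would otherwise break the inversion).

Replicates are paired: within each replicate, every scenario is evaluated
against the same nucleus run and the same reference, so scenario
contrasts share Monte-Carlo noise and their standard errors are small.

## Numerical and scaling choices

* **Desk-scale profile** (default, `reduced`): 200 loci per chromosome,
  all causal, 20 replicates.  The `full` profile uses 1,000 loci per
  chromosome and 100 replicates.  Headline statistics are means over
  replicates with standard errors from the replicate spread.
* RNG streams are `numpy` Philox/PCG streams keyed as
  `default_rng([seed, size_index, accuracy_index, replicate, scenario_stream])`,
  making every unit of work independently reproducible and experiments
  resumable per replicate with byte-identical outputs.
* TBVs are computed as an int8 dose matrix times a float64 effect vector;
  meiosis and dose arithmetic stay in int8 throughout.

## Limitations

* Founder haplotypes carry no ancestral linkage disequilibrium and the
  base population is unstructured; absolute gain rates at reduced locus
  counts differ slightly from a coalescent-founded genome.
* Progeny tests are reduced to an accuracy value; the 14,000 test progeny
  and all multiplier-layer animals are never simulated as genomes.
* The trait is strictly additive with equal-variance effects; no
  dominance, epistasis, or genotype-by-environment structure.
* Selection uses independent pseudo-EBV draws per test; information is
  not accumulated across stages or generations as a BLUP evaluation
  would.
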