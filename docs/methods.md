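# Methods

This note records the statistical model, the simulation design, the
numerical conventions, and the open design choices behind `triadpc`, at
the level of detail a user would need to audit or extend the package.

## The test statistics

For a biallelic marker, `M`, `F`, `C` count a chosen allele in mother,
father and affected child. The two contrasts `X = 2C − F − M` (child
versus the "complement" carrying the non-transmitted parental alleles) and
`Y = M − F` (mother versus father) are centered under, respectively, no
association and no maternally mediated effect; `Y` requires mating
symmetry (exchangeability of spouse genotypes in the source population).
With `Z = (X, Y)ᵀ` and `S` the sample covariance of `Z` over the n
complete trios at a locus, the PC statistic projects `Z̄` onto the
eigenvectors `ê₁, ê₂` of `S`:

    PC = n (ζ̄₁ + ζ̄₂)² / (λ̂₁ + λ̂₂),   ζ̄ₖ = êₖᵀ Z̄.

Because the statistic sums over both components, it equals
`n ((ê₁+ê₂)ᵀ Z̄)² / trace(S)`, and under the joint null it is
asymptotically χ²₍₁₎ (the two PC means are uncorrelated with variances
`λ̂ₖ/n`). The scan statistic is `max_PC = maxₗ PC⁽ˡ⁾` over the q markers.
The comparator is `max_Z²` with per-locus `Z² = (Σd)²/Σd²`, `d = X` or
`d = Y`.

### Numerical conventions

- **Covariance denominator** n − 1. The alternative n rescales PC by a
  factor shared between observed and permuted data, so p-values are
  unaffected; n − 1 is used as the conventional sample covariance.
- **Eigenvector sign**: eigenvectors are canonicalized so the first
  nonzero component is positive. Only the *relative* sign of ê₁ and ê₂
  affects PC (flipping both negates ζ̄₁ + ζ̄₂ and leaves PC unchanged —
  the `eigen_sign` switch exposes this and the permutation p-value is
  bit-identical under either global convention). The relative-sign choice
  is a genuine convention the statistic's definition leaves open; validity
  is guaranteed because the identical convention is applied to every
  permuted dataset.
- **2×2 eigenproblem** solved in closed form (trace/determinant and
  `hypot` discriminant); when `|S_xy| ≤ 1e-10` the eigenvectors are the
  coordinate axes ordered by variance. Covariances of integer scores are
  rationals bounded away from zero well above this tolerance.
- **Degenerate loci**: `trace(S) = 0` (all scores identical and zero)
  gives PC := 0 — the locus carries no evidence but stays in the scan.
  Loci with fewer than 2 complete trios are excluded from the maximum
  (and from Z² when 0 complete trios). If no locus is usable the test
  errors out explicitly. Argmax ties break to the lowest locus index.
- **Missing data**: complete-case per locus; a (trio, locus) cell enters
  only if all three genotypes are present, so per-locus sample sizes
  differ. Masking one cell provably changes only that locus's statistic.

### Permutation inference

Under the joint null the trio labels are exchangeable two ways: the
case/complement swap negates `X`, the mother/father swap negates `Y`.
Each permutation draws both swaps independently, Bernoulli(½) per trio,
and applies them to every locus of the trio — trio-level flipping
preserves the between-marker correlation that the max statistic exploits
(cell-level flipping would destroy the implicit multiplicity correction).
The description of the procedure in the source literature names only the
case/complement swap; the parental swap is additionally required to
generate the maternal-effect half of the joint null, so both are flipped.
`p̂` counts permutation statistics *strictly* larger than the observed one
(so `p̂ = 0` is attainable); the `(b+1)/(B+1)` correction is available but
off by default. Because only sign-weighted sums `Σ±x`, `Σ±y`, `Σ±xy`
change under flips, all B permutations are computed as three matrix
products plus the closed-form eigenproblem, which is what makes the
replicated studies cheap.

## The simulator

The generator reproduces the classic candidate-region benchmark: q = 20
markers evenly spaced over 100 kb; background haplotypes from a
first-order Markov chain with per-marker allele frequencies drawn
U(0.1, 0.9) and adjacent-pair disequilibrium drawn U(−0.9, 0.9); a latent
biallelic disease locus uniform in the region with allele D at frequency
0.1, introduced on a single ancestral haplotype G generations ago; trios
ascertained on an affected child under penetrance
`baseline × f(g)` with `f = (1, R₁, R₂)` applied to the child's D-genotype
(association), the mother's (maternal effect), or multiplicatively to both
(joint). Baseline risk 0.01; dominant `R₁ = R₂ = 2`, recessive
`R₁ = 1, R₂ = 2`. The admixed population mixes two such subpopulations
(30%/70%) differing in D frequency (0.1/0.2), baseline (0.01/0.05),
mutation age (1,000/500 generations) and ancestral haplotype, with both
parents of a trio drawn from the same subpopulation.

Choices the benchmark description leaves open, fixed here once:

- **LD parameterization**: the ±0.9 adjacent-pair draws are interpreted as
  standardized D′ and converted to raw D via the Lewontin bound, so every
  draw is feasible for every frequency pair and the implied Markov
  conditionals are valid probabilities.
- **Recombination map**: 1 cM/Mb uniform (0.001 Morgans across the
  region), at most one crossover per meiosis, breakpoint uniform. A
  D-lineage therefore accumulates Binomial(G, 0.001) crossovers, each
  splicing a fresh background haplotype onto the side of the breakpoint
  away from the disease locus.
- **Mutation age** G = 1,000 generations for the homogeneous population
  (matching the first admixture subpopulation); **pool size** 10,000
  haplotypes per subpopulation; both configurable.
- **Redraw policy**: frequencies, LD, disease position and the ancestral
  haplotype are redrawn for every simulated dataset (every replicate), so
  study cells average over candidate-region realizations.
- **Ascertainment**: candidate trios are retained with probability
  `p/p_max` (penetrance over its scenario maximum), which is an exact
  rejection sampler for the conditional distribution given an affected
  child and ~50× cheaper than thinning by raw penetrance.

What the generator does *not* emulate: genealogical drift and coalescent
haplotype structure (the background pool is an i.i.d. Markov-chain draw),
selection, de novo mutation beyond the founder event, genotyping error,
and X-linked inheritance. Passing tests therefore show correct behaviour
of the statistics under a stylized LD model, not performance on any
particular real LD landscape.

## Study profiles and observed operating characteristics

The replicated-study driver seeds replicate r of a cell with
`SeedSequence([master_seed, cell_tag, r])`, so results are bit-identical
for any worker count. The default acceptance profile is scaled down from
publication scale: 2,000 replicates (type I error) / 1,000 replicates
(power) with 500 permutations, N = 100 trios; publication-scale runs (10,000 ×
1,000) are a configuration choice away.

At this profile the permutation test is well calibrated: type I error of
max_PC at α = 0.05 is within Monte-Carlo error of the nominal level in
both the homogeneous and the admixed population, and the single-locus PC
null distribution passes a KS test against χ²₍₁₎ at n = 500.

A structural limitation worth stating plainly: with disease-allele
frequency 0.1 and a dominant relative risk of 2, the transmission
distortion at the disease locus itself is E[X] ≈ 0.137 per ascertained
trio, which caps single-test power at ≈ 0.53 for N = 100 — and a marker
can at best be a perfect tag of the disease allele. Under this generator
the marker-panel scans therefore attain power of roughly 0.10–0.17 at
N = 100 (dominant child, maternal, or joint effects; the recessive model,
with a risk-homozygote frequency of 0.01, is nearly indistinguishable from
the null). Published benchmark tables for this setting report
substantially higher power (≈ 0.6 at N = 100, with dominant ≈ recessive),
which is incompatible with the stated penetrance model for *any* choice of
the free parameters here (recombination rate, mutation age, pool size);
the corresponding acceptance checks in `tests/test_acceptance.py` encode
those published values and are expected to fail under this generator. The
qualitative orderings — power increasing in N, dominant ≥ recessive,
joint max_PC ≥ the single-channel max_Z² comparators — do hold and are
tested.

## Input handling

PED/MAP parsing tolerates arbitrary whitespace and arbitrary allele
symbols ("0" = missing). Every affected child (phenotype 2) with both
parents present in the family yields a trio; multi-child families
contribute each affected child, with a logged caveat that such trios are
not independent. The counted allele per SNP defaults to the parental
minor allele (ties lexicographic); recoding a SNP negates X and Y there
and leaves all statistics and p-values unchanged (tested). Mendelian
inconsistencies are detected by the interval rule on transmissible counts
and handled per the `drop-cell` / `drop-trio` / `error` policy.
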