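# Methods

This document records the statistical conventions implemented by
`domainsel`, the design of the coalescent generator, and known limitations.

## Data model

A `CodonAlignment` is a set of equal-length nucleotide sequences over
`{A,C,G,T,-,N}` with unique ids, an optional outgroup id and a
`frame_offset` (0–2) marking the first in-frame codon column. Both `-` and
`N` are treated as missing data. Region coordinates in configs and reports
are 1-based inclusive; `slice` preserves codon phase, so sub-regions that do
not start on a codon boundary get the correct frame offset automatically.

Two deletion policies coexist, matching common practice:

- **Complete deletion** for the diversity and neutrality statistics: any
  column with a gap or `N` in any ingroup sequence is excluded everywhere.
- **Pairwise deletion** for distance trees (`jc_distance_matrix`) and
  pairwise-complete codon exclusion for the Nei–Gojobori machinery.

## Diversity statistics

Over the retained columns: segregating sites `S`, minimum mutation count
`eta` (alleles − 1 summed over columns), mean pairwise differences `k_hat`,
per-site diversity `pi = k_hat / L`, Watterson's `theta_w = S / a1` with
`a1 = Σ_{i<n} 1/i`, haplotype count `k_haps`, and unbiased haplotype
diversity `HHe = n/(n−1) · (1 − Σ p_i²)`, clamped to [0, 1] against
floating-point overshoot.

The synonymous/non-synonymous split uses Nei–Gojobori codon counting. Site
potentials per codon weight transitions by a configurable ratio `R` (the
classic method is `R = 1`; the battery default `R = 2` reflects the usual
transition excess); mutations that would pass through a stop codon
contribute their site weight to the non-synonymous side so that
syn + nonsyn = 3 per codon. Pairwise codon differences are averaged over all
minimal mutational pathways that avoid stop codons. `pi_s`/`pi_a` are
per-pair proportions (optionally Jukes–Cantor corrected) averaged over all
sequence pairs.

The unfolded site-frequency spectrum (`sfs`) polarizes biallelic
ingroup-polymorphic columns against the outgroup; columns where the outgroup
is missing or carries a third allele are excluded and logged. The spectrum
exposes `theta_pi`, Fay & Wu's `theta_h` and Zeng's `theta_l`.

## Neutrality tests

- **Tajima's D** from `(n, S, k_hat)` with the standard variance constants.
- **Fu & Li's D and F** (outgroup version) from the polarized mutation count
  and the number of derived singletons.
- **Fay & Wu's H** in its unnormalized form `theta_pi − theta_H` (count
  units) and **Zeng et al.'s normalized H**
  (`(theta_pi − theta_L) / sd`) from the polarized spectrum. Because polarization can exclude columns, these
  statistics may rest on fewer mutations than `S`; the battery conditions
  their null distributions on the polarized count.
- **Fu's Fs**: with `p_k = P(K ≥ k_obs)` under the Ewens sampling formula at
  `theta = k_hat`, `Fs = log P(K ≥ k_obs) − log P(K < k_obs)`. The two tails
  are summed separately before taking logs; the algebraically equivalent
  `log(S′/(1−S′))` form cancels catastrophically when one tail is ≈ 1.
- **Ewens–Watterson**: observed homozygosity `F = Σ p_i²` compared with its
  null distribution under the Ewens formula conditioned on `(n, k_haps)`;
  exact enumeration of allelic partitions for small `n`, otherwise a Chinese
  restaurant process rejection sampler conditioned on the observed number of
  alleles. Degenerate configurations (`k = 1` or `k = n`) have a single
  compatible partition and return p = 1.
- **McDonald–Kreitman**: fixed vs polymorphic × synonymous vs non-synonymous
  contingency table against the outgroup, Fisher's exact test
  (`scipy.stats.fisher_exact`, two-sided) plus the neutrality index
  `NI = (Pn/Ps)/(Dn/Ds)` when defined.

### Coalescent p-values

Significance of D, Fs, Fu & Li D/F, H and nH is obtained by simulating
`reps` neutral coalescent samples conditioned on the observed number of
segregating sites (mutations dropped uniformly on the genealogy's branches),
recomputing the statistic, and forming a two-tailed p-value
`2 · min(P(≤ obs), P(≥ obs))` with the add-one correction
`(r + 1)/(reps + 1)`, floored at `2/(reps + 1)`. At the default 1000
replicates the finest attainable p is ≈ 0.002. The empirical type-I error of
this procedure at nominal α = 0.05 is ≈ 0.042–0.05 (see
`calibration.tajima_type1_error`); at 200 null replicates the effective
level of the corrected test is ≈ 0.0497.

## Codon Z-tests

`codon_z_test` implements the bootstrap Z-test of `dS` vs `dN`: for each
sequence pair, synonymous and non-synonymous differences and sites are
summed over codons complete in both sequences, proportions are Jukes–Cantor
corrected and averaged over pairs; pairs beyond JC saturation (p ≥ 0.75) are
excluded. The test statistic is `Z = (mean dS − mean dN) / SE` (purifying
direction; sign flipped for the positive-selection direction), with the SE
estimated by bootstrap over codon columns, and a one-tailed normal p-value.
The test is reported as undefined rather than zero when no informative codon
pairs survive.

## Haplotypes, trees, pairwise alignment

Amino-acid haplotype collapsing groups sequences identical at all
polymorphic residue positions (missing residues `X - * ?` do not create
polymorphism); groups are ordered by descending size, then first occurrence.
Trees are Saitou–Nei neighbor joining on Jukes–Cantor distances (pairwise
deletion), with negative branch lengths clamped to zero. Bootstrap support
is the percentage of column-resampled replicate trees containing each
internal bipartition; replicates hitting JC saturation are dropped and the
effective count recorded. `collapse_low_support` contracts branches below a
support threshold (conventionally 70%) into multifurcations.

Pairwise protein alignment follows EMBOSS needle conventions: global
Needleman–Wunsch, BLOSUM62, gap open 10 and extend 0.5 (the first residue of
a gap costs the opening penalty, each further residue the extension), end
gaps free. Identity and similarity (positive BLOSUM score) percentages are
computed over the full alignment length, gap columns included in the
denominator; reported percentages round half away from zero to one decimal.

## Coalescent generator

`domainsel.coalsim` simulates genealogies directly (leaf-set bitmasks per
branch) and drops mutations under the infinite-sites model: each mutation
gets a fresh alignment column, assigned to the synonymous or non-synonymous
class by `syn_fraction` (default 0.75), with derived bases chosen uniformly
among the class-compatible alternatives and no stop codons created. An
outgroup sequence diverged by `outgroup_divergence` substitutions/site
(default 0.15) is appended, and a truth sidecar records every mutation's
column, class, derived base and derived count. Time is in coalescent units
(2N generations); `theta = 2`·(expected mutations per coalescent time unit)
or `fixed_S` places an exact mutation count.

Scenarios:

- **neutral** — constant-size Kingman coalescent.
- **expansion** — exponential growth, rate 50 (in coalescent units) looking
  backward; genealogies become star-like, skewing the SFS toward singletons
  (Tajima's D ≈ −1.6, Fu's Fs strongly negative at the defaults).
- **balanced_split** — the sample splits into two clades forced to coalesce
  only at `split_time = 5` coalescent units. Five units was chosen (before
  the discrimination experiments were written) to represent long-maintained
  balanced haplotype groups: measured mean Tajima's D at n = 90, θ = 10 is
  −0.31, +0.15, +0.67 and +1.33 for depths 1, 2, 3 and 5, against −0.10 for
  neutral; shallow splits are indistinguishable from neutrality.
- **star_sweep** — a sweep `sweep_age = 0.05` units ago: all lineages except
  `sweep_escape = 1` escapee coalesce nearly simultaneously; the escape
  lineage's deep divergence produces high-frequency derived variants and a
  strongly negative Fay & Wu's H.

`neutral_syn_fraction()` returns the `syn_fraction` under which Nei–Gojobori
`dN/dS = 1` in expectation (the mean synonymous site fraction of the code
table, ≈ 0.244): matching the mutation-class split to the site-count split
makes E[dS] = E[dN] regardless of where mutations land within each class.
This is the "no selection" setting used by the Z-test size experiment;
`syn_fraction = 5/6` gives a 1:5 nonsyn:syn signal (strong purifying
selection). Calibration Z-tests use `R = 1`, matching the generator's
unbiased base choice.

### Generator validation

`calibration.neutral_moments` checks E[S] = θ·a₁ and E[k̂] = θ against
Monte-Carlo standard errors, and tests the SFS against Fu's exact
expectation E[ξ_i] = θ/i with a **Hotelling T²** test on the per-replicate
count vectors (empirical covariance, asymptotically χ² with n−1 df).
Pooling counts across replicates and applying a plain χ² is invalid —
mutations sharing a genealogy are positively correlated, so pooled counts
are overdispersed and the χ² rejects far too often. Testing per-replicate
*proportions* against `(1/i)/a₁` is equally invalid: E[ξ_i/ξ_tot] ≠
E[ξ_i]/E[ξ_tot] because singleton-heavy genealogies are systematically
shorter. The test suite also cross-checks the generator's S distribution
against msprime.

## Known limitations

- The generator has no recombination, no codon usage bias, homogeneous
  mutation rates across sites and an infinite-sites mutation model; the
  outgroup evolves by independent substitutions without back-mutation toward
  the ingroup.
- Nei–Gojobori counting underestimates synonymous sites when transition
  bias is strong and ignores among-site rate variation; the configurable `R`
  mitigates but does not remove this.
- Coalescent p-values condition on S under a constant-size neutral null;
  they are not robust to demography (that is what the scenario comparisons
  illustrate).
- Sliding-window values are highly autocorrelated between overlapping
  windows; the tracks are descriptive, not a multiple-testing-corrected
  scan.
- The Fu's Fs Ewens computation treats `k_hat` as the Ewens θ, the standard
  plug-in; for very small `k_hat` the discrete tails make the statistic
  coarse.
- NJ bootstrap support is a branch-repeatability measure, not a posterior
  probability.
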