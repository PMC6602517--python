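# Methods

This note documents the statistical model behind each estimator, the codon
pipeline's filtering rules, the synthetic-data generator used for testing and
calibration, and the numerical choices made where more than one reasonable
design existed.

## The four estimators

All four variants start from a DAF spectrum — counts of segregating
nonsynonymous (`Pn`) and synonymous (`Ps`) variants per derived-allele
frequency class `x` at a fixed sample depth `n` — and divergence counts
(`Dn`, `Ds`) to a single outgroup.

**Standard MKT.** `alpha = 1 − (Ds·Pn)/(Dn·Ps)` on the pooled spectrum, with
a two-sided Fisher exact test on the 2×2 table `[[Pn, Ps], [Dn, Ds]]`.
`alpha` is reported as undefined (not ±inf) when `Dn = 0` or `Ps = 0`;
downstream aggregation drops undefined values and counts them.

**FWW correction.** Identical after discarding all frequency classes with
`x < cutoff` (strict; both site classes dropped equally). Default cutoff
0.05. At cutoff 0 it reproduces the standard test exactly.

**Extended MKT.** With `L` the classes below the cutoff and `H` the rest,
the neutral expectation for low-frequency nonsynonymous polymorphism is
`Pn(H)·Ps(L)/Ps(H)`; the weakly deleterious count is
`wd = max(0, Pn(L) − expected)`, and the corrected table uses
`Pn_neutral = Pn(H) + min(Pn(L), expected)` against the full `Ps`. The `min`
clamp keeps `wd ≥ 0` under sampling noise (a note flags when the expectation
exceeds the observation). When the numbers of analyzed sites are known, the
regime fractions of selected sites are

```
f = m_s·Pn_neutral / (m_n·Ps)      (neutral)
b = m_s·wd / (m_n·Ps)              (weakly deleterious)
d = 1 − f − b                      (strongly deleterious)
```

clamped into [0, 1] with a diagnostic note when clamping fires. An empty `H`
synonymous class makes the partition undefined; the result is flagged rather
than silently falling back.

**Asymptotic MKT.** `alpha(x) = 1 − (Ds/Dn)·(Pn(x)/Ps(x))` per frequency
class (non-cumulative; a cumulative option exists but is off by default,
since each class's own counts are what the frequency-dependent bias acts
on). Classes with `Ps(x) = 0` are marked undefined, never dropped silently.
The trajectory is trimmed to an `x` interval — default [0, 0.9]; the top
classes are the ones most contaminated by polarization error — and fitted by
unweighted least squares to `a + b·exp(−c·x)`. The reported estimate is the
fitted value at `x = 1`, `a + b·e^(−c)`, capped at 1.

## Fisher exact test

Two-sided p by summation of hypergeometric point probabilities no larger
than the observed table's. Tables with total count ≤ 400 are enumerated in
exact integer arithmetic (the support has at most ~200 points and Python
integers are exact), so small-sample p-values carry no floating-point
artifacts. Larger tables — concatenated gene sets routinely reach tens of
thousands of counts — switch to vectorized log-gamma arithmetic with a 1e−7
relative slack in the tie comparison so that equal-probability tables are
included as in exact arithmetic. Any table with a zero margin carries no
information about the association and is assigned p = 1 with a
`degenerate_margin` note. No continuity correction is applied.

## Exponential fit: initialization, fallback, uncertainty

The exponential SSE surface is multimodal in `c`, so the fitter restarts
from `c ∈ {0.1, 0.5, 1, 2, 5, 10}`; for each start, `a` and `b` are seeded
by the conditional linear solve (the model is linear in `(a, b)` given `c`).
Each restart runs bounded trust-region least squares (`c ∈ (0, 100]`,
tolerances 1e−8, analytic Jacobian, 120-evaluation cap); candidates compete
on SSE, including capped ones. A straight line is only the `c → 0` limit of
the exponential family, so the ordinary linear fit `a + b·x` (asymptote
`a + b`) is computed too and reported whenever it strictly beats the best
exponential candidate — which also covers exactly-linear and degenerate
inputs where no exponential restart converges. On noise-free exponential
trajectories the recovered asymptote is exact to well below 1e−6 (verified
against a profile grid-search oracle in the test suite).

The 95% CI is a **parametric Poisson bootstrap**: each replicate redraws
every class's `Pn(x)` and `Ps(x)` from Poisson distributions centred on the
observed counts (divergence counts held fixed), rebuilds, re-trims and
refits the trajectory, and the 2.5/97.5 percentiles of the replicate
asymptotes form the interval. This construction is a stand-in choice: a
confidence interval is part of the method's contract, but the original
construction is not specified in the sources available to us, so ours should
not be expected to reproduce any particular published interval. Replicates
that fail to fit (too few defined points, degenerate trajectories) are
dropped and counted; losing more than half flags the interval. Default 1000
replicates, fully determined by one integer seed (per-replicate child
streams, so results do not depend on evaluation order).

## Codon pipeline

From an aligned set of same-species CDS sequences plus one outgroup
orthologue (frame starting at column 0):

1. **Subsampling.** Each column is subsampled without replacement to a fixed
   depth among ingroup lines carrying A/C/G/T (gap `-` and `N` are equally
   invalid). Columns with fewer valid lines are discarded
   (`insufficient_depth`). The default depth is the largest `n` such that at
   least 90% of columns retain `n` valid lines — the depth that maximizes
   informative sites without discarding most of the alignment; it is a free
   parameter and should be set explicitly when comparing datasets. Draws use
   a counter-mode stream per column derived from one seed, and the valid
   bases are sorted before drawing, so results are independent of both
   column processing order and ingroup sequence order.
2. **Codon-level exclusion.** A codon is excluded wholesale when any of its
   positions is undersampled, lacks an outgroup base or cannot be polarized
   (`unpolarizable`), is multiallelic in the ingroup, or when more than one
   position segregates or diverges (`multihit` — no pathway-averaging rule
   is attempted; exclusion is conservative and testable), or when the
   ancestral codon is a stop. Treating the codon, not the site, as the unit
   of exclusion keeps the classification context well defined for the
   surviving changes; every exclusion is logged with its reason.
3. **Polarization.** For a biallelic column the outgroup base identifies the
   ancestral allele; the other allele's count is the derived count. A
   monomorphic ingroup differing from the outgroup is a fixed difference.
   Because a retained codon has at most one varying position and its other
   positions match the outgroup, the ancestral codon equals the outgroup
   codon. Sites both polymorphic and divergent (outgroup allele absent from
   the ingroup) are unpolarizable and excluded, which also means no site is
   double-counted as polymorphism and divergence.
4. **Classification.** A single-nucleotide change is synonymous (neutral
   class) iff ancestral and derived codons encode the same amino acid under
   the standard nuclear genetic code (the only code supported), else
   nonsynonymous (selected class); changes to a stop count as nonsynonymous.
   When overlapping transcript frames propose different classes for one
   site, the most constrained class (selected ≻ neutral) wins.
5. **Site totals.** `m_n`/`m_s` are Nei–Gojobori fractional counts on the
   ancestral codon of every retained codon: each position contributes
   (synonymous one-step mutations)/3 to `m_s` and the complement to `m_n`,
   so `m_n + m_s = 3 ×` retained codons (e.g. TTT → 8/3 + 1/3, ATG → 3 + 0).

The resulting spectrum has classes at `i/depth`, `i = 1..depth−1`, with
zero-count classes preserved.

## Multi-gene analysis

**Concatenation** sums spectra class-wise and divergence counts across
genes. Genes sampled at different depths are first projected onto a common
20-class equal-width grid (class centres `(i+0.5)/20`); mixing depths loses
the exact `i/n` interpretation, so equal-depth inputs are summed on their
native grid. Concatenation is associative and order-invariant.

**Heterogeneity.** The per-gene 2×2 tables form strata. The
Cochran–Mantel–Haenszel chi-square (df = 1, no continuity correction, via
statsmodels) tests for a common polymorphism/divergence association; the
Breslow–Day statistic with Tarone's adjustment (df = K−1) tests whether the
per-gene odds ratios are homogeneous. The Breslow–Day computation is done
in-package because the statsmodels implementation solves its quadratic in a
form that degenerates when the Mantel–Haenszel odds ratio is exactly 1 (the
expected-cell equation becomes linear); our solver handles that case and
matches statsmodels everywhere else. Both variants are always available
because a "heterogeneity test (CMH statistic)" is ambiguous: the CMH
statistic canonically tests common association, not homogeneity.

**Bootstrap comparison.** Each replicate draws `sample_size` genes with
replacement, concatenates, and estimates `alpha` with the chosen variant;
defaults are 100 replicates at the group's own size. Summaries are mean, SD
and percentile 2.5/97.5 interval (percentile rather than BCa — only a
resampling interval is called for, and the percentile interval is the
simplest defensible choice). Undefined replicate estimates are dropped and
counted; losing more than 20% flags the summary. Group comparisons run
independent child streams per group (derived from one seed) and report the
replicate-wise difference with its own percentile interval. Replicate
streams are indexed by replicate number, so a fixed seed gives bit-identical
results regardless of surrounding code. "Compare against the whole-genome
distribution" is the special case of comparing a subset against the full
dataset. The recombination-rate filter is strict (`rate > threshold`).

## Synthetic data generator

The generator draws expected site-frequency spectra with Poisson noise
rather than simulating genealogies: tests need calibrated ground truth, not
coalescent realism. For a gene with `m_s` neutral sites at diversity scale
`theta_s` and sample depth `n`, the expected neutral count at derived count
`i` is `theta_s·m_s/i` (the standard neutral expectation). Selected sites
mix three regimes with fractions `f + b + d = 1`:

- the neutral fraction `f` contributes `(m_n/m_s)·f` times the neutral
  spectrum shape and drives selected divergence,
- the weakly deleterious fraction `b` contributes a low-frequency-skewed
  spectrum ∝ `1/i^(1+weak_skew)` (default skew 1, i.e. `1/i²`), normalized
  to the same total mass as the neutral shape, and no divergence,
- the strongly deleterious fraction `d` contributes nothing.

Neutral divergence is `Poisson(ds_mean)` and selected divergence
`Poisson(ds_mean·(m_n/m_s)·f/(1−alpha_true))`, so the expected standard-MKT
`alpha` equals `alpha_true` exactly when `b = 0` — the calibration used in
the recovery tests. Defaults (`n = 20`, `m_n = 750`, `m_s = 250`,
`theta_s = 0.02`, `ds_mean = 40`) give a typical gene ≈ 18 synonymous
segregating variants and ≈ 40 synonymous fixed differences, a realistic
desk-scale gene for a Drosophila-like diversity level.

What the generator deliberately omits: linkage and Hill–Robertson
interference, demography and non-equilibrium spectra, sampling noise in the
frequencies themselves (frequencies sit exactly on the `i/n` grid),
polarization error, and variation of `theta` across genes beyond Poisson
noise. Passing recovery tests therefore demonstrates estimator correctness
under the model's own assumptions, not robustness to the violations real
data exhibit.

Two packaged scenarios matter for the tests: an adaptive cohort
(`alpha_true = 0.5`, no weak load) for unbiased recovery, and a two-group
comparison (true `alpha` 0.6 vs 0.44, 475 + 2000 genes, the first group
assigned recombination rates above 7 cM/Mb) exercising filtering,
bootstrapping and group comparison end-to-end. The comparison scenario
carries no weakly deleterious load so that its group means are governed
purely by the planted `alpha` values; eMKT's bias-correction behaviour is
stressed separately with `b = 0.3`, `weak_skew = 1` cohorts where the
standard estimate is strongly biased downward and eMKT must both exceed it
and land closer to the truth.

Toy alignments (`make_toy_alignment`) plant individual events — synonymous
and nonsynonymous polymorphisms at chosen derived counts, fixed differences,
and one instance of every exclusion reason — on a conserved background
(ancestral codon TTT with substitutions at chosen positions; filler codon
GGC), and return the exact tables the pipeline must produce, making the
spectrum code testable against construction rather than against itself.

## Problem sizes and runtime choices

Recovery and comparison checks run at 200 genes per cohort, 40 cohorts for
the directional eMKT check, and 100 bootstrap replicates of 400 genes for
the two-group comparison; the asymptotic-fit bootstrap uses 200 replicates
in the acceptance script and 60–100 in tests. These sizes give standard
errors comfortably below the tolerances being asserted (e.g. pooled-alpha
SE ≈ 0.01 against a ±0.03 band) while keeping the whole suite fast.

## Known limitations

- One outgroup only; no probabilistic ancestral-state reconstruction, so
  high-frequency classes retain polarization-error risk (mitigated by the
  default [0, 0.9] trim in the asymptotic fit, not removed).
- No divergence correction for multiple hits (no Jukes–Cantor adjustment);
  divergence counts are raw fixed differences.
- Multi-hit codons are excluded rather than pathway-averaged, slightly
  undercounting changes in rapidly evolving codons.
- The standard nuclear genetic code only.
- `alpha` aggregation across genes assumes exchangeability within a group;
  the CMH/Breslow–Day statistics quantify, but do not correct for,
  between-gene heterogeneity.
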