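# Methods

## The analysis

`regevol` implements the classic allele-specific-expression decomposition of
regulatory divergence. Two parental genotypes and their reciprocal F1
hybrids are sequenced (one pooled RNA-seq library each); reads that align
perfectly and uniquely to only one parental genome are allele-informative.
Within a hybrid both alleles share one trans-acting environment, so the
hybrid allelic log-ratio measures the **cis** effect:

```
total = log2(g1 / g2)          # mixed-parental genotype counts
cis   = log2(a1 / a2)          # hybrid allele counts
trans = total − cis
%cis  = 100 · |cis| / (|cis| + |trans|)
```

The mixed-parental sample is built in silico by pooling equal read numbers
from the two parents and counting allele-informative reads with the same
machinery as in hybrids, so `total` and `cis` sit on one scale and the
identity `total = cis + trans` holds exactly by construction.

Significance per gene: exact binomial tests at p = 1/2 for parental
imbalance (mixed pair) and allelic imbalance (cis, hybrid pair); Fisher's
exact test of mixed vs hybrid pairs for trans; all two-sided under the
minlike convention (sum of outcomes no more probable than the observed
one — the convention of `scipy.stats` and R's `fisher.test`/`binom.test`).
Benjamini–Hochberg controls the FDR at 0.05 within each test family; the
exact tests' discrete null p-values are not uniform, but a BH vs
Benjamini–Yekutieli comparison on simulated data shows the gene calls are
insensitive to the choice.

## Depth equalization

Exact-test power depends on counts, so depths are equalized by sampling
reads without replacement, never by rescaling:

* whole libraries are down-sampled to a common target via a multivariate
  hypergeometric draw over genes (every mapped read equally likely to be
  retained);
* allele-informative counts per gene are equalized across the mixed and
  hybrid samples by univariate hypergeometric draws down to the per-gene
  minimum total.

Both operations conserve the target exactly and are unbiased; a data set
down-sampled from twice the depth has the same power as one natively
collected at the target (verified by simulation in the test suite).
Down-sampling precedes the 20-read floor.

## Gene filters

1. **Minimum reads** — a gene needs ≥ 20 reads in every library (total data
   set) or ≥ 20 allele-informative reads (`a1 + a2`) in every mixed and
   hybrid sample (allele data set). The boundary is inclusive.
2. **Allele assignment QC** — genes are dropped when more than 10% of one
   parent's reads align solely to the other parent's genome (the
   cross-mapping rate is an input column; the simulator fabricates it).
3. **Imprinting screen** — a per-gene Fisher test of the allelic pair
   between reciprocal hybrids, BH-FDR 0.05; significant genes show
   parent-of-origin expression, which is not cis divergence.
4. **Mitochondrial genes** are excluded a priori (maternal-only) and do not
   enter the imprinting test family; they are kept only for the
   maternal-fraction QC metric, which should be ≈ 1 in a clean experiment.

Masks are idempotent and order-independent; the allele data set is their
intersection.

## Categorical calls

**Regulatory class** combines the three significance flags with the cis and
trans effect signs: conserved (none), all cis, all trans, cis + trans (all
three, same sign), cis × trans (all three, opposite signs), compensatory
(cis and trans without a parental difference — the effects cancel), and
ambiguous for every remaining combination. The rule table is a
reconstruction from the category names and the test battery; it matches the
scheme this classification family has used since its microarray-era
introductions.

**Inheritance mode** compares hybrid total expression with each parent
using pairwise calls that require both BH significance and ≥ 1.25-fold
difference (a difference *less than* 1.25-fold is similar, so exactly
1.25-fold counts as different). Hybrid similar to both parents → similar;
similar to exactly one → that parent dominant; different from both →
additive if strictly between the parents, over-/under-dominant
(misexpression) if outside the parental range. Two deliberate edge rules:
a hybrid count exactly equal to a parent's is treated as resembling that
parent, and a hybrid similar to both parents while the parents differ from
each other (reachable because the fold rule is not transitive) is called
similar — the conservative reading, since the hybrid is indistinguishable
from either parent.

**Trajectory class** tracks each gene's parental fold change `F =
max(c1, c2)/min(c1, c2)` across three comparisons ordered by divergence
time. A step is "similar" when adjacent fold changes differ by less than
1.25× (`max(F_i, F_j)/min(F_i, F_j) < 1.25`), otherwise
increased/decreased. The 3 × 3 step pairs give nine classes: I =
(increased, increased), II = (similar, similar), and IIIa–IIIg for the
remaining seven in the fixed order (inc, sim), (dec, sim), (inc, dec),
(dec, inc), (sim, inc), (sim, dec), (dec, dec). An alternative reading —
binning each comparison's fold at 1.25 before comparing — was considered
and rejected because it collapses all sub-threshold dynamics into one bin.

Reciprocal hybrids are analyzed separately throughout; the pipeline emits
one result table per hybrid.

## Genome-scale summaries

Overall divergence between two count vectors is `1 − ρ` (Spearman, average
ranks for ties): rank-based, so invariant to monotone transforms and robust
to outliers. Uncertainty comes from a gene bootstrap (pairs resampled
jointly, default 10,000 replicates, 2.5%/97.5% percentiles). Differences in
`1 − ρ` between comparisons are declared significant under two criteria,
both reported because both are in common use: the replicate distribution of
the difference excluding zero (each comparison resampled independently
within a replicate), and non-overlap of the two comparisons' own 95%
intervals (the second is the more conservative). Proportions of significant
genes are compared between comparisons with Fisher's exact test, and an OLS
regression of `total` on `cis` quantifies how much expression divergence
the cis component explains.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes — not
reads, mapping, or genomes:

* **Baseline abundance** `mu_g = 2^N(mean, sd)` (log-normal, default mean 6,
  sd 1.5 on log2): heavy-tailed like real libraries.
* **Regulatory architecture** per gene from a configurable mixture
  (conserved, all cis, all trans, cis + trans, cis × trans, compensatory);
  |log2| effect magnitudes uniform (defaults log2 1.5 – 2.0) with random
  sign; compensatory genes satisfy `trans = −cis` exactly.
* **Parental expectations**: the total divergence `u = cis + trans` is split
  symmetrically, parent 1 ∝ `mu·2^{+u/2}` and parent 2 ∝ `mu·2^{−u/2}`.
  The per-gene expression ratio is exactly `2^u` either way, but the
  symmetric split keeps the two libraries' weight sums equal in
  expectation; a one-sided assignment combined with per-library multinomial
  normalization would leak a global compositional log-shift (Jensen's
  inequality: `E[2^u] > 1` even with sign-balanced effects) into every
  conserved gene's measured ratio. The residual stochastic shift from
  finite genes is well below one binomial standard error at the default
  scales.
* **Hybrid expectations**: the midpoint of the parental expected counts
  shifted by a per-gene dominance parameter `d ∈ [−1, 1]` (−1 = parent-2
  level, 0 = additive, +1 = parent-1 level).
* **Counts**: multinomial allocation of `library_size` reads per library
  (column sums exact); optional overdispersion multiplies gene weights by
  Gamma(1/φ, φ) draws (negative-binomial-like marginals; default off so the
  exact tests' calibration properties hold).
* **Allele-informative counts**: each sample's gene count is thinned
  binomially by a per-gene informative fraction drawn from
  Beta(mk, (1−m)k) (default mean 0.4, concentration 30 — allele
  assignability varies between genes with their sequence divergence);
  hybrids split allele 1 vs allele 2 binomially with `p = 2^cis/(1+2^cis)`;
  parents emit reads for their own genome only.
* **Artifacts on demand**: maternal-only mitochondrial genes (cross 1 =
  parent-1 mother, cross 2 = parent-2 mother); an imprinting artifact
  shifting the allele-1 share of selected genes in cross 1 only; a
  fabricated cross-mapping-rate channel (background uniform on [0, 0.09],
  configurable fraction of genes at an elevated rate) to exercise the QC
  filter.

All randomness derives from one seed through deterministically spawned
per-purpose streams; fixed seeds reproduce byte-identical tables.

**What the generator does not model** — and hence what passing tests do not
show about real data: mapping bias and reference bias in allele assignment,
positional/GC coverage artifacts, biological replicate variance beyond the
optional gamma overdispersion, correlated expression between genes, and
real imprinting biology. Tests on these data certify the statistical
machinery, not the upstream bioinformatics.

## Numerical choices

* Zero handling in log-ratios: effects are computed only for genes past the
  20-read floors; if one member of a pair is still 0, 0.5 is added to both
  members for the point estimate only — inference always uses raw counts.
  Both members zero → effect missing.
* `%cis` is undefined (missing) when cis = trans = 0.
* BH is computed on the non-missing p-values only; missing q-values
  propagate and count as non-significant.
* The vectorized binomial p-value uses the symmetry of the p = 1/2 pmf
  (`2·P(X ≤ min(k, n−k))`, 1 at `k = n/2`), which equals the minlike value
  exactly; it is tested against both `scipy.stats.binomtest` and an
  exact-rational enumeration oracle.
* Per-stage seeds are spawned deterministically from the run seed
  (`numpy.random.SeedSequence`), and every stage's seed is recorded in the
  run log.

## Problem sizes

Default analyses in the test suite and acceptance script use 1,000–2,000
genes at library depths of 10^6–8·10^6 reads and 2–10 simulation seeds,
with bootstrap resolutions of 400–1,000 replicates where intervals are
exercised repeatedly (the user-facing default remains 10,000). These sizes
give per-gene allele depths of several hundred to ~2,000 reads, the regime
the method's 20-read floor and exact tests were designed for.

## Known limitations

* Single pooled libraries per genotype, as in the source design: no
  replicate-aware dispersion modeling; the Fisher/binomial tests detect
  small differences at high depth, which is why the 1.25-fold rule guards
  the categorical calls.
* A genome-wide trans shift is indistinguishable from normalization, so
  compositional effects fold into trans estimates by definition of the
  decomposition.
* The regulatory rule table treats borderline flag combinations (e.g. cis
  significant alone) as ambiguous rather than guessing.
* `cis × trans` genes whose effects nearly cancel are intrinsically
  confusable with compensatory genes; recovery tests quantify this.
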