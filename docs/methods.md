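# Methods

## The pair-homozygosity framework

The core statistic is identity by state between two phased haplotypes:
H(h₁, h₂) = (matching sites)/L over a fixed panel of L biallelic SNPs.
Three conventions matter and are fixed throughout:

- **Denominator.** L is the *full* filtered panel, including sites that are
  monomorphic in the pair or in the whole dataset.  H is therefore
  comparable across pairs and chromosomes, and equals 1 − normalized
  Hamming distance exactly.
- **Pairing.** "All possible combinations" means every unordered pair of
  haplotypes in scope, each appearing once (ids in lexicographic order).
  The two haplotypes of one individual form a valid pair (their H is the
  individual's classical homozygosity) and are included by default;
  `include_within_individual=False` removes them when between-individual
  variation is the question.
- **Phase errors.** Pair statistics pool over all pairs, so switch errors
  in upstream phasing average out of group-level means; no attempt is made
  to model them.

Distribution summaries use 0.002-wide histogram bins on [0.7, 1.0]
(auto-widened if data fall outside), which resolves the peaks of interest
(outgroup pairs ≈0.72, within-European pairs ≈0.94) without over-binning.

## Site filtering

Input panels are reduced to biallelic SNPs in a fixed rule order: indels
out unconditionally, then multi-allelic sites, then sites called in ≤80%
of individuals overall, then sites called in ≤80% of individuals within
any single group.  Thresholds are strict inequalities ("more than 80%"),
and a genotype counts as called only when both alleles are present and
phased (unphased heterozygotes are treated as missing, unphased
homozygotes are accepted since phase carries no information for them).
The indels-before-call-rate order is a choice this package fixes; the
alternative order changes only how removals are attributed between rules,
not the retained panel.  Residual missingness errors by default
(`missing_policy="error"`), since proper imputation is out of scope; the
`major_allele_fill` policy (group-major allele, ties → reference) exists
for synthetic or mildly degraded panels and warns when used.

## Chimeric haplotypes and the admixture estimator

A chimera replaces k = round(f·L) recipient alleles with donor alleles
(round-half-to-even, so k is platform-stable).  Two placement modes exist:

- `contiguous_blocks` (default, n_blocks=10): k sites in 10 near-equal
  disjoint runs with randomly placed gaps — shaped like real introgressed
  segments;
- `random_sites`: k sites uniformly without replacement.

The pooled mean of chimera-vs-reference homozygosity is provably invariant
to placement (it is a linear mixture of the recipient-vs-reference and
donor-vs-reference means, exact in expectation up to the rounding of f·L),
which the test suite checks by running both modes.  One `ChimeraSpec`
yields one replaced-site set, deterministic in (f, mode, n_blocks, seed,
L) and shared across all recipient×donor pairs of a panel; this changes
nothing about the pooled mean and lets the all-pairs distribution be
computed with dense matrix products.  The panel generator, by contrast,
gives each synthetic admixed haplotype its own sub-seeded site set, so an
admixed *group* carries heterogeneous introgression mosaics.

When chimeras are paired against the recipient group, each chimera's own
recipient haplotype is excluded from the reference set (it would contribute
a trivial near-1 value); the recipient individual's other haplotype stays.

`estimate_admixture_fraction` scans a grid of f values (default 0.00–0.50,
step 0.01), builds the chimera distribution at each f, and minimizes the
distance to the observed target-vs-recipient distribution.  The default
objective compares means — under the mixture identity the mean is a
sufficient location statistic, and the objective is then piecewise-linear
in f with a unique minimum up to sampling noise.  A 1-Wasserstein
objective is available when distribution shape matters.  Ties resolve to
the smallest f.

## Runs of homozygosity

A haplotype pair is scanned as a pseudo-diploid (heterozygous = alleles
differ).  Candidate runs are *maximal* windows containing at most
`max_het_per_run` heterozygous sites (default 1): each candidate is
bounded by the heterozygous sites that would exceed the allowance, so no
candidate can be extended in either direction.  Candidates are emitted
left to right and truncated to start after the previously accepted
segment, which makes reported segments disjoint and assigns shared
stretches to the leftmost run; the minimum span (default 10 kb) and
minimum site count (default 25) are applied after truncation.  This exact
scan replaces PLINK's windowed heuristic deliberately: it is deterministic,
has a clean maximality semantics, and is testable against brute-force
interval enumeration.  The site-count and density parameters PLINK would
add beyond the two published ones are configuration defaults here, so
exact PLINK output matching is not a goal.  Coordinates are 1-based
inclusive site positions internally; BED export is 0-based half-open.

The coverage-versus-homozygosity diagnostic fits homozygosity ~ ROH
coverage per group combination and compares classes by their mean residual
from a pooled fit: if high wild-boar homozygosity were driven by recent
inbreeding, wild pairs would need *more* ROH coverage to reach the same
homozygosity, not less.

## Neighbor joining

Each haplotype is an independent taxon; distance is the per-site mismatch
proportion, 1 − H (the specific distance flavor is this package's fixed
choice among IBS-type options).  The Saitou–Nei Q-criterion is applied
with deterministic tie-breaking (lexicographically smallest pair of
subtree labels, a subtree labelled by its smallest leaf; the Q matrix is
symmetrized with `min(Q, Qᵀ)` so float rounding cannot hide a tie).
Negative branch lengths are clamped to zero by default with the count
recorded — note PHYLIP's NEIGHBOR leaves them negative.  The unrooted
result keeps a trifurcating central node; rooting on an outgroup requires
the outgroup to be a clade of the unrooted topology and splits the
separating edge equally.  The O(n³) implementation is intended for panels
of at most a few hundred haplotypes.  On additive matrices NJ recovery is
exact, which the suite verifies against randomly generated trees and a
four-point-condition oracle, plus an independent scikit-bio cross-check.

## The synthetic-data generator

The generator is a deliberately minimal stand-in for the unavailable
re-sequencing panel: the *simplest* model whose group-level expected
homozygosities have closed forms that can be calibrated exactly to the
published means.

- **Ancestral frequencies.** Per site, p̄ ~ Beta(a, a) with
  a = 2θ/(1 − 4θ), giving E[p̄(1−p̄)] = θ exactly.  (A uniform distribution
  cannot reach the variance needed for θ = 0.0875, hence the Beta.)
- **Population drift.** Each population draws p ~ Balding–Nichols(p̄, F),
  i.e. Beta(p̄(1−F)/F, (1−p̄)(1−F)/F), so E[p(1−p)] = (1−F)θ.
- **Closed forms.** Within a population H = 1 − 2(1−F)θ; between any two
  distinct populations H = 1 − 2θ, independent of their F values, because
  both drift from the same shared ancestor.  The "two continental clades"
  are therefore a star of populations — sufficient for every statistic in
  scope, which depends only on within/between means, but it does mean all
  between-population means coincide rather than grade with divergence
  time.
- **Calibration.** θ = (1 − H_between)/2 from the between-clade mean;
  F_g = 1 − (1 − H_g)/(2θ) per group.  Defaults come from the published
  means: H_between = 0.825 → θ = 0.0875; within-European-wild 0.941 →
  F = 0.6629 (strong glacial bottleneck); within-Asian-wild 0.84 →
  F = 0.0857, reused for Asian commercial/local whose within-group means
  are not published separately.  `expected_homozygosity(calibrate(t))`
  returns the targets exactly (algebraic round trip).
- **Admixed group.** Each "European commercial" haplotype is a chimera of
  a fresh recipient-population haplotype and a fresh donor-population
  haplotype at fraction `true_f` (default 0.20), with a per-haplotype
  replaced-site set.  Its cross-group expectations are the f-weighted
  mixtures; the within-admixed closed form additionally treats two
  haplotypes' site sets as independent (an O(f²)-accurate approximation
  for randomly placed blocks).
- **Outgroup.** Balding–Nichols alone cannot lower a between-population
  mean below 1 − 2θ, so the outgroup redraws its ancestral frequency
  independently at a fraction m of sites (default 0.3), giving
  E[H(out, ingroup)] = (1−m)(1−2θ) + m/2 ≈ 0.73 — deep divergence without
  adding a second calibration target (the observed outgroup peak is a
  figure read-off, not a published number, and is deliberately not
  calibrated to).  F_outgroup = 0.2 reflects a small island population.
- **Linkage.** `ld_block_sites=0` (independent sites) by default: every
  statistic compared here is a mean over sites, unaffected by LD, and
  independence keeps the closed-form ↔ empirical correspondence tight.  A
  block-copying mode (copy a block from a random earlier haplotype, or
  redraw it with probability 0.5) induces genuine LD — unbiased in per-site
  frequency but with founder-inflated frequency variance — for tests that
  need correlated sites.
- **Inbred individuals.** A contiguous fraction of haplotype A is copied
  onto haplotype B of a designated individual, producing one long exactly
  shared segment (a guaranteed ROH) on top of background homozygosity.
- **Scale and seeds.** Default panels use L = 50,000 sites at a uniform
  600 bp spacing (the pig chromosome-1 SNP density, at about one eighth of
  its site count) and 40 haplotypes per core group — large enough that
  group means sit within ≈0.001–0.002 of their closed forms, small enough
  that the full analysis runs in minutes.  The config seed is mandatory;
  every stochastic step derives its own generator from (seed, chromosome,
  purpose), so panels are reproducible and different chromosomes under one
  seed share individuals but have independent sites.

**What passing tests do and do not show.**  The generator reproduces the
*first-moment structure* of the real data (group-level homozygosity means,
their ordering, the admixture mixture arithmetic) and simple LD/ROH
features, so tests demonstrate that the pipeline's statistics and the
estimator are correct and well-calibrated under the stated model.  It does
not emulate recombination-map structure, site-frequency-spectrum details,
gradated divergence between more than two levels of population structure,
phasing/imputation error, or selection — conclusions about those aspects
of real data are outside what the suite can certify.

## Numerical choices

- Pairwise homozygosity over a panel is computed as a single ±1 matrix
  product; with L < 2²⁴ the dot products are exact integers in float32 and
  the final division is done in float64, so matrix and scalar routes agree
  bit-for-bit.
- Pearson cross-chromosome outliers: residuals from the least-squares line
  exceeding 3 residual SDs; an individual is flagged when more than 90% of
  its matched pairs are outliers.  Both thresholds are configurable — the
  published analysis identified the corresponding "clouds" visually, so
  these defaults are this package's operationalization.
- TSV/JSON emitters fix float formatting so identical runs are
  byte-identical.
- Degenerate inputs error early with named offenders: empty panels or
  tables, unknown groups, length mismatches, unsorted positions,
  overlapping ROH segments, non-symmetric distance matrices, outgroups
  that are not clades.
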