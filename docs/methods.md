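# Methods

`abcorigin` asks a single question: did the Khon Mueang (KM), the majority
population of northern Thailand, originate by admixture between local
Mon-Khmer (MK) speakers and incoming Tai-Kadai (TK) groups, or as a recent
offshoot of the Tai-Kadai themselves?  It answers it the likelihood-free
way: simulate both demographic histories under the coalescent, reduce
observed and simulated data to the same summary statistics, and let a
local weighted logistic regression on the nearest simulations turn the
comparison into model posterior probabilities.  Alongside the ABC machinery
the package implements the hierarchical Y-haplogroup caller used to build
per-population haplogroup frequency tables from binary marker genotypes.

## Demographic models

Both models relate three haploid demes of constant effective size `N_MK`,
`N_KM`, `N_TK` (gene copies, since both marker systems — mtDNA and the
non-recombining Y — are uniparental and haploid).  Times are in
generations before present.

* **Tree-like.** KM and TK merge into a common ancestral deme at `T1`;
  that deme keeps the TK size until it joins MK at `T2 > T1`, after which
  a single deme of size `N_anc` remains.  This encodes "KM is a recent
  split from the TK ancestors".
* **Admixture.** KM is founded at `Tadm` by an admixture pulse: looking
  backward, each KM lineage reassigns to TK with probability `alpha` and
  to MK with probability `1 − alpha`.  The two parental demes merge into
  the ancestral deme (`N_anc`) at `T1 > Tadm`.

There is no migration outside the pulse, no recombination, and no size
change within a deme: over the two-millennium timescale of the Tai-Kadai
expansion, constant sizes are the defensible default and anything richer
would not be identifiable from two loci.

### Priors

All priors are independent uniforms; ordering constraints (`T1 < T2`,
`Tadm < T1`) are enforced by redraw.  Defaults:

| parameter | default prior | rationale |
|---|---|---|
| `N_MK,N_KM,N_TK,N_anc` | U(100, 50 000) | spans village isolates to large pooled groups (gene copies, haploid) |
| `T1` | U(40, 120) generations | brackets the Tai-Kadai arrival ~2 000 years ago at 25 y/generation |
| `T2` | U(100, 4 000) | from "shortly before T1" to the upper range of mainland SE-Asian settlement |
| `Tadm` | U(10, 120), `< T1` | admixture after the split, possibly very recent |
| `alpha` | U(0, 1) | uninformative TK-side contribution |

Every bound is configuration, not code.

## Coalescent simulator

One genealogy per simulated dataset (both marker systems are single
non-recombining loci).  Within each deme lineage pairs coalesce at rate
`1/N` per generation; waiting times are exact exponentials from the
competing-risks construction across demes, truncated at the demographic
events, which are processed in time order.  The simulator is event-driven
and exact — no generation discretisation.

Mutations are laid on the genealogy afterwards:

* **HVR-I (sequences).** Finite-sites model on `L = 360` bp.  The total
  mutation count is Poisson(total branch length × μ × L); each mutation
  picks a branch proportionally to length and a uniform site.  A mutation
  is a transition with probability `κ/(κ+2)` (default `κ = 10`, the strong
  transition bias characteristic of the mitochondrial control region) and
  otherwise one of the two transversions.  Default `μ = 5×10⁻⁶` per site
  per generation, a pedigree-scale control-region rate; repeated hits at a
  site apply sequentially, so back-mutation and homoplasy arise naturally.
* **Y-STRs.** 17 fully linked loci share the one genealogy.  Each locus
  mutates at its own rate (default `6.9×10⁻⁴` per locus per generation, a
  standard Y-STR average) under the strict stepwise model: every mutation
  moves the repeat count by ±1 with equal probability.  Ancestral repeat
  defaults to 20; leaf counts are floored at one repeat.

Both mutation stages consume pre-drawn randomness so a seeded run is
bit-reproducible regardless of traversal details.

## Summary statistics

The same fixed suites are applied to observed and simulated panels.

**HVRI suite** (for K populations, `4K + K(K−1)` values): per population
the number of haplotypes, the number of private polymorphic sites,
Tajima's D, and the mean number of pairwise differences; per unordered
pair of populations the mean between-population pairwise difference and a
haplotype-distance Fst.

**YSTR suite** (`8K` values): per population, the mean and the sample
standard deviation (denominator n−1) over loci of four per-locus
quantities — number of alleles `k`, unbiased gene diversity
`n/(n−1)(1−Σp²)`, modified Garza–Williamson index `k/(R+1)` (the `+1`
keeps monomorphic loci defined at exactly 1), and allelic range
`R = max − min`.

Conventions worth stating precisely:

* **Missing data** (`N`/`-` in sequences, `NA` repeats): pairwise deletion
  for sequence distances, per-site exclusion for site-based counts,
  non-missing alleles only at STR loci.  A locus with fewer than two
  usable alleles is dropped from that population's over-locus moments.
* **Fst** is `1 − Hw/Hb` on haplotype distances, where `Hb` is the mean
  distance over all cross-population pairs and `Hw` averages the two
  within-population diversities computed over *ordered pairs including
  self-comparisons* (denominator `n²`).  This convention makes Fst of two
  identical panels exactly 0 (the distinct-pair convention would make it
  negative); the separately reported within-population mean pairwise
  difference keeps the familiar distinct-pair (`n(n−1)/2`) form.  `Hb = 0`
  returns 0; results are clamped to `[−1, 1]`.
* **Private polymorphic sites**: sites segregating within the focal
  population at which the focal population carries at least one allele
  absent, at that site, from all other populations pooled.
* **Tajima's D** uses the standard constants; `S = 0` is undefined and
  flagged.  At `n = 2` the variance constants vanish together with the
  numerator, and the analytic limit 0 is returned.
* Undefined statistics are reported as NaN with a flag — never silently
  dropped — so every simulation contributes a row of fixed layout.

## Haplogroup assignment

The caller places each binary-marker genotype on a rooted tree whose
branches own diagnostic markers.  A branch is *supported* if any of its
markers is called derived and *contradicted* if any is called ancestral
(multi-marker branches therefore need one derived and zero ancestral
calls).  A node is attainable when its own branch is supported, nothing on
its root path is contradicted, and unsupported intermediate branches are
merely untyped — a derived call implies the derived state at every
ancestor.  The assignment is the deepest attainable node (preorder
tie-break), or the root when nothing is attainable.  A conflict flag is
raised when some supported branch is incompatible with the chosen
placement (off-path support, or support beneath an explicit ancestral
call); the assignment then stops at the deepest unconflicted node rather
than aborting the panel.

The shipped tree file is a synthetic reconstruction: it is built from the
published table of 23 haplogroups and their diagnostic SNPs plus standard
2016-era Y-nomenclature topology, with internal scaffold nodes (CT,
K-P128, NO-P195, …) carrying markers from the genotyped 104-marker list.
Haplogroup naming lives entirely in the tree file, so a different
nomenclature is a data change.

Frequency tables divide assignment counts by population size; rows sum to
exactly 100 % before rendering (one-decimal TSV output).

## ABC model choice

1. **Standardization.** The two models' reference tables are pooled and
   every statistic is centred and scaled by the pooled simulation mean and
   standard deviation — otherwise the Euclidean distance would be
   dominated by large-magnitude statistics such as pairwise differences.
   The observed vector is standardized with the *simulation* moments.
   Zero-variance statistics are dropped (logged); NaN cells (undefined
   statistics, e.g. Tajima's D on monomorphic simulations) are imputed by
   the pooled mean, keeping the table at its nominal size.
2. **Rejection.** The `n_keep` simulations nearest the observed vector in
   Euclidean distance are retained; ties break by simulation index via a
   stable sort, so runs are deterministic.
3. **Local weighted regression.** The model indicator is regressed on the
   standardized statistics by weighted maximum likelihood with
   Epanechnikov weights `w(d) = 1 − (d/d_max)²` (bandwidth = the largest
   retained distance).  The multinomial logit is fitted by Newton-Raphson
   on the baseline-coded likelihood (the two-model case reduces to a
   binomial logit); quasi-separation triggers a refit with a ridge of
   10⁻⁶, and a fit that still fails falls back to the weighted counting
   estimator with an explicit non-convergence flag.  Retention by a single
   model yields posterior 1/0 with a degeneracy flag.  The posterior is
   the fitted probability evaluated at the observed vector, reported at
   each retention threshold (default 25 000/50 000/75 000/100 000) so
   stability across thresholds can be inspected.

## Synthetic data and what the tests show

The study template transcribes the published design: 24 populations in
three language groups, per-population sample sizes for each marker system
(group totals 433/137/539 for HVR-I and 204/65/267 for Y-STRs), and
per-population haplogroup compositions.  Marker fixtures convert the
one-decimal percentages to integer counts by largest-remainder rounding
(so each population hits its printed N exactly) and write derived calls
along each sample's root path.  Pseudo-observed datasets (PODs) render
single coalescent draws in exactly the observed file formats.

What the generator does *not* emulate: real HVR-I base composition and
site-rate heterogeneity, genotyping error and allelic dropout,
within-group population structure (each language group is one panmictic
deme), and any linkage between the mtDNA and Y panels of one individual.
Passing tests therefore demonstrate that the pipeline is correct and
powerful *under the model class it implements*, not that the demographic
conclusions transfer to any particular real dataset.

### Model-recovery design

The recovery study uses HVRI-type PODs with 25 samples per group, 20 000
simulations per model in the reference tables, and retention of the 1 000
nearest.  The sequence suite is used because it carries between-population
distances and Fst, which separate the two demographies; the Y-STR suite as
specified is within-population only and nearly blind to the difference.
POD-generating parameters are drawn from identifiable sub-regions of the
default priors — central admixture proportion (`alpha ∈ (0.3, 0.7)`),
recent pulse (`Tadm ∈ (10, 40)`), deep MK split (`T2 ∈ (1 000, 4 000)`),
moderate sizes (`N ∈ (1 000, 20 000)`) — because near the boundaries
(`alpha → 0/1`, `Tadm → T1`) the two models are genuinely the same process
and no method can tell them apart.  Reference tables always use the full
default priors.

## Numerical and engineering choices

* Distances between complete (no-missing) sequence matrices are computed
  as one-hot BLAS products and promoted to float64 integers, so the fast
  path agrees with the direct definition to machine precision.
* All randomness flows through one `numpy.random.Generator`; every public
  simulation entry point takes a seed or generator, and identical seeds
  give byte-identical artifacts.
* Largest-remainder rounding breaks remainder ties by insertion order
  (deterministic).
* Reference tables are CSV with a two-line role header (statistic names,
  parameter names) and `%.17g` floats, so write→read round-trips exactly.
* Parameters a model does not use (`Tadm`, `alpha` under tree-like; `T2`
  under admixture) are stored as NaN in the fixed eight-column parameter
  block.

## Limitations

* Model choice only: no parameter posteriors, no regression adjustment of
  parameters, no posterior predictive checks.
* Two models and three demes are wired into the demography; adding models
  means extending `coalsim`, not configuration alone.
* The published frequency table's printed percentages follow no single
  rounding convention, and a few cells match no integer count at their
  printed N; fixtures reproduce every cell to within the table's own
  rounding slack (0.3) and the headline cells exactly.
* The strict stepwise mutation model ignores multi-step mutations and
  length constraints beyond the floor at one repeat.
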