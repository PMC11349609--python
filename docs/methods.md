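# Methods

This note records the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish about behaviour on real data.

## Distances

Distances are Kimura two-parameter, computed per pair from the transition
proportion `P` and transversion proportion `Q` over the sites where both
sequences carry a plain A/C/G/T (**pairwise deletion**; the default of
standard distance software, and the choice that maximises usable sites on
patchy multi-locus data). Ambiguity codes (R, Y, …), N, `-` and `?` are
all treated as missing for distances; they are preserved verbatim on I/O.

* `k2p_all`: `d = -½ln(1-2P-Q) - ¼ln(1-2Q)`.
* `k2p_tv`: `d = -½ln(1-2Q)` — Kimura's transversion component, the
  natural reading of "transversions only" for slow loci such as 12S rRNA.

When a logarithm argument is ≤ 0 the pair is **saturated**: the distance
is undefined and raised as `SaturationError`, never returned as NaN from
the scalar API. Matrix construction converts saturated or zero-overlap
pairs to flagged NaN cells and logs their count; group summaries exclude
them and report how many were excluded. Note that `k2p_all ≥ k2p_tv`
holds exactly at the expectations of the K2P process for any time and
transition/transversion rate ratio, but can be inverted by sampling noise
in transversion-rich finite counts; the test suite checks the inequality
where it is a theorem.

Group summaries give mean/min/max over all cross pairs (between) and over
distinct pairs (within, undefined for singleton groups), with an optional
percent scale (100×d) and a square presentation with means above and
ranges below the diagonal.

## Dating

Two calibration rules, both strictly increasing in distance:

* **Rate rule** (cytb): `t = d% / r`, default `r = 2.1` percent per My.
  The rate is interpreted as *pairwise* divergence per My — i.e. `d` is
  the full tip-to-tip divergence — because only this reading reproduces
  the published point estimates and range endpoints from the published
  clade-average distances (8.16% → 3.89 My; 6.05 → 2.88; 10.74 → 5.11).
* **12S transversion rule**: `t = (d% − 0.0584)/0.0854`. Distances below
  the 0.0584 intercept produce negative times, reported with a
  "< intercept resolution" flag rather than clamped: the calibration
  simply cannot resolve divergences that shallow.

Ranges are propagated by applying the rule to the min/max of the distance
summary; no other uncertainty is quantified.

## Trees

Neighbour-joining is the built-in tree builder (standard Q-criterion
agglomeration). Ties on the Q-criterion are broken toward the
lexicographically smallest label pair (internal nodes carry their
smallest descendant label), so output is deterministic. Negative branch
lengths are clamped to zero with the clamped total logged. Outgroup
rooting places the root at the midpoint of the edge separating the
outgroup from the ingroup and fails loudly when no such edge exists.
User-supplied Newick trees (e.g. from external ML/Bayesian runs) are
first-class wherever a tree is consumed.

## Delimitation statistics

* **Monophyly** is exact descendant-set equality on the rooted tree.
* **Rosenberg's P(AB)** is computed by exact recursion over random
  sequential pairwise coalescence of `a + b` exchangeable lineages:
  `R(1,1)=1`, `R(i,j) = [C(i,2)R(i-1,j) + C(j,2)R(i,j-1)] / C(i+j,2)`
  for reciprocal monophyly, and `M(1,j)=1` with the same recursion for
  single-clade monophyly. Both variants are exposed because the two
  readings circulate in the literature; **reciprocal is the default** and
  the report records which was used. Arithmetic is exact rational on
  request. P(AB) is reported as NA when the tested monophyly does not
  hold, and significance statements are plain threshold comparisons with
  no multiple-testing correction.
* **Intra/inter** pools within-group distinct pairs over both groups and
  divides by the mean of all cross pairs.
* **Prob correct** is a reimplementation choice, not a plugin clone: each
  individual is classified by its nearest non-self neighbour
  (leave-one-out); distance ties involving a non-conspecific count as
  incorrect (conservative). The CI is the normal approximation
  `p ± 1.96·sqrt(p(1-p)/n)` truncated to [0, 1]; the exact construction
  behind published intervals of this kind is unstated, so the simplest
  standard interval was chosen.
* Distances for the last two statistics default to patristic distances on
  the supplied tree (tree-based, like the original tooling), with any
  sequence-distance matrix as an alternative; the report records the mode.

## Haplotype networks

Column masking is **global**: any column containing a gap, `?`, N or
ambiguity code in any sequence is removed for all sequences, matching the
behaviour of standard network software. Identical sequences collapse into
haplotypes ordered by decreasing count then sequence (byte-stable
output). The network is a minimum-spanning network: an edge of weight `w`
is kept iff `w ≤ w* + ε`, where `w*` is the minimax connection weight of
its endpoints; `ε = 0` yields the union of all minimum spanning trees, so
equal-weight alternatives appear as reticulations. The exact
statistical-parsimony 95% connection limit is **not** reimplemented (its
published estimator is intricate, and the motivating networks were
single-component); a user-set `max_steps` stands in, default unlimited.
This is a fidelity gap: very divergent haplotype pairs that statistical
parsimony would refuse to connect remain connected by default.

## Morphometrics

The driver enforces the order: missingness filters → collinearity pruning
→ UPGMA clustering on the observed (pre-imputation) data → PMM imputation
→ PCA / size-and-shape / classification on the single imputed table.
Using the imputed table for both the raw and size-corrected ordinations
is a deliberate simplification of an ambiguity in common practice.

* **Filters**: variables with > 20% missing first, then individuals with
  > 15% missing over the surviving variables; every removal is logged
  with its fraction.
* **Pruning**: iteratively drop the non-anchor of the largest-|r| pair
  above 0.90 (pairwise-complete Pearson); the anchor is the variable with
  fewer missing cells, ties going to the earlier column. 0.90 is the
  conservative end of the conventional 0.90–0.95 band; configurable.
* **Imputation** is chained-equations predictive mean matching: per
  iteration and per incomplete variable, an OLS regression on all other
  variables (fit on rows where the target is observed) predicts all rows,
  and each missing cell takes the observed value of one of 5 closest-
  prediction donors, sampled with the seeded generator; 50 iterations by
  default. Single imputation (one completed table) is used because the
  downstream ordination consumes one table; the seed is recorded in the
  run manifest.
* **Univariate tests**: Bartlett's test gates each variable at α = 0.05
  to one-way ANOVA + Tukey HSD (family-wise within the variable; no
  across-variable correction) or to Kruskal–Wallis.
* **Size and shape**: `gm_i = (Π_j x_ij)^(1/p)`;
  `shape_ij = ln(x_ij/gm_i)`. Shape vectors sum to zero and are invariant
  to per-specimen rescaling, which is what "size-corrected" means here —
  only isometric size is removed.
* **PCA** is an eigendecomposition of the correlation matrix; components
  are ordered by variance fraction and each loading vector's sign is
  fixed so its largest-magnitude entry is positive (determinism).
* **Euclidean distances** with missing cells are pairwise-complete and
  rescaled by `sqrt(p/m)`, the convention of common statistical software;
  UPGMA node heights are half the merging average distance, so the
  dendrogram is ultrametric.
* **k-NN classification** is leave-one-out on optionally standardized
  variables; voting ties are broken by the single nearest neighbour's
  label. The neighbourhood size is unstated in the motivating analyses,
  so `k = "auto"` scans odd k in 1..15 and keeps the smallest k
  maximizing LOO accuracy; the chosen k is always reported.

## Synthetic data

Sequences evolve site-independently under the K2P rate matrix along an
ultrametric species tree of group ancestors (branch lengths in My), with
a **star genealogy** within groups: equal tip branches of
`within_group_time`, ending at a group ancestor. The star is a deliberate
simplification of a coalescent — it induces the within/between distance
hierarchy the analysis consumes while keeping all expectations
closed-form (expected pairwise K2P distance = rate × divergence time,
the same convention the dating module inverts, so round trips are exact
in expectation). The per-lineage rate is `pairwise_rate/200` per site per
My, split by `kappa` (transition/transversion rate ratio, default 4, a
typical mitochondrial value).

Morphometric tables are multiplicative:
`x_ij = base_j × size_factor_g × exp(size deviate) × exp(noise)`, with
lognormal individual size deviates (`cv_size`, default 3%) and per-cell
noise (`cv_noise`). Optional near-duplicate "clone" variables (0.5%
jitter) exercise the collinearity filter, and cells are deleted
completely at random. The canonical fixture uses 8% noise and 4% size
spread, matching the 5–15% per-variable coefficients of variation typical
of adult dasyurid skull measurements, so that only near-duplicates cross
the 0.90 pruning threshold.

The canonical fixture study has four populations of 7 (WA, NT, Qld, PNG)
with a 3.9-My split between {WA,NT} and {Qld,PNG}, 0.6-My splits within,
a 2-sample outgroup at 14 My, a fast locus (2.1 %/My, 600 bp) and a slow
locus (0.35 %/My, 567 bp, zero within-group time — conspecific sequences
are identical, so shared haplotypes exist by construction); and a
morphometric table of 15 + 8 + 7 specimens where one group is 10%
smaller and the other two are identically distributed.

**What passing tests do not show**: real data have coalescent variance,
rate variation among sites and lineages, indel structure, non-random
missingness and measurement error correlated within collectors — none of
which the generators emulate. The synthetic checks validate the
*machinery* (estimators invert the generating model; procedures follow
their stated contracts), not the biological robustness of any rule of
thumb.

## Problem sizes and numerical choices

The test suite and the acceptance script run simulations at sizes chosen
to keep the whole run desk-scale on one CPU: 10 kb alignments with 6
samples for round-trip checks (6 replicates), a 10⁵-site single pair for
chain-expectation checks, 200 replicates for the size-ANOVA power check,
and the 30-sequence fixture for end-to-end stages. NJ and the network
builder are O(n³)/O(n² log n) and comfortable to a few hundred tips.
Exact rational arithmetic is used for monophyly probabilities in tests;
doubles in reports. Degenerate inputs (saturated pairs, singleton groups,
constant variables, all-masked alignments) raise or flag rather than
propagate NaN silently.

## Known limitations

* No maximum-likelihood or Bayesian tree inference, topology tests,
  model selection, or haplotype phasing — trees and phased alignments are
  inputs.
* The statistical-parsimony connection limit is approximated by a step
  cutoff.
* The Springer 12S calibration cannot resolve shallow divergences
  (distances below its intercept) and the rate rule carries no
  uncertainty beyond range propagation.
* Prob-correct and the k-NN classifier are reimplementation choices where
  the original tooling's internals are unpublished; both are documented
  contracts rather than clones.
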