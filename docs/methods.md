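# Methods

## The model

`mlof` scores the probability that a set of pathogenic missense variants
acts through loss of function, from two structural summaries computed on
a predicted monomer model (AlphaFold-DB conventions: single chain
numbered along the reference sequence, per-residue pLDDT in the B-factor
column; only Cα atoms are used).

**EDC.** For every retained residue the Euclidean Cα distance to the
nearest disease-variant position and to the nearest non-disease residue
is taken, each excluding the residue itself (a residue would otherwise
contribute distance 0 to its own class and poison the averages; the rule
is applied symmetrically to both searches).  EDC is the ratio of the
common logarithms of the two means, oriented so that the disease term is
the numerator: clustered disease positions leave most residues far from
the nearest disease site while the non-disease set covers the structure,
giving EDC > 1; dispersed positions give EDC near 1.  Residues with
pLDDT below 70 are removed before any distance is measured — pathogenic
missense variants concentrate in structured regions, and retaining a
large disordered shell would make any variant set look clustered
relative to the model volume.  At least three distinct, confidently
modelled variant positions are required (5 and 10 are stricter tiers);
a mean nearest distance ≤ 1 Å would make a logarithm non-positive and is
rejected as degenerate geometry.

**Mean ΔΔG_rank.** Predicted stability changes (kcal/mol, one value per
substitution, FoldX-style) are consumed as tables; the package never runs
a predictor.  Because raw ΔΔG scales vary between proteins, values are
rank-normalised per protein: ascending ranks, ties averaged, rescaled by
(r−1)/(m−1) — the unique affine map sending the mildest substitution to
0 and the most damaging to 1.  The substitution universe is restricted to
amino-acid changes reachable by a single nucleotide change; reachability
is computed over all codons of the standard genetic code by default,
with a most-frequent-human-codon mode available for sensitivity analysis
(usage restriction can only shrink the universe, and the precise
restriction used upstream of published ΔΔG sets is not recoverable from
the tables themselves).  Substitutions present in several overlapping
fragments of one protein take the mean ΔΔG before ranking.  A variant
set is summarised by the mean of its per-variant ranks; variants in
disordered regions keep their ranks and count toward the weight.

**From metrics to mLOF.** Gaussian kernel densities of each metric are
fitted separately to LOF-mechanism and non-LOF-mechanism reference
genes, evaluated at 1024 equidistant points spanning the pooled data
range extended by three bandwidths per side (so capped observations
always fall inside the grid).  The bandwidth is three times the
Sheather–Jones solve-the-equation plug-in bandwidth of each class
sample; the ×3 factor smooths the resulting probability curve into
monotonicity, which is asserted by a regression test.  The plug-in
solver follows the classical two-stage formulation (pilot bandwidths
1.24·s·n^(−1/7) and 1.23·s·n^(−1/9), s = min(SD, IQR/1.349)); it is
pinned against R's `bw.SJ(method="ste")` to 1% on frozen samples (R
evaluates the pair sums on a 1000-bin approximation, so exact equality
is not expected) and falls back to Silverman's rule with a warning on
pathological samples.  Observations are capped at empirical percentile
bounds before scoring: by default each cap sits at the owning class's
own tail (for mean ΔΔG_rank, the 90th percentile of the LOF sample and
the 10th of the non-LOF sample; mirrored for EDC, whose LOF-like tail is
low), with a pooled-percentile alternative one configuration switch
away.  The capped observation is scored at the nearest grid point (ties
toward the lower index) as f_LOF/(f_LOF + f_non-LOF), and the two
marginal probabilities are combined by the case-specific weighted mean
described in the README — each metric weighted by the number of
observations behind the other, which shifts weight onto EDC when
variants sit in disordered regions and onto ΔΔG when few positions are
structured.  When EDC is uncomputable the score degrades to P_LOF(ΔΔG)
alone and is flagged `ddg_only` in every downstream report.

**Posteriors.** Gene-level priors pDN, pGOF, pLOF are three independent
binary probabilities from an upstream proteome-scale model, not a
simplex; each is updated independently on the odds scale, with mLOF as
the LOF likelihood and 1−mLOF for the two non-LOF mechanisms, so that
logit(postLOF) = logit(mLOF) + logit(pLOF) exactly.  A published typeset
variant of these update rules is retained behind a `literal` flag for
comparison only: its postLOF denominator factors the prior out (the
update collapses to the mLOF score itself) and its postGOF denominator
mixes the DN prior into the GOF update, so it cannot be the intended
Bayes form; the corrected odds form reproduces the printed DN update
exactly and is the default.  The suggested mechanism is the argmax of
the three posteriors (deterministic tie-break LOF > DN > GOF).  Warnings:
`ALL_PRIORS_LOW` when every prior falls below 0.2 (the gene is atypical
for the prior model's training data), `DISCORDANT` when the prior's
favoured side of the LOF/non-LOF divide contradicts the side of the
0.508 threshold the mLOF score falls on, and `DDG_ONLY` as above.  All
floors and thresholds are configurable.

## Evaluation procedures

Scores are oriented so larger = LOF; positive calls are made at
score ≥ t.  AUROC is computed in rank-sum (Mann–Whitney, ties half)
form and cross-checked against trapezoidal ROC integration in the tests.
The optimal threshold minimises the Euclidean distance to the ROC (0,1)
corner over midpoints between adjacent distinct scores plus ±∞
sentinels; ties break toward higher specificity, then the lower
threshold (with midpoint candidates the ≥-vs-> choice at the threshold
is immaterial for distinct scores).  Balanced precision rescales
precision to a notional 1:1 class balance, TPR/(TPR+FPR); the balanced
precision-recall curve is swept over descending distinct-score
thresholds, truncated at first full recall, and integrated over recall
by the trapezoid rule.  Bootstrap intervals are seeded percentile
intervals over 1,000 resamples drawn at the unit of analysis (gene or
phenotype, never individual variants); resamples on which a statistic is
undefined (e.g. single-class) are redrawn with a capped retry.
Multiplexed-assay scores are classified by distance from the mean of a
reference (synonymous-variant) distribution in units of its SD, with
the tail direction chosen per assay.

## Phenotype-level analyses

Phenotypes are classified by inheritance from gene-level OMIM
inheritance plus phenotype-level HPO annotations.  The underlying
definitions overlap, so a fixed precedence is applied and documented:
X-linked genes first (XLR), then phenotypes annotated with both modes
(AD/AR-same), then the mixed-inheritance gene rules (a gene is "mixed"
when it has at least one AD and one AR phenotype, each with at least
three distinct missense positions — the same eligibility rule used for
scoring), then exclusive AR and AD.  X-linked dominant phenotypes have
no class of their own and fall out as unclassified.  Mechanism classes
for AD phenotypes: LOF requires a reported LOF mechanism or sufficient
dosage-pathogenicity evidence and excludes DN/GOF-labelled genes; GOF
and DN require the respective reported mechanism and exclude
mixed-inheritance genes; Unknown covers AD phenotypes of exclusively AD
genes with no reported mechanism.

Mechanism composition assigns each scored phenotype its argmax posterior
mechanism and reports group fractions.  Credible intervals propagate the
uncertainty of the threshold estimate: under each bootstrapped threshold
a phenotype is called LOF when its mLOF score clears that threshold and
otherwise takes the better of its DN/GOF posteriors; the 2.5/97.5
percentiles of the resulting fractions form the interval.  (A pure
argmax rule, which ignores the threshold and degenerates the intervals,
is available as a parameter.)  A multi-phenotype gene is *hybrid* when
at least one phenotype scores on each side of the threshold.  Divergent
phenotype pairs are ranked by |ΔmLOF| within genes, excluding
recessive-only genes and pairs whose variant sets are identical or
nested (their scores are not independent); a pair is flagged when its
delta exceeds the 95th percentile of all pair deltas and it straddles
the threshold.

Ontology semantic similarity uses Lin's measure,
2·IC(MICA)/(IC(a)+IC(b)), with information content −ln of the fraction
of corpus phenotypes annotated to a term or any of its descendants; the
root has IC 0 and similarity through the root alone is 0.  IC always
comes from the user-supplied annotation corpus — nothing is hard-coded —
and phenotype-level similarity is the symmetric best-match average of
pairwise Lin scores, the common default of the established ontology
packages, pinned here by a hand-enumerated seven-term fixture.
DN prioritisation among AD–AR pairs flags a pair high-confidence
non-LOF when the dominant phenotype scores below the threshold and below
its recessive partner, keeps genes whose DN prior exceeds their GOF
prior, takes one pair per gene (highest similarity) and reports pairs
with similarity above 0.5.

## Synthetic data

All tests and the acceptance script run on generated inputs; every
generator is a pure function of its parameters and seed.

* **Structures** are Cα traces at 3.8 Å virtual-bond spacing: line,
  ring, ideal α-helix (2.3 Å radius, 1.5 Å rise, 100° turn) or a compact
  random packing ("globule") with 3.8 Å minimum separation; pLDDT is
  constant, per-residue, or seeded Gaussian noise.
* **Variant planting** offers a contracting-ball construction (any
  geometry; positions drawn evenly from a candidate pool that shrinks
  around a focal residue) and a stride construction on chain geometries
  (picks {0, s, 2s, …} with the stride shrinking from even coverage down
  to 3).  The stride family makes EDC exactly non-decreasing in the
  clustering parameter — each stride step moves the far tail linearly
  away while within-gap distances shrink sublinearly, and stride ≥ 3
  keeps every disease residue a non-disease neighbour so the denominator
  is pinned — and is what the monotonicity tests use.  The ball
  construction concentrates positions spatially but re-assigns discrete
  picks between parameter values, which can wiggle EDC by a few
  hundredths; it is used for fixtures, where only the end-to-end
  contrast matters.
* **ΔΔG tables** cover the full single-nucleotide universe; the
  LOF-like mode draws strongly destabilising values (normal, mean
  3.0 kcal/mol) at designated pathogenic positions over a mild
  background (mean 0.8), the non-LOF-like mode draws mild values with
  slightly milder pathogenic positions.
* **Reference cohorts** draw per-gene (EDC, mean ΔΔG_rank) pairs from
  class-conditional distributions: EDC normal with LOF located at 1.02
  (SD 0.10) and non-LOF at 1.25 (SD 0.15); mean ΔΔG_rank beta with LOF
  mass high (Beta(6,3)) and non-LOF low (Beta(3,6)); 150 genes per class
  and 3–25 variants per gene by default.  The locations encode the
  direction of separation seen in disease genes (LOF: dispersed,
  destabilising; non-LOF: clustered, mild) at a realistic overlap; the
  scales are round values chosen once for that overlap.  The cohort is a
  stand-in for the real reference genes, which require external
  snapshots; a fitted model from any user-supplied reference table drops
  in unchanged.
* **Phenotype cohorts** plant known hybrid/non-hybrid genes by drawing
  per-phenotype scores on chosen sides of the threshold (0.05 margin),
  and toy ontologies are rooted is_a trees with seeded leaf annotations.

What passing tests on these fixtures shows: the implementation computes
its defined quantities exactly (oracle equivalence), is deterministic,
and recovers planted structure under the stated class separations.  What
they cannot show: performance on real proteins, where EDC geometry, ΔΔG
error structure, annotation noise and class overlap differ from the
parametric stand-ins; toy structures in particular are small, so modest
variant sets sit closer to the clustered regime than in real proteins
and fixtures use larger variant sets to compensate.

## Numerical choices and limitations

Grid lookups use the nearest grid point rather than interpolation,
matching the stated scoring procedure; ties break toward the lower
index.  Ranks use average ties.  Bootstrap seeds derive from the
caller's seed via numpy Generators; identical seeds reproduce every
report byte-for-byte.  Problem sizes in the tests and the acceptance
script (150 + 150 reference genes, 300 held-out genes, 1,000 bootstrap
resamples, 100-structure oracle sweeps, 80-residue fixtures) were chosen
as the smallest sizes at which the estimates are stable.  Known
limitations: monomer models only (no complexes, no mmCIF), no ΔΔG
prediction or genomic-coordinate mapping, priors are consumed rather
than derived, and two-dimensional joint densities of the two metrics are
out of scope (the weighted mean deliberately avoids modelling their
dependence).
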