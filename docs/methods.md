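# Methods

## The sex-determination model

`gynomap` models gynodioecy in diploid wild strawberry as cyto-nuclear
epistasis among a maternally inherited cytoplasmic male sterility factor
(CMS) and three unlinked nuclear loci:

* **LG4 (*MS/mf*)** — an inhibitor locus. A single dominant *MS* copy blocks
  the LG6 restorer, so *MS_* plants on a sterilizing cytoplasm are female.
  *MS* is dominant to *mf* and epistatically dominant to *R*.
* **LG6 (*R/r*)** — a restorer-of-fertility locus. One dominant *R* copy
  restores pollen function; *rr* plants on a sterilizing cytoplasm are
  female. Male sterility is recessive at this locus.
* **LGx (*T/t*)** — a third locus at which *tt* homozygotes are male
  sterile. Whether LGx is an independently evolved restorer of a second CMS
  or a free-standing recessive sterility locus is genetically open; the
  default rule treats *tt* as sterilizing on any CMS cytoplasm, and an
  alternative rule (`second_cms_phenotype`) scopes the *tt* path to a
  configurable set of mitotypes. Both choices reproduce the observed family
  ratios, because the study's crossing design never separates them.

A plant is FEMALE iff its cytoplasm carries CMS **and** (it carries ≥ 1
*MS*, or is *rr*, or is *tt*); otherwise it is HERMAPHRODITE. Without CMS
every nuclear genotype is hermaphroditic. The three mitotypes observed in
the study populations (B, C, F) are all treated as CMS-bearing, since
sterility segregates on all three backgrounds.

**Assumptions.** The three loci assort independently (asserted by the
segregation data; the package does not model linkage among them). Cytoplasm
is strictly maternal. Sex is binary (female / hermaphrodite); partial male
fertility is out of scope. *MSMS* homozygotes are excluded from default
hypothesis spaces — hermaphrodite sires are necessarily *mfmf* under the
model, so *MS* transmits only maternally and is effectively always
heterozygous — but remain representable (`include_msms=True`).

All gamete, progeny and sex-ratio distributions are exact rationals
(`fractions.Fraction`), so expected ratios such as 1:3, 1:1, 0:1 and 2:1 are
reproduced bit-exactly; floats appear only inside the statistics.

**Ratio labels** follow the female:hermaphrodite convention of the crossing
tables throughout. The classic two-locus complementary-epistasis ratio
(selfing a *Rr Tt* plant) is therefore written 7:9 — seven sixteenths female
— which the genetics literature usually names "9:7" with the dominant class
first. Tests assert the exact fraction 7/16 to avoid the ambiguity.

**Viability selection** is a list of conjunctive genotype-class rules, each
with a survival probability, applied before phenotyping and renormalized
among survivors. The one observed case — about half of *Rr* progeny dying
(25 % of all offspring) when one particular hermaphrodite sires
interpopulation crosses, turning an expected 1:1 into the observed 2:1 —
ships as a named, cross-scoped preset (`MRD93_INTERPOP_LETHAL`).

## Segregation statistics

* **χ² goodness of fit**: Pearson, *no* continuity correction (this is what
  reproduces the printed family statistics; Yates-corrected variants sit
  behind a flag), df = 1 for two-class ratios, p from the continuous χ²
  distribution. Families with fewer than 10 sexed progeny are reported
  `applied=False` (the tables' "NA" rule).
* **Degenerate hypotheses** (0:1, 1:0) bypass χ²: a perfect fit scores 0
  with p = 1; any observation in the impossible class rejects outright and
  is flagged as an anomaly (single anomalous females do occur in real
  families; tolerant likelihood scoring lives in the inference engine, not
  in the test).
* **Fisher's exact test** is two-sided by the minimum-likelihood convention
  (sum of hypergeometric probabilities ≤ the observed table's), stated
  explicitly because two-sided conventions differ; it is cross-checked
  against full enumeration for n ≤ 30 in the test suite.
* **Multiple testing**: none by default, matching the source analyses;
  Bonferroni and Benjamini–Hochberg are available.

Three printed family χ² values are irreproducible by any of these
conventions (recomputation gives 1.82 vs printed 2.70; 10.0 vs 4.6; 0.66 vs
0.07). The bundled fixture marks them and the tests assert the
*disagreement*, not the printed numbers.

## Joint parental genotype inference

The published analysis infers parental genotypes cross by cross with ad hoc
reasoning. `infer_genotypes` formalizes it as one exhaustive search:

* Each parent's hypothesis space is every phenotype-consistent multilocus
  genotype (hermaphrodites: mfmf × {RR, Rr} × {TT, Tt}, 4 hypotheses;
  females: 14 — five *mfmf* genotypes that are *rr* or *tt*, plus nine
  carrying one *MS* copy), intersected with user constraints.
* The score of a joint assignment is the sum over families of the binomial
  log-likelihood of the observed female count at the model-predicted female
  fraction, **minus a homozygote-parsimony penalty** `het_penalty`
  (default 2.5 nats) per heterozygous parental locus.
* Branch-and-bound search over connected components of the crossing design
  returns the maximizing assignment(s); exact ties are enumerated, never
  broken silently. Parents whose partners are all placed contribute
  separably and collapse to their conditional argmax set, which keeps the
  12-parent design tractable (a few thousand node evaluations, ~2 s).
* Coordinates whose alternatives leave the data likelihood numerically
  unchanged (no informative segregation anywhere in the design) are
  reported as *undetermined* with their interchangeable alternatives.

**Why a parsimony prior.** Pure maximum likelihood over the full design
does not return the published genotype table: one female-skewed family
(13:4 against a predicted 1:1 — a deviation the study itself reports as
unexplained) is enough to drag its dam toward spurious heterozygosity at
two loci by ≈ 2 nats. The cross-by-cross reasoning in the source implicitly
invokes heterozygosity only where segregation demands it; the penalty makes
that Occam principle explicit and tunable. The default of 2.5 nats requires
roughly a χ²₁ of 5 (p ≈ 0.025) of likelihood support before a heterozygous
call is made, which also protects synthetic-data inference from
noise-driven heterozygote calls at family sizes near 50. `het_penalty=0`
recovers pure ML, and then exact ties are reported as such.

**Anomaly tolerance.** `anomaly_eps` (default 0.01) is a per-progeny
misclassification probability folded into the expected fraction, so one
anomalous female in an otherwise all-hermaphrodite family penalizes rather
than zeroes the likelihood. Strict mode is `anomaly_eps=0`.

**Lethality model selection.** When viability presets are supplied the
engine fits with and without them and reports both best log-likelihoods; on
the bundled crossing table the lethality preset improves the joint fit by
≈ 8 log-units, which is the quantitative form of the 2:1 argument.

Families with fewer than `n_min` (default 10) sexed progeny are excluded
from both the likelihood and the per-family χ² diagnostics;
`include_small_families=True` restores them, since tiny families are still
qualitatively informative.

## Two-point LOD mapping and the candidate interval

Male sterility is coded as a recessive Mendelian locus (sterile *rr*,
fertile *R–*; a dominant coding covers the inhibitor-locus case). For a
selfed-F2 family and a codominant biallelic marker,

LOD(r) = Σᵢ log₁₀ [ P(markerᵢ, traitᵢ | r) / P(markerᵢ, traitᵢ | r = ½) ],

with joint class probabilities from squaring the coupling-phase gamete
frequencies {(1−r)/2, (1−r)/2, r/2, r/2} through selfing and collapsing by
trait dominance. Phase is resolved by maximizing over both assignments; the
grid is r ∈ {0, 0.005, …, 0.5}; individuals missing at a marker are dropped
for that marker only; LOD(½) is identically 0. For perfect cosegregation
the maximum is the closed form n_rr·log₁₀4 + n_R–·log₁₀(4/3): 8.94 for the
8 + 33 mapping family, consistent with (and slightly above) the published
peak of 8.8, whose exact provenance — missing calls, or internals of the
original map-construction software — is unrecoverable; the package
therefore asserts a lower bound, not equality. Markers above LOD 3 are
flagged significant.

The candidate region is the maximal run of zero-mismatch markers (a
mismatch is an individual impossible at r = 0 under the best phase)
containing the LOD peak, bounded by the nearest flanking markers with ≥ 1
mismatch; interval length is the simple bound-position difference,
(36,607,138 − 34,839,229)/10⁶ = 1.768 Mb at three decimals. A
`mismatch_tolerance` knob relaxes "perfect" for noisy data. Coordinates are
1-based inclusive throughout, matching marker names like `Fvb6_35142280`.

## Gene-class window scan

Genes are binned by start coordinate (configurable to midpoint) into
half-open windows [k·w, (k+1)·w) in 0-based coordinates — stated to avoid
double counting at boundaries — tiling each assembly chromosome; the final
partial window keeps its count with density scaled by its true span, and
window counts always sum to the class total. Clusters are maximal runs of
windows at or above a per-Mb density threshold, ranked by peak window
count, then total count, then coordinates.

## The synthetic-data generator

The simulator emulates the study conditions end to end: parent panels drawn
under Hardy–Weinberg from per-population allele and mitotype frequencies
(presets carry the two study populations' observed allele counts — NM-LNF:
r at 9/12, t at 1/12, MS absent, mitotype F fixed; OR-MRD: MS at 3/12, r
and t at 1/12, mitotypes 90 % C / 10 % B); crosses with independent
assortment of the model loci; markers linked to the LG6 locus recombining
at the Haldane fraction of their physical distance (no interference;
default scale 3.5 cM/Mb, roughly the study map's 326 cM over a ~225 Mb
genome, configurable); cross-scoped viability; i.i.d. missing marker calls
(default dropout 5 % where enabled — the real tables show scattered missing
data but no mechanism). Selfs reuse the dam's genotype and phase.
Randomness flows from one master seed with per-family substreams keyed by a
CRC32 hash of the family id, so adding a family never perturbs the others
and identical spec + seed gives byte-identical output files.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: genotyping error (missingness is the only
data pathology), segregation distortion beyond explicit viability rules,
cross-compatibility / seed-set variation (the study's poor H×H seed set in
one direction is represented only by the dropout knob), marker–marker
interference (each marker recombines independently with the anchored
locus), multi-generation pedigrees, and selection on female fitness.

### Validation studies and problem sizes

* **χ² calibration**: 500 simulated *Rr*-self families of 50 progeny; the
  test against 1:3 at α = 0.05 rejects ≈ 4–5 % of families (the exact
  binomial-lattice value is 4.8 %), asserted within [3 %, 8 %].
* **Parameter recovery**: 100 synthetic full diallels of 6 parents at 50
  progeny per family. A full diallel needs every parent as both dam and
  sire, which only hermaphrodites can serve, so panels are 6 hermaphrodites
  drawn from the two population presets, alternating by replicate. A
  replicate is recovered when the generating assignment is in the reported
  maximum-likelihood set, with undetermined coordinates counting as ties.
  Measured recovery is 90–94 % across seeds; the residual misses are true
  weak-signal heterozygotes (a *Rr Tt* parent whose only evidence is a
  single self's 7:9-vs-1:3 contrast, worth ≈ 4 nats in expectation against
  the 2.5-nat parsimony penalty) — the bias side of the prior that makes
  the real-data inference stable.

## Numerical choices

* Exact rational arithmetic for all model distributions; expected fractions
  are converted to floats only inside likelihoods and statistics.
* Inference caches expected fractions per (dam genotype, sire genotype,
  active viability rules) and per-cross log-likelihood kernels; the
  branch-and-bound bound is the saturated binomial log-likelihood at the
  clipped empirical fraction. Score ties use an absolute tolerance of 1e-9;
  undetermined-coordinate detection uses 1e-6 on the data log-likelihood.
* Degenerate inputs: zero-progeny families parse and are flagged, never
  tested; empty cross lists score 0; a viability configuration that kills
  every progeny class raises; monomorphic markers are flagged inapplicable
  rather than scored.

## Known limitations

* The parsimony prior is a fixed per-locus penalty, not a
  population-genetic prior; with strong allele-frequency information an
  empirical-Bayes Hardy–Weinberg prior would be better calibrated.
* Two-point LOD only: no multipoint likelihood, no marker ordering, no QTL
  interval mapping; the trait is placed relative to one marker at a time.
* The fitness costs of restoration discussed in the gynodioecy literature
  are not modeled; nor are polyploid relatives of the study system.
* The inference engine treats families as independent binomial draws;
  shared-environment or maternal effects would violate that silently.
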