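# Methods

This note documents the models, rules and numerical choices behind
`dnsvkit`, and what the synthetic cohorts do and do not establish.

## Coordinates and junction model

Positions are 0-based throughout; intervals are half-open.  A *breakend* is
a (chromosome, position, orientation) triple in which `+` means the
sequence to the left of the position is retained into the rearrangement
joint and `-` means the sequence to the right is retained (the common BEDPE
reading).  A *junction* is the canonical ordered pair of breakends fused by
one rearrangement.  Under this convention the orientation pair classifies
every intrachromosomal junction: deletion-type `(+,-)`, tandem-duplication
type `(-,+)`, and the inversion "head" `(+,+)` / "tail" `(-,-)` pair; all
interchromosomal junctions form a fifth class.  BEDPE is the external
format (breakend position = the `end` coordinate of each half), with
evidence carried in a key=value attribute column (`SCORE`, `DR`, `CR1/CR2`
clipped reads per trio role, `VAF`, `FLAGS`); upstream caller-specific VCF
conversion is outside scope, so this attribute schema is the package's
interchange contract.

## De novo filter cascade

Stage order is fixed: (1) size ≥ 50 bp and absence of a matching parental
call; (2) chrY removal; (3) parental clipped-read veto — ≥ 4 clipped reads
at either breakpoint or ≥ 2 at both, in either parent; (4) removal of
junctions recurring in ≥ 3 distinct samples; (5) caller flags PASS or
MGE10kb with score > 30 (strict) and discordant reads > 10 (strict),
rescuing IMPRECISE calls that carry an independent colocalized read-depth
CNV; (6) VAF ≥ 0.1 (0.1 itself is kept).

Choices the rules leave open:

* **Call matching** (parent/child and cross-sample): same orientation
  class, each breakpoint within 200 bp, and reciprocal span overlap ≥ 0.5
  for intrachromosomal junctions.  200 bp reflects typical short-read
  breakpoint uncertainty; no tolerance is externally prescribed.
* **Recurrence counting** is over distinct samples of any role, carrier
  included, and is evaluated against the candidate pool as it stands after
  the proband-specific and chrY stages.  Making recurrence a property of
  the candidate pool (rather than of whatever survives unrelated evidence
  filters) keeps the clip, recurrence and VAF predicates commutative,
  which the test suite verifies.
* **Rescue scope**: the IMPRECISE + read-depth rescue bypasses only the
  flag/score/discordant stage.  It addresses breakpoint imprecision, not
  de novo evidence, so the parental-clip, recurrence and VAF stages still
  apply to rescued calls.
* Translocations arising by retrotransposon-mediated 3′ transduction are
  excluded via an input annotation flag; detecting them is out of scope.
* Visual inspection of real data has no algorithmic counterpart; synthetic
  runs use ground-truth comparison instead, and the CLI exports a review
  queue for real data.

## Clustering

Junctions are clustered per proband (de novo events are private to a
child, so cohort-wide clustering would only dilute the background model).
With n junctions on a genome of length G, breakend density is
λ = 2n/G, and a junction pair at minimum inter-breakend distance d (over
shared chromosomes; ∞ otherwise) has background probability
p = 1 − exp(−2λd) of lying at least that close.  All C(n,2) pairs are
tested, the Benjamini–Hochberg step at α = 0.05 fixes the significance
cutoff, and significant pairs are merged transitively (single linkage,
ties broken by smaller p then lexicographic junction id).  The procedure
is scale-invariant (only λd matters), monotone in α, and agrees with a
naive O(n³) repeated-merge agglomeration, which the tests exercise as an
independent oracle.  It is an approximation in the spirit of
likelihood-based rearrangement clustering: no fixed distance threshold
exists anywhere in the pipeline.

## Copy-number profiles and classification

Crossing a `-` breakend left-to-right raises copy number by 1 and a `+`
breakend lowers it by 1, from a diploid baseline.  This dosage algebra
yields (2,1,2) for a deletion, (2,3,2) for a tandem duplication, a flat
profile for a balanced inversion pair, and (2,3,4,3,2) for
DUP-TRP/INV-DUP.  Profile segments shorter than 300 bp are treated as
breakend-offset slivers (two nominally identical positions rarely agree to
the base pair) and carry no signal; 300 bp absorbs a 200 bp matching
window plus margin.  Read-depth segments, when provided, corroborate the
junction-derived states by majority-bp vote; a contradiction flags the
profile discordant and classification falls back to junction-only
evidence.  Read-depth-only segments never mint clusters — depth calls
without read orientation cannot be placed in a rearrangement
configuration.

The decision tree, in order: single junctions map to DEL / TANDEM_DUP (or
Unclassified).  An inversion head+tail pair maps by its profile —
(3,4,3) gains → DUP-TRP/INV-DUP; flat with spans equal within
max(1 kb, 10 % of span) → reciprocal inversion (balanced before
unbalanced); two losses → Loss-Inv-Loss; one loss → Inv-Loss; loss+gain →
Loss-invDup; two gains → DUP-NML-DUP; a single gain is an inverted
insertion handled as below.  Two deletion-type junctions with disjoint
spans → Loss-Loss ("adjacent" means co-clustered and disjoint; no numeric
gap bound is imposed).  Insertion-shaped pairs (one site chromosome with a
near-zero gap, one donor segment; direct `{(+,-),(-,+)}` or inverted
`{(+,+),(-,-)}` orientation) map to: reciprocal translocation when both
gaps are tiny and copy number flat; dispersed or inverted duplication when
the donor gain is read-depth-confirmed; templated insertion when the donor
is ≤ 10 kb without depth confirmation (a depth caller cannot see
sub-10 kb gains, so a short flat template and a short duplicated template
are observationally identical); deletion bridge when a ≤ 10 kb template
spans a site loss; translocation-loss otherwise when losses are present.
Three same-chromosome junctions with the alternating profile (3,2,3,2,3)
and no loss → DUP-NML-DUP-NML-DUP.  Everything else is Unclassified.
A coherent three-junction local chain cannot consist of three
same-orientation-pair junctions (six breakends cannot pair 3 `+` with 3
`-` into inverted pairs), so its signature is one direct-orientation
junction plus an inversion head and tail; the profile is the class key.

Complexity rule: an event is *complex* iff it has ≥ 2 clustered junctions
and is not one of the four balanced/insertional simple configurations
(reciprocal inversion, reciprocal translocation, templated insertion,
dispersed duplication).  Inverted duplication and all loss/gain-bearing
multi-junction classes count as complex.

**Rescue.**  For an Unclassified cluster, junctions removed at the
quality/VAF stages (never the parental-clip or recurrence stages — those
bear on de novo status) within ±1 Mb of the cluster footprint are tried
one at a time, smallest id first; the first that resolves the cluster is
adopted, at most one per cluster.

## Parent of origin and meiotic timing

Only allele-balance phasing is implemented (read-backed phasing needs
BAMs, which the package does not consume); events therefore need ≥ 3
informative SNPs in the dosage-altered region to be phasable.  Two
informative configurations are used:

* **Origin** (duplications CN = 3 and hemizygous deletions): parents are
  opposite homozygotes.  At a duplication the duplicating parent's allele
  is at 2/3 (other parent 1/3); at a deletion the surviving allele names
  the retained parent.
* **Timing** (maternal duplications only): mother heterozygous, father
  homozygous.  Minor-allele fraction ≈ 1/3 ⇒ both maternal homologs
  present ⇒ the exchange preceded homolog separation (meiosis I);
  fraction ≈ 0 or ≈ 2/3 ⇒ a doubled single homolog ⇒ meiosis II, before
  sister-chromatid separation.  Paternal duplications receive no timing
  call: they can also arise premeiotically during spermatogenesis, so the
  meiotic stage is not identifiable.

Allele fractions are binned with a half-width of 0.12 around 0, 1/3 and
2/3 — roughly 1.4 binomial standard errors at 30× coverage, keeping
cross-bin leakage near 1 % while discarding ~15 % of sites as
uninformative.  The decision rule at each step: the winning class must
hold a fraction of informative sites strictly greater than 0.9 and carry
at least 3 SNPs (the floor applies to the winner; ambiguous otherwise).
The fraction reading of the "ratio > 0.9" rule is deliberate — a literal
ratio of counts a/b > 0.9 would declare winners at near-parity.

## Cohort statistics

* Exact binomial (two-tailed, minimum-likelihood tail sum), two-sample
  Kolmogorov–Smirnov (asymptotic p) and Fisher's exact test are delegated
  to scipy.stats behind the package surface; the tests verify them
  against direct enumeration.
* Telomere-distance binning uses 5 Mb bins of distance to the nearest
  chromosome end, with per-bin eligible sequence computed analytically
  from the same genome map, so densities are per Mb.  The event position
  is the lower breakend (midpoint vs breakend is not externally
  prescribed).  The subtelomeric ratio divides the event density within
  15 Mb of a telomere by the genome-wide density; GRCh38 primary autosome
  lengths are used without assembly-gap masking.
* Permutation enrichment re-places query intervals uniformly at random in
  a workspace, preserving lengths (queries may first be extended by ±5,
  10, 25, 50 or 500 kb windows and are clipped to the workspace).  The
  one-sided empirical p is (#{overlap ≥ observed} + 1)/(N + 1), floored at
  1/(N+1) — 1/1001 at the default 1000 samples.  Windows are reported
  separately without multiplicity correction.  Curated target gene sets
  (e.g. a pre-filtered disease-gene panel) enter as plain BED input.
* The dnSV rate is simply events per offspring genome, with the
  denominator supplied explicitly by the caller.
* Detectability: reciprocal inversions/translocations, and events whose
  deletion components all span < 3 exons of the canonical transcript, are
  classified as not detectable by array/WES.

## Synthetic cohorts

The generator emulates the *observable call level* of a short-read trio
study, not reads.  Defaults mirror a large rare-disease trio cohort:
class weights proportional to the observed per-class counts of the
resolvable classes, ~32 % maternal origin (≈ 68 % paternal), 85 % of
maternal duplications from meiosis II, binomial allele depths at 30×, one
de novo event per family.  Event segments are drawn log-uniformly
(5–200 kb per complex segment, 5 kb–1 Mb for simple events, templates
0.5–2 kb, dispersed/inverted-duplication donors 20–200 kb so a depth
caller can see them); real cohorts show deletion/duplication medians of a
few kb / tens of kb with ranges up to tens of Mb, which a desk-scale
synthetic genome (3 × 100 Mb by default) cannot hold, so the size model
is compressed rather than matched in range.  True de novo calls draw
scores of 40–300, 12–60 discordant reads, VAF 0.3–0.7 and 0–1 parental
clipped reads; inherited events duplicate the proband junction into one
parent's call set with ≥ 4 clipped reads at a breakpoint; artifacts are
emitted identically in ≥ 3 unrelated probands.  A separate stress
generator draws every evidence field across its threshold (scores 25–35,
discordant 8–13, VAF 0.05–0.15, sizes 40–60 bp, random flag sets) for
filter-boundary testing.  Everything is a pure function of the seed, and
outputs are byte-identical across runs.

What passing synthetic tests shows: the implementation applies its stated
rules exactly, the classifier inverts its own generative signatures
(including under 100 bp breakpoint jitter), and the phasing estimator
recovers planted parameters.  What it does not show: robustness to real
alignment artifacts, segmental-duplication confusion, caller-specific
biases, or breakpoint-homology effects — none of which are modelled.

## Problem sizes

Test and acceptance runs use cohorts of 20–100 families, filter-oracle
comparisons on 1000 calls, clustering-oracle comparisons on 200 instances
of ≤ 30 junctions, and 200 duplications for timing recovery; these sizes
give stable statistics (binomial standard errors of a few percent) while
keeping the full suite in seconds.

## Known limitations

* Unclassified complex configurations are a sink, not a model: the real
  long tail of complex events (e.g. nested deletions sharing a
  breakpoint, chains beyond three junctions) is generated neither by the
  simulator nor resolved by the classifier.
* Clustering approximates published likelihood-based tools at the level
  of the documented distance test; code-level output parity with any
  specific tool is a non-goal.
* The phasing arm ignores X-chromosome dosage special-casing and mosaic
  mixtures; duplications arising mitotically in early development are
  expected to land in the ambiguous class by design.
* CN corroboration assumes one read-depth segmentation per proband;
  multi-caller consensus is not modelled.
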