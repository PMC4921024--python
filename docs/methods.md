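# Methods

## Model and assumptions

`domfuse` detects gene fusions from domain architecture alone: a gene is a
fusion candidate when it carries two or more non-overlapping alignments to
domain models that, elsewhere in the database, each represent an entire
standalone gene. No sequence alignment is performed by the package itself;
it consumes the tabular output of a domain scan (model, gene, coordinates
on both, E-value, optionally percent identity). All coordinates are
1-based inclusive and alignment length is `end − start + 1` throughout.

The central assumption is that the database is large enough for the
*full-gene* property to be informative: a domain model only counts as a
plausible fusion component if some gene exists whose sequence is
essentially that domain and nothing else (bidirectional coverage strictly
greater than 90% of both model and gene by a single alignment). This is
what separates genuine fusions of standalone genes from ordinary
multi-domain proteins whose parts never occur independently.

## Detection pipeline

Per gene, hits below the E-value cut (default 1e-5, strict `<`) feed three
stages:

1. **naive multi-domain**: existence of two hits sharing at most
   `overlap_tolerance` residues (default 0, i.e. strictly disjoint).
2. **candidate selection**: among hits to full-gene models covering at
   least `domain_coverage_min` (default 0.5) of the model, a
   maximum-cardinality pairwise non-overlapping subset is selected by an
   exact dynamic program over start-sorted intervals. The DP key is
   (cardinality, summed alignment length) maximized, with remaining ties
   broken by lexicographic model-id sequence and then start coordinates,
   so the selection is fully deterministic and regression-stable. For
   maximum cardinality alone this is equivalent to greedy earliest-end
   interval scheduling; the DP additionally realizes the tie-break order
   exactly (verified against exhaustive subset enumeration in the tests).
   A gene with three or more disjoint domains yields one candidate with
   multiple gaps, not several pairwise calls.
3. **eight filter criteria** (defaults in the README table). Comparison
   directions follow the stated wording: "must exceed 600" is strict,
   "at least 40%" / "a minimum of 50" are inclusive, the promiscuity
   ceilings ("fewer than") are strict. Criterion 4 is evaluated on each
   gap midpoint: its distance to the N terminus is the midpoint coordinate
   and to the C terminus `length − midpoint`; both must reach 60 residues
   **and** 10% of gene length. Criterion 6 counts, over all of the gene's
   E-value-passing hits, those spanning any junction between consecutive
   selected alignments. The verdict is the conjunction of all eight flags
   by default; an `at_least_k` policy is available because the length
   criterion is known to exclude genuinely short bifunctional fusions
   (many vitamin-pathway enzymes are < 600 aa), and a user may want to
   explore relaxations without editing code.

### Domain-set consolidation

Domain catalogues contain many models that are effectively the same
domain. Two models are linked when, over the union of genes either hits,
the fraction of genes on which their alignments essentially coincide
(gene-interval Jaccard ≥ 0.8) reaches 0.5; consolidated sets are the
single-linkage connected components, and models without hits are
singletons. The procedure is intentionally simple and fully specified so a
brute-force oracle can verify it; both constants are configurable
(`set_interval_jaccard_min`, `set_similarity_min`).

### Co-occurrence and pair matches

Criterion 7 uses, per model, the number of *foreign* consolidated sets
with a member on at least one gene the model hits. Criterion 8 counts, per
model pair, the distinct genes on which the two models align with mutual
overlap of at least half the shorter alignment — genes where the pair
looks like one domain under two names rather than two fused partners.
These are database-scale statistics: the 1500/1000 ceilings were tuned on
a multi-million-gene corpus and do not bind on desk-scale fixtures (a
thousand-gene cohort cannot produce 1500 co-occurring sets). On synthetic
cohorts the promiscuous-module decoys are therefore screened by the
length criterion, which is also their biologically typical failure mode
(two-component and ABC modules assemble into proteins well under 600 aa).

### Rosetta-stone check

Independently of the eight criteria, each selected domain can be validated
as a Rosetta stone component: its alignment covers ≥ 90% of the model, its
percent identity exceeds 50, and the domain occurs somewhere else as a
gene's only domain. A hit without percent identity makes the check *not
evaluable* (`None`), never a failure.

## Evaluation semantics

Truth sets carry three statuses. `confirmed_fusion` genes form the
denominator; `uncertain` genes are excluded from both sides of the
confusion accounting (neither credited nor penalized, and predictions on
them are dropped from the prediction count); `rejected` genes simply are
not truth. The false-positive rate is reported as
(predictions − captured)/predictions within the scored scope, alongside
the raw counts, so alternative denominators can be recomputed; published
FP figures for this kind of detector depend on an unstated denominator and
are not reproducible from the capture counts alone. Percentages are
rounded half-up at presentation only.

## Cohort statistics

Roles are counted per gene-role pair (a bifunctional gene contributes to
both its roles). Roles propagated to fewer than 10 genomes or carrying a
generic descriptor (predicted, hypothetical, putative, possible, probable;
case-insensitive whole-word match) are excluded before the cohort moments
are computed. The *frequently fused* test flags a role when its fused
proportion strictly exceeds `mean + 2·SD` of the per-role proportions
(equivalently z > 2; at mean 0.11 and SD 0.25 the threshold is 0.61) and a
one-sided exact binomial test of its fused count against the cohort mean
gives p < 0.05. The binomial test is a design choice — the underlying
significance test behind published "t > 2 and p < 0.05" formulations is
generally unnamed — and it is deliberately the second, sample-size-aware
gate so small-n roles cannot be flagged on proportion alone.

The test is implemented in threshold form rather than as a z-quotient so a
degenerate cohort (SD = 0, every role exactly at the mean) is well defined
and flags nothing; per-role z is reported as NaN in that case. SD uses
ddof = 1. Genome proportionality reports both the pooled fused fraction
(Σ fused / Σ genes) and the closed-form through-origin least-squares slope
Σxy/Σx².

## Pathway layer

The reaction map is supplied as data (role → reactions; reaction →
substrate and product metabolite sets). A fused role pair (A, B) is
*adjacent* when a product of A's reactions is a substrate of B's; both
directions are emitted with the shared metabolites, and an option treats
all reactions as reversible (orientation union) since curated tables do
not state how reversibility was handled. Variety counts distinct unordered
(role, partner) architectures once each; frequency is fused copies over
all copies of the role within a genome subset, each gene copy counting
once, with an absent role reported as `None` rather than 0%.

## Synthetic cohorts

The generator emulates the curated false-positive taxonomy, not sequence
evolution: there is no homology simulation and no real model content, so
passing tests demonstrate the pipeline's *logic* (stage semantics,
criterion arithmetic, decoy rejection) and nothing about scan quality on
real proteomes. Default study conditions: 2 genomes × 500 genes, 10%
planted fusions, 10% each of the three decoy classes, seed 42.

Geometry per class: core domains are uniform 280–400 aa; single-domain
genes are a domain plus log-normal flanks capped at 2.5% of the domain per
side; fusions are two distinct core domains (each also planted as a
standalone gene, the Rosetta-stone configuration) separated by a 60–120 aa
linker, which makes every default criterion satisfiable by construction
(minimum gene length 620 > 600, combined coverage ≥ 0.73). Sub-domain
decoys align 80–160 aa windows of 450–650 aa models, so those models never
reach full-gene coverage anywhere. Promiscuous modules are uniform 130–240
aa and pair into genes of at most ~560 aa. Alignment ends are trimmed by
up to `coverage_noise_max` (default 2%) of the model per side. Class
labels are assigned by exact stratification (rounded per-class counts,
shuffled by the seeded generator): planted counts sit at their
expectation, and the final-stage count is invariant to changes in decoy
fractions, which the invariant tests rely on. All sampling comes from one
`numpy` generator in a fixed documented order, so a fixed seed gives
byte-identical output tables.

Problem sizes throughout the tests and the acceptance script (1,000-gene
cohorts, 200-gene oracle sweeps, 50-model consolidation instances) were
chosen so every brute-force oracle remains exact and the whole suite runs
in seconds on one CPU.

## Known limitations

* Promiscuity ceilings (criteria 7–8) are inert below database scale; the
  package applies them faithfully but desk-scale fixtures cannot exercise
  them as binding filters.
* Consolidation is single linkage: one bridging model can merge two
  otherwise distinct footprint clusters.
* The generator's decoys are geometrically clean; real scan output
  contains partially overlapping, frame-shifted and truncated hits whose
  rejection is only covered by the invariant-violation handling in the
  readers.
* The caller treats each gene independently given the atlas; it does not
  re-estimate full-gene status or promiscuity after filtering (no
  iteration).
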