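# Methods

## The system being modelled

A disomic yeast carries one native and one synthetic (Sc2.0-style) copy of
a ~1 Mb chromosome. The synthetic copy is partitioned by loxPsym sites into
segments; Cre induction (SCRaMbLE) recombines pairs of sites on that copy
only. Selection keeps survivors that retain centromere function and a
centromere-adjacent prototrophy marker on the synthetic homolog, so the
screen reads out rearranged-but-viable karyotypes. The package simulates
this screen, re-derives the rearranged structures from sequencing-style
evidence, and computes the fitness, association and expression statistics
used to separate two mechanisms of aneuploidy recovery: bulk dosage relief
(losing most of the extra copy) and the deletion of a specific ~20-kb
region.

## Chromosome representation

The reference is an ordered `SegmentMap` (BED-convention 0-based half-open
coordinates on disk; 1-based word/junction positions in memory). A
rearranged chromosome is a `ChromosomeStructure`: a topology (linear or
circular) plus a word of signed segment occurrences. Circular words are
rotation- and mirror-equivalent; `canonical_form` picks the
lexicographically smallest representative under the ordering (segment
index, `+` before `−`) — an arbitrary but fixed convention.

The default synthetic map has 40 segments totalling exactly 1,028,952 bp
with 563 genes apportioned by length. The segment count is a free
parameter (the real loxPsym count is not published); 40 gives ~26 kb
between sites, a plausible inter-loxPsym scale, and makes the 20-kb causal
segment (placed mid-right-arm, exactly 20,000 bp) one segment. The
centromeric segment is fixed at 5 kb with the marker on its right
neighbour, so minimal circular survivors retain ~1–2% of content.

## The SCRaMbLE generator and its calibration

Each strain draws, in order:

1. **Circularization** with probability 0.89 (the observed circular-strain
   fraction). Junctions are drawn geometrically close to the two telomeres
   (mean 3 segments from each end): a circle forms by a single
   intramolecular event between sites near the telomeres, so nascent
   circles are large.
2. **An event count** from a zero-truncated negative binomial with
   (truncated) mean 4.42 and shape 2.0. The shape is chosen so the count
   distribution has a long right tail (a few percent of strains carry ten
   or more events) without a stated family in the source data.
   `mean_events = 0` is the documented degenerate case meaning "no events";
   means in (0, 1] are rejected because a zero-truncated distribution
   cannot have them.
3. **Events** with types from the multinomial (deletion 0.622, inversion
   0.292, duplication 0.086) and geometric span lengths with mean 1.2
   segments — predominantly single-segment events, the regime reported for
   loxPsym recombination, whose frequency decays with inter-site distance.
   Junction pairs for deletions and circularizations are
   *viability-conditioned*: products that lose the centromere or marker are
   never recovered under selection, so the sampler redraws junctions until
   the product survives. This matters: with unconditioned junctions,
   rejection of whole strains would systematically deplete deletions and
   event counts in the selected population, and the generator's defaults
   would no longer describe the selected strains they are meant to emulate.

Fitness is `R = β₀ + β_mass·(1 − retained) + β_region·1[causal deleted] + ε`
with defaults β₀ = 5, β_mass = 45 (percentage points; full chromosome loss
recovers ~50 points), β_region = 25, ε ~ N(0, 8), floored at 0, realized as
200 colony diameters around 1.2 mm × (1 + R/100) with 12% CV. A configured
fraction of strains (default 3/219 in the pipeline) is flagged as
whole-genome-duplication escapees; the flag only changes the wt:syn read
ratio to 2:1.

**What the generator does not emulate.** Real circular strains lose most of
both arms through cascades of daughter-circle deletions; compressing that
cascade into a handful of counted events while keeping the published event
mix and mean is not jointly possible, because parsimony reconstruction
merges abutting deletions and absorbs seam-adjacent deletions into the
circularization. The defaults favour event-level fidelity (the mix and
count statistics survive the reconstruction round trip); simulated circular
strains therefore retain more content than the real ones. Retention-level
quantities should be treated as qualitative in this simulator. Passing
tests show that the *analysis* stages recover planted event, fitness and
expression structure — not that the generator reproduces every marginal of
the real strain collection.

## Evidence model

Evidence is segment-level: expected depth = baseline × copies × recovery
factor (1/3 for circular molecules — circles are recovered ~3× less
efficiently in library preparation — else 1), Poisson noise optional;
junctions are the adjacency types present in the word with Poisson support;
PCRTag-like wt/syn read counts are Poisson around 300 per copy. Copy
numbers are re-estimated by rounding depths against a single-copy unit.
The unit starts from the centromere-adjacent anchor segments (always
retained under selection, so the circular deficit self-normalizes), then a
small set of hypotheses (anchor mean ÷ {1, 1.5, 2}, robust median) is
refined by Poisson maximum likelihood over all retained segments and scored
by chi-square; the largest acceptable unit wins (fewest total copies).
Candidates explaining under 70% of retained segments are aliasing artefacts
and are rejected.

The ploidy anomaly test is an exact two-sided binomial test of the
synthetic-read fraction against 1/2; a strain is flagged when p < α (0.05)
and the major:minor ratio is at least 1.5.

## Reconstruction and event calling

Structures are threaded through an adjacency graph (nodes: oriented segment
ends; segment edges with copy-number multiplicity; junction edges from
evidence). Traversals must use every copy, step only across observed
junctions, and explain every junction at least once; they are enumerated
with backtracking up to a cap (pipeline default 50), deduplicated by
canonical form and ranked by parsimony. Ambiguity (possible with
duplications) is reported, never silently resolved; junctions contradicting
copy numbers are surfaced as conflicts.

`min_event_distance` returns a shortest event list from the reference:

* **Exact** breadth-first search over canonical states for references of at
  most 8 segments (node budget 200k generated states) — the regime in which
  it is cross-checked against an independent brute-force oracle.
* **Greedy** otherwise: collapse tandem repeats (duplications), bring
  separated copies together, then sort the residual signed permutation by
  greedy breakpoint-reducing reversals (inversions) after rank-relabelling,
  and account missing reference runs as deletions; for circles, rotations
  and mirrors at strip boundaries are tried and the cheapest decomposition
  kept, with the circularization junctions at the outermost retained
  content. The result is an upper bound flagged `is_minimal` only when it
  meets an adjacency-count lower bound (each event creates at most two
  adjacency types absent from the reference) or when the exact search
  certifies it. Replaying the returned events always reproduces the
  target's canonical structure (verified on every call).

Known bias of parsimony calling, inherent and not correctable from
junction evidence: two deletions that abut form a single gap, and a
deletion abutting the circularization seam is indistinguishable from a
tighter circularization. Both undercount deletions by roughly two
percentage points of the pooled mix under the default generator.

## Fitness statistics

* Growth recovery, `(Sᵢ − Sᵣ)/Sᵣ × 100`, from colony-size means (medians
  behind a flag); a warning below 200 colonies per sample.
* Doubling time: log₁₀-transform, OLS slope in every 7-consecutive-reading
  window, k = max slope, DT = log₁₀(2)/k. Exact on pure exponentials by
  construction; under multiplicative noise the max-over-windows rule is
  slightly upward-biased in k (DT a few percent low).
* Retention–recovery: Pearson r plus OLS with a pointwise 95% confidence
  band of the fitted mean.
* Association scan: per segment, two-sided Welch t-test of recovery between
  deletion and retention groups (the source does not name its test; Welch
  is the defensible default for unequal, skewed groups), optional seeded
  label-permutation p, Bonferroni family-wise control at α = 0.05 over
  tested segments. Segments without contrast are returned untested with a
  reason. Note that under the mass-action fitness model *every* segment's
  deletion status carries real signal through retention; a type-I-error
  check therefore requires switching the fitness coefficients off.
* Stability: g = ln(target)/ln(1 − p) with a `math.inf` "never" sentinel at
  p = 0, plus a binomial-thinning Monte Carlo companion.

## Expression and ESR scoring

Counts are negative binomial with shape 100 (~10% CV, bulk-RNA-seq-like)
around means of baseline 200: duplicated genes ×(1 + synthetic copies)
except a buffered fraction (10%) held at 1×; induced-ESR genes shift up and
repressed-ESR genes down by 1.2 and 1.6 log₂ units × burden respectively,
with burden = 1 − recovery/100 (the repressed set needs the larger effect
for equal call power at its lower counts). No normalization pipeline is
modelled; libraries are size-matched by construction.

Per-gene calls against a reference strain use a dispersion-aware normal
test on the count pair (null variance 2(μ + μ²/shape); an exact binomial
would be badly anti-conservative under NB noise) at p < 0.001. Scores
report the fraction of iESR genes up and rESR genes down, exact
hypergeometric enrichment p-values over the gene universe, and
Benjamini–Hochberg q across reported tests. The reversal flag requires
*both* fractions to fall to at most half the unSCRaMbLEd disome's values.
Fold-change summaries use a pseudocount only where the reference count is
zero, so noise-free ratios are exact; a duplicated gene with log₂FC < 0.32
(< 1.25×) counts as buffered.

## Pipeline determinism and problem sizes

A run is a pure function of (config, seed): one integer seed is fanned out
to the stages through `numpy` SeedSequence spawning, and the report JSON is
byte-identical across repeated runs (timestamps live only in the log).
Ploidy-flagged strains stay in the population table but are excluded from
the association scan and ESR scoring. Default problem sizes — 219 strains
on a 40-segment map, noise-free evidence for the event-mix round trip,
100-replicate parameter-recovery checks, a 10,000-strain ploidy null, and
200-case reconstruction/oracle sweeps — keep a full run and the test suite
in the minutes range on a single core while leaving the Monte Carlo
standard errors well inside the tolerances they are checked against.

## Limitations

* Retention distributions of circular strains are compressed relative to
  the real screen (see the generator section); size ranges and
  preservation profiles are qualitative.
* Minimality of event decompositions is certified only on small problems;
  large decompositions are upper bounds with a lower-bound flag.
* The expression model is strain-level with known dispersion; replicate
  structure, library-size variation and normalization are out of scope.
* Inter-chromosomal rearrangements, read-level simulation and the real
  strain collection's sequencing data are out of scope throughout.
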