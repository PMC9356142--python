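# Methods

This note documents the models and procedures implemented in `recedit`,
the defaults and why they were chosen, what the synthetic fixtures do and
do not emulate, and the package's known limitations.

## Coordinates and allele algebra

All coordinates are 0-based, half-open. An insertion with start *i* places
its bases before index *i*; a deletion with start *s* and length *d*
removes `seq[s:s+d]`. An **allele** is a concrete sequence with a lineage
(the chain of guide/outcome events that produced it) and a probability
mass: the wildtype has mass 1, and each child's mass is its parent's mass
times the predicted outcome frequency, conditional on the indel (non-HDR)
repair channel. Alleles are identified by sequence: lineages that converge
on the same sequence are merged by summing mass, because a gRNA targets
sequences, not histories. Degenerate bases (N) are rejected in design
windows and tolerated only in background sequence used for off-target
counting.

Deletions flanked by microhomology are positionally ambiguous — removing
either copy of a repeat yields the same child — so every deletion is
**canonicalised** to its leftmost placement; the canonical form is the
class representative throughout. The junction microhomology length *m* is
the longest *k* with `seq[s+i] == seq[s+d+i]` for all *i < k*; a deletion
with microhomology *m* can slide across *m+1* equivalent placements.

## Bundled outcome predictor

Published machine-learned predictors of Cas9 repair outcomes can be
plugged in through a named-adapter seam (`register_predictor`), and
whatever is registered is validated against the distribution contract
(normalisation, frequency-sorted, canonical deletions). The bundled model
is deliberately simple, deterministic and hand-computable while preserving
the qualitative structure recursive retargeting exploits — strong
microhomology-mediated deletions and small duplications of cut-adjacent
sequence:

* every canonical deletion class (length *d* ≤ `d_max`) whose span covers
  or abuts the cut receives weight `(1+m)² · exp(−d/lambda_del)`, with *m*
  capped at `mh_max`;
* a +1 insertion duplicating the base 5′ of the cut receives `beta_ins1`,
  and a +2 insertion duplicating the preceding dinucleotide `beta_ins2`
  (insertion identity is always a duplication — the dominant empirical
  class — because retargeting needs concrete allele sequences);
* weights are normalised to frequencies; outcomes below `min_report_freq`
  are pooled into a truncated-mass remainder (reported frequencies are not
  renormalised).

Defaults: `lambda_del = 10` nt (deletion-length decay scale),
`beta_ins1 = 3.0`, `beta_ins2 = 0.3`, `d_max = 30` nt, `mh_max = 15`,
`min_report_freq = 0.01`. With these weights a 3-bp microhomology spanning
a 6-bp deletion scores `(1+3)²·e^{−0.6} ≈ 8.78`, beating the +1
duplication (3.0) and every microhomology-free deletion (≤ `e^{−0.1} ≈
0.905`) — the model's hand-checkable worked example.

One aggregate property of this model matters for interpretation: the
summed weight of all enumerable deletion classes in a typical window is
large (≈ 85 for a central cut on a repeat-suppressed window, more on
random sequence), so while the +1 duplication is the *rank-1* outcome in a
repeat-free window, it never carries a large *fraction* of the indel mass
(at most ~6 % even when the cut sits at the window edge). Sites whose
retargeting value comes from the +1 class alone therefore cannot clear the
20 % recursive threshold under these defaults; concentrated microhomology
deletions are what make a site recursive in this model. Real predictors
trained on editing data concentrate insertion mass far more strongly; with
such an adapter the same search machinery will classify +1-dominant sites
as recursive.

## Guides, filters, off-targets

SpCas9 guides are 20-nt protospacers adjacent to NGG; the blunt cut sits
3 nt 5′ of the PAM (between protospacer positions 17 and 18). NAG PAMs and
bulge-tolerant matching are out of scope. On-target efficacy uses a
bundled heuristic in [0,1] — base 0.6, +0.2 for GC content in [0.40,
0.70], −0.2 for a ≥5-nt homopolymer, −0.2 for a protospacer ending in TT —
pluggable by name like the outcome predictor. Off-target counting is exact
and exhaustive: all background positions on both strands within `mm_max`
(default 2) mismatches of the protospacer and followed by NGG, minus the
intended site; a numpy index vectorises this so a mini-genome is queried
per guide in microseconds. Exhaustive counting is the right trade at
fixture scale and is swappable for seed-heuristic engines at genome scale.

Filters (defaults): `min_on_target = 0.5`, `max_offtarget_hits = 0`,
`mm_max = 2`, `proximity_bp = 10`. Retargeting guides (level ≥ B) must not
match the wildtype — they would otherwise re-cut unedited alleles — and no
guide at any level may match the HDR allele the donor is meant to install.
The proximity clause keeps a retargeting guide's cut within
`proximity_bp` of the prior edit so the new HDR event overwrites it; the
radius is a design choice exposed in config. Proximity is measured against
the edit's whole ambiguity interval (the *m+1* equivalent placements of a
microhomology deletion), not just the leftmost placement — anchoring on
the canonical start alone would spuriously reject guides cutting at the
right end of a tandem repeat.

## Recursive search

The search is breadth-wise over levels. Level A targets the wildtype
(designed from the window, or supplied by the caller); its top
`top_outcomes_per_allele` (default 2) predicted outcomes become the
level-1 frontier. At each level, candidates enumerated near the frontier
edits are scored by the retargeting score

    score(g) = M(g) × R(g)

where `M(g)` is the summed mass of frontier alleles the guide matches
exactly and `R(g)` is the fraction of the guide's own predicted outcome
mass (evaluated on its highest-mass target) whose child alleles admit at
least one further filter-passing guide — a one-step look-ahead that bounds
cost; deeper look-ahead is a non-goal. The product form was chosen because
both factors are frequencies of serial events; the score is a priority
metric for comparing reagents at a locus, not a quantitative predictor of
HDR improvement. Up to `guides_per_level_max` (default 2) candidates with
targeted mass ≥ `min_targeted_mass` (default 0.05) are kept, ranked by
score with fully specified tie-breaks (on-target score, then leftmost cut,
then + strand) so the search is deterministic and serialized cascades are
byte-identical across runs. At the final level, where no further
retargeting is sought, qualifying candidates are re-ranked solely by
efficacy and specificity (on-target descending, off-target hits
ascending). Recursion stops cleanly at `max_levels` (default 3, i.e.
A/B/C) or when no candidate reaches the mass threshold.

Labels follow the level letter plus the rank of targeted-outcome
abundance: B1 targets more mass than B2, regardless of selection order.
Because alleles merge by sequence, a guide can legitimately appear at two
levels (e.g. the −6 child of level A and the −3−3 grandchild of level B
are the same sequence, so C1 may reuse B2's protospacer).

**Retargeting efficiency** at level ℓ is the mass of the union of frontier
alleles targeted by the level-(ℓ+1) guides divided by the total indel mass
cut open at level ℓ. The union (rather than the sum over guides) keeps the
ratio in [0,1] when two guides share a target. A site is classified
**recursive** when the level-0 efficiency strictly exceeds
`recursive_threshold = 0.20`. A site report's overall rank score is the
A-level guide's retargeting score, consistent with the score's role as a
priority metric.

## Mass-flow simulator

The simulator propagates expected allele-mass fractions; it does not
sample cells. Each round, every allele matched by an active guide loses
`cut_efficiency` (default 0.9) of its mass; `hdr_fraction` (default 0.25)
of the removed mass enters the absorbing HDR pool and the rest is
redistributed over the predicted outcomes of that cut (truncated outcome
mass goes to an inert residual-indel pool). The HDR pool and unmatched
alleles are inert, so mass is conserved exactly and HDR never decreases.
*Sequential* delivery activates one level per round in order, re-exposing
the donor each round (modelled simply as a constant `hdr_fraction`);
*simultaneous* activates all levels every round until `rounds_max`
(default 10) or the targetable mass drops below `min_mass` (default
1e-4). Within the model, adding a retargeting level never decreases final
HDR or the HDR:indel ratio, and the size of the gain tracks the
retargeting efficiency. Deterministic expectation dynamics are sufficient
for ranking cascades; a seeded multinomial mode would be an extension, not
a requirement. RNP degradation, target-site blocking, cell division and
toxicity are not modelled.

## Scans

Three drivers share the engine (extract window → constrain the A cut →
run the recursion → emit a record embedding the serialized cascade, so a
scan row is bit-identical to a direct per-window design):

* **genome**: every enumerable guide is a candidate entry point; a cheap
  entry gate — the top-2 outcome concentration at its cut must reach
  `entry_concentration_min` (default 0.5) — runs before the expensive
  recursion; only sites classified recursive are emitted, and overlapping
  hits whose A cuts fall within `dedup_radius` (default 5 bp) collapse to
  the best-scoring. Windows are ±50 bp around the cut; a `step` parameter
  allows coarse scans.
* **cds_ends**: one window (±30 bp) per start/stop codon from a GFF3,
  after collapsing redundant isoform entries that share the same codon;
  the A cut must fall within `proximity_bp` of the codon. The
  endogenous-tagging use case.
* **variants**: one ±50 bp window per VCF variant, excluding indels longer
  than 50 bp; the HDR allele installs the variant (or, with `revert`,
  corrects it — the direction is a flag because both uses are real), and
  the A cut must fall near the variant. Records with REF==ALT or
  non-ACGT alleles are skipped with a logged identifier.

Default donors are ssODN-style: a 3-bp GAT insertion at the first cut with
45-bp homology arms (40–50 bp is the accepted range).

## Synthetic fixtures

The generator emulates the tool's three real input kinds — genome FASTA,
GFF3 annotation, VCF — with planted constructs whose cascade structure is
known by design and *verified at generation time by running the real
search*; the truth table records only what that verification reproduced.
Defaults: 4 contigs × 5 kb, three `mh_deletion_chain` constructs, one
`plus1_dup`, one `non_recursive`, four genes, six variants plus one 60-bp
deletion that exercises the length filter.

* `mh_deletion_chain` — a 6×3-bp tandem repeat with a single planted PAM.
  The −3 unit deletion dominates (~40 % of indel mass), each child still
  carries the array, and the site yields a three-level A1/B1/C1 cascade of
  successive 3-bp alt-EJ deletions, clears the genome-scan entry gate, and
  classifies recursive. Flank bases abutting the array are chosen
  per-position distinct from the repeat phase so retargeting guides sit
  more than 2 mismatches from the wildtype site; repeat units are unique
  per genome.
* `plus1_dup` — a 14-nt period-6 repeat cut near the window edge (the
  short left arm suppresses the deletion background): the planted 6-bp
  microhomology deletion carries >27 % of the mass (recursive, two
  levels), and the +1 duplication of the cut-adjacent base is the rank-2
  predicted outcome — the strongest +1 prominence the bundled model's
  weights permit (see the aggregate-mass property above).
* `non_recursive` — a repeat-suppressed window with one planted PAM whose
  dispersed spectrum (top-2 concentration ≤ 0.12) guarantees no
  retargeting guide reaches the mass threshold.

The random background is sampled with tandem microhomology capped at 4 nt
for all periods ≤ 30, so the background cannot produce accidental
recursive entry points; constructs' neighbourhoods are PAM-stripped so
each planted site has exactly one entry guide; and a genome-wide
both-strand uniqueness check on 23-mers guarantees planted guides are
off-target-free by construction. Generation is byte-reproducible from the
seed.

What the fixtures do **not** emulate: real indel spectra (the bundled
model's weights are stylised), chromatin or sequence-context effects on
cutting, SNV/substitution repair outcomes, large rearrangements, and
realistic genome repeat structure. Passing tests therefore demonstrate the
correctness and determinism of the algorithms — enumeration, scoring,
search, bookkeeping, simulation, format handling — not predictive accuracy
on biological data, which is inherited from whichever outcome predictor
and efficacy scorer are plugged in.

## Numerical choices and problem sizes

Frequencies are exact ratios of double-precision weights; mass-balance
checks use a 1e-9 tolerance. Serialized floats are rounded to 10 decimals
to keep JSON/TSV byte-stable. Outcome ties break by shorter indel first,
then lexicographic child sequence; guide ties as above. The test suite and
the acceptance script run on 4×5-kb fixture genomes with search depth 3 —
sizes at which the exhaustive off-target oracle and per-guide entry gate
(≈2.5 ms per predicted distribution) keep a full genome scan to a few
seconds — chosen as the smallest sizes at which every pipeline behaviour
(entry gating, deduplication, codon deduplication, variant filtering,
scan/unit agreement) is exercised.

## Known limitations

* The bundled predictor and efficacy heuristic are stylised stand-ins with
  documented contracts; quantitative site rankings on real genomes should
  use published predictor adapters.
* The retargeting score is a priority metric; it does not predict the
  magnitude of HDR improvement, and the simulator's HDR numbers are
  model-internal quantities, not forecasts.
* Off-target counting is exhaustive and mismatch-only (no CFD/MIT
  weighting, no bulges); at genome scale a seed-indexed engine should
  stand behind the same interface.
* One nuclease (SpCas9, NGG) is supported.
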