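# Methods

This note documents the models, rules and numerical choices behind
`ptmatlas`, and what the synthetic-data generator does and does not
emulate.

## Coordinates and data model

All positions are 1-based, inclusive, on the protein sequence; intervals
are closed `[start, end]`. The identifier space is the accession; inputs
keyed by gene symbol (disease associations, some variant tables) are
reconciled through an optional symbol→accession mapping table, and
unmappable symbols are dropped with a logged count. The atom of the
analysis is the deduplicated **site**: one (accession, position) pair
carrying the union of canonical modification types, source databases and
verbatim names across all input tables.

Canonicalisation maps raw modification names onto umbrella types by
ordered, case-insensitive regex patterns (phosphoserine → phosphorylation;
N6-acetyllysine → acetylation; mono-/di-/tri-methyllysine → methylation;
O-GlcNAc → o-glycosylation; …). The finer name is retained in
`raw_names`; unmapped names pass through lowercased and are logged once
each, so rare modifications are never silently lost. When a reported
residue conflicts with the FASTA sequence, the sequence wins (isoform or
release drift is the usual cause) and the conflict is logged; sites beyond
the sequence end are dropped and logged.

## Network

Consensus filtering keeps proteins reported (as either endpoint of any
edge) by at least two source databases. The study universe is the
first-order subnetwork of the seed proteins: seeds, their direct
interactors, and *every* consensus edge among that node set, so
interactor–interactor edges contribute to degree. Edges are undirected;
duplicates and self-loops are removed; multi-source support is recorded
but not weighted.

The hub threshold is the **nearest-rank 75th percentile** of the degree
multiset: the value at rank ⌈0.75 · n⌉ of the ascending degrees. A node is
a hub when its degree meets or exceeds that threshold, i.e. hubs are the
top quartile of the degree distribution. Nearest-rank (rather than
interpolation) keeps the threshold an observed degree and makes the hub
set non-empty for every non-empty network. The alternative reading
"75% of the maximum degree" is deliberately not used: it collapses to one
or two nodes on heavy-tailed degree distributions and contradicts the
top-quartile sense of "highly connected".

## Hotspots

The motif is the ±7-residue window around a site, clipped to `[1, L]`
(≤ 15 aa). A side is flagged truncated when the nominal window reaches the
corresponding terminus. Thresholds are **not pro-rated** for truncated
windows — a terminal window must satisfy the same absolute count — which
is the simplest symmetric rule.

* **PTM hotspot**: the window around site *c* contains ≥ k (default 5)
  *other* deduplicated sites. The counting unit is the site, not the type
  occurrence: a two-type crosstalk site counts once.
* **Crosstalk hotspot**: the window around an in-situ crosstalk site
  contains ≥ k (default 3) crosstalk sites *including* the centre, so
  three clustered crosstalk sites suffice. The stricter centre-exclusive
  reading is available via `--crosstalk-exclude-center` /
  `include_center=False`. Crosstalk sites are sites with ≥ 2 canonical
  types; a `--min-types` style restriction can be explored by filtering
  the catalog before scanning.

Qualifying windows of one kind on one protein are stitched into maximal
regions by merging intervals that share at least one position. Intervals
that merely touch end-to-start (`end + 1 == start`) are **not** merged:
stitching is defined over overlapping motifs. The covered position set is
identical either way, so coverage (Σ region lengths / L) is unaffected by
this choice; only the region count can differ. Coverage raises an error if
handed overlapping regions, since that violates the stitching contract.

Positional profiles count, over all anchors matching a subject, the
co-occurring sites at each relative offset in −7…+7 and normalise by the
grand total. Two modes mirror the two figure conventions: centre-exclusive
(offset 0 skipped; co-occurrence is any PTM site) and centre-inclusive
(offset 0 tallied; optionally restricted to a co-occurring type). For a
type *combination*, an anchor must carry **exactly** that type set, which
keeps combination classes disjoint; superset matching is available via
`exact_combination=False`.

## Disease classes and variants

Disease terms are matched case-insensitively on whitespace-normalised
names; `~`-prefixed terms match as substrings. CVD takes priority over OD,
so the three classes partition any universe. The shipped cardiovascular
term list is a configurable starter list, an input rather than ground
truth.

Variants are protein-coordinate substitutions; `p.Xaa123Yaa` notation is
parsed through the standard three-to-one amino-acid code. Modern curation
labels collapse to three classes (LP/P → disease, LB/B → polymorphism,
US → unclassified). A variant within ±7 of a site is a motif-associated
variant (MAV); a variant near several sites yields one MAV per anchoring
site, while headline totals count each distinct variant once. The offset
histogram is emitted in **both** counting conventions (variant–site pairs
and distinct variants per offset), explicitly labelled, because either
reading is defensible. Reference-residue disagreements with the FASTA are
flagged, never corrected.

## Disorder

Disorder tracks (per-residue O / DB / DN labels from external predictors)
are an input format; no predictor is run or reimplemented. Per-type
fractions use sites as the denominator and sum to 1 per type; sites on
proteins without a track are labelled `unknown` and excluded from
fractions. A site carrying several types contributes once per type to the
per-type table, so the table's site total exceeds the catalog size when
crosstalk is present.

## Synthetic data generator

The generator emulates the statistical shape of the real inputs:

* **Sequences** — lognormal lengths (mean 450 aa, σ = 0.35, clipped to
  [150, 1500]), i.i.d. residues at approximately human composition.
* **Sites** — per-type Poisson counts proportional to length, positions
  uniform over the residues each type may occupy (S/T/Y phosphorylation,
  K acylations/ubiquitination/methylation/sumoylation, N n-glycosylation,
  C s-nitrosylation/glutathionylation, …). Background positions are drawn
  without replacement across types, so no crosstalk arises by collision.
  The constraint map includes at least two types per modifiable residue
  class (low-density sulfation on Y and deamidation on N fill the gaps),
  so a competing partner type always exists.
* **Crosstalk** — each non-cluster site independently gains a second
  competing type with probability `crosstalk_fraction` (default 0.05),
  making the realised crosstalk fraction exactly Bernoulli and testable.
* **Hotspot clusters** — designated proteins receive 7 sites (PTM) or 4
  two-type sites (crosstalk) within an 8-residue span; every cluster
  member therefore sees all others within ±7 and the planted cluster
  always qualifies, so scanner sensitivity must be 1.0. Cluster residues
  are rewritten to match the chosen types. Default densities
  (5.04 sites/100 aa in total) keep the background false-window
  probability below 10⁻³ for both hotspot kinds, cleanly separating
  planted structure from background. A denser `compendium_config` preset
  (~18 sites/100 aa, phosphorylation-dominated) reproduces the qualitative
  shape of curated human PTM compendia for demonstration; it is not used
  for planted-hotspot scoring because its background legitimately creates
  hotspots.
* **Sources** — each site record is attributed to each simulated PTM
  database with configured probabilities (at least one), exercising
  cross-source deduplication. Each PPI edge is attributed to ≥ 2 of five
  simulated databases, except edges of designated single-source proteins
  (10% by default), which must fail the consensus rule. Hub proteins get
  30 extra partners.
* **Disorder** — alternating geometric ordered/disordered segments with
  mean ordered length 30 aa and disordered length chosen to hit the target
  ordered fraction (default 0.65); a disordered segment is
  disordered-binding with probability 0.4.
* **Variants** — Poisson(6) per protein, class mix 0.45/0.35/0.20.
  Disease variants are placed at a modification site with probability
  `p0 = 0.30` and otherwise at a non-site position inside a ±7 motif, so
  the recovered at-site fraction among disease MAVs is exactly
  Bernoulli(p0). Other classes are placed uniformly.
* **Disease** — a true category per protein (CVD 0.40 / OD 0.45 /
  ND 0.15) realised as associations drawn from the shipped CVD term list
  and a disjoint other-disease list, so classification can be scored
  exactly.

Fixed seed ⇒ byte-identical bundles. What the generator does **not**
emulate: real sequence composition and homology, motif grammar around
sites, study-bias correlations between databases, isoform coordinate
drift, and any coupling between cis-crosstalk pairs and site positions.
Passing recovery tests therefore demonstrates correctness of the
*computation*, not robustness to the biases of real curated data.

## Recovery scoring and statistical checks

`verify_recovery` scores sensitivity per planted hotspot window (a
stitched region of the right kind overlapping the planted interval).
False positives are counted over pure-background proteins only — proteins
with a planted cluster of either kind are excluded, since a dense
crosstalk cluster legitimately satisfies the PTM rule as well. The
false-positive bound is model-based: for a background protein with *s*
relevant sites on length *L*, the per-centre window count is approximated
as Poisson with mean (s−1)·14/L, a protein trips with probability
1 − (1 − p_w)^s, and the observed count is checked against the summed
expectation + 3 SD.

Parameter-recovery checks compare emitted statistics to their configured
targets within 3 standard errors: site counts against the analytic Poisson
expectation given realised lengths (minus logged truncations, plus planted
cluster sites); the ordered fraction with SE computed on the *segment*
count, since residues within a segment are perfectly correlated; the
crosstalk fraction and at-site enrichment as plain binomials on their
eligible denominators.

## Problem sizes

The default study bundle is 200 interactor proteins (~4,700 sites); oracle
equivalence checks run 1,000 random instances per operation (n ≤ 50 sites,
L ≤ 500). These sizes give stable 3-SE checks while keeping the full suite
and the acceptance script in the tens of seconds.

## Known limitations

* Real database dump layouts are supported through a generic TSV dialect
  plus thin adapters; historical column layouts of specific releases are
  not reproduced bit-for-bit.
* Cis-crosstalk records are ingested and conservation-filtered (≥ 80 by
  default) but not analysed further; crosstalk analysis here means in-situ
  (same-site) competition.
* Hotspot thresholds are definitions, not statistics: no null model or
  enrichment test is attached to them.
* Disease classification is term-list matching, not ontology traversal;
  the shipped CVD list is a starting point.
* Gene-ontology/pathway enrichment and disorder prediction are external
  services/executables and out of scope.
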