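# Methods

`jaydiet` re-implements the inference chain of a multi-marker fecal-DNA
metabarcoding diet study of the Canada jay (*Perisoreus canadensis*), a
boreal food-caching corvid: amplicon read QC, identity-filtered taxonomic
assignment calibrated by barcode-gap analysis, compilation of a
heterogeneous 662-item diet dataset, and a rule-based classifier that
decides whether each winter-adult or nestling food item was likely recovered
from a cache or obtained fresh. This note records the models, parameter
choices and numerical conventions, what the synthetic generators do and do
not emulate, and the open design decisions we resolved.

## Read QC

Reads are processed per (sample, marker) in the order used for
unidirectional Ion Torrent amplicons:

1. **Primer trimming** — anchored, IUPAC-aware matching of the forward
   primer at the 5′ end and the reverse-complemented reverse primer at the
   3′ end, tolerating up to 2 mismatches per flank (configurable). Reads
   missing either flank are rejected with a logged reason. Anchored (rather
   than floating) search reflects amplicon structure; adapters and MID tags
   are assumed already removed by demultiplexing, which is out of scope.
2. **Length filter** — drop reads shorter than 100 bp. The boundary is
   inclusive on the keep side: a 100 bp read survives.
3. **Quality trimming** — sliding-window mean-Phred trimming in the style
   of single-end `sickle`: window length is 0.1 of the read length (minimum
   1), and the read is cut at the start of the first window whose mean
   quality falls below Q20. The original study cites the tool without
   parameters, so the tool's defaults are used. The length filter is
   re-applied after trimming.
4. **Dereplication** — exact (100%-identity) collapse per (sample, marker)
   with read counts; output order is canonical (sample, marker, descending
   count, sequence), so it is independent of input order.
5. **Abundance floor** — unique sequences carried by fewer than 100 reads
   are removed; a 100-read sequence survives. The floor is applied per
   (sample, marker) rather than globally because the sample is the unit of
   diet inference. Whether the floor precedes or follows taxonomic
   assignment is configurable (`abundance_filter_order`); the default is
   before, which is cheaper and never changes which sequences are reported.

## Taxonomic assignment and barcode-gap calibration

References are consumed as pre-aligned FASTA with
`record_id|species|genus|family` headers. Reference QC drops records with
more than 2% ambiguous bases (measured over non-gap positions) or more than
12 gap characters at either alignment end.

The **naive search** stands in for a BLAST query against external
databases: every query is aligned locally (Smith–Waterman, match +1,
mismatch −1, linear gap −2; numba-jitted kernel) against every reference,
reporting percent identity (matching columns over alignment columns),
alignment length (columns) and the raw score. Tie-breaking is fixed —
first-maximum cell, diagonal-over-up-over-left traceback — so results are
deterministic. Hits below 95% identity or spanning fewer than 100 bp are
discarded (both boundaries inclusive on the keep side). The candidate is
the top surviving hit by (identity, length, score) lexicographic order; if
distinct species tie exactly on all three keys the candidate is promoted to
their lowest common rank. This selection rule is our own: the study does
not state how multiple surviving hits yield one name, and a deterministic,
conservative rule is the defensible default.

**p-distance** is the proportion of differing sites among sites where
neither sequence carries a gap or ambiguity (pairwise deletion), matching
`ape::dist.dna(model = "raw", pairwise.deletion = TRUE)`. Only the
proportion variant is implemented; a count variant would differ only by the
comparable-site denominator.

**Barcode-gap analysis**: for a focal group at a given rank, the maximum
within-group distance is compared against the minimum distance from group
members to outside members. The comparison universe is congeners for
species-level tests and confamilials for genus-level tests (configurable to
the whole library). A gap requires *strict* inequality
(`min_inter > max_intra`); equality means no gap. Groups without intra
pairs (singletons) or without outside members yield an *undetermined*
verdict, which the fallback treats like "no gap" — a conservative pullback.

**Rank fallback**: COI-5P (and ITS2, if ever used) report species when a
species-level gap exists, otherwise genus. rbcLa reports species, else
genus when a genus-level gap exists, else family. Family-rank assignments
are only valid for the plant marker; the returned rank is never more
specific than the candidate's. Queries whose gap result is missing are
reported as unassigned and flagged rather than dropped.

## Diet compilation

Observations follow the supplementary-table schema: method (DO direct
observation, SC stomach contents, FS fecal metabarcoding), age class,
food group (A arthropods; P "plants" including vascular plants, fungi and
slime moulds; V vertebrate tissue), optional subcategories, dates that may
be partial. Seasons are winter (Nov 1–Mar 31) and non-winter
(May 1–Oct 31); April is deliberately a third category ("neither") rather
than being silently assigned, because nestling samples are largely
April-dated. Partial dates are kept for food-group tallies, excluded (and
counted) in seasonal tallies. Printed percentages use
round-half-away-from-zero to whole percent, which reproduces the published
rounding (121/662 → 18%).

## Cached-vs-fresh classifier

Each item identified to species is designated `unknown`,
`either_possible`, `likely_fresh` or `likely_cached`. Likely cached
requires at least one of four criteria on the observation's month/day:

* **C1** the taxon's declared migratory-absence window covers the date;
* **C2** the observed life stage has declared presence windows and none
  covers the date;
* **C3** the taxon's underground (hibernation/dormancy) window covers the
  date;
* **C4** snow depth on the date exceeds the item's height above the
  substrate. The study states the principle (snow "would have precluded
  access") without a numeric rule; we operationalise it as
  `depth > substrate_height_cm` with both values known. Snow is looked up
  at the observation's station on the exact date, else the nearest record
  within `max_gap_days` (default 3; earlier day wins ties).

All four criteria are evaluated and every firing criterion is recorded.
Failing all four: year-round accessible taxa are `either_possible`; items
inside a declared fresh-availability window are `likely_fresh`
(strengthened — `fresh_strong` — when the taxon was unavailable in the
preceding summer/fall storage season); everything else is
`either_possible`. Items not identified to species, with unknown natural
history, or flagged as misidentified are `unknown`. A profile declaring
both `year_round` and a migratory absence is rejected as contradictory.

Published expert determinations are representable as a per-item override
column that takes precedence over rule evaluation and is logged as such;
the packaged study table uses this mechanism, since the published
designations encode expert judgment that no trait table fully captures.

Cohort tallies cover adults in winter and nestlings, overall and per food
group; the identified-to-species denominator (87 winter-adult, 125 nestling
items in the packaged table) is reported separately from the full cohort
sizes (194 and 212). Sac-level cached presence counts sacs with at least
one designated item in the denominator and sacs with at least one
likely-cached item in the numerator.

## Synthetic data: what it emulates and what it does not

**Reference libraries** evolve on a two-level star tree (base → taxon
ancestor → sequence) under Jukes–Cantor-style uniform substitutions. Branch
substitution probabilities are set by exact JC branch composition (the
non-uniform eigenvalue `u = 1 − 4/3·q` multiplies along a path) so that
`intra_divergence` and `inter_divergence` are the expected *pairwise*
p-distances within and between taxa. When `inter ≤ intra` the ancestor
branch clamps to zero, collapsing all taxa into one cloud — the geometry in
which barcode gaps vanish and rank fallback must engage. Auto-generated
rank labels pair species two-per-genus and genera two-per-family so every
species has congeners; with an odd taxon count the last species is a
singleton and its gap verdict is undetermined by construction.

**Reads** are forward primer + substitution-mutated template +
reverse-complemented reverse primer, with truncated-normal integer Phred
scores clipped to [0, 60]. The `min_abundance_spike` option gives the first
template exactly that many error-free reads, pinning its dereplicated count
for threshold experiments. No chimeras, indels or homopolymer
(flow-sequencing) error structure are simulated, so passing QC tests here
says nothing about indel-heavy platforms.

**Observations** are built criterion-first: for a ground-truth cached item
one criterion is drawn and the taxon's trait row and date are forced so it
provably holds (C4 items are dated onto days with >5 cm simulated snow and
given a 5 cm substrate height); fresh items are built so no criterion can
fire and the date sits inside a declared fresh window with
`storable_season_available = false`. Each item carries its own synthetic
taxon, so profiles never interact. The default date window (Nov 1–Mar 31)
and the 40 cm winter snow profile mirror the study region's winter; items
alternate between FS-nestling (grouped into sacs of ~10 items) and
SC-adult records to emulate the two sampled cohorts. Ground truth is exact
by construction, which is precisely why classifier recovery is expected to
be 100%/0% — the test validates the rule engine, not real-world label
noise, observer error or ambiguous phenology.

**Snow series** are piecewise-constant daily depths with optional clipped
Gaussian jitter, in the (station, date, depth_cm) schema of public daily
climate records.

**The packaged 662-item observation table** is a synthetic reconstruction:
the original supplementary tables are not machine-readable here, so the
table is built programmatically to satisfy every printed marginal of the
study simultaneously (method split 121/147/394; direct-observation food
groups 20/23/78 with 6/34/35 of 75 vertebrate subcategories; winter-adult
194/87 with 34/48/5 designations; nestling 212/125 with 35/42/48; plant
cells 32/56 and 22/33; stomach food-group splits 49%/36% winter and
66%/30% non-winter; 10 of 15 designated sacs with a cached item, 20 sacs
total). Cells the printed text does not pin down (the FS-vs-SC split of
nestling designations, sac membership, individual dates and most taxon
names) are fixed once and are not data about real jays; analyses that
depend on them beyond the printed marginals would be meaningless.

## Problem sizes and numerical choices

The validation experiments run at desk scale, chosen to exercise every code
path with comfortable statistical margins: rank-recovery libraries use 6–8
taxa × 4 sequences × 300 bp with 2 error-free reads per template;
oracle-equivalence checks use 200 random libraries of ≤50 sequences and 100
random Smith–Waterman pairs; classifier recovery uses 400 observations at a
0.5 cached fraction (3 binomial SE ≈ ±0.075). Distance comparisons in the
gap oracle are exact float equality — both routes compute the same rational
number (site counts over comparable sites) in double precision. Alignment
determinism rests on the fixed tie-break conventions above. All generators
take explicit integer seeds; identical specs and seeds give byte-identical
outputs.

## Known limitations

* The naive search is a stand-in for BLAST against curated databases; it
  has no E-values, no heuristics and is quadratic per pair, so it is meant
  for packaged references, not genome-scale libraries.
* ITS2 is plumbed through (it follows the COI-5P fallback scheme) but, as
  in the study, no fungal inference is attempted.
* The classifier's C2 depends on a life-stage annotation on the
  observation; metabarcoding records have none, so C2 can only fire for
  stomach-content or direct observations with stage information.
* April observations belong to neither season; cohort membership for
  nestlings is by age class, not season, so this does not affect the
  published cohort denominators.
* Percentage rounding is half-away-from-zero; one printed value (10/15
  sacs, "66%") appears floor-rounded in the study and is reported here as
  the fraction with one decimal (66.7).
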