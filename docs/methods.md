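# Methods

This note records the model assumptions, parameter defaults and design
choices behind `amplityper`, and what the synthetic tests do and do not
establish about real data.

## Coordinates and alphabets

All positions reported anywhere in the package are 1-based alignment
columns, matching the convention of published variable-site tables.
Degapped *read* coordinates exist only inside the phasing forward model and
are always labelled as such. Sequences are stored uppercase over the IUPAC
nucleotide alphabet plus `-`; `U` maps to `T` with a logged note.
Ambiguity characters are treated as **literal states** throughout typing
and distance computation: an `R` at a column is a state of its own, not a
superposition of A and G. This is deliberate — in direct Sanger reads a
stable additive polymorphic site is a reproducible character that defines a
typed variant (e.g. a ribotype carrying `S` at one column); reading it as
uncertainty belongs to the phasing module alone. An optional `overlap` mode
in the Provesti distance treats `R` vs `A` as a match for users who want
the other convention; it is off by default.

## Variable sites and simple indel coding

A column is variable when it carries at least two distinct states. The
consensus is the majority state, ties resolved to the first sequence's
state and logged. Adjacent gap-bearing columns whose gap pattern (the set
of gapped sequences) is identical collapse into one indel event — simple
indel coding, under which a 4 bp insertion is a single character rather
than four. A run where the pattern changes splits into separate events, so
a 1 bp indel shared by three types next to a 1 bp indel private to one type
yields two events even when the columns touch.

Note that the fixture tables carry an explicitly printed consensus row
which is *not* everywhere the majority state of the tabulated sequences
(the most frequent type dominates several columns). For reconstructed
tables the printed consensus therefore overrides the recomputed majority;
for arbitrary alignments the majority rule applies.

**Homopolymer-attached indels.** An event is flagged when its
inserted/deleted residues consist solely of one base and the ungapped
context adjacent to the event contains a run of ≥ `min_run` copies of that
base (the two flanks count together, since the indel sits inside one
stretch). Defaults: base `T`, `min_run` 4 — the shortest run plausibly
called a "poly-T stretch"; both are configurable. Flagged events are
excluded from type definition by default, reflecting the standard
treatment of homopolymer slippage as a typing-unreliable character; they
are still counted (separately) in event distances, which is how network
edges acquire "+1 poly-T indel" annotations.

## Type catalogs

One type per distinct state vector over the retained characters; counts
accumulate per species; default naming is A, B, C, … by descending count
with ties broken by first occurrence (reconstruction fixtures supply the
published names instead via an explicit vector→name mapping).

**Main designation.** A type is main when its total count reaches
`min_main_count` (default 10, chosen to separate the frequent types from
the largest variants) *and* it is not expressible as an already-designated
main plus extra non-consensus states. Candidates are processed in
descending count order, so a large type is never demoted because of a
smaller one. This ordering matters: in the ITS catalog the all-consensus
type (n = 13) is accepted as a main because the three larger mains are
examined first and none of them is structurally contained in it, while a
rare type that merely adds one substitution to a main is demoted even at
`min_main_count = 1`.

**Variant and intermediate roles.** A non-main type is `variant_of(M)`
when it equals M plus extra non-consensus states, preferring an M for
which all other mains are consensus at those extra columns. It is
`intermediate(M1, M2)` when, at every column distinguishing M1 from M2, it
carries either an ambiguity code covering both states or one of the two
states, genuinely mixing the mains rather than collapsing onto either.
When several pairs qualify, pairs are tried in order of closeness (sum of
Hamming distances from the type to the two mains), with the nearer and
then larger main named first; this reproduces the intuitive readings
(a type with an additive `R` at the single column separating two mains is
a transition between exactly those two). Everything else is `unique`.
Roles never leak into names: a type keeps its catalog name whatever its
role, since published catalogs name some structural variants with their
own letters.

**Lineage calls.** An individual combining chlorotype and ribotype(s) maps
to the Eastern-Mediterranean group (chlorotype in the A group and all
ribotypes in the ribotype-A group), the Western/Central-Mediterranean group
(chlorotype outside the A group), or `admixed` (A-group chlorotype with at
least one non-A-group ribotype — the contact-zone pattern). With only one
marker present the call is made from that marker; only an individual
missing both markers is `undetermined`.

## Phasing model

The forward model assumes a direct read over two co-amplified templates is
their position-wise superposition: with balanced copy numbers the read
shows the IUPAC union of the two template bases at every position; with
skewed copy numbers it shows the dominant template's base, the minor base
surfacing only at positions sampled at the minor-detection rate (default
0.1, seeded — the underrepresentation of the minor copy is not quantified
anywhere, so this is a free parameter of the simulation, not an estimate).
The read ends where the shorter template ends. Peak heights, basecaller
noise and mixtures of more than two paralogs are outside the model.

**Detection.** A read is heterozygous when it has at least one ambiguity
and some window of 20 positions contains ≥ 4 ambiguities; the breakpoint
is the first position of that dense run. Reads with only isolated additive
sites are *not* phased — they define typed variants. The thresholds are
package defaults (no published values exist); with the default 6 bp
insertion and ≥ 1 SNP the dense tail makes detection deterministic unless
the insertion falls within the last ~20 read positions, in which case the
tail is genuinely too short to distinguish from isolated sites.

**Base subtraction.** Before the breakpoint, the recovered second copy at
position k is the member of the read's ambiguity set at k that differs
from the reference base; unambiguous positions pass through. From the
breakpoint on, the reference register is re-scored over offsets
0, ±1 … ±10 by the fraction of remaining positions whose shifted reference
base lies inside the read's ambiguity set; the best-supported offset (ties
to the smallest shift) must explain ≥ 90 % of the tail, otherwise the
result is truncated at the breakpoint with an explicit error. In the
positional superposition model the winning offset is 0 for any consistent
reference and the insertion is recovered through the subtraction itself;
the offset search exists to reject unrelated references rather than
silently mis-subtract, and deliberately does not hard-code the 6 bp event
(any indel up to 10 bp is representable). For balanced noise-free traces
the round trip is exact: subtracting either true template returns the
other over the resolvable window, and re-superimposing the pair reproduces
the read byte for byte. Reference candidates are tried in ascending
geographic distance (ties by id, logged), and a candidate is accepted only
if its subtraction re-superimposes to the exact read — an incorrect
neighbour cannot be silently accepted.

Recovered copies are re-emitted in alignment coordinates (gaps re-inserted
from a matching alignment row) and carry the
`extracted_from_heterozygote` provenance flag end-to-end, so downstream
tabulations can report which sequences exist only through phasing.

## Distances and networks

Provesti's distance here is the haploid special case: the proportion of
compared columns at which two state vectors differ, gaps being ordinary
states and columns with a missing-data symbol (`N`, `?`) dropped from the
denominator. On literal-state vectors without missing data it is a true
metric (identity, symmetry, triangle inequality), which the tests verify
against a per-column brute-force comparer on random triples. The
multi-allele generalisation is out of scope because every individual
contributes one sequence per marker.

Event distances decompose the differing characters of two condensed rows
into substitutions and indel events, homopolymer-attached events counted
separately — pass rows from a matrix condensed with
`exclude_homopolymer=False` so those events are present to be counted.

The minimum spanning network scans edges in ascending weight. Within one
weight class, an edge whose endpoints were in separate components *before
the class started* is kept: edges that still merge components are primary
(they form a spanning tree per connected component), the rest are
alternatives — connections tying exactly the threshold at which their
endpoints' components merged (epsilon = 0; only exact ties create grey
edges, consistent with the sparse alternative edges of published
networks). This is equivalent to "the edge lies in some minimum spanning
tree", which the tests verify via the cycle property against the chosen
tree and via exhaustive spanning-tree enumeration for ≤ 6 nodes. Infinite
distances yield component-wise networks with a warning. The two
chloroplast markers are never concatenated for network building; they are
analysed marker by marker.

## Synthetic data

**Table reconstructions.** The three published variable-site tables are
transcribed as constants and expanded into full-length gapped alignments
(427 / 899 / 699 bp; one sequence per counted individual; 158 / 142 / 143
sequences — the printed n-columns over-count the stated totals by one each
for the two chloroplast tables, a discrepancy reproduced, not resolved).
The invariant background is filled from a fixed-seed stream so alignments
are byte-stable across runs. The poly-T context around the two 1 bp
chloroplast indels is embedded explicitly (a 6 T run) so the homopolymer
rule fires on exactly those events and not on the mixed-residue 4 bp indel
or the single-column deletion elsewhere; the table shows only that those
indels are poly-T attached, not the run length. The single-column gap at
position 366 is encoded as its own event (grouping is by contiguity and
pattern), although the source counts only three indels for this marker.
Population assignments and coordinates attached to fixture alignments are
synthetic stand-ins. Because full-row transcriptions, not deposited
accessions, are the input, results involving outgroup species and the
enlarged GenBank alignments (33 / 23 / 57 type inventories) are out of
reach and deliberately untested.

**Simulated datasets.** `generate_dataset` emulates the study structure:
one homogeneous region carrying only the ubiquitous ribotype, plus
regional blocks each seeded with one divergent regional ribotype (1–5
SNPs and the 6 bp `CGTCCT` insertion placed at the same column in the last
third) and a region-specific chlorotype per chloroplast marker;
populations of two individuals; heterozygotes — individuals carrying the
ubiquitous and the regional copy simultaneously — occur at fraction 0.27
within the regional blocks, where co-occurring paralogs exist. The
skewed-mix fraction defaults to 0 (the noise-free balanced setting used by
the exact-recovery checks); it can be raised to exercise dominant-only
extraction. All generation is a pure function of (spec, seed).

What passing these tests shows: the rules are internally consistent and
exactly invertible under their own forward model at realistic marker
lengths and divergences. What they do not show: robustness to basecall
noise, unequal peak heights, more than two paralogs per individual,
alignment errors, or references that differ from the true co-template —
real chromatograms will violate the noise-free assumption, and the
package's defence is rejection (unresolvable-tail and consistency errors)
rather than correction.

## Numerical and procedural choices

- Problem sizes in the test suite and the acceptance script (1000 phasing
  pairs, 150 random network matrices of ≤ 6 nodes, 10⁴ distance triples,
  32-individual default dataset) are desk-scale choices: each check runs in
  seconds while exercising every code path; the exhaustive network oracle
  is capped at 6 nodes because spanning-tree enumeration grows as n^(n-2).
- Determinism: the pipeline writes byte-identical tables given the same
  config and seed; all tie-breaks (consensus, reference choice, naming)
  are deterministic and logged.
- KML export is written with the standard library's XML tools against the
  OGC KML 2.2 namespace; placemarks without coordinates are skipped with a
  warning.
- Errors are stage-named in the pipeline driver and partial outputs are
  retained, so a failing phasing stage does not discard the catalogs
  already written.
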