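# Methods

## Scope and data model

`viropost` implements the computation that turns raw virus-detection
output into ecology-ready abundance tables, for workflows in which the
heavy external tools (virus detectors, genome-quality estimators, read
mappers, aligners, binners) have already run or will run separately. The
package exchanges only their plain-text formats. All coordinates are
stored 1-based inclusive, the convention of BLAST tabular output and of
detector summaries; conversion to half-open intervals happens only
inside the interval-union routines. Every table is tab-separated with an
`NA` missing-value token, and floats are serialised with `repr` so that
parse ∘ serialise is the identity on all typed fields — a property the
test suite asserts per schema.

Two header dialects are accepted for the detector and quality tables
(the tools' native column names — `seq_name`, `score`, `hallmarks`,
`checkv_quality`, `provirus` — and the package's own canonical names),
because the surrounding tools do not agree on a schema. Quality tiers
are normalised case-insensitively onto the five canonical CheckV
strings; an unrecognised tier maps to `Not-determined` with a warning
rather than silently passing through. Validation is strict everywhere
else: out-of-range scores, inconsistent gene counts, provirus
coordinates without a provirus topology, duplicate FASTA ids and
non-IUPAC characters are all typed errors.

## Provirus reconciliation

A provirus is a viral genome integrated in a host contig. Scores and
quality metrics computed on the whole contig are contaminated by host
sequence, so the workflow re-runs detection on the trimmed viral region
(a "round 2") and this package substitutes the re-scored records for
their parents: a parent with k ≥ 1 trimmed children contributes exactly
its k children, giving the count law n₁ − p + k. Child records take ids
of the form `<parent>|provirus_<start>_<end>` — parseable and
collision-free — with the region on the round-1 parent. Records without
children, in particular every plain virus, pass through untouched.
Overlapping trimmed regions from one parent are kept with a warning
(they may be tandem prophages). A quality-table provirus flag *without*
trimmed coordinates keeps the record untrimmed with a warning, because
fabricating a region would violate the invariant that a provirus
record's length equals its region span; the trimmed metrics arrive with
the round-2 child.

Filtration presets are applied after reconciliation, so a provirus is
always judged on its trimmed length and re-scored metrics. All preset
thresholds are inclusive (≥), exactly as printed in their definitions:
conservative = (score 0.8, 2,500 bp, 1 hallmark), relaxed = (0.7,
2,500 bp, 0). The sequence-quality rule used ahead of the abundance
table is deliberately different — strictly greater-than ("longer than
5 kb", "longer than 1 kb") — and both conventions are kept as stated
rather than harmonised.

Genome type (dsDNA/ssDNA/RNA) and host domain
(prokaryotic/eukaryotic) are inferred from the taxonomic lineage by
scanning ranks right-to-left so the most specific mapped rank wins;
e.g. any lineage containing *Caudoviricetes* maps to (dsDNA,
prokaryotic). The bundled map covers the common unambiguous taxa and is
user-overridable via a small YAML file, since any hard-coded table ages.

## Gene-content filtration

Keep iff `viral_genes ≥ min_viral_genes` (default 1) and
`host_genes / viral_genes ≤ max_host_viral_ratio` (default 1, read as an
inclusive maximum). The rules are tested in that order and a dropped
record carries the first failed rule's code. With `min_viral_genes = 0`
the ratio is undefined at zero viral genes; the convention is to keep
such a record iff it also has zero host genes. The filter is a partition
(kept ∪ dropped = input), idempotent, monotone in viral genes and
antitone in host genes — all property-tested.

## vOTU clustering

The species-level operational unit for uncultivated viruses is defined
by ANI ≥ 95 % over an aligned fraction ≥ 85 % of the shorter genome.
Both thresholds are inclusive, following the tool flags (`≥ 0.95`,
`≥ 0.85`) rather than the looser prose "> 95 %".

**Pairwise merge.** Self-hits are discarded. When an aligner emits both
orientations of a pair, the orientation with the greater summed
alignment length is kept (tie: lexicographically first), making the
result independent of input order. ANI is the alignment-length-weighted
mean of per-alignment percent identities — overlapping alignments are
*not* de-overlapped for the identity average, matching the upstream
definition ("average across all aligned regions") — while the
per-sequence coverages divide the union of aligned intervals by the
declared length, so overlapping alignments never push coverage past 1.
Reverse-strand spans are normalised before the union. The implementation
is checked against an exact-arithmetic oracle (rational sums and
explicit position sets) to 1e-9 on random tables.

**Greedy clustering.** Sequences are sorted by length descending (ties:
id ascending). Each unassigned sequence in scan order founds a cluster;
every later unassigned sequence whose pair with that representative
clears both thresholds joins it, where AF is the coverage of the shorter
sequence of the pair (at equal lengths, the larger of the two
coverages). A sequence joins the *first* qualifying representative —
the standard centroid-scan behaviour; assigning to the best-ANI
representative instead is a known variant, not implemented. Sequences
with no qualifying pair become singletons, so the clusters always
partition the input and the representative is by construction the
longest member. The implementation is compared with a literal
transcription of this definition on hundreds of random instances,
including all-tie lengths.

## Coverage and abundance matrices

Read mapping itself is out of scope; its result is abstracted as
*placements* — aligned spans on a contig — or, alternatively, as a
precomputed per-sample coverage table in CoverM-style columns. From
placements: covered fraction = |union of spans| / length, mean depth =
Σ span lengths / length, read count = number of placements. There is no
MAPQ or base-quality weighting, which the workflow delegates to the
mapper's own filters. The statistics are exact against a per-position
counting oracle.

The matrix is complete over representatives × samples (missing cells
are 0, which conserves total observed depth) with the detection
annotations joined on. Horizontal-coverage filtration zeroes an
abundance cell where the covered fraction is below the threshold —
a few piled-up reads on a small fraction of a genome are not evidence
of presence — and then drops rows with no remaining signal, so the
tables can go straight into ecology software; the zero-then-drop choice
makes the row sets nested across the default thresholds 0.1 / 0.5 / 0.9.
Dropping rows rather than keeping zeroed ones is a deliberate,
documented choice where the upstream description is silent.

## Bin curation

Protein redundancy (duplicated proteins within a bin) signals
contamination. The conservative mode keeps bins with redundancy < 2;
the relaxed mode keeps ≤ 5; the 2–5 band is thus kept only under
relaxed, reflecting that such bins may, but often do not, indicate
contamination. Giant viruses (NCLDVs) legitimately reach ~10 redundant
proteins, so named bins can be exempted per-bin up to redundancy 10 —
an explicit override rather than an automatic heuristic, because
genome-type calls on bins are themselves uncertain. Multi-scaffold bins
are concatenated in membership-table order with a 10-N linker (length
formula Σ members + 10·(k − 1)); single-member bins are rejected as
inputs. In the combined bins + unbinned-vOTUs table a bin row carries
the length-weighted mean of its members' depths and covered fractions
and the sum of their read counts; length-weighting was chosen (over a
plain mean) so that a long scaffold dominates a bin's abundance the
same way it dominates its sequence content.

## Synthetic fixtures

The generators emulate the *statistical shape* of real inputs, not
their biology. The mutation model is substitution-only with an exact
substitution count (`round(divergence·len)`), so identity and divergence
are in closed form and the clustering truth is analytic. A planted
community has one independent random ancestor per cluster (its longest
member, and therefore the known representative) and members mutated at
the within-cluster divergence and slightly truncated; the emitted
alignment table carries one full-length alignment per within-cluster
pair with identity 100·(1 − realised divergence), plus self-hits.
Between-cluster pairs (~75 % divergence at the defaults) are far beyond
what a local aligner reports, so no rows are emitted for them; a real
aligner's tabular output can be substituted directly. Defaults — 3 %
within-cluster and 25 % between-cluster divergence, lengths 3–12 kb —
place members safely inside the 95 % species threshold and ancestors
safely outside it.

Detector-table fixtures plant exact pass/fail compositions per filter by
sampling each field from the qualifying or disqualifying region, then
shuffling so class is not positional. Placement fixtures tile
non-overlapping spans, so the realised covered fraction is
`round(target·length)/length` — exact whenever `target·length` is
integral. The full-pipeline fixture adds per-sample low-score decoys and
one flanked provirus (with its second-round tables) per sample, so the
CLI path exercises prefixing, preset filtration, reconciliation,
extraction, clustering, coverage and binning together.

What passing these tests shows — and does not. They demonstrate the
algorithms are implemented exactly as specified and are deterministic;
they cannot demonstrate robustness to features the generators omit:
indels and rearrangements (which make ANI alignment-dependent), chimeric
contigs, uneven read mappability, or detector miscalibration on real
assemblies.

## Determinism and problem sizes

All randomness flows through a single seed (numpy `default_rng`);
outputs carry no timestamps except the summary reports, and float
serialisation is shortest-round-trip, so a repeated run is byte-identical
— asserted end-to-end. The default verification sizes (200 random
alignment tables for the ANI oracle, 500 instances for the clustering
oracle, a 20 × 5 community, 100 random placement sets, 25 reconciliation
fixtures, a 2-sample / 8-cluster pipeline fixture) were chosen as the
smallest scales at which every code path and tie case is exercised;
all generators accept larger sizes unchanged.

## Known limitations

* No SAM/BAM or gzip-transparent parsing; coverage comes from placement
  or coverage tables.
* The weighted-mean ANI inherits the upstream convention of not
  de-overlapping alignments; pairs dominated by repeats can weight
  repeated regions more than once in the identity average (coverages
  are immune, being union-based).
* Greedy centroid clustering is order-dependent by design; a sequence
  near two representatives joins the first in scan order, not the
  closest.
* Bin abundance as a length-weighted member mean assumes members are
  genuinely one genome; for a contaminated bin the value has no clean
  interpretation — which is why redundancy filtration runs first.
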