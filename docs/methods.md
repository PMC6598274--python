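# Methods

## The recognition model

CasX (Cas12e) requires a TTCN protospacer-adjacent motif immediately 5′ of a
20-bp protospacer on the guide-matching strand. The scanner therefore looks
for the 24-base degenerate motif `TTC` + 21×`N` on both strands of every
contig. A site is reported with:

* `start`/`end` — 1-based inclusive coordinates of the 24-mer on the
  *forward* reference strand (`end − start = 23`), regardless of strand;
* `pam`, `guide`, `site_seq` — read on the site's own strand, so a "−"
  site's `site_seq` is the reverse complement of the forward-strand window.

Overlapping and nested windows are all reported: each carries its own PAM
and is independently cleavable. The scanner is motif-generic (any IUPAC
string); the CasX motif is the default.

### Matching semantics

Genomes arrive soft-masked: repeats are lowercase, not `N`-masked, so they
remain searchable. Matching is case-insensitive and sites are reported
uppercase. Genome letters outside `{A,C,G,T}` — assembly-gap `N` runs and
IUPAC ambiguity codes — match **no** motif letter, including motif `N`.
Rationale: an assembly gap is absence of knowledge, not a permissive
wildcard; letting `N` stretches match would mint phantom guides that no
nuclease could be programmed against. This exclusion is the one place where
site counts could differ from a scanner that treats genome `N` as matchable,
and it only matters within 24 bp of a gap.

### Implementation and verification

The production scanner compiles the motif to a character-class regex over
uppercase `A/C/G/T` only and uses a zero-width lookahead to enumerate
overlapping windows; minus-strand hits are forward windows matching the
reverse-complemented motif. It is verified against an independent
brute-force oracle (`synthetic_fixtures.brute_force_scan`) that slides a
window over both strands applying per-letter IUPAC matching — no shared
scanning code — with exact set equality required over seeded genomes
spanning 1–100 kb and GC 0.25–0.65 with gap runs injected.

`scan_genome` streams contigs and guarantees a canonical output order
(contig in input order; `+` block then `−` block; ascending start) in both
execution modes. `file-buffered` mode writes each (contig, strand) block to
a temporary catalog-TSV file as soon as it is computed and streams the
concatenation back, bounding peak memory by one contig rather than the
genome's full hit list — the mode that makes mammalian-scale scans feasible
in modest RAM. With `workers > 1` the (contig, strand) tasks run in a
process pool and are reassembled in task order, so output is byte-identical
for any worker count. Tests assert byte-identical catalogs across both
modes and 1 vs 2 workers.

## Annotation

**Uniqueness.** A site is a *unique cutter* when its guide 20-mer occurs at
exactly one editing site genome-wide (`n_guide_matches = 1`). Guides are
compared as literal strings on their own strands with no reverse-complement
collapsing: a second cleavable locus carrying the same protospacer appears
as its own catalog entry with the same guide string, while a genomic match
without an adjacent PAM would not be cleaved and deliberately does not
count. Uniqueness is therefore only meaningful on a whole-genome catalog.

**PAM usage.** Sites partition by their 4th PAM base into TTCA/TTCC/TTCG/
TTCT, tallied over all sites or unique cutters only; fractions are
normalized within the chosen subset.

**Exon overlap.** A site is assigned to a gene when its full 24-bp interval
overlaps any exon of that gene by ≥ 1 base, on either strand (guides
overlapping an exon support knockout/knock-in at that exon irrespective of
orientation). Exons are pooled over all transcripts of a gene and merged
(overlapping or abutting intervals union); gene biotype is not filtered —
every `gene_id` with at least one exon row counts as a known gene. Interval
queries use an interval tree; correctness is checked against a quadratic
all-pairs oracle.

**Summaries.** The per-genome row reports total and unique sites, unique
percentage, and the median over contigs of per-contig density (sites/Mbp),
with zero-site contigs included as density 0. The per-gene row reports the
percentage of genes with ≥ 1 (unique) exon-overlapping site and the median
(unique) sites per gene over *all* annotated genes, zero-hit genes
included; even-length medians are the mean of the two middle values. These
inclusive conventions are the package's choice where alternatives exist
(e.g. excluding zero-hit genes would bias medians upward) and are the first
thing to revisit if full-scale medians disagree with other tools while
total counts match. Percentages are computed at full precision and printed
to 2 decimals.

## Composition and PAM depletion

GC content is (G+C)/(A+C+G+T) with lowercase counted and non-ACGT letters
excluded from the denominator. The expected-PAM model is **zero-order**
(independent bases): the `TTC` prefix is common to all four PAMs and
cancels, so the expected fraction of PAM `TTCx` is simply the genome
frequency of `x`. The per-PAM observed/expected ratio then isolates
dinucleotide structure: in CpG-depleted genomes the CpG-containing TTCG PAM
falls well below 1 while TTCA stays near 1. A zero-order null is the
minimal model that exposes this effect; higher-order Markov nulls are out
of scope and the model choice is recorded in the output header.

## Strain comparison

Each strain catalog is reduced to its set of distinct guide 20-mers
(presence/absence — duplicates within a strain collapse). The guide
universe is the sorted union over **all** strains in the comparison, and
the distance between two strains is the fractional Hamming distance of
their presence rows, equivalently |Gᵤ Δ Gᵥ| / |universe|. A single shared
denominator (rather than pairwise unions) is what row-wise Hamming on one
binary table computes, and it makes the distance a proper metric (symmetry,
zero diagonal and the triangle inequality are property-tested).

Display order comes from complete-linkage agglomerative clustering.
Fractional Hamming distances over a shared universe tie frequently (equal
numerators over one denominator), so the merge loop is written out
explicitly with a fixed tie rule — equal inter-cluster distances resolve
toward the pair with the lower original indices, and the earlier-created
cluster sits on the left — making the leaf order fully deterministic.
On tie-free matrices the order provably coincides with SciPy's complete
linkage, which the test suite uses as an independent cross-check alongside
a naive reference agglomeration.

Caveat: site dropout in a poorly assembled strain is indistinguishable from
biological absence; distances are reported as-is with no assembly-quality
correction.

## The synthetic-data generator

`synthetic_fixtures` emulates the statistical features of real genomes that
drive the pipeline's outputs, under explicit seeds (no global random
state):

* **Composition** — i.i.d. bases at a target GC (default 0.41, a
  mammalian-like, AT-rich value); marginal GC lands within ±0.02 at 100 kb.
* **CpG suppression** — a first-order Markov chain built from a target
  dinucleotide matrix: independence, except the CG cell is multiplied by
  the suppression factor and the removed mass is reallocated *within the C
  row* (to CC and CT) and, mirror-symmetrically, *within the G column* (to
  AG and GG). Keeping the C-row and G-column totals at their zero-order
  values is what makes the fixture clean for testing PAM depletion: naive
  alternatives (renormalizing the C row, or shifting the mass to C→T as in
  deamination) leak the removed probability into CpA/TpG, which reads out
  as spurious TTCA enrichment on the minus strand (a minus-strand TTCA is a
  forward-strand TpG). With suppression 0.25 at 1 Mbp the realized
  CG/independence ratio is ≈ 0.26 and the TTCG observed/expected ratio
  ≈ 0.27 while TTCA stays within 10% of 1.
* **Gap runs** — `N` runs at seeded positions, placed to avoid planted
  sites, for exercising the gap-exclusion rule.
* **Planted sites** — exact `TTC`+x+guide 24-mers (or their reverse
  complements) written at known positions; overlapping plants are checked
  for base-level compatibility and conflicts raise an error naming the
  pair. Recovery must be exact in coordinates, strand, PAM and guide.
* **Derived strains** — per-base independent substitution at a given rate
  (mutated bases become one of the other three uniformly; gap `N`s are left
  untouched). Expected parent–strain divergence is monotone in the rate,
  which propagates to monotone guide-set Hamming distances.
* **Toy annotations** — non-overlapping multi-exon gene models written as
  Ensembl-dialect GTF exon rows.

What the fixtures do **not** emulate: repeat families and segmental
duplications (so synthetic uniqueness percentages run near 100%, far above
the 68–94% of real genomes), indels and rearrangements between strains,
transcript-level gene structure, and chromosome-scale contig number. Tests
passing on fixtures therefore validate the *mechanics* (matching, counting,
interval logic, distances) and directional statistics (TTCG depletion,
divergence monotonicity), not real-genome magnitudes.

## Numerical and edge-case choices

* Coordinates are 1-based inclusive everywhere in memory and in the TSV
  catalog; only BED export converts (0-based half-open). Overlap assignment
  is invariant under that conversion (property-tested).
* Catalog row order is deterministic: contig in input order, then start,
  then `+` before `−`.
* Empty inputs: a genome with no contigs cannot be summarized (error); an
  empty catalog writes a header-only file; an empty PAM subset has counts 0
  and no fractions; zero base frequencies make expected PAM fractions
  undefined (error) rather than silently infinite ratios.
* Sequences shorter than the motif yield no sites, not an error.
* `.gz` paths are compressed/decompressed transparently on read and write.
* Timestamps in output headers are suppressible (`--no-timestamps`) so
  reruns are byte-identical.

## Problem sizes

The test suite and the reproduction script run on seeded synthetic genomes
of 1 kb–1 Mbp (scanner validation sweeps twenty 1–100-kb genomes; density,
uniqueness and depletion checks use 1 Mbp; strain comparisons use 30–200-kb
parents), sizes at which every statistic tested has comfortably converged
while the full run stays in the tens of seconds. The same code paths scale
to full genomes via the file-buffered scan mode.
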