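# casx-sites

Genome-wide cataloging of **CasX (Cas12e) editing sites** and cross-strain
comparison of guide availability.

CasX is a compact RNA-guided DNA endonuclease with a 4-bp **TTCN** PAM and a
20-bp guide sequence, making its recognition unit the 24-base degenerate
motif `TTCN₂₁` (`TTC` + 21 unconstrained positions). The longer PAM (versus
Cas9's NGG) promises fewer off-target near-matches, but it also means fewer
candidate sites — so the practical questions for anyone designing a CasX
experiment are: *how many sites does my genome offer, how many are unique
cutters, which genes can I reach through an exon, and do those answers hold
in my strain?*

`casx-sites` answers these for any genome in FASTA form:

* **scan** — find every `TTCN + N₂₀` window on both strands (overlapping and
  nested hits included; soft-masked lowercase is searched normally;
  assembly-gap `N`s never match, so gaps cannot mint phantom guides).
* **annotate** — mark each site's guide as a *unique cutter* (its 20-mer
  occurs at exactly one editing site genome-wide; uniqueness is assessed
  only among PAM-adjacent sites), tally PAM usage (TTCA/TTCC/TTCG/TTCT),
  and assign sites to genes whose exons they overlap (Ensembl GTF).
* **stats** — genome GC content and observed-vs-expected PAM usage under a
  zero-order base-composition null, which exposes the TTCG depletion that
  CpG-poor vertebrate genomes show.
* **compare** — across related genomes (e.g. mouse strains), build the
  binary presence/absence matrix of guide 20-mers over their shared guide
  universe, compute pairwise fractional Hamming distances
  d(u,v) = |Gᵤ Δ Gᵥ| / |universe|, and order strains by complete-linkage
  hierarchical clustering.

A `synthetic_fixtures` module generates seeded random genomes (tunable GC,
CpG suppression, gap runs, planted sites, derived strains) so the whole
pipeline is testable without downloading any reference data.

## Worked example

Generate a 100-kb synthetic genome with a toy gene annotation, then run the
pipeline:

```bash
casx-sites make-fixtures --out-dir fx --seed 7
casx-sites scan --fasta fx/genome.fa --out catalog.tsv --no-timestamps
casx-sites annotate --catalog catalog.tsv --gtf fx/genes.gtf \
    --fai fx/genome.fa.fai --out annotated.tsv \
    --genome-summary genome_summary.tsv --gene-summary gene_summary.tsv \
    --pam-usage pam.tsv
casx-sites stats --fasta fx/genome.fa --catalog catalog.tsv \
    --out comp.tsv --depletion-out depletion.tsv
```

The catalog lists one row per site (1-based inclusive coordinates; PAM,
guide and full 24-mer read on the site's own strand):

```
contig  start  end  strand  pam   guide                 site_seq                  n_guide_matches  unique  gene_ids
chr1    20     43   +       TTCT  TTTCAGTTTGTAACGACAGG  TTCTTTTCAGTTTGTAACGACAGG  1                1       .
chr1    25     48   +       TTCA  GTTTGTAACGACAGGCGTCG  TTCAGTTTGTAACGACAGGCGTCG  1                1       .
```

`genome_summary.tsv` gives the one-row genome summary — total and unique
sites plus the median per-contig density in sites/Mbp:

```
genome  total_sites  unique_sites  unique_pct  total_sites_per_mbp_median  unique_sites_per_mbp_median
genome  3286         3286          100.00      32860.00                    32860.00
```

3,286 sites in 100 kb is one site per ~30 bp — close to the 1-per-32-bp
expectation for a uniform genome (each strand offers L−23 windows, each
matching `TTC` with probability 4⁻³). All guides are unique here because a
short first-order random genome has essentially no repeated 20-mers; real
genomes, with repeat families, sit lower (typically 68–94%).

`depletion.tsv` compares observed PAM usage against the zero-order
expectation (the `TTC` prefix cancels, so the expected fraction of PAM
`TTCx` is just the genome frequency of base `x`). This fixture genome was
generated with CpG suppression 0.5, and the CpG-containing TTCG PAM duly
shows up at about half its expected rate while TTCA stays near 1:

```
pam   observed  expected  ratio
TTCA  0.305234  0.290361  1.0512
TTCC  0.252891  0.211825  1.1939
TTCG  0.105295  0.198646  0.5301
TTCT  0.336579  0.299168  1.1251
```

`gene_summary.tsv` reports the share of genes with at least one (unique)
exon-overlapping site and the median sites per gene — the numbers that tell
you whether a knockout campaign can reach essentially every gene:

```
genome  genes  cut_pct  unique_cut_pct  sites_per_gene_median  unique_sites_per_gene_median
genome  25     100.00   100.00          21                     21
```

To compare strains, scan each strain FASTA and feed the catalogs to
`compare`, which writes the labeled Hamming-distance matrix, a per-strain
guide-count summary, and the complete-linkage leaf order:

```bash
casx-sites compare --catalogs ref=ref.tsv --catalogs strainA=a.tsv \
    --catalogs strainB=b.tsv --out-dist dist.tsv --out-order order.txt
```

## Library use

```python
from casx_sites import scan_genome_catalog, annotate_uniqueness, sequence_io

catalog = scan_genome_catalog(sequence_io.read_fasta("genome.fa"))
annotate_uniqueness(catalog)
print(len(catalog), sum(1 for s in catalog if s.unique))
```

All coordinates are 1-based inclusive (Ensembl convention) in memory and in
the TSV catalog; BED export converts to 0-based half-open. See
`docs/methods.md` for the model and design choices.
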