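"""Catalog annotation and summary statistics.

Three annotations are applied to a scanned catalog:

* guide uniqueness — a site is a *unique cutter* when its 20-bp guide string
  occurs at exactly one editing site genome-wide.  Uniqueness is assessed
  only among PAM-adjacent sites: a locus matching the guide without a PAM
  would not be cleaved, so it does not count.  Guides are compared as
  literal strings on their own strands, with no reverse-complement
  collapsing.
* PAM usage — the partition of sites by their 4th PAM base (TTCA/C/G/T),
  over all sites or unique cutters only.
* exon overlap — a site is assigned to a gene when its full 24-bp interval
  overlaps any exon of that gene by at least one base, on either strand.

Summaries mirror the per-genome (site counts and per-contig density
medians) and per-gene (cut percentages and per-gene site medians) tables a
genome-wide catalog is reported with.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from statistics import median
from typing import Iterable, Mapping

from intervaltree import IntervalTree

from .motif_scan import CASX_PAMS
from .records import EditSite, GeneModel, SiteCatalog


@dataclass
class PamUsage:
    counts: dict[str, int]
    fractions: dict[str, float]
    subset: str = "all"

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class GenomeSummary:
    """Genome-wide site statistics (one table row per genome)."""

    total_sites: int
    unique_sites: int
    unique_pct: float
    density_per_contig: dict[str, float]
    unique_density_per_contig: dict[str, float]
    total_density_median: float
    unique_density_median: float


@dataclass
class GeneSummary:
    """Exon-overlap statistics over all annotated genes."""

    n_genes: int
    cut_pct: float
    unique_cut_pct: float
    median_sites_per_gene: float
    median_unique_sites_per_gene: float


@dataclass
class GeneHitCounts:
    n_sites: int = 0
    n_unique: int = 0


def annotate_uniqueness(catalog: SiteCatalog) -> SiteCatalog:
    """Fill ``n_guide_matches`` and ``unique`` for every site, in place.

    Requires the whole genome's catalog: uniqueness is genome-wide across
    contigs and strands.
    """
    counts = Counter(site.guide for site in catalog.sites)
    for site in catalog.sites:
        site.n_guide_matches = counts[site.guide]
        site.unique = site.n_guide_matches == 1
    catalog.guide_counts = counts
    return catalog


def count_pam_usage(catalog: SiteCatalog, subset: str = "all") -> PamUsage:
    """Tally sites by PAM 4-mer, over all sites or unique cutters only."""
    if subset not in ("all", "unique"):
        raise ValueError(f"subset must be 'all' or 'unique', not {subset!r}")
    if subset == "unique":
        sites: Iterable[EditSite] = (s for s in catalog.sites if s.unique)
    else:
        sites = catalog.sites
    counts = {pam: 0 for pam in CASX_PAMS}
    for site in sites:
        counts[site.pam] = counts.get(site.pam, 0) + 1
    total = sum(counts.values())
    fractions = {pam: n / total for pam, n in counts.items()} if total else {}
    return PamUsage(counts=counts, fractions=fractions, subset=subset)


def overlap_sites_with_exons(
    catalog: SiteCatalog, genes: Mapping[str, GeneModel] | Iterable[GeneModel]
) -> dict[str, GeneHitCounts]:
    """Assign sites to genes by exon overlap; fill ``gene_ids`` in place.

    Returns per-gene counts (distinct sites, and unique cutters among them)
    for *every* gene in the annotation, zero-hit genes included.  A site on
    a contig absent from the annotation simply gets no genes.
    """
    if isinstance(genes, Mapping):
        gene_list = list(genes.values())
    else:
        gene_list = list(genes)
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for gene in gene_list:
        for start, end in gene.exons:
            trees[gene.contig][start : end + 1] = gene.gene_id  # half-open
    per_gene = {gene.gene_id: GeneHitCounts() for gene in gene_list}
    for site in catalog.sites:
        tree = trees.get(site.contig)
        if tree is None:
            site.gene_ids = frozenset()
            continue
        hits = frozenset(iv.data for iv in tree.overlap(site.start, site.end + 1))
        site.gene_ids = hits
        for gid in hits:
            per_gene[gid].n_sites += 1
            if site.unique:
                per_gene[gid].n_unique += 1
    return per_gene


def summarize_genome(catalog: SiteCatalog, contig_lengths: Mapping[str, int]) -> GenomeSummary:
    """Site totals, uniqueness percentage and per-contig density medians.

    Densities are sites per Mbp per contig; medians run over *all* contigs
    in the index, counting zero-site contigs as density 0.
    """
    if not contig_lengths:
        raise ValueError("empty genome: no contigs in index")
    per_contig: Counter = Counter()
    unique_per_contig: Counter = Counter()
    unique_sites = 0
    for site in catalog.sites:
        if site.contig not in contig_lengths:
            raise KeyError(f"site contig {site.contig!r} not in the FASTA index")
        per_contig[site.contig] += 1
        if site.unique:
            unique_per_contig[site.contig] += 1
            unique_sites += 1
    total_sites = len(catalog.sites)
    density = {
        c: per_contig[c] / (length / 1e6) for c, length in contig_lengths.items()
    }
    unique_density = {
        c: unique_per_contig[c] / (length / 1e6) for c, length in contig_lengths.items()
    }
    return GenomeSummary(
        total_sites=total_sites,
        unique_sites=unique_sites,
        unique_pct=100.0 * unique_sites / total_sites if total_sites else 0.0,
        density_per_contig=density,
        unique_density_per_contig=unique_density,
        total_density_median=median(density.values()),
        unique_density_median=median(unique_density.values()),
    )


def summarize_genes(per_gene: Mapping[str, GeneHitCounts]) -> GeneSummary:
    """Cut percentages and per-gene medians over all annotated genes.

    Medians include zero-hit genes; even-length medians are the mean of the
    two middle values.
    """
    n_genes = len(per_gene)
    if n_genes == 0:
        raise ValueError("no genes in annotation")
    site_counts = [c.n_sites for c in per_gene.values()]
    unique_counts = [c.n_unique for c in per_gene.values()]
    cut = sum(1 for n in site_counts if n > 0)
    unique_cut = sum(1 for n in unique_counts if n > 0)
    return GeneSummary(
        n_genes=n_genes,
        cut_pct=100.0 * cut / n_genes,
        unique_cut_pct=100.0 * unique_cut / n_genes,
        median_sites_per_gene=median(site_counts),
        median_unique_sites_per_gene=median(unique_counts),
    )


# ---------------------------------------------------------------------------
# TSV emission (Table-style single rows)
# ---------------------------------------------------------------------------

def write_genome_summary(summary: GenomeSummary, path: str | Path, label: str = "genome") -> None:
    with open(path, "w") as out:
        out.write(
            "genome\ttotal_sites\tunique_sites\tunique_pct\t"
            "total_sites_per_mbp_median\tunique_sites_per_mbp_median\n"
        )
        out.write(
            f"{label}\t{summary.total_sites}\t{summary.unique_sites}\t"
            f"{summary.unique_pct:.2f}\t{summary.total_density_median:.2f}\t"
            f"{summary.unique_density_median:.2f}\n"
        )


def write_gene_summary(summary: GeneSummary, path: str | Path, label: str = "genome") -> None:
    with open(path, "w") as out:
        out.write(
            "genome\tgenes\tcut_pct\tunique_cut_pct\t"
            "sites_per_gene_median\tunique_sites_per_gene_median\n"
        )
        out.write(
            f"{label}\t{summary.n_genes}\t{summary.cut_pct:.2f}\t"
            f"{summary.unique_cut_pct:.2f}\t{summary.median_sites_per_gene:g}\t"
            f"{summary.median_unique_sites_per_gene:g}\n"
        )


def write_pam_usage(usages: Iterable[PamUsage], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("pam\tcount\tfraction\tsubset\n")
        for usage in usages:
            for pam in sorted(usage.counts):
                frac = usage.fractions.get(pam, float("nan"))
                out.write(f"{pam}\t{usage.counts[pam]}\t{frac:.6f}\t{usage.subset}\n")
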