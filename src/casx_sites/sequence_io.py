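"""Readers and writers for the formats the pipeline touches.

FASTA (streaming, via Bio.SeqIO), faidx indexes, Ensembl-dialect GTF exon
annotations, and the tool's own site-catalog TSV / BED6 outputs.  All
in-memory and TSV coordinates are 1-based inclusive; BED export converts to
0-based half-open.  Paths ending in ``.gz`` are transparently compressed on
both read and write.
"""

from __future__ import annotations

import gzip
import io
import re
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Iterator, Mapping, TextIO

from Bio import SeqIO
from intervaltree import IntervalTree

from .records import ContigRecord, EditSite, GeneModel, SiteCatalog

CATALOG_COLUMNS = (
    "contig",
    "start",
    "end",
    "strand",
    "pam",
    "guide",
    "site_seq",
    "n_guide_matches",
    "unique",
    "gene_ids",
)


class FormatError(ValueError):
    """A file does not conform to its declared format."""


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Iterator[ContigRecord]:
    """Stream contigs from a FASTA file in file order.

    Sequence case is preserved (soft masking survives).  Contig name is the
    first whitespace-delimited token of the header, matching faidx naming.
    Memory use is proportional to one contig, not the genome.
    """
    with _open_text(path) as handle:
        # Bio.SeqIO silently yields nothing on malformed input, so validate
        # the leading line ourselves.
        head = handle.read(8192)
        for line in head.splitlines():
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(f"{path}: first non-blank line is not a FASTA header")
                break
        handle.seek(0)
        seen: set[str] = set()
        for rec in SeqIO.parse(handle, "fasta"):
            name = rec.id
            if not name:
                raise FormatError(f"{path}: empty contig name")
            if name in seen:
                raise FormatError(f"{path}: duplicate contig name {name!r}")
            seen.add(name)
            yield ContigRecord(name=name, sequence=str(rec.seq))


def write_fasta(records: Iterable[ContigRecord], path: str | Path, width: int = 60) -> None:
    with _open_text(path, "wt") as out:
        for rec in records:
            out.write(f">{rec.name}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def read_fasta_index(path: str | Path) -> dict[str, int]:
    """Parse a faidx (.fai) index into a contig -> length mapping.

    Genome size is ``sum(read_fasta_index(p).values())``.
    """
    lengths: dict[str, int] = {}
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected >=2 tab-separated fields")
            try:
                lengths[fields[0]] = int(fields[1])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer length field {fields[1]!r}"
                ) from None
    return lengths


def write_fasta_index(records: Iterable[ContigRecord], path: str | Path) -> None:
    """Write a minimal faidx-style index (name and length columns exact)."""
    offset = 0
    with _open_text(path, "wt") as out:
        for rec in records:
            # offset/linebases/linewidth assume write_fasta's 60-column layout
            offset += len(rec.name) + 2
            out.write(f"{rec.name}\t{rec.length}\t{offset}\t60\t61\n")
            n_lines = -(-rec.length // 60)
            offset += rec.length + n_lines


def contig_lengths(path: str | Path, fai: str | Path | None = None) -> dict[str, int]:
    """Contig lengths from a .fai index if given, else from the FASTA itself."""
    if fai is not None:
        return read_fasta_index(fai)
    return {rec.name: rec.length for rec in read_fasta(path)}


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_GENE_ID_RE = re.compile(r'gene_id\s+"([^"]*)"')


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Union of 1-based inclusive intervals; overlapping or abutting merge."""
    tree = IntervalTree()
    for start, end in intervals:
        tree[start : end + 2] = None  # +2: make abutting intervals touch
    tree.merge_overlaps(strict=False)
    return tuple(sorted((iv.begin, iv.end - 2) for iv in tree))


def parse_gtf_exons(path: str | Path) -> dict[str, GeneModel]:
    """Extract per-gene merged exon models from an Ensembl-dialect GTF.

    Only ``exon`` feature rows contribute; exons are pooled over all
    transcripts of a gene and merged.  Gene biotype is not filtered: every
    gene_id with at least one exon counts as a known gene.
    """
    exons: dict[str, list[tuple[int, int]]] = defaultdict(list)
    gene_contig: dict[str, str] = {}
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated columns")
            contig, _source, feature, start_s, end_s, _score, _strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if start > end:
                raise FormatError(f"{path}:{lineno}: start {start} > end {end}")
            m = _GENE_ID_RE.search(attrs)
            if not m:
                raise FormatError(f"{path}:{lineno}: exon row lacks gene_id attribute")
            gene_id = m.group(1)
            exons[gene_id].append((start, end))
            gene_contig.setdefault(gene_id, contig)
    return {
        gid: GeneModel(gene_id=gid, contig=gene_contig[gid], exons=merge_intervals(ivs))
        for gid, ivs in exons.items()
    }


# ---------------------------------------------------------------------------
# Site-catalog TSV / BED
# ---------------------------------------------------------------------------

def _site_row(site: EditSite) -> str:
    nmatch = "." if site.n_guide_matches is None else str(site.n_guide_matches)
    uniq = "." if site.unique is None else ("1" if site.unique else "0")
    genes = ",".join(sorted(site.gene_ids)) if site.gene_ids else "."
    return "\t".join(
        (
            site.contig,
            str(site.start),
            str(site.end),
            site.strand,
            site.pam,
            site.guide,
            site.site_seq,
            nmatch,
            uniq,
            genes,
        )
    )


def catalog_sort_key(contig_order: Mapping[str, int]):
    """Deterministic row order: contig in input order, then start, + before -."""

    def key(site: EditSite):
        return (contig_order.get(site.contig, len(contig_order)), site.start, site.strand)

    return key


def write_catalog(
    sites: Iterable[EditSite],
    path: str | Path,
    *,
    contig_order: Mapping[str, int] | None = None,
    header_comments: Iterable[str] = (),
) -> None:
    """Write sites as catalog TSV.  ``contig_order`` triggers the canonical
    row sort; otherwise input order is kept (scan output is already ordered).
    """
    sites = list(sites)
    if contig_order is not None:
        sites.sort(key=catalog_sort_key(contig_order))
    with _open_text(path, "wt") as out:
        for comment in header_comments:
            out.write(f"# {comment}\n")
        out.write("\t".join(CATALOG_COLUMNS) + "\n")
        for site in sites:
            out.write(_site_row(site) + "\n")


def _parse_site_row(fields: list[str], where: str) -> EditSite:
    if len(fields) != len(CATALOG_COLUMNS):
        raise FormatError(f"{where}: expected {len(CATALOG_COLUMNS)} columns")
    contig, start, end, strand, pam, guide, site_seq, nmatch, uniq, genes = fields
    if strand not in ("+", "-"):
        raise FormatError(f"{where}: unknown strand symbol {strand!r}")
    if uniq not in ("0", "1", "."):
        raise FormatError(f"{where}: unique flag must be 0/1/. not {uniq!r}")
    return EditSite(
        contig=contig,
        start=int(start),
        end=int(end),
        strand=strand,
        pam=pam,
        guide=guide,
        site_seq=site_seq,
        n_guide_matches=None if nmatch == "." else int(nmatch),
        unique=None if uniq == "." else uniq == "1",
        gene_ids=frozenset() if genes == "." else frozenset(genes.split(",")),
    )


def read_catalog(path: str | Path) -> SiteCatalog:
    """Read a catalog TSV; inverse of :func:`write_catalog`."""
    sites: list[EditSite] = []
    with _open_text(path) as handle:
        header_seen = False
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if tuple(fields) != CATALOG_COLUMNS:
                    raise FormatError(f"{path}:{lineno}: unrecognized catalog header")
                header_seen = True
                continue
            sites.append(_parse_site_row(fields, f"{path}:{lineno}"))
        if not header_seen:
            raise FormatError(f"{path}: missing catalog header")
    return SiteCatalog.from_sites(sites)


def write_bed(sites: Iterable[EditSite], path: str | Path) -> None:
    """BED6 export: 0-based half-open, name = guide, score = 0."""
    with _open_text(path, "wt") as out:
        for site in sites:
            out.write(
                f"{site.contig}\t{site.start - 1}\t{site.end}\t{site.guide}\t0\t{site.strand}\n"
            )
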