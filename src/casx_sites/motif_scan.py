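"""Degenerate-motif scanning for CasX editing sites.

The default motif is the CasX recognition unit: a TTCN PAM followed by a
20-bp unconstrained protospacer, i.e. ``TTC`` + 21 * ``N`` (24 bases total).
Every window matching the motif on either strand is reported; overlapping
and nested hits are all kept, since each carries its own PAM and is
independently cleavable.

Matching semantics: soft-masked (lowercase) genome letters match normally
and are reported uppercase.  Genome letters outside {A,C,G,T} — assembly-gap
Ns and ambiguity codes — match *no* motif letter, including motif N, so gaps
never generate phantom guides.
"""

from __future__ import annotations

import re
import tempfile
from concurrent.futures import ProcessPoolExecutor
from pathlib import Path
from typing import Iterable, Iterator, Literal

from .records import ContigRecord, EditSite, SiteCatalog
from . import sequence_io

CASX_MOTIF = "TTC" + "N" * 21
PAM_LENGTH = 4
CASX_PAMS = ("TTCA", "TTCC", "TTCG", "TTCT")

IUPAC_CODES: dict[str, str] = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN",
    "TGCAYRSWMKVHDBN",
)


def reverse_complement(sequence: str) -> str:
    """Reverse complement over the IUPAC alphabet; result is uppercase."""
    seq = sequence.upper()
    bad = set(seq) - set(IUPAC_CODES)
    if bad:
        raise ValueError(f"non-IUPAC letters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(pattern_base: str, genome_base: str) -> bool:
    """Does one genome letter satisfy one IUPAC pattern letter?

    Case-insensitive; genome letters outside {A,C,G,T} never match, even
    against pattern N.
    """
    try:
        allowed = IUPAC_CODES[pattern_base.upper()]
    except KeyError:
        raise ValueError(f"non-IUPAC pattern letter {pattern_base!r}") from None
    return genome_base.upper() in allowed


def motif_to_regex(motif: str) -> str:
    """Compile an IUPAC motif to a regex over uppercase A/C/G/T only."""
    parts = []
    for letter in motif.upper():
        try:
            allowed = IUPAC_CODES[letter]
        except KeyError:
            raise ValueError(f"non-IUPAC motif letter {letter!r}") from None
        parts.append(allowed if len(allowed) == 1 else f"[{allowed}]")
    return "".join(parts)


def scan_strand(
    contig_name: str, sequence: str, strand: str, motif: str = CASX_MOTIF
) -> list[EditSite]:
    """All motif hits on one strand of a contig, ascending start.

    Minus-strand hits are forward-strand windows whose reverse complement
    matches the motif; their pam/guide/site_seq are read on the minus strand
    while coordinates stay on the forward strand.
    """
    if strand not in ("+", "-"):
        raise ValueError(f"bad strand {strand!r}")
    target = motif if strand == "+" else reverse_complement(motif)
    # Lookahead regex reports overlapping windows; uppercase once so
    # soft-masked bases match and are reported uppercase.
    pattern = re.compile(f"(?=({motif_to_regex(target)}))")
    seq = sequence.upper()
    sites = []
    for m in pattern.finditer(seq):
        window = m.group(1)
        start = m.start() + 1
        site_seq = window if strand == "+" else reverse_complement(window)
        sites.append(
            EditSite(
                contig=contig_name,
                start=start,
                end=start + len(window) - 1,
                strand=strand,
                pam=site_seq[:PAM_LENGTH],
                guide=site_seq[PAM_LENGTH:],
                site_seq=site_seq,
            )
        )
    return sites


def scan_sequence(contig_name: str, sequence: str, motif: str = CASX_MOTIF) -> list[EditSite]:
    """All motif hits on both strands: "+" block then "-" block, by start."""
    return scan_strand(contig_name, sequence, "+", motif) + scan_strand(
        contig_name, sequence, "-", motif
    )


def _scan_task(args: tuple[str, str, str, str]) -> list[EditSite]:
    name, seq, strand, motif = args
    return scan_strand(name, seq, strand, motif)


def scan_genome(
    genome: Iterable[ContigRecord],
    motif: str = CASX_MOTIF,
    mode: Literal["in-memory", "file-buffered"] = "in-memory",
    workers: int = 1,
    tmp_dir: str | Path | None = None,
) -> Iterator[EditSite]:
    """Scan every contig of a genome, yielding sites in the canonical order:
    contig in input order, "+" block then "-" block, ascending start.

    ``file-buffered`` writes each (contig, strand) block to a temporary
    catalog-TSV file as soon as it is computed and streams the concatenation
    back, so peak memory is bounded by one contig and its largest strand
    block rather than the whole genome's hits.  Both modes produce identical
    site streams for any worker count.
    """
    if mode not in ("in-memory", "file-buffered"):
        raise ValueError(f"unknown scan mode {mode!r}")
    if workers < 1:
        raise ValueError("workers must be >= 1")

    def blocks() -> Iterator[list[EditSite]]:
        if workers == 1:
            for rec in genome:
                for strand in ("+", "-"):
                    yield scan_strand(rec.name, rec.sequence, strand, motif)
        else:
            with ProcessPoolExecutor(max_workers=workers) as pool:
                tasks = (
                    (rec.name, rec.sequence, strand, motif)
                    for rec in genome
                    for strand in ("+", "-")
                )
                # map() preserves task order, so output order is
                # deterministic regardless of worker scheduling.
                yield from pool.map(_scan_task, tasks, chunksize=1)

    if mode == "in-memory":
        for block in blocks():
            yield from block
    else:
        with tempfile.TemporaryDirectory(dir=tmp_dir) as tdir:
            paths = []
            for i, block in enumerate(blocks()):
                path = Path(tdir) / f"block_{i:06d}.tsv"
                sequence_io.write_catalog(block, path)
                paths.append(path)
                del block
            for path in paths:
                yield from sequence_io.read_catalog(path).sites


def scan_genome_catalog(
    genome: Iterable[ContigRecord],
    motif: str = CASX_MOTIF,
    mode: Literal["in-memory", "file-buffered"] = "in-memory",
    workers: int = 1,
    tmp_dir: str | Path | None = None,
) -> SiteCatalog:
    """Materialize :func:`scan_genome` into a :class:`SiteCatalog`."""
    return SiteCatalog.from_sites(
        scan_genome(genome, motif=motif, mode=mode, workers=workers, tmp_dir=tmp_dir)
    )
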