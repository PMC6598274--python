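"""Core in-memory records shared across the pipeline.

Coordinates are 1-based inclusive throughout (Ensembl/GTF convention);
conversion to 0-based half-open happens only at the BED boundary.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator


@dataclass(frozen=True)
class ContigRecord:
    """One FASTA contig: name (first header token) and verbatim sequence."""

    name: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """A gene's merged exon footprint on one contig.

    ``exons`` is a tuple of 1-based inclusive ``(start, end)`` intervals,
    sorted, non-overlapping and non-abutting.
    """

    gene_id: str
    contig: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: no exons")
        prev_end = None
        for start, end in self.exons:
            if start > end:
                raise ValueError(f"gene {self.gene_id}: interval {start}>{end}")
            if prev_end is not None and start <= prev_end + 1:
                raise ValueError(f"gene {self.gene_id}: exons not merged")
            prev_end = end


@dataclass
class EditSite:
    """One PAM + protospacer hit.

    ``start``/``end`` delimit the 24-mer on the forward reference strand
    (end - start = 23).  ``pam``, ``guide`` and ``site_seq`` are read on the
    site's own strand, so for "-" sites ``site_seq`` is the reverse complement
    of the forward-strand reference window.

    Annotation fields are filled by :mod:`casx_sites.site_annotation`:
    ``n_guide_matches`` is None until uniqueness has been computed.
    """

    contig: str
    start: int
    end: int
    strand: str
    pam: str
    guide: str
    site_seq: str
    n_guide_matches: int | None = None
    unique: bool | None = None
    gene_ids: frozenset[str] = field(default_factory=frozenset)

    def validate(self) -> None:
        if self.end - self.start != len(self.site_seq) - 1:
            raise ValueError("end - start does not match site_seq length")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.site_seq != self.pam + self.guide:
            raise ValueError("site_seq != pam + guide")


@dataclass
class SiteCatalog:
    """All sites of one genome plus the genome-wide guide occurrence tally."""

    sites: list[EditSite]
    guide_counts: Counter = field(default_factory=Counter)

    def __iter__(self) -> Iterator[EditSite]:
        return iter(self.sites)

    def __len__(self) -> int:
        return len(self.sites)

    @classmethod
    def from_sites(cls, sites: Iterable[EditSite]) -> "SiteCatalog":
        sites = list(sites)
        return cls(sites=sites, guide_counts=Counter(s.guide for s in sites))

    def guides(self) -> set[str]:
        """Distinct guide 20-mers present in this catalog."""
        if self.guide_counts:
            return set(self.guide_counts)
        return {s.guide for s in self.sites}
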