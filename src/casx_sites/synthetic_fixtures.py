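"""Seeded synthetic genomes, planted sites, toy gene annotations, and the
independent brute-force scanner used as an oracle by the test suite.

The generator emulates the statistical structure that drives real PAM-usage
patterns: a tunable GC fraction, optional CpG suppression (a first-order
Markov chain built from a target dinucleotide distribution: independence of
bases except that the CG cell is multiplied by the suppression factor, with
the removed mass reallocated inside the C row (to CC and CT) and, mirror
symmetrically, inside the G column (to AG and GG).  Keeping the C-row and
G-column totals at their zero-order values means CpG depletion appears
without enriching CpA/TpG — so TTCG sites are depleted on both strands
while TTCA usage stays at its zero-order expectation), assembly-gap N runs,
and exactly-known planted PAM+protospacer sites for recovery testing.
Strain variants are derived by independent per-base substitution.

All randomness flows from explicit seeds; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .motif_scan import CASX_MOTIF, PAM_LENGTH, iupac_match, reverse_complement
from .records import ContigRecord, EditSite, GeneModel
from . import sequence_io

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class PlantedSite:
    """A site to write into a synthetic genome (1-based position of the
    leftmost base of the 24-mer on the forward strand)."""

    position: int
    strand: str
    guide: str


@dataclass(frozen=True)
class FixtureSpec:
    length: int
    gc: float = 0.41
    cpg_suppression: float = 1.0
    n_gap_runs: int = 0
    gap_run_length: int = 100
    planted: tuple[PlantedSite, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0,1)")
        if not 0 < self.cpg_suppression <= 1:
            raise ValueError("cpg_suppression must be in (0,1]")
        for p in self.planted:
            if p.position < 1 or p.position + 23 > self.length:
                raise ValueError(f"planted site at {p.position} does not fit")


def _random_bases(length: int, gc: float, cpg_suppression: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    if cpg_suppression == 1.0:
        idx = rng.choice(4, size=length, p=p)
        return np.take(_BASES, idx).tobytes().decode()
    # Target dinucleotide matrix: independent bases except CG suppressed,
    # the deficit reallocated within the C row (-> CC, CT) and mirror
    # symmetrically within the G column (-> AG, GG).  Row/column totals for
    # C and G stay at their zero-order values, so CpG depletion does not
    # leak into CpA/TpG enrichment on either strand.
    A, C, G, T = range(4)
    F = np.outer(p, p)
    deficit = F[C, G] * (1 - cpg_suppression)
    F[C, G] *= cpg_suppression
    w_c, w_t = p[C] / (p[C] + p[T]), p[T] / (p[C] + p[T])
    F[C, C] += deficit * w_c
    F[C, T] += deficit * w_t
    F[G, G] += deficit * w_c
    F[A, G] += deficit * w_t
    cum_rows = np.cumsum(F / F.sum(axis=1, keepdims=True), axis=1)
    u = rng.random(length)
    out = np.empty(length, dtype=np.uint8)
    prev = int(rng.choice(4, p=p))
    for i in range(length):
        b = int(np.searchsorted(cum_rows[prev], u[i], side="right"))
        b = min(b, 3)
        out[i] = _BASES[b]
        prev = b
    return out.tobytes().decode()


def _plant_window(planted: PlantedSite, rng: np.random.Generator) -> str:
    """Forward-strand 24-mer a plant writes into the genome."""
    if planted.strand not in ("+", "-"):
        raise ValueError(f"bad strand {planted.strand!r}")
    if len(planted.guide) != len(CASX_MOTIF) - PAM_LENGTH:
        raise ValueError("guide must be 20 bases")
    x = "ACGT"[rng.integers(0, 4)]
    forward = "TTC" + x + planted.guide.upper()
    return forward if planted.strand == "+" else reverse_complement(forward)


def plant_site(
    sequence: str,
    position: int,
    strand: str,
    guide: str,
    rng: np.random.Generator | None = None,
    pam_base: str | None = None,
) -> str:
    """Write one PAM+protospacer 24-mer into a sequence at a 1-based position.

    A forward plant writes ``TTC`` + x + guide; a reverse plant writes the
    reverse complement of that 24-mer.  x is the seeded 4th PAM base unless
    ``pam_base`` pins it.  Planting over an assembly-gap N is an error.
    """
    if position < 1 or position + 23 > len(sequence):
        raise ValueError(f"planted site at {position} does not fit")
    if pam_base is not None:
        x = pam_base.upper()
    else:
        if rng is None:
            rng = np.random.default_rng(0)
        x = "ACGT"[rng.integers(0, 4)]
    forward = "TTC" + x + guide.upper()
    window = forward if strand == "+" else reverse_complement(forward)
    lo, hi = position - 1, position + 23
    if "N" in sequence[lo:hi].upper():
        raise ValueError(f"planted site at {position} overlaps an N run")
    return sequence[:lo] + window + sequence[hi:]


def random_genome(spec: FixtureSpec, name: str = "chr1") -> ContigRecord:
    """Generate a reproducible synthetic contig per the fixture spec.

    Planted windows are checked for pairwise compatibility: two overlapping
    plants demanding different bases at one position raise an error naming
    the conflicting pair.
    """
    rng = np.random.default_rng(spec.seed)
    seq = _random_bases(spec.length, spec.gc, spec.cpg_suppression, rng)

    # Resolve planted windows first so gap placement can avoid them.
    windows: list[tuple[PlantedSite, str]] = []
    for p in spec.planted:
        windows.append((p, _plant_window(p, rng)))
    assigned: dict[int, tuple[str, PlantedSite]] = {}
    for p, window in windows:
        for offset, base in enumerate(window):
            pos = p.position + offset
            if pos in assigned and assigned[pos][0] != base:
                other = assigned[pos][1]
                raise ValueError(
                    f"conflicting plants at genome position {pos}: "
                    f"site@{p.position}{p.strand} vs site@{other.position}{other.strand}"
                )
            assigned[pos] = (base, p)

    # Gap runs at seeded positions, avoiding planted windows and each other.
    occupied = [(p.position, p.position + 23) for p in spec.planted]
    gap_runs: list[int] = []
    attempts = 0
    while len(gap_runs) < spec.n_gap_runs:
        attempts += 1
        if attempts > 1000 * max(1, spec.n_gap_runs):
            raise ValueError("could not place gap runs without conflicts")
        start = int(rng.integers(1, spec.length - spec.gap_run_length + 2))
        run = (start, start + spec.gap_run_length - 1)
        if any(run[0] <= e and s <= run[1] for s, e in occupied):
            continue
        occupied.append(run)
        gap_runs.append(start)
    for start in gap_runs:
        lo = start - 1
        seq = seq[:lo] + "N" * spec.gap_run_length + seq[lo + spec.gap_run_length :]

    for p, window in windows:
        lo = p.position - 1
        seq = seq[:lo] + window + seq[lo + 24 :]
    return ContigRecord(name=name, sequence=seq)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

_ORACLE_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def brute_force_scan(
    sequence: str, contig: str = "seq", motif: str = CASX_MOTIF
) -> list[EditSite]:
    """Naive O(L * |motif|) sliding-window scan of both strands.

    Ground truth for the production scanner: no regex, no shared scanning
    code — each window position is tested letter by letter with
    :func:`iupac_match`, and minus-strand windows are complemented inline.
    """
    m = len(motif)
    L = len(sequence)
    sites: list[EditSite] = []
    for strand in ("+", "-"):
        for i in range(L - m + 1):
            window = sequence[i : i + m].upper()
            if strand == "+":
                ok = all(iupac_match(motif[k], window[k]) for k in range(m))
                site_seq = window
            else:
                ok = True
                for k in range(m):
                    genome_letter = window[m - 1 - k]
                    comp = _ORACLE_COMPLEMENT.get(genome_letter)
                    if comp is None or not iupac_match(motif[k], comp):
                        ok = False
                        break
                if ok:
                    site_seq = "".join(
                        _ORACLE_COMPLEMENT[c] for c in reversed(window)
                    )
            if ok:
                sites.append(
                    EditSite(
                        contig=contig,
                        start=i + 1,
                        end=i + m,
                        strand=strand,
                        pam=site_seq[:PAM_LENGTH],
                        guide=site_seq[PAM_LENGTH:],
                        site_seq=site_seq,
                    )
                )
    return sites


# ---------------------------------------------------------------------------
# Strain derivation
# ---------------------------------------------------------------------------

def derive_strain(
    genome: ContigRecord, mutation_rate: float, seed: int, name: str | None = None
) -> ContigRecord:
    """Per-base independent substitution at the given rate.

    Only A/C/G/T letters mutate (gap Ns stay put); a mutated base becomes
    one of the other three, uniformly.  Deterministic per seed.
    """
    if not 0 <= mutation_rate < 1:
        raise ValueError("mutation_rate must be in [0,1)")
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(genome.sequence.upper().encode(), dtype=np.uint8).copy()
    idx = np.full(arr.shape, -1, dtype=np.int64)
    for base, j in _BASE_INDEX.items():
        idx[arr == ord(base)] = j
    mask = (rng.random(arr.shape[0]) < mutation_rate) & (idx >= 0)
    shift = rng.integers(1, 4, size=arr.shape[0])
    new_idx = (idx + shift) % 4
    arr[mask] = _BASES[new_idx[mask]]
    return ContigRecord(name=name or f"{genome.name}_mut", sequence=arr.tobytes().decode())


# ---------------------------------------------------------------------------
# Toy gene annotations and fixture corpus
# ---------------------------------------------------------------------------

def random_gene_models(
    contig_length: int,
    n_genes: int,
    rng: np.random.Generator,
    contig: str = "chr1",
    exon_length: tuple[int, int] = (80, 400),
    intron_length: tuple[int, int] = (50, 500),
    max_exons: int = 3,
) -> list[GeneModel]:
    """Non-overlapping toy genes, each 1..max_exons exons, laid left to right."""
    genes: list[GeneModel] = []
    cursor = 1
    for i in range(n_genes):
        cursor += int(rng.integers(100, 1000))
        exons = []
        for _ in range(int(rng.integers(1, max_exons + 1))):
            length = int(rng.integers(*exon_length))
            if cursor + length > contig_length:
                break
            exons.append((cursor, cursor + length - 1))
            cursor += length + int(rng.integers(*intron_length))
        if not exons:
            break
        genes.append(GeneModel(gene_id=f"gene{i + 1}", contig=contig, exons=tuple(exons)))
    return genes


def write_gtf(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write exon rows (one transcript per gene) in Ensembl GTF dialect."""
    with open(path, "w") as out:
        out.write("#!genome-build synthetic\n")
        for gene in genes:
            for start, end in gene.exons:
                attrs = f'gene_id "{gene.gene_id}"; transcript_id "{gene.gene_id}.t1";'
                out.write(
                    f"{gene.contig}\tsynthetic\texon\t{start}\t{end}\t.\t+\t.\t{attrs}\n"
                )


def make_fixture_corpus(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Materialize a small standard test corpus: a 100 kb genome with planted
    sites and gaps, its faidx index, a toy GTF, and three derived strains."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    planted = tuple(
        PlantedSite(position=int(pos), strand=strand, guide="".join(
            "ACGT"[b] for b in rng.integers(0, 4, size=20)
        ))
        for pos, strand in zip(
            sorted(rng.choice(np.arange(1, 100_000 - 23, 40), size=20, replace=False)),
            ["+", "-"] * 10,
        )
    )
    spec = FixtureSpec(
        length=100_000, gc=0.41, cpg_suppression=0.5, n_gap_runs=3, planted=planted,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    genome = random_genome(spec)
    genes = random_gene_models(spec.length, 25, rng)
    paths = {
        "fasta": out_dir / "genome.fa",
        "fai": out_dir / "genome.fa.fai",
        "gtf": out_dir / "genes.gtf",
    }
    sequence_io.write_fasta([genome], paths["fasta"])
    sequence_io.write_fasta_index([genome], paths["fai"])
    write_gtf(genes, paths["gtf"])
    for i, rate in enumerate((0.001, 0.01, 0.1), start=1):
        strain = derive_strain(genome, rate, seed=spec.seed + i, name=f"strain{i}")
        p = out_dir / f"strain{i}.fa"
        sequence_io.write_fasta([strain], p)
        paths[f"strain{i}"] = p
    return paths
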