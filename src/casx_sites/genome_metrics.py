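"""Genome composition statistics and PAM-usage depletion.

GC content counts soft-masked lowercase with uppercase; letters outside
A/C/G/T (gap Ns, ambiguity codes) are tallied separately and excluded from
the GC denominator.

The expected-PAM model is zero-order: under independent bases the TTC
prefix is common to all four TTCx PAMs and cancels, so the expected
fraction of sites with 4th PAM base ``b`` is simply freq(b).  The
observed/expected ratio per PAM then exposes dinucleotide effects the
zero-order null cannot produce — most notably TTCG depletion in
CpG-depleted vertebrate genomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .records import ContigRecord
from .site_annotation import PamUsage

BASES = ("A", "C", "G", "T")


@dataclass
class BaseComposition:
    counts: dict[str, int]
    n_other: int

    @property
    def total_acgt(self) -> int:
        return sum(self.counts.values())

    @property
    def gc_fraction(self) -> float:
        total = self.total_acgt
        if total == 0:
            raise ValueError("no A/C/G/T bases: GC fraction undefined")
        return (self.counts["G"] + self.counts["C"]) / total

    @property
    def base_frequencies(self) -> dict[str, float]:
        total = self.total_acgt
        if total == 0:
            raise ValueError("no A/C/G/T bases")
        return {b: n / total for b, n in self.counts.items()}


@dataclass
class PamDepletion:
    observed: dict[str, float]
    expected: dict[str, float]
    ratio: dict[str, float]
    model: str = "zero-order"


def base_composition(genome: Iterable[ContigRecord] | str) -> BaseComposition:
    """Base counts and GC fraction over a genome (or single sequence)."""
    if isinstance(genome, str):
        genome = [ContigRecord(name="seq", sequence=genome)]
    counts = {b: 0 for b in BASES}
    n_other = 0
    length = 0
    for rec in genome:
        seq = rec.sequence.upper()
        length += len(seq)
        for b in BASES:
            counts[b] += seq.count(b)
    n_other = length - sum(counts.values())
    if length == 0:
        raise ValueError("empty genome")
    return BaseComposition(counts=counts, n_other=n_other)


def expected_pam_fractions(comp: BaseComposition) -> dict[str, float]:
    """Expected TTCx PAM fractions under independent bases: freq of base x."""
    freqs = comp.base_frequencies
    if any(f == 0 for f in freqs.values()):
        zero = [b for b, f in freqs.items() if f == 0]
        raise ValueError(f"degenerate composition: zero frequency for {zero}")
    return {f"TTC{b}": freqs[b] for b in BASES}


def pam_depletion(observed: PamUsage, comp: BaseComposition) -> PamDepletion:
    """Observed vs zero-order-expected PAM fractions and their ratio."""
    expected = expected_pam_fractions(comp)
    obs = {pam: observed.fractions.get(pam, 0.0) for pam in expected}
    ratio = {pam: obs[pam] / expected[pam] for pam in expected}
    return PamDepletion(observed=obs, expected=expected, ratio=ratio)


def write_composition(comp: BaseComposition, path: str | Path, label: str = "genome") -> None:
    with open(path, "w") as out:
        out.write("genome\tA\tC\tG\tT\tother\tgc_fraction\n")
        c = comp.counts
        out.write(
            f"{label}\t{c['A']}\t{c['C']}\t{c['G']}\t{c['T']}\t"
            f"{comp.n_other}\t{comp.gc_fraction:.6f}\n"
        )


def write_depletion(dep: PamDepletion, path: str | Path) -> None:
    with open(path, "w") as out:
        out.write(f"# expected model: {dep.model}\n")
        out.write("pam\tobserved\texpected\tratio\n")
        for pam in sorted(dep.observed):
            out.write(
                f"{pam}\t{dep.observed[pam]:.6f}\t{dep.expected[pam]:.6f}\t"
                f"{dep.ratio[pam]:.4f}\n"
            )
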