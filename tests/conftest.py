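import pytest

from casx_sites.records import ContigRecord, EditSite
from casx_sites.synthetic_fixtures import FixtureSpec, PlantedSite, random_genome


def site_key(site: EditSite):
    """Identity of a site independent of annotation fields."""
    return (site.contig, site.start, site.end, site.strand, site.site_seq)


def make_site(contig="c1", start=1, strand="+", pam="TTCA", guide="A" * 20) -> EditSite:
    return EditSite(
        contig=contig,
        start=start,
        end=start + 23,
        strand=strand,
        pam=pam,
        guide=guide,
        site_seq=pam + guide,
    )


@pytest.fixture
def small_genome() -> ContigRecord:
    """10 kb seeded genome with two planted sites and one gap run."""
    spec = FixtureSpec(
        length=10_000,
        gc=0.45,
        n_gap_runs=1,
        gap_run_length=50,
        planted=(
            PlantedSite(position=101, strand="+", guide="ACGTACGTACGTACGTACGT"),
            PlantedSite(position=5_001, strand="-", guide="TTTTACGTACGTACGTCCCC"),
        ),
        seed=20,
    )
    return random_genome(spec)
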