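"""Uniqueness, PAM usage, exon overlap, and table summaries."""

from collections import Counter

import pytest

from casx_sites.records import GeneModel, SiteCatalog
from casx_sites.site_annotation import (
    annotate_uniqueness,
    count_pam_usage,
    overlap_sites_with_exons,
    summarize_genes,
    summarize_genome,
    GeneHitCounts,
)
from casx_sites.motif_scan import scan_sequence
from casx_sites.synthetic_fixtures import FixtureSpec, PlantedSite, random_genome

from conftest import make_site


class TestUniqueness:
    def test_single_site_unique(self):
        cat = SiteCatalog.from_sites([make_site()])
        annotate_uniqueness(cat)
        assert cat.sites[0].n_guide_matches == 1
        assert cat.sites[0].unique is True

    def test_shared_guide_across_contigs(self):
        cat = SiteCatalog.from_sites(
            [make_site(contig="c1"), make_site(contig="c2", start=500)]
        )
        annotate_uniqueness(cat)
        assert all(s.n_guide_matches == 2 and not s.unique for s in cat.sites)

    def test_no_reverse_complement_collapsing(self):
        g1 = "A" * 20
        g2 = "T" * 20  # rc of g1; must be treated as a different guide
        cat = SiteCatalog.from_sites(
            [make_site(guide=g1), make_site(start=100, strand="-", guide=g2, pam="TTCA")]
        )
        annotate_uniqueness(cat)
        assert all(s.unique for s in cat.sites)

    def test_planted_multiplicity_matches_brute_tally(self):
        # k copies of one guide, one copy of another, on a real scanned genome
        g = "ACGTACGTACGTACGTACGT"
        h = "TTTTCCCCGGGGAAAATTTT"
        planted = tuple(
            PlantedSite(position=p, strand="+", guide=g) for p in (101, 201, 301)
        ) + (PlantedSite(position=401, strand="+", guide=h),)
        genome = random_genome(FixtureSpec(length=2_000, planted=planted, seed=77))
        cat = SiteCatalog.from_sites(scan_sequence(genome.name, genome.sequence))
        annotate_uniqueness(cat)
        # independent tally, no hashing through guide_counts
        for site in cat.sites:
            expected = sum(1 for other in cat.sites if other.guide == site.guide)
            assert site.n_guide_matches == expected
            assert site.unique is (expected == 1)
        g_sites = [s for s in cat.sites if s.guide == g]
        h_sites = [s for s in cat.sites if s.guide == h]
        assert len(g_sites) == 3 and all(s.n_guide_matches == 3 for s in g_sites)
        assert len(h_sites) == 1 and h_sites[0].unique

    def test_accounting_invariants(self):
        genome = random_genome(FixtureSpec(length=5_000, seed=13))
        cat = SiteCatalog.from_sites(scan_sequence(genome.name, genome.sequence))
        annotate_uniqueness(cat)
        assert sum(cat.guide_counts.values()) == len(cat.sites)
        assert set(s.guide for s in cat.sites) == set(cat.guide_counts)
        for s in cat.sites:
            assert s.unique is (s.n_guide_matches == 1)


class TestPamUsage:
    def test_uniform_fractions(self):
        cat = SiteCatalog.from_sites(
            [
                make_site(start=1 + 30 * i, pam=pam, guide=b * 20)
                for i, (pam, b) in enumerate(
                    zip(("TTCA", "TTCC", "TTCG", "TTCT"), "ACGT")
                )
            ]
        )
        usage = count_pam_usage(cat)
        assert usage.fractions == {p: 0.25 for p in ("TTCA", "TTCC", "TTCG", "TTCT")}

    def test_unique_only_subset(self):
        sites = [
            make_site(start=1, pam="TTCA", guide="A" * 20),
            make_site(start=100, pam="TTCG", guide="C" * 20),
            make_site(start=200, pam="TTCG", guide="C" * 20),
        ]
        cat = SiteCatalog.from_sites(sites)
        annotate_uniqueness(cat)
        usage = count_pam_usage(cat, subset="unique")
        assert usage.counts["TTCA"] == 1
        assert usage.fractions["TTCA"] == 1.0

    def test_counts_partition_sites(self):
        genome = random_genome(FixtureSpec(length=20_000, seed=21))
        cat = SiteCatalog.from_sites(scan_sequence(genome.name, genome.sequence))
        annotate_uniqueness(cat)
        assert count_pam_usage(cat, "all").total == len(cat.sites)
        assert count_pam_usage(cat, "unique").total == sum(
            1 for s in cat.sites if s.unique
        )
        # tally agrees with a direct Counter over the catalog
        direct = Counter(s.pam for s in cat.sites)
        for pam, n in count_pam_usage(cat, "all").counts.items():
            assert n == direct.get(pam, 0)

    def test_empty_subset(self):
        usage = count_pam_usage(SiteCatalog.from_sites([]))
        assert usage.total == 0
        assert usage.fractions == {}

    def test_bad_subset(self):
        with pytest.raises(ValueError):
            count_pam_usage(SiteCatalog.from_sites([]), subset="some")


class TestExonOverlap:
    def test_single_base_overlap_assigned(self):
        cat = SiteCatalog.from_sites([make_site(start=10)])  # site [10,33]
        genes = {"g1": GeneModel("g1", "c1", ((33, 60),))}
        per_gene = overlap_sites_with_exons(cat, genes)
        assert cat.sites[0].gene_ids == frozenset({"g1"})
        assert per_gene["g1"].n_sites == 1

    def test_adjacency_excluded(self):
        cat = SiteCatalog.from_sites([make_site(start=10)])
        genes = {"g1": GeneModel("g1", "c1", ((34, 60),))}
        per_gene = overlap_sites_with_exons(cat, genes)
        assert cat.sites[0].gene_ids == frozenset()
        assert per_gene["g1"].n_sites == 0

    def test_multi_exon_counts_once(self):
        cat = SiteCatalog.from_sites([make_site(start=10)])  # spans [10,33]
        genes = {"g1": GeneModel("g1", "c1", ((5, 12), (20, 40)))}
        per_gene = overlap_sites_with_exons(cat, genes)
        assert per_gene["g1"].n_sites == 1

    def test_contig_without_annotation_gets_no_genes(self):
        cat = SiteCatalog.from_sites([make_site(contig="cX")])
        per_gene = overlap_sites_with_exons(
            cat, {"g1": GeneModel("g1", "c1", ((1, 100),))}
        )
        assert cat.sites[0].gene_ids == frozenset()
        assert per_gene["g1"].n_sites == 0

    def test_counts_match_quadratic_oracle(self):
        import numpy as np

        rng = np.random.default_rng(55)
        genes = {}
        for i in range(10):
            start = int(rng.integers(1, 5_000))
            n_ex = int(rng.integers(1, 4))
            exons, cursor = [], start
            for _ in range(n_ex):
                length = int(rng.integers(30, 200))
                exons.append((cursor, cursor + length - 1))
                cursor += length + int(rng.integers(2, 100))
            genes[f"g{i}"] = GeneModel(f"g{i}", "c1", tuple(exons))
        sites = [
            make_site(start=int(p), strand=("+", "-")[i % 2])
            for i, p in enumerate(rng.integers(1, 6_000, size=60))
        ]
        for i, s in enumerate(sites):
            s.unique = i % 3 == 0
        cat = SiteCatalog.from_sites(sites)
        per_gene = overlap_sites_with_exons(cat, genes)
        for gid, gene in genes.items():
            hits = [
                s
                for s in sites
                if any(s.start <= e and ex_s <= s.end for ex_s, e in gene.exons)
            ]
            assert per_gene[gid].n_sites == len(hits)
            assert per_gene[gid].n_unique == sum(1 for s in hits if s.unique)

    def test_representation_symmetry_zero_based(self):
        # converting everything to 0-based half-open and re-deriving overlap
        # gives the same assignment
        cat = SiteCatalog.from_sites([make_site(start=s) for s in (1, 10, 50, 77)])
        genes = {"g": GeneModel("g", "c1", ((24, 60), (90, 120)))}
        overlap_sites_with_exons(cat, genes)
        for site in cat.sites:
            s0, e0 = site.start - 1, site.end  # half-open
            manual = any(
                s0 < (ex_e + 1 - 1) + 1 and (ex_s - 1) < e0
                for ex_s, ex_e in genes["g"].exons
            )
            assert (site.gene_ids == frozenset({"g"})) is manual


class TestGenomeSummary:
    def test_single_contig(self):
        cat = SiteCatalog.from_sites([make_site(start=1), make_site(start=100, guide="C" * 20, pam="TTCC")])
        annotate_uniqueness(cat)
        summary = summarize_genome(cat, {"c1": 1_000_000})
        assert summary.total_sites == 2
        assert summary.unique_sites == 2
        assert summary.unique_pct == 100.0
        assert summary.total_density_median == 2.0

    def test_unique_pct(self):
        sites = [
            make_site(start=1),
            make_site(start=100),
            make_site(start=200, guide="C" * 20, pam="TTCC"),
        ]
        cat = SiteCatalog.from_sites(sites)
        annotate_uniqueness(cat)
        summary = summarize_genome(cat, {"c1": 10_000})
        assert summary.unique_pct == pytest.approx(100 / 3)

    def test_median_over_contigs(self):
        # 1 Mbp contig with 10 sites (density 10) and 0.5 Mbp with 10 (density 20)
        sites = [make_site(contig="a", start=1 + 30 * i) for i in range(10)]
        sites += [make_site(contig="b", start=1 + 30 * i) for i in range(10)]
        cat = SiteCatalog.from_sites(sites)
        annotate_uniqueness(cat)
        summary = summarize_genome(cat, {"a": 1_000_000, "b": 500_000})
        assert summary.density_per_contig == {"a": 10.0, "b": 20.0}
        assert summary.total_density_median == 15.0

    def test_zero_site_contigs_count_as_zero(self):
        cat = SiteCatalog.from_sites([make_site(contig="a")])
        annotate_uniqueness(cat)
        summary = summarize_genome(cat, {"a": 1_000_000, "b": 1_000_000, "c": 1_000_000})
        assert summary.total_density_median == 0.0

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            summarize_genome(SiteCatalog.from_sites([]), {})


class TestGeneSummary:
    def test_hand_enumerated_two_genes(self):
        per_gene = {
            "g1": GeneHitCounts(n_sites=4, n_unique=3),
            "g2": GeneHitCounts(n_sites=0, n_unique=0),
        }
        summary = summarize_genes(per_gene)
        assert summary.cut_pct == 50.0
        assert summary.unique_cut_pct == 50.0
        assert summary.median_sites_per_gene == 2  # mean of 0 and 4
        assert summary.median_unique_sites_per_gene == 1.5

    def test_all_zero(self):
        summary = summarize_genes({f"g{i}": GeneHitCounts() for i in range(5)})
        assert summary.cut_pct == 0.0
        assert summary.median_sites_per_gene == 0

    def test_single_fully_cut_gene(self):
        summary = summarize_genes({"g": GeneHitCounts(n_sites=1, n_unique=1)})
        assert summary.cut_pct == 100.0
        assert summary.unique_cut_pct == 100.0
        assert summary.median_sites_per_gene == 1

    def test_unique_cut_never_exceeds_cut(self):
        import numpy as np

        rng = np.random.default_rng(3)
        for _ in range(20):
            per_gene = {}
            for i in range(int(rng.integers(1, 30))):
                n = int(rng.integers(0, 10))
                per_gene[f"g{i}"] = GeneHitCounts(n, int(rng.integers(0, n + 1)))
            s = summarize_genes(per_gene)
            assert s.unique_cut_pct <= s.cut_pct <= 100.0

    def test_no_genes_rejected(self):
        with pytest.raises(ValueError):
            summarize_genes({})
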