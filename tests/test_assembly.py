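"""Read filters, clustering, consensus calling, and locus filters."""

import numpy as np
import pytest

from radphylo.assembly import (
    CleanRead,
    OrthologLocus,
    WithinCluster,
    assemble,
    assemble_sample,
    call_consensus,
    cluster_across,
    cluster_within,
    ConsensusLocus,
    filter_max_snps,
    filter_paralog_shared_hets,
    quality_filter,
    remove_duplicates,
    trim_to_length,
)
from radphylo.io import BarcodedRead
from radphylo.seqcodes import identity

from .conftest import make_read, mutate, random_seq


class TestQualityFilter:
    def test_high_quality_unchanged(self):
        r = make_read("r", "ACGTACGT", 30)
        assert quality_filter(r).seq == "ACGTACGT"

    def test_low_quality_masked_to_n(self):
        r = BarcodedRead("r", "ACGT", (30, 19, 30, 30))
        assert quality_filter(r).seq == "ANGT"

    def test_rejected_when_n_count_exceeds_max(self):
        quals = (10,) * 5 + (30,) * 5
        r = BarcodedRead("r", "ACGTACGTAC", quals)
        assert quality_filter(r, max_n=4) is None

    def test_boundary_exactly_max_n_accepted(self):
        quals = (10,) * 4 + (30,) * 6
        r = BarcodedRead("r", "ACGTACGTAC", quals)
        assert quality_filter(r, max_n=4).seq == "NNNNACGTAC"


class TestTrim:
    def test_trims_to_length(self):
        r = make_read("r", "A" * 96)
        assert trim_to_length(r, 90).seq == "A" * 90

    def test_exact_length_identity(self):
        r = make_read("r", "A" * 90)
        assert trim_to_length(r, 90).seq == "A" * 90

    def test_short_read_rejected(self):
        assert trim_to_length(make_read("r", "A" * 80), 90) is None


class TestDeduplicate:
    def test_collapses_identical(self):
        reads = [CleanRead(f"r{i}", "ACGT") for i in range(3)]
        reads.append(CleanRead("r3", "AAAA"))
        reps, groups = remove_duplicates(reads)
        assert len(reps) == 2
        assert sorted(len(g) for g in groups.values()) == [1, 3]

    def test_all_distinct_identity(self):
        reads = [CleanRead("a", "ACGT"), CleanRead("b", "AAAA")]
        reps, groups = remove_duplicates(reads)
        assert sorted(r.read_id for r in reps) == ["a", "b"]

    def test_empty(self):
        assert remove_duplicates([]) == ([], {})

    def test_count_conservation(self, rng):
        reads = [
            CleanRead(f"r{i}", random_seq(rng, 10)) for i in range(20)
        ] * 2
        reads = [CleanRead(f"r{i}", r.seq) for i, r in enumerate(reads)]
        reps, groups = remove_duplicates(reads)
        assert sum(len(g) for g in groups.values()) == len(reads)


class TestIdentity:
    def test_identical(self):
        s = "A" * 90
        assert identity(s, s) == 1.0

    def test_nine_mismatches_in_ninety(self):
        a = "A" * 90
        b = mutate(a, range(9))
        assert identity(a, b) == pytest.approx(0.90)

    def test_n_excluded_from_both_sides(self):
        assert identity("AN", "AC") == 1.0  # only 1 comparable position

    def test_iupac_allele_set_intersection(self):
        assert identity("R", "A") == 1.0  # R = {A,G} intersects {A}
        assert identity("R", "C") == 0.0

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="length mismatch"):
            identity("AC", "ACG")

    def test_all_n_returns_zero(self):
        assert identity("NN", "NN") == 0.0


def brute_force_clusters(reads, threshold, multiplicity=None):
    """Independent reference: full pairwise identity matrix (pure-python
    character comparison with N exclusion), same greedy ordering rules."""
    mult = multiplicity or {}

    def ident(a, b):
        num = den = 0
        for x, y in zip(a, b):
            if x == "N" or y == "N":
                continue
            den += 1
            num += x == y
        return num / den if den else 0.0

    ordered = sorted(reads, key=lambda r: (-mult.get(r.read_id, 1), r.read_id))
    seeds, clusters = [], []
    for r in ordered:
        for i, s in enumerate(seeds):
            if ident(r.seq, s) >= threshold:
                clusters[i].append(r.read_id)
                break
        else:
            seeds.append(r.seq)
            clusters.append([r.read_id])
    return [tuple(c) for c in clusters]


class TestClusterWithin:
    def test_four_identical_reads_one_cluster_depth_four(self):
        reads = [CleanRead(f"r{i}", "ACGT" * 10) for i in range(4)]
        clusters, discarded = cluster_within(reads, "s")
        assert len(clusters) == 1 and discarded == 0
        assert clusters[0].depth == 4

    def test_divergent_groups_split(self, rng):
        a = random_seq(rng, 90)
        b = mutate(a, range(18))  # 20% divergent
        reads = [CleanRead(f"a{i}", a) for i in range(3)] + [
            CleanRead(f"b{i}", b) for i in range(3)
        ]
        clusters, _ = cluster_within(reads, "s", threshold=0.90)
        assert len(clusters) == 2

    def test_singleton_discarded_at_min_depth(self, rng):
        a = random_seq(rng, 90)
        lone = mutate(a, range(27))  # 30% divergent
        reads = [CleanRead("a0", a), CleanRead("a1", a), CleanRead("z", lone)]
        clusters, discarded = cluster_within(reads, "s", min_depth=2)
        assert len(clusters) == 1 and discarded == 1

    def test_threshold_out_of_range(self):
        with pytest.raises(ValueError, match="threshold"):
            cluster_within([], "s", threshold=1.5)

    def test_members_within_threshold_of_seed(self, rng):
        reads = []
        for g in range(3):
            base = random_seq(rng, 60)
            for i in range(4):
                reads.append(
                    CleanRead(f"g{g}r{i}", mutate(base, rng.choice(60, size=2)))
                )
        clusters, _ = cluster_within(reads, "s", threshold=0.90, min_depth=1)
        for c in clusters:
            for seq in c.seqs:
                assert identity(seq, c.seed) >= 0.90

    def test_partition_of_retained_reads(self, rng):
        reads = [CleanRead(f"r{i}", random_seq(rng, 30)) for i in range(12)]
        clusters, discarded = cluster_within(reads, "s", min_depth=1)
        ids = [m for c in clusters for m in c.member_ids]
        assert sorted(ids) == sorted(r.read_id for r in reads)
        assert len(set(ids)) == len(ids)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_reference(self, seed):
        """Greedy output equals the brute-force pairwise-matrix reference
        for small read sets (<= 8 sequences)."""
        rng = np.random.default_rng(seed)
        base = random_seq(rng, 40)
        reads = []
        for i in range(8):
            n_mut = int(rng.integers(0, 10))
            reads.append(
                CleanRead(f"r{i}", mutate(base, rng.choice(40, size=n_mut, replace=False)))
            )
        mult = {r.read_id: int(rng.integers(1, 4)) for r in reads}
        clusters, _ = cluster_within(
            reads, "s", threshold=0.9, min_depth=1, multiplicity=mult
        )
        got = [c.member_ids for c in clusters]
        assert got == brute_force_clusters(reads, 0.9, mult)

    def test_threshold_monotonicity_on_fixture(self, rng):
        """Clusters separate at a low threshold never merge at a higher
        one under the same ordering."""
        base = random_seq(rng, 50)
        reads = [
            CleanRead("a", base),
            CleanRead("b", mutate(base, range(3))),
            CleanRead("c", mutate(base, range(10))),
            CleanRead("d", mutate(base, range(25))),
        ]
        sizes = {}
        for t in (0.6, 0.8, 0.95):
            clusters, _ = cluster_within(reads, "s", threshold=t, min_depth=1)
            sizes[t] = len(clusters)
        assert sizes[0.6] <= sizes[0.8] <= sizes[0.95]


def _cluster(seqs, counts=None, sample="s"):
    counts = counts or [1] * len(seqs)
    return WithinCluster(
        sample_id=sample,
        seed=seqs[0],
        member_ids=tuple(f"m{i}" for i in range(len(seqs))),
        seqs=tuple(seqs),
        counts=tuple(counts),
    )


class TestConsensus:
    def test_unanimous_site(self):
        cons = call_consensus(_cluster(["A"] * 4))
        assert cons.seq == "A" and cons.depth == 4

    def test_balanced_het_iupac(self):
        cons = call_consensus(_cluster(["A", "A", "G", "G"]))
        assert cons.seq == "R"

    def test_minor_alleles_below_rule_ignored(self):
        # depth 8: 6xA + 1xG + 1xT -> A (each minor allele fails count>=2)
        cons = call_consensus(_cluster(["A"] * 6 + ["G", "T"]))
        assert cons.seq == "A"

    def test_depth_two_split_called_het(self):
        cons = call_consensus(_cluster(["A", "G"]))
        assert cons.seq == "R"

    def test_three_supported_alleles_discards_cluster(self):
        assert call_consensus(_cluster(["A", "A", "G", "G", "T", "T"])) is None

    def test_all_n_site_stays_n(self):
        cons = call_consensus(_cluster(["NA", "NA"]))
        assert cons.seq == "NA"

    def test_multiplicity_weighted(self):
        # 1 distinct read with count 6 vs 1 with count 2: 6A+2G -> het (both >=2, freq 0.25)
        cons = call_consensus(_cluster(["A", "G"], counts=[6, 2]))
        assert cons.seq == "R"


class TestClusterAcross:
    def test_orthologs_stack_into_one_locus(self, rng):
        base = random_seq(rng, 90)
        consensi = [
            ConsensusLocus(f"s{i}", f"s{i}|c0", mutate(base, [i, i + 10]), 4)
            for i in range(4)
        ]
        loci, collisions = cluster_across(consensi, threshold=0.90)
        assert len(loci) == 1 and collisions == 0
        assert loci[0].n_samples == 4

    def test_divergent_loci_stay_separate(self, rng):
        a = random_seq(rng, 90)
        b = mutate(a, range(27))
        consensi = [
            ConsensusLocus("s1", "s1|c0", a, 4),
            ConsensusLocus("s2", "s2|c0", b, 4),
        ]
        loci, _ = cluster_across(consensi, threshold=0.90)
        assert len(loci) == 2

    def test_within_sample_collision_discarded(self, rng):
        a = random_seq(rng, 90)
        consensi = [
            ConsensusLocus("s1", "s1|c0", a, 4),
            ConsensusLocus("s1", "s1|c1", mutate(a, range(4)), 4),  # 95% identical
            ConsensusLocus("s2", "s2|c0", mutate(a, [0]), 4),
        ]
        loci, collisions = cluster_across(consensi, threshold=0.90)
        assert collisions == 1 and loci == []


class TestLocusFilters:
    def test_shared_het_three_rows_discarded(self):
        rows = {f"s{i}": "R" if i < 3 else "A" for i in range(6)}
        locus = OrthologLocus("l", rows)
        assert filter_paralog_shared_hets(locus, max_shared=2) is False

    def test_shared_het_boundary_two_rows_kept(self):
        rows = {f"s{i}": "R" if i < 2 else "A" for i in range(6)}
        assert filter_paralog_shared_hets(OrthologLocus("l", rows)) is True

    def test_no_ambiguity_kept(self, toy_locus):
        assert filter_paralog_shared_hets(toy_locus) is True

    def test_snp_filter_boundary(self):
        base = "A" * 20
        keep = OrthologLocus(
            "k", {"s1": base, "s2": mutate(base, range(10))}
        )
        drop = OrthologLocus(
            "d", {"s1": base, "s2": mutate(base, range(11))}
        )
        assert filter_max_snps(keep, 10) is True  # exactly 10: "more than 10"
        assert filter_max_snps(drop, 10) is False

    def test_het_expansion_counts_as_variable(self):
        locus = OrthologLocus("l", {"s1": "R", "s2": "A"})
        assert locus.n_snps() == 1
        invariant = OrthologLocus("l2", {"s1": "A", "s2": "A", "s3": "N"})
        assert invariant.n_snps() == 0


class TestPipeline:
    def _reads(self, seq, sample, n=4, qual=35):
        return [make_read(f"{sample}.{i}", seq, qual) for i in range(n)]

    def test_stage_conservation(self, rng):
        seq = random_seq(rng, 90)
        reads = self._reads(seq, "s1", 4) + [
            make_read("s1.low", seq, 10),  # rejected by QC
            make_read("s1.short", seq[:50]),  # rejected by trim
        ]
        consensi, stats = assemble_sample(reads, "s1")
        assert stats.n_input == 6
        assert stats.n_qc_rejected == 1 and stats.n_short_rejected == 1
        assert stats.n_reads_clean == 4
        assert stats.n_clusters + stats.n_lowdepth >= 1
        assert stats.n_consensus == len(consensi) == 1

    def test_mutation_free_invariant(self, rng):
        """Identical samples at every locus: one cluster per locus per
        sample, zero variable sites, both locus filters keep everything."""
        seqs = [random_seq(rng, 90) for _ in range(5)]
        per_sample = {
            s: [make_read(f"{s}.{j}.{i}", seq) for j, seq in enumerate(seqs)
                for i in range(3)]
            for s in ("s1", "s2", "s3")
        }
        result = assemble(per_sample)
        assert len(result.loci) == 5
        assert result.n_shared_het_discarded == 0
        assert result.n_snp_discarded == 0
        for locus in result.loci:
            assert locus.n_samples == 3
            assert locus.n_snps() == 0

    def test_report_matches_recount(self, rng):
        seq_a, seq_b = random_seq(rng, 90), random_seq(rng, 90)
        per_sample = {
            "s1": self._reads(seq_a, "s1", 4) + self._reads(seq_b, "s1b", 2),
            "s2": self._reads(seq_a, "s2", 3),
        }
        result = assemble(per_sample)
        report = result.report().set_index("sample_id")
        assert report.loc["s1", "n_reads"] == 6
        assert report.loc["s1", "n_clusters"] == 2
        assert report.loc["s1", "mean_depth"] == pytest.approx(3.0)
        assert report.loc["s2", "n_clusters"] == 1
        assert report.loc["s2", "mean_depth"] == pytest.approx(3.0)

    def test_empty_sample_zero_row(self):
        result = assemble({"s1": []})
        report = result.report()
        assert report.loc[0, "n_reads"] == 0
        assert report.loc[0, "n_consensus_loci"] == 0
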