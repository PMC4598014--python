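"""De novo RAD locus assembly.

The read-to-locus cascade: per-base quality masking, length trimming, exact
PCR-duplicate removal, greedy within-sample clustering with a minimum
coverage cutoff, diploid consensus calling with IUPAC heterozygote codes,
greedy across-sample ortholog clustering, and the paralog/SNP locus filters.

All comparisons are ungapped and positional: RAD loci are restriction-site
anchored, so reads of one locus share an orientation and a frame, and the
pipeline operates on fixed-length reads.  Cluster depth counts sequencing
reads (duplicates included), matching the coverage semantics of a minimum
2x cutoff.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BarcodedRead
from .seqcodes import MASK_TO_CODE, N_MASK, encode, decode, het_code, identity

DEFAULT_LOCUS_LENGTH = 90
DEFAULT_PHRED_MIN = 20
DEFAULT_MAX_N = 4
DEFAULT_THRESHOLD = 0.90
DEFAULT_MIN_DEPTH = 2
DEFAULT_MAX_SNPS = 10
DEFAULT_MAX_SHARED_HETS = 2


@dataclass(frozen=True)
class CleanRead:
    """A quality-masked, fixed-length read ready for clustering."""

    read_id: str
    seq: str


@dataclass
class WithinCluster:
    """A within-sample read cluster (one putative allele stack).

    ``seqs``/``counts`` are the distinct member sequences with their read
    multiplicities; ``depth`` is the total read count (sum of counts).
    """

    sample_id: str
    seed: str
    member_ids: tuple[str, ...]
    seqs: tuple[str, ...]
    counts: tuple[int, ...]

    @property
    def depth(self) -> int:
        return int(sum(self.counts))


@dataclass(frozen=True)
class ConsensusLocus:
    """Diploid consensus of one within-sample cluster (IUPAC codes at hets)."""

    sample_id: str
    consensus_id: str
    seq: str
    depth: int


@dataclass
class OrthologLocus:
    """An across-sample positional stack of consensus sequences."""

    locus_id: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.locus_id}: rows of unequal length {lengths}")

    @property
    def n_samples(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def matrix(self) -> np.ndarray:
        """(n_samples, length) allele-mask matrix, rows in sample_id order."""
        return np.vstack([encode(self.rows[s]) for s in sorted(self.rows)])

    def variable_sites(self) -> np.ndarray:
        """Boolean mask over sites: >=2 distinct non-N resolved states.

        IUPAC heterozygote codes are expanded to their allele sets; N is
        excluded entirely.
        """
        m = self.matrix()
        non_n = m != N_MASK
        pooled = np.zeros(self.length, dtype=np.uint8)
        for i in range(m.shape[0]):
            pooled |= np.where(non_n[i], m[i], 0).astype(np.uint8)
        return np.array([bin(int(x)).count("1") >= 2 for x in pooled])

    def n_snps(self) -> int:
        return int(self.variable_sites().sum())

    def het_counts(self) -> np.ndarray:
        """Per-site count of rows carrying an ambiguity code (not N)."""
        m = self.matrix()
        popcount = np.vectorize(lambda x: bin(int(x)).count("1"))(m)
        is_het = (popcount >= 2) & (m != N_MASK)
        return is_het.sum(axis=0)


# ---------------------------------------------------------------------------
# Read-level filters


def quality_filter(
    read: BarcodedRead,
    phred_min: int = DEFAULT_PHRED_MIN,
    max_n: int = DEFAULT_MAX_N,
) -> BarcodedRead | None:
    """Mask low-quality calls to N; reject reads with too many Ns.

    Every base with Phred < ``phred_min`` becomes N; the read is rejected
    (None) when the post-masking N count exceeds ``max_n``.
    """
    seq = "".join(
        "N" if q < phred_min else b for b, q in zip(read.seq, read.qual)
    )
    if seq.count("N") > max_n:
        return None
    return BarcodedRead(read.read_id, seq, read.qual)


def trim_to_length(
    read: BarcodedRead, length: int = DEFAULT_LOCUS_LENGTH
) -> CleanRead | None:
    """Keep the first ``length`` bases; reject shorter reads (None)."""
    if len(read.seq) < length:
        return None
    return CleanRead(read.read_id, read.seq[:length])


def remove_duplicates(
    reads: list[CleanRead],
) -> tuple[list[CleanRead], dict[str, list[str]]]:
    """Collapse identical sequence strings to one representative each.

    Returns (representatives, groups) where ``groups`` maps each
    representative's read id to all member read ids (itself included), so
    downstream coverage counts are conserved: sum of group sizes = input size.
    """
    by_seq: dict[str, list[CleanRead]] = {}
    for r in reads:
        by_seq.setdefault(r.seq, []).append(r)
    reps: list[CleanRead] = []
    groups: dict[str, list[str]] = {}
    for members in by_seq.values():
        members = sorted(members, key=lambda r: r.read_id)
        rep = members[0]
        reps.append(rep)
        groups[rep.read_id] = [m.read_id for m in members]
    return reps, groups


# ---------------------------------------------------------------------------
# Clustering


def cluster_within(
    reads: list[CleanRead],
    sample_id: str,
    threshold: float = DEFAULT_THRESHOLD,
    min_depth: int = DEFAULT_MIN_DEPTH,
    multiplicity: dict[str, int] | None = None,
) -> tuple[list[WithinCluster], int]:
    """Greedy seed clustering of one sample's reads.

    Reads are visited in order of (descending multiplicity, read id); the
    first unassigned read seeds a cluster and each later read joins the first
    seed with identity >= ``threshold``.  ``multiplicity`` gives pre-
    deduplication read counts (default 1 each).  Clusters whose total depth
    falls below ``min_depth`` are discarded; returns (clusters, n_discarded).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    mult = multiplicity or {}
    ordered = sorted(reads, key=lambda r: (-mult.get(r.read_id, 1), r.read_id))
    seeds: list[np.ndarray] = []
    assignments: list[list[CleanRead]] = []
    for read in ordered:
        arr = encode(read.seq)
        for i, seed in enumerate(seeds):
            if identity(arr, seed) >= threshold:
                assignments[i].append(read)
                break
        else:
            seeds.append(arr)
            assignments.append([read])
    clusters: list[WithinCluster] = []
    n_discarded = 0
    for seed, members in zip(seeds, assignments):
        counts = tuple(mult.get(r.read_id, 1) for r in members)
        cluster = WithinCluster(
            sample_id=sample_id,
            seed=decode(seed),
            member_ids=tuple(r.read_id for r in members),
            seqs=tuple(r.seq for r in members),
            counts=counts,
        )
        if cluster.depth < min_depth:
            n_discarded += 1
        else:
            clusters.append(cluster)
    return clusters, n_discarded


def call_consensus(
    cluster: WithinCluster, consensus_id: str | None = None
) -> ConsensusLocus | None:
    """Call a diploid consensus for one cluster.

    Per site, alleles with frequency >= 0.25 among non-N calls and read count
    >= 2 are well supported (the count requirement relaxes to >= 1 below
    depth 4, so a 2x cluster with a 1+1 split is called heterozygous).
    Exactly two supported alleles yield the IUPAC two-base code; three or
    more flag the cluster as error-rich and it is discarded (None); otherwise
    the majority base is called, N where no non-N call exists.
    """
    length = len(cluster.seed)
    arrs = [encode(s) for s in cluster.seqs]
    depth = cluster.depth
    count_req = 2 if depth >= 4 else 1
    out: list[str] = []
    for pos in range(length):
        counts: Counter[str] = Counter()
        for arr, mult in zip(arrs, cluster.counts):
            mask = int(arr[pos])
            if mask != N_MASK:
                counts[MASK_TO_CODE[mask]] += mult
        if not counts:
            out.append("N")
            continue
        total = sum(counts.values())
        supported = sorted(
            b for b, c in counts.items() if c >= count_req and c / total >= 0.25
        )
        if len(supported) >= 3:
            return None
        if len(supported) == 2:
            out.append(het_code(*supported))
        else:
            top = max(counts.values())
            out.append(min(b for b, c in counts.items() if c == top))
    return ConsensusLocus(
        sample_id=cluster.sample_id,
        consensus_id=consensus_id or f"{cluster.sample_id}|{cluster.member_ids[0]}",
        seq="".join(out),
        depth=depth,
    )


def cluster_across(
    consensi: list[ConsensusLocus],
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[list[OrthologLocus], int]:
    """Greedy ortholog clustering of consensus sequences across samples.

    Sequences are visited in order of (descending depth, sample id,
    consensus id).  Each cluster is stacked positionally into an
    :class:`OrthologLocus`; a cluster receiving two or more consensi from
    one sample is discarded as a putative within-sample paralog collision.
    Returns (loci, n_collisions_discarded).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    ordered = sorted(consensi, key=lambda c: (-c.depth, c.sample_id, c.consensus_id))
    seeds: list[np.ndarray] = []
    groups: list[list[ConsensusLocus]] = []
    for cons in ordered:
        arr = encode(cons.seq)
        for i, seed in enumerate(seeds):
            if identity(arr, seed) >= threshold:
                groups[i].append(cons)
                break
        else:
            seeds.append(arr)
            groups.append([cons])
    loci: list[OrthologLocus] = []
    n_collisions = 0
    for idx, group in enumerate(groups):
        samples = [c.sample_id for c in group]
        if len(samples) != len(set(samples)):
            n_collisions += 1
            continue
        loci.append(
            OrthologLocus(
                locus_id=f"locus_{idx}",
                rows={c.sample_id: c.seq for c in group},
            )
        )
    return loci, n_collisions


# ---------------------------------------------------------------------------
# Locus filters


def filter_paralog_shared_hets(
    locus: OrthologLocus, max_shared: int = DEFAULT_MAX_SHARED_HETS
) -> bool:
    """Keep unless some site carries an ambiguity code in > max_shared rows.

    A heterozygous site shared by many samples is the classic signature of a
    collapsed paralog pair rather than a segregating allele.
    """
    return bool((locus.het_counts() <= max_shared).all())


def filter_max_snps(locus: OrthologLocus, max_snps: int = DEFAULT_MAX_SNPS) -> bool:
    """Keep unless the locus has more than ``max_snps`` variable sites."""
    return locus.n_snps() <= max_snps


def drop_excluded(
    loci: list[OrthologLocus], exclude_ids: set[str]
) -> list[OrthologLocus]:
    """Exclusion-list hook: drop loci by id (e.g. flagged contaminants)."""
    return [loc for loc in loci if loc.locus_id not in exclude_ids]


# ---------------------------------------------------------------------------
# Pipeline driver


@dataclass
class SampleStats:
    """Per-sample pipeline accounting (one Table-style report row)."""

    sample_id: str
    n_input: int = 0
    n_qc_rejected: int = 0
    n_short_rejected: int = 0
    n_duplicates: int = 0
    n_reads_clean: int = 0
    n_clusters: int = 0
    n_lowdepth: int = 0
    n_error_rich: int = 0
    mean_depth: float = 0.0
    n_consensus: int = 0


@dataclass
class AssemblyResult:
    """Output of a full assembly run, with stage-by-stage accounting."""

    loci: list[OrthologLocus]
    sample_stats: dict[str, SampleStats]
    n_paralog_collisions: int = 0
    n_shared_het_discarded: int = 0
    n_snp_discarded: int = 0
    consensi: list[ConsensusLocus] = field(default_factory=list)

    def report(self) -> pd.DataFrame:
        """Per-sample table: clean reads, clusters passing depth, mean
        cluster depth, and consensus loci."""
        rows = [
            {
                "sample_id": s.sample_id,
                "n_reads": s.n_reads_clean,
                "n_clusters": s.n_clusters,
                "mean_depth": round(s.mean_depth, 2),
                "n_consensus_loci": s.n_consensus,
            }
            for s in self.sample_stats.values()
        ]
        return pd.DataFrame(rows)

    def stage_log(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.sample_stats.values()])


def assemble_sample(
    reads: list[BarcodedRead],
    sample_id: str,
    *,
    threshold: float = DEFAULT_THRESHOLD,
    min_depth: int = DEFAULT_MIN_DEPTH,
    phred_min: int = DEFAULT_PHRED_MIN,
    max_n: int = DEFAULT_MAX_N,
    locus_length: int = DEFAULT_LOCUS_LENGTH,
) -> tuple[list[ConsensusLocus], SampleStats]:
    """Run one sample through QC, trimming, dedup, clustering and consensus."""
    stats = SampleStats(sample_id=sample_id, n_input=len(reads))
    clean: list[CleanRead] = []
    for read in reads:
        filtered = quality_filter(read, phred_min=phred_min, max_n=max_n)
        if filtered is None:
            stats.n_qc_rejected += 1
            continue
        trimmed = trim_to_length(filtered, length=locus_length)
        if trimmed is None:
            stats.n_short_rejected += 1
            continue
        clean.append(trimmed)
    stats.n_reads_clean = len(clean)
    reps, groups = remove_duplicates(clean)
    stats.n_duplicates = len(clean) - len(reps)
    mult = {rid: len(members) for rid, members in groups.items()}
    clusters, n_low = cluster_within(
        reps, sample_id, threshold=threshold, min_depth=min_depth, multiplicity=mult
    )
    stats.n_clusters = len(clusters)
    stats.n_lowdepth = n_low
    stats.mean_depth = (
        float(np.mean([c.depth for c in clusters])) if clusters else 0.0
    )
    consensi: list[ConsensusLocus] = []
    for i, cluster in enumerate(clusters):
        cons = call_consensus(cluster, consensus_id=f"{sample_id}|c{i}")
        if cons is None:
            stats.n_error_rich += 1
        else:
            consensi.append(cons)
    stats.n_consensus = len(consensi)
    return consensi, stats


def assemble(
    per_sample_reads: dict[str, list[BarcodedRead]],
    *,
    threshold: float = DEFAULT_THRESHOLD,
    min_depth: int = DEFAULT_MIN_DEPTH,
    phred_min: int = DEFAULT_PHRED_MIN,
    max_n: int = DEFAULT_MAX_N,
    locus_length: int = DEFAULT_LOCUS_LENGTH,
    max_snps: int = DEFAULT_MAX_SNPS,
    max_shared_hets: int = DEFAULT_MAX_SHARED_HETS,
    exclude_ids: set[str] | None = None,
) -> AssemblyResult:
    """Full cascade: per-sample assembly, ortholog clustering, locus filters."""
    all_consensi: list[ConsensusLocus] = []
    sample_stats: dict[str, SampleStats] = {}
    for sample_id, reads in per_sample_reads.items():
        consensi, stats = assemble_sample(
            reads,
            sample_id,
            threshold=threshold,
            min_depth=min_depth,
            phred_min=phred_min,
            max_n=max_n,
            locus_length=locus_length,
        )
        all_consensi.extend(consensi)
        sample_stats[sample_id] = stats
    loci, n_collisions = cluster_across(all_consensi, threshold=threshold)
    kept: list[OrthologLocus] = []
    n_het_drop = 0
    n_snp_drop = 0
    for locus in loci:
        if not filter_paralog_shared_hets(locus, max_shared=max_shared_hets):
            n_het_drop += 1
        elif not filter_max_snps(locus, max_snps=max_snps):
            n_snp_drop += 1
        else:
            kept.append(locus)
    if exclude_ids:
        kept = drop_excluded(kept, exclude_ids)
    return AssemblyResult(
        loci=kept,
        sample_stats=sample_stats,
        n_paralog_collisions=n_collisions,
        n_shared_het_discarded=n_het_drop,
        n_snp_discarded=n_snp_drop,
        consensi=all_consensi,
    )
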