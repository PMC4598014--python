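"""Supermatrix construction and light tree utilities.

Locus-level filtering into minimum-sample (m) data sets, tail trimming,
parsimony-informative-site accounting, concatenation with '?' for absent
sample-locus cells, clustering-threshold scans, and a neighbor-joining +
bootstrap stand-in used for topology-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .assembly import OrthologLocus, assemble
from .io import BarcodedRead
from .seqcodes import IUPAC_TO_SET

MISSING_CHARS = frozenset("?-N")


@dataclass(frozen=True)
class MatrixStats:
    n_loci: int
    n_sites: int
    n_pis: int
    pct_pis: float
    pct_missing: float


@dataclass
class Supermatrix:
    """Concatenated locus alignments with a partition map.

    ``partitions`` holds (locus_id, start, end) in 0-based half-open
    coordinates; absent sample-locus cells are '?'.  ``m`` records the
    minimum-samples threshold the matrix was built under.
    """

    rows: dict[str, str]
    partitions: list[tuple[str, int, int]]
    m: int

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("rows of unequal length")
        ids = [p[0] for p in self.partitions]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate locus ids in partitions")
        pos = 0
        for locus_id, start, end in self.partitions:
            if start != pos or end <= start:
                raise ValueError(f"partition {locus_id} does not tile the matrix")
            pos = end
        if self.rows and pos != self.n_sites:
            raise ValueError("partitions do not cover the matrix")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.rows)

    @property
    def n_sites(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def stats(self) -> MatrixStats:
        n_sites = self.n_sites
        n_cells = n_sites * len(self.rows)
        n_missing = sum(s.count("?") for s in self.rows.values())
        n_pis = count_pis(list(self.rows.values()))
        return MatrixStats(
            n_loci=len(self.partitions),
            n_sites=n_sites,
            n_pis=n_pis,
            pct_pis=n_pis / n_sites if n_sites else 0.0,
            pct_missing=n_missing / n_cells if n_cells else 0.0,
        )


def count_pis(rows: list[str]) -> int:
    """Number of parsimony-informative columns in an aligned set of rows.

    A column is informative when at least two distinct resolved states each
    occur in at least two rows.  IUPAC ambiguity codes, N, '?' and '-' are
    treated as missing for this count.
    """
    if not rows:
        return 0
    length = len(rows[0])
    if any(len(r) != length for r in rows):
        raise ValueError("rows of unequal length")
    n = 0
    for col in zip(*rows):
        counts: dict[str, int] = {}
        for c in col:
            if c in MISSING_CHARS or len(IUPAC_TO_SET.get(c, "NN")) != 1:
                continue
            counts[c] = counts.get(c, 0) + 1
        if sum(1 for v in counts.values() if v >= 2) >= 2:
            n += 1
    return n


def trim_tail(locus: OrthologLocus, n: int = 5) -> OrthologLocus:
    """Drop the last ``n`` columns of every row (tail base quality decay)."""
    if n == 0:
        return locus
    if locus.length <= n:
        raise ValueError(
            f"{locus.locus_id}: length {locus.length} <= trim {n}"
        )
    return OrthologLocus(
        locus_id=locus.locus_id,
        rows={s: seq[:-n] for s, seq in locus.rows.items()},
    )


def filter_min_samples(loci: list[OrthologLocus], m: int) -> list[OrthologLocus]:
    """Retain loci shared by at least ``m`` samples."""
    return [loc for loc in loci if loc.n_samples >= m]


def filter_pis_bearing(loci: list[OrthologLocus], min_pis: int = 1) -> list[OrthologLocus]:
    """Retain loci with at least ``min_pis`` parsimony-informative sites."""
    return [loc for loc in loci if count_pis(list(loc.rows.values())) >= min_pis]


def concatenate(
    loci: list[OrthologLocus],
    all_sample_ids: list[str],
    m: int,
) -> tuple[Supermatrix, MatrixStats]:
    """Concatenate already-filtered loci, padding absent cells with '?'."""
    ids = [loc.locus_id for loc in loci]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate locus ids")
    parts: list[tuple[str, int, int]] = []
    chunks: dict[str, list[str]] = {s: [] for s in all_sample_ids}
    pos = 0
    for loc in loci:
        parts.append((loc.locus_id, pos, pos + loc.length))
        for s in all_sample_ids:
            chunks[s].append(loc.rows.get(s, "?" * loc.length))
        pos += loc.length
    matrix = Supermatrix(
        rows={s: "".join(chunks[s]) for s in all_sample_ids},
        partitions=parts,
        m=m,
    )
    return matrix, matrix.stats()


def build_supermatrix(
    loci: list[OrthologLocus],
    all_sample_ids: list[str],
    m: int,
    tail_trim: int = 5,
    min_pis: int = 1,
    trim_first: bool = True,
) -> tuple[Supermatrix, MatrixStats]:
    """Tail-trim, keep PIS-bearing loci, apply the m threshold, concatenate.

    ``trim_first`` controls whether the informative-site filter sees trimmed
    (default) or untrimmed loci.
    """
    if trim_first:
        loci = [trim_tail(loc, tail_trim) for loc in loci]
        loci = filter_pis_bearing(loci, min_pis)
    else:
        loci = filter_pis_bearing(loci, min_pis)
        loci = [trim_tail(loc, tail_trim) for loc in loci]
    loci = filter_min_samples(loci, m)
    return concatenate(loci, all_sample_ids, m)


def threshold_scan(
    per_sample_reads: dict[str, list[BarcodedRead]],
    thresholds: list[int] | None = None,
    m: int = 4,
    tail_trim: int = 5,
    **assembly_kwargs,
) -> pd.DataFrame:
    """Repeat the full assembly across clustering thresholds.

    Thresholds are percentages (default 60..95 step 5).  For each threshold
    the table reports the number of retained loci (m applied, tails trimmed),
    total parsimony-informative sites, and loci bearing at least one such
    site.  The ``recommended`` column marks the argmax of n_pis (ties broken
    toward the higher threshold).
    """
    if thresholds is None:
        thresholds = list(range(60, 96, 5))
    records = []
    for t in thresholds:
        result = assemble(
            per_sample_reads, threshold=t / 100.0, **assembly_kwargs
        )
        loci = [
            trim_tail(loc, tail_trim)
            for loc in result.loci
            if loc.length > tail_trim
        ]
        loci = filter_min_samples(loci, m)
        pis_per_locus = [count_pis(list(loc.rows.values())) for loc in loci]
        records.append(
            {
                "threshold": t,
                "n_loci": len(loci),
                "n_pis": int(sum(pis_per_locus)),
                "n_loci_with_pis": int(sum(1 for p in pis_per_locus if p >= 1)),
            }
        )
    table = pd.DataFrame(records)
    best = max(records, key=lambda r: (r["n_pis"], r["threshold"]))
    table["recommended"] = table["threshold"] == best["threshold"]
    return table


# ---------------------------------------------------------------------------
# Distance trees (topology-recovery checks)


def _pairwise_p_distances(matrix: Supermatrix) -> DistanceMatrix:
    from .seqcodes import N_MASK, _LUT  # reuse the mask LUT; '?'/'-' map to 0

    samples = matrix.sample_ids
    enc = {}
    for s in samples:
        raw = np.frombuffer(matrix.rows[s].encode("ascii"), dtype=np.uint8)
        enc[s] = _LUT[raw]  # 0 for '?'/'-'/invalid -> missing
    n = len(samples)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = enc[samples[i]], enc[samples[j]]
            comparable = (a != 0) & (b != 0) & (a != N_MASK) & (b != N_MASK)
            n_comp = int(comparable.sum())
            if n_comp == 0:
                raise ValueError(
                    f"no shared non-missing sites between "
                    f"{samples[i]} and {samples[j]}"
                )
            mismatches = int(((a & b) == 0)[comparable].sum())
            d[i, j] = d[j, i] = mismatches / n_comp
    return DistanceMatrix(d, ids=samples)


def nj_tree(matrix: Supermatrix) -> dendropy.Tree:
    """Unrooted neighbor-joining tree from pairwise p-distances.

    Distances use sites where both rows are non-missing; heterozygote codes
    match when allele sets intersect.
    """
    if len(matrix.rows) < 4:
        raise ValueError("need at least 4 samples for an unrooted NJ tree")
    dm = _pairwise_p_distances(matrix)
    skb = _skbio_nj(dm)
    tree = dendropy.Tree.get(data=str(skb), schema="newick")
    tree.is_rooted = False
    return tree


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial splits of an unrooted tree, each as the smaller-side
    leaf-label set (ties broken lexicographically)."""
    labels = frozenset(t.label for t in tree.taxon_namespace)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        above = labels - below
        if len(below) < 2 or len(above) < 2:
            continue
        out.add(canonical_split(below, labels))
    return out


def canonical_split(side: frozenset[str], all_labels: frozenset[str]) -> frozenset[str]:
    """Canonical representation of a bipartition: the smaller side, ties
    broken by sorted-label tuple."""
    other = all_labels - side
    if len(side) < len(other):
        return frozenset(side)
    if len(other) < len(side):
        return frozenset(other)
    return frozenset(min(side, other, key=lambda s: tuple(sorted(s))))


def bootstrap_support(
    matrix: Supermatrix, n_replicates: int = 100, seed: int = 0
) -> dict[frozenset[str], float]:
    """Site-resampling bootstrap support for the NJ tree's splits.

    Columns are resampled with replacement; support is the fraction of
    replicate NJ trees containing each split of the original tree.
    """
    base_splits = tree_bipartitions(nj_tree(matrix))
    rng = np.random.default_rng(seed)
    counts = {s: 0 for s in base_splits}
    n_sites = matrix.n_sites
    samples = matrix.sample_ids
    row_arrays = {s: np.frombuffer(matrix.rows[s].encode(), dtype=np.uint8) for s in samples}
    for _ in range(n_replicates):
        idx = rng.integers(0, n_sites, size=n_sites)
        boot = Supermatrix(
            rows={s: row_arrays[s][idx].tobytes().decode() for s in samples},
            partitions=[("all", 0, n_sites)],
            m=matrix.m,
        )
        rep_splits = tree_bipartitions(nj_tree(boot))
        for s in base_splits:
            if s in rep_splits:
                counts[s] += 1
    return {s: c / n_replicates for s, c in counts.items()}


def is_monophyletic(
    tree: dendropy.Tree, tips: set[str], outgroup: set[str]
) -> bool:
    """True iff ``tips`` form a clade when the tree is rooted on ``outgroup``.

    Equivalent, on the unrooted tree, to the existence of an edge separating
    ``tips`` from everything else including the outgroup.
    """
    labels = frozenset(t.label for t in tree.taxon_namespace)
    tips = set(tips)
    if not tips <= labels:
        raise ValueError(f"unknown tips: {sorted(tips - labels)}")
    if tips & outgroup:
        raise ValueError("tip set overlaps the outgroup")
    if len(tips) <= 1 or tips == set(labels - frozenset(outgroup)):
        return True
    sides: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        sides.add(below)
        sides.add(labels - below)
    return frozenset(tips) in sides


def export_phylip(matrix: Supermatrix, path) -> None:
    from .io import write_phylip

    write_phylip(matrix.rows, path)


def export_nexus(matrix: Supermatrix, path) -> None:
    from .io import write_nexus

    write_nexus(matrix.rows, path, charsets=matrix.partitions)
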