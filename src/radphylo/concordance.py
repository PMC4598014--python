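"""Bayesian concordance analysis over per-locus tree samples.

Each locus brings a posterior sample of gene trees; topologies are
tabulated per locus after burn-in, and a Gibbs sampler under a Dirichlet-
process prior reassigns loci to topologies so that loci borrow strength:
a topology already used by many loci is a priori more likely for the next
locus, with concentration α controlling the expected discordance (small α
= little expected discordance, large α = loci decouple).  The concordance
factor (CF) of a split is the proportion of loci whose assigned topology
contains it; sample-wide means with 95% credibility intervals, a greedy
primary concordance tree, and a CI-overlap conflict rule are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

Split = frozenset  # canonical smaller-side label set


@dataclass
class LocusTopologyTable:
    """Post-burn-in topology counts for one locus's tree sample."""

    locus_id: str
    counts: dict[str, int]
    tip_labels: frozenset[str]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError(f"{self.locus_id}: empty topology table")
        if any(c < 1 for c in self.counts.values()):
            raise ValueError(f"{self.locus_id}: counts must be >= 1")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def fractions(self) -> dict[str, float]:
        t = self.total
        return {k: v / t for k, v in self.counts.items()}


@dataclass
class ConcordanceResult:
    splits: list[tuple[Split, float, float, float]]  # (split, mean, lo, hi)
    primary_tree: str
    n_topologies_seen: int
    n_splits_seen: int
    alpha: float
    convergence: float  # max across splits of |mean CF run1 - mean CF run2|
    tip_labels: frozenset[str] = field(default_factory=frozenset)
    p_all_concordant: float = 0.0  # fraction of samples with one shared topology

    def cf(self, split: Split) -> tuple[float, float, float]:
        for s, m, lo, hi in self.splits:
            if s == split:
                return m, lo, hi
        return 0.0, 0.0, 0.0


# ---------------------------------------------------------------------------
# Topology canonicalization


def canonical_topology(tree: dendropy.Tree) -> str:
    """Canonical newick string of a tree's unrooted topology.

    The tree is conceptually rooted on the lexicographically smallest tip;
    clades are written with children sorted, branch lengths dropped.  Two
    trees share the string iff they share the unrooted topology.
    """
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    ref = labels[0]
    clusters = _ref_clusters(tree, ref)
    rest = frozenset(labels) - {ref}
    return f"({ref},{_newick_from_clusters(rest, clusters)});"


def _ref_clusters(tree: dendropy.Tree, ref: str) -> set[frozenset[str]]:
    """Non-trivial clades of the topology rooted at tip ``ref``."""
    all_labels = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    n = len(all_labels)
    clusters: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        clade = below if ref not in below else all_labels - below
        if 2 <= len(clade) <= n - 2:
            clusters.add(clade)
    return clusters


def _newick_from_clusters(
    labels: frozenset[str], clusters: set[frozenset[str]]
) -> str:
    """Build a canonical nested-parentheses string from compatible clades."""
    inner = [c for c in clusters if c < labels]
    maximal = [
        c for c in inner if not any(c < d for d in inner if d != c)
    ]
    covered: set[str] = set().union(*maximal) if maximal else set()
    parts = [
        _newick_from_clusters(c, {d for d in inner if d <= c}) for c in maximal
    ]
    parts.extend(sorted(labels - covered))
    parts.sort()
    if len(parts) == 1:
        return parts[0]
    return "(" + ",".join(parts) + ")"


def topology_splits(topology: str) -> frozenset[Split]:
    """Non-trivial bipartitions of a canonical topology string, each as the
    canonical smaller-side label set."""
    tree = dendropy.Tree.get(data=topology, schema="newick")
    all_labels = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    out: set[Split] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if 2 <= len(below) <= len(all_labels) - 2:
            out.add(canonical_split(below, all_labels))
    return frozenset(out)


def canonical_split(side: frozenset[str], all_labels: frozenset[str]) -> Split:
    other = all_labels - side
    if len(side) != len(other):
        return frozenset(side if len(side) < len(other) else other)
    return frozenset(min(side, other, key=lambda s: tuple(sorted(s))))


def splits_compatible(a: Split, b: Split, all_labels: frozenset[str]) -> bool:
    """Two bipartitions are compatible iff some quadrant intersection is
    empty (they can coexist in one tree)."""
    ac, bc = all_labels - a, all_labels - b
    return not (a & b) or not (a & bc) or not (ac & b) or not (ac & bc)


# ---------------------------------------------------------------------------
# Tabulation


def tabulate_topologies(
    trees: list[dendropy.Tree],
    locus_id: str,
    burnin_frac: float = 0.10,
) -> LocusTopologyTable:
    """Summarize a sequential tree sample into topology counts.

    The first ceil(burnin_frac * n) trees are discarded; the remainder are
    canonicalized and counted.
    """
    if not 0.0 <= burnin_frac < 1.0:
        raise ValueError("burnin_frac must be in [0, 1)")
    n_burn = math.ceil(burnin_frac * len(trees))
    kept = trees[n_burn:]
    if not kept:
        raise ValueError(f"{locus_id}: no trees left after burn-in")
    tip_sets = {
        frozenset(leaf.taxon.label for leaf in t.leaf_node_iter()) for t in kept
    }
    if len(tip_sets) != 1:
        raise ValueError(f"{locus_id}: tip sets differ within the tree sample")
    counts: dict[str, int] = {}
    for t in kept:
        key = canonical_topology(t)
        counts[key] = counts.get(key, 0) + 1
    return LocusTopologyTable(
        locus_id=locus_id, counts=counts, tip_labels=tip_sets.pop()
    )


def tabulate_from_files(
    paths: dict[str, str], burnin_frac: float = 0.10
) -> list[LocusTopologyTable]:
    """mbsum-style tabulation of per-locus newick sample files."""
    from .io import read_newick_list

    tables = []
    for locus_id, path in sorted(paths.items()):
        tables.append(
            tabulate_topologies(read_newick_list(path), locus_id, burnin_frac)
        )
    tip_sets = {t.tip_labels for t in tables}
    if len(tip_sets) > 1:
        bad = [t.locus_id for t in tables if t.tip_labels != tables[0].tip_labels]
        raise ValueError(f"tip-set mismatch across loci: {bad}")
    return tables


def require_complete(loci, sample_subset: set[str], min_pis: int = 2):
    """Restrict ortholog loci to a sample subset, keeping only loci where
    every subset sample is present and the subset rows retain at least
    ``min_pis`` parsimony-informative sites."""
    from .assembly import OrthologLocus
    from .supermatrix import count_pis

    kept = []
    for locus in loci:
        if not sample_subset <= locus.rows.keys():
            continue
        rows = {s: locus.rows[s] for s in sorted(sample_subset)}
        if count_pis(list(rows.values())) < min_pis:
            continue
        kept.append(OrthologLocus(locus_id=locus.locus_id, rows=rows))
    return kept


# ---------------------------------------------------------------------------
# Topology-space analytics


def count_topology_space(n_tips: int) -> tuple[int, int]:
    """(number of unrooted binary topologies, number of non-trivial splits)
    for ``n_tips`` labelled tips: (2n-5)!! and 2^(n-1) - n - 1."""
    if n_tips < 4:
        raise ValueError("need at least 4 tips")
    n_topologies = 1
    for k in range(3, 2 * n_tips - 4, 2):
        n_topologies *= k
    n_splits = 2 ** (n_tips - 1) - n_tips - 1
    return n_topologies, n_splits


# ---------------------------------------------------------------------------
# Dirichlet-process concordance sampler


def _gibbs_run(
    tables: list[LocusTopologyTable],
    alpha: float,
    n_gen: int,
    burnin_frac: float,
    tau: int,
    split_sets: dict[str, frozenset[Split]],
    split_index: dict[Split, int],
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """One Gibbs run; returns (post-burn-in CF samples with shape
    (n_samples, n_splits), fraction of samples where one topology covers
    all loci)."""
    n_loci = len(tables)
    cand: list[list[str]] = [sorted(t.counts) for t in tables]
    q: list[np.ndarray] = []
    for t, cs in zip(tables, cand):
        fr = t.fractions()
        q.append(np.array([fr[c] for c in cs]))
    # global assignment counts by topology key
    assign: list[str] = []
    counts: dict[str, int] = {}
    for i in range(n_loci):
        j = rng.choice(len(cand[i]), p=q[i] / q[i].sum())
        assign.append(cand[i][j])
        counts[assign[i]] = counts.get(assign[i], 0) + 1
    base = alpha / tau
    n_burn = math.ceil(burnin_frac * n_gen)
    samples = np.zeros((n_gen - n_burn, len(split_index)))
    # per-topology split membership as index arrays
    member_idx = {
        top: np.array([split_index[s] for s in splits], dtype=int)
        for top, splits in split_sets.items()
    }
    n_all_concordant = 0
    for gen in range(n_gen):
        for i in range(n_loci):
            cur = assign[i]
            counts[cur] -= 1
            w = np.array(
                [q[i][j] * (counts.get(c, 0) + base) for j, c in enumerate(cand[i])]
            )
            j = rng.choice(len(w), p=w / w.sum()) if len(w) > 1 else 0
            assign[i] = cand[i][j]
            counts[assign[i]] = counts.get(assign[i], 0) + 1
        if gen >= n_burn:
            row = samples[gen - n_burn]
            for top, c in counts.items():
                if c:
                    row[member_idx[top]] += c
            row /= n_loci
            if max(counts.values()) == n_loci:
                n_all_concordant += 1
    return samples, n_all_concordant / max(n_gen - n_burn, 1)


def concordance_mcmc(
    tables: list[LocusTopologyTable],
    alpha: float,
    n_gen: int = 2000,
    n_runs: int = 2,
    seed: int = 0,
    burnin_frac: float = 0.10,
) -> ConcordanceResult:
    """Dirichlet-process concordance Gibbs sampler.

    At each sweep, locus i draws a topology T from its table candidates with
    probability proportional to q_i(T) * (n_{-i}(T) + α/τ), where q_i is the
    locus's posterior fraction for T, n_{-i}(T) the number of other loci
    currently assigned T, and τ the number of possible unrooted topologies
    for the tip count.  CFs are recorded each generation as the fraction of
    loci whose assignment contains the split; means and central 95%
    intervals pool the post-burn-in samples of all runs.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    if len(tables) < 2:
        raise ValueError("need at least 2 loci")
    tip_sets = {t.tip_labels for t in tables}
    if len(tip_sets) != 1:
        raise ValueError("tip-set mismatch across loci")
    tip_labels = tip_sets.pop()
    tau, _ = count_topology_space(len(tip_labels))

    topologies = sorted({top for t in tables for top in t.counts})
    split_sets = {top: topology_splits(top) for top in topologies}
    all_splits = sorted(
        {s for splits in split_sets.values() for s in splits},
        key=lambda s: tuple(sorted(s)),
    )
    split_index = {s: i for i, s in enumerate(all_splits)}

    per_run: list[np.ndarray] = []
    p_all: list[float] = []
    for r in range(n_runs):
        rng = np.random.default_rng((seed + 1) * 7919 + r)
        samples, frac = _gibbs_run(
            tables, alpha, n_gen, burnin_frac, tau,
            split_sets, split_index, rng,
        )
        per_run.append(samples)
        p_all.append(frac)
    pooled = np.vstack(per_run)
    means = pooled.mean(axis=0)
    lo = np.percentile(pooled, 2.5, axis=0)
    hi = np.percentile(pooled, 97.5, axis=0)
    if n_runs >= 2:
        run_means = [r.mean(axis=0) for r in per_run[:2]]
        convergence = float(np.max(np.abs(run_means[0] - run_means[1]))) if len(
            all_splits
        ) else 0.0
    else:
        convergence = 0.0
    cf_by_split = {s: float(means[i]) for s, i in split_index.items()}
    primary = primary_concordance_tree(cf_by_split, tip_labels)
    splits_out = [
        (s, float(means[i]), float(lo[i]), float(hi[i]))
        for s, i in sorted(split_index.items(), key=lambda kv: kv[1])
    ]
    return ConcordanceResult(
        splits=splits_out,
        primary_tree=primary,
        n_topologies_seen=len(topologies),
        n_splits_seen=len(all_splits),
        alpha=alpha,
        convergence=convergence,
        tip_labels=tip_labels,
        p_all_concordant=float(np.mean(p_all)),
    )


def primary_concordance_tree(
    cf_by_split: dict[Split, float], tip_labels: frozenset[str]
) -> str:
    """Greedy primary concordance tree from per-split mean CFs.

    Splits enter in order of descending CF (ties broken lexicographically on
    the sorted label tuple); each is kept iff compatible with all kept so
    far.  The kept set defines a (possibly unresolved) topology string.
    """
    ordered = sorted(
        cf_by_split.items(), key=lambda kv: (-kv[1], tuple(sorted(kv[0])))
    )
    kept: list[Split] = []
    for split, _cf in ordered:
        if all(splits_compatible(split, k, tip_labels) for k in kept):
            kept.append(split)
    ref = min(tip_labels)
    clusters = {
        (s if ref not in s else tip_labels - s) for s in kept
    }
    rest = frozenset(tip_labels) - {ref}
    return f"({ref},{_newick_from_clusters(rest, clusters)});"


def primary_tree_splits(result: ConcordanceResult) -> list[Split]:
    return sorted(
        topology_splits(result.primary_tree), key=lambda s: tuple(sorted(s))
    )


def conflict_assessment(
    result: ConcordanceResult, cf_floor: float = 0.05
) -> dict[Split, bool]:
    """Significance flags for the primary-tree splits.

    A primary split is significantly supported iff no incompatible split
    with mean CF above ``cf_floor`` exists, or none of their 95% intervals
    overlaps the split's own interval.
    """
    flags: dict[Split, bool] = {}
    labels = result.tip_labels
    for split in primary_tree_splits(result):
        mean, lo, hi = result.cf(split)
        conflicting = [
            (s, m, l, h)
            for s, m, l, h in result.splits
            if s != split
            and m > cf_floor
            and not splits_compatible(s, split, labels)
        ]
        overlap = any(l <= hi and lo <= h for _, _, l, h in conflicting)
        flags[split] = not conflicting or not overlap
    return flags
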