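"""Synthetic RAD-seq data with known ground truth.

Gene trees are simulated under the multispecies coalescent on a species
tree with branch lengths in coalescent units; introgression is modelled
per locus: with probability γ the recipient species' lineages are moved
into the donor population at a stated time before coalescing onward.
Sequences evolve by Jukes-Cantor along the gene tree; diploid genotypes
carry IUPAC codes at heterozygous sites; reads are emitted with barcodes,
a Phred quality profile, per-base errors, a depth distribution and
per-(sample, locus) dropout.

All randomness flows from one seed through per-locus ``SeedSequence``
substreams, so enlarging ``n_loci`` never perturbs earlier loci.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .assembly import OrthologLocus
from .io import BarcodedRead
from .seqcodes import DNA, het_code

# ---------------------------------------------------------------------------
# Configuration


def default_barcodes(n: int, length: int = 5, min_distance: int = 3) -> list[str]:
    """Deterministic barcode codebook with pairwise Hamming distance >= 3."""
    chosen: list[str] = []
    for combo in itertools.product(DNA, repeat=length):
        bc = "".join(combo)
        if all(
            sum(a != b for a, b in zip(bc, prev)) >= min_distance for prev in chosen
        ):
            chosen.append(bc)
        if len(chosen) == n:
            return chosen
    raise ValueError(f"cannot build {n} barcodes of length {length}")


@dataclass
class Introgression:
    """Per-locus lineage reattachment: with probability gamma, lineages of
    the recipient species move to the donor population at ``time``."""

    donor: str
    recipient: str
    gamma: float
    time: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if self.time <= 0:
            raise ValueError("introgression time must be positive")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic data set.

    The default species tree has the four-taxon + outgroup shape assumed by
    the D-statistic, (((P1,P2),P3),O), with internal branches of one
    coalescent unit (appreciable incomplete lineage sorting).  ``theta`` is
    the per-site mutation parameter: a branch of b coalescent units carries
    theta/2 * b expected substitutions per site.
    """

    species_tree: str = "(((P1:1.0,P2:1.0):1.0,P3:2.0):2.0,O:4.0);"
    individuals: dict[str, int] = field(
        default_factory=lambda: {"P1": 1, "P2": 1, "P3": 1, "O": 2}
    )
    introgression: Introgression | None = None
    n_loci: int = 200
    locus_length: int = 90
    theta: float = 0.01
    heterozygosity: float = 0.005
    dropout: float = 0.0
    depth_mean: float = 4.0
    depth_poisson: bool = False
    phred_mean: float = 38.0
    phred_sd: float = 3.0
    sequencing_error: bool = True
    barcode_length: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("heterozygosity", "dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")

    @property
    def sample_ids(self) -> list[str]:
        out = []
        for sp in sorted(self.individuals):
            for i in range(self.individuals[sp]):
                out.append(f"{sp}_{i}")
        return out

    def species_of(self, sample_id: str) -> str:
        return sample_id.rsplit("_", 1)[0]

    def barcodes(self) -> dict[str, str]:
        codes = default_barcodes(len(self.sample_ids), self.barcode_length)
        return dict(zip(self.sample_ids, codes))


# ---------------------------------------------------------------------------
# Gene trees under the multispecies coalescent


class GeneNode:
    """Lightweight gene-tree node (height in coalescent units)."""

    __slots__ = ("label", "height", "children")

    def __init__(self, label: str | None, height: float, children=()):
        self.label = label
        self.height = height
        self.children = list(children)

    def newick(self) -> str:
        return self._nwk(parent_height=None) + ";"

    def _nwk(self, parent_height: float | None) -> str:
        if self.children:
            inner = ",".join(
                sorted(c._nwk(self.height) for c in self.children)
            )
            body = f"({inner})"
        else:
            body = self.label
        if parent_height is None:
            return body
        return f"{body}:{parent_height - self.height:.6f}"

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.label]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class _SpeciesTree:
    """Flattened species tree: population ids, ages, merge schedule."""

    tip_pop: dict[str, int]  # species name -> population id
    merges: list[tuple[float, int, int, int]]  # (age, child_a, child_b, parent)
    root_pop: int

    @classmethod
    def parse(cls, newick: str) -> "_SpeciesTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        if any(len(n.child_nodes()) > 2 for n in tree.preorder_node_iter()):
            raise ValueError("species tree must be binary")
        ages: dict[int, float] = {}
        pop_of: dict[int, int] = {}
        tip_pop: dict[str, int] = {}
        next_id = 0
        # leaf ages 0; internal age = child age + child edge length
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                ages[id(node)] = 0.0
                pop_of[id(node)] = next_id
                tip_pop[node.taxon.label] = next_id
                next_id += 1
            else:
                kids = node.child_nodes()
                kid_ages = [
                    ages[id(k)] + (k.edge.length or 0.0) for k in kids
                ]
                if max(kid_ages) - min(kid_ages) > 1e-9:
                    raise ValueError("species tree must be ultrametric")
                ages[id(node)] = kid_ages[0]
                pop_of[id(node)] = next_id
                next_id += 1
        merges = []
        root = tree.seed_node
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                continue
            kids = node.child_nodes()
            merges.append(
                (ages[id(node)], pop_of[id(kids[0])], pop_of[id(kids[1])],
                 pop_of[id(node)])
            )
        merges.sort(key=lambda m: m[0])
        return cls(tip_pop=tip_pop, merges=merges, root_pop=pop_of[id(root)])

    def mrca_age(self, species_a: str, species_b: str) -> float:
        """Divergence time of two species (age of their populations' merge)."""
        group = {self.tip_pop[species_a]}
        other = {self.tip_pop[species_b]}
        for age, a, b, parent in self.merges:
            if a in group or b in group:
                group.add(parent)
                group.update({a, b})
            if a in other or b in other:
                other.add(parent)
                other.update({a, b})
            if group & other:
                return age
        raise ValueError(f"no common ancestor of {species_a}, {species_b}")


def _coalesce_in_pop(
    lineages: list[GeneNode],
    t_start: float,
    t_end: float,
    rng: np.random.Generator,
) -> tuple[list[GeneNode], float]:
    """Coalesce lineages at rate k(k-1)/2 within [t_start, t_end]."""
    t = t_start
    while len(lineages) >= 2:
        k = len(lineages)
        wait = rng.exponential(2.0 / (k * (k - 1)))
        if t + wait >= t_end:
            return lineages, t_end
        t += wait
        i, j = rng.choice(k, size=2, replace=False)
        i, j = int(i), int(j)
        merged = GeneNode(None, t, [lineages[i], lineages[j]])
        lineages = [l for idx, l in enumerate(lineages) if idx not in (i, j)]
        lineages.append(merged)
    return lineages, t_end


def simulate_gene_tree(
    sp_tree: _SpeciesTree,
    samples_by_species: dict[str, list[str]],
    rng: np.random.Generator,
    introgression: Introgression | None = None,
    introgressed: bool = False,
) -> GeneNode:
    """One gene tree (single lineage per individual) under the MSC, with
    optional donor←recipient lineage movement at the introgression time."""
    pops: dict[int, list[GeneNode]] = {}
    for species, samples in samples_by_species.items():
        pop = sp_tree.tip_pop[species]
        pops.setdefault(pop, []).extend(
            GeneNode(s, 0.0) for s in sorted(samples)
        )
    events: list[tuple[float, str, tuple]] = [
        (age, "merge", (a, b, parent)) for age, a, b, parent in sp_tree.merges
    ]
    if introgressed and introgression is not None:
        t_mig = introgression.time
        div = sp_tree.mrca_age(introgression.donor, introgression.recipient)
        if t_mig >= div:
            raise ValueError(
                f"introgression time {t_mig} is not before the "
                f"donor/recipient divergence at {div}"
            )
        events.append((t_mig, "migrate", ()))
    events.sort(key=lambda e: e[0])
    t_now = 0.0
    for t_event, kind, payload in events:
        for pop in list(pops):
            pops[pop], _ = _coalesce_in_pop(pops[pop], t_now, t_event, rng)
        if kind == "migrate":
            src = sp_tree.tip_pop[introgression.recipient]
            dst = sp_tree.tip_pop[introgression.donor]
            pops.setdefault(dst, []).extend(pops.pop(src, []))
        else:
            a, b, parent = payload
            merged = pops.pop(a, []) + pops.pop(b, [])
            pops.setdefault(parent, []).extend(merged)
        t_now = t_event
    root_lineages = [l for ls in pops.values() for l in ls]
    root_lineages, _ = _coalesce_in_pop(root_lineages, t_now, np.inf, rng)
    return root_lineages[0]


def simulate_gene_trees(
    config: SimulationConfig,
) -> tuple[list[GeneNode], list[bool]]:
    """Per-locus gene trees and introgression flags."""
    sp_tree = _SpeciesTree.parse(config.species_tree)
    samples_by_species: dict[str, list[str]] = {}
    for s in config.sample_ids:
        samples_by_species.setdefault(config.species_of(s), []).append(s)
    unknown = set(samples_by_species) - set(sp_tree.tip_pop)
    if unknown:
        raise ValueError(f"species not in tree: {sorted(unknown)}")
    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(config.n_loci)
    trees: list[GeneNode] = []
    flags: list[bool] = []
    gamma = config.introgression.gamma if config.introgression else 0.0
    for child in streams:
        rng = np.random.default_rng(child)
        flag = bool(rng.random() < gamma) if gamma > 0 else False
        trees.append(
            simulate_gene_tree(
                sp_tree, samples_by_species, rng,
                introgression=config.introgression, introgressed=flag,
            )
        )
        flags.append(flag)
    return trees, flags


# ---------------------------------------------------------------------------
# Sequences


def _jc_mutate(
    seq: np.ndarray, distance: float, rng: np.random.Generator
) -> np.ndarray:
    """Jukes-Cantor transition over ``distance`` substitutions/site."""
    if distance <= 0:
        return seq.copy()
    p_change = 0.75 * (1.0 - np.exp(-4.0 * distance / 3.0))
    hit = rng.random(seq.size) < p_change
    out = seq.copy()
    if hit.any():
        shift = rng.integers(1, 4, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % 4
    return out


def simulate_locus(
    tree: GeneNode, config: SimulationConfig, rng: np.random.Generator
) -> dict[str, str]:
    """Evolve one locus along a gene tree; return diploid IUPAC genotypes.

    The root sequence is uniform random; each branch applies the exact JC
    transition for theta/2 * branch-length substitutions per site.  Each
    individual's second allele copy differs at a site with probability
    ``heterozygosity`` (uniform among the other three bases), encoded as
    the IUPAC two-base code.
    """
    length = config.locus_length
    root_seq = rng.integers(0, 4, size=length)
    tip_seqs: dict[str, np.ndarray] = {}

    def descend(node: GeneNode, seq: np.ndarray) -> None:
        if not node.children:
            tip_seqs[node.label] = seq
            return
        for child in node.children:
            d = 0.5 * config.theta * (node.height - child.height)
            descend(child, _jc_mutate(seq, d, rng))

    descend(tree, root_seq)
    genotypes: dict[str, str] = {}
    for sample in sorted(tip_seqs):
        alleles = tip_seqs[sample]
        chars = [DNA[b] for b in alleles]
        if config.heterozygosity > 0:
            het = rng.random(length) < config.heterozygosity
            for pos in np.flatnonzero(het):
                other = DNA[(alleles[pos] + rng.integers(1, 4)) % 4]
                chars[pos] = het_code(chars[pos], other)
        genotypes[sample] = "".join(chars)
    return genotypes


@dataclass
class GroundTruth:
    """What the generator knows: gene trees, introgression flags, true
    genotypes and the sample x locus presence matrix."""

    gene_trees: list[str]
    introgressed: list[bool]
    genotypes: list[dict[str, str]]
    presence: dict[str, list[bool]]  # sample -> per-locus presence

    def true_loci(self) -> list[OrthologLocus]:
        return [
            OrthologLocus(locus_id=f"true_{i}", rows=dict(g))
            for i, g in enumerate(self.genotypes)
        ]


def simulate_dataset(config: SimulationConfig) -> GroundTruth:
    """Gene trees + genotypes for every locus (no reads yet)."""
    trees, flags = simulate_gene_trees(config)
    ss = np.random.SeedSequence((config.seed, 1))
    streams = ss.spawn(config.n_loci)
    genotypes = [
        simulate_locus(tree, config, np.random.default_rng(child))
        for tree, child in zip(trees, streams)
    ]
    presence = {s: [True] * config.n_loci for s in config.sample_ids}
    return GroundTruth(
        gene_trees=[t.newick() for t in trees],
        introgressed=flags,
        genotypes=genotypes,
        presence=presence,
    )


# ---------------------------------------------------------------------------
# Reads


def emit_reads(
    truth: GroundTruth, config: SimulationConfig
) -> dict[str, list[BarcodedRead]]:
    """Barcoded reads per sample, with dropout, depth, qualities and errors.

    Each read copies one allele per heterozygous site (unphased 50/50),
    prepends the sample barcode, draws qualities from the Normal Phred
    profile (clipped to [2, 41]) and flips bases at rate 10^(-q/10).
    Updates ``truth.presence`` in place to reflect dropout.
    """
    barcodes = config.barcodes()
    ss = np.random.SeedSequence((config.seed, 2))
    streams = dict(zip(config.sample_ids, ss.spawn(len(config.sample_ids))))
    out: dict[str, list[BarcodedRead]] = {s: [] for s in config.sample_ids}
    for sample in config.sample_ids:
        rng = np.random.default_rng(streams[sample])
        bc = barcodes[sample]
        for locus_idx, genotype in enumerate(truth.genotypes):
            if sample not in genotype:
                truth.presence[sample][locus_idx] = False
                continue
            if config.dropout > 0 and rng.random() < config.dropout:
                truth.presence[sample][locus_idx] = False
                continue
            if config.depth_poisson:
                depth = int(rng.poisson(config.depth_mean))
            else:
                depth = int(round(config.depth_mean))
            if depth == 0:
                truth.presence[sample][locus_idx] = False
                continue
            seq = genotype[sample]
            for r in range(depth):
                bases = _sample_haplotype(seq, rng)
                full = bc + bases
                quals = np.clip(
                    np.rint(
                        rng.normal(config.phred_mean, config.phred_sd, len(full))
                    ),
                    2, 41,
                ).astype(int)
                if config.sequencing_error:
                    err_p = 10.0 ** (-quals / 10.0)
                    errs = rng.random(len(full)) < err_p
                else:
                    errs = np.zeros(len(full), dtype=bool)
                if errs.any():
                    arr = list(full)
                    for pos in np.flatnonzero(errs):
                        cur = arr[pos]
                        options = [b for b in DNA if b != cur]
                        arr[pos] = options[int(rng.integers(0, len(options)))]
                    full = "".join(arr)
                out[sample].append(
                    BarcodedRead(
                        f"{sample}:L{locus_idx}:R{r}", full, tuple(quals)
                    )
                )
    return out


def _sample_haplotype(genotype: str, rng: np.random.Generator) -> str:
    from .seqcodes import IUPAC_TO_SET

    chars = []
    for c in genotype:
        alleles = IUPAC_TO_SET[c]
        if len(alleles) == 1:
            chars.append(c)
        else:
            opts = sorted(alleles)
            chars.append(opts[int(rng.integers(0, len(opts)))])
    return "".join(chars)


def emit_fastq(
    truth: GroundTruth, config: SimulationConfig, outdir
) -> dict[str, str]:
    """Write one FASTQ per sample plus ground-truth sidecar files.

    Returns sample -> FASTQ path.  Sidecars: gene trees (newick, one per
    line), introgression flags and presence matrix (TSV), true genotypes
    (FASTA per locus block).
    """
    from pathlib import Path

    from .io import write_fastq

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reads = emit_reads(truth, config)
    paths: dict[str, str] = {}
    for sample, rs in reads.items():
        p = outdir / f"{sample}.fastq"
        write_fastq(rs, str(p))
        paths[sample] = str(p)
    (outdir / "gene_trees.nwk").write_text("\n".join(truth.gene_trees) + "\n")
    flag_lines = ["locus\tintrogressed"] + [
        f"true_{i}\t{int(f)}" for i, f in enumerate(truth.introgressed)
    ]
    (outdir / "introgression.tsv").write_text("\n".join(flag_lines) + "\n")
    samples = config.sample_ids
    pres_lines = ["locus\t" + "\t".join(samples)]
    for i in range(config.n_loci):
        pres_lines.append(
            f"true_{i}\t" + "\t".join(
                str(int(truth.presence[s][i])) for s in samples
            )
        )
    (outdir / "presence.tsv").write_text("\n".join(pres_lines) + "\n")
    with open(outdir / "true_genotypes.fasta", "w") as fh:
        for i, genotype in enumerate(truth.genotypes):
            for sample in sorted(genotype):
                fh.write(f">true_{i}|{sample}\n{genotype[sample]}\n")
    return paths
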