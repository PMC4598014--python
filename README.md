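# radphylo

RAD-seq phylogenomics at desk scale: de novo locus assembly with the classic
filter cascade, supermatrix construction under minimum-sample thresholds,
four-taxon Patterson's D-statistic admixture tests with bootstrap
significance, and Bayesian concordance-factor analysis over per-locus gene
tree samples — all exercisable end to end on ground-truthed coalescent
simulations, no downloads required.

## Who this is for

Researchers analysing restriction-site associated DNA (RAD-seq) data for
interspecific phylogenetics: resolving species relationships from thousands
of short anonymous loci, and asking whether gene-tree conflict among those
loci reflects incomplete lineage sorting (ILS) or admixture between species.

## What it does

**Locus assembly** (`radphylo.assembly`). Single-end reads are demultiplexed
by 5-nt barcodes (one mismatch allowed; pairwise barcode Hamming distance
≥ 3 guarantees unambiguity), quality-masked (Phred < 20 → N, > 4 Ns →
discard), trimmed to 90 bases, deduplicated, and clustered greedily within
each sample at 90% identity with a 2× minimum coverage cutoff. Diploid
consensus sequences carry IUPAC codes at heterozygous sites. Consensi are
clustered across samples at the same threshold; loci with a heterozygous
site shared by more than two samples are discarded as putative paralogs and
loci with more than 10 SNPs are discarded.

**Supermatrix** (`radphylo.supermatrix`). Loci are tail-trimmed (last 5
bases), restricted to those bearing parsimony-informative sites (PIS) and to
those shared by at least *m* samples, and concatenated with `?` for absent
sample×locus cells. Includes a clustering-threshold scan (60–95%), PIS and
missingness accounting, and a neighbor-joining + bootstrap utility for
topology-recovery checks.

**Patterson's D** (`radphylo.dstat`). For a four-taxon tree (((P1,P2),P3),O),
bi-allelic sites incongruent with the species tree are ABBA or BABA; under
ILS alone both are equally frequent, and

    D = (ΣABBA − ΣBABA) / (ΣABBA + ΣBABA),
    w_ABBA = (1−p1)·p2·p3,   w_BABA = p1·(1−p2)·p3,

with p_i the derived-allele frequency in individual i (heterozygotes
contribute ½ — hence the quarter-fraction pattern sums). The outgroup is a
pooled set of individuals required to be monomorphic at used sites.
Significance comes from 1000 locus-bootstrap replicates: Z = |D|/SD is
converted to a two-tailed normal p-value at α = 0.01 (Z > 2.576). The
all-pairs reciprocal battery over two focal species (3 + 3 individuals → 18
tests) is built by `enumerate_tests`.

**Concordance** (`radphylo.concordance`). Per-locus tree samples are
tabulated into topology counts (10% burn-in); a Gibbs sampler under a
Dirichlet-process prior with concentration α reassigns loci to topologies,
yielding sample-wide concordance factors (CFs) with 95% credibility
intervals, a greedy primary concordance tree, and a CI-overlap conflict
rule for clade support.

**Simulator** (`radphylo.simulate`). Gene trees under the multispecies
coalescent on a species tree in coalescent units, with per-locus
introgression (probability γ of reattaching the recipient species' lineages
to the donor), Jukes–Cantor sequences, diploid heterozygosity, barcoded
reads with a Phred quality profile, per-base errors, depth and dropout —
plus the full ground truth.

## Worked example

Simulate 300 loci under (((P1,P2),P3),O) with and without P3→P2 gene flow,
then run the D test:

```python
from radphylo.simulate import SimulationConfig, Introgression, simulate_dataset
from radphylo.dstat import DTestSpec, bootstrap_test

spec = DTestSpec("P1_0", "P2_0", "P3_0", frozenset({"O_0", "O_1"}))
for gamma in (0.0, 0.3):
    intro = Introgression("P3", "P2", gamma) if gamma else None
    truth = simulate_dataset(SimulationConfig(n_loci=300, seed=11,
                                              introgression=intro))
    r = bootstrap_test(truth.true_loci(), spec, n_boot=1000, seed=1)
    print(gamma, round(r.d, 3), round(r.z, 2), r.significant)
```

Output:

```
gamma=0.0: ABBA=25.00 BABA=23.00 D=0.042 Std(D)=0.195 Z=0.21 sig=False
gamma=0.3: ABBA=90.00 BABA=22.00 D=0.607 Std(D)=0.099 Z=6.11 sig=True
```

Without gene flow the two incongruent patterns balance (D ≈ 0, not
significant). With γ = 0.3 (86 of 300 loci introgressed), P2 and P3 share an
excess of derived alleles: ABBA ≫ BABA, D = 0.61, Z = 6.1 — a strongly
significant admixture signal in the expected direction.

The same workflow is available from the shell:

```bash
radphylo simulate --n-loci 200 --gamma 0.3 --seed 1 --outdir sim/
radphylo demux --fastq merged.fastq --barcodes barcodes.tsv --outdir demux/
radphylo assemble --indir demux/ --outdir asm/
radphylo matrix --loci asm/loci --m 4 --out-prefix m4
radphylo dstat --loci asm/loci --species map.tsv --focal him,pur --outgroup arc
radphylo concord --trees trees/ --alpha 0.1 --alpha 100 --seed 1
```

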