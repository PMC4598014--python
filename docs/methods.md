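# Methods

This note documents the models and procedures implemented in `radphylo`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Locus assembly

The cascade mirrors standard de novo RAD-seq practice (pyRAD-style):

1. **Demultiplexing.** Reads are assigned to the nearest barcode within
   `max_mismatch` (default 1) Hamming mismatches; an `N` in the read counts
   as a mismatch. With all pairwise barcode distances ≥ 3 (validated at map
   load), one-mismatch assignment is provably unambiguous; exact ties (only
   possible when that precondition is violated) are logged and routed to
   the unassigned pool.
2. **Quality masking.** Bases with Phred < 20 become `N`; reads with more
   than 4 Ns after masking are discarded. Qualities are Phred+33.
3. **Trimming.** Reads are cut to 90 bases (the post-barcode,
   post-restriction-site read length of 101-cycle single-end data); shorter
   reads are discarded.
4. **Deduplication.** Identical sequence strings collapse to one
   representative that remembers its read multiplicity, so downstream
   coverage still counts reads.
5. **Within-sample clustering.** Greedy seed clustering at 90% identity:
   reads are visited in order of (descending multiplicity, read id); each
   read joins the first existing seed with identity ≥ threshold, else seeds
   a new cluster. Clusters below 2× total depth are discarded. The
   greedy ordering is a determinism choice — the underlying method does not
   specify one — and is verified against a brute-force reference clustering
   on small inputs.
6. **Consensus calling.** Per site, an allele is *well supported* when its
   frequency among non-N calls is ≥ 0.25 and its read count is ≥ 2; the
   count requirement relaxes to ≥ 1 below depth 4 so that a 2× cluster with
   a 1+1 split is called heterozygous rather than arbitrarily resolved.
   Exactly two supported alleles yield the IUPAC code; three or more flag
   the cluster as error-rich and discard it whole (the conservative cure
   for collapsed paralogs and error pile-ups); otherwise the majority base
   is called (lexicographic tie-break), `N` where nothing is callable.
7. **Across-sample clustering.** The same greedy rule over consensus
   sequences, ordered by (descending depth, sample, id). A cluster that
   receives two consensi from one sample is discarded as a within-sample
   paralog collision.
8. **Locus filters.** A site with an ambiguity code in more than two
   samples discards the locus (shared heterozygosity is the classic
   multi-copy signature); more than 10 variable sites discards the locus.
   For SNP counting, ambiguity codes are expanded to their allele sets and
   `N` is excluded entirely; `max_shared` counts rows bearing any ambiguity
   at the site, not phased alleles. An exclusion-list hook drops loci by id
   (e.g. externally flagged contaminants).

All sequence comparison is ungapped and positional: RAD loci are
enzyme-anchored, fixed-length, and the simulator is indel-free. Identity is
matches / comparable positions, where positions with `N` in either sequence
are excluded from both numerator and denominator and IUPAC codes match when
their allele sets intersect. Reverse-complement matching is unnecessary
because enzyme-anchored reads share orientation.

Every stage logs input = retained + discarded, and the per-sample report
(reads after QC, clusters passing depth, mean cluster depth, consensus
loci) is recomputed from the pipeline state rather than accumulated.

## Supermatrix

Loci are tail-trimmed by 5 columns (base quality decays at the read end),
filtered to those with ≥ 1 parsimony-informative site, then to those with
≥ *m* samples, and concatenated with `?` for absent cells. Whether the PIS
filter sees trimmed or untrimmed loci is configurable (`trim_first`,
default trim-then-filter). A column is parsimony-informative when at least
two resolved states each occur in ≥ 2 rows; ambiguity codes, `N`, `?` and
`-` count as missing for this purpose. `pct_missing` counts whole absent
loci (cells written `?`), not interior Ns, which are tracked separately —
this matches the usual meaning of "missing data" in RAD supermatrices.
Partitions are 0-based half-open internally and exported 1-based inclusive
in NEXUS charset blocks.

The threshold scan repeats the entire assembly at each clustering threshold
(default 60–95% by 5) and reports loci, total PIS, and PIS-bearing loci;
the recommended threshold is the argmax of total PIS with ties broken
upward.

Neighbor-joining on pairwise p-distances (shared non-missing sites only;
allele-set intersection for heterozygotes; an error names any pair with no
shared sites) plus a site-resampling bootstrap stands in for full ML/
Bayesian tree inference, which is out of scope; it exists to verify
topology recovery, not to produce publishable trees. Monophyly of a tip set
is evaluated as the existence of an unrooted edge separating the set from
everything else including the outgroup.

## Patterson's D

A site is polarized when P1, P2, P3 carry non-missing diploid genotypes, at
least one outgroup individual is non-missing, exactly two alleles segregate
among the four roles, and the pooled outgroup is monomorphic counting
heterozygote halves. The outgroup allele is ancestral; with p_i the derived
frequency in individual i (0, ½, 1), the site contributes
w_ABBA = (1−p1)p2p3 and w_BABA = p1(1−p2)p3. Strict outgroup-monomorphic
polarization was chosen over frequency-weighted (1−p_O) factors because it
is deterministic and conservative; sites with some (but not all) outgroup
individuals missing are used. The published quarter-fraction pattern sums
arise exactly from the ½ heterozygote weights.

A locus enters a test when it contains P1, P2, P3 and ≥ 1 outgroup
individual. D = (ΣABBA − ΣBABA)/(ΣABBA + ΣBABA), reported as 0 with a flag
when both sums are zero. The bootstrap resamples *loci* (the exchangeable
units of RAD data, preserving within-locus linkage), B = 1000 by default;
sd is the ddof-1 standard deviation of replicate D values; Z = |D|/sd;
p = 2(1−Φ(Z)); significant iff p < α = 0.01 (equivalently Z > 2.576 — the
conventional "Z > 2.55" rule of thumb is honored by testing p < α, with Z
reported). Zero bootstrap SD with non-zero D reports Z = +∞ and p = 0.
The bootstrap is bit-reproducible given the seed and locus order.

`pdisc` — the discordant-site fraction — is defined here as
(ΣABBA + ΣBABA) / number of polarized sites; the denominator convention
varies across implementations, so the definition is surfaced in the API
docs and the quantity is treated as descriptive only.

The reciprocal battery: for focal species X and Y, every unordered pair
within X (canonical order by sample id) as (P1, P2) crossed with every
individual of Y as P3, then roles swapped; the outgroup pools all
individuals of the outgroup species. 3 + 3 individuals give
C(3,2)·3·2 = 18 tests.

## Bayesian concordance

Per-locus tree samples are canonicalized (unrooted, branch lengths
dropped, deterministic string form) and counted after discarding the first
⌈10%⌉ of trees. Given tables q_i(T), the Gibbs sampler reassigns locus i to
topology T with probability ∝ q_i(T)·(n_{−i}(T) + α/τ), where n_{−i}(T)
counts other loci currently assigned T and τ = (2n−5)!! is the number of
unrooted binary topologies for n tips. This is the standard Chinese-
restaurant form of a Dirichlet process with a uniform base measure over
topology space — a deliberate simplification of BUCKy's prior-partition
machinery that preserves the semantics of α (small α = little expected
discordance, large α = loci decouple toward their own posteriors) while
remaining verifiable by exhaustive enumeration on small systems. The
sampler is validated against the Pólya-urn enumeration (rising-factorial
weights) on 3-locus toys and against the α→∞ closed form.

Topologies absent from a locus's table have probability zero for that
locus (no smoothing), matching the mbsum→BUCKy data flow. Two independent
runs are pooled for CF means and central 95% intervals (2.5/97.5
percentiles of post-burn-in samples, 10% burn-in); the convergence
diagnostic is the max across splits of the between-run difference in mean
CF. The primary concordance tree adds splits in descending mean-CF order
(lexicographic tie-break) when compatible with all previously added splits.
A primary-tree clade is *significantly supported* when no incompatible
split has mean CF > 0.05, or when none of their 95% intervals overlaps the
clade's own interval.

`require_complete` restricts loci to a sample subset (complete matrices,
as concordance analysis requires) and keeps only loci with ≥ 2
parsimony-informative sites among the subset rows.

## Synthetic data

Gene trees follow the multispecies coalescent: within each species-tree
branch, k lineages coalesce at rate k(k−1)/2 per coalescent unit;
populations merge at divergence times computed from the (ultrametric,
binary) species tree. Introgression is per-locus lineage reattachment: with
probability γ, all lineages of the recipient species still present at the
introgression time (default 0.5, necessarily before the donor/recipient
divergence) move to the donor population. This matches the ABBA/BABA
generative story and gives a clean per-locus ground-truth flag, at the cost
of not modelling continuous migration.

Sequences evolve by exact Jukes–Cantor transitions: a branch of b
coalescent units carries d = θ/2·b expected substitutions per site, and a
site changes with probability ¾(1−e^(−4d/3)) to a uniform other base, so
tip-to-tip divergence follows the JC closed form exactly. Each individual
contributes one sampled lineage; its second allele copy differs at a site
with independent probability `heterozygosity`, encoded as the IUPAC code.
This makes heterozygosity an orthogonal dial (setting it to 0 provably
removes all ambiguity codes) rather than an emergent property of
within-species coalescence — a deliberate trade of realism for
controllability; real data's correlation between heterozygosity and
population history is not emulated.

Reads copy one allele per heterozygous site (unphased, 50/50 per read),
prepend the sample barcode, draw qualities from a Normal(38, 3) Phred
profile clipped to [2, 41], and flip bases at rate 10^(−q/10) (optionally
disabled for error-free runs). Depth is constant (default 4×) or Poisson;
dropout is Bernoulli per sample×locus. Randomness flows from a single seed
through per-locus `SeedSequence` substreams, so extending `n_loci` never
perturbs earlier loci. Indels, paralog families, selection, read pairs and
restriction-site mutation models beyond Bernoulli dropout are out of scope,
so passing tests demonstrate correctness of the algorithms under those
idealizations, not robustness to every artifact of real libraries.

Default study conditions: species tree (((P1:1, P2:1):1, P3:2):2, O:4) in
coalescent units (internal branches of 1 unit give ~25% triplet
discordance — substantial ILS), θ = 0.01 (≈ 1–4% pairwise divergence,
typical of within-genus RAD data), heterozygosity 0.005, 200 loci of 90 bp.
The simulator's triplet-discordance behaviour is cross-checked against the
coalescent closed form (2/3)e^(−T) and against an independent msprime
simulation of the same demography.

## Problem sizes and verification

The shipped checks run at desk scale: end-to-end exact recovery uses 50
loci × 6 samples with sequencing error disabled, heterozygosity 0 and
θ = 0.004 (small enough that orthologous loci stay below the 10-SNP
paralog cutoff, so the cascade's output is predicted exactly by the ground
truth); D calibration uses 500 null and 100 introgressed replicates of 200
loci with B = 200; the concordance oracle uses 3 loci × 2 topologies ×
4000 generations. The full suite runs in a few minutes on one core.

Known limitation, measured and documented rather than hidden: at 200 loci
and θ = 0.01 a null D test carries only ~25 ABBA+BABA counts. The bootstrap
SD is unbiased there (mean sd_boot matches the empirical SD of D to three
decimals) and D itself is close to normal, but the per-test studentized Z
is heavy-tailed, so the nominal α = 0.01 cutoff rejects ~2.5–4% of null
replicates. The effect is independent of B and vanishes as counts grow
(more loci or higher θ); with the locus counts of a real m4-scale data set
(≈ 700–1300) the normal calibration is adequate. Practitioners testing
sparse data sets should treat borderline Z scores (2.5–3.5) with caution —
which is precisely why a conservative α was standard practice.
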