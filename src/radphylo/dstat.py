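"""Four-taxon Patterson's D-statistic admixture tests.

Under the species tree (((P1,P2),P3),O), bi-allelic sites where P3 shares
the derived allele with P2 (ABBA) or with P1 (BABA) are equally frequent
under incomplete lineage sorting alone; an excess of one pattern indicates
gene flow between P3 and one of the ingroup pair.  Diploid genotypes enter
with fractional weights (a heterozygote carries the derived allele at
frequency 1/2), the outgroup is a pooled set of individuals required to be
monomorphic at used sites, and significance comes from a locus bootstrap:

    D = (sum ABBA - sum BABA) / (sum ABBA + sum BABA)
    w_ABBA = (1 - p1) * p2 * p3,   w_BABA = p1 * (1 - p2) * p3

with p_i the derived-allele frequency in individual i at the site.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .assembly import OrthologLocus
from .seqcodes import CODE_TO_MASK, N_MASK, encode

_POP = np.array([bin(i).count("1") for i in range(16)], dtype=np.int8)


@dataclass(frozen=True)
class DTestSpec:
    """One four-taxon test: three single individuals + a pooled outgroup."""

    p1: str
    p2: str
    p3: str
    outgroup: frozenset[str]

    def __post_init__(self) -> None:
        roles = [self.p1, self.p2, self.p3]
        if len(set(roles)) != 3 or set(roles) & self.outgroup:
            raise ValueError("P1, P2, P3 and outgroup must be disjoint")
        if not self.outgroup:
            raise ValueError("outgroup must be non-empty")


@dataclass(frozen=True)
class DTestResult:
    spec: DTestSpec
    sum_abba: float
    sum_baba: float
    d: float
    sd_boot: float
    z: float
    p_two_tailed: float
    n_loci: int
    pdisc: float
    significant: bool
    d_undefined: bool = False


def derived_frequency(code: str, derived: str) -> float | None:
    """Derived-allele frequency of a diploid IUPAC genotype: 1, 0.5, 0.

    Returns None (missing) for N, gaps/'?' or codes with more than two
    alleles.
    """
    mask = CODE_TO_MASK.get(code)
    if mask is None or mask == N_MASK or _POP[mask] > 2:
        return None
    dmask = CODE_TO_MASK[derived]
    return float(_POP[mask & dmask]) / float(_POP[mask])


def polarize_site(
    p1: str, p2: str, p3: str, outgroup: list[str]
) -> tuple[float, float, float] | None:
    """Polarize one alignment column into derived frequencies for P1-P3.

    The site is used iff P1, P2, P3 are all non-missing diploid genotypes,
    at least one outgroup individual is non-missing, exactly two alleles
    segregate among the four roles, and the pooled outgroup is monomorphic
    (every outgroup allele copy, heterozygote halves included, is the same
    base).  The outgroup allele is ancestral; the other is derived.
    """
    masks = [CODE_TO_MASK.get(c, 0) for c in (p1, p2, p3)]
    if any(m == 0 or m == N_MASK or _POP[m] > 2 for m in masks):
        return None
    out_masks = [
        m
        for m in (CODE_TO_MASK.get(c, 0) for c in outgroup)
        if m != 0 and m != N_MASK and _POP[m] <= 2
    ]
    if not out_masks:
        return None
    out_union = 0
    for m in out_masks:
        out_union |= m
    if _POP[out_union] != 1:
        return None  # polymorphic (or heterozygous) outgroup pool
    union = masks[0] | masks[1] | masks[2] | out_union
    if _POP[union] != 2:
        return None
    derived = union & ~out_union
    return tuple(float(_POP[m & derived]) / float(_POP[m]) for m in masks)


def site_weights(p1: float, p2: float, p3: float) -> tuple[float, float]:
    """ABBA/BABA weights of a polarized site."""
    return (1.0 - p1) * p2 * p3, p1 * (1.0 - p2) * p3


def locus_weights(
    locus: OrthologLocus, spec: DTestSpec
) -> tuple[float, float, int] | None:
    """Summed (ABBA, BABA, n_polarized_sites) for one locus, or None when
    the locus lacks P1, P2, P3 or every outgroup individual."""
    rows = locus.rows
    if not ({spec.p1, spec.p2, spec.p3} <= rows.keys()):
        return None
    out_ids = sorted(spec.outgroup & rows.keys())
    if not out_ids:
        return None
    m1, m2, m3 = (encode(rows[s]) for s in (spec.p1, spec.p2, spec.p3))
    mo = np.vstack([encode(rows[s]) for s in out_ids])

    valid = lambda m: (m != 0) & (m != N_MASK) & (_POP[m] <= 2)
    v123 = valid(m1) & valid(m2) & valid(m3)
    vo = valid(mo)
    out_union = np.zeros(locus.length, dtype=np.uint8)
    for i in range(mo.shape[0]):
        out_union |= np.where(vo[i], mo[i], 0).astype(np.uint8)
    mono_out = _POP[out_union] == 1
    union = (m1 | m2 | m3 | out_union).astype(np.uint8)
    usable = v123 & mono_out & (_POP[union] == 2)
    if not usable.any():
        return 0.0, 0.0, 0
    derived = (union & ~out_union).astype(np.uint8)
    p1 = _POP[(m1 & derived)] / np.maximum(_POP[m1], 1)
    p2 = _POP[(m2 & derived)] / np.maximum(_POP[m2], 1)
    p3 = _POP[(m3 & derived)] / np.maximum(_POP[m3], 1)
    w_abba = np.where(usable, (1 - p1) * p2 * p3, 0.0)
    w_baba = np.where(usable, p1 * (1 - p2) * p3, 0.0)
    return float(w_abba.sum()), float(w_baba.sum()), int(usable.sum())


def d_statistic(
    loci: list[OrthologLocus], spec: DTestSpec
) -> tuple[float, float, float, int, float, np.ndarray]:
    """Patterson's D over a locus set.

    Returns (sum_abba, sum_baba, D, n_loci, pdisc, per_locus) where
    ``per_locus`` is an (n_loci, 2) array of per-locus ABBA/BABA sums used
    by the bootstrap.  ``pdisc`` is (sum ABBA + sum BABA) divided by the
    number of polarized sites.  When both sums are zero D is reported as 0.
    """
    per_locus: list[tuple[float, float]] = []
    n_polarized = 0
    for locus in loci:
        w = locus_weights(locus, spec)
        if w is None:
            continue
        per_locus.append((w[0], w[1]))
        n_polarized += w[2]
    if not per_locus:
        raise ValueError("no usable loci for this test")
    arr = np.asarray(per_locus)
    sum_abba, sum_baba = float(arr[:, 0].sum()), float(arr[:, 1].sum())
    denom = sum_abba + sum_baba
    d = (sum_abba - sum_baba) / denom if denom > 0 else 0.0
    pdisc = denom / n_polarized if n_polarized else 0.0
    return sum_abba, sum_baba, d, len(per_locus), pdisc, arr


def bootstrap_test(
    loci: list[OrthologLocus],
    spec: DTestSpec,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.01,
) -> DTestResult:
    """Full D test with a locus bootstrap.

    Loci are resampled with replacement ``n_boot`` times; sd_boot is the
    (n-1) standard deviation of the replicate D values, Z = |D|/sd_boot,
    and the two-tailed p-value comes from the standard normal.  A zero
    bootstrap SD with non-zero D is reported as Z = +inf, p = 0.
    """
    if n_boot < 2:
        raise ValueError(f"n_boot must be >= 2, got {n_boot}")
    sum_abba, sum_baba, d, n_loci, pdisc, arr = d_statistic(loci, spec)
    if n_loci < 2:
        raise ValueError("need at least 2 usable loci to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_loci, size=(n_boot, n_loci))
    boot_sums = arr[idx].sum(axis=1)  # (n_boot, 2)
    denom = boot_sums.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        boot_d = np.where(
            denom > 0, (boot_sums[:, 0] - boot_sums[:, 1]) / denom, 0.0
        )
    sd_boot = float(np.std(boot_d, ddof=1))
    d_undefined = (sum_abba + sum_baba) == 0
    if sd_boot > 0:
        z = abs(d) / sd_boot
        p = 2.0 * float(norm.sf(z))
    elif d != 0.0:
        z, p = float("inf"), 0.0
    else:
        z, p = 0.0, 1.0
    return DTestResult(
        spec=spec,
        sum_abba=sum_abba,
        sum_baba=sum_baba,
        d=d,
        sd_boot=sd_boot,
        z=z,
        p_two_tailed=p,
        n_loci=n_loci,
        pdisc=pdisc,
        significant=p < alpha,
        d_undefined=d_undefined,
    )


def enumerate_tests(
    species: dict[str, str],
    focal_pair: tuple[str, str],
    outgroup_species: set[str],
) -> list[DTestSpec]:
    """All-pairs reciprocal test enumeration for two focal species.

    For each unordered pair within species X (canonically ordered by sample
    id) as (P1, P2) and each individual of species Y as P3, one test; then
    the reciprocal with X and Y swapped.  The outgroup pools every
    individual of the outgroup species.  With 3 + 3 focal individuals this
    yields C(3,2)*3 per direction = 18 tests.
    """
    by_species: dict[str, list[str]] = {}
    for sample, sp in species.items():
        by_species.setdefault(sp, []).append(sample)
    for sp in by_species:
        by_species[sp].sort()
    outgroup = frozenset(
        s for sp in outgroup_species for s in by_species.get(sp, [])
    )
    if not outgroup:
        raise ValueError("no outgroup individuals found")
    specs: list[DTestSpec] = []
    x, y = focal_pair
    for pair_sp, p3_sp in ((x, y), (y, x)):
        pair_inds = by_species.get(pair_sp, [])
        p3_inds = by_species.get(p3_sp, [])
        for p1, p2 in combinations(pair_inds, 2):
            for p3 in p3_inds:
                specs.append(DTestSpec(p1=p1, p2=p2, p3=p3, outgroup=outgroup))
    return specs


def run_all_tests(
    loci: list[OrthologLocus],
    species: dict[str, str],
    focal_pair: tuple[str, str],
    outgroup_species: set[str],
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Run the full reciprocal battery and return a results table."""
    specs = enumerate_tests(species, focal_pair, outgroup_species)
    rows = []
    for i, spec in enumerate(specs, start=1):
        res = bootstrap_test(loci, spec, n_boot=n_boot, seed=seed + i, alpha=alpha)
        rows.append(
            {
                "test": i,
                "P1": spec.p1,
                "P2": spec.p2,
                "P3": spec.p3,
                "O": "+".join(sorted(spec.outgroup)),
                "D": round(res.d, 4),
                "Std(D)": round(res.sd_boot, 4),
                "Z": round(res.z, 2) if np.isfinite(res.z) else np.inf,
                "ABBA": res.sum_abba,
                "BABA": res.sum_baba,
                "n_loci": res.n_loci,
                "pdisc": round(res.pdisc, 4),
                "significant": res.significant,
            }
        )
    return pd.DataFrame(rows)


def d_from_sums(sum_abba: float, sum_baba: float) -> float:
    """D computed directly from pattern sums."""
    denom = sum_abba + sum_baba
    if denom <= 0:
        return 0.0
    return (sum_abba - sum_baba) / denom
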