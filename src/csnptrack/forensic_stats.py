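"""Per-locus forensic parameters and panel-level cumulative statistics.

Conventions follow the forensic desktop tools the panel was characterised
with: match probability, discrimination power, power of exclusion and the
typical paternity index are computed from *observed genotype* frequencies,

    MP  = sum_g f_g^2            DP  = 1 - MP
    PE  = h^2 (1 - 2 h H^2)      TPI = 1 / (2 H)

with h the observed heterozygote proportion and H = 1 - h, while the
polymorphism information content uses *allele* frequencies,

    PIC = 1 - sum_i p_i^2 - sum_{i<j} 2 p_i^2 p_j^2.

Hardy-Weinberg equilibrium is tested exactly for biallelic loci by
enumerating the conditional distribution of heterozygote counts given the
allele counts, and by a seeded Monte-Carlo shuffle of the allele vector for
multi-allelic loci; pairwise inter-locus independence is tested by a seeded
permutation test on the G statistic of the joint genotype table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.special import gammaln

from .model_io import (
    AlleleFrequencySet,
    GenotypeCounts,
    GenotypeTable,
    LocusForensicParams,
    PanelSummary,
)

__all__ = [
    "HweTestResult",
    "PairwiseLdResult",
    "allele_frequencies",
    "match_probability",
    "power_of_exclusion",
    "pic",
    "typical_pi",
    "hwe_exact",
    "pairwise_independence",
    "bonferroni_alpha",
    "panel_summary",
    "locus_params",
]


@dataclass(frozen=True)
class HweTestResult:
    rsid: str
    p_value: float
    method: str  # "exact-enumeration" | "monte-carlo"
    n_steps: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"{self.rsid}: p={self.p_value} outside [0,1]")


@dataclass(frozen=True)
class PairwiseLdResult:
    locus_a: str
    locus_b: str
    p_value: float
    n_permutations: int
    seed: int
    bonferroni_alpha: float


def allele_frequencies(counts: GenotypeCounts) -> AlleleFrequencySet:
    """Allele frequencies by gene counting: count / (2 x genotypes)."""
    n = counts.n
    if n == 0:
        raise ValueError(f"{counts.rsid}: no called genotypes")
    ac = counts.allele_counts
    return AlleleFrequencySet(
        rsid=counts.rsid,
        freqs={a: c / (2 * n) for a, c in ac.items()},
        n_samples=n,
    )


def match_probability(counts: GenotypeCounts) -> tuple[float, float]:
    """(MP, DP): the chance two random individuals share a genotype, and 1 - MP."""
    mp = sum(f * f for f in counts.genotype_freqs.values())
    return mp, 1.0 - mp


def power_of_exclusion(counts: GenotypeCounts) -> float:
    """PE = h^2 (1 - 2 h H^2) from the observed heterozygote proportion h."""
    h = counts.het_freq
    H = 1.0 - h
    return h * h * (1.0 - 2.0 * h * H * H)


def pic(freqs: AlleleFrequencySet) -> float:
    """Polymorphism information content from allele frequencies."""
    p = list(freqs.freqs.values())
    s2 = sum(x * x for x in p)
    cross = sum(2.0 * p[i] ** 2 * p[j] ** 2 for i, j in combinations(range(len(p)), 2))
    return 1.0 - s2 - cross


def typical_pi(counts: GenotypeCounts) -> float:
    """TPI = 1 / (2 H); +inf (with a warning) when no homozygotes were seen."""
    H = counts.hom_freq
    if H == 0.0:
        warnings.warn(
            f"{counts.rsid}: no homozygotes observed, TPI is infinite", stacklevel=2
        )
        return math.inf
    return 1.0 / (2.0 * H)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def _log_table_prob(het: int, n_a: int, n: int) -> float:
    """log P(het | allele count n_a, sample size n) under HWE (biallelic).

    Conditional (Levene) distribution:
    P = n! / (hom_a! het! hom_b!) * n_a! n_b! / (2n)! * 2^het
    """
    n_b = 2 * n - n_a
    hom_a = (n_a - het) // 2
    hom_b = (n_b - het) // 2
    return (
        gammaln(n + 1)
        - gammaln(hom_a + 1)
        - gammaln(het + 1)
        - gammaln(hom_b + 1)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n + 1)
        + het * math.log(2.0)
    )


def _hwe_exact_biallelic(counts: GenotypeCounts) -> float:
    ac = counts.allele_counts
    alleles = sorted(ac)
    a, b = alleles
    n = counts.n
    n_a = ac[a]
    het_obs = sum(c for g, c in counts.counts.items() if len(set(g.split("/"))) == 2)
    # heterozygote count has the parity of n_a and ranges over feasible tables
    n_minor = min(n_a, 2 * n - n_a)
    hets = range(n_minor % 2, n_minor + 1, 2)
    logps = {h: _log_table_prob(h, n_a, n) for h in hets}
    log_obs = logps[het_obs]
    # two-sided exact tail: all tables no more probable than the observed one
    p = sum(math.exp(lp) for lp in logps.values() if lp <= log_obs + 1e-12)
    return min(p, 1.0)


def _genotype_log_prob_given_alleles(counts: GenotypeCounts) -> float:
    """log P(genotype table | allele counts) for any number of alleles."""
    n = counts.n
    ac = counts.allele_counts
    het = sum(c for g, c in counts.counts.items() if len(set(g.split("/"))) == 2)
    lp = gammaln(n + 1) - gammaln(2 * n + 1) + het * math.log(2.0)
    for c in counts.counts.values():
        lp -= gammaln(c + 1)
    for c in ac.values():
        lp += gammaln(c + 1)
    return lp


def _hwe_monte_carlo(
    counts: GenotypeCounts, n_steps: int, seed: int
) -> float:
    rng = np.random.default_rng(seed)
    alleles: list[str] = []
    for g, c in counts.counts.items():
        a, b = g.split("/")
        alleles.extend([a, b] * c)
    vec = np.array(alleles)
    log_obs = _genotype_log_prob_given_alleles(counts)
    hits = 0
    for _ in range(n_steps):
        rng.shuffle(vec)
        pairs = vec.reshape(-1, 2)
        keys: dict[str, int] = {}
        for x, y in pairs:
            k = f"{x}/{y}" if x <= y else f"{y}/{x}"
            keys[k] = keys.get(k, 0) + 1
        lp = _genotype_log_prob_given_alleles(GenotypeCounts(counts.rsid, keys))
        if lp <= log_obs + 1e-12:
            hits += 1
    return (hits + 1) / (n_steps + 1)


def hwe_exact(
    counts: GenotypeCounts, n_steps: int = 100_000, seed: int | None = None
) -> HweTestResult:
    """Exact Hardy-Weinberg test.

    Biallelic loci are tested by full enumeration of the conditional
    heterozygote-count distribution; multi-allelic loci by a seeded
    Monte-Carlo shuffle of the allele vector.  The p-value is the total
    probability of tables no more probable than the observed one.
    """
    if counts.n < 2:
        raise ValueError(f"{counts.rsid}: need at least 2 genotypes")
    k = len(counts.allele_counts)
    if k == 1:
        warnings.warn(f"{counts.rsid}: monomorphic locus, p = 1", stacklevel=2)
        return HweTestResult(counts.rsid, 1.0, "exact-enumeration")
    if k == 2:
        return HweTestResult(
            counts.rsid, _hwe_exact_biallelic(counts), "exact-enumeration"
        )
    if seed is None:
        raise ValueError("multi-allelic Monte-Carlo test needs an explicit seed")
    p = _hwe_monte_carlo(counts, n_steps, seed)
    return HweTestResult(counts.rsid, p, "monte-carlo", n_steps=n_steps, seed=seed)


# ---------------------------------------------------------------------------
# Pairwise independence (linkage equilibrium)


def bonferroni_alpha(n_loci: int, alpha: float = 0.05) -> float:
    """Per-test threshold alpha / C(L, 2) over all locus pairs."""
    m = math.comb(n_loci, 2)
    if m == 0:
        raise ValueError("need at least 2 loci")
    return alpha / m


def _g_statistic(col_a: np.ndarray, col_b: np.ndarray) -> float:
    """G statistic (likelihood-ratio chi-square) of the joint genotype table."""
    ua, ia = np.unique(col_a, return_inverse=True)
    ub, ib = np.unique(col_b, return_inverse=True)
    table = np.zeros((len(ua), len(ub)))
    np.add.at(table, (ia, ib), 1.0)
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    mask = table > 0
    return 2.0 * float((table[mask] * np.log(table[mask] / expected[mask])).sum())


def pairwise_independence(
    table: GenotypeTable,
    n_permutations: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[PairwiseLdResult]:
    """Permutation test of genotype association for every locus pair.

    For each pair, one locus's genotype column is permuted across samples
    ``n_permutations`` times; the p-value is the fraction of permutations
    with a G statistic at least as large as observed (add-one estimator).
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    loci = table.loci
    if len(loci) < 2 or len(table.samples) < 2:
        raise ValueError("need at least 2 loci and 2 samples")
    samples = table.samples
    columns = {
        rs: np.array([str(table.get(s, rs)) for s in samples]) for rs in loci
    }
    m_alpha = bonferroni_alpha(len(loci), alpha)
    rng = np.random.default_rng(seed)
    results = []
    for a, b in combinations(loci, 2):
        col_a, col_b = columns[a], columns[b]
        called = (col_a != ".") & (col_b != ".")
        ca, cb = col_a[called], col_b[called]
        g_obs = _g_statistic(ca, cb)
        hits = 0
        cb_perm = cb.copy()
        for _ in range(n_permutations):
            rng.shuffle(cb_perm)
            if _g_statistic(ca, cb_perm) >= g_obs - 1e-12:
                hits += 1
        p = (hits + 1) / (n_permutations + 1)
        results.append(
            PairwiseLdResult(a, b, p, n_permutations, seed, m_alpha)
        )
    return results


# ---------------------------------------------------------------------------
# Panel-level summaries


def panel_summary(params: list[LocusForensicParams]) -> PanelSummary:
    """Cumulative panel statistics from per-locus forensic parameters."""
    if not params:
        raise ValueError("no loci")
    log_mp = sum(math.log(p.mp) for p in params)
    cumulative_mp = math.exp(log_mp)
    combined_pe = 1.0 - math.exp(sum(math.log1p(-p.pe) for p in params))
    combined_dp_published = 1.0 - math.exp(sum(math.log(p.dp) for p in params))
    dps = [p.dp for p in params]
    pes = [p.pe for p in params]
    return PanelSummary(
        cumulative_mp=cumulative_mp,
        combined_pe=combined_pe,
        combined_dp_standard=1.0 - cumulative_mp,
        combined_dp_published=combined_dp_published,
        mean_dp=sum(dps) / len(dps),
        mean_pe=sum(pes) / len(pes),
        dp_range=(min(dps), max(dps)),
        pe_range=(min(pes), max(pes)),
        n_loci=len(params),
    )


def locus_params(
    counts: GenotypeCounts, n_steps: int = 100_000, seed: int | None = 0
) -> LocusForensicParams:
    """All per-locus forensic parameters from observed genotype counts."""
    mp, dp = match_probability(counts)
    freqs = allele_frequencies(counts)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tpi = typical_pi(counts)
        hwe = hwe_exact(counts, n_steps=n_steps, seed=seed)
    return LocusForensicParams(
        rsid=counts.rsid,
        mp=mp,
        dp=dp,
        pe=power_of_exclusion(counts),
        pic=pic(freqs),
        tpi=tpi,
        hwe_p=hwe.p_value,
    )
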