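"""Mendelian consistency, paternity indices, and identity likelihood ratios.

Paternity indices use the standard no-mutation formulas.  With T(x | G)
the transmission probability of allele x from genotype G (1 for a
homozygote carrying x, 1/2 for a heterozygote carrying x, 0 otherwise):

single parent (duo), child a/a:   PI = T(a | parent) / p_a
single parent (duo), child a/b:   PI = [T(a|parent) p_b + T(b|parent) p_a]
                                       / (2 p_a p_b)
known other parent (trio):        PI = sum over (maternal, paternal)
                                       reconstructions of
                                       T(m|mother) T(f|father) divided by
                                       the same sum with T(f|father)
                                       replaced by p_f.

The combined paternity index (CPI) is the product over loci, accumulated
in log space.  An excluding locus (no shared allele in duo mode, no valid
reconstruction in trio mode) gives PI = 0 and forces CPI = 0; the panel
was validated on families without mutations, so no mutation model is
applied.  Identity evidence follows the likelihood-ratio formulation: a
profile's random-match probability is the product of per-locus HWE
genotype probabilities (p^2 for homozygotes, 2pq for heterozygotes), and
the identity LR of a full match is its reciprocal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

from .model_io import (
    AlleleFrequencySet,
    Genotype,
    IdentityResult,
    KinshipResult,
)

__all__ = [
    "PedigreeCase",
    "mendelian_consistent",
    "duo_pi",
    "trio_pi",
    "cpi",
    "identity_lr",
    "compare_profiles",
    "harmonize_genotype",
    "harmonize_profile",
]

Profile = Mapping[str, Genotype]
FreqMap = Mapping[str, AlleleFrequencySet]


@dataclass(frozen=True)
class PedigreeCase:
    """A child, an alleged parent, an optional second parent, and frequencies."""

    child: Profile
    parent: Profile
    second_parent: Profile | None
    freqs: FreqMap

    def shared_loci(self) -> list[str]:
        loci = [rs for rs in self.child if rs in self.parent and rs in self.freqs]
        if self.second_parent is not None:
            loci = [rs for rs in loci if rs in self.second_parent]
        return loci


def harmonize_genotype(genotype: Genotype, freqs: AlleleFrequencySet) -> Genotype:
    """Map a genotype onto the reference allele set, complementing if needed.

    Sequencing pipelines may report a locus on the opposite strand to the
    frequency reference (the packaged trio read counts do, at several
    loci).  If any allele is absent from the reference set the whole
    genotype is complemented — a single per-locus strand flip; if it still
    does not fit, an error names the locus.
    """
    if genotype.is_missing:
        return genotype
    alleles = set(freqs.alleles)
    if set(genotype.alleles) <= alleles:
        return genotype
    flipped = genotype.complement()
    if set(flipped.alleles) <= alleles:
        return flipped
    raise ValueError(
        f"{freqs.rsid}: genotype {genotype} not resolvable against alleles "
        f"{'/'.join(freqs.alleles)} on either strand"
    )


def harmonize_profile(profile: Profile, freqs: FreqMap) -> dict[str, Genotype]:
    """Strand-harmonize every genotype in a profile against the reference."""
    return {
        rs: harmonize_genotype(g, freqs[rs]) if rs in freqs else g
        for rs, g in profile.items()
    }


def mendelian_consistent(
    child: Genotype, parent1: Genotype, parent2: Genotype | None = None
) -> bool | None:
    """Mendelian-transmission check; returns None when any genotype is missing.

    Duo: the child and parent share at least one allele.  Trio: there is
    an assignment of one child allele to each parent.
    """
    if child.is_missing or parent1.is_missing:
        return None
    if parent2 is None:
        return any(parent1.count(a) > 0 for a in child.alleles)
    if parent2.is_missing:
        return None
    a, b = child.alleles
    for x, y in ((a, b), (b, a)):
        if parent1.count(x) > 0 and parent2.count(y) > 0:
            return True
    return False


def _transmission(allele: str, genotype: Genotype) -> float:
    return genotype.count(allele) / 2.0


def _check_freqs(genotype: Genotype, freqs: AlleleFrequencySet) -> None:
    for a in genotype.alleles:
        if freqs.freqs.get(a, 0.0) == 0.0:
            raise ValueError(
                f"{freqs.rsid}: allele {a} has zero frequency; consider a "
                f"frequency floor (e.g. 5/(2n))"
            )


def duo_pi(child: Genotype, parent: Genotype, freqs: AlleleFrequencySet) -> float:
    """Single-parent paternity index; 0 when the pair shares no allele."""
    _check_freqs(child, freqs)
    a, b = child.alleles
    if a == b:
        return _transmission(a, parent) / freqs[a]
    num = _transmission(a, parent) * freqs[b] + _transmission(b, parent) * freqs[a]
    return num / (2.0 * freqs[a] * freqs[b])


def trio_pi(
    child: Genotype,
    mother: Genotype,
    alleged_father: Genotype,
    freqs: AlleleFrequencySet,
) -> float:
    """Paternity index with the mother known.

    Raises when mother and child are themselves incompatible (the paternal
    allele is then undefined).
    """
    _check_freqs(child, freqs)
    a, b = child.alleles
    reconstructions = [(a, b)] if a == b else [(a, b), (b, a)]
    num = 0.0
    den = 0.0
    for mat, pat in reconstructions:
        t_m = _transmission(mat, mother)
        num += t_m * _transmission(pat, alleged_father)
        den += t_m * freqs[pat]
    if den == 0.0:
        raise ValueError(
            f"{freqs.rsid}: mother-child exclusion, paternity index undefined"
        )
    return num / den


def cpi(case: PedigreeCase, mode: str = "duo") -> KinshipResult:
    """Per-locus paternity indices and their product over the shared loci.

    Profiles are strand-harmonized against the frequency reference first.
    Loci missing in any involved profile are skipped and reported; in trio
    mode a mother-child exclusion makes the locus undefined and it is
    skipped with a warning.
    """
    if mode not in ("duo", "trio"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "trio" and case.second_parent is None:
        raise ValueError("trio mode needs a second parent profile")
    loci = case.shared_loci()
    if not loci:
        raise ValueError("no shared loci between profiles and frequency reference")

    child = harmonize_profile(case.child, case.freqs)
    parent = harmonize_profile(case.parent, case.freqs)
    second = (
        harmonize_profile(case.second_parent, case.freqs)
        if case.second_parent is not None
        else None
    )

    per_locus: dict[str, float] = {}
    consistent: dict[str, bool] = {}
    skipped: list[str] = []
    for rs in loci:
        c, p = child[rs], parent[rs]
        s = second[rs] if second is not None else None
        if c.is_missing or p.is_missing or (mode == "trio" and s.is_missing):
            skipped.append(rs)
            continue
        f = case.freqs[rs]
        if mode == "duo":
            pi = duo_pi(c, p, f)
            consistent[rs] = mendelian_consistent(c, p) is True
        else:
            try:
                pi = trio_pi(c, s, p, f)
            except ValueError:
                warnings.warn(
                    f"{rs}: mother-child exclusion, locus skipped from CPI",
                    stacklevel=2,
                )
                skipped.append(rs)
                continue
            consistent[rs] = mendelian_consistent(c, p, s) is True
        per_locus[rs] = pi
    if not per_locus:
        raise ValueError("no usable loci (all missing or undefined)")
    return KinshipResult(
        case_type=mode,
        per_locus_pi=per_locus,
        consistent=consistent,
        skipped_loci=tuple(skipped),
    )


def identity_lr(profile: Profile, freqs: FreqMap) -> IdentityResult:
    """Random-match probability of a profile and its identity LR (1/RMP).

    Missing genotypes and loci without frequencies are skipped and
    reported.  The product accumulates in log space.
    """
    log_rmp = 0.0
    used: list[str] = []
    nocall: list[str] = []
    for rs, g in profile.items():
        if rs not in freqs:
            nocall.append(rs)
            continue
        g = harmonize_genotype(g, freqs[rs])
        if g.is_missing:
            nocall.append(rs)
            continue
        f = freqs[rs]
        _check_freqs(g, f)
        a, b = g.alleles
        pr = f[a] * f[a] if a == b else 2.0 * f[a] * f[b]
        log_rmp += math.log(pr)
        used.append(rs)
    if not used:
        raise ValueError("no called loci with frequencies in profile")
    rmp = math.exp(log_rmp)
    return IdentityResult(
        rmp=rmp,
        lr=math.exp(-log_rmp),
        matching_loci=tuple(used),
        nocall_loci=tuple(nocall),
    )


def compare_profiles(
    a: Profile, b: Profile, freqs: FreqMap | None = None
) -> IdentityResult:
    """Concordance of two profiles: per-locus match/mismatch/no-call tally.

    The LR is 1/RMP(a) over the compared loci when every shared called
    locus matches (requires ``freqs``), and 0 on any mismatch.  Genotypes
    are strand-harmonized before comparison when frequencies are given.
    """
    shared = [rs for rs in a if rs in b]
    if not shared:
        raise ValueError("profiles share no loci")
    matches: list[str] = []
    mismatches: list[str] = []
    nocalls: list[str] = []
    for rs in shared:
        ga, gb = a[rs], b[rs]
        if freqs is not None and rs in freqs:
            ga = harmonize_genotype(ga, freqs[rs])
            gb = harmonize_genotype(gb, freqs[rs])
        if ga.is_missing or gb.is_missing:
            nocalls.append(rs)
        elif ga == gb:
            matches.append(rs)
        else:
            mismatches.append(rs)
    if mismatches or freqs is None or not matches:
        return IdentityResult(
            rmp=math.nan if freqs is None else 0.0,
            lr=0.0,
            matching_loci=tuple(matches),
            mismatching_loci=tuple(mismatches),
            nocall_loci=tuple(nocalls),
        )
    matched_profile = {rs: a[rs] for rs in matches}
    base = identity_lr(matched_profile, freqs)
    return IdentityResult(
        rmp=base.rmp,
        lr=base.lr,
        matching_loci=tuple(matches),
        mismatching_loci=(),
        nocall_loci=tuple(nocalls),
    )
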