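"""Seeded synthetic-data generators for the whole toolkit.

Genotypes are drawn under Hardy-Weinberg equilibrium from per-locus
allele frequencies (defaulting to the published panel's observed
frequencies in the study population); trios follow Mendelian transmission
with an optional per-allele mutation rate (default 0, matching the
mutation-free families the panel was validated on); reads are single-end
sequences drawn over per-locus flanking templates with a uniform per-base
substitution error rate.  Every generator is a pure function of its
configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model_io import (
    AlleleFrequencySet,
    Genotype,
    GenotypeTable,
    LocusDef,
    load_panel_frequencies,
)

__all__ = ["SimConfig", "sim_genotypes", "sim_trio", "sim_reads", "sim_panel_loci"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the generators.

    Defaults mirror the published panel's characterisation: the observed
    allele frequencies of the 22 markers, 114 unrelated individuals, and
    mutation-free transmission.  Read simulation defaults to 100-base
    single-end reads at 30x per allele copy with error-free bases.
    """

    seed: int
    n_individuals: int = 114
    freqs: tuple[AlleleFrequencySet, ...] = ()
    coverage: int = 30
    error_rate: float = 0.0
    read_length: int = 100
    mutation_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.coverage < 1:
            raise ValueError("coverage must be >= 1")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError("error rate must be in [0, 0.1]")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation rate must be in [0, 1]")
        if not self.freqs:
            object.__setattr__(
                self, "freqs", tuple(load_panel_frequencies())
            )

    def freq_map(self) -> dict[str, AlleleFrequencySet]:
        return {f.rsid: f for f in self.freqs}


def _draw_allele(rng: np.random.Generator, freqs: AlleleFrequencySet) -> str:
    alleles = list(freqs.alleles)
    p = np.array([freqs[a] for a in alleles], dtype=float)
    p = p / p.sum()
    return alleles[int(rng.choice(len(alleles), p=p))]


def sim_genotypes(cfg: SimConfig) -> GenotypeTable:
    """HWE genotypes for ``n_individuals`` at every configured locus.

    Each genotype is two independent allele draws from the locus's
    frequencies (random mating, no inbreeding).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_individuals
    samples = [f"ind{i:04d}" for i in range(n)]
    table = GenotypeTable(provenance="simulated")
    for fs in cfg.freqs:
        alleles = list(fs.alleles)
        p = np.array([fs[a] for a in alleles], dtype=float)
        draws = rng.choice(len(alleles), size=(n, 2), p=p / p.sum())
        for sample, (i, j) in zip(samples, draws):
            table.set(sample, fs.rsid, Genotype(alleles[i], alleles[j]))
    return table


def _transmit(rng: np.random.Generator, parent: Genotype, fs: AlleleFrequencySet, mu: float) -> str:
    allele = parent.alleles[int(rng.integers(2))]
    if mu > 0.0 and rng.random() < mu:
        others = [a for a in fs.alleles if a != allele]
        if others:
            allele = others[int(rng.integers(len(others)))]
    return allele


def sim_trio(
    cfg: SimConfig,
) -> tuple[dict[str, Genotype], dict[str, Genotype], dict[str, Genotype]]:
    """(child, mother, father) profiles: HWE parents, Mendelian child."""
    rng = np.random.default_rng(cfg.seed)
    mother: dict[str, Genotype] = {}
    father: dict[str, Genotype] = {}
    child: dict[str, Genotype] = {}
    for fs in cfg.freqs:
        m = Genotype(_draw_allele(rng, fs), _draw_allele(rng, fs))
        f = Genotype(_draw_allele(rng, fs), _draw_allele(rng, fs))
        c = Genotype(
            _transmit(rng, m, fs, cfg.mutation_rate),
            _transmit(rng, f, fs, cfg.mutation_rate),
        )
        mother[fs.rsid], father[fs.rsid], child[fs.rsid] = m, f, c
    return child, mother, father


def sim_panel_loci(cfg: SimConfig, flank_length: int = 400) -> list[LocusDef]:
    """Panel definitions with pseudo-random flanking sequences.

    Flanks are generated per locus from the configuration seed (reference
    genome not required); chromosome/position are synthetic placeholders.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xF1A]))
    loci = []
    for i, fs in enumerate(cfg.freqs):
        up = "".join(rng.choice(_BASES, size=flank_length))
        down = "".join(rng.choice(_BASES, size=flank_length))
        loci.append(
            LocusDef(
                rsid=fs.rsid,
                chrom=str(i + 1),
                pos=1_000_000 * (i + 1),
                ref_alleles=tuple(fs.alleles),
                annotation="synonymous",
                upstream_flank=up,
                downstream_flank=down,
            )
        )
    return loci


def sim_reads(
    profile: dict[str, Genotype],
    loci: list[LocusDef],
    cfg: SimConfig,
) -> list[tuple[str, str]]:
    """Single-end reads covering each variant, as (read id, sequence) pairs.

    Per locus and allele copy, ``coverage`` reads are drawn from the
    flank+allele+flank template with uniform start positions constrained
    to overlap the variant base, then per-base substitution errors are
    applied at ``error_rate``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5EAD]))
    by_rsid = {d.rsid: d for d in loci}
    L = cfg.read_length
    reads: list[tuple[str, str]] = []
    for rsid, genotype in profile.items():
        if genotype.is_missing or rsid not in by_rsid:
            continue
        d = by_rsid[rsid]
        if len(d.upstream_flank) < L or len(d.downstream_flank) < L:
            raise ValueError(f"{rsid}: flanks shorter than read length {L}")
        var_pos = len(d.upstream_flank)
        for copy_idx, allele in enumerate(genotype.alleles):
            template = d.upstream_flank + allele + d.downstream_flank
            lo = max(0, var_pos - L + 1)
            starts = rng.integers(lo, var_pos + 1, size=cfg.coverage)
            for j, s in enumerate(starts):
                seq = np.array(list(template[s : s + L]))
                if cfg.error_rate > 0.0:
                    errs = rng.random(len(seq)) < cfg.error_rate
                    if errs.any():
                        subs = rng.choice(_BASES, size=int(errs.sum()))
                        # substitution must change the base
                        cur = seq[errs]
                        clash = subs == cur
                        while clash.any():
                            subs[clash] = rng.choice(_BASES, size=int(clash.sum()))
                            clash = subs == cur
                        seq[errs] = subs
                reads.append((f"{rsid}:{copy_idx}:{j}", "".join(seq)))
    return reads


def write_fastq(reads: list[tuple[str, str]], path) -> None:
    """Write (id, sequence) pairs as FASTQ with uniform placeholder quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
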