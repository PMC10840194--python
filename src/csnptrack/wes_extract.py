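"""Genotype extraction from raw reads by flanking-probe matching.

Each panel locus gets a probe: the k bases immediately upstream (5') of
the variant position.  A read containing the probe as an exact substring
— in either orientation — reports the base it carries at the variant
offset; per-locus tallies of those bases form the read evidence from
which genotypes are called by simple count/fraction thresholds.  Exact
matching is sufficient because panel loci are chosen to have unique,
variant-free +/-400 bp flanks; a Hamming-distance-1 tolerant mode is
available for noisier data.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio.Seq import reverse_complement

from .model_io import BASES, Genotype, GenotypeTable, LocusDef, ReadEvidence

__all__ = [
    "LocusProbe",
    "CallThresholds",
    "probes_from_loci",
    "count_alleles",
    "call_genotype",
    "extract_profile",
    "read_sequences",
]


@dataclass(frozen=True)
class LocusProbe:
    """An exact-match probe ending immediately 5' of the variant base."""

    rsid: str
    sequence: str
    variant_offset: int | None = None  # offset of the variant base after the probe

    def __post_init__(self) -> None:
        if len(self.sequence) < 12:
            raise ValueError(f"{self.rsid}: probe shorter than 12 bases")
        if not set(self.sequence) <= BASES:
            raise ValueError(f"{self.rsid}: probe contains non-ACGT bases")

    @property
    def rc_sequence(self) -> str:
        return reverse_complement(self.sequence)


@dataclass(frozen=True)
class CallThresholds:
    """Allele-calling filters applied to per-locus read counts."""

    min_reads_per_allele: int = 3
    min_allele_fraction: float = 0.15
    min_total_reads: int = 6

    def __post_init__(self) -> None:
        if min(self.min_reads_per_allele, self.min_total_reads) < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0.0 <= self.min_allele_fraction <= 0.5:
            raise ValueError("min_allele_fraction must be in [0, 0.5]")


def probes_from_loci(loci: Iterable[LocusDef], k: int = 20) -> list[LocusProbe]:
    """Build probes from the last k upstream-flank bases of each locus."""
    probes = []
    for d in loci:
        if len(d.upstream_flank) < k:
            raise ValueError(f"{d.rsid}: upstream flank shorter than k={k}")
        probes.append(LocusProbe(d.rsid, d.upstream_flank[-k:]))
    return probes


def read_sequences(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a FASTA/FASTQ file (gzip transparent)."""
    from Bio import SeqIO

    path = Path(path)
    name = path.name.removesuffix(".gz")
    fmt = "fastq" if name.endswith((".fq", ".fastq")) else "fasta"
    opener = gzip.open if path.name.endswith(".gz") else open
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, fmt):
            yield str(rec.seq).upper()


def count_alleles(
    reads: Iterable[str], probes: list[LocusProbe], max_mismatch: int = 0
) -> dict[str, ReadEvidence]:
    """Tally the base following each probe over all reads.

    Each read contributes at most once per locus: the forward orientation
    is tried first, then the reverse complement.  Non-ACGT observed bases
    are tallied separately in ``ReadEvidence.other``.
    """
    seen = set()
    for p in probes:
        if p.rsid in seen:
            raise ValueError(f"duplicate probe for {p.rsid}")
        seen.add(p.rsid)
    counts: dict[str, dict[str, int]] = {p.rsid: {} for p in probes}
    other: dict[str, int] = {p.rsid: 0 for p in probes}
    finders = [
        (p.rsid, p.sequence, p.rc_sequence, len(p.sequence)) for p in probes
    ]
    for read in reads:
        for rsid, fwd, rc, k in finders:
            base = _base_after_probe(read, fwd, k, max_mismatch)
            if base is None:
                # a probe match on the opposite strand: the base preceding
                # the reverse-complemented probe, complemented back
                base = _base_before_probe(read, rc, max_mismatch)
            if base is None:
                continue
            if base in BASES:
                counts[rsid][base] = counts[rsid].get(base, 0) + 1
            else:
                other[rsid] += 1
    return {
        rsid: ReadEvidence(rsid, counts[rsid], other=other[rsid])
        for rsid in counts
    }


def _find(read: str, probe: str, max_mismatch: int) -> int:
    if max_mismatch == 0:
        return read.find(probe)
    k = len(probe)
    for i in range(len(read) - k + 1):
        mism = 0
        for a, b in zip(read[i : i + k], probe):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            return i
    return -1


def _base_after_probe(read: str, probe: str, k: int, max_mismatch: int) -> str | None:
    i = _find(read, probe, max_mismatch)
    if i < 0 or i + k >= len(read):
        return None
    return read[i + k]


_RC = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _base_before_probe(read: str, rc_probe: str, max_mismatch: int) -> str | None:
    i = _find(read, rc_probe, max_mismatch)
    if i <= 0:
        return None
    base = read[i - 1]
    return _RC.get(base, base)


def call_genotype(
    evidence: ReadEvidence, thresholds: CallThresholds = CallThresholds()
) -> tuple[Genotype, str]:
    """Call a genotype from allele read counts; returns (genotype, reason).

    Alleles below the count or fraction thresholds are dropped; the call
    is a no-call when too few reads survive, and a flagged no-call
    (possible contamination) when more than two alleles survive.
    """
    total = evidence.total
    surviving = {
        a: c
        for a, c in evidence.counts.items()
        if c >= thresholds.min_reads_per_allele
        and (total == 0 or c / total >= thresholds.min_allele_fraction)
    }
    n_reads = sum(surviving.values())
    if not surviving or n_reads < thresholds.min_total_reads:
        return Genotype.missing(), "insufficient-reads"
    alleles = sorted(surviving)
    if len(alleles) == 1:
        return Genotype(alleles[0], alleles[0]), "ok"
    if len(alleles) == 2:
        return Genotype(alleles[0], alleles[1]), "ok"
    return Genotype.missing(), "anomaly:more-than-two-alleles"


def extract_profile(
    reads: Iterable[str],
    probes: list[LocusProbe],
    thresholds: CallThresholds = CallThresholds(),
    sample_id: str = "sample",
    max_mismatch: int = 0,
) -> tuple[GenotypeTable, dict[str, ReadEvidence], dict[str, str]]:
    """Extract one sample's panel profile from raw reads.

    Returns the called profile (as a one-sample :class:`GenotypeTable`
    with provenance ``"wes"``), the per-locus read evidence, and a map of
    per-locus call reasons for no-calls/anomalies.
    """
    evidence = count_alleles(reads, probes, max_mismatch=max_mismatch)
    if all(ev.total == 0 for ev in evidence.values()):
        warnings.warn("no reads matched any probe; profile is all-missing", stacklevel=2)
    table = GenotypeTable(provenance="wes")
    reasons: dict[str, str] = {}
    for rsid, ev in evidence.items():
        genotype, reason = call_genotype(ev, thresholds)
        table.set(sample_id, rsid, genotype)
        if reason != "ok":
            reasons[rsid] = reason
    return table, evidence, reasons
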