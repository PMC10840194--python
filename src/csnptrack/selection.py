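"""Two-stage coding-SNP screening pipeline over variant tables.

The pipeline mirrors how the published 22-marker panel was chosen from an
exome variant database:

1. primary screen — synonymous SNPs with MAF >= 0.3 or at least 3 alleles;
2. refined screen — biallelic MAF >= 0.4 or triallelic MAF >= 0.1, no
   other variant within +/-400 bp, flank maps uniquely;
3. ranking — per autosomal chromosome, keep the top six by MAF
   (multi-allelic variants always retained) subject to >10 Mb pairwise
   spacing, then emit the single best marker per chromosome.

The MAF of a multi-allelic site is its smallest allele frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "VariantRecord",
    "SelectionConfig",
    "primary_screen",
    "refine_screen",
    "rank_and_space",
    "select_panel",
    "read_variants_vcf",
]

_AUTOSOMES = {str(i) for i in range(1, 23)}


@dataclass(frozen=True)
class VariantRecord:
    """One SNP site with population allele frequencies and annotation."""

    rsid: str
    chrom: str
    pos: int
    freqs: dict[str, float]  # allele -> frequency
    annotation: str = ""
    unique_flank: bool = True

    def __post_init__(self) -> None:
        if len(self.freqs) < 2:
            raise ValueError(f"{self.rsid}: need >= 2 alleles")
        total = sum(self.freqs.values())
        if abs(total - 1.0) > 1e-4:
            raise ValueError(f"{self.rsid}: frequencies sum to {total}")

    @property
    def n_alleles(self) -> int:
        return len(self.freqs)

    @property
    def maf(self) -> float:
        return min(self.freqs.values())

    @property
    def is_autosomal(self) -> bool:
        return self.chrom.removeprefix("chr") in _AUTOSOMES


@dataclass(frozen=True)
class SelectionConfig:
    primary_maf_min: float = 0.3
    primary_min_alleles: int = 3
    refined_biallelic_maf_min: float = 0.4
    refined_triallelic_maf_min: float = 0.1
    flank_radius_bp: int = 400
    top_k_per_chrom: int = 6
    min_spacing_bp: int = 10_000_000
    final_per_chrom: int = 1

    def __post_init__(self) -> None:
        numeric = (
            self.primary_maf_min,
            self.primary_min_alleles,
            self.refined_biallelic_maf_min,
            self.refined_triallelic_maf_min,
            self.flank_radius_bp,
            self.top_k_per_chrom,
            self.min_spacing_bp,
            self.final_per_chrom,
        )
        if any(v <= 0 for v in numeric):
            raise ValueError("all thresholds must be positive")
        if self.refined_biallelic_maf_min < self.primary_maf_min:
            raise ValueError("refined biallelic MAF threshold below primary")


def primary_screen(
    variants: list[VariantRecord], cfg: SelectionConfig = SelectionConfig()
) -> list[VariantRecord]:
    """Keep synonymous variants with MAF >= threshold or >= 3 alleles."""
    missing = [v.rsid for v in variants if not v.annotation]
    if missing:
        raise ValueError(f"variants without annotation: {', '.join(missing)}")
    return [
        v
        for v in variants
        if v.annotation == "synonymous"
        and (v.maf >= cfg.primary_maf_min or v.n_alleles >= cfg.primary_min_alleles)
    ]


def _flank_clean(
    v: VariantRecord, all_variants: list[VariantRecord], radius: int
) -> bool:
    for other in all_variants:
        if other.chrom != v.chrom:
            continue
        if other.pos == v.pos and other.rsid == v.rsid:
            continue
        if abs(other.pos - v.pos) <= radius:
            return False
    return True


def refine_screen(
    variants: list[VariantRecord],
    all_variants: list[VariantRecord],
    cfg: SelectionConfig = SelectionConfig(),
) -> list[VariantRecord]:
    """Refined MAF rule + variant-free +/-radius flank + unique flank."""
    out = []
    for v in variants:
        if v.n_alleles == 2:
            if v.maf < cfg.refined_biallelic_maf_min:
                continue
        elif v.maf < cfg.refined_triallelic_maf_min:
            continue
        if not v.unique_flank:
            continue
        if not _flank_clean(v, all_variants, cfg.flank_radius_bp):
            continue
        out.append(v)
    return out


def _rank_key(v: VariantRecord) -> tuple:
    # MAF descending, then position ascending, then rsid — deterministic
    return (-v.maf, v.pos, v.rsid)


def rank_and_space(
    variants: list[VariantRecord], cfg: SelectionConfig = SelectionConfig()
) -> list[VariantRecord]:
    """Greedy top-k per autosomal chromosome with pairwise spacing, then one per chromosome.

    Candidates are taken in MAF order (multi-allelic sites first, so they
    are always retained in the candidate set); a candidate is kept only if
    it lies more than ``min_spacing_bp`` from every already-kept candidate
    on the chromosome.  The final panel keeps the best ``final_per_chrom``
    (by the same order) per chromosome.
    """
    if not variants:
        warnings.warn("empty candidate list; empty panel", stacklevel=2)
        return []
    by_chrom: dict[str, list[VariantRecord]] = {}
    for v in variants:
        if not v.is_autosomal:
            continue
        by_chrom.setdefault(v.chrom, []).append(v)
    panel = []
    for chrom in sorted(by_chrom, key=lambda c: int(c.removeprefix("chr"))):
        cands = sorted(
            by_chrom[chrom], key=lambda v: (v.n_alleles <= 2, *_rank_key(v))
        )
        kept: list[VariantRecord] = []
        for v in cands:
            if len(kept) >= cfg.top_k_per_chrom:
                break
            if all(abs(v.pos - u.pos) > cfg.min_spacing_bp for u in kept):
                kept.append(v)
        kept.sort(key=_rank_key)
        panel.extend(kept[: cfg.final_per_chrom])
    return panel


def select_panel(
    variants: list[VariantRecord], cfg: SelectionConfig = SelectionConfig()
) -> list[VariantRecord]:
    """Full pipeline: primary screen, refined screen, rank and space."""
    primary = primary_screen(variants, cfg)
    refined = refine_screen(primary, variants, cfg)
    return rank_and_space(refined, cfg)


def read_variants_vcf(
    path: str | Path,
    af_tag: str = "AF",
    annotation_tag: str = "ANN",
    annotations: dict[str, str] | None = None,
) -> tuple[list[VariantRecord], int]:
    """Read SNP sites from a VCF; returns (records, n_indels_skipped).

    Allele frequencies come from the ``af_tag`` INFO field (ALT allele
    frequencies; the REF frequency is the remainder).  Annotations come
    from ``annotation_tag`` or, if given, from a ``rsid -> label`` sidecar
    mapping.
    """
    from cyvcf2 import VCF

    records: list[VariantRecord] = []
    skipped = 0
    for var in VCF(str(path)):
        alts = var.ALT or []
        if len(var.REF) != 1 or any(len(a) != 1 for a in alts) or not alts:
            skipped += 1
            continue
        af = var.INFO.get(af_tag)
        if af is None:
            raise ValueError(f"{var.CHROM}:{var.POS}: missing INFO/{af_tag}")
        alt_freqs = list(af) if isinstance(af, tuple) else [float(af)]
        freqs = dict(zip(alts, (float(x) for x in alt_freqs)))
        freqs[var.REF] = max(0.0, 1.0 - sum(freqs.values()))
        rsid = var.ID or f"{var.CHROM}:{var.POS}"
        if annotations is not None:
            ann = annotations.get(rsid, "")
        else:
            ann = str(var.INFO.get(annotation_tag) or "")
        records.append(
            VariantRecord(
                rsid=rsid,
                chrom=str(var.CHROM),
                pos=int(var.POS),
                freqs=freqs,
                annotation=ann,
            )
        )
    return records, skipped
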