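"""Domain types and readers/writers shared by every part of the toolkit.

The central objects are small frozen dataclasses: a panel marker
(:class:`LocusDef`), population allele frequencies
(:class:`AlleleFrequencySet`), an unordered genotype (:class:`Genotype`)
and collections of them (:class:`GenotypeTable`, :class:`GenotypeCounts`),
plus result containers for the forensic statistics, kinship and identity
computations.  All tabular I/O is plain TSV (tab-separated, UTF-8, header
row, ``.`` for missing values).

The package ships reference fixtures for the published 22-marker coding-SNP
panel: per-locus forensic parameters, observed and theoretical allele
frequencies in the East-Asian study population, per-locus allele read
counts of a whole-exome-sequenced trio, and the panel's marker definitions
(GRCh37 coordinates).
"""

from __future__ import annotations

import json
import math
import warnings
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "BASES",
    "COMPLEMENT",
    "LocusDef",
    "AlleleFrequencySet",
    "Genotype",
    "GenotypeTable",
    "GenotypeCounts",
    "LocusForensicParams",
    "PanelSummary",
    "ReadEvidence",
    "KinshipResult",
    "IdentityResult",
    "read_frequency_table",
    "write_frequency_table",
    "read_genotype_table",
    "write_genotype_table",
    "read_forensic_params",
    "read_read_evidence",
    "write_read_evidence",
    "write_report",
    "load_panel_loci",
    "load_panel_params",
    "load_panel_frequencies",
    "load_trio_evidence",
]

BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
IUPAC = frozenset("ACGTRYSWKMBDHVN")

MISSING = "."


def _fixture(name: str) -> Path:
    return Path(str(resources.files("csnptrack") / "fixtures" / name))


@dataclass(frozen=True)
class LocusDef:
    """One panel marker: identity, position and sequence context.

    ``pos`` is 1-based on GRCh37.  ``upstream_flank``/``downstream_flank``
    are the bases adjacent to the variant position (at most 400 each) and
    may be empty when only the tabular statistics are needed.
    """

    rsid: str
    chrom: str
    pos: int
    ref_alleles: tuple[str, ...]
    gene: str = ""
    annotation: str = ""
    upstream_flank: str = ""
    downstream_flank: str = ""

    def __post_init__(self) -> None:
        if not 2 <= len(self.ref_alleles) <= 3:
            raise ValueError(f"{self.rsid}: need 2-3 alleles, got {self.ref_alleles}")
        if len(set(self.ref_alleles)) != len(self.ref_alleles):
            raise ValueError(f"{self.rsid}: duplicate alleles {self.ref_alleles}")
        for a in self.ref_alleles:
            if a not in BASES:
                raise ValueError(f"{self.rsid}: invalid allele {a!r}")
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: pos must be >= 1")
        for fl in (self.upstream_flank, self.downstream_flank):
            if len(fl) > 400:
                raise ValueError(f"{self.rsid}: flank longer than 400 bp")
            if not set(fl) <= IUPAC:
                raise ValueError(f"{self.rsid}: flank contains non-IUPAC bases")


@dataclass(frozen=True)
class AlleleFrequencySet:
    """Population allele frequencies at one locus."""

    rsid: str
    freqs: Mapping[str, float]
    n_samples: int | None = None

    # printed tables round to 3 decimals; allow that much slack
    SUM_TOL = 2e-3

    def __post_init__(self) -> None:
        if not self.freqs:
            raise ValueError(f"{self.rsid}: empty frequency set")
        for a, p in self.freqs.items():
            if a not in BASES:
                raise ValueError(f"{self.rsid}: invalid allele {a!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.rsid}: frequency {p} outside [0,1]")
        total = sum(self.freqs.values())
        if abs(total - 1.0) > self.SUM_TOL:
            raise ValueError(
                f"{self.rsid}: allele frequencies sum to {total:.4f}, not 1"
            )
        object.__setattr__(self, "freqs", dict(self.freqs))

    @property
    def alleles(self) -> tuple[str, ...]:
        return tuple(self.freqs)

    @property
    def maf(self) -> float:
        """Minor-allele frequency: the smallest allele proportion, 0 if monomorphic."""
        if len(self.freqs) < 2:
            return 0.0
        return min(self.freqs.values())

    def __getitem__(self, allele: str) -> float:
        return self.freqs[allele]


@dataclass(frozen=True, order=True)
class Genotype:
    """An unordered pair of single-base alleles, or a no-call.

    ``Genotype("A", "C") == Genotype("C", "A")``; homozygotes carry the
    allele twice.  ``Genotype.missing()`` represents a no-call.
    """

    alleles: tuple[str, ...]

    def __init__(self, *alleles: str) -> None:
        if alleles:
            if len(alleles) != 2:
                raise ValueError(f"genotype needs exactly 2 alleles, got {alleles}")
            for a in alleles:
                if a not in BASES:
                    raise ValueError(f"invalid allele {a!r}")
        object.__setattr__(self, "alleles", tuple(sorted(alleles)))

    @classmethod
    def missing(cls) -> "Genotype":
        return cls()

    @property
    def is_missing(self) -> bool:
        return not self.alleles

    @property
    def is_het(self) -> bool:
        return len(self.alleles) == 2 and self.alleles[0] != self.alleles[1]

    @property
    def is_hom(self) -> bool:
        return len(self.alleles) == 2 and self.alleles[0] == self.alleles[1]

    def complement(self) -> "Genotype":
        if self.is_missing:
            return self
        return Genotype(*(COMPLEMENT[a] for a in self.alleles))

    def count(self, allele: str) -> int:
        return self.alleles.count(allele)

    def __str__(self) -> str:
        return "/".join(self.alleles) if self.alleles else MISSING


class GenotypeTable:
    """Per-sample, per-locus genotypes: ``table[sample][rsid] -> Genotype``."""

    def __init__(
        self,
        data: Mapping[str, Mapping[str, Genotype]] | None = None,
        provenance: str = "",
    ) -> None:
        self._data: dict[str, dict[str, Genotype]] = {
            s: dict(loci) for s, loci in (data or {}).items()
        }
        self.provenance = provenance

    def set(self, sample: str, rsid: str, genotype: Genotype) -> None:
        self._data.setdefault(sample, {})[rsid] = genotype

    def __getitem__(self, sample: str) -> dict[str, Genotype]:
        return self._data[sample]

    def get(self, sample: str, rsid: str) -> Genotype:
        return self._data.get(sample, {}).get(rsid, Genotype.missing())

    @property
    def samples(self) -> list[str]:
        return list(self._data)

    @property
    def loci(self) -> list[str]:
        seen: dict[str, None] = {}
        for loci in self._data.values():
            for rsid in loci:
                seen.setdefault(rsid)
        return list(seen)

    def profile(self, sample: str) -> dict[str, Genotype]:
        return dict(self._data[sample])

    def validate_against(self, panel: Iterable[LocusDef]) -> None:
        """Every rsid in the table must belong to the panel."""
        known = {d.rsid for d in panel}
        extra = sorted(set(self.loci) - known)
        if extra:
            raise ValueError(f"loci not in panel: {', '.join(extra)}")

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenotypeTable) and self._data == other._data

    def __len__(self) -> int:
        return len(self._data)

    def items(self):
        return self._data.items()


@dataclass(frozen=True)
class GenotypeCounts:
    """Observed genotype counts at one locus over a population sample."""

    rsid: str
    counts: Mapping[str, int]  # genotype key "A/C" (alleles sorted) -> count

    def __post_init__(self) -> None:
        cleaned: dict[str, int] = {}
        for g, n in self.counts.items():
            if n < 0:
                raise ValueError(f"{self.rsid}: negative count for {g}")
            a, b = sorted(g.split("/"))
            cleaned["/".join((a, b))] = cleaned.get(f"{a}/{b}", 0) + n
        object.__setattr__(self, "counts", cleaned)

    @classmethod
    def from_genotypes(cls, rsid: str, genotypes: Iterable[Genotype]) -> "GenotypeCounts":
        counts: dict[str, int] = {}
        for g in genotypes:
            if g.is_missing:
                continue
            counts[str(g)] = counts.get(str(g), 0) + 1
        return cls(rsid, counts)

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def genotype_freqs(self) -> dict[str, float]:
        n = self.n
        if n == 0:
            raise ValueError(f"{self.rsid}: no called genotypes")
        return {g: c / n for g, c in self.counts.items()}

    @property
    def het_freq(self) -> float:
        """Observed heterozygote proportion h (homozygote proportion is 1 - h)."""
        n = self.n
        if n == 0:
            raise ValueError(f"{self.rsid}: no called genotypes")
        het = sum(c for g, c in self.counts.items() if len(set(g.split("/"))) == 2)
        return het / n

    @property
    def hom_freq(self) -> float:
        return 1.0 - self.het_freq

    @property
    def allele_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for g, c in self.counts.items():
            for a in g.split("/"):
                out[a] = out.get(a, 0) + c
        return out


@dataclass(frozen=True)
class LocusForensicParams:
    """Per-locus forensic parameters (one row of the published panel table)."""

    rsid: str
    mp: float
    dp: float
    pe: float
    pic: float
    tpi: float
    hwe_p: float

    def __post_init__(self) -> None:
        for name in ("mp", "dp", "pe", "pic", "hwe_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.rsid}: {name}={v} outside [0,1]")
        if self.tpi <= 0:
            raise ValueError(f"{self.rsid}: TPI must be positive")
        # allow print rounding between MP and DP columns
        if abs(self.mp + self.dp - 1.0) > 1.5e-3:
            raise ValueError(f"{self.rsid}: MP + DP = {self.mp + self.dp} != 1")


@dataclass(frozen=True)
class PanelSummary:
    """Panel-level cumulative statistics over a set of locus parameters.

    Two combined-discrimination-power variants are kept: the standard
    ``1 - prod(MP)`` and the alternative ``1 - prod(DP)`` that matches how
    the published panel's combined DP was evidently computed.
    """

    cumulative_mp: float
    combined_pe: float
    combined_dp_standard: float
    combined_dp_published: float
    mean_dp: float
    mean_pe: float
    dp_range: tuple[float, float]
    pe_range: tuple[float, float]
    n_loci: int

    def to_dict(self) -> dict:
        return {
            "n_loci": self.n_loci,
            "cumulative_mp": self.cumulative_mp,
            "combined_pe": self.combined_pe,
            "combined_dp_standard": self.combined_dp_standard,
            "combined_dp_published": self.combined_dp_published,
            "mean_dp": self.mean_dp,
            "mean_pe": self.mean_pe,
            "dp_range": list(self.dp_range),
            "pe_range": list(self.pe_range),
        }


@dataclass(frozen=True)
class ReadEvidence:
    """Per-locus allele read counts extracted from sequencing reads."""

    rsid: str
    counts: Mapping[str, int]
    other: int = 0  # reads whose base at the variant offset is not A/C/G/T

    def __post_init__(self) -> None:
        for a, c in self.counts.items():
            if len(a) != 1:
                raise ValueError(f"{self.rsid}: allele {a!r} is not a single base")
            if c < 0:
                raise ValueError(f"{self.rsid}: negative count for {a}")
        object.__setattr__(self, "counts", dict(self.counts))

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class KinshipResult:
    """Per-locus paternity indices and their product (CPI)."""

    case_type: str  # "duo" | "trio"
    per_locus_pi: Mapping[str, float]
    consistent: Mapping[str, bool]
    skipped_loci: tuple[str, ...] = ()

    @property
    def cpi(self) -> float:
        log_sum = 0.0
        for pi in self.per_locus_pi.values():
            if pi == 0.0:
                return 0.0
            log_sum += math.log(pi)
        return math.exp(log_sum)

    @property
    def excluding_loci(self) -> tuple[str, ...]:
        return tuple(rs for rs, ok in self.consistent.items() if not ok)

    @property
    def n_excluding(self) -> int:
        return len(self.excluding_loci)

    def to_dict(self) -> dict:
        return {
            "case_type": self.case_type,
            "cpi": self.cpi,
            "n_loci": len(self.per_locus_pi),
            "per_locus_pi": dict(self.per_locus_pi),
            "excluding_loci": list(self.excluding_loci),
            "skipped_loci": list(self.skipped_loci),
        }


@dataclass(frozen=True)
class IdentityResult:
    """Random-match probability of a profile and the identity likelihood ratio.

    Under the prosecution hypothesis (Hp) the questioned sample and the
    reference come from the same person, so a full genotype match has
    probability 1; under the defense hypothesis (Hd) the questioned sample
    comes from an unrelated individual, so the match probability is the
    profile's random-match probability.  Hence LR = 1/RMP on a full match
    and 0 as soon as any compared locus mismatches.
    """

    rmp: float
    lr: float
    mismatching_loci: tuple[str, ...] = ()
    matching_loci: tuple[str, ...] = ()
    nocall_loci: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "rmp": self.rmp,
            "lr": self.lr,
            "matching_loci": list(self.matching_loci),
            "mismatching_loci": list(self.mismatching_loci),
            "nocall_loci": list(self.nocall_loci),
        }


# ---------------------------------------------------------------------------
# TSV readers / writers


def read_frequency_table(
    path: str | Path, column: str = "frequency"
) -> list[AlleleFrequencySet]:
    """Read a long-form allele-frequency TSV (rsid, allele, frequency).

    ``column`` selects which frequency column to use when the file carries
    several (the packaged fixture also stores a theoretical column).
    Duplicate (rsid, allele) rows and per-locus sums off 1 raise.
    """
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "allele": str})
    required = {"rsid", "allele", column}
    if not required <= set(df.columns):
        raise ValueError(f"frequency table needs columns {sorted(required)}")
    if df.duplicated(["rsid", "allele"]).any():
        dups = df[df.duplicated(["rsid", "allele"])]["rsid"].unique()
        raise ValueError(f"duplicate rsid/allele rows for: {', '.join(dups)}")
    out = []
    for rsid, grp in df.groupby("rsid", sort=False):
        freqs = dict(zip(grp["allele"], grp[column].astype(float)))
        try:
            out.append(AlleleFrequencySet(rsid=str(rsid), freqs=freqs))
        except ValueError as exc:
            raise ValueError(f"bad frequencies at {rsid}: {exc}") from exc
    return out


def write_frequency_table(
    freq_sets: Iterable[AlleleFrequencySet], path: str | Path
) -> None:
    rows = [
        {"rsid": fs.rsid, "allele": a, "frequency": p}
        for fs in freq_sets
        for a, p in fs.freqs.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_genotype_table(path: str | Path, provenance: str = "") -> GenotypeTable:
    """Read genotypes from a TSV with columns sample_id, rsid, allele1, allele2.

    Homozygotes are written with the allele twice; an empty/``.`` allele2
    means the genotype is missing (a no-call), never an implied homozygote.
    """
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=[]
    )
    required = {"sample_id", "rsid", "allele1", "allele2"}
    if not required <= set(df.columns):
        raise ValueError(f"genotype table needs columns {sorted(required)}")
    table = GenotypeTable(provenance=provenance)
    for row in df.itertuples(index=False):
        a1 = row.allele1.strip()
        a2 = row.allele2.strip()
        if a1 in ("", MISSING) or a2 in ("", MISSING):
            g = Genotype.missing()
        else:
            g = Genotype(a1, a2)
        table.set(row.sample_id, row.rsid, g)
    return table


def write_genotype_table(table: GenotypeTable, path: str | Path) -> None:
    rows = []
    for sample, loci in table.items():
        for rsid, g in loci.items():
            a1, a2 = (g.alleles if not g.is_missing else (MISSING, MISSING))
            rows.append(
                {"sample_id": sample, "rsid": rsid, "allele1": a1, "allele2": a2}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_forensic_params(path: str | Path) -> list[LocusForensicParams]:
    df = pd.read_csv(path, sep="\t")
    required = {"rsid", "DP", "PE", "MP", "PIC", "TPI", "HWE_p"}
    if not required <= set(df.columns):
        raise ValueError(f"forensic-parameter table needs columns {sorted(required)}")
    return [
        LocusForensicParams(
            rsid=row.rsid,
            mp=row.MP,
            dp=row.DP,
            pe=row.PE,
            pic=row.PIC,
            tpi=row.TPI,
            hwe_p=row.HWE_p,
        )
        for row in df.itertuples(index=False)
    ]


def read_read_evidence(path: str | Path) -> dict[str, dict[str, ReadEvidence]]:
    """Read per-sample, per-locus allele read counts (sample, rsid, allele, count)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "rsid": str, "allele": str})
    required = {"sample", "rsid", "allele", "count"}
    if not required <= set(df.columns):
        raise ValueError(f"read-evidence table needs columns {sorted(required)}")
    out: dict[str, dict[str, ReadEvidence]] = {}
    for (sample, rsid), grp in df.groupby(["sample", "rsid"], sort=False):
        counts = dict(zip(grp["allele"], grp["count"].astype(int)))
        out.setdefault(str(sample), {})[str(rsid)] = ReadEvidence(str(rsid), counts)
    return out


def write_read_evidence(
    evidence: Mapping[str, Mapping[str, ReadEvidence]], path: str | Path
) -> None:
    rows = [
        {"sample": sample, "rsid": rsid, "allele": a, "count": c}
        for sample, loci in evidence.items()
        for rsid, ev in loci.items()
        for a, c in ev.counts.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_report(
    result: PanelSummary | KinshipResult | IdentityResult,
    path: str | Path,
    display_digits: int = 6,
) -> None:
    """Write a result as JSON plus a human-readable text rendering.

    The JSON carries full precision; ``display_digits`` only affects the
    ``.txt`` companion written next to it.
    """
    if isinstance(result, PanelSummary) and result.n_loci == 0:
        raise ValueError("no loci")
    payload = result.to_dict()
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2) + "\n")

    def fmt(v):
        if isinstance(v, float):
            return f"{v:.{display_digits}g}"
        return str(v)

    lines = []
    for key, value in payload.items():
        if isinstance(value, Mapping):
            lines.append(f"{key}:")
            lines.extend(f"  {k}\t{fmt(v)}" for k, v in value.items())
        elif isinstance(value, list):
            lines.append(f"{key}:\t{', '.join(map(str, value)) or '-'}")
        else:
            lines.append(f"{key}:\t{fmt(value)}")
    path.with_suffix(".txt").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Packaged fixtures


def load_panel_loci() -> list[LocusDef]:
    """The 22 published panel markers (GRCh37 coordinates, no flanks)."""
    df = pd.read_csv(_fixture("panel_loci.tsv"), sep="\t", dtype=str)
    return [
        LocusDef(
            rsid=row.rsid,
            chrom=row.chrom,
            pos=int(row.pos),
            ref_alleles=tuple(row.alleles.split("/")),
            gene=row.gene,
            annotation=row.annotation,
        )
        for row in df.itertuples(index=False)
    ]


def load_panel_params() -> list[LocusForensicParams]:
    """Published per-locus forensic parameters of the 22-marker panel."""
    return read_forensic_params(_fixture("panel_forensic_params.tsv"))


def load_panel_frequencies(theoretical: bool = False) -> list[AlleleFrequencySet]:
    """Published allele frequencies of the panel in the study population.

    ``theoretical=True`` returns the reference-population column instead of
    the observed one (stored for completeness; computations use observed).
    """
    column = "theoretical_frequency" if theoretical else "frequency"
    return read_frequency_table(_fixture("panel_allele_freqs.tsv"), column=column)


def load_trio_evidence() -> dict[str, dict[str, ReadEvidence]]:
    """Published per-allele read counts of the whole-exome-sequenced trio.

    Samples are ``C`` (child), ``M`` (mother) and ``F`` (father).  Alleles
    are as printed, i.e. on the sequencing strand; several loci therefore
    need complement harmonization against the frequency reference (see
    :func:`csnptrack.kinship_identity.harmonize_profile`).
    """
    return read_read_evidence(_fixture("trio_read_counts.tsv"))
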