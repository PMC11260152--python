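"""Core data model for the mapping-by-sequencing pipeline.

The pipeline consumes one multi-sample VCF with four libraries from a single
cross: an affected father (homozygous for the causal allele), a pool of the two
carrier mothers, a pool of homozygous offspring and a pool of heterozygous
offspring.  All internal coordinates are 0-based half-open; VCF positions are
converted at the file boundary, BED is consumed natively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum, IntEnum
from typing import Iterator

import numpy as np
import pandas as pd


class Role(str, Enum):
    """The four sequencing libraries of the cross design."""

    FATHER_HOM = "FATHER_HOM"
    MOTHERS_HET = "MOTHERS_HET"
    POOL_HOM = "POOL_HOM"
    POOL_HET = "POOL_HET"


#: column prefix used for each role inside a :class:`VariantTable`
ROLE_PREFIX = {
    Role.FATHER_HOM: "fa",
    Role.MOTHERS_HET: "mo",
    Role.POOL_HOM: "hom",
    Role.POOL_HET: "het",
}

#: default number of diploid individuals contributing to each library
DEFAULT_N_INDIVIDUALS = {
    Role.FATHER_HOM: 1,
    Role.MOTHERS_HET: 2,
    Role.POOL_HOM: 12,
    Role.POOL_HET: 14,
}


class Genotype(IntEnum):
    MISSING = -1
    HOM_REF = 0
    HET = 1
    HOM_ALT = 2


class VariantClass(str, Enum):
    SNP = "SNP"
    MNP = "MNP"
    INDEL = "INDEL"


class CosegCall(IntEnum):
    """Per-variant cosegregation call.  ``NOT_EVALUATED`` means the scan has
    not looked at the site yet (tri-state flag of the data model)."""

    NOT_EVALUATED = -2
    UNEVALUABLE = -1
    NOT_COSEG = 0
    COSEG = 1


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention used for all reported
    coverages, interval lengths and densities)."""

    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class LibraryRole:
    """A library role together with the number of pooled individuals."""

    role: Role
    n_individuals: int = 1

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")


@dataclass
class Observation:
    """Depth and genotype evidence from one library at one site."""

    ref_depth: int
    alt_depth: int
    genotype: Genotype

    @property
    def depth(self) -> int:
        return self.ref_depth + self.alt_depth

    @property
    def alt_fraction(self) -> float:
        d = self.depth
        return math.nan if d == 0 else self.alt_depth / d


@dataclass
class VariantObservation:
    """One biallelic VCF site with per-library evidence and pipeline flags.

    ``start`` is the 0-based coordinate; ``pos`` exposes the 1-based VCF
    position.  The three flags are tri-state: ``None`` means unevaluated.
    """

    chrom: str
    start: int
    ref: str
    alt: str
    variant_class: VariantClass
    qual: float
    obs: dict[Role, Observation]
    in_repeat: bool | None = None
    informative: bool | None = None
    cosegregating: CosegCall = CosegCall.NOT_EVALUATED

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("alt allele must differ from ref allele")
        for o in self.obs.values():
            if o.ref_depth < 0 or o.alt_depth < 0:
                raise ValueError("depths must be >= 0")

    @property
    def pos(self) -> int:
        """1-based position (VCF convention)."""

        return self.start + 1


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome ids and lengths in bp."""

    chroms: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chroms]
        if len(set(names)) != len(names):
            raise ValueError("chromosome ids must be unique")
        if any(l <= 0 for _, l in self.chroms):
            raise ValueError("chromosome lengths must be > 0")

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chroms]

    def length_of(self, chrom: str) -> int:
        for c, l in self.chroms:
            if c == chrom:
                return l
        raise KeyError(chrom)

    @property
    def total_bp(self) -> int:
        return sum(l for _, l in self.chroms)


_BASE_COLUMNS = ["chrom", "start", "ref", "alt", "vclass", "qual"]
_FLAG_DEFAULTS = {"in_repeat": -1, "informative": -1, "coseg": int(CosegCall.NOT_EVALUATED)}


class VariantTable:
    """Columnar container for variant observations.

    A thin wrapper around a :class:`pandas.DataFrame` with one row per site and
    per-role depth/genotype columns (``fa_ref``, ``fa_alt``, ``fa_gt``, ...).
    Behaves as a sequence of :class:`VariantObservation` for record-level use;
    the frame is the interchange object of the vectorised filter/scan stages.
    Tri-state flags are stored as int8 (-1 = unevaluated).
    """

    def __init__(self, df: pd.DataFrame, meta: dict | None = None):
        for col in _BASE_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"missing column {col!r}")
        df = df.copy()
        for p in ROLE_PREFIX.values():
            for suffix, default in (("_ref", 0), ("_alt", 0), ("_gt", int(Genotype.MISSING))):
                col = p + suffix
                if col not in df.columns:
                    df[col] = default
        for col, default in _FLAG_DEFAULTS.items():
            if col not in df.columns:
                df[col] = np.int8(default)
            df[col] = df[col].astype(np.int8)
        self.df = df.reset_index(drop=True)
        self.meta = dict(meta or {})

    # -- sequence protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[VariantObservation]:
        for i in range(len(self.df)):
            yield self[i]

    def __getitem__(self, i: int) -> VariantObservation:
        r = self.df.iloc[i]
        obs = {
            role: Observation(int(r[p + "_ref"]), int(r[p + "_alt"]), Genotype(int(r[p + "_gt"])))
            for role, p in ROLE_PREFIX.items()
        }
        tri = lambda v: None if v < 0 else bool(v)
        return VariantObservation(
            chrom=str(r["chrom"]),
            start=int(r["start"]),
            ref=str(r["ref"]),
            alt=str(r["alt"]),
            variant_class=VariantClass(r["vclass"]),
            qual=float(r["qual"]),
            obs=obs,
            in_repeat=tri(int(r["in_repeat"])),
            informative=tri(int(r["informative"])),
            cosegregating=CosegCall(int(r["coseg"])),
        )

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_records(cls, records: list[VariantObservation], meta: dict | None = None) -> "VariantTable":
        rows = []
        for v in records:
            row = {
                "chrom": v.chrom,
                "start": v.start,
                "ref": v.ref,
                "alt": v.alt,
                "vclass": v.variant_class.value,
                "qual": v.qual,
                "in_repeat": -1 if v.in_repeat is None else int(v.in_repeat),
                "informative": -1 if v.informative is None else int(v.informative),
                "coseg": int(v.cosegregating),
            }
            for role, p in ROLE_PREFIX.items():
                o = v.obs.get(role, Observation(0, 0, Genotype.MISSING))
                row[p + "_ref"] = o.ref_depth
                row[p + "_alt"] = o.alt_depth
                row[p + "_gt"] = int(o.genotype)
            rows.append(row)
        df = pd.DataFrame(rows, columns=_BASE_COLUMNS + [c for c in rows[0]][6:] if rows else _BASE_COLUMNS)
        if not rows:
            df = pd.DataFrame(columns=_BASE_COLUMNS)
        return cls(df, meta)

    def to_records(self) -> list[VariantObservation]:
        return list(self)

    def subset(self, mask) -> "VariantTable":
        t = VariantTable(self.df.loc[np.asarray(mask)], self.meta)
        return t

    def sort(self) -> "VariantTable":
        return VariantTable(self.df.sort_values(["chrom", "start"], kind="mergesort"), self.meta)

    def alt_fraction(self, role: Role) -> np.ndarray:
        p = ROLE_PREFIX[role]
        ref = self.df[p + "_ref"].to_numpy(float)
        alt = self.df[p + "_alt"].to_numpy(float)
        total = ref + alt
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, alt / total, np.nan)

    def depth(self, role: Role) -> np.ndarray:
        p = ROLE_PREFIX[role]
        return (self.df[p + "_ref"] + self.df[p + "_alt"]).to_numpy(int)


@dataclass
class WindowStat:
    """One sliding-window record of the cosegregation scan."""

    chrom: str
    start: int
    end: int
    n_informative: int
    n_cosegregating: int
    proportion: float  # NaN when n_informative < min_informative
    partial: bool = False


@dataclass
class Run:
    """A maximal stretch of consecutive cosegregating informative variants
    (optionally tolerating a bounded number of interruptions)."""

    chrom: str
    start: int  # 0-based start of the first variant in the run
    end: int  # 0-based half-open end just past the last variant start
    n_coseg: int
    n_interruptions: int = 0


@dataclass
class CandidateInterval:
    """A called candidate region delimited by the outermost run variants."""

    chrom: str
    start: int
    end: int
    run_length: int  # count of cosegregating variants in the run
    n_variants: int  # cosegregating + tolerated interruptions
    density: float  # cosegregating variants per Mb, full precision

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def length_mb(self) -> float:
        """Display length in Mb, rounded half-up to 2 decimals (the reporting
        convention: 1,670,000–2,960,000 prints as 1.29 Mb)."""

        return round_half_up(self.length_bp / 1e6, 2)

    @property
    def density_display(self) -> float:
        return round_half_up(self.density, 1)


@dataclass
class GeneModel:
    """Exon/intron structure of one transcript with its CDS.

    ``exons`` are 0-based half-open genomic intervals sorted in genomic order;
    transcription order follows ``strand``.  ``cds_start``/``cds_end`` bound
    the coding span on the genome.  ``chrom_seq`` holds the chromosome
    sequence so splicing and translation can be done locally.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    chrom_seq: str | None = None
    frame_warning: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        ex = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if e1 > s2:
                raise ValueError("exons must not overlap")
        self.exons = ex
        if self.cds_length % 3 != 0:
            self.frame_warning = True

    # -- structure ---------------------------------------------------------
    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_coding_length(self, genomic_index: int) -> int:
        s, e = self.exons[genomic_index]
        return max(0, min(e, self.cds_end) - max(s, self.cds_start))

    @property
    def cds_length(self) -> int:
        return sum(self.exon_coding_length(i) for i in range(len(self.exons)))

    def transcription_order(self) -> list[int]:
        """Genomic exon indices in 5'->3' transcription order."""

        idx = list(range(len(self.exons)))
        return idx if self.strand == "+" else idx[::-1]
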