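"""Quality filtering, repeat masking and informative-variant identification.

An *informative* site is homozygous-alternate in the affected father and
heterozygous in the carrier-mother pool, so the two offspring pools become
diagnostic for linkage to the causal locus.  The exact thresholds are
conventional and fully config-exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import RepeatMask
from .model import Genotype, ROLE_PREFIX, Role, VariantObservation, VariantTable


@dataclass
class FilterThresholds:
    """Quality/informativeness thresholds.

    ``mode`` selects how parental states are judged: ``"fraction"`` uses
    allele-depth fractions (father alternate fraction >= ``father_min_alt_frac``
    for homozygous, mothers within ``mothers_het_band`` for heterozygous);
    ``"call"`` trusts the VCF genotype calls instead.
    """

    min_qual: float = 20.0
    min_depth: int = 10  # per library
    scan_classes: tuple[str, ...] = ("SNP", "MNP")
    father_min_alt_frac: float = 0.95
    mothers_het_band: tuple[float, float] = (0.25, 0.75)
    mode: str = "fraction"

    def __post_init__(self) -> None:
        lo, hi = self.mothers_het_band
        if not (0 <= lo <= hi <= 1) or not (0 <= self.father_min_alt_frac <= 1):
            raise ValueError("fraction bounds must lie in [0, 1]")
        if self.min_qual < 0 or self.min_depth < 0:
            raise ValueError("min values must be >= 0")
        if self.mode not in ("fraction", "call"):
            raise ValueError("mode must be 'fraction' or 'call'")


@dataclass
class FilterReport:
    """Pass/fail bookkeeping: reason counts sum to (input - output)."""

    n_input: int = 0
    n_output: int = 0
    reasons: dict = field(default_factory=dict)
    n_indels_forwarded: int = 0


def quality_filter(table: VariantTable, thresholds: FilterThresholds) -> tuple[VariantTable, FilterReport]:
    """Retain biallelic SNP/MNP sites passing QUAL, per-library depth and
    genotype-completeness requirements.

    Each removed site is counted under its first failing reason in the order
    class > qual > missing_gt > depth.  Indels are removed from the scan set
    but remain available (via the input table) for consequence annotation.
    Idempotent: re-filtering the output removes nothing.
    """

    df = table.df
    n = len(df)
    ok_class = df["vclass"].isin(thresholds.scan_classes).to_numpy()
    ok_qual = df["qual"].to_numpy() >= thresholds.min_qual
    ok_gt = np.ones(n, bool)
    ok_depth = np.ones(n, bool)
    for p in ROLE_PREFIX.values():
        ok_gt &= df[p + "_gt"].to_numpy() != int(Genotype.MISSING)
        ok_depth &= (df[p + "_ref"] + df[p + "_alt"]).to_numpy() >= thresholds.min_depth
    passed = ok_class & ok_qual & ok_gt & ok_depth

    reasons = {}
    remaining = ~passed
    for name, ok in (("class", ok_class), ("qual", ok_qual), ("missing_gt", ok_gt), ("depth", ok_depth)):
        hit = remaining & ~ok
        if hit.any():
            reasons[name] = int(hit.sum())
        remaining &= ok
    report = FilterReport(
        n_input=n,
        n_output=int(passed.sum()),
        reasons=reasons,
        n_indels_forwarded=int((df["vclass"] == "INDEL").sum()),
    )
    return table.subset(passed), report


def _informative_mask(table: VariantTable, thresholds: FilterThresholds) -> np.ndarray:
    if thresholds.mode == "call":
        fa = table.df["fa_gt"].to_numpy() == int(Genotype.HOM_ALT)
        mo = table.df["mo_gt"].to_numpy() == int(Genotype.HET)
        return fa & mo
    fa_f = table.alt_fraction(Role.FATHER_HOM)
    mo_f = table.alt_fraction(Role.MOTHERS_HET)
    lo, hi = thresholds.mothers_het_band
    with np.errstate(invalid="ignore"):
        return (fa_f >= thresholds.father_min_alt_frac) & (mo_f >= lo) & (mo_f <= hi)


def is_informative(variant: VariantObservation, thresholds: FilterThresholds) -> bool:
    """Father consistent with homozygous-alternate and mothers with
    heterozygous, under the configured evidence mode."""

    if thresholds.mode == "call":
        return (
            variant.obs[Role.FATHER_HOM].genotype == Genotype.HOM_ALT
            and variant.obs[Role.MOTHERS_HET].genotype == Genotype.HET
        )
    fa = variant.obs[Role.FATHER_HOM].alt_fraction
    mo = variant.obs[Role.MOTHERS_HET].alt_fraction
    lo, hi = thresholds.mothers_het_band
    return bool(fa >= thresholds.father_min_alt_frac and lo <= mo <= hi)


def mark_informative(table: VariantTable, thresholds: FilterThresholds) -> VariantTable:
    """Set the informative flag on every site and return the informative
    subset (sorted by chromosome and coordinate)."""

    mask = _informative_mask(table, thresholds)
    table.df["informative"] = mask.astype(np.int8)
    return table.subset(mask).sort()


def apply_repeat_mask(table: VariantTable, mask: RepeatMask | None) -> VariantTable:
    """Drop variants inside repetitive elements (flagging all sites).  With no
    mask this is the identity."""

    if mask is None:
        table.df["in_repeat"] = np.int8(0)
        return table
    starts = table.df["start"].to_numpy()
    chroms = table.df["chrom"].to_numpy()
    inside = np.zeros(len(table.df), bool)
    for chrom in np.unique(chroms):
        tree = mask.trees.get(chrom)
        if tree is None:
            continue
        idx = np.nonzero(chroms == chrom)[0]
        ivs = sorted((iv.begin, iv.end) for iv in tree)
        if not ivs:
            continue
        begins = np.array([b for b, _ in ivs])
        ends = np.array([e for _, e in ivs])
        j = np.searchsorted(begins, starts[idx], side="right") - 1
        hit = (j >= 0) & (starts[idx] < ends[np.clip(j, 0, None)])
        inside[idx] = hit
    table.df["in_repeat"] = inside.astype(np.int8)
    return table.subset(~inside)
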