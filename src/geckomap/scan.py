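"""The core mapping computation: per-variant cosegregation calls, the sliding
window proportion scan, run detection and candidate-interval calling.

A variant *cosegregates* with the causal locus when the homozygous-offspring
pool looks homozygous-alternate (and, optionally, the heterozygous pool looks
heterozygous).  Tightly linked informative variants cosegregate almost surely;
unlinked ones only when all maternal transmissions happen to line up, so long
runs of consecutive cosegregating variants pinpoint the locus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    CandidateInterval,
    CosegCall,
    GenomeLayout,
    Genotype,
    Role,
    Run,
    VariantObservation,
    VariantTable,
    WindowStat,
)


@dataclass
class CosegThresholds:
    """Decision rule for the per-variant cosegregation call.

    ``mode="fraction"`` applies allele-depth fraction thresholds (homozygous
    pool alternate fraction >= ``hom_min_alt_frac``; heterozygous pool within
    ``het_band``); ``mode="genotype"`` trusts the VCF genotype calls.
    ``require`` selects whether the heterozygous pool must also agree
    (``"both"``) or the homozygous pool alone decides (``"hom"``, the
    default): at ~25x pool coverage the heterozygous-pool allele fraction is
    noisy enough that demanding it stay inside a tight band breaks long runs
    at truly linked sites, while the homozygous-pool requirement alone keeps
    the chance-cosegregation rate of unlinked variants at the percent level.
    Pools below ``min_depth`` make a site UNEVALUABLE rather than breaking it.
    """

    hom_min_alt_frac: float = 0.90
    het_band: tuple[float, float] = (0.35, 0.65)
    min_depth: int = 10
    mode: str = "fraction"
    require: str = "hom"

    def __post_init__(self) -> None:
        lo, hi = self.het_band
        if not (0 <= lo <= hi <= 1) or not (0 <= self.hom_min_alt_frac <= 1):
            raise ValueError("bounds must lie in [0, 1]")
        if self.hom_min_alt_frac <= hi:
            raise ValueError("hom bound must exceed the het upper bound")
        if self.mode not in ("fraction", "genotype"):
            raise ValueError("mode must be 'fraction' or 'genotype'")
        if self.require not in ("hom", "both"):
            raise ValueError("require must be 'hom' or 'both'")


def call_cosegregation(variant: VariantObservation, thresholds: CosegThresholds) -> CosegCall:
    """Cosegregation call for a single informative variant."""

    hom = variant.obs[Role.POOL_HOM]
    het = variant.obs[Role.POOL_HET]
    pools = (hom, het) if thresholds.require == "both" else (hom,)
    if any(o.depth < thresholds.min_depth for o in pools):
        return CosegCall.UNEVALUABLE
    if thresholds.mode == "genotype":
        ok = hom.genotype == Genotype.HOM_ALT
        if thresholds.require == "both":
            ok = ok and het.genotype == Genotype.HET
    else:
        lo, hi = thresholds.het_band
        ok = hom.alt_fraction >= thresholds.hom_min_alt_frac
        if thresholds.require == "both":
            ok = ok and lo <= het.alt_fraction <= hi
    return CosegCall.COSEG if ok else CosegCall.NOT_COSEG


def call_cosegregation_table(table: VariantTable, thresholds: CosegThresholds) -> VariantTable:
    """Vectorised cosegregation call over an informative-variant table; sets
    the ``coseg`` column in place and returns the table."""

    hom_d = table.depth(Role.POOL_HOM)
    het_d = table.depth(Role.POOL_HET)
    unev = hom_d < thresholds.min_depth
    if thresholds.require == "both":
        unev |= het_d < thresholds.min_depth
    if thresholds.mode == "genotype":
        ok = table.df["hom_gt"].to_numpy() == int(Genotype.HOM_ALT)
        if thresholds.require == "both":
            ok &= table.df["het_gt"].to_numpy() == int(Genotype.HET)
    else:
        lo, hi = thresholds.het_band
        with np.errstate(invalid="ignore"):
            hom_f = table.alt_fraction(Role.POOL_HOM)
            het_f = table.alt_fraction(Role.POOL_HET)
            ok = hom_f >= thresholds.hom_min_alt_frac
            if thresholds.require == "both":
                ok &= (het_f >= lo) & (het_f <= hi)
    call = np.where(unev, int(CosegCall.UNEVALUABLE), np.where(ok, int(CosegCall.COSEG), int(CosegCall.NOT_COSEG)))
    table.df["coseg"] = call.astype(np.int8)
    return table


def window_scan(
    table: VariantTable,
    layout: GenomeLayout | None = None,
    window_bp: int = 1_000_000,
    step_bp: int = 100_000,
    min_informative: int = 10,
) -> list[WindowStat]:
    """Sliding-window proportion of cosegregating among informative variants.

    Windows are anchored at coordinate 0 on each chromosome, half-open,
    advancing by ``step_bp``; every variant counts in every overlapping
    window.  Terminal windows are truncated at the chromosome end and flagged
    ``partial``.  A window with fewer than ``min_informative`` informative
    variants has an undefined (NaN) proportion.
    """

    if step_bp > window_bp:
        raise ValueError("step must not exceed the window size")
    if step_bp <= 0:
        raise ValueError("step must be > 0")
    df = table.df
    chrom_names = layout.names if layout is not None else sorted(df["chrom"].unique())
    out: list[WindowStat] = []
    for chrom in chrom_names:
        sub = df[df["chrom"] == chrom].sort_values("start")
        pos = sub["start"].to_numpy()
        coseg = (sub["coseg"].to_numpy() == int(CosegCall.COSEG)).astype(np.int64)
        cum = np.concatenate([[0], np.cumsum(coseg)])
        length = layout.length_of(chrom) if layout is not None else int(pos[-1]) + 1 if len(pos) else 0
        if length == 0:
            continue
        starts = np.arange(0, length, step_bp)
        for s in starts:
            e = min(s + window_bp, length)
            i = int(np.searchsorted(pos, s, side="left"))
            j = int(np.searchsorted(pos, e, side="left"))
            n_inf = j - i
            n_coseg = int(cum[j] - cum[i])
            prop = n_coseg / n_inf if n_inf >= min_informative else float("nan")
            out.append(
                WindowStat(
                    chrom=chrom,
                    start=int(s),
                    end=int(e),
                    n_informative=n_inf,
                    n_cosegregating=n_coseg,
                    proportion=prop,
                    partial=(e - s) < window_bp,
                )
            )
    return out


def find_runs(table: VariantTable, min_run: int = 100, max_interruptions: int = 0) -> list[Run]:
    """Maximal runs of consecutive cosegregating informative variants.

    UNEVALUABLE sites are skipped entirely: low-depth sites carry no evidence
    and must not make the run criterion depth-dependent.  A run may contain up
    to ``max_interruptions`` non-cosegregating sites in its interior; runs are
    trimmed so they start and end on a cosegregating variant, and runs with
    fewer than ``min_run`` cosegregating variants are dropped.
    """

    df = table.df
    runs: list[Run] = []
    for chrom in sorted(df["chrom"].unique()):
        sub = df[df["chrom"] == chrom].sort_values("start")
        calls = sub["coseg"].to_numpy()
        pos = sub["start"].to_numpy()
        keep = calls != int(CosegCall.UNEVALUABLE)
        calls, pos = calls[keep], pos[keep]
        evaluated = calls != int(CosegCall.NOT_EVALUATED)
        calls, pos = calls[evaluated], pos[evaluated]
        runs.extend(_runs_in_sequence(calls == int(CosegCall.COSEG), pos, chrom, min_run, max_interruptions))
    return runs


def _runs_in_sequence(
    is_coseg: np.ndarray, pos: np.ndarray, chrom: str, min_run: int, max_interruptions: int
) -> list[Run]:
    """Maximal <=k-interruption windows over a boolean sequence, trimmed to
    cosegregating endpoints (sentinel construction over interruption
    positions)."""

    n = len(is_coseg)
    if n == 0:
        return []
    zeros = np.nonzero(~is_coseg)[0]
    z = np.concatenate([[-1], zeros, [n]])
    k = max_interruptions
    # window between z[i] and z[i + k + 1] (exclusive) holds <= k interruptions
    candidates: set[tuple[int, int]] = set()
    for i in range(0, max(1, len(z) - k - 1)):
        j = min(i + k + 1, len(z) - 1)
        lo, hi = z[i] + 1, z[j] - 1
        # trim to cosegregating endpoints
        while lo <= hi and not is_coseg[lo]:
            lo += 1
        while hi >= lo and not is_coseg[hi]:
            hi -= 1
        if hi < lo:
            continue
        candidates.add((int(lo), int(hi)))
    out: list[Run] = []
    for lo, hi in sorted(candidates):
        if any((a <= lo and hi <= b) and (a, b) != (lo, hi) for a, b in candidates):
            continue  # nested inside a larger window: not maximal
        n_coseg = int(is_coseg[lo : hi + 1].sum())
        if n_coseg < min_run:
            continue
        out.append(
            Run(
                chrom=chrom,
                start=int(pos[lo]),
                end=int(pos[hi]) + 1,
                n_coseg=n_coseg,
                n_interruptions=(hi - lo + 1) - n_coseg,
            )
        )
    return out


def interval_density(n_variants: int, length_bp: int) -> float:
    """Cosegregating variants per Mb, full precision (display rounding is the
    caller's concern — reported interval endpoints are themselves rounded, so
    densities must always be computed from unrounded coordinates)."""

    if length_bp <= 0:
        raise ValueError("interval length must be > 0")
    if n_variants == 0:
        return 0.0
    return n_variants / (length_bp / 1e6)


def call_candidate_intervals(runs: list[Run]) -> list[CandidateInterval]:
    """Candidate intervals delimited by the outermost run variants, ranked by
    run length, then density, then chromosome, then coordinate."""

    intervals = [
        CandidateInterval(
            chrom=r.chrom,
            start=r.start,
            end=r.end,
            run_length=r.n_coseg,
            n_variants=r.n_coseg + r.n_interruptions,
            density=interval_density(r.n_coseg, r.end - r.start),
        )
        for r in runs
    ]
    intervals.sort(key=lambda iv: (-iv.run_length, -iv.density, iv.chrom, iv.start))
    return intervals
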