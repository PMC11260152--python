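"""Synthetic cross and pooled-sequencing generator.

Emulates the mapping cross: an affected father homozygous for the causal
allele (*mss/mss*), two carrier mothers (*mss/+*), and two phenotype-sorted
offspring pools (12 homozygotes, 14 heterozygotes).  Each mother carries one
complete "mss-line" haplotype — alternate at every informative site, in phase
with the causal allele — and one wild haplotype, so cosegregation of distant
informative variants decays with genetic distance through recombination.
Meiosis follows the Haldane model (Poisson crossovers, no interference), with
an optional crossover-free core around the causal locus.  Sequencing is
modelled as Poisson total depth per library and per-read error, with diploid
maximum-likelihood genotype calls (what a variant caller would emit for each
library, pools included).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import io as gio
from .model import GenomeLayout, Genotype, VariantTable

#: maternal haplotype phases
MSS_LINE, WILD = 0, 1


def default_layout() -> GenomeLayout:
    """Five 10-Mb chromosomes: a desk-scale stand-in for a 2.2 Gb genome."""

    return GenomeLayout(tuple((f"chr{i}", 10_000_000) for i in range(1, 6)))


@dataclass
class CrossSimConfig:
    """Parameters of the simulated cross and pooled sequencing.

    Defaults mirror the study conditions: pools of 12 homozygous and 14
    heterozygous offspring, ~25x coverage per library, ~2,000 informative
    variants per Mb, 1 cM/Mb recombination, and a ~1.3 Mb fully linked core
    around the causal locus.  The background (non-informative) density and the
    genotype missingness rate are plumbing knobs, not claims about the study.
    """

    layout: GenomeLayout = field(default_factory=default_layout)
    causal_chrom: str = "chr3"
    causal_pos: int = 5_000_000
    informative_density_near: float = 2000.0  # variants per Mb near the locus
    informative_density_far: float = 2000.0  # variants per Mb elsewhere
    near_radius_bp: int = 650_000  # half-width of the "near" band
    background_density: float = 500.0  # non-informative variants per Mb
    recomb_rate_cm_per_mb: float = 1.0
    linked_core_bp: int = 1_300_000  # crossover-free window centred on the locus
    n_pool_hom: int = 12
    n_pool_het: int = 14
    coverage: float = 25.0
    error_rate: float = 0.002
    missing_rate: float = 0.01
    repeat_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error rate must be in [0, 0.5)")
        if min(self.n_pool_hom, self.n_pool_het) < 1:
            raise ValueError("pool sizes must be >= 1")
        for d in (self.informative_density_near, self.informative_density_far, self.background_density):
            if d < 0:
                raise ValueError("densities must be >= 0")
        if self.recomb_rate_cm_per_mb < 0:
            raise ValueError("recombination rate must be >= 0")
        if self.causal_chrom not in self.layout.names:
            raise ValueError("causal chromosome not in genome layout")
        if not (0 <= self.causal_pos < self.layout.length_of(self.causal_chrom)):
            raise ValueError("causal locus outside the genome")


def substream(seed: int, *names: str) -> np.random.Generator:
    """Named RNG substream: one pipeline seed, independent module streams."""

    import zlib

    keys = [zlib.crc32(n.encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31] + keys))


@dataclass
class Gamete:
    """A recombinant maternal gamete: crossover breakpoints plus the phase
    (MSS_LINE or WILD) carried at coordinate 0."""

    breakpoints: np.ndarray
    start_phase: int

    def phase_at(self, pos: int) -> int:
        return self.phases_at(np.asarray([pos]))[0]

    def phases_at(self, positions: np.ndarray) -> np.ndarray:
        n_cross = np.searchsorted(self.breakpoints, positions, side="right")
        return (self.start_phase + n_cross) % 2


def simulate_meiosis(
    chrom_length_bp: int,
    rate_cm_per_mb: float,
    rng: np.random.Generator,
    *,
    exclude: tuple[int, int] | None = None,
) -> Gamete:
    """One maternal meiosis over one chromosome (Haldane model).

    Crossover count is Poisson with mean ``length_Mb * rate / 100`` Morgans and
    breakpoint positions uniform.  Breakpoints falling inside ``exclude``
    (the fully linked core) are dropped.  The returned gamete alternates
    parental phase at each breakpoint, starting from a fair coin.
    """

    if rate_cm_per_mb < 0:
        raise ValueError("rate must be >= 0")
    morgans = chrom_length_bp / 1e6 * rate_cm_per_mb / 100.0
    n = rng.poisson(morgans)
    breaks = np.sort(rng.uniform(0, chrom_length_bp, size=n))
    if exclude is not None and n:
        lo, hi = exclude
        breaks = breaks[(breaks < lo) | (breaks >= hi)]
    return Gamete(breakpoints=breaks, start_phase=int(rng.integers(2)))


def sample_pool_depths(
    true_alt_fraction: float,
    n_chromosomes_in_pool: int,
    coverage: float,
    error_rate: float,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Sequencing depths for one library at one site.

    Total depth ~ Poisson(coverage); each read is alternate with probability
    ``f (1 - e) + (1 - f) e``.  ``n_chromosomes_in_pool`` only validates that
    the true fraction is a feasible chromosome count.
    """

    if not (0.0 <= true_alt_fraction <= 1.0):
        raise ValueError("true_alt_fraction must be in [0, 1]")
    if n_chromosomes_in_pool >= 1:
        k = true_alt_fraction * n_chromosomes_in_pool
        if abs(k - round(k)) > 1e-9:
            raise ValueError("true_alt_fraction is not a multiple of 1/n_chromosomes_in_pool")
    total = int(rng.poisson(coverage))
    p_alt = true_alt_fraction * (1 - error_rate) + (1 - true_alt_fraction) * error_rate
    alt = int(rng.binomial(total, p_alt)) if total else 0
    return total - alt, alt


def _sample_depths_vec(f: np.ndarray, coverage: float, error: float, rng) -> tuple[np.ndarray, np.ndarray]:
    total = rng.poisson(coverage, size=f.shape)
    p = f * (1 - error) + (1 - f) * error
    alt = rng.binomial(total, p)
    return (total - alt).astype(np.int32), alt.astype(np.int32)


def call_genotypes(ref_d: np.ndarray, alt_d: np.ndarray, error_rate: float) -> np.ndarray:
    """Maximum-likelihood diploid genotype per site from allele depths.

    Each library (pools included) is genotyped as a diploid sample with
    per-read alternate probability e, 1/2 or 1-e — the same simplification a
    standard small-cohort caller applies to a pool BAM.  Zero depth is MISSING.
    """

    e = max(error_rate, 1e-6)
    probs = np.array([e, 0.5, 1.0 - e])
    ref_d = np.asarray(ref_d, dtype=np.int64)
    alt_d = np.asarray(alt_d, dtype=np.int64)
    ll = alt_d[:, None] * np.log(probs)[None, :] + ref_d[:, None] * np.log1p(-probs)[None, :]
    gt = np.argmax(ll, axis=1).astype(np.int8)  # 0=HOM_REF, 1=HET, 2=HOM_ALT
    gt[(ref_d + alt_d) == 0] = int(Genotype.MISSING)
    return gt


@dataclass
class OffspringTruth:
    pool: str  # "hom" or "het"
    gametes: dict[str, Gamete]


@dataclass
class TruthRecord:
    """Hidden ground truth of a simulated cross, for recovery tests."""

    causal_chrom: str
    causal_pos: int
    offspring: list[OffspringTruth]
    core_start: int
    core_end: int
    seed: int

    def pool_gametes(self, pool: str, chrom: str) -> list[Gamete]:
        return [o.gametes[chrom] for o in self.offspring if o.pool == pool]

    def linked_segment(self, hom_only: bool = True) -> tuple[int, int]:
        """The realized fully linked segment around the causal locus: bounded
        by the nearest flanking crossover among the (hom-)pool gametes."""

        pools = ("hom",) if hom_only else ("hom", "het")
        length = next(l for c, l in _layout_of(self).chroms if c == self.causal_chrom)
        lo, hi = 0, length
        for pool in pools:
            for g in self.pool_gametes(pool, self.causal_chrom):
                left = g.breakpoints[g.breakpoints <= self.causal_pos]
                right = g.breakpoints[g.breakpoints > self.causal_pos]
                if left.size:
                    lo = max(lo, int(left[-1]))
                if right.size:
                    hi = min(hi, int(right[0]))
        return lo, hi


def _layout_of(truth: TruthRecord) -> GenomeLayout:
    return truth._layout  # attached by simulate_cross


@dataclass
class SimResult:
    truth: TruthRecord
    variants: VariantTable
    repeat_mask: "gio.RepeatMask"
    config: CrossSimConfig
    paths: dict[str, str] = field(default_factory=dict)


def simulate_cross(config: CrossSimConfig, out_dir: str | None = None) -> SimResult:
    """Simulate the full cross and pooled sequencing experiment.

    Offspring are drawn by Mendelian segregation until both pools are filled
    (pool membership is the maternal phase at the causal locus; incomplete
    dominance makes heterozygotes phenotypically sortable, so phenotype equals
    genotype here).  Informative sites sit on the mss-line maternal haplotype
    genome-wide; the father is homozygous-alternate at all of them.  Output is
    deterministic for a fixed ``config.seed``.
    """

    rng_sites = substream(config.seed, "sites")
    rng_meiosis = substream(config.seed, "meiosis")
    rng_depth = substream(config.seed, "depths")
    rng_missing = substream(config.seed, "missing")
    rng_repeat = substream(config.seed, "repeats")

    # -- informative + background site positions per chromosome ------------
    positions: dict[str, np.ndarray] = {}
    informative_flag: dict[str, np.ndarray] = {}
    core_lo = config.causal_pos - config.linked_core_bp // 2
    core_hi = config.causal_pos + config.linked_core_bp // 2
    for chrom, length in config.layout.chroms:
        mb = length / 1e6
        if chrom == config.causal_chrom and config.informative_density_near != config.informative_density_far:
            near_lo = max(0, config.causal_pos - config.near_radius_bp)
            near_hi = min(length, config.causal_pos + config.near_radius_bp)
            n_near = rng_sites.poisson(config.informative_density_near * (near_hi - near_lo) / 1e6)
            n_far = rng_sites.poisson(config.informative_density_far * (length - (near_hi - near_lo)) / 1e6)
            near = rng_sites.integers(near_lo, near_hi, size=n_near)
            far = rng_sites.uniform(0, length - (near_hi - near_lo), size=n_far)
            far = np.where(far >= near_lo, far + (near_hi - near_lo), far).astype(np.int64)
            inf_pos = np.concatenate([near, far])
        else:
            n_inf = rng_sites.poisson(config.informative_density_far * mb)
            inf_pos = rng_sites.integers(0, length, size=n_inf)
        n_bg = rng_sites.poisson(config.background_density * mb)
        bg_pos = rng_sites.integers(0, length, size=n_bg)
        pos = np.concatenate([inf_pos, bg_pos])
        flag = np.concatenate([np.ones(len(inf_pos), bool), np.zeros(len(bg_pos), bool)])
        order = np.argsort(pos, kind="stable")
        pos, flag = pos[order], flag[order]
        keep = np.ones(len(pos), bool)  # drop duplicate coordinates
        keep[1:] = np.diff(pos) > 0
        positions[chrom] = pos[keep]
        informative_flag[chrom] = flag[keep]
    if sum(informative_flag[c].sum() for c in positions) == 0:
        raise ValueError("configuration produced zero informative variants")

    # -- offspring by Mendelian segregation into the two pools -------------
    exclude = {config.causal_chrom: (core_lo, core_hi)}
    offspring: list[OffspringTruth] = []
    n_hom = n_het = 0
    attempts = 0
    while n_hom < config.n_pool_hom or n_het < config.n_pool_het:
        attempts += 1
        if attempts > 200 * (config.n_pool_hom + config.n_pool_het):
            raise RuntimeError("pool filling did not converge")
        gametes = {
            chrom: simulate_meiosis(
                length, config.recomb_rate_cm_per_mb, rng_meiosis, exclude=exclude.get(chrom)
            )
            for chrom, length in config.layout.chroms
        }
        maternal = gametes[config.causal_chrom].phase_at(config.causal_pos)
        if maternal == MSS_LINE and n_hom < config.n_pool_hom:
            offspring.append(OffspringTruth("hom", gametes))
            n_hom += 1
        elif maternal == WILD and n_het < config.n_pool_het:
            offspring.append(OffspringTruth("het", gametes))
            n_het += 1

    truth = TruthRecord(
        causal_chrom=config.causal_chrom,
        causal_pos=config.causal_pos,
        offspring=offspring,
        core_start=core_lo,
        core_end=core_hi,
        seed=config.seed,
    )
    truth._layout = config.layout  # for realized-segment queries

    # -- per-site true pool fractions and library observations -------------
    frames = []
    n_hom_chrom = 2 * config.n_pool_hom
    n_het_chrom = 2 * config.n_pool_het
    bg_patterns = [  # (father gt, mothers gt), probabilities below
        (Genotype.HET, Genotype.HOM_REF),
        (Genotype.HOM_REF, Genotype.HET),
        (Genotype.HET, Genotype.HET),
        (Genotype.HOM_ALT, Genotype.HOM_ALT),
    ]
    bg_probs = np.array([0.35, 0.35, 0.2, 0.1])
    gt_to_f = {Genotype.HOM_REF: 0.0, Genotype.HET: 0.5, Genotype.HOM_ALT: 1.0}

    for chrom, length in config.layout.chroms:
        pos = positions[chrom]
        inf = informative_flag[chrom]
        n = len(pos)
        if n == 0:
            continue
        # maternal mss-line inheritance per offspring at informative sites
        hom_mat = np.zeros(n, dtype=np.int32)
        het_mat = np.zeros(n, dtype=np.int32)
        for o in offspring:
            carried = o.gametes[chrom].phases_at(pos) == MSS_LINE
            if o.pool == "hom":
                hom_mat += carried
            else:
                het_mat += carried
        f_fa = np.where(inf, 1.0, 0.0)
        f_mo = np.where(inf, 0.5, 0.0)
        f_hom = np.where(inf, (config.n_pool_hom + hom_mat) / n_hom_chrom, 0.0)
        f_het = np.where(inf, (config.n_pool_het + het_mat) / n_het_chrom, 0.0)

        # background sites: per-site independent transmission (linkage
        # equilibrium approximation; these never pass the informative filter)
        n_bg = int((~inf).sum())
        if n_bg:
            pat = rng_sites.choice(len(bg_patterns), size=n_bg, p=bg_probs)
            fa_gt = np.array([int(bg_patterns[i][0]) for i in pat])
            mo_gt = np.array([int(bg_patterns[i][1]) for i in pat])
            f_fa_bg = np.array([gt_to_f[Genotype(g)] for g in fa_gt])
            f_mo_bg = np.array([gt_to_f[Genotype(g)] for g in mo_gt])
            pool_f = lambda n_ind: (
                rng_sites.binomial(n_ind, f_fa_bg) + rng_sites.binomial(n_ind, f_mo_bg)
            ) / (2 * n_ind)
            f_fa[~inf] = f_fa_bg
            f_mo[~inf] = f_mo_bg
            f_hom[~inf] = pool_f(config.n_pool_hom)
            f_het[~inf] = pool_f(config.n_pool_het)

        df = pd.DataFrame({"chrom": chrom, "start": pos, "true_informative": inf})
        for prefix, f_true in (("fa", f_fa), ("mo", f_mo), ("hom", f_hom), ("het", f_het)):
            ref_d, alt_d = _sample_depths_vec(f_true, config.coverage, config.error_rate, rng_depth)
            gt = call_genotypes(ref_d, alt_d, config.error_rate)
            if config.missing_rate > 0:
                miss = rng_missing.random(n) < config.missing_rate
                ref_d, alt_d = ref_d.copy(), alt_d.copy()
                ref_d[miss] = alt_d[miss] = 0
                gt[miss] = int(Genotype.MISSING)
            df[prefix + "_ref"], df[prefix + "_alt"], df[prefix + "_gt"] = ref_d, alt_d, gt
            df["true_f_" + prefix] = f_true
        frames.append(df)

    df = pd.concat(frames, ignore_index=True)
    # alleles: SNPs with a deterministic ref/alt choice per site
    bases = np.array(list("ACGT"))
    ref_i = rng_sites.integers(0, 4, size=len(df))
    alt_i = (ref_i + rng_sites.integers(1, 4, size=len(df))) % 4
    df["ref"], df["alt"] = bases[ref_i], bases[alt_i]
    df["vclass"] = "SNP"
    # QUAL: mostly comfortable, a small tail below typical thresholds
    qual = np.round(rng_sites.uniform(30, 60, size=len(df)), 1)
    low = rng_sites.random(len(df)) < 0.03
    qual[low] = np.round(rng_sites.uniform(0, 20, size=int(low.sum())), 1)
    df["qual"] = qual

    table = VariantTable(
        df,
        meta={
            "seed": config.seed,
            "causal_chrom": config.causal_chrom,
            "causal_pos": config.causal_pos,
            "layout": config.layout,
        },
    )

    # -- repeat intervals ---------------------------------------------------
    repeat_ivs: dict[str, list[tuple[int, int]]] = {}
    for chrom, length in config.layout.chroms:
        target = config.repeat_fraction * length
        covered = 0
        ivs = []
        while covered < target:
            w = int(rng_repeat.integers(2_000, 20_000))
            s = int(rng_repeat.integers(0, max(1, length - w)))
            ivs.append((s, s + w))
            covered += w
        repeat_ivs[chrom] = ivs
    mask = gio.mask_from_intervals(repeat_ivs)

    result = SimResult(truth=truth, variants=table, repeat_mask=mask, config=config)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "vcf": os.path.join(out_dir, "sim.vcf"),
            "repeats": os.path.join(out_dir, "repeats.bed"),
            "truth": os.path.join(out_dir, "truth.json"),
            "layout": os.path.join(out_dir, "layout.tsv"),
        }
        gio.write_vcf(
            table,
            paths["vcf"],
            layout=config.layout,
            header_extra=[f"##geckomap_seed={config.seed}"],
        )
        gio.write_bed({c: [(int(s), int(e)) for s, e in mask.intervals(c)] for c in mask.trees}, paths["repeats"])
        gio.write_genome_layout(config.layout, paths["layout"])
        with open(paths["truth"], "w") as fh:
            json.dump(
                {
                    "seed": config.seed,
                    "causal_chrom": config.causal_chrom,
                    "causal_pos": config.causal_pos,
                    "core_start": truth.core_start,
                    "core_end": truth.core_end,
                    "n_pool_hom": config.n_pool_hom,
                    "n_pool_het": config.n_pool_het,
                    "config": {
                        k: v for k, v in asdict(config).items() if k != "layout"
                    },
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")
        result.paths = paths
    return result
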