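"""End-to-end orchestration: simulate (or load) -> filter -> scan -> report.

A single :class:`PipelineConfig` carries every threshold and path; one seed
drives named RNG substreams, so a full run is reproducible from one number.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field

import yaml

from . import io as gio
from .filters import FilterThresholds, apply_repeat_mask, mark_informative, quality_filter
from .model import GenomeLayout, Role, VariantTable
from .scan import (
    CosegThresholds,
    call_candidate_intervals,
    call_cosegregation_table,
    find_runs,
    window_scan,
)
from .simulate import CrossSimConfig, simulate_cross

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved configuration of a full run.

    ``max_interruptions`` defaults to 2: at ~25x pool coverage an isolated
    truly linked site fails the cosegregation rule with probability ~2e-5
    (three or more sequencing errors among the homozygous-pool reads), so a
    fully linked region thousands of variants long accrues occasional
    single-site breaks that carry no linkage information, while an unlinked
    region would need ~18 failures per 100 sites and can never bridge them.
    """

    vcf: str | None = None
    roles: dict[str, str] = field(default_factory=dict)  # sample name -> role
    repeats: str | None = None
    layout: str | None = None  # layout TSV (chrom lengths)
    simulate: bool = False
    sim: CrossSimConfig = field(default_factory=CrossSimConfig)
    filter: FilterThresholds = field(default_factory=FilterThresholds)
    coseg: CosegThresholds = field(default_factory=CosegThresholds)
    window_bp: int = 1_000_000
    step_bp: int = 100_000
    min_informative: int = 10
    min_run: int = 100
    max_interruptions: int = 2
    seed: int = 0
    out_prefix: str = "geckomap"
    depth_fields: tuple[str, ...] = ("AD",)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "sim" in kwargs and isinstance(kwargs["sim"], dict):
            sim = dict(kwargs["sim"])
            if "layout" in sim and not isinstance(sim["layout"], GenomeLayout):
                sim["layout"] = GenomeLayout(tuple((c, int(l)) for c, l in sim["layout"]))
            kwargs["sim"] = CrossSimConfig(**sim)
        if "filter" in kwargs and isinstance(kwargs["filter"], dict):
            f = dict(kwargs["filter"])
            if "mothers_het_band" in f:
                f["mothers_het_band"] = tuple(f["mothers_het_band"])
            if "scan_classes" in f:
                f["scan_classes"] = tuple(f["scan_classes"])
            kwargs["filter"] = FilterThresholds(**f)
        if "coseg" in kwargs and isinstance(kwargs["coseg"], dict):
            c = dict(kwargs["coseg"])
            if "het_band" in c:
                c["het_band"] = tuple(c["het_band"])
            kwargs["coseg"] = CosegThresholds(**c)
        if "depth_fields" in kwargs:
            kwargs["depth_fields"] = tuple(kwargs["depth_fields"])
        return cls(**kwargs)

    def validate(self) -> None:
        if not self.simulate:
            if not self.vcf:
                raise ValueError("either a VCF or simulate=true is required")
            if not os.path.exists(self.vcf):
                raise FileNotFoundError(self.vcf)
            if not self.roles:
                raise ValueError("a sample-to-role mapping is required to scan a VCF")
            mapped = {Role(v) for v in self.roles.values()}
            if mapped != set(Role):
                raise ValueError("role map must cover all four roles exactly")
            if self.repeats and not os.path.exists(self.repeats):
                raise FileNotFoundError(self.repeats)
        if self.step_bp > self.window_bp:
            raise ValueError("step must not exceed window")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["layout"] = list(self.sim.layout.chroms)
        return d


def run_pipeline(config: PipelineConfig, out_dir: str | None = None) -> dict:
    """Run every stage in order and return the machine-readable report.

    With ``out_dir`` set, window stats (TSV), candidate intervals (BED) and
    the report (JSON) are written under ``out_prefix``.
    """

    config.validate()
    report: dict = {"config": config.resolved(), "stages": {}}

    if config.simulate:
        sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
        sim = simulate_cross(sim_cfg, out_dir=None)
        table, mask, layout = sim.variants, sim.repeat_mask, sim_cfg.layout
        report["truth"] = {
            "causal_chrom": sim.truth.causal_chrom,
            "causal_pos": sim.truth.causal_pos,
            "core_start": sim.truth.core_start,
            "core_end": sim.truth.core_end,
        }
    else:
        role_map = {s: Role(r) for s, r in config.roles.items()}
        table = gio.read_variants(config.vcf, role_map, depth_fields=config.depth_fields)
        mask = gio.read_repeat_mask(config.repeats) if config.repeats else None
        layout = gio.read_genome_layout(config.layout) if config.layout else None
    report["stages"]["input"] = {"n_variants": len(table)}

    table, filter_report = quality_filter(table, config.filter)
    report["stages"]["quality_filter"] = dataclasses.asdict(filter_report)

    n_before = len(table)
    table = apply_repeat_mask(table, mask)
    report["stages"]["repeat_mask"] = {"n_input": n_before, "n_output": len(table)}

    informative = mark_informative(table, config.filter)
    report["stages"]["informative"] = {"n_informative": len(informative)}

    informative = call_cosegregation_table(informative, config.coseg)
    n_coseg = int((informative.df["coseg"] == 1).sum())
    n_unev = int((informative.df["coseg"] == -1).sum())
    report["stages"]["cosegregation"] = {"n_coseg": n_coseg, "n_unevaluable": n_unev}

    windows = window_scan(
        informative,
        layout=layout,
        window_bp=config.window_bp,
        step_bp=config.step_bp,
        min_informative=config.min_informative,
    )
    runs = find_runs(informative, min_run=config.min_run, max_interruptions=config.max_interruptions)
    intervals = call_candidate_intervals(runs)
    report["stages"]["scan"] = {"n_windows": len(windows), "n_runs": len(runs), "n_intervals": len(intervals)}
    report["intervals"] = [
        {
            "chrom": iv.chrom,
            "start": iv.start,
            "end": iv.end,
            "run_length": iv.run_length,
            "n_variants": iv.n_variants,
            "length_mb": iv.length_mb,
            "density_per_mb": iv.density,
        }
        for iv in intervals[:20]
    ]
    if intervals:
        report["top_interval"] = report["intervals"][0]

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        prefix = os.path.join(out_dir, config.out_prefix)
        gio.write_windows_tsv(windows, prefix + ".windows.tsv")
        gio.write_intervals_bed(intervals, prefix + ".intervals.bed")
        gio.write_report_json(report, prefix + ".report.json")
    report["_windows"] = windows
    report["_intervals"] = intervals
    report["_informative"] = informative
    return report
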