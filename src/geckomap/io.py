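"""Readers and writers for the standard formats at the pipeline boundary.

VCF is read with cyvcf2, gene models with gffutils + pyfaidx, repeat masks as
BED3 into interval trees.  The pipeline's own tabular outputs are TSV (window
stats), BED (candidate intervals) and JSON (run report).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .model import (
    CandidateInterval,
    GeneModel,
    GenomeLayout,
    Genotype,
    ROLE_PREFIX,
    Role,
    VariantTable,
    WindowStat,
    round_half_up,
)

log = logging.getLogger(__name__)

# cyvcf2 gt_types codes: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
_CYVCF2_GT = {0: Genotype.HOM_REF, 1: Genotype.HET, 2: Genotype.MISSING, 3: Genotype.HOM_ALT}


def _variant_class(ref: str, alt: str) -> str:
    if len(ref) == len(alt):
        return "SNP" if len(ref) == 1 else "MNP"
    return "INDEL"


def read_variants(
    vcf_path: str,
    role_map: dict[str, Role],
    *,
    depth_fields: tuple[str, ...] = ("AD",),
    multiallelic: str = "skip",
    require_depths: bool = True,
) -> VariantTable:
    """Read a 4-library VCF into a :class:`VariantTable`.

    ``role_map`` maps VCF sample names to :class:`Role`; all four roles must be
    present exactly once.  Depths come from ``AD`` (ref,alt per sample) or from
    the Platypus dialect ``("NR", "NV")`` (total and variant reads).  With
    ``require_depths=False`` absent depth fields fall back to GT-only mode
    (depths 0/0).  Multiallelic sites are skipped (counted in ``meta``) or
    split into per-alt records with ``multiallelic="split"``.
    """

    from cyvcf2 import VCF

    if multiallelic not in ("skip", "split"):
        raise ValueError("multiallelic must be 'skip' or 'split'")
    vcf = VCF(str(vcf_path), gts012=False)
    samples = list(vcf.samples)
    roles_seen = {}
    for s in samples:
        if s not in role_map:
            raise KeyError(f"sample {s!r} has no role mapping")
        roles_seen.setdefault(role_map[s], []).append(s)
    for role in Role:
        if role not in roles_seen:
            raise KeyError(f"no sample mapped to role {role.value}")
        if len(roles_seen[role]) > 1:
            raise ValueError(f"more than one sample mapped to role {role.value}")
    sample_idx = {role: samples.index(roles_seen[role][0]) for role in Role}

    rows: list[dict] = []
    n_multi = 0
    for v in vcf:
        alts = v.ALT
        if len(alts) != 1:
            n_multi += 1
            if multiallelic == "skip":
                continue
        gt_types = v.gt_types
        for ai, alt in enumerate(alts if multiallelic == "split" else alts[:1]):
            ref_d, alt_d = _depths_for(v, len(samples), depth_fields, require_depths, ai)
            row = {
                "chrom": v.CHROM,
                "start": v.start,
                "ref": v.REF,
                "alt": alt,
                "vclass": _variant_class(v.REF, alt),
                "qual": float(v.QUAL) if v.QUAL is not None else 0.0,
            }
            for role, p in ROLE_PREFIX.items():
                i = sample_idx[role]
                gt = _CYVCF2_GT.get(int(gt_types[i]), Genotype.MISSING)
                rd, ad = int(ref_d[i]), int(alt_d[i])
                if gt == Genotype.MISSING:
                    rd = ad = 0
                row[p + "_ref"], row[p + "_alt"], row[p + "_gt"] = rd, ad, int(gt)
            rows.append(row)
    df = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["chrom", "start", "ref", "alt", "vclass", "qual"]
    )
    table = VariantTable(df, meta={"n_multiallelic": n_multi, "source": str(vcf_path)})
    if n_multi:
        log.info("skipped/split %d multiallelic sites", n_multi)
    return table


def _depths_for(v, n_samples: int, depth_fields: tuple[str, ...], require: bool, alt_index: int = 0):
    """Extract per-sample (ref_depth, alt_depth) for one alt allele."""

    try:
        if list(depth_fields) == ["AD"]:
            ad = v.format("AD")
            if ad is None:
                raise KeyError("AD")
            ad = np.asarray(ad)
            ref_d = np.clip(ad[:, 0], 0, None)
            col = 1 + alt_index
            alt_d = np.clip(ad[:, col] if ad.shape[1] > col else 0, 0, None)
        else:  # Platypus NR/NV dialect
            nr = np.asarray(v.format(depth_fields[0]))[:, 0]
            nv = np.asarray(v.format(depth_fields[1]))[:, 0]
            nr = np.clip(nr, 0, None)
            nv = np.clip(nv, 0, None)
            ref_d, alt_d = nr - nv, nv
    except (KeyError, TypeError):
        if require:
            raise KeyError(
                f"depth field(s) {depth_fields} absent; pass require_depths=False for GT-only mode"
            )
        ref_d = np.zeros(n_samples, int)
        alt_d = np.zeros(n_samples, int)
    return ref_d, alt_d


def write_vcf(
    table: VariantTable,
    path: str,
    *,
    sample_names: dict[Role, str] | None = None,
    layout: GenomeLayout | None = None,
    header_extra: list[str] | None = None,
) -> None:
    """Write a :class:`VariantTable` as a deterministic, uncompressed VCF 4.2
    with GT:AD per library (byte-identical for identical inputs)."""

    sample_names = sample_names or {r: r.value for r in Role}
    gt_str = {Genotype.HOM_REF: "0/0", Genotype.HET: "0/1", Genotype.HOM_ALT: "1/1", Genotype.MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=geckomap\n")
        for line in header_extra or []:
            fh.write(line.rstrip("\n") + "\n")
        if layout is not None:
            for chrom, length in layout.chroms:
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        cols += [sample_names[r] for r in Role]
        fh.write("\t".join(cols) + "\n")
        df = table.df
        for r in df.itertuples(index=False):
            fields = [
                str(r.chrom),
                str(int(r.start) + 1),
                ".",
                str(r.ref),
                str(r.alt),
                f"{float(r.qual):.1f}",
                "PASS",
                ".",
                "GT:AD",
            ]
            for role in Role:
                p = ROLE_PREFIX[role]
                gt = gt_str[Genotype(int(getattr(r, p + "_gt")))]
                fields.append(f"{gt}:{int(getattr(r, p + '_ref'))},{int(getattr(r, p + '_alt'))}")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# repeat mask
# ---------------------------------------------------------------------------


@dataclass
class RepeatMask:
    """Merged repeat intervals per chromosome (0-based half-open)."""

    trees: dict[str, IntervalTree]

    @property
    def masked_bp(self) -> int:
        return sum(iv.end - iv.begin for t in self.trees.values() for iv in t)

    def contains(self, chrom: str, start: int) -> bool:
        """Membership of a variant by its 0-based start coordinate."""

        t = self.trees.get(chrom)
        return bool(t is not None and t.overlaps_point(start))

    def contains_pos(self, chrom: str, pos: int) -> bool:
        """Membership by 1-based position (VCF convention)."""

        return self.contains(chrom, pos - 1)

    def intervals(self, chrom: str) -> list[tuple[int, int]]:
        t = self.trees.get(chrom)
        return sorted((iv.begin, iv.end) for iv in t) if t else []


def read_repeat_mask(bed_path: str) -> RepeatMask:
    """Read a BED3 file into a merged-per-chromosome repeat mask."""

    trees: dict[str, IntervalTree] = {}
    with open(bed_path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{bed_path}:{ln}: expected >= 3 tab-separated fields")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as e:
                raise ValueError(f"{bed_path}:{ln}: malformed coordinates") from e
            if end <= start:
                raise ValueError(f"{bed_path}:{ln}: end must be > start")
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    for t in trees.values():
        t.merge_overlaps(strict=False)
    return RepeatMask(trees)


def mask_from_intervals(intervals: dict[str, list[tuple[int, int]]]) -> RepeatMask:
    trees = {c: IntervalTree.from_tuples(ivs) for c, ivs in intervals.items() if ivs}
    for t in trees.values():
        t.merge_overlaps(strict=False)
    return RepeatMask(trees)


def write_bed(intervals: dict[str, list[tuple[int, int]]], path: str) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(intervals):
            for s, e in sorted(intervals[chrom]):
                fh.write(f"{chrom}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


def read_gene_models(gff_path: str, fasta_path: str) -> list[GeneModel]:
    """Read GFF3 gene/mRNA/exon/CDS hierarchy plus FASTA into gene models.

    One model per mRNA.  Exon order is stored genomic; transcription order
    follows the strand.  A CDS length not divisible by 3 sets the model's
    ``frame_warning`` flag instead of failing.
    """

    import gffutils
    from pyfaidx import Fasta

    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    fa = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    models: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA"):
        exons = sorted((f.start - 1, f.end) for f in db.children(mrna, featuretype="exon"))
        cds = sorted((f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS"))
        if not exons or not cds:
            continue
        chrom = mrna.seqid
        model = GeneModel(
            gene_id=mrna.attributes.get("ID", [mrna.id])[0],
            chrom=chrom,
            strand=mrna.strand,
            exons=exons,
            cds_start=min(s for s, _ in cds),
            cds_end=max(e for _, e in cds),
            chrom_seq=str(fa[chrom][:]),
        )
        if model.frame_warning:
            log.warning("gene %s: CDS length %d not divisible by 3", model.gene_id, model.cds_length)
        models.append(model)
    return models


def write_gff3(models: list[GeneModel], path: str) -> None:
    """Write gene models as a minimal GFF3 gene/mRNA/exon/CDS hierarchy."""

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            g0, g1 = m.span
            gid = m.gene_id
            base = f"{m.chrom}\tgeckomap"
            fh.write(f"{base}\tgene\t{g0 + 1}\t{g1}\t.\t{m.strand}\t.\tID=gene-{gid}\n")
            fh.write(f"{base}\tmRNA\t{g0 + 1}\t{g1}\t.\t{m.strand}\t.\tID={gid};Parent=gene-{gid}\n")
            for i, (s, e) in enumerate(m.exons, 1):
                fh.write(
                    f"{base}\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\tID={gid}.exon{i};Parent={gid}\n"
                )
            for i, (s, e) in enumerate(m.exons, 1):
                cs, ce = max(s, m.cds_start), min(e, m.cds_end)
                if cs < ce:
                    fh.write(
                        f"{base}\tCDS\t{cs + 1}\t{ce}\t.\t{m.strand}\t0\tID={gid}.cds{i};Parent={gid}\n"
                    )


def write_fasta(seqs: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# sequencing arithmetic, layout and tabular outputs
# ---------------------------------------------------------------------------


def mean_coverage(n_read_pairs: int, read_length_bp: int, genome_size_bp: int) -> float:
    """Fold coverage of paired-end sequencing, rounded half-up to 1 decimal:
    ``n_read_pairs * 2 * read_length / genome_size``."""

    if genome_size_bp <= 0:
        raise ValueError("genome size must be > 0")
    if read_length_bp <= 0:
        raise ValueError("read length must be > 0")
    if n_read_pairs < 0:
        raise ValueError("read pair count must be >= 0")
    return round_half_up(n_read_pairs * 2 * read_length_bp / genome_size_bp, 1)


def read_genome_layout(path: str) -> GenomeLayout:
    chroms = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, length = line.split("\t")[:2]
            chroms.append((name, int(length)))
    return GenomeLayout(tuple(chroms))


def write_genome_layout(layout: GenomeLayout, path: str) -> None:
    with open(path, "w") as fh:
        for name, length in layout.chroms:
            fh.write(f"{name}\t{length}\n")


def write_windows_tsv(windows: list[WindowStat], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tn_informative\tn_coseg\tproportion\n")
        for w in windows:
            prop = "NA" if np.isnan(w.proportion) else f"{w.proportion:.6f}"
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.n_informative}\t{w.n_cosegregating}\t{prop}\n")


def write_intervals_bed(intervals: list[CandidateInterval], path: str) -> None:
    """BED with name=run_length;n_variants;density(1dp) and score=run length."""

    with open(path, "w") as fh:
        for iv in intervals:
            name = f"run={iv.run_length};n={iv.n_variants};density={round_half_up(iv.density, 1)}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{iv.run_length}\t.\n")


def write_report_json(report: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if hasattr(o, "__dict__"):
        return o.__dict__
    raise TypeError(f"not JSON serialisable: {type(o)}")
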