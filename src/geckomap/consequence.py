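"""Transcript and protein consequences of candidate variants.

Annotates variants against gene models (splice-donor/-acceptor disruption,
in-frame deletion, frameshift, coding substitution) and predicts the isoform
consequences the cross analysis cares about: single-exon skipping — the
typical outcome of a canonical splice-donor mutation — and retention of an
intron 5' prefix up to a cryptic donor.  The functional verdict is an
explicit heuristic: an isoform is POSSIBLY_FUNCTIONAL iff its reading frame
is preserved and no premature stop codon is introduced.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import NamedTuple

import numpy as np
from Bio.Seq import Seq

from .model import GeneModel, VariantObservation


class ConsequenceClass(str, Enum):
    INTERGENIC = "INTERGENIC"
    INTRONIC = "INTRONIC"
    SYNONYMOUS = "SYNONYMOUS"
    NONSYNONYMOUS = "NONSYNONYMOUS"
    INFRAME_DELETION = "INFRAME_DELETION"
    FRAMESHIFT = "FRAMESHIFT"
    SPLICE_DONOR_DISRUPTION = "SPLICE_DONOR_DISRUPTION"
    SPLICE_ACCEPTOR_DISRUPTION = "SPLICE_ACCEPTOR_DISRUPTION"


class IsoformKind(str, Enum):
    REFERENCE = "REFERENCE"
    EXON_SKIP = "EXON_SKIP"
    INTRON_PREFIX_RETENTION = "INTRON_PREFIX_RETENTION"


class Verdict(str, Enum):
    POSSIBLY_FUNCTIONAL = "POSSIBLY_FUNCTIONAL"
    LIKELY_NONFUNCTIONAL = "LIKELY_NONFUNCTIONAL"


@dataclass
class VariantConsequence:
    gene_id: str
    consequence: ConsequenceClass
    exonic_nt_removed: int = 0
    intronic_nt_removed: int = 0


@dataclass
class IsoformConsequence:
    kind: IsoformKind
    frame_preserved: bool
    protein_length: int
    missing_residues: tuple[int, int] | None  # 1-based inclusive
    premature_stop: bool
    functional_verdict: Verdict
    protein: str = ""
    start_lost: bool = False


class Translation(NamedTuple):
    protein: str
    has_stop: bool
    stop_is_terminal: bool


def translate_cds(cds_sequence: str) -> Translation:
    """Standard-code translation up to the first stop codon.

    ``stop_is_terminal`` is true when the first stop codon is the last
    complete codon of the input.  Trailing nucleotides beyond the last full
    codon are ignored.
    """

    if len(cds_sequence) == 0:
        raise ValueError("empty coding sequence")
    seq = cds_sequence.upper()
    if set(seq) - set("ACGT"):
        raise ValueError("sequence must be over {A,C,G,T}")
    n_codons = len(seq) // 3
    full = str(Seq(seq[: 3 * n_codons]).translate())
    stop_i = full.find("*")
    if stop_i == -1:
        return Translation(full, False, False)
    return Translation(full[:stop_i], True, stop_i == n_codons - 1)


class ProteinDiff(NamedTuple):
    delta: int
    missing_range: tuple[int, int] | None  # 1-based inclusive, in the reference
    mismatch: str | None


def protein_diff(reference_protein: str, variant_protein: str) -> ProteinDiff:
    """Longest-common-prefix/suffix decomposition of two proteins.

    Returns the contiguous missing block (1-based residue range in the
    reference, maximal-prefix alignment) when the difference is a single
    deletion; otherwise a mismatch summary.
    """

    if not reference_protein or not variant_protein:
        raise ValueError("proteins must be non-empty")
    ref, var = reference_protein, variant_protein
    if ref == var:
        return ProteinDiff(0, None, None)
    lcp = 0
    while lcp < min(len(ref), len(var)) and ref[lcp] == var[lcp]:
        lcp += 1
    lcs = 0
    while lcs < min(len(ref), len(var)) - lcp and ref[len(ref) - 1 - lcs] == var[len(var) - 1 - lcs]:
        lcs += 1
    delta = len(var) - len(ref)
    if delta < 0 and lcp + lcs >= len(var):
        lcs = len(var) - lcp
        return ProteinDiff(delta, (lcp + 1, len(ref) - lcs), None)
    n_mismatch = sum(a != b for a, b in zip(ref, var)) + abs(delta)
    return ProteinDiff(delta, None, f"{n_mismatch} differing positions (prefix {lcp}, suffix {lcs})")


# ---------------------------------------------------------------------------
# transcript assembly
# ---------------------------------------------------------------------------


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def build_transcript(
    gene: GeneModel,
    *,
    skip_tx_index: int | None = None,
    insertion: tuple[int, int] | None = None,
) -> tuple[str, int, int]:
    """Assemble a (possibly modified) mature transcript.

    ``skip_tx_index`` removes the exon with that 5'->3' transcription-order
    index; ``insertion`` splices an extra genomic interval (e.g. an intron
    prefix) into the transcript at its genomic position.  Returns
    ``(transcript_seq, cds_offset, insertion_offset)`` where ``cds_offset`` is
    the transcript coordinate of the first coding base (-1 if the start codon
    was removed) and ``insertion_offset`` the transcript coordinate of the
    inserted interval (-1 if none).
    """

    if gene.chrom_seq is None:
        raise ValueError("gene model carries no chromosome sequence")
    order = gene.transcription_order()
    pieces: list[tuple[int, int, str]] = []
    for tx_i, gi in enumerate(order):
        if tx_i == skip_tx_index:
            continue
        s, e = gene.exons[gi]
        pieces.append((s, e, "exon"))
    if insertion is not None:
        pieces.append((insertion[0], insertion[1], "insert"))
    pieces.sort()
    if gene.strand == "-":
        pieces = pieces[::-1]
    # first coding base on the genome (strand-aware)
    anchor = gene.cds_start if gene.strand == "+" else gene.cds_end - 1
    seq_parts: list[str] = []
    cds_offset = -1
    ins_offset = -1
    offset = 0
    for s, e, kind in pieces:
        part = gene.chrom_seq[s:e]
        if gene.strand == "-":
            part = _revcomp(part)
        if kind == "insert":
            ins_offset = offset
        elif s <= anchor < e:
            within = (anchor - s) if gene.strand == "+" else (e - 1 - anchor)
            cds_offset = offset + within
        seq_parts.append(part)
        offset += e - s
    return "".join(seq_parts), cds_offset, ins_offset


def reference_protein(gene: GeneModel) -> str:
    """Translation of the reference spliced CDS."""

    seq, cds_offset, _ = build_transcript(gene)
    if cds_offset < 0:
        raise ValueError("reference model has no start codon in its exons")
    return translate_cds(seq[cds_offset:]).protein


def spliced_cds(gene: GeneModel) -> str:
    """The concatenated coding sequence (exons clipped to the CDS span,
    transcription orientation)."""

    parts = []
    for gi in sorted(range(gene.n_exons)):
        s, e = gene.exons[gi]
        cs, ce = max(s, gene.cds_start), min(e, gene.cds_end)
        if cs < ce:
            parts.append(gene.chrom_seq[cs:ce])
    seq = "".join(parts)
    return _revcomp(seq) if gene.strand == "-" else seq


# ---------------------------------------------------------------------------
# isoform consequences
# ---------------------------------------------------------------------------


def _verdict(frame_preserved: bool, premature_stop: bool, start_lost: bool = False) -> Verdict:
    ok = frame_preserved and not premature_stop and not start_lost
    return Verdict.POSSIBLY_FUNCTIONAL if ok else Verdict.LIKELY_NONFUNCTIONAL


def skip_exon(gene: GeneModel, exon_index: int) -> IsoformConsequence:
    """Consequence of skipping one exon (0-based transcription-order index).

    The transcript is rebuilt without the exon, the CDS re-spliced and
    translated; the reading frame is preserved iff the exon's coding length is
    a multiple of 3.  Skipping the exon carrying the start codon is flagged
    (``start_lost``) and yields no translation.
    """

    order = gene.transcription_order()
    if not (0 <= exon_index < len(order)):
        raise IndexError("exon index out of range")
    gi = order[exon_index]
    coding_removed = gene.exon_coding_length(gi)
    if coding_removed == 0:
        raise ValueError("exon is entirely non-coding; skipping it does not change the protein")
    seq, cds_offset, _ = build_transcript(gene, skip_tx_index=exon_index)
    if cds_offset < 0:
        return IsoformConsequence(
            kind=IsoformKind.EXON_SKIP,
            frame_preserved=False,
            protein_length=0,
            missing_residues=None,
            premature_stop=False,
            functional_verdict=Verdict.LIKELY_NONFUNCTIONAL,
            start_lost=True,
        )
    ref_prot = reference_protein(gene)
    tr = translate_cds(seq[cds_offset:])
    frame_preserved = coding_removed % 3 == 0
    if frame_preserved:
        expected_len = len(ref_prot) - coding_removed // 3
        premature = len(tr.protein) < expected_len
    else:
        premature = tr.has_stop
    missing = None
    if frame_preserved and not premature:
        diff = protein_diff(ref_prot, tr.protein)
        missing = diff.missing_range
    return IsoformConsequence(
        kind=IsoformKind.EXON_SKIP,
        frame_preserved=frame_preserved,
        protein_length=len(tr.protein),
        missing_residues=missing,
        premature_stop=premature,
        functional_verdict=_verdict(frame_preserved, premature),
        protein=tr.protein,
    )


def retain_intron_prefix(gene: GeneModel, intron_index: int, prefix_nt: int) -> IsoformConsequence:
    """Consequence of retaining the first ``prefix_nt`` nucleotides of an
    intron (0-based transcription-order index; intron i follows exon i).

    The prefix — in transcript orientation — is inserted after the upstream
    exon and the product translated.  ``prefix_nt=0`` reproduces the
    reference isoform.
    """

    order = gene.transcription_order()
    n_introns = gene.n_exons - 1
    if not (0 <= intron_index < n_introns):
        raise IndexError("intron index out of range")
    introns = gene.introns
    gi = order[intron_index]  # upstream exon, genomic index
    if gene.strand == "+":
        s, e = introns[gi]
        interval = (s, s + prefix_nt)
    else:
        s, e = introns[gi - 1]
        interval = (e - prefix_nt, e)
    if prefix_nt > e - s:
        raise ValueError("prefix longer than the intron")
    if prefix_nt < 0:
        raise ValueError("prefix must be >= 0")
    ref_prot = reference_protein(gene)
    if prefix_nt == 0:
        return IsoformConsequence(
            kind=IsoformKind.REFERENCE,
            frame_preserved=True,
            protein_length=len(ref_prot),
            missing_residues=None,
            premature_stop=False,
            functional_verdict=Verdict.POSSIBLY_FUNCTIONAL,
            protein=ref_prot,
        )
    seq, cds_offset, ins_offset = build_transcript(gene, insertion=interval)
    if cds_offset < 0:
        raise ValueError("gene model has no start codon in its exons")
    tr = translate_cds(seq[cds_offset:])
    coding_inserted = prefix_nt if ins_offset >= cds_offset else 0
    frame_preserved = coding_inserted % 3 == 0
    if frame_preserved:
        expected_len = len(ref_prot) + coding_inserted // 3
        premature = len(tr.protein) < expected_len
    else:
        premature = tr.has_stop
    return IsoformConsequence(
        kind=IsoformKind.INTRON_PREFIX_RETENTION,
        frame_preserved=frame_preserved,
        protein_length=len(tr.protein),
        missing_residues=None,
        premature_stop=premature,
        functional_verdict=_verdict(frame_preserved, premature),
        protein=tr.protein,
    )


# ---------------------------------------------------------------------------
# variant classification
# ---------------------------------------------------------------------------


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def classify_variant(
    variant: VariantObservation, gene: GeneModel, splice_window: int = 2
) -> VariantConsequence:
    """Classify one variant against one gene model.

    Deletions overlapping the first ``splice_window`` intronic nucleotides
    after an exon (transcription orientation) disrupt the canonical donor
    site; the last ``splice_window`` intronic nucleotides are the acceptor.
    Exonic/intronic removed-nucleotide bookkeeping is returned for deletions
    (nucleotides outside any exon count as intronic).  Within-gene variants
    that touch neither coding sequence nor a splice window are reported
    INTRONIC (UTR-exonic variants are lumped here).
    """

    if variant.chrom != gene.chrom:
        raise ValueError(f"variant on {variant.chrom}, gene on {gene.chrom}")
    ref, alt = variant.ref, variant.alt
    is_deletion = len(ref) > len(alt) and ref.startswith(alt)
    is_insertion = len(alt) > len(ref) and alt.startswith(ref)
    if is_deletion:
        interval = (variant.start + len(alt), variant.start + len(ref))
    elif is_insertion:
        interval = (variant.start + len(ref), variant.start + len(ref))
    else:
        interval = (variant.start, variant.start + len(ref))

    g0, g1 = gene.span
    if interval[1] <= g0 or interval[0] >= g1:
        return VariantConsequence(gene.gene_id, ConsequenceClass.INTERGENIC)

    exonic = sum(_overlap(interval, ex) for ex in gene.exons)
    intronic = (interval[1] - interval[0]) - exonic if is_deletion else 0
    exonic_removed = exonic if is_deletion else 0
    coding = sum(
        _overlap(interval, (max(s, gene.cds_start), min(e, gene.cds_end)))
        for s, e in gene.exons
        if max(s, gene.cds_start) < min(e, gene.cds_end)
    )

    donor_windows, acceptor_windows = [], []
    for s, e in gene.introns:
        w = min(splice_window, e - s)
        if gene.strand == "+":
            donor_windows.append((s, s + w))
            acceptor_windows.append((e - w, e))
        else:
            donor_windows.append((e - w, e))
            acceptor_windows.append((s, s + w))
    touches = lambda wins: any(_overlap(interval, w) > 0 for w in wins)
    if is_insertion:
        # a pure insertion has a zero-length interval; test the junction point
        touches = lambda wins: any(w[0] < interval[0] < w[1] for w in wins)
    if touches(donor_windows):
        return VariantConsequence(
            gene.gene_id, ConsequenceClass.SPLICE_DONOR_DISRUPTION, exonic_removed, intronic
        )
    if touches(acceptor_windows):
        return VariantConsequence(
            gene.gene_id, ConsequenceClass.SPLICE_ACCEPTOR_DISRUPTION, exonic_removed, intronic
        )

    if is_deletion:
        if coding == 0:
            return VariantConsequence(gene.gene_id, ConsequenceClass.INTRONIC, exonic_removed, intronic)
        cls = ConsequenceClass.INFRAME_DELETION if coding % 3 == 0 else ConsequenceClass.FRAMESHIFT
        return VariantConsequence(gene.gene_id, cls, exonic_removed, intronic)
    if is_insertion:
        inside_cds = gene.cds_start < interval[0] < gene.cds_end and any(
            s < interval[0] < e for s, e in gene.exons
        )
        if not inside_cds:
            return VariantConsequence(gene.gene_id, ConsequenceClass.INTRONIC)
        n_ins = len(alt) - len(ref)
        cls = ConsequenceClass.NONSYNONYMOUS if n_ins % 3 == 0 else ConsequenceClass.FRAMESHIFT
        return VariantConsequence(gene.gene_id, cls)

    # substitution (SNP/MNP)
    if coding == 0:
        return VariantConsequence(gene.gene_id, ConsequenceClass.INTRONIC)
    if coding < len(ref):
        # substitution straddling a coding edge: conservatively protein-changing
        return VariantConsequence(gene.gene_id, ConsequenceClass.NONSYNONYMOUS)
    if gene.chrom_seq is None:
        raise ValueError("substitution effect requires the chromosome sequence")
    mutated = (
        gene.chrom_seq[: variant.start] + alt + gene.chrom_seq[variant.start + len(ref) :]
    )
    mut_gene = GeneModel(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        strand=gene.strand,
        exons=list(gene.exons),
        cds_start=gene.cds_start,
        cds_end=gene.cds_end,
        chrom_seq=mutated,
    )
    same = reference_protein(mut_gene) == reference_protein(gene)
    cls = ConsequenceClass.SYNONYMOUS if same else ConsequenceClass.NONSYNONYMOUS
    return VariantConsequence(gene.gene_id, cls)


# ---------------------------------------------------------------------------
# synthetic gene models
# ---------------------------------------------------------------------------

_AA_CYCLE = "ACDEFGHIKLNPQRSTVY"  # 18 residues, no M/W: unambiguous boundaries
_CODON = {
    "A": "GCT", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGA",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCA", "Q": "CAA", "R": "CGT", "S": "TCA", "T": "ACA", "V": "GTC",
    "W": "TGG", "Y": "TAT",
}


def make_synthetic_gene(
    coding_exon_lengths: list[int],
    *,
    protein: str | None = None,
    intron_lengths: list[int] | None = None,
    utr5: int = 60,
    utr3: int = 80,
    strand: str = "+",
    gene_id: str = "toy",
    chrom: str = "chrT",
    offset: int = 500,
    rng: np.random.Generator | None = None,
) -> GeneModel:
    """Build a fully specified synthetic gene model with its chromosome.

    ``coding_exon_lengths`` give the coding nucleotides per exon (their sum,
    including the stop codon, must be divisible by 3).  The protein is either
    supplied, drawn from ``rng``, or a deterministic cyclic pattern; it is
    reverse-translated codon-by-codon, so the translation oracle is string
    surgery.  Introns carry canonical GT..AG ends.
    """

    total_cds = sum(coding_exon_lengths)
    if total_cds % 3 != 0:
        raise ValueError("total coding length must be divisible by 3")
    n_aa = total_cds // 3 - 1  # minus the stop codon
    if protein is None:
        if rng is not None:
            protein = "M" + "".join(rng.choice(list(_AA_CYCLE), size=n_aa - 1))
        else:
            protein = "M" + "".join(_AA_CYCLE[i % len(_AA_CYCLE)] for i in range(n_aa - 1))
    if len(protein) != n_aa or not protein.startswith("M"):
        raise ValueError("protein must start with M and match the coding length")
    cds = "".join(_CODON[a] for a in protein) + "TAA"

    if intron_lengths is None:
        intron_lengths = [200 + 50 * i for i in range(len(coding_exon_lengths) - 1)]
    if len(intron_lengths) != len(coding_exon_lengths) - 1:
        raise ValueError("need one intron length per internal junction")

    filler = "TACG"
    fill = lambda n: (filler * (n // 4 + 1))[:n]
    # transcript-orientation genome assembly
    pieces = []
    cursor = 0
    exon_tx: list[tuple[int, int]] = []  # transcript-orientation coordinates
    pos = offset
    pieces.append(fill(offset))
    cds_cursor = 0
    for i, clen in enumerate(coding_exon_lengths):
        exon_seq = cds[cds_cursor : cds_cursor + clen]
        cds_cursor += clen
        if i == 0:
            exon_seq = fill(utr5) + exon_seq
        if i == len(coding_exon_lengths) - 1:
            exon_seq = exon_seq + fill(utr3)
        exon_tx.append((pos, pos + len(exon_seq)))
        pieces.append(exon_seq)
        pos += len(exon_seq)
        if i < len(intron_lengths):
            il = intron_lengths[i]
            if il < 4 + 2 * 1:
                raise ValueError("introns must be at least 6 nt")
            intron = "GT" + fill(il - 4) + "AG"
            pieces.append(intron)
            pos += il
    pieces.append(fill(300))
    genome_fwd = "".join(pieces)
    cds_start_tx = exon_tx[0][0] + utr5
    cds_end_tx = exon_tx[-1][1] - utr3

    if strand == "+":
        chrom_seq = genome_fwd
        exons = exon_tx
        cds_start, cds_end = cds_start_tx, cds_end_tx
    else:
        chrom_seq = _revcomp(genome_fwd)
        L = len(genome_fwd)
        exons = sorted((L - e, L - s) for s, e in exon_tx)
        cds_start, cds_end = L - cds_end_tx, L - cds_start_tx
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds_start=cds_start,
        cds_end=cds_end,
        chrom_seq=chrom_seq,
    )


def make_pax7_like_gene(strand: str = "+") -> GeneModel:
    """A five-exon toy gene encoding a 503-aa protein whose exon 4 contributes
    exactly the codons for residues 151-195 (the structure relevant to the
    donor-site deletion and exon-4 skip analysis)."""

    # codons 1-150 across exons 1-3, codons 151-195 in exon 4, rest + stop in exon 5
    return make_synthetic_gene(
        [150, 150, 150, 135, 927],
        intron_lengths=[300, 250, 400, 350],
        strand=strand,
        gene_id="pax7_toy",
    )
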