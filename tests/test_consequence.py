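import numpy as np
import pytest

from geckomap.consequence import (
    ConsequenceClass,
    IsoformKind,
    Verdict,
    build_transcript,
    classify_variant,
    make_pax7_like_gene,
    make_synthetic_gene,
    protein_diff,
    reference_protein,
    retain_intron_prefix,
    skip_exon,
    spliced_cds,
    translate_cds,
)
from geckomap.model import GeneModel, VariantClass

from conftest import make_variant

# independent translation oracle: standard code as a flat lookup, TCAG order
_CODE = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_IDX = {"T": 0, "C": 1, "A": 2, "G": 3}


def oracle_translate(seq):
    prot = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        c = seq[i : i + 3]
        aa = _CODE[16 * _IDX[c[0]] + 4 * _IDX[c[1]] + _IDX[c[2]]]
        if aa == "*":
            return "".join(prot)
        prot.append(aa)
    return "".join(prot)


# ---------------------------------------------------------------------------
# translation
# ---------------------------------------------------------------------------


def test_translate_minimal_orfs():
    t = translate_cds("ATGTAA")
    assert t.protein == "M" and t.has_stop and t.stop_is_terminal
    t2 = translate_cds("ATGAAATAG")
    assert t2.protein == "MK" and t2.stop_is_terminal
    t3 = translate_cds("ATGTAAAAA")  # stop followed by another codon
    assert t3.protein == "M" and not t3.stop_is_terminal


def test_translate_rejects_empty_and_non_dna():
    with pytest.raises(ValueError):
        translate_cds("")
    with pytest.raises(ValueError):
        translate_cds("ATGNNN")


def test_translate_matches_codon_table_oracle(rng):
    for _ in range(20):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        assert translate_cds(seq).protein == oracle_translate(seq)


# ---------------------------------------------------------------------------
# protein diff
# ---------------------------------------------------------------------------


def test_identical_proteins_diff_to_zero():
    d = protein_diff("MABCDEF", "MABCDEF")
    assert d.delta == 0 and d.missing_range is None and d.mismatch is None


def test_exon4_skip_diff_recovers_residues_151_to_195():
    gene = make_pax7_like_gene()
    ref = reference_protein(gene)
    var = skip_exon(gene, 3).protein
    d = protein_diff(ref, var)
    assert d.delta == -45 and d.missing_range == (151, 195)


def test_random_single_block_deletions_are_recovered(rng):
    aas = list("ACDEFGHIKLNPQRSTVWY")
    for _ in range(30):
        n = int(rng.integers(30, 120))
        ref = "".join(rng.choice(aas, size=n))
        i = int(rng.integers(1, n - 5))
        k = int(rng.integers(1, min(10, n - i)))
        var = ref[:i] + ref[i + k :]
        d = protein_diff(ref, var)
        assert d.delta == -k
        lo, hi = d.missing_range
        # alignment ambiguity allowed: the reported block must reproduce var
        assert hi - lo + 1 == k
        assert ref[: lo - 1] + ref[hi:] == var


def test_substitutions_yield_mismatch_summary():
    d = protein_diff("MABCDEF", "MABXDEF")
    assert d.missing_range is None and d.mismatch is not None


# ---------------------------------------------------------------------------
# exon skipping
# ---------------------------------------------------------------------------


def test_exon4_skip_of_503aa_gene_yields_458aa_frame_preserved():
    gene = make_pax7_like_gene()
    ref = reference_protein(gene)
    assert len(ref) == 503
    iso = skip_exon(gene, 3)
    assert iso.kind == IsoformKind.EXON_SKIP
    assert iso.frame_preserved and not iso.premature_stop
    assert iso.protein_length == 458
    assert iso.missing_residues == (151, 195)
    assert iso.functional_verdict == Verdict.POSSIBLY_FUNCTIONAL


def test_exon4_skip_on_reverse_strand_gene_is_identical():
    gene = make_pax7_like_gene(strand="-")
    iso = skip_exon(gene, 3)
    assert iso.protein_length == 458 and iso.missing_residues == (151, 195)


def test_skipping_100nt_exon_shifts_the_frame():
    gene = make_synthetic_gene([150, 100, 230])
    iso = skip_exon(gene, 1)
    assert not iso.frame_preserved
    assert iso.functional_verdict == Verdict.LIKELY_NONFUNCTIONAL


def test_skipping_start_codon_exon_is_flagged():
    gene = make_synthetic_gene([150, 150, 150])
    iso = skip_exon(gene, 0)
    assert iso.start_lost and iso.protein_length == 0
    assert iso.functional_verdict == Verdict.LIKELY_NONFUNCTIONAL


@pytest.mark.parametrize("strand", ["+", "-"])
def test_random_gene_skips_match_string_surgery_oracle(rng, strand):
    """Skipping any fully coding internal exon reproduces the translation of
    the CDS with that exon's substring excised."""

    for _ in range(8):
        n_exons = int(rng.integers(3, 6))
        lengths = [int(3 * rng.integers(20, 80)) for _ in range(n_exons)]
        if int(rng.integers(0, 2)):
            lengths[1] += 1  # sometimes out of frame
            lengths[2] += 2
        gene = make_synthetic_gene(lengths, strand=strand, rng=rng)
        cds = spliced_cds(gene)
        # a frameshifted ribosome reads past the CDS: append the 3'UTR
        if strand == "+":
            utr3 = gene.chrom_seq[gene.cds_end : gene.exons[-1][1]]
        else:
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            utr3 = "".join(comp[c] for c in reversed(gene.chrom_seq[gene.exons[0][0] : gene.cds_start]))
        skip_i = int(rng.integers(1, n_exons - 1))
        offset = sum(lengths[:skip_i])
        surgery = cds[:offset] + cds[offset + lengths[skip_i] :] + utr3
        iso = skip_exon(gene, skip_i)
        assert iso.protein == oracle_translate(surgery)
        if iso.frame_preserved and not iso.premature_stop:
            ref = reference_protein(gene)
            assert (len(ref) - iso.protein_length) * 3 == lengths[skip_i]


# ---------------------------------------------------------------------------
# intron prefix retention
# ---------------------------------------------------------------------------


def test_retaining_118nt_intron_prefix_disrupts_the_frame():
    gene = make_pax7_like_gene()
    iso = retain_intron_prefix(gene, 3, 118)
    assert iso.kind == IsoformKind.INTRON_PREFIX_RETENTION
    assert not iso.frame_preserved
    assert iso.functional_verdict == Verdict.LIKELY_NONFUNCTIONAL


def test_zero_prefix_is_the_reference_isoform():
    gene = make_pax7_like_gene()
    iso = retain_intron_prefix(gene, 3, 0)
    assert iso.kind == IsoformKind.REFERENCE
    assert iso.protein == reference_protein(gene)
    assert iso.functional_verdict == Verdict.POSSIBLY_FUNCTIONAL


def test_three_nt_prefix_without_stop_adds_one_residue():
    gene = make_pax7_like_gene()
    iso = retain_intron_prefix(gene, 3, 3)  # intron starts GT..: codon GTx = Val
    assert iso.frame_preserved and not iso.premature_stop
    assert iso.protein_length == 504


@pytest.mark.parametrize("strand", ["+", "-"])
def test_full_intron_retention_equals_merged_exon_model(strand):
    """Retaining a whole intron is the same transcript as a gene model in
    which the two flanking exons are merged across that intron."""

    gene = make_synthetic_gene([150, 150, 150], strand=strand)
    order = gene.transcription_order()
    gi = order[1] if strand == "+" else order[1]
    introns = gene.introns
    intron = introns[gi] if strand == "+" else introns[gi - 1]
    iso = retain_intron_prefix(gene, 1, intron[1] - intron[0])
    # merged-exon model: join the exons flanking that genomic intron
    exons = sorted(gene.exons)
    merged = []
    for s, e in exons:
        if merged and merged[-1][1] == intron[0] and s == intron[1]:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    merged_gene = GeneModel(
        gene_id="merged",
        chrom=gene.chrom,
        strand=gene.strand,
        exons=merged,
        cds_start=gene.cds_start,
        cds_end=gene.cds_end,
        chrom_seq=gene.chrom_seq,
    )
    seq_a, cds_a, _ = build_transcript(gene, insertion=(intron[0], intron[1]))
    seq_b, cds_b, _ = build_transcript(merged_gene)
    assert seq_a == seq_b and cds_a == cds_b
    assert iso.protein == oracle_translate(seq_b[cds_b:])


def test_prefix_bounds_validated():
    gene = make_pax7_like_gene()
    with pytest.raises(ValueError):
        retain_intron_prefix(gene, 3, 10_000)
    with pytest.raises(IndexError):
        retain_intron_prefix(gene, 9, 10)


# ---------------------------------------------------------------------------
# variant classification
# ---------------------------------------------------------------------------


def _deletion_variant(gene, del_start, del_len):
    """VCF-style left-anchored deletion removing [del_start, del_start+del_len)."""

    anchor = del_start - 1
    ref = gene.chrom_seq[anchor : del_start + del_len]
    alt = gene.chrom_seq[anchor]
    return make_variant(chrom=gene.chrom, start=anchor, ref=ref, alt=alt, vclass=VariantClass.INDEL)


def test_13nt_deletion_at_exon4_boundary_is_donor_disruption():
    gene = make_pax7_like_gene()
    exon4_end = gene.exons[3][1]
    v = _deletion_variant(gene, exon4_end - 6, 13)  # 6 exonic + 7 intronic nt
    c = classify_variant(v, gene)
    assert c.consequence == ConsequenceClass.SPLICE_DONOR_DISRUPTION
    assert c.exonic_nt_removed == 6 and c.intronic_nt_removed == 7


def test_13nt_boundary_deletion_on_reverse_strand():
    gene = make_pax7_like_gene(strand="-")
    # transcription exon 4 is genomic exon index 1; its donor intron is 3' in
    # transcript orientation = genomically *before* it
    gi = gene.transcription_order()[3]
    exon4_start = gene.exons[gi][0]
    v = _deletion_variant(gene, exon4_start - 7, 13)  # 7 intronic + 6 exonic
    c = classify_variant(v, gene)
    assert c.consequence == ConsequenceClass.SPLICE_DONOR_DISRUPTION
    assert c.exonic_nt_removed == 6 and c.intronic_nt_removed == 7


def test_6nt_inframe_coding_deletion_removes_two_residues():
    gene = make_pax7_like_gene()
    s = gene.exons[1][0] + 30
    v = _deletion_variant(gene, s, 6)
    c = classify_variant(v, gene)
    assert c.consequence == ConsequenceClass.INFRAME_DELETION
    assert c.exonic_nt_removed == 6 and c.intronic_nt_removed == 0


def test_frameshift_and_intronic_and_intergenic():
    gene = make_pax7_like_gene()
    fs = classify_variant(_deletion_variant(gene, gene.exons[1][0] + 30, 7), gene)
    assert fs.consequence == ConsequenceClass.FRAMESHIFT
    mid_intron = (gene.introns[0][0] + gene.introns[0][1]) // 2
    intronic = classify_variant(_deletion_variant(gene, mid_intron, 4), gene)
    assert intronic.consequence == ConsequenceClass.INTRONIC
    snp = make_variant(chrom=gene.chrom, start=5, ref="T", alt="C")
    assert classify_variant(snp, gene).consequence == ConsequenceClass.INTERGENIC


def test_deletion_bookkeeping_sums_to_length_on_gene_battery(rng):
    gene = make_pax7_like_gene()
    g0, g1 = gene.span
    for _ in range(40):
        start = int(rng.integers(g0 + 1, g1 - 40))
        length = int(rng.integers(1, 30))
        c = classify_variant(_deletion_variant(gene, start, length), gene)
        assert c.exonic_nt_removed + c.intronic_nt_removed == length


def test_synonymous_vs_nonsynonymous_snp():
    gene = make_pax7_like_gene()
    # codon 2 is 'A' -> GCT at CDS offset 3..6 in exon 1
    cds_pos = gene.exons[0][0] + 60 + 3  # 60 nt 5'UTR then codon 2
    assert gene.chrom_seq[cds_pos : cds_pos + 3] == "GCT"
    syn = make_variant(chrom=gene.chrom, start=cds_pos + 2, ref="T", alt="A")  # GCT->GCA = Ala
    non = make_variant(chrom=gene.chrom, start=cds_pos, ref="G", alt="A")  # GCT->ACT = Thr
    assert classify_variant(syn, gene).consequence == ConsequenceClass.SYNONYMOUS
    assert classify_variant(non, gene).consequence == ConsequenceClass.NONSYNONYMOUS


def test_acceptor_window_disruption():
    gene = make_pax7_like_gene()
    intron1_end = gene.introns[0][1]
    v = _deletion_variant(gene, intron1_end - 2, 2)
    assert classify_variant(v, gene).consequence == ConsequenceClass.SPLICE_ACCEPTOR_DISRUPTION


def test_wrong_chromosome_rejected():
    gene = make_pax7_like_gene()
    with pytest.raises(ValueError):
        classify_variant(make_variant(chrom="chrZ", start=100), gene)


# ---------------------------------------------------------------------------
# hypothesis properties
# ---------------------------------------------------------------------------

from hypothesis import given, settings, strategies as st

_AA = st.sampled_from("ACDEFGHIKLMNPQRSTVWY")


@settings(max_examples=80, deadline=None, derandomize=True)
@given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=6, max_size=60), st.data())
def test_protein_diff_reconstructs_any_single_deletion(ref, data):
    i = data.draw(st.integers(0, len(ref) - 2))
    k = data.draw(st.integers(1, len(ref) - 1 - i))
    var = ref[:i] + ref[i + k :]
    if not var:
        return
    d = protein_diff(ref, var)
    assert d.delta == -k
    lo, hi = d.missing_range
    assert ref[: lo - 1] + ref[hi:] == var and hi - lo + 1 == k
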