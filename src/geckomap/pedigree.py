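"""Genotype tallies, Mendelian expectations and segregation checks for the
crossing and genotyping data.

Genotype classes are written as allele pairs like ``"mss/mss"``, ``"mss/+"``
and ``"+/+"``; heterozygotes are canonicalised with the wild-type allele
(``+``) last.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


def canonical_genotype(genotype: str) -> str:
    alleles = genotype.split("/")
    if len(alleles) != 2 or not all(alleles):
        raise ValueError(f"malformed genotype {genotype!r}")
    alleles.sort(key=lambda a: (a == "+", a))
    return "/".join(alleles)


@dataclass
class GenotypeTally:
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be >= 0")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def count(self, genotype: str) -> int:
        return self.counts.get(canonical_genotype(genotype), 0)


def tally_genotypes(records, classes: tuple[str, ...] | None = None) -> GenotypeTally:
    """Count genotype class labels.  With ``classes`` given, any label outside
    the allowed set is an error; otherwise classes are taken from the data."""

    allowed = None if classes is None else {canonical_genotype(c) for c in classes}
    counts: dict[str, int] = {} if allowed is None else {c: 0 for c in allowed}
    for rec in records:
        g = canonical_genotype(rec)
        if allowed is not None and g not in allowed:
            raise ValueError(f"unknown genotype class {rec!r}")
        counts[g] = counts.get(g, 0) + 1
    return GenotypeTally(counts)


def expected_offspring_distribution(
    cross: tuple[str, str], alleles: tuple[str, str] = ("mss", "+")
) -> dict[str, float]:
    """Mendelian offspring genotype probabilities for a single biallelic
    autosomal locus, e.g. ``("mss/mss", "mss/+") -> {"mss/mss": .5,
    "mss/+": .5, "+/+": 0}``.  All three genotype classes over ``alleles``
    are reported, including those impossible for the cross."""

    p1 = canonical_genotype(cross[0]).split("/")
    p2 = canonical_genotype(cross[1]).split("/")
    probs: dict[str, float] = {}
    for a in p1:
        for b in p2:
            g = canonical_genotype(f"{a}/{b}")
            probs[g] = probs.get(g, 0.0) + 0.25
    universe = sorted(set(p1) | set(p2) | set(alleles), key=lambda a: (a == "+", a))
    for a in universe:
        for b in universe:
            probs.setdefault(canonical_genotype(f"{a}/{b}"), 0.0)
    return probs


@dataclass
class SegregationResult:
    statistic: float | None
    df: int | None
    pvalue: float | None
    method: str
    mendelian_violation: bool = False
    violating_classes: tuple[str, ...] = ()


def segregation_test(
    observed: GenotypeTally,
    expected: dict[str, float],
    *,
    method: str = "chi-square",
) -> SegregationResult:
    """Goodness-of-fit of an observed genotype tally to Mendelian expectation.

    Classes with zero expectation and zero observation are dropped.  A
    nonzero count in a zero-expectation class is a Mendelian violation and
    yields no p-value.  The default is the chi-square test without continuity
    correction; ``method="binomial"`` runs an exact binomial test for
    two-class crosses.
    """

    if observed.total <= 0:
        raise ValueError("observed total must be > 0")
    classes = sorted(set(observed.counts) | set(expected), key=lambda g: (g.count("+"), g))
    obs = np.array([observed.counts.get(c, 0) for c in classes], float)
    exp_p = np.array([expected.get(c, 0.0) for c in classes], float)
    violating = [c for c, o, p in zip(classes, obs, exp_p) if p == 0 and o > 0]
    if violating:
        return SegregationResult(None, None, None, method, True, tuple(violating))
    keep = exp_p > 0
    obs, exp_p, classes = obs[keep], exp_p[keep], [c for c, k in zip(classes, keep) if k]
    if not np.isclose(exp_p.sum(), 1.0):
        raise ValueError("expected probabilities must sum to 1 over retained classes")
    if method == "binomial":
        if len(classes) != 2:
            raise ValueError("the exact binomial test needs exactly two classes")
        res = stats.binomtest(int(obs[0]), int(obs.sum()), exp_p[0])
        return SegregationResult(None, None, float(res.pvalue), "binomial")
    if method != "chi-square":
        raise ValueError("method must be 'chi-square' or 'binomial'")
    exp = exp_p * obs.sum()
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    dof = len(classes) - 1
    p = float(stats.chi2.sf(chi2, dof)) if dof > 0 else 1.0
    return SegregationResult(chi2, dof, p, "chi-square")


def amplicon_genotype(
    wild_allele_product_bp: int, deletion_bp: int, observed_product_lengths
) -> str:
    """Genotype from the PCR products of primers flanking a deletion: the wild
    allele amplifies at the full length, the deletion allele ``deletion_bp``
    shorter; heterozygotes show both products."""

    if deletion_bp <= 0:
        raise ValueError("deletion_bp must be > 0")
    observed = set(observed_product_lengths)
    if not observed:
        raise ValueError("no observed product lengths")
    wild = wild_allele_product_bp
    mutant = wild - deletion_bp
    unexpected = observed - {wild, mutant}
    if unexpected:
        raise ValueError(f"unexpected product length(s): {sorted(unexpected)}")
    if observed == {wild, mutant}:
        return "mss/+"
    if observed == {mutant}:
        return "mss/mss"
    return "+/+"
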