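"""Candidate-gene reduction inside the GWAS peak.

Annotated variants (SnpEff-style impact classes, consumed as input) are
reduced to candidate genes by three rules: the variant must fall in the
associated region; its predicted impact must be HIGH or MODERATE; and
its alternate-allele frequency in the two serologically opposing
homozygote groups must show a hard contrast -- >= 0.9 in one group and
exactly 0 in the other (zero observed alternate alleles, not a
tolerance).  Genes are ranked membrane-annotated first (GO:0005886,
plasma membrane), then by the number of passing variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotatedVariant",
    "GeneInfo",
    "CandidateGene",
    "MEMBRANE_GO",
    "group_allele_freq",
    "contrast_filter",
    "candidate_genes",
]

MEMBRANE_GO = "GO:0005886"
QUALIFYING_IMPACTS = frozenset({"HIGH", "MODERATE"})
IMPACT_CLASSES = frozenset({"HIGH", "MODERATE", "LOW", "MODIFIER"})


@dataclass(frozen=True)
class AnnotatedVariant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene_id: str
    impact: str
    fa_group1: float | None = None  # alt-allele freq, homozygote group 1
    fa_group2: float | None = None

    def __post_init__(self) -> None:
        if self.impact not in IMPACT_CLASSES:
            raise ValueError(f"unknown impact class {self.impact!r}")
        for f in (self.fa_group1, self.fa_group2):
            if f is not None and not 0.0 <= f <= 1.0:
                raise ValueError(f"allele frequency {f} outside [0, 1]")


@dataclass(frozen=True)
class GeneInfo:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    go_terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")

    @property
    def is_membrane(self) -> bool:
        return MEMBRANE_GO in self.go_terms


@dataclass
class CandidateGene:
    gene: GeneInfo
    passing_variants: list[AnnotatedVariant]

    @property
    def n_passing(self) -> int:
        return len(self.passing_variants)


def group_allele_freq(dosage, group_ids) -> "np.ndarray":
    """Per-variant alternate-allele frequency within a sample group.

    ``dosage``: samples x variants DataFrame of alt dosages (NaN missing).
    Frequency = alt count / (2 x non-missing samples); variants with all
    calls missing get NaN and are logged.
    """
    group_ids = list(group_ids)
    if not group_ids:
        raise ValueError("empty sample group")
    sub = dosage.loc[group_ids]
    n_called = sub.notna().sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = sub.sum(axis=0, skipna=True) / (2.0 * n_called)
    freq[n_called == 0] = np.nan
    for snp in sub.columns[n_called == 0]:
        logger.warning("variant %s: all calls missing in group; skipped", snp)
    return freq


def contrast_filter(fa1: float, fa2: float, hi: float = 0.9) -> bool:
    """Hard homozygote-group contrast: >=hi in one group, exactly 0 in the other."""
    if fa1 is None or fa2 is None or not np.isfinite(fa1) or not np.isfinite(fa2):
        return False
    return (fa1 >= hi and fa2 == 0.0) or (fa2 >= hi and fa1 == 0.0)


def candidate_genes(
    variants,
    genes,
    peak: tuple[str, int, int],
    impacts: frozenset[str] = QUALIFYING_IMPACTS,
    membrane_go: str = MEMBRANE_GO,
    hi: float = 0.9,
) -> list[CandidateGene]:
    """Rank genes in the peak that carry qualifying contrast variants.

    A gene qualifies if it overlaps the peak interval (any-bp overlap,
    1-based inclusive) and has >= 1 variant of qualifying impact passing
    the frequency-contrast rule.  Ranking: membrane-annotated genes
    first, then by passing-variant count (descending), then gene_id.
    """
    chrom, start, end = peak
    by_gene: dict[str, list[AnnotatedVariant]] = {}
    for v in variants:
        if v.impact not in impacts:
            continue
        if not (v.chrom == chrom and start <= v.pos <= end):
            continue
        if contrast_filter(v.fa_group1, v.fa_group2, hi=hi):
            by_gene.setdefault(v.gene_id, []).append(v)

    out = []
    for g in genes:
        if g.chrom != chrom or g.end < start or g.start > end:
            continue
        passing = [v for v in by_gene.get(g.gene_id, []) if g.start <= v.pos <= g.end]
        if passing:
            out.append(CandidateGene(gene=g, passing_variants=sorted(
                passing, key=lambda v: (v.pos, v.alt))))
    is_mem = lambda c: membrane_go in c.gene.go_terms  # noqa: E731
    out.sort(key=lambda c: (not is_mem(c), -c.n_passing, c.gene.gene_id))
    return out
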