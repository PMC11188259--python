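"""Serology vs SNP-haplotype concordance.

A serological genotype (e.g. I2/I8) agrees with a called diplotype
(e.g. H01/H02) when the two haplotypes can be assigned one-to-one to the
two serological alleles under an allele->haplotype map.  Reports give
the per-line cross-tabulation, per-class accuracies (each homozygote
class and the heterozygote class) and the overall percentage, rounded
half away from zero to a whole percent -- the convention behind the
published 82/92/99% figures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .fixtures import CrosstabCell, LineCrosstab

__all__ = ["match", "ClassStats", "ConcordanceReport", "concordance", "concordance_from_crosstab"]


def pct_round(k: int, n: int) -> int:
    """Integer percent, round half away from zero."""
    if n == 0:
        raise ZeroDivisionError("empty class")
    return int(math.floor(100.0 * k / n + 0.5))


def match(
    serology: tuple[str, str],
    diplotype: tuple[str, str],
    allele_map: dict[str, frozenset[str] | set[str]],
) -> bool:
    """True iff the haplotype pair can realise the serological genotype.

    There must exist an assignment of the two haplotypes to the two
    serological alleles with each haplotype in the mapped set of its
    assigned allele.  Symmetric in the order of both pairs.
    """
    s1, s2 = serology
    h1, h2 = diplotype
    for s in (s1, s2):
        if s not in allele_map:
            raise KeyError(f"serological allele {s!r} not in allele map")
    m1, m2 = allele_map[s1], allele_map[s2]
    return (h1 in m1 and h2 in m2) or (h1 in m2 and h2 in m1)


@dataclass
class ClassStats:
    n: int
    n_concordant: int

    @property
    def pct(self) -> int:
        return pct_round(self.n_concordant, self.n)


@dataclass
class ConcordanceReport:
    line_id: str
    crosstab: dict[tuple[tuple[str, str], tuple[str, str]], int]
    n_total: int
    n_concordant: int
    per_class: dict[str, ClassStats]
    n_ambiguous: int = 0  # samples excluded for a non-unique diplotype call

    @property
    def overall_pct(self) -> int:
        return pct_round(self.n_concordant, self.n_total)

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "line_id": self.line_id,
                "serology": "/".join(ser),
                "diplotype": "/".join(dip),
                "n": n,
            }
            for (ser, dip), n in sorted(self.crosstab.items())
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Concordance report: {self.line_id}",
            f"  overall: {self.n_concordant}/{self.n_total} = {self.overall_pct}%",
        ]
        for label, st in sorted(self.per_class.items()):
            lines.append(
                f"  {label}: {st.n_concordant}/{st.n} = {st.pct}%"
            )
        if self.n_ambiguous:
            lines.append(f"  excluded (ambiguous diplotype): {self.n_ambiguous}")
        return "\n".join(lines)


def _class_label(serology: tuple[str, str]) -> str:
    return "/".join(sorted(serology))


def concordance_from_crosstab(tab: LineCrosstab) -> ConcordanceReport:
    """Score a pre-counted serology x diplotype cross-tabulation."""
    crosstab: dict = {}
    per_class: dict[str, ClassStats] = {}
    n_total = n_conc = 0
    for cell in tab.cells:
        key = (cell.serology, cell.diplotype)
        crosstab[key] = crosstab.get(key, 0) + cell.n
        ok = match(cell.serology, cell.diplotype, tab.allele_map)
        label = _class_label(cell.serology)
        st = per_class.setdefault(label, ClassStats(0, 0))
        st.n += cell.n
        n_total += cell.n
        if ok:
            st.n_concordant += cell.n
            n_conc += cell.n
    return ConcordanceReport(
        line_id=tab.line_id,
        crosstab=crosstab,
        n_total=n_total,
        n_concordant=n_conc,
        per_class=per_class,
    )


def concordance(
    samples,
    allele_maps: dict[str, dict[str, frozenset[str]]],
    exclude_ambiguous: bool = True,
) -> tuple[dict[str, ConcordanceReport], ConcordanceReport]:
    """Per-line and aggregate concordance from per-sample records.

    ``samples`` is an iterable of objects/tuples
    ``(line_id, serology pair, DiplotypeCall-or-haplotype-pair)``.
    Samples whose diplotype call is not unique are counted separately
    and, by default, excluded from the denominator (the panel yields
    unique calls in practice; ambiguity arises only for short
    haplotypes in the heterozygous state).

    The aggregate pools raw counts across lines, each line scored under
    its own allele map.
    """
    cells_by_line: dict[str, list[CrosstabCell]] = {}
    ambiguous: dict[str, int] = {}
    for rec in samples:
        line_id, serology, dip = rec
        if hasattr(dip, "unique"):  # DiplotypeCall
            if not dip.unique:
                ambiguous[line_id] = ambiguous.get(line_id, 0) + 1
                if exclude_ambiguous:
                    continue
                # fall back to an arbitrary-but-deterministic compatible pair
                dip_pair = min(dip.compatible_pairs) if dip.compatible_pairs else None
                if dip_pair is None:
                    continue
            else:
                dip_pair = dip.best_pair
        else:
            dip_pair = tuple(dip)
        cells_by_line.setdefault(line_id, []).append(
            CrosstabCell(
                serology=tuple(sorted(serology)),
                diplotype=tuple(sorted(dip_pair)),
                n=1,
            )
        )

    reports: dict[str, ConcordanceReport] = {}
    for line_id, cells in sorted(cells_by_line.items()):
        tab = LineCrosstab(
            line_id=line_id, allele_map=allele_maps[line_id], cells=tuple(cells)
        )
        rep = concordance_from_crosstab(tab)
        rep.n_ambiguous = ambiguous.get(line_id, 0)
        reports[line_id] = rep
    return reports, aggregate_reports(reports.values())


def aggregate_reports(reports) -> ConcordanceReport:
    """Pool counts across per-line reports into one aggregate report."""
    crosstab: dict = {}
    per_class: dict[str, ClassStats] = {}
    n_total = n_conc = n_amb = 0
    for rep in reports:
        for key, n in rep.crosstab.items():
            crosstab[key] = crosstab.get(key, 0) + n
        for label, st in rep.per_class.items():
            agg = per_class.setdefault(label, ClassStats(0, 0))
            agg.n += st.n
            agg.n_concordant += st.n_concordant
        n_total += rep.n_total
        n_conc += rep.n_concordant
        n_amb += rep.n_ambiguous
    return ConcordanceReport(
        line_id="ALL",
        crosstab=crosstab,
        n_total=n_total,
        n_concordant=n_conc,
        per_class=per_class,
        n_ambiguous=n_amb,
    )
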