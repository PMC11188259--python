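"""Packaged reference data.

Two kinds of fixture live here:

* the published 15-SNP *RHCE* panel and its 16 known haplotype profiles
  (transcribed from the defining study's haplotype table), and
* the per-line serology x diplotype cross-tabulations reported for the
  five sample sets with I-system segregation (WL1, WL2, WL7 and the two
  NIU DNA-bank sets).

Cross-tab cells the source reports only in aggregate (e.g. the exact
diplotype of a single discordant bird, or the heterozygote breakdown of
the NIU sets) are filled with the minimal het/hom-confusion pattern
consistent with the reported per-line consistency rates; such cells are
flagged ``printed=False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .panel import ALT, DEL, REF, HaplotypeProfile, HaplotypeTable, PanelSNP

__all__ = [
    "fixture_table2",
    "fixture_line_crosstabs",
    "CrosstabCell",
    "LineCrosstab",
    "GLOBAL_ALLELE_MAP",
]

# serological allele -> haplotypes it detects, pooled over all lines
GLOBAL_ALLELE_MAP: dict[str, frozenset[str]] = {
    "I2": frozenset({"H02"}),
    "I8": frozenset({"H01", "H03", "H04", "H10"}),
    "I4": frozenset({"H03"}),
    "I3": frozenset({"H11"}),
}

# H07 and H16 were discovered in different lines (RIR1 vs WL6) but share
# an identical panel projection: all-reference over the retained SNPs
# 1-7 and deleted over 8-15.  The panel alone cannot separate them.
PANEL_EQUIVALENT = frozenset({frozenset({"H07", "H16"})})


def _data_text(name: str) -> str:
    return resources.files("iblood.data").joinpath(name).read_text()


def fixture_table2() -> HaplotypeTable:
    """Load and validate the packaged panel/haplotype table.

    Returns exactly 15 SNPs in genomic order and the 16 haplotypes
    H01-H08, H10-H17, with serological annotations for H01, H02, H03,
    H04, H10 and H11 and deleted trailing blocks for the four short
    haplotypes H07, H12, H13 and H16.
    """
    import io

    snp_df = pd.read_csv(io.StringIO(_data_text("rhce_panel_snps.tsv")), sep="\t")
    hap_df = pd.read_csv(
        io.StringIO(_data_text("rhce_haplotypes.tsv")), sep="\t", index_col="rsid"
    )
    sero_df = pd.read_csv(
        io.StringIO(_data_text("rhce_serology.tsv")), sep="\t", index_col="haplotype"
    )

    snps = tuple(
        PanelSNP(
            rsid=r.rsid,
            chrom=str(r.chrom),
            pos=int(r.pos),
            ref=r.ref,
            alt=r.alt,
            order_index=int(r.order_index),
            build=r.build,
            exon=r.exon,
            codon_change=r.codon_change,
            aa_change=r.aa_change,
        )
        for r in snp_df.itertuples()
    )

    haplotypes: dict[str, HaplotypeProfile] = {}
    for name in hap_df.columns:
        states = []
        for snp in snps:
            base = hap_df.at[snp.rsid, name]
            if base == "-":
                states.append(DEL)
            elif base == snp.ref:
                states.append(REF)
            elif base == snp.alt:
                states.append(ALT)
            else:
                raise ValueError(
                    f"haplotype table row {snp.rsid}, column {name}: base {base!r} "
                    f"is neither ref {snp.ref!r} nor alt {snp.alt!r}"
                )
        sero = sero_df.at[name, "serological_alleles"]
        sources = sero_df.at[name, "sources"]
        haplotypes[name] = HaplotypeProfile(
            name=name,
            alleles=tuple(states),
            serological_alleles=(
                frozenset() if sero == "." else frozenset(sero.split(","))
            ),
            sources=tuple(sources.split(",")) if isinstance(sources, str) else (),
        )

    table = HaplotypeTable(
        snps=snps, haplotypes=haplotypes, panel_equivalent=PANEL_EQUIVALENT
    )
    errors = table.validate()
    if errors:
        raise ValueError("corrupt packaged haplotype table: " + "; ".join(errors))
    return table


@dataclass(frozen=True)
class CrosstabCell:
    """One cell of a serology x diplotype cross-tab."""

    serology: tuple[str, str]  # unordered serological genotype
    diplotype: tuple[str, str]  # unordered haplotype pair
    n: int
    printed: bool = True  # False: filled in, only the marginal was reported


@dataclass(frozen=True)
class LineCrosstab:
    line_id: str
    allele_map: dict[str, frozenset[str]]
    cells: tuple[CrosstabCell, ...]

    @property
    def n_total(self) -> int:
        return sum(c.n for c in self.cells)


def _cells(rows, printed_default=True) -> tuple[CrosstabCell, ...]:
    out = []
    for row in rows:
        ser, dip, n, *rest = row
        printed = rest[0] if rest else printed_default
        out.append(
            CrosstabCell(
                serology=tuple(sorted(ser)),
                diplotype=tuple(sorted(dip)),
                n=int(n),
                printed=printed,
            )
        )
    return tuple(out)


def fixture_line_crosstabs() -> dict[str, LineCrosstab]:
    """The five reported serology x diplotype cross-tabulations.

    Counts follow the published per-line narratives: e.g. for WL1 all 19
    I2I2 birds were H02 homozygotes; of 28 serological I8I8 birds 14 were
    H01/H01 and 14 H01/H02; of 42 I2I8 birds 40 were H01/H02 and 2
    H01/H01.  WL2 heterozygotes are encoded H02/H03 (the line carries H02
    and H03; the printed "H01 and H03" is treated as typographical).
    """
    wl1 = LineCrosstab(
        line_id="WL1",
        allele_map={"I2": frozenset({"H02"}), "I8": frozenset({"H01"})},
        cells=_cells(
            [
                (("I2", "I2"), ("H02", "H02"), 19),
                (("I8", "I8"), ("H01", "H01"), 14),
                (("I8", "I8"), ("H01", "H02"), 14),
                (("I2", "I8"), ("H01", "H02"), 40),
                (("I2", "I8"), ("H01", "H01"), 2),
            ]
        ),
    )
    wl2 = LineCrosstab(
        line_id="WL2",
        allele_map={"I2": frozenset({"H02"}), "I8": frozenset({"H03"})},
        cells=_cells(
            [
                (("I2", "I2"), ("H02", "H02"), 29),
                (("I8", "I8"), ("H03", "H03"), 6),
                (("I8", "I8"), ("H02", "H03"), 1, False),
                (("I2", "I8"), ("H02", "H03"), 38),
                (("I2", "I8"), ("H03", "H03"), 5),
            ]
        ),
    )
    wl7 = LineCrosstab(
        line_id="WL7",
        allele_map={"I2": frozenset({"H02"}), "I8": frozenset({"H01"})},
        cells=_cells(
            [
                (("I2", "I2"), ("H02", "H02"), 4),
                (("I8", "I8"), ("H01", "H01"), 15),
                (("I2", "I8"), ("H01", "H02"), 32),
                (("I2", "I8"), ("H01", "H01"), 11),
            ]
        ),
    )
    niu_map = {"I2": frozenset({"H02"}), "I8": frozenset({"H03", "H04"})}
    niu_ped = LineCrosstab(
        line_id="NIU-pedigree",
        allele_map=niu_map,
        cells=_cells(
            [
                (("I2", "I2"), ("H02", "H02"), 21),
                (("I8", "I8"), ("H04", "H04"), 5),
                (("I8", "I8"), ("H03", "H03"), 1),
                (("I8", "I8"), ("H02", "H04"), 2, False),
                (("I8", "I8"), ("H02", "H03"), 1, False),
                (("I2", "I8"), ("H02", "H04"), 6, False),
                (("I2", "I8"), ("H02", "H03"), 3, False),
                (("I2", "I8"), ("H04", "H04"), 1, False),
            ]
        ),
    )
    niu_nonped = LineCrosstab(
        line_id="NIU-non-pedigree",
        allele_map=niu_map,
        cells=_cells(
            [
                (("I2", "I2"), ("H02", "H02"), 15),
                (("I2", "I2"), ("H02", "H03"), 1, False),
                (("I8", "I8"), ("H03", "H03"), 38),
                (("I8", "I8"), ("H02", "H03"), 2, False),
                (("I2", "I8"), ("H02", "H03"), 26, False),
                (("I2", "I8"), ("H03", "H03"), 6, False),
            ]
        ),
    )
    return {
        t.line_id: t for t in (wl1, wl2, wl7, niu_ped, niu_nonped)
    }
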