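"""RHCE 15-SNP panel haplotypes and diplotype calling.

The chicken I blood system is encoded by *RHCE* on microchromosome 23.
A panel of 15 coding SNPs across the gene defines a closed set of known
haplotypes (H01-H17); a diploid sample genotyped on the panel carries an
unordered pair of them (a diplotype).  Four haplotypes are "short": the
3' end of the gene is deleted, so allele-specific PCR yields no product
(FAIL) over the trailing SNP block.  A full/short heterozygote amplifies
only the full chromosome at those sites and therefore *appears*
homozygous there -- short haplotypes are only directly observable in the
homozygous (FAIL) state.  Diplotype calling must enumerate every
haplotype pair whose expected panel genotype matches the observation
exactly and flag this ambiguity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

__all__ = [
    "REF",
    "ALT",
    "DEL",
    "CALLS",
    "PanelSNP",
    "HaplotypeProfile",
    "HaplotypeTable",
    "PanelGenotype",
    "DiplotypeCall",
    "expected_genotype",
    "call_diplotype",
    "predict_serology",
    "epitope_class",
    "validate_table",
]

# allele states of a haplotype at a panel SNP
REF = "REF"
ALT = "ALT"
DEL = "DEL"  # site lies inside the haplotype's deleted span

# diploid panel calls (allele-specific PCR readout)
CALLS = ("RR", "RA", "AA", "FAIL")

# 1-based order indices of the six epitope SNPs (L43F .. Y147H, exons 2-3)
# that consistently separate the I2 haplotype from the four I8 haplotypes.
EPITOPE_SPAN = (4, 9)


@dataclass(frozen=True)
class PanelSNP:
    """One assayed SNP of the gene panel."""

    rsid: str
    chrom: str
    pos: int  # 1-based bp in the build given by `build`
    ref: str
    alt: str
    order_index: int  # 1..n_snps, genomic order
    build: str = ""
    exon: str = ""
    codon_change: str = ""
    aa_change: str = ""

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.rsid}: ref and alt alleles are identical")


@dataclass(frozen=True)
class HaplotypeProfile:
    """A named haplotype: one allele state per panel SNP.

    DEL entries, if present, must form a contiguous trailing block
    (the deletion removes the 3' end of the gene).
    """

    name: str
    alleles: tuple[str, ...]  # over {REF, ALT, DEL}
    serological_alleles: frozenset[str] = frozenset()
    sources: tuple[str, ...] = ()

    @property
    def is_short(self) -> bool:
        return DEL in self.alleles

    def bases(self, snps: tuple[PanelSNP, ...]) -> tuple[str, ...]:
        """Render the profile as actual bases ('-' inside the deletion)."""
        out = []
        for snp, state in zip(snps, self.alleles):
            out.append("-" if state == DEL else (snp.ref if state == REF else snp.alt))
        return tuple(out)


@dataclass
class HaplotypeTable:
    """The panel definition: SNPs in genomic order plus known haplotypes.

    ``panel_equivalent`` declares pairs of haplotype names that are known
    to share an identical panel profile (distinct haplotypes discovered in
    different populations that the 15-SNP projection cannot separate).
    Undeclared duplicate profiles are validation errors.
    """

    snps: tuple[PanelSNP, ...]
    haplotypes: dict[str, HaplotypeProfile]
    panel_equivalent: frozenset[frozenset[str]] = frozenset()

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def names(self) -> list[str]:
        return sorted(self.haplotypes)

    def __getitem__(self, name: str) -> HaplotypeProfile:
        return self.haplotypes[name]

    def pairs(self) -> list[tuple[str, str]]:
        """All unordered haplotype pairs, with repetition (n*(n+1)/2)."""
        return list(itertools.combinations_with_replacement(self.names(), 2))

    def representative(self, name: str) -> str:
        """Canonical name of a haplotype's panel-equivalence class.

        Declared panel-equivalent haplotypes share an allele vector; the
        lexicographically smallest name represents the class.
        """
        for group in self.panel_equivalent:
            if name in group:
                return min(group)
        return name

    def expected_genotype(self, a: str, b: str) -> tuple[str, ...]:
        return expected_genotype(self.haplotypes[a], self.haplotypes[b])

    def validate(self) -> list[str]:
        return validate_table(self)


@dataclass(frozen=True)
class PanelGenotype:
    """One sample's diploid panel readout."""

    sample_id: str
    calls: tuple[str, ...]  # over {RR, RA, AA, FAIL}

    def __post_init__(self) -> None:
        bad = [c for c in self.calls if c not in CALLS]
        if bad:
            raise ValueError(f"malformed panel calls: {sorted(set(bad))}")


@dataclass
class DiplotypeCall:
    """Result of matching a sample's panel genotype against the table."""

    sample_id: str
    compatible_pairs: frozenset[tuple[str, str]]
    unique: bool
    short_ambiguous: bool
    novel: bool
    inferred_alleles: tuple[str, ...] | None = None  # for novel homozygous profiles

    @property
    def best_pair(self) -> tuple[str, str] | None:
        if self.unique:
            return next(iter(self.compatible_pairs))
        return None


def expected_genotype(
    hap_a: HaplotypeProfile, hap_b: HaplotypeProfile
) -> tuple[str, ...]:
    """Panel genotype a diplotype (hap_a, hap_b) would produce.

    Per SNP: REF/REF -> RR, ALT/ALT -> AA, REF/ALT -> RA.  A site deleted
    on one haplotype amplifies hemizygously and appears homozygous for
    the retained allele; deleted on both -> FAIL (no PCR product).
    """
    if len(hap_a.alleles) != len(hap_b.alleles):
        raise ValueError("haplotypes have different panel lengths")
    calls = []
    for x, y in zip(hap_a.alleles, hap_b.alleles):
        if x == DEL and y == DEL:
            calls.append("FAIL")
        elif x == DEL or y == DEL:
            kept = y if x == DEL else x
            calls.append("RR" if kept == REF else "AA")
        elif x == y:
            calls.append("RR" if x == REF else "AA")
        else:
            calls.append("RA")
    return tuple(calls)


def _check_calls(calls: tuple[str, ...], n_snps: int) -> None:
    if len(calls) != n_snps:
        raise ValueError(f"expected {n_snps} calls, got {len(calls)}")
    bad = [c for c in calls if c not in CALLS]
    if bad:
        raise ValueError(f"malformed panel calls: {sorted(set(bad))}")


def call_diplotype(
    sample_id: str,
    calls: tuple[str, ...],
    table: HaplotypeTable,
    candidates: set[str] | frozenset[str] | None = None,
) -> DiplotypeCall:
    """Enumerate every haplotype pair exactly compatible with ``calls``.

    Compatibility is exact equality with the pair's expected genotype --
    panel assays are discrete calls, so no error tolerance is applied.
    ``candidates`` restricts the enumeration to haplotypes known to
    segregate in the sample's line (a full/short heterozygote is
    indistinguishable from the full homozygote, so against the complete
    table many homozygous-looking profiles are ambiguous; within a line
    that does not carry the short haplotype the call is unique).
    A profile with no compatible pair and no heterozygous (RA) site is
    reported as a candidate novel haplotype in the homozygous state, with
    its allele string inferred directly from the calls (this is how novel
    full-length and short haplotypes are discovered in practice).
    """
    calls = tuple(calls)
    _check_calls(calls, table.n_snps)
    pairs = table.pairs()
    if candidates is not None:
        unknown = set(candidates) - set(table.haplotypes)
        if unknown:
            raise KeyError(f"unknown candidate haplotypes: {sorted(unknown)}")
        pairs = [(a, b) for a, b in pairs if a in candidates and b in candidates]
    # Pairs are canonicalised modulo declared panel equivalences: the
    # panel cannot distinguish equivalent haplotypes, so only the class
    # representative is reported and uniqueness is judged on classes.
    compatible = frozenset(
        tuple(sorted((table.representative(a), table.representative(b))))
        for a, b in pairs
        if table.expected_genotype(a, b) == calls
    )
    unique = len(compatible) == 1

    def n_short(pair: tuple[str, str]) -> int:
        return sum(table[h].is_short for h in pair)

    has_mixed = any(n_short(p) == 1 for p in compatible)
    has_full = any(n_short(p) == 0 for p in compatible)
    short_ambiguous = has_mixed and has_full

    novel = False
    inferred: tuple[str, ...] | None = None
    if not compatible and "RA" not in calls:
        novel = True
        inferred = tuple(
            DEL if c == "FAIL" else (REF if c == "RR" else ALT) for c in calls
        )
    return DiplotypeCall(
        sample_id=sample_id,
        compatible_pairs=compatible,
        unique=unique,
        short_ambiguous=short_ambiguous,
        novel=novel,
        inferred_alleles=inferred,
    )


def predict_serology(
    call: DiplotypeCall, allele_map: dict[str, frozenset[str] | set[str]]
) -> str:
    """Serological genotype implied by a unique diplotype call.

    ``allele_map`` maps serological-allele labels to the haplotype sets
    they detect (a haplotype may serve several alleles).  Returns
    "ambiguous" for non-unique calls or when several distinct serological
    genotypes are consistent, and "unknown" when a haplotype is unmapped.
    """
    if not call.unique:
        return "ambiguous"
    a, b = call.best_pair  # type: ignore[misc]
    alleles_of = {
        h: sorted(s for s, haps in allele_map.items() if h in haps) for h in (a, b)
    }
    if not alleles_of[a] or not alleles_of[b]:
        return "unknown"
    genotypes = {
        "/".join(sorted((sa, sb)))
        for sa in alleles_of[a]
        for sb in alleles_of[b]
    }
    if len(genotypes) == 1:
        return genotypes.pop()
    return "ambiguous"


def epitope_class(
    hap: HaplotypeProfile, span: tuple[int, int] = EPITOPE_SPAN
) -> str:
    """Classify a haplotype by the six-SNP epitope cluster (exons 2-3).

    ALT at every epitope SNP -> "I2-like"; REF at every one -> "I8-like";
    "indeterminate" if the deletion masks the span; "other" if mixed.
    """
    lo, hi = span
    states = hap.alleles[lo - 1 : hi]
    if DEL in states:
        return "indeterminate"
    if all(s == ALT for s in states):
        return "I2-like"
    if all(s == REF for s in states):
        return "I8-like"
    return "other"


def validate_table(table: HaplotypeTable) -> list[str]:
    """Structural checks; returns all violations (empty list = ok)."""
    errors: list[str] = []
    n = table.n_snps
    positions = [s.pos for s in table.snps]
    if any(b >= a for a, b in zip(positions[1:], positions)):
        errors.append("panel SNP positions not strictly increasing")
    for i, snp in enumerate(table.snps, start=1):
        if snp.order_index != i:
            errors.append(f"{snp.rsid}: order_index {snp.order_index} != row {i}")
    seen: dict[tuple[str, ...], str] = {}
    for name, hap in table.haplotypes.items():
        if hap.name != name:
            errors.append(f"haplotype key {name!r} != profile name {hap.name!r}")
        if len(hap.alleles) != n:
            errors.append(f"{name}: profile length {len(hap.alleles)} != {n} SNPs")
            continue
        bad = [s for s in hap.alleles if s not in (REF, ALT, DEL)]
        if bad:
            errors.append(f"{name}: invalid allele states {sorted(set(bad))}")
        del_idx = [i for i, s in enumerate(hap.alleles) if s == DEL]
        if del_idx and del_idx != list(range(del_idx[0], n)):
            errors.append(f"{name}: DEL entries are not a contiguous trailing block")
        if hap.alleles in seen:
            other = seen[hap.alleles]
            if frozenset({name, other}) not in table.panel_equivalent:
                errors.append(
                    f"duplicated allele vector: {other} and {name} are identical"
                )
        else:
            seen[hap.alleles] = name
    return errors
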