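"""Synthetic data with the statistical structure the pipeline assumes.

The generators emulate the study design end to end:

* diploid lines segregating 2-3 haplotypes at the causal locus, with
  diplotypes drawn under Hardy-Weinberg from line haplotype frequencies;
* serology labels derived from the diplotype through an allele map, then
  corrupted by a het<->hom confusion model (the only discrepancy class
  the serological record shows: weak antisera fail to distinguish
  homozygotes of the dominant allele from heterozygotes);
* array genotypes whose correlation with the causal locus decays as
  exp(-d / ld_decay_bp), plus independent background SNPs;
* DNA pools (by default 5 sets x 3 serology classes, 4-15 birds each)
  whose per-SNP intensity is the mean B-allele dosage fraction plus
  truncated Gaussian noise (theta, the standard array contrast proxy --
  sigma defaults to 0.03);
* per-base Poisson depth tracks (default lambda = 4, the study's
  combined low-pass coverage) containing the 6243-bp deletion at 0, 1
  or 2 copies.

Every generator is deterministic given its config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .depth import RHCE_DELETION_SPAN, CoverageTrack
from .panel import HaplotypeTable, PanelGenotype
from .pooled import PoolSpec

__all__ = [
    "SerologyErrorModel",
    "LineConfig",
    "GenomeConfig",
    "CoverageConfig",
    "TruthRecord",
    "simulate_line",
    "simulate_pools",
    "simulate_array_genotypes",
    "simulate_coverage",
]


@dataclass(frozen=True)
class SerologyErrorModel:
    """Het<->hom confusion in serological typing.

    ``p_het_as_hom``: probability a true heterozygote is recorded as
    homozygous for ``dominant_allele`` (hemagglutination at dilute
    antisera is subjective; heterozygotes are missed in that direction).
    ``p_hom_miscall``: probability a true homozygote is recorded as
    heterozygous with the dominant allele.
    """

    p_het_as_hom: float = 0.0
    dominant_allele: str = "I8"
    p_hom_miscall: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_het_as_hom", "p_hom_miscall"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


NO_ERROR = SerologyErrorModel()


@dataclass(frozen=True)
class LineConfig:
    line_id: str
    haplotype_freqs: dict[str, float]
    n_samples: int
    serology_error: SerologyErrorModel = NO_ERROR
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        total = sum(self.haplotype_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {total}, not 1")


@dataclass(frozen=True)
class GenomeConfig:
    n_background_snps: int = 100
    causal_chrom: str = "23"
    causal_interval: tuple[int, int] = (2_200_000, 2_400_000)
    ld_decay_bp: float = 50_000.0
    allele_freq_range: tuple[float, float] = (0.1, 0.9)
    n_causal_snps: int = 25

    def __post_init__(self) -> None:
        if self.n_background_snps < 0:
            raise ValueError("n_background_snps must be >= 0")
        if self.causal_interval[0] > self.causal_interval[1]:
            raise ValueError("causal interval start > end")


@dataclass(frozen=True)
class CoverageConfig:
    mean_depth_lambda: float = 4.0
    deletion_span: tuple[int, int] = RHCE_DELETION_SPAN
    region: tuple[int, int] = (RHCE_DELETION_SPAN[0] - 3000, RHCE_DELETION_SPAN[1] + 3000)
    chrom: str = "23"
    build: str = "GRCg6a"

    def __post_init__(self) -> None:
        if self.mean_depth_lambda <= 0:
            raise ValueError("lambda must be > 0")
        lo, hi = self.region
        s, e = self.deletion_span
        if not (lo <= s <= e <= hi):
            raise ValueError("deletion_span must lie inside region")


@dataclass(frozen=True)
class TruthRecord:
    sample_id: str
    diplotype: tuple[str, str]
    serology_true: tuple[str, str]
    serology_recorded: tuple[str, str]
    deletion_copies: int


def _invert_allele_map(allele_map: dict[str, frozenset[str]]) -> dict[str, str]:
    out: dict[str, str] = {}
    for allele in sorted(allele_map):
        for hap in allele_map[allele]:
            out.setdefault(hap, allele)
    return out


def _record_serology(
    true_pair: tuple[str, str],
    err: SerologyErrorModel,
    alleles_present: list[str],
    rng: np.random.Generator,
) -> tuple[str, str]:
    a, b = true_pair
    if a != b:
        if rng.random() < err.p_het_as_hom:
            return (err.dominant_allele, err.dominant_allele)
        return true_pair
    if rng.random() < err.p_hom_miscall:
        if err.dominant_allele != a:
            other = err.dominant_allele
        else:
            others = [x for x in alleles_present if x != a]
            if not others:
                return true_pair
            other = others[0]
        return tuple(sorted((a, other)))
    return true_pair


def simulate_line(
    config: LineConfig,
    table: HaplotypeTable,
    allele_map: dict[str, frozenset[str]],
) -> tuple[list[TruthRecord], list[PanelGenotype], pd.DataFrame]:
    """Simulate one line: truth, panel readouts and serology records.

    Diplotypes are Hardy-Weinberg draws from the line's haplotype
    frequencies; panel calls follow the deletion-masking rules of
    :func:`iblood.panel.expected_genotype`; recorded serology applies
    the error model to the true serology.
    """
    names = sorted(config.haplotype_freqs)
    unknown = set(names) - set(table.haplotypes)
    if unknown:
        raise KeyError(f"unknown haplotype names: {sorted(unknown)}")
    probs = np.array([config.haplotype_freqs[n] for n in names])
    hap_allele = _invert_allele_map(allele_map)
    alleles_present = sorted({hap_allele.get(n, "?") for n in names})

    rng = np.random.default_rng(config.seed)
    draws = rng.choice(len(names), size=(config.n_samples, 2), p=probs)

    truth: list[TruthRecord] = []
    genotypes: list[PanelGenotype] = []
    sero_rows = []
    for i, (ia, ib) in enumerate(draws):
        sid = f"{config.line_id}_{i:04d}"
        pair = tuple(sorted((names[ia], names[ib])))
        sero_true = tuple(sorted((hap_allele.get(pair[0], "?"), hap_allele.get(pair[1], "?"))))
        sero_rec = _record_serology(sero_true, config.serology_error, alleles_present, rng)
        copies = sum(table[h].is_short for h in pair)
        truth.append(
            TruthRecord(
                sample_id=sid,
                diplotype=pair,
                serology_true=sero_true,
                serology_recorded=sero_rec,
                deletion_copies=copies,
            )
        )
        genotypes.append(
            PanelGenotype(sample_id=sid, calls=table.expected_genotype(*pair))
        )
        sero_rows.append(
            {
                "sample_id": sid,
                "line_id": config.line_id,
                "allele1": sero_rec[0],
                "allele2": sero_rec[1],
            }
        )
    return truth, genotypes, pd.DataFrame(sero_rows)


def simulate_array_genotypes(
    truth: list[TruthRecord],
    table: HaplotypeTable,
    gc: GenomeConfig,
    seed: int = 0,
    causal_haplotypes: frozenset[str] = frozenset({"H02"}),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Array genotypes correlated with the causal diplotype.

    Each sample's two gametes carry a causal indicator (membership of
    the haplotype in ``causal_haplotypes``; the B allele tags the causal
    haplotype).  A causal-region SNP at distance d copies the gamete
    indicator with probability exp(-d / ld_decay_bp) and otherwise draws
    a fresh allele at the causal-allele frequency; background SNPs are
    independent Hardy-Weinberg draws.

    Returns (snp_info indexed by snp_id with chrom/pos/ref/alt, dosage
    DataFrame samples x SNPs with B-allele counts).
    """
    rng = np.random.default_rng(seed)
    n = len(truth)
    gametes = np.array(
        [[h in causal_haplotypes for h in t.diplotype] for t in truth], dtype=float
    )
    p_b = float(gametes.mean()) if n else 0.5
    p_b = min(max(p_b, 1e-6), 1 - 1e-6)

    lo, hi = gc.causal_interval
    causal_pos = (lo + hi) // 2
    m = gc.n_causal_snps
    positions = np.unique(np.linspace(lo, hi, num=m, dtype=int))
    # guarantee a perfectly linked SNP at the causal position itself
    positions = np.unique(np.append(positions, causal_pos))

    info_rows = []
    cols = {}
    for pos in positions:
        rho = (
            1.0
            if not np.isfinite(gc.ld_decay_bp)
            else float(np.exp(-abs(int(pos) - causal_pos) / gc.ld_decay_bp))
        )
        copy_mask = rng.random(size=(n, 2)) < rho
        fresh = (rng.random(size=(n, 2)) < p_b).astype(float)
        alleles = np.where(copy_mask, gametes, fresh)
        snp_id = f"c23_{pos}"
        cols[snp_id] = alleles.sum(axis=1)
        info_rows.append((snp_id, gc.causal_chrom, int(pos)))

    for k in range(gc.n_background_snps):
        p = rng.uniform(*gc.allele_freq_range)
        snp_id = f"bg_{k:05d}"
        cols[snp_id] = rng.binomial(2, p, size=n).astype(float)
        info_rows.append((snp_id, "1", 1000 * (k + 1)))

    snp_info = pd.DataFrame(info_rows, columns=["snp_id", "chrom", "pos"]).set_index(
        "snp_id"
    )
    snp_info["ref"] = "A"
    snp_info["alt"] = "C"  # the "B" array allele, as a concrete base
    dosage = pd.DataFrame(cols, index=[t.sample_id for t in truth])
    return snp_info, dosage


def simulate_pools(
    truth: list[TruthRecord],
    dosage: pd.DataFrame,
    b_serology_allele: str = "I2",
    n_sets: int = 5,
    size_range: tuple[int, int] = (4, 15),
    sigma: float = 0.03,
    seed: int = 0,
) -> tuple[list[PoolSpec], pd.DataFrame]:
    """Build the pool design and intensity matrix from recorded serology.

    For each set, one pool per serology class (0, 1 or 2 copies of
    ``b_serology_allele`` in the recorded genotype) of random size in
    ``size_range`` is drawn without replacement from the class.  Pool
    intensity theta(pool, snp) is the members' mean B-dosage fraction
    plus Gaussian noise truncated to [0, 1].
    """
    rng = np.random.default_rng(seed)
    lo, hi = size_range
    by_class: dict[int, list[str]] = {0: [], 1: [], 2: []}
    for t in truth:
        by_class[sum(a == b_serology_allele for a in t.serology_recorded)].append(
            t.sample_id
        )
    for c, ids in by_class.items():
        if len(ids) < lo:
            raise ValueError(
                f"insufficient samples of expected-count class {c}: "
                f"{len(ids)} < {lo}"
            )

    pools: list[PoolSpec] = []
    rows = []
    for s in range(1, n_sets + 1):
        for c in (0, 1, 2):
            ids = by_class[c]
            size = int(rng.integers(lo, min(hi, len(ids)) + 1))
            members = tuple(sorted(rng.choice(ids, size=size, replace=False)))
            pool_id = f"set{s}_class{c}"
            pools.append(
                PoolSpec(
                    pool_id=pool_id,
                    set_id=f"set{s}",
                    expected_count=c,
                    member_ids=members,
                )
            )
            frac = dosage.loc[list(members)].mean(axis=0).to_numpy() / 2.0
            noisy = frac + rng.normal(0.0, sigma, size=frac.size) if sigma > 0 else frac
            rows.append(np.clip(noisy, 0.0, 1.0))
    theta = pd.DataFrame(
        rows, index=[p.pool_id for p in pools], columns=dosage.columns
    )
    return pools, theta


def simulate_coverage(
    record: TruthRecord,
    cc: CoverageConfig,
    seed: int = 0,
    noiseless: bool = False,
) -> CoverageTrack:
    """Per-base depth track containing the deletion at the truth's copy state.

    Depth ~ Poisson(lambda * copies / 2) inside the deletion span
    (copies = 2 - deletion_copies) and Poisson(lambda) outside; the
    noiseless mode returns the exact expectation instead.
    """
    rng = np.random.default_rng(seed)
    lo, hi = cc.region
    s, e = cc.deletion_span
    size = hi - lo + 1
    lam = np.full(size, cc.mean_depth_lambda, dtype=float)
    copies = 2 - record.deletion_copies
    lam[s - lo : e - lo + 1] = cc.mean_depth_lambda * copies / 2.0
    depth = lam if noiseless else rng.poisson(lam).astype(float)
    return CoverageTrack(
        sample_id=record.sample_id,
        chrom=cc.chrom,
        start=lo,
        depth=depth,
        build=cc.build,
    )
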