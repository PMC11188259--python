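"""Pooled-DNA intensity-regression GWAS.

DNA from serologically matched birds is combined into pools (five sets,
each with one I2I2, one I2I8 and one I8I8 pool of 4-15 birds) and each
pool is typed once on a SNP array.  The pool's B-allele intensity
fraction theta at a SNP estimates the pool's mean B-allele dosage / 2.
For every SNP the expected allele count implied by the pool's serology
class (0, 1 or 2) is regressed against theta; a SNP tracking the causal
locus separates the three classes and fits with high R^2.

The published procedure regresses expected count on intensity (response
and explanatory reversed from the usual orientation).  For simple linear
regression R^2 and the slope p-value are invariant under that swap, so
the orientation is implemented exactly as described and is harmless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QCConfig",
    "PoolSpec",
    "SNPSummary",
    "recode_genotype",
    "qc_filter",
    "fit_snp_regression",
    "run_pool_gwas",
    "top_region",
    "PooledIntensityGWAS",
    "PooledGWASResults",
]

_TINY_P = float(np.nextafter(0, 1))  # p in (0, 1]: perfect fits clamp here

_RECODE = {"AA": 0, "AB": 1, "BA": 1, "BB": 2}
_MISSING = {"", ".", "NA", "NN", "--", "./.", None}


@dataclass(frozen=True)
class QCConfig:
    """SNP inclusion thresholds for the pooled analysis."""

    maf_min: float = 0.1
    max_missing: float = 0.1
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("maf_min", "max_missing", "alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class PoolSpec:
    """One DNA pool: its serology class and members."""

    pool_id: str
    set_id: str
    expected_count: int  # B-allele copies implied by the serology class
    member_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.expected_count not in (0, 1, 2):
            raise ValueError(f"expected_count must be 0/1/2, got {self.expected_count}")
        if not 4 <= len(self.member_ids) <= 15:
            raise ValueError(
                f"pool {self.pool_id}: {len(self.member_ids)} members (need 4-15)"
            )


@dataclass(frozen=True)
class SNPSummary:
    snp_id: str
    chrom: str
    pos: int
    slope: float
    r2: float
    p: float
    n_pools: int


def recode_genotype(call: str | None) -> int | None:
    """Diploid call -> B-allele count: AA->0, AB->1, BB->2; missing -> None."""
    if call in _MISSING:
        return None
    if call in _RECODE:
        return _RECODE[call]
    raise ValueError(f"malformed genotype call: {call!r}")


def qc_filter(theta: pd.DataFrame, qc: QCConfig | None = None) -> list[str]:
    """Retain SNPs by MAF and missingness estimated from pool intensities.

    ``theta``: pools x SNPs intensity matrix.  With no individual
    genotypes available, the allele frequency of a SNP is estimated as
    its mean theta across pools, folded to <= 0.5.  SNPs with folded
    frequency >= maf_min (inclusive) and missing fraction <= max_missing
    (inclusive) are retained.
    """
    if theta.shape[1] == 0:
        raise ValueError("empty intensity matrix")
    qc = qc or QCConfig()
    missing_frac = theta.isna().mean(axis=0)
    mean_theta = theta.mean(axis=0, skipna=True)
    maf = np.minimum(mean_theta, 1.0 - mean_theta)
    keep = theta.columns[(maf >= qc.maf_min) & (missing_frac <= qc.max_missing)]
    if len(keep) == 0:
        warnings.warn("no SNPs pass QC (all monomorphic or missing)", stacklevel=2)
    return list(keep)


def fit_snp_regression(
    expected: np.ndarray, theta: np.ndarray
) -> tuple[float, float, float]:
    """OLS of expected pool allele count on intensity -> (slope, r2, p).

    r2 is the squared Pearson correlation; p is the two-sided t-test on
    the slope with n-2 df.  Degenerate input (either variable constant)
    yields slope 0, r2 0, p 1 by contract.
    """
    y = np.asarray(expected, dtype=float)
    x = np.asarray(theta, dtype=float)
    if y.shape != x.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {x.shape}")
    if y.size < 3:
        raise ValueError(f"need at least 3 pools, got {y.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite intensity values")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return 0.0, 0.0, 1.0
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    p = float(res.pvalue)
    return float(res.slope), min(r2, 1.0), min(max(p, _TINY_P), 1.0)


def _bulk_regression(
    y: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised per-column simple OLS of y on each column of X.

    NaN cells in X drop the corresponding pool for that SNP only.
    Returns (slope, r2, p, n) arrays of length X.shape[1].
    """
    y = np.asarray(y, dtype=float)[:, None]
    X = np.asarray(X, dtype=float)
    ok = np.isfinite(X)
    n = ok.sum(axis=0).astype(float)
    Xz = np.where(ok, X, 0.0)
    Yz = np.where(ok, y, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = Xz.sum(axis=0) / n
        my = Yz.sum(axis=0) / n
        sxx = (np.where(ok, (X - mx) ** 2, 0.0)).sum(axis=0)
        syy = (np.where(ok, (y - my) ** 2, 0.0)).sum(axis=0)
        sxy = (np.where(ok, (X - mx) * (y - my), 0.0)).sum(axis=0)
        slope = sxy / sxx
        r2 = sxy**2 / (sxx * syy)
        tstat = np.sqrt(r2 * (n - 2) / np.maximum(1.0 - r2, 1e-300))
        p = 2.0 * stats.t.sf(np.abs(tstat), np.maximum(n - 2, 1))
    degenerate = (sxx <= 0) | (syy <= 0) | (n < 3)
    slope = np.where(degenerate, 0.0, slope)
    r2 = np.where(degenerate, 0.0, np.minimum(r2, 1.0))
    p = np.where(degenerate, 1.0, np.clip(p, _TINY_P, 1.0))
    return slope, r2, p, n.astype(int)


class PooledIntensityGWAS:
    """Model object for the pooled intensity-regression scan.

    Parameters
    ----------
    pools : sequence of PoolSpec
    theta : DataFrame, pools x SNPs
        B-allele intensity fractions; index must match pool ids.
    snp_info : DataFrame, optional
        Indexed by snp_id with columns ``chrom`` and ``pos``; SNPs
        without metadata are reported with chrom "." and pos 0.
    qc : QCConfig
    """

    def __init__(
        self,
        pools,
        theta: pd.DataFrame,
        snp_info: pd.DataFrame | None = None,
        qc: QCConfig | None = None,
    ):
        self.pools = list(pools)
        if len(self.pools) < 3:
            raise ValueError("need at least 3 pools")
        classes = {p.expected_count for p in self.pools}
        if len(classes) < 2:
            raise ValueError("all pools in one expected-count class")
        order = [p.pool_id for p in self.pools]
        missing = set(order) - set(theta.index)
        if missing:
            raise KeyError(f"pools without intensities: {sorted(missing)}")
        self.theta = theta.loc[order]
        self.snp_info = snp_info
        self.qc = qc or QCConfig()

    def fit(self) -> "PooledGWASResults":
        keep = qc_filter(self.theta, self.qc)
        theta = self.theta[keep]
        y = np.array([p.expected_count for p in self.pools], dtype=float)
        slope, r2, p, n = _bulk_regression(y, theta.to_numpy())
        tab = pd.DataFrame(
            {
                "snp_id": keep,
                "slope": slope,
                "r2": r2,
                "p": p,
                "n_pools": n,
            }
        )
        if self.snp_info is not None:
            info = self.snp_info.reindex(keep)
            tab["chrom"] = info["chrom"].fillna(".").astype(str).to_numpy()
            tab["pos"] = info["pos"].fillna(0).astype(int).to_numpy()
        else:
            tab["chrom"] = "."
            tab["pos"] = 0
        tab = tab[["snp_id", "chrom", "pos", "slope", "r2", "p", "n_pools"]]
        tab = tab.sort_values(
            ["p", "chrom", "pos", "snp_id"], kind="mergesort"
        ).reset_index(drop=True)
        return PooledGWASResults(tab, self.qc)


class PooledGWASResults:
    """Per-SNP regression table, ranked by p (ties by chrom, pos)."""

    def __init__(self, table: pd.DataFrame, qc: QCConfig):
        self.table = table
        self.qc = qc

    @property
    def best(self) -> pd.Series:
        return self.table.iloc[0]

    def top_region(
        self, window_bp: int, chrom_lengths: dict[str, int] | None = None
    ) -> tuple[str, int, int]:
        return top_region(self.table, window_bp, chrom_lengths)

    def manhattan_frame(self) -> pd.DataFrame:
        out = self.table[["chrom", "pos"]].copy()
        out["neg_log10_p"] = -np.log10(self.table["p"])
        return out.sort_values(["chrom", "pos"]).reset_index(drop=True)

    def summary(self, top: int = 10) -> str:
        lines = [
            "Pooled intensity-regression GWAS",
            f"  SNPs retained after QC (MAF>={self.qc.maf_min}, "
            f"missing<={self.qc.max_missing}): {len(self.table)}",
            f"  top {min(top, len(self.table))} SNPs by p:",
            self.table.head(top).to_string(index=False),
        ]
        return "\n".join(lines)


def run_pool_gwas(
    pools,
    theta: pd.DataFrame,
    qc: QCConfig | None = None,
    snp_info: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One-shot wrapper: fit the model and return the ranked SNP table."""
    return PooledIntensityGWAS(pools, theta, snp_info=snp_info, qc=qc).fit().table


def top_region(
    summaries: pd.DataFrame,
    window_bp: int,
    chrom_lengths: dict[str, int] | None = None,
) -> tuple[str, int, int]:
    """1-based inclusive interval of width window_bp centred on the best SNP.

    The best SNP minimises p; ties break by (chrom, pos) ascending.  The
    interval is clipped at 1 and, when known, at the chromosome length.
    """
    if len(summaries) == 0:
        raise ValueError("empty summary table")
    best = summaries.sort_values(["p", "chrom", "pos"], kind="mergesort").iloc[0]
    chrom, pos = str(best["chrom"]), int(best["pos"])
    start = pos - window_bp // 2
    end = start + window_bp - 1
    if start < 1:
        start, end = 1, window_bp
    if chrom_lengths and chrom in chrom_lengths:
        L = chrom_lengths[chrom]
        if end > L:
            end = L
            start = max(1, L - window_bp + 1)
    return chrom, start, end
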