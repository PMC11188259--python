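"""Individual-genotype case/control association.

Birds with known serology are genotyped individually (the 54K array, a
subset of the 600K content) and tested SNP-by-SNP with a 1-df allelic
chi-square on the 2x2 case/control x allele count table, without
continuity correction; when any expected cell is below 5 the exact
Fisher p-value replaces the asymptotic one.  SNPs pass QC at MAF >= 0.05
and call rate >= 0.99.  Genome-wide significance uses the Bonferroni
threshold -log10(alpha / m) for m independently segregating markers; m
defaults to the post-QC SNP count and is exposed as a parameter because
published thresholds may rest on an effective-marker count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssocQC",
    "allelic_test",
    "allele_table",
    "bonferroni_threshold",
    "CaseControlGWAS",
    "CaseControlResults",
    "run_case_control",
]


@dataclass(frozen=True)
class AssocQC:
    maf_min: float = 0.05
    call_rate_min: float = 0.99
    alpha: float = 0.05
    m_independent: int | None = None  # None -> post-QC SNP count

    def __post_init__(self) -> None:
        for name in ("maf_min", "call_rate_min", "alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def allele_table(
    case_dosage: np.ndarray, control_dosage: np.ndarray
) -> np.ndarray:
    """2x2 allele-count table [[case_B, case_A], [control_B, control_A]].

    Dosages are B-allele counts 0/1/2 with NaN for missing calls.
    """
    out = np.empty((2, 2), dtype=float)
    for i, d in enumerate((case_dosage, control_dosage)):
        d = np.asarray(d, dtype=float)
        d = d[np.isfinite(d)]
        b = d.sum()
        out[i] = (b, 2 * d.size - b)
    return out


def allelic_test(
    case_dosage: np.ndarray, control_dosage: np.ndarray
) -> tuple[float, float]:
    """1-df allelic chi-square (no continuity correction) -> (chi2, p).

    Tables with a zero margin carry no information: chi2 = 0, p = 1.
    When any expected cell is < 5 the p-value falls back to Fisher's
    exact test (the chi-square statistic is still reported).
    """
    for d in (case_dosage, control_dosage):
        d = np.asarray(d, dtype=float)
        if d[np.isfinite(d)].size == 0:
            raise ValueError("empty case or control group")
    tab = allele_table(case_dosage, control_dosage)
    return _test_table(tab)


def _test_table(tab: np.ndarray) -> tuple[float, float]:
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        return 0.0, 1.0
    total = tab.sum()
    expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / total
    chi2 = float(((tab - expected) ** 2 / expected).sum())
    if (expected < 5).any():
        p = float(stats.fisher_exact(np.round(tab).astype(int))[1])
    else:
        p = float(stats.chi2.sf(chi2, df=1))
    return chi2, min(max(p, float(np.nextafter(0, 1))), 1.0)


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    """Genome-wide significance on the -log10 scale: -log10(alpha/m)."""
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return float(-np.log10(alpha / m))


class CaseControlGWAS:
    """Model object for a per-line case/control scan.

    Parameters
    ----------
    dosage : DataFrame, samples x SNPs
        B-allele dosages 0/1/2, NaN = missing.
    cases, controls : sample-id sequences (must be disjoint)
    snp_info : DataFrame indexed by snp_id with chrom/pos
    qc : AssocQC
    """

    def __init__(
        self,
        dosage: pd.DataFrame,
        cases,
        controls,
        snp_info: pd.DataFrame | None = None,
        qc: AssocQC | None = None,
    ):
        cases, controls = list(cases), list(controls)
        overlap = set(cases) & set(controls)
        if overlap:
            raise ValueError(f"case/control overlap: {sorted(overlap)}")
        for ids, label in ((cases, "case"), (controls, "control")):
            missing = set(ids) - set(dosage.index)
            if missing:
                raise KeyError(f"{label} ids absent from genotypes: {sorted(missing)}")
            if not ids:
                raise ValueError(f"empty {label} group")
        self.dosage = dosage
        self.cases = cases
        self.controls = controls
        self.snp_info = snp_info
        self.qc = qc or AssocQC()

    @classmethod
    def from_vcf(cls, path, cases, controls, qc: AssocQC | None = None):
        from .io import read_vcf

        snp_info, dosage = read_vcf(path)
        return cls(dosage, cases, controls, snp_info=snp_info, qc=qc)

    def _qc_mask(self, sub: pd.DataFrame) -> pd.Index:
        call_rate = sub.notna().mean(axis=0)
        with np.errstate(invalid="ignore"):
            freq = sub.mean(axis=0, skipna=True) / 2.0
        maf = np.minimum(freq, 1.0 - freq)
        keep = (maf >= self.qc.maf_min) & (call_rate >= self.qc.call_rate_min)
        return sub.columns[keep.fillna(False)]

    def fit(self) -> "CaseControlResults":
        used = self.dosage.loc[self.cases + self.controls]
        keep = self._qc_mask(used)
        case_m = used.loc[self.cases, keep].to_numpy(dtype=float)
        ctrl_m = used.loc[self.controls, keep].to_numpy(dtype=float)

        rows = []
        for j, snp in enumerate(keep):
            tab = allele_table(case_m[:, j], ctrl_m[:, j])
            chi2, p = _test_table(tab)
            rows.append((snp, chi2, p, tab[0, 0], tab[0, 1], tab[1, 0], tab[1, 1]))
        tab_df = pd.DataFrame(
            rows,
            columns=[
                "snp_id", "chi2", "p",
                "case_b", "case_a", "control_b", "control_a",
            ],
        )
        tab_df["neg_log10_p"] = -np.log10(tab_df["p"])
        if self.snp_info is not None:
            info = self.snp_info.reindex(keep)
            tab_df.insert(1, "chrom", info["chrom"].fillna(".").astype(str).to_numpy())
            tab_df.insert(2, "pos", info["pos"].fillna(0).astype(int).to_numpy())
        else:
            tab_df.insert(1, "chrom", ".")
            tab_df.insert(2, "pos", 0)
        m = self.qc.m_independent or len(tab_df)
        thr = bonferroni_threshold(max(m, 1), self.qc.alpha) if len(tab_df) else np.inf
        tab_df["significant"] = tab_df["neg_log10_p"] >= thr
        tab_df = tab_df.sort_values(
            ["chrom", "pos", "snp_id"], kind="mergesort"
        ).reset_index(drop=True)
        return CaseControlResults(tab_df, threshold=thr, m=m, qc=self.qc)


class CaseControlResults:
    def __init__(self, table: pd.DataFrame, threshold: float, m: int, qc: AssocQC):
        self.table = table
        self.threshold = threshold
        self.m = m
        self.qc = qc

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def manhattan_frame(self) -> pd.DataFrame:
        return self.table[["chrom", "pos", "neg_log10_p"]].copy()

    def summary(self, top: int = 10) -> str:
        t = self.table.sort_values(["p", "chrom", "pos"], kind="mergesort")
        return "\n".join(
            [
                "Case/control allelic association",
                f"  SNPs tested after QC (MAF>={self.qc.maf_min}, "
                f"call rate>={self.qc.call_rate_min}): {len(self.table)}",
                f"  Bonferroni -log10(p) threshold (m={self.m}, "
                f"alpha={self.qc.alpha}): {self.threshold:.6f}",
                f"  significant SNPs: {int(self.table['significant'].sum())}",
                f"  top {min(top, len(t))} SNPs by p:",
                t.head(top).to_string(index=False),
            ]
        )


def run_case_control(
    dosage: pd.DataFrame,
    cases,
    controls,
    qc: AssocQC | None = None,
    snp_info: pd.DataFrame | None = None,
) -> CaseControlResults:
    """One-shot wrapper around :class:`CaseControlGWAS`."""
    return CaseControlGWAS(dosage, cases, controls, snp_info=snp_info, qc=qc).fit()
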