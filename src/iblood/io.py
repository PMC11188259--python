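"""File boundaries: VCF, TSV/CSV tables, bedGraph, configs.

Conventions: VCFv4.2 with GT (1-based positions); pool intensities as
long TSV (pool_id, snp_id, theta); serology CSV (sample_id, line_id,
allele1, allele2); panel calls as long TSV (sample_id, snp_id, call);
bedGraph is 0-based half-open on disk and converted to the internal
1-based inclusive convention exactly once, here.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .depth import CoverageTrack, ExonModel
from .filtering import AnnotatedVariant, GeneInfo
from .panel import PanelGenotype
from .pooled import PoolSpec
from .simulate import TruthRecord

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_pool_specs",
    "write_pool_specs",
    "read_intensities",
    "write_intensities",
    "read_serology",
    "write_serology",
    "read_panel_calls",
    "write_panel_calls",
    "read_bedgraph",
    "write_bedgraph",
    "read_exon_model",
    "write_exon_model",
    "read_gene_table",
    "read_annotation_table",
    "read_truth",
    "write_truth",
    "PipelineConfig",
    "load_config",
]

_GT_DOSAGE = {0: 0.0, 1: 1.0, 2: np.nan, 3: 2.0}  # cyvcf2 gt_types


def read_vcf(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """VCF -> (snp_info indexed by snp_id, samples x SNPs dosage matrix)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts = [], [], [], [], []
    dosages = []
    for i, rec in enumerate(vcf):
        snp_id = rec.ID or f"{rec.CHROM}_{rec.POS}"
        ids.append(snp_id)
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0] if rec.ALT else ".")
        dosages.append([_GT_DOSAGE[g] for g in rec.gt_types])
    vcf.close()
    snp_info = pd.DataFrame(
        {"snp_id": ids, "chrom": chroms, "pos": poss, "ref": refs, "alt": alts}
    ).set_index("snp_id")
    dosage = pd.DataFrame(np.array(dosages).T if dosages else [], index=samples,
                          columns=ids)
    return snp_info, dosage


def write_vcf(path, snp_info: pd.DataFrame, dosage: pd.DataFrame) -> None:
    """Write a minimal VCFv4.2 with GT from a dosage matrix (NaN = ./.)."""
    import pysam

    header = pysam.VariantHeader()
    info = snp_info.sort_values(["chrom", "pos"], kind="mergesort")
    for chrom in dict.fromkeys(info["chrom"].astype(str)):
        length = int(info.loc[info["chrom"].astype(str) == chrom, "pos"].max()) + 10_000
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    for s in dosage.index:
        header.add_sample(str(s))

    gt_of = {0.0: (0, 0), 1.0: (0, 1), 2.0: (1, 1)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for snp_id, row in info.iterrows():
            rec = out.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,
                stop=int(row["pos"]),
                alleles=(str(row.get("ref", "A")), str(row.get("alt", "C"))),
                id=str(snp_id),
            )
            col = dosage[snp_id]
            for s in dosage.index:
                v = col[s]
                rec.samples[str(s)]["GT"] = (
                    (None, None) if pd.isna(v) else gt_of[float(v)]
                )
                rec.samples[str(s)].phased = False
            out.write(rec)


def write_pool_specs(path, pools: list[PoolSpec]) -> None:
    pd.DataFrame(
        {
            "pool_id": [p.pool_id for p in pools],
            "set_id": [p.set_id for p in pools],
            "expected_count": [p.expected_count for p in pools],
            "member_ids": [",".join(p.member_ids) for p in pools],
        }
    ).to_csv(path, sep="\t", index=False)


def read_pool_specs(path) -> list[PoolSpec]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for i, r in enumerate(df.itertuples(), start=2):
        try:
            out.append(
                PoolSpec(
                    pool_id=r.pool_id,
                    set_id=r.set_id,
                    expected_count=int(r.expected_count),
                    member_ids=tuple(r.member_ids.split(",")),
                )
            )
        except (ValueError, AttributeError) as exc:
            raise ValueError(f"{path}, line {i}: {exc}") from exc
    return out


def write_intensities(path, theta: pd.DataFrame) -> None:
    """pools x SNPs matrix -> long TSV (pool_id, snp_id, theta)."""
    long = theta.stack().rename("theta").reset_index()
    long.columns = ["pool_id", "snp_id", "theta"]
    long.to_csv(path, sep="\t", index=False)


def read_intensities(path) -> pd.DataFrame:
    long = pd.read_csv(path, sep="\t")
    for col in ("pool_id", "snp_id", "theta"):
        if col not in long.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    wide = long.pivot(index="pool_id", columns="snp_id", values="theta")
    wide.columns.name = None
    wide.index.name = None
    return wide


def write_serology(path, rows: pd.DataFrame) -> None:
    rows.to_csv(path, index=False)


def read_serology(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    need = {"sample_id", "line_id", "allele1", "allele2"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_panel_calls(path, genotypes: list[PanelGenotype], rsids: list[str]) -> None:
    rows = [
        {"sample_id": g.sample_id, "snp_id": rsid, "call": call}
        for g in genotypes
        for rsid, call in zip(rsids, g.calls)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_panel_calls(path, rsids: list[str]) -> list[PanelGenotype]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for sid, grp in df.groupby("sample_id", sort=True):
        calls = grp.set_index("snp_id")["call"]
        missing = [r for r in rsids if r not in calls.index]
        if missing:
            raise ValueError(f"{path}: sample {sid} lacks calls for {missing}")
        out.append(PanelGenotype(sample_id=sid, calls=tuple(calls[r] for r in rsids)))
    return out


def write_bedgraph(path, track: CoverageTrack) -> None:
    """CoverageTrack (1-based inclusive) -> bedGraph (0-based half-open)."""
    d = track.depth
    breaks = np.flatnonzero(np.diff(d)) + 1
    starts = np.concatenate(([0], breaks))
    ends = np.concatenate((breaks, [d.size]))
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            val = d[s]
            out = int(val) if float(val).is_integer() else float(val)
            fh.write(
                f"{track.chrom}\t{track.start - 1 + s}\t{track.start - 1 + e}\t{out}\n"
            )


def read_bedgraph(path, sample_id: str = "", build: str = "") -> CoverageTrack:
    """bedGraph (0-based half-open) -> CoverageTrack (1-based inclusive)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "depth"],
        comment="t",  # tolerates a "track ..." header line
    )
    if df.empty:
        raise ValueError(f"{path}: empty bedGraph")
    chroms = df["chrom"].astype(str).unique()
    if len(chroms) > 1:
        raise ValueError(f"{path}: multiple chromosomes {list(chroms)}")
    df = df.sort_values("start")
    lo0, hi0 = int(df["start"].iloc[0]), int(df["end"].iloc[-1])
    depth = np.zeros(hi0 - lo0, dtype=float)
    prev_end = lo0
    for i, r in enumerate(df.itertuples(), start=1):
        s, e = int(r.start), int(r.end)
        if s < prev_end:
            raise ValueError(f"{path}, record {i}: overlapping intervals")
        depth[s - lo0 : e - lo0] = float(r.depth)
        prev_end = e
    return CoverageTrack(
        sample_id=sample_id, chrom=str(chroms[0]), start=lo0 + 1, depth=depth,
        build=build,
    )


def write_exon_model(path, model: ExonModel) -> None:
    rows = [
        {
            "gene_id": model.gene_id,
            "chrom": model.chrom,
            "strand": model.strand,
            "build": model.build,
            "exon_number": k,
            "start": s,
            "end": e,
        }
        for k, (s, e) in enumerate(model.exons, start=1)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_exon_model(path) -> ExonModel:
    df = pd.read_csv(path, sep="\t").sort_values("exon_number")
    return ExonModel(
        gene_id=str(df["gene_id"].iloc[0]),
        chrom=str(df["chrom"].iloc[0]),
        strand=str(df["strand"].iloc[0]),
        build=str(df["build"].iloc[0]) if "build" in df else "",
        exons=tuple((int(r.start), int(r.end)) for r in df.itertuples()),
    )


def read_gene_table(path) -> list[GeneInfo]:
    """TSV (gene_id, chrom, start, end, go_terms comma-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for i, r in enumerate(df.itertuples(), start=2):
        try:
            go = frozenset() if pd.isna(r.go_terms) or r.go_terms in ("", ".") else frozenset(
                r.go_terms.split(","))
            out.append(
                GeneInfo(
                    gene_id=r.gene_id, chrom=str(r.chrom),
                    start=int(r.start), end=int(r.end), go_terms=go,
                )
            )
        except (ValueError, AttributeError) as exc:
            raise ValueError(f"{path}, line {i}: {exc}") from exc
    return out


def read_annotation_table(path) -> list[AnnotatedVariant]:
    """TSV (chrom, pos, ref, alt, gene_id, impact[, fa_group1, fa_group2])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for i, r in enumerate(df.itertuples(), start=2):
        try:
            out.append(
                AnnotatedVariant(
                    chrom=str(r.chrom), pos=int(r.pos), ref=r.ref, alt=r.alt,
                    gene_id=r.gene_id, impact=r.impact,
                    fa_group1=float(r.fa_group1) if hasattr(r, "fa_group1") else None,
                    fa_group2=float(r.fa_group2) if hasattr(r, "fa_group2") else None,
                )
            )
        except (ValueError, AttributeError) as exc:
            raise ValueError(f"{path}, line {i}: {exc}") from exc
    return out


def write_truth(path, truth: list[TruthRecord]) -> None:
    payload = [
        {
            "sample_id": t.sample_id,
            "diplotype": list(t.diplotype),
            "serology_true": list(t.serology_true),
            "serology_recorded": list(t.serology_recorded),
            "deletion_copies": t.deletion_copies,
        }
        for t in truth
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path) -> list[TruthRecord]:
    payload = json.loads(Path(path).read_text())
    return [
        TruthRecord(
            sample_id=d["sample_id"],
            diplotype=tuple(d["diplotype"]),
            serology_true=tuple(d["serology_true"]),
            serology_recorded=tuple(d["serology_recorded"]),
            deletion_copies=int(d["deletion_copies"]),
        )
        for d in payload
    ]


# ---------------------------------------------------------------------------
# pipeline configuration

from pydantic import BaseModel, ConfigDict  # noqa: E402


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PoolStageConfig(_Section):
    maf_min: float = 0.1
    max_missing: float = 0.1
    alpha: float = 0.05
    sigma: float = 0.03
    n_sets: int = 5
    window_bp: int = 200_000
    seed: int = 1


class AssocStageConfig(_Section):
    maf_min: float = 0.05
    call_rate_min: float = 0.99
    alpha: float = 0.05
    m_independent: int | None = None


class FilterStageConfig(_Section):
    hi: float = 0.9


class DeletionStageConfig(_Section):
    tau_hom: float = 0.15
    tau_het_low: float = 0.3
    tau_het_high: float = 0.7
    min_len: int = 500
    merge_gap: int = 50


class SimulateStageConfig(_Section):
    n_samples: int = 300
    p_het_as_hom: float = 0.0
    p_hom_miscall: float = 0.0
    n_background_snps: int = 100
    n_causal_snps: int = 25
    ld_decay_bp: float = 50_000.0
    mean_depth_lambda: float = 4.0
    seed: int = 1


class PipelineConfig(_Section):
    """Schema-versioned whole-pipeline configuration.

    Unknown keys are rejected; every stochastic stage carries an
    explicit seed.
    """

    schema_version: int = 1
    build: str = "GRCg6a"
    simulate: SimulateStageConfig = SimulateStageConfig()
    pool_gwas: PoolStageConfig = PoolStageConfig()
    assoc: AssocStageConfig = AssocStageConfig()
    filter: FilterStageConfig = FilterStageConfig()
    deletion: DeletionStageConfig = DeletionStageConfig()


def load_config(path) -> PipelineConfig:
    """Load a JSON or YAML pipeline config; unknown keys are schema errors."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return PipelineConfig.model_validate(data or {})
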