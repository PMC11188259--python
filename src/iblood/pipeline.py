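"""End-to-end synthetic run: simulate -> map -> filter -> type -> score.

`run_demo` exercises the whole inference chain on one synthetic line and
returns a machine-readable summary; the CLI's ``all`` subcommand is a
thin wrapper around it.  The synthetic gene layout places four genes in
the pooled-GWAS peak with only the causal one membrane-annotated and
carrying hard-contrast coding variants, mirroring the structure of the
real candidate-reduction step at toy scale.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ibio
from .assoc import AssocQC, run_case_control
from .concordance import concordance
from .depth import breakpoint_consensus, call_deletion, exon_overlap, normalize_depth, rhce_exon_model
from .filtering import MEMBRANE_GO, AnnotatedVariant, GeneInfo, candidate_genes, group_allele_freq
from .fixtures import fixture_table2
from .panel import call_diplotype
from .pooled import PooledIntensityGWAS, QCConfig
from .simulate import (
    CoverageConfig,
    GenomeConfig,
    LineConfig,
    SerologyErrorModel,
    simulate_array_genotypes,
    simulate_coverage,
    simulate_line,
    simulate_pools,
)

__all__ = ["run_demo", "DEMO_ALLELE_MAP", "DEMO_FREQS"]

# H07 keeps the exon 2-3 epitope cluster (the deletion removes only the
# 3' end of the gene), and its retained SNPs are I8-like, so serology
# reads it as I8.
DEMO_ALLELE_MAP = {"I2": frozenset({"H02"}), "I8": frozenset({"H01", "H07"})}
# a WL-style line segregating I2 (H02) and I8 (H01) plus a low-frequency
# short haplotype, so every downstream stage has something to find
DEMO_FREQS = {"H02": 0.45, "H01": 0.40, "H07": 0.15}


def _demo_genes(gc: GenomeConfig) -> list[GeneInfo]:
    lo, hi = gc.causal_interval
    centre = (lo + hi) // 2
    width = (hi - lo) // 10
    return [
        GeneInfo("GENE_A", gc.causal_chrom, lo, lo + width, frozenset()),
        GeneInfo("GENE_B", gc.causal_chrom, lo + 2 * width, lo + 3 * width,
                 frozenset({MEMBRANE_GO})),
        GeneInfo("RHCE", gc.causal_chrom, centre - width // 2, centre + width // 2,
                 frozenset({MEMBRANE_GO, "GO:0015701"})),
        GeneInfo("GENE_C", gc.causal_chrom, hi - width, hi, frozenset()),
    ]


def run_demo(
    config: "ibio.PipelineConfig | None" = None,
    outdir: str | Path | None = None,
    seed: int | None = None,
) -> dict:
    """Run the whole chain on synthetic data; return a summary dict."""
    config = config or ibio.PipelineConfig()
    if seed is not None:
        sim = config.simulate.model_copy(update={"seed": seed})
        pool = config.pool_gwas.model_copy(update={"seed": seed + 1})
        config = config.model_copy(update={"simulate": sim, "pool_gwas": pool})
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    table = fixture_table2()
    err = SerologyErrorModel(
        p_het_as_hom=config.simulate.p_het_as_hom,
        dominant_allele="I8",
        p_hom_miscall=config.simulate.p_hom_miscall,
    )
    line_cfg = LineConfig(
        line_id="SIM1",
        haplotype_freqs=DEMO_FREQS,
        n_samples=config.simulate.n_samples,
        serology_error=err,
        seed=config.simulate.seed,
    )
    truth, genotypes, serology = simulate_line(line_cfg, table, DEMO_ALLELE_MAP)

    gc = GenomeConfig(
        n_background_snps=config.simulate.n_background_snps,
        n_causal_snps=config.simulate.n_causal_snps,
        ld_decay_bp=config.simulate.ld_decay_bp,
    )
    snp_info, dosage = simulate_array_genotypes(
        truth, table, gc, seed=config.simulate.seed + 17
    )

    # stage 1: pooled intensity-regression GWAS
    pools, theta = simulate_pools(
        truth,
        dosage,
        n_sets=config.pool_gwas.n_sets,
        sigma=config.pool_gwas.sigma,
        seed=config.pool_gwas.seed,
    )
    qc = QCConfig(
        maf_min=config.pool_gwas.maf_min,
        max_missing=config.pool_gwas.max_missing,
        alpha=config.pool_gwas.alpha,
    )
    pool_res = PooledIntensityGWAS(pools, theta, snp_info=snp_info, qc=qc).fit()
    peak = pool_res.top_region(config.pool_gwas.window_bp)

    # stage 2: individual case/control GWAS (cases = recorded I2I2)
    rec = {t.sample_id: t.serology_recorded for t in truth}
    cases = [s for s, r in rec.items() if r == ("I2", "I2")]
    controls = [s for s, r in rec.items() if r != ("I2", "I2")]
    cc_res = run_case_control(
        dosage,
        cases,
        controls,
        qc=AssocQC(
            maf_min=config.assoc.maf_min,
            call_rate_min=config.assoc.call_rate_min,
            alpha=config.assoc.alpha,
            m_independent=config.assoc.m_independent,
        ),
        snp_info=snp_info,
    )

    # stage 3: candidate-gene filtering on opposing recorded homozygotes
    genes = _demo_genes(gc)
    gene_of = {}
    for g in genes:
        for sid in snp_info.index:
            if (
                str(snp_info.at[sid, "chrom"]) == g.chrom
                and g.start <= int(snp_info.at[sid, "pos"]) <= g.end
            ):
                gene_of.setdefault(sid, g.gene_id)
    hom_i2 = [s for s, r in rec.items() if r == ("I2", "I2")]
    hom_i8 = [s for s, r in rec.items() if r == ("I8", "I8")]
    fa1 = group_allele_freq(dosage, hom_i2)
    fa2 = group_allele_freq(dosage, hom_i8)
    variants = [
        AnnotatedVariant(
            chrom=str(snp_info.at[sid, "chrom"]),
            pos=int(snp_info.at[sid, "pos"]),
            ref="A",
            alt="C",
            gene_id=gene_of[sid],
            impact="MODERATE" if gene_of[sid] in ("RHCE", "GENE_B") else "LOW",
            fa_group1=float(fa1[sid]),
            fa_group2=float(fa2[sid]),
        )
        for sid in snp_info.index
        if sid in gene_of
    ]
    candidates = candidate_genes(variants, genes, peak, hi=config.filter.hi)

    # stage 4: panel typing + concordance
    line_haps = frozenset(DEMO_FREQS)
    samples = []
    for t, g in zip(truth, genotypes):
        call = call_diplotype(g.sample_id, g.calls, table, candidates=line_haps)
        samples.append((line_cfg.line_id, t.serology_recorded, call))
    reports, aggregate = concordance(samples, {line_cfg.line_id: DEMO_ALLELE_MAP})

    # stage 5: deletion scan on short-haplotype homozygotes
    cc_cfg = CoverageConfig(mean_depth_lambda=config.simulate.mean_depth_lambda)
    del_truth = [t for t in truth if t.deletion_copies == 2][:3]
    calls = []
    flank = (cc_cfg.region[0], cc_cfg.deletion_span[0] - 500)
    for k, t in enumerate(del_truth):
        track = simulate_coverage(t, cc_cfg, seed=config.simulate.seed + 100 + k)
        ratio = normalize_depth(track, flank)
        calls.append(
            call_deletion(
                ratio,
                tau_hom=config.deletion.tau_hom,
                tau_het_low=config.deletion.tau_het_low,
                tau_het_high=config.deletion.tau_het_high,
                min_len=config.deletion.min_len,
                merge_gap=config.deletion.merge_gap,
            )
        )
    deletion_summary: dict = {"n_hom_del_samples": len(del_truth)}
    if len(calls) >= 2:
        (chrom, s, e), disc = breakpoint_consensus(calls)
        n_full, n_part, _ = exon_overlap(calls[0], rhce_exon_model())
        deletion_summary.update(
            consensus={"chrom": chrom, "start": int(s), "end": int(e),
                       "length": int(e - s + 1)},
            max_discrepancy_bp=int(disc),
            exons_fully_deleted=n_full,
            exons_partially_deleted=n_part,
        )

    best = pool_res.best
    summary = {
        "n_samples": len(truth),
        "pool_gwas": {
            "n_snps_tested": int(len(pool_res.table)),
            "top_snp": str(best["snp_id"]),
            "top_chrom": str(best["chrom"]),
            "top_pos": int(best["pos"]),
            "top_r2": float(best["r2"]),
            "top_p": float(best["p"]),
            "peak": {"chrom": peak[0], "start": peak[1], "end": peak[2]},
        },
        "case_control": {
            "n_snps_tested": int(len(cc_res.table)),
            "threshold_neg_log10_p": float(cc_res.threshold),
            "n_significant": int(cc_res.table["significant"].sum()),
            "significant_chroms": sorted(
                set(cc_res.significant["chrom"].astype(str))
            ),
        },
        "candidates": [
            {
                "gene_id": c.gene.gene_id,
                "membrane": c.gene.is_membrane,
                "n_passing_variants": c.n_passing,
            }
            for c in candidates
        ],
        "top_candidate": candidates[0].gene.gene_id if candidates else None,
        "concordance": {
            line_id: {
                "n": r.n_total,
                "n_concordant": r.n_concordant,
                "overall_pct": r.overall_pct,
            }
            for line_id, r in reports.items()
        },
        "deletion": deletion_summary,
    }

    if out is not None:
        ibio.write_truth(out / "truth.json", truth)
        ibio.write_serology(out / "serology.csv", serology)
        ibio.write_panel_calls(
            out / "panel_calls.tsv", genotypes, [s.rsid for s in table.snps]
        )
        ibio.write_vcf(out / "genotypes.vcf", snp_info, dosage)
        ibio.write_pool_specs(out / "pools.tsv", pools)
        ibio.write_intensities(out / "intensities.tsv", theta)
        pool_res.table.to_csv(out / "pool_gwas.tsv", sep="\t", index=False)
        pool_res.manhattan_frame().to_csv(
            out / "pool_gwas_manhattan.tsv", sep="\t", index=False
        )
        cc_res.table.to_csv(out / "case_control.tsv", sep="\t", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
        manifest = {
            "tool": "iblood",
            "version": __import__("iblood").__version__,
            "seeds": {
                "simulate": config.simulate.seed,
                "pool_gwas": config.pool_gwas.seed,
            },
            "config": config.model_dump(),
        }
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    return summary
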