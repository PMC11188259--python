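"""Synthetic-data generators: fixed points, sampling laws, determinism."""

import numpy as np
import pandas as pd
import pytest

from iblood.simulate import (
    CoverageConfig,
    GenomeConfig,
    LineConfig,
    SerologyErrorModel,
    TruthRecord,
    simulate_array_genotypes,
    simulate_coverage,
    simulate_line,
    simulate_pools,
)

AMAP = {"I2": frozenset({"H02"}), "I8": frozenset({"H01"})}


class TestSimulateLine:
    def test_monomorphic_line_fixed_point(self, table):
        cfg = LineConfig("L", {"H02": 1.0}, n_samples=25, seed=0)
        truth, genotypes, _ = simulate_line(cfg, table, AMAP)
        expected = table.expected_genotype("H02", "H02")
        assert all(t.diplotype == ("H02", "H02") for t in truth)
        assert all(g.calls == expected for g in genotypes)

    def test_no_error_model_records_truth(self, table):
        cfg = LineConfig(
            "L", {"H01": 0.5, "H02": 0.5}, n_samples=200,
            serology_error=SerologyErrorModel(0.0, "I8", 0.0), seed=1,
        )
        truth, _, _ = simulate_line(cfg, table, AMAP)
        assert all(t.serology_recorded == t.serology_true for t in truth)

    def test_het_fraction_matches_binomial_oracle(self, table):
        # HW with two equifrequent haplotypes: P(het) = 0.5,
        # s.e. = sqrt(0.25 / n)
        n = 10_000
        cfg = LineConfig("L", {"H02": 0.5, "H03": 0.5}, n_samples=n, seed=5)
        truth, _, _ = simulate_line(cfg, table, AMAP)
        het = np.mean([t.diplotype[0] != t.diplotype[1] for t in truth])
        assert abs(het - 0.5) <= 3 * np.sqrt(0.25 / n)

    def test_deletion_copies_counts_short_haplotypes(self, table):
        cfg = LineConfig("L", {"H01": 0.5, "H07": 0.5}, n_samples=300, seed=2)
        truth, _, _ = simulate_line(cfg, table, {"I8": frozenset({"H01", "H07"})})
        for t in truth:
            assert t.deletion_copies == sum(h == "H07" for h in t.diplotype)

    def test_unknown_haplotype_rejected(self, table):
        cfg = LineConfig("L", {"H99": 1.0}, n_samples=5)
        with pytest.raises(KeyError):
            simulate_line(cfg, table, AMAP)

    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(ValueError):
            LineConfig("L", {"H01": 0.6, "H02": 0.5}, n_samples=5)

    def test_seed_determinism_is_exact(self, table):
        cfg = LineConfig(
            "L", {"H01": 0.4, "H02": 0.6}, n_samples=100,
            serology_error=SerologyErrorModel(0.2, "I8", 0.05), seed=42,
        )
        a = simulate_line(cfg, table, AMAP)
        b = simulate_line(cfg, table, AMAP)
        assert a[0] == b[0]
        assert [g.calls for g in a[1]] == [g.calls for g in b[1]]
        assert a[2].equals(b[2])


def _truth_with_classes(n_per_class):
    """Synthetic truth with exact serology classes for pool construction."""
    out = []
    specs = [(("I8", "I8"), 0), (("I2", "I8"), 1), (("I2", "I2"), 2)]
    k = 0
    for sero, _ in specs:
        for _ in range(n_per_class):
            out.append(
                TruthRecord(f"s{k:03d}", ("H01", "H02"), sero, sero, 0)
            )
            k += 1
    return out


class TestSimulatePools:
    def test_noiseless_theta_levels(self):
        truth = _truth_with_classes(8)
        ids = [t.sample_id for t in truth]
        dosage = pd.DataFrame(
            {
                "all_bb": 2.0,  # every member alt-hom -> theta 1
                "all_ab": 1.0,  # every member het -> theta 0.5
            },
            index=ids,
        )
        # mixed pool {AA, BB}: alternate dosages 0/2 -> mean 1 -> theta 0.5
        dosage["mixed"] = [0.0, 2.0] * (len(ids) // 2)
        pools, theta = simulate_pools(truth, dosage, sigma=0.0, seed=0,
                                      size_range=(4, 8))
        assert np.allclose(theta["all_bb"], 1.0)
        assert np.allclose(theta["all_ab"], 0.5)
        assert set(p.expected_count for p in pools) == {0, 1, 2}
        assert len(pools) == 15

    def test_theta_ordered_by_class_at_causal_snp(self):
        truth = _truth_with_classes(10)
        ids = [t.sample_id for t in truth]
        causal = [0.0] * 10 + [1.0] * 10 + [2.0] * 10
        dosage = pd.DataFrame({"causal": causal}, index=ids)
        pools, theta = simulate_pools(truth, dosage, sigma=0.0, seed=1)
        means = {
            c: theta.loc[[p.pool_id for p in pools if p.expected_count == c],
                         "causal"].mean()
            for c in (0, 1, 2)
        }
        assert means[0] <= means[1] <= means[2]

    def test_insufficient_class_is_error(self):
        truth = _truth_with_classes(8)
        truth = [t for t in truth if t.serology_recorded != ("I2", "I2")]
        dosage = pd.DataFrame({"v": 1.0}, index=[t.sample_id for t in truth])
        with pytest.raises(ValueError, match="insufficient"):
            simulate_pools(truth, dosage)

    def test_theta_bounded_after_noise(self):
        truth = _truth_with_classes(8)
        dosage = pd.DataFrame({"v": 2.0}, index=[t.sample_id for t in truth])
        _, theta = simulate_pools(truth, dosage, sigma=0.5, seed=3)
        assert ((theta >= 0) & (theta <= 1)).all().all()


class TestSimulateArrayGenotypes:
    def _truth(self, table, n, seed=0, freqs=None):
        cfg = LineConfig("L", freqs or {"H01": 0.5, "H02": 0.5}, n, seed=seed)
        return simulate_line(cfg, table, AMAP)[0]

    def test_perfect_ld_limit_equals_causal_dosage(self, table):
        truth = self._truth(table, 120, seed=9)
        gc = GenomeConfig(n_background_snps=0, ld_decay_bp=np.inf, n_causal_snps=5)
        _, dosage = simulate_array_genotypes(truth, table, gc, seed=1)
        causal_dosage = np.array(
            [sum(h == "H02" for h in t.diplotype) for t in truth], dtype=float
        )
        for col in dosage.columns:
            assert np.array_equal(dosage[col].to_numpy(), causal_dosage)

    def test_zero_background_yields_only_causal_records(self, table):
        truth = self._truth(table, 20)
        gc = GenomeConfig(n_background_snps=0, n_causal_snps=7)
        snp_info, dosage = simulate_array_genotypes(truth, table, gc, seed=2)
        assert all(s.startswith("c23_") for s in snp_info.index)
        assert (snp_info["chrom"] == "23").all()

    def test_background_follows_hardy_weinberg(self, table):
        truth = self._truth(table, 4000, seed=3)
        gc = GenomeConfig(n_background_snps=3, n_causal_snps=2)
        _, dosage = simulate_array_genotypes(truth, table, gc, seed=4)
        for col in [c for c in dosage.columns if c.startswith("bg_")]:
            d = dosage[col].to_numpy()
            p_hat = d.mean() / 2
            hom_alt = (d == 2).mean()
            se = np.sqrt(p_hat**2 * (1 - p_hat**2) / d.size)
            assert abs(hom_alt - p_hat**2) <= 3 * se + 1e-3

    def test_determinism(self, table):
        truth = self._truth(table, 50)
        gc = GenomeConfig(n_background_snps=10, n_causal_snps=5)
        a = simulate_array_genotypes(truth, table, gc, seed=11)
        b = simulate_array_genotypes(truth, table, gc, seed=11)
        assert a[0].equals(b[0]) and a[1].equals(b[1])


class TestSimulateCoverage:
    def _rec(self, copies):
        return TruthRecord("s", ("H07", "H07"), ("I8", "I8"), ("I8", "I8"), copies)

    def test_noiseless_levels(self):
        cc = CoverageConfig(mean_depth_lambda=4.0)
        lo = cc.region[0]
        s, e = cc.deletion_span
        hom = simulate_coverage(self._rec(2), cc, noiseless=True)
        assert np.all(hom.depth[s - lo : e - lo + 1] == 0.0)
        assert np.all(hom.depth[: s - lo] == 4.0)
        het = simulate_coverage(self._rec(1), cc, noiseless=True)
        assert np.all(het.depth[s - lo : e - lo + 1] == 2.0)

    def test_no_deletion_matches_poisson_oracle(self):
        cc = CoverageConfig(mean_depth_lambda=4.0)
        track = simulate_coverage(self._rec(0), cc, seed=6)
        s, e = cc.deletion_span
        lo = cc.region[0]
        inside = track.depth[s - lo : e - lo + 1]
        assert inside.min() >= 0 and (inside == 0).mean() < 0.1
        n = track.depth.size
        assert abs(track.depth.mean() - 4.0) <= 3 * np.sqrt(4.0 / n)

    def test_span_must_sit_inside_region(self):
        with pytest.raises(ValueError):
            CoverageConfig(deletion_span=(10, 20), region=(15, 100))

    def test_determinism(self):
        cc = CoverageConfig()
        a = simulate_coverage(self._rec(1), cc, seed=8)
        b = simulate_coverage(self._rec(1), cc, seed=8)
        assert np.array_equal(a.depth, b.depth)
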