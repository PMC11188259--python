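"""Panel table integrity, expected genotypes and diplotype enumeration."""

import random

import pytest

from iblood.panel import (
    ALT,
    DEL,
    REF,
    HaplotypeProfile,
    HaplotypeTable,
    PanelSNP,
    call_diplotype,
    epitope_class,
    expected_genotype,
    predict_serology,
    validate_table,
)


def rsid_index(table, rsid):
    return next(i for i, s in enumerate(table.snps) if s.rsid == rsid)


class TestTableFixture:
    def test_panel_shape(self, table):
        assert table.n_snps == 15
        assert len(table.haplotypes) == 16
        assert "H09" not in table.haplotypes

    def test_h01_is_all_reference(self, table):
        assert table["H01"].bases(table.snps) == (
            "G", "C", "C", "G", "A", "T", "T", "A", "T", "G", "A", "T", "G", "C", "G",
        )

    def test_h02_alternate_pattern(self, table):
        # alternate at SNPs 2-9 and 13-15
        states = table["H02"].alleles
        alt_at = {i + 1 for i, s in enumerate(states) if s == ALT}
        assert alt_at == set(range(2, 10)) | {13, 14, 15}
        assert table["H02"].bases(table.snps) == (
            "G", "T", "T", "C", "G", "C", "C", "G", "C", "G", "A", "T", "A", "A", "A",
        )

    def test_h10_differs_from_h04_only_at_last_snp(self, table):
        diff = [
            s.rsid
            for s, a, b in zip(table.snps, table["H04"].alleles, table["H10"].alleles)
            if a != b
        ]
        assert diff == ["rs737604974"]

    def test_short_haplotypes_have_trailing_deleted_block(self, table):
        shorts = {n for n, h in table.haplotypes.items() if h.is_short}
        assert shorts == {"H07", "H12", "H13", "H16"}
        for name in shorts:
            assert table[name].alleles[7:] == (DEL,) * 8
            assert DEL not in table[name].alleles[:7]

    def test_serological_annotations(self, table):
        annotated = {
            n: h.serological_alleles
            for n, h in table.haplotypes.items()
            if h.serological_alleles
        }
        assert annotated == {
            "H01": {"I8"},
            "H02": {"I2"},
            "H03": {"I4", "I8"},
            "H04": {"I8"},
            "H10": {"I8"},
            "H11": {"I3"},
        }

    def test_fixture_validates(self, table):
        assert validate_table(table) == []


class TestValidate:
    def _tiny(self, profiles, equivalent=frozenset()):
        snps = tuple(
            PanelSNP(rsid=f"rs{i}", chrom="1", pos=100 * i, ref="A", alt="C",
                     order_index=i)
            for i in range(1, 4)
        )
        haps = {
            name: HaplotypeProfile(name=name, alleles=tuple(states))
            for name, states in profiles.items()
        }
        return HaplotypeTable(snps=snps, haplotypes=haps, panel_equivalent=equivalent)

    def test_duplicate_allele_vector_is_error(self):
        t = self._tiny({"A1": (REF, ALT, REF), "A2": (REF, ALT, REF)})
        errors = validate_table(t)
        assert any("duplicated allele vector" in e for e in errors)

    def test_declared_equivalence_is_accepted(self):
        t = self._tiny(
            {"A1": (REF, ALT, REF), "A2": (REF, ALT, REF)},
            equivalent=frozenset({frozenset({"A1", "A2"})}),
        )
        assert validate_table(t) == []

    def test_non_contiguous_deletion_is_error(self):
        t = self._tiny({"A1": (REF, DEL, REF)})
        errors = validate_table(t)
        assert any("contiguous trailing block" in e for e in errors)


class TestExpectedGenotype:
    @pytest.mark.parametrize(
        "pair, rsid, call",
        [
            (("H01", "H02"), "rs740623580", "RR"),  # both carry G
            (("H01", "H02"), "rs869007872", "RA"),  # C vs T
            (("H07", "H07"), "rs738898886", "FAIL"),  # deleted on both
            (("H01", "H07"), "rs738898886", "RR"),  # hemizygous REF
            (("H02", "H12"), "rs314800215", "AA"),  # hemizygous ALT
        ],
    )
    def test_site_rules(self, table, pair, rsid, call):
        g = table.expected_genotype(*pair)
        assert g[rsid_index(table, rsid)] == call

    def test_full_short_het_appears_homozygous(self, table):
        g = table.expected_genotype("H01", "H07")
        assert "FAIL" not in g and "RA" not in g


class TestCallDiplotype:
    def test_unique_homozygote_within_line_candidates(self, table):
        g = table.expected_genotype("H02", "H02")
        call = call_diplotype("s", g, table, candidates={"H01", "H02"})
        assert call.unique and call.best_pair == ("H02", "H02")

    def test_full_table_reveals_short_shadow_of_h02(self, table):
        # against the complete table, H02/H02 is indistinguishable from
        # H02/H12 (the short haplotype hides under the full one)
        g = table.expected_genotype("H02", "H02")
        call = call_diplotype("s", g, table)
        assert call.compatible_pairs == {("H02", "H02"), ("H02", "H12")}
        assert call.short_ambiguous and not call.unique

    def test_full_short_ambiguity(self, table):
        g = table.expected_genotype("H01", "H07")
        call = call_diplotype("s", g, table)
        assert {("H01", "H07"), ("H01", "H01")} <= call.compatible_pairs
        assert call.short_ambiguous

    def test_homozygous_short_is_unique(self, table):
        g = table.expected_genotype("H07", "H07")
        call = call_diplotype("s", g, table)
        assert call.unique and call.best_pair == ("H07", "H07")

    def test_novel_homozygous_profile_inferred(self, table):
        calls = ("AA",) * 15  # no haplotype is all-alternate
        call = call_diplotype("s", calls, table)
        assert not call.compatible_pairs
        assert call.novel
        assert call.inferred_alleles == (ALT,) * 15

    def test_unexplained_het_profile_is_not_novel(self, table):
        calls = ("RA",) * 15
        call = call_diplotype("s", calls, table)
        if not call.compatible_pairs:
            assert not call.novel

    def test_soundness_over_all_pairs(self, table):
        # every pair's expected genotype must recover that pair (its
        # canonical representative) among the compatible set
        assert len(table.pairs()) == 136
        for a, b in table.pairs():
            g = table.expected_genotype(a, b)
            call = call_diplotype("s", g, table)
            canon = tuple(sorted((table.representative(a), table.representative(b))))
            assert canon in call.compatible_pairs

    def test_agrees_with_independent_enumeration(self, table):
        # independent oracle: per-site compatibility sets intersected
        site_rule = {
            (REF, REF): "RR", (ALT, ALT): "AA", (REF, ALT): "RA", (ALT, REF): "RA",
            (DEL, DEL): "FAIL", (DEL, REF): "RR", (REF, DEL): "RR",
            (DEL, ALT): "AA", (ALT, DEL): "AA",
        }

        def oracle(calls):
            out = set()
            names = table.names()
            for i, a in enumerate(names):
                for b in names[i:]:
                    ok = all(
                        site_rule[(x, y)] == c
                        for x, y, c in zip(table[a].alleles, table[b].alleles, calls)
                    )
                    if ok:
                        out.add(tuple(sorted(
                            (table.representative(a), table.representative(b)))))
            return out

        rng = random.Random(20240619)
        for _ in range(300):
            calls = tuple(rng.choice(("RR", "RA", "AA", "FAIL")) for _ in range(15))
            assert call_diplotype("s", calls, table).compatible_pairs == oracle(calls)

    def test_independent_of_table_row_order(self, table):
        shuffled = HaplotypeTable(
            snps=table.snps,
            haplotypes=dict(reversed(list(table.haplotypes.items()))),
            panel_equivalent=table.panel_equivalent,
        )
        g = table.expected_genotype("H01", "H03")
        assert (
            call_diplotype("s", g, table).compatible_pairs
            == call_diplotype("s", g, shuffled).compatible_pairs
        )

    def test_malformed_calls_rejected(self, table):
        with pytest.raises(ValueError):
            call_diplotype("s", ("XX",) * 15, table)


class TestSerologyPrediction:
    def test_examples(self, table):
        niu_map = {"I2": {"H02"}, "I8": {"H03", "H04"}}
        wl1_map = {"I2": {"H02"}, "I8": {"H01"}}

        def call_of(a, b, candidates):
            return call_diplotype(
                "s", table.expected_genotype(a, b), table, candidates=candidates
            )

        assert predict_serology(call_of("H01", "H02", {"H01", "H02"}), wl1_map) == "I2/I8"
        assert predict_serology(call_of("H03", "H04", {"H03", "H04", "H02"}), niu_map) == "I8/I8"
        assert predict_serology(call_of("H05", "H05", {"H05"}), wl1_map) == "unknown"

    def test_non_unique_is_ambiguous(self, table):
        call = call_diplotype("s", table.expected_genotype("H01", "H07"), table)
        assert predict_serology(call, {"I8": {"H01"}}) == "ambiguous"


class TestEpitopeClass:
    @pytest.mark.parametrize(
        "name, expected",
        [
            ("H02", "I2-like"),
            ("H01", "I8-like"),
            ("H03", "I8-like"),
            ("H04", "I8-like"),
            ("H10", "I8-like"),
            ("H07", "indeterminate"),
            ("H08", "other"),
        ],
    )
    def test_classes(self, table, name, expected):
        assert epitope_class(table[name]) == expected
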