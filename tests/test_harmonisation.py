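import numpy as np
import pytest

from adipomr.errors import ConfigError, HarmonisationError, MissingSNPError
from adipomr.harmonisation import (
    FLAG_DROPPED_MISMATCH,
    FLAG_DROPPED_MISSING_OUTCOME,
    FLAG_DROPPED_PALINDROMIC,
    FLAG_FLIPPED,
    FLAG_KEPT,
    InstrumentSpec,
    clump,
    extract_region,
    harmonise_pair,
    select_instrument,
)
from adipomr.sumstats_io import AssociationRecord, LDMatrix


def rec(snp, p=1e-10, chrom="1", pos=1000, ea="A", oa="G", beta=0.1, se=0.02, eaf=0.3, **kw):
    return AssociationRecord(snp, chrom, pos, ea, oa, beta, se, p, 10_000, eaf, **kw)


def ld_from(ids, r):
    return LDMatrix(tuple(ids), np.asarray(r, dtype=float))


class TestInstrumentSpec:
    def test_tss_required_iff_cis_mode(self):
        with pytest.raises(ConfigError):
            InstrumentSpec(mode="monogenic_cis")
        with pytest.raises(ConfigError):
            InstrumentSpec(mode="polygenic", gene_tss=("1", 100))
        spec = InstrumentSpec(mode="monogenic_cis", gene_tss=("1", 100))
        assert spec.gene_tss == ("1", 100)


class TestSelectInstrument:
    def test_no_genomewide_significant_snps_gives_empty_instrument(self):
        records = [rec(f"rs{i}", p=1e-6) for i in range(10)]
        spec = InstrumentSpec(mode="polygenic")
        assert select_instrument(records, spec) == []

    def test_single_cis_snp_within_window_is_kept(self):
        # one significant SNP 500 kb from the TSS: a valid single-SNP cis instrument
        spec = InstrumentSpec(mode="monogenic_cis", gene_tss=("1", 1_000_000))
        kept = select_instrument([rec("rs1", p=1e-9, pos=1_500_000)], spec)
        assert [r.snp_id for r in kept] == ["rs1"]

    def test_cis_window_is_closed_and_excludes_beyond_1mb(self):
        spec = InstrumentSpec(mode="monogenic_cis", gene_tss=("1", 1_000_000))
        at_edge = rec("rs_edge", p=1e-9, pos=2_000_000)
        beyond = rec("rs_far", p=1e-9, pos=2_500_000)
        other_chrom = rec("rs_chr2", p=1e-9, chrom="2", pos=1_000_000)
        kept = select_instrument([at_edge, beyond, other_chrom], spec)
        assert [r.snp_id for r in kept] == ["rs_edge"]


class TestClump:
    def test_mutually_correlated_snps_collapse_to_smallest_p(self):
        ids = ["a", "b", "c"]
        records = [rec("a", p=1e-9), rec("b", p=1e-12, pos=2000), rec("c", p=1e-10, pos=3000)]
        kept = clump(records, ld_from(ids, np.ones((3, 3))), 0.01)
        assert [r.snp_id for r in kept] == ["b"]

    def test_greedy_rule_on_three_snp_example(self):
        # A(1e-10), B(1e-9, r2_AB=0.005), C(1e-8, r2_AC=0.5): threshold 0.01 keeps {A, B}
        ids = ["A", "B", "C"]
        r = np.eye(3)
        r[0, 1] = r[1, 0] = np.sqrt(0.005)
        r[0, 2] = r[2, 0] = np.sqrt(0.5)
        records = [rec("A", p=1e-10), rec("B", p=1e-9, pos=2000), rec("C", p=1e-8, pos=3000)]
        kept = clump(records, ld_from(ids, r), 0.01)
        assert sorted(x.snp_id for x in kept) == ["A", "B"]

    def test_weak_correlation_threshold_admits_all_three(self):
        ids = ["A", "B", "C"]
        r = np.eye(3)
        r[0, 1] = r[1, 0] = np.sqrt(0.005)
        r[0, 2] = r[2, 0] = np.sqrt(0.12)
        r[1, 2] = r[2, 1] = np.sqrt(0.009)
        records = [rec("A", p=1e-10), rec("B", p=1e-9, pos=2000), rec("C", p=1e-8, pos=3000)]
        kept = clump(records, ld_from(ids, r), 0.15)
        assert sorted(x.snp_id for x in kept) == ["A", "B", "C"]

    def test_result_satisfies_greedy_certificate_and_order_invariance(self, rng):
        # certificate: kept SNPs pairwise below threshold; every rejected SNP
        # conflicts with a kept SNP of smaller p
        m = 12
        ids = [f"rs{i}" for i in range(m)]
        a = rng.uniform(-1, 1, (m, m))
        r = np.clip((a + a.T) / 2, -0.99, 0.99)
        np.fill_diagonal(r, 1.0)
        ld = ld_from(ids, r)
        records = [rec(ids[i], p=float(rng.uniform(1e-12, 1e-8)), pos=1000 * (i + 1)) for i in range(m)]
        thr = 0.1
        kept = clump(records, ld, thr)
        kept_ids = [k.snp_id for k in kept]
        idx = {s: i for i, s in enumerate(ids)}
        pv = {x.snp_id: x.pvalue for x in records}
        for i, a_id in enumerate(kept_ids):
            for b_id in kept_ids[:i]:
                assert ld.r2[idx[a_id], idx[b_id]] < thr
        for x in records:
            if x.snp_id not in kept_ids:
                assert any(
                    ld.r2[idx[x.snp_id], idx[k]] >= thr and pv[k] < pv[x.snp_id] for k in kept_ids
                )
        shuffled = list(records)
        rng.shuffle(shuffled)
        assert [k.snp_id for k in clump(shuffled, ld, thr)] == kept_ids

    def test_snp_missing_from_ld_raises(self):
        with pytest.raises(MissingSNPError):
            clump([rec("zz")], ld_from(["a"], [[1.0]]), 0.01)


class TestHarmonisePair:
    EXP = rec("rs1", beta=0.2, se=0.02, ea="A", oa="G", eaf=0.3)

    @pytest.mark.parametrize(
        "out_ea,out_oa,expect_flag,expect_sign",
        [
            ("A", "G", FLAG_KEPT, +1),        # identical alleles
            ("G", "A", FLAG_FLIPPED, -1),     # swapped report
            ("T", "C", FLAG_KEPT, +1),        # strand complement
            ("C", "T", FLAG_FLIPPED, -1),     # strand complement, swapped
            ("A", "C", FLAG_DROPPED_MISMATCH, 0),  # incompatible alleles
        ],
    )
    def test_allele_configurations(self, out_ea, out_oa, expect_flag, expect_sign):
        out = rec("rs1", beta=0.1, se=0.03, ea=out_ea, oa=out_oa, eaf=0.3)
        if expect_sign == 0:
            with pytest.raises(HarmonisationError):
                harmonise_pair([self.EXP], [out])
            return
        h = harmonise_pair([self.EXP], [out])
        assert h.provenance["rs1"] == expect_flag
        assert h.beta_outcome[0] == pytest.approx(expect_sign * 0.1)

    @pytest.mark.parametrize(
        "exp_eaf,out_ea,out_oa,out_eaf,expect",
        [
            (0.50, "A", "T", 0.50, "dropped"),   # both ambiguous (inside band)
            (0.30, "A", "T", 0.50, "dropped"),   # outcome ambiguous
            (0.30, "A", "T", 0.30, ("kept", +1)),    # frequencies agree
            (0.30, "A", "T", 0.70, ("flipped", -1)),  # opposite strand labelling
            (0.30, "T", "A", 0.70, ("flipped", -1)),  # label swap already frequency-consistent
            (0.42, "A", "T", 0.42, ("kept", +1)),    # band edge counts as resolvable
            (None, "A", "T", 0.30, "dropped"),   # missing eaf disables resolution
        ],
    )
    def test_palindromic_resolution_by_frequency(self, exp_eaf, out_ea, out_oa, out_eaf, expect):
        exp = rec("rs1", beta=0.2, ea="A", oa="T", eaf=exp_eaf)
        out = rec("rs1", beta=0.1, ea=out_ea, oa=out_oa, eaf=out_eaf)
        if expect == "dropped":
            with pytest.raises(HarmonisationError):
                harmonise_pair([exp], [out])
            # flag visible when another SNP keeps the set alive
            keeper_exp = rec("rs2", pos=2000)
            keeper_out = rec("rs2", pos=2000, beta=0.05)
            h = harmonise_pair([exp, keeper_exp], [out, keeper_out])
            assert h.provenance["rs1"] == FLAG_DROPPED_PALINDROMIC
        else:
            flag, sign = expect
            h = harmonise_pair([exp], [out])
            assert h.provenance["rs1"] == (FLAG_KEPT if flag == "kept" else FLAG_FLIPPED)
            assert h.beta_outcome[0] == pytest.approx(sign * 0.1)

    def test_missing_outcome_snp_flagged_and_dropped(self):
        exp2 = rec("rs2", pos=2000)
        out2 = rec("rs2", pos=2000, beta=0.07)
        h = harmonise_pair([self.EXP, exp2], [out2])
        assert h.provenance["rs1"] == FLAG_DROPPED_MISSING_OUTCOME
        assert h.snp_ids == ("rs2",)

    def test_all_dropped_raises(self):
        with pytest.raises(HarmonisationError):
            harmonise_pair([self.EXP], [rec("other", pos=99)])

    def test_idempotent_on_already_harmonised_records(self):
        exposure = [rec("rs1", beta=0.2), rec("rs2", pos=2000, beta=0.15)]
        outcome = [
            rec("rs1", beta=0.1, ea="G", oa="A", eaf=0.7),   # swapped
            rec("rs2", pos=2000, beta=-0.02, ea="T", oa="C"),  # complemented
        ]
        h1 = harmonise_pair(exposure, outcome)
        # re-expressing the harmonised outcome on the exposure alleles and
        # re-harmonising must change nothing
        harmonised_outcome = [
            rec(s, beta=float(b), se=float(se), ea=e.effect_allele, oa=e.other_allele, pos=e.pos)
            for s, b, se, e in zip(h1.snp_ids, h1.beta_outcome, h1.se_outcome, exposure)
        ]
        h2 = harmonise_pair(exposure, harmonised_outcome)
        np.testing.assert_array_equal(h1.beta_outcome, h2.beta_outcome)
        assert all(h2.provenance[s] == FLAG_KEPT for s in h2.snp_ids)

    def test_invariant_under_flipping_every_outcome_record(self):
        exposure = [rec("rs1", beta=0.2), rec("rs2", pos=2000, beta=0.15)]
        outcome = [rec("rs1", beta=0.1), rec("rs2", pos=2000, beta=-0.04)]
        flipped = [
            rec(r.snp_id, beta=-r.beta, se=r.se, ea=r.other_allele, oa=r.effect_allele,
                eaf=1 - r.eaf, pos=r.pos)
            for r in outcome
        ]
        h1 = harmonise_pair(exposure, outcome)
        h2 = harmonise_pair(exposure, flipped)
        np.testing.assert_allclose(h1.beta_outcome, h2.beta_outcome)
        np.testing.assert_allclose(h1.eaf, h2.eaf)


class TestExtractRegion:
    def test_boundary_snp_included_in_closed_window(self):
        records = [
            rec("idx", pos=500_000),
            rec("edge_lo", pos=400_000),
            rec("edge_hi", pos=600_000),
            rec("out", pos=600_001),
            rec("other", chrom="2", pos=500_000),
        ]
        region = extract_region(records, "idx", 100_000)
        assert set(region.snp_ids) == {"idx", "edge_lo", "edge_hi"}
        assert region.window == ("1", 400_000, 600_000)

    def test_zero_window_keeps_only_index(self):
        records = [rec("idx", pos=500_000), rec("near", pos=500_001)]
        region = extract_region(records, "idx", 0)
        assert region.snp_ids == ("idx",)

    def test_matches_brute_force_filter_on_uniform_region(self, rng):
        # ~500 SNPs uniform over +/-200 kb; a 100 kb window keeps about half
        center = 1_000_000
        positions = np.unique(rng.integers(center - 200_000, center + 200_001, size=500))
        records = [rec(f"rs{i}", pos=int(p)) for i, p in enumerate(positions)]
        records.append(rec("idx", pos=center))
        region = extract_region(records, "idx", 100_000)
        brute = {r.snp_id for r in records if abs(r.pos - center) <= 100_000}
        assert set(region.snp_ids) == brute
        assert 0.4 < len(brute) / len(records) < 0.6

    def test_missing_index_snp_raises(self):
        with pytest.raises(MissingSNPError):
            extract_region([rec("a")], "nope", 1000)
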