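"""Instrument selection: strength formulas, cis windows, clumping, exclusions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cismr import (
    ConfigurationError,
    DataError,
    GeneRegion,
    NoInstrumentsError,
    SelectionConfig,
    apply_exclusions,
    clump,
    select_cis_candidates,
    select_genome_wide,
    snp_f_statistic,
    snp_variance_explained,
)
from cismr.simulate import simulate_ld_block
from cismr.sumstats import LdMatrix

from conftest import make_dataset, make_snp


class TestStrengthFormulas:
    def test_zero_beta_gives_zero_r2(self):
        assert snp_variance_explained(0.3, 0.0, 0.003, 1000) == 0.0

    def test_vanishing_se_limit(self):
        assert snp_variance_explained(0.3, 0.02, 1e-9, 1000) > 0.999

    def test_r2_against_direct_arithmetic(self):
        eaf, beta, se, n = 0.3, 0.02, 0.003, 344_182
        het = 2 * eaf * (1 - eaf)
        expected = (het * beta**2) / (het * beta**2 + het * n * se**2)
        got = snp_variance_explained(eaf, beta, se, n)
        assert got == pytest.approx(expected, abs=1e-15)
        # chained F from the same r2
        f = snp_f_statistic(got, n)
        assert f == pytest.approx(expected * (n - 2) / (1 - expected), abs=1e-9)

    def test_boundary_eaf_rejected(self):
        with pytest.raises(DataError):
            snp_variance_explained(0.0, 0.02, 0.003, 1000)
        with pytest.raises(DataError):
            snp_variance_explained(1.0, 0.02, 0.003, 1000)

    def test_f_trivial_values(self):
        assert snp_f_statistic(0.0, 1000) == 0.0
        assert snp_f_statistic(0.5, 4) == pytest.approx(2.0)
        with pytest.raises(DataError):
            snp_f_statistic(1.0, 1000)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        eaf=st.floats(0.01, 0.99),
        beta=st.floats(-0.5, 0.5),
        se=st.floats(1e-4, 0.1),
        n=st.integers(10, 10**6),
    )
    def test_r2_algebraic_simplification(self, eaf, beta, se, n):
        """The allele-frequency form equals beta²/(beta² + N·se²)."""
        full = snp_variance_explained(eaf, beta, se, n)
        simplified = beta**2 / (beta**2 + n * se**2)
        assert full == pytest.approx(simplified, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        r2a=st.floats(0.0, 0.5), dr=st.floats(1e-6, 0.4), n=st.integers(10, 10**6)
    )
    def test_f_monotone_in_r2_and_n(self, r2a, dr, n):
        assert snp_f_statistic(r2a + dr, n) > snp_f_statistic(r2a, n)
        assert snp_f_statistic(r2a + dr, n + 100) > snp_f_statistic(r2a + dr, n)


REGION = GeneRegion(gene="SLC5A2", chrom="16", start=31_494_323,
                    end=31_502_089, flank_kb=1000)


class TestCisCandidates:
    def test_boundary_snp_is_retained(self):
        lo, hi = REGION.window
        snps = [make_snp(rsid="rs_lo", pos=lo), make_snp(rsid="rs_hi", pos=hi),
                make_snp(rsid="rs_out", pos=lo - 1)]
        ds = make_dataset(snps)
        got = {s.rsid for s in select_cis_candidates(ds, REGION, 5e-8)}
        assert got == {"rs_lo", "rs_hi"}

    def test_other_chromosome_excluded_even_at_tiny_p(self):
        ds = make_dataset([make_snp(rsid="rs22", chrom="22",
                                    pos=31_500_000, pvalue=1e-300)])
        assert select_cis_candidates(ds, REGION, 5e-8) == []

    def test_build_mismatch_is_config_error(self):
        ds = make_dataset([make_snp()], build="GRCh38")
        with pytest.raises(ConfigurationError):
            select_cis_candidates(ds, REGION, 5e-8)

    def test_planted_window_snps_match_exhaustive_scan(self):
        rng = np.random.default_rng(42)
        lo, hi = REGION.window
        snps = []
        for i in range(50):
            inside = i < 12
            pos = (int(rng.integers(lo, hi)) if inside
                   else int(rng.integers(1, lo - 10)))
            p = 1e-12 if inside else float(rng.uniform(1e-6, 1.0))
            snps.append(make_snp(rsid=f"rs{i}", pos=pos, pvalue=p))
        ds = make_dataset(snps)
        got = {s.rsid for s in select_cis_candidates(ds, REGION, 5e-8)}
        # independent exhaustive scan
        expected = {
            s.rsid for s in snps
            if s.chrom == REGION.chrom and lo <= s.pos <= hi and s.pvalue < 5e-8
        }
        assert got == expected == {f"rs{i}" for i in range(12)}


class TestClump:
    def test_perfect_ld_keeps_smaller_p(self):
        a = make_snp(rsid="rsA", pos=1_000_000, pvalue=1e-10)
        b = make_snp(rsid="rsB", pos=1_050_000, pvalue=1e-8)
        ld = LdMatrix(["rsA", "rsB"], np.array([[1.0, 1.0], [1.0, 1.0]]))
        kept = clump([a, b], ld, r2_thresh=0.3, window_kb=100)
        assert [s.rsid for s in kept] == ["rsA"]

    def test_distance_gate_keeps_distant_correlated_pair(self):
        a = make_snp(rsid="rsA", pos=1_000_000, pvalue=1e-10)
        b = make_snp(rsid="rsB", pos=1_500_000, pvalue=1e-8)
        ld = LdMatrix(["rsA", "rsB"], np.array([[1.0, 0.9], [0.9, 1.0]]))
        kept = clump([a, b], ld, r2_thresh=0.3, window_kb=100)
        assert {s.rsid for s in kept} == {"rsA", "rsB"}

    def test_missing_ld_pair_treated_as_unlinked(self, caplog):
        a = make_snp(rsid="rsA", pos=1_000_000, pvalue=1e-10)
        b = make_snp(rsid="rsB", pos=1_010_000, pvalue=1e-8)
        ld = LdMatrix(["rsA"], np.array([[1.0]]))
        with caplog.at_level("WARNING"):
            kept = clump([a, b], ld, r2_thresh=0.3, window_kb=100)
        assert {s.rsid for s in kept} == {"rsA", "rsB"}
        assert any("absent from LD matrix" in m for m in caplog.messages)

    @staticmethod
    def _brute_force(cands, ld, r2_thresh, window_kb):
        """Independent greedy reference: explicit discard bookkeeping."""
        order = sorted(cands, key=lambda s: (s.pvalue, s.pos, s.rsid))
        kept, discarded = [], set()
        for s in order:
            if s.rsid in discarded:
                continue
            kept.append(s)
            for t in order:
                if t.rsid == s.rsid or t.rsid in discarded:
                    continue
                if t.rsid in {k.rsid for k in kept}:
                    continue
                r2 = ld.r2_between(s.rsid, t.rsid)
                if (r2 is not None and r2 > r2_thresh
                        and str(t.chrom) == str(s.chrom)
                        and abs(t.pos - s.pos) <= window_kb * 1000):
                    discarded.add(t.rsid)
        return sorted((s.rsid for s in kept))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_on_random_ld(self, seed):
        rng = np.random.default_rng(seed)
        snps = [
            make_snp(rsid=f"rs{i}", pos=1_000_000 + i * 30_000,
                     pvalue=float(rng.uniform(1e-12, 1e-6)))
            for i in range(6)
        ]
        a = rng.uniform(0, 1, (6, 6))
        r2 = (a + a.T) / 2
        np.fill_diagonal(r2, 1.0)
        ld = LdMatrix([s.rsid for s in snps], r2)
        got = [s.rsid for s in clump(snps, ld, 0.3, 100)]
        assert sorted(got) == self._brute_force(snps, ld, 0.3, 100)

    def test_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(11)
        snps = [
            make_snp(rsid=f"rs{i}", pos=1_000_000 + i * 40_000,
                     pvalue=float(rng.uniform(1e-12, 1e-6)))
            for i in range(8)
        ]
        ld = simulate_ld_block([s.rsid for s in snps], block_size=4, rho=0.8)
        once = clump(snps, ld, 0.3, 200)
        assert clump(once, ld, 0.3, 200) == once
        shuffled = list(reversed(snps))
        assert clump(shuffled, ld, 0.3, 200) == once

    def test_empty_input(self):
        ld = LdMatrix(["rs1"], np.eye(1))
        assert clump([], ld, 0.3, 100) == []


class TestExclusions:
    CONFIG = SelectionConfig()

    def test_high_eaf_excluded_at_maf_step(self):
        snp = make_snp(rsid="rsHi", eaf=0.995)
        keeper = make_snp(rsid="rsOk")
        outcome = make_dataset([make_snp(rsid="rsHi", pvalue=0.5),
                                make_snp(rsid="rsOk", pvalue=0.5)], trait="out")
        inst = apply_exclusions([snp, keeper], outcome, self.CONFIG)
        assert inst.rsids == ["rsOk"]
        assert inst.provenance[0] == ("maf", 2, 1)

    def test_absent_from_outcome_excluded(self):
        a, b = make_snp(rsid="rsA"), make_snp(rsid="rsB")
        outcome = make_dataset([make_snp(rsid="rsA", pvalue=0.5)], trait="out")
        inst = apply_exclusions([a, b], outcome, self.CONFIG)
        assert inst.rsids == ["rsA"]

    def test_empty_result_names_first_emptying_filter(self):
        weak = make_snp(rsid="rsW", beta=1e-5, se=0.01)  # F ~ 0
        outcome = make_dataset([make_snp(rsid="rsW", pvalue=0.5)], trait="out")
        with pytest.raises(NoInstrumentsError) as err:
            apply_exclusions([weak], outcome, self.CONFIG)
        assert err.value.filter_name == "f_stat"

    def test_planted_violations_match_rule_check_oracle(self):
        """One candidate violating each exclusion rule plus clean keepers."""
        cands = [
            make_snp(rsid="rs_maf", eaf=0.005),
            make_snp(rsid="rs_weak", beta=1e-5, se=0.01),
            make_snp(rsid="rs_absent"),
            make_snp(rsid="rs_outp"),
            *[make_snp(rsid=f"rs_ok{i}") for i in range(6)],
        ]
        outcome_snps = [
            make_snp(rsid="rs_maf", pvalue=0.5),
            make_snp(rsid="rs_weak", pvalue=0.5),
            make_snp(rsid="rs_outp", pvalue=1e-6),
            *[make_snp(rsid=f"rs_ok{i}", pvalue=0.5) for i in range(6)],
        ]
        outcome = make_dataset(outcome_snps, trait="out")
        inst = apply_exclusions(cands, outcome, self.CONFIG)

        def rule_check(s):  # independent exhaustive oracle
            maf = min(s.eaf, 1 - s.eaf)
            r2 = s.beta**2 / (s.beta**2 + s.n * s.se**2)
            f = r2 * (s.n - 2) / (1 - r2)
            if maf < 0.01 or f < 10 or s.rsid not in outcome:
                return False
            return not (outcome.get(s.rsid).pvalue < 5e-5)

        assert set(inst.rsids) == {s.rsid for s in cands if rule_check(s)}
        assert set(inst.rsids) == {f"rs_ok{i}" for i in range(6)}
        counts = [after for _, _, after in inst.provenance]
        assert counts == sorted(counts, reverse=True)  # monotone chain

    def test_strength_annotations_present_for_survivors(self):
        snp = make_snp()
        outcome = make_dataset([make_snp(pvalue=0.5)], trait="out")
        inst = apply_exclusions([snp], outcome, self.CONFIG)
        r2 = snp_variance_explained(snp.eaf, snp.beta, snp.se, snp.n)
        assert inst.per_snp_r2["rs1"] == pytest.approx(r2)
        assert inst.per_snp_f["rs1"] == pytest.approx(snp_f_statistic(r2, snp.n))


class TestGenomeWide:
    def _setup(self):
        rng = np.random.default_rng(3)
        regions = (
            GeneRegion(gene="SLC5A1", chrom="22", start=32_439_248,
                       end=32_509_016, flank_kb=500),
            GeneRegion(gene="SLC5A2", chrom="16", start=31_494_323,
                       end=31_502_089, flank_kb=1000),
        )
        snps = []
        for i in range(40):
            if i < 5:  # planted inside an excluded region, very significant
                chrom, pos = "22", 32_450_000 + i * 1000
            elif i < 10:
                chrom, pos = "16", 31_000_000 + i * 10_000
            else:
                chrom, pos = "3", 50_000_000 + i * 600_000
            p = 1e-50 if i < 5 else float(10.0 ** rng.uniform(-30, -4))
            snps.append(make_snp(rsid=f"rs{i}", chrom=chrom, pos=pos, pvalue=p))
        ds = make_dataset(snps)
        outcome = make_dataset(
            [make_snp(rsid=f"rs{i}", pvalue=0.5) for i in range(40)], trait="out"
        )
        ld = simulate_ld_block([f"rs{i}" for i in range(40)], block_size=1, rho=0.0)
        config = SelectionConfig(
            mode="genome_wide", p_threshold=5e-8, clump_r2=0.001,
            clump_window_kb=10_000, excluded_regions=regions,
        )
        return ds, outcome, ld, config, regions

    def test_excluded_region_snp_removed_despite_significance(self):
        ds, outcome, ld, config, _ = self._setup()
        inst = select_genome_wide(ds, config, ld, outcome)
        assert not any(r.startswith("rs0") or r in {"rs1", "rs2", "rs3", "rs4"}
                       for r in inst.rsids)

    def test_subthreshold_snp_removed(self):
        ds = make_dataset([make_snp(rsid="rs_sub", chrom="3",
                                    pos=1_000_000, pvalue=6e-8)])
        _, outcome, ld, config, _ = self._setup()
        with pytest.raises(NoInstrumentsError) as err:
            select_genome_wide(ds, config, ld, outcome)
        assert err.value.filter_name == "p_threshold"

    def test_matches_brute_force_oracle(self):
        ds, outcome, ld, config, regions = self._setup()
        inst = select_genome_wide(ds, config, ld, outcome)

        def oracle():
            out = []
            for s in ds:
                if s.pvalue >= 5e-8:
                    continue
                if any(r.contains(s.chrom, s.pos) for r in regions):
                    continue
                maf = min(s.eaf, 1 - s.eaf)
                r2 = s.beta**2 / (s.beta**2 + s.n * s.se**2)
                f = r2 * (s.n - 2) / (1 - r2)
                if maf < 0.01 or f < 10:
                    continue
                if s.rsid not in outcome or outcome.get(s.rsid).pvalue < 5e-5:
                    continue
                out.append(s.rsid)  # identity LD: clumping removes nothing
            return set(out)

        assert set(inst.rsids) == oracle()

    def test_requires_excluded_regions(self):
        ds, outcome, ld, config, _ = self._setup()
        bad = SelectionConfig(mode="genome_wide", excluded_regions=())
        with pytest.raises(ConfigurationError):
            select_genome_wide(ds, bad, ld, outcome)
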