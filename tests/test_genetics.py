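import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import panelgxe as p
from panelgxe.errors import DataError
from panelgxe.genetics import GenotypeTable, LdBlock, genotype_counts


def _table(columns: dict, genes: dict) -> GenotypeTable:
    geno = pd.DataFrame(columns, dtype=float)
    geno.index = [f"S{i}" for i in range(len(geno))]
    info = pd.DataFrame({"gene": [genes[c] for c in geno.columns]},
                        index=pd.Index(geno.columns, name="snp_id"))
    return GenotypeTable(geno, info)


class TestMafAndHwe:
    def test_maf_examples(self):
        col = [0] * 25 + [1] * 50 + [2] * 25
        assert p.minor_allele_frequency(col) == (0.5, False)
        col = [0] * 90 + [1] * 10
        assert p.minor_allele_frequency(col) == (0.05, False)

    def test_maf_flip_when_coded_allele_is_major(self):
        maf, flipped = p.minor_allele_frequency([2] * 100)
        assert maf == 0.0 and flipped

    @pytest.mark.parametrize("counts, chi2", [
        ((25, 50, 25), 0.0),
        ((50, 0, 50), 100.0),     # expected (25, 50, 25): 25 + 50 + 25
        ((36, 48, 16), 0.0),      # q = 0.4: exact HW proportions
    ])
    def test_hwe_examples(self, counts, chi2):
        res = p.hwe_test(*counts)
        assert res.chi2 == pytest.approx(chi2, abs=1e-9)
        if chi2 == 0.0:
            assert res.p == pytest.approx(1.0)

    def test_hwe_monomorphic_flagged(self):
        res = p.hwe_test(100, 0, 0)
        assert res.monomorphic and res.p == 1.0

    def test_hwe_matches_textbook_chisquare(self):
        """Exact agreement with scipy's chi-square on random count triples."""
        rng = np.random.default_rng(11)
        for _ in range(1000):
            n = int(rng.integers(20, 500))
            q = rng.uniform(0.05, 0.95)
            counts = rng.multinomial(n, [(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
            n0, n1, n2 = counts
            qhat = (n1 + 2 * n2) / (2 * n)
            if qhat in (0.0, 1.0):
                continue
            expected = n * np.array([(1 - qhat) ** 2, 2 * qhat * (1 - qhat),
                                     qhat ** 2])
            oracle = stats.chisquare(counts, expected, ddof=1)
            res = p.hwe_test(n0, n1, n2)
            assert res.chi2 == pytest.approx(oracle.statistic, abs=1e-9)
            assert res.p == pytest.approx(oracle.pvalue, abs=1e-9)

    def test_hwe_exclusion_removes_only_violators(self):
        rng = np.random.default_rng(3)
        ok = rng.binomial(2, 0.3, 500)
        bad = np.concatenate([np.zeros(250), np.full(250, 2.0)])  # no hets
        table = _table({"ok": ok, "bad": bad}, {"ok": "G1", "bad": "G2"})
        kept, log = p.apply_hwe_exclusion(table, alpha=1e-3)
        assert kept.snp_ids == ["ok"]
        assert log["snp_id"].tolist() == ["bad"]

    def test_hwe_exclusion_alpha_zero_keeps_all(self):
        table = _table({"a": [0, 1, 2, 1], "b": [2, 2, 0, 0]},
                       {"a": "G1", "b": "G1"})
        kept, log = p.apply_hwe_exclusion(table, alpha=0.0)
        assert kept.snp_ids == ["a", "b"] and log.empty


class TestEmHaplotypes:
    def test_unambiguous_phase_gives_complete_ld(self):
        ga = [0] * 30 + [2] * 30
        gb = [0] * 30 + [2] * 30
        em = p.em_haplotype_freqs(ga, gb)
        assert p.d_prime(em.freqs).value == pytest.approx(1.0)
        assert em.n_iter <= 2  # counting estimate, one effective step
        assert em.freqs[0] == pytest.approx(0.5) and em.freqs[3] == pytest.approx(0.5)

    def test_independent_snps_factorize(self):
        rng = np.random.default_rng(4)
        ga = rng.binomial(2, 0.4, 5000)
        gb = rng.binomial(2, 0.25, 5000)
        em = p.em_haplotype_freqs(ga, gb)
        assert em.freqs[3] == pytest.approx(0.4 * 0.25, abs=0.01)

    def test_loglik_monotone_and_freqs_sum_to_one(self):
        rng = np.random.default_rng(9)
        ga = rng.integers(0, 3, 80)
        gb = rng.integers(0, 3, 80)
        em = p.em_haplotype_freqs(ga, gb)
        assert em.freqs.sum() == pytest.approx(1.0, abs=1e-12)
        trace = np.array(em.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-9)

    def test_matches_grid_oracle_on_small_samples(self):
        from panelgxe.validation import em_grid_agreement
        gaps = em_grid_agreement(n_pairs=8, seed=6)
        assert gaps["max_loglik_gap"] < 1e-3
        assert gaps["max_d_prime_gap"] < 1e-3


class TestDPrime:
    @pytest.mark.parametrize("freqs, expected", [
        ((0.5, 0.0, 0.0, 0.5), 1.0),
        ((0.25, 0.25, 0.25, 0.25), 0.0),
        ((0.12, 0.08, 0.08, 0.72), 0.5),   # D=0.08, Dmax=0.16
    ])
    def test_examples(self, freqs, expected):
        assert p.d_prime(freqs).value == pytest.approx(expected)

    def test_monomorphic_flagged_as_zero(self):
        res = p.d_prime((0.6, 0.4, 0.0, 0.0))  # locus a monomorphic
        assert res.value == 0.0 and res.monomorphic

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4))
    def test_bounded_and_invariant_to_relabelling(self, raw):
        f = np.array(raw) / np.sum(raw)
        base = p.d_prime(f).value
        assert 0.0 <= base <= 1.0
        swapped = f[[0, 2, 1, 3]]            # swap the two loci
        relabeled = f[[2, 3, 0, 1]]          # relabel alleles at locus a
        assert p.d_prime(swapped).value == pytest.approx(base, abs=1e-12)
        assert p.d_prime(relabeled).value == pytest.approx(base, abs=1e-9)


class TestBlocksAndPruning:
    def _linked_table(self, dp, seed=0):
        from panelgxe.synthetic import (LdBlockSpec, SnpSpec, simulate_genotypes,
                                        two_snp_haplotypes)
        snps = [SnpSpec("a", "G1", 0.3), SnpSpec("b", "G1", 0.3),
                SnpSpec("c", "G2", 0.2)]
        blocks = [LdBlockSpec("G1", ("a", "b"),
                              two_snp_haplotypes(0.3, 0.3, dp))] if dp else []
        return simulate_genotypes(3000, snps, blocks, seed=seed)

    def test_strong_pair_forms_block(self):
        table = self._linked_table(0.98)
        blocks = p.find_ld_blocks(table, threshold=0.8)
        members = {b.members for b in blocks}
        assert ("a", "b") in members and ("c",) in members

    def test_weak_pair_stays_singletons(self):
        table = self._linked_table(0.3)
        blocks = p.find_ld_blocks(table, threshold=0.8)
        assert all(len(b.members) == 1 for b in blocks)

    def test_cross_gene_ld_never_merged(self):
        # identical genotype columns in different genes: |D'| = 1 but no block
        geno = np.random.default_rng(1).binomial(2, 0.4, 2000)
        table = _table({"x": geno, "y": geno}, {"x": "G1", "y": "G2"})
        blocks = p.find_ld_blocks(table, threshold=0.8)
        assert all(len(b.members) == 1 for b in blocks)

    def test_prune_keeps_one_per_block(self):
        blocks = [LdBlock("G1", ("a", "b")), LdBlock("G2", ("c",))]
        retained = p.prune_blocks(["a", "b", "c"], blocks,
                                  pvalues={"a": 0.01, "b": 0.001, "c": 0.04})
        assert retained == ["b", "c"]
        assert p.prune_blocks(["a", "c"], blocks) == ["a", "c"]  # singleton identity

    def test_other_member_rule_differs_at_pairs_only(self):
        blocks = [LdBlock("G1", ("a", "b")), LdBlock("G2", ("c",))]
        pv = {"a": 0.01, "b": 0.001, "c": 0.04}
        primary = p.prune_blocks(["a", "b", "c"], blocks, pvalues=pv)
        alt = p.prune_blocks(["a", "b", "c"], blocks, rule="other_member",
                             pvalues=pv)
        assert alt == ["a", "c"] and len(alt) == len(primary)

    def test_overlapping_blocks_rejected(self):
        blocks = [LdBlock("G1", ("a", "b")), LdBlock("G1", ("b", "c"))]
        with pytest.raises(DataError):
            p.prune_blocks(["a"], blocks)


def test_qc_report_columns(gxe_cohort):
    genotypes, _, _ = gxe_cohort
    qc = genotypes.with_qc()
    for col in ("maf", "hwe_chi2", "hwe_p", "monomorphic"):
        assert col in qc.snp_info.columns
    assert (qc.snp_info["maf"] <= 0.5).all()
    counts = genotype_counts(qc.genotypes["snp_b"])
    assert sum(counts) == 400
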