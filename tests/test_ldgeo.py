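"""D', matched-MAF nulls, Fisher's exact depletion, genotype
combinations, clines and BLUP correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from transmqtl.containers import GenotypeMatrix, LineMetadataTable
from transmqtl.ldgeo import (
    blup_correct,
    d_prime,
    fisher_exact_1sided,
    genotype_combination_frequencies,
    longitude_cline,
    matched_maf_null,
    targeted_te_average,
)
from transmqtl.containers import MethylationPhenotype


def _haplotypes(n_AB, n_Ab, n_aB, n_ab):
    a = np.array([1] * (n_AB + n_Ab) + [0] * (n_aB + n_ab))
    b = np.array([1] * n_AB + [0] * n_Ab + [1] * n_aB + [0] * n_ab)
    return a, b


class TestDPrime:
    def test_perfect_coupling(self):
        # p_A = p_B = 0.1 with all carriers shared: D = 0.09, D' = 1
        a, b = _haplotypes(10, 0, 0, 90)
        pair = d_prime(a, b)
        assert pair.D == pytest.approx(0.09)
        assert pair.Dmax == pytest.approx(0.09)
        assert pair.d_prime == pytest.approx(1.0)

    def test_complete_repulsion(self):
        # p_A = p_B = 0.5, no double carriers: D = -0.25, D' = -1
        a, b = _haplotypes(0, 50, 50, 0)
        pair = d_prime(a, b)
        assert pair.D == pytest.approx(-0.25)
        assert pair.d_prime == pytest.approx(-1.0)

    def test_exact_independence(self):
        # p_AB = p_A * p_B exactly -> D' = 0
        a, b = _haplotypes(10, 10, 40, 40)  # p_A=0.2, p_B=0.5, p_AB=0.1
        pair = d_prime(a, b)
        assert pair.D == pytest.approx(0.0, abs=1e-12)
        assert pair.d_prime == 0.0

    def test_monomorphic_raises(self):
        with pytest.raises(ValueError):
            d_prime(np.zeros(10), np.r_[np.ones(5), np.zeros(5)])

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20),
           st.integers(1, 20))
    def test_invariants(self, nab, nAb, naB, nAB):
        a, b = _haplotypes(nAB, nAb, naB, nab)
        if a.var() == 0 or b.var() == 0:
            return
        pair = d_prime(a, b)
        assert abs(pair.D) <= pair.Dmax + 1e-12 or pair.Dmax == 0
        assert -1 - 1e-9 <= pair.d_prime <= 1 + 1e-9
        assert np.sign(pair.d_prime) == np.sign(pair.D)
        # symmetry in argument order
        rev = d_prime(b, a)
        assert rev.d_prime == pytest.approx(pair.d_prime, abs=1e-12)
        # joint allele-label swap leaves D' unchanged
        swap = d_prime(1 - a, 1 - b)
        assert swap.d_prime == pytest.approx(pair.d_prime, abs=1e-12)


class TestFisherExact:
    def test_hypergeometric_worked_value(self):
        # margins (5,5): P(top-left = 0) = C(5,0) C(5,5) / C(10,5) = 1/252
        assert fisher_exact_1sided([[0, 5], [5, 0]]) == pytest.approx(1 / 252)

    def test_balanced_table_no_depletion(self):
        assert fisher_exact_1sided([[25, 25], [25, 25]]) > 0.5

    def test_maximal_double_carrier_cell_p_one(self):
        assert fisher_exact_1sided([[5, 0], [0, 5]]) == pytest.approx(1.0)

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            fisher_exact_1sided([[-1, 2], [3, 4]])


def _geno_matrix(cols, chrom=None, line_ids=None):
    G = np.column_stack(cols).astype(np.int8)
    m = G.shape[1]
    snps = pd.DataFrame(
        {"snp_id": [f"s{j}" for j in range(m)],
         "chrom": chrom if chrom is not None else [1] * m,
         "pos": np.arange(1, m + 1)}
    )
    f = G.mean(axis=0)
    snps["maf"] = np.minimum(f, 1 - f)
    ids = line_ids or [f"l{i}" for i in range(G.shape[0])]
    return GenotypeMatrix(G, ids, snps)


class TestMatchedMafNull:
    def _panel(self, rng, n=400, m=800, depleted=False):
        """Target on chrom 1, partner on chrom 2, null SNPs on 3-5
        drawn at the partner's frequency."""
        p_t, p_p = 0.3, 0.25
        target = (rng.random(n) < p_t).astype(np.int8)
        if depleted:
            # force the double-carrier haplotype to 10% of independence
            partner = (rng.random(n) < p_p).astype(np.int8)
            both = (target == 1) & (partner == 1)
            kill = both & (rng.random(n) < 0.9)
            partner[kill] = 0
        else:
            partner = (rng.random(n) < p_p).astype(np.int8)
        cols = [target, partner]
        chroms = [1, 2]
        for j in range(m):
            cols.append((rng.random(n) < p_p).astype(np.int8))
            chroms.append(3 + j % 3)
        return _geno_matrix(cols, chrom=chroms)

    def test_independent_pair_p_uniform(self):
        pvals = []
        for seed in range(100):
            geno = self._panel(np.random.default_rng(seed))
            res = matched_maf_null(geno, "s0", "s1", maf_tol=0.05)
            pvals.append(res.p_empirical)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_depletion_detected(self):
        geno = self._panel(np.random.default_rng(0), depleted=True)
        res = matched_maf_null(geno, "s0", "s1", maf_tol=0.05)
        assert res.observed.d_prime < 0
        assert res.p_empirical < 0.01
        assert res.fisher_p_observed < 0.01

    def test_partner_chromosome_excluded(self):
        rng = np.random.default_rng(3)
        geno = self._panel(rng)
        res = matched_maf_null(geno, "s0", "s1", maf_tol=0.05)
        partner_chrom = {1, 2}
        chroms = geno.snps.set_index("snp_id")["chrom"]
        assert all(chroms[s] not in partner_chrom for s in res.matched_snp_ids)
        assert "s1" not in res.matched_snp_ids

    def test_too_few_matches_raises(self):
        rng = np.random.default_rng(1)
        geno = self._panel(rng, m=40)
        with pytest.raises(ValueError, match="maf_tol"):
            matched_maf_null(geno, "s0", "s1", maf_tol=1e-6)


class TestGenotypeCombinations:
    def test_independent_loci_ratio_near_one(self):
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = (rng.random(1000) < 0.3).astype(np.int8)
            b = (rng.random(1000) < 0.4).astype(np.int8)
            out = genotype_combination_frequencies(_geno_matrix([a, b]), ["s0", "s1"])
            row = out[out["combination"] == "1/1"].iloc[0]
            ok += 0.7 <= row["ratio"] <= 1.4
        assert ok >= 19

    def test_planted_tenfold_depletion_detected(self):
        rng = np.random.default_rng(5)
        a = (rng.random(2000) < 0.3).astype(np.int8)
        b = (rng.random(2000) < 0.4).astype(np.int8)
        both = (a == 1) & (b == 1)
        b[both & (rng.random(2000) < 0.9)] = 0
        out = genotype_combination_frequencies(_geno_matrix([a, b]), ["s0", "s1"])
        row = out[out["combination"] == "1/1"].iloc[0]
        assert row["ratio"] < 0.2

    def test_single_snp_counts_are_allele_counts(self):
        a = np.array([1, 0, 1, 1, 0], dtype=np.int8)
        b = np.array([0, 1, 0, 1, 0], dtype=np.int8)
        out = genotype_combination_frequencies(_geno_matrix([a, b]), ["s0"])
        assert out.set_index("combination")["observed"].to_dict() == {"0": 2, "1": 3}


def _metadata(lon, ids=None):
    ids = ids or [f"l{i}" for i in range(len(lon))]
    return LineMetadataTable(
        pd.DataFrame(
            {"line_id": ids, "longitude": lon,
             "latitude": 48.0, "subpopulation": "pop0"}
        )
    )


class TestTargetedTeAverage:
    def _pheno(self, V):
        return MethylationPhenotype(
            values=pd.DataFrame(
                V, index=[f"l{i}" for i in range(V.shape[0])],
                columns=[f"t{j}" for j in range(V.shape[1])],
            )
        )

    def test_all_tes_pass_equals_genomewide_mean(self, rng):
        V = rng.uniform(0, 1, (10, 6))
        scores = pd.Series(7.0, index=[f"t{j}" for j in range(6)])
        avg, te_set = targeted_te_average(self._pheno(V), scores, 6.0)
        np.testing.assert_allclose(avg.to_numpy(), V.mean(axis=1))
        assert len(te_set) == 6

    def test_infinite_threshold_raises(self, rng):
        V = rng.uniform(0, 1, (10, 6))
        scores = pd.Series(7.0, index=[f"t{j}" for j in range(6)])
        with pytest.raises(ValueError, match="threshold"):
            targeted_te_average(self._pheno(V), scores, np.inf)


class TestLongitudeCline:
    def test_exact_line_recovered(self):
        lon = np.linspace(-20, 90, 50)
        vals = pd.Series(0.2 + 0.001 * lon, index=[f"l{i}" for i in range(50)])
        res = longitude_cline(vals, _metadata(lon))
        assert res.slope == pytest.approx(0.001)
        assert res.r2 == pytest.approx(1.0)

    def test_allele_mediated_cline_loses_significance(self):
        """A cline carried entirely by the focal allele: raw regression
        significant, residual regression not, in >= 18/20 seeds."""
        raw_sig, resid_ns = 0, 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 250
            lon = rng.uniform(-25, 100, n)
            # allele frequency follows longitude; value depends on
            # genotype only
            p = 1 / (1 + np.exp(-(lon - 40) / 12))
            g = (rng.random(n) < p).astype(float)
            vals = pd.Series(0.3 - 0.05 * g + rng.normal(0, 0.02, n),
                             index=[f"l{i}" for i in range(n)])
            meta = _metadata(lon)
            raw = longitude_cline(vals, meta)
            resid = longitude_cline(vals, meta, covariate_snp=g)
            raw_sig += raw.p_value < 0.01
            resid_ns += resid.p_value > 0.05
        assert raw_sig >= 18
        assert resid_ns >= 18

    def test_value_independent_of_longitude_p_uniform(self):
        pvals = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            lon = rng.uniform(-25, 100, 80)
            vals = pd.Series(rng.normal(0.3, 0.05, 80),
                             index=[f"l{i}" for i in range(80)])
            pvals.append(longitude_cline(vals, _metadata(lon)).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_lines_outside_window_dropped(self):
        lon = np.r_[np.linspace(-20, 90, 30), [150.0] * 5]
        vals = pd.Series(np.r_[np.linspace(0, 1, 30), [9.0] * 5].clip(0, 1),
                         index=[f"l{i}" for i in range(35)])
        res = longitude_cline(vals, _metadata(lon))
        assert res.n == 30


class TestBlupCorrect:
    def test_identity_kinship_centers(self, rng):
        y = pd.Series(rng.normal(5, 1, 40))
        out = blup_correct(y, np.eye(40))
        # variance-ratio estimate collapses (or shrinks uniformly):
        # corrected values are proportional to centered values
        c = y - y.mean()
        ratio = out.to_numpy() / c.to_numpy()
        assert np.allclose(ratio, ratio[0], atol=1e-6)
        assert abs(out.mean()) < 1e-8

    def test_two_block_shift_removed(self):
        """Strong two-block kinship with a block-shifted phenotype:
        correction removes >= 80% of the between-block difference."""
        rng = np.random.default_rng(9)
        n = 60
        block = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        K = 0.05 * np.eye(n) + 0.95 * (block[:, None] == block[None, :])
        y = pd.Series(0.5 * block + rng.normal(0, 0.05, n))
        out = blup_correct(y, K)
        before = abs(y[block == 1].mean() - y[block == 0].mean())
        after = abs(out[block == 1].mean() - out[block == 0].mean())
        assert after <= 0.2 * before

    def test_idempotent(self):
        rng = np.random.default_rng(11)
        n = 50
        block = np.r_[np.zeros(25), np.ones(25)]
        K = 0.2 * np.eye(n) + 0.8 * (block[:, None] == block[None, :])
        y = pd.Series(0.3 * block + rng.normal(0, 0.1, n))
        once = blup_correct(y, K)
        twice = blup_correct(once, K)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-6)
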