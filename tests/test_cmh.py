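import shutil
import subprocess

import numpy as np
import pytest
from scipy import stats

from evomet.cmh import CmhResult, _cmh_core, cmh_statistic, scan
from conftest import random_table


def _random_tables(rng, K=3, J=3, lo=5, hi=60):
    return rng.integers(lo, hi, size=(K, 2, J)).astype(float)


class TestStatistic:
    def test_null_identity_proportional_rows(self):
        # allele counts proportional to column totals in every stratum: n_k = E_k
        tab = np.array([[[10, 20, 30], [10, 20, 30]],
                        [[5, 15, 25], [5, 15, 25]]], dtype=float)
        Q, df, p = cmh_statistic(tab)
        assert df == 2
        assert Q == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_single_stratum_2x2_equals_scaled_pearson(self):
        tab = np.array([[[10, 2], [5, 13]]], dtype=float)
        Q, df, _ = cmh_statistic(tab)
        chi2 = stats.chi2_contingency(tab[0], correction=False).statistic
        N = tab.sum()
        assert df == 1
        assert Q == pytest.approx((N - 1) / N * chi2, rel=1e-12)

    def test_scaled_pearson_many_random_tables(self, rng):
        for _ in range(200):
            tab = _random_tables(rng, K=1, J=2)
            Q, _, _ = cmh_statistic(tab)
            chi2 = stats.chi2_contingency(tab[0], correction=False).statistic
            N = tab.sum()
            assert Q == pytest.approx((N - 1) / N * chi2, rel=1e-10, abs=1e-10)

    def test_permutation_tail_probability(self, rng):
        """chi-square p matches the margin-preserving Monte-Carlo null."""
        tab = _random_tables(rng, K=4, J=3, lo=20, hi=80)
        Q, df, p = cmh_statistic(tab)
        n = 5000
        draws = np.zeros((n, tab.shape[0], 2, tab.shape[2]))
        for k in range(tab.shape[0]):
            C = tab[k].sum(axis=0).astype(int)
            R = int(tab[k, 0].sum())
            n1 = rng.multivariate_hypergeometric(C, R, size=n)
            draws[:, k, 0, :] = n1
            draws[:, k, 1, :] = C - n1
        Qs, _ = _cmh_core(draws)
        emp = np.mean(Qs >= Q)
        assert emp == pytest.approx(p, abs=0.03)

    def test_invariances(self, rng):
        tab = _random_tables(rng, K=4, J=3)
        Q, _, _ = cmh_statistic(tab)
        # stratum reordering
        Q2, _, _ = cmh_statistic(tab[::-1])
        # allele-row relabeling (G flips sign, quadratic form unchanged)
        Q3, _, _ = cmh_statistic(tab[:, ::-1, :])
        assert Q2 == pytest.approx(Q, rel=1e-12)
        assert Q3 == pytest.approx(Q, rel=1e-9)

    def test_negative_counts_error(self):
        with pytest.raises(ValueError, match="negative"):
            cmh_statistic(np.array([[[1, -1], [2, 2]]], dtype=float))

    def test_degenerate_strata_contribute_zero(self, rng):
        tab = _random_tables(rng, K=2, J=3)
        padded = np.concatenate([tab, np.zeros((1, 2, 3))])  # empty stratum
        assert cmh_statistic(padded)[0] == pytest.approx(cmh_statistic(tab)[0])

    def test_r_mantelhaen_oracle(self, rng, tmp_path):
        """Independent cross-check against R's generalized CMH test."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the oracle check")
        tab = _random_tables(rng, K=5, J=3, lo=10, hi=50)
        Q, df, p = cmh_statistic(tab)
        # R's array is (rows, cols, strata) = (allele, treatment, stratum)
        vals = ", ".join(str(int(v)) for v in tab.transpose(1, 2, 0).ravel(order="F"))
        script = (f"x <- array(c({vals}), dim=c(2, 3, 5)); "
                  "r <- mantelhaen.test(x); "
                  "cat(sprintf('%.12g %.12g', r$statistic, r$p.value))")
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True).stdout.split()
        assert Q == pytest.approx(float(out[0]), rel=1e-9)
        assert p == pytest.approx(float(out[1]), rel=1e-6)


class TestScan:
    def test_monomorphic_unusable(self, toy_table, toy_design):
        res = scan(toy_table, toy_design)
        assert not res.usable[1]
        assert res.p[1] == 1.0 and res.Q[1] == 0.0
        assert res.usable[[0, 2]].all()

    def test_scan_matches_scalar(self, rng, toy_design):
        t = random_table(rng, n_snps=40, pops=toy_design.populations)
        res = scan(t, toy_design)
        layout = toy_design.layout(t.populations)
        for i in range(t.n_snps):
            K, J = layout.shape
            tab = np.zeros((K, 2, J))
            for k in range(K):
                for j in range(J):
                    tab[k, 0, j] = t.alt[i, layout[k, j]]
                    tab[k, 1, j] = t.ref[i, layout[k, j]]
            Q, df, p = cmh_statistic(tab)
            if res.usable[i]:
                assert res.Q[i] == pytest.approx(Q, rel=1e-10)
                assert res.p[i] == pytest.approx(p, rel=1e-8)

    def test_missing_population_errors(self, toy_table, toy_design):
        t = toy_table
        t2 = type(t)(t.chrom, t.pos, t.ref[:, :4], t.alt[:, :4], t.populations[:4])
        with pytest.raises(KeyError, match="absent"):
            scan(t2, toy_design)

    def test_differentiated_snp_attains_min_p(self, rng, balanced_design_10):
        """A treatment frequency gap of 0.4 at coverage 100 dominates 500
        neutral SNPs in nearly every replicate."""
        design = balanced_design_10
        hits = 0
        reps = 30
        for _ in range(reps):
            n, P = 500, 30
            p0 = rng.uniform(0.2, 0.8, size=n)
            freq = np.repeat(p0[:, None], P, axis=1)
            # causal SNP 0: A group shifted up by 0.4
            freq[0] = 0.3
            freq[0, :10] = 0.7
            cov = np.full((n, P), 100)
            alt = rng.binomial(cov, freq)
            t = type(random_table(rng, 2))(
                np.array(["2L"] * n, dtype=object), np.arange(1, n + 1) * 10,
                cov - alt, alt, design.populations)
            res = scan(t, design)
            hits += int(np.argmax(res.Q) == 0)
        assert hits >= int(0.95 * reps)
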