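import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from evomet.io import MetaboliteMatrix, MetaboliteSetLibrary, StudyDesign
from evomet.metabolites import (
    focal_metabolites,
    hypergeometric_enrichment,
    ora,
    pca_summary,
    ward_cluster_order,
)
from evomet.metabolites import test_metabolites as run_metabolite_tests


def _matrix(values: dict, pops: list[str]) -> MetaboliteMatrix:
    ab = pd.DataFrame(values, index=[f"s{i}" for i in range(len(pops))])
    ab.index.name = "sample_id"
    return MetaboliteMatrix(ab, pd.Series(pops, index=ab.index))


def _design2():
    return StudyDesign(["A", "B"], np.array(["A", "B"], dtype=object),
                       np.array([1, 1]))


class TestAnova:
    def test_two_groups_F_equals_t_squared(self, rng):
        y = rng.normal(size=12)
        pops = ["A"] * 6 + ["B"] * 6
        m = _matrix({"m1": y}, pops)
        res = run_metabolite_tests(m, _design2(), bonferroni_cut=0.5)
        t = stats.ttest_ind(y[:6], y[6:]).statistic
        assert res.table["F"].iloc[0] == pytest.approx(t**2, rel=1e-10)

    def test_equal_group_means_give_F_zero(self):
        m = _matrix({"m1": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]}, ["A"] * 3 + ["B"] * 3)
        res = run_metabolite_tests(m, _design2())
        assert res.table["F"].iloc[0] == pytest.approx(0.0)
        assert res.table["p"].iloc[0] == pytest.approx(1.0)

    def test_constant_metabolite_flagged_nan(self):
        m = _matrix({"m1": [2.0] * 6, "m2": [1, 2, 3, 4, 5, 6.0]},
                    ["A"] * 3 + ["B"] * 3)
        res = run_metabolite_tests(m, _design2())
        row = res.table.set_index("metabolite_id").loc["m1"]
        assert np.isnan(row["F"]) and not row["passes_bonferroni"]

    def test_adjusted_p_geq_raw_and_bonferroni_flag(self, rng):
        y = {f"m{i}": rng.normal(size=12) for i in range(8)}
        m = _matrix(y, ["A"] * 6 + ["B"] * 6)
        res = run_metabolite_tests(m, _design2(), bonferroni_cut=1e-3)
        tab = res.table.dropna()
        assert np.all(tab["p_adj"] >= tab["p"] - 1e-12)
        assert np.array_equal(tab["passes_bonferroni"], tab["p"] <= 1e-3)

    def test_posthoc_pvalues_returned_per_pair(self, rng):
        pops = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        design = StudyDesign(["A", "B", "C"], np.array(["A", "B", "C"], dtype=object),
                             np.array([1, 1, 1]))
        m = _matrix({"m1": rng.normal(size=12)}, pops)
        res = run_metabolite_tests(m, design)
        assert set(res.pairwise["pair"]) == {"A-B", "A-C", "B-C"}
        assert res.pairwise[["p_tukey", "p_lsd"]].to_numpy().min() >= 0

    def test_power_recovery_of_shifted_metabolites(self, rng):
        """3 groups x 6 samples, 10/100 metabolites shifted by 3 sigma:
        BH at 0.01 recovers nearly all shifted metabolites on average."""
        recovered = []
        design = StudyDesign(["A", "B", "C"], np.array(["A", "B", "C"], dtype=object),
                             np.array([1, 1, 1]))
        pops = ["A"] * 6 + ["B"] * 6 + ["C"] * 6
        for _ in range(100):
            vals = {}
            for i in range(100):
                y = rng.normal(size=18)
                if i < 10:
                    y[:6] += 3.0
                vals[f"m{i}"] = y
            res = run_metabolite_tests(_matrix(vals, pops), design, posthoc=False)
            hits = res.table.head(10)["p_adj"] <= 0.01
            recovered.append(hits.sum())
        # noncentral-F power at this design is ~0.85 per shifted metabolite
        assert np.mean(recovered) >= 8.0


class TestPca:
    def test_rank_one_matrix(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.outer(a, [1.0, -2.0, 0.5])
        m = _matrix({f"m{i}": X[:, i] for i in range(3)}, ["A", "A", "B", "B"])
        _, _, frac = pca_summary(m)
        assert frac[0] == pytest.approx(1.0)
        assert frac.sum() == pytest.approx(1.0)

    def test_matches_svd_oracle_up_to_sign(self, rng):
        X = rng.normal(size=(10, 6))
        m = _matrix({f"m{i}": X[:, i] for i in range(6)}, ["A"] * 5 + ["B"] * 5)
        scores, loadings, frac = pca_summary(m)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        np.testing.assert_allclose(np.abs(scores), np.abs(U * s), atol=1e-8)
        np.testing.assert_allclose(frac, s**2 / (s**2).sum(), atol=1e-12)

    def test_fraction_invariant_to_sample_order(self, rng):
        X = rng.normal(size=(8, 5))
        m1 = _matrix({f"m{i}": X[:, i] for i in range(5)}, ["A"] * 8)
        perm = rng.permutation(8)
        m2 = _matrix({f"m{i}": X[perm, i] for i in range(5)}, ["A"] * 8)
        np.testing.assert_allclose(pca_summary(m1)[2], pca_summary(m2)[2], atol=1e-10)


class TestWard:
    def test_identical_samples_merge_first(self):
        X = np.array([[0.0, 0], [5, 5], [0, 0], [9, 1]])
        m = _matrix({"m1": X[:, 0], "m2": X[:, 1]}, ["A"] * 4)
        order = ward_cluster_order(m)
        i0, i2 = order.index("s0"), order.index("s2")
        assert abs(i0 - i2) == 1  # identical samples end up adjacent leaves

    def test_five_point_brute_force_agglomeration(self, rng):
        """Merge sequence matches a naive Lance-Williams Ward implementation."""
        from scipy.cluster.hierarchy import linkage

        X = rng.normal(size=(5, 3))
        Z = linkage(X, method="ward")
        # naive O(n^3) Ward via Lance-Williams recurrence
        d = {(i, j): np.sum((X[i] - X[j]) ** 2) for i in range(5) for j in range(i + 1, 5)}
        sizes = {i: 1 for i in range(5)}
        active = set(range(5))
        merges = []
        nxt = 5
        while len(active) > 1:
            (i, j), dij = min(((k, v) for k, v in d.items()
                               if k[0] in active and k[1] in active),
                              key=lambda kv: kv[1])
            merges.append(np.sqrt(dij))
            for k in active - {i, j}:
                ni, nj, nk = sizes[i], sizes[j], sizes[k]
                dik = d[tuple(sorted((i, k)))]
                djk = d[tuple(sorted((j, k)))]
                d[(k, nxt)] = ((ni + nk) * dik + (nj + nk) * djk - nk * dij) / (ni + nj + nk)
            sizes[nxt] = sizes[i] + sizes[j]
            active -= {i, j}
            active.add(nxt)
            nxt += 1
        np.testing.assert_allclose(Z[:, 2], merges, rtol=1e-10)


class TestOra:
    def test_printed_formula_arithmetic(self):
        lib = MetaboliteSetLibrary({"s": [f"x{i}" for i in range(5)]},
                                   [f"x{i}" for i in range(20)])
        cand = ["x0", "x1", "x2", "x10", "x11"]  # 3 hits, n=5, M=5, N=20
        res = ora(cand, lib).table.iloc[0]
        assert res["hits"] == 3
        assert res["expected"] == pytest.approx(1.25)
        assert res["fold_enrichment"] == pytest.approx(2.4)

    def test_p_matches_exact_enumeration(self, rng):
        for _ in range(50):
            N = int(rng.integers(5, 26))
            M = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            universe = [f"g{i}" for i in range(N)]
            members = list(rng.choice(universe, size=M, replace=False))
            cand = set(rng.choice(universe, size=n, replace=False))
            df = hypergeometric_enrichment(cand, {"s": members}, universe)
            h = int(df["hits"].iloc[0])
            exact = sum(
                Fraction(math.comb(M, i) * math.comb(N - M, n - i), math.comb(N, n))
                for i in range(h, min(n, M) + 1)
            )
            assert df["p"].iloc[0] == pytest.approx(float(exact), abs=1e-12)

    def test_zero_hits_and_full_reference(self):
        lib = MetaboliteSetLibrary({"none": ["a"], "all": ["a", "b", "c", "d"]},
                                   ["a", "b", "c", "d"])
        res = ora(["b", "c"], lib).table.set_index("set_id")
        assert res.loc["none", "hits"] == 0
        assert res.loc["none", "fold_enrichment"] == 0
        assert res.loc["none", "p"] == pytest.approx(1.0)
        assert res.loc["all", "hits"] == 2  # whole reference: p = 1
        assert res.loc["all", "p"] == pytest.approx(1.0)

    def test_empty_candidate_list_errors(self):
        lib = MetaboliteSetLibrary({"s": ["a"]}, ["a", "b"])
        with pytest.raises(ValueError, match="empty"):
            ora([], lib)


class TestFocal:
    def _tests_passing(self, mets):
        table = pd.DataFrame({
            "metabolite_id": mets,
            "F": 50.0, "p": 1e-9, "p_adj": 1e-8, "passes_bonferroni": True,
        })
        from evomet.metabolites import MetaboliteTestResult
        return MetaboliteTestResult(table, pd.DataFrame(), 0.01, 1.2e-5)

    def test_top_k_zero_empty(self):
        lib = MetaboliteSetLibrary({"s": ["a"]}, ["a", "b"])
        tr = self._tests_passing(["a", "b"])
        res = ora(["a"], lib)
        assert focal_metabolites(tr, res, 0, lib) == []

    def test_single_pathway_holds_all(self):
        lib = MetaboliteSetLibrary({"hit": ["a", "b"], "other": ["c"]},
                                   ["a", "b", "c", "d", "e"])
        tr = self._tests_passing(["a", "b"])
        res = ora(["a", "b"], lib)
        assert focal_metabolites(tr, res, 1, lib) == ["a", "b"]

    def test_matches_set_algebra(self, rng):
        universe = [f"m{i}" for i in range(30)]
        sets = {f"s{k}": list(rng.choice(universe, size=6, replace=False))
                for k in range(8)}
        lib = MetaboliteSetLibrary(sets, universe)
        passing = list(rng.choice(universe, size=12, replace=False))
        tr = self._tests_passing(passing)
        res = ora(passing, lib)
        for k in (0, 3, 8):
            got = focal_metabolites(tr, res, k, lib)
            top = res.table.sort_values(["p", "set_id"], kind="stable")["set_id"].head(k)
            want = sorted(set(passing) & {m for s in top for m in lib.sets[s]})
            assert got == want
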