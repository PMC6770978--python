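"""Expression analysis: TMM, filtering, moderated DE, GSEA, ORA."""

import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conftest import es_oracle, hypergeom_tail_oracle
from focalcna import expression as expr
from focalcna.genomics_io import CohortDesign


def _counts(seed=0, n_genes=200, n_samples=5, mean=100):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.negative_binomial(5, 5 / (5 + mean), size=(n_genes, n_samples)),
                        index=pd.Index([f"g{i}" for i in range(n_genes)], name="gene_id"),
                        columns=[f"s{j}" for j in range(n_samples)])


def _tmm_oracle(counts: pd.DataFrame, trim_m=0.30, trim_a=0.05) -> np.ndarray:
    """Direct-formula TMM, written with plain loops and explicit sorting."""
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    uq = [np.quantile(x[:, j] / lib[j], 0.75) for j in range(x.shape[1])]
    ref = min(range(x.shape[1]), key=lambda j: abs(uq[j] - np.mean(uq)))
    logf = []
    for j in range(x.shape[1]):
        m_vals, a_vals, w_vals = [], [], []
        for g in range(x.shape[0]):
            o, r = x[g, j], x[g, ref]
            if o > 0 and r > 0:
                po, pr = o / lib[j], r / lib[ref]
                m_vals.append(math.log2(po / pr))
                a_vals.append(0.5 * (math.log2(po) + math.log2(pr)))
                w_vals.append((lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r))
        n = len(m_vals)
        if n == 0:
            logf.append(0.0)
            continue
        lo_m, hi_m = math.floor(n * trim_m) + 1, n - math.floor(n * trim_m)
        lo_a, hi_a = math.floor(n * trim_a) + 1, n - math.floor(n * trim_a)
        rank_m = sps.rankdata(m_vals)
        rank_a = sps.rankdata(a_vals)
        num = den = 0.0
        for i in range(n):
            if lo_m <= rank_m[i] <= hi_m and lo_a <= rank_a[i] <= hi_a:
                num += m_vals[i] / w_vals[i]
                den += 1.0 / w_vals[i]
        logf.append(num / den if den > 0 else 0.0)
    f = 2.0 ** np.array(logf)
    return f / np.exp(np.mean(np.log(f)))


class TestTmm:
    def test_identical_libraries_give_unit_factors(self):
        c = _counts()
        dup = pd.concat([c[["s0"]]] * 4, axis=1)
        dup.columns = list("abcd")
        np.testing.assert_allclose(expr.tmm_norm_factors(dup), 1.0, atol=1e-12)

    def test_doubled_library_gives_unit_factor(self):
        c = _counts(n_samples=3)
        c["s2"] = 2 * c["s0"]
        f = expr.tmm_norm_factors(c)
        assert f["s2"] == pytest.approx(f["s0"], abs=1e-10)

    def test_matches_direct_formula_oracle(self):
        for seed in range(3):
            c = _counts(seed=seed)
            np.testing.assert_allclose(expr.tmm_norm_factors(c).to_numpy(),
                                       _tmm_oracle(c), atol=1e-6)

    def test_scale_invariance_approximate(self):
        # M-values, trimming and the reference choice are exactly invariant
        # to scaling a library; the inverse-variance weights are not (their
        # observation term scales with 1/c), so invariance is approximate
        c = _counts().astype(float)
        f1 = expr.tmm_norm_factors(c)
        c["s1"] *= 4.0
        f2 = expr.tmm_norm_factors(c)
        np.testing.assert_allclose(f1, f2, rtol=0.02)

    def test_zero_library_rejected(self):
        c = _counts()
        c["s0"] = 0
        with pytest.raises(ValueError, match="zero total"):
            expr.tmm_norm_factors(c)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not available")
    def test_matches_edger_reference(self, tmp_path):
        """Cross-check against the Bioconductor reference implementation."""
        c = _counts(seed=42)
        fixture = tmp_path / "counts.tsv"
        c.to_csv(fixture, sep="\t")
        script = tmp_path / "tmm.R"
        script.write_text(
            "suppressMessages(library(edgeR))\n"
            f"x <- as.matrix(read.delim('{fixture}', row.names=1))\n"
            "cat(sprintf('%.10f\\n', calcNormFactors(x, method='TMM')))\n")
        res = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=300)
        assert res.returncode == 0, res.stderr
        ref = np.array([float(v) for v in res.stdout.split()])
        np.testing.assert_allclose(expr.tmm_norm_factors(c).to_numpy(), ref, atol=1e-6)


class TestFilter:
    def test_all_zero_gene_removed(self):
        c = _counts(n_samples=4)
        c.loc["g0"] = 0
        kept = expr.filter_low_expressed(c)
        assert "g0" not in kept.index

    def test_boundary_gene_kept(self):
        # 20 samples, frac 0.05 -> need ceil(1) = 1 sample at CPM >= 1
        rng = np.random.default_rng(1)
        c = pd.DataFrame(rng.integers(50, 200, size=(50, 20)),
                         index=[f"g{i}" for i in range(50)],
                         columns=[f"s{j}" for j in range(20)])
        c.loc["g0"] = 0
        c.loc["g0", "s0"] = 10  # comfortably above 1 CPM in exactly one sample
        kept = expr.filter_low_expressed(c, cpm_min=1.0, frac_min=0.05)
        assert "g0" in kept.index

    def test_planted_pass_fail_sets(self):
        c = _counts(n_samples=10, mean=200)
        # plant genes below 1 CPM everywhere
        for g in ["g0", "g1"]:
            c.loc[g] = 0
        kept = expr.filter_low_expressed(c, cpm_min=1.0, frac_min=0.5)
        assert {"g0", "g1"}.isdisjoint(kept.index)
        assert len(kept) == len(c) - 2


class TestDifferentialExpression:
    def _design(self, n1=4, n2=4):
        return CohortDesign({f"r{i}": "R" for i in range(n1)}
                            | {f"f{i}": "fS" for i in range(n2)})

    def _counts(self, seed=0, n1=4, n2=4, n_genes=100):
        rng = np.random.default_rng(seed)
        d = self._design(n1, n2)
        return pd.DataFrame(
            rng.negative_binomial(10, 10 / (10 + 300), size=(n_genes, n1 + n2)),
            index=[f"g{i}" for i in range(n_genes)], columns=d.samples()), d

    def test_identical_groups_zero_logfc(self):
        c, d = self._counts()
        c.iloc[:, 4:] = c.iloc[:, :4].to_numpy()  # fS mirrors R exactly
        de = expr.differential_expression(c, d)
        np.testing.assert_allclose(de["log2fc"], 0.0, atol=1e-12)

    def test_zero_shrinkage_equals_plain_t(self):
        c, d = self._counts(seed=3)
        de = expr.differential_expression(c, d, shrink=0.0)
        lc = expr.log_cpm(c)
        t_ref, p_ref = sps.ttest_ind(lc.iloc[:, :4], lc.iloc[:, 4:], axis=1,
                                     equal_var=True)
        np.testing.assert_allclose(de["t"], t_ref, atol=1e-10)
        np.testing.assert_allclose(de["p"], p_ref, atol=1e-10)

    def test_planted_twofold_change(self):
        # double only 10 of 500 genes so library-size renormalization
        # barely dilutes the planted effect
        c, d = self._counts(seed=4, n_genes=1000)
        planted = [f"g{i}" for i in range(20)]
        c.loc[planted, d.samples("R")] = 2 * c.loc[planted, d.samples("R")]
        de = expr.differential_expression(c, d)
        est = de.loc[planted, "log2fc"].mean()
        assert est == pytest.approx(1.0, abs=0.15)

    def test_sign_consistency_and_q(self):
        c, d = self._counts(seed=5)
        de = expr.differential_expression(c, d)
        nz = de["t"] != 0
        assert (np.sign(de.loc[nz, "log2fc"]) == np.sign(de.loc[nz, "t"])).all()
        assert (de["q"] >= de["p"] - 1e-15).all()


class TestGsea:
    def _ranked(self, seed=0, n=15):
        rng = np.random.default_rng(seed)
        return pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])

    def test_streaming_equals_brute_force_on_toys(self):
        for seed in range(10):
            ranked = self._ranked(seed, n=int(np.random.default_rng(seed).integers(5, 21)))
            rng = np.random.default_rng(100 + seed)
            k = int(rng.integers(1, len(ranked)))
            members = set(rng.choice(ranked.index, size=k, replace=False))
            assert expr.enrichment_score(ranked, members) == pytest.approx(
                es_oracle(ranked, members), abs=1e-12)

    def test_top_ranked_set_strong_positive(self):
        ranked = pd.Series(np.linspace(5, -5, 30), index=[f"g{i}" for i in range(30)])
        members = {f"g{i}" for i in range(3)}
        es = expr.enrichment_score(ranked, members)
        assert es > 0.8

    def test_whole_universe_set_scores_zero(self):
        ranked = self._ranked(1, n=8)
        assert expr.enrichment_score(ranked, set(ranked.index)) == 0.0

    def test_uniform_random_sets_give_uniform_p(self):
        """Null sets drawn uniformly: GSEA p roughly uniform across replicates."""
        ranked = pd.Series(np.random.default_rng(2).normal(size=40),
                           index=[f"g{i}" for i in range(40)])
        rng = np.random.default_rng(3)
        pvals = []
        for b in range(120):
            members = list(rng.choice(ranked.index, size=6, replace=False))
            res = expr.preranked_gsea(ranked, {"S": members}, n_perm=99, seed=int(b))
            pvals.append(res.loc["S", "p"])
        assert abs(np.mean(pvals) - 0.5) < 0.1
        assert sps.kstest(pvals, "uniform").pvalue > 1e-3

    def test_result_table_contract(self):
        ranked = self._ranked(4, n=20)
        sets = {"A": [f"g{i}" for i in range(4)], "B": [f"g{i}" for i in range(10, 14)]}
        res = expr.preranked_gsea(ranked, sets, n_perm=200, seed=0)
        assert set(res.index) == {"A", "B"}
        assert ((res["es"] >= -1) & (res["es"] <= 1)).all()
        assert ((res["p"] > 0) & (res["p"] <= 1)).all()
        assert (res["q"] >= res["p"] - 1e-15).all()


class TestOra:
    def test_zero_overlap_p1(self):
        res = expr.over_representation(["a", "b"], {"S": ["c", "d"]},
                                       ["a", "b", "c", "d", "e"])
        assert res.loc["S", "p"] == 1.0

    def test_selection_equals_set_matches_oracle(self):
        universe = [f"g{i}" for i in range(12)]
        sel = ["g0", "g1", "g2"]
        res = expr.over_representation(sel, {"S": sel}, universe)
        assert res.loc["S", "p"] == pytest.approx(
            hypergeom_tail_oracle(3, 3, 3, 12), abs=1e-12)

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(6)
        universe = [f"g{i}" for i in range(25)]
        for _ in range(20):
            sel = list(rng.choice(universe, size=rng.integers(1, 12), replace=False))
            members = list(rng.choice(universe, size=rng.integers(1, 15), replace=False))
            res = expr.over_representation(sel, {"S": members}, universe)
            k = len(set(sel) & set(members))
            assert res.loc["S", "p"] == pytest.approx(
                hypergeom_tail_oracle(k, len(sel), len(members), 25), abs=1e-12)

    def test_universe_equals_selection_forces_overlap(self):
        universe = ["a", "b", "c"]
        res = expr.over_representation(universe, {"S": ["a", "b"]}, universe)
        assert res.loc["S", "p"] == pytest.approx(1.0)
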