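"""Expression filtering, TMM normalisation, logCPM, PCs and residualisation."""

import numpy as np
import pandas as pd
import pytest

from retrowas.expression_prep import (
    compute_tpm,
    filter_expressed,
    genotype_pcs,
    logcpm,
    n_surrogate_variables,
    residualize,
    tmm_factors,
)
from retrowas.synthdata import LDBlockSpec, simulate_genotypes


def tmm_oracle(counts: np.ndarray, ref_j: int, obs_j: int, trim_M=0.30, trim_A=0.05):
    """Straight-from-definition TMM factor, coded independently with sorting."""
    obs, ref = counts[:, obs_j].astype(float), counts[:, ref_j].astype(float)
    n_obs, n_ref = obs.sum(), ref.sum()
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    M = np.log2((obs / n_obs) / (ref / n_ref))
    A = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    n = len(M)
    loM, hiM = int(np.floor(n * trim_M)) + 1, n - int(np.floor(n * trim_M))
    loA, hiA = int(np.floor(n * trim_A)) + 1, n - int(np.floor(n * trim_A))
    rM = np.argsort(np.argsort(M)) + 1
    rA = np.argsort(np.argsort(A)) + 1
    sel = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
    return 2 ** (np.sum(M[sel] / w[sel]) / np.sum(1.0 / w[sel]))


class TestTPM:
    def test_equal_counts_equal_lengths(self):
        counts = pd.DataFrame([[10, 20], [10, 20]], index=["a", "b"], columns=["s1", "s2"])
        lengths = pd.Series([100, 100], index=["a", "b"])
        tpm = compute_tpm(counts, lengths)
        assert np.allclose(tpm.to_numpy(), 5e5)

    def test_length_scaling(self):
        counts = pd.DataFrame([[10], [10]], index=["a", "b"], columns=["s1"])
        t1 = compute_tpm(counts, pd.Series([100, 100], index=["a", "b"]))
        t2 = compute_tpm(counts, pd.Series([200, 100], index=["a", "b"]))
        # doubling a's length halves its pre-normalisation share
        assert t2.loc["a", "s1"] / t2.loc["b", "s1"] == pytest.approx(0.5)
        assert t1.loc["a", "s1"] / t1.loc["b", "s1"] == pytest.approx(1.0)

    def test_matches_direct_formula(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 200, (5, 4)), index=list("abcde"), columns=list("wxyz")
        )
        lengths = pd.Series(rng.integers(100, 1000, 5), index=list("abcde"))
        tpm = compute_tpm(counts, lengths)
        for s in counts.columns:
            rate = counts[s] / lengths
            expect = rate / rate.sum() * 1e6
            assert np.allclose(tpm[s], expect, atol=1e-9)
        assert np.allclose(tpm.sum(axis=0), 1e6, atol=1e-3)

    def test_zero_length_rejected(self):
        counts = pd.DataFrame([[1]], index=["a"], columns=["s"])
        with pytest.raises(ValueError):
            compute_tpm(counts, pd.Series([0], index=["a"]))


class TestFilterExpressed:
    def test_boundary_fraction_kept(self):
        counts = pd.DataFrame([[6, 6, 0, 0, 0]], index=["f"], columns=list("abcde"))
        tpm = pd.DataFrame([[0.2, 0.2, 0.0, 0.0, 0.0]], index=["f"], columns=list("abcde"))
        assert filter_expressed(counts, tpm) == ["f"]

    def test_all_zero_removed(self):
        counts = pd.DataFrame([[0, 0, 0, 0, 0]], index=["f"], columns=list("abcde"))
        assert filter_expressed(counts, counts.astype(float)) == []

    def test_joint_condition_same_sample(self):
        # count passes in samples a,b but TPM passes only in c,d: joint fails
        counts = pd.DataFrame([[9, 9, 1, 1, 0]], index=["f"], columns=list("abcde"))
        tpm = pd.DataFrame([[0.01, 0.01, 5.0, 5.0, 0.0]], index=["f"], columns=list("abcde"))
        assert filter_expressed(counts, tpm) == []

    def test_constructed_pass_fail_set(self, rng):
        n_samp = 10
        rows, keep_truth = [], []
        for i in range(100):
            fails = i < 30
            if fails:
                row = rng.integers(0, 5, n_samp)  # counts below threshold
            else:
                row = rng.integers(6, 100, n_samp)
            rows.append(row)
            keep_truth.append(not fails)
        counts = pd.DataFrame(rows, index=[f"f{i}" for i in range(100)])
        tpm = counts * 1.0  # all TPM >= 0.1 where counts pass
        kept = filter_expressed(counts, tpm)
        assert len(kept) == 70
        assert kept == [f"f{i}" for i in range(30, 100)]

    def test_monotone_in_thresholds(self, rng):
        counts = pd.DataFrame(rng.integers(0, 30, (50, 8)))
        tpm = pd.DataFrame(rng.uniform(0, 2, (50, 8)))
        strict = set(filter_expressed(counts, tpm, 6, 0.1, 0.2))
        for kw in ({"min_count": 3}, {"min_tpm": 0.05}, {"min_fraction": 0.1}):
            relaxed = set(filter_expressed(counts, tpm, **{**dict(min_count=6, min_tpm=0.1, min_fraction=0.2), **kw}))
            assert strict <= relaxed

    def test_shape_mismatch_rejected(self):
        counts = pd.DataFrame([[1, 2]], index=["f"])
        tpm = pd.DataFrame([[1.0]], index=["f"])
        with pytest.raises(ValueError):
            filter_expressed(counts, tpm)


class TestTMM:
    def test_identical_columns_unit_factors(self, rng):
        col = rng.integers(1, 500, 50)
        counts = pd.DataFrame({"a": col, "b": col, "c": col})
        nf = tmm_factors(counts)
        assert np.allclose(nf.factors, 1.0, atol=1e-9)

    def test_pure_depth_change_unit_factors(self, rng):
        col = rng.integers(1, 500, 80)
        counts = pd.DataFrame({"a": col, "b": 2 * col})
        nf = tmm_factors(counts)
        assert np.allclose(nf.factors, 1.0, atol=1e-9)

    def test_matches_definition_oracle(self, rng):
        mat = rng.integers(1, 400, (20, 4))
        mat[3, 0] *= 25  # spiked feature distorts sample 0's composition
        counts = pd.DataFrame(mat, columns=list("abcd"))
        nf = tmm_factors(counts)
        ref_j = list(counts.columns).index(nf.reference_sample)
        raw = np.ones(4)
        for j in range(4):
            if j != ref_j:
                raw[j] = tmm_oracle(mat, ref_j, j)
        expect = raw / np.exp(np.mean(np.log(raw)))
        assert np.allclose(nf.factors.to_numpy(), expect, atol=1e-6)

    def test_geometric_mean_one(self, rng):
        counts = pd.DataFrame(rng.integers(1, 1000, (60, 6)))
        nf = tmm_factors(counts)
        assert np.exp(np.mean(np.log(nf.factors))) == pytest.approx(1.0, abs=1e-9)

    def test_single_sample_identity_with_warning(self):
        counts = pd.DataFrame({"a": [1, 2, 3]})
        nf = tmm_factors(counts)
        assert nf.factors.tolist() == [1.0]


class TestLogCPM:
    def test_zero_count_arithmetic(self):
        counts = pd.DataFrame({"s": [0] + [1] * 10})
        counts.loc[11] = 1_000_000 - 10  # library size ~1e6
        lc = logcpm(counts, None, prior_count=0.5)
        # log2(0.5 / (1e6 + 1) * 1e6) ~ -1.0000
        assert lc.loc[0, "s"] == pytest.approx(-1.0, abs=1e-3)

    def test_depth_invariance(self, rng):
        base = rng.integers(100, 1000, 40)
        counts = pd.DataFrame({"a": base})
        scaled = pd.DataFrame({"a": base * 10})
        d = (logcpm(counts) - logcpm(scaled)).abs().to_numpy()
        assert d.max() < 0.01

    def test_matches_direct_formula(self, rng):
        counts = pd.DataFrame(rng.integers(0, 500, (10, 3)), columns=list("abc"))
        from retrowas.expression_prep import tmm_factors as tf

        nf = tf(counts + 1)
        lc = logcpm(counts, None, 0.5)
        lib = counts.sum(axis=0)
        expect = np.log2((counts + 0.5).div(lib + 1.0, axis=1) * 1e6)
        assert np.allclose(lc, expect, atol=1e-9)


class TestGenotypePCs:
    def test_two_populations_separate_on_pc1(self):
        rng = np.random.default_rng(6)
        n, m = 150, 400
        p1 = rng.uniform(0.1, 0.5, m)
        shift = rng.normal(0, 0.12, m)
        p2 = np.clip(p1 + shift, 0.05, 0.95)
        d1 = rng.binomial(2, p1, (n, m)).astype(float)
        d2 = rng.binomial(2, p2, (n, m)).astype(float)
        from retrowas.containers import GenotypeMatrix

        var = pd.DataFrame(
            {"snp": [f"s{i}" for i in range(m)], "chrom": "1",
             "pos": np.arange(m) + 1, "a1": "A", "a2": "G"}
        )
        G = GenotypeMatrix(np.vstack([d1, d2]), var, [f"S{i}" for i in range(2 * n)])
        pcs = genotype_pcs(G, k=4)
        pc1 = pcs["PC1"].to_numpy()
        gap = abs(pc1[:n].mean() - pc1[n:].mean())
        within = max(pc1[:n].std(), pc1[n:].std())
        assert gap > 5 * within

    def test_orthonormal_and_k_columns(self, small_genotypes):
        pcs = genotype_pcs(small_genotypes, k=10)
        assert pcs.shape == (small_genotypes.n_samples, 10)
        gram = pcs.to_numpy().T @ pcs.to_numpy()
        assert np.allclose(gram, np.eye(10), atol=1e-8)


class TestResidualize:
    def test_orthogonal_covariate_leaves_centered_input(self, rng):
        n = 60
        cov = pd.DataFrame({"c": np.repeat([0.0, 1.0], n // 2)}, index=range(n))
        cc = cov["c"].to_numpy() - cov["c"].mean()
        feats = rng.standard_normal((5, n))
        feats -= (feats @ cc)[:, None] * cc[None, :] / (cc @ cc)
        expr = pd.DataFrame(feats, columns=range(n))
        adj, _ = residualize(expr, cov, n_surrogate=0)
        centered = expr.sub(expr.mean(axis=1), axis=0)
        assert np.abs(adj - centered).to_numpy().max() < 1e-8

    def test_feature_equal_to_covariate_vanishes(self, rng):
        n = 50
        c = rng.standard_normal(n)
        cov = pd.DataFrame({"c": c}, index=range(n))
        expr = pd.DataFrame([c], index=["f"], columns=range(n))
        adj, _ = residualize(expr, cov, n_surrogate=0)
        assert np.linalg.norm(adj.loc["f"]) < 1e-8

    def test_zero_mean_and_zero_design_correlation(self, rng):
        n = 120
        cov = pd.DataFrame(
            {"x": rng.standard_normal(n), "g": rng.choice(["a", "b"], n)},
            index=range(n),
        )
        expr = pd.DataFrame(rng.standard_normal((8, n)), columns=range(n))
        adj, sv = residualize(expr, cov, n_surrogate=3)
        assert np.abs(adj.mean(axis=1)).max() < 1e-10
        for col in sv.columns:
            assert np.abs(adj.to_numpy() @ sv[col].to_numpy()).max() < 1e-8

    @pytest.mark.parametrize("n,expected", [(200, 30), (563, 60), (250, 30), (351, 60), (300, 45)])
    def test_surrogate_count_rule(self, n, expected):
        assert n_surrogate_variables(n) == expected
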