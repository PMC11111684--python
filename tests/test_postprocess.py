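"""Predicted-expression correlation, loci, conditional analysis, fine-mapping."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from retrowas.cis_weights import HeritabilityEstimate, WeightSet
from retrowas.postprocess import (
    FinemapResult,
    PredExprCorrelation,
    classify_high_confidence,
    condition_snp_z,
    define_loci,
    finemap_pip,
    joint_conditional,
    pred_expr_cor,
)


def _ws(fid, snp_ids, weights, cls="gene"):
    snps = pd.DataFrame(
        {"snp": snp_ids, "chrom": "1", "pos": range(len(snp_ids)), "a1": "A", "a2": "G"}
    )
    return WeightSet(
        feature_id=fid, snps=snps, weights={"top1": np.asarray(weights, float)},
        cv_r2={"top1": 0.2}, best_method="top1",
        h2=HeritabilityEstimate(0.2, 0.2, 0.8, 9.0, 1e-3), cls=cls,
    )


class TestPredExprCor:
    def test_self_and_identical_weights(self, rng):
        R = np.corrcoef(rng.standard_normal((4, 50)))
        snps = [f"s{i}" for i in range(4)]
        store = {
            "a": _ws("a", snps, [1.0, 0.5, 0.0, 0.0]),
            "b": _ws("b", snps, [2.0, 1.0, 0.0, 0.0]),  # proportional to a
        }
        pec = pred_expr_cor(store, R, snps)
        assert pec.omega[0, 0] == pytest.approx(1.0)
        assert pec.omega[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_matches_dense_formula(self, rng):
        m = 6
        R = np.corrcoef(rng.standard_normal((m, 80)))
        snps = [f"s{i}" for i in range(m)]
        W = rng.standard_normal((m, 3))
        store = {f"f{j}": _ws(f"f{j}", snps, W[:, j]) for j in range(3)}
        pec = pred_expr_cor(store, R, snps)
        cov = W.T @ R @ W
        d = 1 / np.sqrt(np.diag(cov))
        expect = cov * d[:, None] * d[None, :]
        assert np.allclose(pec.omega, expect, atol=1e-10)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            pred_expr_cor({}, np.eye(1), [])


class TestDefineLoci:
    @staticmethod
    def _results(rows):
        df = pd.DataFrame(
            rows, columns=["feature", "chrom", "start", "end", "bonf_p"]
        )
        return df

    def test_overlapping_windows_merge(self):
        res = self._results(
            [("a", "1", 1_000_000, 1_010_000, 0.001), ("b", "1", 1_160_000, 1_170_000, 0.001)]
        )
        assert define_loci(res, merge_bp=100_000) == [["a", "b"]]

    def test_different_chromosomes_split(self):
        res = self._results(
            [("a", "1", 1000, 2000, 0.001), ("b", "2", 1000, 2000, 0.001)]
        )
        assert len(define_loci(res)) == 2

    def test_partition_matches_graph_components(self, rng):
        """Six features with a known overlap graph vs networkx components."""
        import networkx as nx

        rows = [
            ("a", "1", 100_000, 110_000, 1e-3),
            ("b", "1", 250_000, 260_000, 1e-3),
            ("c", "1", 405_000, 415_000, 1e-3),
            ("d", "1", 900_000, 910_000, 1e-3),
            ("e", "2", 100_000, 110_000, 1e-3),
            ("f", "2", 150_000, 160_000, 1e-3),
        ]
        res = self._results(rows)
        loci = define_loci(res, merge_bp=100_000)
        g = nx.Graph()
        for fid, *_ in rows:
            g.add_node(fid)
        for (f1, c1, s1, e1, _), (f2, c2, s2, e2, _) in itertools.combinations(rows, 2):
            if c1 == c2 and s1 - 100_000 <= e2 + 100_000 and s2 - 100_000 <= e1 + 100_000:
                g.add_edge(f1, f2)
        expect = {frozenset(c) for c in nx.connected_components(g)}
        assert {frozenset(l) for l in loci} == expect

    def test_only_significant_features_enter(self):
        res = self._results(
            [("a", "1", 1000, 2000, 0.001), ("b", "1", 1500, 2500, 0.9)]
        )
        assert define_loci(res) == [["a"]]


class TestJointConditional:
    def test_single_feature_joint_equals_marginal(self):
        pec = PredExprCorrelation(np.eye(1), ["a"], ["s"])
        jr = joint_conditional(["a"], {"a": 5.0}, pec, entry_p=0.05)
        assert jr.selected == ["a"]
        assert jr.joint_z["a"] == pytest.approx(5.0)
        assert jr.joint_p["a"] == pytest.approx(2 * stats.norm.sf(5.0))

    def test_uncorrelated_conditionals_equal_marginals(self):
        pec = PredExprCorrelation(np.eye(2), ["a", "b"], ["s"])
        jr = joint_conditional(["a", "b"], {"a": 6.0, "b": 2.0}, pec, entry_p=1e-5)
        assert jr.selected == ["a"]
        assert jr.conditional_z["b"] == pytest.approx(2.0, abs=1e-10)

    def test_identical_features_collinear_flag(self):
        om = np.ones((2, 2))
        pec = PredExprCorrelation(om, ["a", "b"], ["s"])
        jr = joint_conditional(["a", "b"], {"a": 5.0, "b": 5.0}, pec, entry_p=0.05)
        assert jr.selected == ["a"]
        assert jr.collinear == ["b"]

    def test_selected_members_conditional_zero(self, rng):
        m = 4
        om = np.corrcoef(rng.standard_normal((m, 40)))
        feats = [f"f{j}" for j in range(m)]
        pec = PredExprCorrelation(om, feats, ["s"])
        zmap = dict(zip(feats, [8.0, -7.0, 6.5, 1.0]))
        jr = joint_conditional(feats, zmap, pec, entry_p=0.05)
        for f in jr.selected:
            assert abs(jr.conditional_z[f]) < 1e-8

    def test_entry_inf_reproduces_gls(self, rng):
        """With no entry threshold the joint solution is plain GLS."""
        m = 5
        om = np.corrcoef(rng.standard_normal((m, 60)))
        feats = [f"f{j}" for j in range(m)]
        z = rng.standard_normal(m) * 3
        pec = PredExprCorrelation(om, feats, ["s"])
        jr = joint_conditional(feats, dict(zip(feats, z)), pec, entry_p=np.inf)
        assert set(jr.selected) == set(feats)
        inv = np.linalg.inv(om)
        eff = inv @ z
        for j, f in enumerate(feats):
            assert jr.joint_z[f] == pytest.approx(eff[j] / np.sqrt(inv[j, j]), abs=1e-8)


class TestConditionSnpZ:
    def test_uncorrelated_snp_unchanged(self, rng):
        n_snp = 10
        R = np.eye(n_snp)
        snps = [f"s{i}" for i in range(n_snp)]
        # feature weighted on s0 only: conditioning leaves other SNPs alone
        store = {"a": _ws("a", snps, [1.0] + [0.0] * 9)}
        pec = pred_expr_cor(store, R, snps)
        z = rng.standard_normal(n_snp)
        z2 = condition_snp_z(z, R, ["a"], store, snps, {"a": 4.0}, pec)
        assert np.allclose(z2[1:], z[1:], atol=1e-12)

    def test_indicator_weight_dense_formula(self, rng):
        n_snp = 6
        base = rng.standard_normal((200, n_snp))
        R = np.corrcoef(base.T)
        snps = [f"s{i}" for i in range(n_snp)]
        w = np.zeros(n_snp)
        w[2] = 1.0
        store = {"a": _ws("a", snps, w)}
        pec = pred_expr_cor(store, R, snps)
        z = rng.standard_normal(n_snp)
        zf = 5.0
        out = condition_snp_z(z, R, ["a"], store, snps, {"a": zf}, pec)
        rho = (R @ w) / np.sqrt(w @ R @ w)
        assert np.allclose(out, z - rho * zf, atol=1e-12)

    def test_mediated_locus_signal_reduced(self, rng):
        """Conditioning on the causal feature shrinks SNP signal strictly."""
        n_snp = 12
        base = rng.standard_normal((500, n_snp))
        R = np.corrcoef(base.T)
        snps = [f"s{i}" for i in range(n_snp)]
        w = rng.standard_normal(n_snp)
        store = {"a": _ws("a", snps, w)}
        pec = pred_expr_cor(store, R, snps)
        # fully mediated: SNP z proportional to the predicted-expression loading
        rho = (R @ w) / np.sqrt(w @ R @ w)
        zf = 9.0
        z = rho * zf + 0.1 * rng.standard_normal(n_snp)
        out = condition_snp_z(z, R, ["a"], store, snps, {"a": zf}, pec)
        assert np.mean(np.abs(out)) < np.mean(np.abs(z))

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            condition_snp_z(np.zeros(2), np.eye(2), [], {}, ["s1", "s2"], {}, None)


def finemap_oracle(z, om, prior_p=1e-3, v=40.0, max_causal=3):
    """Exhaustive enumeration coded independently of the implementation."""
    k = len(z)
    configs = [()]
    for s in range(1, max_causal + 1):
        configs += list(itertools.combinations(range(k), s))
    logs = []
    for c in configs:
        cov = om + 1e-8 * np.eye(k)
        if c:
            oc = om[:, list(c)]
            cov = cov + v * oc @ oc.T
        ll = stats.multivariate_normal.logpdf(z, np.zeros(k), cov, allow_singular=True)
        logs.append(ll + len(c) * np.log(prior_p) + (k - len(c)) * np.log1p(-prior_p))
    w = np.exp(np.array(logs) - max(logs))
    w /= w.sum()
    pip = np.zeros(k)
    for ci, c in enumerate(configs):
        for j in c:
            pip[j] += w[ci]
    return pip


class TestFinemap:
    def test_single_feature_null_closed_form(self):
        fm = finemap_pip(["f"], np.array([0.0]), np.eye(1), prior_p=1e-3, v=40.0)
        p, v = 1e-3, 40.0
        bf = 1.0 / np.sqrt(1.0 + v)  # N(0; 0, 1+v)/N(0; 0, 1)
        expect = p * bf / (p * bf + (1 - p))
        assert fm.pip["f"] == pytest.approx(expect, abs=1e-6)
        assert fm.pip["f"] == pytest.approx(1.56e-4, abs=1e-6)

    def test_symmetric_features_equal_pips(self):
        fm = finemap_pip(["a", "b"], np.array([3.0, -3.0]), np.eye(2))
        assert fm.pip["a"] == pytest.approx(fm.pip["b"], abs=1e-12)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_matches_enumeration_oracle(self, k, rng):
        om = np.corrcoef(rng.standard_normal((k, 50)))
        z = rng.standard_normal(k) * 3
        fm = finemap_pip([f"f{j}" for j in range(k)], z, om)
        expect = finemap_oracle(z, om)
        got = np.array([fm.pip[f"f{j}"] for j in range(k)])
        assert np.allclose(got, expect, atol=1e-10)

    def test_posterior_sums_to_one_with_null(self, rng):
        om = np.corrcoef(rng.standard_normal((3, 40)))
        fm = finemap_pip(["a", "b", "c"], np.array([5.0, 1.0, 0.0]), om)
        assert 0.0 <= fm.posterior_null <= 1.0
        assert all(0.0 <= p <= 1.0 for p in fm.pip.values())

    def test_strong_signal_in_credible_set(self):
        fm = finemap_pip(["a", "b"], np.array([8.0, 0.5]), np.eye(2))
        assert "a" in fm.credible_set
        assert fm.pip["a"] > 0.99

    def test_enumeration_cap_refused(self):
        with pytest.raises(ValueError, match="cap"):
            finemap_pip(
                [f"f{j}" for j in range(30)], np.zeros(30), np.eye(30), max_causal=3
            )


class TestClassify:
    @staticmethod
    def _inputs():
        twas = pd.DataFrame(
            {
                "feature": ["a", "b", "c", "d"],
                "cls": ["herv"] * 4,
                "z": [9.0, 8.0, 7.0, 1.0],
                "p": [1e-18, 1e-15, 1e-12, 0.3],
                "bonf_p": [1e-14, 1e-11, 1e-8, 1.0],
            }
        )
        joints = [
            type("J", (), {"selected": ["a", "c"]})(),
        ]
        fms = [
            FinemapResult(
                features=["a", "b", "c", "d"],
                pip={"a": 1.0, "b": 0.97, "c": 0.4, "d": 0.1},
                prior_p=1e-3, prior_var=40.0, max_causal=3,
                credible_set=["a"], posterior_null=0.0,
            )
        ]
        return twas, joints, fms

    def test_high_confidence_requires_both(self):
        twas, joints, fms = self._inputs()
        out = classify_high_confidence(twas, joints, fms).set_index("feature")
        assert out.at["a", "high_confidence"]  # joint-selected and PIP 1.0
        assert not out.at["b", "high_confidence"]  # PIP 0.97 but not joint
        assert out.at["b", "tier"] == "pip_only"
        assert not out.at["c", "high_confidence"]  # joint but PIP 0.4
        assert out.at["c", "tier"] == "joint_only"
        assert out.at["d", "tier"] == "none"
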