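"""Synthetic cohort generators: determinism, marginals, LD and truth recovery."""

import numpy as np
import pandas as pd
import pytest

from retrowas.synthdata import (
    ExpressionArchitecture,
    LDBlockSpec,
    ScoreModel,
    fanout_seed,
    make_annotation,
    simulate_expression,
    simulate_fragments,
    simulate_genotypes,
    simulate_gwas_sumstats,
)


class TestGenotypes:
    def test_dosage_domain_and_determinism(self):
        blocks = [LDBlockSpec(n_snps=30, rho=0.4, chrom="1")]
        g1 = simulate_genotypes(100, blocks, seed=5)
        g2 = simulate_genotypes(100, blocks, seed=5)
        assert set(np.unique(g1.dosages)) <= {0.0, 1.0, 2.0}
        assert np.array_equal(g1.dosages, g2.dosages)
        assert g1.variants.equals(g2.variants)

    @pytest.mark.parametrize("rho,tol", [(0.0, 0.05), (0.9, 0.05)])
    def test_adjacent_correlation_targets_rho(self, rho, tol):
        blocks = [LDBlockSpec(n_snps=60, rho=rho, maf_range=(0.05, 0.5))]
        g = simulate_genotypes(2000, blocks, seed=3)
        d = g.dosages
        cors = np.array(
            [np.corrcoef(d[:, j], d[:, j + 1])[0, 1] for j in range(d.shape[1] - 1)]
        )
        if rho == 0.0:
            assert np.mean(np.abs(cors)) < tol
        else:
            assert abs(np.mean(cors) - rho) < tol

    def test_blocks_independent(self):
        blocks = [
            LDBlockSpec(n_snps=20, rho=0.8, chrom="1"),
            LDBlockSpec(n_snps=20, rho=0.8, chrom="2"),
        ]
        g = simulate_genotypes(2000, blocks, seed=9)
        cross = np.corrcoef(g.dosages[:, 19], g.dosages[:, 20])[0, 1]
        assert abs(cross) < 0.06

    def test_maf_within_binomial_se(self):
        g = simulate_genotypes(1500, [LDBlockSpec(n_snps=40, rho=0.0, maf_range=(0.3, 0.3001))], seed=2)
        target = 0.3
        se = np.sqrt(target * (1 - target) / (2 * 1500))
        assert np.all(np.abs(g.maf() - target) < 3 * se + 0.01)

    def test_empty_blocks_rejected(self):
        with pytest.raises(ValueError):
            simulate_genotypes(10, [], seed=0)

    def test_bad_block_specs_rejected(self):
        with pytest.raises(ValueError):
            LDBlockSpec(n_snps=0)
        with pytest.raises(ValueError):
            LDBlockSpec(n_snps=5, rho=1.0)
        with pytest.raises(ValueError):
            LDBlockSpec(n_snps=5, maf_range=(0.0, 0.5))


class TestExpression:
    @staticmethod
    def _setup(n=500, n_feat=50, h2=0.5, seed=21, **arch_kw):
        blocks = [LDBlockSpec(n_snps=20, rho=0.3, chrom=str(b + 1)) for b in range(5)]
        G = simulate_genotypes(n, blocks, seed=seed)
        ann, _ = make_annotation(blocks, n_feat // 2, n_feat - n_feat // 2, seed=seed + 1)
        arch = ExpressionArchitecture(h2_cis=h2, **arch_kw)
        counts, truth, latent, _ = simulate_expression(G, ann, arch, seed=seed + 2)
        return G, ann, counts, truth, latent

    def test_null_h2_uncorrelated_with_genotype(self):
        G, ann, counts, truth, latent = self._setup(h2=0.0)
        assert (truth.features["h2_cis"] == 0).all()
        assert truth.features["causal_snps"].map(len).sum() == 0

    def test_h2_recovery_in_latent(self):
        """Regression R^2 of latent on true genetic value ~ h2 across features."""
        G, ann, counts, truth, latent = self._setup(h2=0.5)
        X = G.standardized()
        snp_pos = {s: i for i, s in enumerate(G.variants["snp"])}
        r2s = []
        for _, row in truth.features.iterrows():
            if not row["causal_snps"]:
                continue
            g = X[:, [snp_pos[s] for s in row["causal_snps"]]] @ np.array(row["causal_effects"])
            y = latent.loc[row["feature"]].to_numpy()
            r2s.append(np.corrcoef(g, y)[0, 1] ** 2)
        assert abs(np.mean(r2s) - 0.5) < 0.07

    def test_planted_modules_raise_within_correlation(self):
        blocks = [LDBlockSpec(n_snps=20, rho=0.3, chrom="1")]
        G = simulate_genotypes(300, blocks, seed=4)
        ann, _ = make_annotation(blocks, 60, 40, seed=5)
        names = ann["name"].tolist()
        spec = [
            {"name": "m0", "features": names[:50], "strength": 0.6},
            {"name": "m1", "features": names[50:100], "strength": 0.6},
        ]
        arch = ExpressionArchitecture(h2_cis=0.0, module_spec=spec)
        _, truth, latent, _ = simulate_expression(G, ann, arch, seed=6)
        lat = latent.to_numpy()
        corr = np.corrcoef(lat)
        within = np.mean([np.abs(corr[i, j]) for i in range(50) for j in range(i + 1, 50)])
        between = np.mean([np.abs(corr[i, j]) for i in range(50) for j in range(50, 100)])
        assert within > between + 0.2

    def test_herv_counts_lower_than_genes(self):
        G, ann, counts, truth, latent = self._setup(h2=0.2)
        mean_by_cls = counts.mean(axis=1).groupby(ann.set_index("name")["cls"]).mean()
        assert mean_by_cls["herv"] < mean_by_cls["gene"]

    def test_invalid_h2_rejected(self):
        with pytest.raises(ValueError):
            ExpressionArchitecture(h2_cis=1.5)
        with pytest.raises(ValueError):
            ExpressionArchitecture(h2_overrides={"f": -0.1})

    def test_overlapping_planted_modules_rejected(self):
        blocks = [LDBlockSpec(n_snps=10, rho=0.0, chrom="1")]
        G = simulate_genotypes(50, blocks, seed=1)
        ann, _ = make_annotation(blocks, 4, 0, seed=2)
        names = ann["name"].tolist()
        arch = ExpressionArchitecture(
            module_spec=[
                {"features": names[:2]},
                {"features": names[1:3]},
            ]
        )
        with pytest.raises(ValueError, match="disjoint"):
            simulate_expression(G, ann, arch, seed=3)


class TestSumstats:
    @staticmethod
    def _cohort(seed=31, n=400):
        blocks = [LDBlockSpec(n_snps=50, rho=0.4, chrom=str(b + 1)) for b in range(4)]
        G = simulate_genotypes(n, blocks, seed=seed)
        ann, _ = make_annotation(blocks, 6, 6, seed=seed + 1)
        arch = ExpressionArchitecture(h2_cis=0.3, n_causal=(1, 1))
        _, truth, _, _ = simulate_expression(G, ann, arch, seed=seed + 2)
        return G, ann, truth

    def test_null_calibration(self):
        G, ann, truth = self._cohort()
        alpha = {f: 0.0 for f in ann["name"]}
        ss = simulate_gwas_sumstats(G, truth, alpha, n_gwas=50_000, seed=7)
        z = ss["z"].to_numpy()
        n = len(z)
        assert abs(z.mean()) < 3.0 / np.sqrt(n) * 1.5
        assert abs(z.var() - 1.0) < 3.0 * np.sqrt(2.0 / n) * 1.5

    def test_determinism(self):
        G, ann, truth = self._cohort()
        alpha = {f: 0.0 for f in ann["name"]}
        s1 = simulate_gwas_sumstats(G, truth, alpha, 1000, seed=3)
        s2 = simulate_gwas_sumstats(G, truth, alpha, 1000, seed=3)
        pd.testing.assert_frame_equal(s1, s2)

    def test_mediated_expectation_at_causal_snp(self):
        """Mean z at the causal SNP over replicates matches sqrt(N)*alpha*b."""
        blocks = [LDBlockSpec(n_snps=10, rho=0.0, chrom="1")]
        G = simulate_genotypes(800, blocks, seed=41)
        ann, _ = make_annotation(blocks, 0, 1, seed=42)
        arch = ExpressionArchitecture(h2_cis=0.4, n_causal=(1, 1))
        _, truth, _, _ = simulate_expression(G, ann, arch, seed=43)
        feat = truth.features.iloc[0]
        assert len(feat["causal_snps"]) == 1
        b = feat["causal_effects"][0]
        alpha_val, n_gwas = 0.05, 20_000
        alpha = {feat["feature"]: alpha_val}
        snp = feat["causal_snps"][0]
        zs = []
        for rep in range(200):
            ss = simulate_gwas_sumstats(G, truth, alpha, n_gwas, seed=100 + rep)
            zs.append(float(ss.set_index("snp").at[snp, "z"]))
        expected = np.sqrt(n_gwas) * alpha_val * b
        mc_se = 1.0 / np.sqrt(200)  # z noise has unit variance
        assert abs(np.mean(zs) - expected) < 4 * mc_se

    def test_bad_inputs_rejected(self):
        G, ann, truth = self._cohort()
        with pytest.raises(ValueError):
            simulate_gwas_sumstats(G, truth, {f: 0.0 for f in ann["name"]}, 0, seed=1)
        with pytest.raises(ValueError, match="alpha"):
            simulate_gwas_sumstats(G, truth, {}, 100, seed=1)


class TestFragments:
    def test_single_feature_unique(self, herv_annotation):
        ann = herv_annotation.iloc[:1]
        aln, truth = simulate_fragments(
            ann, [], {"MER4_A": 1.0}, ScoreModel(), 200, seed=1
        )
        assert all(len(f.feature_ids) == 1 for f in aln.fragments)

    def test_source_fractions_binomial(self, herv_annotation):
        ann = herv_annotation.iloc[:2]
        aln, truth = simulate_fragments(
            ann, [["MER4_A", "MER4_B"]], {"MER4_A": 0.8, "MER4_B": 0.2},
            ScoreModel(), 10_000, seed=8,
        )
        frac = (truth.fragments["source"] == "MER4_A").mean()
        assert abs(frac - 0.8) < 0.012  # 3 binomial SE

    def test_full_ambiguity_gives_multiple_candidates(self, herv_annotation):
        aln, _ = simulate_fragments(
            herv_annotation,
            [["MER4_A", "MER4_B", "MER4_C"]],
            {"MER4_A": 0.5, "MER4_B": 0.3, "MER4_C": 0.2},
            ScoreModel(ambiguity_rate=1.0),
            500,
            seed=2,
        )
        assert all(len(f.feature_ids) >= 2 for f in aln.fragments)

    def test_non_simplex_rejected(self, herv_annotation):
        with pytest.raises(ValueError, match="sums"):
            simulate_fragments(
                herv_annotation, [], {"MER4_A": 0.5, "MER4_B": 0.2, "MER4_C": 0.2},
                ScoreModel(), 10, seed=0,
            )


def test_seed_fanout_fixed_offsets():
    assert fanout_seed(1, "genotypes") != fanout_seed(1, "expression")
    assert fanout_seed(5, "sumstats") == fanout_seed(5, "sumstats")
    assert 0 <= fanout_seed(2**40, "fragments") < 2**31
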