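"""Synthetic cohort generation with known ground truth.

Every input the association pipeline consumes can be generated here:
LD-structured genotype dosages, cis-regulated expression counts for genes
and HERV loci (HERVs systematically lower-expressed), expression-mediated
GWAS z-scores, and multi-mapped fragment alignments from homologous loci.
Ground truth (causal variants, cis-h2, mediation effects, fragment sources,
planted modules) is recorded in a :class:`~retrowas.containers.TruthTable`
so downstream stages can be scored against it.

Genotypes are built from AR(1) latent-Gaussian haplotypes thresholded at
the minor-allele frequency.  Thresholding a bivariate Gaussian attenuates
correlation, so the latent autocorrelation is calibrated per adjacent SNP
pair (via Owen's-T bivariate normal orthant probabilities) such that the
realised *genotype* correlation targets the requested ``rho``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import AlignmentSet, Fragment, GenotypeMatrix, TruthTable

__all__ = [
    "LDBlockSpec",
    "ExpressionArchitecture",
    "ScoreModel",
    "simulate_genotypes",
    "make_annotation",
    "simulate_expression",
    "simulate_gwas_sumstats",
    "simulate_fragments",
    "fanout_seed",
]

# fixed per-stage offsets for fanning a master seed out to stages
STAGE_OFFSETS = {
    "genotypes": 101,
    "annotation": 211,
    "expression": 307,
    "sumstats": 401,
    "fragments": 503,
    "pipeline": 601,
}

HERV_FAMILIES = ["MER4", "ERV316A3", "ERVLE", "HML3", "HERVH", "HERVK", "HARLEQUIN"]

#: non-strand-ambiguous allele pairs used for simulated variants
_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G")]


def fanout_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the master seed by a fixed offset."""
    return int((int(master_seed) + STAGE_OFFSETS[stage]) % (2**31 - 1))


@dataclass(frozen=True)
class LDBlockSpec:
    """One LD block: ``n_snps`` markers with adjacent-pair correlation ``rho``."""

    n_snps: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    rho: float = 0.5
    chrom: str = "1"
    start_bp: int = 1
    spacing_bp: int = 1000

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")


def _bvn_cdf(h: np.ndarray, k: np.ndarray, r: np.ndarray) -> np.ndarray:
    """P(X <= h, Y <= k) for standard bivariate normal with correlation r.

    Owen (1956): Phi2 = (Phi(h)+Phi(k))/2 - T(h,a_h) - T(k,a_k) - beta.
    Assumes h, k != 0 (callers nudge exact zeros off the axis).
    """
    h = np.asarray(h, float)
    k = np.asarray(k, float)
    r = np.clip(np.asarray(r, float), -0.999999, 0.999999)
    root = np.sqrt(1.0 - r * r)
    ah = (k - r * h) / (h * root)
    ak = (h - r * k) / (k * root)
    beta = np.where(h * k > 0, 0.0, np.where(h + k >= 0, 0.0, 0.5))
    return (
        0.5 * (stats.norm.cdf(h) + stats.norm.cdf(k))
        - special.owens_t(h, ah)
        - special.owens_t(k, ak)
        - beta
    )


def _latent_corr_for_target(t1: np.ndarray, t2: np.ndarray, rho: float) -> np.ndarray:
    """Latent Gaussian correlation giving indicator (phi) correlation ``rho``.

    Indicators are 1{Z < t}; their correlation given latent correlation r is
    (Phi2(t1,t2,r) - p1 p2)/sqrt(p1 q1 p2 q2), monotone in r; solved by
    vectorised bisection.
    """
    t1 = np.where(t1 == 0.0, -1e-9, t1)
    t2 = np.where(t2 == 0.0, -1e-9, t2)
    p1, p2 = stats.norm.cdf(t1), stats.norm.cdf(t2)
    denom = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))

    def phi_corr(r):
        return (_bvn_cdf(t1, t2, r) - p1 * p2) / denom

    lo = np.zeros_like(t1)
    hi = np.full_like(t1, 0.999999)
    # phi correlation cannot exceed the attainable max for unequal margins;
    # if the target is unattainable the solution saturates at hi.
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        too_low = phi_corr(mid) < rho
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    return 0.5 * (lo + hi)


def simulate_genotypes(
    n_samples: int, blocks: list[LDBlockSpec], seed: int
) -> GenotypeMatrix:
    """Draw diploid dosages from AR(1) latent-Gaussian haplotypes.

    Within a block adjacent-SNP genotype correlation targets ``rho``;
    blocks are mutually independent.  Dosages lie in {0, 1, 2}.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if not blocks:
        raise ValueError("at least one LD block is required")
    rng = np.random.default_rng(seed)
    cols: list[np.ndarray] = []
    meta_rows: list[dict] = []
    for b, block in enumerate(blocks):
        # MAFs drift smoothly along the block (AR(1) latent mapped through
        # the uniform quantile of maf_range): strongly correlated neighbours
        # share similar allele frequencies, as in real LD, which keeps the
        # target phi correlation attainable after thresholding.
        # two binary variables with margins p1 != p2 have phi correlation
        # capped at sqrt(p1 q2 / (q1 p2)); strong rho therefore forces the
        # MAF chain to drift very slowly so the cap stays above the target.
        c = 1.0 - ((1.0 - block.rho) / 4.0) ** 2 if block.rho > 0 else 0.0
        u = np.empty(block.n_snps)
        u[0] = rng.standard_normal()
        for j in range(1, block.n_snps):
            u[j] = c * u[j - 1] + np.sqrt(1.0 - c**2) * rng.standard_normal()
        lo, hi = block.maf_range
        mafs = lo + (hi - lo) * stats.norm.cdf(u)
        thresh = stats.norm.ppf(mafs)
        if block.n_snps > 1 and block.rho > 0:
            r = _latent_corr_for_target(thresh[:-1], thresh[1:], block.rho)
        else:
            r = np.zeros(max(block.n_snps - 1, 0))
        # two haplotypes per individual, AR(1) chains
        z = np.empty((2 * n_samples, block.n_snps))
        z[:, 0] = rng.standard_normal(2 * n_samples)
        for j in range(1, block.n_snps):
            eps = rng.standard_normal(2 * n_samples)
            z[:, j] = r[j - 1] * z[:, j - 1] + np.sqrt(1.0 - r[j - 1] ** 2) * eps
        alleles = (z < thresh).astype(np.int8)
        dos = alleles[0::2] + alleles[1::2]
        cols.append(dos.astype(float))
        for j in range(block.n_snps):
            a1, a2 = _ALLELE_PAIRS[rng.integers(len(_ALLELE_PAIRS))]
            pos = block.start_bp + j * block.spacing_bp
            meta_rows.append(
                {
                    "snp": f"rs{b}_{j}",
                    "chrom": block.chrom,
                    "pos": pos,
                    "a1": a1,
                    "a2": a2,
                    "block": b,
                }
            )
    dosages = np.concatenate(cols, axis=1)
    samples = [f"S{i:04d}" for i in range(n_samples)]
    return GenotypeMatrix(dosages, pd.DataFrame(meta_rows), samples)


def make_annotation(
    blocks: list[LDBlockSpec],
    n_genes: int,
    n_hervs: int,
    seed: int,
    homology_group_size: int = 1,
) -> tuple[pd.DataFrame, list[list[str]]]:
    """Place gene and HERV features across the LD blocks.

    Returns a BED-like annotation table (0-based half-open) and homology
    groups of HERVs (same family, shared sequence) for the fragment
    simulator; ``homology_group_size`` = 1 yields singletons only.
    """
    rng = np.random.default_rng(seed)
    n_features = n_genes + n_hervs
    classes = ["gene"] * n_genes + ["herv"] * n_hervs
    rows = []
    herv_counter = 0
    for i, cls in enumerate(classes):
        block = blocks[i % len(blocks)]
        span = max(block.n_snps - 1, 1) * block.spacing_bp
        if cls == "gene":
            length = int(rng.lognormal(mean=np.log(3.0e4), sigma=0.6))
            name = f"GENE{i:04d}"
            family = "."
        else:
            length = int(rng.lognormal(mean=np.log(7.0e3), sigma=0.4))
            family = HERV_FAMILIES[herv_counter % len(HERV_FAMILIES)]
            name = f"{family}_{block.chrom}q{herv_counter:02d}"
            herv_counter += 1
        start = block.start_bp + int(rng.integers(0, max(span, 1)))
        rows.append(
            {
                "chrom": block.chrom,
                "start": start,
                "end": start + length,
                "name": name,
                "cls": cls,
                "family": family,
                "strand": "+" if rng.random() < 0.5 else "-",
            }
        )
    ann = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    groups: list[list[str]] = []
    if homology_group_size > 1:
        hervs = ann.loc[ann["cls"] == "herv", "name"].tolist()
        for i in range(0, len(hervs) - homology_group_size + 1, homology_group_size):
            groups.append(hervs[i : i + homology_group_size])
    return ann, groups


@dataclass
class ExpressionArchitecture:
    """Genetic architecture of simulated expression.

    h2_cis : default fraction of latent-expression variance explained by
        the feature's causal cis variants.
    n_causal : (lo, hi) inclusive range for causal variants per feature.
    mean_log_expression : class -> mean of natural-log expression; HERV
        loci are lower-expressed than canonical genes.
    frac_cis : fraction of features given nonzero cis-h2.
    module_spec : planted co-expression modules, each a dict with keys
        ``features`` (member ids) and ``strength`` (shared-factor variance
        fraction of the non-genetic latent component).
    covariate_effects : sample-covariate name -> effect size on the latent
        scale; covariate values are drawn standard normal and returned.
    h2_overrides : per-feature cis-h2 overriding the default.
    latent_sd : SD of the latent log-expression scale.
    """

    h2_cis: float = 0.2
    n_causal: tuple[int, int] = (1, 3)
    mean_log_expression: dict = field(
        default_factory=lambda: {"gene": 5.0, "herv": 2.5}
    )
    frac_cis: float = 1.0
    module_spec: list[dict] = field(default_factory=list)
    covariate_effects: dict = field(default_factory=dict)
    h2_overrides: dict = field(default_factory=dict)
    latent_sd: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2_cis <= 1.0):
            raise ValueError("h2_cis must lie in [0, 1]")
        for v in self.h2_overrides.values():
            if not (0.0 <= v <= 1.0):
                raise ValueError("h2 override outside [0, 1]")


def simulate_expression(
    G: GenotypeMatrix,
    annotation: pd.DataFrame,
    arch: ExpressionArchitecture,
    seed: int,
    cis_window_bp: int = 500_000,
    covariates: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, TruthTable, pd.DataFrame, pd.DataFrame]:
    """Simulate Poisson-lognormal counts with planted cis regulation.

    For each feature a latent (unit-variance) log-expression is composed of
    a genetic value g = X_c b with Var(g)/Var(latent) = h2_cis, an optional
    planted module factor, optional sample-covariate effects, and noise.
    Counts are Poisson with rate exp(mu_class + latent_sd * latent).

    Returns (counts features x samples, truth, latent matrix, sample
    covariates).  The latent matrix and truth carry everything needed to
    score downstream recovery.
    """
    bad = set(annotation["cls"]) - {"gene", "herv"}
    if bad:
        raise ValueError(f"unknown feature classes: {bad}")
    rng = np.random.default_rng(seed)
    n = G.n_samples
    X = G.standardized()
    var = G.variants

    module_of: dict[str, tuple[int, float]] = {}
    module_factors = {}
    truth_modules: dict[str, list[str]] = {}
    for m, spec in enumerate(arch.module_spec):
        members = list(spec["features"])
        name = spec.get("name", f"module{m}")
        if any(f in module_of for f in members):
            raise ValueError("planted modules must be disjoint")
        for f in members:
            module_of[f] = (m, float(spec.get("strength", 0.6)))
        module_factors[m] = rng.standard_normal(n)
        truth_modules[name] = members

    covs = (
        covariates.loc[G.samples].copy()
        if covariates is not None
        else pd.DataFrame(index=G.samples)
    )
    cov_effect = np.zeros(n)
    for cname, eff in arch.covariate_effects.items():
        if cname not in covs.columns:
            covs[cname] = rng.standard_normal(n)
        col = covs[cname]
        if not pd.api.types.is_numeric_dtype(col):
            col = pd.Series(pd.factorize(col)[0], index=col.index)
        vals = col.to_numpy(dtype=float)
        sd = vals.std()
        if sd > 0:
            vals = (vals - vals.mean()) / sd
        cov_effect = cov_effect + eff * vals

    counts = np.zeros((len(annotation), n), dtype=np.int64)
    latents = np.zeros((len(annotation), n))
    feat_rows = []
    for i, feat in annotation.iterrows():
        h2 = float(arch.h2_overrides.get(feat["name"], arch.h2_cis))
        if rng.random() >= arch.frac_cis and feat["name"] not in arch.h2_overrides:
            h2 = 0.0
        in_cis = (
            (var["chrom"] == feat["chrom"])
            & (var["pos"] >= feat["start"] - cis_window_bp)
            & (var["pos"] <= feat["end"] + cis_window_bp)
        )
        cis_idx = np.flatnonzero(in_cis.to_numpy())
        causal_snps: list[str] = []
        effects: list[float] = []
        g_std = np.zeros(n)
        if h2 > 0 and cis_idx.size > 0:
            k = int(rng.integers(arch.n_causal[0], arch.n_causal[1] + 1))
            k = min(k, cis_idx.size)
            chosen = rng.choice(cis_idx, size=k, replace=False)
            b = rng.standard_normal(k)
            g = X[:, chosen] @ b
            sd = g.std()
            if sd > 0:
                g_std = (g - g.mean()) / sd
                # standardized per-SNP effects so that Var(X b) = h2
                effects = list(np.sqrt(h2) * b / sd)
                causal_snps = var["snp"].iloc[chosen].tolist()
            else:
                h2 = 0.0
        else:
            h2 = 0.0

        env = np.sqrt(max(1.0 - h2, 0.0))
        if feat["name"] in module_of:
            m, strength = module_of[feat["name"]]
            noise = rng.standard_normal(n)
            env_part = np.sqrt(strength) * module_factors[m] + np.sqrt(
                1.0 - strength
            ) * noise
        else:
            env_part = rng.standard_normal(n)
        latent = np.sqrt(h2) * g_std + env * env_part + cov_effect
        latents[i] = latent
        mu = arch.mean_log_expression[feat["cls"]]
        rate = np.exp(mu + arch.latent_sd * latent)
        counts[i] = rng.poisson(rate)
        feat_rows.append(
            {
                "feature": feat["name"],
                "causal_snps": causal_snps,
                "causal_effects": effects,
                "h2_cis": h2,
                "alpha": 0.0,
            }
        )

    counts_df = pd.DataFrame(counts, index=annotation["name"].tolist(), columns=G.samples)
    latent_df = pd.DataFrame(latents, index=annotation["name"].tolist(), columns=G.samples)
    truth = TruthTable(features=pd.DataFrame(feat_rows), modules=truth_modules)
    return counts_df, truth, latent_df, covs


def simulate_gwas_sumstats(
    G: GenotypeMatrix,
    truth: TruthTable,
    alpha: dict[str, float],
    n_gwas: int,
    seed: int,
) -> pd.DataFrame:
    """Expression-mediated GWAS z-scores with LD-aware noise.

    Per LD block: z = sqrt(N) * R b + eps with eps ~ MVN(0, R), where the
    joint per-SNP effect b sums alpha_f * b_eqtl over mediating features
    (standardized scales throughout).  Updates ``truth`` with alpha.
    """
    if n_gwas < 1:
        raise ValueError("n_gwas must be >= 1")
    missing = set(truth.features["feature"]) - set(alpha)
    if missing:
        raise ValueError(f"alpha missing for features: {sorted(missing)[:5]} ...")
    rng = np.random.default_rng(seed)
    var = G.variants
    snp_pos = {s: i for i, s in enumerate(var["snp"])}
    b = np.zeros(G.n_variants)
    alphas = []
    for _, row in truth.features.iterrows():
        a = float(alpha[row["feature"]])
        alphas.append(a)
        if a != 0.0:
            for s, eff in zip(row["causal_snps"], row["causal_effects"]):
                b[snp_pos[s]] += a * eff
    truth.features["alpha"] = alphas

    z = np.zeros(G.n_variants)
    blocks = var["block"] if "block" in var.columns else pd.Series(0, index=var.index)
    for blk in blocks.unique():
        idx = np.flatnonzero((blocks == blk).to_numpy())
        sub = G.subset_variants(idx)
        R = sub.ld_matrix()
        # symmetric PSD square root for the noise term
        w_eig, v_eig = np.linalg.eigh(R)
        root = v_eig @ np.diag(np.sqrt(np.clip(w_eig, 0.0, None))) @ v_eig.T
        eps = root @ rng.standard_normal(idx.size)
        z[idx] = np.sqrt(n_gwas) * (R @ b[idx]) + eps

    out = var[["snp", "chrom", "pos", "a1", "a2"]].copy()
    out["z"] = z
    out["n"] = int(n_gwas)
    out["maf"] = G.maf()
    out["info"] = 1.0
    return out


@dataclass(frozen=True)
class ScoreModel:
    """Alignment-score model for the fragment simulator.

    Candidate scores are Gaussian around ``match_score`` (source) or
    ``match_score - mismatch_penalty`` (homologous non-source copies).
    With score noise sd sigma the true source posterior is proportional
    to exp(s * mismatch_penalty / sigma^2) — a softmax in the score with
    scale sigma^2/mismatch_penalty (= 20 at the defaults), so a softmax
    read-reassignment model is exactly calibrated for these fragments.
    """

    match_score: float = 200.0
    mismatch_penalty: float = 80.0
    ambiguity_rate: float = 0.8
    score_sd: float = 40.0


def simulate_fragments(
    annotation: pd.DataFrame,
    homology_groups: list[list[str]],
    pi_true: dict[str, float],
    score_model: ScoreModel,
    n_frags: int,
    seed: int,
) -> tuple[AlignmentSet, TruthTable]:
    """Draw fragments from features and emit candidate alignments.

    Fragment sources follow Categorical(pi_true).  A fragment from a
    feature in a homology group is, with probability ``ambiguity_rate``,
    reported against every group member with the non-source scores degraded
    by ``mismatch_penalty``; otherwise (and for singleton features) it
    aligns uniquely to its source.
    """
    features = annotation["name"].tolist()
    pi = np.array([pi_true.get(f, 0.0) for f in features], dtype=float)
    if abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError(f"pi_true sums to {pi.sum():.12f}, not 1")
    group_of: dict[str, list[str]] = {}
    for grp in homology_groups:
        for f in grp:
            group_of[f] = list(grp)
    rng = np.random.default_rng(seed)
    sources = rng.choice(len(features), size=n_frags, p=pi)
    frags: list[Fragment] = []
    truth_rows = []
    for i, si in enumerate(sources):
        src = features[si]
        fid = f"frag{i:06d}"
        grp = group_of.get(src, [src])
        if len(grp) > 1 and rng.random() < score_model.ambiguity_rate:
            ids = list(grp)
            means = np.array(
                [
                    score_model.match_score
                    if f == src
                    else score_model.match_score - score_model.mismatch_penalty
                    for f in ids
                ]
            )
            scores = list(means + score_model.score_sd * rng.standard_normal(len(ids)))
        else:
            ids = [src]
            scores = [
                score_model.match_score
                + score_model.score_sd * rng.standard_normal()
            ]
        frags.append(Fragment(fid, ids, scores))
        truth_rows.append({"fragment_id": fid, "source": src})
    aln = AlignmentSet(fragments=frags, feature_index=features)
    truth = TruthTable(fragments=pd.DataFrame(truth_rows))
    return aln, truth
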