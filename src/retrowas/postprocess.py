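"""Conditional/joint analysis, expression fine-mapping, and high-confidence calls.

TWAS hits at a locus are often driven by the same underlying GWAS signal
through correlated predicted expression.  This module (i) groups
significant features into loci by cis-window overlap, (ii) greedily
selects conditionally independent features and reports joint statistics,
(iii) computes per-feature posterior inclusion probabilities (PIPs) by
Bayesian model averaging over causal configurations of the predicted-
expression correlation structure, and (iv) labels features that are both
jointly significant and fine-mapped (PIP > 0.5) as high confidence.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cis_weights import WeightSet

logger = logging.getLogger(__name__)


@dataclass
class PredExprCorrelation:
    """Correlation Omega of genetically predicted expression across features."""

    omega: np.ndarray
    features: list[str]
    snps: list[str]

    def sub(self, feats: list[str]) -> np.ndarray:
        idx = [self.features.index(f) for f in feats]
        return self.omega[np.ix_(idx, idx)]


def pred_expr_cor(
    weightsets: dict[str, WeightSet],
    R: np.ndarray,
    snp_ids: list[str],
) -> PredExprCorrelation:
    """Omega_ij = w_i'Rw_j / sqrt(w_i'Rw_i * w_j'Rw_j) on the union SNP set.

    Weight SNPs missing from ``snp_ids`` get zero weight; features whose
    predicted expression has zero variance on the panel are excluded.
    """
    if not snp_ids:
        raise ValueError("empty SNP universe")
    pos = {s: i for i, s in enumerate(snp_ids)}
    feats, cols = [], []
    for fid, ws in weightsets.items():
        w = np.zeros(len(snp_ids))
        found = 0
        for s, wt in zip(ws.snps["snp"], ws.best_weights):
            if wt != 0 and s in pos:
                w[pos[s]] = wt
                found += 1
        if found == 0:
            logger.info("feature %s: no weight SNPs in universe, excluded", fid)
            continue
        feats.append(fid)
        cols.append(w)
    if not feats:
        raise ValueError("no feature overlaps the SNP universe")
    W = np.column_stack(cols)
    cov = W.T @ R @ W
    var = np.diag(cov).copy()
    keep = var > 1e-12
    if not keep.all():
        logger.info("excluding %d zero-variance features", int((~keep).sum()))
        W = W[:, keep]
        cov = cov[np.ix_(keep, keep)]
        var = var[keep]
        feats = [f for f, k in zip(feats, keep) if k]
    d = 1.0 / np.sqrt(var)
    omega = np.clip(cov * d[:, None] * d[None, :], -1.0, 1.0)
    np.fill_diagonal(omega, 1.0)
    return PredExprCorrelation(omega=omega, features=feats, snps=list(snp_ids))


def define_loci(
    results: pd.DataFrame,
    merge_bp: int = 100_000,
    sig_col: str = "bonf_p",
    sig_level: float = 0.05,
) -> list[list[str]]:
    """Transitively merge significant features whose padded windows overlap."""
    sig = results[results[sig_col] < sig_level].copy()
    loci: list[list[str]] = []
    for _, grp in sig.groupby("chrom"):
        grp = grp.sort_values("start")
        current: list[str] = []
        current_end = -np.inf
        for _, row in grp.iterrows():
            lo, hi = row["start"] - merge_bp, row["end"] + merge_bp
            if current and lo <= current_end:
                current.append(row["feature"])
                current_end = max(current_end, hi)
            else:
                if current:
                    loci.append(current)
                current = [row["feature"]]
                current_end = hi
        if current:
            loci.append(current)
    return loci


@dataclass
class JointResult:
    """Greedy conditionally independent selection within one locus."""

    locus: list[str]
    selected: list[str]
    joint_z: dict[str, float]
    joint_p: dict[str, float]
    conditional_z: dict[str, float]
    conditional_p: dict[str, float]
    collinear: list[str] = field(default_factory=list)


def _cond_stat(
    z_all: np.ndarray, omega: np.ndarray, j: int, sel: list[int]
) -> tuple[float, float]:
    """Conditional (Z, variance) of feature j given the selected set."""
    if not sel:
        return float(z_all[j]), 1.0
    oss = omega[np.ix_(sel, sel)]
    ojs = omega[j, sel]
    try:
        sol = np.linalg.solve(oss, np.column_stack([z_all[sel], ojs]))
    except np.linalg.LinAlgError:
        oss = oss + 1e-6 * np.eye(len(sel))
        sol = np.linalg.solve(oss, np.column_stack([z_all[sel], ojs]))
    num = float(z_all[j] - ojs @ sol[:, 0])
    var = float(1.0 - ojs @ sol[:, 1])
    return num, var


def joint_conditional(
    locus_features: list[str],
    z_map: dict[str, float],
    omega_model: PredExprCorrelation,
    entry_p: float = 0.05,
    collinear_var: float = 1e-4,
) -> JointResult:
    """Greedy forward selection of conditionally independent features.

    At each step the feature with the smallest conditional p (given the
    current set) enters while that p is below ``entry_p``; candidates with
    conditional variance < ``collinear_var`` are flagged collinear and
    skipped.  Joint statistics for the selected set S are the generalized
    least squares effects Omega_SS^-1 Z_S standardised by the diagonal of
    Omega_SS^-1.
    """
    feats = [f for f in locus_features if f in omega_model.features]
    if not feats:
        raise ValueError("locus has no features in the correlation model")
    omega = omega_model.sub(feats)
    z_all = np.array([z_map[f] for f in feats])
    order = np.argsort([-abs(z_all[i]) for i in range(len(feats))], kind="stable")

    sel: list[int] = []
    collinear: list[str] = []
    while True:
        best_j, best_p, best_z = None, np.inf, 0.0
        for j in order:
            if j in sel or feats[j] in collinear:
                continue
            num, var = _cond_stat(z_all, omega, j, sel)
            if var < collinear_var:
                if sel:
                    collinear.append(feats[j])
                continue
            cz = num / np.sqrt(var)
            cp = 2.0 * stats.norm.sf(abs(cz))
            if cp < best_p:
                best_j, best_p, best_z = j, cp, cz
        if best_j is None or best_p >= entry_p:
            break
        sel.append(best_j)

    cond_z, cond_p = {}, {}
    for j, f in enumerate(feats):
        if j in sel:
            cond_z[f], cond_p[f] = 0.0, 1.0
            continue
        if f in collinear:
            continue
        num, var = _cond_stat(z_all, omega, j, sel)
        if var < collinear_var:
            collinear.append(f)
            continue
        cz = num / np.sqrt(var)
        cond_z[f] = cz
        cond_p[f] = 2.0 * stats.norm.sf(abs(cz))

    joint_z, joint_p = {}, {}
    if sel:
        oss = omega[np.ix_(sel, sel)]
        try:
            inv = np.linalg.inv(oss)
        except np.linalg.LinAlgError:
            logger.warning("singular Omega_SS, ridge 1e-6 applied")
            inv = np.linalg.inv(oss + 1e-6 * np.eye(len(sel)))
        eff = inv @ z_all[sel]
        for k, j in enumerate(sel):
            jz = eff[k] / np.sqrt(inv[k, k])
            joint_z[feats[j]] = float(jz)
            joint_p[feats[j]] = float(2.0 * stats.norm.sf(abs(jz)))
    return JointResult(
        locus=feats,
        selected=[feats[j] for j in sel],
        joint_z=joint_z,
        joint_p=joint_p,
        conditional_z=cond_z,
        conditional_p=cond_p,
        collinear=collinear,
    )


def condition_snp_z(
    z_snps: np.ndarray,
    R: np.ndarray,
    selected: list[str],
    weightsets: dict[str, WeightSet],
    snp_ids: list[str],
    z_features: dict[str, float],
    omega_model: PredExprCorrelation,
) -> np.ndarray:
    """SNP z-scores conditioned on the selected features' predicted expression.

    z'_k = z_k - rho_kS Omega_SS^-1 Z_S with
    rho_kj = (R w_j)_k / sqrt(w_j'Rw_j).
    """
    if not selected:
        raise ValueError("selected set is empty")
    pos = {s: i for i, s in enumerate(snp_ids)}
    rho_cols = []
    for f in selected:
        ws = weightsets[f]
        w = np.zeros(len(snp_ids))
        for s, wt in zip(ws.snps["snp"], ws.best_weights):
            if s in pos:
                w[pos[s]] = wt
        rw = R @ w
        denom = np.sqrt(float(w @ rw))
        rho_cols.append(rw / denom)
    rho = np.column_stack(rho_cols)
    oss = omega_model.sub(list(selected))
    zs = np.array([z_features[f] for f in selected])
    try:
        sol = np.linalg.solve(oss, zs)
    except np.linalg.LinAlgError:
        sol = np.linalg.solve(oss + 1e-6 * np.eye(len(selected)), zs)
    return z_snps - rho @ sol


@dataclass
class FinemapResult:
    features: list[str]
    pip: dict[str, float]
    prior_p: float
    prior_var: float
    max_causal: int
    credible_set: list[str]
    posterior_null: float


def finemap_pip(
    features: list[str],
    z: np.ndarray,
    omega: np.ndarray,
    prior_p: float = 1e-3,
    v: float = 40.0,
    max_causal: int = 3,
    cred_level: float = 0.9,
    enum_cap: int = 25,
) -> FinemapResult:
    """Posterior inclusion probabilities by exhaustive configuration averaging.

    For a causal configuration c the z-vector is modelled as
    N(0, Omega + v * Omega[:,c] Omega[c,:]) with prior
    prior_p^|c| (1-prior_p)^(K-|c|); PIP_j sums the normalised posterior
    over configurations containing j.  The credible set greedily adds
    features by descending PIP until the posterior mass of configurations
    fully contained in the set reaches ``cred_level``.
    """
    k = len(features)
    if k == 0:
        raise ValueError("empty locus")
    if k > enum_cap and max_causal >= 3:
        raise ValueError(
            f"block of {k} features exceeds the enumeration cap ({enum_cap}); "
            "split the block"
        )
    z = np.asarray(z, dtype=float)
    configs: list[tuple[int, ...]] = [()]
    for size in range(1, min(max_causal, k) + 1):
        configs.extend(itertools.combinations(range(k), size))
    logliks = np.empty(len(configs))
    logpriors = np.empty(len(configs))
    ridge = 1e-8 * np.eye(k)
    for ci, c in enumerate(configs):
        cov = omega + ridge
        if c:
            oc = omega[:, list(c)]
            cov = cov + v * oc @ oc.T
        logliks[ci] = stats.multivariate_normal.logpdf(
            z, mean=np.zeros(k), cov=cov, allow_singular=True
        )
        logpriors[ci] = len(c) * np.log(prior_p) + (k - len(c)) * np.log1p(-prior_p)
    logpost = logliks + logpriors
    logpost -= logpost.max()
    post = np.exp(logpost)
    post /= post.sum()
    pip = {f: 0.0 for f in features}
    for ci, c in enumerate(configs):
        for j in c:
            pip[features[j]] += float(post[ci])
    order = sorted(range(k), key=lambda j: -pip[features[j]])
    chosen: set[int] = set()
    cred: list[str] = []
    for j in order:
        mass = sum(
            post[ci] for ci, c in enumerate(configs) if set(c) <= chosen
        )
        if mass >= cred_level:
            break
        chosen.add(j)
        cred.append(features[j])
    return FinemapResult(
        features=list(features),
        pip=pip,
        prior_p=prior_p,
        prior_var=v,
        max_causal=max_causal,
        credible_set=cred,
        posterior_null=float(post[0]),
    )


def classify_high_confidence(
    twas: pd.DataFrame,
    joints: list[JointResult],
    finemaps: list[FinemapResult],
    pip_threshold: float = 0.5,
) -> pd.DataFrame:
    """Tiered labels per feature; high confidence = joint-selected AND PIP > 0.5."""
    selected = {f for jr in joints for f in jr.selected}
    pip = {}
    for fm in finemaps:
        pip.update(fm.pip)
    out = twas.copy()
    out["joint_selected"] = out["feature"].isin(selected)
    out["pip"] = out["feature"].map(pip)
    out["bonferroni_sig"] = out["bonf_p"] < 0.05
    out["pip_sig"] = out["pip"] > pip_threshold
    out["high_confidence"] = out["joint_selected"] & out["pip_sig"]

    def tier(row) -> str:
        if row["high_confidence"]:
            return "high_confidence"
        if row["joint_selected"]:
            return "joint_only"
        if row["pip_sig"]:
            return "pip_only"
        if row["bonferroni_sig"]:
            return "bonferroni_only"
        return "none"

    out["tier"] = out.apply(tier, axis=1)
    return out
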