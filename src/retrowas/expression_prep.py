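"""Expression filtering, normalisation and covariate adjustment.

Raw counts (genes + HERV loci together) are filtered by a joint
count-and-TPM expression rule, normalised between samples by the trimmed
mean of M-values (TMM), converted to log2 counts per million, and
residualised on known covariates plus surrogate variables before weight
construction and network analysis.

The surrogate variables are the top principal components of the
known-covariate residual matrix — a deterministic stand-in for iterative
surrogate-variable estimation, with the count chosen by the same
sample-size rule (30 components for N in [150, 250], 60 above 350,
linear in between).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

logger = logging.getLogger(__name__)


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: (count/length) renormalised to 1e6 per sample."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()[:5]
        raise ValueError(f"no length for features: {missing}")
    if (lengths <= 0).any():
        raise ValueError("zero or negative feature length")
    rate = counts.div(lengths, axis=0)
    return rate.div(rate.sum(axis=0), axis=1) * 1.0e6


def filter_expressed(
    counts: pd.DataFrame,
    tpm: pd.DataFrame,
    min_count: float = 6,
    min_tpm: float = 0.1,
    min_fraction: float = 0.2,
) -> list[str]:
    """Features expressed in enough samples.

    A feature is kept iff the fraction of samples satisfying *jointly*
    count >= min_count and TPM >= min_tpm reaches ``min_fraction`` — the
    GTEx-style reading where both thresholds must hold in the same sample.
    """
    if counts.shape != tpm.shape or not counts.index.equals(tpm.index):
        raise ValueError("counts and tpm must share shape and feature index")
    ok = (counts.to_numpy() >= min_count) & (tpm.to_numpy() >= min_tpm)
    frac = ok.mean(axis=1)
    return counts.index[frac >= min_fraction].tolist()


@dataclass
class NormalizationFactors:
    """Per-sample TMM factors, geometric mean 1."""

    factors: pd.Series
    reference_sample: str
    trim_M: float
    trim_A: float


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, trim_M: float, trim_A: float) -> float:
    """TMM factor of one sample against the reference (log2 scale -> 2**)."""
    n_obs, n_ref = obs.sum(), ref.sum()
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        return 1.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    M = np.log2(p_obs / p_ref)
    A = 0.5 * np.log2(p_obs * p_ref)
    # precision weights from the delta method on binomial counts
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(M)) < 1e-6:  # pure depth change: factor exactly 1
        return 1.0
    n = M.size
    loM = np.floor(n * trim_M) + 1
    hiM = n + 1 - loM
    loA = np.floor(n * trim_A) + 1
    hiA = n + 1 - loA
    rankM = pd.Series(M).rank().to_numpy()
    rankA = pd.Series(A).rank().to_numpy()
    keep2 = (rankM >= loM) & (rankM <= hiM) & (rankA >= loA) & (rankA <= hiA)
    if not keep2.any():
        return 1.0
    f = np.sum(M[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    return float(2.0**f)


def tmm_factors(
    counts: pd.DataFrame, trim_M: float = 0.30, trim_A: float = 0.05
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values normalisation factors.

    The reference is the sample whose upper quartile (of library-scaled
    counts) is closest to the mean upper quartile; M and A values are
    doubly trimmed (``trim_M`` / ``trim_A`` from each tail), precision
    weighted, and the factors rescaled to geometric mean one.
    """
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if counts.shape[1] < 2:
        logger.warning("single sample: identity TMM factors")
        return NormalizationFactors(
            pd.Series(1.0, index=counts.columns), counts.columns[0], trim_M, trim_A
        )
    if (lib <= 0).any():
        raise ValueError("every sample needs positive total counts")
    uq = np.array([np.quantile(mat[:, j] / lib[j], 0.75) for j in range(mat.shape[1])])
    ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    facs = np.array(
        [
            1.0
            if j == ref_j
            else _tmm_pair(mat[:, j], mat[:, ref_j], trim_M, trim_A)
            for j in range(mat.shape[1])
        ]
    )
    facs = facs / np.exp(np.mean(np.log(facs)))
    return NormalizationFactors(
        pd.Series(facs, index=counts.columns), str(counts.columns[ref_j]), trim_M, trim_A
    )


def logcpm(
    counts: pd.DataFrame,
    factors: NormalizationFactors | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """log2 counts per million on TMM-effective library sizes."""
    lib = counts.sum(axis=0).astype(float)
    if factors is not None:
        if (factors.factors <= 0).any():
            raise ValueError("normalisation factors must be positive")
        lib = lib * factors.factors.reindex(counts.columns)
    denom = lib + 2.0 * prior_count
    return np.log2((counts + prior_count).div(denom, axis=1) * 1.0e6)


def genotype_pcs(
    G: GenotypeMatrix, k: int = 10, prune_r2: float = 0.2, prune_window: int = 50
) -> pd.DataFrame:
    """Top-k principal components of LD-pruned, standardised genotypes.

    SNPs are greedily pruned so no kept pair within ``prune_window`` kept
    neighbours exceeds r^2 = ``prune_r2``; dosages are standardised by
    sqrt(2p(1-p)); the left singular vectors (orthonormal over samples)
    are returned.
    """
    x = G.standardized()
    sd = x.std(axis=0)
    usable = np.flatnonzero(sd > 0)
    kept: list[int] = []
    xc = x - x.mean(axis=0)
    norms = np.sqrt((xc**2).sum(axis=0))
    for j in usable:
        ok = True
        for i in kept[-prune_window:]:
            r = float(xc[:, i] @ xc[:, j] / (norms[i] * norms[j]))
            if r * r > prune_r2:
                ok = False
                break
        if ok:
            kept.append(j)
    u, s, _ = np.linalg.svd(xc[:, kept], full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    if k > rank:
        logger.warning("requested %d PCs but rank is %d", k, rank)
        k = rank
    return pd.DataFrame(
        u[:, :k], index=G.samples, columns=[f"PC{i + 1}" for i in range(k)]
    )


def n_surrogate_variables(n_samples: int) -> int:
    """Sample-size rule: 30 for N in [150, 250], 60 for N > 350, linear between."""
    if n_samples > 350:
        return 60
    if n_samples >= 250:
        return int(np.floor(30 + (n_samples - 250) * 30.0 / 100.0))
    if n_samples >= 150:
        return 30
    return 15


def parallel_analysis_n_sv(
    resid: np.ndarray, n_perm: int = 20, quantile: float = 0.95, seed: int = 0
) -> int:
    """Number of latent factors exceeding a column-permutation eigenvalue null.

    Permuting each feature column independently destroys shared structure
    while preserving marginals; singular values of the real residual matrix
    that exceed the permutation null's per-rank quantile mark genuine
    latent factors.  Guards the surrogate-variable count against absorbing
    per-feature variance when the feature panel is small.
    """
    rng = np.random.default_rng(seed)
    x = resid - resid.mean(axis=0)
    s_real = np.linalg.svd(x, compute_uv=False)
    null = np.empty((n_perm, len(s_real)))
    for p in range(n_perm):
        perm = np.column_stack(
            [x[rng.permutation(x.shape[0]), j] for j in range(x.shape[1])]
        )
        null[p] = np.linalg.svd(perm, compute_uv=False)
    thresh = np.quantile(null, quantile, axis=0)
    exceeds = s_real > thresh
    k = 0
    for e in exceeds:  # leading consecutive run only
        if not e:
            break
        k += 1
    return k


def build_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Numeric design matrix: categoricals one-hot (drop-first), intercept added.

    Collinear columns are dropped (logged by name); raises if the result is
    still rank deficient.
    """
    num = pd.get_dummies(covariates, drop_first=True, dtype=float)
    num.insert(0, "intercept", 1.0)
    mat = num.to_numpy(dtype=float)
    q, r = np.linalg.qr(mat)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(mat.shape) * np.finfo(float).eps * 100
    keep = diag > tol
    dropped = num.columns[~keep].tolist()
    if dropped:
        logger.warning("dropping collinear design columns: %s", dropped)
    out = num.loc[:, keep]
    if np.linalg.matrix_rank(out.to_numpy()) < out.shape[1]:
        raise ValueError(f"design still rank deficient after dropping {dropped}")
    return out


def residualize(
    expr: pd.DataFrame,
    covariates: pd.DataFrame,
    n_surrogate: int | str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """OLS residuals of each feature on [known covariates | surrogate PCs].

    ``expr`` is features x samples; ``covariates`` is samples x columns
    (categoricals allowed).  Surrogate vectors are the top principal
    components of the known-covariate residual matrix; their number comes
    from the sample-size rule (default), or — with ``n_surrogate="auto"``
    — from the rule capped by a parallel-analysis estimate of how many
    latent factors the residual matrix actually supports (prevents the
    surrogates from swallowing per-feature signal on small feature
    panels).  Returns (adjusted expression, surrogate vectors).
    """
    if not expr.columns.equals(covariates.index.astype(expr.columns.dtype)):
        covariates = covariates.loc[expr.columns]
    n = expr.shape[1]
    design = build_design(covariates).to_numpy(dtype=float)
    y = expr.to_numpy(dtype=float).T  # samples x features

    def _resid(dmat: np.ndarray, yy: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(dmat, yy, rcond=None)
        return yy - dmat @ beta

    r1 = _resid(design, y)
    if n_surrogate is None:
        n_surrogate = n_surrogate_variables(n)
    elif n_surrogate == "auto":
        n_surrogate = min(n_surrogate_variables(n), parallel_analysis_n_sv(r1))
        logger.info("auto surrogate-variable count: %d", n_surrogate)
    n_surrogate = min(n_surrogate, min(r1.shape) - 1)
    if n_surrogate > 0:
        u, s, _ = np.linalg.svd(r1 - r1.mean(axis=0), full_matrices=False)
        sv = u[:, :n_surrogate]
        full = np.hstack([design, sv])
    else:
        sv = np.zeros((n, 0))
        full = design
    r2 = _resid(full, y)
    adjusted = pd.DataFrame(r2.T, index=expr.index, columns=expr.columns)
    sv_df = pd.DataFrame(
        sv, index=expr.columns, columns=[f"SV{i + 1}" for i in range(sv.shape[1])]
    )
    return adjusted, sv_df
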