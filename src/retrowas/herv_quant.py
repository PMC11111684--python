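"""Locus-resolved repeat-element quantification by EM reassignment.

Short fragments from homologous HERV proviruses align to several genomic
copies; family-level aggregation throws the locus information away.  This
module instead treats the per-fragment candidate alignments as a mixture
problem: each fragment arose from one feature with mixture weight pi_j,
and the alignment score is evidence for the source.  An EM algorithm with
a symmetric Dirichlet prior (MAP M-step) reassigns ambiguous fragments to
their most probable source locus.

The E-step uses a single-parameter softmax likelihood
``P(score | source=j) proportional to exp(score_ij / score_scale)`` over the
fragment's candidates, plus a reserved "no-feature" slot with a fixed
pseudo-score modelling off-target fragments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .containers import AlignmentSet

logger = logging.getLogger(__name__)

NO_FEATURE = "__no_feature__"


@dataclass
class AbundanceEstimate:
    """EM mixture estimate over K features plus the no-feature slot.

    ``pi`` and per-fragment posteriors each sum to one; ``loglik_trace``
    is the per-iteration log-posterior and is non-decreasing.
    """

    pi: np.ndarray
    posteriors: sparse.csr_matrix
    feature_index: list[str]  # K features + NO_FEATURE
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    n_fragments: int
    prior_strength: float

    def pi_series(self) -> dict[str, float]:
        return dict(zip(self.feature_index, self.pi))


def _build_sparse(alignments: AlignmentSet, score_scale: float, no_feature_offset: float):
    """CSR matrix of candidate likelihood factors exp((s - s_max_i)/scale).

    Column K is the reserved no-feature slot, whose pseudo-score is the
    fragment's minimum candidate score minus ``no_feature_offset``.
    Row-wise max-shifting keeps the exponentials in range; the factors are
    proportional to exp(score/scale) within each row, which is all the
    E-step needs.
    """
    k = len(alignments.feature_index)
    col_of = {f: j for j, f in enumerate(alignments.feature_index)}
    rows, cols, vals = [], [], []
    for i, frag in enumerate(alignments.fragments):
        scores = np.asarray(frag.scores, dtype=float)
        pseudo = scores.min() - no_feature_offset
        all_scores = np.append(scores, pseudo)
        shifted = (all_scores - all_scores.max()) / score_scale
        lik = np.exp(shifted)
        for fid, l in zip(frag.feature_ids, lik[:-1]):
            rows.append(i)
            cols.append(col_of[fid])
            vals.append(l)
        rows.append(i)
        cols.append(k)
        vals.append(lik[-1])
    n = len(alignments.fragments)
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n, k + 1))


def em_reassign(
    alignments: AlignmentSet,
    prior_strength: float = 1e-3,
    score_scale: float = 20.0,
    tol: float = 1e-6,
    max_iter: int = 200,
    no_feature_offset_scales: float = 2.0,
) -> AbundanceEstimate:
    """MAP-EM estimate of the fragment-source mixture pi.

    E-step: P(source=j | fragment i) proportional to pi_j * exp(s_ij/scale)
    over candidates only.  M-step: pi_j = (sum_i p_ij + alpha)/(N + K*alpha)
    with symmetric Dirichlet strength ``alpha = prior_strength``.  Iterates
    until the log-posterior changes by less than ``tol``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if score_scale <= 0:
        raise ValueError("score_scale must be positive")
    if prior_strength < 0:
        raise ValueError("prior_strength must be non-negative")
    k_features = len(alignments.feature_index)
    if k_features < 1:
        raise ValueError("feature index is empty")
    n = alignments.n_fragments
    lik = _build_sparse(
        alignments, score_scale, no_feature_offset_scales * score_scale
    )
    k_total = k_features + 1
    alpha = float(prior_strength)
    pi = np.full(k_total, 1.0 / k_total)

    lik = lik.tocsr()
    data = lik.data
    indptr, indices = lik.indptr, lik.indices

    trace = []
    converged = False
    post_data = np.empty_like(data)
    last_lp = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E-step: responsibilities within each fragment's candidate row
        weighted = data * pi[indices]
        row_sums = np.add.reduceat(weighted, indptr[:-1])
        # log-posterior (MAP objective): sum_i log(sum_j pi_j lik_ij) + alpha*sum log pi
        lp = float(np.sum(np.log(row_sums)))
        if alpha > 0:
            lp += alpha * float(np.sum(np.log(np.maximum(pi, 1e-300))))
        trace.append(lp)
        post_data = weighted / np.repeat(row_sums, np.diff(indptr))
        # M-step (MAP with symmetric Dirichlet)
        counts = np.bincount(indices, weights=post_data, minlength=k_total)
        pi = (counts + alpha) / (n + k_total * alpha)
        if abs(lp - last_lp) < tol:
            converged = True
            break
        last_lp = lp

    if not converged:
        logger.warning("EM hit max_iter=%d without converging", max_iter)
    posteriors = sparse.csr_matrix(
        (post_data, indices.copy(), indptr.copy()), shape=(n, k_total)
    )
    return AbundanceEstimate(
        pi=pi,
        posteriors=posteriors,
        feature_index=list(alignments.feature_index) + [NO_FEATURE],
        loglik_trace=np.asarray(trace),
        n_iter=n_iter,
        converged=converged,
        n_fragments=n,
        prior_strength=alpha,
    )


def assign_counts(est: AbundanceEstimate, mode: str = "best") -> dict[str, float]:
    """Materialise per-feature fragment counts from the EM posteriors.

    best : each fragment counted once toward its argmax-posterior feature
        (ties broken toward the lowest feature index and logged).
    fractional : posterior mass summed per feature.
    unique : only fragments with a single candidate (posterior 1 on one
        real feature up to the no-feature slot) are counted.
    """
    if mode not in {"best", "fractional", "unique"}:
        raise ValueError(f"unknown assignment mode: {mode!r}")
    post = est.posteriors.tocsr()
    k_total = len(est.feature_index)
    counts = np.zeros(k_total)
    if mode == "fractional":
        counts = np.asarray(post.sum(axis=0)).ravel()
    else:
        n_ties = 0
        indptr, indices, data = post.indptr, post.indices, post.data
        for i in range(post.shape[0]):
            sl = slice(indptr[i], indptr[i + 1])
            row_vals = data[sl]
            row_cols = indices[sl]
            if mode == "unique" and len(row_vals) > 2:  # candidates + no-feature
                continue
            best = row_vals.max()
            winners = row_cols[row_vals >= best - 1e-12]
            if len(winners) > 1:
                n_ties += 1
            counts[winners.min()] += 1.0
        if n_ties:
            logger.info("assign_counts(best): %d posterior ties broken by index", n_ties)
    return dict(zip(est.feature_index, counts))


def run_report(est: AbundanceEstimate, alignments: AlignmentSet) -> dict:
    return {
        "n_fragments": est.n_fragments,
        "n_ambiguous": alignments.n_ambiguous(),
        "n_iter": est.n_iter,
        "converged": bool(est.converged),
        "final_log_posterior": float(est.loglik_trace[-1]),
        "prior_strength": est.prior_strength,
    }
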