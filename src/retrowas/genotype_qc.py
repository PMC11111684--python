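"""Variant/sample quality control and summary-statistic harmonisation.

Implements standard GWAS-panel QC: chi-square Hardy–Weinberg tests,
MAF/missingness variant filters with strand-ambiguous removal, sample
filters on heterozygosity, missingness and method-of-moments relatedness
(pihat), and allele-aware harmonisation of external summary statistics
against the weight/LD panel.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, is_strand_ambiguous

logger = logging.getLogger(__name__)


def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """1-df chi-square goodness-of-fit p-value against Hardy–Weinberg.

    Expected genotype counts come from the sample allele frequency;
    monomorphic variants return p = 1.
    """
    n = n_aa + n_ab + n_bb
    if n <= 0:
        raise ValueError("no genotype observations")
    p = (2 * n_aa + n_ab) / (2.0 * n)
    if p <= 0.0 or p >= 1.0:
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) * (1 - p)])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return float(stats.chi2.sf(chi2, df=1))


def hwe_pvalues(G: GenotypeMatrix) -> np.ndarray:
    d = G.dosages
    out = np.ones(G.n_variants)
    for j in range(G.n_variants):
        col = d[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        out[j] = hwe_test(
            int(np.sum(col == 2)), int(np.sum(col == 1)), int(np.sum(col == 0))
        )
    return out


def variant_qc(
    G: GenotypeMatrix,
    maf_min: float = 0.05,
    hwe_p_min: float = 5e-6,
    miss_max: float = 0.05,
    drop_ambiguous: bool = True,
) -> np.ndarray:
    """Boolean keep-mask: MAF > maf_min, HWE p >= hwe_p_min, missing < miss_max,
    and (optionally) no strand-ambiguous A/T or C/G variants."""
    keep = (
        (G.maf() > maf_min)
        & (hwe_pvalues(G) >= hwe_p_min)
        & (G.missing_rate() < miss_max)
    )
    if drop_ambiguous:
        amb = np.array(
            [
                is_strand_ambiguous(a1, a2)
                for a1, a2 in zip(G.variants["a1"], G.variants["a2"])
            ]
        )
        keep &= ~amb
    return keep


def heterozygosity_rate(G: GenotypeMatrix) -> np.ndarray:
    d = G.dosages
    het = np.nansum(d == 1, axis=1).astype(float)
    called = np.sum(~np.isnan(d), axis=1)
    return np.divide(het, called, out=np.zeros(len(het)), where=called > 0)


def ibd_pihat(G: GenotypeMatrix, i: int, j: int, min_shared: int = 100) -> float:
    """Method-of-moments IBD-sharing estimate pihat = P(IBD=1)/2 + P(IBD=2).

    Observed identity-by-state counts across shared non-missing variants
    are compared with their expectations under each IBD state given panel
    allele frequencies (HWE assumed); the solved state probabilities give
    pihat, clamped to [0, 1].
    """
    di, dj = G.dosages[i], G.dosages[j]
    ok = ~np.isnan(di) & ~np.isnan(dj)
    if ok.sum() < min_shared:
        raise ValueError(f"only {int(ok.sum())} shared variants (< {min_shared})")
    di, dj = di[ok], dj[ok]
    p = G.allele_freq()[ok]
    informative = (p > 0) & (p < 1)
    di, dj, p = di[informative], dj[informative], p[informative]
    q = 1.0 - p
    ibs = 2.0 - np.abs(di - dj)
    obs = np.array([(ibs == 0).mean(), (ibs == 1).mean(), (ibs == 2).mean()])
    # expected IBS proportions per locus conditional on IBD state
    e_ibs0_z0 = np.mean(2 * p**2 * q**2)
    e_ibs1_z0 = np.mean(4 * p**3 * q + 4 * p * q**3)
    e_ibs2_z0 = np.mean(p**4 + q**4 + 4 * p**2 * q**2)
    e_ibs1_z1 = np.mean(2 * p * q)
    e_ibs2_z1 = np.mean(p**2 + q**2)
    z0 = obs[0] / e_ibs0_z0 if e_ibs0_z0 > 0 else 0.0
    z1 = (obs[1] - z0 * e_ibs1_z0) / e_ibs1_z1 if e_ibs1_z1 > 0 else 0.0
    z0, z1 = max(z0, 0.0), max(z1, 0.0)
    z2 = obs[2] - z0 * e_ibs2_z0 - z1 * e_ibs2_z1
    total = z0 + z1 + max(z2, 0.0)
    if total > 1.0:  # renormalise the moment estimates onto the simplex
        z0, z1, z2 = z0 / total, z1 / total, max(z2, 0.0) / total
    pihat = 0.5 * z1 + max(z2, 0.0)
    return float(min(max(pihat, 0.0), 1.0))


def pairwise_pihat(G: GenotypeMatrix) -> np.ndarray:
    """All-pairs pihat via indicator-matrix products.

    IBS counts for every pair come from products of genotype-class
    indicator matrices; the per-IBD-state expectations use panel-wide
    allele-frequency means (exact when missingness is zero, a close
    approximation when it is low).
    """
    d = G.dosages
    valid = ~np.isnan(d)
    a0 = np.where(valid & (d == 0), 1.0, 0.0)
    a1 = np.where(valid & (d == 1), 1.0, 0.0)
    a2 = np.where(valid & (d == 2), 1.0, 0.0)
    shared = valid.astype(float) @ valid.astype(float).T
    n_ibs0 = a0 @ a2.T + a2 @ a0.T
    n_ibs1 = a0 @ a1.T + a1 @ a0.T + a1 @ a2.T + a2 @ a1.T
    with np.errstate(invalid="ignore", divide="ignore"):
        obs0 = n_ibs0 / shared
        obs1 = n_ibs1 / shared
        obs2 = 1.0 - obs0 - obs1
    p = G.allele_freq()
    informative = (p > 0) & (p < 1)
    p = p[informative]
    q = 1.0 - p
    e_ibs0_z0 = np.mean(2 * p**2 * q**2)
    e_ibs1_z0 = np.mean(4 * p**3 * q + 4 * p * q**3)
    e_ibs2_z0 = np.mean(p**4 + q**4 + 4 * p**2 * q**2)
    e_ibs1_z1 = np.mean(2 * p * q)
    e_ibs2_z1 = np.mean(p**2 + q**2)
    z0 = np.maximum(obs0 / e_ibs0_z0, 0.0)
    z1 = np.maximum((obs1 - z0 * e_ibs1_z0) / e_ibs1_z1, 0.0)
    z2 = np.maximum(obs2 - z0 * e_ibs2_z0 - z1 * e_ibs2_z1, 0.0)
    total = z0 + z1 + z2
    scale = np.where(total > 1.0, total, 1.0)
    pihat = (0.5 * z1 + z2) / scale
    return np.clip(np.nan_to_num(pihat), 0.0, 1.0)


def ld_prune(G: GenotypeMatrix, r2_max: float = 0.2, window: int = 50) -> np.ndarray:
    """Greedy LD-pruned variant indices: kept pairs within ``window`` kept
    neighbours never exceed r^2 = r2_max."""
    x = np.nan_to_num(G.standardized())
    xc = x - x.mean(axis=0)
    norms = np.sqrt((xc**2).sum(axis=0))
    kept: list[int] = []
    for j in range(G.n_variants):
        if norms[j] == 0:
            continue
        ok = True
        for i in kept[-window:]:
            r = float(xc[:, i] @ xc[:, j] / (norms[i] * norms[j]))
            if r * r > r2_max:
                ok = False
                break
        if ok:
            kept.append(j)
    return np.array(kept, dtype=int)


def sample_qc(
    G: GenotypeMatrix,
    het_sd: float = 3.0,
    miss_max: float = 0.05,
    pihat_max: float = 0.2,
    prune_r2: float | None = 0.2,
) -> list[str]:
    """Kept sample ids after heterozygosity, missingness and relatedness filters.

    Relatedness is estimated on LD-pruned variants (the moment estimator
    assumes independent loci).  Of each related pair (pihat > pihat_max)
    the member with higher missingness is removed (ties: the later id).
    """
    if G.n_samples < 3:
        raise ValueError("need >= 3 samples for the heterozygosity SD filter")
    het = heterozygosity_rate(G)
    miss = np.mean(np.isnan(G.dosages), axis=1)
    sd = het.std()
    bad = np.zeros(G.n_samples, dtype=bool)
    if sd > 0:
        bad |= np.abs(het - het.mean()) > het_sd * sd
    bad |= miss > miss_max
    G_ibd = G.subset_variants(ld_prune(G, prune_r2)) if prune_r2 else G
    pihat = pairwise_pihat(G_ibd)
    # with few markers the moment estimator cannot resolve pihat at the
    # nominal threshold; require exceedance of the panel's noise floor too
    iu = np.triu_indices(G.n_samples, 1)
    off = pihat[iu]
    noise_floor = float(np.median(off) + 5.0 * 1.4826 * np.median(np.abs(off - np.median(off))))
    threshold = max(pihat_max, noise_floor)
    if threshold > pihat_max:
        logger.info(
            "pihat noise floor %.3f exceeds nominal %.2f; using the floor",
            noise_floor, pihat_max,
        )
    order = np.flatnonzero(~bad)
    for a_i in range(len(order)):
        for b_i in range(a_i + 1, len(order)):
            a, b = order[a_i], order[b_i]
            if bad[a] or bad[b]:
                continue
            ph = pihat[a, b]
            if ph > threshold:
                if miss[a] > miss[b]:
                    drop = a
                elif miss[b] > miss[a]:
                    drop = b
                else:
                    drop = max(a, b)  # ties: later id
                bad[drop] = True
                logger.info(
                    "related pair (%s, %s) pihat=%.3f: dropping %s",
                    G.samples[a],
                    G.samples[b],
                    ph,
                    G.samples[drop],
                )
    return [s for s, b in zip(G.samples, bad) if not b]


def harmonize_sumstats(
    ss: pd.DataFrame,
    panel: GenotypeMatrix,
    maf_min: float = 0.05,
    info_min: float = 0.80,
) -> tuple[pd.DataFrame, dict]:
    """Align summary statistics to the panel's variants and allele coding.

    Exact A1/A2 matches keep Z; swapped alleles flip the Z sign;
    strand-ambiguous (A/T, C/G) and irreconcilable records are dropped, as
    are records failing the MAF / imputation-INFO filters when those
    columns are present.  Returns the aligned table and an action report.
    """
    pv = panel.variants.set_index("snp")
    report = {
        "input": len(ss),
        "matched": 0,
        "flipped": 0,
        "ambiguous_dropped": 0,
        "irreconcilable_dropped": 0,
        "not_in_panel": 0,
        "maf_dropped": 0,
        "info_dropped": 0,
    }
    rows = []
    for rec in ss.itertuples(index=False):
        if rec.snp not in pv.index:
            report["not_in_panel"] += 1
            continue
        a1, a2 = rec.a1.upper(), rec.a2.upper()
        if is_strand_ambiguous(a1, a2):
            report["ambiguous_dropped"] += 1
            continue
        if "maf" in ss.columns and not pd.isna(rec.maf) and rec.maf <= maf_min:
            report["maf_dropped"] += 1
            continue
        if "info" in ss.columns and not pd.isna(rec.info) and rec.info <= info_min:
            report["info_dropped"] += 1
            continue
        pa1, pa2 = pv.at[rec.snp, "a1"], pv.at[rec.snp, "a2"]
        if (a1, a2) == (pa1, pa2):
            z = rec.z
            report["matched"] += 1
        elif (a1, a2) == (pa2, pa1):
            z = -rec.z
            report["flipped"] += 1
        else:
            report["irreconcilable_dropped"] += 1
            continue
        row = rec._asdict()
        row.update({"a1": pa1, "a2": pa2, "z": z})
        rows.append(row)
    if not rows:
        raise ValueError("zero overlap between summary statistics and panel")
    out = pd.DataFrame(rows).reset_index(drop=True)
    logger.info("harmonize_sumstats: %s", report)
    return out, report
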