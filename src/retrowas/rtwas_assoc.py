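"""Summary-statistic association of genetically predicted expression.

Given per-feature SNP weights w, harmonised GWAS z-scores z and an LD
reference correlation matrix R, the association statistic is

    Z = w'z / sqrt(w'Rw)

with a two-sided normal p-value, Bonferroni-corrected across the number of
features actually tested per trait.  A light ridge stabilises the LD
matrix of the small reference panel before the quadratic form.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .cis_weights import WeightSet
from .containers import GenotypeMatrix

logger = logging.getLogger(__name__)

DEFAULT_RIDGE_EPS = 0.1


def twas_stat(
    w: np.ndarray, z: np.ndarray, R: np.ndarray, ridge_eps: float = DEFAULT_RIDGE_EPS
) -> tuple[float, float]:
    """(Z, two-sided P) for one feature; raises on degenerate variance."""
    w = np.asarray(w, dtype=float)
    z = np.asarray(z, dtype=float)
    if ridge_eps > 0:
        R = (R + ridge_eps * np.eye(R.shape[0])) / (1.0 + ridge_eps)
    denom = float(w @ R @ w)
    if denom <= 1e-8:
        raise ZeroDivisionError("degenerate variance in TWAS statistic")
    zstat = float(w @ z) / np.sqrt(denom)
    return zstat, float(2.0 * stats.norm.sf(abs(zstat)))


def bonferroni_adjust(p: float, m: int) -> float:
    """min(1, p*m)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p outside [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, p * m)


def run_rtwas(
    weights: dict[str, WeightSet],
    ss: pd.DataFrame,
    ld_source: GenotypeMatrix,
    ridge_eps: float = DEFAULT_RIDGE_EPS,
    low_coverage_frac: float = 0.5,
) -> pd.DataFrame:
    """One association row per usable feature.

    Weight SNPs absent from the (harmonised) summary statistics are
    dropped; features retaining under ``low_coverage_frac`` of their
    weight SNPs are flagged but kept.  m for the Bonferroni correction is
    the number of features actually tested.
    """
    zmap = dict(zip(ss["snp"], ss["z"]))
    panel_pos = {s: i for i, s in enumerate(ld_source.variants["snp"])}
    rows = []
    for fid, ws in weights.items():
        w_full = ws.best_weights
        nz = np.flatnonzero(w_full != 0)
        if nz.size == 0:
            logger.info("feature %s: all-zero weights, skipped", fid)
            continue
        snp_ids = ws.snps["snp"].to_numpy()
        have = np.array(
            [snp_ids[j] in zmap and snp_ids[j] in panel_pos for j in nz]
        )
        flags = []
        if have.mean() < low_coverage_frac:
            flags.append("low_coverage")
        used = nz[have]
        if used.size == 0:
            logger.info("feature %s: no weight SNPs in sumstats, skipped", fid)
            continue
        w = w_full[used]
        z = np.array([zmap[snp_ids[j]] for j in used])
        panel_idx = [panel_pos[snp_ids[j]] for j in used]
        R = ld_source.subset_variants(panel_idx).ld_matrix()
        try:
            zstat, p = twas_stat(w, z, R, ridge_eps=ridge_eps)
        except ZeroDivisionError:
            logger.warning("feature %s: degenerate variance, skipped", fid)
            continue
        rows.append(
            {
                "feature": fid,
                "cls": ws.cls,
                "chrom": ws.chrom,
                "start": ws.start,
                "end": ws.end,
                "best_method": ws.best_method,
                "n_snps_used": int(used.size),
                "z": zstat,
                "p": p,
                "flags": ";".join(flags),
            }
        )
    if not rows:
        raise ValueError("zero usable features in the TWAS")
    res = pd.DataFrame(rows)
    m = len(res)
    res["bonf_p"] = np.minimum(1.0, res["p"] * m)
    res.attrs["m_tested"] = m
    res.attrs["sig_threshold"] = 0.05 / m
    res.attrs["ridge_eps"] = ridge_eps
    return res


def report_fractions(
    results: pd.DataFrame,
    other: pd.DataFrame | None = None,
    sig_col: str = "bonf_p",
    sig_level: float = 0.05,
) -> dict:
    """Counts and integer-rounded percentages of HERV vs gene hits.

    Percentages are round(100*a/b) to the nearest integer, matching how
    result fractions are conventionally reported; with a second table the
    percent change in significant counts is included.
    """
    if results.empty:
        raise ValueError("empty results table")
    sig = results[results[sig_col] < sig_level]
    out: dict = {
        "n_tested": len(results),
        "n_significant": len(sig),
        "n_herv": int((sig["cls"] == "herv").sum()),
        "n_gene": int((sig["cls"] == "gene").sum()),
    }
    if len(sig) > 0:
        out["pct_herv"] = round(100.0 * out["n_herv"] / len(sig))
        out["pct_gene"] = round(100.0 * out["n_gene"] / len(sig))
    if other is not None:
        a = len(results[results[sig_col] < sig_level])
        b = len(other[other[sig_col] < sig_level])
        if a > 0:
            out["pct_change_vs_other"] = round(100.0 * (b - a) / a)
    return out
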