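"""Signed weighted co-expression network, modules, eigengenes, GO enrichment.

A signed adjacency a_ij = ((1 + cor_ij)/2)^beta over genes and HERV loci,
with beta chosen by approximate scale-free topology fit, is filtered
through the topological overlap measure (TOM); modules come from
average-linkage hierarchical clustering of 1 - TOM with a static cut,
eigengene-based merging, and size-ordered colour names (largest module =
"turquoise", unassigned = "grey").  Module function is read off the
canonical genes via hypergeometric GO enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

MODULE_COLOURS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white",
]
GREY = "grey"


def signed_adjacency(corr: np.ndarray, beta: float) -> np.ndarray:
    """a_ij = ((1 + cor_ij)/2)^beta with unit diagonal."""
    a = ((1.0 + np.clip(corr, -1.0, 1.0)) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def scale_free_fit(adjacency: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log connectivity-frequency regression."""
    k = adjacency.sum(axis=1) - 1.0
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max() + 1e-9, n_bins + 1)
    which = np.digitize(logk, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(members.size / k.size))
    if len(xs) < 3:
        return 0.0
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(r**2 * np.sign(-slope))


def pick_beta(
    expr: pd.DataFrame,
    powers: list[int] | None = None,
    target_r2: float = 0.8,
) -> tuple[int, pd.DataFrame]:
    """Smallest power whose scale-free fit reaches ``target_r2``.

    If no power reaches the target the best-fitting power is used (logged).
    Returns (beta, per-power table of fit and mean connectivity).
    """
    if powers is None:
        powers = list(range(1, 21))
    mat = expr.to_numpy(dtype=float)
    sds = mat.std(axis=1)
    if (sds == 0).any():
        logger.warning("dropping %d constant features", int((sds == 0).sum()))
        mat = mat[sds > 0]
    if mat.shape[0] < 50:
        raise ValueError("need >= 50 variable features to assess topology")
    corr = np.corrcoef(mat)
    rows = []
    for b in powers:
        a = signed_adjacency(corr, b)
        fit = scale_free_fit(a)
        rows.append({"power": b, "fit_r2": fit, "mean_k": float(a.sum(axis=1).mean() - 1)})
    table = pd.DataFrame(rows)
    ok = table[table["fit_r2"] >= target_r2]
    if len(ok):
        beta = int(ok["power"].iloc[0])
    else:
        beta = int(table.loc[table["fit_r2"].idxmax(), "power"])
        logger.warning("no power reached fit %.2f; using best beta=%d", target_r2, beta)
    return beta, table


def tom_similarity(A: np.ndarray) -> np.ndarray:
    """Topological overlap: TOM_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 - a_ij)."""
    a = np.asarray(A, dtype=float)
    k = a.sum(axis=1) - 1.0
    l = a @ a - 2.0 * a  # l_ij = sum_{u != i,j} a_iu a_uj for unit diagonal
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):  # diagonal is 0/0
        tom = (l + a) / (kmin + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return tom


def module_eigengene(expr_rows: np.ndarray) -> np.ndarray:
    """First PC across samples of standardized module expression, unit norm.

    Oriented to correlate positively with the mean module expression, so
    flipping all member rows leaves the eigengene's sign convention intact.
    """
    mat = np.asarray(expr_rows, dtype=float)
    if mat.shape[0] < 2:
        raise ValueError("module must have >= 2 features")
    sds = mat.std(axis=1)
    mat = mat[sds > 0]
    mat = (mat - mat.mean(axis=1, keepdims=True)) / mat.std(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(mat, full_matrices=False)
    eig = vt[0]
    mean_expr = mat.mean(axis=0)
    if np.corrcoef(eig, mean_expr)[0, 1] < 0:
        eig = -eig
    return eig / np.linalg.norm(eig)


@dataclass
class ModuleAssignment:
    colours: pd.Series  # feature -> colour (grey = unassigned)
    eigengenes: pd.DataFrame  # samples x modules
    sizes: pd.Series


def detect_modules(
    tom: np.ndarray,
    expr: pd.DataFrame,
    min_module_size: int = 30,
    cut_height: float = 0.99,
    merge_cut_height: float = 0.25,
) -> ModuleAssignment:
    """Average-linkage clustering of 1 - TOM with static cut and eigengene merge.

    Clusters smaller than ``min_module_size`` go grey; modules whose
    eigengenes correlate above 1 - merge_cut_height are merged iteratively;
    colours are assigned by descending size from the fixed palette.
    """
    n = tom.shape[0]
    features = expr.index.tolist()
    if n < min_module_size:
        logger.warning("fewer features than min_module_size: all grey")
        return ModuleAssignment(
            pd.Series(GREY, index=features), pd.DataFrame(index=expr.columns),
            pd.Series(dtype=int),
        )
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    module_ids = [m for m in np.unique(labels) if (labels == m).sum() >= min_module_size]
    assign = {m: np.flatnonzero(labels == m).tolist() for m in module_ids}

    mat = expr.to_numpy(dtype=float)

    def eig_of(idx: list[int]) -> np.ndarray:
        return module_eigengene(mat[idx])

    # iterative eigengene merging
    while len(assign) > 1:
        ids = sorted(assign)
        eigs = {m: eig_of(assign[m]) for m in ids}
        best_pair, best_cor = None, -np.inf
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                c = float(np.corrcoef(eigs[ids[i]], eigs[ids[j]])[0, 1])
                if c > best_cor:
                    best_cor, best_pair = c, (ids[i], ids[j])
        if best_cor <= 1.0 - merge_cut_height:
            break
        a, b = best_pair
        assign[a] = assign[a] + assign[b]
        del assign[b]

    ordered = sorted(assign, key=lambda m: -len(assign[m]))
    colours = pd.Series(GREY, index=features, dtype=object)
    eig_cols = {}
    sizes = {}
    for rank, m in enumerate(ordered):
        colour = MODULE_COLOURS[rank % len(MODULE_COLOURS)]
        idx = assign[m]
        colours.iloc[idx] = colour
        eig_cols[colour] = eig_of(idx)
        sizes[colour] = len(idx)
    eigengenes = pd.DataFrame(eig_cols, index=expr.columns)
    return ModuleAssignment(colours, eigengenes, pd.Series(sizes, dtype=int))


def module_composition(
    assignment: ModuleAssignment, classes: pd.Series
) -> pd.DataFrame:
    """Counts and integer-rounded percentages of HERV vs gene per module."""
    rows = []
    for colour in assignment.colours.unique():
        members = assignment.colours.index[assignment.colours == colour]
        cls = classes.reindex(members)
        n_herv = int((cls == "herv").sum())
        n_gene = int((cls == "gene").sum())
        total = len(members)
        rows.append(
            {
                "module": colour,
                "n_features": total,
                "n_herv": n_herv,
                "n_gene": n_gene,
                "pct_herv": round(100.0 * n_herv / total) if total else 0,
                "pct_gene": round(100.0 * n_gene / total) if total else 0,
            }
        )
    return pd.DataFrame(rows).sort_values("n_features", ascending=False).reset_index(drop=True)


def go_enrich(
    modules: dict[str, list[str]],
    genesets: dict[str, list[str]],
    background: list[str],
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of module genes in each term.

    The background is the gene universe (HERV loci excluded by the caller);
    Bonferroni correction spans all module x term tests performed.
    enrichment_ratio = observed / expected overlap.
    """
    universe = set(background)
    if not universe:
        raise ValueError("empty background universe")
    rows = []
    for mod, members in modules.items():
        mem = set(members) & universe
        if not mem:
            continue
        for term, genes in genesets.items():
            tset = set(genes) & universe
            if not tset:
                continue
            overlap = len(mem & tset)
            # P(X >= overlap) under sampling len(mem) from the universe
            p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(tset), len(mem)))
            expected = len(tset) * len(mem) / len(universe)
            rows.append(
                {
                    "module": mod,
                    "term": term,
                    "overlap": overlap,
                    "module_size": len(mem),
                    "term_size": len(tset),
                    "p": min(p, 1.0),
                    "enrichment_ratio": overlap / expected if expected > 0 else 0.0,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["bonf_p"] = np.minimum(1.0, out["p"] * len(out))
    return out
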