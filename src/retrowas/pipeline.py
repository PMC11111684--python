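"""Configuration and the end-to-end pipeline driver.

The driver runs the full synthetic study: simulate a cohort (genotypes,
annotation, counts, GWAS summary statistics, fragment alignments), quantify
HERV fragments by EM, prepare expression, run genotype QC, build cis-SNP
weights, associate predicted expression with the trait, condition and
fine-map, and build the co-expression network.  Every stage writes its
tables under the output directory and contributes to a JSON run report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpress, expression_prep, genotype_qc, herv_quant, io, postprocess
from .cis_weights import WeightSet, HeritabilityEstimate, build_weights
from .containers import GenotypeMatrix
from .rtwas_assoc import report_fractions, run_rtwas
from .synthdata import (
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

logger = logging.getLogger(__name__)

STAGES = [
    "simulate",
    "quantify",
    "prep",
    "qc",
    "weights",
    "assoc",
    "postprocess",
    "coexpress",
    "report",
]


@dataclass
class RunConfig:
    """All tunable pipeline parameters with their defaults."""

    seed: int = 1
    out_dir: str = "results/pipeline"
    # cohort / genotypes: one LD block per chromosome
    n_samples: int = 200
    n_blocks: int = 20
    snps_per_block: int = 100
    ld_rho: float = 0.6
    maf_min: float = 0.05
    maf_max: float = 0.5
    # features and architecture
    n_genes: int = 80
    n_hervs: int = 40
    h2_cis: float = 0.2
    frac_cis: float = 0.6
    n_causal_min: int = 1
    n_causal_max: int = 3
    gene_mean_log_expr: float = 5.0
    herv_mean_log_expr: float = 2.5
    n_planted_modules: int = 2
    module_size: int = 40
    module_strength: float = 0.6
    # mediated trait architecture
    n_mediated: int = 1
    mediated_class: str = "herv"
    mediated_h2: float = 0.4
    mediated_alpha: float = 0.1
    n_gwas: int = 100_000
    # fragment simulation / EM quantification
    n_frags: int = 20_000
    homology_group_size: int = 3
    em_prior_strength: float = 1e-3
    em_score_scale: float = 20.0
    em_tol: float = 1e-6
    em_max_iter: int = 200
    count_mode: str = "best"
    # expression prep
    min_count: float = 6
    min_tpm: float = 0.1
    min_fraction: float = 0.2
    trim_M: float = 0.30
    trim_A: float = 0.05
    prior_count: float = 0.5
    n_pcs: int = 10
    n_surrogate: int | str = "auto"
    # genotype QC
    qc_maf_min: float = 0.05
    qc_hwe_p_min: float = 5e-6
    qc_miss_max: float = 0.05
    het_sd: float = 3.0
    pihat_max: float = 0.2
    sumstat_maf_min: float = 0.05
    sumstat_info_min: float = 0.80
    # weights
    window_bp: int = 500_000
    lrt_p_gate: float = 0.01
    k_folds: int = 5
    controls_only: bool = False
    # association
    ridge_eps: float = 0.1
    # postprocess
    merge_bp: int = 100_000
    finemap_prior_p: float = 1e-3
    finemap_v: float = 40.0
    max_causal: int = 3
    # coexpression
    beta: int = 12
    min_module_size: int = 30
    cut_height: float = 0.99
    merge_cut_height: float = 0.25

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _make_metadata(n: int, seed: int) -> pd.DataFrame:
    """Clinical/technical sample covariates mirroring a post-mortem cohort."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "institution": rng.choice(["MSSM", "Penn", "Pitt"], size=n),
            "diagnosis": rng.choice(["control", "case"], size=n),
            "rin": np.round(np.clip(rng.normal(7.6, 0.9, n), 4.5, 9.6), 2),
            "sex": rng.choice(["F", "M"], size=n, p=[0.37, 0.63]),
            "pmi": np.round(np.clip(rng.normal(22.5, 15.4, n), 1.4, 168.0), 1),
            "age_bin": rng.integers(1, 6, size=n),
        },
        index=[f"S{i:04d}" for i in range(n)],
    )


def write_weightsets(store: dict[str, WeightSet], out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    index_rows = []
    for fid, ws in store.items():
        payload = {
            "feature_id": ws.feature_id,
            "cls": ws.cls,
            "chrom": ws.chrom,
            "start": ws.start,
            "end": ws.end,
            "snps": ws.snps.to_dict(orient="list"),
            "weights": {m: list(map(float, w)) for m, w in ws.weights.items()},
            "cv_r2": {m: float(v) for m, v in ws.cv_r2.items()},
            "best_method": ws.best_method,
            "h2": dataclasses.asdict(ws.h2),
            "usable": bool(ws.usable),
        }
        (out_dir / f"{fid}.json").write_text(json.dumps(payload))
        index_rows.append(
            {
                "feature": fid,
                "cls": ws.cls,
                "h2": ws.h2.h2,
                "lrt_p": ws.h2.lrt_p,
                "best_method": ws.best_method,
                "cv_r2": ws.cv_r2[ws.best_method],
                "n_snps": int(np.sum(ws.best_weights != 0)),
            }
        )
    pd.DataFrame(index_rows).to_csv(out_dir / "index.tsv", sep="\t", index=False)


def read_weightsets(out_dir: Path) -> dict[str, WeightSet]:
    store = {}
    for path in sorted(Path(out_dir).glob("*.json")):
        d = json.loads(path.read_text())
        store[d["feature_id"]] = WeightSet(
            feature_id=d["feature_id"],
            snps=pd.DataFrame(d["snps"]),
            weights={m: np.array(w) for m, w in d["weights"].items()},
            cv_r2=d["cv_r2"],
            best_method=d["best_method"],
            h2=HeritabilityEstimate(**d["h2"]),
            usable=d["usable"],
            cls=d["cls"],
            chrom=d["chrom"],
            start=d["start"],
            end=d["end"],
        )
    return store


def pipeline_run(cfg: RunConfig, stages: list[str] | None = None) -> dict:
    """Execute the pipeline stages in order; returns the aggregated report."""
    stages = stages or STAGES
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": cfg.to_dict(), "stages": {}, "checksums": {}}
    ctx: dict = {}

    for stage in STAGES:
        if stage not in stages:
            continue
        logger.info("[%s] starting", stage)
        try:
            _STAGE_FUNCS[stage](cfg, out, ctx, report)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    for path in sorted(out.rglob("*.tsv")):
        report["checksums"][str(path.relative_to(out))] = _checksum(path)
    (out / "run_report.json").write_text(json.dumps(report, indent=1, default=str))
    return report


# -- stages ------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, out: Path, ctx: dict, report: dict) -> None:
    seed = cfg.seed
    blocks = [
        LDBlockSpec(
            n_snps=cfg.snps_per_block,
            maf_range=(cfg.maf_min, cfg.maf_max),
            rho=cfg.ld_rho,
            chrom=str(b + 1),
            start_bp=1,
        )
        for b in range(cfg.n_blocks)
    ]
    G = simulate_genotypes(cfg.n_samples, blocks, fanout_seed(seed, "genotypes"))
    ann, homology = make_annotation(
        blocks,
        cfg.n_genes,
        cfg.n_hervs,
        fanout_seed(seed, "annotation"),
        homology_group_size=cfg.homology_group_size,
    )
    meta = _make_metadata(cfg.n_samples, fanout_seed(seed, "annotation") + 1)

    rng = np.random.default_rng(fanout_seed(seed, "expression"))
    feat_names = ann["name"].tolist()
    module_spec = []
    pool = [f for f in feat_names]
    rng.shuffle(pool)
    for m in range(cfg.n_planted_modules):
        members = pool[m * cfg.module_size : (m + 1) * cfg.module_size]
        module_spec.append(
            {"name": f"planted{m}", "features": members, "strength": cfg.module_strength}
        )
    mediated_pool = ann.loc[ann["cls"] == cfg.mediated_class, "name"].tolist()
    mediated = list(rng.choice(mediated_pool, size=cfg.n_mediated, replace=False))
    arch = ExpressionArchitecture(
        h2_cis=cfg.h2_cis,
        n_causal=(cfg.n_causal_min, cfg.n_causal_max),
        mean_log_expression={"gene": cfg.gene_mean_log_expr, "herv": cfg.herv_mean_log_expr},
        frac_cis=cfg.frac_cis,
        module_spec=module_spec,
        covariate_effects={"rin": 0.3, "institution": 0.2},
        h2_overrides={f: cfg.mediated_h2 for f in mediated},
    )
    counts, truth, latent, _ = simulate_expression(
        G, ann, arch, fanout_seed(seed, "expression"),
        cis_window_bp=cfg.window_bp, covariates=meta,
    )
    alpha = {f: 0.0 for f in feat_names}
    for f in mediated:
        alpha[f] = cfg.mediated_alpha
    ss = simulate_gwas_sumstats(G, truth, alpha, cfg.n_gwas, fanout_seed(seed, "sumstats"))

    herv_names = ann.loc[ann["cls"] == "herv", "name"].tolist()
    pi_raw = rng.dirichlet(np.ones(len(herv_names)) * 2.0)
    pi_true = dict(zip(herv_names, pi_raw))
    for g in ann.loc[ann["cls"] == "gene", "name"]:
        pi_true[g] = 0.0
    herv_ann = ann[ann["cls"] == "herv"].reset_index(drop=True)
    aln, frag_truth = simulate_fragments(
        herv_ann, homology, {k: pi_true[k] for k in herv_names}, ScoreModel(),
        cfg.n_frags, fanout_seed(seed, "fragments"),
    )
    truth.fragments = frag_truth.fragments

    genesets = {}
    gs_rng = np.random.default_rng(fanout_seed(seed, "expression") + 7)
    gene_names = ann.loc[ann["cls"] == "gene", "name"].tolist()
    for m, spec in enumerate(module_spec):
        genes = [f for f in spec["features"] if f in gene_names]
        genesets[f"GO:planted{m}"] = genes
    for t in range(5):
        genesets[f"GO:random{t}"] = list(
            gs_rng.choice(gene_names, size=min(15, len(gene_names)), replace=False)
        )

    io.write_dosage_tsv(G, out / "genotypes.tsv")
    io.write_bed_annotation(ann, out / "annotation.bed")
    io.write_counts_tsv(counts, out / "counts.tsv")
    io.write_sumstats_tsv(ss, out / "sumstats.tsv")
    io.write_alignment_tsv(aln, out / "alignments.tsv")
    io.write_truth_json(truth, out / "truth.json")
    io.write_gmt(genesets, out / "genesets.gmt")
    meta.to_csv(out / "metadata.tsv", sep="\t", index_label="sample")
    pd.Series(pi_true).rename("pi").to_csv(out / "pi_true.tsv", sep="\t")

    ctx.update(
        G=G, ann=ann, counts=counts, truth=truth, ss=ss, aln=aln,
        meta=meta, mediated=mediated, pi_true=pi_true, genesets=genesets,
        latent=latent,
    )
    report["stages"]["simulate"] = {
        "n_samples": cfg.n_samples,
        "n_snps": G.n_variants,
        "n_features": len(ann),
        "n_hervs": int((ann["cls"] == "herv").sum()),
        "mediated": mediated,
        "seed": seed,
    }


def _stage_quantify(cfg: RunConfig, out: Path, ctx: dict, report: dict) -> None:
    aln = ctx["aln"]
    est = herv_quant.em_reassign(
        aln,
        prior_strength=cfg.em_prior_strength,
        score_scale=cfg.em_score_scale,
        tol=cfg.em_tol,
        max_iter=cfg.em_max_iter,
    )
    counts = herv_quant.assign_counts(est, mode=cfg.count_mode)
    pd.Series(counts).rename("count").to_csv(out / "em_counts.tsv", sep="\t")
    pi_hat = est.pi_series()
    pi_true = ctx["pi_true"]
    err = max(
        abs(pi_hat.get(f, 0.0) - p) for f, p in pi_true.items() if f in pi_hat
    )
    report["stages"]["quantify"] = {
        **herv_quant.run_report(est, aln),
        "max_pi_error_vs_truth": float(err),
    }
    ctx["em_est"] = est


def _stage_prep(cfg: RunConfig, out: Path, ctx: dict, report: dict) -> None:
    counts, ann, meta, G = ctx["counts"], ctx["ann"], ctx["meta"], ctx["G"]
    lengths = io.feature_lengths(ann)
    tpm = expression_prep.compute_tpm(counts, lengths)
    kept = expression_prep.filter_expressed(
        counts, tpm, cfg.min_count, cfg.min_tpm, cfg.min_fraction
    )
    factors = expression_prep.tmm_factors(counts.loc[kept], cfg.trim_M, cfg.trim_A)
    lcpm = expression_prep.logcpm(counts.loc[kept], factors, cfg.prior_count)
    pcs = expression_prep.genotype_pcs(G, k=cfg.n_pcs)
    covs = pd.concat([meta, pcs], axis=1)
    adjusted, sv = expression_prep.residualize(lcpm, covs, n_surrogate=cfg.n_surrogate)
    adjusted.to_csv(out / "adjusted_expression.tsv", sep="\t", index_label="feature")
    pd.DataFrame(
        {"factor": factors.factors, "library_size": counts.sum(axis=0)}
    ).to_csv(out / "normalization.tsv", sep="\t", index_label="sample")
    ctx.update(adjusted=adjusted, lcpm=lcpm, kept=kept, pcs=pcs, factors=factors)
    report["stages"]["prep"] = {
        "n_input_features": len(counts),
        "n_expressed": len(kept),
        "n_surrogate": sv.shape[1],
        "reference_sample": factors.reference_sample,
    }


def _stage_qc(cfg: RunConfig, out: Path, ctx: dict, report: dict) -> None:
    G, ss = ctx["G"], ctx["ss"]
    vmask = genotype_qc.variant_qc(
        G, cfg.qc_maf_min, cfg.qc_hwe_p_min, cfg.qc_miss_max, drop_ambiguous=True
    )
    Gq = G.subset_variants(vmask)
    kept_samples = genotype_qc.sample_qc(Gq, cfg.het_sd, cfg.qc_miss_max, cfg.pihat_max)
    Gq = Gq.subset_samples(kept_samples)
    ss_h, actions = genotype_qc.harmonize_sumstats(
        ss, Gq, cfg.sumstat_maf_min, cfg.sumstat_info_min
    )
    io.write_sumstats_tsv(ss_h, out / "sumstats_harmonized.tsv")
    ctx.update(Gq=Gq, ss_h=ss_h)
    report["stages"]["qc"] = {
        "n_variants_kept": int(vmask.sum()),
        "n_variants_total": G.n_variants,
        "n_samples_kept": len(kept_samples),
        "sumstat_actions": actions,
    }


def _stage_weights(cfg: RunConfig, out: Path, ctx: dict, report: dict) -> None:
    Gq, adjusted, ann, meta = ctx["Gq"], ctx["adjusted"], ctx["ann"], ctx["meta"]
    expr = adjusted.loc[:, [s for s in Gq.samples if s in adjusted.columns]]
    if cfg.controls_only:
        controls = meta.index[meta["diagnosis"] == "control"]
        cols = [s for s in expr.columns if s in set(controls)]
        expr = expr[cols]
        Gq = Gq.subset_samples(cols)
        logger.info("controls-only weights: %d samples", len(cols))
    else:
        Gq = Gq.subset_samples(list(expr.columns))
    store, log = build_weights(
        expr, ann, Gq,
        window_bp=cfg.window_bp, lrt_p_gate=cfg.lrt_p_gate,
        k_folds=cfg.k_folds, seed=cfg.seed,
    )
    write_weightsets(store, out / "weights")
    log.to_csv(out / "heritability.tsv", sep="\t", index=False)
    ctx.update(store=store, weights_log=log, G_weights=Gq)
    report["stages"]["weights"] = {
        "n_tested": len(log),
        "n_cis_heritable": int((log["status"] == "ok").sum()),
        "n_gated_out": int((log["status"] == "not_heritable").sum()),
        "controls_only": cfg.controls_only,
    }


def _stage_assoc(cfg: RunConfig, out: Path, ctx: dict, report: dict) -> None:
    res = run_rtwas(ctx["store"], ctx["ss_h"], ctx["G_weights"], ridge_eps=cfg.ridge_eps)
    res.to_csv(out / "twas_results.tsv", sep="\t", index=False)
    ctx["twas"] = res
    fr = report_fractions(res)
    report["stages"]["assoc"] = {
        "m_tested": res.attrs["m_tested"],
        "sig_threshold": res.attrs["sig_threshold"],
        **fr,
    }


def _stage_postprocess(cfg: RunConfig, out: Path, ctx: dict, report: dict) -> None:
    res, store, Gq, ss_h = ctx["twas"], ctx["store"], ctx["G_weights"], ctx["ss_h"]
    snp_ids = Gq.variants["snp"].tolist()
    R = Gq.ld_matrix(ridge_eps=cfg.ridge_eps)
    omega = postprocess.pred_expr_cor(store, R, snp_ids)
    loci = postprocess.define_loci(res, merge_bp=cfg.merge_bp)
    entry_p = res.attrs["sig_threshold"]
    z_map = dict(zip(res["feature"], res["z"]))
    joints, finemaps = [], []
    for locus in loci:
        jr = postprocess.joint_conditional(locus, z_map, omega, entry_p=entry_p)
        joints.append(jr)
        feats = [f for f in locus if f in omega.features]
        z_loc = np.array([z_map[f] for f in feats])
        fm = postprocess.finemap_pip(
            feats, z_loc, omega.sub(feats),
            prior_p=cfg.finemap_prior_p, v=cfg.finemap_v, max_causal=cfg.max_causal,
        )
        finemaps.append(fm)
    labels = postprocess.classify_high_confidence(res, joints, finemaps)
    labels.to_csv(out / "classified.tsv", sep="\t", index=False)
    joint_rows = [
        {"feature": f, "joint_z": jr.joint_z[f], "joint_p": jr.joint_p[f]}
        for jr in joints
        for f in jr.selected
    ]
    pd.DataFrame(joint_rows).to_csv(out / "joint.tsv", sep="\t", index=False)
    cond_rows = [
        {
            "feature": f,
            "conditional_z": jr.conditional_z[f],
            "conditional_p": jr.conditional_p[f],
            "selected": f in jr.selected,
        }
        for jr in joints
        for f in jr.conditional_z
    ]
    pd.DataFrame(cond_rows).to_csv(out / "conditional.tsv", sep="\t", index=False)
    fm_rows = [
        {"feature": f, "pip": fm.pip[f], "in_cred90": f in fm.credible_set}
        for fm in finemaps
        for f in fm.features
    ]
    pd.DataFrame(fm_rows).to_csv(out / "finemap.tsv", sep="\t", index=False)
    ctx.update(labels=labels, joints=joints, finemaps=finemaps, omega=omega)
    mediated = ctx.get("mediated", [])
    hc = labels.loc[labels["high_confidence"], "feature"].tolist()
    report["stages"]["postprocess"] = {
        "n_loci": len(loci),
        "n_joint_selected": sum(len(j.selected) for j in joints),
        "high_confidence": hc,
        "mediated_recovered": [f for f in mediated if f in hc],
    }


def _stage_coexpress(cfg: RunConfig, out: Path, ctx: dict, report: dict) -> None:
    lcpm, ann = ctx["lcpm"], ctx["ann"]
    corr = np.corrcoef(lcpm.to_numpy(dtype=float))
    A = coexpress.signed_adjacency(corr, cfg.beta)
    tom = coexpress.tom_similarity(A)
    ma = coexpress.detect_modules(
        tom, lcpm,
        min_module_size=cfg.min_module_size,
        cut_height=cfg.cut_height,
        merge_cut_height=cfg.merge_cut_height,
    )
    classes = ann.set_index("name")["cls"]
    comp = coexpress.module_composition(ma, classes)
    comp.to_csv(out / "module_composition.tsv", sep="\t", index=False)
    ma.colours.rename("module").to_csv(out / "modules.tsv", sep="\t", index_label="feature")
    ma.eigengenes.to_csv(out / "eigengenes.tsv", sep="\t", index_label="sample")
    gene_universe = [f for f in lcpm.index if classes.get(f) == "gene"]
    modules = {
        c: [f for f in ma.colours.index[ma.colours == c] if f in set(gene_universe)]
        for c in ma.sizes.index
    }
    enr = coexpress.go_enrich(modules, ctx["genesets"], gene_universe)
    enr.to_csv(out / "go_enrichment.tsv", sep="\t", index=False)
    ctx.update(module_assignment=ma, composition=comp, enrichment=enr)
    report["stages"]["coexpress"] = {
        "n_modules": int((comp["module"] != "grey").sum()),
        "largest_module": comp.iloc[0].to_dict() if len(comp) else {},
    }


def _stage_report(cfg: RunConfig, out: Path, ctx: dict, report: dict) -> None:
    summary = {
        stage: report["stages"].get(stage, {}) for stage in STAGES if stage != "report"
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=str))


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "quantify": _stage_quantify,
    "prep": _stage_prep,
    "qc": _stage_qc,
    "weights": _stage_weights,
    "assoc": _stage_assoc,
    "postprocess": _stage_postprocess,
    "coexpress": _stage_coexpress,
    "report": _stage_report,
}
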