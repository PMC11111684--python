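"""Readers and writers for the pipeline's on-disk formats.

Conventions: feature annotation is BED-derived, 0-based half-open; VCF and
summary-statistic positions are 1-based.  All tabular artefacts are TSV
(gzip-transparent through pandas); alignments round-trip both as SAM (AS
tag carries the alignment score) and as a simplified three-column TSV.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .containers import (
    ANNOTATION_COLUMNS,
    AlignmentSet,
    Fragment,
    GenotypeMatrix,
    TruthTable,
)

logger = logging.getLogger(__name__)


# -- genotypes ---------------------------------------------------------------

def write_dosage_tsv(G: GenotypeMatrix, path: str | Path) -> None:
    meta = G.variants.copy()
    dos = pd.DataFrame(G.dosages.T, columns=G.samples)
    pd.concat([meta.reset_index(drop=True), dos], axis=1).to_csv(
        path, sep="\t", index=False
    )


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    meta_cols = [c for c in df.columns if c in ("snp", "chrom", "pos", "a1", "a2", "block")]
    samples = [c for c in df.columns if c not in meta_cols]
    return GenotypeMatrix(
        dosages=df[samples].to_numpy(dtype=float).T,
        variants=df[meta_cols].astype({"chrom": str}),
        samples=samples,
    )


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Minimal GT-only VCF; REF = A2, ALT = A1, dosages count ALT copies."""
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = G.variants["chrom"].astype(str).unique()
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(G.samples) + "\n")
        for j, v in G.variants.iterrows():
            calls = [
                gt_of.get(d, "./.") if np.isfinite(d) else "./."
                for d in G.dosages[:, j]
            ]
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t{v['snp']}\t{v['a2']}\t{v['a1']}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_vcf_dosages(path: str | Path) -> tuple[GenotypeMatrix, int]:
    """GenotypeMatrix from a VCF (GT or DS); returns (matrix, n multi-allelic skipped)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta = [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        try:
            ds = v.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dos = ds[:, 0].astype(float)
        else:
            dos = np.empty(len(samples))
            for i, g in enumerate(v.genotypes):
                a, b = g[0], g[1]
                dos[i] = np.nan if (a < 0 or b < 0) else float(a + b)
        rows.append(dos)
        meta.append(
            {
                "snp": v.ID or f"{v.CHROM}:{v.POS}",
                "chrom": str(v.CHROM),
                "pos": int(v.POS),
                "a1": v.ALT[0],
                "a2": v.REF,
            }
        )
    if n_multi:
        logger.info("skipped %d multi-allelic records", n_multi)
    G = GenotypeMatrix(np.array(rows).T, pd.DataFrame(meta), samples)
    return G, n_multi


# -- annotation --------------------------------------------------------------

def write_bed_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_bed_annotation(path: str | Path) -> pd.DataFrame:
    """BED 6+ with name/class/family columns; sorted, 0-based half-open."""
    ann = pd.read_csv(
        path, sep="\t", header=None, names=ANNOTATION_COLUMNS, dtype={"chrom": str}
    )
    bad = ann.index[ann["start"] >= ann["end"]]
    if len(bad):
        raise ValueError(f"start >= end at line {int(bad[0]) + 1}")
    return ann.sort_values(["chrom", "start"]).reset_index(drop=True)


def feature_lengths(ann: pd.DataFrame) -> pd.Series:
    return pd.Series((ann["end"] - ann["start"]).to_numpy(), index=ann["name"].tolist())


# -- counts / expression -----------------------------------------------------

def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="feature")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="feature")
    df.index.name = None
    return df


# -- summary statistics ------------------------------------------------------

SUMSTAT_HEADER = ["SNP", "CHR", "BP", "A1", "A2", "Z", "N", "MAF", "INFO"]
_SUMSTAT_MAP = dict(zip(SUMSTAT_HEADER, ["snp", "chrom", "pos", "a1", "a2", "z", "n", "maf", "info"]))


def write_sumstats_tsv(ss: pd.DataFrame, path: str | Path) -> None:
    out = ss.rename(columns={v: k for k, v in _SUMSTAT_MAP.items()})
    cols = [c for c in SUMSTAT_HEADER if c in out.columns]
    out[cols].to_csv(path, sep="\t", index=False)


def read_sumstats_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns=_SUMSTAT_MAP)
    df["chrom"] = df["chrom"].astype(str)
    return df


# -- alignments --------------------------------------------------------------

def write_alignment_tsv(aln: AlignmentSet, path: str | Path) -> None:
    rows = [
        {"fragment_id": f.fragment_id, "feature_id": fid, "alignment_score": s}
        for f in aln.fragments
        for fid, s in zip(f.feature_ids, f.scores)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_alignment_tsv(path: str | Path, feature_index: list[str]) -> AlignmentSet:
    df = pd.read_csv(path, sep="\t")
    frags = []
    for fid, grp in df.groupby("fragment_id", sort=False):
        frags.append(
            Fragment(str(fid), grp["feature_id"].tolist(), grp["alignment_score"].tolist())
        )
    return AlignmentSet(frags, feature_index)


def write_sam(aln: AlignmentSet, ann: pd.DataFrame, path: str | Path) -> None:
    """One SAM record per candidate alignment; AS carries the score.

    The best-scoring candidate of each fragment is primary; the rest are
    marked secondary (flag 256).
    """
    lengths = dict(zip(ann["name"], ann["end"] - ann["start"]))
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [
            {"SN": f, "LN": int(max(lengths.get(f, 1000), 1))}
            for f in aln.feature_index
        ],
    }
    tid = {f: i for i, f in enumerate(aln.feature_index)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for frag in aln.fragments:
            best = int(np.argmax(frag.scores))
            for k, (fid, score) in enumerate(zip(frag.feature_ids, frag.scores)):
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = frag.fragment_id
                rec.flag = 0 if k == best else 256
                rec.reference_id = tid[fid]
                rec.reference_start = 0
                rec.cigarstring = "1M"  # minimal mapped placeholder
                rec.mapping_quality = 255 if len(frag.feature_ids) == 1 else 0
                rec.set_tag("AS", int(round(score)))
                out.write(rec)


def read_sam(path: str | Path) -> AlignmentSet:
    """AlignmentSet from SAM; candidates grouped by QNAME, score from AS."""
    by_frag: dict[str, Fragment] = {}
    order: list[str] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        feature_index = list(fh.references)
        for rec in fh:
            if rec.is_unmapped:
                continue
            q = rec.query_name
            if q not in by_frag:
                by_frag[q] = Fragment(q, [], [])
                order.append(q)
            by_frag[q].feature_ids.append(rec.reference_name)
            by_frag[q].scores.append(float(rec.get_tag("AS")))
    return AlignmentSet([by_frag[q] for q in order], feature_index)


# -- truth / misc ------------------------------------------------------------

def write_truth_json(truth: TruthTable, path: str | Path) -> None:
    payload = {
        "features": truth.features.to_dict(orient="records"),
        "fragments": truth.fragments.to_dict(orient="records"),
        "modules": truth.modules,
    }
    Path(path).write_text(json.dumps(payload, indent=1, default=float))


def read_truth_json(path: str | Path) -> TruthTable:
    payload = json.loads(Path(path).read_text())
    return TruthTable(
        features=pd.DataFrame(payload["features"]),
        fragments=pd.DataFrame(payload["fragments"]),
        modules=payload["modules"],
    )


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        sets[parts[0]] = parts[2:]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, genes in sets.items():
            fh.write("\t".join([term, "na"] + list(genes)) + "\n")
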