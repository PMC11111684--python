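"""Core in-memory containers shared across pipeline stages.

The pipeline moves four kinds of data around: genotype dosages with variant
metadata, feature annotation (genes and HERV proviruses on a common
coordinate system), candidate fragment alignments for the quantification
stage, and GWAS summary statistics.  DataFrame-backed containers keep the
I/O layer thin and let every stage use plain numpy for the numerics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: columns every variant-metadata table carries, in order
VARIANT_COLUMNS = ["snp", "chrom", "pos", "a1", "a2"]

#: columns of a feature annotation table (BED-derived; 0-based half-open)
ANNOTATION_COLUMNS = ["chrom", "start", "end", "name", "cls", "family", "strand"]

#: GWAS summary-statistic columns; MAF and INFO are optional
SUMSTAT_COLUMNS = ["snp", "chrom", "pos", "a1", "a2", "z", "n"]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def is_strand_ambiguous(a1: str, a2: str) -> bool:
    """A/T and C/G pairs cannot be oriented across strands."""
    return COMPLEMENT.get(a1.upper()) == a2.upper()


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with variant metadata.

    Dosages count copies of the A1 allele and live in {0, 1, 2}; missing
    genotypes are ``nan``.  ``variants`` is a DataFrame with columns
    ``snp, chrom, pos, a1, a2`` aligned to the dosage columns.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError(
                f"{self.dosages.shape[1]} dosage columns but "
                f"{len(self.variants)} variant rows"
            )
        if self.dosages.shape[0] != len(self.samples):
            raise ValueError("sample list does not match dosage rows")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per variant, ignoring missing entries."""
        freq = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def allele_freq(self) -> np.ndarray:
        """A1 allele frequency per variant (not folded)."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def missing_rate(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosages), axis=0)

    def standardized(self, freq: np.ndarray | None = None) -> np.ndarray:
        """Dosages centred at 2p and scaled by sqrt(2p(1-p)); nan -> 0."""
        if freq is None:
            freq = self.allele_freq()
        scale = np.sqrt(2.0 * freq * (1.0 - freq))
        scale = np.where(scale > 0, scale, 1.0)
        x = (self.dosages - 2.0 * freq) / scale
        return np.nan_to_num(x, nan=0.0)

    def subset_variants(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            variants=self.variants.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
        )

    def subset_samples(self, keep: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in keep]
        return GenotypeMatrix(
            dosages=self.dosages[idx, :],
            variants=self.variants.copy(),
            samples=list(keep),
        )

    def ld_matrix(self, ridge_eps: float = 0.0) -> np.ndarray:
        """SNP x SNP correlation matrix, optionally ridge-stabilised.

        With ``ridge_eps`` > 0 the matrix is shrunk as (R + eps*I)/(1+eps),
        which preserves the unit diagonal and guarantees positive
        definiteness.
        """
        x = self.standardized()
        sd = x.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        x = (x - x.mean(axis=0)) / sd
        r = (x.T @ x) / x.shape[0]
        np.fill_diagonal(r, 1.0)
        r = np.clip(r, -1.0, 1.0)
        if ridge_eps > 0:
            r = (r + ridge_eps * np.eye(r.shape[0])) / (1.0 + ridge_eps)
        return r


@dataclass
class Fragment:
    """One sequenced fragment with its candidate alignments."""

    fragment_id: str
    feature_ids: list[str]
    scores: list[float]


@dataclass
class AlignmentSet:
    """Candidate alignments per fragment over an ordered feature index.

    ``feature_index`` lists the K real features; a reserved no-feature slot
    is appended by the EM engine itself, so it never appears here.
    """

    fragments: list[Fragment]
    feature_index: list[str]

    def __post_init__(self) -> None:
        for frag in self.fragments:
            if len(frag.feature_ids) == 0:
                raise ValueError(f"fragment {frag.fragment_id} has no candidates")
            if not all(np.isfinite(frag.scores)):
                raise ValueError(f"fragment {frag.fragment_id} has non-finite score")

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    def n_ambiguous(self) -> int:
        return sum(1 for f in self.fragments if len(f.feature_ids) > 1)


@dataclass
class TruthTable:
    """Ground truth recorded by the synthetic-data generators.

    features : per-feature causal SNP ids, effects, true cis-h2 and
        trait-mediation effect alpha.
    fragments : per-fragment true source feature.
    modules : planted co-expression module membership.
    """

    features: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["feature", "causal_snps", "causal_effects", "h2_cis", "alpha"]
        )
    )
    fragments: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["fragment_id", "source"])
    )
    modules: dict[str, list[str]] = field(default_factory=dict)

    def causal_map(self) -> dict[str, list[str]]:
        return dict(zip(self.features["feature"], self.features["causal_snps"]))
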