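"""Genomic relatedness matrices with SNP weighting schemes, genotype PCA,
and covariate similarity.

The GRM entry for subjects j, k is a weighted average of products of
centered, variance-standardized dosages,

    A_jk = sum_i w_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)) / sum_i w_i,

with p_i the sample allele frequency. The 1/(2p(1-p)) factor is the
standard inverse-variance weight that up-weights rarer alleles; w_i = 1 for
every SNP gives the standard GRM. Functional-priority schemes replace w_i:
W1 uses the total priority score, W2 the regulatory-evidence component
only, and NZW ("non-zero weight") drops SNPs with zero W1 weight and
reverts to standard inverse-variance weights on the retained subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix

SCHEMES = ("standard", "W1", "W2", "NZW")


@dataclass
class SNPWeightVector:
    snp_ids: list[str]
    weights: np.ndarray
    scheme: str

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.snp_ids) != self.weights.size:
            raise ValueError("weights not aligned with SNP ids")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if not np.any(self.weights > 0):
            raise ValueError("at least one weight must be positive")


@dataclass
class KinshipMatrix:
    subject_ids: list[str]
    values: np.ndarray
    n_snps_used: int
    scheme: str = "standard"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.subject_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def write_text(self, path: str | Path) -> None:
        """Lower-triangle TSV: id1, id2, n_snps, value."""
        with open(path, "w") as fh:
            for j in range(self.n_subjects):
                for k in range(j + 1):
                    fh.write(
                        f"{self.subject_ids[j]}\t{self.subject_ids[k]}\t"
                        f"{self.n_snps_used}\t{self.values[j, k]:.10g}\n"
                    )


def read_kinship_text(path: str | Path) -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["id1", "id2", "n_snps", "value"], dtype={0: str, 1: str})
    ids = list(dict.fromkeys(df["id1"]))
    pos = {s: i for i, s in enumerate(ids)}
    n = len(ids)
    vals = np.zeros((n, n))
    for r in df.itertuples():
        j, k = pos[r.id1], pos[r.id2]
        vals[j, k] = vals[k, j] = r.value
    return KinshipMatrix(ids, vals, int(df["n_snps"].iloc[0]))


def standard_weights(g: GenotypeMatrix) -> SNPWeightVector:
    return SNPWeightVector(g.snp_ids, np.ones(g.n_snps), "standard")


def compute_grm(
    g: GenotypeMatrix,
    w: SNPWeightVector | None = None,
    allele_freqs: np.ndarray | None = None,
    standardize: bool = True,
) -> KinshipMatrix:
    """Weighted GRM over fully imputed genotypes.

    ``allele_freqs`` overrides the centering/scaling frequencies (e.g. a
    strict no-leakage mode recomputing p on training subjects only);
    by default the sample frequencies of ``g`` are used.
    ``standardize=False`` drops the inverse-variance factor so the supplied
    weights fully replace it (weights applied to raw centered dosages).
    """
    d = g.dosages
    if np.isnan(d).any():
        raise ValueError("genotypes contain missing values; impute first")
    if w is None:
        w = standard_weights(g)
    if w.snp_ids != g.snp_ids:
        raise ValueError("weight vector not aligned with genotype SNPs")
    p = g.allele_freqs() if allele_freqs is None else np.asarray(allele_freqs, float)
    var = 2 * p * (1 - p)
    active = w.weights > 0
    if standardize and np.any(active & (var == 0)):
        raise ValueError(
            "monomorphic SNP with non-zero weight; apply MAF QC before the GRM"
        )
    centered = d - 2 * p[None, :]
    if standardize:
        scale = np.where(var > 0, np.sqrt(var), 1.0)
        z = centered / scale[None, :]
    else:
        z = centered
    zw = z * np.sqrt(w.weights)[None, :]
    a = (zw @ zw.T) / w.weights.sum()
    a = (a + a.T) / 2.0
    return KinshipMatrix(list(g.subject_ids), a, int(active.sum()), w.scheme)


# ---------------------------------------------------------------------------
# Priority-score weighting schemes
# ---------------------------------------------------------------------------

def _aligned_scores(scores: pd.DataFrame, snp_ids: Sequence[str]) -> pd.DataFrame:
    s = scores.set_index("snp_id") if "snp_id" in scores.columns else scores
    missing = set(snp_ids) - set(s.index)
    if missing:
        raise ValueError(f"priority scores missing for {len(missing)} SNPs")
    return s.loc[list(snp_ids)]


def apply_scheme_w1(scores: pd.DataFrame, snp_ids: Sequence[str]) -> SNPWeightVector:
    """Weight each SNP by its total functional priority score (zeros kept)."""
    s = _aligned_scores(scores, snp_ids)
    wts = s["total_score"].to_numpy(float)
    if not np.any(wts > 0):
        raise ValueError("all priority scores are zero; W1 undefined")
    return SNPWeightVector(list(snp_ids), wts, "W1")


def apply_scheme_w2(scores: pd.DataFrame, snp_ids: Sequence[str]) -> SNPWeightVector:
    """Weight by the regulatory-evidence component only (no MAF component)."""
    s = _aligned_scores(scores, snp_ids)
    wts = s["regulatory_component"].to_numpy(float)
    if not np.any(wts > 0):
        raise ValueError("all regulatory components are zero; W2 undefined")
    return SNPWeightVector(list(snp_ids), wts, "W2")


def apply_scheme_nzw(
    scores: pd.DataFrame, g: GenotypeMatrix
) -> tuple[GenotypeMatrix, SNPWeightVector]:
    """Drop SNPs with zero total score; standard weights on the subset."""
    s = _aligned_scores(scores, g.snp_ids)
    keep = s["total_score"].to_numpy(float) > 0
    if not keep.any():
        raise ValueError("NZW subset is empty")
    sub = g.subset_snps(keep)
    return sub, SNPWeightVector(sub.snp_ids, np.ones(sub.n_snps), "NZW")


def grm_for_scheme(
    g: GenotypeMatrix, scheme: str, scores: pd.DataFrame | None = None
) -> KinshipMatrix:
    """Dispatch: standard/W1/W2/NZW -> KinshipMatrix."""
    if scheme == "standard":
        return compute_grm(g)
    if scores is None:
        raise ValueError(f"scheme {scheme} requires priority scores")
    if scheme == "W1":
        return compute_grm(g, apply_scheme_w1(scores, g.snp_ids))
    if scheme == "W2":
        return compute_grm(g, apply_scheme_w2(scores, g.snp_ids))
    if scheme == "NZW":
        sub, w = apply_scheme_nzw(scores, g)
        k = compute_grm(sub, w)
        k.scheme = "NZW"
        return k
    raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")


# ---------------------------------------------------------------------------
# PCA and covariate similarity
# ---------------------------------------------------------------------------

def genotype_pca(k: KinshipMatrix, n_components: int = 6) -> pd.DataFrame:
    """Principal components of the (double-centered) kinship matrix.

    Eigenvectors sorted by descending eigenvalue and scaled by
    sqrt(eigenvalue); the conventional population-structure axes.
    """
    n = k.n_subjects
    if n_components > n - 1:
        raise ValueError(f"n_components={n_components} exceeds n-1={n - 1}")
    a = k.values
    j = np.eye(n) - np.ones((n, n)) / n
    ac = j @ a @ j
    vals, vecs = np.linalg.eigh((ac + ac.T) / 2)
    order = np.argsort(vals)[::-1][:n_components]
    comps = vecs[:, order] * np.sqrt(np.clip(vals[order], 0, None))
    return pd.DataFrame(
        comps,
        index=pd.Index(k.subject_ids, name="subject_id"),
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )


def encode_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """One-hot encode non-numeric columns; numeric columns pass through."""
    return pd.get_dummies(covariates, dtype=float)


def covariate_similarity(covariates: pd.DataFrame) -> KinshipMatrix:
    """Subject-by-subject similarity from standardized covariates.

    Columns are one-hot encoded (categoricals), standardized to zero mean
    and unit variance, and averaged cross-products form the similarity —
    the same algebra as the GRM with unit weights. Zero-variance columns
    are dropped with a warning; missing values must be imputed first.
    """
    x = encode_covariates(covariates)
    if x.isna().any().any():
        raise ValueError("covariates contain missing values; impute first")
    arr = x.to_numpy(float)
    sd = arr.std(axis=0)
    if np.any(sd == 0):
        dropped = [c for c, s in zip(x.columns, sd) if s == 0]
        warnings.warn(f"dropping zero-variance covariate columns: {dropped}")
        arr = arr[:, sd > 0]
        sd = sd[sd > 0]
    if arr.shape[1] == 0:
        raise ValueError("no informative covariate columns")
    z = (arr - arr.mean(axis=0)) / sd
    a = z @ z.T / z.shape[1]
    return KinshipMatrix(
        list(covariates.index.astype(str)), (a + a.T) / 2, z.shape[1], "covariate"
    )


def combine_similarity(
    matrices: Sequence[KinshipMatrix], mixing: Sequence[float]
) -> KinshipMatrix:
    """Entrywise convex combination of similarity matrices."""
    if len(matrices) != len(mixing):
        raise ValueError("one mixing weight per matrix required")
    mix = np.asarray(mixing, dtype=float)
    if np.any(mix < 0):
        raise ValueError("mixing weights must be non-negative")
    if abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError(f"mixing weights must sum to 1, got {mix.sum()}")
    ids = matrices[0].subject_ids
    for m in matrices[1:]:
        if m.subject_ids != ids:
            raise ValueError("subject ids differ across matrices")
    vals = sum(c * m.values for c, m in zip(mix, matrices))
    scheme = "+".join(f"{m.scheme}:{c:g}" for m, c in zip(matrices, mix))
    return KinshipMatrix(ids, vals, max(m.n_snps_used for m in matrices), scheme)
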