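"""Genotype containers, PLINK bed/bim/fam and text-dosage I/O, and QC filters.

Dosages count copies of the minor allele (0, 1, 2) and are held as a dense
float matrix with NaN marking missing genotypes, the layout every downstream
stage (GRM construction, REML, prediction) consumes directly.

The quality-control filters mirror a standard single-cohort GWAS cleaning:
restrict to autosomes, drop SNPs with minor allele frequency below 0.05, and
drop SNPs whose Hardy-Weinberg goodness-of-fit p-value falls below 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

AUTOSOMES = {str(c) for c in range(1, 23)}
ALLOWED_CHROMS = AUTOSOMES | {"X", "Y", "MT"}

# PLINK 1 .bed header: magic bytes then 0x01 for SNP-major layout.
_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit genotype codes (SNP-major): 00=hom A1 (minor), 01=missing,
# 10=het, 11=hom A2 (major). Mapped to minor-allele dosage.
_BED_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


@dataclass(frozen=True)
class SNPRecord:
    """Metadata for one SNP; chromosome is a label in 1-22/X/Y/MT."""

    snp_id: str
    chromosome: str
    position: int
    allele_minor: str = "A"
    allele_major: str = "G"

    def __post_init__(self) -> None:
        if str(self.chromosome) not in ALLOWED_CHROMS:
            raise ValueError(
                f"chromosome {self.chromosome!r} not in 1-22/X/Y/MT for {self.snp_id}"
            )


class GenotypeMatrix:
    """n subjects x m SNPs of minor-allele dosages {0, 1, 2, NaN}."""

    def __init__(
        self,
        subject_ids: Sequence[str],
        snps: Sequence[SNPRecord],
        dosages: np.ndarray,
    ) -> None:
        subject_ids = [str(s) for s in subject_ids]
        snps = list(snps)
        dosages = np.asarray(dosages, dtype=float)
        if dosages.shape != (len(subject_ids), len(snps)):
            raise ValueError(
                f"dosage shape {dosages.shape} != (n_subjects={len(subject_ids)}, "
                f"n_snps={len(snps)})"
            )
        if len(set(subject_ids)) != len(subject_ids):
            raise ValueError("duplicate subject ids")
        ids = [s.snp_id for s in snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP ids")
        valid = np.isnan(dosages) | np.isin(dosages, (0.0, 1.0, 2.0))
        # imputed matrices carry fractional dosages; only raw matrices enforce codes
        self._codes_ok = bool(valid.all())
        self.subject_ids = subject_ids
        self.snps = snps
        self.dosages = dosages

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def allele_freqs(self) -> np.ndarray:
        """Per-SNP minor-allele frequency over non-missing dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            self.subject_ids,
            [self.snps[i] for i in keep],
            self.dosages[:, keep],
        )

    def subset_subjects(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            [self.subject_ids[i] for i in keep], self.snps, self.dosages[keep]
        )


@dataclass
class QCReport:
    """Bookkeeping for sequentially applied SNP filters (order recorded)."""

    n_input_snps: int
    filter_order: list[str] = field(default_factory=list)
    removed: dict[str, list[str]] = field(default_factory=dict)
    n_pass: dict[str, int] = field(default_factory=dict)
    n_final: int = 0

    def record(self, name: str, removed_ids: list[str], n_remaining: int) -> None:
        self.filter_order.append(name)
        self.removed[name] = removed_ids
        self.n_pass[name] = n_remaining
        self.n_final = n_remaining

    def to_dict(self) -> dict:
        return {
            "n_input_snps": self.n_input_snps,
            "filter_order": self.filter_order,
            "n_removed": {k: len(v) for k, v in self.removed.items()},
            "n_pass": self.n_pass,
            "n_final": self.n_final,
        }


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------

def write_plink(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write PLINK 1 bed (SNP-major) / bim / fam triple."""
    prefix = Path(prefix)
    n = g.n_subjects
    dosage_to_code = {2.0: 0, 1.0: 2, 0.0: 3}  # NaN -> 1 (missing)
    n_bytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        buf = np.empty(n_bytes, dtype=np.uint8)
        for j in range(g.n_snps):
            col = g.dosages[:, j]
            codes = np.fromiter(
                (1 if np.isnan(d) else dosage_to_code[d] for d in col),
                dtype=np.uint8,
                count=n,
            )
            padded = np.zeros(n_bytes * 4, dtype=np.uint8)
            padded[:n] = codes
            packed = (
                padded[0::4]
                | (padded[1::4] << 2)
                | (padded[2::4] << 4)
                | (padded[3::4] << 6)
            )
            buf[:] = packed
            fh.write(buf.tobytes())
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for s in g.snps:
            fh.write(
                f"{s.chromosome}\t{s.snp_id}\t0\t{s.position}\t"
                f"{s.allele_minor}\t{s.allele_major}\n"
            )
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid in g.subject_ids:
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t-9\n")


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK 1 bed/bim/fam triple into a GenotypeMatrix.

    Dosages are oriented as counts of the bim A1 (minor) allele; the PLINK
    missing code maps to NaN. The bed must be SNP-major v1.00.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        usecols=[0, 1],
        names=["fid", "iid"],
        dtype=str,
    )
    n, m = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(
            f"{prefix}.bed: bad magic/mode bytes {raw[:3].hex()} "
            f"(expected 6c1b01, SNP-major v1.00)"
        )
    n_bytes = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != n_bytes * m:
        raise ValueError(
            f"{prefix}.bed: {body.size} data bytes, expected {n_bytes * m} "
            f"for {n} subjects x {m} SNPs"
        )
    body = body.reshape(m, n_bytes)
    # unpack 2-bit codes, subject index runs low bits first within each byte
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = body & 0x03
    codes[:, 1::4] = (body >> 2) & 0x03
    codes[:, 2::4] = (body >> 4) & 0x03
    codes[:, 3::4] = (body >> 6) & 0x03
    dosages = _BED_CODE_TO_DOSAGE[codes[:, :n]].T
    snps = [
        SNPRecord(r.snp_id, str(r.chrom), int(r.pos), r.a1, r.a2)
        for r in bim.itertuples()
    ]
    return GenotypeMatrix(list(fam["iid"]), snps, dosages)


# ---------------------------------------------------------------------------
# Plain-text dosage dialect (fixture-friendly)
# ---------------------------------------------------------------------------

def write_dosage_text(g: GenotypeMatrix, path: str | Path) -> None:
    """Header row of SNP ids, one row per subject, values 0/1/2/NA."""
    df = pd.DataFrame(g.dosages, index=g.subject_ids, columns=g.snp_ids)
    df.index.name = "subject_id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%g")


def read_dosage_text(
    path: str | Path, snp_meta: Sequence[SNPRecord] | None = None
) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if snp_meta is None:
        snp_meta = [
            SNPRecord(c, "1", i + 1) for i, c in enumerate(df.columns)
        ]
    return GenotypeMatrix(list(df.index.astype(str)), snp_meta, df.to_numpy(float))


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

def autosome_filter(
    g: GenotypeMatrix, report: QCReport | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Retain SNPs on chromosomes 1-22 only."""
    report = report or QCReport(n_input_snps=g.n_snps)
    keep = np.array([s.chromosome in AUTOSOMES for s in g.snps])
    removed = [s.snp_id for s, k in zip(g.snps, keep) if not k]
    out = g.subset_snps(keep)
    report.record("autosome", removed, out.n_snps)
    return out, report


def maf_filter(
    g: GenotypeMatrix, threshold: float = 0.05, report: QCReport | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove SNPs with minor allele frequency below ``threshold``.

    MAF is folded (min(p, 1-p)) and computed from non-missing dosages over
    the whole cohort.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError(f"MAF threshold must be in [0, 0.5], got {threshold}")
    report = report or QCReport(n_input_snps=g.n_snps)
    freqs = g.allele_freqs()
    maf = np.minimum(freqs, 1.0 - freqs)
    keep = maf >= threshold
    if not keep.any():
        raise ValueError("MAF filter removed every SNP")
    removed = [s.snp_id for s, k in zip(g.snps, keep) if not k]
    out = g.subset_snps(keep)
    report.record("maf", removed, out.n_snps)
    return out, report


def hwe_test(g: GenotypeMatrix, method: str = "chisq") -> np.ndarray:
    """Per-SNP Hardy-Weinberg equilibrium p-values.

    ``chisq``: 1-df goodness-of-fit of observed genotype counts against
    expectations from the sample allele frequency. ``exact``: the standard
    conditional exact test summing probabilities of heterozygote counts no
    more probable than the observed one. Monomorphic SNPs return p = 1.
    """
    d = g.dosages
    n2 = np.nansum(d == 2.0, axis=0).astype(float)  # hom minor
    n1 = np.nansum(d == 1.0, axis=0).astype(float)  # het
    n0 = np.nansum(d == 0.0, axis=0).astype(float)  # hom major
    n = n0 + n1 + n2
    if (n == 0).any():
        raise ValueError("SNP with no non-missing genotypes")
    p = (2 * n2 + n1) / (2 * n)
    if method == "chisq":
        q = 1.0 - p
        exp = np.stack([n * q * q, 2 * n * p * q, n * p * p])
        obs = np.stack([n0, n1, n2])
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = np.nansum(
                np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0), axis=0
            )
        pvals = stats.chi2.sf(chi2, df=1)
        pvals[(p == 0) | (p == 1)] = 1.0
        return pvals
    if method == "exact":
        return np.array(
            [_hwe_exact(int(a), int(b), int(c)) for a, b, c in zip(n0, n1, n2)]
        )
    raise ValueError(f"unknown HWE method {method!r}")


def _hwe_exact(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact HWE p-value conditional on allele counts (sum of outcomes
    no more probable than observed)."""
    n = n_hom_major + n_het + n_hom_minor
    n_minor = 2 * n_hom_minor + n_het
    n_minor = min(n_minor, 2 * n - n_minor)
    if n == 0 or n_minor == 0:
        return 1.0
    obs_het = n_het
    # log-probability of each feasible heterozygote count (parity fixed)
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    from scipy.special import gammaln

    hom_min = (n_minor - hets) // 2
    hom_maj = n - hets - hom_min
    logp = (
        hets * np.log(2)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(hom_min + 1)
        - gammaln(hom_maj + 1)
        + gammaln(n_minor + 1)
        + gammaln(2 * n - n_minor + 1)
        - gammaln(2 * n + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    p_obs = prob[hets == obs_het]
    if p_obs.size == 0:  # inconsistent counts; treat as non-significant
        return 1.0
    return float(prob[prob <= p_obs[0] * (1 + 1e-12)].sum())


def hwe_filter(
    g: GenotypeMatrix,
    threshold: float = 0.001,
    method: str = "chisq",
    report: QCReport | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove SNPs whose HWE p-value falls below ``threshold``."""
    report = report or QCReport(n_input_snps=g.n_snps)
    pvals = hwe_test(g, method=method)
    keep = pvals >= threshold
    if not keep.any():
        raise ValueError("HWE filter removed every SNP")
    removed = [s.snp_id for s, k in zip(g.snps, keep) if not k]
    out = g.subset_snps(keep)
    report.record("hwe", removed, out.n_snps)
    return out, report


def qc_pipeline(
    g: GenotypeMatrix,
    maf_threshold: float = 0.05,
    hwe_threshold: float = 0.001,
    hwe_method: str = "chisq",
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the full filter chain in fixed order: autosome -> MAF -> HWE."""
    report = QCReport(n_input_snps=g.n_snps)
    g, report = autosome_filter(g, report)
    g, report = maf_filter(g, maf_threshold, report)
    g, report = hwe_filter(g, hwe_threshold, hwe_method, report)
    return g, report


def mean_impute_genotypes(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages with the SNP's mean dosage (kept continuous)."""
    d = g.dosages
    if not np.isnan(d).any():
        return g
    n_obs = np.sum(~np.isnan(d), axis=0)
    if (n_obs == 0).any():
        bad = [s.snp_id for s, k in zip(g.snps, n_obs == 0) if k]
        raise ValueError(f"SNP(s) with all dosages missing: {bad[:5]}")
    col_means = np.nanmean(d, axis=0)
    filled = np.where(np.isnan(d), col_means[None, :], d)
    return GenotypeMatrix(g.subject_ids, g.snps, filled)
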