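"""Synthetic cohort generator with known ground truth.

Emulates the study design of a pediatric asthma cohort of ~832 unrelated
subjects genotyped genome-wide: HWE genotypes over a configurable MAF
spectrum, an additive polygenic trait with specified narrow-sense
heritability, per-SNP functional priority scores in [0, ~0.12] with a
configurable zero-score mass and enrichment at causal SNPs, demographic
covariates, missingness, and longitudinal percent-predicted FEV1
trajectories realizing the normal-growth / reduced-growth / early-decline
patterns. Every quantity a downstream stage estimates (h2, causal set,
breeding values, pattern labels) is returned as ground truth, so parameter
recovery is directly testable.

All randomness flows from the single seed in ``SimConfig``; identical
configs produce bitwise-identical outputs.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, SNPRecord
from .phenotypes import dichotomize_about_mean, fev1_percentile_rank

# zero-score mass matching the observed retention geometry of the functional
# prioritization score (259,156 of 455,481 SNPs carried non-zero weight)
DEFAULT_ZERO_SCORE_FRACTION = 1.0 - 259156 / 455481
SCORE_CAP = 0.12

# marginal frequencies of the four base lung-function patterns (remainder
# unclassifiable), matching the cohort the generator emulates
DEFAULT_PATTERN_PROPORTIONS = {
    "NG": 0.2656,
    "NG-ED": 0.2055,
    "RG": 0.2668,
    "RG-ED": 0.2127,
}

BASE_PATTERNS = ("NG", "NG-ED", "RG", "RG-ED")


@dataclass(frozen=True)
class CovariateSpec:
    """One simulated demographic covariate.

    kind: 'normal' (params = mean, sd), 'binary' (params = prevalence) or
    'categorical' (params = tuple of level probabilities). ``effect`` is the
    additive contribution of the standardized covariate to the trait.
    """

    name: str
    kind: str
    effect: float = 0.0
    params: tuple = ()


def default_covariate_spec() -> tuple[CovariateSpec, ...]:
    """Age/sex/treatment/height/BMI/vitamin-D/race mix of a school-age
    asthma trial cohort."""
    return (
        CovariateSpec("age", "normal", 0.0, (8.95, 2.13)),
        CovariateSpec("age_at_diagnosis", "normal", 0.0, (3.08, 2.44)),
        CovariateSpec("sex_male", "binary", 0.0, (0.607,)),
        CovariateSpec("treatment_steroid", "binary", 0.0, (0.303,)),
        CovariateSpec("height_cm", "normal", 0.0, (133.8, 13.82)),
        CovariateSpec("bmi", "normal", 0.0, (18.22, 3.41)),
        CovariateSpec("vitamin_d", "normal", 0.0, (37.81, 15.60)),
        CovariateSpec("race", "categorical", 0.0, (0.726, 0.083, 0.115, 0.076)),
    )


@dataclass
class SimConfig:
    n_subjects: int = 832
    n_snps: int = 5000
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_true: float = 0.5
    causal_fraction: float = 0.05
    priority_informativeness: float = 4.0
    zero_score_fraction: float = DEFAULT_ZERO_SCORE_FRACTION
    covariate_spec: tuple[CovariateSpec, ...] = field(
        default_factory=default_covariate_spec
    )
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must be within (0, 0.5], got {self.maf_range}")
        if not 0.0 <= self.h2_true <= 1.0:
            raise ValueError(f"h2_true must be in [0,1], got {self.h2_true}")
        if not 0.0 < self.causal_fraction <= 1.0:
            raise ValueError(
                f"causal_fraction must be in (0,1], got {self.causal_fraction}"
            )
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"missing_rate must be in [0,1), got {self.missing_rate}")
        if not 0.0 <= self.zero_score_fraction < 1.0:
            raise ValueError("zero_score_fraction must be in [0,1)")
        if self.priority_informativeness < 0:
            raise ValueError("priority_informativeness must be >= 0")
        if self.n_subjects < 2 or self.n_snps < 1:
            raise ValueError("need n_subjects >= 2 and n_snps >= 1")


@dataclass
class GroundTruth:
    causal_snp_ids: set[str]
    effects: np.ndarray  # length m, zero at non-causal SNPs
    true_breeding_values: np.ndarray  # length n
    h2_realized: float
    pattern_assignments: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "causal_snp_ids": sorted(self.causal_snp_ids),
            "effects": self.effects.tolist(),
            "true_breeding_values": self.true_breeding_values.tolist(),
            "h2_realized": self.h2_realized,
            "pattern_assignments": self.pattern_assignments,
        }
        Path(path).write_text(json.dumps(obj))


def _rng(seed, stream: str) -> np.random.Generator:
    # stable per-stream substream (python's str hash is salted per process)
    tag = zlib.crc32(stream.encode()) % 2**31
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """HWE genotypes: per-SNP frequency uniform on maf_range, dosages
    Binomial(2, p) i.i.d. across subjects; autosomal metadata."""
    rng = _rng(config.seed, "genotypes")
    m, n = config.n_snps, config.n_subjects
    p = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    dosages = rng.binomial(2, p[None, :], size=(n, m)).astype(float)
    snps = [
        SNPRecord(f"snp{i:06d}", str(i % 22 + 1), 10_000 + 100 * i)
        for i in range(m)
    ]
    subjects = [f"S{i:05d}" for i in range(n)]
    return GenotypeMatrix(subjects, snps, dosages)


def simulate_polygenic_phenotype(
    g: GenotypeMatrix, config: SimConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """Additive polygenic trait on standardized genotypes.

    Effects are i.i.d. Gaussian over the causal subset; environmental noise
    is scaled against the realized breeding-value variance so the realized
    variance ratio matches ``h2_true`` in expectation. Returns the
    continuous trait plus its mean-dichotomized binary label.
    """
    rng = _rng(config.seed, "phenotype")
    n, m = g.n_subjects, g.n_snps
    m_causal = max(1, int(round(config.causal_fraction * m)))
    if config.h2_true > 0 and m_causal == 0:
        raise ValueError("h2_true > 0 requires at least one causal SNP")
    causal_idx = np.sort(rng.choice(m, size=m_causal, replace=False))

    effects = np.zeros(m)
    if config.h2_true > 0:
        p = g.allele_freqs()
        sd = np.sqrt(2 * p * (1 - p))
        sd[sd == 0] = 1.0
        z = (g.dosages - 2 * p[None, :]) / sd[None, :]
        beta = rng.normal(0.0, np.sqrt(1.0 / m_causal), size=m_causal)
        effects[causal_idx] = beta
        bv = z[:, causal_idx] @ beta
    else:
        bv = np.zeros(n)

    var_g = float(np.var(bv))
    if config.h2_true >= 1.0:
        noise = np.zeros(n)
    elif config.h2_true <= 0.0 or var_g == 0.0:
        bv = np.zeros(n)
        var_g = 0.0
        noise = rng.normal(0.0, 1.0, size=n)
    else:
        sigma_e = np.sqrt(var_g * (1 - config.h2_true) / config.h2_true)
        noise = rng.normal(0.0, sigma_e, size=n)

    y = bv + noise
    var_y = float(np.var(y))
    h2_real = var_g / var_y if var_y > 0 else 0.0

    labels, thresh = dichotomize_about_mean(y)
    pheno = pd.DataFrame(
        {"trait": y, "label": labels},
        index=pd.Index(g.subject_ids, name="subject_id"),
    )
    truth = GroundTruth(
        causal_snp_ids={g.snp_ids[i] for i in causal_idx},
        effects=effects,
        true_breeding_values=bv,
        h2_realized=h2_real,
    )
    return pheno, truth


def simulate_priority_scores(
    g: GenotypeMatrix, truth: GroundTruth, config: SimConfig
) -> pd.DataFrame:
    """Per-SNP functional priority scores in [0, 0.12].

    A ``zero_score_fraction`` mass of SNPs gets total score exactly 0; the
    remainder get a regulatory-evidence component plus a MAF component.
    Causal SNPs are over-represented among non-zero scores with selection
    odds multiplied by (1 + priority_informativeness); informativeness 0
    makes scores independent of causal status.
    """
    rng = _rng(config.seed, "scores")
    m = g.n_snps
    snp_ids = g.snp_ids
    if set(snp_ids) < truth.causal_snp_ids:
        raise ValueError("ground truth refers to SNPs absent from the genotypes")
    n_zero = int(round(config.zero_score_fraction * m))
    causal = np.array([s in truth.causal_snp_ids for s in snp_ids])
    # weighted sampling without replacement of the retained (non-zero) set
    # via Gumbel top-k on log-weights
    w = np.where(causal, 1.0 + config.priority_informativeness, 1.0)
    keys = np.log(w) + rng.gumbel(size=m)
    retained = np.zeros(m, dtype=bool)
    retained[np.argsort(-keys)[: m - n_zero]] = True

    maf = np.minimum(g.allele_freqs(), 1 - g.allele_freqs())
    reg = np.where(retained, rng.beta(1.2, 10.0, size=m) * 0.10, 0.0)
    maf_comp = np.where(retained, 0.02 * maf / 0.5, 0.0)
    total = np.clip(reg + maf_comp, 0.0, SCORE_CAP)
    return pd.DataFrame(
        {
            "snp_id": snp_ids,
            "total_score": total,
            "regulatory_component": np.minimum(reg, total),
            "maf_component": total - np.minimum(reg, total),
        }
    )


def simulate_covariates(config: SimConfig) -> pd.DataFrame:
    """Draw the demographic covariate table (no missingness injected here)."""
    rng = _rng(config.seed, "covariates")
    n = config.n_subjects
    cols: dict[str, np.ndarray] = {}
    for spec in config.covariate_spec:
        if spec.kind == "normal":
            mu, sd = spec.params
            cols[spec.name] = rng.normal(mu, sd, size=n)
        elif spec.kind == "binary":
            (prev,) = spec.params
            cols[spec.name] = rng.binomial(1, prev, size=n).astype(float)
        elif spec.kind == "categorical":
            probs = np.asarray(spec.params, dtype=float)
            levels = rng.choice(len(probs), size=n, p=probs / probs.sum())
            cols[spec.name] = np.array([f"level{k}" for k in levels], dtype=object)
        else:
            raise ValueError(f"unknown covariate kind {spec.kind!r}")
    idx = pd.Index([f"S{i:05d}" for i in range(n)], name="subject_id")
    return pd.DataFrame(cols, index=idx)


def covariate_trait_contribution(
    covariates: pd.DataFrame, spec: Sequence[CovariateSpec]
) -> np.ndarray:
    """Sum of effect * standardized covariate over numeric covariates."""
    out = np.zeros(len(covariates))
    for s in spec:
        if s.effect == 0 or s.kind == "categorical":
            continue
        v = covariates[s.name].to_numpy(float)
        sd = v.std()
        if sd > 0:
            out += s.effect * (v - v.mean()) / sd
    return out


def assign_patterns(
    n: int,
    seed: int,
    proportions: dict[str, float] | None = None,
) -> dict[str, str]:
    """Assign lung-function pattern labels by the cohort marginals; the
    residual mass is 'unclassified'."""
    proportions = proportions or DEFAULT_PATTERN_PROPORTIONS
    rng = _rng(seed, "patterns")
    labels = list(proportions) + ["unclassified"]
    probs = np.array(list(proportions.values()) + [1.0 - sum(proportions.values())])
    if probs[-1] < -1e-9:
        raise ValueError("pattern proportions exceed 1")
    probs = np.clip(probs, 0, None)
    draw = rng.choice(len(labels), size=n, p=probs / probs.sum())
    return {f"S{i:05d}": labels[k] for i, k in enumerate(draw)}


# trajectory shape parameters: percent-predicted FEV1 reference is an
# internal synthetic growth standard (mean 100, sd 12 at every age), so the
# 25th percentile sits at ~91.9 %pred.  NG sits near 108, RG near 80; ED
# declines ~12% from a peak reached at age 20.
_TRAJ_LEVEL = {"NG": 108.0, "RG": 80.0}
_ED_PEAK_AGE = 20
_ED_DECLINE = 0.12
_AGES = np.arange(6, 26)  # final age 25 -> ED-eligible (>= 23)


def simulate_trajectories(
    subjects: Sequence[str],
    assignments: dict[str, str],
    seed: int,
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Annual (age, %pred FEV1) series realizing the assigned patterns.

    Returns a long-format frame (subject_id, age_years, fev1_pct_pred,
    percentile_rank). Unknown labels raise; 'unclassified' subjects get a
    short 3-visit series that the classifier must refuse to label.
    """
    rng = _rng(seed, "trajectories")
    rows = []
    for sid in subjects:
        lab = assignments[sid]
        if lab == "unclassified":
            ages = _AGES[:3]
            vals = np.full(3, 100.0)
        elif lab in BASE_PATTERNS:
            base = lab.split("-")[0]
            ed = lab.endswith("ED")
            level = _TRAJ_LEVEL[base]
            ages = _AGES
            # slow ramp to plateau at age 15
            vals = level - 5.0 * np.clip((15 - ages) / 9.0, 0, None)
            if ed:
                post = ages > _ED_PEAK_AGE
                frac = (ages[post] - _ED_PEAK_AGE) / (ages[-1] - _ED_PEAK_AGE)
                vals = vals.copy()
                vals[post] = level * (1 - _ED_DECLINE * frac)
        else:
            raise ValueError(f"unknown pattern label {lab!r} for {sid}")
        if noise_sd > 0:
            vals = vals + rng.normal(0, noise_sd, size=len(vals))
        for a, v in zip(ages, vals):
            rows.append((sid, float(a), float(v)))
    df = pd.DataFrame(rows, columns=["subject_id", "age_years", "fev1_pct_pred"])
    df["percentile_rank"] = fev1_percentile_rank(df["fev1_pct_pred"].to_numpy())
    return df


def inject_missingness(
    table: pd.DataFrame, rate: float, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Set entries missing completely at random at ``rate``; returns the
    masked table and the boolean missingness flags for audit."""
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"missing rate must be in [0,1), got {rate}")
    rng = _rng(seed, "missingness")
    mask = pd.DataFrame(
        rng.random(table.shape) < rate, index=table.index, columns=table.columns
    )
    out = table.mask(mask)
    return out, mask


@dataclass
class SyntheticCohort:
    config: SimConfig
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    covariates: pd.DataFrame
    priority_scores: pd.DataFrame
    trajectories: pd.DataFrame
    truth: GroundTruth


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """One-call cohort: genotypes, polygenic trait (+ covariate effects),
    priority scores, covariates, trajectories, ground truth."""
    g = simulate_genotypes(config)
    pheno, truth = simulate_polygenic_phenotype(g, config)
    cov = simulate_covariates(config)
    c_eff = covariate_trait_contribution(cov, config.covariate_spec)
    if np.any(c_eff != 0):
        pheno = pheno.copy()
        pheno["trait"] = pheno["trait"] + c_eff
        labels, _ = dichotomize_about_mean(pheno["trait"].to_numpy())
        pheno["label"] = labels
        var_y = float(np.var(pheno["trait"]))
        truth.h2_realized = (
            float(np.var(truth.true_breeding_values)) / var_y if var_y > 0 else 0.0
        )
    scores = simulate_priority_scores(g, truth, config)
    truth.pattern_assignments = assign_patterns(config.n_subjects, config.seed)
    traj = simulate_trajectories(
        g.subject_ids, truth.pattern_assignments, config.seed
    )
    if config.missing_rate > 0:
        cov, _ = inject_missingness(cov, config.missing_rate, config.seed)
    return SyntheticCohort(config, g, pheno, cov, scores, traj, truth)
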