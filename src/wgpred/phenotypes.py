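"""Phenotype derivation: transforms, dichotomization, mean imputation, and
the longitudinal lung-function pattern classifier.

Continuous asthma traits (airway hyperresponsiveness, log10 IgE, log10
eosinophils, pre-/post-bronchodilator FEV1 %pred, bronchodilator response,
a steroid-responsiveness-like trait) are converted to binary labels by
dichotomizing about the mean; missing values in traits or covariates are
imputed with the column mean (mode for categoricals) to bias toward the
null. Longitudinal percent-predicted FEV1 series are classified into
normal growth (NG) vs reduced growth (RG) by position relative to the 25th
percentile for age, with an early-decline (ED) flag for subjects followed
to at least age 23 who show a premature drop from their post-adolescent
peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def compute_bdr(pre: float | np.ndarray, post: float | np.ndarray) -> np.ndarray:
    """Bronchodilator response (post - pre) / pre; requires pre > 0."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if np.any(pre <= 0):
        raise ValueError("pre-bronchodilator FEV1 must be positive")
    return (post - pre) / pre


def dichotomize_about_mean(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Label 1 iff value > mean(values); returns (labels, threshold)."""
    values = np.asarray(values, dtype=float)
    if np.unique(values[~np.isnan(values)]).size < 2:
        raise ValueError("cannot dichotomize a constant vector")
    thresh = float(np.nanmean(values))
    return (values > thresh).astype(int), thresh


def mean_impute_table(t: pd.DataFrame) -> pd.DataFrame:
    """Impute missing entries with the column mean (mode for non-numeric)."""
    out = t.copy()
    for col in out.columns:
        if out[col].isna().any():
            if pd.api.types.is_numeric_dtype(out[col]):
                out[col] = out[col].fillna(out[col].mean())
            else:
                out[col] = out[col].fillna(out[col].mode().iloc[0])
    return out


# reference distribution of %pred FEV1 at each age for percentile ranking:
# mean 100 by construction of percent-predicted, spread ~12 points
REF_MEAN_PCT_PRED = 100.0
REF_SD_PCT_PRED = 12.0


def fev1_percentile_rank(
    fev1_pct_pred: np.ndarray,
    ref_mean: float = REF_MEAN_PCT_PRED,
    ref_sd: float = REF_SD_PCT_PRED,
) -> np.ndarray:
    """Percentile rank of %pred FEV1 against a Gaussian reference."""
    return stats.norm.cdf((np.asarray(fev1_pct_pred, float) - ref_mean) / ref_sd)


@dataclass(frozen=True)
class LungPattern:
    """Longitudinal lung-function pattern: NG/RG base with an ED flag."""

    base: str  # 'NG' | 'RG' | 'unclassified'
    early_decline: bool = False

    @property
    def label(self) -> str:
        if self.base == "unclassified":
            return "unclassified"
        return f"{self.base}-ED" if self.early_decline else self.base

    @property
    def ed_all(self) -> bool:
        return self.base != "unclassified" and self.early_decline

    @property
    def rg_all(self) -> bool:
        return self.base == "RG"


def smooth_series(values: np.ndarray, window: int = 3) -> np.ndarray:
    """Rolling-median smoother (edges use shrunken windows)."""
    s = pd.Series(values)
    return s.rolling(window, center=True, min_periods=1).median().to_numpy()


def classify_lung_pattern(
    traj: pd.DataFrame,
    min_final_age: float = 23.0,
    decline_threshold: float = 0.05,
    ng_fraction: float = 0.5,
    min_observations: int = 4,
    smooth_window: int = 3,
) -> LungPattern:
    """Classify one subject's trajectory.

    ``traj`` needs columns age_years, fev1_pct_pred and percentile_rank,
    sorted or sortable by age. Base pattern is NG if strictly more than
    ``ng_fraction`` of observations sit above the 25th percentile, else RG.
    Early decline requires follow-up to ``min_final_age`` and a relative
    drop of at least ``decline_threshold`` from a smoothed peak attained
    before the final visit. Too few observations yield the explicit
    'unclassified' status.
    """
    traj = traj.sort_values("age_years")
    ages = traj["age_years"].to_numpy(float)
    if np.any(np.diff(ages) <= 0):
        raise ValueError("ages must be strictly increasing within subject")
    if len(traj) < min_observations:
        return LungPattern("unclassified")
    above = traj["percentile_rank"].to_numpy(float) > 0.25
    base = "NG" if above.mean() > ng_fraction else "RG"

    ed = False
    if ages[-1] >= min_final_age:
        sm = smooth_series(traj["fev1_pct_pred"].to_numpy(float), smooth_window)
        peak_idx = int(np.argmax(sm))
        peak = sm[peak_idx]
        if peak_idx < len(sm) - 1 and peak > 0:
            ed = (peak - sm[-1]) / peak >= decline_threshold
    return LungPattern(base, ed)


def classify_cohort(
    trajectories: pd.DataFrame, **kwargs
) -> dict[str, LungPattern]:
    """classify_lung_pattern per subject of a long-format trajectory table."""
    return {
        sid: classify_lung_pattern(sub, **kwargs)
        for sid, sub in trajectories.groupby("subject_id", sort=True)
    }


def composite_patterns(labels: dict[str, LungPattern]) -> pd.DataFrame:
    """Per-subject indicators for NG, NG-ED, RG, RG-ED, ED-All, RG-All.

    The four base indicators are mutually exclusive and exhaustive over
    classified subjects; ED-All pools {NG-ED, RG-ED} and RG-All pools
    {RG, RG-ED}. Unclassified subjects get NA indicators.
    """
    rows = {}
    for sid, pat in labels.items():
        if pat.base == "unclassified":
            rows[sid] = {c: np.nan for c in
                         ("NG", "NG-ED", "RG", "RG-ED", "ED-All", "RG-All")}
            continue
        lab = pat.label
        rows[sid] = {
            "NG": int(lab == "NG"),
            "NG-ED": int(lab == "NG-ED"),
            "RG": int(lab == "RG"),
            "RG-ED": int(lab == "RG-ED"),
            "ED-All": int(pat.ed_all),
            "RG-All": int(pat.rg_all),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "subject_id"
    return df
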