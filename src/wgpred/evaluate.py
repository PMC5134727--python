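"""Prediction evaluation: AUC, convex-hull AUC, label-permutation p-values,
and the repeated 75/25-split and leave-one-out protocols.

The AUC is the Mann-Whitney probability that a random case outscores a
random control (ties count one half); the convex-hull AUC is the area under
the upper convex hull of the empirical ROC points, which dominates the raw
AUC. Significance against random guessing (AUC 50%) is assessed by label
permutation with the add-one estimator p = (r + 1)/(B + 1), so p is never
exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score_case > score_control) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_points(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Empirical ROC points (fpr, tpr) over all thresholds, incl. (0,0), (1,1)."""
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    pts = np.column_stack([fpr, tpr])
    pts = np.vstack([[0.0, 0.0], pts, [1.0, 1.0]])
    return pts[np.lexsort((pts[:, 1], pts[:, 0]))]


def _upper_hull(pts: np.ndarray) -> np.ndarray:
    """Upper convex hull of points sorted by x (Andrew monotone chain)."""
    hull: list[np.ndarray] = []
    for p in pts:
        while len(hull) >= 2:
            o, a = hull[-2], hull[-1]
            # keep only right turns (concave-from-above chain)
            if (a[0] - o[0]) * (p[1] - o[1]) - (a[1] - o[1]) * (p[0] - o[0]) >= 0:
                hull.pop()
            else:
                break
        hull.append(p)
    return np.array(hull)


def convex_hull_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the upper convex hull of the ROC points."""
    labels = np.asarray(labels).astype(int)
    if labels.sum() in (0, labels.size):
        raise ValueError("AUC requires both classes present")
    hull = _upper_hull(roc_points(scores, labels))
    return float(np.trapezoid(hull[:, 1], hull[:, 0]))


def permutation_pvalue(
    scores: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    statistic: Callable = auc,
) -> tuple[float, np.ndarray]:
    """One-sided label-permutation p for statistic > chance.

    p = (1 + #{stat_perm >= stat_obs}) / (n_perm + 1); the add-one form
    keeps p strictly positive.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    labels = np.asarray(labels).astype(int)
    obs = statistic(scores, labels)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = statistic(scores, rng.permutation(labels))
    p = (1.0 + np.sum(null >= obs)) / (n_perm + 1.0)
    return float(p), null


@dataclass
class EvalResult:
    auc: float
    ch_auc: float
    p_empirical: float
    n_permutations: int
    protocol: str
    per_repeat: pd.DataFrame = field(default_factory=pd.DataFrame)
    aggregate: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "ch_auc": self.ch_auc,
            "p_empirical": self.p_empirical,
            "n_permutations": self.n_permutations,
            "protocol": self.protocol,
            "aggregate": self.aggregate,
        }


def stratified_split(
    labels: np.ndarray,
    train_fraction: float,
    rng: np.random.Generator,
    stratified: bool = True,
    max_resample: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Random train/test index split; stratified keeps class balance and
    both modes guarantee a two-class test set (resampled up to a cap)."""
    labels = np.asarray(labels).astype(int)
    n = labels.size
    for _ in range(max_resample):
        if stratified:
            train = np.zeros(n, dtype=bool)
            for c in (0, 1):
                idx = np.flatnonzero(labels == c)
                k = int(round(train_fraction * idx.size))
                k = min(max(k, 1), idx.size - 1)
                train[rng.choice(idx, size=k, replace=False)] = True
        else:
            train = np.zeros(n, dtype=bool)
            train[rng.choice(n, size=int(round(train_fraction * n)), replace=False)] = True
        test = ~train
        if len(np.unique(labels[test])) == 2 and len(np.unique(labels[train])) == 2:
            return np.flatnonzero(train), np.flatnonzero(test)
    raise ValueError("could not produce a two-class test split")


def repeated_split_eval(
    predict_fn: Callable[[np.ndarray, np.ndarray, int], np.ndarray],
    labels: np.ndarray,
    train_fraction: float = 0.75,
    n_repeats: int = 25,
    n_permutations: int = 999,
    seed: int = 0,
    stratified: bool = True,
) -> EvalResult:
    """Repeated random-split protocol (default 75% train / 25% test, 25
    repeats; averages of AUC, convex-hull AUC and permutation p reported).

    ``predict_fn(train_idx, test_idx, repeat_seed)`` must return test-set
    scores; it owns training (so any variable selection stays inside the
    training fold).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0,1)")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    labels = np.asarray(labels).astype(int)
    rows = []
    for rep in range(n_repeats):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), 1000 + rep])
        )
        tr, te = stratified_split(labels, train_fraction, rng, stratified)
        scores = np.asarray(predict_fn(tr, te, rep), dtype=float)
        a = auc(scores, labels[te])
        ch = convex_hull_auc(scores, labels[te])
        p, _ = permutation_pvalue(scores, labels[te], n_permutations, rng)
        rows.append({"repeat": rep, "auc": a, "ch_auc": ch, "p": p})
    per = pd.DataFrame(rows)
    agg = {
        "mean_auc": float(per["auc"].mean()),
        "sd_auc": float(per["auc"].std(ddof=1)) if n_repeats > 1 else 0.0,
        "mean_ch_auc": float(per["ch_auc"].mean()),
        "sd_ch_auc": float(per["ch_auc"].std(ddof=1)) if n_repeats > 1 else 0.0,
        "mean_p": float(per["p"].mean()),
    }
    return EvalResult(
        auc=agg["mean_auc"],
        ch_auc=agg["mean_ch_auc"],
        p_empirical=agg["mean_p"],
        n_permutations=n_permutations,
        protocol=f"split({train_fraction:g},{n_repeats})",
        per_repeat=per,
        aggregate=agg,
    )


def loo_eval(
    loo_scores_fn: Callable[[], np.ndarray],
    labels: np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
) -> EvalResult:
    """Leave-one-out protocol: one score per subject, then AUC/convex-hull
    AUC/permutation p on the full score vector."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(loo_scores_fn(), dtype=float)
    if scores.size != labels.size:
        raise ValueError("LOO scores must cover every subject")
    a = auc(scores, labels)
    ch = convex_hull_auc(scores, labels)
    p, _ = permutation_pvalue(scores, labels, n_permutations, seed)
    return EvalResult(a, ch, p, n_permutations, "loo")
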