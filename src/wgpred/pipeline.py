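"""End-to-end orchestration: simulate -> QC -> GRM (scheme) -> heritability
-> predict -> evaluate, from one config with one run-level seed.

Every stage draws from a named substream of the run seed so scheme
comparisons share splits and permutations (paired comparisons), and the
manifest echoes the full config plus checksums of every written artifact.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluate as ev
from . import predict as pr
from .genio import mean_impute_genotypes, qc_pipeline, write_dosage_text, write_plink
from .phenotypes import mean_impute_table
from .relatedness import SCHEMES, covariate_similarity, combine_similarity, grm_for_scheme
from .reml import greml_fit, greml_with_pcs, lrt_h2
from .simulate import SimConfig, SyntheticCohort, simulate_cohort

PREDICTORS = ("gblup", "kriging", "nb", "lasso", "svm")


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    maf_threshold: float = 0.05
    hwe_threshold: float = 0.001
    scheme: str = "standard"
    predictor: str = "gblup"
    use_covariates: bool = False
    covariate_mixing: tuple[float, float] = (0.5, 0.5)
    protocol: str = "loo"  # or "split"
    train_fraction: float = 0.75
    n_repeats: int = 25
    n_permutations: int = 199
    n_pcs: int = 6
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if self.predictor not in PREDICTORS:
            raise ValueError(f"predictor must be one of {PREDICTORS}")
        if self.protocol not in ("loo", "split"):
            raise ValueError("protocol must be 'loo' or 'split'")
        if not 0 <= self.maf_threshold <= 0.5:
            raise ValueError("maf_threshold out of range")
        if not 0 < self.hwe_threshold < 1:
            raise ValueError("hwe_threshold out of range")


def _sub_seed(seed: int, stream: str) -> int:
    return (int(seed) * 2654435761 + zlib.crc32(stream.encode())) % 2**31


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _jsonify(obj):
    """Coerce numpy scalars/arrays so manifests are plain JSON."""
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _prepare(config: RunConfig) -> tuple[SyntheticCohort, dict]:
    cohort = simulate_cohort(config.sim)
    g_qc, report = qc_pipeline(
        cohort.genotypes, config.maf_threshold, config.hwe_threshold
    )
    cohort.genotypes = mean_impute_genotypes(g_qc)
    return cohort, report.to_dict()


def _baseline_split_fn(cohort: SyntheticCohort, config: RunConfig):
    g = cohort.genotypes
    labels = cohort.phenotypes["label"].to_numpy()

    def fn(tr: np.ndarray, te: np.ndarray, rep: int) -> np.ndarray:
        gt, gx = g.subset_subjects(tr), g.subset_subjects(te)
        if config.predictor == "nb":
            return pr.NaiveBayesWGP().fit(gt, labels[tr]).predict(gx).scores
        if config.predictor == "lasso":
            return pr.LassoLogisticWGP(
                seed=_sub_seed(config.seed, f"lasso{rep}")
            ).fit_predict(gt, labels[tr], gx).scores
        if config.predictor == "svm":
            return pr.LinearSVMWGP().fit_predict(gt, labels[tr], gx).scores
        raise ValueError(config.predictor)

    return fn


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and optionally writes) the run manifest."""
    cohort, qc_report = _prepare(config)
    g = cohort.genotypes
    labels = cohort.phenotypes["label"].to_numpy()
    y = cohort.phenotypes["trait"].to_numpy()

    kin = grm_for_scheme(g, config.scheme, cohort.priority_scores)
    vc = greml_fit(y, None, kin)
    vc_pcs = greml_with_pcs(y, None, kin, n_pcs=config.n_pcs)
    _, lrt_p = lrt_h2(vc, y, None)
    ridge = pr.ridge_from_varcomp(vc)
    if not np.isfinite(ridge) or ridge <= 0 or not vc.converged:
        ridge = pr.DEFAULT_RIDGE

    kin_eval = kin
    if config.use_covariates:
        cov = mean_impute_table(cohort.covariates)
        kin_eval = combine_similarity(
            [kin, covariate_similarity(cov)], config.covariate_mixing
        )

    eval_seed = _sub_seed(config.seed, "evaluation")
    if config.predictor in ("gblup", "kriging"):
        method = "gblup" if config.predictor == "gblup" else "simple"
        if config.protocol == "loo":
            result = ev.loo_eval(
                lambda: pr.loo_predict(kin_eval, labels, method, ridge).scores,
                labels,
                config.n_permutations,
                eval_seed,
            )
        else:
            ids = np.array(kin_eval.subject_ids)

            def fn(tr, te, rep):
                if method == "gblup":
                    return pr.gblup_predict(
                        kin_eval, labels[tr], ids[tr], ids[te], ridge
                    ).scores
                return pr.kriging_simple_predict(
                    kin_eval, labels[tr], ids[tr], ids[te]
                ).scores

            result = ev.repeated_split_eval(
                fn, labels, config.train_fraction, config.n_repeats,
                config.n_permutations, eval_seed,
            )
    else:
        if config.protocol == "loo":
            raise ValueError("LOO protocol is only supported for GRM predictors")
        result = ev.repeated_split_eval(
            _baseline_split_fn(cohort, config), labels, config.train_fraction,
            config.n_repeats, config.n_permutations, eval_seed,
        )

    manifest = {
        "config": {
            **{k: v for k, v in asdict(config).items() if k != "sim"},
            "sim": asdict(config.sim),
        },
        "qc": qc_report,
        "grm": {"scheme": kin.scheme, "n_snps_used": kin.n_snps_used,
                "n_subjects": kin.n_subjects},
        "heritability": vc.to_dict(),
        "heritability_with_pcs": vc_pcs.to_dict(),
        "lrt_p": lrt_p,
        "ridge": ridge,
        "evaluation": result.to_dict(),
        "h2_true": config.sim.h2_true,
        "h2_realized": cohort.truth.h2_realized,
    }
    manifest = _jsonify(manifest)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_plink(cohort.genotypes, out / "genotypes")
        write_dosage_text(cohort.genotypes, out / "genotypes.dosage.tsv")
        cohort.phenotypes.to_csv(out / "phenotypes.tsv", sep="\t", na_rep="NA")
        cohort.covariates.to_csv(out / "covariates.tsv", sep="\t", na_rep="NA")
        cohort.priority_scores.to_csv(out / "priority_scores.tsv", sep="\t",
                                      index=False)
        cohort.trajectories.to_csv(out / "trajectories.tsv", sep="\t", index=False)
        cohort.truth.to_json(out / "ground_truth.json")
        kin.write_text(out / "grm.tsv")
        manifest["artifacts"] = {
            p.name: _checksum(p) for p in sorted(out.iterdir()) if p.is_file()
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def compare_schemes(config: RunConfig, schemes: list[str]) -> pd.DataFrame:
    """Evaluate identical data/splits/permutation seeds under each weighting
    scheme; reports per-scheme AUC and the paired difference vs the first."""
    if len(schemes) < 2:
        raise ValueError("need at least two schemes to compare")
    cohort, _ = _prepare(config)
    g = cohort.genotypes
    labels = cohort.phenotypes["label"].to_numpy()
    eval_seed = _sub_seed(config.seed, "evaluation")
    rows = []
    for scheme in schemes:
        kin = grm_for_scheme(g, scheme, cohort.priority_scores)
        result = ev.loo_eval(
            lambda: pr.loo_predict(kin, labels, "gblup").scores,
            labels, config.n_permutations, eval_seed,
        )
        rows.append({"scheme": scheme, "auc": result.auc,
                     "ch_auc": result.ch_auc, "p": result.p_empirical})
    df = pd.DataFrame(rows)
    df["auc_diff_vs_first"] = df["auc"] - df["auc"].iloc[0]
    return df
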