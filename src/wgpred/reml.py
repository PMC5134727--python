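"""GREML: restricted maximum likelihood variance components from a GRM.

Fits y ~ N(X b, sigma2_g A + sigma2_e I) by average-information REML with
EM fallback steps, the strategy popularized by GCTA. The GRM A is
eigendecomposed once per fit so every iteration works with a diagonal
covariance (cost O(n) per iteration after the O(n^3) decomposition); this
is algebraically identical to iterating on the full matrices.

Heritability is h2 = sigma2_g / (sigma2_g + sigma2_e); its standard error
comes from the inverse average-information matrix by the delta method. A
likelihood-ratio test against sigma2_g = 0 uses the boundary mixture
0.5*chi2_0 + 0.5*chi2_1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .relatedness import KinshipMatrix, genotype_pca


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    h2: float
    se_h2: float
    loglik_reml: float
    n_iterations: int
    converged: bool
    boundary: bool = False
    beta: np.ndarray = field(default_factory=lambda: np.zeros(0))
    se_sigma2: tuple[float, float] = (np.nan, np.nan)
    n: int = 0
    algorithm_trace: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        """GCTA-hsq-style summary fields."""
        vp = self.sigma2_g + self.sigma2_e
        return {
            "V(G)": float(self.sigma2_g),
            "V(e)": float(self.sigma2_e),
            "Vp": float(vp),
            "V(G)/Vp": float(self.h2),
            "SE": float(self.se_h2),
            "logL": float(self.loglik_reml),
            "n": int(self.n),
            "converged": bool(self.converged),
            "boundary": bool(self.boundary),
        }


class _EigenREML:
    """REML machinery in the eigenbasis of A."""

    def __init__(self, y: np.ndarray, x: np.ndarray, a: np.ndarray) -> None:
        self.n, self.p = x.shape
        d, u = linalg.eigh(a)
        self.d = np.clip(d, 0.0, None)  # numerical PSD
        self.ys = u.T @ y
        self.xs = u.T @ x

    def core(self, sg: float, se: float) -> dict:
        """Log-likelihood, gradient, AI matrix and trace terms at (sg, se)."""
        v = sg * self.d + se
        if np.any(v <= 0):
            return {"loglik": -np.inf}
        vi = 1.0 / v
        xv = self.xs * vi[:, None]
        xtvx = self.xs.T @ xv
        sign, logdet_xtvx = np.linalg.slogdet(xtvx)
        if sign <= 0:
            raise np.linalg.LinAlgError("X'V^-1X not positive definite (singular X?)")
        c = np.linalg.inv(xtvx)
        b = xv.T @ self.ys
        beta = c @ b
        py = self.ys * vi - xv @ beta
        ypy = float(self.ys @ py)
        loglik = -0.5 * (float(np.log(v).sum()) + logdet_xtvx + ypy)

        # tr(P V_k) for V_g' = diag(d), V_e' = I
        tr_pa = float((self.d * vi).sum() - np.trace(
            c @ (self.xs.T @ (self.xs * (self.d * vi**2)[:, None]))))
        tr_p = float(vi.sum() - np.trace(
            c @ (self.xs.T @ (self.xs * (vi**2)[:, None]))))

        apy = self.d * py
        papy = apy * vi - xv @ (c @ (xv.T @ apy))
        ppy = py * vi - xv @ (c @ (xv.T @ py))
        y_pap_y = float(py @ apy)
        y_pp_y = float(py @ py)
        grad = np.array([-0.5 * (tr_pa - y_pap_y), -0.5 * (tr_p - y_pp_y)])
        ai = 0.5 * np.array(
            [
                [float(apy @ papy), float(apy @ ppy)],
                [float(apy @ ppy), float(py @ ppy)],
            ]
        )
        return {
            "loglik": loglik,
            "grad": grad,
            "ai": ai,
            "y_pap_y": y_pap_y,
            "y_pp_y": y_pp_y,
            "tr_pa": tr_pa,
            "tr_p": tr_p,
            "beta": beta,
        }

    def profile_loglik(self, h2: float) -> tuple[float, float]:
        """REML log-likelihood profiled over total variance at fixed h2.

        With V = s2p * (h2 A + (1-h2) I), the REML-optimal total variance
        has the closed form s2p = y'P_R y / (n - p); returns (loglik, s2p).
        """
        r = h2 * self.d + (1.0 - h2)
        if np.any(r <= 0):
            return -np.inf, np.nan
        ri = 1.0 / r
        xr = self.xs * ri[:, None]
        xtrx = self.xs.T @ xr
        _, logdet_xtrx = np.linalg.slogdet(xtrx)
        beta = np.linalg.solve(xtrx, xr.T @ self.ys)
        py = self.ys * ri - xr @ beta
        yp_r_y = float(self.ys @ py)
        dof = self.n - self.p
        s2p = yp_r_y / dof
        if s2p <= 0:
            return -np.inf, np.nan
        ll = -0.5 * (
            dof * np.log(s2p) + float(np.log(r).sum()) + logdet_xtrx + dof
        )
        return ll, s2p

    def loglik(self, sg: float, se: float) -> float:
        v = sg * self.d + se
        if np.any(v <= 0):
            return -np.inf
        vi = 1.0 / v
        xv = self.xs * vi[:, None]
        xtvx = self.xs.T @ xv
        _, logdet = np.linalg.slogdet(xtvx)
        beta = np.linalg.solve(xtvx, xv.T @ self.ys)
        py = self.ys * vi - xv @ beta
        return -0.5 * (float(np.log(v).sum()) + logdet + float(self.ys @ py))


def greml_fit(
    y: np.ndarray,
    x: np.ndarray | None,
    a: KinshipMatrix | np.ndarray,
    tolerance: float = 1e-6,
    max_iter: int = 100,
    profile_refine: bool = True,
) -> VarianceComponents:
    """AI-REML fit of (sigma2_g, sigma2_e) with EM fallback.

    ``x`` is the fixed-effect design including an intercept; None means
    intercept only. Components that step negative are floored at
    1e-6*var(y) and the fit is flagged as a boundary solution.

    Because the two-component model profiles exactly to one dimension
    (h2, with the total variance available in closed form), the fit ends
    with a profile-likelihood polish — a bounded Brent search over h2 —
    which rescues the slow linear EM crawl near variance boundaries;
    ``profile_refine=False`` disables it to expose the raw iteration path.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    amat = a.values if isinstance(a, KinshipMatrix) else np.asarray(a, float)
    if amat.shape != (n, n):
        raise ValueError("kinship matrix does not match phenotype length")
    if x is None:
        x = np.ones((n, 1))
    else:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("fixed-effect design X is rank deficient")

    eng = _EigenREML(y, x, amat)
    vy = float(np.var(y))
    if vy == 0:
        raise ValueError("phenotype has zero variance")
    floor = 1e-6 * vy
    sg, se = vy / 2, vy / 2
    trace: list[dict] = []
    prev_ll = -np.inf
    converged = False
    boundary = False
    core = eng.core(sg, se)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        em = np.array(
            [
                sg + sg**2 * (core["y_pap_y"] - core["tr_pa"]) / n,
                se + se**2 * (core["y_pp_y"] - core["tr_p"]) / n,
            ]
        )
        # candidate updates: AI step with halving safeguard, then EM;
        # first candidate that does not lose likelihood wins
        proposals = []
        if n_iter > 1:
            try:
                delta = np.linalg.solve(core["ai"], core["grad"])
                if np.all(np.isfinite(delta)):
                    for frac in (1.0, 0.5, 0.25, 0.125):
                        proposals.append(np.array([sg, se]) + frac * delta)
            except np.linalg.LinAlgError:
                pass
        proposals.append(em)

        cur_ll = core["loglik"]
        chosen = None
        for cand in proposals:
            cg, ce = max(cand[0], floor), max(cand[1], floor)
            c = eng.core(cg, ce)
            if c["loglik"] >= cur_ll - 1e-10:
                chosen = (cg, ce, c, cand[0] < floor or cand[1] < floor)
                break
        if chosen is None:  # every step loses likelihood: local optimum
            cg, ce = max(em[0], floor), max(em[1], floor)
            chosen = (cg, ce, eng.core(cg, ce), em[0] < floor or em[1] < floor)
        sg, se, core, hit = chosen
        ll = core["loglik"]
        trace.append({"iter": n_iter, "sigma2_g": sg, "sigma2_e": se, "loglik": ll})
        if abs(ll - prev_ll) < tolerance:
            converged = True
            boundary = bool(hit)
            break
        prev_ll = ll

    if profile_refine:
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(
            lambda h: -eng.profile_loglik(h)[0],
            bounds=(0.0, 1.0 - 1e-9),
            method="bounded",
            options={"xatol": 1e-12},
        )
        best_h, (best_ll, best_s2p) = float(res.x), eng.profile_loglik(float(res.x))
        ll0, s2p0 = eng.profile_loglik(0.0)  # exact null boundary
        if ll0 > best_ll:
            best_h, best_ll, best_s2p = 0.0, ll0, s2p0
        if np.isfinite(best_ll):
            sg_r = max(best_h * best_s2p, floor)
            se_r = max((1.0 - best_h) * best_s2p, floor)
            core_r = eng.core(sg_r, se_r)
            # the profile optimum is the canonical endpoint unless clamping
            # made it genuinely worse than the iteration path
            if core_r["loglik"] >= core["loglik"] - 1e-9:
                sg, se, core = sg_r, se_r, core_r
                # Newton/AI polish: quadratic convergence at an interior
                # optimum takes the Brent point to machine precision
                for _ in range(5):
                    try:
                        delta = np.linalg.solve(core["ai"], core["grad"])
                    except np.linalg.LinAlgError:
                        break
                    if not np.all(np.isfinite(delta)):
                        break
                    sg_n = max(sg + delta[0], floor)
                    se_n = max(se + delta[1], floor)
                    core_n = eng.core(sg_n, se_n)
                    if core_n["loglik"] < core["loglik"]:
                        break
                    sg, se, core = sg_n, se_n, core_n
                boundary = bool(sg <= floor or se <= floor)
                converged = True
                trace.append(
                    {"iter": "profile", "sigma2_g": sg, "sigma2_e": se,
                     "loglik": core["loglik"]}
                )

    h2 = sg / (sg + se)
    # delta-method SE from the inverse AI matrix
    try:
        cov = np.linalg.inv(core["ai"])
        grad_h = np.array([se, -sg]) / (sg + se) ** 2
        var_h2 = float(grad_h @ cov @ grad_h)
        se_h2 = float(np.sqrt(max(var_h2, 0.0)))
        se_comp = (
            float(np.sqrt(max(cov[0, 0], 0.0))),
            float(np.sqrt(max(cov[1, 1], 0.0))),
        )
    except np.linalg.LinAlgError:
        se_h2, se_comp = np.nan, (np.nan, np.nan)

    return VarianceComponents(
        sigma2_g=float(sg),
        sigma2_e=float(se),
        h2=float(h2),
        se_h2=se_h2,
        loglik_reml=float(core["loglik"]),
        n_iterations=n_iter,
        converged=converged,
        boundary=boundary,
        beta=np.asarray(core["beta"]),
        se_sigma2=se_comp,
        n=n,
        algorithm_trace=trace,
    )


def greml_with_pcs(
    y: np.ndarray,
    covariates: np.ndarray | None,
    a: KinshipMatrix,
    n_pcs: int = 6,
    **kwargs,
) -> VarianceComponents:
    """GREML with the top genotype principal components as fixed effects."""
    n = len(y)
    cols = [np.ones((n, 1))]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.append(cov)
    if n_pcs > 0:
        pcs = genotype_pca(a, n_pcs).to_numpy()
        cols.append(pcs)
    x = np.hstack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("PC columns are collinear with supplied covariates")
    return greml_fit(y, x, a, **kwargs)


def reml_loglik_null(y: np.ndarray, x: np.ndarray) -> float:
    """Restricted log-likelihood of the sigma2_g = 0 model (same constant
    convention as greml_fit): V = sigma2_e I with the REML variance
    RSS/(n-p)."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    if x.ndim == 1:
        x = x[:, None]
    n, p = x.shape
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    rss = float(np.sum((y - x @ beta) ** 2))
    s2 = rss / (n - p)
    _, logdet_xtx = np.linalg.slogdet(x.T @ x)
    # log|V| + log|X'V^-1 X| + y'Py at V = s2*I
    return -0.5 * (n * np.log(s2) + (logdet_xtx - p * np.log(s2)) + rss / s2)


def lrt_h2(
    full: VarianceComponents, y: np.ndarray, x: np.ndarray | None
) -> tuple[float, float]:
    """Likelihood-ratio test of h2 = 0.

    Returns (statistic, p) with p from the 50:50 chi2_0 / chi2_1 boundary
    mixture. Raises if the full fit's likelihood falls materially below the
    null's (a numerical failure, since the null is nested).
    """
    y = np.asarray(y, float)
    if x is None:
        x = np.ones((y.size, 1))
    ll0 = reml_loglik_null(y, x)
    stat = 2.0 * (full.loglik_reml - ll0)
    # boundary fits floor sigma2_g slightly above zero, so the full
    # likelihood may sit a hair below the analytic null; only a material
    # deficit signals a numerical failure
    if stat < -1e-3:
        raise FloatingPointError(
            f"full REML log-likelihood below the nested null by {-stat / 2:.3g}"
        )
    stat = max(stat, 0.0)
    p = 0.5 * stats.chi2.sf(stat, df=1) + (0.5 if stat <= 0 else 0.0)
    return float(stat), float(p)


def liability_h2(h2_observed: float, prevalence: float) -> float:
    """Optional post-hoc transform of an observed-scale h2 for a
    dichotomized trait to the liability scale."""
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be in (0,1)")
    t = stats.norm.isf(prevalence)
    z = stats.norm.pdf(t)
    return h2_observed * prevalence * (1 - prevalence) / z**2
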