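"""Stage 2: association between genotypic eBLUPs and SNPs.

Three complementary detection methods are provided, all taking the stage-1
genotypic eBLUPs as the response:

* a SNP-by-SNP linear mixed model with a polygenic term structured by the
  additive relationship matrix (Wald test, Bonferroni threshold), computed
  in the rotated eigenbasis of the kinship with the variance components
  fixed at the null fit (EMMAX-style; exact per-SNP REML behind a flag);
* a stepwise multi-locus mixed model that adds the most significant SNP as
  a fixed cofactor each iteration, re-estimating the polygenic variance,
  with the returned model chosen by the extended BIC;
* Bayesian variable selection under a spike-and-slab prior fitted by a
  fully-factorized coordinate-ascent variational approximation, with an
  outer importance-weighted grid over the prior inclusion probability.

The module also estimates the proportion of eBLUP variance explained by all
SNPs jointly (PVE) under the GBLUP/ridge dense model, optionally with a
dominance component.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, gammaln

from .genotypes import GenotypeMatrix

__all__ = [
    "KinshipLMM",
    "KinshipLMMResults",
    "AssociationScan",
    "StepwiseFit",
    "SpikeSlabFit",
    "VarianceDecomposition",
    "fit_null_lmm",
    "scan_single_snp",
    "stepwise_mlmm",
    "spike_slab_fit",
    "estimate_pve",
]


def _align_response(eblups, sample_ids: list[str]) -> np.ndarray:
    if isinstance(eblups, pd.Series):
        missing = [s for s in sample_ids if s not in eblups.index]
        if missing:
            raise ValueError(f"eblups lack samples: {missing[:5]}...")
        return eblups.reindex(sample_ids).to_numpy(dtype=float)
    y = np.asarray(eblups, dtype=float)
    if len(y) != len(sample_ids):
        raise ValueError("response length does not match sample count")
    return y


# ---------------------------------------------------------------------------
# Kinship linear mixed model (single spectral decomposition, 1-D REML)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class KinshipLMMResults:
    """REML fit of y = X beta + u + e with u ~ N(0, sigma2_u A)."""

    mu: float
    beta: np.ndarray
    sigma2_u: float
    sigma2_e: float
    loglik: float
    lambda_ratio: float  # sigma2_u / sigma2_e

    @property
    def heritability_ratio(self) -> float:
        tot = self.sigma2_u + self.sigma2_e
        return self.sigma2_u / tot if tot > 0 else 0.0

    def summary(self) -> str:
        return (
            "Kinship LMM (ReML)\n"
            f"  sigma2_u = {self.sigma2_u:.5f}\n"
            f"  sigma2_e = {self.sigma2_e:.5f}\n"
            f"  h2 ratio = {self.heritability_ratio:.4f}\n"
            f"  logLik   = {self.loglik:.3f}"
        )


class KinshipLMM:
    """Mixed model with covariance ``sigma2_u A + sigma2_e I``.

    A single eigendecomposition of ``A`` reduces every (RE)ML evaluation to
    diagonal weighted least squares; the variance ratio is profiled by 1-D
    bounded optimization.  Non-PSD ``A`` (beyond numerical tolerance) gets
    minimal diagonal jitter with a warning.
    """

    def __init__(self, y, A: np.ndarray, X: np.ndarray | None = None,
                 sample_ids: list[str] | None = None) -> None:
        if sample_ids is not None:
            y = _align_response(y, sample_ids)
        y = np.asarray(y, dtype=float)
        n = len(y)
        if A.shape != (n, n):
            raise ValueError("kinship matrix shape does not match response")
        lam, U = np.linalg.eigh((A + A.T) / 2.0)
        if lam.min() < -1e-8 * max(1.0, lam.max()):
            warnings.warn("kinship not PSD; adding minimal diagonal jitter")
        lam = np.clip(lam, 0.0, None)
        self.eigvals, self.U = lam, U
        self.y = y
        self.ys = U.T @ y
        X = np.ones((n, 1)) if X is None else np.asarray(X, dtype=float)
        self.X = X
        self.Xs = U.T @ X
        self.n, self.p = X.shape

    def _profile(self, log_ratio: float, reml: bool):
        ratio = math.exp(min(log_ratio, 30.0))
        v = ratio * self.eigvals + 1.0
        w = 1.0 / v
        Xw = self.Xs * w[:, None]
        XtVX = self.Xs.T @ Xw
        XtVy = Xw.T @ self.ys
        try:
            beta = np.linalg.solve(XtVX, XtVy)
        except np.linalg.LinAlgError:
            beta = np.linalg.pinv(XtVX) @ XtVy
        rss = float(self.ys @ (w * self.ys) - XtVy @ beta)
        dof = self.n - self.p if reml else self.n
        if rss <= 1e-300:
            return np.inf, None
        s2e = rss / dof
        ll = -0.5 * (dof * (math.log(2 * math.pi * s2e) + 1) + np.log(v).sum())
        if reml:
            ll -= 0.5 * np.linalg.slogdet(XtVX)[1]
        return -ll, {"beta": beta, "sigma2_e": s2e, "ratio": ratio, "loglik": ll}

    def fit(self, reml: bool = True) -> KinshipLMMResults:
        if np.var(self.y) <= 1e-300:
            beta = np.zeros(self.p)
            beta[0] = self.y.mean() if self.p else 0.0
            return KinshipLMMResults(float(beta[0]), beta, 0.0, 0.0, 0.0, 0.0)
        grid = np.linspace(-12.0, 12.0, 49)
        vals = [self._profile(g, reml)[0] for g in grid]
        g0 = grid[int(np.argmin(vals))]
        res = optimize.minimize_scalar(
            lambda x: self._profile(x, reml)[0],
            bounds=(max(g0 - 1.0, -14.0), min(g0 + 1.0, 14.0)),
            method="bounded", options={"xatol": 1e-8},
        )
        _, aux = self._profile(res.x, reml)
        s2e = aux["sigma2_e"]
        return KinshipLMMResults(
            mu=float(aux["beta"][0]),
            beta=aux["beta"],
            sigma2_u=aux["ratio"] * s2e,
            sigma2_e=s2e,
            loglik=aux["loglik"],
            lambda_ratio=aux["ratio"],
        )


def fit_null_lmm(eblups, A: np.ndarray, sample_ids: list[str] | None = None) -> KinshipLMMResults:
    """REML fit of the intercept-only polygenic model (the scan's null)."""
    return KinshipLMM(eblups, A, sample_ids=sample_ids).fit(reml=True)


# ---------------------------------------------------------------------------
# SNP-by-SNP scan
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AssociationScan:
    """Per-SNP effects, Wald statistics and Bonferroni significance."""

    table: pd.DataFrame
    bonferroni_threshold: float
    null_fit: KinshipLMMResults

    @property
    def significant(self) -> pd.DataFrame:
        return self.table.loc[self.table["significant"]]

    def summary(self) -> str:
        k = int(self.table["significant"].sum())
        return (
            f"Single-SNP kinship scan: {len(self.table)} SNPs, "
            f"Bonferroni p < {self.bonferroni_threshold:.3g}, {k} significant\n"
            + self.null_fit.summary()
        )


def _gls_scan(ys, Gs, Xs, w):
    """GLS effect/SE for every SNP column with covariates Xs, weights w.

    Operates in the rotated basis with absolute weights (inverse marginal
    variances), so var(beta_hat) = 1 / Sxx directly.
    """
    sq = np.sqrt(w)
    Xw = Xs * sq[:, None]
    yw = ys * sq
    Q, _ = np.linalg.qr(Xw)
    Gw = Gs * sq[:, None]
    Gres = Gw - Q @ (Q.T @ Gw)
    yres = yw - Q @ (Q.T @ yw)
    sxx = np.einsum("ij,ij->j", Gres, Gres)
    sxy = Gres.T @ yres
    ok = sxx > 1e-10 * np.einsum("ij,ij->j", Gw, Gw).clip(min=1e-300)
    beta = np.where(ok, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
    se = np.where(ok, 1.0 / np.sqrt(np.where(sxx > 0, sxx, 1.0)), np.inf)
    wald = np.where(ok, beta**2 * sxx, 0.0)
    pval = np.where(ok, stats.chi2.sf(wald, 1), 1.0)
    return beta, se, wald, pval, ok


def scan_single_snp(
    eblups,
    geno: GenotypeMatrix,
    A: np.ndarray,
    alpha: float = 0.05,
    exact: bool = False,
) -> AssociationScan:
    """Single-SNP mixed-model scan with Wald tests and Bonferroni control.

    Variance components are estimated once under the null and reused for
    every SNP (EMMAX-style approximation); ``exact=True`` re-estimates them
    per SNP by REML.  Monomorphic SNPs get beta = 0, p = 1.
    """
    y = _align_response(eblups, geno.sample_ids)
    null = KinshipLMM(y, A)
    nres = null.fit(reml=True)
    G = geno.imputed()
    Gs = null.U.T @ G
    var = nres.sigma2_u * null.eigvals + nres.sigma2_e
    w = 1.0 / np.clip(var, 1e-12, None)
    beta, se, wald, pval, ok = _gls_scan(null.ys, Gs, null.Xs, w)
    if exact:
        for j in range(geno.n_snps):
            if not ok[j]:
                continue
            X = np.column_stack([np.ones(len(y)), G[:, j]])
            fit_j = KinshipLMM(y, A, X=X).fit(reml=True)
            vj = fit_j.sigma2_u * null.eigvals + fit_j.sigma2_e
            bj, sj, wj, pj, okj = _gls_scan(
                null.ys, Gs[:, [j]], null.Xs, 1.0 / np.clip(vj, 1e-12, None)
            )
            beta[j], se[j], wald[j], pval[j] = bj[0], sj[0], wj[0], pj[0]
    P = geno.n_snps
    thr = alpha / P if P else np.nan
    table = geno.markers[["id", "chrom", "pos"]].copy()
    table["beta"] = beta
    table["se"] = se
    table["wald"] = wald
    table["pvalue"] = np.clip(pval, np.nextafter(0, 1), 1.0)
    table["significant"] = ok & (table["pvalue"] < thr)
    return AssociationScan(table, thr, nres)


# ---------------------------------------------------------------------------
# Stepwise multi-locus mixed model
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class StepwiseFit:
    """Forward-selection path with extended-BIC model choice."""

    cofactors: list[str]              # SNP ids of the eBIC-best model
    path: list[str]                   # full inclusion order
    step_pvalues: list[float]
    ebic_path: list[float]
    h2_path: list[float]
    best_model_index: int
    heritability_ratio: float         # polygenic ratio at the best model
    table: pd.DataFrame               # effects of the best model's cofactors

    def summary(self) -> str:
        return (
            f"Stepwise multi-locus mixed model: path length {len(self.path)}, "
            f"best model has {len(self.cofactors)} cofactors "
            f"(eBIC = {self.ebic_path[self.best_model_index]:.2f}, "
            f"residual polygenic ratio = {self.heritability_ratio:.3f})"
        )


def _ebic(loglik_ml: float, k: int, n: int, P: int, gamma: float) -> float:
    pen = k * math.log(n) + 2.0 * gamma * (
        gammaln(P + 1) - gammaln(k + 1) - gammaln(P - k + 1)
    )
    return -2.0 * loglik_ml + float(pen)


def stepwise_mlmm(
    eblups,
    geno: GenotypeMatrix,
    A: np.ndarray,
    max_iter: int = 50,
    gamma: float = 1.0,
    h2_stop: float = 0.01,
) -> StepwiseFit:
    """Forward stepwise mixed-model association with eBIC model selection.

    Each iteration adds, as a fixed cofactor, the SNP with the smallest Wald
    p-value (ties broken by genome order), re-estimating the polygenic and
    residual variances, until the polygenic heritability ratio is close to
    zero (< ``h2_stop``) or ``max_iter`` inclusions.  The reported
    significant SNPs are the cofactors of the model minimizing the extended
    BIC (penalty ``gamma``) along the path.
    """
    y = _align_response(eblups, geno.sample_ids)
    n = len(y)
    base = KinshipLMM(y, A)
    G = geno.imputed()
    Gs = base.U.T @ G
    P = geno.n_snps
    ids = geno.markers["id"].tolist()

    included: list[int] = []
    step_pvalues: list[float] = []
    ebic_path: list[float] = []
    h2_path: list[float] = []

    while True:
        X = np.column_stack([np.ones(n)] + [G[:, j] for j in included])
        model = KinshipLMM(y, A, X=X)
        fit_reml = model.fit(reml=True)
        fit_ml = model.fit(reml=False)
        h2 = fit_reml.heritability_ratio
        h2_path.append(h2)
        ebic_path.append(_ebic(fit_ml.loglik, len(included), n, P, gamma))
        # the h2 stop applies once at least one cofactor is in: a lone
        # large-effect SNP can leave the *null* polygenic ratio near zero
        if len(included) >= max_iter or (included and h2 < h2_stop):
            break
        var = fit_reml.sigma2_u * base.eigvals + fit_reml.sigma2_e
        w = 1.0 / np.clip(var, 1e-12, None)
        Xs = base.U.T @ X
        beta, se, wald, pval, ok = _gls_scan(base.ys, Gs, Xs, w)
        pval = np.where(ok, pval, np.inf)
        pval[included] = np.inf
        j = int(np.argmin(pval))  # stable argmin = genome order on ties
        if not np.isfinite(pval[j]):
            break
        included.append(j)
        step_pvalues.append(float(np.clip(pval[j], np.nextafter(0, 1), 1.0)))

    best = int(np.argmin(ebic_path))
    cof_idx = included[:best]
    # effects of the best model
    Xb = np.column_stack([np.ones(n)] + [G[:, j] for j in cof_idx])
    fit_b = KinshipLMM(y, A, X=Xb).fit(reml=True)
    table = pd.DataFrame({
        "id": [ids[j] for j in cof_idx],
        "chrom": geno.markers["chrom"].iloc[cof_idx].to_numpy(),
        "pos": geno.markers["pos"].iloc[cof_idx].to_numpy(),
        "beta": fit_b.beta[1:] if len(cof_idx) else np.empty(0),
        "order": np.arange(len(cof_idx)),
    })
    return StepwiseFit(
        cofactors=[ids[j] for j in cof_idx],
        path=[ids[j] for j in included],
        step_pvalues=step_pvalues,
        ebic_path=ebic_path,
        h2_path=h2_path,
        best_model_index=best,
        heritability_ratio=h2_path[best],
        table=table,
    )


# ---------------------------------------------------------------------------
# Spike-and-slab variational Bayes
# ---------------------------------------------------------------------------

try:  # compiled inner loop; the sweep is inherently sequential over SNPs
    from numba import njit

    @njit(cache=True)
    def _ssvs_sweep(XF, d, alpha, mu, r, sigma2, sa2, logit_pi):
        n, P = XF.shape
        for p in range(P):
            b_old = alpha[p] * mu[p]
            xr = 0.0
            for i in range(n):
                xr += XF[i, p] * r[i]
            xr += d[p] * b_old
            denom = d[p] + 1.0 / sa2
            s2 = sigma2 / denom
            m = xr / denom
            lo = logit_pi + 0.5 * math.log(s2 / (sa2 * sigma2)) + m * m / (2.0 * s2)
            if lo > 35.0:
                a = 1.0
            elif lo < -35.0:
                a = 0.0
            else:
                a = 1.0 / (1.0 + math.exp(-lo))
            mu[p] = m
            alpha[p] = a
            b_new = a * m
            diff = b_new - b_old
            if diff != 0.0:
                for i in range(n):
                    r[i] -= XF[i, p] * diff
except Exception:  # pragma: no cover - numba always present in practice
    njit = None

    def _ssvs_sweep(XF, d, alpha, mu, r, sigma2, sa2, logit_pi):
        n, P = XF.shape
        for p in range(P):
            b_old = alpha[p] * mu[p]
            xr = XF[:, p] @ r + d[p] * b_old
            denom = d[p] + 1.0 / sa2
            s2 = sigma2 / denom
            m = xr / denom
            lo = logit_pi + 0.5 * math.log(s2 / (sa2 * sigma2)) + m * m / (2.0 * s2)
            a = float(expit(lo))
            mu[p] = m
            alpha[p] = a
            r -= XF[:, p] * (a * m - b_old)


def _ssvs_elbo(y_c, XF, d, alpha, mu, r, sigma2, sa2, pi):
    n = len(y_c)
    s2 = sigma2 / (d + 1.0 / sa2)
    var_b = alpha * (s2 + mu**2) - (alpha * mu) ** 2
    a = np.clip(alpha, 1e-12, 1 - 1e-12)
    elbo = (
        -0.5 * n * np.log(2 * np.pi * sigma2)
        - 0.5 * (r @ r) / sigma2
        - 0.5 * np.sum(d * var_b) / sigma2
        + np.sum(a * np.log(pi / a) + (1 - a) * np.log((1 - pi) / (1 - a)))
        + 0.5 * np.sum(alpha * (1.0 + np.log(s2 / (sa2 * sigma2))
                                - (s2 + mu**2) / (sa2 * sigma2)))
    )
    return float(elbo)


@dataclasses.dataclass
class SpikeSlabFit:
    """Variational spike-and-slab fit, importance-averaged over a prior grid."""

    pip: pd.Series                    # posterior inclusion probability per SNP
    beta_mean: pd.Series              # posterior-mean (model-averaged) effects
    hyper_grid: pd.DataFrame          # pi0, slab scale, elbo, weight
    pip_threshold: float
    intercept: float
    column_means: np.ndarray

    @property
    def significant(self) -> pd.Series:
        return self.pip[self.pip > self.pip_threshold]

    def summary(self) -> str:
        return (
            f"Spike-and-slab variational fit: {len(self.pip)} SNPs, "
            f"{int((self.pip > self.pip_threshold).sum())} with PIP > "
            f"{self.pip_threshold:.2f}; grid of {len(self.hyper_grid)} prior points"
        )


def spike_slab_fit(
    eblups,
    geno: GenotypeMatrix | np.ndarray,
    pip_threshold: float = 0.80,
    n_grid: int = 20,
    pi_grid: np.ndarray | None = None,
    slab_var: float | None = None,
    sigma2: float | None = None,
    max_sweeps: int = 300,
    tol: float = 1e-4,
    marker_ids: list[str] | None = None,
) -> SpikeSlabFit:
    """Bayesian variable selection with a spike-and-slab prior, fitted by
    coordinate-ascent variational inference.

    Each SNP effect has prior ``beta_p ~ (1-pi0) delta_0 + pi0 N(0, sb2)``;
    the fully-factorized posterior is optimized per point of a log-spaced
    grid of ``pi0`` in [1/P, 0.5] (slab variance and residual variance
    updated by empirical Bayes unless fixed), and per-SNP inclusion
    probabilities are importance-weighted across the grid by the variational
    lower bound.  A decreasing lower bound raises ``RuntimeError`` (update
    bug guard).
    """
    if isinstance(geno, GenotypeMatrix):
        X = geno.imputed()
        if marker_ids is None:
            marker_ids = geno.markers["id"].tolist()
        y = _align_response(eblups, geno.sample_ids)
    else:
        X = np.asarray(geno, dtype=float)
        y = np.asarray(eblups, dtype=float)
        if marker_ids is None:
            marker_ids = [f"snp{j}" for j in range(X.shape[1])]
    n, P = X.shape
    col_means = X.mean(axis=0)
    XF = np.asfortranarray(X - col_means)
    y_mean = float(np.mean(y))
    y_c = y - y_mean
    d = np.einsum("ij,ij->j", XF, XF)
    d = np.where(d > 0, d, 1e-12)
    var_y = float(y_c @ y_c) / max(n - 1, 1)
    if var_y <= 0:
        var_y = 1e-12

    if pi_grid is None:
        pi_grid = np.exp(np.linspace(np.log(1.0 / max(P, 2)), np.log(0.5), n_grid))
    pi_grid = np.atleast_1d(np.asarray(pi_grid, dtype=float))

    alpha = np.full(P, 0.1)
    mu = np.zeros(P)
    results = []
    for pi in pi_grid:
        sig2 = var_y if sigma2 is None else float(sigma2)
        sa2 = (
            max(var_y / (pi * P * np.mean(d) / n), 1e-6) / sig2
            if slab_var is None else float(slab_var) / sig2
        )
        alpha = alpha.copy()
        mu = mu.copy()
        r = y_c - XF @ (alpha * mu)
        logit_pi = float(np.log(pi / (1.0 - pi)))
        prev = -np.inf
        for sweep in range(max_sweeps):
            _ssvs_sweep(XF, d, alpha, mu, r, sig2, sa2, logit_pi)
            s2 = sig2 / (d + 1.0 / sa2)
            if slab_var is None:
                ssum = float(np.sum(alpha))
                if ssum > 1e-8:
                    sa2 = max(float(np.sum(alpha * (s2 + mu**2))) / (sig2 * ssum), 1e-10)
            if sigma2 is None:
                var_b = alpha * (s2 + mu**2) - (alpha * mu) ** 2
                num = float(r @ r) + float(np.sum(d * var_b)) \
                    + float(np.sum(alpha * (s2 + mu**2))) / sa2
                sig2 = max(num / (n + float(np.sum(alpha))), 1e-12)
            elbo = _ssvs_elbo(y_c, XF, d, alpha, mu, r, sig2, sa2, pi)
            if elbo < prev - 1e-3 * (1.0 + abs(prev)) and sigma2 is not None and slab_var is not None:
                raise RuntimeError("variational lower bound decreased: update bug")
            if abs(elbo - prev) < tol * (1.0 + abs(elbo)):
                prev = elbo
                break
            prev = elbo
        results.append({
            "pi0": float(pi), "slab_var": sa2 * sig2, "sigma2": sig2,
            "elbo": prev, "alpha": alpha.copy(), "mu": mu.copy(),
        })

    elbos = np.array([r_["elbo"] for r_ in results])
    wts = np.exp(elbos - elbos.max())
    wts /= wts.sum()
    pip = np.sum([w * r_["alpha"] for w, r_ in zip(wts, results)], axis=0)
    beta_mean = np.sum([w * r_["alpha"] * r_["mu"] for w, r_ in zip(wts, results)], axis=0)
    grid = pd.DataFrame({
        "pi0": [r_["pi0"] for r_ in results],
        "slab_var": [r_["slab_var"] for r_ in results],
        "sigma2": [r_["sigma2"] for r_ in results],
        "elbo": elbos,
        "weight": wts,
    })
    return SpikeSlabFit(
        pip=pd.Series(pip, index=marker_ids, name="pip"),
        beta_mean=pd.Series(beta_mean, index=marker_ids, name="beta_mean"),
        hyper_grid=grid,
        pip_threshold=pip_threshold,
        intercept=y_mean,
        column_means=col_means,
    )


# ---------------------------------------------------------------------------
# PVE: variance of eBLUPs explained by all SNPs jointly
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class VarianceDecomposition:
    """GBLUP variance decomposition of genotypic eBLUPs."""

    pve_snps: float
    sigma2_a: float
    sigma2_d: float | None
    sigma2_e: float
    converged: bool
    identifiability_warning: str | None = None
    ci_low: float | None = None
    ci_high: float | None = None

    def summary(self) -> str:
        lines = [
            "SNP variance decomposition (GBLUP)",
            f"  sigma2_a = {self.sigma2_a:.5f}",
        ]
        if self.sigma2_d is not None:
            lines.append(f"  sigma2_d = {self.sigma2_d:.5f}")
        lines += [
            f"  sigma2_e = {self.sigma2_e:.5f}",
            f"  PVE_SNPs = {self.pve_snps:.4f}",
            f"  converged: {self.converged}",
        ]
        if self.identifiability_warning:
            lines.append(f"  note: {self.identifiability_warning}")
        return "\n".join(lines)


def _two_kernel_reml(y: np.ndarray, kernels: list[np.ndarray]):
    """Dense REML over variance ratios for >=2 kernels plus residual."""
    n = len(y)
    X = np.ones((n, 1))

    def nll(x):
        V = np.eye(n).copy()
        for ratio, K in zip(np.exp(np.clip(x, -15, 10)), kernels):
            V += ratio * K
        try:
            c, low = np.linalg.cholesky(V), True
        except np.linalg.LinAlgError:
            return np.inf
        logdet = 2.0 * np.log(np.diag(c)).sum()
        Vi_y = np.linalg.solve(V, y)
        Vi_X = np.linalg.solve(V, X)
        XtViX = X.T @ Vi_X
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        rss = float(y @ Vi_y - (X.T @ Vi_y).T @ beta)
        if rss <= 0:
            return np.inf
        dof = n - 1
        s2e = rss / dof
        return 0.5 * (dof * (math.log(2 * math.pi * s2e) + 1) + logdet
                      + np.linalg.slogdet(XtViX)[1])

    x0 = np.zeros(len(kernels))
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 500})
    ratios = np.exp(np.clip(res.x, -15, 10))
    V = np.eye(n).copy()
    for ratio, K in zip(ratios, kernels):
        V += ratio * K
    Vi_y = np.linalg.solve(V, y)
    Vi_X = np.linalg.solve(V, X)
    beta = np.linalg.solve(X.T @ Vi_X, X.T @ Vi_y)
    rss = float(y @ Vi_y - (X.T @ Vi_y).T @ beta)
    s2e = rss / (n - 1)
    return ratios * s2e, s2e, bool(res.success)


def estimate_pve(
    eblups,
    A: np.ndarray,
    D: np.ndarray | None = None,
    n_boot: int = 0,
    seed: int | None = None,
    sample_ids: list[str] | None = None,
) -> VarianceDecomposition:
    """Proportion of eBLUP variance explained jointly by the SNPs.

    Fits eBLUP(g) = 1 mu + g_a (+ g_d) + e with g_a ~ N(0, sigma2_a A) and
    optionally g_d ~ N(0, sigma2_d D); PVE = sigma2_a / (sigma2_a +
    sigma2_d + sigma2_e).  When D is numerically close to the identity the
    dominance component is confounded with the residual; this is reported
    honestly via ``identifiability_warning`` and the ``converged`` flag.
    """
    if sample_ids is not None:
        eblups = _align_response(eblups, sample_ids)
    y = np.asarray(eblups, dtype=float)
    warn = None
    if D is None:
        fit = KinshipLMM(y, A).fit(reml=True)
        s2a, s2d, s2e = fit.sigma2_u, None, fit.sigma2_e
        converged = True
        denom = s2a + s2e
    else:
        n_ = len(y)
        off = D[~np.eye(n_, dtype=bool)]
        rms_off = float(np.sqrt(np.mean(off**2)))
        if rms_off < 0.1:
            warn = (
                f"dominance relationship matrix is near-identity (RMS "
                f"off-diagonal = {rms_off:.3f}): sigma2_d is weakly "
                "identified against the residual"
            )
        (s2a, s2d), s2e, converged = _two_kernel_reml(y, [A, D])
        denom = s2a + s2d + s2e
    pve = s2a / denom if denom > 0 else 0.0
    ci_low = ci_high = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = len(y)
        La = np.linalg.cholesky(A + 1e-8 * np.eye(n))
        draws = []
        for _ in range(n_boot):
            y_star = (y.mean() + La @ rng.standard_normal(n) * math.sqrt(s2a)
                      + rng.normal(0, math.sqrt(s2e), n))
            f = KinshipLMM(y_star, A).fit(reml=True)
            tot = f.sigma2_u + f.sigma2_e
            draws.append(f.sigma2_u / tot if tot > 0 else 0.0)
        ci_low, ci_high = (float(q) for q in np.percentile(draws, [2.5, 97.5]))
    return VarianceDecomposition(
        pve_snps=float(np.clip(pve, 0.0, 1.0)),
        sigma2_a=float(s2a),
        sigma2_d=None if s2d is None else float(s2d),
        sigma2_e=float(s2e),
        converged=converged,
        identifiability_warning=warn,
        ci_low=ci_low,
        ci_high=ci_high,
    )
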