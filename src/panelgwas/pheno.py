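"""Stage 1: plot-level phenotypes to genotypic eBLUPs and heritability.

A multi-environment trial is modelled with a linear mixed model containing
arbitrary fixed design terms (block, year, block:year, plot covariates) and
the two random terms the downstream analysis needs: genotype and
genotype-year interaction,

    y = X beta + Z_g g + Z_gy (g:y) + e,
    g ~ N(0, sigma2_g I),  (g:y) ~ N(0, sigma2_gy I),  e ~ N(0, sigma2_e I).

Because both random terms nest within genotype, the marginal covariance is
block-diagonal by genotype, which makes (RE)ML estimation, backward
elimination, eBLUP extraction and parametric bootstrap cheap even for
thousands of plots.

Model selection follows the classical backward scheme: random terms are
eliminated first by likelihood-ratio tests (boundary-corrected with the
0.5*chi2_0 + 0.5*chi2_1 mixture), then marginal fixed terms by Wald/F tests,
respecting marginality (an interaction blocks the elimination of its main
effects).  The genotype term itself is never dropped: its eBLUPs are the
response of the downstream association stage.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PlotPhenotypes",
    "TrialMixedModel",
    "TrialModelResults",
    "HeritabilityEstimate",
    "transform_response",
    "fit_and_select",
    "heritability",
    "read_phenotypes_tsv",
    "write_phenotypes_tsv",
]

_LOG_GAMMA_MIN, _LOG_GAMMA_MAX = -15.0, 8.0


@dataclasses.dataclass
class PlotPhenotypes:
    """Plot-level trial records.

    ``data`` holds one row per plot with at least the columns ``genotype``,
    ``block``, ``year`` and the response; ``covariates`` names the plot-level
    covariate columns; ``row``/``rank`` are field-grid coordinates when
    present.  A (genotype, block, year) triple identifies at most one record
    per response variable.
    """

    data: pd.DataFrame
    covariates: list[str] = dataclasses.field(default_factory=list)
    response: str = "value"

    def __post_init__(self) -> None:
        missing = {"genotype", "block", "year"} - set(self.data.columns)
        if missing:
            raise ValueError(f"phenotype table lacks columns: {sorted(missing)}")
        dup = self.data.duplicated(subset=["genotype", "block", "year"])
        if dup.any():
            raise ValueError("duplicate (genotype, block, year) records")

    def dropna_response(self) -> pd.DataFrame:
        return self.data.loc[self.data[self.response].notna()].reset_index(drop=True)


def read_phenotypes_tsv(path: str | Path, response: str = "value") -> PlotPhenotypes:
    """Read a phenotype table (TSV with header, NA = missing)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    core = {"genotype", "block", "year", "treatment", "row", "rank", response}
    covars = [c for c in df.columns if c not in core]
    for c in ("genotype", "block", "year"):
        if c in df.columns:
            df[c] = df[c].astype(str)
    return PlotPhenotypes(df, covariates=covars, response=response)


def write_phenotypes_tsv(pheno: PlotPhenotypes, path: str | Path) -> None:
    pheno.data.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Response transformation
# ---------------------------------------------------------------------------

def transform_response(
    values: np.ndarray | pd.Series,
    mode: str = "auto",
    skew_cutoff: float = 2.0,
) -> tuple[np.ndarray, str]:
    """Optionally natural-log-transform a response.

    ``auto`` applies ``log`` when the absolute sample skewness exceeds
    ``skew_cutoff`` (missing values ignored), otherwise leaves the data
    untouched.  Returns the (possibly transformed) values and the applied
    transformation label (``"log"`` or ``"none"``) for provenance.
    """
    v = np.asarray(values, dtype=float)
    if mode not in {"auto", "log", "none"}:
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "none":
        return v, "none"
    apply_log = mode == "log"
    if mode == "auto":
        obs = v[~np.isnan(v)]
        apply_log = len(obs) >= 3 and abs(stats.skew(obs)) > skew_cutoff
    if not apply_log:
        return v, "none"
    bad = np.where(~np.isnan(v) & (v <= 0))[0]
    if len(bad):
        raise ValueError(
            f"log transform requires positive values; first offending record index {bad[0]}"
        )
    return np.log(v), "log"


# ---------------------------------------------------------------------------
# Fixed-effect design construction
# ---------------------------------------------------------------------------

def _is_categorical(s: pd.Series) -> bool:
    return s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool


def _term_columns(df: pd.DataFrame, term: str) -> tuple[np.ndarray, list[str]]:
    """Design columns for one (possibly interaction) term, treatment-coded."""
    blocks: list[np.ndarray] = []
    for part in term.split(":"):
        col = df[part]
        if _is_categorical(col):
            d = pd.get_dummies(col.astype(str), prefix=part, drop_first=True)
            blocks.append(d.to_numpy(dtype=float))
        else:
            blocks.append(col.to_numpy(dtype=float)[:, None])
    out = blocks[0]
    for b in blocks[1:]:
        out = np.einsum("ni,nj->nij", out, b).reshape(len(df), -1)
    names = [f"{term}[{k}]" for k in range(out.shape[1])]
    return out, names


def _build_design(df: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, dict[str, slice]]:
    cols = [np.ones((len(df), 1))]
    slices: dict[str, slice] = {}
    start = 1
    for t in terms:
        arr, _ = _term_columns(df, t)
        cols.append(arr)
        slices[t] = slice(start, start + arr.shape[1])
        start += arr.shape[1]
    return np.hstack(cols), slices


def _droppable(terms: list[str]) -> list[str]:
    """Marginal terms: not strictly contained in another term present."""
    out = []
    for t in terms:
        parts = set(t.split(":"))
        if not any(parts < set(o.split(":")) for o in terms if o != t):
            out.append(t)
    return out


# ---------------------------------------------------------------------------
# Blockwise variance-component engine
# ---------------------------------------------------------------------------

class _GenoYearLMM:
    """(RE)ML for y = X beta + Z_g g + [Z_gy gy] + e, block-diagonal by genotype."""

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        geno_codes: np.ndarray,
        year_codes: np.ndarray,
        include_gy: bool,
        geno_labels: list | None = None,
    ) -> None:
        order = np.lexsort((year_codes, geno_codes))
        self.order = order
        self.y = y[order].astype(float)
        self.X = X[order].astype(float)
        self.g = geno_codes[order]
        self.t = year_codes[order]
        self.include_gy = include_gy
        self.n, self.p = self.X.shape
        self.geno_labels = geno_labels

        # group genotypes sharing the same within-genotype year pattern
        self.patterns: list[dict] = []
        bounds = np.flatnonzero(np.r_[True, np.diff(self.g) != 0, True])
        by_key: dict[tuple, dict] = {}
        for s, e in zip(bounds[:-1], bounds[1:]):
            key = tuple(self.t[s:e])
            d = by_key.setdefault(key, {"rows": [], "genos": []})
            d["rows"].append((s, e))
            d["genos"].append(self.g[s])
        for key, d in by_key.items():
            k = len(key)
            Y = np.stack([self.y[s:e] for s, e in d["rows"]])
            Xa = np.stack([self.X[s:e] for s, e in d["rows"]])
            tvec = np.asarray(key)
            S = (tvec[:, None] == tvec[None, :]).astype(float)
            pat = {"k": k, "Y": Y, "X": Xa, "S": S,
                   "genos": np.asarray(d["genos"]), "spans": list(d["rows"])}
            # sufficient statistics: likelihood evaluations become O(k^2 p^2),
            # independent of the number of genotypes in the pattern
            pat["Sxx"] = np.einsum("gki,glj->klij", Xa, Xa, optimize=True)
            self._pattern_response_stats(pat)
            self.patterns.append(pat)

    @staticmethod
    def _pattern_response_stats(pat: dict) -> None:
        pat["Sxy"] = np.einsum("gki,gl->kli", pat["X"], pat["Y"], optimize=True)
        pat["Syy"] = np.einsum("gk,gl->kl", pat["Y"], pat["Y"], optimize=True)

    def with_response(self, y_sorted: np.ndarray) -> "_GenoYearLMM":
        """Shallow copy of the engine with a new response (engine row order)."""
        eng = object.__new__(_GenoYearLMM)
        eng.__dict__.update(self.__dict__)
        eng.y = np.asarray(y_sorted, dtype=float)
        eng.patterns = []
        for pat in self.patterns:
            pat2 = dict(pat)
            pat2["Y"] = np.stack([eng.y[s:e] for s, e in pat["spans"]])
            self._pattern_response_stats(pat2)
            eng.patterns.append(pat2)
        return eng

    def _accumulate(self, gam_g: float, gam_gy: float):
        p = self.p
        XtCiX = np.zeros((p, p))
        XtCiy = np.zeros(p)
        ytCiy = 0.0
        logdet = 0.0
        cache = []
        for pat in self.patterns:
            k = pat["k"]
            C = np.eye(k) + gam_g * np.ones((k, k))
            if self.include_gy:
                C += gam_gy * pat["S"]
            sign, ld = np.linalg.slogdet(C)
            if sign <= 0:
                return None
            Ci = np.linalg.inv(C)
            m = pat["Y"].shape[0]
            logdet += m * ld
            XtCiX += np.einsum("kl,klij->ij", Ci, pat["Sxx"])
            XtCiy += np.einsum("kl,kli->i", Ci, pat["Sxy"])
            ytCiy += float(np.einsum("kl,kl->", Ci, pat["Syy"]))
            cache.append(Ci)
        return XtCiX, XtCiy, ytCiy, logdet, cache

    def _profile(self, x: np.ndarray, reml: bool):
        gam_g = float(np.exp(np.clip(x[0], _LOG_GAMMA_MIN, _LOG_GAMMA_MAX)))
        gam_gy = (
            float(np.exp(np.clip(x[1], _LOG_GAMMA_MIN, _LOG_GAMMA_MAX)))
            if self.include_gy
            else 0.0
        )
        acc = self._accumulate(gam_g, gam_gy)
        if acc is None:
            return -np.inf, None
        XtCiX, XtCiy, ytCiy, logdet, cache = acc
        try:
            beta = np.linalg.solve(XtCiX, XtCiy)
        except np.linalg.LinAlgError:
            beta = np.linalg.pinv(XtCiX) @ XtCiy
        rss = float(ytCiy - XtCiy @ beta)
        n, p = self.n, self.p
        dof = n - p if reml else n
        if rss <= 1e-300 or dof <= 0:
            return -np.inf, None
        sigma2e = rss / dof
        ll = -0.5 * (dof * (np.log(2 * np.pi * sigma2e) + 1) + logdet)
        if reml:
            sign, ldx = np.linalg.slogdet(XtCiX)
            ll -= 0.5 * ldx
        aux = {
            "gam_g": gam_g,
            "gam_gy": gam_gy,
            "beta": beta,
            "sigma2e": sigma2e,
            "XtCiX": XtCiX,
            "cache": cache,
        }
        return ll, aux

    def fit(self, reml: bool = True, x0: np.ndarray | None = None) -> dict:
        nll = lambda x: -self._profile(np.atleast_1d(x), reml)[0]
        if self.include_gy:
            starts = [np.array([0.0, -1.0]) if x0 is None else np.asarray(x0)]
            starts.append(np.array([-2.0, -3.0]))
            best = None
            for s in starts:
                res = optimize.minimize(nll, s, method="Nelder-Mead",
                                        options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 400})
                if best is None or res.fun < best.fun:
                    best = res
                if np.isfinite(best.fun):
                    break
            if not np.isfinite(best.fun):
                raise RuntimeError("mixed-model fit failed to converge from all starts")
            xopt = best.x
        else:
            res = optimize.minimize_scalar(
                nll, bounds=(_LOG_GAMMA_MIN, _LOG_GAMMA_MAX), method="bounded",
                options={"xatol": 1e-7},
            )
            xopt = np.array([res.x])
        ll, aux = self._profile(xopt, reml)
        s2e = aux["sigma2e"]
        out = {
            "loglik": ll,
            "reml": reml,
            "beta": aux["beta"],
            "sigma2_e": s2e,
            "sigma2_g": aux["gam_g"] * s2e,
            "sigma2_gy": aux["gam_gy"] * s2e if self.include_gy else 0.0,
            "gam_g": aux["gam_g"],
            "gam_gy": aux["gam_gy"],
            "cov_beta": s2e * np.linalg.pinv(aux["XtCiX"]),
            "x": xopt,
        }
        out.update(self._blups(aux))
        return out

    def _blups(self, aux: dict) -> dict:
        """Genotype eBLUPs and their prediction-error variances."""
        gam_g = aux["gam_g"]
        s2e = aux["sigma2e"]
        s2g = gam_g * s2e
        genos: list = []
        blups: list = []
        pevs: list = []
        for pat, Ci in zip(self.patterns, aux["cache"]):
            R = pat["Y"] - pat["X"] @ aux["beta"]
            cvec = Ci.sum(axis=1)
            u = gam_g * (R @ cvec)
            pev = s2g * max(0.0, 1.0 - gam_g * float(cvec.sum()))
            genos.extend(pat["genos"].tolist())
            blups.extend(u.tolist())
            pevs.extend([pev] * len(pat["genos"]))
        order = np.argsort(genos)
        return {
            "eblup_codes": np.asarray(genos)[order],
            "eblups": np.asarray(blups)[order] * 1.0,
            "pev": np.asarray(pevs)[order],
        }

    def simulate(self, fitres: dict, rng: np.random.Generator) -> np.ndarray:
        """Parametric draw of a response vector (in engine row order)."""
        mean = self.X @ fitres["beta"]
        g_codes = self.g
        uniq_g = np.unique(g_codes)
        g_draw = rng.normal(0.0, np.sqrt(fitres["sigma2_g"]), size=len(uniq_g))
        g_map = dict(zip(uniq_g.tolist(), g_draw))
        y = mean + np.array([g_map[c] for c in g_codes])
        if self.include_gy and fitres["sigma2_gy"] > 0:
            gy_key = self.g.astype(np.int64) * (self.t.max() + 1) + self.t
            uniq_gy, inv = np.unique(gy_key, return_inverse=True)
            y += rng.normal(0.0, np.sqrt(fitres["sigma2_gy"]), size=len(uniq_gy))[inv]
        y += rng.normal(0.0, np.sqrt(fitres["sigma2_e"]), size=self.n)
        return y


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TrialModelResults:
    """Selected stage-1 model: terms, variance components and eBLUPs."""

    fixed_terms: list[str]
    random_terms: list[str]
    sigma2_g: float
    sigma2_gy: float
    sigma2_e: float
    eblups: pd.Series
    pev: pd.Series
    loglik: float
    n_y: float
    n_r: float
    beta: np.ndarray
    response_mean: float
    elimination_log: list[tuple]
    model: "TrialMixedModel"
    _engine: _GenoYearLMM
    _fitres: dict

    @property
    def variance_components(self) -> dict[str, float]:
        return {
            "sigma2_g": self.sigma2_g,
            "sigma2_gy": self.sigma2_gy,
            "sigma2_e": self.sigma2_e,
        }

    def heritability(self, n_boot: int = 1000, seed: int | None = None) -> "HeritabilityEstimate":
        return heritability(self, n_boot=n_boot, seed=seed)

    def summary(self) -> str:
        lines = [
            "Trial mixed model (ReML)",
            f"  fixed terms : {', '.join(self.fixed_terms) or '(intercept only)'}",
            f"  random terms: {', '.join(self.random_terms)}",
            f"  sigma2_g    : {self.sigma2_g:.4f}",
            f"  sigma2_g:y  : {self.sigma2_gy:.4f}",
            f"  sigma2_e    : {self.sigma2_e:.4f}",
            f"  logLik      : {self.loglik:.3f}",
            f"  n_y / n_r   : {self.n_y:.2f} / {self.n_r:.2f}",
            f"  n genotypes : {len(self.eblups)}",
        ]
        for what, term, statv, pval, action in self.elimination_log:
            lines.append(f"  [{what}] {term}: stat={statv:.3f} p={pval:.4g} -> {action}")
        return "\n".join(lines)


class TrialMixedModel:
    """Stage-1 mixed model for a multi-environment trial.

    Parameters
    ----------
    pheno
        :class:`PlotPhenotypes` (or a DataFrame with the same column contract).
    fixed_candidates
        Candidate fixed terms, e.g. ``["block", "year", "block:year", "PRUW"]``;
        interactions use ``:``.
    random_candidates
        Candidate random terms; must contain ``"genotype"`` and may contain
        ``"genotype:year"``.  The genotype term is never eliminated.
    """

    def __init__(
        self,
        pheno: PlotPhenotypes | pd.DataFrame,
        fixed_candidates: list[str] | None = None,
        random_candidates: list[str] | None = None,
        response: str | None = None,
    ) -> None:
        if isinstance(pheno, pd.DataFrame):
            pheno = PlotPhenotypes(pheno, response=response or "value")
        self.pheno = pheno
        self.response = response or pheno.response
        self.fixed_candidates = list(fixed_candidates or ["block", "year", "block:year"])
        rc = list(random_candidates or ["genotype", "genotype:year"])
        if "genotype" not in rc:
            raise ValueError("random_candidates must contain 'genotype'")
        extra = set(rc) - {"genotype", "genotype:year"}
        if extra:
            raise ValueError(
                f"unsupported random terms {sorted(extra)}: this model class handles "
                "genotype and genotype:year random effects"
            )
        self.random_candidates = rc
        df = pheno.data.loc[pheno.data[self.response].notna()].reset_index(drop=True)
        if df.empty:
            raise ValueError("no non-missing response records")
        self.df = df
        self.y = df[self.response].to_numpy(dtype=float)
        self.geno_labels, self.geno_codes = np.unique(df["genotype"], return_inverse=True)
        _, self.year_codes = np.unique(df["year"], return_inverse=True)

    def _engine(self, fixed_terms: list[str], include_gy: bool, y=None) -> _GenoYearLMM:
        X, _ = _build_design(self.df, fixed_terms)
        return _GenoYearLMM(
            self.y if y is None else y, X, self.geno_codes, self.year_codes, include_gy
        )

    def fit(self, select: bool = True, alpha: float = 0.05) -> TrialModelResults:
        fixed = list(self.fixed_candidates)
        include_gy = "genotype:year" in self.random_candidates
        log: list[tuple] = []

        if select:
            # --- backward elimination of random terms (LRT, boundary mixture)
            while include_gy:
                full = self._engine(fixed, True).fit(reml=False)
                red = self._engine(fixed, False).fit(reml=False)
                statv = max(0.0, 2.0 * (full["loglik"] - red["loglik"]))
                pval = 1.0 if statv <= 0 else 0.5 * stats.chi2.sf(statv, 1)
                if pval >= alpha:
                    include_gy = False
                    log.append(("random", "genotype:year", statv, pval, "dropped"))
                else:
                    log.append(("random", "genotype:year", statv, pval, "kept"))
                    break

            # --- backward elimination of fixed terms (Wald/F on marginal terms)
            while True:
                cand = _droppable(fixed)
                if not cand:
                    break
                X, slices = _build_design(self.df, fixed)
                eng = _GenoYearLMM(self.y, X, self.geno_codes, self.year_codes, include_gy)
                fitres = eng.fit(reml=False)
                worst, worst_p, worst_stat = None, -1.0, np.nan
                for t in cand:
                    sl = slices[t]
                    b = fitres["beta"][sl]
                    covb = fitres["cov_beta"][sl, sl]
                    q = len(b)
                    try:
                        w = float(b @ np.linalg.solve(covb, b))
                    except np.linalg.LinAlgError:
                        w = float(b @ np.linalg.pinv(covb) @ b)
                    pval = stats.chi2.sf(w, q)
                    if pval > worst_p:
                        worst, worst_p, worst_stat = t, pval, w / q
                if worst_p >= alpha:
                    fixed.remove(worst)
                    log.append(("fixed", worst, worst_stat, worst_p, "dropped"))
                else:
                    log.append(("fixed", worst, worst_stat, worst_p, "kept"))
                    break

        # --- final ReML refit
        eng = self._engine(fixed, include_gy)
        fitres = eng.fit(reml=True)
        eblups = pd.Series(
            fitres["eblups"], index=self.geno_labels[fitres["eblup_codes"]], name="eblup"
        )
        pev = pd.Series(fitres["pev"], index=eblups.index, name="pev")
        cells = self.df.groupby(["genotype", "year"]).size()
        n_y = float(cells.groupby(level=0).size().mean())
        n_r = float(cells.mean())
        random_terms = ["genotype"] + (["genotype:year"] if include_gy else [])
        return TrialModelResults(
            fixed_terms=fixed,
            random_terms=random_terms,
            sigma2_g=fitres["sigma2_g"],
            sigma2_gy=fitres["sigma2_gy"],
            sigma2_e=fitres["sigma2_e"],
            eblups=eblups,
            pev=pev,
            loglik=fitres["loglik"],
            n_y=n_y,
            n_r=n_r,
            beta=fitres["beta"],
            response_mean=float(np.mean(self.y)),
            elimination_log=log,
            model=self,
            _engine=eng,
            _fitres=fitres,
        )


def fit_and_select(
    pheno: PlotPhenotypes,
    fixed_candidates: list[str] | None = None,
    random_candidates: list[str] | None = None,
    alpha: float = 0.05,
    response: str | None = None,
) -> TrialModelResults:
    """Backward-eliminate candidate terms and return the ReML-refitted model."""
    return TrialMixedModel(
        pheno, fixed_candidates, random_candidates, response=response
    ).fit(select=True, alpha=alpha)


# ---------------------------------------------------------------------------
# Heritability
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class HeritabilityEstimate:
    """Broad-sense heritability on a genotype-mean basis, with bootstrap CIs."""

    HC2: float
    HO2: float
    CVg: float
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    n_boot: int

    def summary(self) -> str:
        rows = []
        for k in ("HC2", "HO2", "CVg"):
            v = getattr(self, k)
            lo, hi = self.ci_low.get(k, np.nan), self.ci_high.get(k, np.nan)
            rows.append(f"  {k:4s} = {v:8.4f}  [{lo:.4f}, {hi:.4f}]")
        return "Heritability (parametric bootstrap, n_boot=%d)\n%s" % (
            self.n_boot, "\n".join(rows),
        )


def _h2_point(s2g: float, s2gy: float, s2e: float, n_y: float, n_r: float,
              pev_mean: float, resp_mean: float) -> tuple[float, float, float]:
    if s2g <= 0:
        return 0.0, 0.0, 0.0
    hc2 = s2g / (s2g + s2gy / n_y + s2e / (n_y * n_r))
    ho2 = float(np.clip(1.0 - pev_mean / s2g, 0.0, 1.0))
    cvg = 100.0 * np.sqrt(s2g) / abs(resp_mean) if resp_mean != 0 else np.inf
    return hc2, ho2, cvg


def heritability(
    results: TrialModelResults, n_boot: int = 1000, seed: int | None = None
) -> HeritabilityEstimate:
    """HC2 (balanced-design formula), HO2 (generalized, eBLUP-reliability
    based) and the genotypic coefficient of variation, with percentile
    parametric-bootstrap confidence intervals.

    HC2 = sigma2_g / [sigma2_g + sigma2_gy / n_y + sigma2_e / (n_y n_r)] with
    n_y, n_r arithmetic means; HO2 = 1 - mean PEV of eBLUP differences /
    (2 sigma2_g), which tolerates unbalanced data.
    """
    hc2, ho2, cvg = _h2_point(
        results.sigma2_g, results.sigma2_gy, results.sigma2_e,
        results.n_y, results.n_r, float(results.pev.mean()), results.response_mean,
    )
    ci_low: dict[str, float] = {}
    ci_high: dict[str, float] = {}
    if n_boot > 0 and results.sigma2_g > 0:
        rng = np.random.default_rng(seed)
        eng = results._engine
        draws = {"HC2": [], "HO2": [], "CVg": []}
        for _ in range(n_boot):
            y_star = eng.simulate(results._fitres, rng)
            eng_b = eng.with_response(y_star)
            fb = eng_b.fit(reml=True, x0=results._fitres.get("x"))
            b_hc2, b_ho2, b_cvg = _h2_point(
                fb["sigma2_g"], fb["sigma2_gy"], fb["sigma2_e"],
                results.n_y, results.n_r, float(np.mean(fb["pev"])),
                float(np.mean(y_star)),
            )
            draws["HC2"].append(b_hc2)
            draws["HO2"].append(b_ho2)
            draws["CVg"].append(b_cvg)
        for k, v in draws.items():
            lo, hi = np.percentile(np.asarray(v), [2.5, 97.5])
            ci_low[k], ci_high[k] = float(lo), float(hi)
    return HeritabilityEstimate(hc2, ho2, cvg, ci_low, ci_high, n_boot)
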