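"""Heteroscedastic linear models: varIdent GLS, likelihood ratios, selection.

Fits Gaussian linear models in which the residual standard deviation may
differ between the levels of a grouping factor (the *varIdent* variance
structure): with g(i) the variance group of observation i,

    y_i = x_i' beta + e_i,   e_i ~ N(0, sigma_ref^2 * r_{g(i)}^2),

where the reference group's ratio is fixed at 1.  Estimation profiles the
fixed effects and sigma_ref out of the (restricted) log-likelihood: given
log variance-ratios, beta is weighted least squares with weights 1/r^2 and
sigma_ref^2 has a closed form, so only the g-1 free log-ratios are
optimised (quasi-Newton).  With no variance groups the fit reduces exactly
to ordinary least squares.

Model comparison follows the standard sequence for this model family:
the variance structure is chosen by REML AIC (REML likelihoods of models
with the same fixed effects are comparable), fixed terms are then tested by
likelihood-ratio tests under ML, and the final model is refit by REML.
AIC counts every estimated parameter: p fixed effects, the g-1 free
variance ratios, and sigma_ref.

Log-likelihood conventions match R's ``nlme::gls``; on shared fixtures the
coefficients, sigma, variance ratios, logLik and AIC agree to printed
precision (see scripts/crosscheck_gls.py).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["ModelSpec", "CoefEntry", "FitResult", "LRTResult", "fit", "lrt", "backward_select"]


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model description on a tidy table.

    ``fixed_factors`` are nominal columns entering additively with
    treatment contrasts; ``variance_groups`` names the factor whose levels
    get their own residual sd (None = homoscedastic).  Reference levels
    default to the alphabetically first level of each factor.
    """

    response: str
    fixed_factors: tuple = ()
    variance_groups: str | None = None
    estimation: str = "REML"  # "ML" or "REML"
    reference_levels: tuple = ()  # ((factor, level), ...)

    def __post_init__(self) -> None:
        if self.estimation not in ("ML", "REML"):
            raise ValueError("estimation must be 'ML' or 'REML'")
        object.__setattr__(self, "fixed_factors", tuple(self.fixed_factors))
        object.__setattr__(self, "reference_levels", tuple(self.reference_levels))

    def reference_for(self, factor: str, levels: list[str]) -> str:
        for f, lev in self.reference_levels:
            if f == factor:
                if lev not in levels:
                    raise ValueError(f"reference level {lev!r} is not a level of {factor!r}")
                return lev
        return sorted(levels)[0]


@dataclass
class CoefEntry:
    estimate: float
    se: float
    t: float
    p: float


@dataclass
class LRTResult:
    L_ratio: float
    df: int
    p: float

    def __str__(self) -> str:
        return f"L-ratio = {self.L_ratio:.3f}, d.f. = {self.df}, p = {self.p:.4g}"


@dataclass
class FitResult:
    """A fitted (possibly heteroscedastic) linear model."""

    spec: ModelSpec
    coefficients: dict  # term -> CoefEntry
    variance_ratios: dict  # group level -> sd ratio (reference = 1)
    sigma_ref: float
    logLik: float
    AIC: float
    df_residual: int
    converged: bool
    nobs: int
    n_fixed: int
    n_variance: int  # free ratios (g - 1), 0 if homoscedastic
    fitted: np.ndarray = field(repr=False, default=None)
    residuals: np.ndarray = field(repr=False, default=None)

    @property
    def beta(self) -> np.ndarray:
        return np.array([c.estimate for c in self.coefficients.values()])

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"term": t, "estimate": c.estimate, "se": c.se, "t": c.t, "p": c.p}
                for t, c in self.coefficients.items()
            ]
        )

    def summary(self) -> str:
        lines = [
            f"Generalised least squares fit by {self.spec.estimation}",
            f"  response: {self.spec.response}   n = {self.nobs}",
            f"  logLik = {self.logLik:.4f}   AIC = {self.AIC:.4f}",
        ]
        for term, c in self.coefficients.items():
            p_str = "< 0.0001" if c.p < 1e-4 else f"= {c.p:.4f}"
            lines.append(
                f"  {term}: coefficient +/- s.e. = {c.estimate:.3f} +/- {c.se:.3f}, "
                f"t = {c.t:.2f}, p {p_str}"
            )
        if self.variance_ratios:
            ratios = ", ".join(f"{g}: {r:.4f}" for g, r in self.variance_ratios.items())
            lines.append(f"  variance structure (sd ratios): {ratios}")
        lines.append(f"  residual sd (reference group): {self.sigma_ref:.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# design matrix


def build_design(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, list[str]]:
    """Intercept + treatment-contrast dummies for each fixed factor."""
    n = len(data)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    for factor in spec.fixed_factors:
        if factor not in data.columns:
            raise ValueError(f"factor {factor!r} not in data")
        values = data[factor].astype(str).to_numpy()
        levels = sorted(pd.unique(values))
        ref = spec.reference_for(factor, levels)
        for lev in levels:
            if lev == ref:
                continue
            cols.append((values == lev).astype(float))
            names.append(f"{factor}[{lev}]")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns via QR pivoting on the Gram matrix
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        aliased = [names[j] for j in range(len(names)) if diag[j] < 1e-8 * diag.max()]
        raise ValueError(f"design matrix is rank deficient; aliased terms: {aliased or names}")
    return X, names


# ---------------------------------------------------------------------------
# profiled likelihood


def _profile(
    log_ratios: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    group_idx: np.ndarray,
    n_groups: int,
    reml: bool,
):
    """Profiled (restricted) log-likelihood at fixed log variance-ratios.

    Returns (logLik, beta, sigma_ref, cov_unscaled, weights)."""
    n, p = X.shape
    ratios = np.ones(n_groups)
    ratios[1:] = np.exp(log_ratios)
    w = 1.0 / ratios[group_idx] ** 2
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    res = yw - Xw @ beta
    rss = float(res @ res)
    N = n - p if reml else n
    ll = 0.5 * (np.sum(np.log(w)) - N * (np.log(2 * np.pi) + 1 - np.log(N) + np.log(rss)))
    xtx = Xw.T @ Xw
    if reml:
        sign, logdet = np.linalg.slogdet(xtx)
        ll -= 0.5 * logdet
    sigma = np.sqrt(rss / N)
    return float(ll), beta, float(sigma), np.linalg.inv(xtx), w


def fit(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Fit the model described by ``spec`` on a tidy table.

    Raises on a rank-deficient design or on variance groups with fewer than
    2 observations; non-convergence of the ratio optimiser is flagged on
    the result, not silent.
    """
    if spec.response not in data.columns:
        raise ValueError(f"response {spec.response!r} not in data")
    y = data[spec.response].to_numpy(dtype=float)
    X, names = build_design(data, spec)
    n, p = X.shape
    if n <= p:
        raise ValueError("more parameters than observations")
    reml = spec.estimation == "REML"

    if spec.variance_groups is None:
        ll, beta, sigma, cov_u, w = _profile(np.empty(0), y, X, np.zeros(n, dtype=int), 1, reml)
        ratios: dict[str, float] = {}
        n_var = 0
        converged = True
        group_levels: list[str] = []
    else:
        if spec.variance_groups not in data.columns:
            raise ValueError(f"variance_groups {spec.variance_groups!r} not in data")
        gvals = data[spec.variance_groups].astype(str).to_numpy()
        group_levels = sorted(pd.unique(gvals))
        ref = spec.reference_for(spec.variance_groups, group_levels)
        group_levels = [ref] + [g for g in group_levels if g != ref]
        lut = {g: i for i, g in enumerate(group_levels)}
        group_idx = np.array([lut[g] for g in gvals])
        counts = np.bincount(group_idx, minlength=len(group_levels))
        if (counts < 2).any():
            small = [group_levels[i] for i in np.where(counts < 2)[0]]
            raise ValueError(f"variance groups with < 2 observations: {small}")
        n_groups = len(group_levels)
        n_var = n_groups - 1

        # warm start: per-group sd of OLS residuals relative to the reference
        beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
        res0 = y - X @ beta0
        sds = np.array(
            [max(res0[group_idx == i].std(ddof=0), 1e-8) for i in range(n_groups)]
        )
        x0 = np.log(sds[1:] / sds[0])

        def nll(t: np.ndarray) -> float:
            return -_profile(t, y, X, group_idx, n_groups, reml)[0]

        opt = optimize.minimize(nll, x0, method="BFGS", options={"gtol": 1e-8})
        converged = bool(opt.success)
        if not converged:
            opt2 = optimize.minimize(nll, opt.x, method="Nelder-Mead",
                                     options={"xatol": 1e-10, "fatol": 1e-10})
            if opt2.fun <= opt.fun:
                opt = opt2
            converged = bool(opt2.success)
        if not converged:
            warnings.warn("variance-ratio optimisation did not converge", stacklevel=2)
        ll, beta, sigma, cov_u, w = _profile(opt.x, y, X, group_idx, n_groups, reml)
        ratios = {g: (1.0 if i == 0 else float(np.exp(opt.x[i - 1])))
                  for i, g in enumerate(group_levels)}

    df_resid = n - p
    # standard errors always use the df-corrected residual variance (the
    # convention of reference GLS software), regardless of ML vs REML
    sigma_se2 = sigma**2 * ((n if spec.estimation == "ML" else n - p) / (n - p))
    cov = sigma_se2 * cov_u
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)
    coefficients = {
        name: CoefEntry(float(b), float(s), float(t), float(pv))
        for name, b, s, t, pv in zip(names, beta, se, tvals, pvals)
    }
    k = p + n_var + 1
    aic = -2 * ll + 2 * k
    fitted = X @ beta
    return FitResult(
        spec=spec,
        coefficients=coefficients,
        variance_ratios=ratios,
        sigma_ref=sigma,
        logLik=ll,
        AIC=aic,
        df_residual=df_resid,
        converged=converged,
        nobs=n,
        n_fixed=p,
        n_variance=n_var,
        fitted=fitted,
        residuals=y - fitted,
    )


# ---------------------------------------------------------------------------
# likelihood-ratio test


def _n_params(f: FitResult) -> int:
    return f.n_fixed + f.n_variance + 1


def lrt(full: FitResult, reduced: FitResult) -> LRTResult:
    """Likelihood-ratio test of two nested fits on identical rows.

    REML likelihoods are only comparable between models with identical
    fixed effects; mixing estimation methods is refused.
    """
    if full.spec.estimation != reduced.spec.estimation:
        raise ValueError("models were fitted by different estimation methods")
    if full.nobs != reduced.nobs:
        raise ValueError("models were fitted on different numbers of rows")
    same_fixed = (
        set(full.spec.fixed_factors) == set(reduced.spec.fixed_factors)
        and full.n_fixed == reduced.n_fixed
    )
    if full.spec.estimation == "REML" and not same_fixed:
        raise ValueError(
            "REML likelihoods of models with different fixed effects are not comparable; "
            "refit by ML for fixed-effect tests"
        )
    df = _n_params(full) - _n_params(reduced)
    if df < 0:
        raise ValueError("'full' model has fewer parameters than 'reduced'")
    stat = 2.0 * (full.logLik - reduced.logLik)
    if stat < -1e-6:
        warnings.warn(
            f"negative likelihood ratio ({stat:.3g}): the 'full' optimum is worse "
            "than the reduced model; check convergence",
            stacklevel=2,
        )
    stat = max(stat, 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return LRTResult(L_ratio=float(stat), df=df, p=p)


# ---------------------------------------------------------------------------
# backward selection


def _ols_f_test(full: FitResult, reduced: FitResult) -> float:
    """Exact F-test p-value between nested homoscedastic OLS fits."""
    rss_f = float(full.residuals @ full.residuals)
    rss_r = float(reduced.residuals @ reduced.residuals)
    df_num = full.n_fixed - reduced.n_fixed
    df_den = full.nobs - full.n_fixed
    if df_num <= 0:
        return 1.0
    F = ((rss_r - rss_f) / df_num) / (rss_f / df_den)
    return float(stats.f.sf(max(F, 0.0), df_num, df_den))


def backward_select(
    start: ModelSpec, data: pd.DataFrame, alpha: float = 0.05
) -> tuple[FitResult, list[dict]]:
    """Backward model selection in the standard two-stage sequence.

    1. Variance structure (if ``start`` names variance groups): the
       heteroscedastic and homoscedastic models with the full fixed
       structure are compared by REML AIC.
    2. Fixed structure: terms are deleted one at a time under ML.  The
       candidate with the weakest evidence is dropped while its deletion
       p-value is >= ``alpha`` (exact F between homoscedastic OLS models,
       chi-square LRT otherwise); every candidate's ML AIC is recorded in
       the trace.
    3. The final model is refit by REML and returned with the trace.
    """
    trace: list[dict] = []

    variance_groups = start.variance_groups
    if variance_groups is not None:
        het = fit(replace(start, estimation="REML"), data)
        hom = fit(replace(start, estimation="REML", variance_groups=None), data)
        keep_het = het.AIC <= hom.AIC
        trace.append(
            {
                "step": "variance",
                "candidate": f"varIdent({variance_groups})",
                "AIC_heteroscedastic": het.AIC,
                "AIC_homoscedastic": hom.AIC,
                "decision": "keep varIdent" if keep_het else "drop varIdent",
            }
        )
        if not keep_het:
            variance_groups = None

    factors = list(start.fixed_factors)
    if not factors:
        final = fit(replace(start, estimation="REML", variance_groups=variance_groups), data)
        trace.append({"step": "fixed", "candidate": "(Intercept)", "AIC": final.AIC,
                      "decision": "intercept-only start returned unchanged"})
        return final, trace

    while factors:
        try:
            full_ml = fit(
                replace(start, estimation="ML", variance_groups=variance_groups,
                        fixed_factors=tuple(factors)),
                data,
            )
        except ValueError as err:
            raise ValueError(f"fit failed for model with factors {factors}: {err}") from err
        candidates = []
        for f in factors:
            reduced_factors = tuple(x for x in factors if x != f)
            try:
                red_ml = fit(
                    replace(start, estimation="ML", variance_groups=variance_groups,
                            fixed_factors=reduced_factors),
                    data,
                )
            except ValueError as err:
                raise ValueError(
                    f"fit failed for candidate model without {f!r}: {err}"
                ) from err
            if variance_groups is None:
                p = _ols_f_test(full_ml, red_ml)
                test = "F"
            else:
                p = lrt(full_ml, red_ml).p
                test = "LRT"
            candidates.append((f, p, red_ml.AIC, test))
            trace.append(
                {"step": "fixed", "candidate": f"- {f}", "AIC": red_ml.AIC,
                 "p_value": p, "test": test, "AIC_full": full_ml.AIC}
            )
        # weakest term first; ties broken toward the smaller candidate AIC
        f, p, aic, test = max(candidates, key=lambda c: (c[1], -c[2]))
        if p >= alpha:
            factors.remove(f)
            trace.append({"step": "fixed", "candidate": f"- {f}", "decision": "dropped",
                          "p_value": p})
        else:
            break

    final = fit(
        replace(start, estimation="REML", variance_groups=variance_groups,
                fixed_factors=tuple(factors)),
        data,
    )
    trace.append(
        {"step": "final", "candidate": " + ".join(factors) or "(Intercept)",
         "AIC": final.AIC, "decision": "final REML refit"}
    )
    return final, trace
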