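"""Depth-structured statistics for genotype classes and shell strength.

Covers the inferential toolkit of the study: Fisher contingency tests of
class-by-depth tables (exact for 2x2, Monte Carlo for larger tables), grouped
binomial and quasibinomial logistic regressions of MT-allele presence on
depth, shell-strength normalisation and linear models with AIC selection, a
collinearity screen for the shell-trait predictors, and the practical
weak-shell rule for spotting heavily introgressed mussels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import gammaln

from ._rng import stream

__all__ = [
    "ModelFit",
    "normalize_strength",
    "contingency_test",
    "fit_logistic_grouped",
    "fit_quasibinomial_grouped",
    "fit_linear",
    "collinearity_screen",
    "weak_shell_flag",
]


@dataclass
class ModelFit:
    """Tidy summary of a fitted regression model.

    ``odds_factor`` (exp of each slope) is populated for logistic-link fits;
    ``dispersion`` is the Pearson chi-square / df estimate for quasibinomial
    fits (1.0 by convention for pure-likelihood fits).
    """

    model: str
    terms: list[str]
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    p_values: dict[str, float]
    n: int
    log_likelihood: float | None = None
    aic: float | None = None
    dispersion: float | None = None
    odds_factor: dict[str, float] | None = None
    extra: dict = field(default_factory=dict)

    def coef_table(self) -> pd.DataFrame:
        rows = []
        for t in self.terms:
            lo, hi = self.conf_int[t]
            rows.append(
                {
                    "term": t,
                    "estimate": self.coefficients[t],
                    "se": self.std_errors[t],
                    "ci_low": lo,
                    "ci_high": hi,
                    "p": self.p_values[t],
                }
            )
        return pd.DataFrame(rows)


def normalize_strength(force_kg: float, sl_mm: float):
    """Length-normalised shell strength: puncture force / shell length in cm."""
    force_kg = np.asarray(force_kg, dtype=float)
    sl_mm = np.asarray(sl_mm, dtype=float)
    if (sl_mm <= 0).any():
        raise ValueError("shell length must be positive")
    if (force_kg < 0).any():
        raise ValueError("force must be non-negative")
    out = force_kg / (sl_mm / 10.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# contingency


def _log_table_prob(table: np.ndarray) -> float:
    """Log probability of an r x c table under the fixed-margins null."""
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    return (
        gammaln(r + 1).sum()
        + gammaln(c + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def contingency_test(
    counts, n_mc: int = 100_000, seed: int = 0
) -> dict:
    """Fisher's exact test of independence for an r x c count table.

    2x2 tables use the exact two-sided hypergeometric test.  Larger tables
    use a Monte Carlo estimate of the exact p: ``n_mc`` tables are sampled
    under fixed margins (by permuting column labels) and the p-value is the
    fraction with null probability no larger than the observed table's (with
    the +1 continuity correction), reported with its Monte Carlo SE.
    Empty rows/columns are dropped first.
    """
    t = np.asarray(counts, dtype=float)
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    t = np.round(t).astype(np.int64)
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need at least a 2x2 table after dropping empty margins")
    if t.shape == (2, 2):
        p = stats.fisher_exact(t, alternative="two-sided")[1]
        return {"p_value": float(min(p, 1.0)), "method": "exact", "mc_se": 0.0}

    rng = stream(seed, "fisher_mc")
    obs_lp = _log_table_prob(t)
    row_of = np.repeat(np.arange(t.shape[0]), t.sum(axis=1))
    col_labels = np.repeat(np.arange(t.shape[1]), t.sum(axis=0))
    n_tot = len(col_labels)
    hits = 0
    chunk = max(1, min(n_mc, 20_000_000 // max(n_tot, 1)))
    done = 0
    tol = 1e-9  # ties in table probability count as at-least-as-extreme
    while done < n_mc:
        b = min(chunk, n_mc - done)
        keys = rng.random((b, n_tot))
        perm_cols = col_labels[np.argsort(keys, axis=1)]
        ncell = t.shape[0] * t.shape[1]
        flat = row_of[None, :] * t.shape[1] + perm_cols
        flat = flat + np.arange(b)[:, None] * ncell
        counts_b = np.bincount(flat.ravel(), minlength=b * ncell).reshape(
            b, *t.shape
        )
        lps = (
            gammaln(t.sum(axis=1) + 1).sum()
            + gammaln(t.sum(axis=0) + 1).sum()
            - gammaln(t.sum() + 1)
            - gammaln(counts_b + 1).sum(axis=(1, 2))
        )
        hits += int((lps <= obs_lp + tol).sum())
        done += b
    p = (hits + 1) / (n_mc + 1)
    se = float(np.sqrt(p * (1 - p) / n_mc))
    return {"p_value": float(p), "method": "monte_carlo", "mc_se": se, "n_mc": n_mc}


# ---------------------------------------------------------------------------
# grouped logistic / quasibinomial


def _grouped_glm(successes, totals, x, scale=None) -> ModelFit:
    successes = np.asarray(successes, dtype=float)
    totals = np.asarray(totals, dtype=float)
    x = np.asarray(x, dtype=float)
    if successes.shape != totals.shape or successes.shape != x.shape:
        raise ValueError("successes, totals and x must be aligned")
    if ((successes < 0) | (successes > totals)).any():
        raise ValueError("need 0 <= successes <= totals")
    if len(np.unique(x)) < 2:
        raise ValueError("need at least two distinct covariate values")
    design = sm.add_constant(x)
    model = sm.GLM(
        np.column_stack([successes, totals - successes]),
        design,
        family=sm.families.Binomial(),
    )
    import warnings

    with warnings.catch_warnings():
        # separation is detected and raised as an explicit error below
        warnings.simplefilter("ignore")
        res = model.fit(scale=scale)
    if not res.converged:
        raise RuntimeError("logistic fit did not converge (separation?)")
    p_hat = res.fittedvalues
    if (p_hat < 1e-10).any() or (p_hat > 1 - 1e-10).any():
        raise RuntimeError("logistic fit on the boundary: complete separation")
    terms = ["intercept", "x"]
    ci = res.conf_int()
    dispersion = float(res.scale) if scale is not None else 1.0
    quasi = scale is not None
    fit = ModelFit(
        model="quasibinomial_glm" if quasi else "binomial_glm",
        terms=terms,
        coefficients=dict(zip(terms, map(float, res.params))),
        std_errors=dict(zip(terms, map(float, res.bse))),
        conf_int={t: (float(ci[i, 0]), float(ci[i, 1])) for i, t in enumerate(terms)},
        p_values=dict(zip(terms, map(float, res.pvalues))),
        n=int(totals.sum()),
        log_likelihood=None if quasi else float(res.llf),
        aic=None if quasi else float(res.aic),
        dispersion=dispersion,
        odds_factor={t: float(np.exp(res.params[i])) for i, t in enumerate(terms)},
        extra={
            "fitted_proportions": np.asarray(p_hat),
            "fitted_odds": np.asarray(p_hat / (1 - p_hat)),
            "x": x,
            "df_resid": int(res.df_resid),
        },
    )
    return fit


def fit_logistic_grouped(successes, totals, x) -> ModelFit:
    """Maximum-likelihood logistic regression on grouped binomial data.

    Identical MLE to the Bernoulli-expanded individual-level fit.  Wald 95%
    CIs; ``odds_factor['x']`` is the multiplicative change in the odds per
    unit of the covariate.
    """
    return _grouped_glm(successes, totals, x, scale=None)


def fit_quasibinomial_grouped(successes, totals, x) -> ModelFit:
    """Quasibinomial fit: same mean model, SEs scaled by sqrt(Pearson X2/df).

    The dispersion is the grouped-binomial Pearson statistic
    sum n_i (p_i - mu_i)^2 / (mu_i (1 - mu_i)) divided by (groups - 2).
    """
    totals_arr = np.asarray(totals, dtype=float)
    succ_arr = np.asarray(successes, dtype=float)
    df_resid = len(totals_arr) - 2
    if df_resid <= 0:
        raise ValueError("quasibinomial dispersion needs residual df > 0")
    ml = _grouped_glm(successes, totals, x, scale=None)
    mu = ml.extra["fitted_proportions"]
    p_obs = succ_arr / totals_arr
    pearson_x2 = float(np.sum(totals_arr * (p_obs - mu) ** 2 / (mu * (1 - mu))))
    phi = pearson_x2 / df_resid
    fit = _grouped_glm(successes, totals, x, scale=phi)
    fit.dispersion = phi
    fit.model = "quasibinomial_glm"
    return fit


# ---------------------------------------------------------------------------
# linear models with AIC selection


def _gaussian_aic(res) -> float:
    # k counts the mean parameters plus the residual variance
    k = res.df_model + 1 + 1
    return float(2 * k - 2 * res.llf)


def fit_linear(
    data: pd.DataFrame,
    response: str,
    candidate_models: list[list[str]] | dict[str, list[str]],
) -> tuple[ModelFit, pd.DataFrame]:
    """OLS over candidate predictor sets; returns the best-AIC fit + table.

    Each candidate is a list of terms; a term is a column name or "a:b" for
    an interaction.  AIC uses the Gaussian likelihood with estimated
    variance (k = mean parameters + 1).  Residual diagnostics (Shapiro
    normality p, Breusch-Pagan homoscedasticity p) are attached to each fit.
    """
    if isinstance(candidate_models, dict):
        names, cands = list(candidate_models), list(candidate_models.values())
    else:
        cands = list(candidate_models)
        names = [" + ".join(c) if c else "intercept_only" for c in cands]
    y = data[response].to_numpy(dtype=float)
    if len(y) < 3:
        raise ValueError("too few observations")
    rows, fits = [], []
    for name, terms in zip(names, cands):
        X = _design(data, terms)
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            raise ValueError(
                f"rank-deficient design for {name!r}: collinear columns {list(X.columns)}"
            )
        res = sm.OLS(y, X).fit()
        aic = _gaussian_aic(res)
        resid = res.resid
        shapiro_p = float(stats.shapiro(resid).pvalue) if len(resid) <= 5000 else float(
            stats.normaltest(resid).pvalue
        )
        bp_p = float(sm.stats.het_breuschpagan(resid, X.to_numpy())[1]) if X.shape[1] > 1 else np.nan
        ci = res.conf_int()
        fit = ModelFit(
            model=f"ols[{name}]",
            terms=list(X.columns),
            coefficients=dict(zip(X.columns, map(float, res.params))),
            std_errors=dict(zip(X.columns, map(float, res.bse))),
            conf_int={
                t: (float(ci.loc[t, 0]), float(ci.loc[t, 1])) for t in X.columns
            },
            p_values=dict(zip(X.columns, map(float, res.pvalues))),
            n=int(res.nobs),
            log_likelihood=float(res.llf),
            aic=aic,
            dispersion=1.0,
            extra={
                "r_squared": float(res.rsquared),
                "shapiro_p": shapiro_p,
                "breusch_pagan_p": bp_p,
                "f_statistic": float(res.fvalue) if X.shape[1] > 1 else np.nan,
                "df": (int(res.df_model), int(res.df_resid)),
            },
        )
        fits.append(fit)
        rows.append(
            {
                "model": name,
                "aic": aic,
                "loglik": float(res.llf),
                "r_squared": float(res.rsquared),
                "k": int(res.df_model + 2),
            }
        )
    table = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].min()
    best = fits[int(np.argmin([f.aic for f in fits]))]
    return best, table


def _design(data: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    cols = {"intercept": np.ones(len(data))}
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            cols[t] = data[a].to_numpy(float) * data[b].to_numpy(float)
        else:
            cols[t] = data[t].to_numpy(float)
    return pd.DataFrame(cols, index=data.index)


def collinearity_screen(
    predictors: pd.DataFrame, r_threshold: float = 0.8
) -> dict:
    """Bivariate and PCA collinearity screen of candidate predictors.

    Flags pairs with |Pearson r| above ``r_threshold`` and recommends
    dropping the later column of each flagged pair.  Constant columns are
    excluded from the correlations and reported separately.  PCA variance
    shares (on standardised predictors) indicate effective dimensionality.
    """
    if predictors.shape[1] < 2 or predictors.shape[0] < 3:
        raise ValueError("need >= 2 predictors and >= 3 observations")
    sd = predictors.std(ddof=1)
    constant = list(sd.index[sd == 0])
    use = predictors.drop(columns=constant)
    corr = use.corr()
    flagged = []
    for i, a in enumerate(corr.columns):
        for b in corr.columns[i + 1 :]:
            if abs(corr.loc[a, b]) > r_threshold:
                flagged.append((a, b, float(corr.loc[a, b])))
    z = (use - use.mean()) / use.std(ddof=1)
    evals = np.linalg.eigvalsh(np.cov(z.to_numpy(), rowvar=False))[::-1]
    shares = evals / evals.sum()
    return {
        "correlations": corr,
        "flagged_pairs": flagged,
        "drop_recommendations": sorted({b for _, b, _ in flagged}),
        "constant_columns": constant,
        "pc_variance_shares": shares,
    }


def weak_shell_flag(strength_norm, sl_mm, sh_mm):
    """Practical weak-shell rule for heavily MT-introgressed mussels.

    True iff normalised strength < 2 kg cm^-1 SL AND SL:SH > 2, both strict.
    Accepts scalars or aligned arrays.
    """
    strength = np.asarray(strength_norm, dtype=float)
    sl = np.asarray(sl_mm, dtype=float)
    sh = np.asarray(sh_mm, dtype=float)
    if (sh <= 0).any() or (sl <= 0).any():
        raise ValueError("shell dimensions must be positive")
    if (strength < 0).any():
        raise ValueError("strength must be non-negative")
    out = (strength < 2.0) & (sl / sh > 2.0)
    return bool(out) if out.ndim == 0 else out
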