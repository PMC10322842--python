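"""Regression and correlation machinery for the demographic analyses.

* proportional-odds (cumulative logit) ordinal regression of the 4-level
  self-estimate on gender and age bands, with likelihood-ratio tests per
  predictor block;
* hierarchical OLS: F test for the R^2 gain of a nested model extension
  (e.g. adding the self-rating dummies to a demographic model);
* Type-II partial eta^2 effect sizes per term;
* Fox-Monette generalised variance inflation factors (GVIF), reported as
  GVIF^(1/(2 df)) so multi-column terms are comparable to classical VIF;
* Spearman rank correlation with mid-ranks for ties.

Ordinal model fitting is delegated to ``statsmodels`` ``OrderedModel``
(logistic link); everything is returned through small result types so the
rest of the pipeline never touches statsmodels objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .synthetic_cohort import SELF_ESTIMATE_LABELS

__all__ = [
    "OrdinalFit",
    "AnovaRow",
    "CollinearityRow",
    "CorrelationResult",
    "fit_proportional_odds",
    "predict_ordinal_proba",
    "lr_test",
    "age_bands",
    "self_estimate_demographic_model",
    "hierarchical_f_change",
    "partial_eta_squared",
    "gvif",
    "spearman",
]

#: Five age bands spanning the included 19-70 range.
AGE_BAND_EDGES = (19, 30, 40, 50, 60, 71)
AGE_BAND_LABELS = ("19-29", "30-39", "40-49", "50-59", "60-70")


@dataclass
class OrdinalFit:
    """Proportional-odds fit: ascending latent thresholds, one coefficient
    per covariate column, log-likelihood."""

    thresholds: np.ndarray  # (k_categories - 1,), strictly ascending
    beta: pd.Series  # indexed by covariate column name (empty for null fit)
    loglik: float
    n: int
    categories: tuple
    beta_se: pd.Series | None = None  # asymptotic standard errors, when available
    n_params: int = field(init=False)

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.thresholds) > 0):
            raise ValueError(f"thresholds not ascending: {self.thresholds}")
        if not np.isfinite(self.loglik):
            raise ValueError("non-finite log-likelihood")
        self.n_params = len(self.thresholds) + len(self.beta)


@dataclass(frozen=True)
class AnovaRow:
    term: str
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta2: float


@dataclass(frozen=True)
class CollinearityRow:
    term: str
    df: int
    gvif: float
    gvif_scaled: float  # gvif ** (1 / (2 df))


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    n: int


def _as_ordinal(y, categories) -> np.ndarray:
    cats = list(categories) if categories is not None else sorted(pd.unique(pd.Series(y)))
    s = pd.Series(y)
    if s.dtype == object:
        s = s.astype(str).str.strip().str.casefold()
        cats = [str(c).strip().casefold() for c in cats]
    codes = pd.Categorical(s, categories=cats, ordered=True).codes
    if (codes < 0).any():
        bad = sorted(pd.unique(s[codes < 0]))
        raise ValueError(f"responses outside the category set: {bad}")
    return codes, tuple(cats)


def fit_proportional_odds(
    y,
    X: pd.DataFrame | None = None,
    categories=SELF_ESTIMATE_LABELS,
) -> OrdinalFit:
    """Fit a cumulative-logit proportional-odds model.

    ``y`` holds ordinal labels (or codes) over ``categories``; ``X`` holds
    the covariate columns (no intercept — it is absorbed by the
    thresholds).  With ``X`` empty or None the null (thresholds-only) model
    is fitted.  Raises if y has fewer than two observed categories or the
    optimiser fails to converge (e.g. complete separation).
    """
    codes, cats = _as_ordinal(y, categories)
    observed = np.unique(codes)
    if len(observed) < 2:
        raise ValueError("all responses in a single category; ordinal fit undefined")
    # collapse to observed categories (empty categories carry no likelihood)
    remap = {c: i for i, c in enumerate(observed)}
    codes = np.asarray([remap[c] for c in codes])
    obs_cats = tuple(cats[c] for c in observed)
    if len(observed) < len(cats):
        import warnings

        warnings.warn(
            f"empty response categories collapsed: fitted over {obs_cats}",
            stacklevel=2,
        )

    if X is None or (hasattr(X, "shape") and X.shape[1] == 0):
        return _fit_null_ordinal(codes, obs_cats)

    X = pd.DataFrame(X)
    Xv = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    model = OrderedModel(codes, Xv, distr="logit")
    res = model.fit(method="bfgs", maxiter=500, disp=False, gtol=1e-8)
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError(
            "proportional-odds fit did not converge (possible complete separation)"
        )
    k = Xv.shape[1]
    thresholds = model.transform_threshold_params(res.params)[1:-1]
    return OrdinalFit(
        thresholds=np.asarray(thresholds, dtype=float),
        beta=pd.Series(res.params[:k], index=list(X.columns)),
        loglik=float(res.llf),
        n=len(codes),
        categories=obs_cats,
        beta_se=pd.Series(np.asarray(res.bse[:k], dtype=float), index=list(X.columns)),
    )


def _fit_null_ordinal(codes: np.ndarray, cats) -> OrdinalFit:
    """Thresholds-only model, fitted numerically over the cutpoints.

    (The MLE has the closed form logit of the cumulative proportions, which
    the tests use as an independent check.)
    """
    counts = np.bincount(codes, minlength=len(cats)).astype(float)

    def nll(raw):
        th = np.concatenate([[raw[0]], raw[0] + np.cumsum(np.exp(raw[1:]))])
        cum = np.concatenate([[0.0], 1.0 / (1.0 + np.exp(-th)), [1.0]])
        p = np.diff(cum)
        if (p <= 0).any():
            return np.inf
        return -float(counts @ np.log(p))

    k = len(cats) - 1
    x0 = np.concatenate([[-1.0], np.zeros(k - 1)])
    from scipy.optimize import minimize

    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    raw = res.x
    th = np.concatenate([[raw[0]], raw[0] + np.cumsum(np.exp(raw[1:]))])
    return OrdinalFit(
        thresholds=th,
        beta=pd.Series(dtype=float),
        loglik=-float(res.fun),
        n=len(codes),
        categories=tuple(cats),
    )


def predict_ordinal_proba(fit: OrdinalFit, X: pd.DataFrame | None = None) -> np.ndarray:
    """Category probabilities per row: sigma(theta_k - x beta) differences."""
    if X is None or len(fit.beta) == 0:
        eta = np.zeros(1 if X is None else len(X))
    else:
        eta = pd.DataFrame(X)[fit.beta.index].to_numpy(dtype=float) @ fit.beta.to_numpy()
    z = fit.thresholds[None, :] - eta[:, None]
    cum = 1.0 / (1.0 + np.exp(-z))
    cum = np.concatenate([np.zeros((len(eta), 1)), cum, np.ones((len(eta), 1))], axis=1)
    return np.diff(cum, axis=1)


def lr_test(full: OrdinalFit, reduced: OrdinalFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested ordinal fits on the same data.

    Returns ``(chi2, df, p)`` with chi2 = 2 (ll_full - ll_reduced) clipped
    at 0 and df the parameter-count difference.
    """
    if full.n != reduced.n:
        raise ValueError(f"fits are not on the same data: n = {full.n} vs {reduced.n}")
    df = full.n_params - reduced.n_params
    if df <= 0:
        raise ValueError("'full' model has no extra parameters over 'reduced'")
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return chi2, df, float(stats.chi2.sf(chi2, df))


def age_bands(age) -> pd.Categorical:
    """Assign ages to the five analysis bands (19-29 ... 60-70)."""
    return pd.cut(
        pd.to_numeric(pd.Series(age)),
        bins=list(AGE_BAND_EDGES),
        labels=list(AGE_BAND_LABELS),
        right=False,
        include_lowest=True,
    )


def self_estimate_demographic_model(players: pd.DataFrame) -> dict:
    """Ordinal model of self-estimates on gender and age bands, with LR
    tests for each predictor block.

    Returns the three fits plus ``(chi2, df, p)`` for gender and for age
    bands, and the male odds ratio exp(beta_male) — the multiplicative
    change in odds of a higher self-rating for men vs women.
    """
    male = (players["gender"].astype(str).str.casefold() == "male").astype(float)
    bands = pd.get_dummies(age_bands(players["age"]), drop_first=True, dtype=float)
    X_full = pd.concat([male.rename("male"), bands], axis=1)
    y = players["self_estimate"]

    full = fit_proportional_odds(y, X_full)
    no_gender = fit_proportional_odds(y, X_full.drop(columns="male"))
    no_age = fit_proportional_odds(y, X_full[["male"]])
    return {
        "full": full,
        "gender_lr": lr_test(full, no_gender),
        "age_lr": lr_test(full, no_age),
        "male_odds_ratio": float(np.exp(full.beta["male"])),
    }


def _rss(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def hierarchical_f_change(
    y, X_base: pd.DataFrame, X_full: pd.DataFrame
) -> tuple[float, int, int, float, float]:
    """F test for the variance captured by the columns added in ``X_full``.

    ``X_base``'s columns must be a subset of ``X_full``'s; both get an
    intercept.  Returns ``(F, df_num, df_den, p, delta_R2)``.
    """
    X_base, X_full = pd.DataFrame(X_base), pd.DataFrame(X_full)
    extra = [c for c in X_full.columns if c not in X_base.columns]
    if set(X_base.columns) - set(X_full.columns):
        raise ValueError("X_base has columns not present in X_full")
    if not extra:
        raise ValueError("X_full adds no columns over X_base")
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    Zb = np.column_stack([np.ones(n), X_base.to_numpy(dtype=float)])
    Zf = np.column_stack([np.ones(n), X_full.to_numpy(dtype=float)])
    p_full = Zf.shape[1]
    if np.linalg.matrix_rank(Zf) < p_full:
        raise ValueError("full design is rank deficient (aliased added columns?)")
    rss_b, _ = _rss(y, Zb)
    rss_f, _ = _rss(y, Zf)
    df_num = len(extra)
    df_den = n - p_full
    F = ((rss_b - rss_f) / df_num) / (rss_f / df_den)
    tss = float(((y - y.mean()) ** 2).sum())
    delta_r2 = (rss_b - rss_f) / tss
    return float(F), df_num, df_den, float(stats.f.sf(F, df_num, df_den)), float(delta_r2)


def partial_eta_squared(
    y, X: pd.DataFrame, terms: dict[str, list[str]]
) -> list[AnovaRow]:
    """Type-II ANOVA rows with partial eta^2 per term.

    ``terms`` maps term names to the columns of ``X`` (no intercept) they
    own; together the lists must partition ``X``'s columns.  SS_term =
    RSS(model without the term) - RSS(full); partial eta^2 =
    SS_term / (SS_term + RSS_full).
    """
    X = pd.DataFrame(X)
    claimed = [c for cols in terms.values() for c in cols]
    if sorted(claimed) != sorted(X.columns):
        raise ValueError("terms must partition the columns of X")
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    Zf = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    p_full = Zf.shape[1]
    if np.linalg.matrix_rank(Zf) < p_full:
        raise ValueError("design is rank deficient; aliased terms")
    rss_f, _ = _rss(y, Zf)
    df_den = n - p_full
    rows = []
    for term, cols in terms.items():
        Xr = X.drop(columns=cols)
        Zr = np.column_stack([np.ones(n), Xr.to_numpy(dtype=float)])
        rss_r, rank_r = _rss(y, Zr)
        if rank_r < Zr.shape[1]:
            raise ValueError(f"term {term!r} aliased with the remaining columns")
        ss = rss_r - rss_f
        df_num = len(cols)
        F = (ss / df_num) / (rss_f / df_den)
        rows.append(
            AnovaRow(
                term=term,
                F=float(F),
                df_num=df_num,
                df_den=df_den,
                p=float(stats.f.sf(F, df_num, df_den)),
                partial_eta2=float(ss / (ss + rss_f)),
            )
        )
    return rows


def gvif(X: pd.DataFrame, term_map: dict[str, list[str]]) -> list[CollinearityRow]:
    """Fox-Monette generalised VIF per term from the predictor correlation
    matrix: GVIF = det(R11) det(R22) / det(R).  For df = 1 terms this is
    the classical VIF = 1 / (1 - R_j^2).  Reported alongside
    GVIF^(1/(2 df)).
    """
    X = pd.DataFrame(X)
    cols = list(X.columns)
    R = np.corrcoef(X.to_numpy(dtype=float), rowvar=False)
    if not np.all(np.isfinite(R)):
        raise ValueError("constant column or undefined correlations in X")
    det_R = np.linalg.det(R)
    if abs(det_R) < 1e-300:
        raise ValueError("singular predictor correlation matrix")
    rows = []
    for term, tcols in term_map.items():
        i1 = [cols.index(c) for c in tcols]
        i2 = [i for i in range(len(cols)) if i not in i1]
        det1 = np.linalg.det(R[np.ix_(i1, i1)])
        det2 = np.linalg.det(R[np.ix_(i2, i2)]) if i2 else 1.0
        g = float(det1 * det2 / det_R)
        df = len(i1)
        rows.append(CollinearityRow(term=term, df=df, gvif=g, gvif_scaled=g ** (1.0 / (2 * df))))
    return rows


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with mid-ranks for ties; two-sided p from
    the t reference ``t = rho sqrt((n - 2) / (1 - rho^2))``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError(f"need >= 3 pairs, got {len(x)}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in x or y")
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        raise ValueError("zero variance in ranks")
    res = stats.spearmanr(x, y)
    return CorrelationResult(rho=float(res.statistic), p=float(res.pvalue), n=len(x))
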