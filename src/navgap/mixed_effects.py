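"""Random-intercept linear mixed models by profiled REML, with conditional
modes (BLUPs) per group.

Model: y = X beta + Z u + e,  u_j ~ N(0, sigma_u^2),  e ~ N(0, sigma_e^2 I),
with Z the group-membership indicator matrix.  Writing lambda =
sigma_u^2 / sigma_e^2 and W = I + lambda Z Z', both beta and sigma_e^2
profile out of the REML criterion, which becomes a 1-D function of lambda:

    -2 l_R(lambda) = (n - p) (log 2 pi + log s2 + 1)
                     + sum_j log(1 + lambda n_j) + log |X' W^-1 X|,

with s2 = RSS_W / (n - p) the GLS residual variance.  Because W is
block-diagonal with W_j = I + lambda J, all the pieces reduce to per-group
sums, so each evaluation is O(n p + k p^2).  The criterion is maximised by
bounded scalar search on log10(lambda); the boundary lambda = 0 (no group
variance) is admitted and flagged.

Conditional modes are the standard shrinkage estimator

    u_j = lambda n_j / (1 + lambda n_j) * mean(residual in group j),

with conditional variance sigma_e^2 lambda / (1 + lambda n_j).

The analysis fits four such models on the filtered cohort: self-estimate
(numeric -2/-1/1/2 coding) and performance score, each with fixed effects
for age and gender and a random intercept for country or cluster.  The
per-group modes are the adjusted country/cluster means the gap statistic
consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .cultural_atlas import ClusterMap, assign_cluster
from ._coding import encode_self_estimates

__all__ = [
    "LmmFit",
    "fit_random_intercept_lmm",
    "conditional_modes",
    "reml_loglik",
    "design_matrix",
    "country_and_cluster_modes",
]

_LOG10_LAMBDA_BOUNDS = (-8.0, 8.0)


@dataclass
class LmmFit:
    """REML fit of a random-intercept model."""

    beta: np.ndarray
    beta_names: list[str]
    sigma_u2: float
    sigma_e2: float
    lam: float  # variance ratio sigma_u2 / sigma_e2
    reml_loglik: float
    modes: pd.DataFrame  # index group; columns mode, se, n
    at_boundary: bool  # lambda hit 0: group variance unidentified or absent
    n_obs: int
    n_groups: int


def _group_stats(X: np.ndarray, y: np.ndarray, codes: np.ndarray, k: int):
    nj = np.bincount(codes, minlength=k).astype(float)
    tj = np.bincount(codes, weights=y, minlength=k)  # per-group sum of y
    p = X.shape[1]
    S = np.empty((k, p))  # per-group column sums of X
    for c in range(p):
        S[:, c] = np.bincount(codes, weights=X[:, c], minlength=k)
    return nj, tj, S


def _profiled_criterion(lam, n, p, nj, tj, S, XtX, Xty, yty):
    """(reml_loglik, beta, sigma_e2) at a fixed variance ratio lambda."""
    w = lam / (1.0 + lam * nj)
    XtWX = XtX - (S * w[:, None]).T @ S
    XtWy = Xty - S.T @ (w * tj)
    yWy = yty - float(w @ tj**2)
    if p:
        beta = np.linalg.solve(XtWX, XtWy)
        rss = yWy - float(beta @ XtWy)
        sign, logdet = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return -np.inf, np.full(p, np.nan), np.nan
    else:
        beta = np.empty(0)
        rss = yWy
        logdet = 0.0
    dof = n - p
    s2 = rss / dof
    if s2 <= 0:
        return -np.inf, beta, s2
    ll = -0.5 * (
        dof * (np.log(2.0 * np.pi) + np.log(s2) + 1.0)
        + float(np.log1p(lam * nj).sum())
        + logdet
    )
    return ll, beta, s2


def fit_random_intercept_lmm(
    y,
    X,
    groups,
    beta_names: list[str] | None = None,
    log10_lambda_bounds: tuple[float, float] = _LOG10_LAMBDA_BOUNDS,
) -> LmmFit:
    """Fit y ~ X beta + (1 | groups) by REML.

    ``X`` should include an intercept column if one is wanted.  Raises on a
    rank-deficient design (naming the collinear columns) or fewer than two
    groups.  The search runs over log10(lambda) on ``log10_lambda_bounds``;
    if the criterion is no better in the interior than at lambda = 0 the
    fit is returned at the boundary with all modes zero.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if len(y) != n:
        raise ValueError(f"y has {len(y)} rows, X has {n}")
    if not (np.isfinite(y).all() and np.isfinite(X).all()):
        raise ValueError("missing or non-finite values in y or X")
    codes, uniques = pd.factorize(np.asarray(groups), sort=True)
    if (codes < 0).any():
        raise ValueError("missing values in groups")
    if len(codes) != n:
        raise ValueError(f"groups has {len(codes)} rows, X has {n}")
    k = len(uniques)
    if k < 2:
        raise ValueError(f"need >= 2 groups, got {k}")
    beta_names = beta_names or [f"x{j}" for j in range(p)]
    if p and np.linalg.matrix_rank(X) < p:
        _, R = np.linalg.qr(X)
        bad = [beta_names[j] for j in range(p) if abs(R[j, j]) < 1e-10 * max(1.0, abs(R[0, 0]))]
        raise ValueError(f"rank-deficient fixed-effect design; collinear columns: {bad}")

    nj, tj, S = _group_stats(X, y, codes, k)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    def neg(loglam):
        return -_profiled_criterion(10.0**loglam, n, p, nj, tj, S, XtX, Xty, yty)[0]

    res = minimize_scalar(neg, bounds=log10_lambda_bounds, method="bounded",
                          options={"xatol": 1e-10})
    # Brent localises x only to ~sqrt(machine eps); polish to full precision
    # by solving the analytic profile-score equation d(-2 l_R)/d lambda = 0
    x = float(res.x)

    def score(lam):
        w2 = 1.0 / (1.0 + lam * nj) ** 2
        XtWX = XtX - (S * (lam / (1.0 + lam * nj))[:, None]).T @ S
        XtWy = Xty - S.T @ ((lam / (1.0 + lam * nj)) * tj)
        yWy = yty - float((lam / (1.0 + lam * nj)) @ tj**2)
        if p:
            A_inv = np.linalg.inv(XtWX)
            beta_l = A_inv @ XtWy
            rss = yWy - float(beta_l @ XtWy)
            rs = tj - S @ beta_l
            tr_term = float(np.einsum("jp,pq,jq,j->", S, A_inv, S, w2))
        else:
            rss = yWy
            rs = tj
            tr_term = 0.0
        drss = -float(w2 @ rs**2)
        return (n - p) * drss / rss + float((nj / (1.0 + lam * nj)).sum()) - tr_term

    from scipy.optimize import brentq

    lam = float(10.0**x)
    g_lo, g_hi = score(lam / 2.0), score(lam * 2.0)
    if g_lo < 0.0 < g_hi:
        lam = float(brentq(score, lam / 2.0, lam * 2.0, xtol=1e-14, rtol=1e-15))
        x = float(np.log10(lam))
    ll_hat = -float(neg(x))
    ll0, *_ = _profiled_criterion(0.0, n, p, nj, tj, S, XtX, Xty, yty)
    # snap to lambda = 0 when the interior "gain" is within numerical noise
    # of the boundary criterion (e.g. the flat ridge with one obs per group)
    tol0 = 1e-6 * max(1.0, abs(ll_hat))
    at_boundary = ll0 >= ll_hat - tol0 or x <= log10_lambda_bounds[0] + 1e-6
    if at_boundary:
        lam = 0.0
    ll, beta, s2 = _profiled_criterion(lam, n, p, nj, tj, S, XtX, Xty, yty)

    resid_sum = tj - S @ beta if p else tj
    mean_resid = resid_sum / nj
    shrink = lam * nj / (1.0 + lam * nj)
    u = shrink * mean_resid
    se = np.sqrt(s2 * lam / (1.0 + lam * nj))
    modes = pd.DataFrame(
        {"mode": u, "se": se, "n": nj.astype(int)},
        index=pd.Index(uniques, name="group"),
    )
    return LmmFit(
        beta=beta,
        beta_names=list(beta_names),
        sigma_u2=lam * s2,
        sigma_e2=s2,
        lam=lam,
        reml_loglik=float(ll),
        modes=modes,
        at_boundary=bool(at_boundary),
        n_obs=n,
        n_groups=k,
    )


def conditional_modes(fit: LmmFit) -> pd.DataFrame:
    """Per-group conditional modes (BLUPs) with standard errors and sizes."""
    return fit.modes.copy()


def reml_loglik(y, X, groups, sigma_u2: float, sigma_e2: float) -> float:
    """REML log-likelihood at explicit variance components.

    Same criterion as the profiled fit; useful for verifying that the 1-D
    profile search agrees with a direct 2-parameter optimisation.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    codes, uniques = pd.factorize(np.asarray(groups), sort=True)
    k = len(uniques)
    nj, tj, S = _group_stats(X, y, codes, k)
    if sigma_e2 <= 0:
        return -np.inf
    lam = sigma_u2 / sigma_e2
    w = lam / (1.0 + lam * nj)
    XtWX = X.T @ X - (S * w[:, None]).T @ S
    XtWy = X.T @ y - S.T @ (w * tj)
    yWy = float(y @ y) - float(w @ tj**2)
    if p:
        beta = np.linalg.solve(XtWX, XtWy)
        rss = yWy - float(beta @ XtWy)
        _, logdetX = np.linalg.slogdet(XtWX)
    else:
        rss = yWy
        logdetX = 0.0
    # log|V| = n log sigma_e2 + sum log(1 + lam n_j); log|X'V^-1X| =
    # log|X'W^-1X| - p log sigma_e2
    return -0.5 * (
        (n - p) * np.log(2.0 * np.pi)
        + (n - p) * np.log(sigma_e2)
        + float(np.log1p(lam * nj).sum())
        + logdetX
        + rss / sigma_e2
    )


def design_matrix(df: pd.DataFrame, age_center: float = 19.0) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design: intercept, age centred at ``age_center`` (years),
    male indicator (female = reference)."""
    age = pd.to_numeric(df["age"]).to_numpy(dtype=float) - age_center
    male = (
        df["gender"].astype(str).str.strip().str.casefold() == "male"
    ).to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df)), age, male])
    return X, ["intercept", "age_c", "male"]


def country_and_cluster_modes(
    analysis: pd.DataFrame,
    cluster_map: ClusterMap | None = None,
    responses: dict[str, str] | None = None,
) -> dict[tuple[str, str], LmmFit]:
    """Fit the four mode-extraction models on a filtered analysis set.

    ``analysis`` needs columns ``age, gender, country, self_estimate,
    score`` (a ``cluster`` column is derived from ``cluster_map`` when
    absent).  Returns ``{(response, grouping): LmmFit}`` for response in
    {self_estimate, performance} and grouping in {country, cluster}.  The
    cluster models fit cluster directly as the grouping factor rather than
    aggregating country modes.
    """
    df = analysis.copy()
    if "cluster" not in df.columns:
        if cluster_map is None:
            raise ValueError("cluster_map required to derive the cluster column")
        df["cluster"] = [assign_cluster(c, cluster_map) for c in df["country"]]
        if df["cluster"].isna().any():
            bad = sorted(df.loc[df["cluster"].isna(), "country"].unique())
            raise ValueError(f"unmapped countries in analysis set: {bad}")
    responses = responses or {
        "self_estimate": "self_estimate_numeric",
        "performance": "score",
    }
    if "self_estimate_numeric" in responses.values() and "self_estimate_numeric" not in df:
        df["self_estimate_numeric"] = encode_self_estimates(df["self_estimate"])
    X, names = design_matrix(df)
    fits: dict[tuple[str, str], LmmFit] = {}
    for rname, col in responses.items():
        y = df[col].to_numpy(dtype=float)
        for grouping in ("country", "cluster"):
            fits[(rname, grouping)] = fit_random_intercept_lmm(
                y, X, df[grouping].to_numpy(), beta_names=names
            )
    return fits
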