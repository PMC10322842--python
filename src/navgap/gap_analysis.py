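"""The over/under-confidence gap and its cultural correlates.

For each unit (country or cluster) the pipeline has two adjusted means:
the conditional mode of the numeric self-estimate and the conditional mode
of the wayfinding performance score, each controlled for age and gender.
Both sets of modes are min-max normalised to [0, 1] across units, and

    gap = normalised self-estimate - normalised performance

lies in [-1, 1]: +1 is the maximum possible overestimation (highest
self-belief, lowest performance), -1 the maximum possible underestimation,
0 a perfectly calibrated unit.  Country and cluster tables are normalised
separately so the two scales do not mix.

The gap is then rank-correlated with the six Hofstede dimensions (and any
optional indices such as GDP per capita), with Bonferroni correction over
the six dimensions tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._coding import SELF_ESTIMATE_CODES, encode_self_estimate, encode_self_estimates
from .cultural_atlas import HOFSTEDE_DIMENSIONS, canonical_country
from .mixed_effects import LmmFit, country_and_cluster_modes
from .regression_suite import spearman

__all__ = [
    "SELF_ESTIMATE_CODES",
    "encode_self_estimate",
    "encode_self_estimates",
    "min_max_normalize",
    "compute_gap",
    "correlate_with_culture",
    "gender_split_gaps",
]


def min_max_normalize(values) -> pd.Series:
    """Min-max normalise to [0, 1]: the minimum unit maps to 0, the maximum
    to 1.  Invariant to positive affine transforms of the input.  Raises if
    all values are equal (the normalisation is undefined)."""
    s = pd.Series(values, dtype=float)
    if len(s) < 2:
        raise ValueError(f"need >= 2 values to normalise, got {len(s)}")
    if not np.isfinite(s.to_numpy()).all():
        raise ValueError("non-finite values")
    lo, hi = s.min(), s.max()
    if hi == lo:
        raise ValueError("all values equal; min-max normalisation undefined")
    return (s - lo) / (hi - lo)


def compute_gap(selfest_modes, perf_modes) -> pd.DataFrame:
    """Per-unit gap records from two mode vectors over the same units.

    Inputs are Series indexed by unit (raw conditional modes; normalisation
    happens here).  Returns a frame with columns ``selfest_norm,
    perf_norm, gap`` indexed by unit; every gap is in [-1, 1].
    """
    selfest_modes = pd.Series(selfest_modes, dtype=float)
    perf_modes = pd.Series(perf_modes, dtype=float)
    only_se = set(selfest_modes.index) - set(perf_modes.index)
    only_pf = set(perf_modes.index) - set(selfest_modes.index)
    if only_se or only_pf:
        raise ValueError(
            f"unit mismatch: only in self-estimates {sorted(only_se)}, "
            f"only in performance {sorted(only_pf)}"
        )
    se = min_max_normalize(selfest_modes)
    pf = min_max_normalize(perf_modes).reindex(se.index)
    out = pd.DataFrame({"selfest_norm": se, "perf_norm": pf, "gap": se - pf})
    out.index.name = "unit"
    return out


def correlate_with_culture(
    gaps: pd.DataFrame,
    profiles: pd.DataFrame,
    dimensions=HOFSTEDE_DIMENSIONS,
    m_tests: int | None = None,
    value_col: str = "gap",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation of a per-unit value with cultural dimensions.

    ``gaps`` is indexed by unit (country names), ``profiles`` by canonical
    country with one column per dimension.  Units with a missing profile
    value are dropped pairwise per dimension (``n_used`` records the
    count).  p-values are Bonferroni-corrected over ``m_tests`` (defaults
    to the number of Hofstede dimensions tested, 6); rows with fewer than
    3 complete pairs or degenerate ranks are flagged not-computable.
    """
    m = m_tests if m_tests is not None else len(dimensions)
    prof = profiles.copy()
    prof.index = [canonical_country(c) for c in prof.index]
    joined = gaps.join(prof, how="left")
    rows = []
    for dim in dimensions:
        if dim not in joined.columns:
            rows.append(
                {"dimension": dim, "rho": np.nan, "p_raw": np.nan,
                 "p_bonferroni": np.nan, "n_used": 0, "significant": False,
                 "computable": False}
            )
            continue
        sub = joined[[value_col, dim]].dropna()
        try:
            res = spearman(sub[value_col], sub[dim])
            p_adj = min(1.0, m * res.p)
            rows.append(
                {"dimension": dim, "rho": res.rho, "p_raw": res.p,
                 "p_bonferroni": p_adj, "n_used": res.n,
                 "significant": p_adj < alpha, "computable": True}
            )
        except ValueError:
            rows.append(
                {"dimension": dim, "rho": np.nan, "p_raw": np.nan,
                 "p_bonferroni": np.nan, "n_used": len(sub),
                 "significant": False, "computable": False}
            )
    return pd.DataFrame(rows)


def gaps_from_fits(fits: dict[tuple[str, str], LmmFit], grouping: str) -> pd.DataFrame:
    """Gap table for one grouping level from the four-model fit dict."""
    se = fits[("self_estimate", grouping)].modes["mode"]
    pf = fits[("performance", grouping)].modes["mode"]
    return compute_gap(se, pf)


def gender_split_gaps(
    analysis: pd.DataFrame,
    cluster_map=None,
    grouping: str = "country",
) -> dict[str, pd.DataFrame]:
    """Re-run modes -> normalise -> gap within each gender stratum.

    Returns ``{"female": gap_table, "male": gap_table}`` over the chosen
    grouping.  Raises if a stratum is empty or covers fewer than two units
    (normalisation would be undefined).
    """
    from .mixed_effects import fit_random_intercept_lmm
    from .cultural_atlas import assign_cluster

    df = analysis.copy()
    if grouping == "cluster" and "cluster" not in df.columns:
        if cluster_map is None:
            raise ValueError("cluster_map required to derive the cluster column")
        df["cluster"] = [assign_cluster(c, cluster_map) for c in df["country"]]
    if "self_estimate_numeric" not in df.columns:
        df["self_estimate_numeric"] = encode_self_estimates(df["self_estimate"])

    out: dict[str, pd.DataFrame] = {}
    gender = df["gender"].astype(str).str.strip().str.casefold()
    for g in ("female", "male"):
        stratum = df[gender == g]
        if len(stratum) == 0:
            raise ValueError(f"no players in the {g} stratum")
        if stratum[grouping].nunique() < 2:
            raise ValueError(f"{g} stratum covers < 2 {grouping} units")
        # gender is constant within a stratum, so the fixed part is
        # intercept + centred age only
        age = pd.to_numeric(stratum["age"]).to_numpy(float) - 19.0
        X = np.column_stack([np.ones(len(stratum)), age])
        names = ["intercept", "age_c"]
        groups = stratum[grouping].to_numpy()
        se_fit = fit_random_intercept_lmm(
            stratum["self_estimate_numeric"].to_numpy(float), X, groups, names
        )
        pf_fit = fit_random_intercept_lmm(
            stratum["score"].to_numpy(float), X, groups, names
        )
        out[g] = compute_gap(se_fit.modes["mode"], pf_fit.modes["mode"])
    return out
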