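"""Numeric coding of the 4-level self-estimate scale.

The scale has no neutral option, and neither does the coding: very bad =
-2, bad = -1, good = 1, very good = 2 (no zero).
"""

from __future__ import annotations

import pandas as pd

SELF_ESTIMATE_CODES: dict[str, int] = {
    "very bad": -2,
    "bad": -1,
    "good": 1,
    "very good": 2,
}


def encode_self_estimate(label: str) -> int:
    """Numeric code for one self-estimate label (case-insensitive).

    Raises ``ValueError`` naming the offending value for anything not on
    the 4-point scale.
    """
    key = str(label).strip().casefold()
    try:
        return SELF_ESTIMATE_CODES[key]
    except KeyError:
        raise ValueError(
            f"unknown self-estimate label {label!r}; expected one of "
            f"{list(SELF_ESTIMATE_CODES)}"
        ) from None


def encode_self_estimates(labels) -> pd.Series:
    """Vectorised coding of a label sequence; raises on any unknown label."""
    s = pd.Series(labels).astype(str).str.strip().str.casefold()
    coded = s.map(SELF_ESTIMATE_CODES)
    if coded.isna().any():
        bad = sorted(s[coded.isna()].unique())
        raise ValueError(f"unknown self-estimate labels: {bad}")
    return coded.astype(int)
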