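"""Country -> cultural-cluster mapping and user-supplied cultural profiles.

The analysis aggregates countries into the 11 global cultural clusters of
Ronen & Shenkar (Germanic, Nordic, Confucian Asia, ...).  The 46-country
membership table is bundled as package data; players from countries outside
it are flagged as unmapped and dropped by the inclusion cascade.

Country-level cultural profiles (the six Hofstede dimensions, optionally GDP
per capita and a gender-inequality index) are user-supplied as CSV: the
source studies publish them under their own terms, so no values are bundled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "ClusterMap",
    "CulturalProfile",
    "CLUSTER_LABELS",
    "HOFSTEDE_DIMENSIONS",
    "N_COUNTRIES",
    "N_CLUSTERS",
    "canonical_country",
    "load_cluster_map",
    "assign_cluster",
    "load_profiles",
    "profiles_frame",
]

#: The 11 cluster labels, fixed strings.
CLUSTER_LABELS = (
    "African",
    "Anglo",
    "Arabic",
    "Confucian Asia",
    "East Europe",
    "Far East",
    "Germanic",
    "Latin America",
    "Latin Europe",
    "Near East",
    "Nordic",
)

#: The six Hofstede cultural dimensions used for gap correlations.
HOFSTEDE_DIMENSIONS = (
    "power_distance",
    "individualism",
    "masculinity",
    "uncertainty_avoidance",
    "long_term_orientation",
    "indulgence",
)

#: Optional country-level indices the correlation step also accepts.
OPTIONAL_PROFILE_COLUMNS = ("gdp_per_capita", "gender_inequality_index")

N_COUNTRIES = 46
N_CLUSTERS = 11


def canonical_country(name: str, aliases: Mapping[str, str] | None = None) -> str:
    """Canonicalise a country name: trim whitespace, resolve aliases.

    Matching elsewhere is case-insensitive exact match after trimming; no
    fuzzy matching is attempted (a silent misjoin is worse than an explicit
    drop).  ``aliases`` maps alternative spellings (e.g. ``"Russia"``) to the
    canonical form used by the cluster table (``"Russian Federation"``).
    """
    name = str(name).strip()
    if aliases:
        folded = {str(k).strip().casefold(): v for k, v in aliases.items()}
        name = folded.get(name.casefold(), name)
    return name


@dataclass(frozen=True)
class ClusterMap:
    """Immutable country -> cluster mapping for the 46 analysed countries."""

    entries: Mapping[str, str]
    _lookup: Mapping[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_lookup", {c.casefold(): cl for c, cl in self.entries.items()}
        )

    @property
    def countries(self) -> tuple[str, ...]:
        return tuple(self.entries)

    @property
    def clusters(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.entries.values())))

    def get(self, country: str, aliases: Mapping[str, str] | None = None) -> str | None:
        """Cluster for ``country``, or ``None`` if unmapped.  Never raises."""
        try:
            key = canonical_country(country, aliases).casefold()
        except Exception:
            return None
        return self._lookup.get(key)

    def validate(self) -> None:
        n_c = len(set(self.entries))
        n_cl = len(set(self.entries.values()))
        if n_c != N_COUNTRIES or n_cl != N_CLUSTERS:
            raise ValueError(
                f"corrupted cluster map: {n_c} countries / {n_cl} clusters, "
                f"expected {N_COUNTRIES} / {N_CLUSTERS}"
            )
        unknown = set(self.entries.values()) - set(CLUSTER_LABELS)
        if unknown:
            raise ValueError(f"corrupted cluster map: unknown cluster labels {sorted(unknown)}")


def load_cluster_map() -> ClusterMap:
    """Load the bundled 46-country / 11-cluster membership table.

    Raises ``ValueError`` if the bundled file does not satisfy the expected
    counts (a corrupted installation is a hard failure, not a warning).
    """
    with resources.files("navgap.data").joinpath("cluster_map.csv").open("r") as fh:
        df = pd.read_csv(fh)
    cmap = ClusterMap(dict(zip(df["country"].map(canonical_country), df["cluster"])))
    cmap.validate()
    return cmap


def assign_cluster(
    country: str,
    cluster_map: ClusterMap,
    aliases: Mapping[str, str] | None = None,
) -> str | None:
    """Cluster label for ``country``, or ``None`` for unmapped countries.

    Total on arbitrary strings: unmapped is a value, not an error.  The
    inclusion cascade drops unmapped players and records the count.
    """
    if not isinstance(country, str) or not country.strip():
        return None
    return cluster_map.get(country, aliases)


@dataclass(frozen=True)
class CulturalProfile:
    """One country's cultural-dimension scores plus optional indices.

    Missing optional fields are ``None`` (explicitly flagged, never silently
    zero).  Membership in the cluster table is resolved lazily by the caller:
    a profile for an unmapped country is retained.
    """

    country: str
    power_distance: float
    individualism: float
    masculinity: float
    uncertainty_avoidance: float
    long_term_orientation: float
    indulgence: float
    gdp_per_capita: float | None = None
    gender_inequality_index: float | None = None

    def __post_init__(self) -> None:
        for dim in HOFSTEDE_DIMENSIONS:
            v = getattr(self, dim)
            if not math.isfinite(float(v)):
                raise ValueError(f"{self.country}: non-finite {dim} score {v!r}")


def load_profiles(
    path: str | Path, aliases: Mapping[str, str] | None = None
) -> list[CulturalProfile]:
    """Read cultural profiles from CSV (one row per country).

    Required columns: ``country`` plus the six dimensions; optional columns
    ``gdp_per_capita`` and ``gender_inequality_index``.  A non-numeric
    dimension cell raises with the 1-based data row number.
    """
    df = pd.read_csv(path)
    missing = {"country", *HOFSTEDE_DIMENSIONS} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    profiles: list[CulturalProfile] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = row._asdict()
        kwargs: dict = {"country": canonical_country(rec["country"], aliases)}
        for col in HOFSTEDE_DIMENSIONS:
            try:
                kwargs[col] = float(rec[col])
                if not math.isfinite(kwargs[col]):
                    raise ValueError
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: row {i}: non-numeric {col} value {rec[col]!r}"
                ) from None
        for col in OPTIONAL_PROFILE_COLUMNS:
            v = rec.get(col)
            kwargs[col] = None if v is None or pd.isna(v) else float(v)
        profiles.append(CulturalProfile(**kwargs))
    return profiles


def profiles_frame(profiles: list[CulturalProfile]) -> pd.DataFrame:
    """Profiles as a DataFrame indexed by canonical country name."""
    rows = [
        {
            "country": p.country,
            **{d: getattr(p, d) for d in HOFSTEDE_DIMENSIONS},
            **{c: getattr(p, c) for c in OPTIONAL_PROFILE_COLUMNS},
        }
        for p in profiles
    ]
    return pd.DataFrame(rows).set_index("country")
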