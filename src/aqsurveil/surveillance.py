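"""City-level rate normalization and correlation against pollution measures.

The surveillance statistic chain: a filter's matched messages are grouped by
city and divided by each city's total message count (the normalized rate),
then the per-city rates are correlated (Pearson) with the city's average
(ADV) or maximum (MDV) daily PM2.5 value. A dependent-correlation z test
compares the ADV- and MDV-based coefficients, which share the rate vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import MessageCorpus
from .errors import (
    InsufficientDataError,
    PairingError,
    SchemaError,
    UndefinedCorrelationError,
)
from .filters import FilterResult


@dataclass
class PollutionTable:
    """Per-city pollution summary: average and maximum daily value (µg/m³)."""

    frame: pd.DataFrame  # columns: city, adv, mdv

    def __post_init__(self) -> None:
        required = {"city", "adv", "mdv"}
        missing = required - set(self.frame.columns)
        if missing:
            raise SchemaError(f"pollution table missing columns: {sorted(missing)}")
        f = self.frame
        if f["city"].duplicated().any():
            dupes = f.loc[f["city"].duplicated(), "city"].tolist()
            raise SchemaError(f"duplicate cities in pollution table: {dupes[:5]}")
        if (f["adv"] <= 0).any() or (f["mdv"] <= 0).any():
            raise SchemaError("pollution values must be positive")
        if (f["adv"] > f["mdv"]).any():
            bad = f.loc[f["adv"] > f["mdv"], "city"].tolist()
            raise SchemaError(f"ADV exceeds MDV for cities: {bad[:5]}")

    @property
    def cities(self) -> list[str]:
        return self.frame["city"].tolist()

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_csv(cls, path) -> "PollutionTable":
        frame = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
        return cls(frame=frame[["city", "adv", "mdv"]].copy())

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


@dataclass
class CityRateTable:
    """Per-city matched counts, totals, and normalized rates."""

    frame: pd.DataFrame  # columns: city, matched, total, rate
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        f = self.frame
        if ((f["matched"] < 0) | (f["matched"] > f["total"])).any():
            raise SchemaError("matched counts must satisfy 0 <= matched <= total")
        if not np.allclose(f["rate"], f["matched"] / f["total"]):
            raise SchemaError("rate column inconsistent with matched/total")

    @classmethod
    def from_csv(cls, path) -> "CityRateTable":
        return cls(frame=pd.read_csv(path, encoding="utf-8", float_precision="round_trip"))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


@dataclass
class CorrelationResult:
    """Pearson r with its two-sided p, plus the pairing it was computed on."""

    r: float
    n: int
    p_value: float
    metric: Optional[str] = None
    cities: tuple = ()
    excluded: list[tuple[str, str]] = field(default_factory=list)


def normalize_city(name: str, aliases: Optional[Mapping[str, str]] = None) -> str:
    """Exact matching after whitespace trimming plus an optional alias map.

    Fuzzy matching is deliberately not attempted: city-name reconciliation
    between message metadata and monitoring-station tables is the caller's
    responsibility via ``aliases``.
    """
    name = name.strip()
    if aliases:
        name = aliases.get(name, name)
    return name


def city_rates(
    result: FilterResult,
    corpus: MessageCorpus,
    cities: Optional[Sequence[str]] = None,
) -> CityRateTable:
    """Matched / total message counts per city.

    ``cities`` restricts and orders the output (e.g. to the pollution
    table's city list); cities with zero collected messages are excluded and
    reported, never given an imputed rate.
    """
    totals = corpus.city_totals()
    matched_by_city: dict[str, int] = {}
    matched_ids = result.matched
    for m in corpus:
        if m.id in matched_ids:
            matched_by_city[m.city] = matched_by_city.get(m.city, 0) + 1

    if cities is None:
        cities = sorted(totals)
    rows = []
    excluded: list[tuple[str, str]] = []
    for city in cities:
        total = totals.get(city, 0)
        if total == 0:
            excluded.append((city, "no messages collected from city"))
            continue
        matched = matched_by_city.get(city, 0)
        rows.append((city, matched, total, matched / total))
    frame = pd.DataFrame(rows, columns=["city", "matched", "total", "rate"])
    return CityRateTable(frame=frame, excluded=excluded)


def pearson(x, y, metric: Optional[str] = None) -> CorrelationResult:
    """Product-moment correlation with a two-sided t-based p value.

    Raises rather than propagating NaN: zero variance in either vector is an
    :class:`UndefinedCorrelationError`, fewer than 3 pairs an
    :class:`InsufficientDataError`.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise InsufficientDataError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"need >= 3 pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined for a zero-variance vector"
        )
    res = stats.pearsonr(x, y)
    return CorrelationResult(
        r=float(res.statistic), n=n, p_value=float(res.pvalue), metric=metric
    )


def correlate(
    rates: CityRateTable,
    pollution: PollutionTable,
    metric: str = "adv",
    aliases: Optional[Mapping[str, str]] = None,
) -> CorrelationResult:
    """Inner-join rates with pollution on city and correlate rate vs metric."""
    metric = metric.lower()
    if metric not in ("adv", "mdv"):
        raise SchemaError(f"metric must be 'adv' or 'mdv', got {metric!r}")

    r = rates.frame.copy()
    p = pollution.frame.copy()
    r["city_key"] = r["city"].map(lambda c: normalize_city(c, aliases))
    p["city_key"] = p["city"].map(lambda c: normalize_city(c, aliases))
    joined = r.merge(p, on="city_key", suffixes=("_rate", "_pm")).sort_values(
        "city_key"
    )

    excluded = list(rates.excluded)
    rate_keys = set(r["city_key"])
    pm_keys = set(p["city_key"])
    for c in sorted(pm_keys - rate_keys):
        excluded.append((c, "city absent from rate table"))
    for c in sorted(rate_keys - pm_keys):
        excluded.append((c, "city absent from pollution table"))

    if len(joined) < 3:
        raise InsufficientDataError(
            f"only {len(joined)} cities joined; need >= 3"
        )
    result = pearson(joined["rate"], joined[metric], metric=metric.upper())
    result.cities = tuple(joined["city_key"])
    result.excluded = excluded
    return result


def dependent_corr_z(
    r1: float, r2: float, r_between: float, n: int
) -> tuple[float, float]:
    """Meng–Rosenthal–Rubin z test for two overlapping dependent correlations.

    ``r1`` and ``r2`` share one variable (here: the rate vector correlated
    with ADV and with MDV); ``r_between`` is the correlation of the two
    non-shared variables (ADV vs MDV). Returns (z, two-sided p).
    """
    if n < 4:
        raise InsufficientDataError(f"need n >= 4, got {n}")
    if r1 == r2:
        return 0.0, 1.0
    rbar2 = (r1**2 + r2**2) / 2.0
    f = min(1.0, (1.0 - r_between) / (2.0 * (1.0 - rbar2)))
    h = (1.0 - f * rbar2) / (1.0 - rbar2)
    dz = np.arctanh(r1) - np.arctanh(r2)
    z = dz * np.sqrt((n - 3) / (2.0 * (1.0 - r_between) * h))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


@dataclass
class CorrelationComparison:
    z: float
    p_value: float
    method: str
    r1: float
    r2: float
    r_between: float
    n: int


def compare_correlations(
    res_a: CorrelationResult,
    res_b: CorrelationResult,
    r_between: Optional[float] = None,
    pollution: Optional[PollutionTable] = None,
) -> CorrelationComparison:
    """Compare two correlations computed on the same cities against two
    pollution measures.

    ``r_between`` (the ADV–MDV correlation over the shared cities) may be
    given directly or derived from ``pollution`` restricted to the shared
    city set.
    """
    if res_a.cities != res_b.cities or res_a.n != res_b.n:
        raise PairingError("correlations were not computed on the same city set")
    if r_between is None:
        if pollution is None:
            raise PairingError("supply r_between or the pollution table")
        sub = pollution.frame[
            pollution.frame["city"].map(normalize_city).isin(res_a.cities)
        ]
        r_between = pearson(sub["adv"], sub["mdv"]).r
    z, p = dependent_corr_z(res_a.r, res_b.r, r_between, res_a.n)
    return CorrelationComparison(
        z=z,
        p_value=p,
        method="meng-rosenthal-rubin-z",
        r1=res_a.r,
        r2=res_b.r,
        r_between=float(r_between),
        n=res_a.n,
    )


def rate_conservation(result: FilterResult, corpus: MessageCorpus) -> bool:
    """Σ_c matched_c equals the number of matched, city-resolvable messages."""
    table = city_rates(result, corpus)
    return int(table.frame["matched"].sum()) == sum(
        1 for m in corpus if m.id in result.matched
    )
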