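"""Survey-weighted prevalence and direct age standardization (ESP 2013).

Stratum prevalence is the calibration-weight-weighted mean of a binary
indicator. Direct standardization averages age-band prevalences with the
fixed band weights of the European Standard Population, 2013 revision;
bands absent from the data are dropped and the standard weights renormalized
over the bands present, so sparse strata stay computable (flagged, never
imputed).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from .cohort import AgeBandScheme, EDUCATION_LEVELS

ESP2013_TOTAL = 100_000


@dataclass(frozen=True)
class StandardPopulation:
    """Ordered (age band, standard weight) pairs."""

    bands: tuple[str, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.bands) != len(self.weights):
            raise ValueError("bands and weights must align")
        if any(w <= 0 for w in self.weights):
            raise ValueError("standard weights must be positive")

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=list(self.bands), dtype=float)

    def weight_for(self, band: str) -> float:
        try:
            return self.weights[self.bands.index(band)]
        except ValueError:
            raise KeyError(f"band {band!r} not in standard population") from None

    @classmethod
    def esp2013(cls) -> "StandardPopulation":
        """Full ESP 2013 fixture (bands 0 .. 95+, weights sum to 100,000)."""
        path = resources.files("hearineq.data") / "esp2013.csv"
        df = pd.read_csv(path)
        total = df["weight"].sum()
        if total != ESP2013_TOTAL:
            raise ValueError(f"ESP 2013 fixture weights sum to {total}, expected {ESP2013_TOTAL}")
        return cls(tuple(df["band"]), tuple(float(w) for w in df["weight"]))

    @classmethod
    def esp2013_for_scheme(cls, scheme: AgeBandScheme) -> "StandardPopulation":
        """ESP 2013 aggregated onto an analysis age-band scheme.

        Each scheme band receives the summed weight of the ESP five-year
        bands it covers (an open band collects everything at or above its
        lower bound, e.g. 85+ = 85-89 + 90-94 + 95+).
        """
        full = cls.esp2013()
        esp_lo = [int(b.split("-")[0].rstrip("+")) for b in full.bands]
        weights = []
        for (lo, hi), label in zip(scheme.bands, scheme.labels):
            upper = np.inf if hi is None else hi
            w = sum(
                wt
                for b_lo, wt in zip(esp_lo, full.weights)
                if lo <= b_lo < upper
            )
            if w == 0:
                raise ValueError(f"scheme band {label} covers no ESP band")
            weights.append(float(w))
        return cls(scheme.labels, tuple(weights))


@dataclass
class StratumPrevalence:
    """Weighted prevalence for one analysis cell."""

    key: dict
    p: float
    n_obs: int
    sum_w: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"prevalence {self.p} outside [0, 1]")
        if self.n_obs < 1:
            raise ValueError("a reported cell needs at least one observation")


def weighted_prevalence(y, w, key: dict | None = None) -> StratumPrevalence | None:
    """p = sum(w*y) / sum(w); None marks an unavailable cell (never 0)."""
    y_a = np.asarray(y, dtype=float)
    w_a = np.asarray(w, dtype=float)
    if y_a.size == 0:
        return None
    sw = w_a.sum()
    if sw <= 0:
        return None
    return StratumPrevalence(
        key=key or {},
        p=float((w_a * y_a).sum() / sw),
        n_obs=int(y_a.size),
        sum_w=float(sw),
    )


def direct_standardize(
    band_prevalence: Mapping[str, float], standard: StandardPopulation
) -> float | None:
    """Directly standardized prevalence over the bands present in the data.

    Standard weights are renormalized over the overlap between the data and
    the standard; no overlap yields None (unavailable).
    """
    num = 0.0
    den = 0.0
    for band, w in zip(standard.bands, standard.weights):
        p = band_prevalence.get(band)
        if p is None or (isinstance(p, float) and np.isnan(p)):
            continue
        num += w * p
        den += w
    if den == 0.0:
        return None
    return num / den


# Coarse reporting age groups: ASPs are published for 50-64, 65+ and Total.
AGE_GROUPS = ("50-64", "65+", "Total")


def _band_in_group(band: str, group: str) -> bool:
    if group == "Total":
        return True
    lo = int(band.split("-")[0].rstrip("+"))
    return lo < 65 if group == "50-64" else lo >= 65


def build_prevalence_table(
    cohort: pd.DataFrame,
    outcome: str,
    standard: StandardPopulation,
    strata: Iterable[str] = ("region", "gender", "education"),
    age_groups: Iterable[str] = AGE_GROUPS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Weighted band prevalences and age-standardized prevalences (ASP).

    ``outcome`` is ``"hl"`` (hearing loss, full cohort denominator) or
    ``"ha_use_among_eligible"`` (hearing-aid use, denominator restricted to
    eligible records). Returns ``(band_table, asp_table)``: the band table
    has one row per stratum x age band with p, n_obs, sum_w; the ASP table
    one row per stratum x coarse age group with the standardized prevalence
    (NaN where unavailable).
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    strata = list(strata)
    if outcome == "hl":
        data = cohort
        y = data["hl"].astype(float)
    elif outcome == "ha_use_among_eligible":
        data = cohort[cohort["ha_eligible"]]
        y = data["ha_use"].astype(float)
    else:
        raise ValueError(f"unknown outcome {outcome!r}")

    band_rows = []
    if not data.empty:
        work = data.assign(_y=y.to_numpy(), _wy=y.to_numpy() * data["weight"].to_numpy())
        grouped = work.groupby(strata + ["age_band"], observed=True, dropna=False)
        agg = grouped.agg(
            n_obs=("_y", "size"), sum_w=("weight", "sum"), sum_wy=("_wy", "sum")
        ).reset_index()
        agg["p"] = agg["sum_wy"] / agg["sum_w"]
        band_rows = agg.drop(columns="sum_wy").to_dict("records")
    band_table = pd.DataFrame(
        band_rows, columns=strata + ["age_band", "n_obs", "sum_w", "p"]
    )

    asp_rows = []
    keys = (
        band_table[strata].drop_duplicates().to_dict("records")
        if not band_table.empty
        else []
    )
    for key in keys:
        mask = np.ones(len(band_table), dtype=bool)
        for k, v in key.items():
            mask &= (band_table[k] == v).to_numpy()
        sub = band_table[mask]
        by_band = dict(zip(sub["age_band"], sub["p"]))
        for group in age_groups:
            in_group = {b: p for b, p in by_band.items() if _band_in_group(b, group)}
            asp = direct_standardize(in_group, standard)
            asp_rows.append(
                {
                    **key,
                    "age_group": group,
                    "asp": np.nan if asp is None else asp,
                    "n_obs": int(
                        sub.loc[[_band_in_group(b, group) for b in sub["age_band"]], "n_obs"].sum()
                    ),
                }
            )
    asp_table = pd.DataFrame(asp_rows, columns=strata + ["age_group", "asp", "n_obs"])
    return band_table, asp_table


def weighted_education_shares(cohort: pd.DataFrame) -> np.ndarray:
    """Calibration-weighted education distribution (low, medium, high)."""
    totals = cohort.groupby("education", observed=False)["weight"].sum()
    shares = totals.reindex(list(EDUCATION_LEVELS)).fillna(0.0).to_numpy(float)
    s = shares.sum()
    if s <= 0:
        raise ValueError("no positive weight in cohort")
    return shares / s
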