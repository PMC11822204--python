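"""Cohort derivation: exclusion cascade and analysis-variable construction.

Survey microdata arrive as person-wave rows (each wave treated as an
independent cross-section). The cascade drops, in order: rows with missing
age or age below 50, rows missing any outcome or sociodemographic variable
(self-reported hearing quality, hearing-aid use, education, gender, country),
and rows missing the cross-sectional calibration weight. Each row is counted
in exactly one drop bucket, at the first failing step.

Analysis variables derived afterwards: the hearing-loss indicator (hearing
rated worse than "good", i.e. SRHQ 4 or 5, with a sensitivity variant that
also counts hearing-aid users), hearing-aid eligibility (aid user or
less-than-good hearing), region (country lookup table) and age band.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Canonical microdata columns, in file order.
MICRODATA_COLUMNS = (
    "person_id",
    "wave",
    "country",
    "age",
    "gender",
    "education",
    "srhq",
    "ha_use",
    "weight",
)

#: Ordered education levels (ISCED 0-2, 3-4, 5-6).
EDUCATION_LEVELS = ("low", "medium", "high")

#: Columns whose missingness triggers the outcome/sociodemographic drop.
OUTCOME_SOCIODEMO_COLUMNS = ("srhq", "ha_use", "education", "gender", "country")

MIN_AGE = 50


@dataclass
class ExclusionLog:
    """Reconciled record counts for the exclusion cascade."""

    n_input: int = 0
    n_dropped_age: int = 0
    n_dropped_outcome_sociodemo: int = 0
    n_dropped_weight: int = 0
    n_retained: int = 0

    def __post_init__(self) -> None:
        dropped = (
            self.n_dropped_age
            + self.n_dropped_outcome_sociodemo
            + self.n_dropped_weight
        )
        if self.n_input != self.n_retained + dropped:
            raise ValueError(
                f"exclusion log does not reconcile: input {self.n_input} != "
                f"retained {self.n_retained} + dropped {dropped}"
            )

    def to_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_dropped_age": self.n_dropped_age,
            "n_dropped_outcome_sociodemo": self.n_dropped_outcome_sociodemo,
            "n_dropped_weight": self.n_dropped_weight,
            "n_retained": self.n_retained,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_text(self) -> str:
        return (
            f"Input person-wave observations: {self.n_input}\n"
            f"  dropped, missing age or age < {MIN_AGE}: {self.n_dropped_age}\n"
            f"  dropped, missing outcome/sociodemographic data: "
            f"{self.n_dropped_outcome_sociodemo}\n"
            f"  dropped, missing calibration weight: {self.n_dropped_weight}\n"
            f"Retained: {self.n_retained}\n"
        )


def filter_cohort(records: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the exclusion cascade; return the retained rows and a log.

    Rows failing several criteria are counted once, at the first failing
    step (age, then outcome/sociodemographic missingness, then weight).
    """
    n_input = len(records)
    if n_input == 0:
        return records.copy(), ExclusionLog()

    age = pd.to_numeric(records["age"], errors="coerce")
    bad_age = age.isna() | (age < MIN_AGE)

    bad_outcome = pd.Series(False, index=records.index)
    for col in OUTCOME_SOCIODEMO_COLUMNS:
        bad_outcome |= records[col].isna()
    bad_outcome &= ~bad_age

    weight = pd.to_numeric(records["weight"], errors="coerce")
    bad_weight = weight.isna() & ~bad_age & ~bad_outcome

    keep = ~(bad_age | bad_outcome | bad_weight)
    out = records.loc[keep].copy()
    log = ExclusionLog(
        n_input=n_input,
        n_dropped_age=int(bad_age.sum()),
        n_dropped_outcome_sociodemo=int(bad_outcome.sum()),
        n_dropped_weight=int(bad_weight.sum()),
        n_retained=int(keep.sum()),
    )
    return out, log


def _check_srhq(srhq: np.ndarray) -> None:
    bad = ~np.isin(srhq, (1, 2, 3, 4, 5))
    if bad.any():
        raise ValueError(
            f"self-reported hearing quality must be in 1..5, got {np.unique(np.asarray(srhq)[bad])}"
        )


def classify_hearing_loss(srhq, ha_use, definition: str = "standard"):
    """Hearing-loss indicator from self-reported hearing quality.

    ``standard``: hearing rated less than good (SRHQ 4 "fair" or 5 "poor").
    ``sensitivity``: additionally counts hearing-aid users who rate their
    (aided) hearing good or better, guarding against treated hearing loss
    masking as good hearing.

    Accepts scalars or arrays; returns a bool of matching shape.
    """
    srhq_a = np.asarray(srhq, dtype=float)
    ha_a = np.asarray(ha_use, dtype=bool)
    _check_srhq(srhq_a)
    hl = srhq_a >= 4
    if definition == "standard":
        out = hl
    elif definition == "sensitivity":
        out = hl | ha_a
    else:
        raise ValueError(f"unknown hearing-loss definition {definition!r}")
    return out if out.ndim else bool(out)


def ha_eligible(srhq, ha_use):
    """Hearing-aid analysis denominator: aid user, or less-than-good hearing."""
    srhq_a = np.asarray(srhq, dtype=float)
    ha_a = np.asarray(ha_use, dtype=bool)
    _check_srhq(srhq_a)
    out = ha_a | (srhq_a >= 4)
    return out if out.ndim else bool(out)


def default_region_mapping() -> dict[str, str]:
    """Bundled 28-country welfare-regime mapping (editable via CSV)."""
    path = resources.files("hearineq.data") / "region_map.csv"
    df = pd.read_csv(path)
    return dict(zip(df["country"], df["region"]))


def load_region_mapping(path) -> dict[str, str]:
    df = pd.read_csv(path)
    expected = {"country", "region"}
    if set(df.columns) != expected:
        raise ValueError(f"region mapping must have columns {sorted(expected)}")
    return dict(zip(df["country"], df["region"]))


def assign_region(country, mapping: Mapping[str, str]):
    """Map country codes to one of the four European regions."""
    if isinstance(country, str):
        if country not in mapping:
            raise KeyError(f"country code {country!r} has no region mapping")
        return mapping[country]
    s = pd.Series(country)
    unmapped = sorted(set(s.dropna()) - set(mapping))
    if unmapped:
        raise KeyError(f"country codes with no region mapping: {unmapped}")
    return s.map(mapping).to_numpy()


@dataclass(frozen=True)
class AgeBandScheme:
    """Ordered, disjoint age bands; the last band may be open-ended.

    Bands are half-open ``[lo, hi)`` with ``hi=None`` for an open final band.
    Ages outside every band are out-of-scheme (excluded from that analysis).
    """

    name: str
    bands: tuple[tuple[int, int | None], ...]

    def __post_init__(self) -> None:
        prev_hi = None
        for lo, hi in self.bands:
            if hi is not None and hi <= lo:
                raise ValueError(f"empty band [{lo}, {hi})")
            if prev_hi is not None and (prev_hi is ... or lo < prev_hi):
                raise ValueError("bands must be ordered and disjoint")
            prev_hi = hi if hi is not None else ...

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(_band_label(lo, hi) for lo, hi in self.bands)

    def assign(self, age):
        """Band label for each age; None / NaN-label for out-of-scheme ages."""
        age_a = np.atleast_1d(np.asarray(age, dtype=float))
        out = np.full(age_a.shape, None, dtype=object)
        for (lo, hi), label in zip(self.bands, self.labels):
            upper = np.inf if hi is None else hi
            mask = (age_a >= lo) & (age_a < upper)
            out[mask] = label
        return out[0] if np.isscalar(age) or np.ndim(age) == 0 else out

    @classmethod
    def fiveyear_50_85plus(cls) -> "AgeBandScheme":
        bands = tuple((lo, lo + 5) for lo in range(50, 85, 5)) + ((85, None),)
        return cls("fiveyear_50_85plus", bands)

    @classmethod
    def coarse(cls) -> "AgeBandScheme":
        return cls("coarse", ((50, 65), (65, None)))

    @classmethod
    def sensitivity_65_79(cls) -> "AgeBandScheme":
        return cls("sensitivity_65_79", ((65, 70), (70, 75), (75, 80)))

    @classmethod
    def named(cls, name: str) -> "AgeBandScheme":
        schemes = {
            "fiveyear_50_85plus": cls.fiveyear_50_85plus,
            "coarse": cls.coarse,
            "sensitivity_65_79": cls.sensitivity_65_79,
        }
        if name not in schemes:
            raise ValueError(f"unknown age-band scheme {name!r}; choose from {sorted(schemes)}")
        return schemes[name]()


def _band_label(lo: int, hi: int | None) -> str:
    return f"{lo}+" if hi is None else f"{lo}-{hi - 1}"


def assign_age_band(age, scheme: AgeBandScheme):
    return scheme.assign(age)


def derive_analysis_table(
    records: pd.DataFrame,
    region_mapping: Mapping[str, str] | None = None,
    scheme: AgeBandScheme | None = None,
    hl_definition: str = "standard",
) -> pd.DataFrame:
    """Attach region, hl, ha_eligible and age_band to a filtered cohort.

    Rows whose age falls outside the scheme (e.g. 80+ under the 65-79
    sensitivity restriction) are excluded.
    """
    if region_mapping is None:
        region_mapping = default_region_mapping()
    if scheme is None:
        scheme = AgeBandScheme.fiveyear_50_85plus()
    out = records.copy()
    out["age"] = pd.to_numeric(out["age"])
    out["srhq"] = pd.to_numeric(out["srhq"]).astype(int)
    out["ha_use"] = out["ha_use"].astype(bool)
    out["weight"] = pd.to_numeric(out["weight"])
    if (out["weight"] <= 0).any():
        raise ValueError("calibration weights must be positive")
    out["region"] = assign_region(out["country"].to_numpy(), region_mapping)
    out["hl"] = classify_hearing_loss(out["srhq"], out["ha_use"], hl_definition)
    out["ha_eligible"] = ha_eligible(out["srhq"], out["ha_use"])
    out["age_band"] = scheme.assign(out["age"].to_numpy())
    out = out[out["age_band"].notna()].reset_index(drop=True)
    out["education"] = pd.Categorical(
        out["education"], categories=list(EDUCATION_LEVELS), ordered=True
    )
    if out["education"].isna().any():
        raise ValueError(f"education must be one of {EDUCATION_LEVELS}")
    return out
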