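"""Config-driven analysis pipeline and delimited-text I/O.

Chains cohort filtering, survey-weighted prevalence, ESP-2013 direct age
standardization, ridit-based RII/SII and the stratified bootstrap, and
writes tidy output tables (sample characteristics, age-standardized
prevalence by education with inequality indices, an age-trend table) plus a
run manifest sufficient to reproduce the run bit-for-bit.

`RIIEstimator` is the per-replicate pipeline: given a prepared analysis
stratum it recomputes, for any row resample, the weighted education
distribution, its ridit scores, the weighted band prevalences, the
standardized prevalences per education level and finally the inequality
index. It is what the bootstrap re-evaluates B times.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    AgeBandScheme,
    EDUCATION_LEVELS,
    MICRODATA_COLUMNS,
    ExclusionLog,
    default_region_mapping,
    derive_analysis_table,
    filter_cohort,
    load_region_mapping,
)
from .inequality import fit_inequality_line, ridit_scores
from .standardize import (
    AGE_GROUPS,
    StandardPopulation,
    _band_in_group,
    build_prevalence_table,
)
from .uncertainty import BootstrapSpec, bootstrap_estimate

# ---------------------------------------------------------------------------
# Microdata I/O

_NUMERIC_COLUMNS = ("age", "srhq", "weight")
_VALID_GENDERS = {"man", "woman"}


def read_microdata(path) -> pd.DataFrame:
    """Read canonical person-wave microdata CSV with validation.

    Empty fields are missing. Malformed rows are rejected with their line
    numbers; schema mismatches list the missing/unknown columns.
    """
    df = pd.read_csv(
        path,
        dtype={"person_id": str, "country": str, "gender": str, "education": str},
        keep_default_na=True,
        na_values=[""],
    )
    missing = [c for c in MICRODATA_COLUMNS if c not in df.columns]
    unknown = [c for c in df.columns if c not in MICRODATA_COLUMNS and c != "region"]
    if missing or unknown:
        raise ValueError(
            f"microdata schema mismatch in {path}: missing columns {missing}, "
            f"unknown columns {unknown}"
        )

    errors: list[str] = []

    def _lines(mask) -> list[int]:
        # +2: one for the header, one for 1-based numbering.
        return [int(i) + 2 for i in np.flatnonzero(mask)[:10]]

    for col in _NUMERIC_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            errors.append(f"non-numeric {col} at lines {_lines(bad)}")
        df[col] = coerced

    bad_srhq = df["srhq"].notna() & ~df["srhq"].isin([1, 2, 3, 4, 5])
    if bad_srhq.any():
        errors.append(f"srhq outside 1..5 at lines {_lines(bad_srhq)}")
    bad_w = df["weight"].notna() & (df["weight"] <= 0)
    if bad_w.any():
        errors.append(f"non-positive weight at lines {_lines(bad_w)}")
    bad_g = df["gender"].notna() & ~df["gender"].isin(list(_VALID_GENDERS))
    if bad_g.any():
        errors.append(f"unknown gender at lines {_lines(bad_g)}")
    bad_e = df["education"].notna() & ~df["education"].isin(list(EDUCATION_LEVELS))
    if bad_e.any():
        errors.append(f"unknown education level at lines {_lines(bad_e)}")

    ha_raw = df["ha_use"]
    ha_map = {
        "1": True, "0": False, "true": True, "false": False,
        "True": True, "False": False, 1: True, 0: False,
        1.0: True, 0.0: False, True: True, False: False,
    }
    mapped = ha_raw.map(lambda v: ha_map.get(v, None) if pd.notna(v) else np.nan)
    bad_ha = pd.Series([m is None for m in mapped], index=df.index)
    if bad_ha.any():
        errors.append(f"ha_use not 0/1 at lines {_lines(bad_ha)}")
    df["ha_use"] = mapped.where(~bad_ha, np.nan)

    if errors:
        raise ValueError(f"invalid microdata in {path}: " + "; ".join(errors))
    return df


# ---------------------------------------------------------------------------
# Fast per-replicate pipeline estimator

class RIIEstimator:
    """Inequality index recomputed from scratch on row resamples.

    Parameters mirror the analysis choices: outcome ("hl" or
    "ha_use_among_eligible"), the index ("RII", or "SII" in percentage
    points), the coarse reporting age group the estimate refers to, and the
    regression weighting ("none" = OLS, "shares" = share-weighted).
    """

    def __init__(
        self,
        standard: StandardPopulation,
        outcome: str = "hl",
        index: str = "RII",
        age_group: str = "Total",
        weighting: str = "none",
    ):
        if outcome not in ("hl", "ha_use_among_eligible"):
            raise ValueError(f"unknown outcome {outcome!r}")
        if index not in ("RII", "SII"):
            raise ValueError(f"unknown index {index!r}")
        self.standard = standard
        self.outcome = outcome
        self.index = index
        self.age_group = age_group
        self.weighting = weighting

    def prepare(self, cohort: pd.DataFrame) -> None:
        bands = [
            b for b in self.standard.bands if _band_in_group(b, self.age_group)
        ]
        self._band_index = {b: i for i, b in enumerate(bands)}
        self._esp = np.array([self.standard.weight_for(b) for b in bands])
        self._n_band = len(bands)

        band_codes = cohort["age_band"].map(self._band_index)
        in_group = band_codes.notna().to_numpy()
        self._band = np.where(in_group, band_codes.fillna(0).to_numpy(int), -1)
        self._edu = (
            pd.Categorical(
                cohort["education"], categories=list(EDUCATION_LEVELS), ordered=True
            ).codes.astype(int)
        )
        self._w = cohort["weight"].to_numpy(float)
        if self.outcome == "hl":
            self._y = cohort["hl"].to_numpy(float)
            self._in_denominator = in_group
        else:
            self._y = cohort["ha_use"].to_numpy(float)
            self._in_denominator = in_group & cohort["ha_eligible"].to_numpy(bool)
        self._n_edu = len(EDUCATION_LEVELS)

    def evaluate(self, idx: np.ndarray) -> float:
        sel = idx[self._in_denominator[idx]]
        if sel.size == 0:
            return float("nan")
        edu = self._edu[sel]
        band = self._band[sel]
        w = self._w[sel]
        wy = w * self._y[sel]

        cell = edu * self._n_band + band
        m = self._n_edu * self._n_band
        sw = np.bincount(cell, weights=w, minlength=m).reshape(self._n_edu, self._n_band)
        swy = np.bincount(cell, weights=wy, minlength=m).reshape(self._n_edu, self._n_band)

        edu_w = sw.sum(axis=1)
        if (edu_w <= 0).any():
            return float("nan")
        shares = edu_w / edu_w.sum()
        x = ridit_scores(shares)

        present = sw > 0
        esp = np.where(present, self._esp, 0.0)
        den = esp.sum(axis=1)
        if (den <= 0).any():
            return float("nan")
        with np.errstate(invalid="ignore"):
            p = np.where(present, swy / np.where(sw > 0, sw, 1.0), 0.0)
        asp = (esp * p).sum(axis=1) / den

        fit_w = shares if self.weighting == "shares" else None
        intercept, slope = fit_inequality_line(x, asp, fit_w)
        if self.index == "SII":
            return float(-slope * 100.0)
        top = intercept + slope
        if top <= 0:
            return float("nan")
        return float(intercept / top)


# ---------------------------------------------------------------------------
# Analysis configuration and run

@dataclass
class AnalysisConfig:
    """Everything a pipeline run needs; serializable to/from YAML."""

    input: str
    output_dir: str
    region_map: str | None = None
    standard_population: str | None = None
    outcomes: tuple[str, ...] = ("hl", "ha_use_among_eligible")
    hl_definition: str = "standard"
    age_scheme: str = "fiveyear_50_85plus"
    indices: tuple[str, ...] = ("RII",)
    rii_weighting: str = "none"
    bootstrap_B: int = 1000
    ci_method: str = "bca"
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        for o in self.outcomes:
            if o not in ("hl", "ha_use_among_eligible"):
                raise ValueError(f"unknown outcome {o!r}")
        for i in self.indices:
            if i not in ("RII", "SII"):
                raise ValueError(f"unknown index {i!r}")
        AgeBandScheme.named(self.age_scheme)
        if self.hl_definition not in ("standard", "sensitivity"):
            raise ValueError(f"unknown hl_definition {self.hl_definition!r}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("outcomes", "indices"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["outcomes"] = list(self.outcomes)
        d["indices"] = list(self.indices)
        return d


@dataclass
class RunManifest:
    config: dict
    config_hash: str
    package_version: str
    seed: int
    started: str
    exclusion_log: dict
    cell_counts: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _config_hash(config: AnalysisConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_analysis(config: AnalysisConfig) -> RunManifest:
    """Run the full pipeline and write output tables to ``output_dir``.

    Outputs: ``characteristics.csv`` (sample profile by region x gender),
    ``prevalence_<outcome>.csv`` (ASP by education and age group),
    ``inequality_<outcome>.csv`` (index, CI, bootstrap metadata),
    ``age_trend.csv`` (weighted prevalence by age band, education, gender),
    ``exclusion_log.json``/``.txt`` and ``manifest.json``. Deterministic
    under fixed config and seed.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    records = read_microdata(config.input)
    mapping = (
        load_region_mapping(config.region_map)
        if config.region_map
        else default_region_mapping()
    )
    scheme = AgeBandScheme.named(config.age_scheme)
    standard = (
        StandardPopulation.esp2013_for_scheme(scheme)
        if config.standard_population is None
        else _custom_standard(config.standard_population, scheme)
    )

    filtered, log = filter_cohort(records)
    cohort = derive_analysis_table(filtered, mapping, scheme, config.hl_definition)

    # The HA-use analysis sample must be a subset of the HL sample.
    assert cohort.loc[cohort["ha_use"].astype(bool), "ha_eligible"].all()

    _write_characteristics(cohort, outdir / "characteristics.csv")
    _write_age_trend(cohort, outdir / "age_trend.csv")

    cell_counts = (
        cohort.groupby(["region", "gender"], observed=True)
        .size()
        .rename("n")
        .reset_index()
        .to_dict("records")
    )

    for outcome in config.outcomes:
        _, asp_table = build_prevalence_table(cohort, outcome, standard)
        asp_table.to_csv(outdir / f"prevalence_{outcome}.csv", index=False)

        # Per-age-group indices only where cells support them: the HA-use
        # sample is too sparse to subdivide by age, so it gets Total only.
        groups = list(AGE_GROUPS) if outcome == "hl" else ["Total"]
        rows = []
        for (region, gender), stratum in cohort.groupby(
            ["region", "gender"], observed=True
        ):
            for index in config.indices:
                for group in groups:
                    est = RIIEstimator(
                        standard,
                        outcome=outcome,
                        index=index,
                        age_group=group,
                        weighting=config.rii_weighting,
                    )
                    spec = BootstrapSpec(
                        B=config.bootstrap_B,
                        ci_level=config.ci_level,
                        ci_method=config.ci_method if index == "RII" else "percentile",
                        stratify_by=("region", "gender"),
                        seed=config.seed,
                    )
                    try:
                        res = bootstrap_estimate(stratum, est, spec)
                    except ValueError:
                        rows.append(
                            {
                                "region": region, "gender": gender, "index": index,
                                "age_group": group, "point": np.nan, "lo": np.nan,
                                "hi": np.nan, "B": spec.B, "ci_method": spec.ci_method,
                                "n_undefined": spec.B, "flagged": True,
                            }
                        )
                        continue
                    rows.append(
                        {
                            "region": region, "gender": gender, "index": index,
                            "age_group": group, "point": res.point,
                            "lo": res.ci[0], "hi": res.ci[1], "B": spec.B,
                            "ci_method": res.ci_method,
                            "n_undefined": res.n_undefined,
                            "flagged": res.too_many_undefined,
                        }
                    )
        pd.DataFrame(rows).to_csv(outdir / f"inequality_{outcome}.csv", index=False)

    (outdir / "exclusion_log.json").write_text(log.to_json())
    (outdir / "exclusion_log.txt").write_text(log.to_text())

    manifest = RunManifest(
        config=config.to_dict(),
        config_hash=_config_hash(config),
        package_version=__version__,
        seed=config.seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
        exclusion_log=log.to_dict(),
        cell_counts={"region_gender": cell_counts},
    )
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest


def _custom_standard(path, scheme: AgeBandScheme) -> StandardPopulation:
    df = pd.read_csv(path)
    sp = StandardPopulation(tuple(df["band"]), tuple(float(w) for w in df["weight"]))
    if set(scheme.labels) - set(sp.bands):
        raise ValueError(
            f"standard population {path} lacks bands for scheme {scheme.name}"
        )
    return sp


def _write_characteristics(cohort: pd.DataFrame, path) -> None:
    rows = []
    for (region, gender), g in cohort.groupby(["region", "gender"], observed=True):
        w = g["weight"]
        row = {
            "region": region,
            "gender": gender,
            "n": len(g),
            "age_mean": g["age"].mean(),
            "age_sd": g["age"].std(),
            "srhq_mean": g["srhq"].mean(),
            "hl_pct_weighted": 100 * np.average(g["hl"], weights=w),
            "ha_pct_weighted": 100 * np.average(g["ha_use"].astype(float), weights=w),
        }
        for level in EDUCATION_LEVELS:
            m = g["education"] == level
            row[f"edu_{level}_n"] = int(m.sum())
            row[f"edu_{level}_pct"] = 100 * m.mean()
            row[f"edu_{level}_pct_weighted"] = 100 * w[m].sum() / w.sum()
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _write_age_trend(cohort: pd.DataFrame, path) -> None:
    rows = []
    for (gender, edu, band), g in cohort.groupby(
        ["gender", "education", "age_band"], observed=True
    ):
        rows.append(
            {
                "gender": gender,
                "education": edu,
                "age_band": band,
                "hl_pct": 100 * np.average(g["hl"], weights=g["weight"]),
                "n": len(g),
            }
        )
        elig = g[g["ha_eligible"]]
        if len(elig):
            rows[-1]["ha_use_among_eligible_pct"] = 100 * np.average(
                elig["ha_use"].astype(float), weights=elig["weight"]
            )
        else:
            rows[-1]["ha_use_among_eligible_pct"] = np.nan
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Rendering

_DASH = "—"


def _fmt(v, nd=1) -> str:
    return _DASH if v is None or (isinstance(v, float) and np.isnan(v)) else f"{v:.{nd}f}"


def render_tables(outdir, fmt: str = "text") -> list[Path]:
    """Re-render pipeline CSV outputs as aligned text tables (1-decimal).

    The tidy CSVs keep full precision; text rendering rounds percentages and
    indices to one decimal and prints an em-dash for unavailable cells.
    """
    outdir = Path(outdir)
    written = []
    for csv_path in sorted(outdir.glob("prevalence_*.csv")) + sorted(
        outdir.glob("inequality_*.csv")
    ):
        df = pd.read_csv(csv_path)
        lines = []
        if csv_path.name.startswith("prevalence"):
            header = ["region", "gender", "education", "age_group", "ASP %"]
            lines.append("\t".join(header))
            for _, r in df.iterrows():
                lines.append(
                    "\t".join(
                        [
                            str(r["region"]), str(r["gender"]), str(r["education"]),
                            str(r["age_group"]), _fmt(100 * r["asp"]),
                        ]
                    )
                )
        else:
            header = ["region", "gender", "index", "age_group", "point", "95% CI"]
            lines.append("\t".join(header))
            for _, r in df.iterrows():
                ci = (
                    _DASH
                    if np.isnan(r["lo"])
                    else f"({_fmt(r['lo'])}–{_fmt(r['hi'])})"
                )
                lines.append(
                    "\t".join(
                        [
                            str(r["region"]), str(r["gender"]), str(r["index"]),
                            str(r["age_group"]), _fmt(r["point"]), ci,
                        ]
                    )
                )
        target = csv_path.with_suffix(".txt")
        target.write_text("\n".join(lines) + "\n")
        written.append(target)
    return written
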