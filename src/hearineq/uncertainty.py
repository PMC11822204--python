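"""Bootstrap resampling of the full estimation pipeline.

Records are resampled with replacement, stratified so each analysis stratum
keeps its original size, and the entire chain — education distribution,
ridit scores, weighted band prevalences, age standardization, inequality
index — is recomputed on every replicate. Intervals are percentile
(empirical 2.5/97.5 quantiles, linear interpolation of order statistics) or
bias-corrected and accelerated (BCa), which corrects for median bias (z0)
and skewness (acceleration a, from a jackknife) and cannot stray below the
range of the replicates — so an all-positive replicate distribution never
yields a non-positive RII bound.

Replicates on which the index is undefined (predicted prevalence at rank 1
non-positive) are excluded from the quantiles and counted, never silently
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from hashlib import sha256
from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd
from scipy.stats import norm

UNDEFINED_WARN_FRACTION = 0.2


@dataclass(frozen=True)
class BootstrapSpec:
    """How to resample and how to turn replicates into an interval."""

    B: int = 1000
    ci_level: float = 0.95
    ci_method: str = "percentile"  # or "bca"
    stratify_by: tuple[str, ...] = ("region", "gender")
    seed: int = 0
    #: leave-one-out jackknife below this n; grouped (delete-d) above.
    jackknife_exact_max_n: int = 2000
    jackknife_groups: int = 50

    def __post_init__(self) -> None:
        if self.B < 2:
            raise ValueError("need at least 2 bootstrap replicates")
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError("ci_level must be in (0, 1)")
        if self.ci_method not in ("percentile", "bca"):
            raise ValueError(f"unknown ci_method {self.ci_method!r}")


@dataclass
class BootstrapResult:
    point: float
    replicates: np.ndarray
    ci: tuple[float, float]
    ci_method: str
    n_undefined: int
    too_many_undefined: bool = False
    acceleration_fallback: bool = False


@runtime_checkable
class ResampleEstimator(Protocol):
    """Estimator evaluated on row-index resamples of a prepared cohort."""

    def prepare(self, cohort: pd.DataFrame) -> None: ...

    def evaluate(self, idx: np.ndarray) -> float: ...


class _CallableAdapter:
    """Wraps a plain DataFrame -> float estimator into the resample protocol."""

    def __init__(self, fn: Callable[[pd.DataFrame], float]):
        self._fn = fn
        self._df: pd.DataFrame | None = None

    def prepare(self, cohort: pd.DataFrame) -> None:
        self._df = cohort.reset_index(drop=True)

    def evaluate(self, idx: np.ndarray) -> float:
        return float(self._fn(self._df.iloc[idx]))


def stratum_rng(master_seed: int, key: Sequence) -> np.random.Generator:
    """Independent RNG stream per stratum, stable under adding other strata."""
    digest = sha256(repr(tuple(key)).encode()).digest()
    sub = int.from_bytes(digest[:4], "big") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([master_seed % (2**31), sub]))


def percentile_interval(replicates: np.ndarray, level: float) -> tuple[float, float]:
    """Empirical central interval, linear interpolation of order statistics."""
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(replicates, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


def bca_interval(
    replicates: np.ndarray,
    point: float,
    jackknife: np.ndarray,
    level: float = 0.95,
) -> tuple[tuple[float, float], bool]:
    """Bias-corrected and accelerated interval.

    z0 from the fraction of replicates below the point estimate; a from the
    skewness of jackknife (leave-one-out or grouped) estimates. Returns
    ``((lo, hi), acceleration_fallback)`` where the flag marks a degenerate
    jackknife (zero variance) handled with a = 0.
    """
    reps = np.asarray(replicates, dtype=float)
    reps = reps[np.isfinite(reps)]
    B = reps.size
    if B < 2:
        raise ValueError("need at least 2 defined replicates")
    if np.ptp(reps) == 0:
        return (float(reps[0]), float(reps[0])), False

    frac_below = np.count_nonzero(reps < point) / B
    # Guard the probit at 0 or 1 (all replicates on one side of the point).
    frac_below = min(max(frac_below, 1.0 / (B + 1)), B / (B + 1))
    z0 = norm.ppf(frac_below)

    jk = np.asarray(jackknife, dtype=float)
    jk = jk[np.isfinite(jk)]
    dev = jk.mean() - jk
    denom = (dev**2).sum() ** 1.5
    fallback = False
    if denom == 0.0:
        a = 0.0
        fallback = True
    else:
        a = (dev**3).sum() / (6.0 * denom)

    alpha = (1.0 - level) / 2.0
    out = []
    for a_k in (alpha, 1.0 - alpha):
        if z0 == 0.0 and a == 0.0:
            adj = a_k  # no correction: reduce exactly to the percentile levels
        else:
            z = z0 + norm.ppf(a_k)
            adj = norm.cdf(z0 + z / (1.0 - a * z))
        out.append(float(np.quantile(reps, adj, method="linear")))
    return (out[0], out[1]), fallback


def _stratum_indices(cohort: pd.DataFrame, stratify_by: Sequence[str]) -> list[np.ndarray]:
    if not stratify_by:
        return [np.arange(len(cohort))]
    codes = pd.MultiIndex.from_frame(cohort[list(stratify_by)].astype(str)).factorize()[0]
    return [np.flatnonzero(codes == c) for c in np.unique(codes)]


def jackknife_estimates(
    estimator: ResampleEstimator, n: int, spec: BootstrapSpec, rng: np.random.Generator
) -> np.ndarray:
    """Leave-one-out (small n) or grouped delete-d jackknife estimates."""
    if n <= spec.jackknife_exact_max_n:
        all_idx = np.arange(n)
        return np.array(
            [estimator.evaluate(np.delete(all_idx, i)) for i in range(n)], dtype=float
        )
    groups = rng.permutation(n) % spec.jackknife_groups
    all_idx = np.arange(n)
    return np.array(
        [estimator.evaluate(all_idx[groups != g]) for g in range(spec.jackknife_groups)],
        dtype=float,
    )


def bootstrap_estimate(
    cohort: pd.DataFrame,
    estimator: ResampleEstimator | Callable[[pd.DataFrame], float],
    spec: BootstrapSpec,
) -> BootstrapResult:
    """Stratified bootstrap of an estimator over person-wave records.

    The estimator must be defined (finite) on the original cohort. Each
    replicate resamples every stratum with replacement at its original size.
    """
    if not isinstance(estimator, ResampleEstimator):
        estimator = _CallableAdapter(estimator)
    cohort = cohort.reset_index(drop=True)
    estimator.prepare(cohort)
    n = len(cohort)
    full_idx = np.arange(n)
    point = float(estimator.evaluate(full_idx))
    if not np.isfinite(point):
        raise ValueError("estimator undefined on the original cohort")

    strata = _stratum_indices(cohort, spec.stratify_by)
    rngs = [
        stratum_rng(spec.seed, ("bootstrap", tuple(cohort.loc[s[0], list(spec.stratify_by)]) if spec.stratify_by else ()))
        for s in strata
    ]
    replicates = np.empty(spec.B, dtype=float)
    # Pre-draw all resample positions per stratum for speed and determinism.
    draws = [
        rng.integers(0, len(s), size=(spec.B, len(s))) for s, rng in zip(strata, rngs)
    ]
    for b in range(spec.B):
        idx = np.concatenate([s[d[b]] for s, d in zip(strata, draws)])
        replicates[b] = estimator.evaluate(idx)

    defined = replicates[np.isfinite(replicates)]
    n_undefined = spec.B - defined.size
    if defined.size < 2:
        raise ValueError("fewer than 2 defined bootstrap replicates")

    fallback = False
    if spec.ci_method == "percentile":
        ci = percentile_interval(defined, spec.ci_level)
    else:
        jk_rng = stratum_rng(spec.seed, ("jackknife",))
        jk = jackknife_estimates(estimator, n, spec, jk_rng)
        ci, fallback = bca_interval(defined, point, jk, spec.ci_level)

    return BootstrapResult(
        point=point,
        replicates=replicates,
        ci=ci,
        ci_method=spec.ci_method,
        n_undefined=n_undefined,
        too_many_undefined=n_undefined > UNDEFINED_WARN_FRACTION * spec.B,
        acceleration_fallback=fallback,
    )
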