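"""Ridit scoring and the Relative / Slope Index of Inequality.

Ordered education categories are mapped onto (0, 1) by ridit scoring: each
category sits at the midpoint of its cumulative population share, so rank 0
is the hypothetical bottom and rank 1 the top of the education distribution.
A least-squares line of the education-specific age-standardized prevalences
on these scores summarizes the gradient:

    RII = yhat(0) / yhat(1)   (relative; > 1 means excess risk at the bottom)
    SII = yhat(0) - yhat(1)   (absolute, in the units of the outcome)

Both are invariant to the number of categories and, because the ridit scores
are share-weighted to mean 0.5, comparable across populations with different
education distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_SHARE_TOL = 1e-9


def ridit_scores(shares, normalize: bool = False) -> np.ndarray:
    """Cumulative-proportion midpoints of ordered category shares.

    x_e = (cumulative share below e) + share_e / 2. Shares must be
    non-negative and sum to 1 (pass ``normalize=True`` for rounded published
    percentages). For shares (0.2, 0.5, 0.3) the scores are
    (0.1, 0.45, 0.85).
    """
    s = np.asarray(shares, dtype=float)
    if s.ndim != 1 or s.size < 1:
        raise ValueError("shares must be a 1-d sequence")
    if (s < 0).any():
        raise ValueError("shares must be non-negative")
    total = s.sum()
    if normalize:
        if total <= 0:
            raise ValueError("shares sum to zero")
        s = s / total
    elif abs(total - 1.0) > _SHARE_TOL:
        raise ValueError(f"shares sum to {total}, expected 1")
    cum = np.cumsum(s)
    return cum - s / 2


def fit_inequality_line(x, y, weights=None) -> tuple[float, float]:
    """Least-squares line of prevalences on ridit scores.

    Returns (intercept, slope) of yhat(x) = intercept + slope * x. With
    ``weights`` (education shares) the fit is weighted least squares;
    the default is ordinary least squares.
    """
    x_a = np.asarray(x, dtype=float)
    y_a = np.asarray(y, dtype=float)
    if x_a.size < 2:
        raise ValueError("need at least two categories to fit a line")
    if np.ptp(x_a) == 0:
        raise ValueError("all ridit scores equal; education distribution degenerate")
    w = np.ones_like(x_a) if weights is None else np.asarray(weights, dtype=float)
    sw = w.sum()
    xm = (w * x_a).sum() / sw
    ym = (w * y_a).sum() / sw
    sxx = (w * (x_a - xm) ** 2).sum()
    slope = (w * (x_a - xm) * (y_a - ym)).sum() / sxx
    intercept = ym - slope * xm
    return float(intercept), float(slope)


def rii(x, y, weights=None) -> float:
    """Relative Index of Inequality: yhat(0) / yhat(1).

    Returns NaN when the predicted prevalence at rank 1 is non-positive
    (undefined ratio; callers such as the bootstrap count these).
    """
    intercept, slope = fit_inequality_line(x, y, weights)
    top = intercept + slope
    if top <= 0:
        return float("nan")
    return intercept / top


def sii(x, y, weights=None) -> float:
    """Slope Index of Inequality: yhat(0) - yhat(1) = -slope."""
    _, slope = fit_inequality_line(x, y, weights)
    return -slope


def inequality_from_shares(
    shares, asp, index: str = "RII", weighting: str = "none", normalize_shares: bool = False
) -> float:
    """RII or SII from ordered education shares and per-category prevalences.

    ``weighting="none"`` fits ordinary least squares (the default, which
    reproduces published regional estimates); ``"shares"`` weights each
    category by its population share.
    """
    s = np.asarray(shares, dtype=float)
    x = ridit_scores(s, normalize=normalize_shares)
    w = None if weighting == "none" else s / s.sum()
    if weighting not in ("none", "shares"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if index == "RII":
        return rii(x, asp, w)
    if index == "SII":
        return sii(x, asp, w)
    raise ValueError(f"unknown index {index!r}")


@dataclass
class InequalityEstimate:
    """Point estimate of an inequality index with optional bootstrap CI."""

    index: str  # "RII" or "SII"
    point: float
    ci: tuple[float, float] | None = None
    ci_method: str = "none"  # "percentile", "bca" or "none"
    B: int = 0
    key: dict | None = None

    def __post_init__(self) -> None:
        if self.index not in ("RII", "SII"):
            raise ValueError(f"unknown index {self.index!r}")
        if self.index == "RII" and np.isfinite(self.point) and self.point <= 0:
            raise ValueError("RII must be positive")
        if self.ci is not None:
            lo, hi = self.ci
            if not (lo <= hi):
                raise ValueError("CI bounds out of order")
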