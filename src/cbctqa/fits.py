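"""Fixed-exponent power-law fits and the scaling-law arithmetic.

Two empirical laws connect dose and image quality across cone-beam
protocols: the normalized dose index grows with the cube of the tube
potential (nCBDI = c * kVp^3) and image noise falls with the inverse
square root of the weighted dose index (noise = c * wCBDI^(-1/2)). Both
are one-parameter fits y = c * x^p with the exponent *fixed* by the model;
the least-squares coefficient has the closed form

    c = sum(x^p * y) / sum(x^(2p)).

Agreement is summarized by the Pearson correlation between y and x^p
("normalized cross-correlation"; an uncentered cosine variant is available
for sensitivity checks), the residual standard deviation, and the maximum
absolute deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .dosimetry import DoseIndexRecord
from .errors import DegenerateDataError

ArrayLike = Sequence[float]


@dataclass(frozen=True)
class FitResult:
    """Result of fitting y = coefficient * x^exponent with the exponent fixed."""

    coefficient: float
    exponent: float
    residual_sd: float
    max_abs_deviation: float
    ncc: float
    n: int

    def predict(self, x: ArrayLike) -> np.ndarray:
        return self.coefficient * np.asarray(x, dtype=float) ** self.exponent

    def to_dict(self) -> dict:
        return {
            "exponent": self.exponent,
            "coefficient": self.coefficient,
            "residual_sd": self.residual_sd,
            "max_abs_deviation": self.max_abs_deviation,
            "ncc": self.ncc,
            "n": self.n,
        }


def _as_pair(x: ArrayLike, y: ArrayLike) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"series must be 1-D and equal length, got {x.shape} vs {y.shape}")
    return x, y


def normalized_cross_correlation(
    x: ArrayLike, y: ArrayLike, centered: bool = True
) -> float:
    """Correlation between two series.

    ``centered=True`` (default) is the Pearson product-moment correlation;
    ``centered=False`` is the uncentered cosine similarity, provided for
    sensitivity checks only.
    """
    x, y = _as_pair(x, y)
    if x.size < 3:
        raise ValueError(f"need at least 3 points, got {x.size}")
    if centered:
        x = x - x.mean()
        y = y - y.mean()
    denom = np.sqrt((x**2).sum() * (y**2).sum())
    if denom == 0:
        raise DegenerateDataError("a series has zero variance; correlation undefined")
    return float((x * y).sum() / denom)


def fit_fixed_power(x: ArrayLike, y: ArrayLike, p: float) -> FitResult:
    """Least-squares fit of y = c * x^p with p fixed.

    The residual SD uses denominator n (population form), matching how the
    scatter about a one-parameter curve is usually quoted.
    """
    x, y = _as_pair(x, y)
    if x.size == 0:
        raise ValueError("empty input")
    if (p != int(p) or p < 0) and np.any(x <= 0):
        raise ValueError(f"x must be > 0 elementwise for exponent {p}")
    xp = x**p
    c = float((xp * y).sum() / (xp * xp).sum())
    residuals = y - c * xp
    ncc = normalized_cross_correlation(y, xp) if x.size >= 3 else float("nan")
    return FitResult(
        coefficient=c,
        exponent=p,
        residual_sd=float(residuals.std()),
        max_abs_deviation=float(np.abs(residuals).max()),
        ncc=ncc,
        n=int(x.size),
    )


def fit_fixed_power_log(x: ArrayLike, y: ArrayLike, p: float) -> FitResult:
    """Log-space alternative: least squares on log y = log c + p log x.

    Equivalent to the geometric-mean coefficient; exposed as an option, not
    the default, because the headline fits are quoted in linear space.
    """
    x, y = _as_pair(x, y)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("log-space fit requires positive x and y")
    c = float(np.exp(np.mean(np.log(y) - p * np.log(x))))
    residuals = y - c * x**p
    return FitResult(
        coefficient=c,
        exponent=p,
        residual_sd=float(residuals.std()),
        max_abs_deviation=float(np.abs(residuals).max()),
        ncc=normalized_cross_correlation(y, x**p) if x.size >= 3 else float("nan"),
        n=int(x.size),
    )


def kvp_power_ratio(kvp_a: float, kvp_b: float, p: float, decimals: int = 2) -> float:
    """(kvp_a / kvp_b)^p, rounded to the reporting precision (2 decimals)."""
    if kvp_a <= 0 or kvp_b <= 0:
        raise ValueError("tube potentials must be > 0")
    return round((kvp_a / kvp_b) ** p, decimals)


def group_ncbdi_ratio(
    records: Sequence[DoseIndexRecord],
    kvp_a: float,
    kvp_b: float,
    pairing: Literal["group_means", "matched"] = "group_means",
) -> tuple[float, float]:
    """Ratio of mean nCBDI between two tube-potential groups, with its SD.

    ``group_means`` (default) divides the group means and propagates the
    per-group sample SDs to first order:
    sd(ratio) = ratio * sqrt((sd_a/mean_a)^2 + (sd_b/mean_b)^2).
    ``matched`` pairs records in group order (requires equal group sizes),
    takes per-pair ratios, and reports their mean and SD.
    """
    a = np.array([r.ncbdi for r in records if r.kvp == kvp_a])
    b = np.array([r.ncbdi for r in records if r.kvp == kvp_b])
    for kvp, g in ((kvp_a, a), (kvp_b, b)):
        if g.size == 0:
            raise DegenerateDataError(f"no dose records at {kvp:g} kVp")
    if pairing == "matched":
        if a.size != b.size:
            raise DegenerateDataError(
                f"matched pairing needs equal group sizes ({a.size} vs {b.size})"
            )
        ratios = a / b
        sd = float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0
        return float(ratios.mean()), sd
    ratio = float(a.mean() / b.mean())
    rel_a = a.std(ddof=1) / a.mean() if a.size > 1 else 0.0
    rel_b = b.std(ddof=1) / b.mean() if b.size > 1 else 0.0
    return ratio, float(ratio * np.hypot(rel_a, rel_b))


def bootstrap_coefficient_sd(
    x: ArrayLike,
    y: ArrayLike,
    p: float,
    n_boot: int = 1000,
    seed: int = 0,
) -> float:
    """Bootstrap SD of the fixed-power coefficient (diagnostic utility)."""
    x, y = _as_pair(x, y)
    rng = np.random.default_rng(seed)
    coeffs = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, x.size, size=x.size)
        coeffs[i] = fit_fixed_power(x[idx], y[idx], p).coefficient
    return float(coeffs.std(ddof=1))
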