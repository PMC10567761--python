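"""Bivariate generalization of the reference interval.

In 2D the analogue of the central-95% interval is the highest-density region
of the principal binormal distribution: the ellipse around the mean enclosing
95% of its probability mass.  For a Gaussian this contour is available in
closed form — the squared Mahalanobis distance of a d-dimensional Gaussian is
chi-square with d degrees of freedom, so the 95% boundary sits at the
chi-square(2) quantile r^2 = -2 ln(1 - mass).  (Integrating the density from
the mean outwards gives the identical contour; a numeric cross-check lives in
the test suite.)

Slicing the ellipse at a fixed value of one analyte yields the *chord
interval* for the other: the conditional acceptable range given the partner
reading, which shrinks as the partner reading moves off-center and vanishes
entirely once the partner reading alone leaves the joint region.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, norm

from .mixture import GaussianComponent

__all__ = [
    "DensityEllipse",
    "ChordInterval",
    "hdr_ellipse",
    "chord_interval",
    "conditional_interval",
    "contour_polyline",
]

#: Correlations beyond this are treated as degenerate (near-singular) input.
MAX_ABS_CORRELATION = 0.999


@dataclass(frozen=True)
class DensityEllipse:
    """Highest-density contour of a bivariate Gaussian at a given mass."""

    mean: np.ndarray
    covariance: np.ndarray
    mass: float
    mahalanobis_sq: float

    def mahalanobis_sq_at(self, point) -> float:
        dev = np.asarray(point, float) - self.mean
        return float(dev @ np.linalg.solve(self.covariance, dev))

    def contains(self, point) -> bool:
        return self.mahalanobis_sq_at(point) <= self.mahalanobis_sq

    def to_json(self) -> str:
        return json.dumps(
            {
                "mean": self.mean.tolist(),
                "covariance": self.covariance.ravel().tolist(),
                "mass": self.mass,
                "mahalanobis_sq": self.mahalanobis_sq,
            },
            indent=2,
        )


@dataclass(frozen=True)
class ChordInterval:
    """Conditional range of the free analyte at a fixed partner value.

    ``interval`` is None when the fixed reading alone falls outside the
    joint region's projection — the partner value by itself is abnormal.
    """

    fixed_index: int
    fixed_value: float
    interval: tuple[float, float] | None

    @property
    def empty(self) -> bool:
        return self.interval is None

    def to_json(self) -> str:
        return json.dumps(
            {
                "fixed_index": self.fixed_index,
                "fixed_value": self.fixed_value,
                "interval": None if self.empty else list(self.interval),
            },
            indent=2,
        )


def _check_cov2(cov: np.ndarray) -> None:
    if cov.shape != (2, 2):
        raise ValueError("hdr_ellipse requires a 2D component")
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() <= 0:
        raise ValueError("covariance must be symmetric positive-definite")
    rho = cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1])
    if abs(rho) > MAX_ABS_CORRELATION:
        raise ValueError(f"near-singular covariance (|rho| = {abs(rho):.4f} > {MAX_ABS_CORRELATION})")


def hdr_ellipse(comp: GaussianComponent, mass: float = 0.95) -> DensityEllipse:
    """Density contour of a bivariate Gaussian enclosing ``mass`` probability.

    The boundary is the set of points at squared Mahalanobis distance
    ``chi2_2.ppf(mass) = -2 ln(1 - mass)`` from the mean (5.99146 at 95%).
    """
    if comp.dim != 2:
        raise ValueError("hdr_ellipse requires a 2D component")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    _check_cov2(comp.covariance)
    r_sq = float(chi2.ppf(mass, df=2))  # == -2 ln(1 - mass)
    return DensityEllipse(
        mean=comp.mean.copy(), covariance=comp.covariance.copy(), mass=mass, mahalanobis_sq=r_sq
    )


def chord_interval(ellipse: DensityEllipse, fixed_index: int, fixed_value: float) -> ChordInterval:
    """Slice the ellipse at a fixed coordinate; the chord is the conditional RI.

    Solves the quadratic in the free coordinate from
    ``(x - mu)^T Sigma^{-1} (x - mu) = r^2``.  Two real roots give the
    interval; no real roots mean the fixed reading lies outside the joint
    region's projection and the interval does not exist.
    """
    if fixed_index not in (0, 1):
        raise ValueError("fixed_index must be 0 or 1")
    free = 1 - fixed_index
    prec = np.linalg.inv(ellipse.covariance)
    s = float(fixed_value) - float(ellipse.mean[fixed_index])
    # prec[free,free]*t^2 + 2*prec[free,fixed]*s*t + prec[fixed,fixed]*s^2 = r^2
    a = prec[free, free]
    b = 2.0 * prec[free, fixed_index] * s
    c = prec[fixed_index, fixed_index] * s * s - ellipse.mahalanobis_sq
    disc = b * b - 4.0 * a * c
    if disc < 0:
        return ChordInterval(fixed_index=fixed_index, fixed_value=float(fixed_value), interval=None)
    root = np.sqrt(disc)
    mu_free = float(ellipse.mean[free])
    lo = mu_free + (-b - root) / (2.0 * a)
    hi = mu_free + (-b + root) / (2.0 * a)
    return ChordInterval(
        fixed_index=fixed_index, fixed_value=float(fixed_value), interval=(float(lo), float(hi))
    )


def conditional_interval(
    comp: GaussianComponent, fixed_index: int, fixed_value: float, coverage: float = 0.95
) -> tuple[float, float]:
    """Central ``coverage`` interval of the conditional Gaussian given the
    partner reading.

    This is the alternative conditional-RI semantic: the distribution of the
    free analyte conditional on the fixed one is itself Gaussian, so its
    central interval always exists — unlike the chord of the joint region,
    it never vanishes however extreme the partner reading.
    """
    if comp.dim != 2:
        raise ValueError("conditional_interval requires a 2D component")
    if fixed_index not in (0, 1):
        raise ValueError("fixed_index must be 0 or 1")
    free = 1 - fixed_index
    cov = comp.covariance
    mu_c = comp.mean[free] + cov[free, fixed_index] / cov[fixed_index, fixed_index] * (
        fixed_value - comp.mean[fixed_index]
    )
    var_c = cov[free, free] - cov[free, fixed_index] ** 2 / cov[fixed_index, fixed_index]
    z = norm.ppf(0.5 * (1.0 + coverage))
    sd = np.sqrt(var_c)
    return float(mu_c - z * sd), float(mu_c + z * sd)


def contour_polyline(ellipse: DensityEllipse, n_points: int = 360) -> np.ndarray:
    """Closed boundary polyline of the ellipse (for plotting / CSV export).

    Points are parameterized by angle through the covariance's spectral
    decomposition; the first and last point coincide, closing the loop.
    """
    if n_points < 8:
        raise ValueError("n_points must be >= 8")
    eigvals, eigvecs = np.linalg.eigh(ellipse.covariance)
    r = np.sqrt(ellipse.mahalanobis_sq)
    theta = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    circle = np.stack([np.cos(theta), np.sin(theta)])
    pts = (eigvecs @ (np.sqrt(eigvals)[:, None] * circle)) * r
    pts = ellipse.mean[:, None] + pts
    closed = np.concatenate([pts.T, pts.T[:1]], axis=0)
    return closed
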