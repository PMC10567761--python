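"""Reference intervals from principal Gaussians, bootstrap errors, age trends.

A reference interval (RI) is the central ``coverage`` (default 95%) range of
the healthy distribution of an analyte.  Here the healthy distribution is the
principal component of a per-segment Gaussian mixture, so the limits are the
analytic quantiles mu +/- z*sigma of that component rather than empirical
percentiles of assigned points.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .cohort_io import DEFAULT_MIN_N, split_by_analyte
from .mixture import (
    GaussianComponent,
    MixtureModel,
    fit_mixture,
    healthy_component,
    outlier_fraction,
    select_principal,
)

logger = logging.getLogger(__name__)

#: Default age windows (years) over which the high-limit trend is linear.
DEFAULT_LINEAR_AGE_RANGES: dict[str, tuple[int, int]] = {
    "2160-0": (20, 60),  # creatinine
    "3094-0": (20, 50),  # urea
}


@dataclass
class RIConfig:
    """Knobs of the per-segment estimation pipeline."""

    coverage: float = 0.95
    k: int = 2
    method: str = "em"
    seed: int | None = 0
    min_n: int = DEFAULT_MIN_N
    tol: float = 1e-6
    max_iter: int = 500
    reg: float | None = None
    n_init: int = 5
    principal_rule: str = "largest_weight"
    merge_overlapping: bool = True

    def __post_init__(self):
        if not 0.0 < self.coverage < 1.0:
            raise ValueError("coverage must lie in (0, 1)")


@dataclass
class ReferenceInterval:
    analyte: str | None
    gender: str | None
    age: int | None
    low: float
    high: float
    coverage: float
    n: int
    outlier_fraction: float
    low_se: float | None = None
    high_se: float | None = None
    reliable: bool = True
    model: MixtureModel | None = field(default=None, repr=False)


@dataclass
class BootstrapRI:
    mean_low: float
    mean_high: float
    std_low: float
    std_high: float
    b: int
    n_failed: int


@dataclass
class AgeTrend:
    """Polynomial fit of an RI limit against age.

    ``coefficients`` are in ascending order of the age power (intercept
    first), in mg/dl per year^power.
    """

    degree: int
    coefficients: np.ndarray
    r_squared: float
    p_values: np.ndarray
    age_range: tuple[float, float]
    analyte: str | None = None
    gender: str | None = None
    limit: str | None = None

    @property
    def slope(self) -> float:
        if self.degree != 1:
            raise ValueError("slope is defined for linear trends only")
        return float(self.coefficients[1])

    @property
    def intercept(self) -> float:
        return float(self.coefficients[0])

    def predict(self, age) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(age, float), self.coefficients)

    def to_dict(self) -> dict:
        return {
            "analyte": self.analyte,
            "gender": self.gender,
            "limit": self.limit,
            "degree": self.degree,
            "coefficients": np.asarray(self.coefficients, float).tolist(),
            "r_squared": float(self.r_squared),
            "p_values": np.asarray(self.p_values, float).tolist(),
            "age_range": list(self.age_range),
        }


def ri_from_component(comp: GaussianComponent, coverage: float = 0.95) -> tuple[float, float]:
    """Analytic RI limits of a 1D Gaussian component.

    The low and high limits are the (1-coverage)/2 and (1+coverage)/2
    quantiles of N(mu, sigma^2): mu -/+ z*sigma with z the standard-normal
    quantile (1.95996 at 95% coverage, i.e. the 2.5th/97.5th percentiles).
    """
    if comp.dim != 1:
        raise ValueError("ri_from_component requires a 1D component")
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must lie in (0, 1)")
    z = norm.ppf(0.5 * (1.0 + coverage))
    mu = float(comp.mean[0])
    sigma = comp.sd
    return mu - z * sigma, mu + z * sigma


def estimate_ri_segment(
    values,
    config: RIConfig | None = None,
    analyte: str | None = None,
    gender: str | None = None,
    age: int | None = None,
) -> ReferenceInterval:
    """Mixture-decompose one segment's values and extract the healthy RI.

    Pipeline: fit a K-component mixture, select the principal (healthy)
    component, take its analytic quantile limits.  Segments smaller than
    ``config.min_n`` are flagged unreliable and carry no estimate.
    """
    config = config or RIConfig()
    x = np.asarray(values, float).ravel()
    if x.size < config.min_n:
        return ReferenceInterval(
            analyte=analyte, gender=gender, age=age,
            low=np.nan, high=np.nan, coverage=config.coverage,
            n=int(x.size), outlier_fraction=np.nan, reliable=False,
        )
    model = fit_mixture(
        x, k=config.k, method=config.method, seed=config.seed,
        tol=config.tol, max_iter=config.max_iter, reg=config.reg,
        n_init=config.n_init,
    )
    reference = float(np.median(x)) if config.principal_rule == "nearest_median" else None
    idx = select_principal(model, rule=config.principal_rule, reference=reference)
    comp = healthy_component(model, idx, merge_overlapping=config.merge_overlapping)
    low, high = ri_from_component(comp, config.coverage)
    return ReferenceInterval(
        analyte=analyte, gender=gender, age=age,
        low=low, high=high, coverage=config.coverage,
        n=int(x.size), outlier_fraction=float(1.0 - comp.weight),
        reliable=True, model=model,
    )


def _segment_seed(base: int | None, *labels: int) -> int:
    """Deterministic per-segment child seed, independent of iteration order."""
    entropy = [0 if base is None else int(base), *[int(v) & 0xFFFF for v in labels]]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


def ri_table(
    table: pd.DataFrame,
    config: RIConfig | None = None,
    bin_width: int = 1,
    bootstrap: int = 0,
    bootstrap_frac: float = 0.5,
) -> pd.DataFrame:
    """Estimate RIs for every gender/age segment of every analyte in a table.

    Returns one row per segment with columns ``analyte, gender, age, n, low,
    high, low_se, high_se, outlier_fraction, reliable``.  The per-segment
    mixture seeds are derived deterministically from ``config.seed``, so the
    table is reproducible.  With ``bootstrap > 0`` limit standard errors are
    estimated by :func:`bootstrap_ri`.
    """
    from .cohort_io import segment_by_gender_age  # local to avoid cycle confusion

    config = config or RIConfig()
    rows = []
    for ai, (code, sub) in enumerate(sorted(split_by_analyte(table).items())):
        seg = segment_by_gender_age(sub, bin_width=bin_width, min_n=config.min_n)
        for key, values in sorted(seg.segments.items()):
            gi = 0 if key.gender == "female" else 1
            seg_cfg = replace(config, seed=_segment_seed(config.seed, ai, gi, key.age))
            ri = estimate_ri_segment(values, seg_cfg, analyte=code, gender=key.gender, age=key.age)
            if ri.reliable and bootstrap > 0:
                bs = bootstrap_ri(values, b=bootstrap, frac=bootstrap_frac,
                                  seed=seg_cfg.seed, config=seg_cfg)
                ri.low_se, ri.high_se = bs.std_low, bs.std_high
            rows.append(
                {
                    "analyte": code, "gender": key.gender, "age": key.age,
                    "n": ri.n, "low": ri.low, "high": ri.high,
                    "low_se": ri.low_se, "high_se": ri.high_se,
                    "outlier_fraction": ri.outlier_fraction, "reliable": ri.reliable,
                }
            )
    return pd.DataFrame(rows)


def bootstrap_ri(
    values,
    b: int = 100,
    frac: float = 0.5,
    seed: int | None = 0,
    config: RIConfig | None = None,
) -> BootstrapRI:
    """Bootstrap the RI limits: B resamples of ``floor(frac * n)`` values
    drawn with replacement, a full re-estimate on each, then the per-limit
    mean and standard deviation across replicates (defaults: 100 resamples of
    half the data size).

    Replicates whose fit fails are dropped and counted; more than 20%
    failures raises.
    """
    if b < 2:
        raise ValueError("b must be >= 2")
    if not 0.0 < frac <= 1.0:
        raise ValueError("frac must lie in (0, 1]")
    config = config or RIConfig()
    x = np.asarray(values, float).ravel()
    m = int(np.floor(frac * x.size))
    rng = np.random.default_rng(seed)
    lows, highs = [], []
    failed = 0
    for i in range(b):
        sample = rng.choice(x, size=m, replace=True)
        try:
            rep_cfg = replace(config, seed=int(rng.integers(2**31)), min_n=min(config.min_n, m))
            ri = estimate_ri_segment(sample, rep_cfg)
            if not ri.reliable or not np.isfinite([ri.low, ri.high]).all():
                raise RuntimeError("replicate produced no estimate")
        except Exception:  # noqa: BLE001 — any replicate failure just drops it
            failed += 1
            continue
        lows.append(ri.low)
        highs.append(ri.high)
    if failed > 0.2 * b:
        raise RuntimeError(f"bootstrap failed on {failed}/{b} replicates")
    lows = np.asarray(lows)
    highs = np.asarray(highs)
    return BootstrapRI(
        mean_low=float(lows.mean()), mean_high=float(highs.mean()),
        std_low=float(lows.std(ddof=0)), std_high=float(highs.std(ddof=0)),
        b=b, n_failed=failed,
    )


def _fit_poly_trend(ages, limits, degree, age_range, analyte, gender, limit):
    ages = np.asarray(ages, float).ravel()
    y = np.asarray(limits, float).ravel()
    if ages.size != y.size:
        raise ValueError("ages and limits must have equal length")
    if age_range is not None:
        mask = (ages >= age_range[0]) & (ages <= age_range[1])
        ages, y = ages[mask], y[mask]
    else:
        age_range = (float(ages.min()), float(ages.max())) if ages.size else (np.nan, np.nan)
    if ages.size < degree + 2:
        raise ValueError(
            f"need at least {degree + 2} points within the age range, got {ages.size}"
        )
    X = sm.add_constant(np.vander(ages, degree + 1, increasing=True)[:, 1:], has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-series fits emit rank warnings
        res = sm.OLS(y, X).fit()
        r2 = float(res.rsquared)
        pvalues = np.asarray(res.pvalues, float)
    if not np.isfinite(r2):
        logger.warning("degenerate trend series (zero variance); reporting R^2 = 0")
        r2 = 0.0
    coeffs = np.asarray(res.params, float)
    return AgeTrend(
        degree=degree, coefficients=coeffs, r_squared=r2,
        p_values=pvalues,
        age_range=(float(age_range[0]), float(age_range[1])),
        analyte=analyte, gender=gender, limit=limit,
    )


def fit_linear_trend(
    ages, limits, age_range: tuple[float, float] | None = None,
    analyte: str | None = None, gender: str | None = None, limit: str = "high",
) -> AgeTrend:
    """OLS of an RI limit on age over the linear (adult) regime.

    Over adulthood the high limit widens approximately linearly with age
    (normal wear and tear); the default windows are 20-60 years for
    creatinine and 20-50 for urea (see ``DEFAULT_LINEAR_AGE_RANGES``).
    """
    if age_range is None and analyte in DEFAULT_LINEAR_AGE_RANGES:
        age_range = DEFAULT_LINEAR_AGE_RANGES[analyte]
    return _fit_poly_trend(ages, limits, 1, age_range, analyte, gender, limit)


def fit_cubic_trend(
    ages, limits, age_range: tuple[float, float] | None = None,
    analyte: str | None = None, gender: str | None = None, limit: str = "high",
) -> AgeTrend:
    """Degree-3 OLS of an RI limit on age; captures the accelerating
    deterioration in the elderly (> 60) that a line cannot."""
    return _fit_poly_trend(ages, limits, 3, age_range, analyte, gender, limit)


def annual_deterioration_rate(trend: AgeTrend, ref_age: float = 20.0) -> float:
    """Relative annual change of an RI limit, in percent per year.

    Computed as ``100 * slope / value_at(ref_age)`` — the limit's yearly
    drift expressed relative to its level at the anchor age (default 20,
    the start of adulthood).  A widening high limit reflects loss of renal
    clearance at this rate per year.
    """
    if trend.degree != 1:
        raise ValueError("annual_deterioration_rate requires a linear trend")
    anchor = trend.intercept + ref_age * trend.slope
    if anchor <= 0:
        raise ValueError(f"predicted limit at ref_age={ref_age} is non-positive")
    return 100.0 * trend.slope / anchor
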