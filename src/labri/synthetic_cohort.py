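"""Synthetic lab-result cohorts with the statistical structure of routine data.

The real datasets this machinery targets are licensed clinical archives that
cannot be redistributed, so every estimation stage is exercised against a
generator that encodes the documented structure of such data:

* a healthy (principal) Gaussian per gender/age segment whose mean and width
  widen linearly with age through adulthood and accelerate (cubic term) after
  60, while the low limit stays essentially constant;
* a pathological outlier component — shifted toward higher values and wider —
  whose weight ramps with age (1% at 20 to 11% at 90 for creatinine, to 16%
  for urea);
* positively correlated joint creatinine-urea values within a visit;
* repeat visits per person (median 2, mean 3.2 tests/person);
* occasional implausible entries emulating unit/data-entry errors.

Alongside the long-format result table the generator emits a truth table
(component labels, injection flags) so oracle tests can compare estimates
against the generating parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort_io import DEFAULT_THRESHOLDS, LOINC_CREATININE, LOINC_UREA

__all__ = [
    "AnalyteGenderSpec",
    "CohortSpec",
    "default_spec",
    "generate_cohort",
    "healthy_mean_sd",
    "outlier_weight",
]

_Z95 = float(norm.ppf(0.975))  # 1.95996; converts a 95% half-width to an SD


@dataclass
class AnalyteGenderSpec:
    """Generating parameters for one analyte/gender (all concentrations mg/dl).

    The healthy component is parameterized through its RI limits: the low
    limit is constant with age (waste compounds have no physiological floor
    trend), the high limit follows ``intercept + slope*age`` plus an
    additive cubic term above ``cubic_onset`` capturing accelerated old-age
    deterioration.  Mean and SD follow as the center and (half-width / z)
    of that 95% band.
    """

    low_limit: float
    high_intercept: float
    high_slope: float
    cubic_coeff: float = 0.0
    outlier_weight_young: float = 0.01
    outlier_weight_old: float = 0.11
    outlier_offset_sd: float = 3.0
    outlier_sd_multiplier: float = 2.5


@dataclass
class CohortSpec:
    """Full cohort recipe: analytes x genders, joint structure, bookkeeping."""

    analytes: dict[str, dict[str, AnalyteGenderSpec]]
    correlation: float = 0.5
    ages: tuple[int, ...] = tuple(range(20, 91))
    n_per_segment: int = 10_000
    visit_geometric_p: float = 0.3125  # mean 3.2 visits/person, median 2
    implausible_rate: float = 0.001
    implausible_factor: float = 100.0  # emulates a two-decade unit error
    age_young: int = 20
    age_old: int = 90
    cubic_onset: int = 60
    start_date: str = "2020-01-01"

    def __post_init__(self):
        if not -1.0 < self.correlation < 1.0:
            raise ValueError("|correlation| must be < 1")
        for code, per_gender in self.analytes.items():
            for g, a in per_gender.items():
                if not 0.0 <= a.outlier_weight_young <= 1.0 or not 0.0 <= a.outlier_weight_old <= 1.0:
                    raise ValueError(f"outlier weights for {code}/{g} must lie in [0, 1]")
                if a.low_limit <= 0:
                    raise ValueError(f"low limit for {code}/{g} must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ages"] = list(self.ages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        d["analytes"] = {
            code: {g: AnalyteGenderSpec(**a) for g, a in per_gender.items()}
            for code, per_gender in d["analytes"].items()
        }
        d["ages"] = tuple(d["ages"])
        return cls(**d)


def default_spec(n_per_segment: int = 10_000, ages=None) -> CohortSpec:
    """The default creatinine + urea cohort recipe.

    High-limit trends are seeded from adult-population regression
    coefficients for the two analytes (creatinine male
    ``0.00387*age + 1.108239`` mg/dl, urea male ``0.13385*age + 17.18661``
    mg/dl, analogous female lines); low limits sit inside the stable observed
    bands (creatinine 0.4-0.6, urea 5.0-9.0 mg/dl); outlier weights ramp
    linearly from 1% at age 20 to 11% (creatinine) / 16% (urea) at age 90.
    """
    spec = CohortSpec(
        analytes={
            LOINC_CREATININE: {
                "male": AnalyteGenderSpec(
                    low_limit=0.55, high_intercept=1.108239, high_slope=0.00387,
                    cubic_coeff=1.0e-5, outlier_weight_old=0.11,
                ),
                "female": AnalyteGenderSpec(
                    low_limit=0.45, high_intercept=0.83276, high_slope=0.00298,
                    cubic_coeff=1.0e-5, outlier_weight_old=0.11,
                ),
            },
            LOINC_UREA: {
                "male": AnalyteGenderSpec(
                    low_limit=7.0, high_intercept=17.18661, high_slope=0.13385,
                    cubic_coeff=2.0e-4, outlier_weight_old=0.16,
                ),
                "female": AnalyteGenderSpec(
                    low_limit=6.0, high_intercept=14.8156, high_slope=0.10959,
                    cubic_coeff=2.0e-4, outlier_weight_old=0.16,
                ),
            },
        },
        n_per_segment=n_per_segment,
    )
    if ages is not None:
        spec.ages = tuple(int(a) for a in ages)
    return spec


def healthy_mean_sd(spec: CohortSpec, analyte: str, gender: str, age: int) -> tuple[float, float]:
    """Generating mean and SD of the healthy component for one segment.

    Derived from the segment's 95% band: the constant low limit and the
    age-dependent high limit ``intercept + slope*age + cubic*(age-onset)^3``
    (cubic term active above the onset age only).
    """
    a = spec.analytes[analyte][gender]
    high = a.high_intercept + a.high_slope * age
    if age > spec.cubic_onset:
        high += a.cubic_coeff * (age - spec.cubic_onset) ** 3
    low = a.low_limit
    if high <= low:
        raise ValueError(f"degenerate band for {analyte}/{gender} at age {age}")
    mean = 0.5 * (low + high)
    sd = (high - low) / (2.0 * _Z95)
    return mean, sd


def outlier_weight(spec: CohortSpec, analyte: str, gender: str, age: int) -> float:
    """Age-ramped weight of the pathological component (linear, clamped)."""
    a = spec.analytes[analyte][gender]
    return float(
        np.interp(age, [spec.age_young, spec.age_old], [a.outlier_weight_young, a.outlier_weight_old])
    )


def _visit_sizes(rng: np.random.Generator, p: float, total: int) -> np.ndarray:
    """Geometric visits-per-person sizes trimmed so they sum to ``total``."""
    sizes: list[int] = []
    acc = 0
    while acc < total:
        block = rng.geometric(p, size=max(8, int((total - acc) * p) + 8))
        for s in block:
            take = min(int(s), total - acc)
            sizes.append(take)
            acc += take
            if acc >= total:
                break
    return np.asarray(sizes, dtype=int)


def generate_cohort(spec: CohortSpec, seed: int | None = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort: long-format result table plus aligned truth table.

    Per gender/age segment, persons accrue geometric visit counts until the
    segment holds ``spec.n_per_segment`` visits; each visit draws pathology
    labels hierarchically (a "sick" visit tends to move both analytes) and
    then correlated bivariate values.  Implausible entries are injected per
    result at ``implausible_rate`` by multiplying the value by
    ``implausible_factor``.  Identical seed, identical output.
    """
    rng = np.random.default_rng(seed)
    codes = sorted(spec.analytes)
    if len(codes) != 2:
        raise ValueError("generate_cohort expects exactly two analytes")
    rho = spec.correlation
    chol = np.linalg.cholesky(np.array([[1.0, rho], [rho, 1.0]]))
    start = np.datetime64(spec.start_date)

    frames: list[pd.DataFrame] = []
    truth_frames: list[pd.DataFrame] = []
    person_counter = 0
    for gender in ("female", "male"):
        for age in spec.ages:
            n_v = int(spec.n_per_segment)
            if n_v == 0:
                continue
            sizes = _visit_sizes(rng, spec.visit_geometric_p, n_v)
            ids = np.repeat(
                np.array([f"P{person_counter + i:07d}" for i in range(sizes.size)]),
                sizes,
            )
            person_counter += sizes.size
            visit_idx = np.concatenate([np.arange(s) for s in sizes])
            dates = (start + visit_idx.astype("timedelta64[D]")).astype(str)

            # hierarchical component labels: a visit is "sick" with the larger
            # of the two analyte outlier weights; given a sick visit, each
            # analyte goes to its outlier component with probability w_a/w_max,
            # so every analyte's marginal outlier fraction equals its ramp
            # exactly while abnormality stays correlated across the panel
            w = np.array([outlier_weight(spec, c, gender, age) for c in codes])
            w_max = float(w.max())
            is_sick = rng.random(n_v) < w_max
            is_outlier = np.zeros((n_v, 2), dtype=bool)
            if w_max > 0:
                for j in range(2):
                    is_outlier[:, j] = is_sick & (rng.random(n_v) < w[j] / w_max)
            z = rng.standard_normal((n_v, 2)) @ chol.T

            params = []
            for code in codes:
                mean, sd = healthy_mean_sd(spec, code, gender, age)
                a = spec.analytes[code][gender]
                params.append((mean, sd, mean + a.outlier_offset_sd * sd, sd * a.outlier_sd_multiplier))

            def _values_from(zmat: np.ndarray, outlier_mask: np.ndarray) -> np.ndarray:
                out = np.empty_like(zmat)
                for j, (mean, sd, mean_o, sd_o) in enumerate(params):
                    out[:, j] = np.where(
                        outlier_mask[:, j], mean_o + sd_o * zmat[:, j], mean + sd * zmat[:, j]
                    )
                return out

            # raw Gaussian draws; the wide outlier component can rarely dip
            # below zero, and those rows are left in place (the plausibility
            # filter removes them downstream) so that each segment remains an
            # exact two-Gaussian mixture for the recovery oracles
            values = _values_from(z, is_outlier)

            # unit-error injection only where the corrupted value is guaranteed
            # implausible (above the analyte's plausibility threshold)
            injected = np.zeros((n_v, 2), dtype=bool)
            for j, code in enumerate(codes):
                thr = DEFAULT_THRESHOLDS.get(code, np.inf)
                eligible = values[:, j] * spec.implausible_factor > thr
                injected[:, j] = eligible & (rng.random(n_v) < spec.implausible_rate)
            values = np.where(injected, values * spec.implausible_factor, values)

            for j, code in enumerate(codes):
                frames.append(
                    pd.DataFrame(
                        {
                            "person_id": ids,
                            "gender": gender,
                            "age": age,
                            "analyte": code,
                            "value": values[:, j],
                            "unit": "mg/dl",
                            "date": dates,
                        }
                    )
                )
                truth_frames.append(
                    pd.DataFrame(
                        {
                            "person_id": ids,
                            "gender": gender,
                            "age": age,
                            "analyte": code,
                            "value": values[:, j],
                            "date": dates,
                            "component": np.where(is_outlier[:, j], "outlier", "healthy"),
                            "injected": injected[:, j],
                        }
                    )
                )
    if not frames:
        cols = ["person_id", "gender", "age", "analyte", "value", "unit", "date"]
        tcols = ["person_id", "gender", "age", "analyte", "value", "date", "component", "injected"]
        return pd.DataFrame(columns=cols), pd.DataFrame(columns=tcols)
    table = pd.concat(frames, ignore_index=True)
    truth = pd.concat(truth_frames, ignore_index=True)
    return table, truth
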