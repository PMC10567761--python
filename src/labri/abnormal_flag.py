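"""Continuous abnormal flags from a persisted population model.

The classical abnormal flag is binary: inside or outside the reference
interval.  Because the estimation pipeline yields a full distribution per
gender/age segment, the flag can instead be the *highest-density-region
percentile* of a reading: the probability mass of the region of points at
least as dense as the reading.  It is 0 at the population center, grows with
distance from it, and crosses the flag threshold (default 0.95) exactly at
the RI limit (1D) or the 95% ellipse (2D) — a reading's percentile is a
graded risk measure, not merely a flag.

The :class:`PopulationModel` is the persisted store of principal Gaussians
and outlier fractions keyed by (analyte panel, gender, age); its
:func:`predict` front end flags single readings and panels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .cohort_io import segment_by_gender_age, split_by_analyte, join_analytes
from .mixture import GaussianComponent
from .reference_intervals import RIConfig, _segment_seed
from . import mixture as _mx

__all__ = [
    "PopulationModel",
    "ModelEntry",
    "FlagResult",
    "AnalyteFlag",
    "hdr_percentile",
    "build_population_model",
    "predict",
]

SCHEMA_VERSION = 1

ModelKey = tuple[tuple[str, ...], str, int]  # (analyte panel, gender, age)


def hdr_percentile(comp: GaussianComponent, x) -> float:
    """Highest-density-region mass at a reading: P(f(X) >= f(x)), X ~ N(mu, Sigma).

    Equivalently the chi-square(d) CDF of the squared Mahalanobis distance of
    ``x``; in 1D this reduces to ``2*Phi(|x - mu| / sigma) - 1``.  Returns 0
    exactly at the mean (the densest point) and approaches 1 far out.
    """
    xv = np.atleast_1d(np.asarray(x, float))
    if xv.size != comp.dim:
        raise ValueError(f"reading has dim {xv.size}, component has dim {comp.dim}")
    dev = xv - comp.mean
    maha_sq = float(dev @ np.linalg.solve(comp.covariance, dev))
    return float(chi2.cdf(maha_sq, df=comp.dim))


@dataclass
class ModelEntry:
    component: GaussianComponent
    outlier_fraction: float
    n: int


@dataclass
class AnalyteFlag:
    value: float
    percentile: float
    flag: bool


@dataclass
class FlagResult:
    """Per-analyte and joint percentile flags for one set of readings."""

    analytes: dict[str, AnalyteFlag]
    joint_percentile: float | None
    joint_flag: bool | None
    threshold: float

    def to_dict(self) -> dict:
        out = {
            code: {"value": f.value, "percentile": f.percentile, "flag": f.flag}
            for code, f in self.analytes.items()
        }
        if self.joint_percentile is not None:
            out["joint"] = {"percentile": self.joint_percentile, "flag": self.joint_flag}
        out["threshold"] = self.threshold
        return out


@dataclass
class PopulationModel:
    """Store of principal Gaussians keyed by (analyte panel, gender, age).

    A missing key raises — the model never silently substitutes a default
    segment or extrapolates across ages.
    """

    entries: dict[ModelKey, ModelEntry] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def get(self, analytes, gender: str, age: int) -> ModelEntry:
        key = (tuple(analytes), str(gender), int(age))
        if key not in self.entries:
            raise KeyError(
                f"no model for segment (analytes={key[0]}, gender={gender}, age={age})"
            )
        return self.entries[key]

    def has(self, analytes, gender: str, age: int) -> bool:
        return (tuple(analytes), str(gender), int(age)) in self.entries

    # --- persistence -----------------------------------------------------
    def to_json(self) -> str:
        entries = [
            {
                "analytes": list(key[0]),
                "gender": key[1],
                "age": key[2],
                "component": e.component.to_dict(),
                "outlier_fraction": e.outlier_fraction,
                "n": e.n,
            }
            for key, e in sorted(self.entries.items())
        ]
        return json.dumps(
            {"schema_version": SCHEMA_VERSION, "metadata": self.metadata, "entries": entries},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PopulationModel":
        d = json.loads(text)
        if d.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema version {d.get('schema_version')}")
        model = cls(metadata=d.get("metadata", {}))
        for e in d["entries"]:
            key = (tuple(e["analytes"]), str(e["gender"]), int(e["age"]))
            model.entries[key] = ModelEntry(
                component=GaussianComponent.from_dict(e["component"]),
                outlier_fraction=float(e["outlier_fraction"]),
                n=int(e["n"]),
            )
        return model

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "PopulationModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json(fh.read())


def _fit_entry(values: np.ndarray, config: RIConfig, seed: int) -> ModelEntry:
    model = _mx.fit_mixture(
        values, k=config.k, method=config.method, seed=seed,
        tol=config.tol, max_iter=config.max_iter, reg=config.reg, n_init=config.n_init,
    )
    reference = None
    if config.principal_rule == "nearest_median":
        reference = np.median(values, axis=0) if values.ndim > 1 else float(np.median(values))
    idx = _mx.select_principal(model, rule=config.principal_rule, reference=reference)
    comp = _mx.healthy_component(model, idx, merge_overlapping=config.merge_overlapping)
    return ModelEntry(
        component=comp,
        outlier_fraction=float(1.0 - comp.weight),
        n=int(values.shape[0]),
    )


def build_population_model(
    table: pd.DataFrame,
    config: RIConfig | None = None,
    bin_width: int = 1,
) -> PopulationModel:
    """Fit the full augmented model from a filtered long-format result table.

    For every gender/age segment: a 1D principal Gaussian per analyte, and —
    when the table carries exactly two analytes — the joint 2D principal
    binormal from the records matched on (person, date).  Segments below
    ``config.min_n`` become explicit gaps (recorded in the metadata), never
    silent defaults.  Deterministic for a given ``config.seed``.
    """
    config = config or RIConfig()
    model = PopulationModel(
        metadata={
            "coverage": config.coverage,
            "seed": config.seed,
            "method": config.method,
            "k": config.k,
            "min_n": config.min_n,
            "gaps": [],
        }
    )
    per_analyte = dict(sorted(split_by_analyte(table).items()))
    codes = list(per_analyte)

    for ai, (code, sub) in enumerate(per_analyte.items()):
        seg = segment_by_gender_age(sub, bin_width=bin_width, min_n=config.min_n)
        for key, values in sorted(seg.segments.items()):
            gi = 0 if key.gender == "female" else 1
            if values.size < config.min_n:
                model.metadata["gaps"].append([code, key.gender, key.age, int(values.size)])
                continue
            seed = _segment_seed(config.seed, ai, gi, key.age)
            model.entries[((code,), key.gender, key.age)] = _fit_entry(values, config, seed)

    if len(codes) == 2:
        joint, _report = join_analytes(per_analyte[codes[0]], per_analyte[codes[1]])
        panel = tuple(codes)
        for (gender, age), grp in joint.groupby(["gender", "age"], sort=True):
            values = grp[list(codes)].to_numpy(float)
            gi = 0 if gender == "female" else 1
            if values.shape[0] < config.min_n:
                model.metadata["gaps"].append(["+".join(codes), gender, int(age), int(values.shape[0])])
                continue
            seed = _segment_seed(config.seed, len(codes), gi, int(age))
            entry = _fit_entry(values, config, seed)
            entry.n = int(values.shape[0])
            model.entries[(panel, str(gender), int(age))] = entry
    return model


def predict(
    model: PopulationModel,
    gender: str,
    age: int,
    readings: dict[str, float],
    threshold: float = 0.95,
) -> FlagResult:
    """Flag a reading or panel of readings against the population model.

    Each analyte gets its HDR percentile from the segment's 1D entry; when
    all readings form a stored panel, the joint percentile comes from the
    matching multivariate entry.  A reading can be abnormal alone yet normal
    jointly (or vice versa) — correlation between analytes makes the joint
    percentile more informative than the marginals.
    """
    if not readings:
        raise ValueError("readings must not be empty")
    flags: dict[str, AnalyteFlag] = {}
    for code, value in readings.items():
        entry = model.get((code,), gender, age)
        p = hdr_percentile(entry.component, [value])
        flags[code] = AnalyteFlag(value=float(value), percentile=p, flag=p > threshold)

    joint_p: float | None = None
    joint_f: bool | None = None
    if len(readings) >= 2:
        panel = tuple(sorted(readings))
        entry = model.get(panel, gender, age)
        x = np.array([readings[c] for c in panel], float)
        joint_p = hdr_percentile(entry.component, x)
        joint_f = joint_p > threshold
    return FlagResult(analytes=flags, joint_percentile=joint_p, joint_flag=joint_f, threshold=threshold)
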