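"""Whole-tumor 3-D ROI extraction, first-order histogram features, ICC.

Feature conventions
-------------------
* percentiles: linear interpolation between order statistics with plotting
  position h = (n-1)q + 1 (numpy's default "linear" method);
* sd: sample standard deviation (n-1 denominator);
* rms: sqrt(mean(x^2)) — the "root-mean-square deviation" of first-order
  radiomics.  The alternative reading (rms == sd) is available through the
  separate ``sd`` field, so either can be selected downstream;
* mad: mean absolute deviation about the mean;
* skewness / kurtosis: standardized 3rd/4th sample moments without bias
  correction; kurtosis is excess (normal -> 0).

Moments below their minimum sample size (sd: n>=2, skewness: n>=3,
kurtosis: n>=4) and on zero-variance samples are NaN, never fabricated.

Inter-reader agreement uses the two-way random-effects, absolute-agreement,
single-measure intraclass correlation ICC(2,1) from the subject x reader
ANOVA mean squares.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .cest import ParametricMap

__all__ = [
    "PERCENTILE_LEVELS",
    "HistogramFeatures",
    "ROISample",
    "extract_roi",
    "compute_features",
    "average_readers",
    "icc_two_way",
]

#: Reported percentile levels (%).
PERCENTILE_LEVELS = (1, 5, 10, 15, 25, 50, 75, 85, 90, 95, 99)


@dataclass(frozen=True)
class ROISample:
    """Finite voxel values pooled from one reader's 3-D ROI on one map."""

    values: np.ndarray
    source_kind: str = "mtrasym_pct"
    patient_id: str = ""
    reader_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size == 0:
            raise ValueError("ROI sample is empty")
        if not np.all(np.isfinite(v)):
            raise ValueError("ROI sample contains non-finite values")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class HistogramFeatures:
    """First-order feature vector of one ROI sample."""

    mean: float
    sd: float
    rms: float
    mad: float
    p1: float
    p5: float
    p10: float
    p15: float
    p25: float
    p50: float
    p75: float
    p85: float
    p90: float
    p95: float
    p99: float
    iqr: float
    skewness: float
    kurtosis: float
    n_voxels: int

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}

    @property
    def percentiles(self) -> np.ndarray:
        return np.array([getattr(self, f"p{q}") for q in PERCENTILE_LEVELS])


def extract_roi(
    pmap: ParametricMap,
    mask: np.ndarray,
    exclusion_mask: np.ndarray | None = None,
    patient_id: str = "",
    reader_id: str = "",
) -> ROISample:
    """Pool map voxels where mask=1, exclusion=0 and the value is finite.

    The exclusion mask removes cystic/necrotic/hemorrhagic areas so only the
    solid tumor enters the histogram.  An empty result (tumor below one
    voxel) is an error.
    """
    m = np.asarray(mask).astype(bool)
    if m.shape != pmap.values.shape:
        raise ValueError("mask grid must match map grid")
    if exclusion_mask is not None:
        ex = np.asarray(exclusion_mask).astype(bool)
        if ex.shape != m.shape:
            raise ValueError("exclusion mask grid must match map grid")
        m = m & ~ex
    vals = pmap.values[m]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("ROI contains no valid voxels")
    return ROISample(vals, source_kind=pmap.kind,
                     patient_id=patient_id, reader_id=reader_id)


def compute_features(sample: ROISample | Sequence[float]) -> HistogramFeatures:
    """First-order histogram features of an ROI sample."""
    if not isinstance(sample, ROISample):
        sample = ROISample(np.asarray(sample, dtype=float))
    x = sample.values
    n = x.size
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if n >= 2 else float("nan")
    rms = float(np.sqrt(np.mean(x * x)))
    mad = float(np.mean(np.abs(x - mean)))
    pcts = np.percentile(x, PERCENTILE_LEVELS, method="linear")
    zero_var = n >= 2 and np.ptp(x) == 0.0
    if n >= 3 and not zero_var:
        skew = float(sps.skew(x, bias=True))
    else:
        skew = float("nan")
    if n >= 4 and not zero_var:
        kurt = float(sps.kurtosis(x, fisher=True, bias=True))
    else:
        kurt = float("nan")
    p = dict(zip([f"p{q}" for q in PERCENTILE_LEVELS], map(float, pcts)))
    return HistogramFeatures(
        mean=mean, sd=sd, rms=rms, mad=mad, **p,
        iqr=p["p75"] - p["p25"], skewness=skew, kurtosis=kurt, n_voxels=n,
    )


def average_readers(a: HistogramFeatures, b: HistogramFeatures) -> HistogramFeatures:
    """Element-wise mean of two readers' feature vectors.

    This is the reduction applied before any statistics: each patient's
    feature is the average of the two observers' measurements.  n_voxels is
    the floored mean.
    """
    out = {}
    for f in dc_fields(HistogramFeatures):
        va, vb = getattr(a, f.name), getattr(b, f.name)
        out[f.name] = (va + vb) / 2.0
    out["n_voxels"] = int((a.n_voxels + b.n_voxels) // 2)
    return HistogramFeatures(**out)


def icc_two_way(measurements: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Parameters
    ----------
    measurements : array, shape (n_subjects, n_raters)
        One measurement per subject per rater, no missing cells.

    Notes
    -----
    With MSR/MSC/MSE the subject, rater and residual mean squares of the
    two-way ANOVA and k raters over n subjects,

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n).
    """
    y = np.asarray(measurements, dtype=float)
    if y.ndim != 2 or y.shape[0] < 3 or y.shape[1] < 2:
        raise ValueError("need >=3 subjects and >=2 raters")
    if not np.all(np.isfinite(y)):
        raise ValueError("missing cells are not supported")
    if np.ptp(y) == 0.0:
        raise ValueError("zero total variance: ICC undefined")
    n, k = y.shape
    grand = y.mean()
    row_m = y.mean(axis=1)
    col_m = y.mean(axis=0)
    ss_rows = k * np.sum((row_m - grand) ** 2)
    ss_cols = n * np.sum((col_m - grand) ** 2)
    ss_tot = np.sum((y - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))
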