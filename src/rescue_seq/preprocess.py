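"""Expression preprocessing: pedestal-log transform, detection filtering,
quantile normalization and CV-vs-mean noise flooring.

The procedure mirrors a bulk RNA-seq preprocessing chain in which raw
abundances are pedestalled (a constant added to stabilize the log at zero),
log2-transformed, filtered for detection, quantile-normalized across samples,
and finally floored at a data-derived "noise floor": the expression level
below which the coefficient of variation (CV = SD/mean per gene per class)
departs from its linear trend against mean expression, indicating
noise-dominated measurements.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import interp1d
from statsmodels.nonparametric.smoothers_lowess import lowess

from .matrix import LOG2, ExpressionMatrix, StateError

GRID_POINTS = 200
DEFAULT_DELTA = 0.5  # gross CV excess over the linear trend, absolute units


def pedestal_log_transform(m: ExpressionMatrix, pedestal: float = 2.0) -> ExpressionMatrix:
    """Replace every value v by log2(v + pedestal).

    The pedestal (default 2) keeps zero counts finite — log2(0 + 2) = 1 — and
    compresses low-end variance. Strictly monotone, so ranks are preserved.
    """
    if m.space == LOG2:
        raise StateError("matrix is already log2-transformed")
    if pedestal <= 0:
        raise ValueError("pedestal must be positive")
    arr = m.values.to_numpy(dtype=float)
    if arr.size and arr.min() < 0:
        raise ValueError("negative expression value in linear input")
    out = pd.DataFrame(np.log2(arr + pedestal), index=m.values.index, columns=m.values.columns)
    return m.with_values(out, LOG2)


def detection_filter(m: ExpressionMatrix, threshold: float = 1.0) -> ExpressionMatrix:
    """Keep only genes with at least one sample value strictly above *threshold*.

    With pedestal 2, a post-transform value of 1 corresponds to zero raw
    abundance, so the default drops genes never observed above zero.
    """
    if m.space != LOG2:
        raise StateError("detection filter expects log2-space values")
    keep = (m.values > threshold).any(axis=1)
    if m.values.shape[0] and not keep.any():
        warnings.warn("no gene passed the detection filter; returning an empty matrix")
    return m.with_values(m.values.loc[keep])


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample to the identical value distribution.

    The target distribution is the rank-wise mean of the column-sorted values.
    Ties within a column receive the average of the rank-wise means over the
    tied ranks, so tied input values stay tied on output.
    """
    if m.values.shape[1] == 0:
        raise ValueError("quantile normalization needs at least one sample")
    arr = m.values.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("missing values are not allowed")
    n_genes, n_samples = arr.shape
    if n_genes == 0:
        return m.with_values(m.values.copy())
    sorted_means = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(n_samples):
        order = np.argsort(arr[:, j], kind="stable")
        mapped = np.empty(n_genes)
        mapped[order] = sorted_means
        # average mapped values over tied input values
        col = pd.Series(mapped)
        out[:, j] = col.groupby(arr[:, j]).transform("mean").to_numpy()
    return m.with_values(pd.DataFrame(out, index=m.values.index, columns=m.values.columns))


@dataclass
class NoiseModel:
    """Per-class smoothed CV-vs-mean curves and the derived expression floor.

    ``floor_value`` is the log2 expression below which measurements are
    considered noise-biased: the largest mean expression at which any class's
    LOWESS-smoothed CV exceeds a straight line fitted to the smooth over the
    upper half of the mean range by more than ``deviation_tolerance``.
    """

    per_class_fit: dict[str, tuple[np.ndarray, np.ndarray]]
    floor_value: float
    smoother_span: float
    deviation_tolerance: dict[str, float]

    def to_json(self, path=None) -> str:
        payload = {
            "floor_value": self.floor_value,
            "smoother_span": self.smoother_span,
            "deviation_tolerance": self.deviation_tolerance,
            "per_class_fit": {
                cls: {"mean_grid": list(map(float, g)), "smoothed_cv": list(map(float, c))}
                for cls, (g, c) in self.per_class_fit.items()
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @staticmethod
    def from_json(path) -> "NoiseModel":
        with open(path) as fh:
            payload = json.load(fh)
        fits = {
            cls: (np.asarray(d["mean_grid"], dtype=float), np.asarray(d["smoothed_cv"], dtype=float))
            for cls, d in payload["per_class_fit"].items()
        }
        return NoiseModel(fits, payload["floor_value"], payload["smoother_span"],
                          payload["deviation_tolerance"])


def fit_noise_model(m: ExpressionMatrix, span: float = 0.3,
                    delta: float | None = None) -> NoiseModel:
    """Fit per-class CV ~ mean LOWESS curves and locate the noise floor.

    Per class, each gene contributes (mean, CV) computed across that class's
    samples on the (normalized, log2) values; genes with mean <= 0 are
    excluded, and constant genes contribute CV = 0. A tricube-weighted local
    linear smoother is fitted without robustness iterations: here the
    high-CV points at low expression are the signal being sought, and robust
    reweighting would suppress exactly that deviation. A straight line is
    then fitted to the smooth over the upper half of the mean range. A class
    deviates grossly when its smooth exceeds the line's extrapolation by more
    than *delta* (default 0.5, absolute CV units) anywhere; the floor is
    located at the half-height of the excess, which under local smoothing of
    a step-like noise onset estimates the underlying boundary. When no class
    deviates, the floor is the minimum observed value and flooring is a
    no-op.
    """
    if m.space != LOG2:
        raise StateError("noise model expects log2-space values")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    fits: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    tolerances: dict[str, float] = {}
    candidates: list[float] = []
    for cls in m.class_names:
        cols = m.samples_of(cls)
        if len(cols) < 3:
            raise ValueError(f"class {cls!r} has fewer than 3 samples")
        sub = m.values[cols].to_numpy(dtype=float)
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        ok = mean > 0
        mean, sd = mean[ok], sd[ok]
        if mean.size < 10:
            raise ValueError(f"class {cls!r} has too few positive-mean genes to fit")
        cv = np.where(sd == 0, 0.0, sd / mean)
        smoothed = lowess(cv, mean, frac=span, it=0, return_sorted=True)
        grid = np.linspace(mean.min(), mean.max(), GRID_POINTS)
        curve = interp1d(smoothed[:, 0], smoothed[:, 1], bounds_error=False,
                         fill_value=(smoothed[0, 1], smoothed[-1, 1]))(grid)
        fits[cls] = (grid, curve)
        # straight line over the upper half of the mean range
        mid = 0.5 * (grid[0] + grid[-1])
        upper = grid >= mid
        coeffs = np.polyfit(grid[upper], curve[upper], 1)
        line = np.polyval(coeffs, grid)
        tol = float(delta) if delta is not None else DEFAULT_DELTA
        tolerances[cls] = tol
        excess = curve - line
        if excess.max(initial=0.0) > tol:
            # the smoother spreads a sharp noise step over its span; the
            # half-height of the excess locates the underlying boundary
            cut = 0.5 * float(excess.max())
            candidates.append(float(grid[np.nonzero(excess > cut)[0].max()]))
    min_observed = float(m.values.to_numpy().min()) if m.values.size else 0.0
    floor = max(candidates) if candidates else min_observed
    floor = max(floor, min_observed)
    return NoiseModel(fits, floor, span, tolerances)


def apply_floor(m: ExpressionMatrix, nm: NoiseModel) -> ExpressionMatrix:
    """Floor values below the noise floor and drop genes never above it.

    Idempotent: values are raised to ``floor_value`` if lower, then genes with
    no sample strictly above the floor are removed as noise-biased.
    """
    if m.space != LOG2:
        raise StateError("apply_floor expects log2-space values")
    keep = (m.values > nm.floor_value).any(axis=1)
    floored = m.values.loc[keep].clip(lower=nm.floor_value)
    return m.with_values(floored)


@dataclass
class PreprocessLog:
    """Genes discarded at each preprocessing step."""

    not_detected: list[str] = field(default_factory=list)
    noise_biased: list[str] = field(default_factory=list)


def preprocess_pipeline(m: ExpressionMatrix, pedestal: float = 2.0,
                        detection_threshold: float = 1.0, span: float = 0.3,
                        delta: float | None = None,
                        ) -> tuple[ExpressionMatrix, NoiseModel, PreprocessLog]:
    """Run the full chain: pedestal-log2, detect, quantile-normalize, floor."""
    log = PreprocessLog()
    logged = pedestal_log_transform(m, pedestal)
    detected = detection_filter(logged, detection_threshold)
    log.not_detected = sorted(set(logged.gene_ids) - set(detected.gene_ids))
    normalized = quantile_normalize(detected)
    nm = fit_noise_model(normalized, span=span, delta=delta)
    floored = apply_floor(normalized, nm)
    log.noise_biased = sorted(set(normalized.gene_ids) - set(floored.gene_ids))
    return floored, nm, log
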