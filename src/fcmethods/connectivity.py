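"""Zero-lag and lagged region-pair connectivity from ROI time series.

Zero-lag connectivity is the Pearson correlation between two regions'
BOLD series over the volumes retained by motion censoring.  Lagged
connectivity evaluates the cross-correlation curve at a non-integer
temporal offset (e.g. 6 s regardless of the site's repetition time) by
computing correlations at integer-TR shifts and interpolating the curve
with a cubic spline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .qc import CensorMask


@dataclass
class ConnectivityMatrix:
    """Symmetric region-pair connectivity for one subject."""

    values: np.ndarray
    subject_id: str = ""
    scale: str = "pearson_r"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        finite = np.isfinite(v)
        if not np.allclose(np.where(finite, v, 0.0),
                           np.where(finite.T, v.T, 0.0), atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")

    @property
    def r(self) -> int:
        return self.values.shape[0]


def connectivity_matrix(timeseries: np.ndarray,
                        mask: CensorMask | None = None,
                        subject_id: str = "") -> ConnectivityMatrix:
    """Pearson correlation over kept volumes for every region pair.

    Parameters
    ----------
    timeseries : (T, R) array
        One column per region.
    mask : CensorMask, optional
        Volumes to keep; all volumes if omitted.

    A region whose kept series is constant gets missing (NaN)
    correlations with a warning rather than a silent zero.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("timeseries must be 2-D (T, R)")
    if mask is not None:
        if mask.n_volumes != ts.shape[0]:
            raise ValueError(
                f"mask length {mask.n_volumes} != n_volumes {ts.shape[0]}")
        ts = ts[mask.keep]
    if ts.shape[0] < 3:
        raise ValueError(
            f"need >= 3 kept volumes, got {ts.shape[0]}")
    sd = ts.std(axis=0)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(ts, rowvar=False)
    corr = np.atleast_2d(corr)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} region(s) with constant signal; "
            "their correlations are set to missing", stacklevel=2)
        corr[constant, :] = np.nan
        corr[:, constant] = np.nan
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return ConnectivityMatrix(values=corr, subject_id=subject_id)


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Fisher variance-stabilizing transform arctanh(r)."""
    return np.arctanh(r)


def inverse_fisher_z(z: np.ndarray) -> np.ndarray:
    return np.tanh(z)


@dataclass
class LagCurve:
    """Cross-correlation curve of a region pair over signed lags (s).

    Positive lag means the second series is delayed relative to the
    first: r(tau) = corr(a(t), b(t + tau)).
    """

    lags: np.ndarray
    r_at_lag: np.ndarray
    evaluated_lag: float
    r_pos: float = field(default=np.nan)
    r_neg: float = field(default=np.nan)
    r_zero: float = field(default=np.nan)

    def interpolate(self, tau: float) -> float:
        spline = CubicSpline(self.lags, self.r_at_lag)
        return float(spline(tau))


def _corr_at_shift(a: np.ndarray, b: np.ndarray, k: int) -> float:
    """corr(a(t), b(t+k)) over the overlapping segment, re-standardized."""
    n = a.size
    if k >= 0:
        x, y = a[:n - k] if k else a, b[k:]
    else:
        x, y = a[-k:], b[:n + k]
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x ** 2).sum() * (y ** 2).sum())
    if denom == 0:
        return np.nan
    return float((x * y).sum() / denom)


def required_length(tr_seconds: float, eval_lag_seconds: float,
                    extra_lags: int = 2) -> tuple[int, int]:
    """(max integer lag in samples, minimum contiguous series length)."""
    k_max = int(np.ceil(eval_lag_seconds / tr_seconds)) + extra_lags
    return k_max, 2 * k_max + 3


def lagged_connectivity(series_a: np.ndarray, series_b: np.ndarray,
                        tr_seconds: float, eval_lag_seconds: float,
                        extra_lags: int = 2) -> LagCurve:
    """Cross-correlation curve splined to the exact evaluation lag.

    Correlations are computed at integer-TR shifts out to
    ``ceil(eval_lag/tr) + extra_lags`` samples, each over its
    overlapping segment (re-standardized per lag), then cubic-spline
    interpolated to +/- ``eval_lag_seconds``.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and equally long")
    if eval_lag_seconds < 0:
        raise ValueError("eval_lag_seconds must be non-negative")
    k_max, n_min = required_length(tr_seconds, eval_lag_seconds, extra_lags)
    if a.size < n_min:
        raise ValueError(
            f"series of length {a.size} too short for a +/-"
            f"{eval_lag_seconds} s window at TR={tr_seconds}; "
            f"need at least {n_min} contiguous volumes")
    shifts = np.arange(-k_max, k_max + 1)
    lags = shifts * tr_seconds
    r = np.array([_corr_at_shift(a, b, int(k)) for k in shifts])
    spline = CubicSpline(lags, r)
    return LagCurve(
        lags=lags, r_at_lag=r, evaluated_lag=eval_lag_seconds,
        r_pos=float(spline(eval_lag_seconds)),
        r_neg=float(spline(-eval_lag_seconds)),
        r_zero=float(spline(0.0)),
    )


def longest_uncensored_run(mask: CensorMask) -> slice:
    """Slice of the longest contiguous run of kept volumes.

    Lagged connectivity needs contiguous samples; dropped volumes would
    distort temporal offsets, so the longest clean run is used instead
    of stitching or interpolating.
    """
    keep = mask.keep
    best_start, best_len, start = 0, 0, None
    for i, k in enumerate(keep):
        if k and start is None:
            start = i
        if (not k or i == keep.size - 1) and start is not None:
            end = i + 1 if k else i
            if end - start > best_len:
                best_start, best_len = start, end - start
            start = None
    return slice(best_start, best_start + best_len)


def lag_matrices(timeseries: np.ndarray, tr_seconds: float,
                 eval_lag_seconds: float,
                 mask: CensorMask | None = None,
                 extra_lags: int = 2) -> np.ndarray:
    """All-pairs lagged connectivity, vectorized.

    Returns an (R, R) array C where ``C[i, j]`` is the splined
    cross-correlation r(+eval_lag) of pair (i, j) — i.e. region j
    delayed by eval_lag relative to region i.  By role antisymmetry
    ``C[j, i]`` is the pair's value at -eval_lag.
    """
    ts = np.asarray(timeseries, dtype=float)
    if mask is not None:
        ts = ts[longest_uncensored_run(mask)]
    n, n_reg = ts.shape
    k_max, n_min = required_length(tr_seconds, eval_lag_seconds, extra_lags)
    if n < n_min:
        raise ValueError(
            f"longest contiguous run ({n} volumes) too short for a +/-"
            f"{eval_lag_seconds} s window at TR={tr_seconds}; "
            f"need at least {n_min}")
    shifts = np.arange(-k_max, k_max + 1)
    curves = np.empty((shifts.size, n_reg, n_reg))
    for s_i, k in enumerate(shifts):
        k = int(k)
        x = ts[:n - k] if k > 0 else ts[-k:]
        y = ts[k:] if k > 0 else ts[:n + k] if k < 0 else ts
        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)
        xs = np.sqrt((xc ** 2).sum(axis=0))
        ys = np.sqrt((yc ** 2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            curves[s_i] = (xc.T @ yc) / np.outer(xs, ys)
    spline = CubicSpline(shifts * tr_seconds, curves, axis=0)
    return np.asarray(spline(eval_lag_seconds))
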