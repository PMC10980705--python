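"""ThT aggregation-kinetics processing and structure-kinetics correlation.

Thioflavin T (ThT) fluorescence reports cross-beta fibril mass; a plate
well that aggregates shows a sigmoidal rise whose half-time T_1/2 is the
standard aggregation readout, and 1/T_1/2 the aggregation speed.  Blank
wells (buffer + ThT) are subtracted point-wise before fitting.  The fitted
form is the 4-parameter logistic

    y(t) = baseline + (plateau - baseline) / (1 + exp(-slope * (t - T_half)))

with T_half at the inflection.  Structural metrics are then correlated
with speeds by Spearman rank correlation (or Pearson, optionally on
ranks).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import pearsonr, rankdata, spearmanr

__all__ = [
    "ThTCurve",
    "SigmoidFit",
    "CorrelationResult",
    "blank_subtract",
    "fit_tht_sigmoid",
    "fit_single_well",
    "aggregation_speed",
    "correlate",
    "load_plate",
    "logistic4",
]


@dataclass
class ThTCurve:
    """ThT time series for one sample: replicate wells plus blanks."""

    times: np.ndarray                # hours, strictly increasing
    signal: np.ndarray               # (n_times, n_replicates) a.u.
    blanks: np.ndarray | float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.signal.shape[0] != self.times.size:
            self.signal = self.signal.T
        if self.signal.shape[0] != self.times.size:
            raise ValueError("signal shape does not match times")
        if not np.all(np.isfinite(self.times)):
            raise ValueError("times must be finite")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_replicates(self) -> int:
        return self.signal.shape[1]


@dataclass
class SigmoidFit:
    baseline: float
    plateau: float
    T_half: float
    slope: float
    rss: float
    converged: bool
    t_half_in_range: bool = True


@dataclass
class CorrelationResult:
    method: str
    r: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")
        if self.n < 3:
            raise ValueError("need n >= 3 samples")


def logistic4(t, baseline, plateau, t_half, slope):
    z = np.clip(-slope * (np.asarray(t) - t_half), -700.0, 700.0)
    return baseline + (plateau - baseline) / (1.0 + np.exp(z))


def blank_subtract(curve: ThTCurve) -> ThTCurve:
    """Subtract the per-timepoint mean blank from every replicate."""
    if curve.blanks is None:
        raise ValueError("curve has no blanks")
    if np.isscalar(curve.blanks):
        mean_blank = float(curve.blanks)
    else:
        blanks = np.atleast_2d(np.asarray(curve.blanks, dtype=float))
        if blanks.shape[0] != curve.times.size:
            blanks = blanks.T
        if blanks.shape[0] != curve.times.size:
            raise ValueError("blank shape does not match times")
        mean_blank = blanks.mean(axis=1, keepdims=True)
    return ThTCurve(
        times=curve.times,
        signal=curve.signal - mean_blank,
        blanks=None,
    )


def fit_single_well(
    times: np.ndarray,
    y: np.ndarray,
    min_amplitude_snr: float = 4.0,
) -> SigmoidFit:
    """Least-squares 4PL fit of one blank-subtracted well.

    Multistart over inflection-time and slope guesses.  A well whose fitted
    amplitude does not exceed ``min_amplitude_snr`` times the residual
    noise is a no-aggregation call (``converged=False``).
    """
    times = np.asarray(times, dtype=float)
    y = np.asarray(y, dtype=float)
    if times.size < 8:
        raise ValueError("need at least 8 time points to fit")

    lo, hi = float(y.min()), float(y.max())
    span = times[-1] - times[0]
    best = None
    for frac in (0.25, 0.5, 0.75):
        for slope0 in (0.5, 2.0, 8.0):
            p0 = (lo, hi, times[0] + frac * span, slope0 / max(span, 1e-9) * 10)
            try:
                popt, _ = curve_fit(
                    logistic4, times, y, p0=p0, maxfev=20000
                )
            except RuntimeError:
                continue
            rss = float(((logistic4(times, *popt) - y) ** 2).sum())
            if best is None or rss < best[1]:
                best = (popt, rss)
    if best is None:
        return SigmoidFit(lo, hi, np.nan, np.nan, np.inf, converged=False)

    (baseline, plateau, t_half, slope), rss = best
    res_std = float(np.sqrt(rss / max(times.size - 4, 1)))
    amplitude = plateau - baseline
    converged = (
        amplitude > 0
        and amplitude > min_amplitude_snr * res_std
        and np.isfinite(t_half)
        and t_half > 0
    )
    in_range = bool(times[0] <= t_half <= times[-1])
    return SigmoidFit(
        baseline=float(baseline),
        plateau=float(plateau),
        T_half=float(t_half) if converged else np.nan,
        slope=float(slope),
        rss=rss,
        converged=bool(converged),
        t_half_in_range=in_range,
    )


def fit_tht_sigmoid(
    curve: ThTCurve,
    mean_curve: bool = False,
    min_amplitude_snr: float = 4.0,
) -> SigmoidFit:
    """Fit a (blank-subtracted) ThT curve.

    By default each replicate well is fitted separately and the fit whose
    T_half is the median across converged wells is returned; with
    ``mean_curve=True`` the replicate-mean trace is fitted instead.  If no
    well converges the sample is a no-aggregation call.
    """
    if curve.blanks is not None:
        curve = blank_subtract(curve)
    if mean_curve:
        return fit_single_well(
            curve.times, curve.signal.mean(axis=1), min_amplitude_snr
        )
    fits = [
        fit_single_well(curve.times, curve.signal[:, k], min_amplitude_snr)
        for k in range(curve.n_replicates)
    ]
    good = [f for f in fits if f.converged]
    if not good:
        return fits[0]
    good.sort(key=lambda f: f.T_half)
    return good[(len(good) - 1) // 2]


def aggregation_speed(fit: SigmoidFit) -> float:
    """1/T_half (1/h); non-aggregators get speed 0."""
    if not fit.converged or not np.isfinite(fit.T_half) or fit.T_half <= 0:
        return 0.0
    return 1.0 / fit.T_half


def correlate(
    metric: np.ndarray,
    kinetics: np.ndarray,
    method: str = "spearman",
    use_ranks: bool = False,
) -> CorrelationResult:
    """Correlate a structural metric with aggregation kinetics.

    ``method="spearman"`` is the default headline statistic (the published
    comparison ranks both quantities); ``method="pearson"`` optionally on
    ranks (``use_ranks=True``) is also available.  Ties receive average
    ranks.
    """
    x = np.asarray(metric, dtype=float)
    y = np.asarray(kinetics, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("metric and kinetics must be aligned 1-D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 mutants")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input")
    if method == "spearman":
        r = float(spearmanr(x, y).statistic)
        label = "spearman"
    elif method == "pearson":
        if use_ranks:
            x = rankdata(x)
            y = rankdata(y)
            label = "pearson_on_ranks"
        else:
            label = "pearson"
        r = float(pearsonr(x, y).statistic)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(method=label, r=r, n=int(x.size))


def load_plate(path: str | Path) -> dict[str, ThTCurve]:
    """Read a plate CSV (columns: time_h, <mutant>_r<k> wells, blank_<k>).

    Returns one ThTCurve per mutant, each carrying the plate's blank wells.
    """
    df = pd.read_csv(path)
    if "time_h" not in df.columns:
        raise ValueError("plate CSV must contain a time_h column")
    times = df["time_h"].to_numpy()
    blank_cols = [c for c in df.columns if c.startswith("blank")]
    blanks = df[blank_cols].to_numpy() if blank_cols else None
    groups: dict[str, list[str]] = {}
    for col in df.columns:
        if col == "time_h" or col in blank_cols:
            continue
        name = col.rsplit("_r", 1)[0]
        groups.setdefault(name, []).append(col)
    return {
        name: ThTCurve(times=times, signal=df[cols].to_numpy(), blanks=blanks)
        for name, cols in groups.items()
    }
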