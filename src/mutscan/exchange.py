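"""Single-exponential decay fits for exchange kinetics.

Covers per-residue hydrogen-deuterium exchange (HDX) peak-volume decays
(times in hours) and mant-GDP nucleotide-release fluorescence (times in
seconds). Each series is fit to A*exp(-k*t); the fit is kept for
analysis only when R^2 > 0.7 against the mean-only model, a conservative
filter for peaks that do not decay single-exponentially. Mutant-vs-wild-
type comparisons use the rate ratio k_obs,mut / k_obs,WT, discretized
into five bins (boundaries at 1/3, 1/2, 2 and 3; the 2x and 3x edges
belong to the inner bin).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

R2_KEEP_THRESHOLD = 0.7

FOLD_CHANGE_BINS = ("much_slower", "slower", "similar", "faster", "much_faster")


class FoldChangeUndefinedError(ValueError):
    """Fold change requested for a fit that did not pass the R^2 filter."""


@dataclass
class DecaySeries:
    """One decay time series for a residue or fluorescence probe."""

    residue_or_probe: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.size < 4:
            raise ValueError("need >=4 equal-length time points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class ExchangeFit:
    """Results of a single-exponential fit (A*exp(-k*t) [+ offset])."""

    amplitude: float
    rate_k_obs: float
    r_squared: float
    kept: bool
    residue_or_probe: str = ""
    offset: float = 0.0
    message: str = ""

    @property
    def tau(self) -> float:
        """Time constant 1/k_obs, in the input time unit."""
        return 1.0 / self.rate_k_obs


class ExponentialDecayModel:
    """Least-squares single-exponential decay model for one series.

    Initialization is log-linear (regressing log values on time), then
    refined by nonlinear least squares — robust for sparse ~12-point HDX
    series. An additive offset term is optional (off by default: a plain
    single exponential).
    """

    def __init__(self, series: DecaySeries, offset: bool = False) -> None:
        self.series = series
        self.offset = offset

    def _initial(self) -> tuple[float, float]:
        t, y = self.series.times, self.series.values
        pos = y > 0
        if pos.sum() >= 2:
            slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
            return float(np.exp(intercept)), float(max(-slope, 1e-9))
        return float(abs(y[0]) + 1e-12), 1.0 / float(t[-1] - t[0])

    def fit(self) -> ExchangeFit:
        t, y = self.series.times, self.series.values
        name = self.series.residue_or_probe
        if np.ptp(y) == 0:
            return ExchangeFit(
                amplitude=float(y[0]), rate_k_obs=np.nan, r_squared=0.0,
                kept=False, residue_or_probe=name, message="constant series",
            )
        A0, k0 = self._initial()
        try:
            if self.offset:
                popt, _ = curve_fit(
                    lambda tt, A, k, c: A * np.exp(-k * tt) + c,
                    t, y, p0=[A0, k0, float(y.min())], maxfev=20000,
                )
                A, k, c = (float(v) for v in popt)
            else:
                popt, _ = curve_fit(
                    lambda tt, A, k: A * np.exp(-k * tt), t, y,
                    p0=[A0, k0], maxfev=20000,
                )
                A, k = (float(v) for v in popt)
                c = 0.0
        except RuntimeError as exc:
            return ExchangeFit(
                amplitude=np.nan, rate_k_obs=np.nan, r_squared=-np.inf,
                kept=False, residue_or_probe=name, message=str(exc),
            )
        pred = A * np.exp(-k * t) + c
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot
        kept = bool(r2 > R2_KEEP_THRESHOLD and k > 0)
        msg = "" if kept else ("non-positive rate" if k <= 0 else "poor fit")
        return ExchangeFit(
            amplitude=A, rate_k_obs=k, r_squared=r2, kept=kept,
            residue_or_probe=name, offset=c, message=msg,
        )


def fit_exponential(series: DecaySeries, offset: bool = False) -> ExchangeFit:
    """Fit A*exp(-k*t) to a decay series; flag kept iff R^2 > 0.7."""
    return ExponentialDecayModel(series, offset=offset).fit()


def filter_fits(
    fits: Sequence[ExchangeFit], r2_min: float = R2_KEEP_THRESHOLD
) -> list[ExchangeFit]:
    """Fits passing the strict R^2 > r2_min filter (R^2 exactly at the
    threshold is excluded)."""
    return [f for f in fits if f.r_squared > r2_min and f.rate_k_obs > 0]


def fold_change(mutant: ExchangeFit, wildtype: ExchangeFit) -> float:
    """Rate ratio k_obs,mutant / k_obs,WT; both fits must be kept."""
    if not (mutant.kept and wildtype.kept):
        raise FoldChangeUndefinedError(
            "fold change undefined: one of the fits failed the R^2 filter"
        )
    return mutant.rate_k_obs / wildtype.rate_k_obs


def bin_fold_change(ratio: float) -> str:
    """Five-way categorization of a rate ratio.

    <1/3 much_slower; [1/3,1/2) slower; [1/2,2] similar; (2,3] faster;
    >3 much_faster. The exact 2x and 3x boundaries go to the inner bin.
    """
    if not ratio > 0:
        raise ValueError("fold change must be positive")
    if ratio < 1 / 3:
        return "much_slower"
    if ratio < 1 / 2:
        return "slower"
    if ratio <= 2:
        return "similar"
    if ratio <= 3:
        return "faster"
    return "much_faster"
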