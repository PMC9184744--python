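"""Periodicity statistics for 1D-projected localization data.

The membrane-associated periodic skeleton (MPS) appears in super-resolution
images of axons as rings spaced ~190 nm apart. Its standard quantification:
project localizations onto the segment's longitudinal axis, bin them into a 1D
profile, compute the normalized autocorrelation, and average curves over many
segments. The *amplitude* of the averaged curve — the value at the first peak
(~190 nm) minus the mean of the first two valleys (~95 and ~285 nm) — measures
the degree of periodicity; the first-peak lag is the period estimate. Two-color
data are compared through the cross-correlation of the two channel profiles,
whose first extremum lag expresses the inter-channel phase shift; phase-aligned
averaging of per-segment profiles reveals where a partner protein sits within
the repeat.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError
from .io import SegmentROI

logger = logging.getLogger(__name__)

#: default histogram bin for projected positions, nm
DEFAULT_BIN_SIZE = 10.0
#: default search windows for the first peak and the two flanking valleys, nm
DEFAULT_PEAK_WINDOW = (140.0, 240.0)
DEFAULT_VALLEY_WINDOWS = ((50.0, 140.0), (240.0, 330.0))


@dataclass
class Profile1D:
    """Binned 1D profile of projected localization counts."""

    bin_size: float
    origin: float
    counts: np.ndarray
    segment_label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if not self.bin_size > 0:
            raise AnalysisError("bin_size must be > 0")
        if (self.counts < 0).any():
            raise AnalysisError("profile counts must be non-negative")

    @property
    def bin_centers(self) -> np.ndarray:
        return self.origin + (np.arange(self.counts.size) + 0.5) * self.bin_size

    @property
    def span(self) -> float:
        return self.counts.size * self.bin_size


@dataclass
class CorrelationCurve:
    """Normalized correlation values on a uniform lag grid (nm)."""

    lags: np.ndarray
    values: np.ndarray
    n_segments_averaged: int = 1
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.shape != self.values.shape:
            raise AnalysisError("lags and values must have the same shape")

    @property
    def bin_size(self) -> float:
        return float(self.lags[1] - self.lags[0]) if self.lags.size > 1 else 0.0

    def value_at(self, lag: float) -> float:
        idx = int(np.argmin(np.abs(self.lags - lag)))
        return float(self.values[idx])


@dataclass(frozen=True)
class PeriodicityResult:
    """Amplitude and period read off a (usually averaged) autocorrelation curve."""

    amplitude: float
    period: float | None
    peak_lag: float | None
    valley_lags: tuple[float, float] | None
    peak_window: tuple[float, float]
    valley_windows: tuple[tuple[float, float], tuple[float, float]]
    degenerate: bool = False


@dataclass(frozen=True)
class PhaseEstimate:
    """First-harmonic phase of a profile at a fixed period."""

    phase: float  # radians in [0, 2*pi)
    period: float
    strength: float  # in [0, 1]; 0 for a flat profile


@dataclass(frozen=True)
class TestResult:
    """Two-sample comparison summary (pooled-variance Student's t)."""

    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t: float
    p: float
    n_a: int
    n_b: int


def project_to_axis(segment_table: pd.DataFrame, axis: SegmentROI | str = "auto") -> np.ndarray:
    """Project localizations onto the segment's longitudinal axis.

    With an explicit :class:`SegmentROI` the axial coordinate relative to
    ``endpoint_a`` is returned. With ``axis="auto"`` the axis is the principal
    eigenvector of the 2D coordinate covariance through the centroid, and
    positions are shifted so they span ``[0, max)``.
    """
    xy = segment_table[["x_nm", "y_nm"]].to_numpy(float)
    if isinstance(axis, SegmentROI):
        a = np.asarray(axis.endpoint_a, float)
        return (xy - a) @ axis.axis
    if axis != "auto":
        raise AnalysisError(f"axis must be a SegmentROI or 'auto', got {axis!r}")
    if len(xy) < 2:
        raise AnalysisError("automatic axis estimation needs at least 2 localizations")
    centered = xy - xy.mean(axis=0)
    cov = centered.T @ centered / len(xy)
    eigvals, eigvecs = np.linalg.eigh(cov)
    u = eigvecs[:, int(np.argmax(eigvals))]
    if u[0] < 0 or (u[0] == 0 and u[1] < 0):  # deterministic sign
        u = -u
    t = centered @ u
    return t - t.min()


def bin_profile(
    positions: np.ndarray,
    bin_size: float = DEFAULT_BIN_SIZE,
    range: tuple[float, float] | None = None,
    segment_label: str = "",
) -> Profile1D:
    """Histogram positions into half-open bins ``[origin + i*b, origin + (i+1)*b)``.

    Positions outside ``range`` are dropped (count logged at DEBUG level). A
    position landing exactly on an interior edge falls in the upper bin.
    """
    positions = np.asarray(positions, dtype=float)
    if not bin_size > 0:
        raise AnalysisError("bin_size must be > 0")
    if range is None:
        if positions.size == 0:
            raise AnalysisError("cannot infer binning range from an empty position list")
        range = (0.0, float(positions.max()) + bin_size)
    lo, hi = float(range[0]), float(range[1])
    if not hi > lo:
        raise AnalysisError("binning range must be non-empty")
    n_bins = int(math.ceil((hi - lo) / bin_size))
    inside = (positions >= lo) & (positions < lo + n_bins * bin_size)
    dropped = int(positions.size - inside.sum())
    if dropped:
        logger.debug("bin_profile: dropped %d positions outside range", dropped)
    idx = np.floor((positions[inside] - lo) / bin_size).astype(int)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    return Profile1D(bin_size=bin_size, origin=lo, counts=counts, segment_label=segment_label)


def _lagged_covariance(da: np.ndarray, db: np.ndarray, lag: int) -> float:
    """Overlap-normalized lagged covariance sum(da[i] * db[i+lag]) / N_overlap."""
    n = da.size
    if lag >= 0:
        overlap = n - lag
        if overlap <= 0:
            return 0.0
        return float(da[: n - lag] @ db[lag:]) / overlap
    return _lagged_covariance(db, da, -lag)


def autocorrelation(profile: Profile1D, max_lag: float = 600.0) -> CorrelationCurve:
    """Normalized 1D autocorrelation of a binned profile.

    Uses the mean-subtracted, overlap-normalized estimator

        g(l) = [ sum_i (c_i - cbar)(c_{i+l} - cbar) / N_overlap(l) ] / s^2

    with the profile mean ``cbar`` and population variance ``s^2``, so
    ``g(0) = 1`` exactly and a pure sampled cosine yields a cosine. No
    wraparound. A zero-variance profile returns an all-zero curve with
    ``degenerate=True`` rather than raising.
    """
    c = profile.counts
    n_lags = int(math.floor(max_lag / profile.bin_size)) + 1
    if n_lags > c.size:
        raise AnalysisError(
            f"profile spans {profile.span:.0f} nm; too short for max_lag={max_lag:.0f} nm"
        )
    lags = np.arange(n_lags) * profile.bin_size
    var = c.var()
    if var == 0:
        return CorrelationCurve(lags, np.zeros(n_lags), degenerate=True)
    d = c - c.mean()
    values = np.array([_lagged_covariance(d, d, k) for k in np.arange(n_lags)]) / var
    return CorrelationCurve(lags, values)


def cross_correlation(
    profile_a: Profile1D, profile_b: Profile1D, max_lag: float = 600.0
) -> CorrelationCurve:
    """Normalized cross-correlation on a symmetric lag grid.

    Sign convention: the value at lag ``l`` compares ``a_i`` with ``b_{i+l}``,
    so if b is a copy of a shifted *forward* by k bins (``b_i = a_{i-k}``) the
    extremum sits at ``+k`` bins. Restricted to lags >= 0,
    ``cross_correlation(p, p)`` equals ``autocorrelation(p)``.
    """
    if not math.isclose(profile_a.bin_size, profile_b.bin_size) or not math.isclose(
        profile_a.origin, profile_b.origin
    ):
        raise AnalysisError("cross_correlation requires profiles with identical binning")
    if profile_a.counts.size != profile_b.counts.size:
        raise AnalysisError("cross_correlation requires profiles of equal length")
    b = profile_a.bin_size
    n_lags = int(math.floor(max_lag / b))
    if n_lags + 1 > profile_a.counts.size:
        raise AnalysisError("profiles too short for requested max_lag")
    lags = np.arange(-n_lags, n_lags + 1) * b
    va, vb = profile_a.counts.var(), profile_b.counts.var()
    if va == 0 or vb == 0:
        return CorrelationCurve(lags, np.zeros(lags.size), degenerate=True)
    da = profile_a.counts - profile_a.counts.mean()
    db = profile_b.counts - profile_b.counts.mean()
    norm = math.sqrt(va * vb)
    values = np.array(
        [_lagged_covariance(da, db, k) for k in np.arange(-n_lags, n_lags + 1)]
    ) / norm
    return CorrelationCurve(lags, values)


def average_curves(curves: list[CorrelationCurve]) -> CorrelationCurve:
    """Unweighted per-lag mean of correlation curves sharing a lag grid.

    Degenerate curves are excluded (count logged); averaging an empty list
    after exclusions is an error.
    """
    usable = [c for c in curves if not c.degenerate]
    excluded = len(curves) - len(usable)
    if excluded:
        logger.info("average_curves: excluded %d degenerate curves", excluded)
    if not usable:
        raise AnalysisError("no non-degenerate curves to average")
    lags = usable[0].lags
    for c in usable[1:]:
        if c.lags.shape != lags.shape or not np.allclose(c.lags, lags):
            raise AnalysisError("curves must share a lag grid")
    values = np.mean([c.values for c in usable], axis=0)
    n = sum(c.n_segments_averaged for c in usable)
    return CorrelationCurve(lags, values, n_segments_averaged=n)


def _extremum_in_window(
    curve: CorrelationCurve, window: tuple[float, float], kind: str
) -> tuple[float, float]:
    """(lag, value) of the argmax/argmin within a closed lag window; ties -> smaller lag."""
    mask = (curve.lags >= window[0]) & (curve.lags <= window[1])
    if not mask.any():
        raise AnalysisError(f"curve does not cover the window {window}")
    sub_lags = curve.lags[mask]
    sub_vals = curve.values[mask]
    idx = int(np.argmax(sub_vals)) if kind == "max" else int(np.argmin(sub_vals))
    return float(sub_lags[idx]), float(sub_vals[idx])


def periodicity_metrics(
    curve: CorrelationCurve,
    peak_window: tuple[float, float] = DEFAULT_PEAK_WINDOW,
    valley_windows: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_VALLEY_WINDOWS,
) -> PeriodicityResult:
    """Amplitude and period of an (averaged) autocorrelation curve.

    The period is the first-peak lag (argmax in ``peak_window``); the amplitude
    is the peak value minus the mean of the two valley minima.
    """
    if curve.degenerate:
        return PeriodicityResult(
            amplitude=0.0,
            period=None,
            peak_lag=None,
            valley_lags=None,
            peak_window=peak_window,
            valley_windows=valley_windows,
            degenerate=True,
        )
    if curve.lags.max() < max(valley_windows[0][1], valley_windows[1][1], peak_window[1]):
        raise AnalysisError("curve shorter than the requested search windows")
    peak_lag, peak_val = _extremum_in_window(curve, peak_window, "max")
    v1_lag, v1_val = _extremum_in_window(curve, valley_windows[0], "min")
    v2_lag, v2_val = _extremum_in_window(curve, valley_windows[1], "min")
    amplitude = peak_val - 0.5 * (v1_val + v2_val)
    return PeriodicityResult(
        amplitude=float(amplitude),
        period=peak_lag,
        peak_lag=peak_lag,
        valley_lags=(v1_lag, v2_lag),
        peak_window=peak_window,
        valley_windows=valley_windows,
    )


def estimate_phase(profile: Profile1D, period: float) -> PhaseEstimate:
    """First-harmonic phase of a profile at a fixed period.

    Projects the mean-subtracted counts onto the first harmonic at the given
    period over the bin centers; the argument of the resulting complex sum,
    mapped to ``[0, 2*pi)``, is the phase — i.e. the crest position expressed
    as an angle, so 0 means a crest at ``x = 0`` and a crest at ``period/2``
    gives pi. ``strength`` is the modulus normalized by ``sum |c_i - cbar|``;
    a flat profile returns phase 0 and strength 0 by convention.
    """
    if not period > 0:
        raise AnalysisError("period must be > 0")
    if profile.span < 2 * period:
        raise AnalysisError("profile must span at least two periods for phase estimation")
    c = profile.counts
    d = c - c.mean()
    denom = np.abs(d).sum()
    if denom == 0:
        return PhaseEstimate(phase=0.0, period=period, strength=0.0)
    z = np.sum(d * np.exp(1j * 2 * np.pi * profile.bin_centers / period))
    phase = float(np.angle(z)) % (2 * np.pi)
    return PhaseEstimate(phase=phase, period=period, strength=float(abs(z) / denom))


def _circular_shift(counts: np.ndarray, shift_bins: float) -> np.ndarray:
    """Circularly shift by a fractional number of bins with linear interpolation.

    ``out[i] = counts[(i + shift_bins) mod n]`` — a positive shift moves
    content toward smaller indices.
    """
    n = counts.size
    src = (np.arange(n) + shift_bins) % n
    lo = np.floor(src).astype(int) % n
    hi = (lo + 1) % n
    frac = src - np.floor(src)
    return (1 - frac) * counts[lo] + frac * counts[hi]


def align_and_average(
    reference_profiles: list[Profile1D],
    partner_profiles: list[Profile1D],
    period: float,
) -> tuple[Profile1D, Profile1D]:
    """Phase-align paired profiles on the reference channel and average.

    Each pair is circularly shifted (linear interpolation, modulo the period)
    by ``-phase(reference) * period / (2*pi)`` so the reference crest moves to
    the origin; shifted profiles are then averaged per channel. The output
    spans the largest whole number of periods common to all profiles.
    """
    if len(reference_profiles) != len(partner_profiles):
        raise AnalysisError("reference and partner profile lists must have equal length")
    if not reference_profiles:
        raise AnalysisError("empty profile lists")
    bin_size = reference_profiles[0].bin_size
    for p in (*reference_profiles, *partner_profiles):
        if not math.isclose(p.bin_size, bin_size):
            raise AnalysisError("all profiles must share a bin size")
    min_bins = min(p.counts.size for p in (*reference_profiles, *partner_profiles))
    n_periods = int(math.floor(min_bins * bin_size / period))
    if n_periods < 2:
        raise AnalysisError("profiles must span at least two periods")
    n_out = int(round(n_periods * period / bin_size))
    ref_acc = np.zeros(n_out)
    par_acc = np.zeros(n_out)
    for ref, par in zip(reference_profiles, partner_profiles):
        shift_nm = estimate_phase(ref, period).phase * period / (2 * np.pi)
        shift_bins = shift_nm / bin_size
        ref_acc += _circular_shift(ref.counts[:n_out], shift_bins)
        par_acc += _circular_shift(par.counts[:n_out], shift_bins)
    n = len(reference_profiles)
    return (
        Profile1D(bin_size, 0.0, ref_acc / n, segment_label="aligned-average-reference"),
        Profile1D(bin_size, 0.0, par_acc / n, segment_label="aligned-average-partner"),
    )


def compare_conditions(amplitudes_a, amplitudes_b) -> TestResult:
    """Two-sided unpaired Student's t-test (pooled variance) between replicate values."""
    a = np.asarray(amplitudes_a, dtype=float)
    b = np.asarray(amplitudes_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise AnalysisError("compare_conditions needs at least 2 values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # degenerate: both groups constant
        t = 0.0 if a.mean() == b.mean() else math.copysign(math.inf, a.mean() - b.mean())
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=True)
    return TestResult(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sem_a=float(a.std(ddof=1) / math.sqrt(a.size)),
        sem_b=float(b.std(ddof=1) / math.sqrt(b.size)),
        t=float(t),
        p=float(p),
        n_a=int(a.size),
        n_b=int(b.size),
    )
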