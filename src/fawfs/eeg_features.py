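"""Nonlinear and spectral EEG features.

Per channel-epoch the extractor produces a fixed 12-component vector:

* power-spectrum entropy (Shannon entropy of the normalized periodogram),
* Shannon entropy of the binarized signal (fraction above the median),
* correlation dimension (Grassberger-Procaccia scaling exponent),
* Kolmogorov K2 entropy (correlation entropy from consecutive embedding
  dimensions),
* C0 complexity (fraction of energy outside the above-mean-power Fourier
  components),
* total band power and relative delta/theta/alpha/beta/gamma power,
* spectral peak frequency.

The chaos-theoretic quantities are defined as limits; here they are
estimated on finite epochs with a configurable delay embedding and a
log-log scaling region, the standard finite-data practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.spatial.distance import pdist

from .datatypes import EEGRecording

__all__ = [
    "EmbeddingParams",
    "DegenerateInputError",
    "power_spectrum_entropy",
    "shannon_binary_entropy",
    "correlation_dimension",
    "kolmogorov_entropy",
    "c0_complexity",
    "band_powers",
    "extract_feature_vector",
    "FEATURE_NAMES",
    "EEG_BANDS",
]

EEG_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

FEATURE_NAMES: tuple[str, ...] = (
    "power_spectrum_entropy",
    "shannon_entropy",
    "correlation_dimension",
    "k2_entropy",
    "c0_complexity",
    "total_power",
    "rel_delta",
    "rel_theta",
    "rel_alpha",
    "rel_beta",
    "rel_gamma",
    "peak_frequency",
)


class DegenerateInputError(ValueError):
    """Raised when a feature is undefined on the given input
    (constant signal, zero energy, too few embedded points)."""


@dataclass(frozen=True)
class EmbeddingParams:
    """Delay-embedding parameters for the correlation-integral features.

    ``tau=None`` selects the delay automatically as the first zero
    crossing of the autocorrelation (fallback 1). The scaling region is
    the radius range between the given percentiles of the pairwise
    embedded distances, sampled at ``n_radii`` log-spaced points.
    """

    m: int = 5
    tau: int | None = None
    theiler_window: int | None = None
    r_percentiles: tuple[float, float] = (5.0, 50.0)
    n_radii: int = 12

    def validate(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.tau is not None and self.tau < 1:
            raise ValueError("tau must be >= 1")
        lo, hi = self.r_percentiles
        if not 0 <= lo < hi <= 100:
            raise ValueError("r_percentiles must satisfy 0 <= lo < hi <= 100")
        if self.n_radii < 2:
            raise ValueError("n_radii must be >= 2")


def _autocorr_delay(x: np.ndarray) -> int:
    """First zero crossing of the autocorrelation; fallback 1."""
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0.0:
        return 1
    for lag in range(1, min(x.size - 1, x.size // 2)):
        if np.dot(x[:-lag], x[lag:]) / denom <= 0.0:
            return lag
    return 1


def _embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    n_points = x.size - (m - 1) * tau
    if n_points < 1:
        raise DegenerateInputError("signal too short for the requested embedding")
    idx = np.arange(n_points)[:, None] + tau * np.arange(m)[None, :]
    return x[idx]


def correlation_integrals(
    x: np.ndarray, m: int, tau: int, theiler: int, radii: np.ndarray
) -> np.ndarray:
    """C(r) = fraction of Theiler-excluded point pairs within radius r.

    Pairs (i, j) with |i - j| <= theiler are excluded to avoid counting
    temporally correlated neighbours as recurrences.
    """
    pts = _embed(np.asarray(x, dtype=float), m, tau)
    n = pts.shape[0]
    if n < 2:
        raise DegenerateInputError("too few embedded points")
    d = pdist(pts)  # condensed upper triangle, pair (i, j), i < j
    if theiler > 0:
        ii, jj = np.triu_indices(n, k=1)
        d = d[(jj - ii) > theiler]
    if d.size == 0:
        raise DegenerateInputError("Theiler window leaves no pairs")
    return np.searchsorted(np.sort(d), radii, side="right") / d.size


def _scaling_radii(x: np.ndarray, m: int, tau: int, theiler: int,
                   params: EmbeddingParams) -> np.ndarray:
    pts = _embed(np.asarray(x, dtype=float), m, tau)
    d = pdist(pts)
    n = pts.shape[0]
    if theiler > 0:
        ii, jj = np.triu_indices(n, k=1)
        d = d[(jj - ii) > theiler]
    d = d[d > 0]
    if d.size == 0:
        raise DegenerateInputError("all embedded points identical")
    lo, hi = np.percentile(d, params.r_percentiles)
    if lo <= 0:
        lo = d.min()
    if not hi > lo:
        raise DegenerateInputError("degenerate pairwise-distance distribution")
    return np.geomspace(lo, hi, params.n_radii)


def _resolve(x: np.ndarray, params: EmbeddingParams) -> tuple[int, int, int]:
    params.validate()
    tau = params.tau if params.tau is not None else _autocorr_delay(x)
    theiler = params.theiler_window if params.theiler_window is not None else tau
    return params.m, tau, theiler


def correlation_dimension(signal: np.ndarray, params: EmbeddingParams | None = None) -> float:
    """Grassberger-Procaccia correlation dimension.

    Least-squares slope of ln C(r) against ln r over the scaling region.
    """
    if params is None:
        params = EmbeddingParams()
    x = np.asarray(signal, dtype=float)
    if np.ptp(x) == 0.0:
        raise DegenerateInputError("constant signal has no correlation dimension")
    m, tau, theiler = _resolve(x, params)
    if x.size - (m - 1) * tau < 50:
        raise DegenerateInputError("need at least 50 embedded points")
    radii = _scaling_radii(x, m, tau, theiler, params)
    c = correlation_integrals(x, m, tau, theiler, radii)
    keep = c > 0
    if keep.sum() < 2:
        raise DegenerateInputError("correlation integral vanishes on the region")
    slope = np.polyfit(np.log(radii[keep]), np.log(c[keep]), 1)[0]
    return float(slope)


def kolmogorov_entropy(signal: np.ndarray, params: EmbeddingParams | None = None) -> float:
    """K2 (correlation) entropy in nats per sample.

    K2 = (1/tau) * ln(C_m(r) / C_{m+1}(r)), averaged over the scaling
    radii. Near zero for deterministic periodic signals; large for noise.
    """
    if params is None:
        params = EmbeddingParams()
    x = np.asarray(signal, dtype=float)
    if np.ptp(x) == 0.0:
        raise DegenerateInputError("constant signal has no K2 entropy")
    m, tau, theiler = _resolve(x, params)
    if x.size - m * tau < 50:
        raise DegenerateInputError("need at least 50 embedded points at m+1")
    radii = _scaling_radii(x, m, tau, theiler, params)
    c_m = correlation_integrals(x, m, tau, theiler, radii)
    c_m1 = correlation_integrals(x, m + 1, tau, theiler, radii)
    keep = (c_m > 0) & (c_m1 > 0)
    if not keep.any():
        raise DegenerateInputError("correlation integrals vanish at m+1")
    ratios = np.log(c_m[keep] / c_m1[keep])
    return float(np.mean(ratios) / tau)


def power_spectrum_entropy(signal: np.ndarray, fs: float) -> float:
    """Shannon entropy (bits) of the normalized periodogram."""
    x = np.asarray(signal, dtype=float)
    if x.size < 8:
        raise DegenerateInputError("need at least 8 samples")
    if np.ptp(x) == 0.0:
        raise DegenerateInputError("constant signal has zero spectral power")
    _, pxx = sps.periodogram(x - x.mean(), fs=fs)
    total = pxx.sum()
    if total <= 0:
        raise DegenerateInputError("zero total power")
    p = pxx / total
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def shannon_binary_entropy(x: float) -> float:
    """Binary Shannon entropy H(x) in bits, with H(0) = H(1) = 0."""
    if not 0.0 <= x <= 1.0:
        raise ValueError("x must lie in [0, 1]")
    if x in (0.0, 1.0):
        return 0.0
    return float(-x * np.log2(x) - (1.0 - x) * np.log2(1.0 - x))


def c0_complexity(signal: np.ndarray) -> float:
    """C0 complexity: energy fraction outside the dominant spectrum.

    DFT the signal, keep coefficients whose squared magnitude exceeds the
    mean squared magnitude, invert to the regular part Y, and return
    ||X - Y||^2 / ||X||^2. Always in [0, 1]; near 0 for a pure tone at a
    DFT frequency, large for broadband noise.
    """
    x = np.asarray(signal, dtype=float)
    energy = float(np.sum(np.abs(x) ** 2))
    if energy == 0.0:
        raise DegenerateInputError("all-zero signal")
    spec = np.fft.fft(x)
    power = np.abs(spec) ** 2
    keep = power > power.mean()
    y = np.fft.ifft(np.where(keep, spec, 0.0)).real
    return float(np.sum(np.abs(x - y) ** 2) / energy)


def band_powers(
    signal: np.ndarray, fs: float, bands: dict[str, tuple[float, float]] | None = None
) -> dict[str, float]:
    """Absolute and relative band power via periodogram integration.

    Returns ``{"total": P, "abs_<band>": ..., "rel_<band>": ...}``;
    relative powers are fractions of total periodogram power and sum to
    at most 1.
    """
    if bands is None:
        bands = EEG_BANDS
    x = np.asarray(signal, dtype=float)
    if np.ptp(x) == 0.0:
        raise DegenerateInputError("constant signal has zero band power")
    nyq = fs / 2.0
    for name, (lo, hi) in bands.items():
        if not 0 <= lo < hi <= nyq:
            raise ValueError(f"band {name} ({lo}-{hi} Hz) outside (0, {nyq}) Hz")
    f, pxx = sps.periodogram(x - x.mean(), fs=fs)
    total = float(np.trapezoid(pxx, f))
    if total <= 0:
        raise DegenerateInputError("zero total power")
    out: dict[str, float] = {"total": total}
    for name, (lo, hi) in bands.items():
        sel = (f >= lo) & (f <= hi)
        p = float(np.trapezoid(pxx[sel], f[sel])) if sel.sum() > 1 else 0.0
        out[f"abs_{name}"] = p
        out[f"rel_{name}"] = p / total
    return out


def spectral_peak_frequency(signal: np.ndarray, fs: float) -> float:
    """Frequency (Hz) of the periodogram maximum (DC excluded)."""
    x = np.asarray(signal, dtype=float)
    if np.ptp(x) == 0.0:
        raise DegenerateInputError("constant signal has no spectral peak")
    f, pxx = sps.periodogram(x - x.mean(), fs=fs)
    return float(f[1:][np.argmax(pxx[1:])])


def extract_feature_vector(
    epoch: EEGRecording,
    channel: int | str = 0,
    params: EmbeddingParams | None = None,
) -> dict[str, float]:
    """The 12 named features of one channel of one epoch.

    Deterministic for fixed input and parameters; degenerate-input errors
    are re-raised with the offending feature named.
    """
    if isinstance(channel, str):
        channel = epoch.channel_labels.index(channel)
    x = epoch.data[channel]
    fs = epoch.fs
    values: dict[str, float] = {}
    frac_above = float(np.mean(x > np.median(x)))
    computations = {
        "power_spectrum_entropy": lambda: power_spectrum_entropy(x, fs),
        "shannon_entropy": lambda: shannon_binary_entropy(frac_above),
        "correlation_dimension": lambda: correlation_dimension(x, params),
        "k2_entropy": lambda: kolmogorov_entropy(x, params),
        "c0_complexity": lambda: c0_complexity(x),
        "peak_frequency": lambda: spectral_peak_frequency(x, fs),
    }
    for name, fn in computations.items():
        try:
            values[name] = fn()
        except DegenerateInputError as exc:
            raise DegenerateInputError(f"{name}: {exc}") from exc
    try:
        bp = band_powers(x, fs)
    except DegenerateInputError as exc:
        raise DegenerateInputError(f"band_powers: {exc}") from exc
    values["total_power"] = bp["total"]
    for band in EEG_BANDS:
        values[f"rel_{band}"] = bp[f"rel_{band}"]
    return {name: values[name] for name in FEATURE_NAMES}
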