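"""EEG signal conditioning: down-sampling, band-pass, EOG removal, epoching.

The conditioning chain mirrors common frontal-EEG practice for depression
studies: decimate the raw 1000 Hz acquisition to 250 Hz, zero-phase
band-pass to the physiological band, then suppress electro-oculogram
(blink) artifacts with a Kalman smoother followed by wavelet thresholding.

Blinks on Fp1/Fp2/Fpz are slow, high-amplitude transients. The Kalman
stage fits a scalar local-level (random-walk) state model per channel;
with a process/observation variance ratio favouring slow dynamics, the
smoothed state tracks the blink trajectory plus any baseline drift, and
subtracting it removes the bulk of the artifact. The residual is then
wavelet-decomposed and the approximation band soft-thresholded (universal
threshold) to suppress whatever low-frequency transient energy remains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps

from .datatypes import EEGRecording

__all__ = [
    "DenoiseConfig",
    "downsample",
    "bandpass",
    "remove_eog",
    "epoch",
    "concatenate",
]


@dataclass(frozen=True)
class DenoiseConfig:
    """Parameters of the conditioning chain.

    Band edges in Hz (defaults 0.5-50, the conventional EEG band);
    wavelet family/level and the universal soft-threshold rule for the
    residual cleanup; Kalman process/observation variances setting how
    slow a trajectory the local-level model tracks.
    """

    band_low: float = 0.5
    band_high: float = 50.0
    wavelet_name: str = "db4"
    decomposition_level: int = 5
    threshold_rule: str = "universal"
    kalman_process_var: float = 1e-3
    kalman_obs_var: float = 1.0

    def validate(self, fs: float) -> None:
        if not 0 < self.band_low < self.band_high < fs / 2:
            raise ValueError(
                f"band ({self.band_low}, {self.band_high}) Hz invalid for fs={fs}"
            )
        if self.kalman_process_var <= 0 or self.kalman_obs_var <= 0:
            raise ValueError("Kalman variances must be positive")
        if self.threshold_rule != "universal":
            raise ValueError(f"unknown threshold rule {self.threshold_rule!r}")
        if self.decomposition_level < 1:
            raise ValueError("decomposition_level must be >= 1")


def downsample(rec: EEGRecording, target_fs: float) -> EEGRecording:
    """Integer-ratio decimation with an anti-alias low-pass (zero phase).

    ``target_fs`` must divide ``rec.fs`` exactly; arbitrary resampling is
    out of scope. ``target_fs == rec.fs`` returns a copy unchanged.
    """
    if target_fs > rec.fs:
        raise ValueError("target_fs must not exceed the recording fs")
    ratio = rec.fs / target_fs
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9:
        raise ValueError(f"fs ratio {ratio} is not an integer")
    if q == 1:
        return rec.copy()
    data = sps.decimate(rec.data, q, ftype="fir", axis=1, zero_phase=True)
    return EEGRecording(data, target_fs, list(rec.channel_labels))


def bandpass(rec: EEGRecording, cfg: DenoiseConfig) -> EEGRecording:
    """Zero-phase 4th-order Butterworth band-pass (forward-backward)."""
    cfg.validate(rec.fs)
    sos = sps.butter(
        4, [cfg.band_low, cfg.band_high], btype="bandpass", fs=rec.fs, output="sos"
    )
    data = sps.sosfiltfilt(sos, rec.data, axis=1)
    return EEGRecording(data, rec.fs, list(rec.channel_labels))


def _kalman_local_level(x: np.ndarray, q: float, r: float) -> np.ndarray:
    """RTS-smoothed local-level state estimate of a 1-D series.

    State model: level_t = level_{t-1} + w_t, w ~ N(0, q);
    observation:  x_t = level_t + v_t,     v ~ N(0, r).
    The smoothed level is the slow trajectory (drift + blink lobe).
    """
    n = x.size
    # forward filter
    m_pred = np.empty(n)
    p_pred = np.empty(n)
    m_filt = np.empty(n)
    p_filt = np.empty(n)
    m, p = x[0], r
    for t in range(n):
        if t > 0:
            m, p = m_filt[t - 1], p_filt[t - 1] + q
        m_pred[t], p_pred[t] = m, p
        k = p / (p + r)
        m_filt[t] = m + k * (x[t] - m)
        p_filt[t] = (1.0 - k) * p
    # backward RTS pass
    m_smooth = np.empty(n)
    m_smooth[-1] = m_filt[-1]
    for t in range(n - 2, -1, -1):
        g = p_filt[t] / p_pred[t + 1]
        m_smooth[t] = m_filt[t] + g * (m_smooth[t + 1] - m_pred[t + 1])
    return m_smooth


def remove_eog(rec: EEGRecording, cfg: DenoiseConfig | None = None) -> EEGRecording:
    """Suppress electro-oculogram artifacts: Kalman smoother then wavelets.

    Per channel: (i) the local-level Kalman smoother estimates the slow
    high-amplitude artifact trajectory, which is subtracted; (ii) the
    residual is wavelet-decomposed (``wavelet_name``, ``decomposition_level``)
    and the approximation coefficients soft-thresholded at the universal
    threshold sigma*sqrt(2 ln n), suppressing remaining low-frequency
    transients. Length and sampling rate are unchanged.
    """
    if cfg is None:
        cfg = DenoiseConfig()
    if cfg.kalman_process_var <= 0 or cfg.kalman_obs_var <= 0:
        raise ValueError("Kalman variances must be positive")
    n = rec.n_samples
    max_level = pywt.dwt_max_level(n, pywt.Wavelet(cfg.wavelet_name).dec_len)
    if cfg.decomposition_level > max_level:
        raise ValueError(
            f"decomposition level {cfg.decomposition_level} too deep for "
            f"signal length {n} (max {max_level})"
        )
    out = np.empty_like(rec.data)
    for c in range(rec.n_channels):
        x = rec.data[c]
        level_est = _kalman_local_level(
            x, cfg.kalman_process_var, cfg.kalman_obs_var
        )
        resid = x - level_est
        coeffs = pywt.wavedec(resid, cfg.wavelet_name, level=cfg.decomposition_level)
        # noise scale from the finest detail band (robust MAD estimate)
        sigma = np.median(np.abs(coeffs[-1])) / 0.6745 if coeffs[-1].size else 0.0
        thr = sigma * np.sqrt(2.0 * np.log(max(n, 2)))
        if thr > 0:
            coeffs[0] = pywt.threshold(coeffs[0], thr, mode="soft")
        out[c] = pywt.waverec(coeffs, cfg.wavelet_name)[:n]
    return EEGRecording(out, rec.fs, list(rec.channel_labels))


def epoch(rec: EEGRecording, length_s: float, overlap_s: float = 0.0) -> list[EEGRecording]:
    """Cut the recording into fixed-length windows with the given overlap.

    Windows tile the recording with stride ``length_s - overlap_s``; a
    trailing partial window is discarded.
    """
    if not 0 <= overlap_s < length_s:
        raise ValueError("require 0 <= overlap_s < length_s")
    if length_s > rec.duration + 1e-12:
        raise ValueError("epoch length exceeds recording duration")
    win = int(round(length_s * rec.fs))
    stride = int(round((length_s - overlap_s) * rec.fs))
    if stride < 1:
        raise ValueError("stride must be at least one sample")
    epochs = []
    start = 0
    while start + win <= rec.n_samples:
        epochs.append(
            EEGRecording(rec.data[:, start : start + win].copy(), rec.fs,
                         list(rec.channel_labels))
        )
        start += stride
    return epochs


def concatenate(epochs: list[EEGRecording]) -> EEGRecording:
    """Concatenate zero-overlap epochs back into one recording."""
    if not epochs:
        raise ValueError("no epochs to concatenate")
    fs = epochs[0].fs
    if any(e.fs != fs for e in epochs):
        raise ValueError("epochs have inconsistent sampling rates")
    data = np.concatenate([e.data for e in epochs], axis=1)
    return EEGRecording(data, fs, list(epochs[0].channel_labels))
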