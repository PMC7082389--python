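"""10-s window summaries of ABP/ICP waveforms.

All downstream indices (PRx, RAP, AMP/aABP) are built from per-window
quantities: the 10-s mean of each channel, the heart rate (fundamental
frequency of ABP searched within the cardiac 40-180 cycles/min band) and the
fundamental cardiac amplitudes of ABP (aABP) and ICP (AMP).

Amplitudes are *fundamental spectral amplitudes*: the window mean is removed,
the cardiac peak located on the discrete spectrum, refined off-grid by local
parabolic interpolation, and the amplitude read off as twice the magnitude of
the complex projection onto the refined frequency (so a pure sinusoid
a*sin(2*pi*f*t) yields exactly a). No beat detection is performed; the method
is purely spectral.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigurationError, ValidityRule

CARDIAC_BAND_CPM = (40.0, 180.0)


@dataclass
class WaveformRecording:
    """One uniformly sampled channel, in mm Hg, NaN marking missing samples."""

    channel: str                 # "ABP" | "ICP" | "PBTO2"
    sampling_rate: float         # Hz
    samples: np.ndarray
    start_time: float = 0.0      # seconds

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        # small tolerance: rates inferred from printed timestamps carry
        # float rounding noise
        if self.channel in ("ABP", "ICP") and self.sampling_rate < 50 * (1 - 1e-6):
            raise ConfigurationError(
                f"sampling_rate: {self.channel} requires >= 50 Hz, got {self.sampling_rate}"
            )
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    def time_axis(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.samples)) / self.sampling_rate


# ----------------------------------------------------------------------
# per-window primitives
# ----------------------------------------------------------------------

def window_mean(segment: np.ndarray) -> float:
    """Arithmetic mean of the finite samples; NaN if none."""
    segment = np.asarray(segment, dtype=float)
    good = np.isfinite(segment)
    if not good.any():
        return float("nan")
    return float(segment[good].mean())


def _project_amplitude(seg: np.ndarray, rate: float, f_hz: np.ndarray) -> np.ndarray:
    """|2/N * sum (x - mean) e^{-2 pi i f t}| for one or more windows.

    seg: (n_win, n_samp); f_hz: (n_win,). Vectorized over windows.
    """
    n = seg.shape[1]
    t = np.arange(n) / rate
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)   # all-NaN windows
        x = seg - np.nanmean(seg, axis=1, keepdims=True)
    x = np.where(np.isfinite(x), x, 0.0)
    phase = np.exp(-2j * np.pi * f_hz[:, None] * t[None, :])
    return 2.0 * np.abs((x * phase).mean(axis=1))


def _refine_peak(seg: np.ndarray, rate: float, f0_hz: np.ndarray,
                 step_hz: float, n_iter: int = 2) -> np.ndarray:
    """Parabolic refinement of the spectral peak on directly evaluated
    projection magnitudes; shrinks the step each iteration."""
    f = f0_hz.copy()
    step = step_hz
    for _ in range(n_iter):
        m_lo = _project_amplitude(seg, rate, f - step)
        m_mid = _project_amplitude(seg, rate, f)
        m_hi = _project_amplitude(seg, rate, f + step)
        denom = m_lo - 2 * m_mid + m_hi
        with np.errstate(invalid="ignore", divide="ignore"):
            delta = np.where(np.abs(denom) > 1e-300,
                             0.5 * (m_lo - m_hi) / denom, 0.0)
        delta = np.clip(delta, -1.0, 1.0)
        f = f + delta * step
        step /= 3.0
    return f


def _band_peak(seg: np.ndarray, rate: float,
               band_cpm: tuple[float, float]) -> np.ndarray:
    """Refined peak frequency (Hz) in the cardiac band per window; NaN where
    the window is flat or has no in-band bin."""
    n = seg.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)   # all-NaN windows
        x = seg - np.nanmean(seg, axis=1, keepdims=True)
    x = np.where(np.isfinite(x), x, 0.0)
    var = x.var(axis=1)
    spec = np.abs(np.fft.rfft(x, axis=1))
    freqs = np.fft.rfftfreq(n, 1.0 / rate)      # Hz
    lo, hi = band_cpm[0] / 60.0, band_cpm[1] / 60.0
    in_band = (freqs >= lo) & (freqs <= hi)
    if not in_band.any():
        return np.full(seg.shape[0], np.nan)
    idx = np.flatnonzero(in_band)
    k = idx[np.argmax(spec[:, idx], axis=1)]
    df = freqs[1] - freqs[0]
    # three-point quadratic interpolation on log magnitude
    km = np.clip(k - 1, 0, n // 2)
    kp = np.clip(k + 1, 0, spec.shape[1] - 1)
    with np.errstate(divide="ignore"):
        la = np.log(spec[np.arange(len(k)), km] + 1e-300)
        lb = np.log(spec[np.arange(len(k)), k] + 1e-300)
        lc = np.log(spec[np.arange(len(k)), kp] + 1e-300)
    denom = la - 2 * lb + lc
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = np.where(np.abs(denom) > 1e-12, 0.5 * (la - lc) / denom, 0.0)
    delta = np.clip(delta, -0.5, 0.5)
    f = (k + delta) * df
    f = _refine_peak(seg, rate, f, step_hz=df / 4.0)
    f = np.clip(f, lo, hi)
    return np.where(var > 0, f, np.nan)


def fundamental_frequency(segment: np.ndarray, rate: float,
                          band_cpm: tuple[float, float] = CARDIAC_BAND_CPM) -> float:
    """Heart rate in cycles/min: frequency of the largest in-band spectral
    magnitude after mean removal, refined off-grid. NaN for a flat segment."""
    segment = np.asarray(segment, dtype=float)
    f = _band_peak(segment[None, :], rate, band_cpm)[0]
    return float(f * 60.0) if np.isfinite(f) else float("nan")


def fundamental_amplitude(segment: np.ndarray, rate: float, f0_cpm: float) -> float:
    """Amplitude (mm Hg, half peak-to-peak) of the sinusoidal component at
    f0_cpm, after mean removal. NaN when f0 is missing."""
    if not np.isfinite(f0_cpm):
        return float("nan")
    segment = np.asarray(segment, dtype=float)
    return float(_project_amplitude(segment[None, :], rate,
                                    np.array([f0_cpm / 60.0]))[0])


# ----------------------------------------------------------------------
# recording-level summarization
# ----------------------------------------------------------------------

def align_channels(a: WaveformRecording, b: WaveformRecording
                   ) -> tuple[WaveformRecording, WaveformRecording]:
    """Bring two channels onto the faster channel's grid over their common
    span (linear interpolation of the slower channel)."""
    if a.sampling_rate == b.sampling_rate and a.start_time == b.start_time:
        n = min(len(a.samples), len(b.samples))
        return (WaveformRecording(a.channel, a.sampling_rate, a.samples[:n], a.start_time),
                WaveformRecording(b.channel, b.sampling_rate, b.samples[:n], b.start_time))
    fast, slow = (a, b) if a.sampling_rate >= b.sampling_rate else (b, a)
    t0 = max(a.start_time, b.start_time)
    t1 = min(a.start_time + a.duration, b.start_time + b.duration)
    if t1 <= t0:
        raise ConfigurationError("channels have no overlapping time span")
    t = np.arange(t0, t1 - 0.5 / fast.sampling_rate, 1.0 / fast.sampling_rate)
    def _interp(rec: WaveformRecording) -> np.ndarray:
        tt = rec.time_axis()
        good = np.isfinite(rec.samples)
        if good.sum() < 2:
            return np.full(len(t), np.nan)
        out = np.interp(t, tt[good], rec.samples[good])
        # do not invent data across gaps: mark samples outside coverage
        out[(t < tt[good][0]) | (t > tt[good][-1])] = np.nan
        return out
    ra = WaveformRecording(a.channel, fast.sampling_rate, _interp(a), t0)
    rb = WaveformRecording(b.channel, fast.sampling_rate, _interp(b), t0)
    return ra, rb


def summarize_recording(abp: WaveformRecording, icp: WaveformRecording,
                        pbto2: WaveformRecording | None = None,
                        window_seconds: float = 10.0,
                        band_cpm: tuple[float, float] = CARDIAC_BAND_CPM,
                        validity: ValidityRule | None = None) -> pd.DataFrame:
    """Tile the common span of the channels into consecutive non-overlapping
    windows and compute one summary row per complete window.

    Returns columns: window_start, mean_abp, mean_icp, heart_rate, aabp, amp,
    mean_pbto2, valid. The heart rate is anchored on ABP (the more robust
    channel); the ICP amplitude is read at the same frequency, allowing a
    +/-1-bin re-pick on the ICP spectrum.
    """
    validity = validity or ValidityRule()
    abp, icp = align_channels(abp, icp)
    rate = abp.sampling_rate
    nwin = int(round(window_seconds * rate))
    n_windows = len(abp.samples) // nwin
    if n_windows == 0:
        raise ConfigurationError("recording shorter than one window")
    A = abp.samples[: n_windows * nwin].reshape(n_windows, nwin)
    I = icp.samples[: n_windows * nwin].reshape(n_windows, nwin)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)   # fully missing windows
        mean_abp = np.nanmean(np.where(np.isfinite(A), A, np.nan), axis=1)
        mean_icp = np.nanmean(np.where(np.isfinite(I), I, np.nan), axis=1)
    miss_a = 1.0 - np.isfinite(A).mean(axis=1)
    miss_i = 1.0 - np.isfinite(I).mean(axis=1)

    f_hz = _band_peak(A, rate, band_cpm)
    hr = f_hz * 60.0
    aabp = np.full(n_windows, np.nan)
    amp = np.full(n_windows, np.nan)
    ok = np.isfinite(f_hz)
    if ok.any():
        aabp[ok] = _project_amplitude(A[ok], rate, f_hz[ok])
        # re-pick the ICP peak within +/-1 bin of the ABP fundamental
        df = rate / nwin
        cand = f_hz[ok][:, None] + np.array([-df, 0.0, df])[None, :]
        lo, hi = band_cpm[0] / 60.0, band_cpm[1] / 60.0
        cand = np.clip(cand, lo, hi)
        mags = np.stack([_project_amplitude(I[ok], rate, cand[:, j])
                         for j in range(3)], axis=1)
        f_icp = cand[np.arange(ok.sum()), np.argmax(mags, axis=1)]
        f_icp = np.clip(_refine_peak(I[ok], rate, f_icp, step_hz=df / 4.0), lo, hi)
        amp[ok] = _project_amplitude(I[ok], rate, f_icp)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        var_a = np.nanvar(np.where(np.isfinite(A), A, np.nan), axis=1)
    valid = (
        np.isfinite(mean_abp) & np.isfinite(mean_icp)
        & (mean_abp >= validity.abp_range[0]) & (mean_abp <= validity.abp_range[1])
        & (mean_icp >= validity.icp_range[0]) & (mean_icp <= validity.icp_range[1])
        & (miss_a <= validity.max_missing_frac)
        & (miss_i <= validity.max_missing_frac)
        & (var_a > 0)
        & np.isfinite(hr)
    )

    out = pd.DataFrame({
        "window_start": abp.start_time + np.arange(n_windows) * window_seconds,
        "mean_abp": mean_abp,
        "mean_icp": mean_icp,
        "heart_rate": hr,
        "aabp": aabp,
        "amp": amp,
        "valid": valid,
    })
    if pbto2 is not None:
        # PbtO2 probes run far slower than the cardiac band; only its mean is used
        p_al, _ = align_channels(pbto2, icp)
        P = p_al.samples[: n_windows * nwin]
        if len(P) < n_windows * nwin:
            P = np.concatenate([P, np.full(n_windows * nwin - len(P), np.nan)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out["mean_pbto2"] = np.nanmean(
                np.where(np.isfinite(P.reshape(n_windows, nwin)),
                         P.reshape(n_windows, nwin), np.nan), axis=1)
    else:
        out["mean_pbto2"] = np.nan
    return out
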