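"""Minute-resolution derived indices: PRx, RAP, CPP and AMP/aABP.

PRx is the moving Pearson correlation of 30 consecutive 10-s means of ABP
and ICP, updated every minute; positive values indicate impaired
cerebrovascular pressure reactivity. RAP — the index of cerebrospinal
compensatory reserve — is the same moving correlation applied to (mean ICP,
ICP pulse amplitude). CPP = MAP - ICP; AMP/aABP indexes transmission of the
arterial pulse into the cranium.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PipelineConfig


def moving_correlation(x: np.ndarray, y: np.ndarray, window: int = 30,
                       step: int = 6, min_valid_frac: float = 0.8
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Moving Pearson correlation over non-anticipating windows.

    Returns ``(end_indices, values)``: ``values[j]`` is the correlation of
    the valid pairs in ``x[e-window:e], y[e-window:e]`` with
    ``e = end_indices[j] = window + j*step`` — i.e. attributed to the window's
    end. Windows with fewer than ``min_valid_frac * window`` valid pairs, or
    zero variance in either input, yield NaN (never an exception).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be aligned and equally long")
    n = len(x)
    if n < window:
        return np.empty(0, dtype=int), np.empty(0)
    ends = np.arange(window, n + 1, step)
    idx = ends[:, None] + np.arange(-window, 0)[None, :]
    X, Y = x[idx], y[idx]
    ok = np.isfinite(X) & np.isfinite(Y)
    m = ok.sum(axis=1).astype(float)
    Xz = np.where(ok, X, 0.0)
    Yz = np.where(ok, Y, 0.0)
    sx, sy = Xz.sum(axis=1), Yz.sum(axis=1)
    sxx, syy = (Xz ** 2).sum(axis=1), (Yz ** 2).sum(axis=1)
    sxy = (Xz * Yz).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = m * sxy - sx * sy
        vx = m * sxx - sx ** 2
        vy = m * syy - sy ** 2
        r = cov / np.sqrt(vx * vy)
    bad = (m < min_valid_frac * window) | (vx <= 0) | (vy <= 0)
    r = np.where(bad, np.nan, np.clip(r, -1.0, 1.0))
    return ends, r


def _window_series(summaries: pd.DataFrame, col: str) -> np.ndarray:
    """Column as a float array with invalid windows masked to NaN."""
    v = summaries[col].to_numpy(dtype=float).copy()
    v[~summaries["valid"].to_numpy(dtype=bool)] = np.nan
    return v


def compute_prx(summaries: pd.DataFrame, window: int = 30, step: int = 6
                ) -> tuple[np.ndarray, np.ndarray]:
    """PRx: moving correlation of the 10-s means of ABP and ICP."""
    return moving_correlation(_window_series(summaries, "mean_abp"),
                              _window_series(summaries, "mean_icp"),
                              window, step)


def compute_rap(summaries: pd.DataFrame, window: int = 30, step: int = 6
                ) -> tuple[np.ndarray, np.ndarray]:
    """RAP: moving correlation of mean ICP and the ICP pulse amplitude."""
    return moving_correlation(_window_series(summaries, "mean_icp"),
                              _window_series(summaries, "amp"),
                              window, step)


def compute_cpp_and_ratio(summaries: pd.DataFrame, aabp_guard: float = 1.0
                          ) -> pd.DataFrame:
    """Per-window CPP = mean ABP - mean ICP and AMP/aABP transmission ratio.

    The ratio is left missing when aABP falls below ``aabp_guard`` mm Hg
    (a near-zero denominator carries no physiological information).
    """
    out = summaries.copy()
    out["cpp"] = out["mean_abp"] - out["mean_icp"]
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = out["amp"] / out["aabp"]
    ratio[out["aabp"] < aabp_guard] = np.nan
    out["amp_ratio"] = ratio
    return out


def compute_indices(summaries: pd.DataFrame,
                    config: PipelineConfig | None = None) -> pd.DataFrame:
    """Assemble the minute-resolution index table from 10-s window summaries.

    Each row covers one minute [60m, 60(m+1)): minute means of the valid
    windows inside it, CPP as the difference of those means, the minute mean
    of the per-window AMP/aABP ratio, and the PRx/RAP values whose 5-min
    correlation window *ends* at that minute's end. Minutes without any valid
    window carry NaN throughout (missing is propagated, never imputed).
    """
    config = config or PipelineConfig()
    wsec = config.window_seconds
    per_min = max(1, int(round(60.0 / wsec)))
    sw = compute_cpp_and_ratio(summaries, aabp_guard=config.aabp_guard_mmhg)

    start0 = float(sw["window_start"].iloc[0])
    widx = ((sw["window_start"] - start0) / wsec).round().astype(int)
    minute = widx // per_min
    n_min = int(minute.max()) + 1 if len(minute) else 0

    cols = ["mean_icp", "mean_abp", "amp", "aabp", "heart_rate",
            "mean_pbto2", "amp_ratio"]
    valid = sw["valid"].to_numpy(dtype=bool)
    agg = {}
    for c in cols:
        v = sw[c].to_numpy(dtype=float).copy()
        v[~valid] = np.nan
        s = pd.Series(v).groupby(minute.to_numpy()).mean()
        full = np.full(n_min, np.nan)
        full[s.index.to_numpy()] = s.to_numpy()
        agg[c] = full

    out = pd.DataFrame({
        "minute": np.arange(n_min),
        "timestamp_s": start0 + (np.arange(n_min) + 1) * 60.0,
        "mean_icp": agg["mean_icp"],
        "mean_abp": agg["mean_abp"],
        "cpp": agg["mean_abp"] - agg["mean_icp"],
        "amp": agg["amp"],
        "aabp": agg["aabp"],
        "amp_ratio": agg["amp_ratio"],
        "heart_rate": agg["heart_rate"],
        "pbto2": agg["mean_pbto2"],
    })

    out["prx"] = np.nan
    out["rap"] = np.nan
    w, st = config.corr_window_samples, config.corr_step_samples
    ends, prx = compute_prx(sw, w, st)
    _, rap = compute_rap(sw, w, st)
    # map correlation-window end indices to the minute whose end they coincide with
    at_minute = ends // per_min - 1
    sel = (ends % per_min == 0) & (at_minute >= 0) & (at_minute < n_min)
    out.loc[at_minute[sel], "prx"] = prx[sel]
    out.loc[at_minute[sel], "rap"] = rap[sel]
    return out
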