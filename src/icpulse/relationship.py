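"""Per-patient AMP-ICP phenotyping and binned-LOWESS relationship curves.

The minute-by-minute relationship between mean ICP and ICP pulse amplitude
is fitted per patient with a penalized cubic regression spline whose basis
dimension (5) allows three monotonicity segments — flat at low ICP, a steep
rising segment, and a possible terminal decline ("upper breakpoint",
the switch from a positive to a negative AMP-ICP relationship attributed to
critical cerebrovascular collapse). The fitted derivative is segmented into
one of four patterns: upper_breakpoint, rightward_deflection,
monotonic_increase, monotonic_decrease.

Aggregate curves of any index against ICP or CPP are built by first
averaging each patient's minutes in 10 mm Hg bins (so long recordings do not
dominate) and then LOWESS-smoothing the pooled bin means, with a
patient-level bootstrap confidence band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.gam.api import BSplines
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

PATTERNS = ("upper_breakpoint", "rightward_deflection",
            "monotonic_increase", "monotonic_decrease")


def bin_patient_means(x: np.ndarray, values: np.ndarray,
                      bin_width: float = 10.0, min_count: int = 5,
                      patient_id: str | None = None) -> pd.DataFrame:
    """Per-bin means of ``values`` over half-open bins of ``x`` anchored at 0.

    Bins are [0,10), [10,20), ...; bins with fewer than ``min_count``
    contributing minutes are omitted. Minutes where either coordinate is
    missing contribute nowhere.
    """
    x = np.asarray(x, dtype=float)
    values = np.asarray(values, dtype=float)
    good = np.isfinite(x) & np.isfinite(values)
    if not good.any():
        return pd.DataFrame(columns=["patient", "bin_left", "bin_mid", "mean", "count"])
    left = np.floor(x[good] / bin_width) * bin_width
    df = pd.DataFrame({"bin_left": left, "value": values[good]})
    g = df.groupby("bin_left")["value"].agg(["mean", "count"]).reset_index()
    g = g[g["count"] >= min_count].reset_index(drop=True)
    g["bin_mid"] = g["bin_left"] + bin_width / 2
    g.insert(0, "patient", patient_id)
    return g[["patient", "bin_left", "bin_mid", "mean", "count"]]


def lowess_curve(points: pd.DataFrame, frac: float = 0.5,
                 grid: np.ndarray | None = None, n_boot: int = 500,
                 seed: int = 0, ci: float = 0.95) -> pd.DataFrame:
    """LOWESS through pooled per-patient bin means with a bootstrap band.

    ``points`` needs columns patient, bin_mid, mean. The 95% (by default)
    pointwise band resamples *patients* with replacement, refits, and takes
    percentiles — so between-patient heterogeneity, not minute noise, drives
    the band width. Requires at least 10 points.

    The default span of 0.5 reflects the binned input: with 10 mm Hg bins
    there are only ~8-15 distinct midpoints over a physiological ICP range,
    and a wider span averages over most of the range, flattening exactly the
    local features (e.g. an upper breakpoint) the curve is meant to show.
    """
    req = {"patient", "bin_mid", "mean"}
    if not req <= set(points.columns):
        raise ValueError(f"points needs columns {sorted(req)}")
    if len(points) < 10:
        raise ValueError("fewer than 10 binned points; pool more patients "
                         "or widen the bins before smoothing")
    x = points["bin_mid"].to_numpy(dtype=float)
    y = points["mean"].to_numpy(dtype=float)
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 50)
    fit = sm_lowess(y, x, frac=frac, xvals=grid)

    rng = np.random.default_rng(seed)
    ids = points["patient"].unique()
    boots = np.full((n_boot, len(grid)), np.nan)
    by_patient = {p: g for p, g in points.groupby("patient")}
    for b in range(n_boot):
        sample = rng.choice(ids, size=len(ids), replace=True)
        rep = pd.concat([by_patient[p] for p in sample], ignore_index=True)
        xb = rep["bin_mid"].to_numpy(dtype=float)
        yb = rep["mean"].to_numpy(dtype=float)
        if len(np.unique(xb)) < 2:
            continue
        boots[b] = sm_lowess(yb, xb, frac=frac, xvals=grid)
    alpha = (1 - ci) / 2
    with np.errstate(invalid="ignore"):
        lo = np.nanpercentile(boots, 100 * alpha, axis=0)
        hi = np.nanpercentile(boots, 100 * (1 - alpha), axis=0)
    return pd.DataFrame({"grid": grid, "fit": fit, "lo": lo, "hi": hi})


# ----------------------------------------------------------------------
# AMP-ICP spline fit and pattern classification
# ----------------------------------------------------------------------

@dataclass
class AmpIcpFit:
    """Fitted AMP(ICP) curve on a 1 mm Hg grid spanning the observed range."""

    grid: np.ndarray
    fitted: np.ndarray
    derivative: np.ndarray
    alpha: float            # GCV-selected smoothing weight
    ok: bool = True
    reason: str | None = None


def _gcv_alpha(y: np.ndarray, basis: np.ndarray, penalty: np.ndarray,
               alphas: np.ndarray) -> float:
    """Generalized cross-validation over a penalty-weight grid for the
    penalized least-squares spline (Gaussian, identity link)."""
    n = len(y)
    xtx = basis.T @ basis
    xty = basis.T @ y
    best_alpha, best_gcv = float(alphas[0]), np.inf
    for a in alphas:
        m = xtx + a * penalty
        try:
            minv = np.linalg.inv(m)
        except np.linalg.LinAlgError:
            continue
        beta = minv @ xty
        edf = float(np.trace(minv @ xtx))
        resid = y - basis @ beta
        denom = max(n - edf, 1e-8)
        gcv = n * float(resid @ resid) / denom ** 2
        if gcv < best_gcv:
            best_gcv, best_alpha = gcv, float(a)
    return best_alpha


def fit_amp_icp_curve(mean_icp: np.ndarray, amp: np.ndarray,
                      spline_df: int = 5, grid_step: float = 1.0,
                      min_minutes: int = 60, min_span: float = 20.0,
                      alphas: np.ndarray | None = None) -> AmpIcpFit:
    """Penalized cubic regression spline of AMP on mean ICP.

    Basis dimension ``spline_df`` (default 5 — enough flexibility for three
    monotonicity segments), smoothing weight by GCV, coefficients by the
    Gaussian penalized-least-squares solve (the GAM normal equations).
    Returns the fitted values and first derivative on a ``grid_step``
    grid over the observed ICP range. Fits with fewer than ``min_minutes``
    valid minutes or an ICP span under ``min_span`` mm Hg are reported as
    not-ok (pattern "indeterminate" downstream).
    """
    icp = np.asarray(mean_icp, dtype=float)
    amp = np.asarray(amp, dtype=float)
    good = np.isfinite(icp) & np.isfinite(amp)
    icp, amp = icp[good], amp[good]
    empty = np.empty(0)
    if len(icp) < min_minutes:
        return AmpIcpFit(empty, empty, empty, np.nan, ok=False,
                         reason="insufficient_data")
    span = icp.max() - icp.min()
    if span < min_span:
        return AmpIcpFit(empty, empty, empty, np.nan, ok=False,
                         reason="insufficient_span")

    order = np.argsort(icp)
    icp, amp = icp[order], amp[order]
    bs = BSplines(icp[:, None], df=[spline_df], degree=[3],
                  include_intercept=True)
    if alphas is None:
        alphas = np.logspace(-2, 5, 12)
    basis, penalty = bs.basis, bs.penalty_matrices[0]
    alpha = _gcv_alpha(amp, basis, penalty, np.asarray(alphas))
    beta = np.linalg.solve(basis.T @ basis + alpha * penalty, basis.T @ amp)
    grid = np.arange(icp.min(), icp.max() + grid_step / 2, grid_step)
    grid = np.clip(grid, icp.min(), icp.max())
    fitted = bs.transform(grid[:, None]) @ beta
    deriv = np.gradient(fitted, grid)
    return AmpIcpFit(grid=grid, fitted=fitted, derivative=deriv, alpha=alpha)


def _runs(state: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encode a sign sequence into (value, start, stop) spans."""
    out = []
    i = 0
    while i < len(state):
        j = i
        while j < len(state) and state[j] == state[i]:
            j += 1
        out.append((int(state[i]), i, j))
        i = j
    return out


def classify_pattern(fit: AmpIcpFit, eps: float = 0.01,
                     ub_min_frac: float = 0.10,
                     plateau_min_frac: float = 0.20) -> tuple[str, float | None]:
    """Label the fitted AMP-ICP curve by its derivative-sign segments.

    With a dead band ``eps`` (mm Hg AMP per mm Hg ICP): derivative >= +eps
    throughout -> monotonic_increase; <= -eps throughout ->
    monotonic_decrease; a positive segment followed by a terminal negative
    segment covering at least ``ub_min_frac`` of the ICP range ->
    upper_breakpoint (breakpoint = the derivative zero-crossing); a net-rising
    curve whose terminal low-slope plateau covers at least
    ``plateau_min_frac`` of the range -> rightward_deflection; otherwise the
    closest case by positive/negative derivative areas. Returns
    ``(label, breakpoint_icp_or_None)``; a failed fit yields "indeterminate".
    """
    if not fit.ok or len(fit.grid) < 3:
        return "indeterminate", None
    d, g = fit.derivative, fit.grid
    span = g[-1] - g[0]
    if span <= 0:
        return "indeterminate", None
    if np.all(d >= eps):
        return "monotonic_increase", None
    if np.all(d <= -eps):
        return "monotonic_decrease", None

    state = np.where(d > eps, 1, np.where(d < -eps, -1, 0))
    runs = _runs(state)
    last_val, last_i, last_j = runs[-1]
    tail_frac = (g[last_j - 1] - g[last_i]) / span
    had_positive_before = any(v == 1 for v, _, j in runs[:-1])

    if last_val == -1 and had_positive_before and tail_frac >= ub_min_frac:
        # zero-crossing of the derivative entering the terminal decline
        k = last_i
        while k > 0 and d[k - 1] <= 0:
            k -= 1
        if k == 0:
            bp = float(g[last_i])
        else:
            d0, d1 = d[k - 1], d[k]
            w = d0 / (d0 - d1) if d0 != d1 else 0.5
            bp = float(g[k - 1] + w * (g[k] - g[k - 1]))
        return "upper_breakpoint", bp

    net_rise = fit.fitted[-1] > fit.fitted[0]
    if last_val == 0 and net_rise and tail_frac >= plateau_min_frac:
        return "rightward_deflection", None

    # fallback — closest case by segment areas: the mean derivative over the
    # upper quarter of the ICP range decides how the curve ends (the df-5
    # spline smears sharp plateau/collapse onsets, so exact run boundaries
    # are unreliable on borderline curves)
    pos_area = float(np.trapezoid(np.clip(d, 0, None), g))
    neg_area = float(np.trapezoid(np.clip(-d, 0, None), g))
    if net_rise:
        tail = g >= g[-1] - 0.25 * span
        mean_tail = float(d[tail].mean())
        if mean_tail <= -eps and (d[~tail] > eps).any():
            k = int(np.flatnonzero(tail)[0])
            while k < len(d) and d[k] > 0:
                k += 1
            bp = float(g[min(k, len(g) - 1)])
            return "upper_breakpoint", bp
        if mean_tail < eps:
            return "rightward_deflection", None
        return "monotonic_increase", None
    if neg_area > pos_area:
        return "monotonic_decrease", None
    return "monotonic_increase", None


def phenotype_patient(mean_icp: np.ndarray, amp: np.ndarray,
                      spline_df: int = 5, eps: float = 0.01,
                      **fit_kwargs) -> tuple[str, float | None, AmpIcpFit]:
    """Fit and classify in one call; returns (label, breakpoint, fit)."""
    fit = fit_amp_icp_curve(mean_icp, amp, spline_df=spline_df, **fit_kwargs)
    label, bp = classify_pattern(fit, eps=eps)
    return label, bp, fit
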