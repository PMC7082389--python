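"""Episode selection and matched case-control construction.

Refractory intracranial hypertension is defined as an initial ICP below
25 mm Hg followed by a sustained rise above 40 mm Hg for at least an hour,
in a recording spanning at least 12 h of ICP/ABP monitoring. Cases are
compared to controls matched exactly on sex and by nearest Mahalanobis
distance on (age, admission GCS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class EpisodeResult:
    """Outcome of episode detection on one minute-resolution ICP series.

    ``status`` is one of ``"episode"`` (bounds set, half-open minutes),
    ``"no_episode"`` or ``"too_short"``; ``reason`` is a machine-readable
    code for rejections.
    """

    status: str
    start_min: int | None = None
    end_min: int | None = None
    reason: str | None = None

    @property
    def found(self) -> bool:
        return self.status == "episode"


def detect_refractory_episode(icp_minutes: np.ndarray,
                              high_icp: float = 40.0,
                              min_minutes: int = 60,
                              low_icp: float = 25.0,
                              min_hours: float = 12.0,
                              initial_rule: str = "any_minute") -> EpisodeResult:
    """First sustained run of ICP above ``high_icp`` preceded by low ICP.

    A qualifying run is >= ``min_minutes`` *contiguous* valid minutes with
    ICP strictly above ``high_icp`` (a missing minute breaks contiguity —
    sustained elevation cannot be asserted across a gap). The initial-ICP
    precondition is, under the default ``"any_minute"`` rule, at least one
    valid minute below ``low_icp`` strictly before the run; under
    ``"first_hour_median"``, a first-hour median below ``low_icp``.
    """
    icp = np.asarray(icp_minutes, dtype=float)
    if len(icp) < min_hours * 60:
        return EpisodeResult("too_short", reason="series_shorter_than_12h")

    finite = np.isfinite(icp)
    if initial_rule == "any_minute":
        low_idx = np.flatnonzero(finite & (icp < low_icp))
        first_low = int(low_idx[0]) if len(low_idx) else None
    elif initial_rule == "first_hour_median":
        first_hour = icp[:60][finite[:60]]
        ok = len(first_hour) > 0 and float(np.median(first_hour)) < low_icp
        first_low = -1 if ok else None
    else:
        raise ValueError(f"unknown initial_rule {initial_rule!r}")
    if first_low is None:
        return EpisodeResult("no_episode", reason="no_initial_low_icp")

    above = finite & (icp > high_icp)
    i = 0
    n = len(icp)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        if j - i >= min_minutes and i > first_low:
            return EpisodeResult("episode", start_min=i, end_min=j)
        i = j
    return EpisodeResult("no_episode", reason="no_sustained_high_icp_run")


def first_hours_mean(minute_values: np.ndarray, hours: float = 5.0) -> float:
    """Mean of the valid minutes in the first ``hours`` of monitoring."""
    v = np.asarray(minute_values, dtype=float)[: int(round(hours * 60))]
    good = np.isfinite(v)
    if not good.any():
        return float("nan")
    return float(v[good].mean())


# ----------------------------------------------------------------------
# case-control matching
# ----------------------------------------------------------------------

def _covariate_inverse_cov(table: pd.DataFrame) -> np.ndarray:
    """Inverse covariance of (age, gcs) over everyone, for Mahalanobis
    distance; degenerate (constant) covariates fall back to unit variance."""
    z = table[["age", "gcs"]].to_numpy(dtype=float)
    cov = np.cov(z, rowvar=False)
    cov = np.atleast_2d(cov)
    d = np.diag(cov).copy()
    d[d <= 0] = 1.0
    if np.linalg.matrix_rank(cov) < 2:
        cov = np.diag(d)
    return np.linalg.pinv(cov)


def match_controls(cases: pd.DataFrame, pool: pd.DataFrame,
                   seed: int = 0) -> tuple[pd.DataFrame, list]:
    """1:1 nearest-neighbour matching without replacement.

    Exact on sex, then minimal Mahalanobis distance on (age, GCS); cases are
    visited in a seeded random order and each control is used at most once.
    Returns ``(pairs, unmatched)``: pairs has columns case_id, control_id,
    distance; unmatched lists case ids with no same-sex control left.
    Both inputs need columns id, age, sex, gcs and must be disjoint.
    """
    for name, df in (("cases", cases), ("pool", pool)):
        missing = {"id", "age", "sex", "gcs"} - set(df.columns)
        if missing:
            raise ValueError(f"{name} table lacks columns {sorted(missing)}")
    if set(cases["id"]) & set(pool["id"]):
        raise ValueError("cases and pool must be disjoint")

    vi = _covariate_inverse_cov(pd.concat([cases, pool], ignore_index=True))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cases))
    available = pool.reset_index(drop=True).copy()
    taken = np.zeros(len(available), dtype=bool)

    rows, unmatched = [], []
    cz = cases[["age", "gcs"]].to_numpy(dtype=float)
    pz = available[["age", "gcs"]].to_numpy(dtype=float)
    for i in order:
        same_sex = (available["sex"].to_numpy() == cases["sex"].iloc[i]) & ~taken
        cand = np.flatnonzero(same_sex)
        if len(cand) == 0:
            unmatched.append(cases["id"].iloc[i])
            continue
        diff = pz[cand] - cz[i]
        dist = np.sqrt(np.einsum("ij,jk,ik->i", diff, vi, diff))
        # ties broken by control id for determinism
        best = cand[np.lexsort((available["id"].to_numpy()[cand], dist))[0]]
        taken[best] = True
        rows.append({"case_id": cases["id"].iloc[i],
                     "control_id": available["id"].iloc[best],
                     "distance": float(dist[np.flatnonzero(cand == best)[0]])})
    pairs = pd.DataFrame(rows, columns=["case_id", "control_id", "distance"])
    return pairs, unmatched
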