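"""ICP-level group statistics and the case-control early-PRx comparison.

Minutes are assigned to three severity levels of mean ICP — base [0, 25),
elevated [25, 50), severe [50, 150] mm Hg — and every variable is first
averaged *within* patient at each level (a patient contributes only with at
least 30 valid minutes there), so each patient counts once per cell
regardless of recording length. Cells are across-patient mean (sd, n);
adjacent levels are compared with Welch's t test, uncorrected for
multiplicity. The case-control comparison applies the Wilcoxon rank-sum
test to first-5-h means of PRx and ICP between matched groups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import first_hours_mean

LEVELS = ("base", "elevated", "severe")
LEVEL_EDGES = (0.0, 25.0, 50.0, 150.0)

#: variables summarized in the group table, keyed by IndexSeries column
GROUP_VARIABLES = {
    "ICP": "mean_icp",
    "AMP": "amp",
    "AMP/aABP": "amp_ratio",
    "CPP": "cpp",
    "MAP": "mean_abp",
    "aABP": "aabp",
    "HR": "heart_rate",
    "PRx": "prx",
    "RAP": "rap",
    "PbtO2": "pbto2",
}


def assign_icp_level(mean_icp, edges: tuple = LEVEL_EDGES):
    """Severity level of a minute mean ICP; None outside [0, 150] mm Hg.

    Lower-closed convention: 25 -> elevated, 50 -> severe. Vectorized input
    returns an object array with None for excluded minutes.
    """
    icp = np.asarray(mean_icp, dtype=float)
    scalar = icp.ndim == 0
    icp = np.atleast_1d(icp)
    out = np.full(icp.shape, None, dtype=object)
    ok = np.isfinite(icp) & (icp >= edges[0]) & (icp <= edges[3])
    out[ok & (icp < edges[1])] = "base"
    out[ok & (icp >= edges[1]) & (icp < edges[2])] = "elevated"
    out[ok & (icp >= edges[2])] = "severe"
    return out[0] if scalar else out


def patient_level_means(series: pd.DataFrame, variables: dict[str, str] | None = None,
                        min_minutes: int = 30,
                        edges: tuple = LEVEL_EDGES) -> pd.DataFrame:
    """Per-level means of each variable for one patient's minute table.

    Rows: (level, variable, mean, n_minutes); levels with fewer than
    ``min_minutes`` valid minutes of a variable are omitted for it.
    """
    variables = variables or GROUP_VARIABLES
    levels = assign_icp_level(series["mean_icp"].to_numpy(), edges)
    rows = []
    for level in LEVELS:
        in_level = levels == level
        for name, col in variables.items():
            if col not in series.columns:
                continue
            v = series[col].to_numpy(dtype=float)[in_level]
            v = v[np.isfinite(v)]
            if len(v) >= min_minutes:
                rows.append({"level": level, "variable": name,
                             "mean": float(v.mean()), "n_minutes": len(v)})
    return pd.DataFrame(rows, columns=["level", "variable", "mean", "n_minutes"])


def pairwise_ttest(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch t test between two sets of per-patient means."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        return float("nan")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # degenerate: with no within-group variability the t statistic is
        # undefined, so no evidence can be quantified
        return 1.0
    return float(sps.ttest_ind(a, b, equal_var=False).pvalue)


def rank_sum_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null distribution when both groups have <= 25 values and no ties;
    normal approximation with continuity correction otherwise. All values
    tied -> p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        return float("nan")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    if len(a) == len(b) and np.array_equal(np.sort(a), np.sort(b)):
        # identical samples: no evidence of any difference by construction
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(a), len(b)) <= 25 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def group_summary(patient_series: dict[str, pd.DataFrame],
                  variables: dict[str, str] | None = None,
                  min_minutes: int = 30,
                  edges: tuple = LEVEL_EDGES) -> pd.DataFrame:
    """The three-level group table: mean (sd, n) per variable x level plus
    Welch p-values for elevated-vs-base and severe-vs-elevated."""
    variables = variables or GROUP_VARIABLES
    frames = []
    for pid, series in patient_series.items():
        pm = patient_level_means(series, variables, min_minutes, edges)
        pm.insert(0, "patient", pid)
        frames.append(pm)
    if not frames:
        raise ValueError("no patient series supplied")
    nonempty = [f for f in frames if len(f)]
    if not nonempty:
        raise ValueError("no patient reaches the per-level minute minimum")
    long = pd.concat(nonempty, ignore_index=True)

    rows = []
    for name in variables:
        row: dict = {"variable": name}
        per_level = {}
        for level in LEVELS:
            v = long.loc[(long["variable"] == name) & (long["level"] == level),
                         "mean"].to_numpy(dtype=float)
            per_level[level] = v
            row[f"mean_{level}"] = float(v.mean()) if len(v) else float("nan")
            row[f"sd_{level}"] = float(v.std(ddof=1)) if len(v) > 1 else float("nan")
            row[f"n_{level}"] = len(v)
        row["p_elevated_vs_base"] = pairwise_ttest(per_level["base"],
                                                   per_level["elevated"])
        row["p_severe_vs_elevated"] = pairwise_ttest(per_level["elevated"],
                                                     per_level["severe"])
        rows.append(row)
    return pd.DataFrame(rows)


def format_group_summary(table: pd.DataFrame) -> str:
    """Aligned plain-text rendering of the group table (variable rows,
    three level columns as mean (sd), two p-value columns)."""
    headers = ["Variable", "0-25 mm Hg", "25-50 mm Hg", "50-150 mm Hg",
               "p (elev vs base)", "p (sev vs elev)"]
    lines = []
    for _, r in table.iterrows():
        cells = [str(r["variable"])]
        for level in LEVELS:
            m, s, n = r[f"mean_{level}"], r[f"sd_{level}"], r[f"n_{level}"]
            cells.append("-" if n == 0 else f"{m:.2f} ({s:.2f}; n={n})")
        for p in (r["p_elevated_vs_base"], r["p_severe_vs_elevated"]):
            cells.append("-" if not np.isfinite(p)
                         else ("<0.001" if p < 0.001 else f"{p:.3f}"))
        lines.append(cells)
    widths = [max(len(h), *(len(row[i]) for row in lines)) if lines else len(h)
              for i, h in enumerate(headers)]
    fmt = "  ".join(f"{{:<{w}}}" for w in widths)
    out = [fmt.format(*headers)]
    out += [fmt.format(*row) for row in lines]
    return "\n".join(out)


def case_control_compare(case_series: dict[str, pd.DataFrame],
                         control_series: dict[str, pd.DataFrame],
                         pairs: pd.DataFrame | None = None,
                         hours: float = 5.0) -> dict[str, float]:
    """Rank-sum comparison of first-``hours`` mean PRx and mean ICP between
    cases and matched controls.

    If ``pairs`` (case_id, control_id) is given, only the paired patients
    enter; the test itself is unpaired (independent groups). Requires at
    least 5 pairs/patients per group with valid first-hours means.
    """
    if pairs is not None:
        case_series = {k: case_series[k] for k in pairs["case_id"] if k in case_series}
        control_series = {k: control_series[k] for k in pairs["control_id"]
                          if k in control_series}

    def _means(series: dict[str, pd.DataFrame], col: str) -> np.ndarray:
        vals = [first_hours_mean(s[col].to_numpy(dtype=float), hours)
                for s in series.values()]
        return np.array([v for v in vals if np.isfinite(v)])

    prx_cases, prx_controls = _means(case_series, "prx"), _means(control_series, "prx")
    icp_cases, icp_controls = _means(case_series, "mean_icp"), _means(control_series, "mean_icp")
    if min(len(prx_cases), len(prx_controls)) < 5:
        raise ValueError("need at least 5 cases and 5 controls with valid "
                         "first-hours PRx means")
    return {
        "prx_p": rank_sum_test(prx_cases, prx_controls),
        "icp_p": rank_sum_test(icp_cases, icp_controls),
        "n_cases": int(len(prx_cases)),
        "n_controls": int(len(prx_controls)),
    }
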