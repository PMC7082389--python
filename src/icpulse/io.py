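"""CSV interchange formats and the end-to-end pipeline driver.

Recordings travel as CSV with a ``time_s`` column plus channel columns
(``abp_mmhg``, ``icp_mmhg``, optionally ``pbto2_mmhg``); window summaries,
index series and every report are CSV as well. ``run_pipeline`` chains all
stages — summarize, derive indices, detect episodes, phenotype, aggregate
curves, group statistics, case-control comparison — deterministically under
the configured seed, and writes a run log with the configuration hash.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import detect_refractory_episode, match_controls
from .config import FormatError, PipelineConfig
from .indices import compute_indices
from .preprocess import WaveformRecording, summarize_recording
from .relationship import bin_patient_means, lowess_curve, phenotype_patient
from .stats import case_control_compare, format_group_summary, group_summary

_CHANNEL_COLUMNS = {"abp_mmhg": "ABP", "icp_mmhg": "ICP", "pbto2_mmhg": "PBTO2"}


def write_recording(path: str | Path,
                    recordings: dict[str, WaveformRecording]) -> None:
    """Write a recording set as CSV (time_s plus one column per channel)."""
    ref = recordings.get("ABP") or next(iter(recordings.values()))
    t = ref.time_axis()
    data = {"time_s": t}
    for col, chan in _CHANNEL_COLUMNS.items():
        if chan in recordings:
            s = recordings[chan].samples
            data[col] = s[: len(t)] if len(s) >= len(t) else np.pad(
                s, (0, len(t) - len(s)), constant_values=np.nan)
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6f")


def read_recording(path: str | Path,
                   expected_rate: float | None = None
                   ) -> dict[str, WaveformRecording]:
    """Read a recording CSV back into uniformly gridded channels.

    Rows are sorted by time; the sampling rate is inferred from the median
    timestamp increment (and checked against ``expected_rate`` if given).
    Gaps become NaN stretches on the uniform grid; a timestamp further than
    one sample interval from its grid slot is a format error reported with
    its line number. Unknown columns are ignored with a warning.
    """
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise FormatError(f"{path}: missing required column time_s")
    known = {"time_s", *_CHANNEL_COLUMNS}
    for col in df.columns:
        if col not in known:
            warnings.warn(f"{path}: ignoring unknown channel column {col!r}")
    df = df.sort_values("time_s", kind="mergesort").reset_index(drop=True)
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    dt = float(np.median(np.diff(t)))
    if dt <= 0:
        raise FormatError(f"{path}: non-increasing timestamps")
    rate = 1.0 / dt
    if expected_rate is not None and abs(rate - expected_rate) > 0.01 * expected_rate:
        raise FormatError(f"{path}: inferred rate {rate:.3f} Hz does not match "
                          f"configured {expected_rate} Hz")
    t0 = t[0]
    idx = np.round((t - t0) / dt).astype(int)
    resid = np.abs(t - (t0 + idx * dt))
    # off-grid beyond a quarter sample, or two samples claiming one grid
    # slot, means the file is not uniformly sampled
    bad = np.flatnonzero(resid > 0.25 * dt)
    if len(bad):
        raise FormatError(f"{path}: non-uniform timestamp at line {bad[0] + 2} "
                          f"(t={t[bad[0]]!r})")
    dup = np.flatnonzero(np.diff(idx) == 0)
    if len(dup):
        raise FormatError(f"{path}: non-uniform timestamps: line {dup[0] + 3} "
                          f"duplicates the sample slot of its predecessor")
    n = idx[-1] + 1
    out: dict[str, WaveformRecording] = {}
    for col, chan in _CHANNEL_COLUMNS.items():
        if col not in df.columns:
            continue
        grid = np.full(n, np.nan)
        grid[idx] = df[col].to_numpy(dtype=float)
        out[chan] = WaveformRecording(chan, rate, grid, start_time=t0)
    if not out:
        raise FormatError(f"{path}: no recognized channel columns")
    return out


def write_sidecar(path: str | Path, truth, metadata: dict) -> None:
    """Ground truth + patient metadata as a JSON sidecar."""
    payload = {
        "metadata": metadata,
        "ground_truth": {
            "phenotype": truth.phenotype,
            "breakpoint_icp": truth.breakpoint_icp,
            "coupling_per_minute": np.asarray(truth.coupling_per_minute).tolist(),
            "icp_per_minute": np.asarray(truth.icp_per_minute).tolist(),
            "pbto2_baseline": truth.pbto2_baseline,
            "pbto2_knee_cpp": truth.pbto2_knee_cpp,
            "pbto2_slope": truth.pbto2_slope,
        },
    }
    Path(path).write_text(json.dumps(payload))


# ----------------------------------------------------------------------
# pipeline driver
# ----------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, input_dir: str | Path,
                 out_dir: str | Path) -> dict:
    """Run every analysis stage over a directory of recordings.

    ``input_dir`` holds one ``<id>.csv`` recording per patient and a
    ``metadata.csv`` (columns id, age, sex, gcs). Emits, under ``out_dir``:
    windows/, indices/, episodes.csv, phenotypes.csv, curve_amp_icp.csv,
    group_summary.csv/.txt, case_control.json (when enough matched cases
    exist) and run_log.json. Returns a stage-by-stage summary dict.
    """
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    rec_paths = sorted(p for p in input_dir.glob("*.csv")
                       if p.name != "metadata.csv")
    if not rec_paths:
        raise FormatError(f"{input_dir}: no recording CSVs found "
                          "(expected <id>.csv files)")
    meta_path = input_dir / "metadata.csv"
    metadata = pd.read_csv(meta_path) if meta_path.exists() else None

    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "windows").mkdir(exist_ok=True)
    (out_dir / "indices").mkdir(exist_ok=True)

    series: dict[str, pd.DataFrame] = {}
    episode_rows, phen_rows = [], []
    for p in rec_paths:
        pid = p.stem
        recs = read_recording(p)
        if "ABP" not in recs or "ICP" not in recs:
            raise FormatError(f"{p}: recording lacks ABP or ICP channel")
        summ = summarize_recording(recs["ABP"], recs["ICP"], recs.get("PBTO2"),
                                   window_seconds=config.window_seconds,
                                   band_cpm=config.cardiac_band_cpm,
                                   validity=config.validity)
        summ.to_csv(out_dir / "windows" / f"{pid}.csv", index=False)
        idx = compute_indices(summ, config)
        idx.to_csv(out_dir / "indices" / f"{pid}.csv", index=False)
        series[pid] = idx

        ep = detect_refractory_episode(
            idx["mean_icp"].to_numpy(), high_icp=config.episode_high_icp,
            min_minutes=config.episode_min_minutes, low_icp=config.episode_low_icp,
            min_hours=config.episode_min_hours,
            initial_rule=config.episode_initial_rule)
        episode_rows.append({"id": pid, "status": ep.status,
                             "start_min": ep.start_min, "end_min": ep.end_min,
                             "reason": ep.reason})

        label, bp, _fit = phenotype_patient(
            idx["mean_icp"].to_numpy(), idx["amp"].to_numpy(),
            spline_df=config.spline_df, eps=config.classify_eps)
        phen_rows.append({"id": pid, "pattern": label, "breakpoint_icp": bp})

    episodes = pd.DataFrame(episode_rows)
    episodes.to_csv(out_dir / "episodes.csv", index=False)
    phenotypes = pd.DataFrame(phen_rows)
    phenotypes.to_csv(out_dir / "phenotypes.csv", index=False)

    # pooled AMP-ICP relationship curve
    binned = pd.concat(
        [bin_patient_means(s["mean_icp"].to_numpy(), s["amp"].to_numpy(),
                           bin_width=config.bin_width_mmhg,
                           min_count=config.min_bin_minutes, patient_id=pid)
         for pid, s in series.items()], ignore_index=True)
    curve_info: dict = {"n_points": int(len(binned))}
    if len(binned) >= 10:
        curve = lowess_curve(binned, frac=config.lowess_frac,
                             n_boot=config.bootstrap_replicates, seed=config.seed)
        curve.to_csv(out_dir / "curve_amp_icp.csv", index=False)
        curve_info["written"] = True
    else:
        curve_info["written"] = False

    table = group_summary(series, min_minutes=config.min_level_minutes)
    table.to_csv(out_dir / "group_summary.csv", index=False)
    (out_dir / "group_summary.txt").write_text(format_group_summary(table) + "\n")

    cc_result: dict | None = None
    if metadata is not None:
        case_ids = set(episodes.loc[episodes["status"] == "episode", "id"])
        cases = metadata[metadata["id"].isin(case_ids)]
        pool = metadata[~metadata["id"].isin(case_ids)]
        if len(cases) >= 5 and len(pool) >= 5:
            pairs, unmatched = match_controls(cases, pool, seed=config.seed)
            if len(pairs) >= 5:
                cc_result = case_control_compare(series, series, pairs,
                                                 hours=config.first_hours)
                cc_result["unmatched_cases"] = list(unmatched)
                (out_dir / "case_control.json").write_text(json.dumps(cc_result))

    log = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "n_patients": len(rec_paths),
        "n_episodes": int((episodes["status"] == "episode").sum()),
        "phenotype_counts": phenotypes["pattern"].value_counts().to_dict(),
        "curve": curve_info,
        "case_control": cc_result,
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, default=str))
    return log
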