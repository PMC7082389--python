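"""Seeded synthetic cerebrovascular waveform generator.

Real multimodal neuromonitoring recordings of refractory intracranial
hypertension are not publicly available, so this module generates ABP/ICP
(and optionally PbtO2) recordings with *known* ground truth for everything
the analysis estimates:

* ABP = mean level + band-limited slow (vasogenic) waves + a cardiac pulse
  (fundamental plus harmonics at the instantaneous heart rate) + white noise.
* ICP mean level follows a piecewise-linear trajectory; its slow-wave
  component shares the ABP slow waves with a signed mixing coefficient so the
  correlation of 10-s means — the quantity PRx estimates — is controlled
  directly: coupling -1..+1 maps intact to impaired cerebrovascular
  reactivity.
* The ICP cardiac pulse amplitude follows an exponential pressure-volume
  (elastance) law A(p) = a0 * exp(k * (p - p_ref)) of the mean ICP p, with
  two optional high-ICP regimes: a plateau (amplitude stops growing once CPP
  falls below ``amp_plateau_cpp``; the "rightward deflection" phenotype) and
  a collapse (amplitude declines linearly once CPP falls below
  ``collapse_threshold``; the "upper breakpoint" phenotype attributed to
  critical cerebrovascular collapse).
* PbtO2 is flat at a baseline for CPP >= 70 mm Hg and falls ~0.5 mm Hg per
  mm Hg of further CPP decrease, floored at zero.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import ConfigurationError
from .preprocess import WaveformRecording

PHENOTYPES = ("upper_breakpoint", "rightward_deflection",
              "monotonic_increase", "monotonic_decrease")

#: Phenotype proportions of the refractory-hypertension cohort this package
#: emulates: 6 upper-breakpoint, 13 rightward-deflection, 12 monotonic
#: increase and 2 monotonic decrease out of 33.
DEFAULT_PHENOTYPE_MIX = {
    "upper_breakpoint": 6 / 33,
    "rightward_deflection": 13 / 33,
    "monotonic_increase": 12 / 33,
    "monotonic_decrease": 2 / 33,
}

Trajectory = float | Sequence[tuple[float, float]]


def _as_trajectory(value: Trajectory, duration: float) -> np.ndarray:
    """Normalize a constant or piecewise-linear (time, value) input to knots."""
    if np.isscalar(value):
        return np.array([[0.0, float(value)], [duration, float(value)]])
    arr = np.asarray(value, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ConfigurationError("trajectory must be a scalar or (time, value) pairs")
    return arr


def _sample_trajectory(value: Trajectory, duration: float, t: np.ndarray) -> np.ndarray:
    knots = _as_trajectory(value, duration)
    return np.interp(t, knots[:, 0], knots[:, 1])


@dataclass
class SimConfig:
    """Parameters of one synthetic patient recording.

    Pressures in mm Hg, rates in Hz, heart rate in cycles/min, the elastance
    coefficient in 1/mm Hg (slope of log pulse amplitude vs mean ICP).
    """

    duration_s: float = 4 * 3600.0
    sampling_rate: float = 50.0
    heart_rate: Trajectory = 77.5
    map_baseline: float = 95.0
    abp_pulse_amplitude: float = 19.0     # fundamental cardiac amplitude of ABP
    abp_harmonic_ratio: float = 0.3
    slow_wave_amplitude: float = 3.0      # RMS of the ABP slow-wave component
    slow_wave_band: tuple[float, float] = (0.005, 0.05)   # Hz
    reactivity_coupling: Trajectory = -0.2
    icp_slow_amplitude: float = 1.5       # RMS of the ICP slow-wave component
    icp_trajectory: Trajectory = 12.0
    amp_baseline: float = 1.8             # a0: ICP pulse amplitude at reference ICP
    elastance_coefficient: float = 0.025  # k, 1/mm Hg
    reference_pressure: float = 17.5      # mm Hg
    collapse_threshold: float | None = None   # CPP below which AMP declines
    collapse_slope: float = 0.15          # mm Hg AMP lost per mm Hg ICP past collapse
    amp_plateau_cpp: float | None = None  # CPP below which AMP stops growing
    icp_harmonic_ratio: float = 0.25
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be positive")
        if self.sampling_rate < 50:
            raise ConfigurationError("sampling_rate must be >= 50 Hz")
        lo, hi = self.slow_wave_band
        if not (0 < lo < hi < self.sampling_rate / 2):
            raise ConfigurationError("slow_wave_band must satisfy 0 < lo < hi < Nyquist")
        hr = _as_trajectory(self.heart_rate, self.duration_s)[:, 1]
        if (hr < 40).any() or (hr > 180).any():
            raise ConfigurationError("heart_rate must stay within 40-180 cycles/min")
        c = _as_trajectory(self.reactivity_coupling, self.duration_s)[:, 1]
        if (np.abs(c) > 1).any():
            raise ConfigurationError("reactivity_coupling magnitude must be <= 1")


@dataclass
class GroundTruth:
    """What the generator actually used — the targets of parameter recovery."""

    coupling_per_minute: np.ndarray
    phenotype: str
    icp_per_minute: np.ndarray
    breakpoint_icp: float | None          # mean ICP where collapse begins
    pbto2_baseline: float
    pbto2_knee_cpp: float
    pbto2_slope: float


def _band_limited_noise(n: int, rate: float, band: tuple[float, float],
                        rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise restricted to ``band`` (FFT masking)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        raise ConfigurationError("slow_wave_band contains no resolvable frequency")
    spec[~mask] = 0.0
    x = np.fft.irfft(spec, n)
    rms = x.std()
    return x / rms if rms > 0 else x


def _streams(config: SimConfig) -> dict[str, np.random.Generator]:
    names = ("slow_shared", "slow_indep", "abp_noise", "icp_noise", "pbto2_noise")
    return {name: np.random.default_rng([config.seed, i])
            for i, name in enumerate(names)}


def _cardiac_phase(config: SimConfig, t: np.ndarray) -> np.ndarray:
    hr_hz = _sample_trajectory(config.heart_rate, config.duration_s, t) / 60.0
    return 2 * np.pi * np.cumsum(hr_hz) / config.sampling_rate


def amp_model(config: SimConfig, mean_icp: np.ndarray) -> np.ndarray:
    """ICP pulse amplitude as a function of mean ICP (exponential elastance
    with optional plateau and collapse regimes; CPP taken against the
    configured mean arterial baseline)."""
    p = np.asarray(mean_icp, dtype=float)
    a = config.amp_baseline * np.exp(
        config.elastance_coefficient * (p - config.reference_pressure))
    if config.amp_plateau_cpp is not None:
        p_plat = config.map_baseline - config.amp_plateau_cpp
        a_plat = config.amp_baseline * np.exp(
            config.elastance_coefficient * (p_plat - config.reference_pressure))
        a = np.where(p > p_plat, a_plat, a)
    if config.collapse_threshold is not None:
        p_col = config.map_baseline - config.collapse_threshold
        a_col = config.amp_baseline * np.exp(
            config.elastance_coefficient * (p_col - config.reference_pressure))
        if config.amp_plateau_cpp is not None:
            p_plat = config.map_baseline - config.amp_plateau_cpp
            if p_col > p_plat:
                a_col = config.amp_baseline * np.exp(
                    config.elastance_coefficient * (p_plat - config.reference_pressure))
        a = np.where(p > p_col,
                     np.maximum(a_col - config.collapse_slope * (p - p_col), 0.05),
                     a)
    return a


def generate_abp(config: SimConfig) -> WaveformRecording:
    """Arterial pressure: baseline + slow waves + cardiac pulse + noise."""
    n = int(round(config.duration_s * config.sampling_rate))
    t = np.arange(n) / config.sampling_rate
    rngs = _streams(config)
    phase = _cardiac_phase(config, t)
    slow = (config.slow_wave_amplitude
            * _band_limited_noise(n, config.sampling_rate, config.slow_wave_band,
                                  rngs["slow_shared"])
            if config.slow_wave_amplitude > 0 else np.zeros(n))
    pulse = (config.abp_pulse_amplitude * np.sin(phase)
             + config.abp_harmonic_ratio * config.abp_pulse_amplitude * np.sin(2 * phase))
    noise = (config.noise_sd * rngs["abp_noise"].standard_normal(n)
             if config.noise_sd > 0 else 0.0)
    return WaveformRecording("ABP", config.sampling_rate,
                             config.map_baseline + slow + pulse + noise)


def generate_icp(config: SimConfig, abp: WaveformRecording) -> WaveformRecording:
    """Intracranial pressure coupled to the ABP of the same config/seed.

    The slow-wave component mixes the shared ABP slow wave with an
    independent one so the 10-s-mean ABP/ICP correlation targets the
    configured reactivity coupling; the cardiac amplitude follows
    :func:`amp_model` of the instantaneous mean ICP.
    """
    n = int(round(config.duration_s * config.sampling_rate))
    if len(abp.samples) != n:
        raise ConfigurationError("abp was not generated from this config")
    t = np.arange(n) / config.sampling_rate
    mean_icp = _sample_trajectory(config.icp_trajectory, config.duration_s, t)
    if (mean_icp < 0).any():
        raise ConfigurationError("icp_trajectory implies negative ICP")
    rngs = _streams(config)
    phase = _cardiac_phase(config, t)
    if config.slow_wave_amplitude > 0:
        shared = _band_limited_noise(n, config.sampling_rate,
                                     config.slow_wave_band, rngs["slow_shared"])
    else:
        shared = np.zeros(n)
    indep = _band_limited_noise(n, config.sampling_rate,
                                config.slow_wave_band, rngs["slow_indep"])
    c = _sample_trajectory(config.reactivity_coupling, config.duration_s, t)
    slow = config.icp_slow_amplitude * (c * shared + np.sqrt(1 - c ** 2) * indep)
    a = amp_model(config, mean_icp)
    pulse = a * np.sin(phase + 0.3) + config.icp_harmonic_ratio * a * np.sin(2 * phase + 0.6)
    noise = (config.noise_sd * rngs["icp_noise"].standard_normal(n)
             if config.noise_sd > 0 else 0.0)
    return WaveformRecording("ICP", config.sampling_rate,
                             mean_icp + slow + pulse + noise)


def generate_pbto2(cpp_series: np.ndarray, baseline: float = 27.0,
                   knee_cpp: float = 70.0, slope: float = 0.5,
                   noise_sd: float = 0.0,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Brain tissue oxygenation from a CPP series (any time resolution).

    Plateau at ``baseline`` for CPP >= ``knee_cpp``; linear decline of
    ``slope`` mm Hg PbtO2 per mm Hg CPP below the knee; floored at 0.
    """
    cpp = np.asarray(cpp_series, dtype=float)
    p = baseline - slope * np.clip(knee_cpp - cpp, 0.0, None)
    if noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        p = p + noise_sd * rng.standard_normal(cpp.shape)
    return np.clip(p, 0.0, None)


def generate_patient(config: SimConfig, with_pbto2: bool = False,
                     pbto2_baseline: float = 27.0, pbto2_knee_cpp: float = 70.0,
                     pbto2_slope: float = 0.5, pbto2_noise_sd: float = 2.0
                     ) -> tuple[dict[str, WaveformRecording], GroundTruth]:
    """Full recording set plus the generator's ground truth."""
    abp = generate_abp(config)
    icp = generate_icp(config, abp)
    n_min = int(config.duration_s // 60)
    t_min = (np.arange(n_min) + 0.5) * 60.0
    icp_min = _sample_trajectory(config.icp_trajectory, config.duration_s, t_min)
    coupling_min = _sample_trajectory(config.reactivity_coupling,
                                      config.duration_s, t_min)
    recs = {"ABP": abp, "ICP": icp}
    if with_pbto2:
        cpp_min = config.map_baseline - icp_min
        pb = generate_pbto2(cpp_min, pbto2_baseline, pbto2_knee_cpp, pbto2_slope,
                            pbto2_noise_sd, _streams(config)["pbto2_noise"])
        # minute-resolution probe held constant within each minute
        per_sample = np.repeat(pb, int(60 * config.sampling_rate))
        n = len(abp.samples)
        per_sample = np.pad(per_sample[:n], (0, max(0, n - len(per_sample))),
                            constant_values=np.nan)
        recs["PBTO2"] = WaveformRecording("PBTO2", config.sampling_rate, per_sample)
    if config.collapse_threshold is not None:
        phenotype = "upper_breakpoint"
        breakpoint_icp = config.map_baseline - config.collapse_threshold
    elif config.amp_plateau_cpp is not None and config.elastance_coefficient > 0:
        phenotype, breakpoint_icp = "rightward_deflection", None
    elif config.elastance_coefficient >= 0:
        phenotype, breakpoint_icp = "monotonic_increase", None
    else:
        phenotype, breakpoint_icp = "monotonic_decrease", None
    truth = GroundTruth(coupling_per_minute=coupling_min, phenotype=phenotype,
                        icp_per_minute=icp_min, breakpoint_icp=breakpoint_icp,
                        pbto2_baseline=pbto2_baseline, pbto2_knee_cpp=pbto2_knee_cpp,
                        pbto2_slope=pbto2_slope)
    return recs, truth


# ----------------------------------------------------------------------
# cohorts
# ----------------------------------------------------------------------

@dataclass
class SimPatient:
    id: str
    config: SimConfig
    recordings: dict[str, WaveformRecording]
    truth: GroundTruth
    metadata: dict = field(default_factory=dict)


def _apportion(n: int, mix: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n patients to phenotypes."""
    total = sum(mix.values())
    if not np.isclose(total, 1.0):
        raise ConfigurationError("phenotype_mix proportions must sum to 1")
    quotas = {k: n * v / total for k, v in mix.items()}
    counts = {k: int(np.floor(q)) for k, q in quotas.items()}
    rem = n - sum(counts.values())
    order = sorted(mix, key=lambda k: (-(quotas[k] - counts[k]), k))
    for k in order[:rem]:
        counts[k] += 1
    return counts


def _icp_linked_coupling(icp_knots: np.ndarray) -> list[tuple[float, float]]:
    """Coupling trajectory tied to the ICP trajectory: near-intact reactivity
    (+0.05) below 25 mm Hg ramping to clearly impaired (+0.65) above 50."""
    ts = np.linspace(icp_knots[0, 0], icp_knots[-1, 0], 64)
    icp = np.interp(ts, icp_knots[:, 0], icp_knots[:, 1])
    c = np.interp(icp, [25.0, 50.0], [0.05, 0.65])
    return list(zip(ts.tolist(), c.tolist()))


def _phenotype_config(phenotype: str, duration_s: float, sampling_rate: float,
                      noise_sd: float, seed: int, rng: np.random.Generator,
                      coupling: Trajectory | str, icp_baseline: float,
                      icp_peak: float | None) -> SimConfig:
    map_b = float(np.clip(rng.normal(95.0, 4.0), 80.0, 110.0))
    hr = float(np.clip(rng.normal(78.0, 10.0), 55.0, 110.0))
    peak = icp_peak
    kwargs: dict = {}
    if phenotype == "upper_breakpoint":
        peak = 80.0 if peak is None else peak
        kwargs["collapse_threshold"] = 30.0
    elif phenotype == "rightward_deflection":
        peak = 70.0 if peak is None else peak
        kwargs["amp_plateau_cpp"] = 50.0
    elif phenotype == "monotonic_increase":
        peak = 70.0 if peak is None else peak
    elif phenotype == "monotonic_decrease":
        peak = 40.0 if peak is None else peak
        kwargs["elastance_coefficient"] = -0.02
        kwargs["amp_baseline"] = 2.5
    else:
        raise ConfigurationError(f"unknown phenotype {phenotype!r}")
    if peak is not None and peak != icp_baseline:
        # rise over the first 60% of the record, then hold at the peak
        traj = [(0.0, icp_baseline), (0.6 * duration_s, float(peak)),
                (duration_s, float(peak))]
    else:
        traj = icp_baseline
    if isinstance(coupling, str):
        if coupling != "icp_linked":
            raise ConfigurationError(f"unknown coupling mode {coupling!r}")
        coup: Trajectory = _icp_linked_coupling(_as_trajectory(traj, duration_s))
    else:
        coup = coupling
    return SimConfig(duration_s=duration_s, sampling_rate=sampling_rate,
                     heart_rate=hr, map_baseline=map_b,
                     reactivity_coupling=coup, icp_trajectory=traj,
                     noise_sd=noise_sd, seed=seed, **kwargs)


def generate_cohort(n_patients: int,
                    phenotype_mix: dict[str, float] | None = None,
                    seed: int = 0,
                    duration_s: float = 4 * 3600.0,
                    sampling_rate: float = 50.0,
                    noise_sd: float = 1.0,
                    coupling: Trajectory | str | Sequence[float] = "icp_linked",
                    icp_baseline: float = 10.0,
                    icp_peak: float | None = None,
                    with_pbto2: bool = False) -> list[SimPatient]:
    """A cohort of synthetic patients realizing a phenotype mix.

    ``coupling`` is either ``"icp_linked"`` (reactivity deteriorates as ICP
    rises — the cohort-level behaviour the analysis describes), a single
    trajectory applied to every patient, or a sequence of per-patient
    constants. Metadata (age, sex, GCS) mirrors a severe-TBI cohort: age
    ~ N(30.3, 12.5) truncated to [16, 80], 78.8% male, GCS <= 8 with
    probability 0.848. Deterministic given the seed.
    """
    if n_patients < 1:
        raise ConfigurationError("n_patients must be >= 1")
    mix = dict(phenotype_mix) if phenotype_mix else dict(DEFAULT_PHENOTYPE_MIX)
    unknown = set(mix) - set(PHENOTYPES)
    if unknown:
        raise ConfigurationError(f"unknown phenotypes in mix: {sorted(unknown)}")
    counts = _apportion(n_patients, mix)
    labels = [k for k in PHENOTYPES for _ in range(counts.get(k, 0))]
    rng = np.random.default_rng([seed, 1000])
    rng.shuffle(labels)

    per_patient_coupling: list | None = None
    if not isinstance(coupling, str) and np.ndim(coupling) == 1 \
            and np.size(coupling) == n_patients:
        per_patient_coupling = [float(c) for c in np.asarray(coupling, float)]

    patients = []
    for i, label in enumerate(labels):
        coup = per_patient_coupling[i] if per_patient_coupling is not None else coupling
        cfg = _phenotype_config(label, duration_s, sampling_rate, noise_sd,
                                seed=int(rng.integers(0, 2 ** 31)), rng=rng,
                                coupling=coup, icp_baseline=icp_baseline,
                                icp_peak=icp_peak)
        recs, truth = generate_patient(cfg, with_pbto2=with_pbto2)
        age = float(np.clip(rng.normal(30.3, 12.54), 16.0, 80.0))
        sex = "M" if rng.random() < 0.788 else "F"
        gcs = int(rng.integers(3, 9)) if rng.random() < 0.848 else int(rng.integers(9, 16))
        patients.append(SimPatient(
            id=f"p{i:03d}", config=cfg, recordings=recs, truth=truth,
            metadata={"id": f"p{i:03d}", "age": round(age, 1), "sex": sex, "gcs": gcs},
        ))
    return patients
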