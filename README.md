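# icpulse

Multimodal neuromonitoring analysis of refractory intracranial hypertension
after severe traumatic brain injury — as a tested, reusable Python pipeline.

Severe TBI patients are monitored continuously with intraparenchymal
intracranial pressure (ICP), arterial blood pressure (ABP) and, in some,
brain tissue oxygenation (PbtO2) probes. When ICP rises above 40 mm Hg for
an hour or more despite treatment (*refractory intracranial hypertension*),
the cerebrovascular consequences are visible in a handful of derived
indices. `icpulse` computes those indices from ≥50 Hz waveforms and carries
out the downstream cohort analyses:

- **Window summaries** — non-overlapping 10-s windows: mean ABP and ICP,
  heart rate (fundamental frequency of ABP within the cardiac band
  40–180 cycles/min), and the fundamental cardiac amplitudes of ABP (aABP)
  and ICP (AMP), all extracted spectrally.
- **PRx**, the pressure reactivity index: the moving Pearson correlation of
  30 consecutive 10-s means of ABP and ICP, updated every minute. Positive
  PRx (> 0.25 a.u.) indicates impaired cerebrovascular pressure reactivity.
- **RAP**, the cerebrospinal compensatory-reserve index: the same moving
  correlation applied to (mean ICP, AMP) over a 5-min window.
- **CPP** = MAP − ICP, and **AMP/aABP**, the arterial→intracranial pulse
  transmission ratio.
- **Episode selection**: initial ICP < 25 mm Hg followed by a contiguous run
  of > 40 mm Hg lasting ≥ 60 min, in recordings spanning ≥ 12 h.
- **AMP–ICP phenotyping**: a penalized cubic regression spline (basis
  dimension 5, smoothing weight by GCV) fitted to minute-by-minute
  (mean ICP, AMP) pairs, classified by its derivative into
  `monotonic_increase`, `monotonic_decrease`, `rightward_deflection`, or
  `upper_breakpoint` — the switch from a positive to a negative AMP–ICP
  relationship at extreme ICP attributed to critical cerebrovascular
  collapse, with the breakpoint located at the derivative zero-crossing.
- **Aggregate curves**: per-patient means in 10 mm Hg bins of ICP or CPP
  (so long recordings do not dominate), LOWESS-smoothed with a
  patient-level bootstrap 95% band.
- **Group statistics**: per-patient means at three ICP levels
  ([0,25), [25,50), [50,150] mm Hg) summarized as mean (sd, n) with Welch
  t tests between adjacent levels, and a matched case–control comparison
  (exact on sex, nearest Mahalanobis distance on age and GCS) of first-5-h
  PRx and ICP by Wilcoxon rank-sum.

Because the clinical recordings behind such cohorts are private, the package
includes a first-class **synthetic waveform generator**
(`icpulse.synthetic`): seeded ABP/ICP/PbtO2 recordings with cardiac pulse,
band-limited vasogenic slow waves, controllable ABP→ICP slow-wave coupling
(the quantity PRx estimates), an exponential elastance law for the ICP pulse
amplitude with optional plateau and collapse regimes, CPP-dependent brain
oxygenation, and whole cohorts with known ground-truth phenotype mix and
demographic metadata. Every recovery test in the suite is run against this
generator's ground truth.

## Worked example

Simulate one patient whose ICP climbs from 12 to 75 mm Hg while reactivity
deteriorates, with a cerebrovascular collapse below CPP 30 mm Hg, then run
the full index chain and phenotype the AMP–ICP relationship:

```python
import numpy as np
import icpulse as ip
from icpulse.config import PipelineConfig

cfg = ip.SimConfig(
    duration_s=4 * 3600,
    icp_trajectory=[(0.0, 12.0), (9600.0, 75.0), (14400.0, 75.0)],
    reactivity_coupling=[(0.0, 0.05), (9600.0, 0.65), (14400.0, 0.65)],
    collapse_threshold=30.0, seed=42)
recs, truth = ip.generate_patient(cfg, with_pbto2=True)
summ = ip.summarize_recording(recs["ABP"], recs["ICP"], recs["PBTO2"])
idx = ip.compute_indices(summ, PipelineConfig())
label, bp, fit = ip.phenotype_patient(idx["mean_icp"].to_numpy(),
                                      idx["amp"].to_numpy())
```

Hourly means of the resulting minute series, and the phenotype call:

```
first hour : ICP  23.8  CPP  71.2  AMP 2.13  PRx  0.09  PbtO2  25.4
final hour : ICP  75.0  CPP  20.0  AMP 4.40  PRx  0.61  PbtO2   2.2
phenotype: upper_breakpoint, breakpoint 66.8 mm Hg (generator truth 65.0)
```

Reading the numbers: as mean ICP rises to 75 mm Hg, CPP collapses, PRx moves
from near zero (intact reactivity) to strongly positive (impaired), brain
oxygenation falls roughly 0.5 mm Hg per mm Hg of CPP below 70, and the ICP
pulse amplitude — which grew with ICP along the steep part of the
pressure–volume curve — turns downward near ICP 65 mm Hg: an upper
breakpoint, which the spline classifier locates within 2 mm Hg of the
generating collapse point.

The same stages are available from the shell:

```sh
icpulse simulate --out data --n-patients 8 --seed 1
icpulse run-all --in data --out results
icpulse config            # print every numeric default
```

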