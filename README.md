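# qperf — quantitative first-pass myocardial perfusion CMR

`qperf` turns dynamic saturation-recovery (SR) contrast-enhanced cardiac MR
series into pixel-wise maps of myocardial blood flow (MBF, mL/min/g),
myocardial perfusion reserve (MPR, stress/rest ratio) and tracer arrival
time, with AHA 16-segment summaries, ischemic-burden percentages, protocol
validation and a reviewable quality-control report.  It is written for
imaging scientists building or evaluating perfusion-quantification
pipelines: every stage — signal modelling, preprocessing, arterial input
function (AIF) handling, tracer-kinetic fitting, mapping, QC — is an
importable, tested component, and a built-in digital perfusion phantom
provides ground truth for all of them, so the whole chain can be exercised
without patient data.

## The model

Signal is linked to gadolinium concentration through the relaxivity
equation and a pulse-by-pulse Bloch simulation of the SR readout,

    1/T1(t) = 1/T1_0 + r1 · CA(t),        S = f(T1; flip, TR, TS, TD, N_lines),

inverted via a precomputed signal dictionary.  Tissue kinetics follow the
linear indicator-dilution model: the myocardial concentration is the
convolution of the arterial input with a flow-scaled residue function,

    C_myo(t) = F_p · (R ⊛ C_aif)(t),      R(0) = 1, R non-increasing,

so the impulse response I(t) = F_p R(t) yields MBF = I(0).  Four estimators
are provided as statsmodels-style model classes whose `fit()` returns a
results object with estimates, residuals and a `summary()` table:

| class | impulse response | window |
|---|---|---|
| `FermiModel` | Fermi function A/(exp((t−μ)k)+1) | first pass |
| `TwoCompartmentExchangeModel` | bi-exponential 2CXM residue | full curve |
| `PatlakModel` | linearized K_trans / v_p | early window |
| `TikhonovModel` | model-independent, identity penalty | first pass |

## Worked example

```python
import numpy as np
from qperf import PhantomSpec, KineticParams
from qperf.phantom import stress_rest_pair
from qperf.pipeline import run_stress_rest

spec = PhantomSpec(matrix=(36, 36), n_frames=50, n_slices=1,
                   lv_radius=5, inner_radius=8, outer_radius=12, seed=2)
stress, rest = stress_rest_pair(spec, mpr=3.0)   # true stress/rest ratio 3
res_s, res_r, mprs = run_stress_rest(stress, rest, model="2cxm",
                                     slices=[0], register=False)
mpr = mprs[0].mpr
print("rest median MBF :", round(float(np.nanmedian(res_r.maps[0].mbf)), 3))
print("median MPR      :", round(float(np.nanmedian(mpr[np.isfinite(mpr)])), 3))
print("QC              :", res_s.qc.overall)
```

prints

```
rest median MBF : 1.642
median MPR      : 2.996
QC              : pass
```

The rest phantom's plasma flow is 1.0 mL/min/mL; reported as blood flow
per gram (divide by (1 − hematocrit) = 0.58 and tissue density
1.05 g/mL) that is 1.64 mL/min/g, which the pipeline recovers, and the
pixel-median MPR lands within 0.2% of the simulated ratio of 3.

A single-curve fit looks like any statsmodels workflow:

```python
from qperf import FermiModel, crop_first_pass
aif_fp, tissue_fp, _ = crop_first_pass(aif_plasma, tissue)
result = FermiModel(tissue_fp, aif_fp).fit()
print(result.summary())
```

## Command line

`qperf simulate` renders phantom studies (DICOM or archive),
`qperf quantify` runs the full pipeline from a YAML config,
`qperf qc`, `qperf validate-protocol` and `qperf report` cover review
workflows.  See `qperf --help`.

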