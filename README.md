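# srcsep

How accurate does an R2 map have to be before susceptibility source
separation goes wrong?

Susceptibility source separation splits the magnetic susceptibility of
brain tissue into a paramagnetic component χ_para (iron-like) and a
diamagnetic component χ_dia (myelin-like).  The separation leans on the
reversible relaxation rate R2' = R2* − R2: the model couples

    R2'(r)  = D_r · (χ_para + χ_dia)                    (relaxation)
    Δf(r)   = f0 · D ∗ (χ_para − χ_dia) · 10⁻⁶          (dipole field)

with D(k) = 1/3 − (k·b̂)²/|k|² the dipole kernel and D_r the
relaxometric constant (Hz/ppm).  R2* is easy to measure; R2 is not, and
common shortcuts — naive exponential fitting of turbo-spin-echo decays
that ignores stimulated echoes, or skipping the R2 scan and setting
R2 = 0.48 R2* — corrupt R2', and through it the separated maps.

`srcsep` is a simulation pipeline that measures this error propagation
end to end, for researchers developing or applying χ-separation-style
methods:

1. **Phantom** — ROI-labelled brain-like phantom with known χ_para,
   χ_dia, R2, a smooth B1+ field, self-consistent R2* and a
   dipole-consistent frequency map; replicate phantoms play the role of
   subjects.
2. **Signals** — dual-echo TSE magnitudes via an extended-phase-graph
   (EPG) train (TR 2500 / TE 10,93 ms / turbo 8 / 165° refocusing, with
   B1-scaled flip angles and full stimulated-echo pathways) and 6-echo
   complex gradient-echo data (TE 5.0 + k·7.1 ms).
3. **Relaxometry** — R2 by EPG dictionary matching (T2 grid 0.01–2 s in
   0.1 ms steps, B1 grid 0.4–1.6 in 0.005 steps) or by deliberately
   naive exponential fitting; R2* by ARLO; R2' = max(R2* − R2, 0).
4. **Error injection** — global R2 scaling 75–125 % in 1 % steps (50
   altered maps), exponential-fit substitution, or R2 = 0.48 R2*.
5. **Separation** — non-negative two-component inversion of the model
   above by projected conjugate gradients, with D_r either fixed at the
   toolbox default (137 Hz/ppm) or regressed per subject from six
   deep-gray-matter points (R2' vs |χ| from a closed-form QSM).
6. **Evaluation** — per-ROI mean percentage error (MPE) against the
   uncorrupted baseline, CSF exclusion (R2 < 2.5 Hz or R2* < 5 Hz),
   paired t-tests across replicates, and MPE-versus-error sweep curves.

The headline behaviours it reproduces: R2 underestimation inflates R2'
and both separated components (and vice versa, with inverted sign);
the total map χ_para − χ_dia stays nearly unchanged; a per-subject
regressed D_r moves with the error (up for R2 underestimation, down for
overestimation), partially compensating it.

## Worked example

```python
import numpy as np
from srcsep import (RunConfig, build_dictionary, scale_r2_map, separate,
                    compute_r2prime)
from srcsep.evaluation import run_replicate, run_condition
from srcsep.phantom import roi_means
from srcsep.sequences import TSEParams

cfg = RunConfig(seed=0)
rep = run_replicate(cfg, seed=0, dictionary=build_dictionary(TSEParams()))

base, _ = run_condition(rep, None, "default", cfg)          # correct R2
from srcsep.errors import ErrorSpec
low, _ = run_condition(rep, ErrorSpec("global_scale", 0.75), "default", cfg)

rois = rep.truth.rois
for name, maps in (("baseline", base), ("-25% R2", low)):
    para = roi_means(maps["chi_para"], rois, ("globus_pallidus",), rep.include)
    dia = roi_means(maps["chi_dia"], rois, ("globus_pallidus",), rep.include)
    tot = roi_means(maps["chi_total"], rois, ("globus_pallidus",), rep.include)
    print(f"{name:9s} globus pallidus: chi_para {para['globus_pallidus']:6.1f} ppb, "
          f"chi_dia {dia['globus_pallidus']:5.1f} ppb  (total {tot['globus_pallidus']:6.1f})")
```

prints

```
baseline  globus pallidus: chi_para  131.8 ppb, chi_dia  24.9 ppb  (total  107.0)
-25% R2   globus pallidus: chi_para  147.9 ppb, chi_dia  40.8 ppb  (total  107.1)
```

Underestimating R2 by 25 % raised R2', and the solver absorbed the
excess into *both* components: χ_para by about +12 %, χ_dia by about
+64 % (the diamagnetic map is small in this iron-rich nucleus, so the
same ppb excess is a much larger percentage) — while their difference,
the total susceptibility, moved by only 0.1 ppb.

A command-line interface mirrors the stages (`srcsep phantom`,
`fit-r2`, `fit-r2star`, `inject-error`, `separate`, `sweep`,
`run-all`, `evaluate`, `simulate-decay`); `srcsep run-all --out dir/`
writes the per-replicate curve table, its across-replicate aggregate,
the MPE/paired-test report and a config echo.

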