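# permpbpk

A pregnancy physiologically based pharmacokinetic (pPBPK) model of
*cis*- and *trans*-permethrin in the Sprague-Dawley rat, for toxicokinetic
modellers and risk assessors who need maternal **and fetal** internal doses
of a pyrethroid over gestation — in particular the concentration reaching
the fetal brain, the target tissue of developmental neurotoxicity.

The package provides, as plain Python objects:

* **Gestational physiology** — maternal body weight, cardiac output, tissue
  volumes and blood flows over GD0–GD20, plus the growth of the placenta
  and of the litter (lumped into one fetal model).
* **The PBPK core** — a maternal model (gut lumen chain, flow-limited GI
  tissue/liver/rapidly perfused tissue/placenta, diffusion-limited brain,
  muscle, kidney, fat, mammary gland and slowly perfused tissue, one
  well-mixed blood pool) coupled through the placenta to a four-compartment
  fetal model (blood, liver, diffusion-limited brain, rest of body).
  Placental exchange is bidirectional diffusion,

      dA_Pla/dt = Q_Pla (C_Art − C_Pla/PC_Pla) − Ktrans1 · C_Pla/PC_Pla + Ktrans2 · C_Art,F

  with `Ktrans_i = scKtrans_i · BW^0.75`.  Metabolism (blood, GI, liver
  clearances) is maternal only; the system is linear in amounts and exactly
  mass-conservative between doses.
* **Simulation** of daily oral gavage (50 mg/kg permethrin, 40:60 cis/trans)
  with a stiff integrator, and a fast day-frozen matrix-exponential
  propagator for inference-scale workloads.
* **PK metrics** — 24-h trapezoid AUC, Tmax, terminal half-life, named AUC
  ratios, and the study's LOQ/2 substitution rule for
  detected-below-quantification samples.
* **Synthetic toxicokinetic studies** — the in-vivo design (groups of 4
  sacrificed at 1–24 h post-dose on GD1/GD15/GD20, matrix-specific LOQs,
  multiplicative lognormal error) generated from known parameters.
* **Bayesian calibration** — truncated-normal/uniform priors, lognormal
  likelihood (log-scale SD 0.15), independent ensemble-MCMC chains,
  Gelman–Rubin convergence (threshold 1.2), statsmodels-style
  `TKCalibration(...).fit() → results.summary()`.
* **Sobol global sensitivity analysis** — first- and total-order indices of
  the chemical parameters (CV 30% truncated normals) on maternal blood,
  fetal blood and fetal brain concentrations at GD15/GD20.

## Worked example

One 20 mg/kg oral dose of *cis*-permethrin to a 0.277 kg dam on gestation
day 1, simulated with the GD1 posterior-mean chemical parameters:

```python
import numpy as np
from permpbpk import DoseSchedule, GestationalPhysiology, run, pk
from permpbpk.parameters import posterior_mean_params

phys = GestationalPhysiology()
chem = posterior_mean_params("cis", "gd1")
sched = DoseSchedule(dose_per_kg=50, isomer_fraction=0.40,
                     times=(1.0,), scale_to_current_bw=False)
res = run(chem, phys, sched, t_end=2.0, output_dt=0.25)

for mat in ("blood", "brain", "fat"):
    t, c = res.concentration_series(mat)
    sel = (t >= 24) & (t <= 48)
    r = pk.nca(t[sel] - 24.0, c[sel])
    print(f"{mat:6s} AUC(0-24) = {r.auc_0_24:7.2f}  Tmax = {r.tmax:5.2f} h")
```

prints

```
blood  AUC(0-24) =    1.65  Tmax =  3.50 h
brain  AUC(0-24) =    4.28  Tmax =  4.75 h
fat    AUC(0-24) =   45.64  Tmax = 24.00 h
```

i.e. a 24-h blood AUC of 1.65 µg·h/ml (the study's model estimate is
1.60), a brain exposure about 2.6-fold the blood exposure, and fat still
accumulating at 24 h (Tmax at the last sample), the signature of a deep
lipophilic depot.

The same pipeline is exposed on the command line:

```bash
permpbpk simulate --isomer cis --gd 1 --out sim.csv
permpbpk generate --seed 42 --out study.csv      # synthetic study
permpbpk metrics  --in study.csv --out nca.csv
permpbpk calibrate --data study.csv --mode gd1 --out fits/
permpbpk gsa --output maternal_blood --gd 15 --out gsa.csv
permpbpk reproduce --fast --out report/
```

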