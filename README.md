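# balopk

Population-pharmacokinetic and receptor-occupancy simulation of
**balovaptan**, a brain-penetrant vasopressin V1a receptor antagonist.

`balopk` is aimed at pharmacometricians and clinical pharmacologists who
need to simulate balovaptan exposure and brain V1a occupancy under oral
or intravenous regimens: dose/time non-linearity analysis, age-banded
pediatric dose selection against an adult-equivalence target, and
infusion-schedule evaluation against an occupancy-attainment target.
It also generates synthetic NONMEM-style study datasets and provides a
simplified estimation/VPC stage for identifiability work — no clinical
data are required anywhere.

## The model

Amounts in mg; concentrations in ng/mL.  One-compartment disposition
with three coupled non-standard features:

```
dAa/dt = Input − Ktr·Aa − At·Kgut·Aa          (absorption depot)
dAc/dt = Ktr·Aa − Ke·Ac + R_iv(t)             (central compartment)
dAt/dt = Kin − Kout·At·(1 + S·Aa)             (gut-extraction turnover, At(0)=1)

Ktr = (Ntr+1)/MTT      Ke = CL/Vc      Kin = Kout
Vc  = V0 · (1 − VLmax · Ac/(Ac + VL_A50))
```

* **Transit-compartment absorption** — each oral dose enters the depot
  as an analytic gamma-shaped flux (mean transit time `MTT`, `Ntr`
  transit compartments); food slows absorption via `MTT`.
* **Dynamic central volume** — `Vc` shrinks from `V0` (565 L) towards
  `V0·(1−VLmax)` (≈110 L) as the central amount saturates hypothetical
  binding sites.  This makes the elimination half-life
  exposure-dependent: ≈9 h right after a 50 mg infusion, ≈46 h in the
  terminal washout.
* **Gut extraction** — a slow turnover state `At` gates a pre-systemic
  loss; drug in the depot suppresses it, so bioavailability rises with
  dose and with repeated dosing (lowest for small single doses).

Covariates: `Vc` scales proportionally with body weight (reference
76 kg); clearance matures with age as a logistic function reaching 50%
of the adult value at 5.34 years and ≈90% by age 14.  Inter-individual
variability is log-normal on CL, V0 and MTT; residual error combines a
time-after-dose-decaying proportional term with a small additive term
(SD 0.025 ng/mL = half the assay LLOQ).

Brain V1a receptor occupancy is a saturable function of the free plasma
concentration, `RO = 100·Cp·fu/(Kb + Cp·fu)`, with free fraction
`fu = 0.13` and a dissociation constant calibrated within the package
(see `docs/methods.md`).

## Worked example

Typical 76-kg adult receiving the stepped IV schedule — 50, 25 and
15 mg as 60-min infusions on three consecutive days:

```python
import numpy as np
from balopk import (PopulationParameters, Covariates, resolve_individual,
                    DosingRegimen, simulate_individual, receptor_occupancy)

theta = PopulationParameters()                      # packaged estimates
ip = resolve_individual(theta, Covariates(age=30, weight=76))
regimen = DosingRegimen.iv_infusions([50, 25, 15], times=[0, 24, 48], duration=1.0)
grid = np.array([0.0, 1.0, 24.0, 25.0, 48.0, 49.0, 72.0, 96.0])
profile = simulate_individual(regimen, ip, grid=grid)
for t, c in zip(grid[1:], profile.conc[1:]):
    print(f"t = {t:5.0f} h   conc = {c:6.1f} ng/mL   RO = {receptor_occupancy(c):4.1f} %")
```

```
t =     1 h   conc =  348.7 ng/mL   RO = 99.1 %
t =    24 h   conc =   75.2 ng/mL   RO = 95.9 %
t =    25 h   conc =  260.3 ng/mL   RO = 98.8 %
t =    48 h   conc =   59.5 ng/mL   RO = 94.8 %
t =    49 h   conc =  163.5 ng/mL   RO = 98.1 %
t =    72 h   conc =   41.5 ng/mL   RO = 92.8 %
t =    96 h   conc =   14.4 ng/mL   RO = 81.6 %
```

Peaks just after each infusion decline as the maintenance doses step
down; troughs drift lower day by day, yet occupancy stays above 90%
through the 72-h treatment window and then falls off quickly — the
intended prophylaxis profile.  Population versions of the same run
(`simulate_population`, `balopk.ro.evaluate_scenario`) add log-normal
between-subject variability and report percentile bands and
target-attainment fractions.

A command-line interface mirrors the main workflows:

```bash
balopk simulate --regimen regimen.yaml --n 2000 --seed 42 --out profiles.csv
balopk make-synthetic --scheme phase1_rich --n 24 --seed 7 --out synth.csv
balopk ro-scenario --start 50 --followup 25,15 --interval 24 --n 2000 --seed 11
balopk pediatric-dose --scheme updated --adult-dose 10 --n 3000 --seed 5
balopk fit --data synth.csv --free CL,V0 --out fit.json
balopk vpc --data synth.csv --nsim 200 --seed 3 --out vpc.csv
```

## Layout

| module                | contents |
|-----------------------|----------|
| `balopk.model`        | structural model, covariate models, residual error |
| `balopk.simulate`     | ODE integration, steady state, dose proportionality, population runs |
| `balopk.population`   | virtual covariate/eta sampling |
| `balopk.dataset`      | NONMEM-style datasets, study-design presets |
| `balopk.ro`           | receptor occupancy, Kb calibration, scenario search |
| `balopk.pediatric`    | age-banded dose fractions, equivalence reports |
| `balopk.estimation`   | MAP etas, pooled fits, likelihood profiles |
| `balopk.vpc`          | visual predictive checks |
| `balopk.config`       | YAML/JSON parameter files |
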