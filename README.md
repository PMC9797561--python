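# hcmcell

Cellular in-silico trials for hypertrophic cardiomyopathy (HCM).

`hcmcell` is for cardiac modellers and translational researchers who want a
desk-scale, fully scriptable version of the cellular arm of an HCM
modelling-and-simulation study: simulate human cardiomyocyte twitches,
remodel them with genotype-specific biophysical defects, screen populations
of models, and run in-silico drug trials with nonparametric statistics.

## The model

A paced seven-state ODE cell, 1 Hz steady-state pacing:

- **Myofilament** (CaTRPN, B, W, S; U = 1−B−W−S implicit): Hill-type
  troponin calcium binding driven by (Cai/Ca50)^n, cooperative
  tropomyosin blocked/unblocked switching (the K_B equilibrium, manipulated
  through its reverse rate k_ub), crossbridge cycling U→W→S→U, and
  isometric active tension T_a = T_ref·S.
- **Myosin availability**: heads in the super-relaxed state (SRX) cannot
  bind actin. With R = (DRX:SRX)/(DRX:SRX)_control, attachment is scaled by
  f(R)/f(1), f(R) = R·ρ0/(1+R·ρ0). An optional myosin→thin-filament
  feedback rescales calcium sensitivity: Ca50_eff = Ca50·clip(1−γ(R−1)).
- **Calcium subsystem** (Cai, Ca_sr, release gate g): stimulus-triggered SR
  release, Hill-saturating SERCA reuptake, lumped extrusion, a trigger
  influx pulse, rapid cytosolic buffering, and bidirectional troponin
  buffering coupling the two halves.

Genotype remodellings ship as multiplicative scaling specs:
`MYH7_R403Q` (R = 1.3, feedback on), `TNNT2_R92Q` (Ca50×0.7, K_B×0.8),
`TNNI3_R21C` (Ca50×0.7, k_off×0.5). Interventions: Mavacamten via a
calibrated dose→R curve, L-type/late-sodium current block, SERCA
upregulation, and an idealised thin-filament calcium desensitiser
(Ca50×(1+level)). Populations of models use Latin-Hypercube sampling over
[50–200]% of baseline with biomarker-range calibration; scenario
populations are compared with Mann–Whitney or Kruskal–Wallis + Dunn tests.

See `docs/methods.md` for equations, assumptions, calibration rationale and
limitations.

## Worked example

```python
from hcmcell import (default_params, run_to_steady_state, extract_biomarkers,
                     variant_spec, mavacamten_spec)

base = default_params()
for label, spec in [
    ("control", None),
    ("MYH7_R403Q", variant_spec("MYH7_R403Q")),
    ("MYH7_R403Q + 0.5 uM mavacamten",
     variant_spec("MYH7_R403Q").compose(mavacamten_spec(0.5))),
]:
    p = spec.apply(base) if spec else base
    bm = extract_biomarkers(run_to_steady_state(p).trace)
    print(f"{label:32s} amp={bm.tension_amp:6.2f} kPa  rt90={bm.tension_rt90:6.1f} ms")
```

prints

```
control                          amp= 21.19 kPa  rt90= 355.6 ms
MYH7_R403Q                       amp= 24.89 kPa  rt90= 444.3 ms
MYH7_R403Q + 0.5 uM mavacamten   amp= 21.05 kPa  rt90= 353.3 ms
```

The mutant cell is hypercontractile (larger twitch amplitude) with slowed
relaxation (longer RT90, the time from peak tension to 90% decay); the
0.5 µM myosin-inhibitor dose returns both to control, because this variant's
defect is myosin availability itself. Running the same drug on the
thin-filament variants suppresses amplitude but leaves relaxation
prolonged — the package's central genotype-divergence result.

The same workflows are available from a CLI:

```bash
hcmcell simulate --variant TNNT2_R92Q --drug mavacamten:0.5uM --out runs/t2
hcmcell population --n 100 --seed 1 --out runs/pop
hcmcell trial --variant TNNT2_R92Q --doses 0.3,1,3 --n 100 --out runs/trial
```

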