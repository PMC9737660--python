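# ionquench

Fragment-fluence-weighted Birks quenching correction for Al2O3:C
radioluminescence (RL) fibre dosimetry in therapeutic proton, helium, and
carbon beams.

Luminescent detectors under-respond at high linear energy transfer (LET):
light output saturates with ionization density (Birks quenching), so RL
Bragg curves underestimate the dose near the peak. This package implements
a correction built from per-species Birks factors weighted by the fluence
fractions of the primary beam and its nuclear fragments, together with
everything needed to exercise it end to end:

- **`ionquench.beam_model`** — relativistic Bethe stopping power of liquid
  water (I = 75 eV, no shell/density corrections), CSDA range-energy maps,
  analytic Bragg depth-dose curves with range straggling, and an
  exponential-attenuation fragmentation model producing per-species
  fluence-fraction / fluence-averaged-LET profiles on a 0.1 mm water grid
  (a surrogate for Monte Carlo scorer output). Includes the
  fluence-weighted LET combination over all species.
- **`ionquench.rl_signal`** — reduction of 200 Hz RL traces to
  background-corrected integrated signals, through-origin dose-response
  slopes, linearity indices relative to a 1 Gy calibration dose, and
  polynomial linearity correction factors (LCF) with validity-range
  clamping.
- **`ionquench.efficiency`** — relative luminescence efficiency against a
  Co-60 calibration constant, efficiency-vs-LET curves along Bragg curves
  (primary or fluence-weighted LET axis), and the exponential
  decay-to-plateau efficiency fit.
- **`ionquench.quenching`** — the voxelized Birks model, per-species and
  fluence-weighted correction factors, (kB, RL0) fitting with
  frozen-fragment constraints (H fitted first, then He with H frozen, then
  C with H and He frozen), finite-probe volume averaging, and corrected
  depth-dose reconstruction with peak/plateau/falloff difference metrics.
- **`ionquench.workflow`** / **`ionquench.cli`** — validated experiment
  configuration, deterministic synthetic campaigns with known ground-truth
  Birks parameters, and the full pipeline (reduce, linearity, efficiency,
  fit, correct, report).
- **`ionquench.datasets`** — packaged fixture tables: scored per-species
  fluence/LET rows, entrance efficiencies, and published Birks parameters,
  for regression-style comparisons.

kB is stored in the published mass units (ug MeV^-1 cm^-2) and divided by
the density of water before multiplying LET (MeV/cm), making the Birks
product dimensionless. LET is MeV/cm internally; keV/um is value / 10.

## CLI

```sh
ionquench simulate --config cfg.yaml --out bundle/ --seed 1
ionquench fit      --bundle bundle/ --species H --species He
ionquench correct  --bundle bundle/ --params bundle/params.json
ionquench report   --bundle bundle/
```

`simulate` writes the resolved config plus profiles, reference curves and
expected signals; the other commands regenerate the deterministic bundle
from that config, so a bundle directory is fully reproducible. Beam
presets `H160`, `H230`, `He150`, `C290`, `C400` carry the nominal/actual
energies of the five reference beams. `--seed` controls every source of
randomness; omitting `--config` uses the default three-beam campaign.

A minimal config:

```yaml
beams: [H160, He150, C290]
probe: grain_4um
noise_sigma: 0.01
seed: 20221125
```

## Python example

```python
from ionquench import ExperimentConfig, synth_experiment, run_pipeline

cfg = ExperimentConfig(beams=["H160", "He150", "C290"], noise_sigma=0.01)
report = run_pipeline(synth_experiment(cfg), mode="full")
print(report.to_text())         # fitted kB/RL0 and peak/plateau/falloff metrics
print(report.metrics_table())   # one row per beam
```

On a zero-noise bundle the pipeline recovers the ground-truth parameters
to better than 0.1% and the corrected curves reproduce the reference
exactly; the mixed-field carbon correction brings a >25% quenched deficit
at the Bragg peak to within a few percent.

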