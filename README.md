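# phagechar

Quantitative analysis for in-vitro characterization of lytic
bacteriophages. The package is aimed at phage-therapy groups who run the
standard pre-clinical workup — plaque titration, host-range screens,
adsorption and one-step growth assays, pH/temperature stability tests, and
multi-phage "cocktail" killing assays — and want the numbers those assays
are supposed to yield computed reproducibly instead of read off plots.

It ships with presets for three characterized phages infecting
*Escherichia coli*, *Klebsiella pneumoniae* and *Enterobacter cloacae*, and
a synthetic-assay generator that emulates each wet-lab assay with the noise
structure the estimators assume, so the whole pipeline runs end to end
without lab data.

## What it computes

- **Titer / MOI / EOP** — pooled Poisson maximum-likelihood titer
  T̂ = Σc / Σ(d·v) with standard error from serial-dilution plaque counts;
  MOI = PFU/CFU; efficiency of plating EOP = T_test / T_host classified
  High (≥ 0.5), Moderate (0.1–0.5), Low (0.001–0.1), No activity (< 0.001).
- **Host range** — isolate × phage matrices, per-group summaries (spot
  positives, EOP class counts, sum of EOP values) and spot-vs-plaque
  discordance rates.
- **Adsorption kinetics** — rate constant k (mL/min) from the mass-action
  decay P(t) = P₀·e^(−kBt), by log-linear regression against host density B.
- **One-step growth** — latent period L (threshold crossing at 2× baseline,
  midpoint-interpolated) and burst size b (plateau / baseline titer).
- **Stability** — percent viability vs pH or temperature, stable windows
  (viability ≥ 50%) and inactivation bounds.
- **Cocktail killing dynamics** — a deterministic model coupling logistic
  host growth (rate r, shared capacity K), mass-action infection
  (dS_i/dt ⊃ −S_i Σ_j I_ij k_j P_j) and Erlang-delayed lysis releasing b_j
  phage per cell after mean delay L_j, with per-species extinction at
  1 CFU/mL; scenario presets for single phages, the EK1/KL2/EL3/EKL4
  cocktails and a phage-free control.

See `docs/methods.md` for the models, defaults and numerical choices.

## Worked example

```python
from phagechar import (
    PHAGE_PRESETS, NoiseModel,
    make_onestep_series, estimate_latent_burst,
    make_adsorption_series, fit_adsorption,
    scenario_library, simulate, killing_summary,
)

phage = PHAGE_PRESETS["escherichia_myPSH2311"]   # k=1.1e-9 mL/min, L=26 min, b=110
noise = NoiseModel(count_noise=True, seed=1)      # Poisson plate-counting noise

onestep = make_onestep_series(phage, host_density=1e8, moi=0.001, noise=noise)
est = estimate_latent_burst(onestep)
print(est.latent_min, round(est.burst, 1))        # -> 27.5 109.8

ads = make_adsorption_series(phage, host_density=1e8, noise=noise)
fit = fit_adsorption(ads, host_density=1e8)
print(f"{fit.k_ads:.3g}")                         # -> 1.11e-09

lib = scenario_library("normalized")              # bacteria at 1e6 CFU/mL total
summary = killing_summary(simulate(lib["EKL4"]), simulate(lib["control"]))
print(summary[["time_h", "viable_total", "log10_reduction_vs_control"]].round(3))
```

```
 time_h  viable_total  log10_reduction_vs_control
    0.0   1000000.000                       0.000
    2.0   1290421.687                       1.082
    4.0         0.000                       8.301
    6.0         0.000                       8.902
   24.0         0.000                       9.000
```

The one-step estimates recover the preset (latent period 27.5 min against a
true 26 min — half a 5-min sampling interval of resolution — and burst
109.8 against 110); the adsorption fit returns the preset rate constant
within 1%. In the three-phage cocktail simulation the mixed culture is
driven extinct between 2 h and 4 h while the phage-free control grows to
carrying capacity, a 9-log difference at 24 h.

A command-line entry point mirrors the library:

```bash
phagechar synth --preset klebsiella_myPSH1235 --assay onestep --seed 3 --out onestep.csv
phagechar onestep onestep.csv
phagechar cocktail --scenario KL2 --out kl2.csv
phagechar report --demo --seed 1 --out report/
```

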