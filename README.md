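# thermoniche

Trait-based thermal-niche analysis for marine ectotherms: from
closed-chamber respirometry oxygen traces to fitted thermal performance
curves (TPCs), critical thermal limits, and thermal habitat suitability
(THS) maps under current and warming scenarios.

The package targets ecophysiologists studying benthic invertebrates — the
motivating system is the polyp stage of the upside-down jellyfish
*Cassiopea andromeda*, a warm-adapted species spreading through the
Mediterranean — but every stage is generic: any organism whose metabolic
rate is measured in sealed chambers across a temperature gradient can be
pushed through the same pipeline.

## The model

Mass-specific respiration (RR) and net primary production (NPP) come from
ordinary-least-squares slopes of dissolved-oxygen time series:

    RR  = |(β_dark  − β_control)| · 3600 · Vol / DW      [mg O₂ h⁻¹ g⁻¹]
    NPP =  (β_light − β_control)  · 3600 · Vol / DW
    GPP =  NPP + |RR|

with β in mg O₂ L⁻¹ s⁻¹, chamber volume Vol in litres and dry weight DW in
grams. Replicate rates against temperature are fit with a family of seven
TPC models; the centrepiece is the enzyme-kinetics (Pawar) form

    rate(T) = r_tref · e^{−(E/k)(1/T − 1/T_ref)} /
              (1 + E/(E_h − E) · e^{(E_h/k)(1/T_opt − 1/T)})

(temperatures in kelvin, k the Boltzmann constant in eV K⁻¹, E the
activation and E_h ≫ E the deactivation energy in eV), whose maximizer is
exactly the parameter T_opt. The best model is chosen by lowest AIC,
uncertainty comes from a case-resampling bootstrap, and critical thermal
limits CTmin/CTmax are the temperatures where the fitted curve falls to a
threshold fraction θ of its peak (θ = 0.098 by default). Habitat
suitability at temperature T is the normalized curve THS(T) =
rate(T)/rate(T_opt) ∈ [0, 1], projected onto monthly sea-surface
temperature rasters over shallow (≤ 50 m) coastal cells, classified into
five classes, and differenced across warming scenarios.

A synthetic-data module generates every input — oxygen traces drawn from a
known "true" curve with chamber-level biological variability and
optode-level reading noise, plus Mediterranean-like SST climatologies and
shelf bathymetry — so the full analysis runs without any downloads and
parameter recovery is verifiable end to end.

## Worked example

```python
from thermoniche import (ExperimentDesign, gen_respirometry,
                         process_experiment, summarize_rates,
                         fit_family, select_best, thermal_limits)
from thermoniche.respirometry import rates_to_frame
from thermoniche.tpc import aic_table

traces, meta = gen_respirometry(ExperimentDesign(), noise_sd=0.01, seed=1)
rates = process_experiment(traces, meta)
print(summarize_rates(rates).round(3).head(4).to_string(index=False))

df = rates_to_frame(rates)
fits = fit_family(df["temp_C"], df["rr"], seed=1)
best = select_best(fits)
print(aic_table(fits).round(2).to_string(index=False))
lim = thermal_limits(best, threshold=0.098)
print(f"t_opt {best.peak_temperature():.2f}  CTmin {lim.ctmin:.1f}  CTmax {lim.ctmax:.1f}")
```

prints

```
 temp_C  rr_mean  rr_se  npp_mean  npp_se  gpp_mean  gpp_se  n
   12.0    0.095  0.004     0.096   0.004     0.191   0.008  7
   14.0    0.111  0.005     0.110   0.005     0.220   0.010  7
   16.0    0.131  0.008     0.131   0.008     0.262   0.017  6
   18.0    0.157  0.004     0.157   0.004     0.314   0.008  7
         model_id  n_params  rss     aic  delta_aic
            pawar         4 0.14 -603.75       0.00
sharpeschoolfield         6 0.14 -599.75       4.00
        ratkowsky         4 0.15 -592.64      11.11
          briere2         4 0.19 -574.62      29.13
          weibull         4 0.46 -490.59     113.16
         gaussian         3 0.55 -474.87     128.89
        quadratic         3 0.69 -454.61     149.14
t_opt 35.53  CTmin 6.9  CTmax 39.1
```

The per-temperature table mirrors the laboratory summary (mean ± SE of
RR/NPP/GPP over the seven replicate chambers; n drops where simulated
mortality removed replicates). The enzyme-kinetics form wins the AIC
comparison over the generating design, and the recovered optimum (35.53 °C)
and limits sit close to the true curve's 35.7 / 6.4 / 39.0 °C.

The same analysis runs from the shell:

```bash
thermoniche all --seed 1 --outdir out/   # simulate → rates → fit → limits → maps → report
thermoniche fit --outdir out/            # AIC table for an existing rates file
```

`thermoniche all` writes the rates CSVs, a JSON fit report (selected model,
parameters, AIC table, CT limits with a θ-sensitivity table), NetCDF
suitability rasters for 12 months × 3 scenarios, TPC and map figures, a
monthly class-percentage table with scenario deltas, and a manifest with
the seed and a config hash; a rerun with the same config reproduces the
tables byte for byte.

## Layout

- `thermoniche.respirometry` — oxygen traces → mass-specific RR/NPP/GPP
- `thermoniche.models` / `thermoniche.tpc` — TPC family, multi-start NLS,
  AIC selection, bootstrap bands, critical limits
- `thermoniche.suitability` — THS scoring, raster projection,
  classification, scenario deltas
- `thermoniche.synthetic` — experiment and climatology generators
- `thermoniche.pipeline` / `thermoniche.cli` — end-to-end runs, reporting

See `docs/methods.md` for the modelling choices and their rationale.
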