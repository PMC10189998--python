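# thermoallo

Allometric and thermal scaling of exploratory movement speed.

Walking ectotherms such as ground beetles (Carabidae) explore their habitat
at a routine "exploratory" speed that depends strongly on both body size and
ambient temperature. `thermoallo` is a reusable pipeline for quantifying
that dependence from laboratory tracking experiments: it turns raw x–y–t
arena trajectories into one exploratory-speed value per individual, fits and
ranks candidate thermal-performance-curve (TPC) models by AIC, and estimates
a combined body-mass × temperature model

```
v = a0 · M^b · exp(−E/k · (1/(T+273.15) − 1/(T_ref+273.15)))
    ─────────────────────────────────────────────────────────────
    1 + (E/(E_h−E)) · exp((E_h/k) · (1/(T_opt+273.15) − 1/(T+273.15)))
```

where `v` is speed (m/s), `M` body mass (mg), `T` temperature (°C),
`a0` the speed of a 1 mg animal at the reference temperature
`T_ref = 15 °C`, `b` the allometric exponent, `E` and `E_h` the activation
and deactivation energies (eV), `k` the Boltzmann constant
(8.617·10⁻⁵ eV K⁻¹), and `T_opt` the optimum temperature at which speed
peaks (the Sharpe–Schoolfield formulation is re-parameterised so the maximum
falls exactly at `T_opt`). A residual sensitivity analysis then asks whether
species identity or habitat preference explains anything the general model
misses.

Because raw tracking datasets of this kind are rarely redistributable, the
package ships a first-class synthetic-data generator that emulates the
underlying experimental design — 125 individuals of 8 species spanning
10–303 mg, filmed singly at 38 frames/s in a 490 mm circular arena over a
14-level temperature gradient from 8 to 32 °C — as both aggregated speed
tables and raw two-state random-walk trajectories, so every stage of the
pipeline is testable end-to-end.

Intended users: movement ecologists and physiologists analysing image-based
tracking experiments, and modellers who need a calibrated speed–mass–
temperature relationship as an ingredient for interaction or dispersal
models.

## Worked example

```python
from thermoallo import (StudyDesign, NoiseModel, generate_speed_dataset,
                        compare_models, fit_allo_tpc, summary_table,
                        params_from_fit, predict_grid)

# a synthetic study: 125 beetles, 8 species, 14 temperature levels
data = generate_speed_dataset(StudyDesign(seed=42),
                              noise=NoiseModel(sigma=0.30))

# which TPC family describes the thermal response best?
cmp_ = compare_models(data["temperature_C"], data["speed_m_s"],
                      n_starts=50, seed=42)
print(cmp_.table[["model", "aic", "delta_aic"]])

# the combined mass x temperature model
fit = fit_allo_tpc(data, n_starts=100, seed=42)
print(summary_table(fit))
```

Output (this exact run):

```
            model         aic  delta_aic
modified_gaussian -597.272831   0.000000
            pawar -591.451370   5.821461
          weibull -589.740109   7.532723
         gaussian -589.237767   8.035065
        quadratic -585.639372  11.633459

parameter  estimate  std_error    ci_low   ci_high    t_stat      p_value
       a0  0.027961   0.004147  0.019833  0.036089  6.742575 5.780349e-10
        b  0.153080   0.031614  0.091116  0.215043  4.842080 3.870186e-06
        e  0.477883   0.114488  0.253491  0.702276  4.174090 5.694034e-05
      e_h  2.288231   0.743059  0.831863  3.744600  3.079476 2.570965e-03
    t_opt 25.422447   0.963124 23.534758 27.310136 26.395807 8.341225e-52
```

The comparison table ranks the five TPC families by AIC on this one noisy
replicate (ΔAIC is each model's distance from the best). The fit table is
the headline result: a 1 mg animal moves at ≈ 0.028 m/s at 15 °C, speed
scales with mass to the power ≈ 0.15, rises with a ≈ 0.48 eV activation
energy up to an optimum near 25.4 °C, and collapses above it with a
deactivation energy of ≈ 2.3 eV — all within sampling error of the
generating values (a0 = 0.03, b = 0.12, E = 0.37, E_h = 3.11,
T_opt = 26.33).

Predictions on a mass × temperature grid then come from

```python
p = params_from_fit(fit)
grid = predict_grid(p, [10, 105, 303], [10.0, 20.0, 26.0, 30.0])
# grid.speeds, m/s (rows: masses, columns: temperatures)
# [[0.0283 0.0526 0.0615 0.0513]
#  [0.0405 0.0753 0.0881 0.0735]
#  [0.0476 0.0886 0.1036 0.0864]]
```

— larger animals are faster everywhere, every mass peaks near `T_opt`, and
speed falls steeply above the optimum.

The same workflow is available from the shell: `thermoallo simulate`,
`thermoallo track`, `thermoallo fit-tpc`, `thermoallo fit-allo`,
`thermoallo predict`, `thermoallo residual-test` (see `--help` on each).

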