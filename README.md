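# cjskit

Capture-mark-recapture survival analysis for long-term annual ringing
studies: Cormack-Jolly-Seber (CJS) models with transience and
trap-dependence corrections, goodness-of-fit decomposition,
overdispersion-adjusted QAICc model selection, and ANODEV testing of
environmental covariate effects on annual adult survival.

The package was built around the design of a multi-decade seabird
colony study: annual detection occasions with a multi-year monitoring
gap, two disjoint monitoring panels (capture probability structurally
zero outside each panel's years), transient contamination of newly
marked cohorts, Markovian trap-dependent recapture, and candidate
covariates (longline fishing effort, sea surface temperature, the
Southern Oscillation Index) reduced from monthly series to standardized
annual values. Everything runs end-to-end on synthetic data generated
by the package itself, so each stage is testable without the (private)
field data.

## The model

Conditional on first capture, an encounter history contributes

* survival factors Φ_t (probability an adult alive at occasion *t* is
  alive at *t*+1) and capture factors p_t (probability an animal alive
  and present at *t* is caught) for every occasion between its first
  and last detection, and
* the never-seen-again recursion for the tail,
  χ_t = (1 − Φ_t) + Φ_t (1 − p_{t+1}) χ_{t+1},
  with p forced to zero wherever capture is impossible (monitoring gap,
  out-of-panel years).

Both Φ and p are logit-linear in time, sex, trap state (m1 = captured
at the previous occasion, m2 = not) and standardized annual covariates.
Lack of fit of the time-dependent model is decomposed into the
directional components 3.SR (transience), 3.SM (marking memory),
2.CT (immediate trap-dependence) and 2.CL (delayed trap-dependence);
the residual χ²/df is the variance-inflation factor ĉ. Models are
ranked by QAICc = DEV/ĉ + 2np (small-sample term optional), covariates
are tested by the ANODEV F statistic locating the covariate model
between constant and time-dependent references, and their effect size
is the deviance R² = [DEV(Mcst) − DEV(Mcov)] / [DEV(Mcst) − DEV(Mt)].

## Worked example

```python
from cjskit import (StudyDesign, SimulationConfig, simulate_histories,
                    default_covariate_table, gof_suite,
                    suppress_first_encounter, CJSData, fit, parse_spec,
                    anodev, r_squared)

design = StudyDesign.default()          # 1978-2011, gap 2000-2003, 2 panels
covs = default_covariate_table(design, seed=2)
sim = simulate_histories(SimulationConfig(n_individuals=2000),
                         covariates=covs, seed=1)

report = gof_suite(sim.histories, design)
print("GOF (complete data): chi2 = %.1f on %d df"
      % (report.total_chi2, report.total_df))
reduced, n_dropped = suppress_first_encounter(sim.histories)
after = gof_suite(reduced, design)
chi2, df = after.subtotal(("3SR", "3SM", "2CL"))
c_hat = after.c_hat_from(("3SR", "3SM", "2CL"))
print("after suppression (%d dropped): residual chi2 = %.1f on %d df, "
      "c-hat = %.3f" % (n_dropped, chi2, df, c_hat))

data = CJSData.from_histories(reduced, design)
m_t   = fit(parse_spec("t", "m+t"), data, covariates=covs, seed=0)
m_cst = fit(parse_spec(".", "m+t"), data, seed=0)
m_cov = fit(parse_spec("LL_CC_br+SOIyr+SST_CC_2yr", "m+t"), data,
            covariates=covs, seed=0)
print("constant-model survival: %.3f" % m_cst.phi_se_tables[0][0])
n_t = int((~m_t.inestimable_intervals).sum())
res = anodev(m_cst.deviance, m_cov.deviance, m_t.deviance, 3, n_t)
r2 = r_squared(m_cst.deviance, m_cov.deviance, m_t.deviance)
print("three-covariate model: ANODEV F(%d,%d) = %.2f, p = %.4f, R2 = %.3f"
      % (res.df1, res.df2, res.F, res.p, r2))
for name in ("LL_CC_br", "SOIyr", "SST_CC_2yr"):
    row = m_cov.coef_frame().loc["z_" + name]
    print("  slope %-11s %+.3f (SE %.3f)" % (name, row["coef"], row["se"]))
```

prints:

```
GOF (complete data): chi2 = 820.8 on 115 df
after suppression (746 dropped): residual chi2 = 69.5 on 63 df, c-hat = 1.104
constant-model survival: 0.904
three-covariate model: ANODEV F(3,22) = 11.38, p = 0.0001, R2 = 0.608
  slope LL_CC_br    -0.158 (SE 0.052)
  slope SOIyr       -0.182 (SE 0.051)
  slope SST_CC_2yr  -0.097 (SE 0.047)
```

Reading this: the umbrella model fails GOF badly on the contaminated
data (the generator plants 30% transients and a +1.5 logit
trap-happiness offset); suppressing each animal's first encounter
removes the transience signal, and the residual components give a mild
ĉ. The constant model recovers the generating mean survival (0.915 on
the logit intercept, estimated 0.904 at n = 2000), and the three
generated covariate effects are detected jointly (ANODEV p ≈ 1e-4)
with slopes within sampling error of the generating values
(−0.104, −0.212, −0.137).

The same sequence is available from the shell:

```bash
cjskit simulate --seed 1 --n 2000 --out run/
cjskit gof --histories run/histories.csv --remove-transients
cjskit pipeline --config config.yaml --out run/ --seed 1
cjskit covtest --dev-cst 28553.4 --dev-cov 28486.2 --dev-t 28418.3 --n-cov 3 --n 28
```

## Layout

| module | contents |
| --- | --- |
| `cjskit.design` | occasions, gap years, monitoring panels |
| `cjskit.encounter` | encounter histories, `.inp`/CSV I/O, transience suppression, trap-state splitting, m-arrays |
| `cjskit.gof` | 3.SR / 3.SM / 2.CT / 2.CL components, pooling, ĉ |
| `cjskit.engine` | design matrices, CJS likelihood, fitting, survival series |
| `cjskit.covariates` | seasonal windows, lags, correlation screening, averaging/PCA reduction |
| `cjskit.selection` | QAICc, ΔQAICc, ANODEV, deviance R² |
| `cjskit.simulate` | generative CJS simulator and synthetic monthly series |
| `cjskit.pipeline` / `cjskit.cli` | end-to-end orchestration and the `cjskit` command |

See `docs/methods.md` for the modelling assumptions, numerical choices
and known limitations.
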