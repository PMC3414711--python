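# hydratherm

Thermochemistry of gas-phase hydration equilibria of cationized nucleobases
(Ura, Thy, Cyt, Ade with Na+ or K+), from pulsed-ion-beam arrival-time
distributions (ATDs) to van't Hoff enthalpies/entropies and the
tautomer-mixture affinity correlation.

Pipeline stages (one module each):

| stage | module | what it does |
|---|---|---|
| simulate | `hydratherm.synthetic` | drift-cell hydration kinetics (detailed-balance rate matrix), pulsed-injection ATDs with Poisson counting noise, noisy K(T) series |
| reduce | `hydratherm.reduction` | ATD peak integration with baseline correction and Poisson sigmas; equilibrium-attainment test (ratio vs. residence time) |
| K | `hydratherm.equilibrium` | `K = I_n * P_o / (I_{n-1} * P)` with `P_o = 1000 mbar`, uncertainty propagation, series aggregation |
| fit | `hydratherm.vanthoff` | weighted least-squares van't Hoff fit (ln K vs. 1/T) giving dH, dS, covariance, and dG(298), plus compact-uncertainty `62.3(2)` formatting |
| tautomer | `hydratherm.tautomers` | population-weighted metal-ion affinities (MIA), OLS binding-energy-vs-MIA correlation, leave-one-out effective-MIA inversion, simplex feasible-set enumeration |
| plumbing | `hydratherm.pipeline`, `hydratherm.cli`, `hydratherm.io`, `hydratherm.datasets` | TOML config, seeded end-to-end runs, CSV interchange, bundled reference tables |

## CLI

```sh
# noisy K(T) series -> CSV -> van't Hoff fit
hydratherm simulate --dh -61.1 --ds -66.1 --temps 350,400,450,500,550 \
    --noise 0.05 --seed 1 --out series.csv
hydratherm fit --series series.csv --out fit.json

# full ATD route
hydratherm simulate-atd --config sim.toml --seed 1 --out-dir atds/
hydratherm reduce --atd-dir atds/ --pairs pairs.toml --out reduced.csv
hydratherm k --reduced reduced.csv --out series.csv

# tautomer-mixture analyses (bundled reference tables)
hydratherm tautomer --mode weighted-mia --cation Na+
hydratherm tautomer --mode invert --cation K+ --binding 55.6
hydratherm tautomer --mode feasible --cation Na+ --target 177 --tol 1 --grid 0.02

# configured end-to-end run
hydratherm run --config pipeline.toml --out-dir out/
```

`sim.toml` holds `[conditions]` (temperature, pressures, pulse timing) and
`[scheme]` (`max_n`, `forward_pseudo_rates`, `true_thermo`); `pairs.toml`
lists `[[pair]]` entries naming reactant/product ATD CSVs. A pipeline config
is any subset of the `PipelineConfig` fields in TOML (unknown keys are
rejected); `hydratherm.pipeline.PipelineConfig().to_toml()` prints a template
with every default.

## Conventions

- R = 8.314462618 J/(mol K); standard pressure 1000 mbar; dG reported at
  298.15 K.
- Association dH/dS are stored signed (negative); report tables print the
  negated magnitudes, one decimal, round-half-even, with the 1-sigma
  uncertainty's last digit in parentheses.
- Every stochastic operation is a pure function of (inputs, seed); pipeline
  stages derive their seeds from the top-level seed by stable hashing.
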