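# kbb-endoexo

Endo-exogenous extinction-risk modelling for bivoltine butterfly
populations, built around the Karner blue butterfly (*Lycaeides melissa
samuelis*) survey design: repeated transect counts during two flight
periods per year across five isolated populations and 48 permanent sites.
The package is for population ecologists who have transect counts,
monthly site climate and site topography, and want to know which
density-dependent (endogenous) and density-independent (exogenous)
drivers move the per-generation growth rate.

## The model

Raw counts become densities via the transect convention that one
kilometer of walked transect samples a 2.5-ha belt:

    density (adults/ha) = mean count per km / 2.5

The per-generation growth rate is the density ratio between consecutive
generations, λ_t = D_t / D_{t-1}.  Each population × generation gets a
linear model on up to 18 standardized predictors,

    λ_t = β0 + β1·Y_{t-1} + β2·Y_{t-2} + β3·X1_t + … + β17·X16_t + ε_t

where Y are lagged densities (for the spring generation: previous-year
second generation PS and previous-year first generation PF; for the
summer generation: current-year first generation CF and previous-year
second generation PS) and X are 12 stage-windowed climate means
({mean, max, min temperature, precipitation} × {egg, larval/pupal,
flight} windows) plus elevation, slope, canopy cover and the topographic
solar-radiation index

    trasp = (1 − cos(π/180 · (aspect − 30))) / 2 ∈ [0, 1],

0 for north-oriented and 1 for south-oriented slopes.

Fitting runs in three stages: a 500-tree random-forest regression as a
distribution-free robustness/importance baseline; genetic-algorithm
subset selection minimizing the OLS AIC over the 2^18 predictor
combinations; and jack-knife partial least squares on the selected
subset, whose leave-one-out refits give coefficient standard errors and
t-based p-values.  Pooled "All" models across populations of unequal
series length are fitted by stratified balanced bootstrapping (equal
row quota per population in each replicate).

A synthetic-data generator simulates the whole study — climate,
topography, latent density dynamics driven by the same λ equation with
known coefficients, and Poisson-observed transect counts — so that every
stage of the pipeline is testable by parameter recovery.

## Worked example

```python
from kbb_endoexo import make_design_dataset, fit_population

ds, truth = make_design_dataset(400, noise_sd=0.3, seed=7)  # 6 active of 18
res = fit_population(ds, seed=7)
print(res.summary())
```

```
Endo-exogenous growth-rate model (jack-knife PLS)
==========================================================
population: SYN          generation: 1
nobs: 400    candidates: 18   selected: 8
PLS components: 2   R2: 0.938   adj. R2: 0.936
random-forest OOB R2: 0.735
----------------------------------------------------------
variable        coef        se      t/z         p  sig
PS           -0.5262    0.0165   -31.92  6.7e-112  ***
PF            0.4858    0.0158    30.67  5.6e-107  ***
MT_OW        -0.4055    0.0162   -25.09   4.8e-84  ***
AT_SP        -0.0135    0.0148    -0.91      0.36  ns
PT_SP         0.3946    0.0157    25.19   1.7e-84  ***
Canopy        0.2956    0.0146    20.26   2.8e-63  ***
Slope        -0.2863    0.0145   -19.68   9.6e-61  ***
Trasp        -0.0287    0.0154    -1.86     0.063  ns
----------------------------------------------------------
```

The generator planted six active predictors (PS −0.5, PF +0.5, MT_OW
−0.4, PT_SP +0.4, Canopy +0.3, Slope −0.3).  The GA recovered all six
with the right signs and magnitudes within two jack-knife standard
errors; the two extra variables it admitted (AT_SP, Trasp) carry
near-zero, non-significant coefficients — the expected cost of an
AIC-based search.  Coefficients are on the standardized scale, so −0.53
for PS means one standard deviation more density in the previous-year
second generation lowers λ by about half a standard deviation: negative
density dependence.

The same surface drives the full pipeline:

```
kbb-endoexo all --seed 42 --out run42        # synthetic end-to-end run
kbb-endoexo fit --surveys s.csv --climate c.csv --topo t.csv --out run
```

A run directory contains `densities.csv`, one design matrix per model,
`fits.json`, per-generation coefficient tables (`coefficients_gen1.csv`,
rows = candidate variables, columns = populations, blank cells =
GA-removed), and `run_manifest.json` with seeds, toggles and row-level
exclusion accounting.

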