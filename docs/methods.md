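# Methods

## Model and assumptions

The package implements the classical total-collection / indirect-calorimetry
energy balance for growing pigs. Per pig and balance period:

* **Heat production** is computed from chamber gas exchange and urinary N
  with the Brouwer equation, THP (kJ) = 16.18·O₂ + 5.02·CO₂ − 2.17·CH₄ −
  5.99·N, volumes in litres and N in grams. Each daily fed window is scaled
  to 24 h by duration and days are averaged. The respiratory quotient is
  CO₂/O₂.
* **Fasting heat production** is the Brouwer value of the terminal 8-h
  nocturnal fasted window scaled by 24/8. The 24-h fasting urinary N
  excretion is apportioned to the window by duration before the Brouwer
  computation; because both steps are linear this is identical to applying
  the full daily excretion once.
* **Energy partition**: DE removes fecal energy from GE intake; ME further
  removes urinary energy and methane energy at 39.54 kJ/L CH₄; retained
  energy is RE = ME intake − THP, split into protein retention
  RE_P = N retention · 6.25 · 23.86 kJ/g and lipid retention RE_L = RE − RE_P
  (an identity, enforced per pig and per mean); NE = (RE + FHP)/DMI.
  By default each pig's **own** FHP enters its NE, which damps the effect of
  between-animal variation in fasting metabolism; diet-mean and fixed-value
  policies are available.
* **Difference method**: the basal diet's GE/DE/ME/NE are divided by the
  basal mixture's DM fraction (0.975; the 2.5 % mineral/vitamin premix is
  treated as energy-free — the only reading under which that division is
  exact), the mixture contribution is subtracted from each test diet and the
  remainder divided by the test-ingredient fraction. Raw values are then
  converted to DE/GE, ME/DE, NE/ME ratios and chained onto the ingredient's
  bomb-calorimetry GE; these chained values are the headline outputs, the
  raw values are also reported. Inclusion fractions use explicit ingredient
  DM contents when supplied and as-fed percentages otherwise (exact when DM
  contents are equal).
* **Prediction equations**: Pearson correlations (two-sided p from the t
  distribution with n−2 df) and forward-with-backward-elimination stepwise
  OLS on partial-F p-values within four predictor families (composition
  only; composition + GE; + DE; + ME). Families are ranked by greatest R²,
  then least RMSE, then least AIC.

All energies are carried in kJ (volumes L, masses g/kg) and converted to
MJ/kg DM only at reporting. Negative N retention, retained energy or raw
difference values are reported with warnings, never clamped: impossible
physics in the *inputs* (negative volumes, non-positive intakes) raises
errors instead.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| Brouwer coefficients | 16.18 / 5.02 / 2.17 / 5.99 | kJ/L, kJ/g | standard energy equivalences |
| methane gross energy | 39.54 | kJ/L | standard conversion |
| protein energy per g N | 6.25 · 23.86 | g, kJ/g | N→protein factor × protein combustion energy |
| metabolic weight exponent | 0.6 | – | scaling base used for intake and heat in this design |
| basal mixture DM fraction | 0.975 | – | 2.5 % energy-free mineral premix |
| feeding level | 2000 | kJ ME/kg BW^0.6/d | chamber feeding level of the reference design |
| true FHP | 790 | kJ/kg BW^0.6/d | reference-design mean (range 752–828) |
| stepwise α-enter/α-stay | 0.15 / 0.15 | – | conventional stepwise defaults; configurable |
| AIC variant | n·ln(SSE/n)+2(p+1) | – | log-SSE form; the only one consistent with negative AICs on small panels. A likelihood-based variant is selectable. |
| RMSE denominator | n−p−1 | – | residual degrees of freedom |

## The synthetic-data generator

`generate_experiment` emulates a 6-diet × 6-pig × 6-period chamber
experiment. Ingredient truths (GE/DE/ME/NE, composition, per-nutrient
digestibility) compose to diet truths by DM fraction, with minerals
contributing dry matter only. Per pig, the partition is constructed in the
order ME intake → DMI → fecal E → urinary E (a configured fraction of DE,
default 3 %) → CH₄ E (the remainder of DE − ME, validated non-negative
before sampling) → RE = NE intake − FHP → THP = ME intake − RE, so the
closure GE = fecal + urinary + CH₄ + THP + RE holds identically. Gas
volumes are obtained by inverting the Brouwer equation at the diet's fed RQ
(fasted RQ 0.81 for the 8-h window), so the analysis pipeline returns the
intended heat exactly at zero noise.

Body weight is drawn as N(41.1, 2.2²) kg at allotment plus a mean 6.3 kg
gain to the collection days, giving ~47.4 kg means during balance; a
per-period BW increment is available but defaults to 0. Protein retention
is a drawn fraction of RE (mean 0.40, SD 0.06), from which N retention,
urinary N and fecal N (via the diet's CP digestibility) follow. The two
maintenance-level feeding days that precede fasting in the protocol are
emitted as separate windows (`maintenance_windows`) and excluded from all
balance computations.

Measurement noise is multiplicative log-normal with mean one per observable
(gas volumes, fecal/urinary energies, N), logit-additive for
digestibilities, and a 5 % CV on FHP representing between-animal variation.
The default CVs (gas 2 %, fecal energy 3 %, urinary energy 5 %, N 4 %,
digestibility logit SD 0.08) were chosen so that simulated diet-level
standard errors (n = 6) match the magnitudes typical of this design; only
standard errors of means are published for such experiments, so this
calibration is approximate by construction.

What the generator does **not** emulate: physiological growth and
thermoregulation, diurnal activity structure within a day, analyzer drift,
feed-intake refusal dynamics (refusals are assumed already netted out of
intake), and any effect of diet palatability (e.g. glucosinolates) on
intake. Passing recovery tests therefore demonstrates correctness of the
calculation chain and estimator behaviour under idealized measurement
error, not robustness to those real-world effects.

`generate_ingredient_panel` draws sample panels from a multivariate-normal
composition model (correlation matrix validated positive definite) with
linear energy models, reproducing the qualitative correlation structure of
rapeseed-meal panels: EE negative with CP, strongly positive with GE,
NDF–ADF strongly positive. Rows violating physical ranges or the
GE ≥ DE ≥ ME ≥ NE ordering are redrawn.

## Numerical choices

* Round trips (Brouwer inversion) hold to 1e-10 relative; zero-noise energy
  closure to 1e-9 relative; OLS is checked against a direct normal-equations
  solve at 1e-8.
* Diet means are unweighted arithmetic means across pigs; ratio rows
  (ME/DE, NE/ME, urinary E % of DE) are means of per-pig ratios.
* A zero-SSE fit reports RMSE 0 and AIC −∞; stepwise falls back to an
  intercept-only model (with warning) when nothing meets α-enter.
* Rank deficiency raises with the most collinear column pair named.
* Seeds: one master seed; per-pig substreams via spawned seed sequences, so
  datasets are reproducible and insensitive to record ordering.

## Problem sizes in the shipped checks

The test suite's Monte-Carlo recovery check uses 200 replicates of the full
36-pig design; the acceptance script uses 100 replicates. Both recover the
expeller-pressed group NE (truth 10.80 MJ/kg DM) to well within 5 % and
mean FHP (truth 790 kJ/kg BW^0.6/d) to within 2 %; at these replicate
counts the Monte-Carlo standard error of the pooled means is an order of
magnitude below those tolerances.

## Known limitations

* The published 8-sample correlation matrix and regression equations cannot
  be refit from the five shipped samples — three samples come from
  companion studies. The published equations are therefore provided as an
  applicable catalogue (`RSM_NE_EQUATIONS`), and refitting is exposed for
  users who supply the complete panel (see `data/rsm_panel_template.tsv`).
* Mixed-model standard errors and diet-effect p-values (random period and
  chamber effects) are out of scope; the reported means are unweighted.
* Stepwise selection on n = 8 panels is fragile by nature; the package
  reports all four family fits and the full metric set rather than a single
  automatic winner.
* The intermediate 890 kJ ME/kg BW^0.6/d feeding level is generated but not
  analyzed, matching the protocol's exclusion of those days.
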