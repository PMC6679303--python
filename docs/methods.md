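# Methods

This note documents the models, the synthetic study design, the filter
configuration and the numerical choices behind the package, in the order
the pipeline uses them. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## 1. Crop model

`wheatda.crop_model` is a reduced, water-limited, daily-step winter wheat
simulator in the WOFOST tradition. It deliberately keeps every state and
parameter the assimilation touches while replacing WOFOST's heavier
subroutines with documented simplifications:

* **Phenology.** Development stage DVS (0 emergence, 1 anthesis,
  2 maturity) advances with thermal time above `TBASEM`; anthesis at
  `TSUM1` (default 1000 °C·d) and maturity at `TSUM1 + TSUM2`
  (default +900 °C·d). No vernalisation or photoperiod response; the
  thermal-time totals are calibrated so that an early-October sowing
  reaches anthesis in late April and maturity in early June.
* **Leaf cohorts.** Each day's leaf growth forms a cohort with the
  current specific leaf area `SLATB(DVS)`. Cohorts age by
  `(Tmean − TBASE)/(35 − TBASE)` physiological days per calendar day, so
  a leaf at a constant 35 °C lives exactly `SPAN` days; cohorts beyond
  `SPAN` die. Because all living cohorts age equally, ages stay sorted
  and senescence removes a prefix — an O(1) bookkeeping detail that the
  ensemble runs rely on. During the juvenile phase (DVS < 0.3 and
  LAI < 0.75) leaf-area growth is sink-limited to
  `LAI · (exp(RGRLAI · dTeff) − 1)`; assimilate beyond the cap is
  discarded (the phase is short and the excess small).
* **Drought senescence.** Leaves additionally die at the rate
  `PERDL · (1 − T_act/T_pot)` (default `PERDL` = 0.03 d⁻¹ at full
  stomatal closure). This term is essential to the study: it is what
  makes water-stress errors visible in the LAI trajectory, i.e. the
  physical channel behind "soil-moisture assimilation improves the
  canopy simulation". Without it the canopy carries no stress footprint
  and the two assimilated variables decouple.
* **Assimilation and partitioning.** Gross growth is light-use
  efficiency × intercepted PAR (Beer's law, `k_ext` = 0.6; PAR taken as
  half of global radiation) × a daytime-temperature response `TMPFTB`
  × the water-stress factor. Q10 maintenance respiration is subtracted
  and net growth floored at zero, then split root/shoot by `FRTB(DVS)`
  and within the shoot by `FLTB/FSTB/FOTB(DVS)`. `LUE` = 3.0 g DM per
  MJ PAR is in the range wheat radiation-use-efficiency studies report.
  Growth stops at DVS = 2; the storage-organ pool is non-decreasing and
  is the grain yield.
* **Soil water.** A one-layer free-draining bucket of depth `RD`
  (default 50 cm, an effective control volume for the root zone the
  shallow-sensing SM observations constrain). Order of terms:
  infiltration, actual evaporation and transpiration (linear reduction
  factors between wilting point and field capacity / the critical point
  `SMW + 0.5 (SMFCF − SMW)`, jointly capped at the water above wilting
  point), rate-limited percolation of the excess above field capacity
  (`KSUB` = 3 cm d⁻¹), then saturation runoff. The returned flux record
  closes the balance to machine precision by construction, and the test
  suite verifies |residual| < 10⁻⁶ cm over whole seasons.
* **Potential ET.** A Hargreaves-type temperature–radiation formula
  (`0.0135 (Tmean + 17.78) · 0.408 Rs` mm d⁻¹), partitioned into soil
  evaporation and transpiration by canopy cover. This keeps wind and
  humidity optional; the function is the single swap-in point for
  Penman–Monteith.

Defaults (`default_crop_params`, `default_soil_params`) are a winter
wheat set in the spirit of the standard WOFOST cultivar files (TDWI 210
kg ha⁻¹, RGRLAI 0.00817, SPAN 31.3 d, SLA 0.00212 ha kg⁻¹) with a
fluvo-aquic loam retention triplet (0.12 / 0.32 / 0.46). They are
configuration, not ground truth; `wheatda.io` round-trips them through
JSON/YAML.

With the default climate the base run yields ≈ 5.5–7 t ha⁻¹ with peak
LAI ≈ 4–5 and water stress on roughly a third of spring days — a
moderately water-limited season, which is the regime the study needs
(irrigation-response and wet-vs-dry-yield monotonicity are property
tests).

## 2. Synthetic data

`wheatda.synthetic_data` generates everything the analysis consumes.

* **Weather.** Temperature is a seasonal sinusoid (annual mean 12.5 °C,
  half-range 14.5 °C, coldest mid-January) with Gaussian daily noise and
  a fixed 10 °C diurnal range. Rain occurrence is a first-order
  two-state chain with monthly stationary wet-day probabilities (dry
  winter, wet summer; implied annual total ≈ 640 mm) and exponential
  depths. Sunshine fractions are Beta-distributed (lower on wet days)
  and converted to radiation with the Angstrom formula
  `Rs = (a + b·n/N)·Ra` (a = 0.25, b = 0.50) using standard solar
  geometry for `Ra` and daylength `N`. The irrigation schedule follows
  regional flood-irrigation practice: ≈ 75 mm at pre-winter, green-up,
  jointing and heading, 60 mm at milk filling. The generator is a pure
  function of (spec, seed); the rain process is a plausibility device,
  not a calibrated climatology.
* **Observations.** The default plan has 7 LAI dates and 8 SM dates
  between late February and late May on the alternating ~12-day cadence
  of the two satellite streams. Noise is multiplicative:
  `obs = truth · (1 + eps)` with `eps` a *truncated* Gaussian relative
  error — the standard-normal draw is clipped at ±2 and rescaled so the
  sd is exactly the nominal 10% (LAI) or 35% (SM). Truncation reflects
  quality-screened retrieval products; an unbounded 35% Gaussian
  occasionally produces zero or negative moisture "retrievals", which
  no retrieval pipeline would ship and which an identity-operator
  filter has no defence against. An optional additive SM bias field
  emulates the surface-probe vs root-zone mismatch (off by default).
* **Regional grids.** Cells carry a uniform wheat fraction, a truth
  parameter set jittered per cell (10% on the six assimilation
  targets), and observations sampled from that truth on the shared
  plan. The assimilating model runs with base parameters everywhere, so
  the open-loop is cell-invariant by construction.

## 3. Twin-experiment design

One twin (`wheatda.study.run_twin`) differs from the assimilating system
in exactly the ways a real field differs from a regional model:

* The truth's six uncertain quantities — TDWI and WAV (initial
  conditions), RGRLAI and SPAN (canopy), SMFCF and SM0 (retention) —
  are one draw from the same 10% Gaussian prior the ensemble uses.
* The truth's irrigation depths deviate from the nominal schedule by a
  per-event Gaussian factor (sd 0.30, clipped to [0.4, 1.6]): farmers'
  actual applications are not in any regional database. The ensemble
  represents the same uncertainty by per-member forcing perturbation
  (the uncertain-input term of the forecast model). A rain-uncertainty
  channel exists but defaults to off: field-scale rain error is mostly
  unobservable noise between acquisition dates and adds no testable
  signal.
* Observation noise as in §2. The filter itself runs with Q = 0 (model
  and input uncertainties are not given to the filter beyond the
  ensemble spread — the study's stated setting).

A master seed is split into independent streams (weather, truth draw,
observation noise, filter) so every piece reproduces in isolation; all
four schemes share the seed and hence the identical initial ensemble.

What passing twin tests do **not** show about real data: there is no
retrieval physics (no radiative transfer, no backscatter model), the
truth comes from the same model family as the filter (no structural
error), and the SM observation is the model's own root-zone variable
(no sensing-depth bias unless enabled).

## 4. Filter configuration

The EnKF core (`wheatda.enkf`) implements the standard perturbed-
observation filter over an arbitrary state dimension; the study uses
x = (LAI, SM), Ne = 50, identity H. Four configurable safeguards,
all on by default (`SchemeConfig`), address small-ensemble and
multiplicative-noise pathologies that the audits in the test suite
measure directly:

1. **Second-order exact observation perturbations.** The `v_i` are
   centred, decorrelated from the forecast anomalies and rescaled to
   sample covariance exactly `R`. The posterior sample covariance is
   then exactly `(I − KH) P^f`, so every analysis contracts the
   variance of every observed variable — with raw N(0, R) draws at
   Ne = 50 that property only holds in expectation, and its violations
   would be routine. A `"raw"` mode retains the textbook sampler.
2. **Observation-variance reference.** The relative-error rule is
   applied to `max(observed, forecast mean)` rather than the observed
   value alone. With `R = (rel · obs)²` literally, an observation whose
   own multiplicative error pushed it low is assigned a *small*
   variance — the filter trusts most exactly the draws that are most
   wrong, which biases the analysed state (and hence growth and yield)
   downward. The literal `"observed"` mode is available.
3. **Innovation quality control.** Observations whose innovation
   exceeds 3·sqrt(H P^f Hᵀ + R) are rejected — the conventional
   gross-error background check.
4. **Cross-variable gain localisation.** The off-diagonal gain entries
   (LAI row of an SM observation and vice versa) are zeroed. At Ne = 50
   the sampled instantaneous LAI–SM cross-covariance is dominated by
   sampling noise — SM has days of memory while LAI integrates stress
   over weeks, so their same-day correlation carries almost no signal —
   and unlocalised cross-updates measurably degrade the canopy. The
   SM→LAI coupling instead acts through the model dynamics
   (stress-dependent growth and drought senescence), which is the
   physically meaningful channel. An optional Desroziers-style adaptive
   spread factor (per-variable, prequential, bounded to stay
   variance-contracting) is implemented but off by default: with only
   7–8 events per variable its single-event estimates are too noisy to
   help.

After each analysis the full crop state is reconciled
(`reconcile_state`): SM is clamped to the member's [SMW, SM0], leaf
cohort weights are rescaled multiplicatively so Σ wᵢ·slaᵢ equals the
analysed LAI (a fresh cohort is born if the member had no leaves), and
the biomass bookkeeping (wlv, tagp) follows. Analyses happen end-of-day;
records sharing a date form one stacked observation vector with diagonal
R (floored at 10⁻⁶ to keep the innovation covariance invertible).

## 5. Yield estimator and evaluation

The scheme comparison scores the **ensemble median** member yield
against the truth. The study's headline statistic is a median absolute
error, for which the predictive median is the matched point estimate;
the ensemble mean is biased low by several hundred kg ha⁻¹ because
yield is concave in the water-related parameters, and that shared bias
would blur the scheme contrast without informing it.

`wheatda.evaluation.metrics` implements R² (squared Pearson correlation
by default; `r2_method="fit"` gives 1 − SSE/SST), MRE (mean absolute
relative error, %; NaN with a warning if a reference value is zero) and
RMSE. `compare_schemes` builds the scheme table plus unrounded RMSE
decreases relative to the open-loop row, in a canonical scheme order.
`regional_run` applies the strict fraction > 0.40 masking rule, averages
observations sharing (date, variable) within a cell, and reuses the
single open-loop result across cells (it is independent of the
observations and all cells share inputs).

## 6. Problem sizes and numerical choices

The replicated study uses 50 independent twin seasons of 249 days at
Ne = 50 (the scripts expose both knobs); the regional experiment uses a
20×20 grid at Ne = 20; the linear-Gaussian oracle uses Ne = 10⁴ over 10
steps. A full acceptance run takes a few minutes on one CPU.

Degenerate inputs are handled explicitly: zero daylength at polar
latitudes (sunshine fraction defined as 0), TDWI = 0 (no canopy ever),
R = 0 observations (replicates equal the observation exactly),
ensembles of fewer than two members (rejected), perturbation draws that
violate the retention ordering SMW < SMFCF < SM0 (redrawn up to 100
times, then an error). Piecewise tables interpolate linearly and hold
end values outside their knot range. All covariance matrices are
symmetrised before use and the innovation covariance is condition-
checked (error beyond 10¹²).

Statistical caveat, measured rather than assumed: the per-scheme
median-absolute-error comparisons are noisy functionals. Across repeated
50-season studies with different master seeds the joint-vs-open-loop
reduction varies by roughly ±10 percentage points around ~25–30%, and
the SM→LAI paired-median improvement, while usually negative
(improving), is small relative to the 35% observation noise. The paired
per-season contrasts (same seed, same ensemble) are far more stable and
are the better evidence that the filter works; both views are written
out by `analysis/03_scheme_comparison.py`.

## 7. Known limitations

No vernalisation/photoperiod phenology, single-layer soil water, no
nutrient limitation, no CO₂ response, no retrieval forward models, no
covariance inflation (beyond the optional adaptive factor), and
state-only updating — parameters perturbed at ensemble creation stay
fixed per member, so persistent parameter error re-emerges between
analyses; that residual is visible in the open-loop-vs-perfect-obs gap
the study quantifies.
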