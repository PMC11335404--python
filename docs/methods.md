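# Methods

## The estimator

For a population that associates with aggregation sites ("floating
objects", FOBs — drifting logs, debris and man-made drifting FADs), the
abundance `N` in a stratum splits into an associated component `X_a`
(schools resident at an object) and an unassociated component `X_u`:

    N = X_a + X_u
    X_a = m * f_i * p

where `p` is the number of objects in the stratum, `f_i` the fraction of
objects holding at least the detection threshold of species *i*, and `m`
the mean biomass of species *i* per occupied object. Residency is treated
as an alternating renewal process with mean residence time CRT and mean
absence time CAT, so the long-run associated share of any school is

    X_a / N = CRT / (CRT + CAT)

and the recomposition used throughout is

    N = m * f_i * p * (1 + CAT/CRT),     X_u = X_a * CAT/CRT.

`X_u = X_a * CAT/CRT` is evaluated first and `N = X_a + X_u` formed by
addition, so the conservation identity holds to machine precision by
construction and the renewal-ratio identity to rounding error (tested at
1e-12).

Absence times are not observable in drifting arrays, so CAT is modelled
as inversely proportional to object density,

    CAT = 1 / (phi * p),

with `phi` (units 1/(FOB·day)) the per-object association rate of an
unassociated school. The assessments use the endpoint values
`phi = 2e-5` and `6e-5`, which bracket average CATs of 30 and 10 days at
study-area object counts. `cat_from_phi` is composed with the index
assembly rather than algebraically folded into it, so either sub-model can
be replaced independently.

Key consequence, verified exactly in the tests: when `p` is constant over
time the factor `(1 + 1/(phi p CRT))` cancels in the baseline-normalised
series, so the *relative* index is invariant to `phi`; only absolute
levels depend on the assumed CAT range.

## Stratification

Strata are square cells (default 10° × 10°) crossed with calendar
quarters. Cell bounds are half-open `[min, min+size)` so edge points
belong to exactly one cell. The five default cells in the western Indian
Ocean are illustrative placeholders: operational region polygons are
configuration. Cell size and the region list are configurable; the quarter
is fixed to the calendar definition.

## Inputs and their estimators

**Object counts (p̂).** Two regimes. From single-fleet buoy tracks:
multi-ping tracks are reduced to one position per buoy-day (last ping by
default; first/mean available), the daily count of distinct buoys per cell
is averaged over the quarter, and two user-supplied multiplication factors
(other purse-seine fleets; natural objects and debris) scale the result.
Days without a buoy in a cell count as zeros; the averaging window is the
part of the quarter covered by the dataset as a whole, so a partially
covered quarter is not diluted. Both factors default to 1 and must be set
by the user — their operational values are survey-specific calibration
inputs. From all-fleet gridded counts (1° × 1° monthly means of
operational buoys): 1° cells are assigned by their centres, summed per 10°
cell and month, averaged over the quarter's available months, and scaled
by the other-objects factor only (the grid already spans all fleets). A
switch date stitches the two regimes, preferring the grid from that date
onward and recording provenance per stratum.

**Associated biomass (m̂).** Declared catch-per-set is reconciled against
trip landing totals (each trip's sets are scaled so they sum to the
landing; trips without landing records, or with zero declared total,
are left uncorrected and flagged). Species/size compositions from
port-sampled sets are averaged per stratum subject to a minimum of 20
sampled sets; missing strata receive estimated marginal means from an
additive fixed-effects linear model (year + quarter + region) on the
observed per-stratum means, with predictions clipped to [0, 1]. The
identity-link additive form is the simplest faithful reading of a
least-squares-means procedure; it is isolated behind one function so a
different specification can be swapped in. Cells whose factor level never
occurs among observed cells fall back to the species' pooled mean (logged).
m̂ is the mean landing-corrected catch over *all* object sets in the
stratum (sampled or not) times the mean species proportion; strata under
20 total sets produce no index value.

**Occupancy (f̂ and f̂ᵢ).** Echosounder buoys report daily presence or
absence of tuna above a 1-tonne detection threshold. Each buoy's leading
run of absences is removed as the colonization period of a freshly
deployed object; nothing after a buoy's first presence is ever removed,
and never-occupied buoys drop out entirely. The daily fraction of occupied
buoys per stratum requires at least 30 reporting buoys that day; f̂ is the
unweighted mean of the retained daily fractions (weighting by daily buoy
count was the open alternative; unweighted was chosen so sparse late-quarter
days cannot dominate, and the choice is confined to `stratum_occupancy`).
Buoys cannot identify species, so the per-species occupancy is
`f̂ᵢ = f̂ · η̂ᵢ`, with η̂ᵢ the share of port-sampled sets whose catch of
species *i* reaches 1 t (≥, boundary inclusive), again subject to 20
sampled sets per stratum. Missing η̂ cells are imputed from a logit-link
binomial regression of occurrence counts on additive year + quarter +
region factors; separation, non-convergence or unseen factor levels fall
back to the species' pooled observed rate (logged). Note `f̂ᵢ ≤ f̂` is not
enforced as an invariant: η̂ comes from an independent data stream.

As a within-stratum homogeneity diagnostic, each stratum's daily occupancy
series is screened with an augmented Dickey–Fuller test (constant term,
AIC lag selection, significance 0.05); constant series are reported
stationary directly and series under 30 days as "insufficient data".

**Behavioural constants.** The CRT registry defaults to the acoustic
tagging values for the study system: skipjack 4.6 ± 4.8 days, yellowfin
under 10 kg 6.7 ± 7.8 days, bigeye under 10 kg 7.6 ± 7.2 days (standard
deviations are metadata, not used by the point estimator). The registry is
configuration and can be replaced per species/size class.

## Index assembly and uncertainty

Per-stratum estimates are averaged without weights over the strata
available in each quarter ("average abundance per 10° cell"); the
contributing stratum count is recorded. The relative series divides by the
value at a baseline quarter (default: the chronologically first quarter
available per species). The default standard error is the between-strata
standard error of the quarterly mean; a seeded nonparametric bootstrap
over strata is available. Input-level uncertainty (sampling error in m̂,
f̂, p̂) is *not* propagated — the s.e. quantifies spatial spread only,
which is the main open design choice in this module.

The associated-ratio series reports mean(X_a)/mean(N) per quarter; for a
single stratum it reduces exactly to CRT/(CRT+CAT).

## The simulator

The generator produces the structure the estimator assumes, with known
truth, so the whole pipeline can be validated by parameter recovery:

- Each region is a closed system: its schools choose uniformly among its
  objects, and the unassociated sojourn mean is `1/(phi * n_objects_region)`
  (or a directly specified `cat_days`). This mirrors the homogeneity
  assumption behind stratified estimation.
- Sojourns are exponential by default. Only means (with wide spreads) are
  reported for real residence times; the exponential is the minimal model
  consistent with the renewal-ratio identity, and a gamma option with
  matched mean is provided to probe robustness to that choice.
- Schools carry log-normal biomass (default mean-log 3.0, sd-log 0.5,
  i.e. a mean school of ~23 t, the order of purse-seine catches at
  objects); school counts default to a skipjack-dominated mix mirroring
  catch compositions at floating objects.
- Objects drift as reflected random walks inside their home cell, every
  object carries a reporting buoy, and a buoy-day is "present" when the
  biomass of its resident schools reaches the detection threshold (1 t).
  The first `colonization_lag_days` (default 7) after deployment are
  forced absent.
- By default all schools start unassociated (`start_state="empty"`): a
  freshly deployed array really is empty, so each buoy's leading absence
  run genuinely is colonization and the trimming step is exercised under
  its own assumption. The consequence is a transient of roughly one CAT at
  the start of the horizon during which occupancy rises to equilibrium;
  validation therefore reads estimates from quarters past that transient.
  `start_state="stationary"` draws initial states from the two-state
  equilibrium for tests of the stationary regime itself.
- Sets occur on occupied object-days as Bernoulli events (default rate
  0.02 per occupied object-day — a few hundred sets per 1500-object
  quarter), harvest the aggregation's biomass as the true catch, and are
  declared with multiplicative log-normal noise (sd-log 0.2) so the
  landing correction is exercised non-trivially; landings per trip (10
  consecutive sets) equal the true totals. Half the sets are port-sampled
  by default and receive exact species proportions. Fishing is
  non-extractive by default so the true biomass is constant over the
  horizon; the extractive mode removes caught schools and decrements the
  reported truth.
- One pseudo-random stream per observation layer, all spawned from the
  master seed; identical seeds give byte-identical tables.

What the generator does **not** emulate — and hence what passing recovery
tests do not establish about real data: objects never migrate between
strata or leave the study area; buoys never fail, change owner or stop
transmitting; port-sampling proportions are exact rather than estimated
from size sampling; species do not interact and schools neither merge,
split nor grow; CRT has no seasonal, regional or density dependence; and
the CAT model is the same functional form in generator and estimator, so
recovery validates internal consistency, not the inverse-density Ansatz
itself.

## Validation problem sizes and numerical choices

- Equation identities: 1000 random strata, tolerance 1e-12 (conservation
  is exact by construction).
- Renewal equilibrium: 100 schools × 100 days (1e4 school-days) with
  symmetric 0.1-day sojourns — about 5e4 completed renewal cycles, so the
  Monte-Carlo error (~0.2%) supports a 1%-level comparison of the
  time-averaged associated fraction against CRT/(CRT+CAT). The dynamics
  are scale-free in time, so short sojourns test the same mechanism at
  higher statistical power than day-scale ones would in the same number
  of school-days.
- End-to-end recovery: 20 seeded replicates of 2000 schools over 1500
  objects for 181 days; the estimate is read from the second quarter
  (past the colonization transient) and the mean relative bias must stay
  within ±10% (observed: about ±2%).
- Imputation recovery: the additive linear model must reconstruct held-out
  cells of a balanced additive design exactly (1e-9); the binomial model
  must recover logit-additive generating probabilities within 0.02 at 500
  sets per stratum.
- Degenerate inputs: zero object counts make CAT (and the index)
  undefined and raise; zero declared trip totals with positive landings
  are flagged rather than scaled; constant occupancy series short-circuit
  the unit-root test; empty input tables produce empty outputs with
  warnings rather than failures.

## Known limitations

Absolute levels inherit the uncertainty of the CAT Ansatz wholesale — the
phi grid brackets it but does not resolve it; the relative index is the
robust output. The between-strata s.e. understates total uncertainty.
The estimated-marginal-means and binomial imputations assume additivity
across year, quarter and region. The first quarter of a simulated (or
real, freshly instrumented) array carries a colonization transient during
which occupancy-based quantities are biased upward; estimates there
should be read with caution.
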