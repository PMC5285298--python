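# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices and the known limitations of `gpmobility`.

## The structural model

Two practices, each run by a profit-oriented manager and needing one doctor,
sit at distance-related relocation cost *t* from each other. Doctors are
efficient (*v*, effort cost parameter γ_v ∈ (0,1]) or inefficient (*nv*,
γ_nv = 1, a normalisation). A new doctor hired from the labour market is
efficient with probability π and has outside option 0, so equilibrium wages
are 0 unless competition bids them up. Quality is Q = q + e (practice
investment plus doctor effort); practice revenue is m + pQ (capitation plus
the quality price); costs are quadratic in e and q.

Closed forms implemented (and verified by an independent numeric oracle):

* salaried effort e = 1/γ; partner effort e = (2+p)/(2γ); investment q = p
  under either contract;
* expected new-hire profit Π^N = m + p²/2 + p(γ_v + π − γ_v π)/γ_v;
* manager profit with a partner Π^M = [γ(2m+p²) + p(p+2)]/(4γ) − w/2;
* partner utility U^P = b + (p+2)²/(8γ) + (2m + p² + 2w + 4p)/4.

Two expressions in the source derivation are typeset ambiguously; both
readings were resolved by re-deriving from the primitives. The new-hire
profit contains p²/2 (substituting q = p and e_z = 1/γ_z into the profit
function yields it exactly), and the contested profit is defined structurally
as Π̃ = Π^M(0) − w̄₁/2, which makes the identity Π̃ − Π^N = b₁ − b₂ + t hold
to machine precision, as the theory requires.

Partnership regions: membership of S = S₁ ∪ S₂ is evaluated from the printed
inequalities (m < m̄, price above p̄ on the high-π branch, γ < 1). The
package's tests verify that this set is *exactly* the set where
Π^M > max(0, Π^N) by brute-force comparison; the m̄ condition makes the p̄
condition partially redundant, so the printed form is safe even though a
re-derivation gives a slightly different p̄ expression. Ŝ additionally
requires 0 < t < Π_v^M − Π_nv^M.

Stage-1 ties (exact profit equality) resolve to the status-quo new salaried
hire — deterministic and conservative. Equal profit sharing between partner
and manager is hard-coded; a nonzero partner wage is supported as an argument
but defaults to the zero outside option.

### Numeric oracle

`numeric_oracle` solves stage 2 by simultaneous best-response iteration: the
doctor maximises utility over e ∈ [0, 50] and the practice profit over
q ∈ [0, 50], each by golden-section search (interval tolerance 1e-10,
followed by one guarded Newton polish step that removes the O(√ε)
comparison-noise of value-only search — the objectives are exactly quadratic,
so one step suffices), iterating to a fixed point (tolerance 1e-8, max 200
iterations, convergence error otherwise). The search boxes contain every
interior equilibrium for the supported ranges (p ≤ 10, γ ≥ 0.05); at p = 0
the investment optimum sits on the box boundary and the search snaps to it
exactly. Oracle-vs-closed-form agreement is ~1e-11, far inside the 1e-6
verification tolerance.

### Comparative statics

Signs are central finite differences with step h = 1e-5·max(1, |x|),
scale-robust and exact in sign for these smooth expressions. If perturbing a
parameter crosses the feasibility-region boundary (or leaves the parameter
domain), the function warns and returns no sign rather than a meaningless
one.

## The QOF revenue engine

Points per indicator: 0 at or below the lower threshold, max points at or
above the upper threshold, linear between — the ramp is continuous and the
scheme's only nonlinearity. Achievement is stored as a fraction in [0,1]
internally and rendered as percent at I/O. Points are continuous (the ramp is
linear by construction; nothing suggests integer rounding). Records with zero
denominators are dropped from both the numerator and the denominator of the
points proportion: undefined achievement cannot earn points.

The default synthetic registry has 146 indicators, all with the 0.40 lower
threshold, upper thresholds cycling over 0.70/0.75/0.85/0.90, max points
cycling over 3–12 (≈1,100 points total), and prices £76 (2004) and £125
(2005 onward). Four CVD-control indicators (56 points total) have their upper
thresholds raised from 0.70 to 0.90 in 2006 — the only 2006 change, so a
practice whose performance is unchanged can only lose. The price shock is the
revenue difference on that subset from applying the 2006 scheme to 2005
achievement, expressed in money and as a percent of the practice's total 2005
revenue (the regression variable); under the default generator it averages
about −0.8% with a minimum near −2%, i.e. losses of up to a couple of percent
of QOF income.

## The synthetic census

The generator emulates the statistical structure of an English GP workforce
census (2003–2007): ~500 practices with Poisson(4)+1 doctors each (~2,500
doctors), practice deprivation (gamma-distributed, mean ≈ 11), list size,
age-sex mix and opening year drawn from bounded distributions with
census-like means, uniform locations on a ~3°×3° region, and doctors with
age ≈ N(45, 10), 42% female, efficient with probability 0.15.

The quality-price path is p = 0 (2003), 1 (2004, normalising £76/point to
one model unit), and 125/76 ≈ 1.64 from 2005 — the scheme's introduction and
price rise. Structural defaults m = 0.05 and γ_v = 0.5 put the efficient
type inside the partnership region from 2004 onwards, so all three
qualitative implications are live under the defaults.

Per census year, in order:

1. **Exit**: latent index −0.08·max(years-to-retirement, 0) + u, u ~ N(0,1);
   doctors exit as retirement approaches (~6–8% per year). Each doctor has a
   personal statutory retirement age (65 ± 3, reflecting cohort- and
   scheme-specific pension rules), which keeps years-to-retirement from being
   a deterministic function of age — without that variation the exclusion
   variable would be exactly collinear with the age quadratic.
2. **Mobility** (stayers only): structurally feasible when the doctor is
   efficient, the parameters are in S, the relocation-cost draw
   (0.05/mile × distance to a random one of the 10 nearest practices) is
   below the poaching bound, and the rival's amenity (1 − 0.03·LISI) is
   higher. Latent −1.9 + 1.4·feasible + v with corr(u, v) = ρ (default 0.3):
   baseline mobility ≈ 2.3%, rising to ≈ 4% once the scheme starts. The
   u–v correlation is what makes naive mobility regressions selection-biased
   and the stacked-IMR correction binding. Poached efficient movers arrive as
   contested partners.
3. **Partnership promotion**: gated on the stage-1 contract choice (never for
   the inefficient type, never at p = 0), accepted with logistic probability
   in the profit advantage (scale 0.5).
4. **FTE** = clip(91 + 5·(e − 1) + a_i + ε, 11, 100) with doctor intercept
   σ_a = 4 and residual σ_ε = 8. The anchor maps a full-time salaried
   inefficient doctor at p = 0 to 91 (the census mean); the slope of 5 FTE
   points per effort unit keeps partner effort under the QOF from saturating
   the 100 cap, which a direct 100·e/e_max map would do for every partner.
5. **Practice quality** = clip(80 + 4.5·(q + mean effort) + d_j + ε, 0, 100),
   σ_d = 2, σ_ε = 1.5 — roughly 85% pre-QOF rising to ~96% at the 2005 price.
6. **Entry**: vacancies left by exits are filled with probability
   logistic(1.5 − 1.0·p): ~4.7% new-entrant rate in 2004 falling to ~3.1%
   after the price rise (partnership lock-in crowding out salaried entry).
7. **Price shock**: computed once per practice through the revenue engine and
   attached to 2006 rows.

Covariates are dated t−1 for incumbents (practice covariates from the origin
practice for movers) and contemporaneously for entrants, whose history is
unobserved. One internal burn-in year precedes the observation window so the
first emitted year has well-defined lags, mobility and entry. Income is a
latent affine function of FTE and partner status discretised into eight
£25,000 survey bands and recoded to band midpoints; the open top band gets
the midpoint it would have at the same width (£187,500). The eight-band
structure with a £25,000 width necessarily tops out above £175,000 — no
arrangement of equal-width bands can both start the top band at £150,000 and
contain eight bands below it, so the band edges run 0, 25k, …, 175k.

Distances are Vincenty inverse geodesics on WGS-84 (tolerance 1e-12, 200
iterations, great-circle fallback with a warning on near-antipodal
non-convergence; 1609.344 m/mile), verified against an independent geodesic
implementation to ~1e-12 relative error. The distance-to-best-practice
variable is the distance to the highest-QOF practice among the 10 nearest,
ties to the nearer one; the alternative reading (the furthest of the 10) is
available behind a flag because the source description of this variable is
self-contradictory, and no behavioural consequence hinges on the choice.

**What the generator does not emulate**: real UK geography and postcodes,
practice births/closures, survey weighting, doctors holding multiple posts,
any behavioural response to the practice-specific price shock (the shock is a
constructed covariate, so the first-difference fits exercise the estimator's
mechanics rather than recover a known causal effect), and the real QOF's
prevalence adjustment and exception reporting. Passing tests therefore show
that the estimators recover the structure the generator encodes — not that
the substantive conclusions hold in real censuses.

## Estimators

Ordinary fits are statsmodels behind the module surface: OLS (optionally
practice-clustered; conventional SEs by default since no particular
correction is canonical here), Newton–Raphson probit (perfect separation and
NaN/diverging likelihoods surfaced as errors, never silent), and MixedLM
full-ML for the random intercept. MixedLM is fitted with BFGS first and
Powell/L-BFGS as fallbacks, rejecting any "converged" point with a non-finite
likelihood — L-BFGS can stall at the σ_u² = 0 boundary. Variance components
are profile-ML; tests verify them against an independent profile-likelihood
GLS oracle and the σ_u² = 0 degenerate case against OLS. The default grouping
level is the practice (doctors are nested in practices and group counts are
reported at that level), with doctor-level grouping available by flag.

Age enters as a quadratic wherever it appears, centred at 45 for numerical
conditioning, with coefficients reported back on the original scale via the
delta method. Linear probability fits are never clipped; the share of fitted
values outside [0,1] is reported instead.

The selection model is the two-step: year-by-year probits of staying in the
market (exclusion variable: years to statutory retirement), the inverse Mills
ratio λ = φ/Φ evaluated at each year's linear index, stacked across years and
joined to stayer rows as a second-stage covariate. λ is computed as
exp(log φ − log Φ) through `scipy.special.log_ndtr`, accurate to ~1e-12
absolute down to indices of −40 (verified against 30-digit symbolic values).
Years with a single stay class are flagged and skipped with a warning. The
second stage is a random-intercept model when a grouping level is set. No
FIML variant is provided, and the second-stage SEs are not adjusted for the
generated regressor — bias reduction, not efficient inference, is the
estimator's contract here, and the recovery studies measure exactly that.

First differences across 2005–2006 drop any covariate whose within-doctor
difference is constant (gender; age, whose difference is identically one)
with a warning; the price shock and the stacked IMR enter in levels. The
quintile split assigns practices to quintiles of 2004 QOF performance with
ties to the lower quintile. No multiple-testing correction is applied;
significance stars follow the 10/5/1% convention.

## Problem sizes

The test suite and the acceptance script scale their simulation studies to:
1,000 parameter draws for the oracle and identity checks; 50 census seeds at
the full default size (500 practices, ~2,500 doctors, 5 years) for the
implication checks; 100 replications of the 500×8 random-intercept recovery;
200 (ρ = 0.5) and 100 (ρ = 0) replications of the three-year selection
benchmark at 600 doctors/year (the acceptance script uses 50 random-intercept
replications); and 200 replications of the two-period first-difference
benchmark at n = 500. These sizes give Monte-Carlo standard errors an order
of magnitude below the effects being checked.

## Known limitations

* The theory is a duopoly with one doctor per practice and two types; no
  N-practice or continuous-type generalisation, no multi-period contracting.
* The generator's partner-share path drifts downward over the window (new
  entrants are salaried and promotions only partly offset partner exits); the
  cross-sectional partner share, not its trend, is the calibrated quantity.
* The price-shock distribution is milder than a real scheme's tail, because
  the synthetic registry's CVD share of total revenue is ~5% and achievement
  noise is homoskedastic.
* Mobility in the first observable year is defined against the internal
  burn-in year, which shares the first year's price; configurations whose
  first year already has p > 0 therefore start with structurally elevated
  mobility.
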