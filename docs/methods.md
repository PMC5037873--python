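# Methods

## Model and assumptions

Whole-body retinol kinetics are described by a linear, time-invariant
six-component model per tracer arm.  A unit oral bolus enters the gut
compartment; unabsorbed tracer leaves irreversibly from there.  Absorbed
retinol transits the enterocyte pool and reaches plasma either through a
direct shunt (portal uptake / chylomicron-surface exchange, needed to fit
the earliest sample) or through a pure transport delay representing
chylomicron assembly, circulation, and hepatic remnant uptake, followed by
hepatic processing and secretion on retinol-binding protein.  Plasma retinol
exchanges with a single extravascular storage pool, which is the only site
of irreversible utilization.  All fluxes are first order; tracer and tracee
kinetics are identical (true tracer assumption); the tracee system is at
steady state over the two-week study.

The β-carotene arm is structurally parallel.  Intestinal β-carotene
handling and cleavage are collapsed into its gut/enterocyte compartments;
everything from plasma onward shares the retinol arm's coefficients, which
is what the observed parallelism of the two curves from ~12 h onward
expresses.  Non-absorption and non-conversion are not separated — both are
folded into the single constant P(11), so 1/(1+P(11)) is the fraction of
the carotene dose delivered to plasma as retinol.  Bioefficacy estimates
are therefore *relative* to a 75%-absorbed retinol reference.

Delay semantics: the delay elements are **pure transport delays** (output =
input shifted by DT).  The original analysis software realizes delays
internally as short compartment chains with some dispersion, but only a
single delay time per element is reported, with no dispersion parameter, so
the pure delay is the reproducible reference contract here.

## Solution method

The system is linear and the delayed signal is the output of an autonomous
upstream block (gut → enterocyte), whose solution is a closed two-
exponential form.  Each arm's state is therefore computed **exactly** as the
sum of two augmented-matrix exponentials: one subsystem for the direct
enterocyte→plasma route evaluated at t, and one for the delayed route
evaluated at t − DT (zero beforehand).  Integrator rows in the augmented
matrices carry the cumulative first-pass plasma arrival, cumulative
irreversible loss, and the running FD time-integral.  Accuracy is limited
only by floating point — mass-balance residuals are ~10⁻¹⁵, against a 10⁻⁶
contract — and evaluation is fast enough (≈0.5 ms per curve) for the
replicate fitting studies.  An independent fixed-step RK4 integrator with
the method of steps (step 10⁻⁴ d) serves as the test oracle, as does an
adaptive-quadrature occupancy integral for residence times.

Degenerate inputs: L(10,6) = 0 makes residence times and the steady state
infinite; the summary and bioefficacy operations reject it with a
validation error rather than returning infinities.  Near-equal upstream
rate constants are handled with expm1-based stable forms.

## Fitting

Stage one fits the [¹³C₁₀]retinol curve for {L(2,1), L(5,2), DT(3), L(5,4),
L(6,5), L(5,6), L(10,6)}; stage two fits the [¹³C₅]retinol curve for
{P(11), L(15,12), DT(13), L(15,14)} with all shared coefficients fixed at
the stage-one estimates.  The objective weights squared residuals by
1/(0.05·y_obs)² — a 5% fractional standard deviation on the observed
values — with a variance floor of (0.05·max(y)/100)² so near-zero
observations cannot dominate.  The t = 0 sample is excluded (the model
fixes FD(0) = 0) and nonpositive observations are dropped with a logged
notice.  Weighting by observed rather than predicted values is a
documented choice; the original software's convention is not stated.

Rates are optimized in log space (positivity by construction); delay times
are bounded to [0, 1] d.  The optimizer is trust-region-reflective least
squares (through lmfit) with finite-difference Jacobians, ftol = xtol =
10⁻¹⁰.  Covariances come from the unscaled inverse of the weighted
normal-equations matrix (`scale_covar=False`), so a log-space standard
error is directly the fractional standard deviation (FSD) of the rate and
reflects the assumed 5% measurement model rather than the realized
residuals.  A parameter with FSD > 0.5 is flagged poorly identified.
Default starting values are the published cohort means.

## TTP50%

The time to plasma is defined on **first-pass** arrival: the root of
∫₀ᵗ [L(5,4)·q₄ + L(5,2)·q₂] ds = 0.5 × absorbed fraction, found by
bracketing and Brent's method to 0.01 h.  Instantaneous plasma content
never reaches 50% of the absorbed dose in this model class, so cumulative
first-pass arrival is the only self-consistent reading of "time at which
50% of the absorbed tracer is present in plasma"; recycled re-entries from
stores are excluded.  M(5) uses the arithmetic mean of the available
[¹²C]retinol samples.

## Synthetic cohort

The generator reproduces the study conditions: n = 30 subjects, the
0 h–14 d schedule, doses of 2.954 μmol retinyl acetate and
3.237/0.366/0.055 μmol carotene isomers (6.895 μmol RAE), body weight
65.2 ± 10 kg (lognormal), plasma retinol 1.53 ± 0.27 μmol/L truncated to
the observed 1.13–2.32 range, and 5% proportional lognormal measurement
noise (mean-1 factors; the t = 0 sample stays exactly zero).  Kinetic
parameters are drawn independently from lognormal distributions
moment-matched to the published cohort means ± SDs; lognormal because
several cohort CVs exceed 1 (L(2,1): 24.2 ± 39.0), which would make normal
draws frequently negative.  Delay draws are capped at 1 d.  No
between-parameter covariance was published, so independence is the default;
a correlation matrix for the underlying z-scores (Gaussian copula) can be
supplied for sensitivity studies.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: assay background and absolute detection noise on
the earliest samples (noise is purely proportional, so tiny early
observations are unrealistically informative and the early-phase
parameters L(2,1), L(5,2), L(15,12) come out better identified than in the
real study), within-subject error correlation, tracee nonstationarity, and
isotope spectral interference.

## Quality screening

Six rules applied in order with short-circuiting, so each excluded subject
carries the first matching code: missing critical time points (default
6 h, 12 h, 2 d, 14 d); negative FD after background subtraction (tolerance
10⁻⁶); positive terminal log-slope on either curve; converging or
diverging curves, from the slope of log(fd_C5/fd_C10) over the terminal
window (days 2–14) — positive slope means the ratio rises toward 1, i.e.
the semilog curves approach each other (converge); negative means they
spread (diverge); and an abnormally high [¹³C₁₀]retinol peak (default
bound FD 0.30).  In concentration mode the background defaults to each
analyte's t = 0 sample.

A slope counts as significant only if it exceeds **both** 2× its OLS
standard error and an absolute floor of 0.05 d⁻¹.  With a three-point
terminal window the estimated SE has one degree of freedom and a pure
2×SE rule misfires on ~30% of clean subjects; the floor makes the screen
deterministic at this noise level while remaining configurable.

The 45-subject screening fixture draws subjects from the unchanged
population and keeps those whose clean curves pass screening before
injecting the fifteen anomalies (1 missing / 3 negative / 3 positive slope
/ 3 converging / 1 diverging / 4 high peak).  This is deliberate: under
the full published dispersion a minority of genuine draws fail screening
on their own (very slow hepatic release makes the curves genuinely
non-parallel; low plasma turnover pushes the peak over the bound) — the
same physiology the original study excluded subjects for — and the fixture
is meant to isolate the screening logic.  Slope-type injections replace
the terminal window with an exact log-linear segment so the intended flag
is deterministic.

## Numerical and reporting conventions

Days are the internal time unit everywhere; hours appear only at the
reporting layer (TTP50%, t½(5), delay times × 24).  The absorption
constraint is implemented as L(0,1) = L(2,1)/3 exactly (75.0% absorbed);
the commonly printed factor 0.333 is a rounding of one-third.  CSV outputs
carry six significant digits with units in the header; dietary input
U(1) = DR/0.75 is reported as a steady-state extrapolation, flagged as
such.  The μg:μg RAE equivalence string uses molecular weights 546.8 and
286.5 with 2:1 maximal stoichiometry and is presentation-only: published
μg-ratio figures do not state their arithmetic, and no quantitative result
depends on it.

## Problem sizes

Test-suite studies use the sizes stated with each test: 50 noise
replicates for the fitting study, 100 parameter draws for conservation,
10,000 draws for population moments and bioefficacy, 2000-day horizons for
AUC/occupancy quadrature, and a 30-subject cohort for end-to-end recovery.
The full suite runs in well under a minute on one core.

## Known limitations

Single extravascular pool (no liver/periphery split); no saturable
absorption or bioconversion; no retinoic-acid metabolite tracking; the
two-week horizon makes stores estimates somewhat sensitive to the terminal
slope (the original investigators judged ~9% low vs a 56-day design);
bioefficacy estimators assume parallel post-plasma handling of the two
labels.  The day-2 isotope ratio under this model sits slightly *above*
the AUC-ratio bioefficacy (the carotene arm's slower upstream leaves
relatively more recently arrived tracer in plasma at day 2), whereas the
real cohort's observed day-2 ratio sat slightly below its AUC estimate;
the single-sample method's calibration is data-dependent and the package
reports it as an index, not a calibrated estimator.
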