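# Methods

## The model

The cell's proteome is coarse-grained into two sectors whose fractions sum
to one: a ribosomal/biosynthetic sector obeying the growth law
φ_R = ω_R λ, and a nutrient-scavenging sector φ_C = 1 − φ_R. Glucose
limitation is imposed by a non-metabolizable glucose analog at ratio `a`
relative to glucose; with uptake saturated (K_Ma → 0) the drug-free growth
rate is

    λ0(a) = 1 / (ω_R + ω_C (a + 1)).

Trimethoprim at concentration `c` binds the folate-pathway enzyme FolA
with equilibrium constant K_Mc, leaving free enzyme χ/(1 + c/K_Mc) out of
total expression χ. Growth is ribosome-limited until free FolA drops below
a constant demand χ_X, then FolA-limited:

    λ(a, c, χ) = λ0(a) · min(1, (χ/χ_X) / (1 + c/K_Mc)).

Rescaling λ by ω_R, c by K_Mc, and χ by χ_X leaves a single dimensionless
parameter A = ω_C/ω_R; dimensional/rescaled equivalence is enforced to
1e-12 in tests. The kink of the min() is structural (the regime switch),
so the drug-response fit uses a derivative-free optimizer rather than
smoothing it away.

Assumptions worth keeping in mind: demand χ_X is constant; c is treated as
the free ligand concentration (no depletion of drug by binding); the model
does not attempt the non-monotonic growth rescue seen under extreme
limitation.

## The regulation surface

Expression of the drug target is not a free variable: it follows growth.
The measured map F(a, c) is built by ordinary least squares of expression
against c, per limitation node (defaults a ∈ {0, 2.5, 5, 10}), restricted
to c ∈ [0, clamp_c] with clamp_c = 0.4 µg/ml — the concentration above
which expression across conditions converges — and clamped there for
larger c. Replicates enter the regression with equal weight; evaluation
interpolates the node lines piecewise-linearly in `a` and refuses to
extrapolate outside the node hull unless asked. Records with a > 10,
growth < 0.05 1/h, or zero fluorescence are flagged out before any fit.

Feedback rewiring replaces the surface: `constant` pins expression at
χ₁ = F(0, 1 µg/ml); `inverted` runs from 2χ₁ at c = 0 linearly down to χ₁
at c = 1 µg/ml and stays there — the loop turned from negative to
positive.

## Two-stage fitting

Stage one fits (ω_R, ω_C) to near-drug-free records (c < 0.1 µg/ml) by
least squares on λ0(a). Stage two fixes those, substitutes χ = F(a, c),
and fits (K_Mc, χ_X) by Nelder–Mead over log parameters from 8 seeded
multi-starts. Only χ/χ_X enters the model, so χ_X is identified relative
to the surface's expression units; rescaling both leaves predictions
unchanged (tested). If every record sits in the ribosome-limited regime
the demand is unidentifiable and the fit raises rather than returning an
arbitrary value.

With growth-dependent regulation, the per-node regression line is a linear
approximation to a slightly curved expression-versus-c path (the
closed-loop fixed point bends it), which leaves a few-percent systematic
offset in recovered K_Mc even without noise. The parameter-recovery suite
therefore measures two things separately: exact recovery (ω to 1e-6, K_Mc
and χ_X to 1e-4) in the open-loop configuration where expression is
exactly linear in c, and 10%-accurate recovery at 2% measurement noise
(n ≥ 200, 20 seeds) on data generated by the model at the fitted surface.

## Growth and expression quantification

Growth rates are the least-squares slope of ln(signal − blank) versus
time, converted to 1/h, inside a fixed window of background-subtracted
signal: OD 0.02–0.2 for rich medium, 0.03–0.12 for minimal (one order of
magnitude, at least two doublings), 1e2–1e5 cps for luminescence. Rich-
medium data after 1,000 min are discarded (sporadic fast-growing mutants);
fits below 0.1 / 0.03 1/h (rich/minimal) are rejected. When noise
fragments the window, the longest contiguous run wins, earliest on ties.

Two numerical details: window membership is judged on a 3-point rolling
median, and one guard sample is trimmed from each end of the selected run.
Raw thresholding admits boundary points only when noise pushes them inside
the window — upward at entry, downward at exit — which biases the slope
low by ~1.6% at 5% CV; the median + guard variant is unbiased within one
standard error in the round-trip calibration (100 seeds) and leaves
noiseless fits exact. Non-positive background-subtracted values are
dropped pointwise, not clipped, since clipping biases the slope.

Expression levels follow the reporter/control design: the control strain's
background-subtracted fluorescence is linearly interpolated to the
reporter's OD values inside the reporter's exponential window and
subtracted; the expression level is the slope of the corrected
fluorescence against OD. Extrapolation beyond the control's OD range is
refused; a reporter/control growth-rate mismatch beyond 20% (relative)
raises a warning flag. Replicate aggregation before Hill fitting defaults
to mean ± SD per condition; fitting pooled points is also supported.

## Hill fitting and contours

Dose–response curves are normalized by the mean zero-dose growth rate and
fitted with 1/(1 + (c/IC50)^n) over (log10 n, log10 IC50) — positivity and
scaling for free — with 5 seeded multi-starts; parameter SDs come from the
Gauss–Newton covariance and are propagated from log space, the 95% CI on n
is the log-space ±1.96 SD interval. An optional exclusion drops growth
rates below 0.2 1/h, which would otherwise dominate fits of strongly
inhibited curves while carrying little shape information. Checkerboard
contours interpolate normalized growth linearly against log concentration
between bracketing columns (linearly in c when the left bracket is the
zero-dose column); rows that never cross are left/right-censored, and
non-monotone rows (the rescue regime) return the first crossing with a
multiplicity flag rather than being silently averaged.

## Synthetic data: what it emulates, what it does not

The generator closes the loop the analysis assumes: expression follows a
growth-linear law χ(λ) = chi_max − slope_λ·λ (maximum at zero growth),
blended linearly in c toward a common convergence level at clamp_c and
constant beyond; growth follows the resource model given χ; each emitted
record is the unique fixed point of the two (the right-hand side is
non-increasing in λ, so bisection on [0, λ0(a)] finds it; a damped
fixed-point iteration agrees to 1e-10 in tests). Measurement noise is
multiplicative lognormal: 5% CV per signal read (plate-reader scale), 3%
CV on fitted growth rates in the screen ensemble (day-to-day rate
reproducibility), plus a 1e-4 a.u. additive OD floor. OD time courses are
exponential to a hard carrying capacity, so the exponential window stays
exactly log-linear. All randomness derives from the config seed;
identical configs are byte-identical.

The mutant ensemble maps each strain's drug-free growth rate to an
effective limitation ratio (inverting λ0) and computes its drug response
through the fixed point — deliberately encoding only the growth-mediated
pathway, with no gene-specific drug interactions. The screen normalizes by
the same measured g0 it correlates against, so rate noise enters both axes
and produces a small negative ratio artifact even without feedback
(≈ −0.08 at 3% rate CV, n = 500); this is a property of real screens too
and bounds how clean the no-feedback null can be.

Passing tests on these data show the machinery is correct under the
model's own assumptions; they do not show that real plates lack lags,
instrument drift, well-to-well coupling, or gene-specific drug effects —
none of which the generator emulates.

## Calibrated defaults

No fitted parameter values are available to ship, so the package fixes
plausible scales and calibrates the rest once (`scripts/calibrate.py`):
ω_R = ω_C = 0.5 h (maximal drug-free growth 1 1/h; A = 1, so a = 2 halves
drug-free growth), χ_X = 1 (expression in units of demand), drug-free
expression at full growth equal to the demand, and a coarse grid over
K_Mc and the regulation level, scored against the dose-sensitivity chain
n ≈ 1.1 (wild type) / 2.0 (constant) / 5.0 (inverted) / 1.6 (half
growth). The frozen winner is K_Mc = 0.26 µg/ml, chi_max =
converge_level = 1.7, slope_λ = 0.7 per 1/h. Model curves are generated
and fitted on a linear 10-point grid from 0 to 0.8 µg/ml — the
concentration range over which the rewired regulation acts, emulating a
linear microplate drug gradient; the chain is (1.18, 1.96, 4.57, 1.59).

Two known consequences of this parameterization: the pooled
expression–growth correlation saturates at r ≈ −0.77 (the convergence
clamp pins expression while growth still varies, creating a flat branch),
and deep-inhibition checkerboard contours (IC90) coincide across
limitation rows because expression has converged by those concentrations —
the feedback's protective shift appears in shallow-inhibition contours
(~30%) instead.

## Limitations

Single-drug, single-target scope; no drug-interaction metrics, no kill
kinetics, no bistability analysis for the positive-feedback regime, no
ligand-depletion correction. The inverted-regulation curve is fitted over
a range that ends before deep inhibition (as in the underlying
experiments), so its Hill exponent is partly extrapolative and
grid-dependent. Real screen correlations depend on gene-specific effects
the generator intentionally omits; only the sign and ordering structure of
those statistics are meaningful here.
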