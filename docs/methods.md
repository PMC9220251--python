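# Methods

## Scope

`proteokin` analyzes fluorogenic initial-rate assays of the human 20S
proteasome core particle (chymotrypsin-like activity, Suc-LLVY-AMC
substrate) modulated by cationic porphyrinoids. It covers four layers:

1. **Michaelis–Menten core** — initial-rate extraction from progress
   curves and estimation of kcat and Km per modulator concentration.
2. **Competitive inhibition** — apparent-Km analysis and KI estimation.
3. **Two-state concerted allosteric model** — forward evaluation and
   fitting of observed kcat, Km and efficiency as functions of modulator
   concentration, with n concerted allosteric sites and m competitive
   sites.
4. **Synthetic assay generation** — a plate simulator reproducing the
   statistical structure the analysis assumes, so the whole pipeline is
   testable end to end without laboratory data.

## Models

### Michaelis–Menten layer

Initial rates follow v = kcat·E0·S/(Km+S). Rates are extracted from
progress curves as the ordinary-least-squares slope of the trace; the
default window is the full read (the assay is linear over a 45-minute
read at these turnover rates), with an adaptive longest-prefix policy
(R² ≥ 0.995) for traces that curve late. A single multiplicative
calibration constant (signal units per molar AMC, default 1.0) converts
slopes to molar/s; absolute kcat values are scale-consistent in this
constant, which real plate data rarely report. Fitting is by direct
nonlinear least squares on the hyperbola, initialized from the
double-reciprocal (Lineweaver–Burk) estimate; the double-reciprocal
ordinary-least-squares fit itself is exposed as a diagnostic only, since
reciprocal transformation distorts the error structure of noisy data.
Both routes agree to better than 1e-8 relative on noiseless data.

### Competitive layer

A competitive modulator obeys appKm(I) = Km0·(1 + I/KI) with kcat
unchanged. KI is a dissociation constant in molar; the two-state layer
instead uses association constants in M⁻¹ (KI = 1/Ka), and conversions
are always explicit. Two estimators are provided:

- **Secondary plot** (default for Km series): OLS of appKm on I;
  KI = intercept/slope, with the delta-method standard error from the
  full regression covariance. The slope must be positive and exceed
  2 regression standard errors, otherwise the series is declared
  non-inhibitory — this guards against sign-flipping noise on flat
  series.
- **Global rate-law fit** (default for raw plates, used by the pipeline
  and CLI): nonlinear least squares of
  v = kcat·E0·S/(Km0·(1+I/KI)+S) over all wells with log-scale
  residuals. This exists because per-modulator Km estimates degenerate
  once the apparent Km grows far beyond the largest assayed substrate
  concentration (the hyperbola becomes a straight line and only kcat/Km
  is identified); at KI a few hundred nanomolar and modulator up to
  10 µM this regime is reached well inside the assay window, and the
  secondary plot built on those per-point estimates is badly biased.
  The global fit declares "no inhibition" when the competitive term
  fails to improve the small-sample corrected information criterion by
  at least 2.

### Two-state concerted (MWC-type) layer

The enzyme equilibrates between states A and B with allosteric
constants L_U (substrate-unbound) and L_L (substrate-bound). A modulator
binds n equivalent concerted allosteric sites with association constants
K_AU, K_AL, K_BU, K_BL (state × substrate-ligation) and m competitive
sites with K_AI, K_BI. Observed catalytic parameters:

    obs_kcat(I) = [kcatA(1+K_AL I)ⁿ + L_L·kcatB(1+K_BL I)ⁿ] /
                  [(1+K_AL I)ⁿ + L_L(1+K_BL I)ⁿ]

    obs_Km(I)   = KmA[(1+K_AI I)ᵐ(1+K_AU I)ⁿ + L_U(1+K_BI I)ᵐ(1+K_BU I)ⁿ] /
                  [(1+K_AL I)ⁿ + L_L(1+K_BL I)ⁿ]

Free modulator is identified with total modulator (enzyme at 2 nM is
≪ modulator at ≥ 0.1 µM; depletion < 2%). The n concerted sites are
treated as identical and equivalent — one association constant per
state/ligation — which is what the (1+K·I)ⁿ form encodes, even though
structurally the sites sit in distinct α-ring grooves.

**Efficiency.** The package computes catalytic efficiency as the ratio
obs_kcat/obs_Km, which is internally consistent by construction. A
historically printed closed form for the efficiency places the
competitive factors (1+K_AI·I)ᵐ in its *numerator* and uses the
substrate-unbound state weights in its denominator; taken literally it
would make competitive binding *increase* efficiency, and it is not
algebraically equal to the ratio whenever m ≥ 1 or the U/L binding
constants differ. That literal form is retained behind
`efficiency_obs(..., mode="literal")`, and `efficiency_consistency_check`
reports the maximum relative discrepancy between the two on a grid:
zero (to roundoff) in the degenerate limit (m = 0, K_AL = K_AU,
K_BL = K_BU, detailed balance), strictly positive otherwise.

**Detailed balance.** The linkage KmB = KmA·L_U/L_L closes the
thermodynamic cycle A↔B × free↔substrate-bound. It is enforced by
default during fitting (removing KmB as a free parameter) and optional
for pure forward evaluation.

**Reductions.** With all six binding constants equal and L_U = L_L,
obs_Km reduces exactly to the competitive form with KI = 1/k (verified
over random draws to 1e-10); with n = m = 0 all observables are constant;
obs_kcat is always a convex combination of kcatA and kcatB.

## Fitting and model selection

Dose–response fitting minimizes summed squared log-scale residuals over
the kcat and Km series jointly (the observables span different units and
decades, so relative error is the only sensible common scale). The
efficiency series is held out as a consistency check by default — it is
the ratio of the other two and would triple-count the same
measurements — with a flag for joint three-series fitting. All positive
parameters are optimized in log10 space with box bounds (default ±3
decades around the initial values); the surface is multimodal, so a
seeded multi-start (default 16 log-uniform draws, first start at the
supplied initial values) precedes a trust-region-reflective refinement
with tight tolerances. Standard errors are delta-method estimates from
the log10-space Jacobian. The shared-parameter protocol — holding the
substrate-linked constants kcatA, kcatB, KmA, KmB, L_U, L_L fixed across
compounds while the binding constants float — is expressed through the
fixed-parameter mask.

**Site-number selection** fits every candidate (n, m) pair and selects
the smallest pair in lexicographic order whose small-sample corrected
information criterion (AICc) is within a margin (default 2) of the best
candidate; an alternative criterion accepts the smallest pair whose RSS
is within 5% relative of the best. This operationalizes the
"minimal model that accounts for the data" rule. The RSS entering the
criterion is floored at 1e-16 per residual point, representing optimizer
convergence noise on log-scale residuals; without the floor, noiseless
data would make information-criterion differences between exactly
fitting models meaninglessly large.

**Mechanism classification** compares a nested ladder — no modulation,
competitive-only, two-state (m = 0), two-state plus competitive site
(m = 1) — by AICc, preferring the simplest model within the margin, and
then labels the winner using shape rules on the efficiency series: the
biphasic label (activation then competitive inhibition, the corrole
phenotype) requires the efficiency to rise above its I = 0 value and
subsequently fall below it within the grid.

## Identifiability

Two structural limits matter and are deliberately surfaced rather than
hidden:

- With m ≥ 1, the Km observable constrains only the *polynomial*
  (1+K_AI I)(1+K_AU I)ⁿ + L_U(1+K_BI I)(1+K_BU I)ⁿ, not its
  factorization: distinct positive parameter sets reproduce the
  observables exactly (equal residuals to machine precision), so the
  individual competitive and unbound-state constants are identifiable
  only up to this algebraic degeneracy. Tests of noiseless recovery
  therefore assert recovery of the identifiable objects — the predicted
  curves, the numerator polynomial coefficients, and the
  substrate-bound allosteric constants pinned by the kcat series — not
  of every raw parameter.
- Under multiplicative noise, small drifts of K_AL and K_BL (which the
  kcat series constrains mostly through their ratio at high I) are
  amplified through the cubed state-weight denominator into the
  competitive constants. Recovery simulations show the resulting
  sampling distribution of K_AI spans about two decades at a 5%
  coefficient of variation; point estimates of individual competitive
  constants from a single dose–response should be treated with
  corresponding caution.
- For the same reason, a single noisy plate generally cannot resolve
  the cooperativity n when all binding constants float: candidates
  n ∈ {1..4} (with m = 1) reach residuals within the selection margin
  of each other at a 5% coefficient of variation, and the minimal-model
  rule then returns the smallest candidate. Site-number selection is
  therefore meaningful on noiseless model output or on
  replicate-averaged dose responses, which is how it is exercised here.

## Synthetic data

The plate simulator reproduces the assay design: 2 nM enzyme, substrate
at {5, 10, 25, 50, 100} µM, modulator at 0 plus nine log-spaced points
over 0.1–10 µM, three replicates, 45-minute reads. True velocities come
from the Michaelis–Menten law with mechanism-modified kcat/Km; each
replicate is multiplied by lognormal noise with a 5% coefficient of
variation by default (multiplicative noise keeps velocities positive and
matches the heteroscedasticity of plate fluorimetry; the true replicate
scatter of such assays is not published, so the 5% default is an
assumption surfaced in the design object). Random streams are derived
per well from a hash of (seed, S, I, replicate), so subsetting a plate
never changes the remaining wells.

The reference parameter sets are *synthetic*: the two competitive
dissociation constants (3.6e-7 M and 1.4e-6 M) and the corrole's
competitive association constant (1e6 M⁻¹) are literature values, and
the remaining two-state constants were chosen once so that the generated
archetypes reproduce the documented phenotypes — a biphasic corrole
whose efficiency peaks below 0.5 µM and falls below baseline above
~1 µM, and a pure allosteric activator with a ~30-fold lower K_AL and
2–3-fold lower B-state constants sharing all substrate-linked
parameters. Baseline kcat = 1 s⁻¹ and Km = 3.6e-5 M are configuration
constants recorded in every fixture manifest. The simulator does not
model photobleaching, inner-filter effects, substrate depletion or
plate-position effects; passing tests demonstrate correctness of the
estimation machinery under the assumed noise model, not robustness to
those artifacts.

## Problem sizes and numerical choices

Recovery simulations use 200 seeded replicates; model selection scans
n ∈ {1..4} × m ∈ {0..2} with 8–16 starts per candidate. Optimizer
tolerances are 1e-14 (xtol/ftol/gtol) so that noiseless fits reach
residuals at machine level, which the RSS floor then absorbs in the
information criterion. Degenerate inputs (flat series, under-determined
designs, non-positive observables for log-scale fitting) raise typed
errors rather than returning silently wrong numbers.
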