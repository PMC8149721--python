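# Methods

## Models

**Pseudo-order decay.** Cr(VI) disappearance is summarised by empirical
pseudo-first-order decay, C(t) = C₀·e^(−kt) (k in h⁻¹), or
pseudo-second-order decay, the integrated form of dC/dt = −kC², namely
C(t) = C₀/(1 + k·C₀·t) (k in L mg⁻¹ h⁻¹). All times in this package are
hours. These are summaries of an underlying biomass-coupled process, not
mechanisms; their R² quantifies how well each summary holds.

**Specific growth rate.** µ = d ln X/dt during the exponential phase.
Because "exponential phase" is subjective on real curves, the estimator
makes the choice algorithmic: every contiguous window of at least
`min_window` (default 3) points above a detection floor (default 0.01
OD600) is fitted by OLS on (t, ln X); the window with the highest R²
wins, ties broken by longer window, then earlier start. R² values are
compared at 1e-12 resolution so that float noise cannot flip a tie.
Points at or below the floor are excluded, never log-transformed. The
estimate is scale-invariant in the biomass units (log-slope), so no
OD-to-dry-weight conversion is needed. Replicates are estimated
independently and summarised as mean ± SD, matching a triplicate design.

**Haldane–Andrews growth law.** µ(S) = µmax·S/(S + S²/K_I + K_S):
Monod saturation (K_S, mg/L) extended with substrate self-inhibition
(K_I, mg/L). It is unimodal with interior maximum at S* = √(K_S·K_I),
where µ(S*) = µmax/(1 + 2√(K_S/K_I)) — a closed form used as a test
oracle. µmax > 0, K_S > 0, K_I > 0 are enforced at construction.

**Tertiary Monod cometabolism model.** With substrates glucose (C),
Cr(VI) (P) and HCIF (h), the total specific growth rate is the sum of
three Monod terms, each inhibited by the other two substrates:

µ = Σᵢ µmaxᵢ·Sᵢ / (K_Sᵢ + Sᵢ + K₂ᵢ·Sⱼ + K₃ᵢ·Sₖ + K₄ᵢ·Sⱼ·Sₖ)

K₂ᵢ and K₃ᵢ are per-(mg/L) of the inhibiting substrate and K₄ᵢ per
(mg/L)², so each added denominator term carries concentration units like
K_S. The typeset source of this model carries an apparent typo in the
Cr(VI) term (its own-saturation slot prints S_C instead of S_P, making
the chromium term saturate in glucose, contrary to the verbal definitions
of the constants); the package defaults to the symmetry-corrected form
(`form_variant="symmetric"`) and keeps the printed form selectable
(`"as_printed"`) for comparison. HCIF is a solid with no aqueous
concentration; its 1 g/250 mL dose is represented as a pseudo-
concentration of 4000 mg/L so S_h is well defined. Interaction constants
are stored as constants K, not as the K·S products used in tabular
reports; the pipeline reconstructs the product table exactly as
constants × design concentrations.

## Fitting

**Rate constants** are fitted by linearisation — ln C (first order) or
1/C (second order) regressed on t — making them closed-form, exactly
reproducible and checkable against two-point oracles. R² is computed in
the linearised space and clipped to [0, 1] in reports; a regression
implying growth is clipped to k = 0. Concentrations at/below a detection
limit (default 0.05 mg/L) are excluded: complete reduction produces
zeros that the transforms cannot accept. A minimum of two usable points
is required (two points give the exact closed-form constant).

**Nonlinear fits** (Haldane–Andrews: 3 parameters; tertiary interaction
constants: 9 parameters, base µmax/K_S frozen to their single/binary-
substrate values) use bounded trust-region least squares
(`scipy.optimize.least_squares`, method `trf`, `x_scale="jac"`,
ftol = xtol = gtol = 1e-14). Multi-start protocol: start 1 is a
data-driven heuristic; the remaining n_starts − 1 (default total 20) are
drawn log-uniformly over [1e-6, 1e4] per parameter from a generator
seeded by the caller, one draw per start, so start sets are nested in
n_starts and the best-of-starts objective is monotone in it. The seed is
mandatory — without it multi-start results are irreproducible. Interaction
constants may hit the lower bound 0 exactly (an all-zero-interaction truth
is recovered at the bound). R² uses SS_tot about the observed mean (the
conventional definition). An all-flat µ signal is flagged `degenerate`;
designs without variation in some substrate attach identifiability
warnings to the result.

## Synthetic data generator

The generator stands in for raw batch data that exist only as published
figures. It emulates: triplicate measurements with multiplicative
Gaussian noise (default CV 5%), 12-hourly sampling on 0–120 h, biomass
lag/log/decline phases, sigmoidal-to-complete Cr(VI) decay and monotone
glucose depletion. Mass balances (X biomass OD600, concentrations mg/L):

* dX/dt = (µ(S) − k_d·φ)·X, with φ = ε/(S_C + S_h + ε) a smooth
  stand-in for the "growth substrates exhausted" indicator (ε = 20 mg/L;
  a hard indicator would make the RHS discontinuous for the integrator);
* dS_C/dt = −µ_C·X/Y_C and dS_h/dt = −µ_h·X/Y_h, each driven by its own
  term of the tertiary growth law (yields Y in OD per mg/L);
* dS_P/dt = −q_P·X·S_P/(S_P + K_red), a saturating biomass-specific
  reduction rate (q_P in mg/L per OD per h, K_red in mg/L).

These are the minimal standard yield/Monod constructions, chosen so that
every fitting stage has a known generating truth; they are not claims
about the iron/chromium redox chemistry, pH or temperature dependence,
none of which is modelled. Integration is LSODA at rtol 1e-8 with states
clipped at zero. Identical condition + config (including seed) gives
bit-identical output; the noise-free trajectory is always returned.

Two frozen presets encode the study conditions (five initial Cr(VI)
levels 10–100 mg/L, glucose 1 g/250 mL, 35 °C, 120 rpm metadata):

* `set1_binary` (glucose + bacteria): growth at µ ≈ 0.11 h⁻¹ mildly
  inhibited by Cr(VI); glucose exhausted near 50–60 h, biomass declines
  after its peak; Cr(VI) at 10 mg/L is fully reduced by ~50 h while
  100 mg/L retains ≈10% at 90 h.
* `set2_tertiary` (glucose + HCIF + bacteria): stronger Cr(VI)
  inhibition of both growth substrates produces a long lag that relaxes
  as Cr(VI) falls (growth takeoff near 50 h), glucose lasts to
  ~100–120 h, and even 100 mg/L Cr(VI) is fully reduced by ~110 h.

Preset constants (yields, q_P, K_red, decay, interaction constants) were
calibrated once against the noise-free trajectories to reproduce those
milestones and then frozen. `first_order_scenario` additionally provides
a configuration (negligible growth, K_red ≫ cr0) whose Cr(VI) decay is
near-exponential with a known constant k = q_P·x0/K_red, closing the
loop between the simulator and the rate fitter.

What passing tests do **not** show about real data: the generator has no
measurement-limit censoring other than clipping at zero, no
heteroscedastic assay error, no replicate-level batch effects, and its
growth law is exactly the model being fitted — recovery results are
self-consistency checks of the machinery, not evidence that real batch
curves follow these laws.

## Pipeline

`run_analysis` accepts a CSV of measured series or a preset name. Stages:
per-condition µ estimation (decline-phase, non-positive estimates are
filtered before growth-law fitting), first/second-order rate fits on the
replicate-mean Cr(VI) series, final reduction percentage (values at/below
the detection limit count as complete; the first sampled time below the
limit is reported, no interpolation), a Cr(VI) Haldane fit across
conditions when ≥ 4 distinct initial levels are available, glucose/HCIF
Haldane fits and the 9-constant tertiary fit (for preset input these run
on datasets synthesised from the preset's generating parameters, so the
whole report has a known truth; for CSV input they are marked `skipped`
unless the data identify them). Every stage failure is recorded in the
report — nothing is silently dropped. The JSON report (schema_version 1)
carries a provenance block (input SHA-256, config, seed, package
version) and no timestamps, so identical inputs give byte-identical
reports. Flat CSVs mirror the rate-constant table (one row per
condition) and the interaction-product table (9 rows × one column per
initial Cr(VI) level).

## Numerical and design choices

* Single-substrate K_S values are never published for this system; they
  are free fit parameters, and where a generating value is needed the
  package fixes K_S = 0.5 mg/L (glucose) and 5 mg/L (Cr, HCIF).
* Recovery test designs are log-spaced grids spanning the Haldane peak
  (S*/30 to 30·S*, 10 points) and factorial substrate grids (3×3×3 over
  batch-realistic ranges noise-free; a 4×4×4 grid including zero levels
  for noisy recovery, where zero levels decouple the single and joint
  inhibition terms and make all nine constants identifiable).
* Problem sizes throughout (10-point growth curves, 27–64-point designs,
  20 starts, 50 noise replicates) are the smallest at which the
  estimators are well-conditioned; they keep any single fit below a few
  seconds.
* Known limitations: no confidence intervals or profile likelihood, no
  model selection beyond R², no ANOVA/post-hoc machinery, no digitised
  figure data, and the `as_printed` tertiary variant is provided for
  comparison only.
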