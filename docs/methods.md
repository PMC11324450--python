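# Methods

## Constitutive models

Three three-parameter linear viscoelastic models of shear response are
implemented in closed form (`organrheo.models`):

| model | network | parameters | G′(ω) | G″(ω) |
|---|---|---|---|---|
| S-FKV | springpot ∥ dashpot | K_α (Pa·s^α), α, η (Pa·s) | K_α ω^α cos(απ/2) | K_α ω^α sin(απ/2) + ηω |
| FKV | springpot ∥ spring | K_α, α, G (Pa) | K_α ω^α cos(απ/2) + G | K_α ω^α sin(απ/2) |
| SLS (Zener) | spring ∥ (spring–dashpot) | G₁, G₂ (Pa), η (Pa·s) | G₁ + G₂(ωτ)²/(1+(ωτ)²) | G₂ωτ/(1+(ωτ)²), τ = η/G₂ |

The springpot interpolates between a spring (α = 0, K_α = G) and a dashpot
(α = 1, K_α = η). The S-FKV step-strain relaxation modulus is
G(t) = K_α t^(−α)/Γ(1−α) for t > 0; the dashpot contributes an impulsive
η·δ(t) term that exists only at t = 0 and is excluded from numerical
evaluation — all relaxation comparisons start at t = 1 s, the first sampled
point of the 1 Hz relaxation protocol. Γ is SciPy's gamma function; no
bespoke approximation.

**Frequency convention.** The frequency-domain formulas are evaluated with
ω taken as ordinary frequency in Hz by default. The bundled organ
parameter profiles are only internally consistent under this convention:
their published high-frequency extrapolations follow from the tabulated
(K_α, α) exactly when ω is in Hz, and not under ω = 2πf. The same K_α
values are used with t in seconds in the relaxation law; this mixed usage
is deliberately preserved rather than "corrected", because the parameters
were calibrated that way. `convention="rad"` substitutes 2πf, and the flag
is carried into every `FitResult` and written report.

**Units.** All computation is in SI (Pa, Pa·s^α, Pa·s, s, Hz). kPa appears
only at reporting boundaries (`extrapolate_storage`, parameter tables, the
CLI), where values are rounded half-up to 2 decimals for table parity.

## Grünwald–Letnikov oracle

`gl_stress_response` evaluates the S-FKV constitutive law directly from an
arbitrary strain history using first-order GL weights
w_j = (−1)^j C(α, j) (stable recursion w_j = w_{j−1}(j−1−α)/j) with full
memory — histories are ≤ 10⁴ samples, so the O(N²) convolution is cheap —
plus a backward-difference dashpot term. Strain before t = 0 is zero, so
the first backward difference of a step history approximates the dashpot's
impulse. For a step strain the response divided by the step amplitude
converges to the closed-form relaxation modulus; at dt = 1 ms the
discrepancy over t ∈ [1, 10] s is below 0.1 % for all four organ parameter
sets (the acceptance test enforces 2 %). This route shares no code with
the closed forms and serves as their independent check.

## Preprocessing

* **LVE limit** (`detect_lve_limit`): reference = mean G′ of the first
  three strain-sweep points; the limit is the largest amplitude with all
  G′ values up to it within 5 % (default) of the reference. Only G′ is
  used — it dominates the response and is less noisy than G″. The study's
  plateaus are identified graphically, without a numeric criterion; 5 % is
  this package's default. If even the first point deviates the function
  returns None (undefined plateau).
* **Inertial cutoff** (`detect_inertial_cutoff`): the lowest frequency at
  which G′ sits more than 5 % (default) below its running maximum *and
  stays there for every higher frequency*. The persistence requirement is
  ours: instrument inertia only worsens with frequency, and without it a
  single 5 % noise excursion (common at 3 % multiplicative noise)
  false-triggers and truncates clean data. Points at and above the cutoff
  are excluded from fitting (`truncate_at_cutoff`); no physical inertia
  correction is attempted.
* **Contact state** (`contact_axial_state`): axial stress = F/(π(d/2)²);
  axial strain = stress/E. By default the stress is rounded to one
  significant figure before dividing (0.1 N on a 25 mm disc → 203.7 Pa
  exact, 200 Pa nominal), the rounding under which the conventional quoted
  pre-strains (0.2/0.5/1.1/13.3 % for heart/kidney/liver/brain moduli of
  110/44/17.5/1.5 kPa) are exact; `nominal_rounding=False` uses the exact
  area.

## Fitting

`fit_sweep` minimises the sum of squared **relative** residuals of G′ and
G″ jointly (both moduli constrain α; relative weighting stops the larger
G′ from dominating), using SciPy's box-constrained trust-region least
squares with bounds 0 ≤ α ≤ 1 and non-negativity elsewhere. The
initial point is data-derived and deterministic — α₀ from the log–log
slope of G′ vs f, K₀ from the median implied prefactor, η₀ from the
residual high-frequency loss; plateau/increment analogues for SLS — so a
fit is a pure function of the sweep; there are no random restarts.
Boundary-hitting parameters and degenerate (constant-modulus) sweeps
produce warnings, not errors. Zero loss values are floored at
10⁻⁶·max(G′) in the residual denominators.

**Goodness of fit.** r² = 1 − SS_res/SS_tot over the concatenated
(G′, G″) vector on a **log scale**. Both channels enter dimensionless and
equally weighted — the same normalisation as the objective — which is the
natural scale for power-law moduli spanning unequal magnitudes. Under
this definition the generating model is also the best-ranked model
essentially always on its own data, which a raw-scale r² (storage-
dominated) does not guarantee. `compare_models` ranks by r², ties broken
by residual norm, and drops (with a warning) any model whose fit fails
rather than aborting the others.

`fit_strain_dependence` fits K_α = c₀ + c₁ε_A by OLS (statsmodels) and
reparameterises to k₀ = c₀, b = c₁/c₀. Uncertainty on (k₀, b) is treated
as across-sample dispersion, not regression CI.

## Relaxation comparison and extrapolation

`compare_relaxation` aligns predicted and measured traces on their common
times and reports (i) the signed initial discrepancy
(predicted − measured)/measured × 100 % at the first common time (1 s
under the study protocol; negative = prediction undershoots), and (ii) the
decay-shape distance: the maximum relative deviation between the curves
after each is divided by its own 1 s value — zero means identical decay
kinetics regardless of amplitude. The discrepancy transform makes curve
swap antisymmetric: (1 + d₁₂/100)(1 + d₂₁/100) = 1.

`extrapolate_storage` evaluates the fitted G′ at arbitrary frequencies
(Hz convention) and summarises a band by its endpoint values — identical
to the min/max over the band since S-FKV storage is monotone in f.

## Synthetic data: the stated world

`organrheo.profiles` carries one generative profile per organ with the
published values: S-FKV parameters at the reference pre-compression
(heart 2.00 kPa·s^α/0.13/10.3 Pa·s, kidney 0.88/0.12/7.58, liver
0.27/0.16/9.70, brain 0.25/0.16/10.5), the stiffening slope b
(0.10/0.23/0.12/0.07 per % axial strain), a per-strain (α, η) drift table
over 0.5–10.5 %, LVE limit 0.1 % shear strain, inertial onsets
9.5/9.5/4.2/2.8 Hz, elastic moduli 110/44/17.5/1.5 kPa, and 25 mm × ~5.5 mm
disc geometry.

Anchoring: the published per-strain table lists its first row at 0.5 %
axial strain for every organ with exactly the reference S-FKV parameters,
while the per-organ contact strains (0.2/0.5/1.1/13.3 %) differ — an
internal inconsistency of the source data. The profiles anchor the
reference parameters at a common 0.5 % and scale
K_α(ε) = K_ref·(1 + bε)/(1 + b·0.5), so the reference values hold exactly
at the anchor and the linear stiffening ratio between any two pre-strains
is preserved. The published (k₀, b) regression itself does not pass
through its own anchor point, so k₀ is derived from the anchor rather than
taken from the regression table (visible for brain: generator k₀ ≈ 0.24
vs published 0.13).

Generators (`organrheo.synthetic`), all bit-reproducible per (profile,
seed) with child seeds spawned from a `SeedSequence`:

* **Frequency sweeps**: 20 log-spaced points over 0.1–9.5 Hz by default,
  exact model moduli times unit-mean lognormal noise with cv = 3 % (the
  study publishes no noise model; rheometer modulus errors are
  scale-proportional, and 3 % reproduces the study's achievable fit
  quality r² > 0.99). Strictly above the inertial onset, G′ is suppressed
  by 2/(1 + (f/f_onset)⁴) and G″ inflated ∝ f², both continuous at onset —
  a visual stand-in for the instrument artifact, not physics.
* **Strain sweeps**: flat below the LVE limit γ_L, Kraus-type softening
  G′_plateau/(1 + ((γ − γ_L)/γ_L)^0.8) above; the loss modulus softens
  with half the exponent.
* **Relaxation traces**: the power-law relaxation modulus sampled at
  1–10 s, optional amplitude bias emulating the ≤ 30 % initial-value
  mismatch observed between frequency-domain fits and measured relaxation.

What the generator does **not** emulate: sample-to-sample covariance,
slip, temperature dependence (< 10 % between 20 and 37 °C), hyperelastic
finite-strain effects, and any high-frequency physics beyond the measured
band. A green pipeline test therefore establishes that the estimators
recover the stated world's parameters under scale-proportional noise — not
that real tissue obeys the S-FKV law outside 0.1–9.5 Hz.

## Numerical choices and limitations

* Table rounding is half-up to 2 decimals (`round_half_up`), not banker's.
* Relative-residual denominators and the log-r² floor use 10⁻⁶·max(G′).
* The GL oracle errors out if dt exceeds the history's finest spacing
  (with a 10⁻⁹ relative tolerance for float fuzz).
* Model ranking on near-identical r² (degenerate data) falls back to
  residual norm; exact ties keep the fit order S-FKV, FKV, SLS.
* Creep compliance, Prony series, Bayesian/uncertainty-quantified fitting,
  time-domain fitting, and vendor rheometer file formats are out of scope.
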