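# Methods

This note documents the models, numerical choices and limitations of
`dimerdeer` at the level a user needs to judge what results do and do not
show.

## Dipolar forward model

The pair signal uses the isotropic orientation average (Pake kernel)

K(t, r) = ∫₀¹ cos[(3x² − 1) ω t] dx,  ω(r) = 2π D / r³,

evaluated in closed form via Fresnel integrals,
K = √(π/6φ)·[cos φ·C(z) + sin φ·S(z)] with φ = ωt, z = √(6φ/π), which
agrees with high-order Gauss–Legendre quadrature to ~1e-13.  The dipolar
constant D = 52.04 MHz·nm³ assumes two free-electron g-values; it is a
module constant, not measured here.  Orientation selection, exchange
coupling and multi-spin (>2) effects are outside the model: excitation
efficiency enters only through the scalar λ.

The intermolecular background is the homogeneous exponential
exp(−k t^{d/3}) with d = 3 by default (`TraceModel.background_dim`
exposes stretched dimensionalities).  Traces are real-valued from t = 0;
phase and zero-time corrections of raw spectrometer data are out of
scope, as synthetic data never needs them.

## Inversion

The default workflow is sequential: fit a·exp(−kt) to the trace tail
(t ≥ 0.5·t_max, least squares with k ≥ 0), divide out, rescale by the
fitted depth, then solve the Tikhonov non-negative problem as a stacked
augmented least-squares system via NNLS.  The default grid is
1.0–6.0 nm in 0.025 nm steps, which spans every distance the four-site
geometry predicts with margin.

When the sequential fit leaves a residual above max(3·noise_sd, 1e-12) —
for a noiseless trace, any residual at all — a joint refinement
re-optimizes (Δ, k) by Nelder–Mead with the regularized non-negative
solve nested inside.  This recovers nuisance parameters to ~1e-6 on
noiseless data and guards against background-fit bias on short traces.

**Regularization selection.** α minimizes GCV(α) = n‖Kp_α − f‖²/tr(I −
H_α)², with one deliberate choice: the influence matrix H_α is computed
on the NNLS *active set*.  With the fully unconstrained influence matrix
the degrees-of-freedom term dominates an almost flat residual curve and
selection drifts toward heavy oversmoothing; restricting to the active
set counts only the components the constraint actually leaves free and
gives well-calibrated smoothing across the SNR range (more noise still
selects more smoothing).  Candidate α values are 25 points log-spaced
over 1e-4…1e2; singular candidates are skipped, and if all fail the
median candidate is used with a logged warning.

**Uncertainty band.** Residual bootstrap: resample the base-fit
residuals with replacement, add them to the fitted signal, re-solve the
regularized dipolar problem at the base α with background and depth held
fixed (re-fitting the background per replicate injects a baseline offset
that the ill-posed inversion amplifies ~200-fold).  The band is the
pointwise 2.5/97.5 percentile range, widened by twice the bootstrap bias
estimate (replicate mean minus point estimate, the standard correction
for the smoothing bias a regularized estimator carries), clipped at
zero, and expanded where needed to contain the point estimate.  With 100
replicates this attains ~96% mean pointwise coverage at SNR 50 in the
recovery checks, and collapses below 1e-3 width for noiseless input.
n_boot defaults to 100, seed to 0.

The "consensus" multi-method averaging practised in the DEER field is
deliberately reduced to one inversion plus bootstrap uncertainty; exact
reproduction of any particular software's band shape is not attempted.

**Reliability limit.** r_max = c·t_max^{1/3} with c = 3.494 nm·µs^{−1/3},
calibrated so 1.5 µs ↦ 4.0 nm (0.8 µs ↦ ≈3.2 nm).  Results whose modal
distance exceeds the limit carry `reliable = False`.

## Occupancy and cooperativity

Δ = λ·q treats singly labelled dimers as contributing zero modulation
and folds intermolecular pairs into the exponential background —
standard two-spin counting.  λ is never measured here; it is a user
input (default 0.4).  In-cell nitroxide reduction is modelled as
independent per-label survival s (binomial thinning of the occupancy
state); whether published occupancy splits already correct for λ and s
varies by study, so both corrections are explicit and composable.
q = Δ/λ is clipped to [0, 1] with a warning rather than an error, since
noise can push Δ slightly past the λ ceiling; mutually impossible
observables (implied f₀ < 0) do raise.

The cooperativity ratio f₂ / (m/2)² gets its CI from a multinomial
parametric bootstrap of n_dimers dimers (default 5 000 — the published
decompositions carry no sample size, so n_dimers only sets CI width).
Verdicts: cooperative if the 95% CI lies above 1, anti-cooperative if
below, indistinguishable otherwise.  Under a true binomial null the
false-cooperative rate measures ~1% over 200 seeded runs.

## CW unmixing

Full slow-motion lineshape simulation (stochastic Liouville) is replaced
by parametric templates: three equal-integral Lorentzian lines
(center 335.5 mT, hyperfine 1.6 mT, HWHM 0.15 mT) for free ligand, and a
uniform line-position density of width 7.0 mT convolved with a 0.4 mT
Gaussian as the rigid-limit surrogate.  Templates are normalized to unit
absorption double integral *after* discretization and differentiation,
so NNLS weights are exactly spin-count proportional on the default
328–343 mT, 1024-point axis.  Template unmixing recovers mixture
fractions to ≤2 points at SNR 100 across the full range; it does not
estimate g/A tensors, motional rates, or the in-cell Mn²⁺ background.

## Site geometry and hypothesis scoring

Pair distances are Gaussians with configurable (µ, σ); defaults
µ(a1–b1) = 4.1 nm, µ(a1–a2) = µ(b1–b2) = 3.0 nm, µ(a1–b2) = µ(b1–a2) =
2.5 nm, σ = 0.15 nm (the generator presets use σ = 0.1 nm).  µ(a2–b2)
defaults to 2.5 nm but no default hypothesis constrains it, and
simultaneous exclusive occupation of both secondary sites is not among
the default hypotheses (it can be added via composition).  Distributions
can instead be built from coordinate ensembles of label midpoints
(CSV: frame, source, ax..bz in nm) with per-source residence weights and
0.05 nm kernel smoothing.

Scores are overlap coefficients ∫min(P₁, P₂)dr with both curves
renormalized below the reliability limit.  Call thresholds: consistent
≥ 0.5, excluded ≤ 0.1 — two σ = 0.15 nm Gaussians 0.5 nm apart overlap
≈ 0.1, so "excluded" corresponds to a peak misplaced by several
Ångström, the discriminating power distance predictions realistically
have.  Ties rank alphabetically.

## Synthetic scenarios

The generator emulates the measured system, not the measurement
hardware.  A population of n_dimers = 20 000 dimers (multinomial
sampling error ≈0.5% on the occupancy fractions) is drawn from either
the independent (binomial) model or the gated mechanism model, in which
the allowed states are empty / one catalytic site / catalytic +
*opposite* secondary site, parameterized by mean load and gate strength
(= pair fraction q); both-catalytic states have probability zero by
construction.  Singly occupied dimers hold their ligand in a catalytic
site (a1 or b1 equiprobably), the mechanism's "start" state.  Doubly
occupied dimers draw a pair distance from their pairing's Gaussian; the
ground-truth P(r) is the kernel-density estimate of those draws
(bandwidth 0.05 nm).  Washing/kinetics are not simulated — the
configured fractions simply are the post-preparation state.

Preset conditions: `invitro` — 70/21/9 occupancy, λ = 0.4, s = 1,
t_max = 2 µs, dt = 8 ns, background 0.05 µs⁻¹, trace SNR 50
(Δ_truth/noise_sd), CW free fraction 9% at SNR 100.  `incell` —
same binding, s = 0.5 (the true cytoplasmic survival fraction is
unknown; 0.5 is a config-exposed placeholder), t_max = 1.5 µs, SNR 30.
The in-cell Mn background is not synthesized; its effect appears only as
the lower SNR and Δ.  Everything is reproducible from the configured
seeds.

What passing tests show: the chain recovers distances, occupancies,
fractions and pairing calls under Gaussian noise, exponential
backgrounds and the stated geometry.  What they do not show: robustness
to phase/zero-time errors, orientation selection, non-exponential
backgrounds, λ mis-specification, or lineshapes outside the template
family — real data can violate all of these.

## Degenerate inputs and tie-breaks

Modal distance ties break toward the smaller distance.  A scenario with
no doubly occupied dimers yields a valid Δ = 0 trace with a logged
warning.  An all-zero or non-finite trace, an empty distance window
below the reliability limit, or a CW fit with both weights zero raise
typed errors (`dimerdeer.errors`).  Bundle files are plain text; parse
errors name file and line.
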