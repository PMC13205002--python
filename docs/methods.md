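# Methods

This note records what the package actually computes, the defaults it
ships, the choices that were genuinely open, and what the tests do and
do not establish.

## Candidate space and array geometry

Candidates are the Cartesian product of disc diameters
D ∈ {2.0, …, 4.5} mm and edge-to-edge gaps Q ∈ {0.5, …, 3.0} mm at
0.5 mm steps (36 configurations, labelled `DxQy` with trailing `.0`
dropped). The 3 × 2 array uses a uniform centre-to-centre pitch D + Q in
both axes — the row and column pitches are not independently specified
anywhere, so a single pitch is assumed — with the 3-electrode axis along
y and the array centroid at the origin. The coverage area is the
bounding rectangle (2D + Q) × (3D + 2Q); this interpretation reproduces
both published endpoints (0.315 and 2.34 cm²) exactly, which is why it
was adopted. Enumeration order is D-major and is the global tie-break
order for rankings and sample layout.

## Tissue model

Four layers with fixed thicknesses 0.029 / 0.089 / 1.380 / 3.500 mm
(stratum corneum, viable epidermis, dermis, subcutis; 4.998 mm total).
Thicknesses are never personalised: individual variability enters only
through electrical parameters.

Each layer carries a conductivity-form Cole–Cole dispersion
σc(f) = σ∞/(1 + (jωτ)^(1−α)) + σ0, implemented literally as written: in
this form σ∞ + σ0 is the *low*-frequency limit and σ0 the
high-frequency one, a naming tension we note but do not resolve. The
principal branch of the fractional power is used; the value is verified
against an arbitrary-precision symbolic oracle to 1e-12 relative.

Baseline per-layer parameters (defaults in `tissue.DEFAULT_LAYERS`) are
representative values assembled from the skin dielectric-dispersion
literature, chosen so that the stratum corneum is ~10³ less conductive
than the living layers at audio frequencies. They are configuration
data: every value can be overridden through `RunConfig`. Relative
permittivity is carried on each layer but unused by the default solver,
which is a conduction-only quasi-static solve; the real part of σc (not
its magnitude) enters the solver because conduction current dominates in
this regime. The effective frequency defaults to
f_eff = 1/(2·pw) = 5 kHz for the 100 µs phase width — the dominant
spectral content of a rectangular phase.

**Personalisation.** How the four descriptors map to tissue parameters
is not established physiology; we use the simplest monotone, testable
choice: one multiplicative factor on each layer's σ∞ and σ0,
g = clamp(1 + 0.15·(bmi−22)/22 − 0.05·(age−25)/25 + 0.05·(sex−0.5),
0.5, 1.5), with all coefficients in the config. Because g is a single
global scale, the potential for a fixed geometry scales exactly as 1/g;
subjects therefore shift the feature magnitudes (and the neural
activation weight) rather than reorder the field shape. This is a known,
intentional simplification of the default personalisation — per-layer
coefficients can be configured but are not the default.

## Field solve

Geometry is a rectangular layered slab (default 20 × 28 mm laterally,
holding the largest array plus ≥ 3 mm margin) rather than a curved 3-D
finger: layering and electrode geometry, which drive the score, are
preserved at desk scale. Discretisation is cell-centred finite volume on
a tensor grid with vertical coordinates aligned to layer interfaces
(default 1.0 mm lateral step and 2/2/8/8 cells per layer, ≈ 11 k cells);
face conductances are harmonic means, making the operator symmetric
positive definite and exactly current-conserving across interfaces.

Boundary conditions: uniform Neumann current density over each active
disc footprint (total = drive amplitude), insulating elsewhere on top
and sides, and Φ = 0 on the bottom face as a distant-return
abstraction (the return electrode placement is otherwise unspecified; a
config option can designate an array electrode as return by driving it
with opposite sign). For feature extraction a single channel — the
middle-row left electrode, whose position moves with the pitch — is
driven at 2 mA; which channels were driven during the original
simulations is unknown, so this stand-in is fixed and configurable.

The solve uses Jacobi-preconditioned conjugate gradients at relative
tolerance 1e-8 (max 10 000 iterations; ~400 suffice on the default
grid despite the 10³ conductivity contrast), with a symmetric-mode
sparse-LU direct path for cross-checks; the discrete residual is
verified after either path. Current conservation through every
horizontal plane holds to ≪ 1% and the solution is exactly linear in
the source, both asserted in tests.

Features Emax (max |E|), Eavg (volume-weighted mean) and Eint
(Σ|E|·dV, V·m²) are taken over all tissue *below the stratum corneum*
by default: the corneum's contact-edge cells would otherwise dominate
Emax, and perception arises in the innervated deeper layers. A
whole-volume or dermis-only region is selectable. Field values at the
electrode edge are grid-dependent (the continuum problem is singular
there), so absolute Emax should be read as a mesh-scale descriptor —
consistent across candidates on a fixed grid — rather than a converged
point value; Eavg and Eint are grid-robust.

## Nerve fiber model

One straight A-β fiber (9 µm diameter, 21 nodes at 0.9 mm = 100 d
spacing, 2.5 µm nodal gap) lies along the 3-electrode axis at 0.8 mm
depth, mid-dermis; fiber count and placement are not quantified in the
source setting, so one centred fiber is the default and a multi-fiber
max-aggregate is supported. Nodal constants follow classical SENN
parameterisations (ρ_axial = 110 Ω·cm, c = 2 µF/cm², g = 30.4 mS/cm²),
giving Cm ≈ 1.41 pF, Gm ≈ 21.5 nS, Ga ≈ 64.3 nS per node.

The membrane is *passive and linear* — the printed nodal equation has no
ion-channel kinetics — so "activation" is defined as the absolute
potential v_rest + Vn crossing Vth = −55 mV (15 mV depolarisation from
v_rest = −70 mV). Vpeak is reported as absolute potential, consistent
with the absolute-looking threshold. The extracellular second difference
(the activating function) enters interior nodes as the source; terminal
nodes are sealed (zero axial flux), an end condition the source setting
leaves open.

Integration: the drive is piecewise constant on the 1 µs sampling grid,
so the default integrator propagates the linear system *exactly* per
step with a precomputed matrix exponential — fixed-step, deterministic,
and machine-accurate, which is what allows the 1e-6 agreement with a
dense ODE oracle asserted in tests. A classical explicit-Euler path is
retained (`method="euler"`) with the stability precondition
dt ≤ 0.1·Cm/(Gm + 2Ga) ≈ 0.94 µs.

## PCS

PCS = w_neuro · u_pattern · ln(1 + E_focus), all intermediates returned
for audit. "log" is read as the natural logarithm: the base is not
stated, and since a base change rescales all scores by one positive
constant, every ranking, Top-k set and correlation is invariant to the
choice. E_focus = Emax/(Eavg + 1e-9). The balance term C is the
population (n = 3) coefficient of variation of {|Emax|, |Eavg|, |Eint|}
taken on raw SI magnitudes — deliberately mixing units, as the score is
defined operationally on the exported descriptor set; an optional
pre-normalisation by fixed reference scales exists and is off by
default. All-zero descriptors define C = 0 (PCS is zero anyway through
E_focus). With the defaults, Eint (~10⁻⁴) is far below Emax/Eavg, so C
is dominated by the focusing contrast; u_pattern still varies across
candidates and subjects.

## Ranker

One sample per subject-configuration pair; the five-subject training
cohort gives 180 samples. Ten candidates are cross-validated on one
seeded shuffled 5-fold split: linear regression, KNN (k = 1, 3, 5, 7),
random forests (100/300/500 trees), gradient boosting (100, 0.1, 3) and
(200, 0.05, 4); remaining hyperparameters stay at library defaults.
Linear and KNN candidates are standardised inside their pipelines; tree
ensembles are not. Selection is minimum mean CV MAE with ties broken by
candidate order; the final model refits on all samples with
least-squares loss. Fold assignment is per-sample (not grouped by
subject) by default — the grouping convention is unknown — with a
`group_by_subject` mode for leakage-sensitivity checks. Predicting a
new subject always regenerates that subject's simulation features; the
model never sees descriptors alone. On the simulated cohort the
gradient-boosting candidate wins (CV MAE ≈ 0.006 vs label SD ≈ 0.35).

## Evaluation

Trend consistency is the Pearson correlation across configurations
between the per-configuration mean predicted PCS and mean measured
accuracy (unweighted means over subjects); the t-transform p-value is
reported but never used as a gate. Top-k coverage uses the 1-based rank
of each subject's measured-best configuration (accuracy ties break by
enumeration order). The exclusion rule drops configurations with group
mean accuracy < 61.5% AND maximum per-subject accuracy < 80%. Time
saving is 100·(1 − t_rec/t_ex), reported half-up-rounded to one decimal
with the raw value retained.

## Synthetic psychophysics generator

Emulates the verification protocol: 6 subjects × 36 configurations × 15
trials of 5-alternative recognition (chance 0.2). Success probability is
p = clip(0.2 + 0.8·logistic(β₀ + β₁·z), 0.2, 0.95) with z the
standardised PCS; β₀ = 0.33 places the mid-PCS accuracy near 66%, a
realistic operating point well above chance for this task, and β₁ = 1
plants a clearly positive but noisy link. Trial counts are binomial and
fully seeded. Synthetic cohorts draw descriptors uniformly from the
young-healthy-adult box (age 22–27, height 165–180 cm, weight
50–82 kg, sex Bernoulli(0.5)). The five stimulus patterns ship as a
fixture convention (subset sizes 1, 2, 3, 4, 6); PCS is
pattern-agnostic, so the exact subsets affect nothing downstream.

What the generator does *not* model: per-pattern confusion structure,
adaptation, fatigue, electrode-skin impedance drift, or any behavioral
variance unrelated to PCS. Consequently, passing the end-to-end tests
shows that the pipeline recovers a planted monotone PCS-accuracy link
under binomial trial noise — it does not show that real human accuracy
follows PCS; that question requires the behavioral dataset, which the
evaluation module ingests as a CSV when available.

## Problem sizes, determinism, degenerate inputs

Default problem sizes were chosen for desk-scale work: ~11 k-cell grids
(a 180-pair training simulation takes under a minute on one CPU), 21
cable nodes at 1 µs over 1 ms windows. Doubling lateral resolution
leaves layer geometry identical and changes the grid-robust features by
a few percent; this convergence behaviour is documented rather than
asserted, since Emax at the contact edge is mesh-scale by nature.

Every stochastic step (fold shuffling, tree ensembles, cohort sampling,
binomial trials) is driven by explicit seeds; pipelines, solvers and
integrators are deterministic, so identical config + seed reproduces
identical outputs (run outputs embed the config hash). Degenerate inputs
fail loudly: zero-variance correlation inputs, empty regions,
out-of-domain sample points, non-finite features, unstable Euler steps
and non-converged solves all raise with the offending quantity named;
zero drive yields exactly zero fields, trajectories and scores.

## Known limitations

- The slab geometry ignores fingertip curvature and ridge structure;
  absolute field values are indicative, and the score is meaningful for
  *relative* comparison across candidates.
- The descriptor-to-conductivity map is a modelling convention, not
  measured physiology; its single-factor default makes subject effects
  monotone by construction.
- The passive cable cannot produce spikes; threshold crossing of a
  linear response is a proxy for recruitment.
- u_pattern's unit mixing makes C depend on the unit system; SI is
  fixed throughout for that reason.
- The synthetic behavioral link is the package's own construction; all
  statistical results on synthetic data are conditional on it.
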