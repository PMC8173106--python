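# Methods

This note documents the models, defaults and numerical choices behind
`allokit`, and what the synthetic-data validation does and does not show.

## Two-site exchange forward models

Three forward models describe the effective transverse relaxation rate of
an amide nucleus exchanging between a major conformation A and a minor
conformation B under a constant-time CPMG train:

- **Carver–Richards** (`r2eff_carver_richards`): the all-timescale closed
  form, parameterized by the intrinsic rates $R_2^A$, $R_2^B$, the exchange
  rate $k_{ex}$, the minor population $p_B$ and the shift difference
  $\Delta\omega$.
- **Luz–Meiboom** (`r2eff_fast_limit`): the fast-exchange limit,
  $R_{2,\mathrm{eff}} = R_{2,0} + \frac{p_Ap_B\Delta\omega^2}{k_{ex}}
  \left[1 - \frac{4\nu}{k_{ex}}\tanh\frac{k_{ex}}{4\nu}\right]$, used as an
  analytic cross-check; it agrees with the full form to better than 2% once
  $k_{ex} \ge 10\,\Delta\omega$ (rad/s).
- **Bloch–McConnell propagator** (`r2eff_bloch_mcconnell`): numerical
  evolution of the two-site transverse magnetization — free precession for
  $\delta/2$, an ideal 180° pulse as complex conjugation, $\delta/2$ again,
  repeated for an even pulse count filling the relaxation period $T$ — with
  $R_{2,\mathrm{eff}} = -\ln(|M(T)|/|M(0)|)/T$ from equilibrium starting
  populations.  Requested $\nu_\mathrm{CPMG}$ values are rounded to the
  nearest realizable even echo count and the effective value is available.

**Conventions.**  $\nu_\mathrm{CPMG} = 1/(2\delta)$ with $\delta$ the
spacing between successive 180° pulse centers; literature conventions
differ by factors of two, so this is stated explicitly.  The ¹⁵N/¹H
frequency ratio defaults to 0.101329 (configurable per nucleus).  The
constant-time relaxation period defaults to $T = 0.04$ s.  TROSY-selected
data are treated as ordinary in-phase R2eff curves (no
differential-relaxation correction).  Equal intrinsic rates
($R_2^B = R_2^A$) are the default; per-state rates are retained in the
equation but are under-determined at one field.  The arccosh argument is
clamped at 1 from below; clamp events are counted at debug level.  cosh
overflow at extreme $\delta\,k_{ex}$ is avoided by a logarithmic
rearrangement.

**Closed form vs. finite-time propagation — a real, documented gap.**  The
closed form is the *asymptotic* decay rate of the echo-train propagator's
slowest eigenmode; the implementation reproduces that eigenvalue to
numerical precision (&lt; 1e-11 s⁻¹) over the full parameter grid
($k_{ex}$ 200–6000 s⁻¹, $p_B$ 0.01–0.1, $\Delta\omega$ 0.5–4 ppm).  What a
constant-time experiment measures, however, is the finite-time intensity
ratio, which additionally contains a projection-amplitude term
$-\ln(A_\mathrm{slow})/T$.  In intermediate-to-fast exchange with a sparse
minor state ($k_{ex} \gtrsim 2\Delta\omega$ in rad/s, $p_B \le 0.05$) this
term is negligible and the two measures agree within max(1%, 0.2 s⁻¹); in
slow exchange it grows to several s⁻¹ at $T = 0.04$ s and the finite-time
dispersion can even be locally non-monotonic in $\nu_\mathrm{CPMG}$.  This
is a property of two-site physics, not of the implementation; the package
exposes both measures (`measure="finite_time"` / `"asymptotic"`), uses the
finite-time one for data generation because it is what the experiment
produces, and cautions that closed-form fits in deep slow exchange inherit
this model error.

## Dispersion and R1 fitting

Peak intensities convert to rates by
$R_{2,\mathrm{eff}} = -\ln(I/I_0)/T$ with
$\sigma_{R} = \sigma_I/(I\,T)$; non-positive intensities are flagged
unusable rather than aborting a table.  Per-residue fits are weighted
($1/\sigma^2$) least squares over all fields simultaneously with
multi-start initialization ($k_{ex} \in \{500, 1500, 3000, 6000\}$ s⁻¹
$\times\ p_B \in \{0.01, 0.05, 0.1\}$; best of starts) because the
Carver–Richards surface is multimodal.  Bounds:
$k_{ex} \in [10, 10^5]$ s⁻¹, $p_B \in (0, 0.5]$,
$\Delta\omega \in (0, 15]$ ppm, $R_{2,0} \in (0, 100]$ s⁻¹ per field.
Uncertainties come from the fit covariance; a seeded residual bootstrap is
not required for the synthetic validation and is left to the user via
re-fitting resampled curves.

A residue whose exchange contribution
$\Delta R_2 = R_{2,\mathrm{eff}}(50\,\mathrm{Hz}) -
R_{2,\mathrm{eff}}(\nu_\mathrm{max})$ is below twice the pooled measurement
sigma is reported `too_low_to_fit` and no exchange parameters are
extracted.  Model choice between "flat" (no exchange) and the exchange
model uses AICc on the weighted chi-square, with ties
($|\Delta\mathrm{AICc}| < 2$) resolved to flat; at $\sigma = 0.3$ s⁻¹ this
rule selects flat on no-exchange data in well over 95% of replicates and
exchange on strong-exchange data ($R_{ex}\approx 10$ s⁻¹) in all of them.
Single-field fits are allowed but carry a degeneracy warning: in fast
exchange only $p_B\Delta\omega^2/k_{ex}$ is determined at one field.

Global fits share $k_{ex}$ (and optionally $p_B$ — both modes provided)
across a residue group while keeping $\Delta\omega$ per residue and
$R_{2,0}$ per residue and field; group members below the fittability
threshold are excluded with a logged warning, and group misfit is visible
in the reduced chi-square.

A residue that disperses but plateaus well above a reference baseline
(default threshold 2 s⁻¹ over, e.g., the group median $R_{2,0}$) is flagged
as carrying an additional faster exchange process that the sampled CPMG
fields cannot refocus.

R1 series fit $I(t) = I_0 e^{-R_1 t}$ on the standard
0.01–1.1 s seven-delay schedule, with log-linear initialization; data with
no measurable decay across the sampled window are reported failed.

Exchange-rate classes follow the half-open convention
$[0, 1000) \to$ slow, $[1000, 3000] \to$ intermediate,
$(3000, \infty) \to$ fast (s⁻¹).

## CSP, CHESPA, sequences

The combined CSP uses the conventional ¹⁵N weight $w = 0.2$ (configurable);
the significance threshold is the mean plus half the *sample* (n−1)
standard deviation over residues observed in both conditions.  Unobserved
residues are listed in reports but excluded from all statistics.  CHESPA
vectors live in weighted 2D shift space $(\Delta\delta_H,
w\,\Delta\delta_N)$; residues where either vector is shorter than 0.02 ppm
are excluded (noise-dominated angles) and reported, never divided by.
Sequence comparison counts mismatched aligned positions; equal-length pairs
compare positionally, unequal lengths are globally aligned first (match +1,
mismatch 0, linear gap −5) with gapped columns counted separately.

## Kinetics

Absorbance slopes convert to molar velocities with the NADPH extinction
coefficient 6222 M⁻¹cm⁻¹ at 340 nm and a 0.625 cm well pathlength (200 µL
in a 96-well plate), both overridable.  Michaelis–Menten and burst fits are
unweighted nonlinear least squares by default (optional per-point weights
are accepted; with the synthetic generator's proportional velocity noise,
matching weights roughly halve the $K_M$ error).  $K_M$ estimates above the
largest substrate concentration are flagged extrapolated.  Burst traces
drop samples before the instrument dead time (never extrapolated) and fit
$S(t) = a e^{-k_\mathrm{hyd} t} + mt + c$ with the tail-line/early-excess
initialization and a small grid of rate starts; a fit whose amplitude is
indistinguishable from zero ($|a| < 2\sigma_a$) is flagged no-burst.
Because hydride transfer is concentration-independent, rates fitted at
several substrate concentrations are averaged unweighted with the sample SD
as uncertainty.

## ITC

The one-site forward model updates total ligand and macromolecule per
injection with stepwise displaced-volume dilution (an injection of $dV$
into cell volume $V_0$ dilutes cell contents by $1 - dV/V_0$; displaced
liquid overflows unsensed), solves the binding quadratic for bound ligand,
and reports $\Delta H \cdot V_0 \cdot \big(B_i - B_{i-1}(1 - dV_i/V_0)\big)$
plus a constant baseline — ligand leaving the cell bound does not unbind,
so its heat is not re-counted.  A consequence worth knowing: the cumulative
heat equals $n\,\Delta H\,V_0\,[M]_0$ only when saturation is reached
within a small injected volume; macromolecule that overflows unbound never
releases its heat.  Fits use bounded least squares for $(n, K_D, \Delta H,
\mathrm{baseline})$; the first injection can optionally be excluded from
the residuals (syringe-diffusion practice) while still contributing its
dilution.  The Wiseman $c = n[M]/K_D$ is reported and fits outside
$c \in [1, 1000]$ are flagged low-confidence.  Duplicate titrations are
summarized as mean ± sample SD.  Concentrations are explicit inputs
throughout; nothing is inferred from instrument metadata.

## Ensembles

Superposition is a hand-rolled Kabsch SVD with reflections rejected
(determinant +1 enforced by sign-flipping the smallest singular vector) and
collinear point sets refused with a diagnostic.  The per-residue profile
superposes every model on the ensemble mean over the backbone atoms
(N, CA, C — no carbonyl O) of the fit range, recomputes the mean, and
repeats (two passes); the profile is the RMS over models and atoms of the
deviation from the final mean, and the overall value is the mean ± SD over
models of the whole-range RMSD.  "RMSD to iterated mean" was chosen over
mean-pairwise RMSD as the default because it scales linearly in models and
matches how ensemble precision is usually quoted; for an isotropic jitter
of width $\sigma$ per coordinate it converges to $\sigma\sqrt{3}$ per
residue, which the validation uses.  Residue numbering is taken from the
coordinate file unchanged (1-based author numbering); the default fit range
1–150 targets a conserved rigid domain, leaving a C-terminal lobe free.

## Synthetic data: what it emulates, and what passing tests do not show

The generators (`allokit.simulate`) emulate each experiment with one seeded
random stream per stage (byte-identical outputs per seed; tweaking one
stage's parameters does not disturb another's draws):

- dispersions from the **finite-time propagator** (never the fitted closed
  form) with Gaussian R2eff noise, default $\sigma = 0.3$ s⁻¹, two fields
  (600/900 MHz ¹H), a 50–1000 Hz grid in 50 Hz steps starting at the 50 Hz
  reporting point; the default residue set mirrors a homologue/mutant
  study's motifs — a three-residue substrate-binding group sharing
  $k_{ex} = 1500$ s⁻¹, one slow and one fast site, a site with exchange too
  weak to fit, and a fully quenched site;
- shift tables with defined perturbation vectors (parallel, antiparallel
  and spiked constructs) and deliberately unobserved residue stretches
  (167–175, 199–204);
- velocities at eight substrate levels spanning 0.2–4 $K_M$ with 5%
  proportional noise, and 1 kHz burst traces over 0.3 s at three substrate
  concentrations (0.5/1.0/1.5 mM) with 2% amplitude noise; kinetic truth
  defaults $K_M = 151$ µM, $k_\mathrm{cat} = 0.068$ s⁻¹,
  $k_\mathrm{hyd} = 28$ s⁻¹;
- duplicate one-site thermograms at $c \approx 10$ (200 µM cell, 3 mM
  syringe, 25 × 10 µL, $K_D = 20$ µM, $\Delta H = -8$ kcal/mol) with 2%
  of-max heat noise;
- a 206-residue toy backbone ensemble with a rigid core and one flexible
  loop (residues 156–176, 1 Å jitter) plus random global rigid transforms
  per model;
- a synthetic orthologue pair — two 206-residue sequences differing at 16
  designated positions including a threonine→serine toggle site — standing
  in for database accessions.

What this does **not** show: real dispersions carry correlated noise,
off-resonance and finite-pulse effects, and multi-site exchange; real shift
tables carry assignment errors; real plate-reader data have systematic
drifts; real ITC runs need heat-of-dilution blanks; real ensembles have
side chains and physical backbone geometry.  Passing the validation
demonstrates that the estimators recover what they model, at realistic
noise, without self-confirmation — not that the models capture every
feature of real data.

Validation statistics use enough replicates to estimate the property rather
than its sampling noise; e.g. the unweighted $K_M$ recovery median
(population value ≈ 9.5% at these conditions) is measured over 1000 seeded
replicates because a 50-replicate median fluctuates by ±1.5 percentage
points around the 10% bound.

## Known limitations

- Three-site exchange, CEST/R1ρ, finite pulse widths and TROSY
  differential relaxation are out of scope.
- $\Delta\omega$ signs are not determined (no HSQC/HMQC comparison).
- Closed-form fits in deep slow exchange inherit the finite-time
  projection-amplitude model error described above.
- Single-field exchange fits are degenerate in $(p_B, \Delta\omega)$ and
  only flagged, not prevented.
- The ITC model has no blank subtraction or baseline drift; enzyme
  concentration for $k_\mathrm{cat}$ must be supplied by the user.
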