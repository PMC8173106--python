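# allokit

A toolkit for quantifying **dynamic allostery in enzymes** — how motions at
sites far from an active site couple to catalytic function.  It implements,
as one tested pipeline, the quantitative analyses such a study runs: NMR
relaxation-dispersion modelling of micro-millisecond conformational
exchange, chemical-shift perturbation (CSP) mapping and CHESPA projection,
steady-state and pre-steady-state enzyme kinetics, one-site ITC binding
isotherms, and per-residue RMSD profiling of structural ensembles.  It is
written for NMR spectroscopists and enzymologists who want a scriptable,
reproducible alternative to a patchwork of vendor tools, with seeded
synthetic-data generators so every stage can be validated against known
ground truth.

## The models at the core

**Two-site chemical exchange under CPMG.**  A nucleus exchanging between a
major state A (population $p_A$) and a sparsely populated state B
($p_B = 1 - p_A$) at rate $k_{ex} = k_{AB} + k_{BA}$ with shift difference
$\Delta\omega$ shows an elevated effective transverse relaxation rate
$R_{2,\mathrm{eff}}$ that a CPMG pulse train progressively refocuses.  With
$\delta = 1/(2\nu_\mathrm{CPMG})$ the 180°-pulse spacing, the all-timescale
closed form (Carver–Richards) is

$$R_{2,\mathrm{eff}} = \tfrac12\Big[R_2^A + R_2^B + k_{ex} -
2\nu_\mathrm{CPMG}\,\cosh^{-1}\big(D_+\cosh\eta_+ - D_-\cos\eta_-\big)\Big]$$

with the usual $\psi$, $\zeta$, $D_\pm$, $\eta_\pm$ intermediates (see
`allokit.exchange`).  An independent Bloch–McConnell propagator —
free-precession blocks and ideal 180° pulses applied to the two-site
transverse magnetization, $R_{2,\mathrm{eff}} = -\ln(|M(T)|/|M(0)|)/T$ —
serves as the numerical oracle and as the engine for synthetic data, so
fits are never checked against the same expression that generated the data.
Fitted rates are classified as slow ($k_{ex} < 1000\,\mathrm{s^{-1}}$),
intermediate ($1000$–$3000\,\mathrm{s^{-1}}$) or fast
($> 3000\,\mathrm{s^{-1}}$).

**CSP and CHESPA.**  Combined amide perturbations
$\Delta\delta = \sqrt{\Delta\delta_H^2 + (0.2\,\Delta\delta_N)^2}$ are
thresholded at the mean plus half a standard deviation; CHESPA projects a
mutation-induced shift vector **B** onto a reference (e.g. coenzyme-binding)
vector **A**, reporting $\cos\theta = \mathbf{A}\cdot\mathbf{B}/(|A||B|)$
and the fraction $X = |B|\cos\theta/|A|$.

**Kinetics and binding.**  Initial velocities fit
$v = V_\mathrm{max}[S]/(K_M + [S])$; stopped-flow traces fit a burst
$S(t) = a\,e^{-k_\mathrm{hyd}t} + mt + c$ whose exponential phase is the
hydride-transfer (chemical) step, averaged across substrate concentrations;
injection heats fit the one-site binding quadratic with displaced-volume
dilution, yielding $n$, $K_D$ and $\Delta H$.

**Ensembles.**  Multi-model structures are superposed (Kabsch, proper
rotations only) onto an iterated ensemble mean over a chosen fit range and
summarized as a per-residue backbone RMSD profile.

## Worked example

```python
from allokit.simulate import ScenarioSpec, gen_dispersion
from allokit.dispersion import fit_residue, fit_global, classify_kex

spec = ScenarioSpec(seed=0)               # default study conditions
curves, truth = gen_dispersion(spec)      # Bloch-McConnell + noise

print(fit_residue(curves["126"]).summary())
```

```
Dispersion fit: residue 126
  model: carver_richards   status: ok
  n=40  k=5  chi2=44  red.chi2=1.26  AICc=55.75
           kex =       1508 +/- 72.1
           p_b =    0.03948 +/- 0.00368
        dw_ppm =      1.996 +/- 0.107
      r2_0_600 =      11.08 +/- 0.108
      r2_0_900 =      11.01 +/- 0.191
```

The two-field fit recovers the generator truth ($k_{ex} = 1500$ s⁻¹,
$p_B = 0.04$, $\Delta\omega = 2$ ppm, $R_{2,0} = 11$ s⁻¹) within its
standard errors.  The substrate-binding-site group fits globally with a
single shared rate:

```python
group = fit_global({r: curves[r] for r in ("125", "126", "127")})
print(group.kex)                 # 1472 +/- 33 s^-1
print(classify_kex(group.kex))   # 'intermediate_yellow'
```

i.e. a concerted intermediate-timescale motion shared by the three
reporters.  The same pattern runs from the shell:

```bash
allokit simulate --seed 0 --outdir demo/
allokit fit-dispersion demo/dispersion.csv --group 125,126,127
allokit fit-mm demo/velocities.csv --enzyme-um 1.0
allokit run-all --seed 0 --outdir demo_run/
```

## Layout

- `allokit.exchange` — Carver–Richards, Luz–Meiboom and Bloch–McConnell forward models
- `allokit.dispersion` — R2eff conversion, per-residue/global dispersion fits, model selection, R1
- `allokit.shifts` — CSP, thresholding, CHESPA, sequence comparison
- `allokit.kinetics` — Michaelis–Menten and burst-phase fits
- `allokit.itc` — one-site isotherm forward model and fit
- `allokit.ensemble` — Kabsch superposition, per-residue RMSD profiles
- `allokit.simulate` — seeded generators with ground truth for every stage
- `allokit.io`, `allokit.pipeline`, `allokit.cli` — formats, orchestration, CLI

See `docs/methods.md` for the modelling assumptions, defaults and known
limitations.
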