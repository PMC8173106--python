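"""Seeded synthetic-data generators with known ground truth.

Every stage of the analysis (dispersion fitting, CSP/CHESPA, kinetics,
ITC, ensemble RMSD) can be exercised without external downloads: the
generators here emulate the corresponding experiments with parameters a
relaxation/kinetics lab would call typical for a small dynamic reductase,
and return the ground truth alongside the data.

Independence guarantee: dispersion data are generated by the numerical
Bloch-McConnell propagator, never by the closed form used in fitting, so
parameter-recovery tests are not self-confirming.

All randomness flows through numpy Generators seeded from
``ScenarioSpec.seed`` plus a fixed per-stage offset; the same seed yields
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from allokit.dispersion import BOUNDS, DispersionCurve, RelaxationSeries
from allokit.exchange import ExchangeParams, FieldContext, r2eff_bloch_mcconnell
from allokit.itc import BindingParams, ITCExperiment, itc_forward
from allokit.kinetics import BurstTrace, VelocityDataset
from allokit.shifts import ShiftTable
from allokit.ensemble import StructureEnsemble, BACKBONE_ATOMS

__all__ = [
    "ScenarioSpec",
    "gen_dispersion",
    "gen_r1",
    "gen_shift_tables",
    "gen_kinetics",
    "gen_itc",
    "gen_ensemble",
    "gen_homologue_pair",
]

# per-stage rng streams (seed, offset) so stages are independently reproducible
_STAGE = {
    "dispersion": 1, "r1": 2, "shifts": 3, "kinetics": 4,
    "itc": 5, "ensemble": 6, "sequence": 7,
}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STAGE[stage]])


def _default_residues() -> dict[str, ExchangeParams]:
    """Default per-residue exchange truth.

    Mirrors the motifs of a two-homologue/mutant study: a substrate-binding
    group (residues 125-127) sharing an intermediate exchange rate of
    1500 s^-1 with distinct shift differences; a slow and a fast site; a
    residue (T15-like) whose exchange contribution is too low to fit; and
    a quenched site (S164-like) with no minor state at all.
    """
    return {
        "125": ExchangeParams(r2_0=10.0, kex=1500.0, p_b=0.04, delta_omega_ppm=1.0),
        "126": ExchangeParams(r2_0=11.0, kex=1500.0, p_b=0.04, delta_omega_ppm=2.0),
        "127": ExchangeParams(r2_0=9.0, kex=1500.0, p_b=0.04, delta_omega_ppm=3.0),
        "109": ExchangeParams(r2_0=10.0, kex=800.0, p_b=0.03, delta_omega_ppm=2.0),
        "133": ExchangeParams(r2_0=10.0, kex=3500.0, p_b=0.05, delta_omega_ppm=2.5),
        "15": ExchangeParams(r2_0=12.0, kex=1500.0, p_b=0.01, delta_omega_ppm=0.1),
        "164": ExchangeParams(r2_0=10.0, kex=0.0, p_b=0.0, delta_omega_ppm=0.0),
    }


@dataclass
class ScenarioSpec:
    """Ground-truth scenario for all synthetic stages.

    Defaults are the study conditions: two static fields (600/900 MHz 1H),
    a 50-1000 Hz refocusing grid starting at the 50 Hz reporting point,
    0.3 s^-1 R2eff noise, WT kinetic constants k_hyd = 28 s^-1,
    K_M = 151 uM, k_cat = 0.068 s^-1, burst traces at 0.5/1.0/1.5 mM
    substrate, a c ~ 10 one-site titration in duplicate, and an ensemble
    with a flexible 156-176 loop over a rigid core.
    """

    seed: int = 0

    # dispersion
    residues: dict[str, ExchangeParams] = dc_field(default_factory=_default_residues)
    fields_mhz: tuple[float, ...] = (600.0, 900.0)
    nu_grid_hz: tuple[float, ...] = tuple(np.arange(50.0, 1001.0, 50.0))
    t_relax_s: float = 0.04
    sigma_r2: float = 0.3

    # R1
    r1_truth: dict[str, float] = dc_field(
        default_factory=lambda: {"35": 1.6, "80": 1.5, "120": 1.2, "164": 1.3}
    )
    r1_delays_s: tuple[float, ...] = (0.01, 0.1, 0.3, 0.5, 0.7, 0.9, 1.1)
    r1_noise_frac: float = 0.02

    # shifts
    n_residues: int = 206
    unobserved: tuple[int, ...] = tuple(range(167, 176)) + tuple(range(199, 205))
    responding_residues: tuple[int, ...] = (
        14, 15, 109, 110, 111, 113, 125, 126, 127, 132, 133, 135, 153, 164, 178, 205,
    )
    negative_residues: tuple[int, ...] = (119, 120, 153)  # anti-correlated in "A"
    spiked_residues: tuple[int, ...] = (30, 60, 90, 150, 190)
    csp_background_ppm: float = 0.01
    csp_response_ppm: float = 0.15

    # kinetics
    km_um: float = 151.0
    kcat_s: float = 0.068
    enzyme_um: float = 1.0
    substrate_levels: int = 8
    velocity_noise_frac: float = 0.05
    k_hyd_s: float = 28.0
    burst_substrate_mm: tuple[float, ...] = (0.5, 1.0, 1.5)
    burst_amplitude: float = 0.05
    burst_slope: float = -0.01
    burst_offset: float = 0.5
    burst_rate_hz: float = 1000.0
    burst_span_s: float = 0.3
    trace_noise_frac: float = 0.02

    # ITC
    itc_n: float = 1.0
    itc_kd_um: float = 20.0
    itc_dh_kcal: float = -8.0
    itc_cell_um: float = 200.0
    itc_syringe_um: float = 3000.0
    itc_cell_ml: float = 1.4
    itc_injections: int = 25
    itc_injection_ul: float = 10.0
    itc_noise_frac: float = 0.02

    # ensemble
    ens_models: int = 20
    ens_loop: tuple[int, int] = (156, 176)
    ens_core_sigma: float = 0.05
    ens_loop_sigma: float = 1.0

    # homologue pair
    n_substitutions: int = 16
    substitution_site: int = 164


# ---------------------------------------------------------------------
# dispersion


def gen_dispersion(
    spec: ScenarioSpec,
) -> tuple[dict[str, list[DispersionCurve]], dict[str, ExchangeParams]]:
    """Noisy R2eff dispersion curves per residue and field, plus truth.

    R2eff values come from the Bloch-McConnell propagator with Gaussian
    noise of ``spec.sigma_r2``.  Truth parameters outside the fitter
    bounds are refused (except the deliberate no-exchange constructs).
    """
    if 50.0 not in spec.nu_grid_hz:
        raise ValueError("nu grid must include the 50 Hz reporting point")
    for rid, p in spec.residues.items():
        if p.p_b > 0 and not (
            BOUNDS["kex"][0] <= p.kex <= BOUNDS["kex"][1]
            and p.p_b <= BOUNDS["p_b"][1]
            and p.delta_omega_ppm <= BOUNDS["dw_ppm"][1]
            and 0 < p.r2_0 <= BOUNDS["r2_0"][1]
        ):
            raise ValueError(f"truth for residue {rid} outside fitter bounds: {p}")
    rng = _rng(spec.seed, "dispersion")
    nus = np.asarray(spec.nu_grid_hz, dtype=float)
    curves: dict[str, list[DispersionCurve]] = {}
    for rid, p in spec.residues.items():
        curves[rid] = []
        for mhz in spec.fields_mhz:
            fctx = FieldContext(mhz, t_relax=spec.t_relax_s)
            clean = r2eff_bloch_mcconnell(p, nus, fctx)
            noisy = clean + rng.normal(0.0, spec.sigma_r2, nus.size)
            curves[rid].append(
                DispersionCurve(
                    rid, fctx, nus, noisy, np.full(nus.size, spec.sigma_r2)
                )
            )
    return curves, dict(spec.residues)


def gen_r1(spec: ScenarioSpec) -> tuple[dict[str, RelaxationSeries], dict[str, float]]:
    """Monoexponential R1 decay series on the standard delay schedule."""
    rng = _rng(spec.seed, "r1")
    t = np.asarray(spec.r1_delays_s, dtype=float)
    series = {}
    for rid, r1 in spec.r1_truth.items():
        clean = np.exp(-r1 * t)
        noisy = clean * (1.0 + rng.normal(0.0, spec.r1_noise_frac, t.size))
        series[rid] = RelaxationSeries(rid, t, noisy)
    return series, dict(spec.r1_truth)


# ---------------------------------------------------------------------
# shifts


def gen_shift_tables(
    spec: ScenarioSpec,
) -> tuple[dict[str, ShiftTable], dict[str, object]]:
    """Apo/holo/mutant shift tables with defined perturbation vectors.

    Constructs:

    * ``apo_wt`` — baseline amide shifts;
    * ``holo_wt`` — apo plus the reference (coenzyme-binding) perturbation
      A on the responding residues, small random background elsewhere;
    * ``mut_parallel`` — perturbation 0.5*A (CHESPA cos = +1, fraction 0.5);
    * ``mut_antiparallel`` — perturbation -0.5*A on the designated
      negative residues, +0.5*A on the rest of the responding set;
    * ``mut_spiked`` — background CSPs plus 5x-background spikes on the
      designated spiked residues (threshold-recovery construct).

    Unobserved residues are listed but carry no shifts, and are dropped
    entirely from the mutant tables.
    """
    rng = _rng(spec.seed, "shifts")
    observed = [
        r for r in range(1, spec.n_residues + 1) if r not in set(spec.unobserved)
    ]
    apo = {
        r: (float(8.3 + rng.normal(0, 0.4)), float(119.0 + rng.normal(0, 4.0)))
        for r in observed
    }

    # reference perturbation A in (dH, dN) ppm, magnitude-controlled
    vec_a: dict[int, tuple[float, float]] = {}
    for r in observed:
        if r in spec.responding_residues:
            mag = spec.csp_response_ppm * float(rng.uniform(0.7, 1.5))
        else:
            mag = spec.csp_background_ppm * float(rng.uniform(0.2, 1.0))
        ang = float(rng.uniform(0, 2 * math.pi))
        # weighted-space direction mapped back to raw (dH, dN) with w = 0.2
        vec_a[r] = (mag * math.cos(ang), mag * math.sin(ang) / 0.2)

    def shifted(scale: dict[int, float]) -> dict[int, tuple[float, float]]:
        return {
            r: (apo[r][0] + scale.get(r, 0.0) * vec_a[r][0],
                apo[r][1] + scale.get(r, 0.0) * vec_a[r][1])
            for r in observed
        }

    holo = shifted({r: 1.0 for r in observed})
    par = shifted({r: 0.5 for r in observed})
    anti_scale = {
        r: (-0.5 if r in spec.negative_residues else 0.5) for r in observed
    }
    anti = shifted(anti_scale)
    # spiked construct: uniform small background + 5x spikes, built directly
    spiked = {}
    for r in observed:
        base = spec.csp_background_ppm
        mag = 5.0 * base if r in spec.spiked_residues else base * float(
            rng.uniform(0.3, 0.9)
        )
        ang = float(rng.uniform(0, 2 * math.pi))
        spiked[r] = (
            apo[r][0] + mag * math.cos(ang),
            apo[r][1] + mag * math.sin(ang) / 0.2,
        )

    unobs = frozenset(spec.unobserved)
    tables = {
        "apo_wt": ShiftTable(apo, unobs, "apo_wt"),
        "holo_wt": ShiftTable(holo, unobs, "holo_wt"),
        "mut_parallel": ShiftTable(par, unobs, "mut_parallel"),
        "mut_antiparallel": ShiftTable(anti, unobs, "mut_antiparallel"),
        "mut_spiked": ShiftTable(spiked, unobs, "mut_spiked"),
    }
    truth = {
        "vector_a": vec_a,
        "responding": tuple(spec.responding_residues),
        "negative": tuple(spec.negative_residues),
        "spiked": tuple(spec.spiked_residues),
    }
    return tables, truth


# ---------------------------------------------------------------------
# kinetics


def gen_kinetics(
    spec: ScenarioSpec,
) -> tuple[VelocityDataset, dict[float, BurstTrace], dict[str, float]]:
    """Michaelis-Menten velocities and burst traces with known truth.

    Substrate levels span 0.2-4 x K_M; velocity noise is fractional
    Gaussian.  One burst trace per substrate concentration, sampled at
    ``burst_rate_hz`` over ``burst_span_s``.
    """
    rng = _rng(spec.seed, "kinetics")
    vmax = spec.kcat_s * spec.enzyme_um
    s = np.linspace(0.2, 4.0, spec.substrate_levels) * spec.km_um
    v = vmax * s / (spec.km_um + s)
    v_noisy = v * (1.0 + rng.normal(0.0, spec.velocity_noise_frac, s.size))
    velocities = VelocityDataset(s, v_noisy, enzyme_um=spec.enzyme_um)

    t = np.arange(0.0, spec.burst_span_s, 1.0 / spec.burst_rate_hz)
    traces: dict[float, BurstTrace] = {}
    for conc in spec.burst_substrate_mm:
        clean = (
            spec.burst_amplitude * np.exp(-spec.k_hyd_s * t)
            + spec.burst_slope * t
            + spec.burst_offset
        )
        scale = spec.trace_noise_frac * spec.burst_amplitude
        traces[conc] = BurstTrace(t, clean + rng.normal(0.0, scale, t.size))
    truth = {
        "vmax": vmax,
        "km_um": spec.km_um,
        "kcat_s": spec.kcat_s,
        "k_hyd_s": spec.k_hyd_s,
        "amplitude": spec.burst_amplitude,
        "slope": spec.burst_slope,
        "offset": spec.burst_offset,
    }
    return velocities, traces, truth


# ---------------------------------------------------------------------
# ITC


def gen_itc(spec: ScenarioSpec) -> tuple[list[ITCExperiment], BindingParams]:
    """Duplicate one-site thermograms (c ~ 10 by default) plus truth."""
    rng = _rng(spec.seed, "itc")
    truth = BindingParams(spec.itc_n, spec.itc_kd_um, spec.itc_dh_kcal)
    inj = np.full(spec.itc_injections, spec.itc_injection_ul)
    expts = []
    for _ in range(2):
        expt = ITCExperiment(
            spec.itc_cell_ml, spec.itc_cell_um, spec.itc_syringe_um, inj
        )
        heats = itc_forward(truth, expt)
        noise = spec.itc_noise_frac * float(np.max(np.abs(heats)))
        heats = heats + rng.normal(0.0, noise, heats.size) if noise > 0 else heats
        expts.append(
            ITCExperiment(
                spec.itc_cell_ml, spec.itc_cell_um, spec.itc_syringe_um, inj,
                heats_ucal=heats,
            )
        )
    return expts, truth


# ---------------------------------------------------------------------
# ensemble


def _backbone_template(n_residues: int) -> np.ndarray:
    """Idealized extended backbone: (n_residues, 3 atoms, 3) in Angstrom."""
    coords = np.empty((n_residues, len(BACKBONE_ATOMS), 3))
    for i in range(n_residues):
        x = 3.8 * i
        # gentle helix-like curvature so the chain is not collinear
        y = 5.0 * math.sin(i / 8.0)
        z = 5.0 * math.cos(i / 8.0)
        coords[i, 0] = (x - 1.2, y - 0.4, z)        # N
        coords[i, 1] = (x, y + 0.4, z + 0.3)        # CA
        coords[i, 2] = (x + 1.2, y + 0.9, z)        # C
    return coords


def gen_ensemble(
    spec: ScenarioSpec, n_models: int | None = None
) -> tuple[StructureEnsemble, set[int]]:
    """Toy multi-model ensemble: rigid core plus one jittered loop.

    Core atoms receive isotropic Gaussian jitter ``ens_core_sigma``; the
    loop interval receives ``ens_loop_sigma``.  Each model additionally
    carries a random global rigid transform, which superposition must
    remove.  Returns the ensemble and the designated flexible residue set.
    """
    rng = _rng(spec.seed, "ensemble")
    n_models = n_models or spec.ens_models
    n_res = spec.n_residues
    template = _backbone_template(n_res)
    resnum = np.arange(1, n_res + 1)
    lo, hi = spec.ens_loop
    loop_mask = (resnum >= lo) & (resnum <= hi)
    sigma = np.where(loop_mask, spec.ens_loop_sigma, spec.ens_core_sigma)

    models = np.empty((n_models, n_res, len(BACKBONE_ATOMS), 3))
    for m in range(n_models):
        jitter = rng.normal(0.0, 1.0, template.shape) * sigma[:, None, None]
        coords = template + jitter
        # random proper rotation via QR of a Gaussian matrix
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1.0
        shift = rng.normal(0.0, 20.0, 3)
        models[m] = coords @ q.T + shift
    ensemble = StructureEnsemble(models, resnum)
    return ensemble, set(int(r) for r in resnum[loop_mask])


# ---------------------------------------------------------------------
# homologue sequences

_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def gen_homologue_pair(spec: ScenarioSpec) -> tuple[str, str, list[int]]:
    """Synthetic homologue pair with a known substitution count.

    Two same-length protein sequences differing at ``n_substitutions``
    positions, one of which is the designated toggle site (threonine in
    sequence A, serine in sequence B) — a stand-in, labelled synthetic,
    for a pair of orthologue sequences that would otherwise be fetched
    from a database.
    """
    rng = _rng(spec.seed, "sequence")
    n = spec.n_residues
    seq_a = list(rng.choice(list(_AA_ALPHABET), size=n))
    site = spec.substitution_site
    seq_a[site - 1] = "T"
    others = [i for i in range(1, n + 1) if i != site]
    picks = sorted(
        rng.choice(others, size=spec.n_substitutions - 1, replace=False).tolist()
    )
    positions = sorted(picks + [site])
    seq_b = list(seq_a)
    seq_b[site - 1] = "S"
    for pos in picks:
        old = seq_a[pos - 1]
        choices = [a for a in _AA_ALPHABET if a != old]
        seq_b[pos - 1] = str(rng.choice(choices))
    return "".join(seq_a), "".join(seq_b), positions
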