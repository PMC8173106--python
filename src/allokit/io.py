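"""File formats: dispersion/R1/kinetics/ITC CSV, shift TSV, NMR-STAR, PDB, FASTA.

All tabular formats carry mandatory header rows.  Readers and writers are
inverse pairs on valid data; malformed rows raise errors that name the
offending line.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.PDB import PDBParser

from allokit.dispersion import DispersionCurve, RelaxationSeries, compute_r2eff
from allokit.ensemble import BACKBONE_ATOMS, StructureEnsemble
from allokit.exchange import FieldContext
from allokit.itc import ITCExperiment
from allokit.kinetics import BurstTrace, VelocityDataset, absorbance_to_velocity
from allokit.shifts import ShiftTable

__all__ = [
    "read_dispersion",
    "write_dispersion",
    "read_r1",
    "write_r1",
    "read_shift_table",
    "write_shift_table",
    "read_velocities",
    "write_velocities",
    "read_trace",
    "write_trace",
    "read_itc",
    "write_itc",
    "read_ensemble_pdb",
    "write_ensemble_pdb",
    "read_fasta",
]

logger = logging.getLogger(__name__)

_R2EFF_COLS = ["residue", "field_mhz", "nu_cpmg_hz", "r2eff", "sigma"]
_INTENSITY_COLS = [
    "residue", "field_mhz", "nu_cpmg_hz", "intensity", "ref_intensity",
    "sigma_i", "t_relax",
]


def read_dispersion(
    path: str | Path, t_relax: float = 0.04
) -> dict[str, list[DispersionCurve]]:
    """Read dispersion CSV (R2eff dialect or raw-intensity dialect).

    The dialect is detected from the header.  Intensity rows are converted
    via the constant-time relation; non-positive intensities are dropped
    with a warning.  ``t_relax`` applies to the R2eff dialect only (the
    intensity dialect carries its own column).
    """
    df = pd.read_csv(path)
    cols = list(df.columns)
    if cols == _R2EFF_COLS:
        df["_t_relax"] = t_relax
    elif cols == _INTENSITY_COLS:
        rows = []
        for i, row in df.iterrows():
            conv = compute_r2eff(
                row["intensity"], row["ref_intensity"], row["t_relax"], row["sigma_i"]
            )
            if conv is None:
                logger.warning("%s line %d: unusable intensity, dropped", path, i + 2)
                continue
            rows.append(
                {
                    "residue": row["residue"],
                    "field_mhz": row["field_mhz"],
                    "nu_cpmg_hz": row["nu_cpmg_hz"],
                    "r2eff": conv[0],
                    "sigma": conv[1],
                    "_t_relax": row["t_relax"],
                }
            )
        df = pd.DataFrame(rows)
    else:
        raise ValueError(
            f"{path}: unrecognized dispersion header {cols}; expected "
            f"{_R2EFF_COLS} or {_INTENSITY_COLS}"
        )
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax()) + 2
        raise ValueError(f"{path} line {bad}: malformed row")
    out: dict[str, list[DispersionCurve]] = {}
    for (rid, mhz, tr), grp in df.groupby(["residue", "field_mhz", "_t_relax"]):
        fctx = FieldContext(float(mhz), t_relax=float(tr))
        out.setdefault(str(rid), []).append(
            DispersionCurve(
                str(rid), fctx,
                grp["nu_cpmg_hz"].to_numpy(float),
                grp["r2eff"].to_numpy(float),
                grp["sigma"].to_numpy(float),
            )
        )
    return out


def write_dispersion(path: str | Path, curves: dict[str, list[DispersionCurve]]) -> None:
    """Write dispersion curves in the R2eff CSV dialect."""
    rows = []
    for rid in sorted(curves):
        for c in curves[rid]:
            for nu, r2, sg in zip(c.nu_cpmg, c.r2eff, c.sigma):
                rows.append(
                    (rid, c.field.proton_mhz, float(nu), float(r2), float(sg))
                )
    pd.DataFrame(rows, columns=_R2EFF_COLS).to_csv(path, index=False)


def read_r1(path: str | Path) -> dict[str, RelaxationSeries]:
    """Read an R1 CSV (residue, delay_s, intensity)."""
    df = pd.read_csv(path)
    if list(df.columns) != ["residue", "delay_s", "intensity"]:
        raise ValueError(f"{path}: expected header residue,delay_s,intensity")
    out = {}
    for rid, grp in df.groupby("residue"):
        out[str(rid)] = RelaxationSeries(
            str(rid), grp["delay_s"].to_numpy(float), grp["intensity"].to_numpy(float)
        )
    return out


def write_r1(path: str | Path, series: dict[str, RelaxationSeries]) -> None:
    rows = [
        (rid, float(t), float(y))
        for rid in sorted(series)
        for t, y in zip(series[rid].delays, series[rid].intensities)
    ]
    pd.DataFrame(rows, columns=["residue", "delay_s", "intensity"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------
# shift tables


def read_shift_table(path: str | Path, dialect: str | None = None) -> ShiftTable:
    """Read a shift table (TSV or minimal NMR-STAR chemical-shift loop).

    Dialect detected from the extension (.str/.star -> NMR-STAR) unless
    given.  TSV columns: residue, aa, atom (H or N), shift_ppm; a row with
    an empty shift marks the residue unobserved.  Residues with only one
    of the amide pair are flagged incomplete and listed as unobserved.
    """
    path = Path(path)
    if dialect is None:
        dialect = "nmrstar" if path.suffix.lower() in (".str", ".star") else "tsv"
    if dialect == "tsv":
        return _read_shift_tsv(path)
    if dialect == "nmrstar":
        return _read_shift_nmrstar(path)
    raise ValueError(f"unknown shift-table dialect {dialect!r}")


def _assemble_shift_table(
    per_atom: dict[int, dict[str, float]], unobserved: set[int], name: str
) -> ShiftTable:
    shifts = {}
    for rid, atoms in per_atom.items():
        if "H" in atoms and "N" in atoms:
            shifts[rid] = (atoms["H"], atoms["N"])
        else:
            logger.warning(
                "residue %d incomplete (only %s); flagged unobserved",
                rid, "/".join(sorted(atoms)),
            )
            unobserved.add(rid)
    return ShiftTable(shifts, frozenset(unobserved), name)


def _read_shift_tsv(path: Path) -> ShiftTable:
    per_atom: dict[int, dict[str, float]] = {}
    unobserved: set[int] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["residue", "aa", "atom", "shift_ppm"]:
            raise ValueError(f"{path} line 1: expected residue/aa/atom/shift_ppm header")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path} line {lineno}: expected 4 tab-separated fields")
            res_s, _aa, atom, shift_s = parts
            try:
                rid = int(res_s)
            except ValueError as exc:
                raise ValueError(f"{path} line {lineno}: bad residue {res_s!r}") from exc
            if shift_s == "" or atom == ".":
                unobserved.add(rid)
                continue
            if atom not in ("H", "N"):
                logger.debug("%s line %d: atom %s ignored", path, lineno, atom)
                continue
            try:
                per_atom.setdefault(rid, {})[atom] = float(shift_s)
            except ValueError as exc:
                raise ValueError(f"{path} line {lineno}: bad shift {shift_s!r}") from exc
    return _assemble_shift_table(per_atom, unobserved, path.stem)


def _read_shift_nmrstar(path: Path) -> ShiftTable:
    """Minimal NMR-STAR v3 reader: the first _Atom_chem_shift loop."""
    lines = Path(path).read_text().splitlines()
    i = 0
    tags: list[str] = []
    rows: list[list[str]] = []
    while i < len(lines):
        if lines[i].strip() == "loop_":
            j = i + 1
            block_tags = []
            while j < len(lines) and lines[j].strip().startswith("_"):
                block_tags.append(lines[j].strip())
                j += 1
            if any(t.startswith("_Atom_chem_shift.") for t in block_tags):
                tags = block_tags
                while j < len(lines) and lines[j].strip() not in ("stop_",):
                    s = lines[j].strip()
                    if s and not s.startswith("#"):
                        rows.append(s.split())
                    j += 1
                break
            i = j
        else:
            i += 1
    if not tags:
        raise ValueError(f"{path}: no _Atom_chem_shift loop found")

    def col(name: str) -> int:
        full = f"_Atom_chem_shift.{name}"
        if full not in tags:
            raise ValueError(f"{path}: missing tag {full}")
        return tags.index(full)

    c_res, c_atom, c_val = col("Comp_index_ID"), col("Atom_ID"), col("Val")
    per_atom: dict[int, dict[str, float]] = {}
    for k, row in enumerate(rows):
        if len(row) != len(tags):
            raise ValueError(f"{path}: malformed loop row {k + 1}: {row}")
        atom = row[c_atom]
        if atom not in ("H", "N"):
            continue
        per_atom.setdefault(int(row[c_res]), {})[atom] = float(row[c_val])
    return _assemble_shift_table(per_atom, set(), path.stem)


def write_shift_table(path: str | Path, table: ShiftTable) -> None:
    """Write a shift table TSV (unobserved residues as empty-shift rows)."""
    with open(path, "w") as fh:
        fh.write("residue\taa\tatom\tshift_ppm\n")
        for rid in table.residues:
            h, n = table.shifts[rid]
            fh.write(f"{rid}\tX\tH\t{float(h)!r}\n")
            fh.write(f"{rid}\tX\tN\t{float(n)!r}\n")
        for rid in sorted(table.unobserved):
            fh.write(f"{rid}\tX\t.\t\n")


# ---------------------------------------------------------------------
# kinetics


def read_velocities(
    path: str | Path,
    enzyme_um: float | None = None,
    epsilon: float | None = None,
    path_cm: float | None = None,
) -> VelocityDataset:
    """Read a velocity CSV (either ``v_uM_per_s`` or raw ``slope_A_per_s``).

    The raw-slope dialect is converted with the supplied extinction
    coefficient and pathlength (defaults: NADPH at 340 nm, 200 uL well).
    """
    df = pd.read_csv(path)
    cols = list(df.columns)
    if cols == ["[S]_uM", "v_uM_per_s"]:
        v = df["v_uM_per_s"].to_numpy(float)
    elif cols == ["[S]_uM", "slope_A_per_s"]:
        kwargs = {}
        if epsilon is not None:
            kwargs["epsilon"] = epsilon
        if path_cm is not None:
            kwargs["path"] = path_cm
        v = np.array(
            [absorbance_to_velocity(s, **kwargs) * 1e6
             for s in df["slope_A_per_s"].to_numpy(float)]
        )
    else:
        raise ValueError(f"{path}: unrecognized kinetics header {cols}")
    return VelocityDataset(df["[S]_uM"].to_numpy(float), v, enzyme_um=enzyme_um)


def write_velocities(path: str | Path, data: VelocityDataset) -> None:
    pd.DataFrame(
        {"[S]_uM": data.substrate_um, "v_uM_per_s": data.velocity_um_s}
    ).to_csv(path, index=False)


def read_trace(path: str | Path) -> BurstTrace:
    df = pd.read_csv(path)
    if list(df.columns) != ["t_s", "signal"]:
        raise ValueError(f"{path}: expected header t_s,signal")
    return BurstTrace(df["t_s"].to_numpy(float), df["signal"].to_numpy(float))


def write_trace(path: str | Path, trace: BurstTrace) -> None:
    pd.DataFrame({"t_s": trace.time_s, "signal": trace.signal}).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------
# ITC


def read_itc(path: str | Path) -> ITCExperiment:
    """Read an ITC CSV: ``# key: value`` header block then injection table."""
    meta: dict[str, float] = {}
    body_start = 0
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = float(val)
        else:
            body_start = i
            break
    required = {"cell_mL", "cell_uM", "syringe_uM"}
    if not required <= set(meta):
        raise ValueError(f"{path}: header must define {sorted(required)}")
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])))
    if list(df.columns) != ["injection_uL", "heat_ucal"]:
        raise ValueError(f"{path}: expected columns injection_uL,heat_ucal")
    return ITCExperiment(
        meta["cell_mL"], meta["cell_uM"], meta["syringe_uM"],
        df["injection_uL"].to_numpy(float),
        heats_ucal=df["heat_ucal"].to_numpy(float),
        temperature_c=meta.get("temp_C", 20.0),
    )


def write_itc(path: str | Path, expt: ITCExperiment) -> None:
    with open(path, "w") as fh:
        fh.write(f"# cell_mL: {float(expt.cell_ml)!r}\n")
        fh.write(f"# cell_uM: {float(expt.cell_um)!r}\n")
        fh.write(f"# syringe_uM: {float(expt.syringe_um)!r}\n")
        fh.write(f"# temp_C: {float(expt.temperature_c)!r}\n")
        fh.write("injection_uL,heat_ucal\n")
        heats = expt.heats_ucal
        if heats is None:
            heats = np.full(expt.n_injections, math.nan)
        for dv, q in zip(expt.injections_ul, heats):
            fh.write(f"{float(dv)!r},{float(q)!r}\n")


# ---------------------------------------------------------------------
# structures & sequences


def read_ensemble_pdb(path: str | Path, chain_id: str | None = None) -> StructureEnsemble:
    """Read a multi-model PDB into a backbone ensemble (N, CA, C).

    Residues missing any backbone atom in any model are excluded with a
    warning; all models must then share the residue set.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ens", str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"{path}: no models found")
    per_model: list[dict[int, np.ndarray]] = []
    chain_used = None
    for model in models:
        chains = list(model)
        chain = next((c for c in chains if chain_id is None or c.id == chain_id), None)
        if chain is None:
            raise ValueError(f"{path}: chain {chain_id!r} absent from model {model.id}")
        chain_used = chain.id
        resmap = {}
        for res in chain:
            if res.id[0] != " ":
                continue
            if all(a in res for a in BACKBONE_ATOMS):
                resmap[res.id[1]] = np.stack(
                    [res[a].get_coord() for a in BACKBONE_ATOMS]
                )
        per_model.append(resmap)
    common = set(per_model[0])
    union = set()
    for m in per_model:
        common &= set(m)
        union |= set(m)
    dropped = sorted(union - common)
    if dropped:
        logger.warning("%s: %d residue(s) missing backbone atoms in some model: %s",
                       path, len(dropped), dropped)
    if not common:
        raise ValueError(f"{path}: no residues complete in every model")
    resnum = np.array(sorted(common))
    coords = np.stack(
        [np.stack([m[r] for r in resnum]) for m in per_model]
    ).astype(float)
    return StructureEnsemble(coords, resnum, BACKBONE_ATOMS, chain_used or "A")


def write_ensemble_pdb(path: str | Path, ensemble: StructureEnsemble) -> None:
    """Write a backbone-only multi-model PDB (MODEL/ENDMDL records)."""
    elements = {"N": "N", "CA": "C", "C": "C"}
    with open(path, "w") as fh:
        serial = 0
        for m in range(ensemble.n_models):
            fh.write(f"MODEL     {m + 1:4d}\n")
            for i, rid in enumerate(ensemble.residue_numbers):
                for j, atom in enumerate(ensemble.atom_names):
                    serial += 1
                    x, y, z = ensemble.coords[m, i, j]
                    fh.write(
                        f"ATOM  {serial % 100000:5d} {atom:^4s} "
                        f"GLY {ensemble.chain_id}{int(rid):4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                        f"          {elements.get(atom, 'C'):>2s}\n"
                    )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences keyed by record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
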