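"""Readers, writers and report rendering for the documented CSV dialects.

All dialects are plain UTF-8 CSV.  Instrument-style files (ITC heats, FRAP
traces) carry a metadata header block of ``# key: value`` lines before the
column header.  Machine-readable TSV output always uses the ASCII
hyphen-minus.
"""

from __future__ import annotations

import dataclasses
import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dsf import MeltCurve
from .frap import FrapTrace
from .itc import BindingFitResults, Titration

__all__ = [
    "RunConfig",
    "read_melt_csv",
    "read_melt_wide_csv",
    "write_melt_csv",
    "read_titration_csv",
    "write_titration_csv",
    "read_frap_csv",
    "write_frap_csv",
    "read_dose_csv",
    "read_qpcr_csv",
    "render_table1",
]


@dataclass
class RunConfig:
    """Every tunable of the pipeline, serializable to/from YAML or JSON."""

    seed: int = 0
    gas_constant_kcal: float = 1.9872e-3
    itc_temperature_c: float = 15.0
    dsf_noise_floor_factor: float = 5.0
    dsf_truncate_margin_c: float = 2.0
    itc_n_baseline: int = 2
    weak_kd_nM: float = 50_000.0
    weak_c_value: float = 1.0
    affinity_bins_nM: tuple = (100.0, 1000.0, 10000.0)
    ci_mutually_exclusive: bool = True
    frap_method: str = "exponential"
    paired_t_test: bool = False
    fa_clip: float = 0.01
    fit_xtol: float = 1e-14

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "affinity_bins_nM" in data:
            data["affinity_bins_nM"] = tuple(data["affinity_bins_nM"])
        return cls(**data)

    def to_yaml(self) -> str:
        data = dataclasses.asdict(self)
        data["affinity_bins_nM"] = list(data["affinity_bins_nM"])
        return yaml.safe_dump(data, sort_keys=True)


# ------------------------------------------------------------- melt curves


def read_melt_csv(path: str | Path) -> list[MeltCurve]:
    """Long-format melt CSV: well,protein,compound,conc_uM,temperature_C,fluorescence."""
    df = pd.read_csv(path)
    required = {"well", "protein", "compound", "conc_uM", "temperature_C", "fluorescence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    curves = []
    for (well, protein), grp in df.groupby(["well", "protein"], sort=True):
        grp = grp.sort_values("temperature_C")
        compound = grp["compound"].iloc[0]
        compound = None if pd.isna(compound) or compound == "" else str(compound)
        conc = grp["conc_uM"].iloc[0]
        curves.append(
            MeltCurve(
                well_id=str(well), protein_id=str(protein), compound_id=compound,
                compound_conc=0.0 if pd.isna(conc) else float(conc),
                temperatures=grp["temperature_C"].to_numpy(),
                fluorescence=grp["fluorescence"].to_numpy(),
            )
        )
    return curves


def read_melt_wide_csv(data_path: str | Path, plate_map_path: str | Path) -> list[MeltCurve]:
    """Wide-format reader: temperature_C column + one column per well, with a
    plate-map CSV (well,protein,compound,conc_uM) supplying annotations."""
    df = pd.read_csv(data_path)
    if "temperature_C" not in df.columns:
        raise ValueError(f"{data_path}: first column must be temperature_C")
    plate = pd.read_csv(plate_map_path)
    plate_idx = plate.set_index("well")
    curves = []
    for well in [c for c in df.columns if c != "temperature_C"]:
        if well not in plate_idx.index:
            raise KeyError(f"well {well!r} present in data but absent from plate map")
        row = plate_idx.loc[well]
        compound = row["compound"]
        compound = None if pd.isna(compound) or compound == "" else str(compound)
        curves.append(
            MeltCurve(
                well_id=well, protein_id=str(row["protein"]), compound_id=compound,
                compound_conc=0.0 if pd.isna(row["conc_uM"]) else float(row["conc_uM"]),
                temperatures=df["temperature_C"].to_numpy(),
                fluorescence=df[well].to_numpy(dtype=float),
            )
        )
    return curves


def write_melt_csv(curves: list[MeltCurve], path: str | Path) -> None:
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "well": c.well_id, "protein": c.protein_id,
                    "compound": c.compound_id if c.compound_id is not None else "",
                    "conc_uM": c.compound_conc,
                    "temperature_C": c.temperatures, "fluorescence": c.fluorescence,
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False, float_format="%.10g")


# ------------------------------------------------------------- ITC


def _read_metadata_block(path: str | Path) -> tuple[dict, str]:
    meta = {}
    body_lines = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
        else:
            body_lines.append(line)
    return meta, "\n".join(body_lines)


def read_titration_csv(path: str | Path) -> Titration:
    """Integrated-heats CSV with a '#'-prefixed metadata header block."""
    meta, body = _read_metadata_block(path)
    for key in ("syringe_conc_uM", "cell_conc_uM", "cell_volume_ml", "temperature_C"):
        if key not in meta:
            raise ValueError(f"{path}: missing metadata key {key!r}")
    df = pd.read_csv(_io.StringIO(body))
    missing = {"injection_index", "volume_ul", "heat_ucal"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = df.sort_values("injection_index")
    return Titration(
        protein_id=meta.get("protein_id", ""),
        compound_id=meta.get("compound_id", ""),
        syringe_conc=float(meta["syringe_conc_uM"]),
        cell_conc=float(meta["cell_conc_uM"]),
        cell_volume=float(meta["cell_volume_ml"]),
        injection_volumes=df["volume_ul"].to_numpy(),
        temperature=float(meta["temperature_C"]),
        heats=df["heat_ucal"].to_numpy(),
    )


def write_titration_csv(titration: Titration, path: str | Path) -> None:
    lines = [
        f"# protein_id: {titration.protein_id}",
        f"# compound_id: {titration.compound_id}",
        f"# syringe_conc_uM: {titration.syringe_conc:.10g}",
        f"# cell_conc_uM: {titration.cell_conc:.10g}",
        f"# cell_volume_ml: {titration.cell_volume:.10g}",
        f"# temperature_C: {titration.temperature:.10g}",
        "injection_index,volume_ul,heat_ucal",
    ]
    for i, (v, h) in enumerate(zip(titration.injection_volumes, titration.heats)):
        lines.append(f"{i},{v:.10g},{h:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


# ------------------------------------------------------------- FRAP


def read_frap_csv(path: str | Path) -> FrapTrace:
    meta, body = _read_metadata_block(path)
    df = pd.read_csv(_io.StringIO(body))
    missing = {"time_s", "I_roi", "T_nucleus", "BG"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return FrapTrace(
        times=df["time_s"].to_numpy(),
        bleached_roi=df["I_roi"].to_numpy(),
        whole_nucleus=df["T_nucleus"].to_numpy(),
        background=df["BG"].to_numpy(),
        bleach_frame=int(meta.get("bleach_frame", 5)),
        n_prebleach=int(meta.get("n_prebleach", 5)),
        cell_id=meta.get("cell_id", ""),
        treatment=meta.get("treatment", ""),
        concentration=float(meta.get("concentration_uM", 0.0)),
    )


def write_frap_csv(trace: FrapTrace, path: str | Path) -> None:
    lines = [
        f"# cell_id: {trace.cell_id}",
        f"# treatment: {trace.treatment}",
        f"# concentration_uM: {trace.concentration:.10g}",
        f"# bleach_frame: {trace.bleach_frame}",
        f"# n_prebleach: {trace.n_prebleach}",
        "time_s,I_roi,T_nucleus,BG",
    ]
    for t, i, tn, bg in zip(trace.times, trace.bleached_roi, trace.whole_nucleus, trace.background):
        lines.append(f"{t:.10g},{i:.10g},{tn:.10g},{bg:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


# ------------------------------------------------------------- dose grids and qPCR


def read_dose_csv(path: str | Path):
    """Long-format checkerboard CSV into a DoseGrid.

    Columns: drug_a,dose_a_nM,drug_b,dose_b_nM,replicate,od_raw,od_blank;
    rows with both doses 0 are the vehicle wells.  Readings are blanked,
    normalized to vehicle and averaged over replicates.
    """
    from .assays import DoseGrid, normalize_viability

    df = pd.read_csv(path)
    required = {"drug_a", "dose_a_nM", "drug_b", "dose_b_nM", "replicate", "od_raw", "od_blank"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    blank = float(df["od_blank"].mean())
    vehicle = df.loc[(df["dose_a_nM"] == 0) & (df["dose_b_nM"] == 0), "od_raw"]
    if vehicle.empty:
        raise ValueError(f"{path}: no vehicle (both doses 0) rows")
    surviving = normalize_viability(df["od_raw"].to_numpy(), blank, vehicle.to_numpy())
    df = df.assign(fa=1.0 - np.clip(surviving, 0.0, 1.0))
    pivot = df.groupby(["dose_a_nM", "dose_b_nM"])["fa"].mean().unstack()
    doses_a = pivot.index.to_numpy(dtype=float)
    doses_b = pivot.columns.to_numpy(dtype=float)
    n_rep = int(df.groupby(["dose_a_nM", "dose_b_nM"]).size().max())
    return DoseGrid(
        drug_a=str(df["drug_a"].iloc[0]), drug_b=str(df["drug_b"].iloc[0]),
        drug_a_doses=doses_a, drug_b_doses=doses_b,
        fa=pivot.to_numpy(dtype=float), n_replicates=n_rep,
    )


def read_qpcr_csv(path: str | Path) -> pd.DataFrame:
    """qPCR Ct table: sample,gene,ct,role with role in {target,reference,control}."""
    df = pd.read_csv(path)
    missing = {"sample", "gene", "ct", "role"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = set(df["role"]) - {"target", "reference", "control"}
    if bad:
        raise ValueError(f"{path}: unknown role values {sorted(bad)}")
    return df


# ------------------------------------------------------------- reports


def render_table1(fits: list[BindingFitResults]) -> str:
    """Panel-style thermodynamics table (TSV).

    K_D to 1 decimal in nM, energies to 2 decimals; weak-binding rows show
    the text 'Weak binding' with empty numeric cells.
    """
    header = "Protein\tP_uM\tL_uM\tKD_nM\tdH_kcal_mol\tN\tTdS_kcal_mol\tdG_kcal_mol"
    lines = [header]
    for fit in fits:
        t = fit.titration
        protein = t.protein_id if t else ""
        p_um = f"{t.syringe_conc:g}" if t else ""
        l_um = f"{t.cell_conc:g}" if t else ""
        if fit.weak_binding:
            lines.append(f"{protein}\t{p_um}\t{l_um}\tWeak binding\t\t\t\t")
            continue
        err = fit.param_errors
        kd = f"{fit.kd:.1f}"
        if "kd" in err:
            kd += f" +/- {err['kd']:.1f}"
        dh = f"{fit.dh:.2f}"
        if "dh" in err:
            dh += f" +/- {err['dh']:.2f}"
        n = f"{fit.n_sites:.2f}"
        if "n_sites" in err:
            n += f" +/- {err['n_sites']:.2f}"
        lines.append(
            f"{protein}\t{p_um}\t{l_um}\t{kd}\t{dh}\t{n}\t{fit.tds:.2f}\t{fit.dg:.2f}"
        )
    return "\n".join(lines) + "\n"


def results_to_json(results: dict, path: str | Path) -> None:
    """Emit a single JSON document per run for programmatic use."""

    def default(obj):
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        raise TypeError(f"not JSON serializable: {type(obj)}")

    Path(path).write_text(json.dumps(results, indent=2, default=default, sort_keys=True))
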