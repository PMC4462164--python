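"""Readers and writers for the pipeline's delimited-text and stack formats.

Traces and metabolite series are tab-separated text with ``# key = value``
metadata header lines; image stacks are multi-page grayscale TIFFs (one
per channel) with a YAML sidecar carrying the voxel size.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .community import ImageStack, PlateCount
from .config import InputError
from .electrochemistry import CurrentTrace
from .metabolism import MetaboliteSeries
from .transcriptomics import ExpressionTable


def _write_tsv(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k} = {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path) -> tuple[pd.DataFrame, dict]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line.lstrip("#").partition("=")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    return df, meta


def write_trace(trace: CurrentTrace, path) -> None:
    _write_tsv(pd.DataFrame({"time_s": trace.time_s, "voltage_V": trace.voltage_V}),
               path, {"resistor_ohm": trace.resistor_ohm,
                      "electrode_area_cm2": trace.electrode_area_cm2,
                      "label": trace.label})


def read_trace(path, resistor_ohm: float | None = None,
               electrode_area_cm2: float | None = None) -> CurrentTrace:
    df, meta = _read_tsv(path)
    r = resistor_ohm if resistor_ohm is not None else float(meta.get("resistor_ohm", 0))
    a = (electrode_area_cm2 if electrode_area_cm2 is not None
         else float(meta.get("electrode_area_cm2", 0)))
    if r <= 0 or a <= 0:
        raise InputError("resistor/area missing from file metadata and arguments")
    return CurrentTrace(time_s=df["time_s"].to_numpy(),
                        voltage_V=df["voltage_V"].to_numpy(),
                        resistor_ohm=r, electrode_area_cm2=a,
                        label=meta.get("label", ""))


def write_metabolites(series: MetaboliteSeries, path) -> None:
    df = series.conc_mM.copy()
    df.insert(0, "time_h", series.time_h)
    _write_tsv(df, path, {"volume_L": series.volume_L})


def read_metabolites(series_path, volume_L: float | None = None) -> MetaboliteSeries:
    df, meta = _read_tsv(series_path)
    v = volume_L if volume_L is not None else float(meta.get("volume_L", 0))
    if v <= 0:
        raise InputError("volume_L missing from file metadata and arguments")
    return MetaboliteSeries(time_h=df["time_h"].to_numpy(),
                            conc_mM=df.drop(columns="time_h").clip(lower=0.0),
                            volume_L=v)


def write_plate_counts(counts: list[PlateCount], path) -> None:
    _write_tsv(pd.DataFrame([vars(c) for c in counts]), path)


def read_plate_counts(path) -> list[PlateCount]:
    df, _ = _read_tsv(path)
    return [PlateCount(compartment=r.compartment, time_h=float(r.time_h),
                       dilution=float(r.dilution),
                       plated_volume_mL=float(r.plated_volume_mL),
                       total_colonies=int(r.total_colonies),
                       fluorescent_colonies=int(r.fluorescent_colonies))
            for r in df.itertuples()]


def write_stack(stack: ImageStack, gfp_path, dapi_path, sidecar_path) -> None:
    tifffile.imwrite(gfp_path, stack.gfp_voxels.astype(np.float32))
    tifffile.imwrite(dapi_path, stack.dapi_voxels.astype(np.float32))
    with open(sidecar_path, "w") as fh:
        yaml.safe_dump({"voxel_size_um": list(stack.voxel_size_um),
                        "threshold_method": stack.threshold_method}, fh)


def read_stack(gfp_path, dapi_path, sidecar_path=None,
               voxel_size_um=None) -> ImageStack:
    gfp = np.asarray(tifffile.imread(gfp_path), dtype=float)
    dapi = np.asarray(tifffile.imread(dapi_path), dtype=float)
    method = "otsu"
    if sidecar_path is not None:
        with open(sidecar_path) as fh:
            meta = yaml.safe_load(fh)
        voxel_size_um = voxel_size_um or tuple(meta["voxel_size_um"])
        method = meta.get("threshold_method", "otsu")
    if voxel_size_um is None:
        raise InputError("voxel size required (sidecar or argument)")
    return ImageStack(gfp_voxels=np.clip(gfp, 0, None),
                      dapi_voxels=np.clip(dapi, 0, None),
                      voxel_size_um=tuple(voxel_size_um),
                      threshold_method=method)


def write_fluorescence(readings: pd.DataFrame, path) -> None:
    _write_tsv(readings, path)


def read_fluorescence(path) -> pd.DataFrame:
    df, _ = _read_tsv(path)
    return df


def write_expression(table: ExpressionTable, counts_path, conditions_path) -> None:
    df = table.counts.copy()
    df.insert(0, "length_bp", table.length_bp)
    df.insert(0, "gene_id", df.index)
    _write_tsv(df, counts_path)
    with open(conditions_path, "w") as fh:
        yaml.safe_dump({"conditions": table.conditions.to_dict()}, fh)


def read_expression(counts_path, conditions_path) -> ExpressionTable:
    df, _ = _read_tsv(counts_path)
    df = df.set_index("gene_id")
    lengths = df.pop("length_bp")
    with open(conditions_path) as fh:
        cond = yaml.safe_load(fh)["conditions"]
    return ExpressionTable(counts=df, length_bp=lengths,
                           conditions=pd.Series(cond, name="condition"))


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
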