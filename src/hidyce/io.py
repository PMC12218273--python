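"""Readers/writers for all tabular artifacts, plus the run manifest.

All artifacts are TSV with header rows and explicit schemas, UTF-8,
'.' decimal separator; floats are serialised with 9 significant digits
(round-trips integers bit-exactly and floats to that precision).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .binning import BinnedTrace, BinningMode, DyeTrace
from .config import InstrumentConfig, SamplePlan
from .fragment_quant import AlleleRegistry, PeakMeasurement, RegistryEntry
from .lod_stats import DilutionStudy
from .simgen import PixelFrameSeries

FLOAT_FMT = "%.9g"


class SchemaError(ValueError):
    """An artifact file does not match its expected column schema."""


def _check_schema(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


# -- pixel frames ---------------------------------------------------------

FRAME_COLUMNS = ["scan", "capillary", "region_index", "counts"]


def write_frames(frames: PixelFrameSeries, path) -> None:
    n_scan, n_cap, n_reg = frames.counts.shape
    scan, cap, reg = np.meshgrid(
        np.arange(n_scan), np.arange(n_cap), np.arange(n_reg), indexing="ij"
    )
    df = pd.DataFrame({
        "scan": scan.ravel(), "capillary": cap.ravel(),
        "region_index": reg.ravel(), "counts": frames.counts.ravel(),
    })
    _write_tsv(df, path)


def read_frames(path) -> PixelFrameSeries:
    df = pd.read_csv(path, sep="\t")
    _check_schema(df, FRAME_COLUMNS, path)
    n_scan = df["scan"].max() + 1
    n_cap = df["capillary"].max() + 1
    n_reg = df["region_index"].max() + 1
    counts = np.zeros((n_scan, n_cap, n_reg))
    counts[df["scan"], df["capillary"], df["region_index"]] = df["counts"]
    return PixelFrameSeries(counts=counts)


# -- binned traces --------------------------------------------------------

TRACE_COLUMNS = ["scan", "capillary", "region_index", "counts", "saturated"]


def write_binned_trace(trace: BinnedTrace, path) -> None:
    n_scan, n_cap, n_reg = trace.signals.shape
    scan, cap, reg = np.meshgrid(
        np.arange(n_scan), np.arange(n_cap), np.arange(n_reg), indexing="ij"
    )
    df = pd.DataFrame({
        "scan": scan.ravel(), "capillary": cap.ravel(),
        "region_index": reg.ravel(), "counts": trace.signals.ravel(),
        "saturated": trace.saturated.ravel().astype(int),
    })
    _write_tsv(df, path)


def read_binned_trace(trace_path, mode: BinningMode) -> BinnedTrace:
    df = pd.read_csv(trace_path, sep="\t")
    _check_schema(df, TRACE_COLUMNS, trace_path)
    n_scan = df["scan"].max() + 1
    n_cap = df["capillary"].max() + 1
    n_reg = df["region_index"].max() + 1
    signals = np.zeros((n_scan, n_cap, n_reg))
    sat = np.zeros((n_scan, n_cap, n_reg), dtype=bool)
    idx = (df["scan"], df["capillary"], df["region_index"])
    signals[idx] = df["counts"]
    sat[idx] = df["saturated"].astype(bool)
    return BinnedTrace(signals=signals, saturated=sat, mode=mode)


# -- dye traces -----------------------------------------------------------

DYE_COLUMNS = ["scan", "capillary", "dye", "intensity", "saturated"]


def write_dye_trace(trace: DyeTrace, path) -> None:
    n_scan, n_cap, n_dye = trace.intensities.shape
    scan, cap, dye = np.meshgrid(
        np.arange(n_scan), np.arange(n_cap), np.arange(n_dye), indexing="ij"
    )
    sat = np.broadcast_to(
        trace.saturated[:, :, None], trace.intensities.shape
    )
    df = pd.DataFrame({
        "scan": scan.ravel(), "capillary": cap.ravel(), "dye": dye.ravel(),
        "intensity": trace.intensities.ravel(),
        "saturated": sat.ravel().astype(int),
    })
    _write_tsv(df, path)


def read_dye_trace(path) -> DyeTrace:
    df = pd.read_csv(path, sep="\t")
    _check_schema(df, DYE_COLUMNS, path)
    n_scan = df["scan"].max() + 1
    n_cap = df["capillary"].max() + 1
    n_dye = df["dye"].max() + 1
    intensities = np.zeros((n_scan, n_cap, n_dye))
    intensities[df["scan"], df["capillary"], df["dye"]] = df["intensity"]
    sat = np.zeros((n_scan, n_cap), dtype=bool)
    flagged = df[df["saturated"].astype(bool)]
    sat[flagged["scan"], flagged["capillary"]] = True
    return DyeTrace(intensities=intensities, saturated=sat)


# -- registries and measurements ------------------------------------------

REGISTRY_COLUMNS = ["allele", "dye", "position"]
MEASUREMENT_COLUMNS = ["allele", "intensity", "saturated", "unreliable"]


def write_registry(registry: AlleleRegistry, path) -> None:
    df = pd.DataFrame(
        [(e.name, e.dye_channel, e.position) for e in registry],
        columns=REGISTRY_COLUMNS,
    )
    _write_tsv(df, path)


def read_registry(path) -> AlleleRegistry:
    df = pd.read_csv(path, sep="\t")
    _check_schema(df, REGISTRY_COLUMNS, path)
    return AlleleRegistry(tuple(
        RegistryEntry(str(r.allele), int(r.dye), int(r.position))
        for r in df.itertuples()
    ))


def write_measurements(rows: list[dict], path) -> None:
    df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    _write_tsv(df, path)


# -- dilution studies ------------------------------------------------------

STUDY_COLUMNS = ["mutation", "prepared_vaf", "replicate", "R"]


def write_study(study: DilutionStudy, path) -> None:
    rows = []
    for i, v in enumerate(study.vaf_grid):
        for j in range(study.replicates):
            rows.append((study.mutation, v, j, study.R_matrix[i, j]))
    _write_tsv(pd.DataFrame(rows, columns=STUDY_COLUMNS), path)


def read_study(path) -> DilutionStudy:
    df = pd.read_csv(path, sep="\t")
    _check_schema(df, STUDY_COLUMNS, path)
    mutations = df["mutation"].unique()
    if len(mutations) != 1:
        raise SchemaError(f"{path}: expected one mutation, got {list(mutations)}")
    grid = sorted(df["prepared_vaf"].unique())
    n_rep = df["replicate"].max() + 1
    R = np.full((len(grid), n_rep), np.nan)
    for row in df.itertuples():
        R[grid.index(row.prepared_vaf), int(row.replicate)] = row.R
    return DilutionStudy(
        mutation=str(mutations[0]), vaf_grid=tuple(grid),
        replicates=int(n_rep), R_matrix=R,
    )


# -- config / plan documents ----------------------------------------------

def load_config(path) -> InstrumentConfig:
    return InstrumentConfig.from_dict(_load_document(path))


def load_plan(path) -> SamplePlan:
    return SamplePlan.from_dict(_load_document(path))


def dump_config(config: InstrumentConfig, path) -> None:
    _dump_document(config.to_dict(), path)


def dump_plan(plan: SamplePlan, path) -> None:
    _dump_document(plan.to_dict(), path)


def _load_document(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        return yaml.safe_load(text)
    return json.loads(text)


def _dump_document(doc: dict, path) -> None:
    if str(path).endswith((".yaml", ".yml")):
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))
    else:
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))


# -- run manifest ----------------------------------------------------------

@dataclass
class RunManifest:
    """Provenance record tying pipeline outputs to their inputs."""

    config_hash: str
    seed: int
    package_version: str
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    timestamp: str = ""

    @classmethod
    def create(cls, config: InstrumentConfig, seed: int) -> "RunManifest":
        from . import __version__

        blob = json.dumps(config.to_dict(), sort_keys=True).encode()
        return cls(
            config_hash=hashlib.sha256(blob).hexdigest(),
            seed=seed,
            package_version=__version__,
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        )

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))
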