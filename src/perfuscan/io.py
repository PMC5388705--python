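"""Readers and writers for the package's interchange formats.

Formats: registry JSON (see :mod:`perfuscan.temp_models`), relaxation
series CSV (``time_ms, signal, slice, roi`` plus optional ``temperature_C``
and ``nature``), viscosity CSV (``liquid, nature, temperature_C, value,
quantity, nu_mm2_s, rho_g_cm3``), cadaver-temperature CSV, tissue JSON and
sequence YAML.  Floating-point output is fixed at 6 significant digits so
byte-identical reproduction is testable.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .exceptions import InputError
from .relaxometry import EchoDecaySeries, InversionRecoverySeries, ROIStack
from .spgr_sim import SpoiledGRESequence, TissueProperties

FLOAT_FORMAT = "%.6g"


def _round_floats(obj: Any) -> Any:
    """Recursively round floats to 6 significant digits for JSON output."""
    if isinstance(obj, float):
        return float(FLOAT_FORMAT % obj)
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    if isinstance(obj, (np.floating,)):
        return float(FLOAT_FORMAT % float(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist())
    return obj


def write_json(doc: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_round_floats(dict(doc)), indent=1, sort_keys=True) + "\n")


def write_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_csv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    """Read a CSV and verify the schema, naming any missing column."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise InputError(f"{path}: unreadable CSV ({exc})") from exc
    if frame.empty:
        raise InputError(f"{path}: no data rows")
    for col in required:
        if col not in frame.columns:
            raise InputError(f"{path}: missing required column {col!r}")
    return frame


def read_series_csv(path: str | Path, kind: str) -> dict[str, ROIStack]:
    """Group a relaxation-series CSV into one :class:`ROIStack` per ROI.

    ``kind`` is ``t1`` (inversion recovery) or ``t2`` (echo train).  Missing
    ``roi``/``slice`` columns default to a single ROI / slice.  A
    ``temperature_C`` column, when present, becomes part of the ROI key
    (``name@thetaC``) so series acquired at different temperatures are
    fitted separately.  The optional ``voxels`` column carries provenance
    voxel counts (default 1).
    """
    frame = read_csv(path, ("time_ms", "signal"))
    if "roi" not in frame.columns:
        frame["roi"] = "roi0"
    if "temperature_C" in frame.columns:
        frame["roi"] = frame["roi"].astype(str) + "@" + frame["temperature_C"].astype(str) + "C"
    if "slice" not in frame.columns:
        frame["slice"] = 0
    if "voxels" not in frame.columns:
        frame["voxels"] = 1
    stacks: dict[str, ROIStack] = {}
    for roi, roi_frame in frame.groupby("roi", sort=True):
        series, voxels = [], []
        for _, slice_frame in roi_frame.groupby("slice", sort=True):
            times = slice_frame["time_ms"].to_numpy(float)
            signals = slice_frame["signal"].to_numpy(float)
            if kind == "t1":
                series.append(InversionRecoverySeries(times, signals))
            elif kind == "t2":
                series.append(EchoDecaySeries(times, signals))
            else:
                raise InputError(f"kind must be 't1' or 't2', got {kind!r}")
            voxels.append(int(slice_frame["voxels"].iloc[0]))
        stacks[str(roi)] = ROIStack(series=tuple(series), voxel_counts=tuple(voxels))
    return stacks


def load_tissues(path: str | Path | None = None) -> list[TissueProperties]:
    """Load tissue (T1, T2, M0) triplets from a tissue JSON file.

    ``None`` loads the packaged SYNTHETIC placeholder tissues, which are
    plausible stand-ins only — replace them with measured values for any
    real contrast prediction.
    """
    if path is None:
        raw = resources.files("perfuscan").joinpath("data/tissues_synthetic.json").read_text()
    else:
        p = Path(path)
        if not p.exists():
            raise InputError(
                f"tissue file {p} not found; the package ships only synthetic "
                "placeholder tissues (data/tissues_synthetic.json) — supply "
                "measured tissue properties to simulate real contrast"
            )
        raw = p.read_text()
    try:
        doc = json.loads(raw)
    except json.JSONDecodeError as exc:
        raise InputError(f"malformed tissue JSON: {exc}") from exc
    tissues = [
        TissueProperties(label=t["label"], t1=t["t1_ms"], t2=t["t2_ms"],
                         m0=t.get("m0", 1.0))
        for t in doc.get("tissues", [])
    ]
    if not tissues:
        raise InputError("tissue file contains no tissues")
    return tissues


def load_sequence(path: str | Path | None = None) -> SpoiledGRESequence:
    """Load a spoiled-GRE protocol from YAML (``None`` = packaged default).

    ``flip_deg`` may be an explicit list or a ``{start, stop}`` mapping of
    inclusive integer bounds.
    """
    if path is None:
        raw = resources.files("perfuscan").joinpath("data/sequence_default.yaml").read_text()
    else:
        raw = Path(path).read_text()
    try:
        doc = yaml.safe_load(raw)
    except yaml.YAMLError as exc:
        raise InputError(f"malformed sequence YAML: {exc}") from exc
    flips = doc.get("flip_deg", {"start": 0, "stop": 90})
    if isinstance(flips, Mapping):
        flips = tuple(range(int(flips["start"]), int(flips["stop"]) + 1))
    else:
        flips = tuple(int(f) for f in flips)
    return SpoiledGRESequence(
        te=float(doc.get("te_ms", 5.0)),
        tr=float(doc.get("tr_ms", 20.0)),
        flip_angles=flips,
        n_spins=int(doc.get("n_spins", 100)),
        n_excitations=int(doc.get("n_excitations", 100)),
        rf_phase_increment=float(doc.get("rf_phase_increment_deg", 117.0)),
        phase_schedule=doc.get("phase_schedule", "quadratic"),
    )
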