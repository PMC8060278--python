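"""File formats: trace files + manifest, event tables, sensorgrams, reports.

Trace files are plain delimited text, one cycle per file, with columns
``time_s, force_pN, extension_nm``; a JSON manifest lists every file with
its acquisition metadata (tether, cycle, direction, pulling speed,
sampling rate, construct/condition labels, effective stiffness).  Event
tables and sensorgram sets are CSV; analysis reports and fit results are
JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .binding import Sensorgram, SensorgramSet
from .exceptions import ValidationError
from .traces import ForceExtensionTrace

PathLike = Union[str, Path]

TRACE_COLUMNS = ["time_s", "force_pN", "extension_nm"]
EVENT_COLUMNS = ["tether_id", "cycle", "loading_rate_pNs", "unfolding_force_pN",
                 "unfolding_extension_nm", "class"]


def write_trace(trace: ForceExtensionTrace, path: PathLike) -> None:
    df = pd.DataFrame({"time_s": trace.time, "force_pN": trace.force,
                       "extension_nm": trace.extension})
    df.to_csv(path, index=False, float_format="%.9g")


def _manifest_entry(trace: ForceExtensionTrace, filename: str) -> dict:
    return {
        "file": filename,
        "tether_id": trace.tether_id,
        "cycle": trace.cycle,
        "direction": trace.direction,
        "pulling_speed_nm_s": trace.pulling_speed,
        "sampling_rate_hz": trace.sampling_rate,
        "construct": trace.construct,
        "condition": trace.condition,
        "effective_stiffness_pN_nm": trace.effective_stiffness,
    }


def write_experiment(traces: Sequence[ForceExtensionTrace], out_dir: PathLike,
                     manifest_name: str = "manifest.json") -> Path:
    """Write one file per trace plus a manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for trace in traces:
        fname = f"{trace.tether_id}_c{trace.cycle:03d}_{trace.direction}.csv"
        write_trace(trace, out / fname)
        entries.append(_manifest_entry(trace, fname))
    manifest_path = out / manifest_name
    manifest_path.write_text(json.dumps({"traces": entries}, indent=1) + "\n")
    return manifest_path


def read_trace(path: PathLike, meta: dict) -> ForceExtensionTrace:
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"trace file {path} lacks columns {missing}")
    return ForceExtensionTrace(
        time=df["time_s"].to_numpy(),
        force=df["force_pN"].to_numpy(),
        extension=df["extension_nm"].to_numpy(),
        direction=meta["direction"],
        pulling_speed=meta["pulling_speed_nm_s"],
        tether_id=str(meta["tether_id"]),
        cycle=int(meta["cycle"]),
        sampling_rate=meta["sampling_rate_hz"],
        construct=meta.get("construct"),
        condition=meta.get("condition"),
        effective_stiffness=meta.get("effective_stiffness_pN_nm"),
    )


def read_experiment(manifest_path: PathLike) -> List[ForceExtensionTrace]:
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    return [read_trace(base / e["file"], e) for e in manifest["traces"]]


def write_points(points: Sequence[tuple], path: PathLike) -> None:
    """(force pN, extension nm) pairs as 2-column delimited text."""
    arr = np.asarray(points, dtype=float)
    pd.DataFrame({"force_pN": arr[:, 0], "extension_nm": arr[:, 1]}).to_csv(
        path, index=False, float_format="%.9g")


def read_points(path: PathLike) -> List[tuple]:
    df = pd.read_csv(path)
    missing = [c for c in ("force_pN", "extension_nm") if c not in df.columns]
    if missing:
        raise ValidationError(f"point file {path} lacks columns {missing}")
    return list(zip(df["force_pN"].tolist(), df["extension_nm"].tolist()))


def write_events(events: Sequence[dict], path: PathLike) -> None:
    """Event table as delimited text (standard column set)."""
    df = pd.DataFrame(list(events))
    cols = [c for c in EVENT_COLUMNS if c in df.columns]
    df = df[cols + [c for c in df.columns if c not in cols]]
    df.to_csv(path, index=False, float_format="%.9g")


def read_events(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def write_report(report: dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(_to_jsonable(report), indent=1,
                                     sort_keys=True) + "\n")


def read_report(path: PathLike) -> dict:
    return json.loads(Path(path).read_text())


def write_sensorgrams(data: SensorgramSet, out_dir: PathLike,
                      stem: str = "sensorgrams") -> Path:
    """Curves as CSV (time_s + one response column per concentration, in nM)
    plus a JSON sidecar with phase boundaries and any truth parameters."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cols = {"time_s": data.curves[0].time}
    for c in data.curves:
        cols[f"response_{c.concentration * 1e9:g}nM"] = c.response
    pd.DataFrame(cols).to_csv(out / f"{stem}.csv", index=False, float_format="%.9g")
    meta = {
        "concentration_unit": "nM",
        "concentrations_nM": [c.concentration * 1e9 for c in data.curves],
        "t_association_end_s": data.curves[0].t_association_end,
        "truth": data.truth.to_dict() if data.truth is not None else None,
    }
    (out / f"{stem}.json").write_text(json.dumps(_to_jsonable(meta), indent=1) + "\n")
    return out / f"{stem}.csv"


def read_sensorgrams(csv_path: PathLike,
                     json_path: Optional[PathLike] = None) -> SensorgramSet:
    csv_path = Path(csv_path)
    meta = json.loads(Path(json_path or csv_path.with_suffix(".json")).read_text())
    df = pd.read_csv(csv_path)
    t_assoc = meta["t_association_end_s"]
    curves = []
    for col in df.columns:
        if not col.startswith("response_"):
            continue
        conc_nm = float(col[len("response_"):-2])
        curves.append(Sensorgram(
            concentration=conc_nm * 1e-9,
            time=df["time_s"].to_numpy(),
            response=df[col].to_numpy(),
            t_association_end=t_assoc,
        ))
    return SensorgramSet(curves=curves)
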