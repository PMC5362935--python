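"""Plain-text I/O for sweeps, protocols and cell configs.

Sweeps are TSV files with a mandatory header ``time_s  v_cmd_mV  i_pA``
plus a JSON metadata sidecar (same path with ``.json`` appended to the
stem). Protocol and cell configs serialise to JSON or YAML with units in
the key names.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamics import CellState
from .synthetic import AgonistWindow, GroundTruthCell, RampProtocol, Segment, Sweep

__all__ = [
    "write_sweep", "read_sweep",
    "protocol_to_dict", "protocol_from_dict",
    "cell_to_dict", "cell_from_dict",
    "save_config", "load_config",
]

SWEEP_COLUMNS = ["time_s", "v_cmd_mV", "i_pA"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json") if path.suffix != ".json" \
        else path


def write_sweep(sweep: Sweep, path) -> Path:
    """Write a sweep as TSV plus a JSON metadata sidecar; returns the TSV path."""
    path = Path(path)
    df = pd.DataFrame({
        "time_s": sweep.time_s, "v_cmd_mV": sweep.v_cmd_mV, "i_pA": sweep.i_pA,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    with open(_sidecar(path), "w") as fh:
        json.dump(sweep.metadata, fh, indent=1, default=float)
    return path


def read_sweep(path) -> Sweep:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SWEEP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sweep file lacks required columns {missing}")
    meta = {}
    side = _sidecar(path)
    if side.exists():
        with open(side) as fh:
            meta = json.load(fh)
    return Sweep(df["time_s"].to_numpy(), df["v_cmd_mV"].to_numpy(),
                 df["i_pA"].to_numpy(), metadata=meta)


def protocol_to_dict(protocol: RampProtocol) -> dict:
    return {
        "name": protocol.name,
        "sampling_interval_s": protocol.sampling_interval_s,
        "segments": [dataclasses.asdict(s) for s in protocol.segments],
        "agonist_windows": [dataclasses.asdict(w) for w in protocol.agonist_windows],
    }


def protocol_from_dict(d: dict) -> RampProtocol:
    return RampProtocol(
        segments=[Segment(**s) for s in d["segments"]],
        agonist_windows=[AgonistWindow(**w) for w in d.get("agonist_windows", [])],
        sampling_interval_s=d.get("sampling_interval_s", 1e-4),
        name=d.get("name", ""),
    )


def cell_to_dict(cell: GroundTruthCell) -> dict:
    d = dataclasses.asdict(cell)
    d["cell"] = dataclasses.asdict(cell.cell)
    return d


def cell_from_dict(d: dict) -> GroundTruthCell:
    d = dict(d)
    state = CellState(**d.pop("cell")) if "cell" in d else CellState(cl_i_mM=9.0)
    return GroundTruthCell(cell=state, **d)


def save_config(obj: dict, path) -> Path:
    """Write a config dict as JSON or YAML depending on the extension."""
    path = Path(path)
    text = (json.dumps(obj, indent=1, default=float)
            if path.suffix == ".json" else yaml.safe_dump(obj))
    path.write_text(text)
    return path


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    return json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
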