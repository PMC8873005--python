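"""On-disk interchange: sweep families as JSON metadata + CSV samples.

Each cell/protocol pair is stored as ``<name>.json`` (protocol, labels,
units, sampling rate) next to ``<name>.csv`` (column ``time_s`` followed
by one column per sweep).  The layout is deliberately plain text so any
language can consume it.  Units are fixed package-wide: seconds, mV, pA.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ProtocolSpec, SweepSet, Trace

__all__ = ["write_traces", "read_traces", "write_sweepset", "read_sweepset"]

_FMT_VERSION = 1
_MODE_SHORT = {"current_clamp_steps": "cc", "voltage_clamp_steps": "vc",
               "gap_free": "gf"}


def _sweepset_name(sw: SweepSet) -> str:
    base = sw.cell_id or "cell"
    return f"{base}_{_MODE_SHORT[sw.protocol.mode]}"


def write_sweepset(directory: str | Path, sw: SweepSet, name: str | None = None) -> Path:
    """Write one sweep family as a JSON/CSV pair; returns the JSON path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = name or _sweepset_name(sw)
    proto = sw.protocol
    kind = sw.traces[0].kind
    meta = {
        "format_version": _FMT_VERSION,
        "cell_id": sw.cell_id,
        "genotype": sw.genotype,
        "week": sw.week,
        "kind": kind,
        "unit": sw.traces[0].unit,
        "fs_hz": sw.fs,
        "t0_s": sw.traces[0].t0,
        "protocol": {
            "mode": proto.mode,
            "holding": proto.holding,
            "step_amplitudes": list(map(float, proto.step_amplitudes)),
            "step_onset_s": proto.step_onset,
            "step_offset_s": proto.step_offset,
            "sweep_duration_s": proto.sweep_duration,
        },
        "sweeps": [f"sweep_{i:03d}" for i in range(len(sw.traces))],
    }
    jpath = directory / f"{name}.json"
    jpath.write_text(json.dumps(meta, indent=1))
    t = sw.traces[0].times()
    data = {"time_s": t}
    for label, tr in zip(meta["sweeps"], sw.traces):
        data[label] = tr.samples
    pd.DataFrame(data).to_csv(directory / f"{name}.csv", index=False,
                              float_format="%.17g")
    return jpath


def read_sweepset(json_path: str | Path) -> SweepSet:
    """Read one JSON/CSV pair back into a SweepSet (round-trip lossless)."""
    json_path = Path(json_path)
    meta = json.loads(json_path.read_text())
    csv_path = json_path.with_suffix(".csv")
    if not csv_path.exists():
        raise FileNotFoundError(f"missing samples table {csv_path}")
    df = pd.read_csv(csv_path, float_precision="round_trip")
    if "time_s" not in df.columns:
        raise ValueError(f"{csv_path}: missing time_s column")
    missing = [s for s in meta["sweeps"] if s not in df.columns]
    if missing:
        raise ValueError(f"{csv_path}: missing sweep column(s) {missing}")

    fs = float(meta["fs_hz"])
    t = df["time_s"].to_numpy()
    if t.size >= 2:
        dt = np.diff(t)
        expected = 1.0 / fs
        if np.any(np.abs(dt - expected) > expected * 1e-6 + 1e-12):
            raise ValueError(f"{csv_path}: non-uniform time column")

    kind = meta["kind"]
    unit = meta["unit"]
    if (kind, unit) not in (("voltage", "mV"), ("current", "pA")):
        raise ValueError(f"{json_path}: unit {unit!r} inconsistent with kind {kind!r}")

    p = meta["protocol"]
    proto = ProtocolSpec(
        mode=p["mode"],
        holding=p["holding"],
        step_amplitudes=p["step_amplitudes"],
        step_onset=p["step_onset_s"],
        step_offset=p["step_offset_s"],
        sweep_duration=p["sweep_duration_s"],
    )
    traces = [
        Trace(kind=kind, unit=unit, fs=fs, samples=df[s].to_numpy(),
              t0=float(meta.get("t0_s", 0.0)))
        for s in meta["sweeps"]
    ]
    return SweepSet(protocol=proto, traces=traces, cell_id=meta["cell_id"],
                    genotype=meta.get("genotype", ""), week=meta.get("week"))


def write_traces(directory: str | Path, sweepsets: list[SweepSet]) -> list[Path]:
    """Write a collection of sweep families into a directory."""
    return [write_sweepset(directory, sw) for sw in sweepsets]


def read_traces(directory: str | Path) -> list[SweepSet]:
    """Read every JSON/CSV sweep-family pair found in a directory."""
    directory = Path(directory)
    paths = sorted(directory.glob("*.json"))
    return [read_sweepset(p) for p in paths]
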