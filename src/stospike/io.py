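"""File formats, configuration and run manifests.

Spike trains travel as CSV with header ``neuron_id,time_ms``, times in
ms sorted ascending, written with 6 decimal places (the default 0.1 ms
grid is exactly representable).  Distributions are written as CSV
``state,frequency`` with states as bit-strings; phase-specific
distributions add ``phase_ms,period_ms`` columns.  Every CLI run writes
a JSON manifest recording seeds, grid and config digest so that any
deterministic stage can be reproduced bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .network import SpikeRecord
from .states import EmpiricalDistribution

__all__ = [
    "read_spikes", "write_spikes", "write_distribution",
    "read_distribution", "RunManifest", "write_manifest",
]

_TIME_FMT = "%.6f"


def write_spikes(record: SpikeRecord, path) -> None:
    """Write a spike record as ``neuron_id,time_ms`` CSV."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("neuron_id,time_ms\n")
        for nid, t in zip(record.neuron_ids, record.times):
            fh.write(f"{int(nid)},{_TIME_FMT % t}\n")


def read_spikes(path) -> SpikeRecord:
    """Read a spike CSV; rejects malformed rows (with the line number),
    unsorted or negative times."""
    path = Path(path)
    ids, ts = [], []
    with open(path) as fh:
        header = fh.readline().strip()
        if header.replace(" ", "") != "neuron_id,time_ms":
            raise ValueError(f"{path}: unexpected header {header!r}")
        prev = -np.inf
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            try:
                nid = int(parts[0])
                t = float(parts[1])
                if len(parts) != 2:
                    raise ValueError
            except (ValueError, IndexError):
                raise ValueError(f"{path}: malformed row at line {lineno}: "
                                 f"{line!r}") from None
            if t < 0:
                raise ValueError(f"{path}: negative time at line {lineno}")
            if t < prev:
                raise ValueError(f"{path}: unsorted times at line {lineno}")
            prev = t
            ids.append(nid)
            ts.append(t)
    return SpikeRecord(np.array(ids, np.int64), np.array(ts, float))


def write_distribution(dist: EmpiricalDistribution, path) -> None:
    path = Path(path)
    rows = []
    for state, f in sorted(dist.freq.items()):
        s = "".join(str(int(b)) for b in state)
        row = {"state": s, "frequency": repr(float(f))}
        if dist.phase is not None:
            row["phase_ms"] = _TIME_FMT % dist.phase
            row["period_ms"] = _TIME_FMT % dist.period
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_distribution(path) -> EmpiricalDistribution:
    df = pd.read_csv(path, dtype={"state": str})
    freq = {tuple(int(c) for c in s): float(f)
            for s, f in zip(df["state"], df["frequency"])}
    tot = sum(freq.values())
    freq = {k: v / tot for k, v in freq.items()}
    phase = float(df["phase_ms"][0]) if "phase_ms" in df.columns else None
    period = float(df["period_ms"][0]) if "period_ms" in df.columns else None
    return EmpiricalDistribution(freq, n_samples=max(1, len(df)),
                                 phase=phase, period=period)


@dataclass
class RunManifest:
    """Provenance of one CLI run."""

    command: str
    seeds: dict
    dt: Optional[float]
    durations: dict
    outputs: list
    config_digest: Optional[str] = None
    tool_version: str = ""
    created: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def digest_config(obj) -> str:
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(manifest: RunManifest, path) -> None:
    from . import __version__
    manifest.tool_version = __version__
    manifest.created = time.strftime("%Y-%m-%dT%H:%M:%S")
    Path(path).write_text(manifest.to_json() + "\n")
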