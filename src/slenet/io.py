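"""Trace serialisation and run manifests.

Traces write to either a tidy CSV (one row per time/compartment/channel,
rounded at 1e-9) or a lossless hierarchical HDF5 container.  Every
simulation can be paired with a :class:`RunManifest` — a plain-text (JSON)
record of the configuration snapshot, seeds, package version and output
checksums — from which a stochastic run can be replayed bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time

import numpy as np
import pandas as pd

from . import __version__
from .config import ModelConfig, to_flat
from .engine import NSLOW, TraceSet
from .network import COMP_NAMES, NCOMP

SLOW_CHANNELS = ["na_in", "k_in", "cl_in", "ca_total_in", "a_in",
                 "na_out", "k_out", "cl_out", "ca_out", "a_out",
                 "vol_in", "vol_out", "glia_free_buffer", "pump_current",
                 "kcc2_k_current", "gabaa_current", "ca_free_in",
                 "g_exc", "g_inh"]


def traces_to_frame(traces: TraceSet) -> pd.DataFrame:
    """Tidy long-format view of the slow channels plus Vm and LFP."""
    rows = []
    tf = traces.t_fast
    for c in range(NCOMP):
        rows.append(pd.DataFrame({
            "time_ms": tf, "compartment": COMP_NAMES[c],
            "channel": "vm", "value": traces.v[:, c]}))
    rows.append(pd.DataFrame({
        "time_ms": tf, "compartment": "electrode",
        "channel": "lfp", "value": traces.lfp}))
    ts = traces.t_slow
    for c in range(NCOMP):
        for ch in range(NSLOW):
            rows.append(pd.DataFrame({
                "time_ms": ts, "compartment": COMP_NAMES[c],
                "channel": SLOW_CHANNELS[ch],
                "value": traces.slow[:, c, ch]}))
    frame = pd.concat(rows, ignore_index=True)
    frame["value"] = frame["value"].round(9)
    return frame


def write_traces(traces: TraceSet, path, format: str = "h5") -> None:
    """Write a TraceSet; ``format`` is 'csv' (tidy, rounded) or 'h5'."""
    if format == "csv":
        traces_to_frame(traces).to_csv(path, index=False)
        return
    if format != "h5":
        raise ValueError(f"unknown trace format {format!r}")
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["dt"] = traces.dt
        fh.attrs["duration"] = traces.duration
        fh.attrs["fast_dt"] = traces.fast_dt
        fh.attrs["slow_dt"] = traces.slow_dt
        fh.attrs["seed"] = -1 if traces.seed is None else traces.seed
        fh.attrs["meta"] = json.dumps(traces.meta, default=str)
        fh.create_dataset("v", data=traces.v, compression="gzip")
        fh.create_dataset("imem", data=traces.imem, compression="gzip")
        fh.create_dataset("lfp", data=traces.lfp, compression="gzip")
        fh.create_dataset("slow", data=traces.slow, compression="gzip")
        spk = fh.create_group("spikes")
        for c, times in traces.spike_times.items():
            spk.create_dataset(str(c), data=times)


def read_traces(path) -> TraceSet:
    """Read an HDF5 trace container written by :func:`write_traces`."""
    import h5py

    with h5py.File(path, "r") as fh:
        seed = int(fh.attrs["seed"])
        return TraceSet(
            dt=float(fh.attrs["dt"]), duration=float(fh.attrs["duration"]),
            fast_dt=float(fh.attrs["fast_dt"]),
            slow_dt=float(fh.attrs["slow_dt"]),
            v=fh["v"][()], imem=fh["imem"][()], lfp=fh["lfp"][()],
            slow=fh["slow"][()],
            spike_times={int(k): v[()] for k, v in fh["spikes"].items()},
            seed=None if seed < 0 else seed,
            meta=json.loads(fh.attrs["meta"]))


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Reproducibility record for one simulation run."""

    config: dict
    seed: int | None
    version: str = __version__
    protocol: str = ""
    started: str = ""
    finished: str = ""
    outputs: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def start(cls, config: ModelConfig, seed: int | None,
              protocol: str = "") -> "RunManifest":
        return cls(config={k: (None if v is None else float(v))
                           for k, v in to_flat(config).items()},
                   seed=seed, protocol=protocol,
                   started=time.strftime("%Y-%m-%dT%H:%M:%S"))

    def add_output(self, path) -> None:
        self.outputs[str(path)] = _checksum(path)

    def finish(self) -> "RunManifest":
        self.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        return self

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))

    def rebuild_config(self) -> ModelConfig:
        from .config import from_flat
        return from_flat(self.config)
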