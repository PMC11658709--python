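"""HDF5 and delimited-text I/O for kymographs and simulation results."""

from __future__ import annotations

import json

import h5py
import numpy as np

from .kymo import Kymograph
from .parameters import ModelParameters
from .simulate1d import SimulationResult

__all__ = [
    "save_kymograph",
    "load_kymograph",
    "save_kymograph_text",
    "load_kymograph_text",
    "save_simulation",
    "load_simulation",
]


def save_kymograph(path, kymo: Kymograph) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("values", data=kymo.values)
        fh.create_dataset("times", data=kymo.times)
        fh.create_dataset("angles", data=kymo.angles)
        fh.attrs["channel"] = kymo.channel


def load_kymograph(path) -> Kymograph:
    with h5py.File(path, "r") as fh:
        return Kymograph(
            fh["values"][...], fh["times"][...], fh["angles"][...],
            channel=str(fh.attrs.get("channel", "")),
        )


def save_kymograph_text(path, kymo: Kymograph, delimiter: str = "\t") -> None:
    """Delimited text: one row per time point, one column per angle; grid
    metadata in '#'-prefixed header lines."""
    with open(path, "w") as fh:
        fh.write(f"# channel: {kymo.channel}\n")
        # %.17g round-trips doubles exactly
        fh.write("# angles: " + delimiter.join(f"{a:.17g}" for a in kymo.angles) + "\n")
        fh.write("# first column: time (s)\n")
        for ti, row in zip(kymo.times, kymo.values):
            fh.write(f"{ti:.17g}" + delimiter
                     + delimiter.join(f"{v:.17g}" for v in row) + "\n")


def load_kymograph_text(path, delimiter: str = "\t") -> Kymograph:
    channel = ""
    angles = None
    times, rows = [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("channel:"):
                    channel = body.split(":", 1)[1].strip()
                elif body.startswith("angles:"):
                    angles = np.array(
                        [float(x) for x in body.split(":", 1)[1].split()])
                continue
            parts = line.split(delimiter)
            times.append(float(parts[0]))
            rows.append([float(x) for x in parts[1:]])
    values = np.asarray(rows)
    if angles is None:
        angles = np.arange(values.shape[1]) * 2.0 * np.pi / values.shape[1]
    return Kymograph(values, np.asarray(times), angles, channel=channel)


def save_simulation(path, result: SimulationResult) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("times", data=result.times)
        fh.create_dataset("values", data=result.values)
        fh.create_dataset("grid", data=result.grid)
        fh.attrs["fields"] = json.dumps(list(result.fields))
        fh.attrs["params"] = json.dumps(result.params.to_dict())
        fh.attrs["diagnostics"] = json.dumps(result.diagnostics)


def load_simulation(path) -> SimulationResult:
    with h5py.File(path, "r") as fh:
        return SimulationResult(
            times=fh["times"][...],
            values=fh["values"][...],
            grid=fh["grid"][...],
            params=ModelParameters.from_dict(json.loads(fh.attrs["params"])),
            fields=tuple(json.loads(fh.attrs["fields"])),
            diagnostics=json.loads(fh.attrs["diagnostics"]),
        )
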