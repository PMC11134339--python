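"""Plain-text I/O: spike-train tables, fixture directories, mode tables.

A spike-train file holds one spike time (s) per line; '#'-prefixed header
comments carry the neuron id, stimulus frequency/amplitude, duration and
seed as ``key = value`` pairs.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .phase import PhaseNeuron, SpikeTrain, TriangularIPRC

__all__ = ["write_spike_train", "read_spike_train", "write_fixture_dir",
           "read_fixture_dir"]


def write_spike_train(train: SpikeTrain, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# neuron_id = {train.neuron_id}\n")
        fh.write(f"# duration = {train.duration!r}\n")
        for key, val in train.meta.items():
            fh.write(f"# {key} = {val!r}\n")
        for t in train.times:
            fh.write(f"{t:.9f}\n")


def _parse_value(text: str):
    text = text.strip()
    if text in ("None", "'None'"):
        return None
    try:
        val = float(text)
        return int(val) if val.is_integer() and "." not in text else val
    except ValueError:
        return text.strip("'\"")


def read_spike_train(path) -> SpikeTrain:
    path = Path(path)
    meta = {}
    times = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, val = line.lstrip("# ").partition("=")
                    meta[key.strip()] = _parse_value(val)
                continue
            times.append(float(line))
    if "duration" not in meta:
        raise InputError(f"{path} has no duration header")
    duration = float(meta.pop("duration"))
    neuron_id = meta.pop("neuron_id", None)
    return SpikeTrain(np.asarray(times), duration, neuron_id, meta)


def write_fixture_dir(population: Sequence[PhaseNeuron],
                      trains_by_neuron: dict, outdir, seed: int) -> None:
    """Write one spike-train file per (neuron, frequency) plus manifest.tsv
    (neuron id, intrinsic rate, iPRC peak location theta, noise SD, seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for nrn in population:
        theta = nrn.iprc.theta if isinstance(nrn.iprc, TriangularIPRC) else np.nan
        height = getattr(nrn.iprc, "height", np.nan)
        rows.append({"neuron_id": nrn.id, "rate": nrn.rate, "theta": theta,
                     "height": height, "noise_sd": nrn.noise_sd, "seed": seed})
        for f, train in trains_by_neuron.get(nrn.id, {}).items():
            write_spike_train(
                train, outdir / f"neuron{nrn.id}_f{float(f):g}.txt")
    pd.DataFrame(rows).to_csv(outdir / "manifest.tsv", sep="\t", index=False)


def read_fixture_dir(indir) -> tuple[pd.DataFrame, dict]:
    """Load a fixture directory: (manifest, {neuron_id: {freq: SpikeTrain}})."""
    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.tsv", sep="\t")
    trains: dict = {}
    for name in sorted(os.listdir(indir)):
        if not name.endswith(".txt"):
            continue
        train = read_spike_train(indir / name)
        f = train.meta.get("freq")
        trains.setdefault(train.neuron_id, {})[f] = train
    return manifest, trains
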