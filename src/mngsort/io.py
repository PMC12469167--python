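"""Read/write the harmonized recording container.

The on-disk layout is a minimal HDF5 schema that translates directly to the
NIX/Neo containers used for harmonized electrophysiology data::

    /signal/data     float64[n]     voltage trace (V)
    /signal/fs       float64        sampling rate (Hz)
    /signal/t0       float64        time of first sample (s)
    /signal/gaps     float64[g, 2]  optional acquisition gaps (start, end) s
    /stimuli/onsets  float64[m]     background stimulation onsets (s)
    /spikes/times    float64[k]     spike times (s)
    /spikes/tracks   utf-8 str[k]   track labels
    /meta            attributes     free-form string metadata

A plain-text fallback (CSV triplet + YAML sidecar) covers environments
without HDF5 tooling: ``signal.csv`` (t, v), ``stimuli.csv`` (t),
``spikes.csv`` (t, track) and ``meta.yaml`` in one directory.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .recording import (
    DIALECT_GENERIC,
    DialectSpec,
    FormatError,
    Recording,
    SpikeEvent,
    apply_dialect,
)

_REQUIRED = ("signal/data", "signal/fs", "signal/t0", "stimuli/onsets",
             "spikes/times", "spikes/tracks")


def write_recording(rec: Recording, path) -> None:
    """Write a Recording to an HDF5 container (see module docstring).

    The recording is validated first; a signal containing NaN or other
    invariant violations is rejected rather than silently persisted.
    """
    rec.validate()
    path = Path(path)
    with h5py.File(path, "w") as f:
        sig = f.create_group("signal")
        sig.create_dataset("data", data=rec.signal)
        sig.create_dataset("fs", data=float(rec.fs))
        sig.create_dataset("t0", data=float(rec.t0))
        if rec.gaps:
            sig.create_dataset("gaps", data=np.asarray(rec.gaps, dtype=np.float64))
        f.create_group("stimuli").create_dataset("onsets", data=rec.stimulus_onsets)
        spikes = f.create_group("spikes")
        spikes.create_dataset(
            "times", data=np.array([ev.time for ev in rec.spikes], dtype=np.float64)
        )
        spikes.create_dataset(
            "tracks",
            data=np.array([ev.track for ev in rec.spikes], dtype=h5py.string_dtype()),
        )
        meta = f.create_group("meta")
        for k, v in rec.meta.items():
            meta.attrs[k] = str(v)


def read_recording(path, dialect: DialectSpec = DIALECT_GENERIC) -> Recording:
    """Read a Recording from an HDF5 container and apply dialect corrections.

    Raises
    ------
    FormatError
        If a required group or dataset is missing (the error names it).
    ValidationError
        If the stored fields violate a model invariant (e.g. non-monotonic
        stimulus onsets).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        for key in _REQUIRED:
            if key not in f:
                raise FormatError(f"container {path.name} is missing '{key}'")
        times = f["spikes/times"][()]
        tracks = [t.decode() if isinstance(t, bytes) else str(t)
                  for t in f["spikes/tracks"][()]]
        if len(times) != len(tracks):
            raise FormatError("spikes/times and spikes/tracks length mismatch")
        gaps = ()
        if "signal/gaps" in f:
            gaps = tuple(map(tuple, f["signal/gaps"][()]))
        meta = {k: str(v) for k, v in f["meta"].attrs.items()} if "meta" in f else {}
        rec = Recording(
            signal=f["signal/data"][()],
            fs=float(f["signal/fs"][()]),
            t0=float(f["signal/t0"][()]),
            stimulus_onsets=f["stimuli/onsets"][()],
            spikes=tuple(SpikeEvent(float(t), tr) for t, tr in zip(times, tracks)),
            gaps=gaps,
            meta=meta,
        )
    return apply_dialect(rec, dialect)


# ---------------------------------------------------------------------------
# CSV fallback


def write_recording_csv(rec: Recording, directory) -> None:
    """Write the plain-text fallback: CSV triplet + YAML sidecar."""
    rec.validate()
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    t = rec.t0 + np.arange(len(rec.signal)) / rec.fs
    pd.DataFrame({"t": t, "v": rec.signal}).to_csv(d / "signal.csv", index=False)
    pd.DataFrame({"t": rec.stimulus_onsets}).to_csv(d / "stimuli.csv", index=False)
    pd.DataFrame(
        {"t": [ev.time for ev in rec.spikes], "track": [ev.track for ev in rec.spikes]}
    ).to_csv(d / "spikes.csv", index=False)
    sidecar = dict(rec.meta)
    sidecar.update(fs=float(rec.fs), t0=float(rec.t0))
    if rec.gaps:
        sidecar["gaps"] = [list(g) for g in rec.gaps]
    (d / "meta.yaml").write_text(yaml.safe_dump(sidecar))


def read_recording_csv(directory, dialect: DialectSpec = DIALECT_GENERIC) -> Recording:
    """Read the plain-text fallback written by :func:`write_recording_csv`."""
    d = Path(directory)
    for name in ("signal.csv", "stimuli.csv", "spikes.csv", "meta.yaml"):
        if not (d / name).exists():
            raise FormatError(f"CSV container {d} is missing '{name}'")
    sidecar = yaml.safe_load((d / "meta.yaml").read_text()) or {}
    fs = float(sidecar.pop("fs"))
    t0 = float(sidecar.pop("t0", 0.0))
    gaps = tuple(map(tuple, sidecar.pop("gaps", [])))
    signal = pd.read_csv(d / "signal.csv")["v"].to_numpy()
    onsets = pd.read_csv(d / "stimuli.csv")["t"].to_numpy()
    spikes_df = pd.read_csv(d / "spikes.csv")
    spikes = tuple(
        SpikeEvent(float(row.t), str(row.track)) for row in spikes_df.itertuples()
    )
    rec = Recording(
        signal=signal, fs=fs, t0=t0, stimulus_onsets=onsets, spikes=spikes,
        gaps=gaps, meta={k: str(v) for k, v in sidecar.items()},
    )
    return apply_dialect(rec, dialect)
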