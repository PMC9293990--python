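"""Readers and writers for the on-disk formats.

Sweep ensembles live in HDF5 (dataset ``/sweeps`` in pA with ``fs_hz``,
``polarity`` and ``holding_mV`` attributes and ``/stim/onsets_s``);
polysomnography in EDF (classic 16-bit, channels EEG/EMG) with CSV
sidecars for the stimulation schedule (``onset_s, condition,
pulse_width_ms, train_s``) and state labels (``epoch_index, state``);
events in CSV; results and run manifests in JSON. All on-disk times are
seconds, sample indexing is 0-based, intervals are half-open.

EDF files are written by a minimal classic-EDF encoder (equal-rate
channels, 1-s records, zero-padded to whole records) and read back with
``mne``, which also serves as an independent check of the writer.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .psc import EventList, SweepSet
from .sleep import STATES, Recording, TFGrid

__all__ = [
    "SchemaError",
    "read_sweeps",
    "write_sweeps",
    "read_events_csv",
    "write_events_csv",
    "write_edf",
    "write_recording",
    "read_recording",
    "write_tfgrid",
    "read_tfgrid",
    "write_json",
    "write_manifest",
    "load_config",
]


class SchemaError(ValueError):
    """An on-disk file is missing a required field."""


# ---------------------------------------------------------------------------
# sweeps (HDF5)


def write_sweeps(sweeps: SweepSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("sweeps", data=sweeps.sweeps)
        d.attrs["fs_hz"] = float(sweeps.fs)
        d.attrs["polarity"] = sweeps.polarity
        if sweeps.holding_mV is not None:
            d.attrs["holding_mV"] = float(sweeps.holding_mV)
        d.attrs["pulse_width_ms"] = float(sweeps.pulse_width_ms)
        f.create_dataset("stim/onsets_s", data=np.asarray(sweeps.pulse_onsets) / sweeps.fs)
        if sweeps.labels is not None:
            f.create_dataset("labels", data=np.array(sweeps.labels, dtype="S"))


def read_sweeps(path: str | Path) -> SweepSet:
    with h5py.File(path, "r") as f:
        if "sweeps" not in f:
            raise SchemaError("missing dataset 'sweeps'")
        d = f["sweeps"]
        for attr in ("fs_hz", "polarity"):
            if attr not in d.attrs:
                raise SchemaError(f"dataset 'sweeps' is missing attribute {attr!r}")
        fs = float(d.attrs["fs_hz"])
        polarity = d.attrs["polarity"]
        if isinstance(polarity, bytes):
            polarity = polarity.decode()
        if "stim/onsets_s" not in f:
            raise SchemaError("missing dataset 'stim/onsets_s'")
        onsets = np.round(np.asarray(f["stim/onsets_s"]) * fs).astype(int)
        labels = None
        if "labels" in f:
            labels = [s.decode() for s in f["labels"][()]]
        data = d[()]
        if data.size == 0:
            data = data.reshape(0, 0)
        return SweepSet(
            sweeps=data,
            fs=fs,
            pulse_onsets=onsets,
            pulse_width_ms=float(d.attrs.get("pulse_width_ms", 10.0)),
            polarity=polarity,
            holding_mV=float(d.attrs["holding_mV"]) if "holding_mV" in d.attrs else None,
            labels=labels,
        )


# ---------------------------------------------------------------------------
# events (CSV)


def write_events_csv(events: EventList, path: str | Path) -> None:
    events.to_frame().to_csv(path, index=False)


def read_events_csv(path: str | Path) -> EventList:
    df = pd.read_csv(path)
    required = {"sweep", "time_s", "amplitude_pA", "rise5_s"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"events CSV missing columns: {sorted(missing)}")
    return EventList.from_frame(df)


# ---------------------------------------------------------------------------
# EDF (classic, 16-bit) and recordings


def _ascii(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, signals: dict[str, np.ndarray], fs: float) -> None:
    """Write equal-rate channels to a classic EDF file (1-s records).

    Signals are zero-padded to a whole number of records. ``fs`` must be
    an integer number of samples per second.
    """
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))
    names = list(signals)
    arrays = [np.asarray(signals[k], dtype=float).ravel() for k in names]
    n = max(len(a) for a in arrays)
    n_rec = int(np.ceil(n / spr))
    padded = [np.pad(a, (0, n_rec * spr - len(a))) for a in arrays]

    phys_min, phys_max, digital = [], [], []
    for a in padded:
        amax = float(np.max(np.abs(a))) if a.size else 1.0
        amax = amax if amax > 0 else 1.0
        lo, hi = -amax, amax
        phys_min.append(lo)
        phys_max.append(hi)
        scale = (hi - lo) / (32767 - (-32768))
        digital.append(np.clip(np.round((a - lo) / scale) + (-32768), -32768, 32767).astype("<i2"))

    ns = len(names)
    header = bytearray()
    header += _ascii("0", 8)
    header += _ascii("synthetic", 80)
    header += _ascii("optoarousal", 80)
    header += _ascii("01.01.00", 8)
    header += _ascii("00.00.00", 8)
    header += _ascii(str(256 * (1 + ns)), 8)
    header += _ascii("", 44)
    header += _ascii(str(n_rec), 8)
    header += _ascii("1", 8)
    header += _ascii(str(ns), 4)

    def sig_field(values, width):
        return b"".join(_ascii(v, width) for v in values)

    header += sig_field(names, 16)
    header += sig_field([""] * ns, 80)
    header += sig_field(["uV"] * ns, 8)
    header += sig_field([f"{v:.6g}" for v in phys_min], 8)
    header += sig_field([f"{v:.6g}" for v in phys_max], 8)
    header += sig_field(["-32768"] * ns, 8)
    header += sig_field(["32767"] * ns, 8)
    header += sig_field([""] * ns, 80)
    header += sig_field([str(spr)] * ns, 8)
    header += sig_field([""] * ns, 32)

    with open(path, "wb") as f:
        f.write(bytes(header))
        for r in range(n_rec):
            for d in digital:
                f.write(d[r * spr : (r + 1) * spr].tobytes())


def _read_edf_signals(path: str | Path) -> tuple[dict[str, np.ndarray], float]:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    out = {}
    for name in raw.ch_names:
        data = raw.get_data(picks=[name])[0]
        # mne rescales dimensioned channels to SI units (V); recover uV
        ch_idx = raw.ch_names.index(name)
        unit_mul = 1e6 if raw.info["chs"][ch_idx]["unit"] != 0 else 1.0
        key = name.split()[-1] if " " in name else name
        out[key.upper()] = data * unit_mul
    return out, fs


def write_recording(
    recording: Recording,
    path_edf: str | Path,
    path_schedule_csv: str | Path,
    path_states_csv: str | Path,
) -> None:
    write_edf(path_edf, {"EEG": recording.eeg, "EMG": recording.emg}, recording.fs)
    schedule = recording.stim_schedule if recording.stim_schedule is not None else pd.DataFrame(
        columns=["onset_s", "condition", "pulse_width_ms", "train_s"]
    )
    schedule.to_csv(path_schedule_csv, index=False)
    labels = recording.state_labels if recording.state_labels is not None else np.array([])
    pd.DataFrame({"epoch_index": np.arange(len(labels)), "state": labels}).to_csv(path_states_csv, index=False)


def read_recording(
    path_edf: str | Path,
    path_schedule_csv: str | Path,
    path_states_csv: str | Path,
    epoch_length: float = 5.0,
) -> Recording:
    """Assemble a Recording from an EDF file and its CSV sidecars.

    Raises a schema error for unknown state labels; schedule onsets beyond
    the recording end raise an error listing the offending rows.
    """
    signals, fs = _read_edf_signals(path_edf)
    missing = {"EEG", "EMG"} - set(signals)
    if missing:
        raise SchemaError(f"EDF is missing channels: {sorted(missing)}")
    if len(signals["EEG"]) != len(signals["EMG"]):
        raise SchemaError("EEG and EMG channel lengths differ; resampling is refused")

    schedule = pd.read_csv(path_schedule_csv)
    if len(schedule) and "onset_s" not in schedule.columns:
        raise SchemaError("schedule CSV missing column 'onset_s'")
    if not len(schedule):
        schedule = pd.DataFrame(columns=["onset_s", "condition", "pulse_width_ms", "train_s"])

    states_df = pd.read_csv(path_states_csv)
    labels = None
    if len(states_df):
        unknown = set(states_df["state"].astype(str)) - set(STATES)
        if unknown:
            raise SchemaError(f"unknown state label(s) in states CSV: {sorted(unknown)}")
        labels = states_df.sort_values("epoch_index")["state"].to_numpy()

    return Recording(
        eeg=signals["EEG"],
        emg=signals["EMG"],
        fs=fs,
        stim_schedule=schedule,
        state_labels=labels,
        epoch_length=epoch_length,
    )


# ---------------------------------------------------------------------------
# TF grids (HDF5) and JSON results


def write_tfgrid(grid: TFGrid, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=grid.times)
        f.create_dataset("freqs", data=grid.freqs)
        for name in ("power", "diff", "ci_low", "ci_high"):
            layer = getattr(grid, name)
            if layer is not None:
                f.create_dataset(name, data=layer)
        if grid.mask is not None:
            f.create_dataset("mask", data=grid.mask.astype(np.uint8))
        if grid.coi_s is not None:
            f.create_dataset("coi_s", data=grid.coi_s)
        if grid.n_resamples is not None:
            f.attrs["n_resamples"] = int(grid.n_resamples)


def read_tfgrid(path: str | Path) -> TFGrid:
    with h5py.File(path, "r") as f:
        kwargs = {"times": f["times"][()], "freqs": f["freqs"][()]}
        for name in ("power", "diff", "ci_low", "ci_high"):
            if name in f:
                kwargs[name] = f[name][()]
        if "mask" in f:
            kwargs["mask"] = f["mask"][()].astype(bool)
        if "coi_s" in f:
            kwargs["coi_s"] = f["coi_s"][()]
        if "n_resamples" in f.attrs:
            kwargs["n_resamples"] = int(f.attrs["n_resamples"])
        return TFGrid(**kwargs)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder, allow_nan=True) + "\n")


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_manifest(path: str | Path, config: dict, seed: int, outputs: list[str]) -> None:
    """JSON run manifest: config hash, seed, library versions, outputs."""
    import scipy

    from . import __version__

    manifest = {
        "config": config,
        "config_hash": config_hash(config),
        "seed": int(seed),
        "outputs": list(outputs),
        "versions": {
            "optoarousal": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
        },
    }
    write_json(manifest, path)


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    with open(path) as f:
        cfg = yaml.safe_load(f)
    return cfg or {}
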