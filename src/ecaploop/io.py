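"""Readers and writers for recordings, feature tables, session logs,
behavior tables and configuration.

Waveforms go to an HDF5 container (one ``sweeps`` dataset plus geometry /
program attributes and optional ground-truth bookkeeping); every tabular
artifact is a headered CSV written with round-trip float formatting; config
is YAML.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .cloop import CLSessionLog
from .features import ECAPFeatures
from .synth import (GainProcess, GroundTruth, LeadGeometry,
                    MultiChannelRecording, StimulusProgram)

__all__ = ["save_recording", "load_recording", "save_features", "load_features",
           "save_session_log", "load_session_log", "save_table", "load_table",
           "save_config", "load_config", "save_json"]

_FLOAT_FMT = "%.17g"  # exact double round-trip through text


# ---------------------------------------------------------------------------
# recordings (HDF5)
# ---------------------------------------------------------------------------

def save_recording(path: str | Path, recording: MultiChannelRecording) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["sample_rate"] = recording.sample_rate
        f.create_dataset("sweeps", data=recording.sweeps)
        f.create_dataset("currents_ma", data=recording.currents_ma)
        f.attrs["artifact_channels"] = list(recording.artifact_channels)

        g = f.create_group("geometry")
        g.attrs["n_contacts"] = recording.geometry.n_contacts
        g.attrs["spacing_mm"] = recording.geometry.spacing_mm
        g.attrs["stim_index"] = recording.geometry.stim_index
        g.attrs["contact_labels"] = list(recording.geometry.contact_labels)

        p = f.create_group("program")
        p.attrs["frequency_hz"] = recording.program.frequency_hz
        p.attrs["pulse_width_us"] = recording.program.pulse_width_us
        p.attrs["duration_s"] = recording.program.duration_s
        p.create_dataset("current_ma", data=recording.program.pulse_currents())

        if recording.truth is not None:
            tr = f.create_group("truth")
            tr.create_dataset("gains", data=recording.truth["gains"])
            tr.create_dataset("currents_ma", data=recording.truth["currents_ma"])
            tr.create_dataset("ref_amplitude_mv", data=recording.truth["ref_amplitude_mv"])
            for name in ("n1_latency_ms", "amplitude_mv"):
                sub = tr.create_group(name)
                for ch, val in recording.truth[name].items():
                    sub.create_dataset(str(ch), data=val)


def load_recording(path: str | Path) -> MultiChannelRecording:
    with h5py.File(path, "r") as f:
        g = f["geometry"]
        geometry = LeadGeometry(
            n_contacts=int(g.attrs["n_contacts"]),
            spacing_mm=float(g.attrs["spacing_mm"]),
            stim_index=int(g.attrs["stim_index"]),
            contact_labels=tuple(str(x) for x in g.attrs["contact_labels"]),
        )
        p = f["program"]
        program = StimulusProgram(
            frequency_hz=float(p.attrs["frequency_hz"]),
            pulse_width_us=float(p.attrs["pulse_width_us"]),
            duration_s=float(p.attrs["duration_s"]),
            current_ma=p["current_ma"][...],
        )
        truth = None
        if "truth" in f:
            tr = f["truth"]
            truth = {
                "gains": tr["gains"][...],
                "currents_ma": tr["currents_ma"][...],
                "ref_amplitude_mv": tr["ref_amplitude_mv"][...],
                "n1_latency_ms": {int(k): v[()] if v.ndim == 0 else v[...]
                                  for k, v in tr["n1_latency_ms"].items()},
                "amplitude_mv": {int(k): v[()] if v.ndim == 0 else v[...]
                                 for k, v in tr["amplitude_mv"].items()},
            }
        return MultiChannelRecording(
            sample_rate=float(f.attrs["sample_rate"]),
            sweeps=f["sweeps"][...],
            geometry=geometry,
            program=program,
            currents_ma=f["currents_ma"][...],
            artifact_channels=tuple(int(c) for c in f.attrs["artifact_channels"]),
            truth=truth,
        )


# ---------------------------------------------------------------------------
# tables (CSV)
# ---------------------------------------------------------------------------

def save_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)


def load_table(path: str | Path) -> pd.DataFrame:
    # round_trip parser: default float parsing is not correctly rounded
    return pd.read_csv(path, float_precision="round_trip")


def save_features(path: str | Path, features: list[ECAPFeatures]) -> None:
    save_table(path, pd.DataFrame([asdict(f) for f in features]))


def load_features(path: str | Path) -> list[ECAPFeatures]:
    df = load_table(path)
    return [ECAPFeatures(**{k: (bool(v) if k == "detected" else float(v))
                            for k, v in row.items()})
            for row in df.to_dict("records")]


def features_from_table(df: pd.DataFrame) -> list[ECAPFeatures]:
    """Rebuild :class:`ECAPFeatures` rows from a (per-current) feature table."""
    fields = [f.name for f in dataclasses.fields(ECAPFeatures)]
    return [ECAPFeatures(**{k: (bool(row[k]) if k == "detected" else float(row[k]))
                            for k in fields})
            for _, row in df.iterrows()]


def save_session_log(path: str | Path, log: CLSessionLog) -> None:
    df = pd.DataFrame({"time_s": log.time_s, "current_ma": log.current_ma,
                       "amplitude_mv": log.amplitude_mv})
    header = {k: getattr(log, k) for k in
              ("mode", "target_amplitude_mv", "mt_current_ma", "mt_amplitude_mv",
               "ecapt_ma", "frequency_hz", "n_updates", "saturated")}
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def load_session_log(path: str | Path) -> CLSessionLog:
    with open(path) as fh:
        header = json.loads(fh.readline().lstrip("# "))
        df = pd.read_csv(fh, float_precision="round_trip")
    return CLSessionLog(
        mode=header["mode"], target_amplitude_mv=header["target_amplitude_mv"],
        time_s=df["time_s"].to_numpy(), current_ma=df["current_ma"].to_numpy(),
        amplitude_mv=df["amplitude_mv"].to_numpy(),
        mt_current_ma=header["mt_current_ma"], mt_amplitude_mv=header["mt_amplitude_mv"],
        ecapt_ma=header["ecapt_ma"], frequency_hz=header["frequency_hz"],
        n_updates=int(header["n_updates"]), saturated=bool(header["saturated"]))


# ---------------------------------------------------------------------------
# config (YAML) / generic JSON reports
# ---------------------------------------------------------------------------

def save_config(path: str | Path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def save_json(path: str | Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(payload), fh, indent=2)
        fh.write("\n")


def ground_truth_from_dict(d: dict) -> GroundTruth:
    d = dict(d)
    gp = d.pop("gain_process", None)
    if gp is not None:
        d["gain_process"] = GainProcess(**gp)
    return GroundTruth(**d)


def geometry_from_dict(d: dict) -> LeadGeometry:
    d = dict(d)
    if "contact_labels" in d:
        d["contact_labels"] = tuple(d["contact_labels"])
    return LeadGeometry(**d)


def program_from_dict(d: dict) -> StimulusProgram:
    d = dict(d)
    if isinstance(d.get("current_ma"), list):
        d["current_ma"] = np.asarray(d["current_ma"], dtype=float)
    return StimulusProgram(**d)
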