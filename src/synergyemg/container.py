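"""HDF5 container schema shared by all pipeline stages.

One file holds the raw recording (/emg, /cursor, /montage, /trials,
/truth), the preprocessed signals (/preproc), the ICA decomposition
(/ica), the synergy factorizations (/synergy/<input>), module/tuning
tables (/modules) and classification results (/classify). A JSON
manifest sidecar records the configuration and per-stage provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from synergyemg.emg_synth import Montage, SimConfig, SimulatedDataset

STAGE_GROUPS = {
    "simulate": "emg",
    "preprocess": "preproc",
    "ica": "ica",
    "synergy": "synergy",
    "modules": "modules",
    "classify": "classify",
}


def has_stage(path: str | Path, stage: str) -> bool:
    group = STAGE_GROUPS[stage]
    p = Path(path)
    if not p.exists():
        return False
    with h5py.File(p, "r") as f:
        return group in f


def delete_stage(path: str | Path, stage: str) -> None:
    with h5py.File(path, "a") as f:
        group = STAGE_GROUPS[stage]
        if group in f:
            del f[group]


def write_dataset(path: str | Path, ds: SimulatedDataset) -> None:
    with h5py.File(path, "a") as f:
        for name in ("emg", "cursor", "montage", "trials", "truth"):
            if name in f:
                del f[name]
        d = f.create_dataset("emg", data=ds.emg.astype(np.float32))
        d.attrs["fs"] = ds.fs_emg
        d = f.create_dataset("cursor", data=ds.cursor.astype(np.float32))
        d.attrs["fs"] = ds.fs_cursor
        g = f.create_group("montage")
        g.create_dataset("axial_mm", data=ds.montage.axial_mm)
        g.create_dataset("circ_deg", data=ds.montage.circ_deg)
        g.attrs["ground_index"] = ds.montage.ground_index
        g.attrs["radius_mm"] = ds.montage.radius_mm
        g = f.create_group("trials")
        g.create_dataset("start_s", data=ds.trial_start_s)
        g.create_dataset("direction", data=ds.direction)
        g.create_dataset("posture", data=ds.posture)
        g = f.create_group("truth")
        g.create_dataset("A", data=ds.A_true)
        g.create_dataset("envelopes", data=ds.envelopes.astype(np.float32))
        g.attrs["sources_json"] = json.dumps(
            [s.__dict__ for s in ds.sources])
        g.attrs["config_json"] = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in ds.config.__dict__.items()})


def read_dataset(path: str | Path) -> SimulatedDataset:
    from synergyemg.emg_synth import SourceSpec

    with h5py.File(path, "r") as f:
        montage = Montage(
            axial_mm=f["montage/axial_mm"][:],
            circ_deg=f["montage/circ_deg"][:],
            ground_index=int(f["montage"].attrs["ground_index"]),
            radius_mm=float(f["montage"].attrs["radius_mm"]),
        )
        cfg = json.loads(f["truth"].attrs["config_json"])
        for key in ("directions_deg", "postures_deg", "band_hz",
                    "carrier_band_hz"):
            if key in cfg:
                cfg[key] = tuple(cfg[key])
        sources = [SourceSpec(**s)
                   for s in json.loads(f["truth"].attrs["sources_json"])]
        return SimulatedDataset(
            emg=f["emg"][:],
            fs_emg=float(f["emg"].attrs["fs"]),
            cursor=f["cursor"][:],
            fs_cursor=float(f["cursor"].attrs["fs"]),
            montage=montage,
            trial_start_s=f["trials/start_s"][:],
            direction=f["trials/direction"][:],
            posture=f["trials/posture"][:],
            A_true=f["truth/A"][:],
            envelopes=f["truth/envelopes"][:],
            sources=sources,
            config=SimConfig(**cfg),
        )


def write_group(path: str | Path, group: str, arrays: dict,
                attrs: dict | None = None) -> None:
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        for name, arr in arrays.items():
            g.create_dataset(name, data=np.asarray(arr))
        for k, v in (attrs or {}).items():
            g.attrs[k] = v


def read_group(path: str | Path, group: str) -> tuple[dict, dict]:
    with h5py.File(path, "r") as f:
        g = f[group]
        arrays = {}

        def collect(name, obj):
            if isinstance(obj, h5py.Dataset):
                arrays[name] = obj[:]

        g.visititems(collect)
        return arrays, dict(g.attrs)


def validate_container(path: str | Path) -> dict:
    """Schema/invariant checks; returns {"valid": bool, "errors": [...],
    "stages": [...]}."""
    p = Path(path)
    errors: list[str] = []
    stages: list[str] = []
    if not p.exists():
        return {"valid": False, "errors": [f"file not found: {p}"],
                "stages": []}
    try:
        f = h5py.File(p, "r")
    except OSError as exc:
        return {"valid": False, "errors": [f"unreadable file: {exc}"],
                "stages": []}
    with f:
        if "emg" in f:
            stages.append("simulate")
            emg = f["emg"]
            if emg.ndim != 2:
                errors.append("/emg: expected channels x samples")
            fs = float(emg.attrs.get("fs", 0))
            if fs <= 0:
                errors.append("/emg: missing or invalid fs attribute")
            if "trials" in f:
                n_tr = f["trials/direction"].shape[0]
                d = f["trials/direction"][:]
                if not np.isin(d, np.arange(1, 9)).all():
                    errors.append("/trials/direction: labels outside 1..8")
                if f["trials/posture"].shape[0] != n_tr:
                    errors.append("/trials: label lengths differ")
            else:
                errors.append("missing /trials alongside /emg")
            if "truth" in f and "emg" in f:
                if f["truth/A"].shape[0] != emg.shape[0]:
                    errors.append("/truth/A: channel count mismatch with /emg")
        if "ica" in f:
            stages.append("ica")
            if "retained_mask" in f["ica"]:
                mask = f["ica/retained_mask"][:]
                if mask.shape[0] != f["ica/A"].shape[1]:
                    errors.append("/ica: retained_mask length mismatch")
        if "synergy" in f:
            stages.append("synergy")
            for sub in f["synergy"]:
                g = f[f"synergy/{sub}"]
                for name in ("T", "M"):
                    if name in g and np.min(g[name][:]) < 0:
                        errors.append(
                            f"/synergy/{sub}/{name}: negative entries")
        for name in ("preproc", "modules", "classify"):
            if name in f:
                stages.append(name)
    return {"valid": not errors, "errors": errors, "stages": stages}
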