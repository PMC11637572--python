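"""On-disk containers: HDF5/CSV epoch blocks, YAML subject profiles.

The canonical epoch container is an HDF5 file with a single ``epochs``
dataset (n_epochs × n_samples, float32 µV) and the attributes ``fs_hz``,
``level_db_hl``, ``frequency_hz`` and ``seed``.  A long-format CSV twin
exists for small text fixtures.  Subject profiles and cohorts are plain YAML.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .simulate import EpochBlock, StimulusSpec, SubjectProfile


def save_epochs_hdf5(path, block: EpochBlock, seed: int | None = None) -> None:
    with h5py.File(path, "w") as fh:
        dset = fh.create_dataset("epochs", data=block.samples.astype(np.float32))
        dset.attrs["fs_hz"] = block.fs
        dset.attrs["level_db_hl"] = block.stimulus.level
        dset.attrs["frequency_hz"] = block.stimulus.frequency
        dset.attrs["seed"] = -1 if seed is None else int(seed)


def load_epochs_hdf5(path) -> EpochBlock:
    with h5py.File(path, "r") as fh:
        if "epochs" not in fh:
            raise ValueError(f"{path}: missing 'epochs' dataset")
        dset = fh["epochs"]
        for attr in ("fs_hz", "level_db_hl", "frequency_hz"):
            if attr not in dset.attrs:
                raise ValueError(f"{path}: missing required attribute '{attr}'")
        stim = StimulusSpec(
            level=float(dset.attrs["level_db_hl"]),
            frequency=float(dset.attrs["frequency_hz"]),
        )
        seed = int(dset.attrs.get("seed", -1))
        block = EpochBlock(
            samples=np.asarray(dset, dtype=float),
            stimulus=stim,
            fs=float(dset.attrs["fs_hz"]),
            seed_state=None if seed < 0 else str(seed),
        )
    return block


def save_epochs_csv(path, block: EpochBlock, seed: int | None = None) -> None:
    """Long-format CSV twin of the HDF5 container (for small text fixtures)."""
    n_epochs, n_samples = block.samples.shape
    frame = pd.DataFrame(
        {
            "epoch": np.repeat(np.arange(n_epochs), n_samples),
            "sample": np.tile(np.arange(n_samples), n_epochs),
            "amplitude_uv": block.samples.ravel(),
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# fs_hz={block.fs}\n")
        fh.write(f"# level_db_hl={block.stimulus.level}\n")
        fh.write(f"# frequency_hz={block.stimulus.frequency}\n")
        fh.write(f"# seed={-1 if seed is None else int(seed)}\n")
        frame.to_csv(fh, index=False)


def load_epochs_csv(path) -> EpochBlock:
    meta: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, value = line[1:].strip().split("=")
            meta[key.strip()] = float(value)
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        frame = pd.read_csv(fh)
    for attr in ("fs_hz", "level_db_hl", "frequency_hz"):
        if attr not in meta:
            raise ValueError(f"{path}: missing required attribute '{attr}'")
    n_epochs = int(frame["epoch"].max()) + 1
    samples = frame["amplitude_uv"].to_numpy().reshape(n_epochs, -1)
    return EpochBlock(
        samples=samples,
        stimulus=StimulusSpec(meta["level_db_hl"], meta["frequency_hz"]),
        fs=meta["fs_hz"],
    )


def profile_to_dict(profile: SubjectProfile) -> dict:
    return {
        "thresholds": {float(f): float(t) for f, t in profile.thresholds.items()},
        "slope": profile.slope,
        "amp_max": profile.amp_max,
        "latency0": profile.latency0,
        "latency_shift": profile.latency_shift,
        "trough_lag": profile.trough_lag,
        "noise_rms": profile.noise_rms,
        "artifact_rate": profile.artifact_rate,
    }


def profile_from_dict(d: dict) -> SubjectProfile:
    return SubjectProfile(**d)


def save_profiles_yaml(path, profiles: list[SubjectProfile]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump([profile_to_dict(p) for p in profiles], fh, sort_keys=False)


def load_profiles_yaml(path) -> list[SubjectProfile]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if isinstance(data, dict):
        data = [data]
    return [profile_from_dict(d) for d in data]


def ensure_parent(path) -> Path:
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"output directory {path.parent} does not exist")
    return path
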