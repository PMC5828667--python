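"""File formats: one HDF5 container for arrays, delimited text for tables.

Every writer embeds the package version and (when supplied) the run
config hash as root attributes; every reader round-trips exactly what the
writer produced. Malformed files raise with the file name and the failing
expectation rather than returning partial objects.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import GazeDataset, Leadfield, SensorEpochs, SourceEpochs


_STR = h5py.string_dtype(encoding="utf-8")


def _write_strings(f: h5py.File, name: str, values: list[str]) -> None:
    f.create_dataset(name, data=values, dtype=_STR)


def _read_strings(f: h5py.File, name: str) -> list[str]:
    return [
        v.decode("utf-8") if isinstance(v, bytes) else str(v)
        for v in f[name][()]
    ]


def _root_attrs(f: h5py.File, kind: str, config_hash: str | None) -> None:
    f.attrs["pdcflow_version"] = __version__
    f.attrs["kind"] = kind
    if config_hash:
        f.attrs["config_hash"] = config_hash


def _open_for_read(path: str | Path, kind: str) -> h5py.File:
    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except OSError as err:
        raise IOError(f"{path}: not a readable HDF5 container ({err})") from err
    found = f.attrs.get("kind", "")
    if found != kind:
        f.close()
        raise IOError(f"{path}: expected a '{kind}' container, found '{found}'")
    return f


def write_sensor_epochs(
    path: str | Path, ep: SensorEpochs, config_hash: str | None = None
) -> None:
    with h5py.File(path, "w") as f:
        _root_attrs(f, "sensor_epochs", config_hash)
        f.create_dataset("data", data=ep.data)
        f.attrs["fs"] = ep.fs
        f.attrs["reference"] = ep.reference
        _write_strings(f, "ch_names", ep.ch_names)
        if ep.ch_positions is not None:
            f.create_dataset("ch_positions", data=ep.ch_positions)
        _write_strings(f, "history", ep.history)


def read_sensor_epochs(path: str | Path) -> SensorEpochs:
    with _open_for_read(path, "sensor_epochs") as f:
        pos = f["ch_positions"][()] if "ch_positions" in f else None
        return SensorEpochs(
            data=f["data"][()],
            fs=float(f.attrs["fs"]),
            ch_names=_read_strings(f, "ch_names"),
            ch_positions=pos,
            reference=str(f.attrs["reference"]),
            history=_read_strings(f, "history"),
        )


def write_source_epochs(
    path: str | Path, src: SourceEpochs, config_hash: str | None = None
) -> None:
    with h5py.File(path, "w") as f:
        _root_attrs(f, "source_epochs", config_hash)
        f.create_dataset("data", data=src.data)
        f.attrs["fs"] = src.fs
        _write_strings(f, "roi_labels", src.roi_labels)


def read_source_epochs(path: str | Path) -> SourceEpochs:
    with _open_for_read(path, "source_epochs") as f:
        return SourceEpochs(
            data=f["data"][()],
            fs=float(f.attrs["fs"]),
            roi_labels=_read_strings(f, "roi_labels"),
        )


def write_leadfield(
    path: str | Path, lf: Leadfield, config_hash: str | None = None
) -> None:
    with h5py.File(path, "w") as f:
        _root_attrs(f, "leadfield", config_hash)
        f.create_dataset("gain", data=lf.gain)
        f.create_dataset("electrode_positions", data=lf.electrode_positions)
        f.create_dataset("point_positions", data=lf.point_positions)
        f.create_dataset("point_neighbors", data=lf.point_neighbors)


def read_leadfield(path: str | Path) -> Leadfield:
    with _open_for_read(path, "leadfield") as f:
        return Leadfield(
            gain=f["gain"][()],
            electrode_positions=f["electrode_positions"][()],
            point_positions=f["point_positions"][()],
            point_neighbors=f["point_neighbors"][()],
        )


# --- delimited text ---------------------------------------------------------


def write_gaze_tsv(path: str | Path, ds: GazeDataset) -> None:
    """Long format: frame, subject_id, group, x, y, valid (+film)."""
    rows = []
    for f in range(ds.n_frames):
        film = int(ds.film_ids[f])
        for j in range(ds.n_reference):
            x, y, v = ds.reference[f, j]
            rows.append((f, f"R{j:03d}", "reference", film, x, y, int(v > 0.5)))
        for j in range(ds.n_test):
            x, y, v = ds.test_tracks[j, f]
            rows.append((f, f"T{j:03d}", "test", film, x, y, int(v > 0.5)))
    pd.DataFrame(
        rows, columns=["frame", "subject_id", "group", "film", "x", "y", "valid"]
    ).to_csv(path, sep="\t", index=False)


def read_gaze_tsv(path: str | Path, frame_rate: float = 25.0) -> GazeDataset:
    df = pd.read_csv(path, sep="\t")
    need = {"frame", "subject_id", "group", "film", "x", "y", "valid"}
    missing = need - set(df.columns)
    if missing:
        raise IOError(f"{path}: missing columns {sorted(missing)}")
    frames = np.sort(df["frame"].unique())
    ref_ids = sorted(df.loc[df.group == "reference", "subject_id"].unique())
    test_ids = sorted(df.loc[df.group == "test", "subject_id"].unique())
    reference = np.zeros((len(frames), len(ref_ids), 3))
    test_tracks = np.zeros((len(test_ids), len(frames), 3))
    film_ids = np.zeros(len(frames), dtype=int)
    fidx = {f: i for i, f in enumerate(frames)}
    ridx = {s: i for i, s in enumerate(ref_ids)}
    tidx = {s: i for i, s in enumerate(test_ids)}
    for row in df.itertuples():
        i = fidx[row.frame]
        film_ids[i] = row.film
        rec = (row.x, row.y, float(row.valid))
        if row.group == "reference":
            reference[i, ridx[row.subject_id]] = rec
        else:
            test_tracks[tidx[row.subject_id], i] = rec
    return GazeDataset(
        reference=reference,
        test_tracks=test_tracks,
        frame_rate=frame_rate,
        film_ids=film_ids,
    )


def write_outflow_tsv(path: str | Path, table: pd.DataFrame) -> None:
    need = {"subject_id", "group", "roi", "band", "outflow"}
    missing = need - set(table.columns)
    if missing:
        raise ValueError(f"outflow table missing columns {sorted(missing)}")
    table.to_csv(path, sep="\t", index=False)


def read_outflow_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"subject_id", "group", "roi", "band", "outflow"}
    missing = need - set(df.columns)
    if missing:
        raise IOError(f"{path}: missing columns {sorted(missing)}")
    return df


# --- config -----------------------------------------------------------------


def config_hash(config: dict) -> str:
    canon = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_config(path: str | Path, config: dict) -> str:
    h = config_hash(config)
    stamped = dict(config)
    stamped["_meta"] = {"pdcflow_version": __version__, "config_hash": h}
    Path(path).write_text(yaml.safe_dump(stamped, sort_keys=True))
    return h


def read_config(path: str | Path) -> dict:
    obj = yaml.safe_load(Path(path).read_text())
    if not isinstance(obj, dict):
        raise IOError(f"{path}: config must be a mapping")
    obj.pop("_meta", None)
    return obj


def read_raw_eeg(path: str | Path) -> SensorEpochs:
    """Read a continuous EDF/BDF recording into a SensorEpochs container
    (single epoch). Requires mne."""
    import mne

    raw = mne.io.read_raw(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return SensorEpochs(
        data=data[:, :, None],
        fs=float(raw.info["sfreq"]),
        ch_names=list(raw.ch_names),
        reference="as-recorded",
        history=[f"read:{Path(path).name}"],
    )
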