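"""Readers/writers for the pipeline's file formats.

* sessions: HDF5 — channel datasets with ``fs``/``t0`` attributes, LED-on
  epochs as an (n, 2) interval dataset, ``schema_version`` on the root
* tables (trials, hypnograms, cell counts, colocalization): CSV with the
  documented header contracts
* ground truth and run configs: YAML

Every file written here embeds the schema version; sessions and manifests
also carry the config hash and seed when provided.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .types import PhotometrySession, Trace

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1

TRIAL_COLUMNS = ["trial_id", "onset_s"]
TRIAL_OPTIONAL = ["intensity_db", "laser", "outcome", "mouse", "baseline_state"]
HYPNOGRAM_COLUMNS = ["epoch_start_s", "state"]
CELL_COUNT_COLUMNS = ["animal_id", "group", "ap_mm", "dv_strip_mm", "count"]
COLOC_COLUMNS = ["mouse_id", "slice_id", "n_red", "n_green", "n_coloc"]
COLOC_OPTIONAL = ["n_total"]


def config_hash(obj) -> str:
    """Stable sha256 of a config mapping (canonical YAML serialization)."""
    text = yaml.safe_dump(obj, sort_keys=True, default_flow_style=False)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# sessions (HDF5)


def write_session(
    path: str | Path,
    session: PhotometrySession,
    eeg: Trace | None = None,
    emg: Trace | None = None,
    attrs: dict | None = None,
) -> None:
    # track_times=False keeps byte-identical files across identical runs
    with h5py.File(path, "w", track_order=False) as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        for k, v in (attrs or {}).items():
            f.attrs[k] = v
        g = f.create_group("photometry", track_order=False)
        for name, data in (("signal", session.signal), ("isosbestic", session.isosbestic)):
            d = g.create_dataset(name, data=data, track_times=False)
            d.attrs["fs"] = session.fs
            d.attrs["t0"] = 0.0
        if session.led_epochs is not None:
            g.create_dataset(
                "led_epochs", data=np.asarray(session.led_epochs, dtype=float), track_times=False
            )
        for name, tr in (("eeg", eeg), ("emg", emg)):
            if tr is not None:
                d = f.create_dataset(name, data=tr.samples, track_times=False)
                d.attrs["fs"] = tr.fs
                d.attrs["t0"] = 0.0


def read_session(path: str | Path) -> dict:
    """Read a session container; returns a dict with available channels."""
    out: dict = {}
    with h5py.File(path, "r") as f:
        if "photometry" in f:
            g = f["photometry"]
            led = (
                [tuple(row) for row in np.asarray(g["led_epochs"])]
                if "led_epochs" in g
                else None
            )
            out["photometry"] = PhotometrySession(
                signal=np.asarray(g["signal"]),
                isosbestic=np.asarray(g["isosbestic"]),
                fs=float(g["signal"].attrs["fs"]),
                led_epochs=led,
            )
        for name in ("eeg", "emg"):
            if name in f:
                out[name] = Trace(np.asarray(f[name]), float(f[name].attrs["fs"]))
        out["attrs"] = dict(f.attrs)
    return out


# ---------------------------------------------------------------------------
# tables (CSV)


def _check_columns(
    df: pd.DataFrame, required: list[str], kind: str, optional: list[str] = ()
) -> pd.DataFrame:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{kind} table missing columns {missing}")
    extra = [c for c in df.columns if c not in required and c not in optional]
    if extra:
        log.warning("%s table has unknown columns %s; preserved", kind, extra)
    return df


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_trial_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df = _check_columns(df, TRIAL_COLUMNS, "trial", TRIAL_OPTIONAL)
    bad = df.index[~np.isfinite(df["onset_s"])]
    if len(bad):
        raise ValueError(f"trial table has malformed onset_s at rows {list(bad)}")
    return df


def read_hypnogram(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df = _check_columns(df, HYPNOGRAM_COLUMNS, "hypnogram")
    allowed = {"wake", "NREM", "REM"}
    bad = df.index[~df["state"].isin(allowed)]
    if len(bad):
        raise ValueError(f"hypnogram has unknown states at rows {list(bad)}")
    return df


def read_cell_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df = _check_columns(df, CELL_COUNT_COLUMNS, "cell-count")
    bad = df.index[df["count"] < 0]
    if len(bad):
        raise ValueError(f"cell-count table has negative counts at rows {list(bad)}")
    return df


def read_colocalization(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return _check_columns(df, COLOC_COLUMNS, "colocalization", COLOC_OPTIONAL)


# ---------------------------------------------------------------------------
# YAML sidecars


def write_yaml(path: str | Path, obj) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(obj, f, sort_keys=True)


def read_yaml(path: str | Path):
    with open(path) as f:
        return yaml.safe_load(f)
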