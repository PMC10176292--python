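"""Reading and writing recordings and result tables.

Two on-disk dialects are supported for recordings:

* ``tabular`` - a directory holding a long-format intensity table
  (``intensity.tsv``: channel, wavelength, time_s, value) plus JSON sidecars
  for events, looking proportions and participant metadata.  Diffable, used
  throughout the tests.
* ``snirf`` - a minimal SNIRF-style HDF5 container (subset:
  /nirs/data1 time series + measurement list, /nirs/stim*, /nirs/probe).

Result tables are tab-separated with '.' decimal separator; every run also
emits a machine-readable manifest (config echo, seed, versions).
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .montage import N_CHANNELS
from .recording import Event, RawRecording

_META_KEYS = ("participant_id", "age_group", "sampling_rate",
              "tested_during_pandemic")


class SchemaError(ValueError):
    """The file's content does not match the recording schema."""


class FormatError(ValueError):
    """The file is structurally malformed (e.g. non-monotone time)."""


# ---------------------------------------------------------------------------
# tabular dialect
# ---------------------------------------------------------------------------
def write_recording_tabular(rec: RawRecording, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    n_ch, _, n = rec.intensity.shape
    t = rec.times()
    frames = []
    for ci in range(n_ch):
        for wi, wl in enumerate(rec.wavelengths):
            frames.append(pd.DataFrame({
                "channel": ci + 1, "wavelength": wl, "time_s": t,
                "value": rec.intensity[ci, wi],
            }))
    pd.concat(frames, ignore_index=True).to_csv(
        path / "intensity.tsv", sep="\t", index=False, float_format="%.10g")
    (path / "events.json").write_text(json.dumps(
        [vars(e) for e in rec.events], indent=1))
    meta = {k: getattr(rec, k) for k in _META_KEYS}
    meta["wavelengths"] = list(rec.wavelengths)
    meta["looking"] = rec.looking.tolist()
    if rec.channel_usable is not None:
        meta["channel_usable"] = rec.channel_usable.astype(int).tolist()
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    return path


def read_recording_tabular(path: str | Path) -> RawRecording:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    for key in _META_KEYS:
        if key not in meta:
            raise SchemaError(f"meta.json: missing field {key!r}")
    df = pd.read_csv(path / "intensity.tsv", sep="\t")
    need = {"channel", "wavelength", "time_s", "value"}
    if not need <= set(df.columns):
        raise SchemaError(f"intensity.tsv: missing columns {need - set(df.columns)}")
    wavelengths = sorted(df.wavelength.unique())
    if len(wavelengths) != 2:
        raise SchemaError(f"expected 2 wavelengths, found {len(wavelengths)}")
    channels = sorted(df.channel.unique())
    if channels != list(range(1, len(channels) + 1)):
        raise SchemaError("channel ids must be contiguous from 1")
    if len(channels) != N_CHANNELS:
        raise SchemaError(
            f"montage requires {N_CHANNELS} channels; file has {len(channels)}")
    cube = []
    for ch in channels:
        per_wl = []
        for wl in wavelengths:
            s = df[(df.channel == ch) & (df.wavelength == wl)]
            tt = s.time_s.values
            if np.any(np.diff(tt) <= 0):
                raise FormatError(f"channel {ch} @ {wl} nm: non-monotone time")
            per_wl.append(s.value.values)
        cube.append(per_wl)
    events = [Event(**e) for e in json.loads((path / "events.json").read_text())]
    return RawRecording(
        participant_id=meta["participant_id"],
        age_group=meta["age_group"],
        sampling_rate=float(meta["sampling_rate"]),
        intensity=np.asarray(cube, dtype=float),
        events=events,
        looking=np.asarray(meta["looking"], dtype=float),
        channel_usable=(np.asarray(meta["channel_usable"], dtype=bool)
                        if "channel_usable" in meta else None),
        wavelengths=tuple(float(w) for w in meta["wavelengths"]),
        tested_during_pandemic=bool(meta["tested_during_pandemic"]),
    )


# ---------------------------------------------------------------------------
# SNIRF-style HDF5 dialect
# ---------------------------------------------------------------------------
def write_recording_snirf(rec: RawRecording, path: str | Path) -> Path:
    path = Path(path)
    n_ch, _, n = rec.intensity.shape
    with h5py.File(path, "w") as f:
        nirs = f.create_group("nirs")
        data = nirs.create_group("data1")
        # columns ordered channel-major, wavelength-minor
        flat = rec.intensity.reshape(n_ch * 2, n).T
        data.create_dataset("dataTimeSeries", data=flat)
        data.create_dataset("time", data=rec.times())
        for k, (ci, wi) in enumerate(
                (c, w) for c in range(n_ch) for w in range(2)):
            ml = data.create_group(f"measurementList{k + 1}")
            ml.create_dataset("sourceIndex", data=ci + 1)
            ml.create_dataset("detectorIndex", data=ci + 1)
            ml.create_dataset("wavelengthIndex", data=wi + 1)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths))
        for i, e in enumerate(rec.events):
            st = nirs.create_group(f"stim{i + 1}")
            st.create_dataset("name", data=e.condition)
            st.create_dataset("data", data=[[e.onset_s, e.duration_s, 1.0]])
        meta = nirs.create_group("metaDataTags")
        meta.attrs["participant_id"] = rec.participant_id
        meta.attrs["age_group"] = rec.age_group
        meta.attrs["sampling_rate"] = rec.sampling_rate
        meta.attrs["tested_during_pandemic"] = rec.tested_during_pandemic
        meta.create_dataset("looking", data=rec.looking)
    return path


def read_recording_snirf(path: str | Path) -> RawRecording:
    with h5py.File(path, "r") as f:
        if "nirs" not in f or "data1" not in f["nirs"]:
            raise SchemaError("missing /nirs/data1 group")
        data = f["nirs/data1"]
        flat = np.asarray(data["dataTimeSeries"])
        t = np.asarray(data["time"])
        if np.any(np.diff(t) <= 0):
            raise FormatError("non-monotone time vector")
        n_cols = flat.shape[1]
        if n_cols % 2:
            raise SchemaError("expected two wavelengths per channel")
        n_ch = n_cols // 2
        if n_ch != N_CHANNELS:
            raise SchemaError(
                f"montage requires {N_CHANNELS} channels; file has {n_ch}")
        intensity = flat.T.reshape(n_ch, 2, -1)
        wavelengths = tuple(np.asarray(f["nirs/probe/wavelengths"]).tolist())
        events = []
        i = 1
        while f"stim{i}" in f["nirs"]:
            st = f[f"nirs/stim{i}"]
            name = st["name"][()]
            name = name.decode() if isinstance(name, bytes) else str(name)
            onset, dur, _ = np.asarray(st["data"])[0]
            events.append(Event(name, float(onset), float(dur)))
            i += 1
        events.sort(key=lambda e: e.onset_s)
        meta = f["nirs/metaDataTags"]
        fs = float(meta.attrs["sampling_rate"])
        return RawRecording(
            participant_id=str(meta.attrs["participant_id"]),
            age_group=str(meta.attrs["age_group"]),
            sampling_rate=fs,
            intensity=intensity,
            events=events,
            looking=np.asarray(meta["looking"]),
            wavelengths=wavelengths,
            tested_during_pandemic=bool(meta.attrs["tested_during_pandemic"]),
        )


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------
def write_recording(rec: RawRecording, path: str | Path,
                    dialect: str = "tabular") -> Path:
    if dialect == "tabular":
        return write_recording_tabular(rec, path)
    if dialect == "snirf":
        return write_recording_snirf(rec, path)
    raise ValueError(f"unknown dialect {dialect!r}")


def read_recording(path: str | Path, dialect: str = "tabular") -> RawRecording:
    """Read one recording; raises SchemaError/FormatError on bad content."""
    if dialect == "tabular":
        return read_recording_tabular(path)
    if dialect == "snirf":
        return read_recording_snirf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------
_TABLE2_COLUMNS = {
    "chromophore": "Chrom", "hemisphere": "H", "region": "ROI",
    "channel": "CH", "window": "TW", "F": "F", "df1": "df",
    "df2": "df_error", "p": "p", "partial_eta_sq": "eta2_p",
    "posthoc_p": "posthoc_p", "direction": "direction",
    "additivity": "interpretation", "fdr_significant": "fdr_significant",
}


def channel_stats_table(stats: pd.DataFrame) -> pd.DataFrame:
    """Reorder/rename a channel-statistics frame into the published layout
    (Chrom / H / ROI / CH / TW / F / df / p / eta2_p / direction /
    interpretation)."""
    if stats.empty:
        return pd.DataFrame(columns=list(_TABLE2_COLUMNS.values()))
    out = stats[list(_TABLE2_COLUMNS)].rename(columns=_TABLE2_COLUMNS).copy()
    hemi = {"left": "L", "right": "R"}
    roi = {"inferior_frontal": "IF", "superior_temporal": "ST", "other": "-"}
    out["H"] = out["H"].map(hemi)
    out["ROI"] = out["ROI"].map(roi)
    out["TW"] = out["TW"].map({"W1": "5-10s", "W2": "10-15s"})
    return out


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path,
                  manifest: dict | None = None) -> list[Path]:
    """Write named result tables as TSV plus a JSON run manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.6g")
        written.append(p)
    info = dict(manifest or {})
    info.setdefault("versions", {})
    info["versions"].update({
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    })
    p = out_dir / "manifest.json"
    p.write_text(json.dumps(info, indent=1, sort_keys=True, default=str))
    written.append(p)
    return written
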