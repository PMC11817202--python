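"""Reading and writing the formats the pipeline touches.

* EDF: recordings are read through :mod:`mne` and written by a minimal
  16-bit EDF writer (one-second data records, physical units µV).
* Feature tables: CSV with ``subject_id, group, epoch`` metadata
  columns followed by feature columns named ``<band>.<param>.<channel>``
  in canonical order (band-major in delta→gamma order, parameter
  activity/mobility/complexity, channel in montage order).
* Epoch container: a single-file binary cache — magic ``EPK1``, a
  4-byte little-endian JSON-header length, the JSON header (fs, epoch
  length, subject, group, band, channels, shape), then the epoch tensor
  as little-endian 32-bit floats in C order.
"""

import json
import struct
from datetime import datetime
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .bands import Band, band_by_name, sort_band_names
from .errors import ChannelMismatchError, ConfigurationError
from .montage import MONTAGE_19, Montage
from .recording import EEGRecording, EpochSet

METADATA_COLUMNS = ("subject_id", "group", "epoch")
PARAMETERS = ("activity", "mobility", "complexity")


# ---------------------------------------------------------------------------
# feature naming

def feature_name(band: str, parameter: str, channel: str) -> str:
    return f"{band}.{parameter}.{channel}"


def parse_feature_name(name: str) -> Tuple[str, str, str]:
    band, parameter, channel = name.split(".")
    return band, parameter, channel


def canonical_feature_columns(
    bands: Sequence[str],
    parameters: Sequence[str] = PARAMETERS,
    channels: Sequence[str] = MONTAGE_19.channels,
) -> List[str]:
    """Total ordering: band-major, parameter-middle, channel-minor."""
    params = [p for p in PARAMETERS if p in parameters]
    cols = [
        feature_name(b, p, ch)
        for b in sort_band_names(bands)
        for p in params
        for ch in channels
    ]
    if len(set(cols)) != len(cols):
        raise ConfigurationError("feature name collision in requested table")
    return cols


def feature_columns_of(table: pd.DataFrame) -> List[str]:
    return [c for c in table.columns if c not in METADATA_COLUMNS]


def write_feature_table(table: pd.DataFrame, path) -> None:
    if table.empty:
        raise ConfigurationError("refusing to write an empty feature table")
    cols = feature_columns_of(table)
    if len(set(cols)) != len(cols):
        raise ConfigurationError("feature name collision in table")
    # default float formatting is shortest-round-trip: values survive exactly
    table.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    # round_trip parsing: together with the shortest-round-trip writer,
    # CSV round-trips are bit-exact
    return pd.read_csv(path, float_precision="round_trip")


# ---------------------------------------------------------------------------
# epoch container

_MAGIC = b"EPK1"


def write_epochs(es: EpochSet, path) -> None:
    header = {
        "fs": es.fs,
        "epoch_length": es.epoch_length,
        "subject_id": es.subject_id,
        "group": es.group,
        "band": None if es.band is None else [es.band.name, es.band.low, es.band.high],
        "channels": list(es.channels),
        "shape": list(es.data.shape),
        "dtype": "<f4",
    }
    blob = json.dumps(header).encode()
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<I", len(blob)))
        fh.write(blob)
        fh.write(np.ascontiguousarray(es.data, dtype="<f4").tobytes())


def read_epochs(path) -> EpochSet:
    with open(path, "rb") as fh:
        if fh.read(4) != _MAGIC:
            raise ConfigurationError(f"{path} is not an epoch container")
        (hlen,) = struct.unpack("<I", fh.read(4))
        header = json.loads(fh.read(hlen).decode())
        data = np.frombuffer(fh.read(), dtype="<f4").reshape(header["shape"])
    band = None
    if header["band"] is not None:
        name, low, high = header["band"]
        band = Band(name, low, high)
    return EpochSet(
        data=data.astype(np.float64),
        fs=header["fs"],
        epoch_length=header["epoch_length"],
        subject_id=header["subject_id"],
        group=header["group"],
        channels=tuple(header["channels"]),
        band=band,
    )


# ---------------------------------------------------------------------------
# EDF

def write_edf(rec: EEGRecording, path) -> None:
    """Minimal EDF export: 16-bit samples, one-second data records.

    Requires an integer sampling rate; a trailing partial second is
    dropped (signals produced by this package are whole-second).
    """
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9:
        raise ConfigurationError("EDF writer requires an integer sampling rate")
    n_records = rec.n_samples // fs
    if n_records < 1:
        raise ConfigurationError("recording shorter than one EDF data record")
    n_sig = len(rec.channels)
    data = rec.data[:, : n_records * fs]
    phys_min = np.floor(data.min(axis=1))
    phys_max = np.ceil(data.max(axis=1))
    phys_max = np.where(phys_max <= phys_min, phys_min + 1, phys_max)
    dig_min, dig_max = -32768, 32767

    def pad(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    now = datetime(2000, 1, 1)
    header = b"".join(
        [
            pad("0", 8),
            pad(rec.subject_id or "X", 80),
            pad(f"Startdate 01-JAN-2000 {rec.group}", 80),
            pad(now.strftime("%d.%m.%y"), 8),
            pad(now.strftime("%H.%M.%S"), 8),
            pad(str(256 * (1 + n_sig)), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad("1", 8),
            pad(str(n_sig), 4),
        ]
    )
    fields = [
        ("%s", 16, list(rec.channels)),
        ("%s", 80, ["AgAgCl electrode"] * n_sig),
        ("%s", 8, ["uV"] * n_sig),
        ("%g", 8, phys_min.tolist()),
        ("%g", 8, phys_max.tolist()),
        ("%d", 8, [dig_min] * n_sig),
        ("%d", 8, [dig_max] * n_sig),
        ("%s", 80, [""] * n_sig),
        ("%d", 8, [fs] * n_sig),
        ("%s", 32, [""] * n_sig),
    ]
    sig_header = b"".join(
        pad(fmt % v, width) for fmt, width, values in fields for v in values
    )
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(
        np.round((data - phys_min[:, None]) * scale[:, None] + dig_min),
        dig_min,
        dig_max,
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_records):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())


def read_edf(path, montage: Montage = MONTAGE_19) -> EEGRecording:
    """Read an EDF file and normalize its labels onto ``montage``.

    Labels are matched case-insensitively after stripping an ``EEG ``
    prefix and trailing reference suffixes; channels are returned in
    montage order. Unknown or missing channels raise
    :class:`ChannelMismatchError`.
    """
    import mne

    path = Path(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    normalized = [montage.normalize_label(ch) for ch in raw.ch_names]
    known = set(montage.channels)
    unknown = [ch for ch in normalized if ch not in known]
    missing = [ch for ch in montage.channels if ch not in normalized]
    if unknown or missing:
        raise ChannelMismatchError(missing=missing, unknown=unknown)
    order = [normalized.index(ch) for ch in montage.channels]
    data_uv = raw.get_data()[order] * 1e6  # mne loads volts
    subject = (raw.info["subject_info"] or {}).get("his_id", path.stem)
    desc = raw.info["description"] or ""
    group = "patient" if "patient" in desc else ("control" if "control" in desc else "control")
    return EEGRecording(
        subject_id=subject or path.stem,
        group=group,
        fs=float(raw.info["sfreq"]),
        channels=montage.channels,
        data=data_uv,
    )
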