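"""List-mode input/output.

The vendor's native acquisition format is proprietary, so this package
defines two open dialects for pulse-shape list-mode data and uses them
everywhere (the simulator writes them, the pipeline reads them):

``csv_long``
    UTF-8 text, ``.`` decimal separator.  A header block of ``# key: value``
    lines carries the measurement metadata (pump_speed, duration,
    dilution_factor, sample_label, timepoint) and the shared calibration
    (um_per_sample, saturation_level), followed by one CSV row per sample:
    ``particle_id,channel,sample_index,value,acquisition_time``.
    ``sample_index`` is 0-based and contiguous per particle and channel;
    floats are written with ``repr`` so a round trip is bit-exact.

``hdf5``
    Metadata as root attributes; ``particle_id`` and ``acquisition_time``
    datasets aligned with one variable-length float64 dataset per channel
    under ``/pulses`` (an empty array marks an absent optional channel).

Both dialects satisfy ``read_listmode(write_listmode(x)) == x`` exactly.
"""

from __future__ import annotations

import csv
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .config import GatingConfig, load_gating_config  # noqa: F401  (re-export)
from .errors import FormatError, MissingChannelError, ValidationError
from .types import Channel, MeasurementMeta, ParticleRecord, PulseShape

DIALECTS = ("csv_long", "hdf5")

_META_FIELDS = ("pump_speed", "duration", "dilution_factor", "sample_label", "timepoint")
_CSV_COLUMNS = ("particle_id", "channel", "sample_index", "value", "acquisition_time")
_MAGIC = "pulsemorph csv_long v1"


def _run_calibration(records) -> tuple[float, float]:
    """Shared (um_per_sample, saturation_level) of a run; must be uniform."""
    ums = {p.um_per_sample for r in records for p in r.pulses.values()}
    sat = {p.saturation_level for r in records for p in r.pulses.values()}
    if len(ums) != 1 or len(sat) != 1:
        raise ValidationError(
            "all pulses of a run must share um_per_sample and saturation_level"
        )
    return ums.pop(), sat.pop()


# --------------------------------------------------------------------------
# writing
# --------------------------------------------------------------------------

def write_listmode(records, meta: MeasurementMeta, path, dialect: str = "csv_long") -> None:
    """Write a measurement run to ``path`` in the given dialect."""
    records = list(records)
    if not records:
        raise ValidationError("cannot write an empty record list")
    if dialect not in DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    um_per_sample, saturation = _run_calibration(records)

    if dialect == "csv_long":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(f"# {_MAGIC}\n")
            for name in _META_FIELDS:
                fh.write(f"# {name}: {getattr(meta, name)}\n")
            fh.write(f"# um_per_sample: {um_per_sample!r}\n")
            fh.write(f"# saturation_level: {saturation!r}\n")
            writer = csv.writer(fh)
            writer.writerow(_CSV_COLUMNS)
            for rec in records:
                t = repr(rec.acquisition_time)
                for channel in Channel:
                    if channel not in rec.pulses:
                        continue
                    pid = rec.particle_id
                    for i, v in enumerate(rec.pulses[channel].samples):
                        writer.writerow((pid, channel.value, i, repr(float(v)), t))
        return

    vlen = h5py.vlen_dtype(np.float64)
    with h5py.File(path, "w") as h5:
        h5.attrs["format"] = "pulsemorph hdf5 v1"
        for name in _META_FIELDS:
            h5.attrs[name] = getattr(meta, name)
        h5.attrs["um_per_sample"] = um_per_sample
        h5.attrs["saturation_level"] = saturation
        ids = np.array([r.particle_id for r in records], dtype=h5py.string_dtype())
        h5.create_dataset("particle_id", data=ids)
        h5.create_dataset(
            "acquisition_time", data=np.array([r.acquisition_time for r in records])
        )
        grp = h5.create_group("pulses")
        empty = np.array([], dtype=np.float64)
        for channel in Channel:
            if not any(channel in r.pulses for r in records):
                continue
            ds = grp.create_dataset(channel.value, (len(records),), dtype=vlen)
            for i, rec in enumerate(records):
                ds[i] = (
                    rec.pulses[channel].samples if channel in rec.pulses else empty
                )


# --------------------------------------------------------------------------
# reading
# --------------------------------------------------------------------------

def _parse_meta(pairs: dict) -> MeasurementMeta:
    kwargs = {}
    for name in _META_FIELDS:
        if name in pairs:
            raw = pairs[name]
            kwargs[name] = raw if name == "sample_label" else float(raw)
    return MeasurementMeta(**kwargs)


def _read_csv_long(path):
    header: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                header[key.strip()] = val.strip()
    if "um_per_sample" not in header:
        raise FormatError(f"{path}: missing 'um_per_sample' metadata line")
    um_per_sample = float(header["um_per_sample"])
    saturation = float(header.get("saturation_level", 1e4))
    meta = _parse_meta(header)

    df = pd.read_csv(
        path,
        comment="#",
        dtype={"particle_id": str, "channel": str, "sample_index": np.int64,
               "value": np.float64, "acquisition_time": np.float64},
        float_precision="round_trip",  # repr-written floats must round-trip bit-exactly
    )
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    bad = set(df["channel"].unique()) - {c.value for c in Channel}
    if bad:
        raise FormatError(f"{path}: unknown channel name(s) {sorted(bad)}")

    records = []
    # preserve file order of first appearance
    for pid, part in df.groupby("particle_id", sort=False):
        pulses = {}
        for ch_name, block in part.groupby("channel", sort=False):
            idx = block["sample_index"].to_numpy()
            if not np.array_equal(idx, np.arange(len(idx))):
                raise FormatError(
                    f"{path}: particle {pid!r} channel {ch_name}: sample_index "
                    "must be contiguous and increasing from 0"
                )
            pulses[Channel(ch_name)] = PulseShape(
                Channel(ch_name), block["value"].to_numpy(), um_per_sample, saturation
            )
        t = float(part["acquisition_time"].iloc[0])
        records.append(ParticleRecord(pid, pulses, t))  # raises on missing FWS/SWS
    return records, meta


def _read_hdf5(path):
    with h5py.File(path, "r") as h5:
        meta = _parse_meta({k: h5.attrs[k] for k in _META_FIELDS if k in h5.attrs})
        um_per_sample = float(h5.attrs["um_per_sample"])
        saturation = float(h5.attrs["saturation_level"])
        ids = [i.decode() if isinstance(i, bytes) else str(i) for i in h5["particle_id"][:]]
        times = h5["acquisition_time"][:]
        channel_data = {}
        for name in h5["pulses"]:
            if name not in {c.value for c in Channel}:
                raise FormatError(f"{path}: unknown channel name {name!r}")
            channel_data[Channel(name)] = h5["pulses"][name][:]
    records = []
    for i, pid in enumerate(ids):
        pulses = {
            ch: PulseShape(ch, arr[i], um_per_sample, saturation)
            for ch, arr in channel_data.items()
            if arr[i].size
        }
        records.append(ParticleRecord(pid, pulses, float(times[i])))
    return records, meta


def read_listmode(path, dialect: str | None = None):
    """Read a measurement run; returns ``(records, meta)``.

    ``dialect`` is inferred from the file suffix when omitted (``.h5``/
    ``.hdf5`` → hdf5, anything else → csv_long).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if dialect is None:
        dialect = "hdf5" if path.suffix.lower() in (".h5", ".hdf5") else "csv_long"
    if dialect not in DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    try:
        if dialect == "csv_long":
            return _read_csv_long(path)
        return _read_hdf5(path)
    except MissingChannelError:
        raise
    except (FormatError, ValidationError):
        raise
    except Exception as exc:  # h5py/pandas parse failures → structured error
        raise FormatError(f"cannot parse {path} as {dialect}: {exc}") from exc


# --------------------------------------------------------------------------
# scalar feature export
# --------------------------------------------------------------------------

def export_features(table: pd.DataFrame, path) -> None:
    """Write a scalar feature/class table as CSV (one row per particle)."""
    table.to_csv(path, index=False)
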