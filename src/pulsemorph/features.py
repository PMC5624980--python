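"""Curve parameters of pulse shapes and the derived gating ratios.

Five scalar parameters summarise each channel's pulse:

========  =====================================================
maximum   peak intensity (a.u.)
total     area beneath the curve: sum of samples, unit width (a.u.)
length    spatial extent of the whole recorded signal (μm)
sample_length
          extent of the signal above the trigger level (μm),
          measured over the contiguous envelope between the first
          and last above-trigger samples (interior dips included)
fill_factor
          block-similarity in [0, 1]: mean of the above-trigger
          samples divided by the maximum; 1 for a rectangular pulse
========  =====================================================

Two ratios combine them for pellet gating: FWS maximum / FWS fill factor
(size times three-dimensional shape) and SWS total / sample length
(volume-like signal per unit length).  A saturated FWS maximum marks a dense
pellet core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .types import Channel, ParticleRecord, PulseShape

#: curve parameters computed per channel, in export order
PARAMETERS = ("maximum", "total", "length", "sample_length", "fill_factor")


@dataclass(frozen=True)
class ChannelFeatures:
    """The five curve parameters of one channel."""

    maximum: float
    total: float
    length: float
    sample_length: float
    fill_factor: float


def extract_curve_features(pulse: PulseShape, trigger_level: float = 0.0) -> ChannelFeatures:
    """Compute the five curve parameters of one pulse.

    "Above trigger" is strict (``value > trigger_level``); a pulse entirely at
    or below the trigger has sample_length 0 and fill_factor 0.
    """
    s = pulse.samples
    if s.size == 0:
        raise ValidationError("empty pulse")
    maximum = float(s.max())
    total = float(s.sum())
    length = s.size * pulse.um_per_sample

    above = s > trigger_level
    n_above = int(above.sum())
    if n_above == 0:
        return ChannelFeatures(maximum, total, length, 0.0, 0.0)
    idx = np.flatnonzero(above)
    envelope = int(idx[-1] - idx[0] + 1)  # contiguous, interior dips included
    sample_length = envelope * pulse.um_per_sample
    fill_factor = float(s[above].sum() / (maximum * n_above))
    return ChannelFeatures(maximum, total, length, sample_length, min(fill_factor, 1.0))


@dataclass(frozen=True)
class DerivedRatios:
    """Gating ratios; NaN flags an undefined ratio (zero denominator)."""

    fws_max_over_fill: float
    sws_total_over_sample_length: float
    fws_saturated: bool


def derive_ratios(
    fws: ChannelFeatures,
    sws: ChannelFeatures,
    saturation_level: float,
    sample_length: float | None = None,
) -> DerivedRatios:
    """Derive the pellet-gating ratios from FWS and SWS curve parameters.

    ``sample_length`` defaults to the SWS sample length (the size measure the
    gates consume); pass another channel's value to override.
    """
    if sample_length is None:
        sample_length = sws.sample_length
    fws_ratio = fws.maximum / fws.fill_factor if fws.fill_factor > 0 else float("nan")
    sws_ratio = sws.total / sample_length if sample_length > 0 else float("nan")
    return DerivedRatios(fws_ratio, sws_ratio, fws.maximum >= saturation_level)


def _channel_prefix(channel: Channel) -> str:
    return channel.value.lower()


def feature_row(
    record: ParticleRecord,
    trigger_level: float = 0.0,
    saturation_level: float | None = None,
) -> dict:
    """One flat feature dict for one particle (column per channel×parameter)."""
    row: dict = {"particle_id": record.particle_id, "acquisition_time": record.acquisition_time}
    per_channel: dict = {}
    for channel, pulse in record.pulses.items():
        feats = extract_curve_features(pulse, trigger_level)
        per_channel[channel] = feats
        prefix = _channel_prefix(channel)
        for name in PARAMETERS:
            row[f"{prefix}_{name}"] = getattr(feats, name)
    sat = saturation_level if saturation_level is not None else record[Channel.FWS].saturation_level
    ratios = derive_ratios(per_channel[Channel.FWS], per_channel[Channel.SWS], sat)
    row["fws_max_over_fill"] = ratios.fws_max_over_fill
    row["sws_total_over_sample_length"] = ratios.sws_total_over_sample_length
    row["fws_saturated"] = ratios.fws_saturated
    return row


#: columns always present in a feature table, in order
_BASE_COLUMNS = ["particle_id", "acquisition_time"]
_RATIO_COLUMNS = ["fws_max_over_fill", "sws_total_over_sample_length", "fws_saturated"]


def feature_table(
    records,
    trigger_level: float = 0.0,
    saturation_level: float | None = None,
) -> pd.DataFrame:
    """Feature table for a measurement run: one row per particle.

    Channels absent on a particle yield NaN in that channel's columns.
    """
    rows = [feature_row(r, trigger_level, saturation_level) for r in records]
    if not rows:
        columns = _BASE_COLUMNS + [
            f"{_channel_prefix(c)}_{p}" for c in (Channel.FWS, Channel.SWS) for p in PARAMETERS
        ] + _RATIO_COLUMNS
        return pd.DataFrame(columns=columns)
    df = pd.DataFrame(rows)
    ordered = _BASE_COLUMNS + [
        c for c in df.columns if c not in _BASE_COLUMNS + _RATIO_COLUMNS
    ] + _RATIO_COLUMNS
    return df[ordered]
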