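"""Core domain types.

A particle transiting the laser of a scanning flow cytometer produces one
sampled intensity curve ("pulse shape") per detection channel.  The spatial
calibration ``um_per_sample`` converts sample counts to micrometres; length
parameters are the method's primary size measure for hyphal elements.

Conventions used throughout the package:

* sample indices are 0-based;
* intervals over samples (core, envelope) are half-open ``[start, end)``;
* intensity values are arbitrary units, clipped at ``saturation_level``
  during acquisition (the forward-scatter channel saturates on dense pellet
  cores; by default at 1e4).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: Default forward-scatter saturation level (a.u.): dense pellet cores clip here.
DEFAULT_SATURATION = 1e4


class Channel(str, enum.Enum):
    """Detection channels of the cytometer."""

    FWS = "FWS"  # forward scatter: size / opacity
    SWS = "SWS"  # sideward scatter: surface and internal structure
    FL_GREEN = "FL_GREEN"  # fluorescein diacetate viability stain
    FL_ORANGE = "FL_ORANGE"
    FL_RED = "FL_RED"  # propidium iodide

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Channels that must be present on every particle.
MANDATORY_CHANNELS = (Channel.FWS, Channel.SWS)


class MorphClass(str, enum.Enum):
    """Morphological classes of hyphal elements.

    ``background`` are particles failing the viability prefilter (medium
    debris); ``unclassified`` are viable particles matching no gate.
    """

    BACKGROUND = "background"
    UNCLASSIFIED = "unclassified"
    HYPHAE = "hyphae"
    SMALL_CLUMP = "small_clump"
    LARGE_CLUMP = "large_clump"
    PELLET = "pellet"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The four biological classes, in gating-tree order.
BIOLOGICAL_CLASSES = (
    MorphClass.HYPHAE,
    MorphClass.SMALL_CLUMP,
    MorphClass.LARGE_CLUMP,
    MorphClass.PELLET,
)


@dataclass
class PulseShape:
    """One channel's sampled intensity curve for one particle.

    Parameters
    ----------
    channel
        Detection channel.
    samples
        Ordered non-negative intensities (a.u.), one per spatial sample.
    um_per_sample
        Spatial calibration, micrometres per sample; instrument-specific and
        therefore required metadata.
    saturation_level
        Clipping level of the detector (a.u.).
    """

    channel: Channel
    samples: np.ndarray
    um_per_sample: float
    saturation_level: float = DEFAULT_SATURATION

    def __post_init__(self) -> None:
        self.channel = Channel(self.channel)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValidationError(
                f"{self.channel} pulse must be a non-empty 1-D sequence"
            )
        if np.any(self.samples < 0):
            raise ValidationError(f"{self.channel} pulse has negative samples")
        if not self.um_per_sample > 0:
            raise ValidationError("um_per_sample must be positive")
        if not self.saturation_level > 0:
            raise ValidationError("saturation_level must be positive")
        if np.any(self.samples > self.saturation_level):
            raise ValidationError(
                f"{self.channel} pulse exceeds saturation_level "
                f"{self.saturation_level}; values are clipped at acquisition"
            )

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)


@dataclass
class ParticleRecord:
    """All pulse shapes of one particle plus its acquisition-time offset."""

    particle_id: str
    pulses: dict
    acquisition_time: float = 0.0

    def __post_init__(self) -> None:
        self.particle_id = str(self.particle_id)
        self.pulses = {Channel(k): v for k, v in self.pulses.items()}
        from .errors import MissingChannelError

        for ch in MANDATORY_CHANNELS:
            if ch not in self.pulses:
                raise MissingChannelError(self.particle_id, ch)
        cals = {p.um_per_sample for p in self.pulses.values()}
        if len(cals) != 1:
            raise ValidationError(
                f"particle {self.particle_id!r}: all pulses must share "
                f"um_per_sample, got {sorted(cals)}"
            )
        if self.acquisition_time < 0:
            raise ValidationError("acquisition_time must be non-negative")

    @property
    def um_per_sample(self) -> float:
        return next(iter(self.pulses.values())).um_per_sample

    def __getitem__(self, channel) -> PulseShape:
        return self.pulses[Channel(channel)]

    def __contains__(self, channel) -> bool:
        return Channel(channel) in self.pulses


@dataclass
class MeasurementMeta:
    """Acquisition metadata of one measurement run.

    ``pump_speed`` (μl/s) times ``duration`` (s) is the analyzed volume of the
    *diluted* sample; ``dilution_factor`` scales counts back to undiluted
    broth.  ``timepoint`` is process time in hours.
    """

    pump_speed: float = 15.0
    duration: float = 80.0
    dilution_factor: float = 1000.0
    sample_label: str = ""
    timepoint: float = 0.0

    def __post_init__(self) -> None:
        if not self.pump_speed > 0:
            raise ValidationError("pump_speed must be positive")
        if not self.duration > 0:
            raise ValidationError("duration must be positive")
        if not self.dilution_factor > 0:
            raise ValidationError("dilution_factor must be positive")

    @property
    def analyzed_volume_ul(self) -> float:
        """Volume of diluted sample passed through the laser (μl)."""
        return self.pump_speed * self.duration

    @property
    def analyzed_volume_ml(self) -> float:
        return self.analyzed_volume_ul / 1000.0
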