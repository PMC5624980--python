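"""Gating configuration.

All numeric thresholds of the morphological gating tree live here, with the
published defaults for *Penicillium chrysogenum*, and can be overridden from a
YAML file so the method transfers to other strains/instruments.

The decision tree (see :mod:`pulsemorph.gating`):

1. viability prefilter — total green fluorescence (fluorescein diacetate)
   strictly above ``green_fl_total_min`` separates hyphal elements from
   medium background;
2. small vs large elements — SWS total and sample length;
3. large elements — pellet if *all* pellet rules hold (dense core saturates
   the forward scatter), else large clump;
4. small elements — small clump gate first, then hyphae rules, then
   ``fallback_small``.

All inequalities are strict ("higher than" / "below"); a value exactly on a
threshold falls on the complementary side.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional, Sequence

import yaml

from .errors import ConfigError
from .types import DEFAULT_SATURATION


@dataclass
class Interval:
    """Open interval (lo, hi); membership is strict on both sides."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ConfigError(f"interval bounds inverted: ({self.lo}, {self.hi})")

    def contains(self, x) -> bool | object:
        return (x > self.lo) & (x < self.hi)


@dataclass
class GatingConfig:
    """Thresholds of the hierarchical morphological gates.

    Defaults are the published values: pellets need SWS total > 4e4 a.u.,
    sample length > 120 μm, a saturated FWS maximum, FWS maximum / FWS fill
    factor > 7.5e3 and SWS total / sample length > 8e2 a.u./μm.
    """

    # viability prefilter (a.u. of FL_GREEN total)
    green_fl_total_min: float = 30.0
    require_fl: bool = True

    # step 1: large elements = SWS total > AND sample length > (rectangle)
    large_sws_total_min: float = 2e4
    large_sample_length_min: float = 100.0  # μm

    # hyphae rules (small elements)
    hyphae_sample_length: Interval = field(default_factory=lambda: Interval(10.0, 150.0))
    hyphae_sws_total_max: float = 4e4
    hyphae_fws_length_max: float = 190.0  # μm

    # small-clump rules (small elements; takes precedence over hyphae)
    small_clump_sample_length: Interval = field(
        default_factory=lambda: Interval(10.0, 150.0)
    )
    small_clump_sws_total: Interval = field(default_factory=lambda: Interval(1.8e4, 9e4))
    small_clump_fws_length_min: float = 18.0  # μm
    #: optional polygon (FWS length μm, SWS total a.u.) overriding the rectangle
    small_clump_polygon: Optional[Sequence] = None

    # pellet rules (large elements)
    pellet_sws_total_min: float = 4e4
    pellet_sample_length_min: float = 120.0  # μm
    pellet_fws_max_over_fill_min: float = 7.5e3
    pellet_sws_total_over_sample_length_min: float = 8e2  # a.u./μm

    # small elements matching neither gate
    fallback_small: str = "unclassified"  # or "hyphae"

    # feature extraction
    trigger_level: float = 0.0
    saturation_level: float = DEFAULT_SATURATION
    #: channel whose sample length feeds the size gates
    sample_length_channel: str = "SWS"

    def __post_init__(self) -> None:
        for name in (
            "green_fl_total_min",
            "large_sws_total_min",
            "large_sample_length_min",
            "hyphae_sws_total_max",
            "hyphae_fws_length_max",
            "small_clump_fws_length_min",
            "pellet_sws_total_min",
            "pellet_sample_length_min",
            "pellet_fws_max_over_fill_min",
            "pellet_sws_total_over_sample_length_min",
            "saturation_level",
        ):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be strictly positive")
        if self.trigger_level < 0:
            raise ConfigError("trigger_level must be non-negative")
        if self.fallback_small not in ("unclassified", "hyphae"):
            raise ConfigError(
                f"fallback_small must be 'unclassified' or 'hyphae', "
                f"got {self.fallback_small!r}"
            )
        # the pellet gate must be a subset of the large-element gate, else the
        # tree could route a pellet-qualifying particle to the small branch
        if self.pellet_sws_total_min < self.large_sws_total_min:
            raise ConfigError("pellet SWS-total threshold below large-element gate")
        if self.pellet_sample_length_min < self.large_sample_length_min:
            raise ConfigError("pellet sample-length threshold below large-element gate")
        if self.small_clump_polygon is not None:
            poly = [(float(x), float(y)) for x, y in self.small_clump_polygon]
            if len(poly) < 3:
                raise ConfigError("small_clump_polygon needs at least 3 vertices")
            self.small_clump_polygon = poly

    # ------------------------------------------------------------------ I/O
    _INTERVAL_FIELDS = ("hyphae_sample_length", "small_clump_sample_length", "small_clump_sws_total")

    @classmethod
    def from_dict(cls, data: dict) -> "GatingConfig":
        data = dict(data or {})
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown gating config keys: {sorted(unknown)}")
        for name in cls._INTERVAL_FIELDS:
            if name in data and not isinstance(data[name], Interval):
                try:
                    lo, hi = data[name]
                except (TypeError, ValueError) as exc:
                    raise ConfigError(f"{name} must be a [lo, hi] pair") from exc
                data[name] = Interval(float(lo), float(hi))
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "GatingConfig":
        with open(path, "r", encoding="utf-8") as fh:
            try:
                data = yaml.safe_load(fh)
            except yaml.YAMLError as exc:
                raise ConfigError(f"malformed gating config {path}: {exc}") from exc
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError(f"gating config {path} must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        data = asdict(self)
        for name in self._INTERVAL_FIELDS:
            iv = data[name]
            data[name] = [iv["lo"], iv["hi"]]
        return data

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def replace(self, **kwargs) -> "GatingConfig":
        return replace(self, **kwargs)


def load_gating_config(path=None) -> GatingConfig:
    """Load a gating configuration, or the published defaults if ``path`` is None."""
    if path is None:
        return GatingConfig()
    return GatingConfig.from_yaml(path)
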