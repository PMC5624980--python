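"""Pellet core/annulus descriptors from the forward-scatter pulse shape.

A pellet's dense core saturates the forward-scatter (FWS) detector while the
loose "hairy" annular region does not.  Walking inward from both ends of the
above-trigger FWS signal until the first saturated sample yields the two
annular flanks; the stretch between the first and the last saturated sample
is the core (interior unsaturated dips — degraded, vacuolized core regions —
belong to the core, not to the annulus, until the pellet actually breaks
there).

Two descriptors follow:

* relative annular diameter ``RAD = annular diameter / particle length``,
  the annulus's share of the pellet diameter (0 for a fully saturated
  pulse, < 1 always);
* core compactness = fraction of the core interval at saturation, a density
  measure that drops with vacuolization and lysis.

Particle length is the above-trigger envelope of the FWS signal, so both
descriptors are invariant to sub-trigger padding around the pulse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .types import Channel, PulseShape


@dataclass(frozen=True)
class CoreDetection:
    """Sample-unit geometry of a pellet pulse (half-open intervals)."""

    envelope: tuple[int, int]  # above-trigger signal [start, end)
    core: tuple[int, int]  # [first saturated, last saturated + 1)
    left_flank: int  # samples
    right_flank: int  # samples


@dataclass(frozen=True)
class PelletMetrics:
    """Pellet descriptors in micrometres (lengths) and ratios."""

    particle_length: float
    annular_diameter: float
    core_diameter: float
    rad: float
    compactness: float


def detect_core(
    fws: PulseShape, trigger_level: float = 0.0, saturation_tol: float = 0.0
) -> CoreDetection:
    """Locate the saturated core and the annular flanks of a pellet FWS pulse.

    A sample is saturated iff ``value >= saturation_level - saturation_tol``
    (values are clipped at acquisition, so the default tolerance is 0).
    Raises :class:`ValidationError` if no sample saturates — only particles
    gated as pellets have a core by definition.
    """
    s = fws.samples
    above = np.flatnonzero(s > trigger_level)
    if above.size == 0:
        raise ValidationError("pulse entirely at or below trigger level")
    env = (int(above[0]), int(above[-1]) + 1)

    sat = np.flatnonzero(s >= fws.saturation_level - saturation_tol)
    if sat.size == 0:
        raise ValidationError(
            "no saturated FWS sample: particle has no detectable core "
            "(pellet metrics are defined for gated pellets only)"
        )
    core = (int(sat[0]), int(sat[-1]) + 1)
    return CoreDetection(
        envelope=env,
        core=core,
        left_flank=core[0] - env[0],
        right_flank=env[1] - core[1],
    )


def pellet_metrics(
    fws: PulseShape, trigger_level: float = 0.0, saturation_tol: float = 0.0
) -> PelletMetrics:
    """RAD and core compactness of one pellet FWS pulse."""
    det = detect_core(fws, trigger_level, saturation_tol)
    ums = fws.um_per_sample
    n_env = det.envelope[1] - det.envelope[0]
    n_core = det.core[1] - det.core[0]
    n_flanks = det.left_flank + det.right_flank

    core_slice = fws.samples[det.core[0] : det.core[1]]
    n_sat = int(np.count_nonzero(core_slice >= fws.saturation_level - saturation_tol))

    return PelletMetrics(
        particle_length=n_env * ums,
        annular_diameter=n_flanks * ums,
        core_diameter=n_core * ums,
        rad=n_flanks / n_env,
        compactness=n_sat / n_core,
    )


def compute_rad(fws: PulseShape, trigger_level: float = 0.0, saturation_tol: float = 0.0) -> float:
    """Relative annular diameter: annular diameter / particle length."""
    return pellet_metrics(fws, trigger_level, saturation_tol).rad


def compute_compactness(
    fws: PulseShape, trigger_level: float = 0.0, saturation_tol: float = 0.0
) -> float:
    """Core compactness: saturated fraction of the core interval."""
    return pellet_metrics(fws, trigger_level, saturation_tol).compactness


def pellet_metrics_table(
    records,
    classes: pd.Series | None = None,
    trigger_level: float = 0.0,
    saturation_tol: float = 0.0,
) -> pd.DataFrame:
    """Pellet descriptor table for all pellet-classified particles of a run.

    ``classes`` maps particle_id → class label (strings); if given, only
    particles labelled ``"pellet"`` are measured, otherwise every record is
    assumed to be a pellet.
    """
    rows = []
    for rec in records:
        if classes is not None and classes.get(rec.particle_id) != "pellet":
            continue
        m = pellet_metrics(rec[Channel.FWS], trigger_level, saturation_tol)
        rows.append(
            {
                "particle_id": rec.particle_id,
                "particle_length": m.particle_length,
                "annular_diameter": m.annular_diameter,
                "core_diameter": m.core_diameter,
                "rad": m.rad,
                "compactness": m.compactness,
            }
        )
    columns = [
        "particle_id",
        "particle_length",
        "annular_diameter",
        "core_diameter",
        "rad",
        "compactness",
    ]
    return pd.DataFrame(rows, columns=columns)
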