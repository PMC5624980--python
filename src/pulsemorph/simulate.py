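"""Synthetic pulse-shape data with ground truth.

Instrument list-mode data cannot be redistributed, so the package ships a
phenomenological generator that emulates the pulse shapes of the four
morphological classes plus medium background:

* every channel's pulse is a smooth hump (half-sine) over the particle's
  transit, scaled to a class-specific target, padded with sub-trigger zeros;
* pellets get the characteristic trapezoid on the forward scatter: two
  unsaturated annular ramps flanking a core plateau generated *above* the
  saturation level and clipped down to it, optionally with an interior
  unsaturated dip emulating a degraded (vacuolized) core;
* the viability stain is a green-fluorescence pulse whose total is far above
  the gating threshold for biological classes and below it for background;
* multiplicative log-normal noise is applied before saturation clipping, so
  pellet plateaus sit exactly at the saturation level, as in acquisition.

Ground truth (class, sample-unit geometry: envelope length, annular
fraction, saturated core fraction) is stored alongside each particle so the
analyzers' recovery can be checked to within one sample width.

The default class priors place every particle at least 10% (relative)
inside its gate; :func:`SimParams.validate_against` checks this against a
gating configuration and rejects incompatible priors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .config import GatingConfig
from .errors import ConfigError
from .micromorph import BinaryMask
from .types import (
    Channel,
    DEFAULT_SATURATION,
    MeasurementMeta,
    MorphClass,
    ParticleRecord,
    PulseShape,
)

SIM_CLASSES = ("hyphae", "small_clump", "large_clump", "pellet", "background")


@dataclass
class ClassPrior:
    """Geometry prior of one simulated class (uniform ranges).

    ``sample_length_um`` is the above-trigger extent of the SWS (and FWS)
    pulse.  Non-pellet classes draw ``sws_total`` (a.u.) and a forward-
    scatter peak; pellets instead draw SWS total *per μm* of sample length
    (their gate thresholds the ratio), a true annular fraction (→ RAD) and
    a degraded-core dip (→ compactness).
    """

    sample_length_um: tuple[float, float]
    sws_total: tuple[float, float] | None = None
    fws_peak: tuple[float, float] | None = None
    sws_total_per_um: tuple[float, float] | None = None
    annular_fraction: tuple[float, float] = (0.15, 0.45)
    dip_probability: float = 0.0
    dip_fraction: tuple[float, float] = (0.1, 0.5)


def _default_priors() -> dict:
    return {
        # small elements: sample length well inside (10, 150) μm and below
        # the 100 μm large-element boundary; hyphae SWS total below the
        # small-clump interval, small clumps inside (1.8e4, 9e4)
        "hyphae": ClassPrior((20, 80), sws_total=(2e3, 1.4e4), fws_peak=(200, 800)),
        "small_clump": ClassPrior((30, 90), sws_total=(2.2e4, 7.2e4), fws_peak=(1e3, 3e3)),
        # large elements: sample length above 110 μm; large clumps stay below
        # the pellet SWS-total threshold and never saturate the FWS
        "large_clump": ClassPrior((130, 250), sws_total=(2.4e4, 3.6e4), fws_peak=(3e3, 8e3)),
        # pellets: SWS total/sample length well above 8e2 a.u./μm
        "pellet": ClassPrior(
            (150, 350),
            sws_total_per_um=(1000, 1500),
            annular_fraction=(0.15, 0.45),
            dip_probability=0.3,
            dip_fraction=(0.1, 0.5),
        ),
        "background": ClassPrior((6, 40), sws_total=(50, 5e3), fws_peak=(50, 200)),
    }


def _default_mixture() -> dict:
    # a mid-fed-batch population: dispersed forms dominate counts
    return {
        "hyphae": 0.45,
        "small_clump": 0.25,
        "large_clump": 0.15,
        "pellet": 0.10,
        "background": 0.05,
    }


@dataclass
class SimParams:
    """All knobs of the generator."""

    n: int = 1000
    seed: int = 0
    class_mixture: dict = field(default_factory=_default_mixture)
    priors: dict = field(default_factory=_default_priors)
    um_per_sample: float = 2.0
    saturation_level: float = DEFAULT_SATURATION
    pad_samples: int = 2  # sub-trigger zeros appended at each end
    noise_sigma: float = 0.05  # multiplicative log-normal, pre-clipping
    baseline: float = 0.0  # additive floor (a.u.)
    fl_green_viable: tuple[float, float] = (100.0, 1000.0)
    fl_green_background: tuple[float, float] = (1.0, 20.0)
    meta: MeasurementMeta = field(default_factory=MeasurementMeta)

    def __post_init__(self) -> None:
        probs = np.array(list(self.class_mixture.values()), float)
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ConfigError("class_mixture probabilities must be >= 0 and sum to 1")
        unknown = set(self.class_mixture) - set(SIM_CLASSES)
        if unknown:
            raise ConfigError(f"unknown simulated classes: {sorted(unknown)}")
        if self.n < 0:
            raise ConfigError("n must be non-negative")
        if not self.um_per_sample > 0:
            raise ConfigError("um_per_sample must be positive")

    def replace(self, **kwargs) -> "SimParams":
        return replace(self, **kwargs)

    # ------------------------------------------------------------------
    def validate_against(self, config: GatingConfig, margin: float = 0.1) -> None:
        """Reject priors that are not at least ``margin`` inside their gates."""

        def above(lo, threshold, what):
            if not lo >= threshold * (1 + margin):
                raise ConfigError(f"{what}: prior low {lo} not {margin:.0%} above {threshold}")

        def below(hi, threshold, what):
            if not hi <= threshold * (1 - margin):
                raise ConfigError(f"{what}: prior high {hi} not {margin:.0%} below {threshold}")

        p = self.priors
        h, sc, lc, pe = p["hyphae"], p["small_clump"], p["large_clump"], p["pellet"]
        above(h.sample_length_um[0], config.hyphae_sample_length.lo, "hyphae length")
        below(h.sample_length_um[1], config.large_sample_length_min, "hyphae length")
        below(h.sws_total[1], config.small_clump_sws_total.lo, "hyphae SWS total")
        above(sc.sample_length_um[0], config.small_clump_sample_length.lo, "small-clump length")
        below(sc.sample_length_um[1], config.large_sample_length_min, "small-clump length")
        above(sc.sws_total[0], config.small_clump_sws_total.lo, "small-clump SWS total")
        below(sc.sws_total[1], config.small_clump_sws_total.hi, "small-clump SWS total")
        above(lc.sample_length_um[0], config.large_sample_length_min, "large-clump length")
        above(lc.sws_total[0], config.large_sws_total_min, "large-clump SWS total")
        below(lc.sws_total[1], config.pellet_sws_total_min, "large-clump SWS total")
        below(lc.fws_peak[1], config.saturation_level, "large-clump FWS peak")
        above(pe.sample_length_um[0], config.pellet_sample_length_min, "pellet length")
        above(
            pe.sws_total_per_um[0],
            config.pellet_sws_total_over_sample_length_min,
            "pellet SWS total per μm",
        )


# --------------------------------------------------------------------------
# pulse builders
# --------------------------------------------------------------------------

def _hump(n: int) -> np.ndarray:
    """Strictly positive half-sine envelope over n samples."""
    return np.sin(np.pi * (np.arange(n) + 0.5) / n)


def _noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return np.ones(shape)
    return rng.lognormal(mean=0.0, sigma=sigma, size=shape)


def _finish(samples: np.ndarray, params: SimParams) -> np.ndarray:
    """Add baseline, pad with sub-trigger zeros, clip at saturation."""
    s = samples + params.baseline
    pad = np.zeros(params.pad_samples)
    return np.clip(np.concatenate([pad, s, pad]), 0.0, params.saturation_level)


def _pellet_fws(
    n_env: int, prior: ClassPrior, params: SimParams, rng: np.random.Generator
):
    """Trapezoidal pellet FWS pulse; returns (samples, rad, compactness)."""
    sat = params.saturation_level
    a = rng.uniform(*prior.annular_fraction)
    n_flank = int(round(a * n_env))
    n_flank = min(max(n_flank, 0), n_env - 1)  # keep >= 1 core sample
    f_l, f_r = n_flank // 2, n_flank - n_flank // 2
    n_core = n_env - n_flank

    # core generated above saturation, clipped down to it later
    core = np.full(n_core, 1.3 * sat)
    n_dip = 0
    if n_core > 2 and rng.uniform() < prior.dip_probability:
        n_dip = int(round(rng.uniform(*prior.dip_fraction) * n_core))
        n_dip = min(n_dip, n_core - 2)
        if n_dip > 0:
            start = (n_core - n_dip) // 2
            start = max(start, 1)
            core[start : start + n_dip] = 0.5 * sat

    left = np.linspace(0.1 * sat, 0.9 * sat, f_l, endpoint=False) if f_l else np.empty(0)
    right = (
        np.linspace(0.9 * sat, 0.1 * sat, f_r)
        if f_r
        else np.empty(0)
    )
    samples = np.concatenate([left, core, right]) * _noise(rng, n_env, params.noise_sigma)
    # the annulus and the dip are unsaturated by construction; the core
    # plateau stays above saturation whatever the noise drew
    unsat = np.ones(n_env, bool)
    unsat[f_l : f_l + n_core] = False
    samples[unsat] = np.minimum(samples[unsat], 0.995 * sat)
    plateau = np.zeros(n_env, bool)
    plateau[f_l : f_l + n_core] = True
    if n_dip:
        keep = np.zeros(n_core, bool)
        keep[start : start + n_dip] = True
        samples_pl = samples[plateau]
        samples_pl[~keep] = np.maximum(samples_pl[~keep], sat)
        samples_pl[keep] = np.minimum(samples_pl[keep], 0.995 * sat)
        samples[plateau] = samples_pl
    else:
        samples[plateau] = np.maximum(samples[plateau], sat)

    rad = n_flank / n_env
    compactness = (n_core - n_dip) / n_core
    return samples, rad, compactness


def simulate_particle(
    cls: str, params: SimParams, rng: np.random.Generator, particle_id: str = "p0",
    acquisition_time: float = 0.0,
):
    """Draw one particle of class ``cls``; returns ``(record, truth)``.

    ``truth`` holds the class and the generator's geometry in sample units,
    so analyzer recovery bounds are exact: ``true_rad`` and
    ``true_compactness`` are NaN for non-pellets.
    """
    if cls not in SIM_CLASSES:
        raise ConfigError(f"unknown class {cls!r}")
    prior: ClassPrior = params.priors[cls]
    ums = params.um_per_sample
    sat = params.saturation_level

    sl_um = rng.uniform(*prior.sample_length_um)
    n_env = max(int(round(sl_um / ums)), 3)

    # SWS: hump scaled to the class's target total
    if cls == "pellet":
        target_total = (n_env * ums) * rng.uniform(*prior.sws_total_per_um)
    else:
        target_total = rng.uniform(*prior.sws_total)
    shape = _hump(n_env)
    sws = shape * (target_total / shape.sum())
    sws = np.minimum(sws * _noise(rng, n_env, params.noise_sigma), 0.995 * sat)

    true_rad = true_comp = float("nan")
    if cls == "pellet":
        fws, true_rad, true_comp = _pellet_fws(n_env, prior, params, rng)
    else:
        peak = rng.uniform(*prior.fws_peak)
        fws = np.minimum(_hump(n_env) * peak * _noise(rng, n_env, params.noise_sigma), 0.995 * sat)

    # viability stain: short green-fluorescence pulse
    fl_range = params.fl_green_background if cls == "background" else params.fl_green_viable
    n_fl = min(n_env, 10)
    fl_shape = _hump(n_fl)
    fl = fl_shape * (rng.uniform(*fl_range) / fl_shape.sum())

    pulses = {
        Channel.FWS: PulseShape(Channel.FWS, _finish(fws, params), ums, sat),
        Channel.SWS: PulseShape(Channel.SWS, _finish(sws, params), ums, sat),
        Channel.FL_GREEN: PulseShape(Channel.FL_GREEN, _finish(fl, params), ums, sat),
    }
    record = ParticleRecord(particle_id, pulses, acquisition_time)
    truth = {
        "particle_id": particle_id,
        "true_class": cls,
        "true_sample_length": n_env * ums,
        "true_rad": true_rad,
        "true_compactness": true_comp,
    }
    return record, truth


def simulate_run(params: SimParams):
    """Generate a full measurement run.

    Returns ``(records, truth, meta)`` where ``truth`` is a DataFrame with
    one row per particle.  Reproducible: the same ``params.seed`` yields a
    bit-identical dataset.
    """
    rng = np.random.default_rng(params.seed)
    names = list(params.class_mixture)
    probs = np.array([params.class_mixture[c] for c in names], float)
    classes = rng.choice(names, size=params.n, p=probs / probs.sum())

    records, truths = [], []
    duration = params.meta.duration
    for i, cls in enumerate(classes):
        t = (i + 0.5) / max(params.n, 1) * duration
        rec, truth = simulate_particle(cls, params, rng, particle_id=f"p{i:06d}",
                                       acquisition_time=t)
        records.append(rec)
        truths.append(truth)
    truth_df = pd.DataFrame(
        truths,
        columns=["particle_id", "true_class", "true_sample_length", "true_rad", "true_compactness"],
    )
    return records, truth_df, params.meta


# --------------------------------------------------------------------------
# time courses
# --------------------------------------------------------------------------

@dataclass
class Scenario:
    """A schedule of class mixtures over process time (hours)."""

    name: str
    timepoints: Sequence[float]
    mixtures: Sequence[dict]

    def __post_init__(self) -> None:
        if len(self.timepoints) != len(self.mixtures):
            raise ConfigError("timepoints and mixtures must have equal length")


def simulate_timecourse(scenario: Scenario, base_params: SimParams):
    """Simulate one dataset per scheduled timepoint.

    Per-timepoint seeds derive deterministically from the base seed.
    Returns a list of ``(records, truth, meta)`` tuples.
    """
    runs = []
    for i, (t, mixture) in enumerate(zip(scenario.timepoints, scenario.mixtures)):
        meta = replace(base_params.meta, timepoint=float(t), sample_label=scenario.name)
        p = base_params.replace(
            class_mixture=mixture,
            seed=(base_params.seed * 1000 + i) % (2**31 - 1),
            meta=meta,
        )
        runs.append(simulate_run(p))
    return runs


def drifting_pellet_scenario(
    name: str,
    timepoints: Sequence[float],
    pellet_start: float = 0.25,
    pellet_end: float = 0.25,
    background: float = 0.05,
) -> Scenario:
    """Mixture schedule with the pellet weight moving linearly start → end.

    The non-pellet biological weight is shared among hyphae, small and large
    clumps in fixed proportions (0.5 / 0.3 / 0.2), emulating pellet decline
    in favour of dispersed growth under a constant low feed.
    """
    tps = list(timepoints)
    mixtures = []
    for i, _ in enumerate(tps):
        frac = i / max(len(tps) - 1, 1)
        pellet = pellet_start + (pellet_end - pellet_start) * frac
        rest = 1.0 - background - pellet
        mixtures.append(
            {
                "hyphae": 0.5 * rest,
                "small_clump": 0.3 * rest,
                "large_clump": 0.2 * rest,
                "pellet": pellet,
                "background": background,
            }
        )
    return Scenario(name, tps, mixtures)


# --------------------------------------------------------------------------
# microscopy fixtures
# --------------------------------------------------------------------------

def simulate_pellet_mask(
    radius_core: int,
    hair_count: int,
    hair_length: int,
    rng: np.random.Generator,
    um_per_px: float = 1.0,
    hair_width: int = 1,
) -> tuple[BinaryMask, dict]:
    """A "hairy" pellet mask: a solid disk with radial hair lines.

    Returns the mask and a truth dict with the pixel/μm² area and the
    area-threshold microscopy class it implies (assuming a full dark core).
    """
    from skimage import draw, morphology as skmorph

    size = 2 * (radius_core + hair_length) + 9
    c = size // 2
    mask = np.zeros((size, size), bool)
    rr, cc = draw.disk((c, c), radius_core, shape=mask.shape)
    mask[rr, cc] = True
    hairs = np.zeros_like(mask)
    for _ in range(hair_count):
        theta = rng.uniform(0, 2 * np.pi)
        r0 = radius_core - 1
        r1 = radius_core + hair_length
        y0, x0 = c + r0 * np.sin(theta), c + r0 * np.cos(theta)
        y1, x1 = c + r1 * np.sin(theta), c + r1 * np.cos(theta)
        rr, cc = draw.line(int(y0), int(x0), int(y1), int(x1))
        keep = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
        hairs[rr[keep], cc[keep]] = True
    if hair_width > 1:
        hairs = skmorph.binary_dilation(hairs, skmorph.disk(hair_width // 2))
    mask |= hairs

    area_um2 = float(mask.sum()) * um_per_px**2
    core_area_um2 = float(np.pi * radius_core**2) * um_per_px**2
    from .micromorph import (
        LARGE_CLUMP_AREA_MIN,
        HYPHAE_AREA_MIN,
        PELLET_AREA_MIN,
        PELLET_CORE_AREA_MIN,
    )

    if area_um2 > PELLET_AREA_MIN and core_area_um2 > PELLET_CORE_AREA_MIN:
        cls = MorphClass.PELLET
    elif area_um2 > LARGE_CLUMP_AREA_MIN:
        cls = MorphClass.LARGE_CLUMP
    elif area_um2 > HYPHAE_AREA_MIN:
        cls = MorphClass.HYPHAE
    else:
        cls = MorphClass.UNCLASSIFIED
    truth = {"area_um2": area_um2, "core_area_um2": core_area_um2, "area_class": str(cls)}
    return BinaryMask(mask, um_per_px), truth
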