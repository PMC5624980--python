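"""Run-level aggregation: concentrations, SWS fractions, size distributions,
time courses and replicate errors.

Concentrations convert class counts to elements per millilitre of undiluted
broth: ``count / (pump_speed × duration) × dilution_factor``.  The SWS
fraction is a biomass-volume-weighted alternative to counts — each class's
share of the summed sideward-scatter total signal, in percent — which
represents the distribution of fungal biomass better than raw counts, since
one pellet holds orders of magnitude more volume than one hypha.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .types import BIOLOGICAL_CLASSES, MeasurementMeta, MorphClass

#: named unions of classes used for size distributions
CLASS_UNIONS = {
    "hyphal_aggregates": ("small_clump", "large_clump", "pellet"),
    "large_elements": ("large_clump", "pellet"),
}

_CLASS_NAMES = tuple(str(c) for c in BIOLOGICAL_CLASSES)


def sws_fraction(
    table: pd.DataFrame,
    class_column: str = "morph_class",
    include_unclassified: bool = False,
) -> pd.Series:
    """Per-class share of the summed SWS total signal, in percent.

    The denominator runs over all classified viable elements (the four
    biological classes); set ``include_unclassified=True`` to include
    unclassified viable particles in the denominator.  Classes absent from
    the sample report 0.  Fractions over the four classes sum to 100 when
    every viable particle is classified.
    """
    keep = list(_CLASS_NAMES)
    if include_unclassified:
        keep.append(str(MorphClass.UNCLASSIFIED))
    sub = table[table[class_column].isin(keep)]
    denom = sub["sws_total"].sum()
    if not denom > 0:
        raise ValidationError("all SWS totals are zero; SWS fraction undefined")
    sums = sub.groupby(class_column)["sws_total"].sum()
    return pd.Series(
        {c: float(sums.get(c, 0.0)) / denom * 100.0 for c in _CLASS_NAMES},
        name="sws_fraction",
    )


def concentrations(counts: Mapping[str, int], meta: MeasurementMeta) -> dict[str, float]:
    """Class counts → elements per ml of undiluted broth.

    ``concentration = count / analyzed_volume_ml × dilution_factor``; linear
    in both the count and the dilution factor.
    """
    vol_ml = meta.analyzed_volume_ml
    return {cls: n / vol_ml * meta.dilution_factor for cls, n in counts.items()}


def pooled_concentrations(
    replicates: Sequence[tuple[Mapping[str, int], MeasurementMeta]],
) -> pd.DataFrame:
    """Pool replicate measurements of one sample.

    The point estimate is the volume-weighted mean concentration (equivalent
    to pooling counts over the total analyzed volume); the SD is the
    between-replicate standard deviation of the per-replicate concentrations.
    """
    if not replicates:
        raise ValidationError("no replicates given")
    classes = sorted({c for counts, _ in replicates for c in counts})
    rows = []
    for cls in classes:
        per_rep = np.array([concentrations(cnt, m).get(cls, 0.0) for cnt, m in replicates])
        vols = np.array([m.analyzed_volume_ml for _, m in replicates])
        mean = float(np.average(per_rep, weights=vols))
        sd = float(per_rep.std(ddof=1)) if len(per_rep) > 1 else float("nan")
        rows.append({"class": cls, "concentration_per_ml": mean, "sd": sd, "n_replicates": len(per_rep)})
    return pd.DataFrame(rows)


def size_distribution(
    lengths: Sequence[float],
    bin_edges: Sequence[float] | None = None,
    n_bins: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Relative size histogram of element lengths (μm).

    Default binning: ``n_bins`` equal-width bins from 0 to the 99.5th
    percentile (pass explicit ``bin_edges`` for cross-run comparability).
    Frequencies sum to 1 for non-empty input; empty input yields an empty
    histogram.
    """
    lengths = np.asarray(lengths, float)
    if lengths.size and np.any(lengths < 0):
        raise ValidationError("lengths must be non-negative")
    if lengths.size == 0:
        edges = np.asarray(bin_edges, float) if bin_edges is not None else np.array([])
        return edges, np.zeros(max(len(edges) - 1, 0))
    if bin_edges is None:
        hi = float(np.percentile(lengths, 99.5))
        if hi <= 0:
            hi = float(lengths.max()) or 1.0
        bin_edges = np.linspace(0.0, hi, n_bins + 1)
    counts, edges = np.histogram(lengths, bins=np.asarray(bin_edges, float))
    total = counts.sum()
    freqs = counts / total if total > 0 else counts.astype(float)
    return edges, freqs


def class_lengths(
    table: pd.DataFrame,
    classes: Sequence[str] | str,
    length_column: str = "sws_sample_length",
    class_column: str = "morph_class",
) -> np.ndarray:
    """Lengths of particles in a class or named class union.

    ``classes`` may be a class name, a union name from :data:`CLASS_UNIONS`
    ("hyphal_aggregates" = small + large clumps + pellets, "large_elements"
    = large clumps + pellets), or an explicit sequence of class names.
    """
    if isinstance(classes, str):
        classes = CLASS_UNIONS.get(classes, (classes,))
    mask = table[class_column].isin(list(classes))
    return table.loc[mask, length_column].to_numpy(float)


@dataclass
class ClassSummary:
    """Aggregated description of one measurement run."""

    meta: MeasurementMeta
    counts: dict[str, int]
    concentration: dict[str, float]
    sws_fraction: dict[str, float]
    size_histograms: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    mean_length: dict[str, float] = field(default_factory=dict)
    sd_length: dict[str, float] = field(default_factory=dict)
    mean_rad: float = float("nan")
    mean_compactness: float = float("nan")


def summarize_run(
    table: pd.DataFrame,
    meta: MeasurementMeta,
    pellet_table: pd.DataFrame | None = None,
    length_column: str = "sws_sample_length",
    class_column: str = "morph_class",
    bin_edges: Sequence[float] | None = None,
) -> ClassSummary:
    """Build the per-run :class:`ClassSummary` from a classified feature table."""
    counts = {c: int((table[class_column] == c).sum()) for c in _CLASS_NAMES}
    conc = concentrations(counts, meta)
    try:
        fractions = sws_fraction(table, class_column).to_dict()
    except ValidationError:
        fractions = {c: float("nan") for c in _CLASS_NAMES}

    hists, mean_l, sd_l = {}, {}, {}
    for name in list(_CLASS_NAMES) + list(CLASS_UNIONS):
        lengths = class_lengths(table, name, length_column, class_column)
        hists[name] = size_distribution(lengths, bin_edges)
        mean_l[name] = float(lengths.mean()) if lengths.size else float("nan")
        sd_l[name] = float(lengths.std(ddof=1)) if lengths.size > 1 else float("nan")

    mean_rad = mean_comp = float("nan")
    if pellet_table is not None and len(pellet_table):
        mean_rad = float(pellet_table["rad"].mean())
        mean_comp = float(pellet_table["compactness"].mean())

    return ClassSummary(
        meta=meta,
        counts=counts,
        concentration=conc,
        sws_fraction=fractions,
        size_histograms=hists,
        mean_length=mean_l,
        sd_length=sd_l,
        mean_rad=mean_rad,
        mean_compactness=mean_comp,
    )


def timecourse(summaries: Sequence[ClassSummary]) -> pd.DataFrame:
    """Tidy long table of per-class quantities over process time.

    One row per (timepoint, class) with concentration, SWS fraction, count
    and mean ± SD length; pellet descriptors (mean rad/compactness) repeat on
    each class row of a timepoint.
    """
    rows = []
    for s in summaries:
        for cls in _CLASS_NAMES:
            rows.append(
                {
                    "timepoint": s.meta.timepoint,
                    "sample_label": s.meta.sample_label,
                    "class": cls,
                    "count": s.counts.get(cls, 0),
                    "concentration_per_ml": s.concentration.get(cls, 0.0),
                    "sws_fraction_pct": s.sws_fraction.get(cls, float("nan")),
                    "mean_length_um": s.mean_length.get(cls, float("nan")),
                    "sd_length_um": s.sd_length.get(cls, float("nan")),
                    "mean_rad": s.mean_rad,
                    "mean_compactness": s.mean_compactness,
                }
            )
    columns = [
        "timepoint",
        "sample_label",
        "class",
        "count",
        "concentration_per_ml",
        "sws_fraction_pct",
        "mean_length_um",
        "sd_length_um",
        "mean_rad",
        "mean_compactness",
    ]
    return pd.DataFrame(rows, columns=columns)


def replicate_error(replicates: pd.DataFrame) -> pd.DataFrame:
    """Measurement error from repeated measurements of one sample.

    ``replicates`` has one row per replicate and one column per parameter.
    Returns mean, sample SD (ddof=1) and %CV = SD/mean×100 per parameter;
    the %CV is scale-invariant.  At least two replicates are required.
    """
    if len(replicates) < 2:
        raise ValidationError("replicate_error needs at least 2 replicates")
    mean = replicates.mean()
    sd = replicates.std(ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean.abs() * 100.0
    return pd.DataFrame({"mean": mean, "sd": sd, "cv_pct": cv})
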