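"""Hierarchical morphological gating and cluster-assisted gate refinement.

Every viable particle (green-fluorescence total above the viability
threshold) is assigned to exactly one of hyphae, small clumps, large clumps
or pellets by a fixed decision tree; particles matching no gate are
``unclassified`` and non-viable particles are ``background``.

The tree, with all inequalities strict:

* large element: SWS total > 2e4 a.u. AND sample length > 100 μm
* large → pellet iff SWS total > 4e4, sample length > 120 μm, FWS saturated,
  FWS maximum / fill factor > 7.5e3 and SWS total / sample length > 8e2;
  otherwise large clump
* small → small clump iff sample length in (10, 150) μm, SWS total in
  (1.8e4, 9e4) and FWS length > 18 μm (this gate has precedence in the
  interval overlap with hyphae); else hyphae iff sample length in (10, 150),
  SWS total < 4e4 and FWS length < 190 μm; else the configured fallback.

An optional gate-refinement step clusters the standardized feature table
(k-means or average-linkage Euclidean hierarchical clustering, at most five
clusters) and reports the concordance between clusters and gate classes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from matplotlib.path import Path as _MplPath
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import AgglomerativeClustering, KMeans

from .config import GatingConfig
from .errors import ValidationError
from .features import ChannelFeatures, DerivedRatios, feature_table
from .types import BIOLOGICAL_CLASSES, MorphClass

CLUSTER_METHODS = ("kmeans", "hierarchical_average_euclidean")
#: clusterings with more groups than this were never morphologically interpretable
MAX_CLUSTERS = 5


# --------------------------------------------------------------------------
# vectorized gating on a feature table
# --------------------------------------------------------------------------

def _sample_length_column(config: GatingConfig) -> str:
    return f"{config.sample_length_channel.lower()}_sample_length"


def is_viable_table(df: pd.DataFrame, config: GatingConfig) -> pd.Series:
    """Viability prefilter: FL_GREEN total strictly above the threshold."""
    if "fl_green_total" not in df.columns:
        fl = pd.Series(np.nan, index=df.index)
    else:
        fl = df["fl_green_total"]
    if config.require_fl:
        return (fl > config.green_fl_total_min).fillna(False).astype(bool)
    return (fl.isna() | (fl > config.green_fl_total_min)).astype(bool)


def classify_table(df: pd.DataFrame, config: GatingConfig) -> pd.Series:
    """Class label per particle of a feature table (vectorized decision tree)."""
    n = len(df)
    out = pd.Series([MorphClass.BACKGROUND] * n, index=df.index, dtype=object)
    if n == 0:
        return out

    viable = is_viable_table(df, config)
    sl = df[_sample_length_column(config)].to_numpy(float)
    sws_total = df["sws_total"].to_numpy(float)
    fws_length = df["fws_length"].to_numpy(float)
    fws_saturated = df["fws_saturated"].to_numpy(bool)
    r_maxfill = df["fws_max_over_fill"].to_numpy(float)
    r_totsl = df["sws_total_over_sample_length"].to_numpy(float)

    # undefined ratios (zero denominators) cannot be gated
    bad = ~np.isfinite(r_maxfill) | ~np.isfinite(r_totsl)

    large = (sws_total > config.large_sws_total_min) & (sl > config.large_sample_length_min)

    pellet = (
        large
        & (sws_total > config.pellet_sws_total_min)
        & (sl > config.pellet_sample_length_min)
        & fws_saturated
        & (r_maxfill > config.pellet_fws_max_over_fill_min)
        & (r_totsl > config.pellet_sws_total_over_sample_length_min)
    )

    if config.small_clump_polygon is not None:
        path = _MplPath(np.asarray(config.small_clump_polygon, float))
        in_sc_shape = path.contains_points(np.column_stack([fws_length, sws_total]))
        small_clump = (
            np.asarray(config.small_clump_sample_length.contains(sl)) & in_sc_shape
        )
    else:
        small_clump = (
            np.asarray(config.small_clump_sample_length.contains(sl))
            & np.asarray(config.small_clump_sws_total.contains(sws_total))
            & (fws_length > config.small_clump_fws_length_min)
        )
    hyphae = (
        np.asarray(config.hyphae_sample_length.contains(sl))
        & (sws_total < config.hyphae_sws_total_max)
        & (fws_length < config.hyphae_fws_length_max)
    )

    fallback = (
        MorphClass.HYPHAE if config.fallback_small == "hyphae" else MorphClass.UNCLASSIFIED
    )
    viable_np = viable.to_numpy(bool)
    labels = np.where(
        large,
        np.where(pellet, "pellet", "large_clump"),
        np.where(
            small_clump,
            "small_clump",
            np.where(hyphae, "hyphae", str(fallback)),
        ),
    )
    labels = np.where(bad, "unclassified", labels)
    out[viable_np] = labels[viable_np]
    return out.map(MorphClass)


# --------------------------------------------------------------------------
# scalar wrappers
# --------------------------------------------------------------------------

def _as_row(features: dict[str, ChannelFeatures], ratios: DerivedRatios, config: GatingConfig) -> pd.DataFrame:
    row: dict = {}
    for ch, f in features.items():
        prefix = str(ch).lower()
        for name in ("maximum", "total", "length", "sample_length", "fill_factor"):
            row[f"{prefix}_{name}"] = getattr(f, name)
    row["fws_max_over_fill"] = ratios.fws_max_over_fill
    row["sws_total_over_sample_length"] = ratios.sws_total_over_sample_length
    row["fws_saturated"] = ratios.fws_saturated
    return pd.DataFrame([row])


def is_viable(features: dict, config: GatingConfig | None = None) -> bool:
    """True iff the particle's green-fluorescence total exceeds the threshold.

    ``features`` maps channel name to :class:`ChannelFeatures`; the FL_GREEN
    entry may be absent, in which case ``config.require_fl`` decides.
    """
    config = config or GatingConfig()
    fl = features.get("FL_GREEN")
    if fl is None:
        return not config.require_fl
    return fl.total > config.green_fl_total_min


def classify(features: dict, ratios: DerivedRatios, config: GatingConfig | None = None) -> MorphClass:
    """Classify one viable particle from its per-channel features and ratios."""
    config = config or GatingConfig()
    df = _as_row(features, ratios, config)
    if "fl_green_total" not in df.columns:
        df["fl_green_total"] = np.inf if not config.require_fl else np.nan
    # the scalar path classifies a particle already deemed viable
    df["fl_green_total"] = df["fl_green_total"].fillna(np.inf)
    cfg = config.replace(require_fl=False)
    return classify_table(df, cfg).iloc[0]


def classify_run(records, config: GatingConfig | None = None):
    """Gate a whole measurement run.

    Returns ``(table, counts)``: the feature table with ``viable`` and
    ``morph_class`` columns appended, and per-class counts over all six
    labels.  Class counts over the four biological classes plus
    ``unclassified`` partition the viable set.
    """
    config = config or GatingConfig()
    df = feature_table(records, config.trigger_level, config.saturation_level)
    df["viable"] = is_viable_table(df, config)
    df["morph_class"] = classify_table(df, config).map(str)
    counts = {str(c): 0 for c in MorphClass}
    counts.update({k: int(v) for k, v in df["morph_class"].value_counts().items()})
    return df, counts


# --------------------------------------------------------------------------
# cluster-assisted gate refinement
# --------------------------------------------------------------------------

def refine_gates(
    table: pd.DataFrame,
    method: str = "kmeans",
    k: int = 2,
    feature_columns=("sws_sample_length", "sws_total"),
    log_columns=None,
    class_column: str = "morph_class",
    seed: int = 0,
):
    """Cluster the standardized feature table and compare with the gate classes.

    Scatter totals and lengths span decades and are roughly log-normal, so by
    default every feature is log10-transformed before z-scoring (pass an
    explicit ``log_columns`` tuple, possibly empty, to override).  Returns
    ``(labels, concordance)`` where ``concordance`` is the cluster-vs-class
    contingency table; :func:`concordance_score` gives the best-matching
    agreement fraction.
    """
    if method not in CLUSTER_METHODS:
        raise ValidationError(f"unknown clustering method {method!r}")
    if not 2 <= k <= MAX_CLUSTERS:
        raise ValidationError(
            f"k must be between 2 and {MAX_CLUSTERS} (morphologically "
            f"interpretable clusterings), got {k}"
        )
    if len(table) < k:
        raise ValidationError(f"need at least k={k} particles, got {len(table)}")

    if log_columns is None:
        log_columns = tuple(feature_columns)
    X = table.loc[:, list(feature_columns)].to_numpy(float).copy()
    for j, col in enumerate(feature_columns):
        if col in log_columns:
            X[:, j] = np.log10(np.maximum(X[:, j], 1e-12))
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)

    if method == "kmeans":
        model = KMeans(n_clusters=k, n_init=10, random_state=seed)
    else:
        model = AgglomerativeClustering(n_clusters=k, linkage="average", metric="euclidean")
    labels = pd.Series(model.fit_predict(X), index=table.index, name="cluster")

    if class_column in table.columns:
        concordance = pd.crosstab(labels, table[class_column])
    else:
        concordance = pd.crosstab(labels, pd.Series("all", index=table.index))
    return labels, concordance


def concordance_score(contingency: pd.DataFrame) -> float:
    """Best-matching agreement between clusters and classes in [0, 1].

    Clusters are assigned to classes by maximum-weight matching on the
    contingency table; the score is the matched fraction of particles.
    """
    M = contingency.to_numpy(float)
    r, c = linear_sum_assignment(-M)
    return float(M[r, c].sum() / M.sum())
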