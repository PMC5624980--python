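"""Hierarchical gating: viability, decision tree, boundaries, clustering."""

import numpy as np
import pandas as pd
import pytest

from pulsemorph import (
    ChannelFeatures,
    DerivedRatios,
    GatingConfig,
    MorphClass,
    SimParams,
    ValidationError,
    classify,
    classify_run,
    classify_table,
    concordance_score,
    is_viable,
    refine_gates,
    simulate_run,
)


def cf(maximum=1e3, total=1e4, length=100.0, sample_length=80.0, fill=0.8):
    return ChannelFeatures(maximum, total, length, sample_length, fill)


def particle(
    sws_total=1e4,
    sample_length=50.0,
    fws_length=100.0,
    fws_max=1e3,
    fws_fill=0.8,
    fl_total=100.0,
):
    """Feature-table row builder in the gate's own coordinates."""
    return {
        "fws": cf(maximum=fws_max, length=fws_length, fill=fws_fill),
        "sws": cf(total=sws_total, sample_length=sample_length),
        "fl": cf(total=fl_total),
    }


def classify_one(config=None, **kwargs):
    p = particle(**kwargs)
    config = config or GatingConfig()
    ratios = DerivedRatios(
        p["fws"].maximum / p["fws"].fill_factor if p["fws"].fill_factor else float("nan"),
        p["sws"].total / p["sws"].sample_length if p["sws"].sample_length else float("nan"),
        p["fws"].maximum >= config.saturation_level,
    )
    return classify(
        {"FWS": p["fws"], "SWS": p["sws"], "FL_GREEN": p["fl"]}, ratios, config
    )


class TestViability:
    def test_strictly_above_threshold_is_viable(self, default_config):
        assert is_viable({"FL_GREEN": cf(total=31.0)}, default_config)

    def test_exactly_at_threshold_is_background(self, default_config):
        assert not is_viable({"FL_GREEN": cf(total=30.0)}, default_config)

    def test_missing_channel_follows_require_fl(self):
        assert not is_viable({}, GatingConfig(require_fl=True))
        assert is_viable({}, GatingConfig(require_fl=False))


class TestDecisionTree:
    def test_textbook_pellet(self):
        # SWS total/sample length = 1e3 > 8e2; FWS max/fill = 1.25e4 > 7.5e3
        got = classify_one(
            sws_total=1.5e5, sample_length=150.0, fws_max=1e4, fws_fill=0.8
        )
        assert got == MorphClass.PELLET

    def test_unsaturated_large_element_is_a_large_clump(self):
        # a dense core must saturate the forward scatter; 9e3 < 1e4 fails it
        got = classify_one(
            sws_total=1.5e5, sample_length=150.0, fws_max=9e3, fws_fill=0.8
        )
        assert got == MorphClass.LARGE_CLUMP

    def test_small_element_below_clump_interval_is_hyphae(self):
        got = classify_one(sws_total=1e4, sample_length=50.0, fws_length=100.0)
        assert got == MorphClass.HYPHAE

    def test_small_clump_gate_has_precedence_in_the_overlap(self):
        # SWS total 3e4 sits in both the hyphae (<4e4) and clump (1.8e4-9e4)
        # intervals; the clump gate wins
        got = classify_one(sws_total=3e4, sample_length=50.0, fws_length=100.0)
        assert got == MorphClass.SMALL_CLUMP

    def test_fallback_routes_unmatched_small_elements(self):
        # sample length below every small gate's lower bound
        for fallback, expected in [
            ("unclassified", MorphClass.UNCLASSIFIED),
            ("hyphae", MorphClass.HYPHAE),
        ]:
            got = classify_one(
                GatingConfig(fallback_small=fallback), sample_length=5.0, sws_total=1e3
            )
            assert got == expected

    def test_undefined_ratio_routes_to_unclassified(self):
        got = classify_one(sws_total=5e4, sample_length=150.0, fws_fill=0.0)
        assert got == MorphClass.UNCLASSIFIED

    def test_polygon_override_for_small_clump_gate(self):
        # a polygon excluding the point that the rectangle accepts
        cfg = GatingConfig(
            small_clump_polygon=[(0, 5e4), (10, 5e4), (10, 8e4), (0, 8e4)]
        )
        got = classify_one(cfg, sws_total=3e4, sample_length=50.0, fws_length=100.0)
        assert got != MorphClass.SMALL_CLUMP


BOUNDARY_CASES = [
    # (kwargs at the boundary, class at boundary, kwargs just inside, class inside)
    # large-element gate: strict '>' on both axes
    (dict(sws_total=2e4, sample_length=150.0, fws_length=200.0),
     MorphClass.UNCLASSIFIED,
     dict(sws_total=2e4 + 1, sample_length=150.0, fws_length=200.0),
     MorphClass.LARGE_CLUMP),
    # sample length exactly 100: not large, and the small-clump gate catches it
    (dict(sws_total=3e4, sample_length=100.0, fws_length=200.0),
     MorphClass.SMALL_CLUMP,
     dict(sws_total=3e4, sample_length=100.0 + 1e-9, fws_length=200.0),
     MorphClass.LARGE_CLUMP),
    # pellet sample-length threshold 120 um
    (dict(sws_total=9.6e4 + 1, sample_length=120.0, fws_max=1e4),
     MorphClass.LARGE_CLUMP,
     dict(sws_total=9.7e4, sample_length=120.0 + 1e-9, fws_max=1e4),
     MorphClass.PELLET),
    # hyphae sample-length interval (10, 150): endpoints excluded
    (dict(sws_total=1e3, sample_length=10.0),
     MorphClass.UNCLASSIFIED,
     dict(sws_total=1e3, sample_length=10.0 + 1e-9),
     MorphClass.HYPHAE),
    (dict(sws_total=1e3, sample_length=150.0),
     MorphClass.UNCLASSIFIED,
     dict(sws_total=1e3, sample_length=150.0 - 1e-9),
     MorphClass.HYPHAE),
    # hyphae SWS total < 4e4 is strict (FWS length 10 < 18 keeps the
    # small-clump gate out of the way)
    (dict(sws_total=4e4, sample_length=50.0, fws_length=10.0),
     MorphClass.UNCLASSIFIED,
     dict(sws_total=4e4 - 1, sample_length=50.0, fws_length=10.0),
     MorphClass.HYPHAE),
    # hyphae FWS length < 190 um is strict
    (dict(sws_total=1e3, sample_length=50.0, fws_length=190.0),
     MorphClass.UNCLASSIFIED,
     dict(sws_total=1e3, sample_length=50.0, fws_length=190.0 - 1e-9),
     MorphClass.HYPHAE),
    # small-clump SWS interval (1.8e4, 9e4): endpoints excluded
    (dict(sws_total=1.8e4, sample_length=50.0),
     MorphClass.HYPHAE,
     dict(sws_total=1.8e4 + 1, sample_length=50.0),
     MorphClass.SMALL_CLUMP),
    (dict(sws_total=9e4, sample_length=50.0),
     MorphClass.UNCLASSIFIED,
     dict(sws_total=9e4 - 1, sample_length=50.0),
     MorphClass.SMALL_CLUMP),
    # small-clump FWS length > 18 um is strict
    (dict(sws_total=3e4, sample_length=50.0, fws_length=18.0),
     MorphClass.HYPHAE,
     dict(sws_total=3e4, sample_length=50.0, fws_length=18.0 + 1e-9),
     MorphClass.SMALL_CLUMP),
]


@pytest.mark.parametrize("at_kwargs,at_cls,in_kwargs,in_cls", BOUNDARY_CASES)
def test_every_threshold_is_strict(at_kwargs, at_cls, in_kwargs, in_cls):
    """A particle exactly on a threshold falls on the complementary side;
    an epsilon inside falls into the gate."""
    assert classify_one(**at_kwargs) == at_cls
    assert classify_one(**in_kwargs) == in_cls


def test_pellet_ratio_thresholds_are_strict():
    """Both pellet ratios are strict '>' comparisons."""
    fws = cf(maximum=1e4, fill=0.8)
    sws = cf(total=1e5, sample_length=122.0)
    feats = {"FWS": fws, "SWS": sws, "FL_GREEN": cf(total=100.0)}
    # FWS max / fill exactly 7.5e3 -> large clump; just above -> pellet
    at = DerivedRatios(7.5e3, 1e5 / 122.0, True)
    inside = DerivedRatios(7.5e3 * (1 + 1e-9), 1e5 / 122.0, True)
    assert classify(feats, at) == MorphClass.LARGE_CLUMP
    assert classify(feats, inside) == MorphClass.PELLET
    # SWS total / sample length exactly 8e2 -> large clump
    at = DerivedRatios(1.25e4, 8e2, True)
    inside = DerivedRatios(1.25e4, 8e2 * (1 + 1e-9), True)
    assert classify(feats, at) == MorphClass.LARGE_CLUMP
    assert classify(feats, inside) == MorphClass.PELLET


def test_pellet_sws_total_threshold_is_strict_when_binding():
    """With the ratio rule relaxed, SWS total exactly 4e4 is not a pellet."""
    cfg = GatingConfig(pellet_sws_total_over_sample_length_min=100.0)
    at = classify_one(cfg, sws_total=4e4, sample_length=150.0, fws_max=1e4)
    inside = classify_one(cfg, sws_total=4e4 + 1, sample_length=150.0, fws_max=1e4)
    assert at == MorphClass.LARGE_CLUMP
    assert inside == MorphClass.PELLET


class TestClassifyRun:
    def test_empty_run(self, default_config):
        table, counts = classify_run([], default_config)
        assert len(table) == 0
        assert all(v == 0 for v in counts.values())

    def test_partition_property(self, small_run, default_config):
        """Every particle gets exactly one label; viable counts telescope."""
        _, records, truth, _ = small_run
        table, counts = classify_run(records, default_config)
        assert len(table) == len(records)
        assert sum(counts.values()) == len(records)
        viable_labels = {"hyphae", "small_clump", "large_clump", "pellet", "unclassified"}
        n_viable = int(table["viable"].sum())
        assert sum(counts[c] for c in viable_labels) == n_viable
        assert counts["background"] == len(records) - n_viable

    def test_ground_truth_recovery_on_gate_interior_mixture(self, small_run):
        _, records, truth, _ = small_run
        table, _ = classify_run(records)
        merged = table.merge(truth, on="particle_id")
        recovery = (merged["morph_class"] == merged["true_class"]).mean()
        assert recovery >= 0.99

    def test_background_excluded_from_class_counts(self, small_run):
        _, records, truth, _ = small_run
        table, counts = classify_run(records)
        n_bg_truth = (truth["true_class"] == "background").sum()
        assert counts["background"] == n_bg_truth
        assert (table.loc[table["morph_class"] == "background", "viable"] == False).all()


def test_monotonicity_pellets_never_demoted_by_more_sws_signal():
    """Increasing SWS total of a pellet-qualifying large element keeps it a pellet."""
    base = dict(sample_length=150.0, fws_max=1e4, fws_fill=0.8)
    for total in [1.3e5, 2e5, 5e5, 1e6]:
        assert classify_one(sws_total=total, **base) == MorphClass.PELLET


class TestRefineGates:
    @pytest.mark.parametrize("k", [1, 6, 0])
    def test_cluster_count_outside_2_to_5_rejected(self, small_run, k):
        _, records, _, _ = small_run
        table, _ = classify_run(records)
        with pytest.raises(ValidationError):
            refine_gates(table, "kmeans", k)

    def test_unknown_method_rejected(self, small_run):
        table, _ = classify_run(small_run[1])
        with pytest.raises(ValidationError):
            refine_gates(table, "dbscan", 2)

    def test_hierarchical_k2_recovers_small_vs_large_split(self, small_run):
        """Average-linkage Euclidean clustering at k=2 reproduces the
        small-vs-large element gate split."""
        _, records, _, _ = small_run
        table, _ = classify_run(records)
        table = table[table["morph_class"].isin(
            ["hyphae", "small_clump", "large_clump", "pellet"])].copy()
        table["size_group"] = np.where(
            table["morph_class"].isin(["hyphae", "small_clump"]), "small", "large"
        )
        labels, contingency = refine_gates(
            table, "hierarchical_average_euclidean", 2, class_column="size_group"
        )
        assert concordance_score(contingency) >= 0.95

    def test_kmeans_k3_separates_pellets_from_large_clumps(self):
        """On a large-elements-only mixture with distinct pellet geometry,
        k-means finds clusters whose majorities are pellets and large clumps."""
        params = SimParams(
            n=600, seed=21,
            class_mixture={"large_clump": 0.45, "pellet": 0.35, "hyphae": 0.2},
        )
        records, truth, _ = simulate_run(params)
        table, _ = classify_run(records)
        labels, contingency = refine_gates(
            table, "kmeans", 3,
            feature_columns=("sws_sample_length", "sws_total", "fws_maximum"),
            seed=0,
        )
        majority = contingency.idxmax(axis=1)
        assert "pellet" in set(majority)
        assert "large_clump" in set(majority)

    def test_kmeans_seed_reproducible(self, small_run):
        table, _ = classify_run(small_run[1])
        l1, _ = refine_gates(table, "kmeans", 4, seed=7)
        l2, _ = refine_gates(table, "kmeans", 4, seed=7)
        assert (l1 == l2).all()
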