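"""Concentrations, SWS fractions, size distributions, replicate errors."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pulsemorph import (
    MeasurementMeta,
    ValidationError,
    class_lengths,
    classify_run,
    concentrations,
    pooled_concentrations,
    replicate_error,
    size_distribution,
    summarize_run,
    sws_fraction,
    timecourse,
)


def table_of(rows):
    return pd.DataFrame(rows)


class TestSwsFraction:
    def test_two_particle_arithmetic(self):
        t = table_of([
            {"morph_class": "pellet", "sws_total": 8e4},
            {"morph_class": "hyphae", "sws_total": 2e4},
        ])
        f = sws_fraction(t)
        assert f["pellet"] == pytest.approx(80.0)
        assert f["hyphae"] == pytest.approx(20.0)
        assert f["small_clump"] == 0.0

    def test_single_class_sample_is_100_percent(self):
        t = table_of([{"morph_class": "hyphae", "sws_total": v} for v in (1, 2, 3)])
        assert sws_fraction(t)["hyphae"] == pytest.approx(100.0)

    def test_matches_brute_force_summation(self, small_run):
        _, records, _, _ = small_run
        t, _ = classify_run(records)
        f = sws_fraction(t)
        classes = ("hyphae", "small_clump", "large_clump", "pellet")
        total = sum(
            v for _, row in t.iterrows() if row["morph_class"] in classes
            for v in [row["sws_total"]]
        )
        for cls in classes:
            direct = sum(
                row["sws_total"] for _, row in t.iterrows()
                if row["morph_class"] == cls
            )
            assert f[cls] == pytest.approx(direct / total * 100.0, abs=1e-12)
        assert f.sum() == pytest.approx(100.0, abs=1e-9)

    def test_unclassified_excluded_from_denominator_by_default(self):
        t = table_of([
            {"morph_class": "pellet", "sws_total": 8e4},
            {"morph_class": "unclassified", "sws_total": 2e4},
        ])
        assert sws_fraction(t)["pellet"] == pytest.approx(100.0)
        incl = sws_fraction(t, include_unclassified=True)
        assert incl["pellet"] == pytest.approx(80.0)

    def test_all_zero_sws_totals_rejected(self):
        t = table_of([{"morph_class": "hyphae", "sws_total": 0.0}])
        with pytest.raises(ValidationError):
            sws_fraction(t)


class TestConcentrations:
    def test_pellets_per_ml_magnitude(self, meta):
        # 40 pellets in 1200 ul of a 1:1000 dilution -> ~3.3e4 pellets/ml broth
        c = concentrations({"pellet": 40}, meta)
        assert c["pellet"] == pytest.approx(40 / 1.2 * 1000)

    def test_zero_count_gives_zero(self, meta):
        assert concentrations({"pellet": 0}, meta)["pellet"] == 0.0

    def test_arithmetic_oracle(self, meta):
        # pump 15 ul/s x 80 s = 1.2 ml analyzed; 120 counts at 1:1000
        assert concentrations({"hyphae": 120}, meta)["hyphae"] == pytest.approx(1.0e5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        count=st.integers(0, 10**6),
        k=st.integers(1, 20),
        dilution=st.floats(1, 1e4),
    )
    def test_linearity_in_count_and_dilution(self, count, k, dilution):
        meta = MeasurementMeta(pump_speed=15.0, duration=80.0, dilution_factor=dilution)
        c1 = concentrations({"x": count}, meta)["x"]
        ck = concentrations({"x": k * count}, meta)["x"]
        assert ck == pytest.approx(k * c1, rel=1e-12, abs=1e-12)
        meta2 = MeasurementMeta(pump_speed=15.0, duration=80.0, dilution_factor=k * dilution)
        assert concentrations({"x": count}, meta2)["x"] == pytest.approx(
            k * c1, rel=1e-12, abs=1e-12
        )

    def test_pooled_replicates_weighted_by_volume(self):
        reps = [
            ({"pellet": 30}, MeasurementMeta(duration=60.0)),
            ({"pellet": 60}, MeasurementMeta(duration=120.0)),
        ]
        pooled = pooled_concentrations(reps)
        row = pooled.set_index("class").loc["pellet"]
        # volume-weighted mean equals pooling counts over the total volume
        expected = (30 + 60) / ((15 * 60 + 15 * 120) / 1000) * 1000
        assert row["concentration_per_ml"] == pytest.approx(expected)
        assert row["n_replicates"] == 2


class TestSizeDistribution:
    def test_single_bin_gets_everything(self):
        edges, freqs = size_distribution([5, 6, 7], bin_edges=[0, 10])
        assert freqs.tolist() == [1.0]

    def test_uniform_lengths_split_evenly(self):
        rng = np.random.default_rng(0)
        lengths = rng.uniform(0, 100, 10_000)
        _, freqs = size_distribution(lengths, bin_edges=[0, 50, 100])
        assert freqs == pytest.approx([0.5, 0.5], abs=0.02)

    def test_frequencies_sum_to_one(self, small_run):
        _, records, _, _ = small_run
        t, _ = classify_run(records)
        edges, freqs = size_distribution(t["sws_sample_length"])
        assert freqs.sum() == pytest.approx(1.0)
        assert len(edges) == len(freqs) + 1

    def test_empty_input_is_an_empty_histogram(self):
        edges, freqs = size_distribution([])
        assert freqs.size == 0

    def test_large_elements_union_excludes_small_forms(self, small_run):
        _, records, _, _ = small_run
        t, _ = classify_run(records)
        lengths = class_lengths(t, "large_elements")
        n_large = t["morph_class"].isin(["large_clump", "pellet"]).sum()
        assert len(lengths) == n_large
        lengths_agg = class_lengths(t, "hyphal_aggregates")
        n_agg = t["morph_class"].isin(["small_clump", "large_clump", "pellet"]).sum()
        assert len(lengths_agg) == n_agg


class TestTimecourse:
    def test_single_run_block(self, small_run, meta):
        _, records, _, _ = small_run
        t, _ = classify_run(records)
        s = summarize_run(t, meta)
        tc = timecourse([s])
        assert len(tc) == 4  # one row per biological class
        assert set(tc["class"]) == {"hyphae", "small_clump", "large_clump", "pellet"}
        got = tc.set_index("class")["concentration_per_ml"]
        assert got["pellet"] == pytest.approx(
            s.counts["pellet"] / 1.2 * 1000
        )

    def test_empty_input_is_empty_table(self):
        tc = timecourse([])
        assert len(tc) == 0
        assert "concentration_per_ml" in tc.columns


class TestReplicateError:
    def test_identical_replicates_have_zero_cv(self):
        reps = pd.DataFrame({"rad": [0.3, 0.3, 0.3]})
        err = replicate_error(reps)
        assert err.loc["rad", "cv_pct"] == 0.0

    def test_closed_form_two_replicates(self):
        err = replicate_error(pd.DataFrame({"conc": [90.0, 110.0]}))
        assert err.loc["conc", "mean"] == pytest.approx(100.0)
        assert err.loc["conc", "sd"] == pytest.approx(np.sqrt(200.0))
        assert err.loc["conc", "cv_pct"] == pytest.approx(14.142, abs=1e-3)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValidationError):
            replicate_error(pd.DataFrame({"x": [1.0]}))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        values=st.lists(st.floats(1, 1e6), min_size=2, max_size=8),
        scale=st.floats(0.01, 100),
    )
    def test_cv_is_scale_invariant(self, values, scale):
        a = replicate_error(pd.DataFrame({"x": values}))
        b = replicate_error(pd.DataFrame({"x": [scale * v for v in values]}))
        assert b.loc["x", "cv_pct"] == pytest.approx(
            a.loc["x", "cv_pct"], rel=1e-9, abs=1e-9
        )
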