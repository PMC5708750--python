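import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moha import (
    CellTable,
    QualityFilterConfig,
    ThresholdModel,
    apply_morphology_filters,
    apply_qc_round_filter,
    fit_thresholds,
    ordinalize,
)
from oracles import nearest_rank


def make_table(n=10, **cols):
    rng = np.random.default_rng(7)
    base = {
        "cell_id": [f"c{i}" for i in range(n)],
        "sample_id": "s",
        "x": rng.uniform(10, 90, n),
        "y": rng.uniform(10, 90, n),
        "cell_area": np.full(n, 50.0),
        "nuclear_area": np.full(n, 20.0),
        "cytosol_area": np.full(n, 30.0),
        "nuclei_count": np.ones(n, dtype=int),
        "is_epithelial": [True] * n,
    }
    base.update(cols)
    return CellTable("s", pd.DataFrame(base), field_bounds=(0, 100, 0, 100))


class TestMorphologyFilters:
    def test_area_below_minimum_removed(self):
        areas = np.full(10, 20.0)
        areas[0] = 0.5  # below the 1.4 µm² floor
        t = make_table(nuclear_area=areas)
        out, report = apply_morphology_filters(t)
        assert out.n_cells == 9
        assert report.removed["area"] == 1

    def test_each_criterion_removes_engineered_violators(self):
        nuc_area = np.full(12, 20.0)
        nuc_area[0] = 1.0      # too small
        nuc_area[1] = 141.0    # too large
        nuclei = np.ones(12, dtype=int)
        nuclei[2] = 3
        nuclei[3] = 0
        x = np.full(12, 50.0)
        x[4] = 1.0             # inside the 2 µm edge margin
        epi = [True] * 12
        epi[5] = False
        t = make_table(n=12, nuclear_area=nuc_area, nuclei_count=nuclei, x=x,
                       is_epithelial=epi)
        out, report = apply_morphology_filters(t)
        # second independent pass: re-check every surviving cell
        cfg = QualityFilterConfig()
        for _, row in out.cells.iterrows():
            assert cfg.min_area <= row["nuclear_area"] <= cfg.max_area
            assert row["nuclei_count"] in cfg.allowed_nuclei
            assert 2.0 <= row["x"] <= 98.0 and 2.0 <= row["y"] <= 98.0
            assert row["is_epithelial"]
        assert out.n_cells == 12 - 6
        assert report.removed == {"area": 2, "nuclei": 2, "edge": 1, "epithelial": 1}

    def test_small_sample_flagged_excluded(self):
        t = make_table(n=99)
        _, report = apply_morphology_filters(t)
        assert report.excluded
        t2 = make_table(n=100)
        _, report2 = apply_morphology_filters(t2)
        assert not report2.excluded

    def test_bounds_default_to_centroid_box(self):
        t = make_table(n=20)
        t.field_bounds = None
        out, report = apply_morphology_filters(t)
        # extreme cells in x and y sit on the default bounding box -> edge
        assert report.removed["edge"] >= 2


class TestQcRoundFilter:
    def test_score_below_threshold_masks_intensity(self):
        t = make_table(n=3)
        t.cells["AKT@cell"] = [1.0, 2.0, 3.0]
        t.cells["qc:R2"] = [1.0, 0.79, 0.8]
        out = apply_qc_round_filter(t, {"AKT": "R2"}, 0.8)
        vals = out.cells["AKT@cell"]
        assert np.isnan(vals[1]) and vals[0] == 1.0 and vals[2] == 3.0
        assert out.n_cells == 3  # cells retained

    def test_perfect_scores_leave_table_unchanged(self):
        t = make_table(n=5)
        t.cells["AKT@cell"] = np.arange(5.0)
        t.cells["qc:R1"] = 1.0
        out = apply_qc_round_filter(t, {"AKT": "R1"}, 0.8)
        pd.testing.assert_frame_equal(out.cells, t.cells)

    def test_removal_count_matches_brute_force(self, rng):
        n = 40
        t = make_table(n=n)
        markers = ["A", "B", "C"]
        rounds = {"A": "R1", "B": "R1", "C": "R2"}
        for m in markers:
            t.cells[f"{m}@cell"] = rng.uniform(1, 2, n)
        for r in ("R1", "R2"):
            t.cells[f"qc:{r}"] = rng.uniform(0.5, 1.0, n)
        out = apply_qc_round_filter(t, rounds, 0.8)
        expected = sum(
            1
            for m in markers
            for i in range(n)
            if t.cells.loc[i, f"qc:{rounds[m]}"] < 0.8
        )
        got = int(sum(out.cells[f"{m}@cell"].isna().sum() for m in markers))
        assert got == expected

    def test_unknown_round_errors(self):
        t = make_table(n=3)
        t.cells["A@cell"] = 1.0
        with pytest.raises(KeyError, match="R9"):
            apply_qc_round_filter(t, {"A": "R9"}, 0.8)


class TestThresholds:
    def test_percentiles_1_to_100_nearest_rank(self):
        t = make_table(n=100)
        t.cells["A@cell"] = np.arange(1.0, 101.0)
        model = fit_thresholds([t], n_states=3, percentiles=[33, 67])
        assert model.cutpoints["A@cell"] == [33.0, 67.0]

    def test_constant_intensities_collapse_to_one_bin(self):
        t = make_table(n=10)
        t.cells["A@cell"] = 5.0
        model = fit_thresholds([t])
        assert model.cutpoints["A@cell"] == [5.0, 5.0]
        lev = ordinalize(t, model)["A@cell"]
        assert (lev == 0).all()  # ties fall in the lower bin

    def test_median_split_two_states(self):
        t = make_table(n=9)
        t.cells["A@cell"] = np.arange(1.0, 10.0)
        model = fit_thresholds([t], n_states=2, percentiles=[50])
        assert model.cutpoints["A@cell"] == [5.0]

    def test_pooling_across_samples_matches_oracle(self, rng):
        tables = []
        pooled = []
        for i in range(3):
            t = make_table(n=30)
            v = rng.lognormal(0, 1, 30)
            v[rng.integers(0, 30)] = np.nan  # missing values dropped
            t.cells["A@cell"] = v
            tables.append(t)
            pooled.extend(v[~np.isnan(v)])
        model = fit_thresholds(tables)
        assert model.cutpoints["A@cell"] == [
            nearest_rank(pooled, 33),
            nearest_rank(pooled, 67),
        ]

    def test_key_with_no_values_errors(self):
        t = make_table(n=4)
        t.cells["A@cell"] = np.nan
        with pytest.raises(ValueError, match="A@cell"):
            fit_thresholds([t])

    def test_model_json_round_trip(self):
        m = ThresholdModel(3, {"A@cell": [1.0, 2.0]}, [33, 67])
        assert ThresholdModel.from_json(m.to_json()) == m


class TestOrdinalize:
    def test_boundary_levels(self):
        t = make_table(n=4)
        t.cells["A@cell"] = [0.5, 1.0, 1.5, 10.0]
        model = ThresholdModel(3, {"A@cell": [1.0, 2.0]}, [33, 67])
        lev = ordinalize(t, model)["A@cell"].to_numpy()
        # below first cutpoint -> 0; ties -> lower bin; above last -> 2
        assert list(lev) == [0.0, 0.0, 1.0, 2.0]

    def test_missing_stays_missing(self):
        t = make_table(n=2)
        t.cells["A@cell"] = [np.nan, 3.0]
        model = ThresholdModel(3, {"A@cell": [1.0, 2.0]}, [33, 67])
        lev = ordinalize(t, model)["A@cell"].to_numpy()
        assert np.isnan(lev[0]) and lev[1] == 2.0

    def test_model_missing_key_errors(self):
        t = make_table(n=2)
        t.cells["A@cell"] = 1.0
        with pytest.raises(KeyError, match="A@cell"):
            ordinalize(t, ThresholdModel(3, {"B@cell": [1.0, 2.0]}, [33, 67]))

    def test_uniform_data_bins_near_thirds(self):
        n = 10_000
        t = make_table(n=n)
        t.cells["A@cell"] = np.random.default_rng(11).uniform(0, 1, n)
        model = fit_thresholds([t])
        lev = ordinalize(t, model)["A@cell"]
        occ = lev.value_counts(normalize=True)
        for k in (0, 1, 2):
            assert abs(occ[k] - 1 / 3) < 0.02

    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=40),
           st.integers(2, 5))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_ordinalization_is_monotone(self, values, n_states):
        t = make_table(n=len(values))
        t.cells["A@cell"] = values
        model = fit_thresholds([t], n_states=n_states,
                               percentiles=[100 * k / n_states for k in range(1, n_states)])
        lev = ordinalize(t, model)["A@cell"].to_numpy()
        order = np.argsort(values, kind="stable")
        assert (np.diff(lev[order]) >= 0).all()


def test_filter_order_insensitive(rng):
    """Morphology-then-QC equals QC-then-morphology on surviving pairs."""
    n = 60
    t = make_table(n=n)
    nuc = np.full(n, 20.0)
    nuc[rng.choice(n, 10, replace=False)] = 0.9
    t.cells["nuclear_area"] = nuc
    t.cells["A@cell"] = rng.uniform(1, 2, n)
    t.cells["qc:R1"] = rng.uniform(0.5, 1.0, n)
    a, _ = apply_morphology_filters(t)
    a = apply_qc_round_filter(a, {"A": "R1"}, 0.8)
    b = apply_qc_round_filter(t, {"A": "R1"}, 0.8)
    b, _ = apply_morphology_filters(b)
    pd.testing.assert_frame_equal(
        a.cells.reset_index(drop=True), b.cells.reset_index(drop=True)
    )
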