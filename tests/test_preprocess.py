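import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from meanfield_sca.preprocess import (
    ItemPanel, apply_exclusions, collapse_tristate, impute_locf, kmeans_split,
    load_item_metadata, preprocess_panel, reverse_and_median_split, to_counts,
)


def make_panel(values, scale="binary", reversed_items=(), participant="p1"):
    df = pd.DataFrame(values)
    df.columns = [f"item{j}" for j in range(df.shape[1])]
    return ItemPanel(participant=participant, data=df, scale=scale,
                     reversed_items=reversed_items)


class TestCollapseTristate:
    def test_default_collapses_neither_with_positive(self):
        panel = make_panel([[0], [1], [2]], scale="tristate")
        out = collapse_tristate(panel)
        assert list(out.data["item0"]) == [0.0, 0.0, 1.0]

    def test_alternative_collapses_neither_with_negative(self):
        panel = make_panel([[0], [1], [2]], scale="tristate")
        out = collapse_tristate(panel, collapse_with="negative")
        assert list(out.data["item0"]) == [0.0, 1.0, 1.0]

    def test_all_zero_panel_stays_zero(self):
        out = collapse_tristate(make_panel(np.zeros((4, 3)), scale="tristate"))
        assert out.data.to_numpy().sum() == 0

    def test_out_of_range_value_rejected(self):
        with pytest.raises(ValueError):
            collapse_tristate(make_panel([[3]], scale="tristate"))


class TestMedianSplit:
    def test_strictly_above_median_rule(self):
        panel = make_panel([[10], [20], [30], [40], [50]], scale="continuous")
        out = reverse_and_median_split(panel)
        assert list(out.data["item0"]) == [0.0, 0.0, 0.0, 1.0, 1.0]

    def test_constant_item_becomes_all_zero(self):
        out = reverse_and_median_split(make_panel(np.full((6, 1), 42.0),
                                                  scale="continuous"))
        assert out.data.to_numpy().sum() == 0

    def test_reversed_item_recoded_before_split(self):
        panel = make_panel([[80], [90], [10], [20], [30]], scale="continuous",
                           reversed_items=("item0",))
        out = reverse_and_median_split(panel)
        # recoded series (20, 10, 90, 80, 70), median 70
        assert list(out.data["item0"]) == [0.0, 0.0, 1.0, 1.0, 0.0]

    def test_value_outside_range_rejected(self):
        with pytest.raises(ValueError):
            reverse_and_median_split(make_panel([[120.0]], scale="continuous"))

    @given(st.integers(0, 2 ** 31 - 1))
    def test_invariant_to_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.random((12, 3)) * 100
        a = reverse_and_median_split(make_panel(vals, scale="continuous"))
        monotone = 100 * (vals / 100) ** 3  # strictly increasing on [0, 100]
        b = reverse_and_median_split(make_panel(monotone, scale="continuous"))
        assert a.data.equals(b.data)

    def test_kmeans_split_separates_two_clusters(self):
        vals = np.array([[5.0], [6.0], [7.0], [90.0], [92.0], [95.0]])
        out = kmeans_split(make_panel(vals, scale="continuous"))
        assert list(out.data["item0"]) == [0, 0, 0, 1, 1, 1]


class TestLocf:
    def test_missing_cell_carries_previous_value(self):
        panel = make_panel([[1.0], [np.nan], [0.0]])
        out, imputed, dropped = impute_locf(panel)
        assert list(out.data["item0"]) == [1.0, 1.0, 0.0]
        assert imputed == 1 and dropped == 0

    def test_complete_panel_is_identity(self):
        panel = make_panel([[1.0, 0.0], [0.0, 1.0]])
        out, imputed, dropped = impute_locf(panel)
        assert out.data.equals(panel.data.astype(float))
        assert imputed == 0 and dropped == 0

    def test_leading_missing_occasion_dropped(self):
        panel = make_panel([[np.nan], [1.0], [np.nan]])
        out, imputed, dropped = impute_locf(panel)
        assert out.T == 2 and dropped == 1 and imputed == 1

    def test_drop_mode_removes_missing_occasions(self):
        panel = make_panel([[1.0], [np.nan], [0.0]])
        out, imputed, dropped = impute_locf(panel, mode="drop")
        assert out.T == 2 and imputed == 0

    def test_entirely_missing_item_rejected(self):
        with pytest.raises(ValueError, match="entirely missing"):
            impute_locf(make_panel([[np.nan], [np.nan]]))

    def test_locf_never_changes_observed_cells(self):
        rng = np.random.default_rng(17)
        vals = rng.integers(0, 2, (30, 5)).astype(float)
        mask = rng.random((30, 5)) < 0.2
        mask[0] = False  # keep first occasion observed
        with_missing = np.where(mask, np.nan, vals)
        out, imputed, dropped = impute_locf(make_panel(with_missing))
        observed = ~mask
        assert np.array_equal(out.data.to_numpy()[observed], vals[observed])
        assert imputed == int(mask.sum())


class TestExclusions:
    def test_too_few_measurements(self):
        rep = apply_exclusions(make_panel(np.ones((4, 3))))
        assert not rep.included and rep.exclusion_reason == "too_few_measurements"

    def test_insufficient_variance(self):
        vals = np.zeros((50, 10))
        vals[0, 0] = 1  # 0.2% ones, below the 5% floor
        rep = apply_exclusions(make_panel(vals))
        assert rep.exclusion_reason == "insufficient_variance"

    def test_balanced_panel_included(self):
        rng = np.random.default_rng(23)
        rep = apply_exclusions(make_panel(rng.integers(0, 2, (84, 28))))
        assert rep.included and rep.exclusion_reason == "none"


class TestToCounts:
    def test_row_sums_and_densities(self):
        vals = np.zeros((2, 28))
        vals[0, :5] = 1
        y, rho = to_counts(make_panel(vals))
        assert y[0] == 5 and rho[0] == pytest.approx(5 / 28)
        assert y[1] == 0

    def test_worked_example_row_density(self):
        row = np.array([[1, 1, 0, 1, 0, 0, 1, 1, 0]], dtype=float)
        _, rho = to_counts(make_panel(row))
        assert rho[0] == pytest.approx(5 / 9)


class TestFullPipeline:
    def test_idempotent_on_complete_binary_panel(self):
        rng = np.random.default_rng(29)
        vals = rng.integers(0, 2, (40, 6)).astype(float)
        panel = make_panel(vals)
        binary, rep, y, rho = preprocess_panel(panel)
        assert binary.data.equals(panel.data)
        assert rep.included and rep.imputed_cells == 0
        assert np.array_equal(y, vals.sum(axis=1))

    def test_tristate_pipeline_end_to_end(self):
        rng = np.random.default_rng(31)
        vals = rng.integers(0, 3, (30, 8)).astype(float)
        vals[rng.random((30, 8)) < 0.1] = np.nan
        vals[0] = rng.integers(0, 3, 8)  # first occasion observed
        binary, rep, y, rho = preprocess_panel(
            make_panel(vals, scale="tristate"))
        assert rep.included
        assert set(np.unique(binary.data.to_numpy())) <= {0.0, 1.0}


def test_packaged_item_metadata_loads():
    ams = load_item_metadata("ams")
    assert ams["scale"] == "tristate" and len(ams["items"]) == 28
    assert sum(it["reversed"] for it in ams["items"]) == 15
    hnd = load_item_metadata("hnd")
    assert hnd["scale"] == "continuous" and len(hnd["items"]) == 23
    assert sum(it["reversed"] for it in hnd["items"]) == 10
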