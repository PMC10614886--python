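"""Counting, proliferation and expression statistics."""

import numpy as np
import pandas as pd
import pytest

import spindlemetrics as sm
from spindlemetrics.population import fold_change, normalize_to_control


def count_table(rows, poles=None):
    fields = pd.DataFrame(rows, columns=["field_id", "total_cells", "mitotic_cells"])
    if poles is None:
        return sm.CountTable(fields)
    return sm.CountTable(
        fields, pd.DataFrame(poles, columns=["field_id", "cell_id", "n_poles"])
    )


class TestMitoticIndex:
    def test_five_of_hundred_is_five_percent(self):
        pooled, per_field = sm.mitotic_index(count_table([("f0", 100, 5)]))
        assert pooled == pytest.approx(5.0)
        assert per_field.loc["f0"] == pytest.approx(5.0)

    def test_no_mitotic_cells_zero_percent(self):
        pooled, _ = sm.mitotic_index(count_table([("f0", 50, 0), ("f1", 50, 0)]))
        assert pooled == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            sm.mitotic_index(count_table([("f0", 0, 0)]))

    def test_estimate_within_binomial_interval(self):
        # true fraction 0.10, 20 fields x 100 cells: estimate inside the
        # 95 % binomial interval for n = 2000 in the large majority of runs
        p, n = 0.10, 2000
        half_width = 1.96 * np.sqrt(p * (1 - p) / n)
        hits = 0
        n_runs = 200
        for seed in range(n_runs):
            table, _ = sm.generate_count_table(20, 100, p, 0.0, seed=seed)
            est, _ = sm.mitotic_index(table)
            hits += abs(est / 100.0 - p) <= half_width
        assert hits / n_runs >= 0.90


class TestMultipolarFraction:
    def test_three_of_ten(self):
        poles = [("f0", f"c{i}", 3 if i < 3 else 2) for i in range(10)]
        t = count_table([("f0", 100, 10)], poles)
        assert sm.multipolar_fraction(t) == pytest.approx(30.0)

    def test_all_bipolar_zero(self):
        poles = [("f0", f"c{i}", 2) for i in range(8)]
        t = count_table([("f0", 100, 8)], poles)
        assert sm.multipolar_fraction(t) == 0.0

    def test_monopolar_cells_not_multipolar(self):
        poles = [("f0", "c0", 1), ("f0", "c1", 2), ("f0", "c2", 3), ("f0", "c3", 4)]
        t = count_table([("f0", 100, 4)], poles)
        assert sm.multipolar_fraction(t) == pytest.approx(50.0)

    def test_no_scored_cells_rejected(self):
        with pytest.raises(ValueError, match="mitotic"):
            sm.multipolar_fraction(count_table([("f0", 100, 0)]))


def growth_df(wells):
    """wells: list of (well_id, condition, batch, counts-by-time dict)."""
    rows = []
    for well_id, condition, batch, series in wells:
        for t, c in series.items():
            rows.append(
                {"well_id": well_id, "condition": condition, "batch": batch,
                 "time_h": t, "count": c}
            )
    return pd.DataFrame(rows)


class TestNormalizedFoldChange:
    def test_treated_double_of_control(self):
        df = growth_df(
            [
                ("w0", "treated", 0, {0: 100, 120: 800}),
                ("w1", "DMSO", 0, {0: 100, 120: 400}),
            ]
        )
        out = sm.normalized_fold_change(df, "DMSO").set_index("well_id")
        assert out.loc["w0", "normalized_fold_change"] == pytest.approx(2.0)

    def test_control_batch_mean_exactly_one(self):
        df = growth_df(
            [
                ("w0", "DMSO", 0, {0: 100, 96: 350}),
                ("w1", "DMSO", 0, {0: 110, 96: 500}),
                ("w2", "treated", 0, {0: 100, 96: 200}),
            ]
        )
        out = sm.normalized_fold_change(df, "DMSO")
        ctrl = out[out.condition == "DMSO"]["normalized_fold_change"]
        assert ctrl.mean() == pytest.approx(1.0)

    def test_batch_scale_invariance(self):
        wells = [
            ("w0", "treated", 0, {0: 100, 96: 420}),
            ("w1", "DMSO", 0, {0: 100, 96: 380}),
        ]
        out1 = sm.normalized_fold_change(growth_df(wells), "DMSO")
        scaled = [
            (w, c, b, {t: 3.7 * v for t, v in s.items()}) for w, c, b, s in wells
        ]
        out2 = sm.normalized_fold_change(growth_df(scaled), "DMSO")
        np.testing.assert_allclose(
            out1["normalized_fold_change"], out2["normalized_fold_change"]
        )

    def test_missing_control_names_batch(self):
        df = growth_df(
            [
                ("w0", "treated", 0, {0: 100, 96: 400}),
                ("w1", "DMSO", 0, {0: 100, 96: 300}),
                ("w2", "treated", 1, {0: 100, 96: 400}),
            ]
        )
        with pytest.raises(ValueError, match="1"):
            sm.normalized_fold_change(df, "DMSO")

    def test_simulated_rates_recover_closed_form(self):
        # treated doubling every 48 h vs control every 24 h over 120 h:
        # expected normalized fold change 2^(120/48 - 120/24) = 2^-2.5
        hours = np.arange(0.0, 121.0, 2.0)
        frames = []
        for i in range(12):
            t, _ = sm.generate_growth_series(
                np.log(2) / 48, 100, hours, 0.05, seed=i,
                well_id=f"t{i}", condition="treated",
            )
            c, _ = sm.generate_growth_series(
                np.log(2) / 24, 100, hours, 0.05, seed=100 + i,
                well_id=f"c{i}", condition="DMSO",
            )
            frames += [t, c]
        out = sm.normalized_fold_change(pd.concat(frames), "DMSO")
        med = out[out.condition == "treated"]["normalized_fold_change"].median()
        expected = 2.0**-2.5
        assert abs(med - expected) / expected < 0.15

    def test_fold_change_requires_increasing_times(self):
        with pytest.raises(ValueError, match="increasing"):
            fold_change(np.array([0.0, 0.0]), np.array([100.0, 200.0]))


class TestExpression:
    def make_image(self, scale=1.0):
        arr = np.full((50, 50), 100.0)
        arr[10:20, 10:20] = 500.0
        return sm.SpindleImage({"kif18a": scale * arr}, pixel_size=0.1)

    def test_corrected_is_spindle_minus_background(self):
        rec = sm.expression_level(
            self.make_image(), (10, 10, 20, 20), (30, 30, 45, 45), cell_id="c0"
        )
        assert rec.spindle_mean == pytest.approx(500.0)
        assert rec.background_mean == pytest.approx(100.0)
        assert rec.corrected == pytest.approx(400.0)

    def test_linearity_under_intensity_doubling(self):
        r1 = sm.expression_level(self.make_image(1.0), (10, 10, 20, 20), (30, 30, 45, 45))
        r2 = sm.expression_level(self.make_image(2.0), (10, 10, 20, 20), (30, 30, 45, 45))
        assert r2.corrected == pytest.approx(2.0 * r1.corrected)

    def test_control_normalization_mean_one(self):
        recs = [
            sm.expression_level(
                self.make_image(s), (10, 10, 20, 20), (30, 30, 45, 45),
                cell_id=f"ctrl{i}",
            )
            for i, s in enumerate((0.8, 1.0, 1.2))
        ]
        normalize_to_control(recs, {r.cell_id for r in recs})
        assert np.mean([r.normalized for r in recs]) == pytest.approx(1.0)

    def test_overlapping_rois_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            sm.expression_level(self.make_image(), (10, 10, 20, 20), (15, 15, 30, 30))

    def test_negative_corrected_warned_not_raised(self):
        img = self.make_image()
        with pytest.warns(UserWarning, match="negative"):
            rec = sm.expression_level(img, (30, 30, 45, 45), (10, 10, 20, 20))
        assert rec.corrected < 0
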