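"""Clarke error grid, limit of detection and repeatability summaries."""
import numpy as np
import pandas as pd
import pytest

from papeors import (
    cega_zone,
    cega_zones,
    estimate_lod,
    repeatability,
    zone_percentages,
)

R_D_LEFT = 175.0 / 3.0


def clarke_zone_oracle(r: float, p: float) -> str:
    """Independent scalar coding of the published Clarke regions.

    Membership of every closed region is evaluated separately from first
    principles (line equations of the published grid) and the
    alphabetically earliest matching zone wins, which encodes the
    boundary tie-break.
    """
    on_a = abs(p - r) <= 0.2 * r or (r <= 70 and p <= 70)

    upper_b = r >= 70 and p >= 1.2 * r and not (70 < r < 290 and p > r + 110)
    lower_b = (
        r >= 70
        and p <= 0.8 * r
        and not (130 < r < 180 and p < 1.4 * r - 182)
        and not (r > 240 and 70 < p < 180)
        and not (r > 180 and p < 70)
    )
    on_b = upper_b or lower_b

    on_c = (70 <= r <= 290 and p >= r + 110) or (130 <= r <= 180 and p <= 1.4 * r - 182)

    on_d = (
        (r <= R_D_LEFT and 70 <= p <= 180)
        or (R_D_LEFT <= r <= 70 and 1.2 * r <= p <= 180)
        or (r >= 240 and 70 <= p <= 180)
    )

    on_e = (r <= 70 and p >= 180) or (r >= 180 and p <= 70)

    for zone, hit in zip("ABCDE", (on_a, on_b, on_c, on_d, on_e)):
        if hit:
            return zone
    raise AssertionError(f"point ({r}, {p}) not covered")


class TestClarkeZones:
    @pytest.mark.parametrize(
        "reference, predicted, zone",
        [
            (200.0, 200.0, "A"),  # perfect prediction
            (100.0, 119.0, "A"),  # 19% relative error is within 20%
            (50.0, 250.0, "E"),  # hypoglycemia read as hyperglycemia
            (60.0, 65.0, "A"),  # both below 70
            (100.0, 250.0, "C"),  # overcorrection region
            (50.0, 150.0, "D"),  # missed hypoglycemia
            (300.0, 150.0, "D"),  # missed hyperglycemia
            (250.0, 60.0, "E"),
            (200.0, 250.0, "B"),
        ],
    )
    def test_rule_oracle_examples(self, reference, predicted, zone):
        assert cega_zone(reference, predicted) == zone

    @pytest.mark.parametrize(
        "reference, predicted, zone",
        [
            (100.0, 120.0, "A"),  # exactly on the 1.2 R line -> A beats B
            (100.0, 210.0, "B"),  # exactly on the C boundary -> B beats C
            (240.0, 100.0, "B"),  # on the D boundary -> B beats D
            (180.0, 50.0, "B"),  # on the E boundary -> B beats E
            (R_D_LEFT, 70.0, "A"),  # corner of the hypo square -> A
        ],
    )
    def test_boundary_points_go_to_better_zone(self, reference, predicted, zone):
        """Points exactly on a shared boundary take the alphabetically earlier zone."""
        assert cega_zone(reference, predicted) == zone

    def test_agrees_with_bruteforce_oracle_on_grid(self):
        """Zero disagreements with the independent coding on a dense grid."""
        values = np.linspace(0.0, 400.0, 120)
        rr, pp = np.meshgrid(values, values)
        ours = cega_zones(rr.ravel(), pp.ravel())
        theirs = [clarke_zone_oracle(r, p) for r, p in zip(rr.ravel(), pp.ravel())]
        assert int(np.sum(ours != np.asarray(theirs))) == 0

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            cega_zone(-1.0, 100.0)


class TestZonePercentages:
    def test_28_of_32_in_zone_a(self):
        zones = ["A"] * 28 + ["B"] * 4
        result = zone_percentages(zones)
        assert result.zone_percentages["A"] == pytest.approx(87.5)
        assert result.n_points == 32

    def test_all_a(self):
        result = zone_percentages(["A", "A", "A"])
        assert result.zone_percentages["A"] == 100.0
        assert sum(result.zone_percentages.values()) == pytest.approx(100.0)

    def test_uniform_zones(self):
        result = zone_percentages(list("ABCDE"))
        assert all(v == pytest.approx(20.0) for v in result.zone_percentages.values())

    def test_counts_conserved(self):
        zones = list("AABBBCDE")
        result = zone_percentages(zones)
        counts = {z: round(result.zone_percentages[z] * result.n_points / 100) for z in "ABCDE"}
        assert sum(counts.values()) == len(zones)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            zone_percentages([])


class TestEstimateLOD:
    def test_all_zone_a_gives_min_reference(self):
        reference = np.repeat([90.0, 200.0, 400.0], 3)
        predicted = reference * 1.05
        assert estimate_lod(reference, predicted) == 90.0

    def test_no_zone_a_gives_absent(self):
        reference = np.repeat([100.0, 300.0], 3)
        predicted = np.repeat([160.0, 480.0], 3)  # 60% error everywhere
        assert estimate_lod(reference, predicted) is None

    def test_failing_below_passing_above(self):
        """Failures below 100 put the LOD at the smallest passing level."""
        reference = np.repeat([80.0, 90.0, 100.0, 200.0, 300.0], 2)
        predicted = reference * 1.05
        predicted[reference == 80.0] = 160.0  # gross failures at 80
        predicted[reference == 90.0] = 180.0  # and at 90
        assert estimate_lod(reference, predicted) == 100.0

    def test_monotone_adding_passing_level_never_raises_lod(self):
        reference = np.repeat([100.0, 200.0], 2)
        predicted = reference * 1.1
        base = estimate_lod(reference, predicted)
        extended_ref = np.concatenate([reference, [300.0, 300.0]])
        extended_pred = np.concatenate([predicted, [310.0, 305.0]])
        assert estimate_lod(extended_ref, extended_pred) <= base

    def test_replicate_rule_stricter_than_mean(self):
        reference = np.array([100.0, 100.0, 200.0, 200.0])
        predicted = np.array([95.0, 135.0, 205.0, 210.0])  # one bad replicate at 100
        assert estimate_lod(reference, predicted, rule="replicate") == 200.0
        assert estimate_lod(reference, predicted, rule="mean") == 100.0

    def test_calibration_rule(self):
        rng = np.random.default_rng(5)
        reference = np.tile(np.linspace(90, 400, 10), 3)
        predicted = reference + rng.normal(0, 5.0, reference.size)
        lod = estimate_lod(reference, predicted, rule="calibration")
        assert 0 < lod < 90.0  # 3.3 sigma / slope with small residuals

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            estimate_lod([], [])


class TestRepeatability:
    @staticmethod
    def _frame():
        rows = []
        for day in (1, 2):
            for conc in (120.0, 250.0, 400.0):
                for rep in range(3):
                    rows.append({"day": day, "concentration": conc,
                                 "theta": 0.002 * conc})
        return pd.DataFrame(rows)

    def test_identical_replicates_zero_cv(self):
        out = repeatability(self._frame())
        assert np.allclose(out["sd"], 0.0)
        assert np.allclose(out["cv"], 0.0)

    def test_equal_day_means_no_shift(self):
        out = repeatability(self._frame())
        day1 = out[out["day"] == 1].set_index("concentration")["mean"]
        day2 = out[out["day"] == 2].set_index("concentration")["mean"]
        assert np.allclose(day1 - day2, 0.0)

    def test_planted_day_shift_detected(self):
        frame = self._frame()
        frame.loc[frame["day"] == 2, "theta"] *= 1.10
        out = repeatability(frame)
        day1 = out[out["day"] == 1].set_index("concentration")["mean"]
        day2 = out[out["day"] == 2].set_index("concentration")["mean"]
        shift = (day2 / day1 - 1.0).to_numpy()
        assert np.allclose(shift, 0.10, atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            repeatability(pd.DataFrame())
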