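"""qPCR quantitation: standard curves, Cq inversion, 24-h normalization, ratios."""

import numpy as np
import pandas as pd
import pytest

from podosim import (
    build_cohort,
    cq_to_copies,
    fit_standard_curve,
    marker_ratios,
    normalize_to_24h,
    quantify_plate,
)
from podosim.scenarios import fafa_arm

PERFECT_SLOPE = -3.3219  # Cq per log10 copies at 100% efficiency


class TestStandardCurve:
    def test_perfect_doubling_series(self):
        copies = np.array([1e6, 1e5, 1e4, 1e3])
        cq = np.array([15.0, 18.3219, 21.6439, 24.9658])
        curve = fit_standard_curve(copies, cq, gene="podocin")
        assert curve.slope == pytest.approx(PERFECT_SLOPE, abs=1e-3)
        assert curve.efficiency == pytest.approx(1.0, abs=1e-3)
        assert curve.accepted

    def test_flat_cq_rejected(self):
        curve = fit_standard_curve([1e6, 1e4, 1e2], [20.0, 20.0, 20.0])
        assert not curve.accepted

    def test_too_few_points_error(self):
        with pytest.raises(ValueError):
            fit_standard_curve([1e6, 1e4], [15.0, 20.0])

    def test_narrow_span_error(self):
        with pytest.raises(ValueError):
            fit_standard_curve([1e6, 8e5, 6e5], [15.0, 15.3, 15.6])

    def test_noisy_curve_recovers_efficiency(self, rng):
        copies = 10.0 ** np.arange(2, 7)
        true_cq = PERFECT_SLOPE * np.log10(copies) + 35.0
        effs = []
        for _ in range(50):
            curve = fit_standard_curve(copies, true_cq + rng.normal(0, 0.1, copies.size))
            effs.append(curve.efficiency)
        assert np.mean(effs) == pytest.approx(1.0, abs=0.05)


class TestQuantitation:
    def _curve(self):
        copies = 10.0 ** np.arange(1, 7)
        return fit_standard_curve(copies, PERFECT_SLOPE * np.log10(copies) + 35.0)

    def test_cq_at_intercept_is_one_copy(self):
        curve = self._curve()
        assert cq_to_copies(curve.intercept, curve) == pytest.approx(1.0)

    def test_round_trip_exact_without_noise(self):
        curve = self._curve()
        for copies in (17.0, 1e3, 2.4e6):
            cq = curve.slope * np.log10(copies) + curve.intercept
            assert cq_to_copies(cq, curve) == pytest.approx(copies, rel=1e-9)

    def test_one_log_is_3_32_cycles_at_full_efficiency(self):
        curve = self._curve()
        cq_1e3 = curve.slope * 3 + curve.intercept
        assert cq_to_copies(cq_1e3 - 3.3219, curve) == pytest.approx(1e4, rel=1e-3)

    def test_rejected_curve_cannot_quantify(self):
        bad = fit_standard_curve([1e6, 1e4, 1e2], [20.0, 20.0, 20.0])
        with pytest.raises(ValueError):
            cq_to_copies(18.0, bad)


class TestNormalization:
    def test_17h_worked_example(self):
        assert normalize_to_24h(1700.0, 17.0) == pytest.approx(2400.0)

    def test_24h_identity_and_idempotence(self):
        assert normalize_to_24h(123.4, 24.0) == pytest.approx(123.4)
        once = normalize_to_24h(50.0, 12.0)
        assert normalize_to_24h(once, 24.0) == pytest.approx(once)

    def test_zero_measurement_stays_zero(self):
        assert normalize_to_24h(0.0, 17.0) == 0.0

    def test_nonpositive_hours_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_24h(10.0, 0.0)


class TestMarkerRatios:
    def test_podocin_aquaporin2_arithmetic(self):
        r = marker_ratios({"podocin": 400.0, "aquaporin2": 50.0, "nephrin": 100.0})
        assert r["podocin_aquaporin2"] == pytest.approx(8.0)
        assert r["podocin_nephrin"] == pytest.approx(4.0)

    def test_equal_copies_ratio_one(self):
        r = marker_ratios({"podocin": 7.0, "aquaporin2": 7.0})
        assert r["podocin_aquaporin2"] == pytest.approx(1.0)

    def test_zero_denominator_missing_with_warning(self):
        with pytest.warns(UserWarning):
            r = marker_ratios({"podocin": 5.0, "aquaporin2": 0.0})
        assert np.isnan(r["podocin_aquaporin2"])

    def test_ratio_invariant_to_collection_duration(self):
        """Both genes scale with hours, so the ratio does not depend on it."""
        copies = {"podocin": 480.0, "aquaporin2": 30.0}
        for hours in (8.0, 17.0, 24.0):
            scaled = {
                g: float(normalize_to_24h(v * hours / 24.0, hours))
                for g, v in copies.items()
            }
            assert marker_ratios(scaled)["podocin_aquaporin2"] == pytest.approx(16.0)

    def test_gapdh_ratios_for_cortex_mode(self):
        r = marker_ratios({"podocin": 30.0, "nephrin": 10.0, "aquaporin2": 5.0, "gapdh": 10.0})
        assert r["podocin_gapdh"] == pytest.approx(3.0)
        assert r["aquaporin2_gapdh"] == pytest.approx(0.5)


def test_quantify_plate_recovers_truth_copies():
    """End-to-end: simulated plate -> curves -> copies/24 h close to truth."""
    arm = fafa_arm(weeks=[30])
    cohort = build_cohort(arm, seed=77)
    quant, curves = quantify_plate(cohort.plate_table(), arm.qpcr)
    assert all(c.accepted for c in curves.values())
    merged = quant.merge(cohort.urine, on=["animal_id", "week"])
    ratio = merged["podocin_copies_per_24h"] / merged["podocin_true_copies_per_24h"]
    # Cq noise sigma 0.15 -> per-sample copy error ~10%; means agree closely
    assert ratio.mean() == pytest.approx(1.0, abs=0.1)
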