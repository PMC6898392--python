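"""Cohort generator: config validation, truth trajectories, determinism."""

import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

from podosim import build_cohort, simulate_albuminuria, simulate_urine_collection
from podosim.scenarios import control_arm, cr40_arm, fafa_arm


class TestConfigValidation:
    def test_rejects_nonpositive_animal_count(self):
        with pytest.raises(ValidationError, match="n_animals"):
            type(fafa_arm()).model_validate(fafa_arm().model_dump() | {"n_animals": 0})

    def test_rejects_non_monotone_weeks(self):
        with pytest.raises(ValidationError, match="weeks"):
            type(fafa_arm()).model_validate(fafa_arm().model_dump() | {"weeks": [6, 6, 15]})

    def test_rejects_positive_loss_slope(self):
        with pytest.raises(ValidationError, match="slope"):
            type(fafa_arm()).model_validate(
                fafa_arm().model_dump() | {"podocyte_loss_slope": 0.5}
            )

    def test_rejects_non_monotone_albumin_anchors(self):
        bad = fafa_arm().model_dump()
        bad["albumin_link"]["anchors"] = [(50.0, 10.0), (100.0, 20.0)]
        with pytest.raises(ValidationError, match="decrease"):
            type(fafa_arm()).model_validate(bad)


class TestTruthTrajectories:
    def test_six_week_volume_ratio_is_1_6(self):
        """The configured fa/fa : control glomerular volume ratio at week 6."""
        f = fafa_arm().lookup(fafa_arm().glom_volume_trajectory, 6)
        c = control_arm().lookup(control_arm().glom_volume_trajectory, 6)
        assert f / c == pytest.approx(1.6, rel=0.01)

    def test_zero_slope_means_constant_count(self):
        arm = control_arm()
        counts = [arm.true_podocyte_count(w) for w in arm.weeks]
        assert len(set(counts)) == 1

    def test_configured_loss_over_forty_weeks(self):
        arm = fafa_arm()
        drop = arm.true_podocyte_count(6) - arm.true_podocyte_count(46)
        assert drop == pytest.approx(1.49 * 40)

    def test_mean_count_follows_slope_within_sampling_noise(self):
        cohort = build_cohort(fafa_arm(), seed=5)
        mean_n = cohort.glomeruli.groupby("week")["n_podocytes"].mean()
        arm = fafa_arm()
        for week, value in mean_n.items():
            assert value == pytest.approx(arm.true_podocyte_count(week), rel=0.12)

    def test_cr_density_stabilizes_near_82(self):
        arm = cr40_arm()
        n30 = arm.true_podocyte_count(30)
        v30 = arm.lookup(arm.glom_volume_trajectory, 30)
        assert n30 / v30 * 1e6 == pytest.approx(82.0, rel=0.01)


class TestDeterminism:
    def test_identical_seed_reproduces_cohort(self):
        a = build_cohort(fafa_arm(weeks=[6, 15]), seed=9)
        b = build_cohort(fafa_arm(weeks=[6, 15]), seed=9)
        pd.testing.assert_frame_equal(a.glomeruli, b.glomeruli)
        pd.testing.assert_frame_equal(a.urine, b.urine)
        pd.testing.assert_frame_equal(a.standards, b.standards)

    def test_different_seed_changes_draws(self):
        a = build_cohort(fafa_arm(weeks=[6]), seed=9)
        b = build_cohort(fafa_arm(weeks=[6]), seed=10)
        assert not a.glomeruli["volume_um3"].equals(b.glomeruli["volume_um3"])


class TestAlbuminLink:
    @pytest.mark.parametrize(
        "arm_fn,density,expected",
        [
            (fafa_arm, 100.0, 10.0),
            (fafa_arm, 65.0, 100.0),
            (fafa_arm, 82.0, 20.0),
        ],
    )
    def test_anchor_values_noiseless(self, arm_fn, density, expected):
        assert simulate_albuminuria(density, arm_fn()) == pytest.approx(expected)

    def test_control_albumin_below_1_at_density_100(self):
        assert simulate_albuminuria(100.0, control_arm()) < 1.0

    def test_monotone_non_increasing_in_density(self):
        arm = fafa_arm()
        grid = np.linspace(30, 300, 200)
        values = [simulate_albuminuria(d, arm) for d in grid]
        assert all(b <= a + 1e-12 for a, b in zip(values, values[1:]))

    def test_nonpositive_density_rejected(self):
        with pytest.raises(ValueError):
            simulate_albuminuria(0.0, fafa_arm())


class TestUrineCollection:
    def test_24h_collection_is_identity(self, rng):
        arm = fafa_arm()
        row = simulate_urine_collection(
            "a", 30, arm, rng, true_density=100.0, hours=24.0,
            mrna_noise_sd=0.0, cq_noise_sd=0.0,
        )
        assert row["podocin_copies_collected"] == pytest.approx(
            row["podocin_true_copies_per_24h"]
        )

    def test_17h_collection_scales_copies(self, rng):
        arm = fafa_arm()
        row = simulate_urine_collection(
            "a", 30, arm, rng, true_density=100.0, hours=17.0,
            mrna_noise_sd=0.0, cq_noise_sd=0.0,
        )
        assert row["podocin_copies_collected"] == pytest.approx(
            row["podocin_true_copies_per_24h"] * 17.0 / 24.0
        )
        # worked example: 2400 copies/24 h over 17 h -> 1700 collected
        assert 2400.0 * 17.0 / 24.0 == pytest.approx(1700.0)

    def test_truth_podocin_aquaporin2_arm_separation_is_88_fold(self):
        fafa = fafa_arm()
        ctrl = control_arm()
        r_f = fafa.true_mrna_copies_per_24h("podocin", 30) / fafa.true_mrna_copies_per_24h("aquaporin2", 30)
        r_c = ctrl.true_mrna_copies_per_24h("podocin", 30) / ctrl.true_mrna_copies_per_24h("aquaporin2", 30)
        assert r_f / r_c == pytest.approx(88.0, rel=1e-6)


def test_detachment_budget_closes_in_truth():
    """With recovery fraction 1, podocin-derived detachment equals the count drop."""
    arm = fafa_arm()
    arm = arm.model_copy(deep=True)
    arm.mrna_truth.urine_recovery_fraction = 1.0
    weeks = np.array([6.0, 46.0])
    rate_per_day = arm.true_mrna_copies_per_24h("podocin", 30) / arm.mrna_truth.copies_per_podocyte
    detached = rate_per_day * 7.0 * (weeks[-1] - weeks[0])
    loss = (arm.true_podocyte_count(6) - arm.true_podocyte_count(46)) * arm.glomeruli_per_animal
    assert detached == pytest.approx(loss, rel=1e-12)
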