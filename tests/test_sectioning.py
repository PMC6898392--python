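"""Virtual microtome: profile geometry, nuclear slab counting, label scoring."""

import numpy as np
import pandas as pd
import pytest

from podosim import (
    GlomerulusTruth,
    SectionPlan,
    build_cohort,
    count_label_positive,
    section_cohort,
    section_glomerulus,
    sclerosis_index,
)
from podosim.scenarios import cr40_arm, fafa_arm
from podosim.sectioning import profiles_to_frame


def _glom(R=50.0, n=0, d=6.5, ps6=0, sclerotic=False):
    return GlomerulusTruth(
        animal_id="a",
        week=6,
        radius_um=R,
        volume_um3=4.0 / 3.0 * np.pi * R**3,
        n_podocytes=n,
        nucleus_d_um=d,
        aa_true=0.3,
        sclerotic=sclerotic,
        ps6_positive_count=ps6,
    )


class _FixedOffsetRng:
    """Generator stub returning a fixed plane offset for geometry checks."""

    def __init__(self, z):
        self.z = z
        self._rng = np.random.default_rng(0)

    def uniform(self, lo, hi, size=None):
        return self.z

    def __getattr__(self, name):
        return getattr(self._rng, name)


class TestProfileGeometry:
    def test_equatorial_plane_gives_full_radius(self):
        rec = section_glomerulus(_glom(R=50), SectionPlan(), _FixedOffsetRng(0.0))
        assert rec.equivalent_radius_um == pytest.approx(50.0)

    def test_offset_plane_follows_pythagoras(self):
        rec = section_glomerulus(_glom(R=50), SectionPlan(), _FixedOffsetRng(40.0))
        assert rec.equivalent_radius_um == pytest.approx(30.0)

    def test_mean_profile_radius_is_pi_over_4_R(self, rng):
        """Random planes through a sphere: E[r_p] = (pi/4) R."""
        g = _glom(R=50)
        plan = SectionPlan()
        radii = [
            section_glomerulus(g, plan, rng).equivalent_radius_um for _ in range(20_000)
        ]
        assert np.mean(radii) == pytest.approx(np.pi / 4 * 50, rel=0.005)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            SectionPlan(thickness_um=0.0)
        with pytest.raises(ValueError):
            _glom(R=-1.0)


class TestNuclearCounting:
    @pytest.mark.parametrize("T,d", [(1.0, 4.0), (1.5, 6.5), (3.0, 8.0)])
    def test_expected_count_matches_abercrombie_geometry(self, T, d):
        """Counts per tuft profile area approach density x (T + d)."""
        R = 75.0
        density = 250e-6  # per um^3
        n = int(round(density * 4.0 / 3.0 * np.pi * R**3))
        g = _glom(R=R, n=n, d=d)
        plan = SectionPlan(thickness_um=T)
        rng = np.random.default_rng(7)
        counts, areas = [], []
        for _ in range(3000):
            rec = section_glomerulus(g, plan, rng)
            counts.append(rec.nuclear_profile_count)
            areas.append(rec.tuft_area_um2)
        apparent = np.sum(counts) / np.sum(areas)
        assert apparent / (T + d) == pytest.approx(density, rel=0.03)


class TestLabelScoring:
    def test_all_positive_scores_100_percent(self):
        frame = profiles_to_frame([])
        frame = pd.DataFrame(
            {"nuclear_profile_count": [5, 8], "ps6_positive_nuclei": [5, 8]}
        )
        assert count_label_positive(frame) == pytest.approx(100.0)

    def test_zero_positive_scores_0_percent(self):
        frame = pd.DataFrame(
            {"nuclear_profile_count": [5, 8], "ps6_positive_nuclei": [0, 0]}
        )
        assert count_label_positive(frame) == pytest.approx(0.0)

    def test_empty_profiles_report_missing(self):
        frame = pd.DataFrame({"nuclear_profile_count": [0], "ps6_positive_nuclei": [0]})
        with pytest.warns(UserWarning):
            assert np.isnan(count_label_positive(frame))

    def test_cr_cohort_recovers_28_percent_ps6(self):
        cohort = build_cohort(cr40_arm(weeks=[30]), seed=21)
        with pytest.warns(UserWarning):
            plan = SectionPlan(profiles_per_animal=12)
        profiles = section_cohort(cohort, plan, seed=22)
        assert count_label_positive(profiles) == pytest.approx(28.0, abs=3.0)

    def test_fafa_cohort_recovers_78_percent_ps6(self, fafa_cohort):
        _, profiles = fafa_cohort
        sub = profiles[profiles["week"] == 30]
        assert count_label_positive(sub) == pytest.approx(78.0, abs=3.0)


class TestSclerosisIndex:
    def test_fraction_arithmetic(self):
        frame = pd.DataFrame({"sclerotic": [True] * 14 + [False] * 16})
        assert sclerosis_index(frame) == pytest.approx(100 * 14 / 30, abs=0.1)

    def test_no_lesions_scores_zero(self):
        frame = pd.DataFrame({"sclerotic": [False] * 30})
        assert sclerosis_index(frame) == 0.0

    def test_few_profiles_warn_but_compute(self):
        frame = pd.DataFrame({"sclerotic": [True] * 5})
        with pytest.warns(UserWarning):
            assert sclerosis_index(frame) == 100.0

    def test_empty_profiles_error(self):
        with pytest.raises(ValueError):
            sclerosis_index(pd.DataFrame({"sclerotic": []}))


def test_section_cohort_deterministic(fafa_cohort):
    cohort, profiles = fafa_cohort
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        again = section_cohort(cohort, SectionPlan(profiles_per_animal=40), seed=315)
    pd.testing.assert_frame_equal(profiles, again)
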