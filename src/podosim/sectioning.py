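"""Virtual microtome and profile measurement.

Cuts thin (default 1.5 um) sections through spherical tuft models at a
uniformly random offset and records what the imaging layer would measure on
each profile: equivalent-circle radius, the number of podocyte (WT1+)
nuclear profiles appearing in the slab, the GLEPP1-positive area fraction,
phospho-S6-positive nuclear counts, and the sclerosis flag.

A nucleus (sphere of caliper diameter d) is counted whenever it intersects
the slab [z, z + T]; this "profile counting" rule is exactly what makes the
downstream section-thickness correction necessary: the expected count per
tuft profile area is ~ density x (T + d), not density x T.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTruth, GlomerulusTruth

__all__ = [
    "SectionPlan",
    "ProfileRecord",
    "section_glomerulus",
    "section_cohort",
    "count_label_positive",
    "sclerosis_index",
    "profiles_to_frame",
]


@dataclass(frozen=True)
class SectionPlan:
    """Sectioning protocol: slab thickness, profiles per animal, raster scale."""

    thickness_um: float = 1.5
    profiles_per_animal: int = 40
    pixel_size_um: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.thickness_um <= 0:
            raise ValueError("section thickness must be positive")
        if not 1 <= self.profiles_per_animal <= 1000:
            raise ValueError("profiles_per_animal out of range")
        if not 30 <= self.profiles_per_animal <= 50:
            warnings.warn(
                "protocols typically score 30-50 consecutive glomerular profiles",
                stacklevel=2,
            )


@dataclass(frozen=True)
class ProfileRecord:
    """One measured glomerular section profile."""

    glomerulus_id: str
    animal_id: str
    week: int
    equivalent_radius_um: float  # r_p = sqrt(A_p / pi)
    tuft_area_um2: float
    nuclear_profile_count: int  # WT1+ nuclei intersecting the slab
    glepp1_area_fraction: float
    ps6_positive_nuclei: int
    sclerotic: bool

    def __post_init__(self) -> None:
        if not 0 <= self.glepp1_area_fraction <= 1:
            raise ValueError("glepp1_area_fraction must be in [0, 1]")
        if self.ps6_positive_nuclei > self.nuclear_profile_count:
            raise ValueError("positive nuclei cannot exceed counted nuclei")


def _sample_nucleus_heights(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """z-coordinates of n points uniform in a ball of the given radius."""
    if n == 0:
        return np.empty(0)
    xyz = rng.standard_normal((n, 3))
    xyz /= np.linalg.norm(xyz, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return xyz[:, 2] * r


def section_glomerulus(
    g: GlomerulusTruth,
    plan: SectionPlan,
    rng: np.random.Generator,
    glomerulus_id: str | None = None,
) -> ProfileRecord:
    """Cut one random section through a tuft and measure the profile.

    The section plane offset z is uniform over [-R, R] (i.e. conditioned on
    the plane hitting the tuft); the profile radius is sqrt(R^2 - z^2).
    Nuclei are placed uniformly in the tuft ball and counted when their
    sphere of diameter d intersects the slab [z, z + T].  Phospho-S6
    positivity of counted nuclei follows the tuft's positive fraction
    (hypergeometric sampling of which nuclei are in the slab).
    """
    R = g.radius_um
    T = plan.thickness_um
    if R <= 0 or T <= 0:
        raise ValueError("radius and thickness must be positive")
    z = float(rng.uniform(-R, R))
    r_p = float(np.sqrt(max(R**2 - z**2, 0.0)))
    area = np.pi * r_p**2

    h = _sample_nucleus_heights(rng, g.n_podocytes, R)
    half_d = g.nucleus_d_um / 2.0
    in_slab = (h >= z - half_d) & (h <= z + T + half_d)
    n_p = int(in_slab.sum())

    # which of the counted nuclei are pS6+: hypergeometric draw
    ps6_in_slab = (
        int(rng.hypergeometric(g.ps6_positive_count, g.n_podocytes - g.ps6_positive_count, n_p))
        if n_p > 0 and g.ps6_positive_count > 0
        else 0
    )

    aa_p = float(np.clip(rng.normal(g.aa_true, 0.03), 0.0, 1.0))
    return ProfileRecord(
        glomerulus_id=glomerulus_id or f"{g.animal_id}_w{g.week}",
        animal_id=g.animal_id,
        week=g.week,
        equivalent_radius_um=r_p,
        tuft_area_um2=area,
        nuclear_profile_count=n_p,
        glepp1_area_fraction=aa_p,
        ps6_positive_nuclei=ps6_in_slab,
        sclerotic=g.sclerotic,
    )


def section_cohort(
    cohort: CohortTruth,
    plan: SectionPlan,
    seed: int | None = None,
) -> pd.DataFrame:
    """Section every animal/week of a cohort: one section per sampled glomerulus.

    ``plan.profiles_per_animal`` glomeruli are drawn (without replacement
    when possible) from each animal-week's sampled glomeruli, emulating the
    scoring of 30-50 consecutive glomerular profiles per animal.  Returns a
    tidy profile table.
    """
    seed = plan.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 1]))
    rows = []
    gframe = cohort.glomeruli
    for (animal_id, week), sub in gframe.groupby(["animal_id", "week"], sort=True):
        k = min(plan.profiles_per_animal, len(sub))
        idx = rng.choice(len(sub), size=k, replace=len(sub) < plan.profiles_per_animal)
        for i in idx:
            row = sub.iloc[int(i)]
            g = GlomerulusTruth(
                animal_id=row.animal_id,
                week=int(row.week),
                radius_um=row.radius_um,
                volume_um3=row.volume_um3,
                n_podocytes=int(row.n_podocytes),
                nucleus_d_um=row.nucleus_d_um,
                aa_true=row.aa_true,
                sclerotic=bool(row.sclerotic),
                ps6_positive_count=int(row.ps6_positive_count),
            )
            rec = section_glomerulus(g, plan, rng, glomerulus_id=row.glomerulus_id)
            rows.append(rec)
    out = profiles_to_frame(rows)
    out.insert(0, "arm_id", cohort.arm.arm_id)
    return out


def profiles_to_frame(profiles: list[ProfileRecord]) -> pd.DataFrame:
    """Tidy DataFrame from a list of profile records."""
    return pd.DataFrame(
        {
            "glomerulus_id": [p.glomerulus_id for p in profiles],
            "animal_id": [p.animal_id for p in profiles],
            "week": [p.week for p in profiles],
            "equivalent_radius_um": [p.equivalent_radius_um for p in profiles],
            "tuft_area_um2": [p.tuft_area_um2 for p in profiles],
            "nuclear_profile_count": [p.nuclear_profile_count for p in profiles],
            "glepp1_area_fraction": [p.glepp1_area_fraction for p in profiles],
            "ps6_positive_nuclei": [p.ps6_positive_nuclei for p in profiles],
            "sclerotic": [p.sclerotic for p in profiles],
        }
    )


def count_label_positive(profiles: pd.DataFrame) -> float:
    """Percent label-positive podocyte nuclei, averaged over profiles.

    Mean over profiles (with at least one counted nucleus) of
    100 x positive / counted.  Returns NaN when every profile is empty.
    Works for any per-nucleus label scored against the nuclear count
    (phospho-S6 here; Ki67 or PAX8 double labels use the same operation).
    """
    sub = profiles[profiles["nuclear_profile_count"] > 0]
    if sub.empty:
        warnings.warn("no profiles with counted nuclei; percent positive undefined")
        return float("nan")
    frac = sub["ps6_positive_nuclei"] / sub["nuclear_profile_count"]
    return float(100.0 * frac.mean())


def sclerosis_index(profiles: pd.DataFrame) -> float:
    """Percent of glomerular profiles flagged sclerotic (glomerulosclerosis index)."""
    n = len(profiles)
    if n == 0:
        raise ValueError("no profiles")
    if n < 30:
        warnings.warn("fewer than 30 profiles; sclerosis index will be noisy")
    return float(100.0 * profiles["sclerotic"].mean())
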