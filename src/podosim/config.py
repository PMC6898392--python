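"""Experimental-arm configuration and validation.

An :class:`ArmConfig` holds the ground-truth parameters for one experimental
arm (genotype x diet) of a longitudinal rat cohort: glomerular volume
trajectories, podocyte number kinetics, the density->albuminuria link,
urinary mRNA excretion truth, hormone levels, and assay noise settings.
Configs are plain data (pydantic models) and can be loaded from YAML/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

Genotype = Literal["fa/fa", "Fa/fa"]
Diet = Literal["ad-libitum", "CR40"]

GENES = ("podocin", "nephrin", "aquaporin2")


class AlbuminLink(BaseModel):
    """Piecewise-linear map from podocyte density to 24-h albumin excretion.

    ``anchors`` are (density per 1e6 um^3, albumin mg/day) pairs, strictly
    monotone: higher podocyte density -> lower albuminuria.  Values outside
    the anchored range are clamped to the end anchors.  ``noise_sd`` is the
    sigma of multiplicative lognormal noise applied per collection.
    """

    anchors: list[tuple[float, float]]
    noise_sd: float = 0.25

    @field_validator("anchors")
    @classmethod
    def _check_anchors(cls, v: list[tuple[float, float]]) -> list[tuple[float, float]]:
        if len(v) < 2:
            raise ValueError("albumin link needs at least two anchors")
        v = sorted(v)
        dens = [a[0] for a in v]
        alb = [a[1] for a in v]
        if any(d2 <= d1 for d1, d2 in zip(dens, dens[1:])):
            raise ValueError("anchor densities must be strictly increasing")
        if any(a2 >= a1 for a1, a2 in zip(alb, alb[1:])):
            raise ValueError("albumin must strictly decrease as density increases")
        return v

    @field_validator("noise_sd")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("noise_sd must be >= 0")
        return v


class MrnaTruth(BaseModel):
    """True urinary mRNA excretion (copies/24 h) per gene.

    When ``podocin_linked_to_detachment`` is set, the podocin trajectory is
    derived at cohort-build time from the podocyte loss slope:

        copies/24 h = (podocytes detached per day over both kidneys)
                      x copies_per_podocyte x urine_recovery_fraction

    which makes the urinary-pellet podocyte budget close by construction.
    """

    trajectories: dict[str, dict[int, float]]
    copies_per_podocyte: float = 50.0
    urine_recovery_fraction: float = 0.75
    podocin_linked_to_detachment: bool = False
    noise_sd: float = 0.30  # between-collection lognormal sigma

    @field_validator("copies_per_podocyte")
    @classmethod
    def _pos(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("copies_per_podocyte must be > 0")
        return v

    @field_validator("urine_recovery_fraction")
    @classmethod
    def _frac(cls, v: float) -> float:
        if not 0 < v <= 1:
            raise ValueError("urine_recovery_fraction must be in (0, 1]")
        return v


class HormoneTruth(BaseModel):
    """True serum insulin (ng/mL) and urinary IGF1/IGF2 (ng/24 h) per week."""

    insulin: dict[int, float]
    igf1: dict[int, float]
    igf2: dict[int, float]
    noise_sd: float = 0.10  # lognormal sigma applied per animal


class QpcrSettings(BaseModel):
    """Standard-curve geometry and Cq noise for the virtual qPCR instrument."""

    slope: float = -3.3219  # Cq per log10 copies; perfect doubling
    intercept: float = 35.0  # Cq of a single template copy
    cq_noise_sd: float = 0.15
    standard_copies: list[float] = Field(
        default_factory=lambda: [1e6, 1e5, 1e4, 1e3, 1e2, 1e1]
    )
    standard_replicates: int = 2
    detection_cq_cutoff: float = 40.0


class ArmConfig(BaseModel):
    """Ground-truth parameters for one experimental arm over time.

    Volumes are um^3, densities per 1e6 um^3 of tuft, counts per tuft.
    Weekly trajectories are mappings week -> value; lookups between
    configured weeks interpolate linearly and clamp at the ends.
    """

    arm_id: str
    genotype: Genotype
    diet: Diet = "ad-libitum"
    weeks: list[int]
    n_animals: int
    glom_volume_trajectory: dict[int, float]
    podocyte_number_start: float
    podocyte_number_ref_week: int | None = None  # week at which the start count applies
    podocyte_loss_slope: float = 0.0  # podocytes/tuft/week, <= 0
    glepp1_fraction_trajectory: dict[int, float]
    albumin_link: AlbuminLink
    mrna_truth: MrnaTruth
    hormone_truth: HormoneTruth
    ps6_positive_fraction: dict[int, float]
    sclerosis_density_threshold: float = 50.0
    sclerosis_span: float = 13.0  # density units over which sclerosis risk ramps 0->1
    collection_hours_mean: float = 17.0
    collection_hours_sd: float = 1.5
    urine_volume_ml_per_day: float = 15.0  # cosmetic; not used by estimators
    urine_glucose_mg_per_day: float = 5.0  # cosmetic; not used by estimators
    glomeruli_per_animal: int = 60_000  # two kidneys; used only for budget scaling
    glomeruli_sampled_per_week: int = 60
    between_animal_cv: float = 0.15
    within_animal_volume_cv: float = 0.20
    glomerulus_density_cv: float = 0.15
    glepp1_profile_sd: float = 0.03
    nucleus_diameter_um: float = 6.5
    qpcr: QpcrSettings = Field(default_factory=QpcrSettings)
    seed: int = 0

    @field_validator("weeks")
    @classmethod
    def _weeks_increasing(cls, v: list[int]) -> list[int]:
        if not v:
            raise ValueError("weeks must be non-empty")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("weeks must be strictly increasing")
        return v

    @field_validator("n_animals")
    @classmethod
    def _n_pos(cls, v: int) -> int:
        if v <= 0:
            raise ValueError("n_animals must be a positive integer")
        return v

    @field_validator("podocyte_loss_slope")
    @classmethod
    def _slope_nonpos(cls, v: float) -> float:
        if v > 0:
            raise ValueError("podocyte_loss_slope must be <= 0")
        return v

    @field_validator("glom_volume_trajectory")
    @classmethod
    def _vols_pos(cls, v: dict[int, float]) -> dict[int, float]:
        if any(x <= 0 for x in v.values()):
            raise ValueError("glomerular volumes must be positive")
        return v

    @field_validator("glepp1_fraction_trajectory", "ps6_positive_fraction")
    @classmethod
    def _fractions(cls, v: dict[int, float]) -> dict[int, float]:
        if any(not 0 <= x <= 1 for x in v.values()):
            raise ValueError("fractions must lie in [0, 1]")
        return v

    @model_validator(mode="after")
    def _cover_weeks(self) -> "ArmConfig":
        for name in ("glom_volume_trajectory", "glepp1_fraction_trajectory"):
            if not getattr(self, name):
                raise ValueError(f"{name} must not be empty")
        return self

    # -- trajectory lookup ------------------------------------------------

    def lookup(self, trajectory: Mapping[int, float], week: float) -> float:
        """Linear interpolation over a week->value mapping, clamped at ends."""
        wk = np.array(sorted(trajectory))
        vals = np.array([trajectory[int(w)] for w in wk], dtype=float)
        return float(np.interp(week, wk, vals))

    @property
    def count_ref_week(self) -> int:
        """Week at which ``podocyte_number_start`` applies."""
        return self.podocyte_number_ref_week if self.podocyte_number_ref_week is not None else self.weeks[0]

    def true_podocyte_count(self, week: float) -> float:
        """Configured mean podocyte count per tuft at ``week`` (floored at 0)."""
        n = self.podocyte_number_start + self.podocyte_loss_slope * (week - self.count_ref_week)
        return max(n, 0.0)

    def true_detachment_per_day(self, week: float) -> float:
        """Podocytes detaching per day over both kidneys at the configured slope."""
        return abs(self.podocyte_loss_slope) * self.glomeruli_per_animal / 7.0

    def true_mrna_copies_per_24h(self, gene: str, week: float) -> float:
        """True urinary copies/24 h for ``gene``; podocin may be detachment-linked."""
        if gene == "podocin" and self.mrna_truth.podocin_linked_to_detachment:
            return (
                self.true_detachment_per_day(week)
                * self.mrna_truth.copies_per_podocyte
                * self.mrna_truth.urine_recovery_fraction
            )
        traj = self.mrna_truth.trajectories.get(gene)
        if traj is None:
            raise KeyError(f"no mRNA truth configured for gene {gene!r}")
        return self.lookup(traj, week)

    def with_weeks(self, weeks: Sequence[int]) -> "ArmConfig":
        """Copy of this arm restricted/retargeted to a different week grid."""
        return self.model_copy(update={"weeks": list(weeks)})


def load_arm_config(path: str | Path) -> ArmConfig:
    """Load a single arm config from a YAML or JSON file."""
    return ArmConfig.model_validate(_load_mapping(path))


class ScenarioConfig(BaseModel):
    """A full scenario: several arms plus shared sectioning/measurement settings."""

    name: str
    arms: list[ArmConfig]
    profiles_per_animal: int = 40
    section_thickness_um: float = 1.5
    pixel_size_um: float = 0.25

    @field_validator("arms")
    @classmethod
    def _arms_nonempty(cls, v: list[ArmConfig]) -> list[ArmConfig]:
        if not v:
            raise ValueError("scenario needs at least one arm")
        return v


def load_scenario(path: str | Path) -> ScenarioConfig:
    """Load a scenario config (YAML or JSON)."""
    return ScenarioConfig.model_validate(_load_mapping(path))


def _load_mapping(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
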