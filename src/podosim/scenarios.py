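"""Packaged scenario configurations.

These arm configs encode the study conditions of the obese Zucker (fa/fa)
rat nephropathy model: at 6 weeks fa/fa glomerular volume is 1.6-fold the
lean (Fa/fa) control value; fa/fa podocyte number then declines at
-1.49 podocytes/tuft/week over weeks 6-46 while the control stays flat;
podocyte density falls from ~150 through 100 and 65 to ~45 per 1e6 um^3 by
46 weeks, where roughly half of glomerular profiles show segmental
sclerosis; urinary podocin excretion (detachment-linked) sits ~88-fold above
control relative to aquaporin2; serum insulin is 6.4-fold elevated at 6
weeks (IGF1 3.2-fold, IGF2 2.1-fold); and 40% calorie restriction from week
15 freezes the trajectories in place (density stabilizes near 82 vs 65 in
ad-libitum littermates, podocyte phospho-S6 positivity falls from 78% to
28%).

Density -> albuminuria anchors: a density of 100/1e6 um^3 corresponds to
~10 mg/day in fa/fa (but <1 mg/day in controls at the same density), 82 to
~20 mg/day and 65 to ~100 mg/day.
"""

from __future__ import annotations

from typing import Sequence

from .config import ArmConfig, ScenarioConfig

__all__ = [
    "fafa_arm",
    "control_arm",
    "cr40_arm",
    "cr_adlib_arm",
    "fafa_vs_control",
    "calorie_restriction",
]

# fa/fa volume trajectory chosen so density crosses 150 -> 100 -> 65 -> 45
# given N(w) = 220 - 1.49 (w - 6)
_FAFA_VOLUME = {6: 1.467e6, 15: 2.066e6, 30: 2.834e6, 46: 3.564e6}
_CONTROL_VOLUME = {6: 9.17e5, 15: 1.05e6, 30: 1.15e6, 46: 1.25e6}

_FAFA_ALBUMIN = [(45.0, 300.0), (65.0, 100.0), (82.0, 20.0), (100.0, 10.0), (150.0, 2.0), (250.0, 0.5)]
_CONTROL_ALBUMIN = [(65.0, 5.0), (100.0, 0.8), (150.0, 0.4), (250.0, 0.2)]

# Detachment-linked fa/fa podocin truth at slope -1.49, 60,000 glomeruli,
# 50 copies/podocyte, recovery fraction 0.75:
#   (1.49 * 60000 / 7) * 50 * 0.75 = 478,928.6 copies/24 h
_FAFA_PODOCIN_PLATEAU = 1.49 * 60_000 / 7 * 50 * 0.75
_CONTROL_PODOCIN = _FAFA_PODOCIN_PLATEAU / 88.0  # 88-fold arm separation
_AQP2 = 30_000.0


def fafa_arm(weeks: Sequence[int] = (6, 15, 30, 46), n_animals: int = 6, seed: int = 0) -> ArmConfig:
    """Hyperphagic fa/fa arm, ad-libitum diet, weeks 6-46."""
    return ArmConfig(
        arm_id="fafa",
        genotype="fa/fa",
        diet="ad-libitum",
        weeks=list(weeks),
        n_animals=n_animals,
        glom_volume_trajectory=_FAFA_VOLUME,
        podocyte_number_start=220.0,
        podocyte_number_ref_week=6,
        podocyte_loss_slope=-1.49,
        glepp1_fraction_trajectory={6: 0.28, 15: 0.25, 30: 0.21, 46: 0.17},
        albumin_link={"anchors": _FAFA_ALBUMIN, "noise_sd": 0.25},
        mrna_truth={
            "trajectories": {
                "podocin": {6: _FAFA_PODOCIN_PLATEAU},
                "nephrin": {6: _FAFA_PODOCIN_PLATEAU / 12.0},
                "aquaporin2": {6: _AQP2},
            },
            "podocin_linked_to_detachment": True,
        },
        hormone_truth={
            "insulin": {6: 6.4, 46: 6.4},
            "igf1": {6: 32.0, 46: 32.0},
            "igf2": {6: 42.0, 46: 42.0},
        },
        ps6_positive_fraction={6: 0.40, 15: 0.78, 30: 0.78, 46: 0.78},
        seed=seed,
    )


def control_arm(weeks: Sequence[int] = (6, 15, 30, 46), n_animals: int = 6, seed: int = 1) -> ArmConfig:
    """Lean heterozygous Fa/fa littermate controls."""
    return ArmConfig(
        arm_id="control",
        genotype="Fa/fa",
        diet="ad-libitum",
        weeks=list(weeks),
        n_animals=n_animals,
        glom_volume_trajectory=_CONTROL_VOLUME,
        podocyte_number_start=210.0,
        podocyte_number_ref_week=6,
        podocyte_loss_slope=0.0,
        glepp1_fraction_trajectory={6: 0.30, 15: 0.30, 30: 0.29, 46: 0.29},
        albumin_link={"anchors": _CONTROL_ALBUMIN, "noise_sd": 0.25},
        mrna_truth={
            "trajectories": {
                "podocin": {6: _CONTROL_PODOCIN},
                "nephrin": {6: _CONTROL_PODOCIN / 2.0},
                "aquaporin2": {6: _AQP2},
            },
        },
        hormone_truth={
            "insulin": {6: 1.0, 46: 1.0},
            "igf1": {6: 10.0, 46: 10.0},
            "igf2": {6: 20.0, 46: 20.0},
        },
        ps6_positive_fraction={6: 0.10, 46: 0.10},
        seed=seed,
    )


def cr40_arm(weeks: Sequence[int] = (15, 22, 30), n_animals: int = 6, seed: int = 2) -> ArmConfig:
    """fa/fa arm switched to 40% calorie restriction at week 15.

    Glomerular growth nearly stops, podocyte number holds (slope ~0), density
    stabilizes near 82/1e6 um^3, phospho-S6 positivity falls to 28% by week
    30, and urinary podocin excretion drops toward a low plateau.
    """
    return ArmConfig(
        arm_id="cr40",
        genotype="fa/fa",
        diet="CR40",
        weeks=list(weeks),
        n_animals=n_animals,
        glom_volume_trajectory={15: 2.066e6, 22: 2.30e6, 30: 2.512e6},
        podocyte_number_start=206.6,
        podocyte_number_ref_week=15,
        podocyte_loss_slope=0.0,
        glepp1_fraction_trajectory={15: 0.25, 30: 0.24},
        albumin_link={"anchors": _FAFA_ALBUMIN, "noise_sd": 0.25},
        mrna_truth={
            "trajectories": {
                "podocin": {15: _FAFA_PODOCIN_PLATEAU, 22: 2.0e5, 30: 1.5e5},
                "nephrin": {15: _FAFA_PODOCIN_PLATEAU / 12.0, 30: 3.0e4},
                "aquaporin2": {15: _AQP2},
            },
        },
        hormone_truth={
            "insulin": {15: 6.4, 30: 4.0},
            "igf1": {15: 32.0, 30: 14.0},
            "igf2": {15: 42.0, 30: 24.0},
        },
        ps6_positive_fraction={15: 0.78, 22: 0.50, 30: 0.28},
        seed=seed,
    )


def cr_adlib_arm(weeks: Sequence[int] = (15, 22, 30), n_animals: int = 5, seed: int = 3) -> ArmConfig:
    """Ad-libitum fa/fa comparator for the calorie-restriction study."""
    base = fafa_arm(weeks=weeks, n_animals=n_animals, seed=seed)
    return base.model_copy(
        update={
            "arm_id": "cr_adlib",
            "podocyte_number_start": 206.6,
            "podocyte_number_ref_week": 15,
            "glom_volume_trajectory": {15: 2.066e6, 22: 2.41e6, 30: 2.834e6},
            "glepp1_fraction_trajectory": {15: 0.25, 30: 0.21},
            "ps6_positive_fraction": {15: 0.78, 30: 0.78},
        }
    )


def fafa_vs_control(
    weeks: Sequence[int] = (6, 15, 30, 46),
    n_animals: int = 6,
    profiles_per_animal: int = 40,
    seed: int = 0,
) -> ScenarioConfig:
    """Main longitudinal scenario: fa/fa versus lean littermate controls."""
    return ScenarioConfig(
        name="fafa-vs-control",
        arms=[
            fafa_arm(weeks, n_animals, seed=seed),
            control_arm(weeks, n_animals, seed=seed + 1),
        ],
        profiles_per_animal=profiles_per_animal,
    )


def calorie_restriction(
    weeks: Sequence[int] = (15, 22, 30),
    profiles_per_animal: int = 40,
    seed: int = 0,
) -> ScenarioConfig:
    """Calorie-restriction scenario: 40% CR versus ad-libitum fa/fa from week 15."""
    return ScenarioConfig(
        name="calorie-restriction",
        arms=[
            cr40_arm(weeks, seed=seed + 2),
            cr_adlib_arm(weeks, seed=seed + 3),
        ],
        profiles_per_animal=profiles_per_animal,
    )


BUILTIN_SCENARIOS = {
    "fafa-vs-control": fafa_vs_control,
    "calorie-restriction": calorie_restriction,
}
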