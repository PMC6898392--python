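"""Parameter-recovery experiments on the packaged scenarios.

Each function regenerates a packaged study condition from scratch, pushes it
through the full virtual measurement chain (sectioning -> stereology,
Cq -> standard curve -> copies -> 24-h normalization -> ratios), and returns
the recovered quantity.  Because single virtual studies are deliberately
small (n = 6 animals, 30-50 profiles), each experiment is replicated over
independent cohorts and the replicate mean is reported — the expected value
of the pipeline output under the packaged conditions.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import scenarios
from .cohort import build_cohort
from .qpcr import quantify_plate
from .sectioning import (
    SectionPlan,
    count_label_positive,
    sclerosis_index,
    section_cohort,
)
from .stats import fold_change, linear_fit
from .stereology import default_correction_model, estimate_cohort

__all__ = [
    "volume_ratio_at_6_weeks",
    "podocyte_number_slope",
    "podocin_aquaporin2_fold",
    "insulin_fold_at_6_weeks",
    "ps6_percent_cr_30_weeks",
    "sclerosis_index_46_weeks",
    "run_all_targets",
]




def _sub_seed(seed: int, *key: int) -> int:
    """Deterministic child seed (< 2^31) from a master seed and a key path."""
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, *key])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _estimate_arm(arm, seed: int, profiles_per_animal: int, model):
    cohort = build_cohort(arm, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        plan = SectionPlan(thickness_um=1.5, profiles_per_animal=profiles_per_animal)
        profiles = section_cohort(cohort, plan, seed=_sub_seed(seed, 99))
        est = estimate_cohort(profiles, thickness_um=1.5, model=model)
    return cohort, profiles, est


def volume_ratio_at_6_weeks(
    seed: int, n_replicates: int = 24
) -> tuple[float, int]:
    """fa/fa : control ratio of estimated mean glomerular volume at 6 weeks.

    n = 6 animals/arm, 40 profiles/animal, one 1.5-um section per sampled
    glomerulus, 4/pi stereology.  Returns (mean ratio, profiles used).
    """
    model = default_correction_model(1.5)
    ratios = []
    n_used = 0
    for rep in range(n_replicates):
        s = _sub_seed(seed, 1, rep)
        _, pf, est_f = _estimate_arm(scenarios.fafa_arm(weeks=[6]), s, 40, model)
        _, pc, est_c = _estimate_arm(
            scenarios.control_arm(weeks=[6]), _sub_seed(seed, 1, rep, 2), 40, model
        )
        ratios.append(est_f["volume_um3"].mean() / est_c["volume_um3"].mean())
        n_used += len(pf) + len(pc)
    return float(np.mean(ratios)), n_used


def podocyte_number_slope(
    seed: int, n_replicates: int = 160
) -> tuple[float, int]:
    """OLS slope of estimated podocyte number per tuft vs week, fa/fa 6-46 weeks.

    Full chain: sectioning -> volume estimator -> corrected density ->
    N = V x D.  Returns (mean slope in podocytes/week, animal-week points)."""
    model = default_correction_model(1.5)
    slopes = []
    n_pts = 0
    for rep in range(n_replicates):
        s = _sub_seed(seed, 2, rep)
        _, _, est = _estimate_arm(scenarios.fafa_arm(), s, 40, model)
        fit = linear_fit(est["week"], est["podocyte_number"])
        slopes.append(fit.slope)
        n_pts += len(est)
    return float(np.mean(slopes)), n_pts


def podocin_aquaporin2_fold(
    seed: int, n_replicates: int = 32
) -> tuple[float, int]:
    """fa/fa : control fold of the urinary podocin:aquaporin2 ratio at plateau.

    17-h collections every 4 weeks (weeks 22-46), Cq noise sigma 0.15,
    quantified through fitted standard curves and 24-h normalization.
    Returns (mean fold, collections used)."""
    weeks = list(range(22, 47, 4))
    folds = []
    n_coll = 0
    for rep in range(n_replicates):
        vals = {}
        for arm_fn, key in ((scenarios.fafa_arm, 31), (scenarios.control_arm, 32)):
            arm = arm_fn(weeks=weeks)
            cohort = build_cohort(arm, seed=_sub_seed(seed, 3, rep, key))
            quant, _ = quantify_plate(cohort.plate_table(), arm.qpcr)
            vals[key] = quant["podocin_aquaporin2"].to_numpy()
            n_coll += len(quant)
        folds.append(fold_change(vals[31], vals[32]))
    return float(np.mean(folds)), n_coll


def insulin_fold_at_6_weeks(
    seed: int, n_replicates: int = 48
) -> tuple[float, int]:
    """fa/fa : control fold of simulated serum insulin at 6 weeks (n=6/arm)."""
    folds = []
    n_animals = 0
    for rep in range(n_replicates):
        fafa = build_cohort(scenarios.fafa_arm(weeks=[6]), seed=_sub_seed(seed, 4, rep))
        ctrl = build_cohort(
            scenarios.control_arm(weeks=[6]), seed=_sub_seed(seed, 4, rep, 2)
        )
        folds.append(
            fold_change(
                fafa.hormones["insulin_ng_ml"].to_numpy(),
                ctrl.hormones["insulin_ng_ml"].to_numpy(),
            )
        )
        n_animals += len(fafa.hormones) + len(ctrl.hormones)
    return float(np.mean(folds)), n_animals


def ps6_percent_cr_30_weeks(
    seed: int, n_replicates: int = 32
) -> tuple[float, int]:
    """Percent phospho-S6-positive podocytes per glomerulus, CR arm at 30 weeks.

    n = 6 animals, 12 profiles/animal; per-animal percent positive averaged
    across animals.  Returns (mean percent, profiles used)."""
    vals = []
    n_prof = 0
    for rep in range(n_replicates):
        s = _sub_seed(seed, 5, rep)
        cohort = build_cohort(scenarios.cr40_arm(weeks=[30]), seed=s)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            plan = SectionPlan(thickness_um=1.5, profiles_per_animal=12)
            profiles = section_cohort(cohort, plan, seed=_sub_seed(s, 99))
            per_animal = [
                count_label_positive(sub) for _, sub in profiles.groupby("animal_id")
            ]
        vals.append(float(np.nanmean(per_animal)))
        n_prof += len(profiles)
    return float(np.mean(vals)), n_prof


def sclerosis_index_46_weeks(
    seed: int, n_replicates: int = 64
) -> tuple[float, int]:
    """Mean glomerulosclerosis index, fa/fa arm at 46 weeks (40 profiles/animal)."""
    vals = []
    n_prof = 0
    for rep in range(n_replicates):
        s = _sub_seed(seed, 6, rep)
        cohort = build_cohort(scenarios.fafa_arm(weeks=[46]), seed=s)
        plan = SectionPlan(thickness_um=1.5, profiles_per_animal=40)
        profiles = section_cohort(cohort, plan, seed=_sub_seed(s, 99))
        per_animal = [
            sclerosis_index(sub) for _, sub in profiles.groupby("animal_id")
        ]
        vals.append(float(np.mean(per_animal)))
        n_prof += len(profiles)
    return float(np.mean(vals)), n_prof


TARGETS = {
    "t1": volume_ratio_at_6_weeks,
    "t2": podocyte_number_slope,
    "t3": podocin_aquaporin2_fold,
    "t4": insulin_fold_at_6_weeks,
    "t5": ps6_percent_cr_30_weeks,
    "t8": sclerosis_index_46_weeks,
}


def run_all_targets(seed: int, n_replicates: int | None = None) -> dict:
    """Run every packaged recovery experiment; returns id -> {value, n}.

    ``n_replicates`` overrides each experiment's default replicate count
    (chosen per target so the replicate-mean standard error sits well inside
    the recovery tolerance)."""
    out = {}
    for tid, fn in TARGETS.items():
        value, n = fn(seed) if n_replicates is None else fn(seed, n_replicates)
        out[tid] = {"value": round(value, 4), "n": n}
    return out
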