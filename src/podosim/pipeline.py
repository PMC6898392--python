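"""Configuration-driven end-to-end runs with a reproducibility manifest.

Stage order: simulate -> section -> (optional masks) -> podometric
estimation -> urine assays -> detachment budget -> statistics/report.
Every stage writes a tidy table so any of them can be replaced by real
measured data; re-running with the same (config, seed) reproduces identical
outputs, verified by the hashes in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .budget import podocyte_budget
from .cohort import CohortTruth, build_cohort
from .config import ScenarioConfig, load_scenario
from .masks import render_mask, save_mask
from .qpcr import quantify_plate
from .scenarios import BUILTIN_SCENARIOS
from .sectioning import (
    SectionPlan,
    count_label_positive,
    sclerosis_index,
    section_cohort,
)
from .stats import fold_change, linear_fit, mann_whitney_u, spearman_rho
from .stereology import default_correction_model, estimate_cohort

logger = logging.getLogger("podosim")

__all__ = ["RunManifest", "run_pipeline", "resolve_scenario"]


@dataclass(frozen=True)
class RunManifest:
    config_hash: str
    seed: int
    version: str
    outputs: dict[str, str]  # relative path -> sha256
    wall_clock_s: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "version": self.version,
                "outputs": self.outputs,
                "wall_clock_s": round(self.wall_clock_s, 3),
            },
            indent=1,
            sort_keys=True,
        )


def resolve_scenario(scenario: str | Path | ScenarioConfig) -> ScenarioConfig:
    """Accept a ScenarioConfig, a builtin scenario name, or a config file path."""
    if isinstance(scenario, ScenarioConfig):
        return scenario
    name = str(scenario)
    if name in BUILTIN_SCENARIOS:
        return BUILTIN_SCENARIOS[name]()
    return load_scenario(scenario)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _sub_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([seed & 0x7FFFFFFF, *key]).generate_state(1)[0] & 0x7FFFFFFF)


def _arm_report(
    scenario: ScenarioConfig,
    cohorts: dict[str, CohortTruth],
    estimates: pd.DataFrame,
    urine_quant: pd.DataFrame,
    profiles: pd.DataFrame,
) -> dict:
    """Scenario analogs of the printed group comparisons."""
    report: dict = {"scenario": scenario.name, "arms": {}}
    by_arm_est = dict(tuple(estimates.groupby("arm_id")))
    for arm in scenario.arms:
        aid = arm.arm_id
        est = by_arm_est.get(aid, pd.DataFrame())
        arm_block = {"n_animals": arm.n_animals, "weeks": arm.weeks, "per_week": {}}
        for week, sub in est.groupby("week"):
            pw = {
                "volume_um3": float(sub["volume_um3"].mean()),
                "density_per_1e6um3": float(sub["density_per_1e6um3"].mean()),
                "podocyte_number": float(sub["podocyte_number"].mean()),
                "avg_podocyte_volume_um3": float(sub["avg_podocyte_volume_um3"].mean()),
                "non_podocyte_volume_um3": float(sub["non_podocyte_volume_um3"].mean()),
            }
            prof_w = profiles[(profiles["arm_id"] == aid) & (profiles["week"] == week)]
            if len(prof_w):
                pw["ps6_percent_positive"] = count_label_positive(prof_w)
                pw["sclerosis_index_percent"] = sclerosis_index(prof_w)
            arm_block["per_week"][int(week)] = pw
        if len(est) >= 3 and est["week"].nunique() >= 2:
            fit = linear_fit(est["week"], est["podocyte_number"])
            arm_block["podocyte_number_slope_per_week"] = fit.slope
            arm_block["podocyte_number_slope_r2"] = fit.r_squared
        report["arms"][aid] = arm_block

    # two-arm comparisons at shared weeks
    if len(scenario.arms) == 2:
        a, b = (arm.arm_id for arm in scenario.arms)
        shared = sorted(
            set(scenario.arms[0].weeks).intersection(scenario.arms[1].weeks)
        )
        comp = {}
        for week in shared:
            ea = by_arm_est.get(a, pd.DataFrame())
            eb = by_arm_est.get(b, pd.DataFrame())
            xa = ea.loc[ea["week"] == week, "volume_um3"]
            xb = eb.loc[eb["week"] == week, "volume_um3"]
            if len(xa) and len(xb):
                comp[int(week)] = {
                    "volume_fold": fold_change(xa, xb),
                    "volume_mw_p": mann_whitney_u(xa, xb).p_value,
                }
        report["volume_comparisons"] = comp
        ha = cohorts[a].hormones
        hb = cohorts[b].hormones
        w0 = shared[0] if shared else None
        if w0 is not None:
            report["hormone_folds_at_first_week"] = {
                col: fold_change(
                    ha.loc[ha["week"] == w0, col], hb.loc[hb["week"] == w0, col]
                )
                for col in ("insulin_ng_ml", "igf1_ng_24h", "igf2_ng_24h")
            }
        ra = urine_quant[urine_quant["arm_id"] == a]["podocin_aquaporin2"].dropna()
        rb = urine_quant[urine_quant["arm_id"] == b]["podocin_aquaporin2"].dropna()
        if len(ra) and len(rb) and rb.mean() > 0:
            report["podocin_aquaporin2_fold"] = fold_change(ra, rb)

    # albuminuria relationships on the progressing (fa/fa ad-libitum) arm
    prog = [
        arm
        for arm in scenario.arms
        if arm.genotype == "fa/fa" and arm.podocyte_loss_slope < 0
    ]
    if prog:
        aid = prog[0].arm_id
        est = by_arm_est.get(aid)
        urine = cohorts[aid].urine
        if est is not None and len(est) >= 3:
            merged = est.merge(
                urine[["animal_id", "week", "albumin_mg_per_24h"]],
                on=["animal_id", "week"],
            )
            rel = {}
            for name, col in (
                ("density", "density_per_1e6um3"),
                ("volume", "volume_um3"),
                ("podocyte_number", "podocyte_number"),
            ):
                fit = linear_fit(merged[col], merged["albumin_mg_per_24h"])
                rho = spearman_rho(merged[col], merged["albumin_mg_per_24h"])
                rel[name] = {
                    "r_squared": fit.r_squared,
                    "spearman_rho": rho.statistic,
                    "spearman_p": rho.p_value,
                    "n": fit.n,
                }
            report["albumin_relationships"] = rel
    return report


def _budget_block(
    scenario: ScenarioConfig,
    cohorts: dict[str, CohortTruth],
    estimates: pd.DataFrame,
    urine_quant: pd.DataFrame,
) -> dict:
    """Per-arm podocyte budgets from estimated urinary excretion and morphometry."""
    out = {}
    for arm in scenario.arms:
        if arm.podocyte_loss_slope >= 0 or len(arm.weeks) < 2:
            continue
        est = estimates[estimates["arm_id"] == arm.arm_id]
        quant = urine_quant[urine_quant["arm_id"] == arm.arm_id]
        if est["week"].nunique() < 2 or quant.empty:
            continue
        slope = linear_fit(est["week"], est["podocyte_number"]).slope
        if slope >= 0:
            continue
        series = (
            quant.groupby("week")["podocin_copies_per_24h"].mean().sort_index()
        )
        res = podocyte_budget(
            series.to_numpy(),
            series.index.to_numpy(dtype=float),
            arm.mrna_truth.copies_per_podocyte,
            slope,
            arm.glomeruli_per_animal,
        )
        out[arm.arm_id] = {
            "window_weeks": list(res.window_weeks),
            "cumulative_detached": res.cumulative_detached,
            "glomerular_loss": res.glomerular_loss,
            "percent_accounted": res.percent_accounted,
            "morphometric_slope_per_week": slope,
        }
    return out


def _markdown_report(report: dict) -> str:
    lines = [f"# podosim run report — scenario `{report['scenario']}`", ""]
    for aid, blk in report["arms"].items():
        lines.append(f"## Arm `{aid}` (n={blk['n_animals']})")
        if "podocyte_number_slope_per_week" in blk:
            lines.append(
                f"- podocyte number slope: {blk['podocyte_number_slope_per_week']:.3f} "
                f"podocytes/tuft/week (R²={blk['podocyte_number_slope_r2']:.2f})"
            )
        lines.append("")
        lines.append(
            "| week | volume (µm³) | density (/10⁶ µm³) | podocytes/tuft | pS6+ % | sclerosis % |"
        )
        lines.append("|---|---|---|---|---|---|")
        for week, pw in sorted(blk["per_week"].items()):
            lines.append(
                f"| {week} | {pw['volume_um3']:.3e} | {pw['density_per_1e6um3']:.1f} | "
                f"{pw['podocyte_number']:.1f} | {pw.get('ps6_percent_positive', float('nan')):.1f} | "
                f"{pw.get('sclerosis_index_percent', float('nan')):.1f} |"
            )
        lines.append("")
    if "volume_comparisons" in report:
        lines.append("## Between-arm glomerular volume")
        for week, c in sorted(report["volume_comparisons"].items()):
            lines.append(
                f"- week {week}: fold {c['volume_fold']:.2f}, Mann-Whitney p={c['volume_mw_p']:.3g}"
            )
        lines.append("")
    if "hormone_folds_at_first_week" in report:
        hf = report["hormone_folds_at_first_week"]
        lines.append("## Hormone fold-changes (first shared week)")
        for k, v in hf.items():
            lines.append(f"- {k}: {v:.2f}-fold")
        lines.append("")
    if "podocin_aquaporin2_fold" in report:
        lines.append(
            f"## Urinary podocin:aquaporin2 ratio fold: {report['podocin_aquaporin2_fold']:.1f}"
        )
        lines.append("")
    if "albumin_relationships" in report:
        lines.append("## Albuminuria relationships (progressing arm)")
        for name, rel in report["albumin_relationships"].items():
            lines.append(
                f"- albumin vs {name}: R²={rel['r_squared']:.2f}, "
                f"Spearman ρ={rel['spearman_rho']:.2f} (p={rel['spearman_p']:.3g}, n={rel['n']})"
            )
        lines.append("")
    if report.get("budget"):
        lines.append("## Podocyte detachment budget")
        for aid, b in report["budget"].items():
            lines.append(
                f"- `{aid}` weeks {b['window_weeks'][0]:g}-{b['window_weeks'][1]:g}: "
                f"{b['cumulative_detached']:,.0f} detached vs {b['glomerular_loss']:,.0f} lost "
                f"→ {b['percent_accounted']:.1f}% accounted"
            )
        lines.append("")
    return "\n".join(lines)


def run_pipeline(
    scenario: str | Path | ScenarioConfig,
    out_dir: str | Path,
    seed: int = 0,
    masks: bool = False,
    masks_limit: int = 4,
    fmt: str = "csv",
) -> RunManifest:
    """Run the full virtual study and write all stage outputs to ``out_dir``."""
    t0 = time.time()
    cfg = resolve_scenario(scenario)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sep = "\t" if fmt == "tsv" else ","
    written: list[Path] = []

    def write_frame(df: pd.DataFrame, name: str) -> None:
        p = out_dir / f"{name}.{fmt}"
        df.to_csv(p, sep=sep, index=False)
        written.append(p)
        logger.info("wrote %s (%d rows)", p.name, len(df))

    try:
        model = default_correction_model(cfg.section_thickness_um)
        plan = SectionPlan(
            thickness_um=cfg.section_thickness_um,
            profiles_per_animal=cfg.profiles_per_animal,
            pixel_size_um=cfg.pixel_size_um,
        )
        cohorts: dict[str, CohortTruth] = {}
        prof_frames, est_frames, quant_frames = [], [], []
        for k, arm in enumerate(cfg.arms):
            t_arm = time.time()
            cohort = build_cohort(arm, seed=_sub_seed(seed, 10, k))
            cohorts[arm.arm_id] = cohort
            profiles = section_cohort(cohort, plan, seed=_sub_seed(seed, 11, k))
            est = estimate_cohort(profiles, cfg.section_thickness_um, model)
            est["arm_id"] = arm.arm_id
            quant, _curves = quantify_plate(cohort.plate_table(), arm.qpcr)
            quant["arm_id"] = arm.arm_id
            quant = quant.merge(
                cohort.urine[["animal_id", "week", "albumin_mg_per_24h"]],
                on=["animal_id", "week"],
                how="left",
            )
            prof_frames.append(profiles)
            est_frames.append(est)
            quant_frames.append(quant)
            logger.info("arm %s simulated+measured in %.1fs", arm.arm_id, time.time() - t_arm)

        glomeruli = pd.concat([c.glomeruli for c in cohorts.values()], ignore_index=True)
        urine_truth = pd.concat([c.urine for c in cohorts.values()], ignore_index=True)
        hormones = pd.concat([c.hormones for c in cohorts.values()], ignore_index=True)
        profiles = pd.concat(prof_frames, ignore_index=True)
        estimates = pd.concat(est_frames, ignore_index=True)
        urine_quant = pd.concat(quant_frames, ignore_index=True)

        write_frame(glomeruli, "glomeruli")
        write_frame(urine_truth, "urine_truth")
        write_frame(hormones, "hormones")
        write_frame(profiles, "profiles")
        write_frame(estimates, "estimates")
        write_frame(urine_quant, "urine_quant")

        if masks:
            from .sectioning import ProfileRecord

            mask_dir = out_dir / "masks"
            mask_dir.mkdir(exist_ok=True)
            rng = np.random.default_rng(_sub_seed(seed, 12))
            for i, row in profiles.head(masks_limit).iterrows():
                rec = ProfileRecord(
                    glomerulus_id=row.glomerulus_id,
                    animal_id=row.animal_id,
                    week=int(row.week),
                    equivalent_radius_um=row.equivalent_radius_um,
                    tuft_area_um2=row.tuft_area_um2,
                    nuclear_profile_count=int(row.nuclear_profile_count),
                    glepp1_area_fraction=float(row.glepp1_area_fraction),
                    ps6_positive_nuclei=int(row.ps6_positive_nuclei),
                    sclerotic=bool(row.sclerotic),
                )
                mask, sidecar = render_mask(rec, cfg.pixel_size_um, rng)
                p = save_mask(mask, sidecar, mask_dir / f"profile_{i}.tif")
                written.extend([p, p.with_suffix(".json")])

        report = _arm_report(cfg, cohorts, estimates, urine_quant, profiles)
        report["budget"] = _budget_block(cfg, cohorts, estimates, urine_quant)
        report_path = out_dir / "report.json"
        report_path.write_text(json.dumps(report, indent=1, sort_keys=True))
        written.append(report_path)
        md_path = out_dir / "report.md"
        md_path.write_text(_markdown_report(report))
        written.append(md_path)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise

    config_hash = hashlib.sha256(
        json.dumps(cfg.model_dump(), sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = RunManifest(
        config_hash=config_hash,
        seed=seed,
        version=__version__,
        outputs={p.name: _sha256(p) for p in written},
        wall_clock_s=time.time() - t0,
    )
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest
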