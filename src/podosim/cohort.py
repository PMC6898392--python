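"""Longitudinal cohort generator.

Builds virtual rat cohorts whose ground truth follows the configured disease
trajectories: glomerular tuft volumes grow, podocytes detach at a constant
weekly rate, podocyte density falls, albuminuria rises as density falls, and
detached podocytes shed their marker mRNAs (podocin, nephrin) into the urine
pellet where a timed overnight collection samples them.

Everything downstream (virtual sectioning, stereology, qPCR quantitation,
detachment budgets, statistics) is driven by the tables produced here, so
the whole analysis chain is testable against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .config import GENES, ArmConfig

__all__ = [
    "GlomerulusTruth",
    "CohortTruth",
    "build_cohort",
    "simulate_albuminuria",
    "simulate_urine_collection",
]


@dataclass(frozen=True)
class GlomerulusTruth:
    """True geometry and labels of a single glomerular tuft.

    The tuft is modeled as a sphere of radius ``radius_um`` containing
    ``n_podocytes`` podocyte nuclei (spheres of caliper diameter
    ``nucleus_d_um``) at uniform positions.  ``aa_true`` is the true podocyte
    (GLEPP1-positive) volume fraction of the tuft.
    """

    animal_id: str
    week: int
    radius_um: float
    volume_um3: float
    n_podocytes: int
    nucleus_d_um: float
    aa_true: float
    sclerotic: bool
    ps6_positive_count: int

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("glomerular radius must be positive")
        if not 0 <= self.aa_true < 1:
            raise ValueError("aa_true must be in [0, 1)")
        if self.ps6_positive_count > self.n_podocytes:
            raise ValueError("ps6_positive_count cannot exceed n_podocytes")

    @property
    def density_per_1e6um3(self) -> float:
        return self.n_podocytes / self.volume_um3 * 1e6


@dataclass
class CohortTruth:
    """One simulated arm: tidy truth tables plus the generating config."""

    arm: ArmConfig
    glomeruli: pd.DataFrame
    urine: pd.DataFrame
    hormones: pd.DataFrame
    standards: pd.DataFrame
    seed: int = 0
    animal_effects: pd.DataFrame = field(default_factory=pd.DataFrame)

    def iter_glomeruli(self) -> Iterator[GlomerulusTruth]:
        for row in self.glomeruli.itertuples(index=False):
            yield GlomerulusTruth(
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

    def plate_table(self) -> pd.DataFrame:
        """qPCR plate table (samples + dilution standards) for the assay layer."""
        rows = []
        for r in self.urine.itertuples(index=False):
            for gene in GENES:
                rows.append(
                    {
                        "sample_id": f"{r.animal_id}_w{int(r.week)}",
                        "animal_id": r.animal_id,
                        "week": int(r.week),
                        "collection_hours": r.collection_hours,
                        "gene": gene,
                        "cq": getattr(r, f"{gene}_cq"),
                        "role": "sample",
                        "standard_copies": np.nan,
                    }
                )
        out = pd.DataFrame(rows)
        return pd.concat([out, self.standards], ignore_index=True)

    def write_csv(self, out_dir: str | Path, fmt: str = "csv") -> dict[str, Path]:
        """Write the truth tables as tidy CSV/TSV; returns name -> path."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        sep = "\t" if fmt == "tsv" else ","
        paths = {}
        for name in ("glomeruli", "urine", "hormones", "standards"):
            p = out_dir / f"{self.arm.arm_id}_{name}.{fmt}"
            getattr(self, name).to_csv(p, sep=sep, index=False)
            paths[name] = p
        return paths


def simulate_albuminuria(
    density: float,
    arm: ArmConfig,
    rng: np.random.Generator | None = None,
    noise_sd: float | None = None,
) -> float:
    """24-h urinary albumin (mg/day) implied by a podocyte density.

    Piecewise-linear interpolation through the arm's density->albumin anchor
    points (clamped outside the anchored range), optionally with
    multiplicative lognormal noise.  Monotone non-increasing in density.
    """
    if density <= 0:
        raise ValueError("podocyte density must be positive")
    anchors = arm.albumin_link.anchors
    dens = np.array([a[0] for a in anchors])
    alb = np.array([a[1] for a in anchors])
    value = float(np.interp(density, dens, alb))
    sd = arm.albumin_link.noise_sd if noise_sd is None else noise_sd
    if rng is not None and sd > 0:
        value *= float(np.exp(rng.normal(0.0, sd)))
    return value


def simulate_urine_collection(
    animal_id: str,
    week: int,
    arm: ArmConfig,
    rng: np.random.Generator,
    true_density: float,
    hours: float | None = None,
    mrna_noise_sd: float | None = None,
    cq_noise_sd: float | None = None,
) -> dict:
    """Simulate one timed overnight urine collection (truth + instrument side).

    True copies collected scale with collection duration (copies/24 h x
    hours/24); Cq values are generated by inverting the standard-curve model
    ``Cq = m log10(copies) + b`` with additive Gaussian Cq noise.
    """
    q = arm.qpcr
    if hours is None:
        hours = float(
            np.clip(
                rng.normal(arm.collection_hours_mean, arm.collection_hours_sd),
                8.0,
                24.0,
            )
        )
    if hours <= 0:
        raise ValueError("collection_hours must be positive")
    m_sd = arm.mrna_truth.noise_sd if mrna_noise_sd is None else mrna_noise_sd
    c_sd = q.cq_noise_sd if cq_noise_sd is None else cq_noise_sd

    row: dict = {
        "arm_id": arm.arm_id,
        "animal_id": animal_id,
        "week": week,
        "collection_hours": hours,
    }
    for gene in GENES:
        truth24 = arm.true_mrna_copies_per_24h(gene, week)
        if m_sd > 0:
            truth24 *= float(np.exp(rng.normal(0.0, m_sd)))
        collected = truth24 * hours / 24.0
        if collected >= 1.0:
            cq = q.slope * np.log10(collected) + q.intercept
            if c_sd > 0:
                cq += rng.normal(0.0, c_sd)
            cq = min(float(cq), q.detection_cq_cutoff)
        else:
            cq = q.detection_cq_cutoff
        row[f"{gene}_true_copies_per_24h"] = truth24
        row[f"{gene}_copies_collected"] = collected
        row[f"{gene}_cq"] = cq

    alb_day = simulate_albuminuria(true_density, arm, rng)
    row["albumin_mg_per_24h"] = alb_day
    row["albumin_mg_collected"] = alb_day * hours / 24.0
    # Urine volume and glucose are generated for realism only; no estimator
    # consumes them.
    row["urine_volume_ml_per_24h"] = arm.urine_volume_ml_per_day * float(
        np.exp(rng.normal(0.0, 0.2))
    )
    row["glucose_mg_per_24h"] = arm.urine_glucose_mg_per_day * float(
        np.exp(rng.normal(0.0, 0.2))
    )
    return row


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sd = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-(sd**2) / 2.0, sd, size))


def _dilution_series(arm: ArmConfig, rng: np.random.Generator) -> pd.DataFrame:
    q = arm.qpcr
    rows = []
    for gene in GENES:
        for copies in q.standard_copies:
            for rep in range(q.standard_replicates):
                cq = q.slope * np.log10(copies) + q.intercept
                if q.cq_noise_sd > 0:
                    cq += rng.normal(0.0, q.cq_noise_sd)
                rows.append(
                    {
                        "sample_id": f"std_{gene}_{copies:g}_{rep}",
                        "animal_id": "",
                        "week": -1,
                        "collection_hours": np.nan,
                        "gene": gene,
                        "cq": float(cq),
                        "role": "standard",
                        "standard_copies": copies,
                    }
                )
    return pd.DataFrame(rows)


def build_cohort(arm: ArmConfig, seed: int | None = None) -> CohortTruth:
    """Generate the full ground truth for one arm.

    Deterministic given (config, seed).  Per-animal multiplicative effects
    (between-animal CV) apply to the volume trajectory and the starting
    podocyte count; the weekly loss slope is common to all animals, so the
    arm-mean count follows ``start + slope x (week - first_week)``.
    """
    seed = arm.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF]))

    w0 = arm.count_ref_week
    glom_rows, urine_rows, hormone_rows, effect_rows = [], [], [], []
    for i in range(arm.n_animals):
        animal_id = f"{arm.arm_id}_a{i + 1}"
        vol_eff = float(_lognormal_factor(rng, arm.between_animal_cv))
        cnt_eff = float(_lognormal_factor(rng, arm.between_animal_cv))
        effect_rows.append(
            {"animal_id": animal_id, "volume_effect": vol_eff, "count_effect": cnt_eff}
        )
        for week in arm.weeks:
            v_mean = arm.lookup(arm.glom_volume_trajectory, week) * vol_eff
            n_mean = max(
                arm.podocyte_number_start * cnt_eff
                + arm.podocyte_loss_slope * (week - w0),
                0.0,
            )
            d_mean = n_mean / v_mean * 1e6  # per 1e6 um^3
            aa = arm.lookup(arm.glepp1_fraction_trajectory, week)
            ps6_frac = arm.lookup(arm.ps6_positive_fraction, week) if arm.ps6_positive_fraction else 0.0

            k = arm.glomeruli_sampled_per_week
            v_g = v_mean * _lognormal_factor(rng, arm.within_animal_volume_cv, k)
            d_g = d_mean * _lognormal_factor(rng, arm.glomerulus_density_cv, k)
            n_g = rng.poisson(d_g * v_g / 1e6)
            dens_g = n_g / v_g * 1e6
            p_scl = np.clip(
                (arm.sclerosis_density_threshold - dens_g) / arm.sclerosis_span, 0.0, 1.0
            )
            sclerotic = rng.random(k) < p_scl
            ps6 = rng.binomial(n_g, ps6_frac)
            r_g = (3.0 * v_g / (4.0 * np.pi)) ** (1.0 / 3.0)
            for j in range(k):
                glom_rows.append(
                    {
                        "arm_id": arm.arm_id,
                        "animal_id": animal_id,
                        "week": week,
                        "glomerulus_id": f"{animal_id}_w{week}_g{j + 1}",
                        "radius_um": float(r_g[j]),
                        "volume_um3": float(v_g[j]),
                        "n_podocytes": int(n_g[j]),
                        "density_true": float(dens_g[j]),
                        "nucleus_d_um": arm.nucleus_diameter_um,
                        "aa_true": aa,
                        "sclerotic": bool(sclerotic[j]),
                        "ps6_positive_count": int(ps6[j]),
                    }
                )

            urine_rows.append(
                simulate_urine_collection(animal_id, week, arm, rng, true_density=d_mean)
            )
            hormone_rows.append(
                {
                    "arm_id": arm.arm_id,
                    "animal_id": animal_id,
                    "week": week,
                    "insulin_ng_ml": arm.lookup(arm.hormone_truth.insulin, week)
                    * float(np.exp(rng.normal(0.0, arm.hormone_truth.noise_sd))),
                    "igf1_ng_24h": arm.lookup(arm.hormone_truth.igf1, week)
                    * float(np.exp(rng.normal(0.0, arm.hormone_truth.noise_sd))),
                    "igf2_ng_24h": arm.lookup(arm.hormone_truth.igf2, week)
                    * float(np.exp(rng.normal(0.0, arm.hormone_truth.noise_sd))),
                }
            )

    standards = _dilution_series(arm, rng)
    return CohortTruth(
        arm=arm,
        glomeruli=pd.DataFrame(glom_rows),
        urine=pd.DataFrame(urine_rows),
        hormones=pd.DataFrame(hormone_rows),
        standards=standards,
        seed=seed,
        animal_effects=pd.DataFrame(effect_rows),
    )
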