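"""Stereological estimators: glomerular volume, corrected podocyte density,
podocyte number and podocyte volumes.

Glomerular volume uses the classic profile-radius estimator for spheres cut
by random planes: the mean profile radius of a sphere of radius R is
(pi/4) R, so the mean maximal radius is recovered as R = (4/pi) r_bar and
the volume as V = (4/3) pi R^3.

Podocyte nuclear density is estimated from the apparent per-area nuclear
count Q = sum(counts) / sum(tuft profile areas).  Because a nucleus of
caliper diameter d is seen in any slab it touches, Q over-counts relative to
density x thickness: to first order Q = density x (T + d) (the Abercrombie
relation).  The remaining geometric bias (slab sampling near the tuft poles,
finite tuft radius) is absorbed by a quadratic correction whose coefficients
are calibrated once by simulation against known densities across the
relevant nuclear-diameter range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CorrectionModel",
    "PodometricEstimates",
    "estimate_glomerular_volume",
    "calibrate_correction",
    "corrected_podocyte_density",
    "abercrombie_density",
    "podometric_summary",
    "estimate_cohort",
    "default_correction_model",
]


@dataclass(frozen=True)
class CorrectionModel:
    """Quadratic map from the Abercrombie first-order density to true density.

    ``corrected = q0 + q1 * y + q2 * y^2`` with ``y = Q / (T + d)`` in
    nuclei/um^3.  Calibration metadata records the section thickness, the
    nuclear-diameter range and the simulation size used for the fit.
    """

    q0: float
    q1: float
    q2: float
    thickness_um: float
    d_range_um: tuple[float, float]
    default_d_um: float
    draws: int
    seed: int

    def apply(self, y: float) -> float:
        out = self.q0 + self.q1 * y + self.q2 * y * y
        return max(out, 0.0)


@dataclass(frozen=True)
class PodometricEstimates:
    """Per-animal (or per-glomerulus) podometric estimate bundle.

    Identities: N_hat = V_hat x D / 1e6; total + non-podocyte volume =
    V_hat; gv_per_podocyte = V_hat / N_hat.
    """

    volume_um3: float
    density_per_1e6um3: float
    podocyte_number: float
    total_podocyte_volume_um3: float
    avg_podocyte_volume_um3: float
    non_podocyte_volume_um3: float
    gv_per_podocyte_um3: float


def estimate_glomerular_volume(profile_radii_um: np.ndarray | pd.Series) -> float:
    """Mean glomerular volume from section profile radii.

    r_bar = mean profile radius; R = (4/pi) r_bar; V = (4/3) pi R^3.
    """
    r = np.asarray(profile_radii_um, dtype=float)
    if r.size == 0:
        raise ValueError("no profiles")
    if r.size < 30:
        warnings.warn("fewer than 30 profiles; volume estimate will be noisy")
    r_bar = float(r.mean())
    R = 4.0 / np.pi * r_bar
    return 4.0 / 3.0 * np.pi * R**3


def _expected_count_integral(z: np.ndarray, R: float, T: float, d: float) -> np.ndarray:
    """Expected nuclei per unit density in the slab [z, z+T] of a unit-density ball.

    Integral over h in [max(-R, z - d/2), min(R, z + T + d/2)] of the tuft
    cross-section pi (R^2 - h^2): closed form of the slab-intersection
    geometry for nuclei centers uniform in the ball.
    """
    lo = np.maximum(-R, z - d / 2.0)
    hi = np.minimum(R, z + T + d / 2.0)
    hi = np.maximum(hi, lo)

    def F(h):
        return np.pi * (R**2 * h - h**3 / 3.0)

    return F(hi) - F(lo)


def _simulate_apparent_density(
    rng: np.random.Generator,
    density_per_um3: float,
    T: float,
    d: float,
    n_sections: int,
    radius_range: tuple[float, float],
) -> float:
    """Apparent per-area count Q from simulated random sections.

    Sections are cut at uniform offsets through tufts with radii uniform in
    ``radius_range``; counts are Poisson with the exact slab-intersection
    expectation.
    """
    R = rng.uniform(*radius_range, n_sections)
    z = rng.uniform(-R, R)
    lam = density_per_um3 * _expected_count_integral(z, R, T, d)
    counts = rng.poisson(lam)
    areas = np.pi * (R**2 - z**2)
    return counts.sum() / areas.sum()


def calibrate_correction(
    thickness_um: float = 1.5,
    d_range_um: tuple[float, float] = (4.0, 8.0),
    draws: int = 120_000,
    seed: int = 2024,
    default_d_um: float = 6.5,
    radius_range_um: tuple[float, float] = (55.0, 95.0),
    densities_per_1e6um3: tuple[float, ...] = (50.0, 100.0, 175.0, 250.0, 325.0),
) -> CorrectionModel:
    """Fit the quadratic thickness/shape correction by simulation.

    Simulates sections at a grid of true densities and nuclear diameters,
    computes the Abercrombie first-order density y = Q / (T + d) in each
    cell, and least-squares fits true density = q0 + q1 y + q2 y^2.
    """
    if draws < 10_000:
        raise ValueError("calibration needs at least 10,000 simulated sections")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 7]))
    d_grid = np.linspace(d_range_um[0], d_range_um[1], 4)
    cells = [(rho, d) for rho in densities_per_1e6um3 for d in d_grid]
    per_cell = max(draws // len(cells), 2_000)
    ys, rhos = [], []
    for rho, d in cells:
        q = _simulate_apparent_density(
            rng, rho / 1e6, thickness_um, d, per_cell, radius_range_um
        )
        ys.append(q / (thickness_um + d))
        rhos.append(rho / 1e6)
    coef = np.polyfit(np.array(ys), np.array(rhos), deg=2)  # [q2, q1, q0]
    if not np.all(np.isfinite(coef)):
        raise RuntimeError("degenerate correction fit")
    return CorrectionModel(
        q0=float(coef[2]),
        q1=float(coef[1]),
        q2=float(coef[0]),
        thickness_um=thickness_um,
        d_range_um=d_range_um,
        default_d_um=default_d_um,
        draws=per_cell * len(cells),
        seed=seed,
    )


_MODEL_CACHE: dict[tuple, CorrectionModel] = {}


def default_correction_model(thickness_um: float = 1.5) -> CorrectionModel:
    """Cached calibration for the given section thickness (d range 4-8 um)."""
    key = (round(thickness_um, 6),)
    if key not in _MODEL_CACHE:
        _MODEL_CACHE[key] = calibrate_correction(thickness_um=thickness_um)
    return _MODEL_CACHE[key]


def abercrombie_density(
    counts: np.ndarray, areas_um2: np.ndarray, thickness_um: float, d_um: float
) -> float:
    """Closed-form first-order density count / (A x (T + d)), per 1e6 um^3."""
    total_area = float(np.sum(areas_um2))
    if total_area <= 0:
        raise ValueError("total profile area must be positive")
    q = float(np.sum(counts)) / total_area
    return q / (thickness_um + d_um) * 1e6


def corrected_podocyte_density(
    profiles: pd.DataFrame,
    thickness_um: float,
    model: CorrectionModel | None = None,
    d_um: float | None = None,
) -> float:
    """Podocyte nuclear density (per 1e6 um^3) from a profile table.

    Pools counts and tuft areas over profiles (Q = sum n_p / sum A_p),
    forms the first-order density y = Q/(T+d) and applies the calibrated
    quadratic correction.
    """
    model = model if model is not None else default_correction_model(thickness_um)
    if abs(model.thickness_um - thickness_um) > 1e-9:
        warnings.warn("correction model calibrated for a different section thickness")
    d = model.default_d_um if d_um is None else d_um
    total_area = float(profiles["tuft_area_um2"].sum())
    if total_area <= 0:
        raise ValueError("total profile area must be positive")
    q = float(profiles["nuclear_profile_count"].sum()) / total_area
    y = q / (thickness_um + d)
    return model.apply(y) * 1e6


def podometric_summary(
    volume_um3: float, density_per_1e6um3: float, mean_glepp1_fraction: float
) -> PodometricEstimates:
    """Combine the three primary estimates into the full podometric bundle.

    N = V x D / 1e6; total podocyte volume = V x area fraction (Delesse
    principle: area fraction estimates volume fraction); average podocyte
    volume = total / N; non-podocyte volume = V - total.
    """
    if volume_um3 < 0 or density_per_1e6um3 < 0:
        raise ValueError("volume and density must be non-negative")
    if not 0 <= mean_glepp1_fraction <= 1:
        raise ValueError("GLEPP1 fraction must be in [0, 1]")
    n_hat = volume_um3 * density_per_1e6um3 / 1e6
    total_pod = volume_um3 * mean_glepp1_fraction
    non_pod = volume_um3 - total_pod
    if n_hat > 0:
        avg_pod = total_pod / n_hat
        gv_per_pod = volume_um3 / n_hat
    else:
        avg_pod = float("nan")
        gv_per_pod = float("nan")
    return PodometricEstimates(
        volume_um3=volume_um3,
        density_per_1e6um3=density_per_1e6um3,
        podocyte_number=n_hat,
        total_podocyte_volume_um3=total_pod,
        avg_podocyte_volume_um3=avg_pod,
        non_podocyte_volume_um3=non_pod,
        gv_per_podocyte_um3=gv_per_pod,
    )


def estimate_cohort(
    profiles: pd.DataFrame,
    thickness_um: float = 1.5,
    model: CorrectionModel | None = None,
    d_um: float | None = None,
) -> pd.DataFrame:
    """Per-animal, per-week podometric estimates from pooled profiles.

    Mirrors the measurement protocol: each animal-week's 30-50 profiles are
    pooled (mean radius, pooled counts/areas, mean GLEPP1 fraction) into a
    single estimate row.
    """
    model = model if model is not None else default_correction_model(thickness_um)
    rows = []
    for (animal_id, week), sub in profiles.groupby(["animal_id", "week"], sort=True):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            v_hat = estimate_glomerular_volume(sub["equivalent_radius_um"].to_numpy())
            dens = corrected_podocyte_density(sub, thickness_um, model, d_um)
        est = podometric_summary(v_hat, dens, float(sub["glepp1_area_fraction"].mean()))
        row = {
            "animal_id": animal_id,
            "week": int(week),
            "n_profiles": len(sub),
            "volume_um3": est.volume_um3,
            "density_per_1e6um3": est.density_per_1e6um3,
            "podocyte_number": est.podocyte_number,
            "total_podocyte_volume_um3": est.total_podocyte_volume_um3,
            "avg_podocyte_volume_um3": est.avg_podocyte_volume_um3,
            "non_podocyte_volume_um3": est.non_podocyte_volume_um3,
            "gv_per_podocyte_um3": est.gv_per_podocyte_um3,
        }
        if "arm_id" in sub.columns:
            row["arm_id"] = sub["arm_id"].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)
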