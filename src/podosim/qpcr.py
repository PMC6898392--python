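"""Absolute qRT-PCR quantitation via standard curves, 24-h normalization of
timed urine collections, and podocyte-marker ratios.

A standard curve is the least-squares line Cq = m log10(copies) + b fit to a
serial-dilution series; amplification efficiency E = 10^(-1/m) - 1 (E = 1
for perfect doubling, m = -3.3219).  Curves with efficiency outside
[0.6, 1.2] are rejected.  Sample copies follow by inversion,
copies = 10^((Cq - b) / m), and timed collections are scaled to 24 h.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import GENES, QpcrSettings

__all__ = [
    "StandardCurve",
    "fit_standard_curve",
    "cq_to_copies",
    "normalize_to_24h",
    "marker_ratios",
    "quantify_plate",
]


@dataclass(frozen=True)
class StandardCurve:
    """Fitted dilution-series line for one gene."""

    gene: str
    slope: float  # Cq per log10 copies, < 0
    intercept: float  # Cq at 1 copy
    efficiency: float  # 10^(-1/slope) - 1
    r_squared: float
    n_points: int
    accepted: bool


def fit_standard_curve(
    dilution_copies: np.ndarray,
    cq_values: np.ndarray,
    gene: str = "",
    efficiency_bounds: tuple[float, float] = (0.6, 1.2),
) -> StandardCurve:
    """Least-squares standard curve from a serial dilution series.

    Requires >= 3 dilution points spanning at least 2 log10 of template.
    The curve is flagged rejected when the implied amplification efficiency
    falls outside ``efficiency_bounds`` or the slope is non-negative.
    """
    copies = np.asarray(dilution_copies, dtype=float)
    cq = np.asarray(cq_values, dtype=float)
    if copies.size != cq.size:
        raise ValueError("copies and Cq arrays must match")
    if copies.size < 3:
        raise ValueError("need at least 3 dilution points")
    if np.any(copies <= 0):
        raise ValueError("dilution copies must be positive")
    logc = np.log10(copies)
    if logc.max() - logc.min() < 2.0:
        raise ValueError("dilution series must span at least 2 log10")
    if np.ptp(logc) == 0:
        raise ValueError("zero variance in dilution copies")
    fit = sps.linregress(logc, cq)
    slope = float(fit.slope)
    if slope >= 0 or np.ptp(cq) == 0:
        eff = float("nan")
        accepted = False
    else:
        eff = 10.0 ** (-1.0 / slope) - 1.0
        accepted = efficiency_bounds[0] <= eff <= efficiency_bounds[1]
    return StandardCurve(
        gene=gene,
        slope=slope,
        intercept=float(fit.intercept),
        efficiency=eff,
        r_squared=float(fit.rvalue**2) if np.isfinite(fit.rvalue) else 0.0,
        n_points=int(copies.size),
        accepted=accepted,
    )


def cq_to_copies(cq: float | np.ndarray, curve: StandardCurve) -> float | np.ndarray:
    """Absolute template copies from a Cq via the standard curve inverse."""
    if not curve.accepted:
        raise ValueError(f"standard curve for {curve.gene!r} was rejected")
    return 10.0 ** ((np.asarray(cq, dtype=float) - curve.intercept) / curve.slope)


def normalize_to_24h(amount: float | np.ndarray, collection_hours: float) -> float | np.ndarray:
    """Scale a timed-collection amount to a 24-h equivalent (amount x 24/h)."""
    if collection_hours <= 0:
        raise ValueError("collection_hours must be positive")
    return np.asarray(amount, dtype=float) * 24.0 / collection_hours


def marker_ratios(copies_by_gene: dict[str, float]) -> dict[str, float]:
    """Podocyte marker ratios from per-gene copy numbers.

    Returns podocin:aquaporin2 (relative detachment-rate marker) and
    podocin:nephrin (podocyte stress marker).  A zero denominator yields a
    missing value with a warning.  Passing a ``gapdh`` entry also yields
    gene:GAPDH ratios, the form used for renal-cortex comparisons.
    """
    out: dict[str, float] = {}

    def ratio(name: str, num: str, den: str) -> None:
        if num not in copies_by_gene or den not in copies_by_gene:
            return
        d = copies_by_gene[den]
        if d > 0:
            out[name] = copies_by_gene[num] / d
        else:
            warnings.warn(f"zero denominator for {name}; ratio undefined")
            out[name] = float("nan")

    ratio("podocin_aquaporin2", "podocin", "aquaporin2")
    ratio("podocin_nephrin", "podocin", "nephrin")
    if "gapdh" in copies_by_gene:
        for gene in GENES:
            ratio(f"{gene}_gapdh", gene, "gapdh")
    return out


def quantify_plate(
    plate: pd.DataFrame,
    settings: QpcrSettings | None = None,
) -> tuple[pd.DataFrame, dict[str, StandardCurve]]:
    """Quantify a plate table into per-collection copies/24 h and ratios.

    ``plate`` columns: sample_id, gene, cq, role in {sample, standard},
    standard_copies (standards only), plus animal_id/week/collection_hours
    on sample rows.  Returns (per-collection tidy table, per-gene curves).
    Cq at or beyond the detection cutoff is censored to 0 copies.
    """
    settings = settings or QpcrSettings()
    curves: dict[str, StandardCurve] = {}
    for gene, sub in plate[plate["role"] == "standard"].groupby("gene"):
        curves[gene] = fit_standard_curve(
            sub["standard_copies"].to_numpy(), sub["cq"].to_numpy(), gene=gene
        )

    samples = plate[plate["role"] == "sample"]
    rows: dict[tuple, dict] = {}
    for r in samples.itertuples(index=False):
        key = (r.animal_id, int(r.week))
        row = rows.setdefault(
            key,
            {
                "animal_id": r.animal_id,
                "week": int(r.week),
                "collection_hours": float(r.collection_hours),
            },
        )
        curve = curves[r.gene]
        if r.cq >= settings.detection_cq_cutoff:
            copies, censored = 0.0, True
        else:
            copies, censored = float(cq_to_copies(r.cq, curve)), False
        row[f"{r.gene}_copies"] = copies
        row[f"{r.gene}_copies_per_24h"] = float(
            normalize_to_24h(copies, row["collection_hours"])
        )
        row[f"{r.gene}_censored"] = censored

    out_rows = []
    for row in rows.values():
        per24 = {
            g: row.get(f"{g}_copies_per_24h", float("nan")) for g in GENES
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for name, val in marker_ratios(per24).items():
                row[name] = val
        out_rows.append(row)
    return pd.DataFrame(out_rows), curves
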