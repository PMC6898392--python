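"""Raster label masks for profile measurement.

Renders a measured section profile as a single-channel 16-bit label image
(tuft disk, peripheral GLEPP1-positive region, one label per nuclear
profile) plus a JSON sidecar carrying the pixel size, the label legend and
per-nucleus flags.  ``measure_mask`` re-derives a ProfileRecord from such a
mask, so user-supplied label masks (e.g. exported from a segmentation tool)
can enter the pipeline in place of the vector path.

Label legend: 0 background, 1 tuft, 2 GLEPP1-positive tuft, >= 10 nuclear
profiles (one label per nucleus).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from skimage.draw import disk as _disk

from .sectioning import ProfileRecord

__all__ = ["render_mask", "measure_mask", "save_mask", "load_mask"]

TUFT_LABEL = 1
GLEPP1_LABEL = 2
NUCLEUS_LABEL_START = 10


def render_mask(
    profile: ProfileRecord,
    pixel_size_um: float = 0.25,
    rng: np.random.Generator | None = None,
    nucleus_d_um: float = 6.5,
) -> tuple[np.ndarray, dict]:
    """Rasterize a profile into a label mask + sidecar metadata.

    The GLEPP1-positive region is drawn as a peripheral annulus whose area
    fraction of the tuft equals the profile's measured fraction; nuclear
    profiles are disks placed in the interior (non-GLEPP1) zone so the two
    label classes stay disjoint.  When the interior cannot hold the nuclei,
    they are placed anywhere in the tuft and the rendered GLEPP1 fraction
    becomes approximate (noted in the sidecar).
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size must be positive")
    rng = rng if rng is not None else np.random.default_rng(0)
    r_px = profile.equivalent_radius_um / pixel_size_um
    if r_px < 1:
        raise ValueError("profile smaller than one pixel at this resolution")
    pad = int(np.ceil(r_px)) + 4
    side = 2 * pad + 1
    mask = np.zeros((side, side), dtype=np.uint16)
    center = (pad, pad)

    rr, cc = _disk(center, r_px, shape=mask.shape)
    mask[rr, cc] = TUFT_LABEL

    aa = profile.glepp1_area_fraction
    inner_r_px = r_px * np.sqrt(max(1.0 - aa, 0.0))
    if aa > 0:
        rr, cc = _disk(center, r_px, shape=mask.shape)
        d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
        ring = d2 >= inner_r_px**2
        mask[rr[ring], cc[ring]] = GLEPP1_LABEL

    nuc_r_px = max(nucleus_d_um / 2.0 * 0.6 / pixel_size_um, 1.0)
    zone = inner_r_px - nuc_r_px
    exact_layout = zone > nuc_r_px or profile.nuclear_profile_count == 0
    place_r = zone if exact_layout else max(r_px - nuc_r_px, 1.0)
    centers: list[tuple[float, float]] = []
    for k in range(profile.nuclear_profile_count):
        for _ in range(200):
            rho = place_r * np.sqrt(rng.random())
            th = rng.uniform(0, 2 * np.pi)
            y, x = center[0] + rho * np.sin(th), center[1] + rho * np.cos(th)
            if all((y - y0) ** 2 + (x - x0) ** 2 >= (1.6 * nuc_r_px) ** 2 for y0, x0 in centers):
                break
        centers.append((y, x))
        rr, cc = _disk((y, x), nuc_r_px, shape=mask.shape)
        mask[rr, cc] = NUCLEUS_LABEL_START + k

    ps6_labels = [
        NUCLEUS_LABEL_START + k for k in range(profile.ps6_positive_nuclei)
    ]
    sidecar = {
        "pixel_size_um": pixel_size_um,
        "labels": {
            "tuft": TUFT_LABEL,
            "glepp1": GLEPP1_LABEL,
            "nucleus_start": NUCLEUS_LABEL_START,
        },
        "glomerulus_id": profile.glomerulus_id,
        "animal_id": profile.animal_id,
        "week": profile.week,
        "sclerotic": bool(profile.sclerotic),
        "ps6_positive_labels": ps6_labels,
        "glepp1_layout_exact": bool(exact_layout),
    }
    return mask, sidecar


def measure_mask(mask: np.ndarray, sidecar: dict) -> ProfileRecord:
    """Measure a label mask back into a ProfileRecord.

    A_p = non-background pixels x pixel_size^2; r_p = sqrt(A_p / pi);
    n_p = number of distinct nucleus labels present; GLEPP1 fraction =
    GLEPP1 pixels / tuft pixels.
    """
    px = float(sidecar["pixel_size_um"])
    if px <= 0:
        raise ValueError("pixel_size must be positive")
    tuft_pixels = int(np.count_nonzero(mask))
    if tuft_pixels == 0:
        raise ValueError("mask contains no tuft label")
    area = tuft_pixels * px**2
    r_p = float(np.sqrt(area / np.pi))
    nucleus_start = int(sidecar["labels"]["nucleus_start"])
    labels = np.unique(mask)
    nuc_labels = labels[labels >= nucleus_start]
    glepp_px = int(np.count_nonzero(mask == int(sidecar["labels"]["glepp1"])))
    ps6_set = set(sidecar.get("ps6_positive_labels", []))
    ps6 = sum(1 for lab in nuc_labels if int(lab) in ps6_set)
    return ProfileRecord(
        glomerulus_id=str(sidecar.get("glomerulus_id", "mask")),
        animal_id=str(sidecar.get("animal_id", "")),
        week=int(sidecar.get("week", -1)),
        equivalent_radius_um=r_p,
        tuft_area_um2=area,
        nuclear_profile_count=int(len(nuc_labels)),
        glepp1_area_fraction=glepp_px / tuft_pixels,
        ps6_positive_nuclei=int(ps6),
        sclerotic=bool(sidecar.get("sclerotic", False)),
    )


def save_mask(mask: np.ndarray, sidecar: dict, path: str | Path) -> Path:
    """Write a mask as 16-bit label TIFF with its JSON sidecar alongside."""
    path = Path(path)
    tifffile.imwrite(path, mask.astype(np.uint16))
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def load_mask(path: str | Path) -> tuple[np.ndarray, dict]:
    """Round-trip loader for :func:`save_mask` output."""
    path = Path(path)
    mask = tifffile.imread(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return mask, sidecar
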