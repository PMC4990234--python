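"""Plate-image growth quantification and gene-targeting statistics.

The growth index is the pixel area occupied by plant colonies divided
by the pixel area of the culture dish, which normalizes away camera
distance and image resolution. Gene-targeting efficiency is the
percentage of stable (hygromycin-resistant) transformants that are
resistant to 2-fluoroadenine, i.e. that carry a targeted disruption of
the APT locus; the relative transformation frequency (RTF) is the
percentage of viable protoplasts regenerating into stable transformants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label

from mossdge._util import round_half_up


@dataclass(frozen=True)
class PlateMeasurement:
    image_id: str
    plant_area_px: int
    dish_area_px: int

    def __post_init__(self) -> None:
        if not (0 <= self.plant_area_px <= self.dish_area_px):
            raise ValueError("plant area must lie in [0, dish area]")

    @property
    def growth_index(self) -> float:
        return growth_index(self.plant_area_px, self.dish_area_px)


@dataclass(frozen=True)
class TargetingCounts:
    strain: str
    hyg_r: int  # stable (hygromycin-resistant) transformants
    fa_r: int  # 2-fluoroadenine-resistant (targeted) plants
    viable_protoplasts: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.fa_r <= self.hyg_r):
            raise ValueError("need 0 <= 2-FA-resistant <= hygromycin-resistant")


def segment_plate(
    image: np.ndarray, green_margin: int = 10
) -> tuple[int, int]:
    """Segment one dish image into (plant_area_px, dish_area_px).

    The dish is the largest bright connected region (Otsu threshold on
    mean intensity, holes filled); plant pixels are pixels inside the
    dish whose green channel dominates red and blue by at least
    ``green_margin`` grey levels. Deterministic.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError("expected an RGB image array")
    rgb = img[..., :3].astype(float)
    gray = rgb.mean(axis=2)
    if gray.max() == gray.min():
        raise ValueError("no dish detectable: image has no contrast")
    bright = gray > threshold_otsu(gray)
    if not bright.any():
        raise ValueError("no dish detectable: nothing above threshold")
    labels = label(bright)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    dish_mask = ndimage.binary_fill_holes(labels == largest)
    dish_area = int(dish_mask.sum())
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    plant = dish_mask & (g > r + green_margin) & (g > b + green_margin)
    return int(plant.sum()), dish_area


def growth_index(plant_area_px: float, dish_area_px: float) -> float:
    """Colony area normalized to dish area; dimensionless in [0, 1]."""
    if dish_area_px <= 0:
        raise ValueError("dish area must be > 0")
    idx = plant_area_px / dish_area_px
    if not (0 <= idx <= 1):
        raise ValueError("plant area must lie in [0, dish area]")
    return idx


def dose_response_summary(measurements: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD (n-1 denominator) of the growth index per dose.

    ``measurements`` needs columns ``dose`` and ``growth_index``.
    Singleton groups report SD as missing.
    """
    if measurements.empty:
        raise ValueError("need at least one measurement")
    g = measurements.groupby("dose")["growth_index"]
    out = g.agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count").reset_index()
    out.loc[out["n"] < 2, "sd"] = np.nan
    return out


def gt_frequency(counts: TargetingCounts) -> float:
    """%GT = 100 * 2-FA-resistant / hygromycin-resistant, half-up to 1 dp."""
    if counts.hyg_r == 0:
        raise ValueError("hygromycin-resistant count must be > 0")
    return round_half_up(100.0 * counts.fa_r / counts.hyg_r, 1)


def rtf(viable_protoplasts: int, hyg_r: int) -> float:
    """Relative transformation frequency: % of viable protoplasts that
    regenerate into stable (hygromycin-resistant) transformants."""
    if viable_protoplasts <= 0:
        raise ValueError("viable protoplast count must be > 0")
    if hyg_r < 0:
        raise ValueError("transformant count must be >= 0")
    return 100.0 * hyg_r / viable_protoplasts


def gt_table(counts: pd.DataFrame) -> pd.DataFrame:
    """%GT (and RTF where protoplast counts are present) for a table of
    strains with columns strain, hyg_r, fa_r[, viable_protoplasts]."""
    rows = []
    for rec in counts.itertuples(index=False):
        tc = TargetingCounts(
            strain=rec.strain,
            hyg_r=int(rec.hyg_r),
            fa_r=int(rec.fa_r),
        )
        row = {"strain": tc.strain, "gt_pct": gt_frequency(tc)}
        viable = getattr(rec, "viable_protoplasts", None)
        if viable is not None and not pd.isna(viable):
            row["rtf_pct"] = rtf(int(viable), tc.hyg_r)
        rows.append(row)
    return pd.DataFrame(rows)
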