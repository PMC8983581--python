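"""In vitro dilution-series and turbidity analysis.

A dilution series pairs ascending protein concentrations with fluorescence
fields (z-stacks reduced to maximum-intensity projections).  Condensates
are detected per field, and the saturation concentration C_sat is reported
as a bracket: the highest condensate-free concentration below the lowest
condensate-positive one.  Turbidity series (A340 absorbance replicates per
concentration) are summarized as background-subtracted mean ± SD.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .io import ImageStack

logger = logging.getLogger(__name__)

__all__ = ["DilutionSeries", "CsatBracket", "TurbiditySeries",
           "max_projection", "detect_condensates_2d", "csat_bracket",
           "turbidity_summary"]


@dataclass
class DilutionSeries:
    """Ascending concentrations (nmol/L) with one 2-D field each."""

    concentrations: list[float]            # nmol/L, strictly increasing
    images: list[np.ndarray]               # 2-D projections, one per concentration
    pixel_size: float                      # μm per pixel
    true_counts: list[int] | None = None   # ground truth when synthetic

    def __post_init__(self):
        if len(self.concentrations) < 1:
            raise ValueError("empty concentration list")
        if len(self.concentrations) != len(self.images):
            raise ValueError("one image per concentration required")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")


@dataclass
class CsatBracket:
    """C_sat bracket: lower = highest condensate-free concentration (0 if
    none), upper = lowest condensate-positive concentration (inf if none)."""

    lower: float
    upper: float
    monotone: bool = True
    counts: list[int] = field(default_factory=list)

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError(f"bracket lower {self.lower} must be < upper {self.upper}")

    def __str__(self):
        if self.lower == 0 and math.isfinite(self.upper):
            return f"C_sat < {self.upper:g} nmol/L"
        if math.isinf(self.upper):
            return f"no condensates up to {self.lower:g} nmol/L"
        return f"C_sat between {self.lower:g} and {self.upper:g} nmol/L"


@dataclass
class TurbiditySeries:
    """A340 replicates per protein concentration plus a buffer-only blank."""

    concentration: float          # μmol/L
    a340: np.ndarray              # replicate absorbances
    buffer_a340: float            # blank absorbance

    def __post_init__(self):
        self.a340 = np.atleast_1d(np.asarray(self.a340, float))
        if self.a340.size < 1:
            raise ValueError("need at least one A340 replicate")


def max_projection(stack: ImageStack | np.ndarray, channel: int | str = 0) -> np.ndarray:
    """Per-pixel maximum-intensity projection over z."""
    if isinstance(stack, ImageStack):
        data = stack.channel(channel)
    else:
        data = np.asarray(stack)
    if data.ndim == 2:
        return data.copy()
    if data.ndim != 3 or data.shape[0] < 1:
        raise ValueError(f"expected a (z, y, x) stack, got shape {data.shape}")
    return data.max(axis=0)


def detect_condensates_2d(
    projection: np.ndarray,
    pixel_size: float,
    threshold_policy: str = "otsu",
    threshold_value: float | None = None,
    min_area_um2: float = 0.05,
    snr_guard: float = 3.0,
) -> int:
    """Count bright condensates in a 2-D field.

    Connected components above threshold with area ≥ ``min_area_um2`` are
    counted.  A noise guard rejects fields where the candidate foreground
    does not rise ``snr_guard`` standard deviations above the background
    (Otsu on a blank field would otherwise split the noise floor).
    """
    if pixel_size is None or pixel_size <= 0:
        raise ValueError("pixel size (μm) is required")
    img = np.asarray(projection, float)
    if np.ptp(img) < 1e-12:
        return 0
    if threshold_policy == "otsu":
        thr = threshold_otsu(img)
    elif threshold_policy == "absolute":
        if threshold_value is None:
            raise ValueError("absolute policy needs threshold_value")
        thr = float(threshold_value)
    else:
        raise ValueError(f"unknown threshold_policy {threshold_policy!r}")
    mask = img > thr
    if not mask.any() or mask.all():
        return 0
    bg = img[~mask]
    if img[mask].mean() - bg.mean() < snr_guard * max(bg.std(), 1e-12):
        return 0
    min_px = max(1, int(round(min_area_um2 / pixel_size ** 2)))
    lab = cc_label(mask, connectivity=2)
    if lab.max() == 0:
        return 0
    areas = np.bincount(lab.ravel())[1:]
    return int(np.sum(areas >= min_px))


def csat_bracket(
    series: DilutionSeries,
    min_count: int = 3,
    **detector_kwargs,
) -> CsatBracket:
    """Bracket C_sat from per-concentration condensate detection.

    A field is condensate-positive when it contains at least ``min_count``
    detected objects (guards against single-speck false positives).  A
    non-monotone positive/negative pattern is flagged and the bracket taken
    from the first positive concentration, with a warning.
    """
    counts = [detect_condensates_2d(img, series.pixel_size, **detector_kwargs)
              for img in series.images]
    positive = [c >= min_count for c in counts]
    if not any(positive):
        return CsatBracket(lower=float(series.concentrations[-1]),
                           upper=math.inf, counts=counts)
    first_pos = positive.index(True)
    monotone = all(positive[first_pos:])
    if not monotone:
        logger.warning("non-monotone condensate detection pattern %s; "
                       "bracketing from first positive concentration", positive)
    lower = float(series.concentrations[first_pos - 1]) if first_pos > 0 else 0.0
    return CsatBracket(lower=lower, upper=float(series.concentrations[first_pos]),
                       monotone=monotone, counts=counts)


def turbidity_summary(series: list[TurbiditySeries]) -> pd.DataFrame:
    """Background-subtracted mean ± SD of A340 per concentration.

    SD is left undefined (NaN, flagged in the log) below 2 replicates;
    protocols call for at least three independent sets.
    """
    rows = []
    for s in series:
        corrected = s.a340 - s.buffer_a340
        sd = float(np.std(corrected, ddof=1)) if corrected.size >= 2 else float("nan")
        if corrected.size < 2:
            logger.warning("concentration %g μmol/L has %d replicate(s); SD undefined",
                           s.concentration, corrected.size)
        if corrected.size < 3:
            logger.info("concentration %g μmol/L below the 3-replicate convention",
                        s.concentration)
        rows.append({
            "concentration_umol_L": s.concentration,
            "a340_mean": float(np.mean(corrected)),
            "a340_sd": sd,
            "n_replicates": int(corrected.size),
        })
    return pd.DataFrame(rows).sort_values("concentration_umol_L", ignore_index=True)
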