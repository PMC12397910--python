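"""Rule-based condensate (droplet) segmentation and quantification.

Replicates an ImageJ-particle-analysis style workflow: a fixed intensity
threshold defines the foreground, 8-connected components become particles,
and particles are filtered by area and by circularity
(``4*pi*area / perimeter**2``, clipped to 1.0 against digitization
artifacts).  Aggregate statistics (count, total area, mean size, mean
intensity) and a rule-based condensation call (mean thresholded-foreground
intensity on a normalized scale) follow the same conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure

from .errors import InvalidInputError

DEFAULT_INTENSITY_THRESHOLD = 55     # in-cell particle analysis setting
DEFAULT_PHASE_THRESHOLD = 50         # in-vitro phase-diagram setting
DEFAULT_CIRCULARITY = (0.3, 1.0)
DEFAULT_SIZE_RANGE = (0.1, np.inf)
DEFAULT_CONDENSATION_CUTOFF = 0.3


@dataclass
class Particle:
    label: int
    area: float                  # px^2 (or physical units via pixel_size)
    perimeter: float
    circularity: float
    mean_intensity: float
    centroid: tuple


@dataclass
class DropletStats:
    """Aggregate droplet statistics over one segmented image."""

    n_droplets: int
    total_area: float
    mean_size: float
    mean_intensity: float
    particles: pd.DataFrame = field(repr=False, default=None)


def segment_droplets(image, intensity_threshold=DEFAULT_INTENSITY_THRESHOLD,
                     size_range=DEFAULT_SIZE_RANGE,
                     circularity_range=DEFAULT_CIRCULARITY,
                     pixel_size: float | None = None) -> list[Particle]:
    """Threshold, label (8-connectivity), and filter particles.

    Foreground is ``image > intensity_threshold``.  ``size_range`` is in
    px^2 unless ``pixel_size`` (length per pixel) is given, in which case it
    is interpreted in physical area units.  Circularity uses the
    Crofton-formula perimeter and is clipped to <= 1.0.  An empty result is
    returned (not an error) for blank images or thresholds above the
    maximum.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise InvalidInputError("expected a single-channel 2-D image")
    mask = img > intensity_threshold
    if not mask.any():
        return []
    labels = measure.label(mask, connectivity=2)
    px_area = (pixel_size ** 2) if pixel_size else 1.0
    lo, hi = size_range
    clo, chi = circularity_range
    out = []
    for rp in measure.regionprops(labels, intensity_image=img):
        area = rp.area * px_area
        perim = rp.perimeter_crofton * (pixel_size or 1.0)
        if perim > 0:
            circ = min(4.0 * np.pi * rp.area / (rp.perimeter_crofton ** 2), 1.0)
        else:
            circ = 1.0               # single pixel
        if not (lo <= area <= hi):
            continue
        if not (clo <= circ <= chi):
            continue
        out.append(Particle(label=rp.label, area=area, perimeter=perim,
                            circularity=circ,
                            mean_intensity=float(rp.intensity_mean),
                            centroid=tuple(rp.centroid)))
    return out


def droplet_stats(particles, image=None) -> DropletStats:
    """Aggregate count, total/mean area and mean within-particle intensity."""
    if not particles:
        return DropletStats(n_droplets=0, total_area=0.0, mean_size=0.0,
                            mean_intensity=0.0,
                            particles=pd.DataFrame(columns=[
                                "label", "area", "perimeter", "circularity",
                                "mean_intensity"]))
    df = pd.DataFrame([{
        "label": p.label, "area": p.area, "perimeter": p.perimeter,
        "circularity": p.circularity, "mean_intensity": p.mean_intensity,
        "centroid_row": p.centroid[0], "centroid_col": p.centroid[1],
    } for p in particles])
    total = float(df["area"].sum())
    # particle-intensity average weighted by area
    mean_int = float((df["mean_intensity"] * df["area"]).sum() / total)
    return DropletStats(n_droplets=len(particles), total_area=total,
                        mean_size=total / len(particles),
                        mean_intensity=mean_int, particles=df)


def condensation_call(image,
                      mean_intensity_cutoff=DEFAULT_CONDENSATION_CUTOFF,
                      intensity_threshold=DEFAULT_PHASE_THRESHOLD,
                      normalize: str = "max") -> bool:
    """Rule-based condensed/dilute call for a phase-diagram point.

    The image is normalized (``"max"``: divide by its maximum; ``"none"``:
    use raw values, with the cutoff on the raw scale), pixels at or below
    ``intensity_threshold`` (raw scale) are zeroed, and the call is True iff
    the mean of the resulting thresholded image exceeds
    ``mean_intensity_cutoff``.
    """
    img = np.asarray(image, dtype=float)
    fg = np.where(img > intensity_threshold, img, 0.0)
    if normalize == "max":
        peak = img.max()
        if peak <= 0:
            return False
        metric = float(fg.mean() / peak)
    elif normalize == "none":
        metric = float(fg.mean())
    else:
        raise InvalidInputError(f"unknown normalization {normalize!r}")
    return metric > mean_intensity_cutoff


def relative_area(stats: DropletStats, reference: DropletStats) -> float:
    """Total condensate area relative to a reference condition."""
    if reference.total_area <= 0:
        raise InvalidInputError("reference total area must be positive")
    return stats.total_area / reference.total_area


def batch_relative_area(stats_list, reference: DropletStats):
    """Mean and SD of relative areas over a batch of imaged fields."""
    ratios = np.array([relative_area(s, reference) for s in stats_list])
    sd = float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0
    return float(ratios.mean()), sd
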