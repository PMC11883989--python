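"""Dorsal-light-response (DLR) tilt estimation and recovery analysis.

After monocular optic-nerve crush, fish swim tilted (blind eye up) to
rebalance the light reaching each eye; the tilt angle relative to the
horizon decays back to 0 as vision recovers.  The per-frame estimator
binarizes a side-view still, keeps the largest connected component, and
reports the orientation of the principal (major) axis from second-order
central moments, signed counter-clockwise from the horizon in (-90, 90]
degrees (positive = injured-eye-up by convention; head/tail identity is not
needed for the tilt magnitude).  A per-(fish, time point) mean requires at
least five frames.  Group recovery curves are compared with a
repeated-measures two-way ANOVA and Bonferroni-adjusted per-day contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label

from . import stats as stats_battery

__all__ = [
    "TiltMeasurement",
    "estimate_tilt",
    "mean_tilt",
    "recovery_analysis",
]

MIN_FRAMES = 5


@dataclass
class TiltMeasurement:
    fish_id: str
    dpi: int
    frame_angles_deg: np.ndarray
    mean_angle_deg: float


def estimate_tilt(frame: np.ndarray, min_area_px: int = 50) -> float:
    """Body-axis angle vs. the horizon of the single fish in ``frame``."""
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D frame")
    if np.ptp(img) == 0:
        raise ValueError("no fish detected: frame is flat")
    binary = img > threshold_otsu(img)
    labels = label(binary)
    if labels.max() == 0:
        raise ValueError("no fish detected: empty foreground")
    sizes = np.bincount(labels.ravel())[1:]
    biggest = int(np.argmax(sizes)) + 1
    if sizes[biggest - 1] < min_area_px:
        raise ValueError("no fish detected: largest component below minimum "
                         "area")
    rows, cols = np.nonzero(labels == biggest)
    x = cols - cols.mean()
    y = -(rows - rows.mean())  # up-positive so CCW angles are positive
    sxx = np.mean(x * x)
    syy = np.mean(y * y)
    sxy = np.mean(x * y)
    angle = 0.5 * np.degrees(np.arctan2(2 * sxy, sxx - syy))
    if angle <= -90.0:
        angle += 180.0
    elif angle > 90.0:
        angle -= 180.0
    return float(angle)


def mean_tilt(frame_angles_deg, *, fish_id: str = "", dpi: int = 0
              ) -> TiltMeasurement:
    """Mean tilt over frames for one fish at one time point (>= 5 frames)."""
    angles = np.asarray(frame_angles_deg, dtype=float).ravel()
    if angles.size < MIN_FRAMES:
        raise ValueError(
            f"insufficient frames: need at least {MIN_FRAMES} per fish and "
            "time point")
    return TiltMeasurement(fish_id=fish_id, dpi=dpi,
                           frame_angles_deg=angles,
                           mean_angle_deg=float(angles.mean()))


def recovery_curve(measurements: pd.DataFrame) -> pd.DataFrame:
    """Group mean +- SEM per day post injury, SEM over fish (not frames).

    ``measurements`` is tidy with columns ``group``, ``fish_id``, ``dpi``,
    ``mean_angle_deg`` (one row per fish per time point).
    """
    def sem(x):
        x = np.asarray(x, dtype=float)
        return x.std(ddof=1) / np.sqrt(x.size) if x.size > 1 else np.nan

    return (measurements.groupby(["group", "dpi"])["mean_angle_deg"]
            .agg(mean="mean", sem=sem, n="size").reset_index())


def recovery_analysis(measurements: pd.DataFrame, alpha: float = 0.05
                      ) -> pd.DataFrame:
    """Per-dpi significance map between two groups' recovery curves.

    Runs a repeated-measures two-way ANOVA (within: dpi, between: group)
    on per-fish mean angles, then Bonferroni-adjusted per-dpi group
    contrasts; returns one row per dpi with the adjusted p and a boolean
    ``significant`` flag — the "grey box" map of the recovery figures.
    """
    required = {"group", "fish_id", "dpi", "mean_angle_deg"}
    if not required <= set(measurements.columns):
        raise ValueError(f"measurements must have columns {sorted(required)}")
    groups = measurements.groupby("group")["fish_id"].nunique()
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    if groups.min() < 2:
        raise ValueError("need at least 2 fish per group")
    res = stats_battery.rm_anova_bonferroni(
        measurements, dv="mean_angle_deg", subject="fish_id",
        within="dpi", between="group")
    out = res.pairwise.rename(columns={"level": "dpi"})
    out["significant"] = out["adjusted_p"] < alpha
    return out
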