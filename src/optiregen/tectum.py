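"""Tectal reinnervation: crushed/uninjured ΔF/F of the SO/SFGS band.

Each coronal section holds two tectal hemispheres.  The superficial
retinorecipient band (SO + SFGS pooled) of the uninjured hemisphere is
segmented by Otsu thresholding; its annular shell, found by a circle fit,
is mirrored onto the crushed hemisphere so that a fully denervated (dark)
band is still measured.  The band is split into dorsal / medial / ventral
thirds by equal angular sectors about the hemisphere centroid, measured
from the dorsal pole ventralward.  Per sector, ΔF/F is the crushed-side
mean over the uninjured-side mean; per fish, section values are mapped onto
a normalized 0-100% rostro-caudal axis so differently sized brains can be
averaged and compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .phantoms import SECTORS, fold_angle_deg, _sector_of_fold_angle
from . import stats as stats_battery

__all__ = [
    "TectumSection",
    "segment_band",
    "sector_partition",
    "dff_ratio",
    "quantify_section",
    "quantify_fish",
    "normalize_length",
    "compare_groups",
]


@dataclass
class TectumSection:
    """One coronal section image with its ordering metadata."""

    image: np.ndarray
    rostrocaudal_rank: int
    crushed_side: str  # "left" | "right"
    px_per_um: float = 1.0

    def __post_init__(self) -> None:
        if self.crushed_side not in ("left", "right"):
            raise ValueError("crushed_side must be 'left' or 'right'")


def _fit_circle(rows: np.ndarray, cols: np.ndarray) -> tuple[float, float]:
    """Geometric circle-centre fit to a pixel cloud (Kasa init, refined by
    least squares on radial residuals; the algebraic fit alone is biased
    along the symmetry axis of a half-annulus arc)."""
    from scipy.optimize import least_squares

    A = np.column_stack([cols, rows, np.ones_like(rows, dtype=float)])
    b = cols.astype(float) ** 2 + rows.astype(float) ** 2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx0, cy0 = sol[0] / 2.0, sol[1] / 2.0
    r0 = float(np.hypot(cols - cx0, rows - cy0).mean())

    def resid(p):
        return np.hypot(cols - p[0], rows - p[1]) - p[2]

    fit = least_squares(resid, x0=[cx0, cy0, r0], method="lm")
    cx, cy = float(fit.x[0]), float(fit.x[1])
    return cy, cx


def segment_band(section: TectumSection, *, thickness_px: int,
                 min_area_px: int = 50):
    """Segment the SO/SFGS band of both hemispheres.

    Returns ``(crushed_mask, uninjured_mask, info)`` where ``info`` carries
    the hemisphere centroids (row, col) under keys ``"crushed_centroid"``
    and ``"uninjured_centroid"``.  The uninjured band is the Otsu foreground
    of the uninjured hemisphere intersected with the annular shell
    [outer_r - thickness, outer_r] about the fitted band centre; the crushed
    band is its mirror image across the vertical midline.
    """
    img = np.asarray(section.image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D section image")
    h, w = img.shape
    mid = w // 2
    uninjured_cols = (slice(mid, w) if section.crushed_side == "left"
                      else slice(0, mid))
    half = img[:, uninjured_cols]
    if np.ptp(half) == 0:
        raise ValueError("no band found: uninjured hemisphere is flat")
    fg = half > threshold_otsu(half)
    if fg.sum() < min_area_px:
        raise ValueError("no band found: thresholded area below minimum")
    rows, cols = np.nonzero(fg)
    cols = cols + uninjured_cols.start
    cy, cx = _fit_circle(rows, cols)
    dist = np.hypot(cols - cx, rows - cy)
    outer_r = float(np.quantile(dist, 0.995))

    rr, cc = np.mgrid[0:h, 0:w]
    in_shell = ((np.hypot(cc - cx, rr - cy) >= outer_r - thickness_px)
                & (np.hypot(cc - cx, rr - cy) <= outer_r))
    full_fg = np.zeros((h, w), dtype=bool)
    full_fg[:, uninjured_cols] = fg
    uninjured_mask = full_fg & in_shell
    if not uninjured_mask.any():
        raise ValueError("no band found: shell does not intersect the "
                         "thresholded foreground")
    # crushed band: the uninjured shell reflected across the vertical
    # midline (hemispheres are assumed mirror-symmetric), restricted to
    # the same fold-angle support so a fully denervated band is still
    # measured over the matching anatomy
    m_rows, m_cols = np.nonzero(uninjured_mask)
    theta = fold_angle_deg(m_rows.astype(float), m_cols.astype(float),
                           (cy, cx))
    cx_c = w - cx
    theta_all = fold_angle_deg(rr.astype(float), cc.astype(float),
                               (cy, cx_c))
    crushed_mask = ((np.hypot(cc - cx_c, rr - cy)
                     >= outer_r - thickness_px)
                    & (np.hypot(cc - cx_c, rr - cy) <= outer_r)
                    & (theta_all >= theta.min())
                    & (theta_all <= theta.max()))
    lateral = (cc - cx_c) <= 0 if section.crushed_side == "left" \
        else (cc - cx_c) >= 0
    crushed_mask &= lateral
    info = {"uninjured_centroid": (cy, cx),
            "crushed_centroid": (cy, cx_c),
            "outer_r_px": outer_r}
    return crushed_mask, uninjured_mask, info


def sector_partition(mask: np.ndarray, hemisphere_centroid: tuple[float, float]
                     ) -> dict[str, np.ndarray]:
    """Split a band mask into dorsal / medial / ventral angular thirds.

    The angle is measured from the dorsal pole (straight up) ventralward in
    [0, 180] degrees regardless of the lateral direction; boundaries at 60
    and 120 degrees belong to the more dorsal sector.  The three submasks
    are disjoint and their union is the input mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("sector partition of an empty mask")
    rows, cols = np.nonzero(mask)
    theta = fold_angle_deg(rows.astype(float), cols.astype(float),
                           hemisphere_centroid)
    sector_idx = _sector_of_fold_angle(theta)
    out: dict[str, np.ndarray] = {}
    for si, name in enumerate(SECTORS):
        m = np.zeros_like(mask)
        sel = sector_idx == si
        m[rows[sel], cols[sel]] = True
        out[name] = m
    return out


def dff_ratio(crushed_mean: float, uninjured_mean: float,
              mode: str = "ratio") -> float:
    """Crushed-over-uninjured fluorescence ratio (ΔF/F).

    ``mode="ratio"`` returns crushed/uninjured (reaches 1 at full recovery);
    ``mode="delta"`` returns (crushed - uninjured)/uninjured (reaches 0).
    """
    if uninjured_mean <= 0:
        raise ValueError("uninjured mean fluorescence must be positive")
    r = float(crushed_mean) / float(uninjured_mean)
    if mode == "ratio":
        return r
    if mode == "delta":
        return r - 1.0
    raise ValueError("mode must be 'ratio' or 'delta'")


def quantify_section(section: TectumSection, *, thickness_px: int,
                     mode: str = "ratio") -> dict[str, float]:
    """Per-sector ΔF/F of one section."""
    crushed_mask, uninjured_mask, info = segment_band(
        section, thickness_px=thickness_px)
    img = np.asarray(section.image, dtype=float)
    c_sec = sector_partition(crushed_mask, info["crushed_centroid"])
    u_sec = sector_partition(uninjured_mask, info["uninjured_centroid"])
    out = {}
    for s in SECTORS:
        if not c_sec[s].any() or not u_sec[s].any():
            raise ValueError(f"no band found in sector {s}")
        out[s] = dff_ratio(img[c_sec[s]].mean(), img[u_sec[s]].mean(),
                           mode=mode)
    return out


def normalize_length(section_dffs: pd.DataFrame, n_out: int = 20,
                     fish_id: str | None = None) -> pd.DataFrame:
    """Resample per-section ΔF/F onto a fixed 0-100% rostro-caudal grid.

    ``section_dffs`` is tidy with columns ``rank``, ``sector``, ``dff``;
    ranks are mapped to percent tectal length by rank/(n-1)*100 and ΔF/F is
    linearly interpolated onto ``n_out`` evenly spaced positions, adjusting
    for brain-size differences between fish.
    """
    required = {"rank", "sector", "dff"}
    if not required <= set(section_dffs.columns):
        raise ValueError(f"section_dffs must have columns {sorted(required)}")
    grid = np.linspace(0.0, 100.0, n_out)
    rows = []
    for sector, sub in section_dffs.groupby("sector", sort=False):
        sub = sub.sort_values("rank")
        n = len(sub)
        if n < 2:
            raise ValueError("length normalization needs at least 2 sections")
        if not np.array_equal(sub["rank"].to_numpy(), np.arange(n)):
            raise ValueError("section ranks must be consecutive from 0")
        pct = sub["rank"].to_numpy() / (n - 1) * 100.0
        vals = np.interp(grid, pct, sub["dff"].to_numpy())
        for p, v in zip(grid, vals):
            rows.append({"fish_id": fish_id, "sector": sector,
                         "position_pct": p, "dff": v})
    return pd.DataFrame(rows)


def quantify_fish(sections: Iterable[TectumSection], *, thickness_px: int,
                  n_out: int = 20, fish_id: str | None = None,
                  mode: str = "ratio") -> pd.DataFrame:
    """Quantify a whole fish: all sections → normalized sector profiles."""
    recs = []
    for sec in sections:
        dffs = quantify_section(sec, thickness_px=thickness_px, mode=mode)
        for s, v in dffs.items():
            recs.append({"rank": sec.rostrocaudal_rank, "sector": s,
                         "dff": v})
    if not recs:
        raise ValueError("no sections supplied")
    return normalize_length(pd.DataFrame(recs), n_out=n_out, fish_id=fish_id)


def compare_groups(profiles_a: pd.DataFrame, profiles_b: pd.DataFrame,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Two-way ANOVA (group x position) per sector with Fisher's LSD.

    Inputs are tidy per-fish profiles (columns ``fish_id``, ``sector``,
    ``position_pct``, ``dff``) for each group.  Returns one row per
    (sector, position) with the LSD p-value for the group contrast and a
    boolean ``significant`` flag at ``alpha`` — the per-position "grey box"
    map of the reinnervation figures.
    """
    a = profiles_a.assign(group="A")
    b = profiles_b.assign(group="B")
    grid_a = np.sort(profiles_a["position_pct"].unique())
    grid_b = np.sort(profiles_b["position_pct"].unique())
    if not np.allclose(grid_a, grid_b):
        raise ValueError("position grids differ between groups")
    for name, df in (("A", profiles_a), ("B", profiles_b)):
        if df["fish_id"].nunique() < 2:
            raise ValueError(f"group {name} needs at least 2 fish")
    data = pd.concat([a, b], ignore_index=True)
    out = []
    for sector, sub in data.groupby("sector", sort=False):
        res = stats_battery.anova_twoway_lsd(
            sub["dff"].to_numpy(), sub["group"].to_numpy(),
            sub["position_pct"].to_numpy())
        lsd = res.lsd
        for _, row in lsd.iterrows():
            out.append({"sector": sector, "position_pct": row["level_b"],
                        "p": row["p"], "significant": row["p"] < alpha})
    return pd.DataFrame(out)
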