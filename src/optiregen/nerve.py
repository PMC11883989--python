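"""Optic-nerve regeneration index from a whole-mount fluorescence image.

The nerve axis is assumed horizontal (a :func:`rectify` helper rotates by a
user-supplied angle).  Mean GFP intensity is binned in 50 μm steps from the
injury site toward the optic chiasm and converted to the regeneration index

    index = (F - F0) / (Fpre - F0)

where ``F`` is the mean intensity of a bin, ``Fpre`` the mean of the 50 μm
window immediately proximal to the injury site, and ``F0`` the mean
intensity of the whole uninjured nerve (a separate image or a precomputed
scalar).  The index is 0 at background, 1 at pre-injury brightness, and is
deliberately not clipped: noise may push individual bins outside [0, 1] and
clipping would bias group means.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.transform import rotate

__all__ = [
    "NerveProfile",
    "RegenIndexProfile",
    "bin_intensity",
    "regeneration_index",
    "front_position",
    "whole_nerve_mean",
    "rectify",
]


@dataclass
class NerveProfile:
    """Binned axial fluorescence with the two reference levels.

    ``bin_start_um`` are left edges of half-open 50 μm bins measured as
    distance distal to the injury site (0 = injury), ordered injury → chiasm.
    """

    bin_start_um: np.ndarray
    F: np.ndarray
    F_pre: float
    F_0: float
    px_per_um: float
    step_um: float = 50.0

    def with_f0(self, f_0: float) -> "NerveProfile":
        return replace(self, F_0=float(f_0))


@dataclass
class RegenIndexProfile:
    bin_start_um: np.ndarray
    index: np.ndarray
    step_um: float = 50.0

    @property
    def bin_center_um(self) -> np.ndarray:
        return self.bin_start_um + self.step_um / 2.0


def whole_nerve_mean(image: np.ndarray) -> float:
    """Mean intensity of a whole uninjured-nerve image (the F0 reference)."""
    return float(np.mean(np.asarray(image, dtype=float)))


def rectify(image: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate so the nerve axis is horizontal (angle counter-clockwise)."""
    return rotate(np.asarray(image, dtype=float), angle_deg, resize=True,
                  preserve_range=True)


def bin_intensity(image: np.ndarray, injury_x_um: float, chiasm_x_um: float,
                  *, px_per_um: float, step_um: float = 50.0,
                  f_0: float = np.nan) -> NerveProfile:
    """Bin mean fluorescence in ``step_um`` steps from injury to chiasm.

    Each bin averages all pixels (full image height) whose axial pixel-centre
    coordinate falls in the half-open window [start, start + step).  A
    trailing partial bin is dropped.  ``F_pre`` is the mean of the single
    step-wide window immediately proximal to ``injury_x_um``.  ``f_0`` may be
    supplied here or attached later with :meth:`NerveProfile.with_f0`.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D image")
    if px_per_um <= 0:
        raise ValueError("calibration px_per_um must be positive")
    if injury_x_um >= chiasm_x_um:
        raise ValueError("injury_x_um must lie proximal to chiasm_x_um")
    n_bins = int(np.floor((chiasm_x_um - injury_x_um) / step_um))
    if n_bins < 1:
        raise ValueError("span too short: injury-to-chiasm span must cover "
                         "at least one full step")
    x_um = (np.arange(image.shape[1]) + 0.5) / px_per_um
    col_mean = image.mean(axis=0)

    starts = injury_x_um + step_um * np.arange(n_bins)
    F = np.empty(n_bins)
    for i, s in enumerate(starts):
        sel = (x_um >= s) & (x_um < s + step_um)
        if not sel.any():
            raise ValueError("span too short: image does not cover bin "
                             f"starting at {s:.1f} um")
        F[i] = col_mean[sel].mean()
    pre_sel = (x_um >= injury_x_um - step_um) & (x_um < injury_x_um)
    if not pre_sel.any():
        raise ValueError("span too short: image does not cover the "
                         "pre-injury reference window")
    F_pre = float(col_mean[pre_sel].mean())
    return NerveProfile(bin_start_um=starts - injury_x_um, F=F, F_pre=F_pre,
                        F_0=float(f_0), px_per_um=px_per_um, step_um=step_um)


def regeneration_index(profile: NerveProfile) -> RegenIndexProfile:
    """Per-bin (F - F0) / (Fpre - F0); bins preserved, values not clipped."""
    if not np.isfinite(profile.F_0):
        raise ValueError("degenerate references: F_0 has not been set")
    if not profile.F_pre > profile.F_0:
        raise ValueError("degenerate references: F_pre must exceed F_0")
    index = (profile.F - profile.F_0) / (profile.F_pre - profile.F_0)
    return RegenIndexProfile(bin_start_um=profile.bin_start_um.copy(),
                             index=index, step_um=profile.step_um)


def front_position(index_profile: RegenIndexProfile,
                   threshold: float = 0.5) -> float | None:
    """Centre of the most distal bin whose index reaches ``threshold``.

    Returns ``None`` when no bin qualifies (no detectable regrowth).
    """
    if index_profile.index.size < 1:
        raise ValueError("index profile has no bins")
    hits = np.nonzero(index_profile.index >= threshold)[0]
    if hits.size == 0:
        return None
    return float(index_profile.bin_center_um[hits[-1]])
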