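"""Synthetic phantom generators with attached ground truth.

Every downstream quantification module in this package is exercised on
synthetic data produced here: a regenerating optic-nerve phantom, coronal
optic-tectum sections with a partially reinnervated superficial (SO/SFGS)
band, tilted fish silhouettes for the dorsal-light-response assay, cell +
puncta fields for in situ quantification, and negative-binomial RNA-seq
count matrices with a spiked pathway effect.

All generators are deterministic under a fixed seed and return a
machine-readable ground-truth dictionary sufficient to score the analysis
module they feed.  Intensities are arbitrary linear units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "NervePhantomSpec",
    "TectumPhantomSpec",
    "SilhouetteSpec",
    "PunctaPhantomSpec",
    "CountPhantomSpec",
    "make_nerve_phantom",
    "make_tectum_phantoms",
    "make_silhouette",
    "make_puncta_field",
    "make_count_matrix",
    "constant_profile",
    "ramp_profile",
]

SECTORS = ("dorsal", "medial", "ventral")


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise ValueError(message)


# ---------------------------------------------------------------------------
# Optic nerve phantom
# ---------------------------------------------------------------------------

@dataclass
class NervePhantomSpec:
    """Geometry and intensity model of a regenerating-nerve whole mount.

    The nerve runs horizontally.  Proximal to the injury site the nerve is
    intact at ``f_pre_level``; distal to the injury, regenerated axon signal
    holds near ``f_pre_level`` up to the regeneration front at ``front_x_um``
    (an absolute coordinate along the nerve axis) and falls off logistically
    to the background level ``f0_level`` with softness ``front_softness_um``.
    """

    length_um: float = 1500.0
    px_per_um: float = 1.0
    injury_x_um: float = 250.0
    front_x_um: float = 750.0
    f_pre_level: float = 200.0
    f0_level: float = 20.0
    front_softness_um: float = 25.0
    noise_sd: float = 0.0
    height_px: int = 64
    seed: int = 0

    def validate(self) -> None:
        _require(self.f_pre_level > self.f0_level >= 0,
                 "invariant violated: f_pre_level > f0_level >= 0")
        _require(self.injury_x_um < self.front_x_um <= self.length_um,
                 "invariant violated: injury_x_um < front_x_um <= length_um")
        _require(self.noise_sd >= 0, "invariant violated: noise_sd >= 0")
        _require(self.px_per_um > 0, "invariant violated: px_per_um > 0")
        _require(self.height_px >= 1, "invariant violated: height_px >= 1")


def nerve_template(spec: NervePhantomSpec, x_um: np.ndarray) -> np.ndarray:
    """Noise-free axial intensity profile of the nerve phantom."""
    x = np.asarray(x_um, dtype=float)
    distal = spec.f0_level + (spec.f_pre_level - spec.f0_level) * expit(
        (spec.front_x_um - x) / spec.front_softness_um)
    return np.where(x <= spec.injury_x_um, spec.f_pre_level, distal)


def make_nerve_phantom(spec: NervePhantomSpec) -> tuple[np.ndarray, dict]:
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    width = int(round(spec.length_um * spec.px_per_um))
    _require(width >= 2, "invariant violated: image must span >= 2 pixels")
    # pixel-centre axial coordinates in micrometres
    x_um = (np.arange(width) + 0.5) / spec.px_per_um
    template = nerve_template(spec, x_um)
    image = np.tile(template, (spec.height_px, 1))
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    ground_truth = {
        "front_x_um": spec.front_x_um,
        "front_distal_um": spec.front_x_um - spec.injury_x_um,
        "injury_x_um": spec.injury_x_um,
        "f_pre_level": spec.f_pre_level,
        "f0_level": spec.f0_level,
        "px_per_um": spec.px_per_um,
        "template_x_um": x_um,
        "template": template,
    }
    return image, ground_truth


# ---------------------------------------------------------------------------
# Optic tectum phantom
# ---------------------------------------------------------------------------

ProfileFn = Callable[[float], float]


def constant_profile(dorsal: float, medial: float, ventral: float
                     ) -> dict[str, ProfileFn]:
    """Per-sector reinnervation fractions constant along the tectal axis."""
    return {
        "dorsal": lambda t, v=dorsal: v,
        "medial": lambda t, v=medial: v,
        "ventral": lambda t, v=ventral: v,
    }


def ramp_profile(start: float = 0.8, stop: float = 0.4) -> dict[str, ProfileFn]:
    """Reinnervation declining linearly from rostral to caudal, all sectors."""
    return {s: (lambda t, a=start, b=stop: a + (b - a) * t) for s in SECTORS}


@dataclass
class TectumPhantomSpec:
    """Stack of coronal tectum sections, crushed side vs. control side.

    Each section holds two lateral half-annulus bands (the pooled SO/SFGS
    layer) drawn about mirrored hemisphere centres: the control side at
    ``uninjured_level``, the crushed side at
    ``background + fraction * (uninjured - background)`` where ``fraction``
    is the per-sector reinnervation profile evaluated at the section's
    normalized rostro-caudal position in [0, 1].
    """

    n_sections: int = 21
    layer_outer_r_px: int = 80
    layer_thickness_px: int = 12
    reinnervation_profile: Mapping[str, ProfileFn] = field(
        default_factory=lambda: ramp_profile())
    uninjured_level: float = 200.0
    background_level: float = 20.0
    noise_sd: float = 0.0
    crushed_side: str = "left"
    seed: int = 0

    def validate(self) -> None:
        _require(self.n_sections >= 2,
                 "invariant violated: n_sections >= 2 (length normalization "
                 "undefined otherwise)")
        _require(self.uninjured_level > self.background_level,
                 "invariant violated: uninjured_level > background_level")
        _require(self.layer_thickness_px < self.layer_outer_r_px,
                 "invariant violated: layer_thickness_px < layer_outer_r_px")
        _require(self.crushed_side in ("left", "right"),
                 "invariant violated: crushed_side must be 'left' or 'right'")
        _require(self.noise_sd >= 0, "invariant violated: noise_sd >= 0")
        for s in SECTORS:
            _require(s in self.reinnervation_profile,
                     f"invariant violated: reinnervation_profile missing {s}")
            for t in np.linspace(0, 1, 11):
                f = self.reinnervation_profile[s](float(t))
                _require(0.0 <= f <= 1.0,
                         "invariant violated: reinnervation fraction must lie "
                         "in [0, 1]")


def _sector_of_fold_angle(theta_deg: np.ndarray) -> np.ndarray:
    """Sector index from the fold angle off the dorsal pole (0=dorsal,
    1=medial, 2=ventral); boundary angles go to the more dorsal sector."""
    out = np.full(theta_deg.shape, 2, dtype=int)
    out[theta_deg <= 120.0] = 1
    out[theta_deg <= 60.0] = 0
    return out


def fold_angle_deg(rows: np.ndarray, cols: np.ndarray,
                   centroid: tuple[float, float]) -> np.ndarray:
    """Angle in [0, 180] between the dorsal (up) direction and the ray from
    ``centroid`` (row, col) to each pixel; image rows increase downward."""
    dy = -(rows - centroid[0])  # up-positive
    dx = cols - centroid[1]
    r = np.hypot(dx, dy)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.where(r > 0, dy / np.maximum(r, 1e-12), 1.0)
    return np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))


def make_tectum_phantoms(spec: TectumPhantomSpec
                         ) -> tuple[np.ndarray, dict]:
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    r_out = spec.layer_outer_r_px
    margin = 8
    height = 2 * (r_out + margin)
    width = 4 * (r_out + margin)
    cy = height / 2.0
    cx_left = width / 4.0
    cx_right = 3 * width / 4.0
    rows, cols = np.mgrid[0:height, 0:width]

    def band_mask_and_sector(cx: float, lateral_sign: int):
        dy = -(rows - cy)
        dx = cols - cx
        r = np.hypot(dx, dy)
        in_shell = (r >= r_out - spec.layer_thickness_px) & (r <= r_out)
        lateral = (dx * lateral_sign) >= 0
        mask = in_shell & lateral
        theta = fold_angle_deg(rows, cols, (cy, cx))
        return mask, _sector_of_fold_angle(theta)

    left_mask, left_sector = band_mask_and_sector(cx_left, -1)
    right_mask, right_sector = band_mask_and_sector(cx_right, +1)
    if spec.crushed_side == "left":
        crushed_mask, crushed_sector = left_mask, left_sector
        control_mask = right_mask
    else:
        crushed_mask, crushed_sector = right_mask, right_sector
        control_mask = left_mask

    positions = (np.arange(spec.n_sections) / (spec.n_sections - 1))
    stack = np.empty((spec.n_sections, height, width), dtype=float)
    fractions: dict[str, list[float]] = {s: [] for s in SECTORS}
    for k, t in enumerate(positions):
        img = np.full((height, width), spec.background_level, dtype=float)
        img[control_mask] = spec.uninjured_level
        for si, s in enumerate(SECTORS):
            f = float(spec.reinnervation_profile[s](float(t)))
            level = spec.background_level + f * (
                spec.uninjured_level - spec.background_level)
            img[crushed_mask & (crushed_sector == si)] = level
            fractions[s].append(f)
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        stack[k] = img
    fraction_arr = {s: np.array(fractions[s]) for s in SECTORS}
    ground_truth = {
        "positions": positions,
        "fractions": fraction_arr,
        "uninjured_level": spec.uninjured_level,
        "background_level": spec.background_level,
        "crushed_side": spec.crushed_side,
        "centers": {"left": (cy, cx_left), "right": (cy, cx_right)},
        "layer_outer_r_px": r_out,
        "layer_thickness_px": spec.layer_thickness_px,
        "band_masks": {"crushed": crushed_mask, "control": control_mask},
        "expected_dff": {
            s: (spec.background_level + fraction_arr[s]
                * (spec.uninjured_level - spec.background_level))
            / spec.uninjured_level
            for s in SECTORS
        },
    }
    return stack, ground_truth


# ---------------------------------------------------------------------------
# Fish silhouette phantom (dorsal light response)
# ---------------------------------------------------------------------------

@dataclass
class SilhouetteSpec:
    """Elongated-ellipse fish silhouette at a known body-axis tilt.

    ``tilt_deg`` is the angle of the body axis above the horizon,
    counter-clockwise positive (blind-eye-up by convention).  The day-0 /
    uninjured baseline default is 0 degrees; the post-crush regime in this
    assay is roughly 8-12 degrees.
    """

    tilt_deg: float = 0.0
    body_len_px: int = 120
    body_aspect: float = 4.0
    n_frames: int = 5
    jitter_deg: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        _require(-90.0 < self.tilt_deg < 90.0,
                 "invariant violated: -90 < tilt_deg < 90")
        _require(self.body_aspect > 1.0,
                 "invariant violated: body_aspect > 1 (orientation must be "
                 "identifiable)")
        _require(self.n_frames >= 1, "invariant violated: n_frames >= 1")
        _require(self.jitter_deg >= 0, "invariant violated: jitter_deg >= 0")
        _require(self.noise_sd >= 0, "invariant violated: noise_sd >= 0")


def _ellipse_frame(angle_deg: float, body_len_px: int, body_aspect: float,
                   size: int) -> np.ndarray:
    a = body_len_px / 2.0
    b = a / body_aspect
    c = (size - 1) / 2.0
    rows, cols = np.mgrid[0:size, 0:size]
    x = cols - c
    y = -(rows - c)  # up-positive
    th = math.radians(angle_deg)
    u = x * math.cos(th) + y * math.sin(th)
    v = -x * math.sin(th) + y * math.cos(th)
    return ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(float)


def make_silhouette(spec: SilhouetteSpec) -> tuple[np.ndarray, dict]:
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    size = int(math.ceil(spec.body_len_px * 1.5))
    angles = spec.tilt_deg + (
        rng.normal(0.0, spec.jitter_deg, size=spec.n_frames)
        if spec.jitter_deg > 0 else np.zeros(spec.n_frames))
    frames = np.empty((spec.n_frames, size, size), dtype=float)
    for i, ang in enumerate(angles):
        img = _ellipse_frame(float(ang), spec.body_len_px, spec.body_aspect,
                             size)
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        frames[i] = img
    ground_truth = {"tilt_deg": spec.tilt_deg,
                    "frame_angles_deg": np.asarray(angles, dtype=float)}
    return frames, ground_truth


# ---------------------------------------------------------------------------
# Cell + puncta field phantom
# ---------------------------------------------------------------------------

@dataclass
class PunctaPhantomSpec:
    """Field of marker-labelled cells with per-cell transcript puncta.

    Cells are rendered as disks in the marker channel; puncta as Gaussian
    spots in the probe channel, each assigned to a parent cell.  Per-cell
    counts are Poisson(``mean_puncta_per_cell``) unless ``forced_counts``
    pins them.  Cell centres keep a separation of at least
    ``2 * cell_radius_px + 4 * spot_sigma_px`` so that punctum-to-cell
    assignment is unambiguous; an overfull field is rejected.
    """

    n_cells: int = 20
    cell_radius_px: float = 8.0
    mean_puncta_per_cell: float = 3.0
    spot_sigma_px: float = 1.5
    field_size_px: tuple[int, int] = (256, 256)
    marker_level: float = 1.0
    spot_amplitude: float = 1.0
    noise_sd: float = 0.0
    forced_counts: Sequence[int] | None = None
    seed: int = 0

    def validate(self) -> None:
        _require(self.n_cells >= 0, "invariant violated: n_cells >= 0")
        _require(self.cell_radius_px > 0,
                 "invariant violated: cell_radius_px > 0")
        _require(self.mean_puncta_per_cell >= 0,
                 "invariant violated: mean_puncta_per_cell >= 0")
        _require(self.spot_sigma_px > 0,
                 "invariant violated: spot_sigma_px > 0")
        if self.forced_counts is not None:
            _require(len(self.forced_counts) == self.n_cells,
                     "invariant violated: forced_counts length must equal "
                     "n_cells")
            _require(all(int(c) == c and c >= 0 for c in self.forced_counts),
                     "invariant violated: forced_counts must be non-negative "
                     "integers")


def _place_cells(rng: np.random.Generator, spec: PunctaPhantomSpec
                 ) -> np.ndarray:
    h, w = spec.field_size_px
    margin = spec.cell_radius_px + 4 * spec.spot_sigma_px
    min_sep = 2 * spec.cell_radius_px + 4 * spec.spot_sigma_px
    _require(h > 2 * margin and w > 2 * margin,
             "field too small for the requested cell radius")
    centers: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 2000 * max(spec.n_cells, 1)
    while len(centers) < spec.n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                "cell packing limit exceeded: cannot place "
                f"{spec.n_cells} non-overlapping cells in this field "
                "(assignment would be ambiguous)")
        y = rng.uniform(margin, h - margin)
        x = rng.uniform(margin, w - margin)
        if all((y - cy) ** 2 + (x - cx) ** 2 >= min_sep ** 2
               for cy, cx in centers):
            centers.append((y, x))
    return np.asarray(centers, dtype=float).reshape(spec.n_cells, 2)


def make_puncta_field(spec: PunctaPhantomSpec) -> tuple[np.ndarray, dict]:
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.field_size_px
    centers = _place_cells(rng, spec)
    rows, cols = np.mgrid[0:h, 0:w]
    marker = np.zeros((h, w), dtype=float)
    for cy, cx in centers:
        marker[(rows - cy) ** 2 + (cols - cx) ** 2
               <= spec.cell_radius_px ** 2] = spec.marker_level

    if spec.forced_counts is not None:
        counts = np.asarray(spec.forced_counts, dtype=int)
    else:
        counts = rng.poisson(spec.mean_puncta_per_cell, size=spec.n_cells)
    probe = np.zeros((h, w), dtype=float)
    spot_coords: list[tuple[float, float]] = []
    spot_parent: list[int] = []
    place_r = 0.9 * spec.cell_radius_px
    min_spot_sep = 4.0 * spec.spot_sigma_px  # keep puncta resolvable
    for ci, (cy, cx) in enumerate(centers):
        placed: list[tuple[float, float]] = []
        for _ in range(int(counts[ci])):
            # uniform in a disk around the parent cell centre, rejecting
            # positions that would blur into an already-placed punctum
            best = None
            for _attempt in range(200):
                ang = rng.uniform(0, 2 * math.pi)
                rad = place_r * math.sqrt(rng.uniform())
                sy, sx = cy + rad * math.sin(ang), cx + rad * math.cos(ang)
                near = min((math.hypot(sy - py, sx - px)
                            for py, px in placed), default=np.inf)
                if best is None or near > best[0]:
                    best = (near, sy, sx)
                if near >= min_spot_sep:
                    break
            _, sy, sx = best
            placed.append((sy, sx))
            probe += spec.spot_amplitude * np.exp(
                -((rows - sy) ** 2 + (cols - sx) ** 2)
                / (2 * spec.spot_sigma_px ** 2))
            spot_coords.append((sy, sx))
            spot_parent.append(ci)
    if spec.noise_sd > 0:
        marker = marker + rng.normal(0.0, spec.noise_sd, size=marker.shape)
        probe = probe + rng.normal(0.0, spec.noise_sd, size=probe.shape)
    image = np.stack([marker, probe])
    ground_truth = {
        "centers": centers,
        "cell_radius_px": spec.cell_radius_px,
        "counts": counts,
        "spot_coords": np.asarray(spot_coords, dtype=float).reshape(-1, 2),
        "spot_parent": np.asarray(spot_parent, dtype=int),
        "spot_sigma_px": spec.spot_sigma_px,
    }
    return image, ground_truth


# ---------------------------------------------------------------------------
# Negative-binomial count matrix phantom
# ---------------------------------------------------------------------------

@dataclass
class CountPhantomSpec:
    """RNA-seq count matrix: NB genes x samples with a spiked gene set.

    Counts are gamma-Poisson draws with common dispersion; members of
    ``spiked_genes`` have their mean multiplied by ``2**spiked_log2fc`` in
    the second (injured) group before sampling, standing in for the
    injured-vs-uninjured pathway effect.  ``base_mean_dist`` gives the
    (meanlog, sdlog) of the log-normal gene base means.
    """

    n_genes: int = 2000
    n_per_group: int = 4
    base_mean_dist: tuple[float, float] = (4.0, 1.0)
    dispersion: float = 0.1
    spiked_set_name: str = "CHOLESTEROL_BIOSYNTHESIS"
    spiked_genes: Sequence[str] | None = None
    n_spiked: int = 25
    spiked_log2fc: float = 2.0
    library_size_factors: Sequence[float] | None = None
    group_labels: tuple[str, str] = ("uninjured", "injured")
    seed: int = 0

    def validate(self) -> None:
        _require(self.n_genes >= 1, "invariant violated: n_genes >= 1")
        _require(self.n_per_group >= 2,
                 "invariant violated: n_per_group >= 2")
        _require(self.dispersion > 0,
                 "invariant violated: dispersion must be positive")
        if self.library_size_factors is not None:
            _require(len(self.library_size_factors) == 2 * self.n_per_group,
                     "invariant violated: one size factor per sample")
            _require(all(f > 0 for f in self.library_size_factors),
                     "invariant violated: size factors must be positive")


def make_count_matrix(spec: CountPhantomSpec):
    """Return ``(counts, ground_truth)``; counts is a genes x samples
    pandas DataFrame of integers, with sample group labels in the truth."""
    import pandas as pd

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = np.array([f"gene_{i:05d}" for i in range(spec.n_genes)])
    if spec.spiked_genes is None:
        n_spiked = min(spec.n_spiked, spec.n_genes)
        spiked = list(genes[rng.choice(spec.n_genes, size=n_spiked,
                                       replace=False)])
    else:
        spiked = list(spec.spiked_genes)
        _require(set(spiked) <= set(genes),
                 "invariant violated: spiked_set must be a subset of the "
                 "gene universe")
    n = spec.n_per_group
    samples = ([f"{spec.group_labels[0]}_{i + 1}" for i in range(n)]
               + [f"{spec.group_labels[1]}_{i + 1}" for i in range(n)])
    groups = np.array([spec.group_labels[0]] * n + [spec.group_labels[1]] * n)
    sf = (np.ones(2 * n) if spec.library_size_factors is None
          else np.asarray(spec.library_size_factors, dtype=float))

    meanlog, sdlog = spec.base_mean_dist
    base_mean = rng.lognormal(meanlog, sdlog, size=spec.n_genes)
    log2fc = np.zeros(spec.n_genes)
    log2fc[np.isin(genes, spiked)] = spec.spiked_log2fc
    mu = np.empty((spec.n_genes, 2 * n))
    mu[:, :n] = base_mean[:, None]
    mu[:, n:] = (base_mean * 2.0 ** log2fc)[:, None]
    mu = mu * sf[None, :]
    # gamma-Poisson mixture == negative binomial with dispersion alpha
    shape = 1.0 / spec.dispersion
    lam = rng.gamma(shape, mu * spec.dispersion)
    counts = rng.poisson(lam)
    df = pd.DataFrame(counts, index=genes, columns=samples)
    ground_truth = {
        "log2fc": dict(zip(genes, log2fc)),
        "size_factors": dict(zip(samples, sf)),
        "groups": dict(zip(samples, groups)),
        "spiked_set": {spec.spiked_set_name: spiked},
        "spiked_log2fc": spec.spiked_log2fc,
        "dispersion": spec.dispersion,
    }
    return df, ground_truth
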