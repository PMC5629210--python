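"""Synthetic inputs with known ground truth for every analysis module.

Each generator emulates the corresponding acquisition design: recoil
movies with one pre-ablation frame followed by post-ablation frames at
12, 20, 28, 36 and 44 s; FRAP traces with 3 pre-bleach and 57
post-bleach frames at 5 s intervals and a >= 70% bleach; junction images
with Gaussian cross-section bands over a uniform background with
Poisson photon noise plus Gaussian read noise; and persistent-random-
walk nuclear tracks of 30-40 nuclei over 6 h. Every generator is fully
determined by its spec (including the seed) and returns a
machine-readable ground-truth table alongside the data.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .frap import FrapSeries
from .junction import CalibratedImage, JunctionRoi
from .motility import TrackSet
from .recoil import DEFAULT_FRAME_TIMES, RecoilSeries


def _require_positive(**kwargs):
    for name, v in kwargs.items():
        if not v > 0:
            raise ValidationError(f"{name} must be > 0, got {v}")


# ---------------------------------------------------------------------------
# recoil
# ---------------------------------------------------------------------------

@dataclass
class RecoilSpec:
    seed: int = 0
    l0_um: float = 10.0                  # pre-ablation vertex distance
    amplitude_um: float = 1.2            # asymptotic retraction A
    rate_per_s: float = 0.05             # relaxation rate constant k
    noise_sd_um: float = 0.05            # additive Gaussian tracking noise
    frame_times_s: tuple = DEFAULT_FRAME_TIMES
    condition: str = "control"
    experiment: str = "exp1"

    def __post_init__(self):
        _require_positive(l0_um=self.l0_um, rate_per_s=self.rate_per_s)
        if self.amplitude_um < 0 or self.noise_sd_um < 0:
            raise ValidationError("amplitude and noise must be >= 0")


def gen_recoil(spec: RecoilSpec, n_junctions: int = 12):
    """Kelvin-Voigt recoil curves with additive tracking noise.

    Returns (series list, ground-truth DataFrame). Ground truth carries
    the generating A, k and v0 = A*k per junction.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.frame_times_s, dtype=float)
    clean = spec.l0_um + spec.amplitude_um * (1.0 - np.exp(-spec.rate_per_s * t))
    series, truth = [], []
    for j in range(n_junctions):
        noise = rng.normal(0.0, spec.noise_sd_um, size=t.size) if spec.noise_sd_um else 0.0
        series.append(RecoilSeries(
            times=t, distances=clean + noise, l0=spec.l0_um,
            condition=spec.condition, experiment=spec.experiment,
            junction_id=f"j{j:03d}"))
        truth.append(dict(junction_id=f"j{j:03d}", condition=spec.condition,
                          experiment=spec.experiment, seed=spec.seed,
                          l0_um=spec.l0_um, amplitude_um=spec.amplitude_um,
                          rate_per_s=spec.rate_per_s,
                          v0_um_per_s=spec.amplitude_um * spec.rate_per_s))
    return series, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------

@dataclass
class FrapSpec:
    seed: int = 0
    mobile_fraction: float = 0.7
    half_time_s: float = 20.0
    bleach_depth: float = 0.75           # 1 - F(0)/F(i); design target >= 0.7
    prebleach_intensity: float = 100.0
    noise_sd: float = 0.03               # on the normalized scale
    n_prebleach: int = 3
    n_postbleach: int = 57
    interval_s: float = 5.0
    condition: str = "control"
    experiment: str = "exp1"

    def __post_init__(self):
        _require_positive(half_time_s=self.half_time_s, interval_s=self.interval_s,
                          prebleach_intensity=self.prebleach_intensity)
        if not 0 <= self.mobile_fraction <= 1:
            raise ValidationError("mobile fraction must be in [0, 1]")
        if not 0 < self.bleach_depth < 1:
            raise ValidationError("bleach depth must be in (0, 1)")


def gen_frap(spec: FrapSpec, n_junctions: int = 8):
    """One-phase-association FRAP traces with pre-bleach/bleach structure."""
    rng = np.random.default_rng(spec.seed)
    fi = spec.prebleach_intensity
    f0 = fi * (1.0 - spec.bleach_depth)
    t_post = np.arange(spec.n_postbleach) * spec.interval_s
    frap_clean = spec.mobile_fraction * (1.0 - np.exp(-np.log(2.0) * t_post / spec.half_time_s))
    times = np.arange(spec.n_prebleach + spec.n_postbleach) * spec.interval_s
    series, truth = [], []
    for j in range(n_junctions):
        noise = (rng.normal(0.0, spec.noise_sd, size=t_post.size)
                 if spec.noise_sd else np.zeros(t_post.size))
        noise[0] = 0.0  # F(0) defines the bleach frame exactly
        intens = np.concatenate([
            np.full(spec.n_prebleach, fi),
            f0 + (frap_clean + noise) * (fi - f0)])
        series.append(FrapSeries(
            times=times, intensities=intens, n_prebleach=spec.n_prebleach,
            junction_id=f"j{j:03d}", condition=spec.condition,
            experiment=spec.experiment))
        truth.append(dict(junction_id=f"j{j:03d}", condition=spec.condition,
                          experiment=spec.experiment, seed=spec.seed,
                          mobile_fraction=spec.mobile_fraction,
                          half_time_s=spec.half_time_s,
                          immobile_fraction=1.0 - spec.mobile_fraction,
                          bleach_depth=spec.bleach_depth))
    return series, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# junction images
# ---------------------------------------------------------------------------

@dataclass
class JunctionImageSpec:
    seed: int = 0
    shape: tuple = (221, 221)            # (rows, cols); odd so the junction center sits on a pixel
    pixel_size_um: float = 0.1
    junction_angle_deg: float = 90.0     # junction direction; 90 = vertical line
    band_amplitude: float = 500.0        # peak height above background, a.u.
    band_sigma_um: float = 0.3           # Gaussian cross-section width
    two_band: bool = False               # F-actin/NMIIA-like double bundle
    band_offset_um: float = 1.0          # half-separation of the two bands
    background: float = 100.0
    coloc_ratio: float | None = None     # second channel at this amplitude ratio
    poisson_noise: bool = True
    read_noise_sd: float = 2.0
    n_planes: int = 1                    # > 1 renders a stack, apical plane brightest
    plane_scales: tuple = (1.0, 0.7, 0.45)

    def __post_init__(self):
        _require_positive(pixel_size_um=self.pixel_size_um,
                          band_sigma_um=self.band_sigma_um)
        if self.band_sigma_um < self.pixel_size_um:
            raise ValidationError("band sigma below one pixel is unresolvable")
        if self.background < 0 or self.band_amplitude < 0:
            raise ValidationError("background and amplitude must be >= 0")


def _render_plane(spec: JunctionImageSpec, scale: float) -> np.ndarray:
    h, w = spec.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    theta = np.deg2rad(spec.junction_angle_deg)
    tangent = np.array([np.cos(theta), np.sin(theta)])
    normal = np.array([-tangent[1], tangent[0]])
    # signed perpendicular distance to the junction line, in um
    d_um = ((xx - cx) * normal[0] + (yy - cy) * normal[1]) * spec.pixel_size_um
    s2 = 2.0 * spec.band_sigma_um ** 2
    if spec.two_band:
        band = (np.exp(-(d_um - spec.band_offset_um) ** 2 / s2)
                + np.exp(-(d_um + spec.band_offset_um) ** 2 / s2))
    else:
        band = np.exp(-d_um ** 2 / s2)
    return spec.background + scale * spec.band_amplitude * band


def gen_junction_image(spec: JunctionImageSpec):
    """Render a junction image (or 3-plane stack) plus its scan ROI.

    Returns (CalibratedImage, JunctionRoi, truth dict). With
    ``coloc_ratio`` set, truth["coloc_image"] holds a second channel
    whose band amplitude is ``coloc_ratio`` times the reference's, at
    the same position.
    """
    rng = np.random.default_rng(spec.seed)
    scales = spec.plane_scales[: spec.n_planes]
    if len(scales) < spec.n_planes:
        raise ValidationError("not enough plane scales for requested stack depth")

    def noisy(clean):
        img = rng.poisson(clean).astype(float) if spec.poisson_noise else clean.copy()
        if spec.read_noise_sd:
            img = img + rng.normal(0.0, spec.read_noise_sd, size=clean.shape)
        return np.clip(img, 0.0, None)

    planes = np.stack([noisy(_render_plane(spec, sc)) for sc in scales])
    data = planes[0] if spec.n_planes == 1 else planes
    image = CalibratedImage(data=data, pixel_size_um=spec.pixel_size_um,
                            z_spacing_um=0.19 if spec.n_planes > 1 else None,
                            apical_first=True)

    h, w = spec.shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    theta = np.deg2rad(spec.junction_angle_deg)
    tangent = np.array([np.cos(theta), np.sin(theta)])
    half = 30.0  # px of junction covered by the ROI polyline
    roi = JunctionRoi(vertices=np.array([
        [cx - half * tangent[0], cy - half * tangent[1]],
        [cx + half * tangent[0], cy + half * tangent[1]]]))

    truth = dict(seed=spec.seed, band_amplitude=spec.band_amplitude,
                 band_sigma_um=spec.band_sigma_um, background=spec.background,
                 two_band=spec.two_band, band_offset_um=spec.band_offset_um,
                 junction_x_px=cx, junction_y_px=cy,
                 pixel_size_um=spec.pixel_size_um)
    if spec.two_band:
        # injected band mass along the scan direction, per averaged profile
        sigma_px = spec.band_sigma_um / spec.pixel_size_um
        truth["band_mass"] = 2.0 * spec.band_amplitude * sigma_px * np.sqrt(2.0 * np.pi)
    if spec.coloc_ratio is not None:
        co_spec = JunctionImageSpec(**{**asdict(spec),
                                       "band_amplitude": spec.band_amplitude * spec.coloc_ratio,
                                       "coloc_ratio": None,
                                       "seed": spec.seed + 1})
        co_planes = np.stack([noisy(_render_plane(co_spec, sc)) for sc in scales])
        truth["coloc_ratio"] = spec.coloc_ratio
        truth["coloc_image"] = CalibratedImage(
            data=co_planes[0] if spec.n_planes == 1 else co_planes,
            pixel_size_um=spec.pixel_size_um)
    return image, roi, truth


@dataclass
class AhphImageSpec:
    """Whole-cell active-RhoA biosensor scene: junction band over cytoplasm."""

    seed: int = 0
    shape: tuple = (201, 201)            # odd so the band center sits on a pixel
    pixel_size_um: float = 0.1
    cytoplasm_intensity: float = 100.0
    enrichment: float = 3.0              # junction/cytoplasm mean ratio
    band_width_px: int = 20
    poisson_noise: bool = True
    read_noise_sd: float = 2.0

    def __post_init__(self):
        _require_positive(cytoplasm_intensity=self.cytoplasm_intensity,
                          enrichment=self.enrichment)


def gen_ahph_image(spec: AhphImageSpec):
    """Flat-top junction band at ``enrichment`` times the cytoplasm level.

    Returns (image, junction ROI polyline, cytoplasm mask, truth dict).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    cx = (w - 1) / 2.0
    xx = np.arange(w, dtype=float)[None, :] * np.ones((h, 1))
    half = spec.band_width_px / 2.0
    band = np.abs(xx - cx) <= half
    clean = np.where(band, spec.cytoplasm_intensity * spec.enrichment,
                     spec.cytoplasm_intensity)
    img = rng.poisson(clean).astype(float) if spec.poisson_noise else clean.copy()
    if spec.read_noise_sd:
        img = np.clip(img + rng.normal(0.0, spec.read_noise_sd, size=clean.shape), 0.0, None)
    image = CalibratedImage(data=img, pixel_size_um=spec.pixel_size_um)
    roi = JunctionRoi(vertices=np.array([[cx, 5.0], [cx, h - 6.0]]))
    # cytoplasm mask: a margin away from the band on both sides
    cyto = (np.abs(xx - cx) > half + 15) & (np.abs(xx - cx) < w / 2.0 - 5)
    truth = dict(seed=spec.seed, enrichment=spec.enrichment,
                 cytoplasm_intensity=spec.cytoplasm_intensity,
                 band_width_px=spec.band_width_px)
    return image, roi, cyto, truth


# ---------------------------------------------------------------------------
# nuclear tracks
# ---------------------------------------------------------------------------

@dataclass
class TrackSpec:
    seed: int = 0
    n_tracks: int = 35                   # 30-40 nuclei per movie
    duration_min: float = 360.0          # 6 h
    interval_min: float = 5.0
    diffusion_um2_per_min: float = 0.5
    drift_um_per_min: tuple = (0.0, 0.0)
    persistence_min: float = 0.0         # velocity correlation time; 0 = memoryless
    field_um: float = 400.0              # starting positions spread
    condition: str = "control"
    experiment: str = "exp1"

    def __post_init__(self):
        _require_positive(duration_min=self.duration_min, interval_min=self.interval_min)
        if self.diffusion_um2_per_min < 0 or self.persistence_min < 0:
            raise ValidationError("diffusion and persistence must be >= 0")


def gen_tracks(spec: TrackSpec):
    """Persistent-random-walk nuclear tracks sampled at the frame interval.

    With zero persistence, displacements are independent Gaussian steps
    with per-axis variance 2*D*dt plus drift (so MSD = 4*D*tau +
    |v|^2*tau^2). With persistence P > 0 an Ornstein-Uhlenbeck velocity
    process with correlation time P generates directionally persistent
    motion with the same long-time diffusivity.
    """
    rng = np.random.default_rng(spec.seed)
    dt = spec.interval_min
    n_frames = int(np.floor(spec.duration_min / dt)) + 1
    times = np.arange(n_frames) * dt
    drift = np.asarray(spec.drift_um_per_min, dtype=float)
    rows = []
    truth = []
    for i in range(spec.n_tracks):
        start = rng.uniform(0.0, spec.field_um, size=2)
        if spec.persistence_min == 0:
            steps = (rng.normal(0.0, np.sqrt(2.0 * spec.diffusion_um2_per_min * dt),
                                size=(n_frames - 1, 2))
                     + drift * dt)
        else:
            p = spec.persistence_min
            # OU velocity: long-time diffusivity D => sigma_v^2 = D / p
            rho = np.exp(-dt / p)
            sigma_v = np.sqrt(spec.diffusion_um2_per_min / p)
            v = np.zeros((n_frames - 1, 2))
            v[0] = rng.normal(0.0, sigma_v, 2)
            for k in range(1, n_frames - 1):
                v[k] = rho * v[k - 1] + np.sqrt(1 - rho ** 2) * rng.normal(0.0, sigma_v, 2)
            steps = v * dt + drift * dt
        xy = start + np.concatenate([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
        rows.append(pd.DataFrame({
            "track_id": f"t{i:03d}", "time_min": times,
            "x_um": xy[:, 0], "y_um": xy[:, 1],
            "condition": spec.condition, "experiment": spec.experiment}))
        truth.append(dict(track_id=f"t{i:03d}", seed=spec.seed,
                          diffusion_um2_per_min=spec.diffusion_um2_per_min,
                          drift_x=drift[0], drift_y=drift[1],
                          persistence_min=spec.persistence_min,
                          condition=spec.condition, experiment=spec.experiment))
    table = pd.concat(rows, ignore_index=True)
    return (TrackSet(table=table, condition=spec.condition, experiment=spec.experiment),
            pd.DataFrame(truth))


# ---------------------------------------------------------------------------
# wound margins
# ---------------------------------------------------------------------------

@dataclass
class MarginSpec:
    seed: int = 0
    length_um: float = 500.0
    advance_um: float = 30.0             # mean margin advance over the movie
    roughness_um: float = 10.0           # sinusoidal margin roughness amplitude
    roughness_period_um: float = 120.0
    n_points: int = 120

    def __post_init__(self):
        _require_positive(length_um=self.length_um,
                          roughness_period_um=self.roughness_period_um)


def gen_margins(spec: MarginSpec):
    """Rough epithelial margins at t0 and t1 advancing along +x."""
    rng = np.random.default_rng(spec.seed)
    y = np.linspace(0.0, spec.length_um, spec.n_points)
    phase0, phase1 = rng.uniform(0, 2 * np.pi, size=2)
    x0 = spec.roughness_um * np.sin(2 * np.pi * y / spec.roughness_period_um + phase0)
    x1 = (spec.advance_um
          + spec.roughness_um * np.sin(2 * np.pi * y / spec.roughness_period_um + phase1))
    m0 = np.column_stack([x0, y])
    m1 = np.column_stack([x1, y])
    truth = dict(seed=spec.seed, advance_um=spec.advance_um)
    return m0, m1, truth
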