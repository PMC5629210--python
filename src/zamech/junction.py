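"""Junctional fluorescence quantification from calibrated images.

Mirrors the standard line-scan workflow for cell-cell junctions: take a
maximum projection of the most-apical optical sections, draw a line
perpendicular to a homotypic junction (20 um long, intensity averaged
over 30 px along the junction), and quantify the resulting cross-section
profile. Single-peak markers (E-cadherin, RhoA, ROCK1, SRGAP1,
cortactin) are measured as the amplitude of a fitted Gaussian; markers
that form two parallel perijunctional bundles (F-actin, NMIIA) are
measured as the summed intensity over +/-10 px around the band centers.
Pixels lying 10 px beyond the maxima/centers on either side serve as
background and are subtracted. Active-RhoA biosensor (GFP-AHPH) images
are instead read out as the ratio of mean junctional to mean cytoplasmic
fluorescence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .errors import FitError, ValidationError
from .normalize import normalize_to_control

#: minimum junction counts before a batch summary is considered meaningful
MIN_JUNCTIONS_IF = 25
MIN_JUNCTIONS_AHPH = 60


@dataclass
class CalibratedImage:
    """2D image or 3D z-stack with physical pixel calibration."""

    data: np.ndarray           # (y, x) or (z, y, x), a.u. >= 0
    pixel_size_um: float
    z_spacing_um: float | None = None  # 0.19 um sectioning in the source design
    apical_first: bool = True  # stack orientation metadata; never inferred

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (2, 3):
            raise ValidationError("image must be 2D or a 3D stack")
        if not self.pixel_size_um > 0:
            raise ValidationError("pixel size must be > 0")
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise ValidationError("intensities must be finite and >= 0")


@dataclass
class JunctionRoi:
    """Polyline along a junction, pixel coordinates (x, y), 0-based pixel centers."""

    vertices: np.ndarray       # (N, 2) float, sub-pixel allowed
    homotypic: bool = True
    channel: int | None = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[0] < 2 or self.vertices.shape[1] != 2:
            raise ValidationError("ROI needs >= 2 (x, y) vertices")

    def midpoint(self) -> np.ndarray:
        """Point halfway along the polyline arc length."""
        v = self.vertices
        seg = np.diff(v, axis=0)
        lens = np.hypot(seg[:, 0], seg[:, 1])
        total = lens.sum()
        if total == 0:
            raise ValidationError("zero-length ROI")
        target = 0.5 * total
        acc = np.concatenate([[0.0], np.cumsum(lens)])
        i = int(np.searchsorted(acc, target) - 1)
        i = min(max(i, 0), len(seg) - 1)
        frac = (target - acc[i]) / lens[i]
        return v[i] + frac * seg[i]

    def direction(self) -> np.ndarray:
        """Unit tangent of the junction (arc-length weighted mean segment direction)."""
        seg = np.diff(self.vertices, axis=0)
        d = seg.sum(axis=0)
        norm = np.hypot(*d)
        if norm == 0:
            raise ValidationError("degenerate ROI direction")
        return d / norm


@dataclass
class JunctionProfile:
    """Averaged perpendicular intensity cross-section of one junction."""

    positions_um: np.ndarray   # centered on the ROI, strictly increasing
    intensities: np.ndarray
    pixel_size_um: float
    scan_length_um: float = 20.0
    width_px: int = 30

    def __post_init__(self):
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions_um.size != self.intensities.size:
            raise ValidationError("positions and intensities must match")


@dataclass
class JunctionMeasurement:
    kind: str                  # gaussian_peak | band_auc | coloc_at_reference_peak | junction_cytoplasm_ratio
    value: float
    background: float = 0.0
    params: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not np.isfinite(self.value):
            raise ValidationError("measurement value must be finite")
        if self.background < 0:
            raise ValidationError("background must be >= 0")


# ---------------------------------------------------------------------------
# projection and line scans
# ---------------------------------------------------------------------------

def max_project_apical(stack: CalibratedImage, n_sections: int = 3) -> CalibratedImage:
    """Pixelwise maximum over the ``n_sections`` most-apical planes."""
    if stack.data.ndim != 3:
        raise ValidationError("max_project_apical requires a 3D stack")
    if stack.data.shape[0] < n_sections:
        raise ValidationError(
            f"stack has {stack.data.shape[0]} planes, needs >= {n_sections}")
    planes = stack.data[:n_sections] if stack.apical_first else stack.data[-n_sections:]
    return CalibratedImage(planes.max(axis=0), stack.pixel_size_um,
                           z_spacing_um=stack.z_spacing_um)


def extract_line_scan(
    image: CalibratedImage,
    roi: JunctionRoi,
    length_um: float = 20.0,
    width_px: int = 30,
) -> JunctionProfile:
    """Perpendicular intensity profile averaged along the junction.

    Samples by bilinear interpolation at 1 px steps along the
    perpendicular through the ROI midpoint, averaging ``width_px``
    parallel scan lines spaced 1 px along the junction direction.
    """
    if image.data.ndim != 2:
        raise ValidationError("line scans require a 2D image (project stacks first)")
    center = roi.midpoint()
    tangent = roi.direction()
    normal = np.array([-tangent[1], tangent[0]])

    half_len_px = 0.5 * length_um / image.pixel_size_um
    n_steps = int(round(2 * half_len_px)) + 1
    s = np.linspace(-half_len_px, half_len_px, n_steps)          # px along the scan
    offsets = (np.arange(width_px) - (width_px - 1) / 2.0)       # px along the junction

    # sample grid: (n_steps, width_px, 2) in (x, y)
    pts = (center[None, None, :]
           + s[:, None, None] * normal[None, None, :]
           + offsets[None, :, None] * tangent[None, None, :])
    h, w = image.data.shape
    if (pts[..., 0].min() < 0 or pts[..., 0].max() > w - 1
            or pts[..., 1].min() < 0 or pts[..., 1].max() > h - 1):
        raise ValidationError("line scan exits image bounds")
    # map_coordinates wants (row, col) = (y, x)
    sampled = ndimage.map_coordinates(
        image.data, [pts[..., 1].ravel(), pts[..., 0].ravel()], order=1)
    profile = sampled.reshape(n_steps, width_px).mean(axis=1)
    return JunctionProfile(positions_um=s * image.pixel_size_um,
                           intensities=profile, pixel_size_um=image.pixel_size_um,
                           scan_length_um=length_um, width_px=width_px)


# ---------------------------------------------------------------------------
# background rule
# ---------------------------------------------------------------------------

def _background_windows(n: int, centers_idx, offset_px: int = 10, window_px: int = 5):
    """Sample indices strictly beyond 10 px of the outermost centers."""
    left_c, right_c = int(min(centers_idx)), int(max(centers_idx))
    left = np.arange(left_c - offset_px - window_px, left_c - offset_px)
    right = np.arange(right_c + offset_px + 1, right_c + offset_px + 1 + window_px)
    idx = np.concatenate([left, right])
    return idx[(idx >= 0) & (idx < n)]


def estimate_background(profile: JunctionProfile, centers_idx,
                        offset_px: int = 10, window_px: int = 5) -> float:
    """Mean intensity of the pixels lying 10 px beyond the maxima/centers."""
    idx = _background_windows(profile.intensities.size, centers_idx,
                              offset_px, window_px)
    if idx.size == 0:
        raise ValidationError("background windows fall outside the profile")
    return float(profile.intensities[idx].mean())


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------

def _gauss(x, amp, mu, sigma, baseline):
    return amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma ** 2)) + baseline


def gaussian_peak(profile: JunctionProfile, *, edge_px: int = 3) -> JunctionMeasurement:
    """Peak junctional intensity from a Gaussian fit to the profile.

    The fit includes a constant baseline term; the reported value is the
    amplitude over that baseline, so the windowed background estimate is
    reported alongside without being subtracted a second time.
    """
    x, y = profile.positions_um, profile.intensities
    n = y.size
    i_max = int(np.argmax(y))
    flags = []
    if i_max < edge_px or i_max >= n - edge_px:
        flags.append("peak-at-edge")
    baseline0 = float(np.percentile(y, 10))
    amp0 = float(y[i_max] - baseline0)
    if amp0 <= 0 or np.ptp(y) < 1e-12 * max(1.0, abs(y[0])):
        return JunctionMeasurement(kind="gaussian_peak", value=0.0,
                                   background=max(baseline0, 0.0),
                                   flags=flags + ["no-peak"])
    sigma0 = max(2.0 * profile.pixel_size_um, 0.2)
    try:
        popt, _ = curve_fit(
            _gauss, x, y, p0=[amp0, x[i_max], sigma0, baseline0],
            bounds=([0.0, x[0], profile.pixel_size_um / 4, 0.0],
                    [np.inf, x[-1], (x[-1] - x[0]), np.inf]),
            maxfev=20000)
        converged = True
    except RuntimeError:
        popt, converged = [amp0, x[i_max], sigma0, baseline0], False
        flags.append("non-convergence")
    amp, mu, sigma, baseline = map(float, popt)
    background = estimate_background(profile, [int(round((mu - x[0]) / profile.pixel_size_um))])
    return JunctionMeasurement(
        kind="gaussian_peak", value=amp, background=background,
        params=dict(center_um=mu, sigma_um=sigma, baseline=baseline,
                    converged=converged),
        flags=flags)


def find_band_centers(profile: JunctionProfile, search_um: float = 3.0):
    """Centers of the perijunctional band(s).

    The two highest-prominence local maxima within ``search_um`` of the
    scan center; falls back to the single global maximum when only one
    band is present.
    """
    y = profile.intensities
    x = profile.positions_um
    win = np.abs(x) <= search_um
    all_peaks, props = find_peaks(y, prominence=0.0)
    mask = win[all_peaks]
    cand, prom = all_peaks[mask], props["prominences"][mask]
    if cand.size >= 2:
        top = cand[np.argsort(prom)[::-1][:2]]
        return sorted(int(i) for i in top)
    i_max = int(np.argmax(np.where(win, y, -np.inf)))
    return [i_max]


def band_auc(profile: JunctionProfile, half_width_px: int = 10,
             centers_idx=None) -> JunctionMeasurement:
    """Summed background-subtracted intensity over the perijunctional bands.

    Sums ``+/- half_width_px`` pixels around each band center (union of
    windows for two-band profiles) after subtracting the windowed
    background estimate.
    """
    y = profile.intensities
    n = y.size
    if centers_idx is None:
        centers_idx = find_band_centers(profile)
    flags = []
    idx = np.zeros(n, dtype=bool)
    for c in centers_idx:
        lo, hi = c - half_width_px, c + half_width_px
        if lo < 0 or hi >= n:
            flags.append("band-near-edge")
        idx[max(lo, 0): min(hi + 1, n)] = True
    background = estimate_background(profile, centers_idx)
    value = float(np.sum(y[idx] - background))
    return JunctionMeasurement(
        kind="band_auc", value=value, background=background,
        params=dict(centers_idx=[int(c) for c in centers_idx],
                    centers_um=[float(profile.positions_um[c]) for c in centers_idx],
                    n_pixels=int(idx.sum())),
        flags=flags)


def coloc_at_reference_peak(target_profile: JunctionProfile,
                            reference_profile: JunctionProfile) -> JunctionMeasurement:
    """Target intensity at the reference channel's peak position.

    Used for markers read out where a reference stain peaks (e.g.
    phospho-cortactin at the cortactin peak); also reports the
    target/reference amplitude ratio.
    """
    if target_profile.positions_um.size != reference_profile.positions_um.size or \
            not np.allclose(target_profile.positions_um, reference_profile.positions_um):
        raise ValidationError("profiles must share the same scan geometry")
    ref = gaussian_peak(reference_profile)
    if "no-peak" in ref.flags or ref.value <= 0:
        raise FitError("reference profile has no usable peak")
    mu = ref.params["center_um"]
    x = target_profile.positions_um
    i_mu = int(round((mu - x[0]) / target_profile.pixel_size_um))
    i_mu = min(max(i_mu, 0), x.size - 1)
    background = estimate_background(target_profile, [i_mu])
    value = float(np.interp(mu, x, target_profile.intensities) - background)
    ratio = value / ref.value
    return JunctionMeasurement(
        kind="coloc_at_reference_peak", value=value, background=background,
        params=dict(reference_center_um=float(mu), reference_peak=ref.value,
                    ratio=float(ratio)))


def junction_cytoplasm_ratio(
    image: CalibratedImage,
    junction_polyline: JunctionRoi,
    cytoplasm_mask: np.ndarray,
    band_width_px: int = 20,
) -> JunctionMeasurement:
    """Mean junctional / mean cytoplasmic intensity (GFP-AHPH readout).

    The junctional region is the set of pixels within ``band_width_px/2``
    of the polyline (a 20 px wide line covering the junction); the
    cytoplasm arrives as an explicit mask that must be disjoint from the
    junction band.
    """
    if image.data.ndim != 2:
        raise ValidationError("ratio readout requires a 2D image")
    cytoplasm_mask = np.asarray(cytoplasm_mask, dtype=bool)
    if cytoplasm_mask.shape != image.data.shape:
        raise ValidationError("cytoplasm mask shape must match the image")
    if not cytoplasm_mask.any():
        raise ValidationError("empty cytoplasm mask")

    # rasterize the polyline, then take pixels within half the band width
    on_line = np.zeros(image.data.shape, dtype=bool)
    v = junction_polyline.vertices
    for a, b in zip(v[:-1], v[1:]):
        n_pts = int(np.ceil(np.hypot(*(b - a)))) * 2 + 2
        xs = np.linspace(a[0], b[0], n_pts)
        ys = np.linspace(a[1], b[1], n_pts)
        cols = np.clip(np.round(xs).astype(int), 0, image.data.shape[1] - 1)
        rows = np.clip(np.round(ys).astype(int), 0, image.data.shape[0] - 1)
        on_line[rows, cols] = True
    dist = ndimage.distance_transform_edt(~on_line)
    band = dist <= band_width_px / 2.0
    if not band.any():
        raise ValidationError("empty junction band")
    if (band & cytoplasm_mask).any():
        raise ValidationError("cytoplasm mask overlaps the junction band")
    cyto_mean = float(image.data[cytoplasm_mask].mean())
    if cyto_mean <= 0:
        raise ValidationError("zero cytoplasmic mean intensity")
    junc_mean = float(image.data[band].mean())
    return JunctionMeasurement(
        kind="junction_cytoplasm_ratio", value=junc_mean / cyto_mean,
        background=0.0,
        params=dict(junction_mean=junc_mean, cytoplasm_mean=cyto_mean,
                    band_pixels=int(band.sum()),
                    cytoplasm_pixels=int(cytoplasm_mask.sum())))


# ---------------------------------------------------------------------------
# batch reporting
# ---------------------------------------------------------------------------

def normalize_measurements(table: pd.DataFrame, control_label: str,
                           value_col: str = "value") -> pd.DataFrame:
    """Per-experiment control normalization of a measurement table."""
    return normalize_to_control(table, value_col, control_label)


def summarize_measurements(table: pd.DataFrame, *, readout: str = "IF",
                           force: bool = False) -> pd.DataFrame:
    """Per-condition summary with a minimum-sampling guard.

    Refuses to summarize fewer than 25 junctions for immunofluorescence
    readouts or 60 for the GFP-AHPH biosensor unless ``force`` is set.
    """
    minimum = MIN_JUNCTIONS_AHPH if readout.upper() in ("AHPH", "GFP-AHPH") else MIN_JUNCTIONS_IF
    counts = table.groupby("condition")["value"].count()
    too_few = counts[counts < minimum]
    if not too_few.empty and not force:
        raise ValidationError(
            f"fewer than {minimum} junctions for condition(s) "
            f"{sorted(too_few.index)}; pass force=True to override")
    return table.groupby("condition")["value"].agg(["count", "mean", "sem"]).reset_index()


# ---------------------------------------------------------------------------
# ROI I/O
# ---------------------------------------------------------------------------

def read_roi(path) -> JunctionRoi:
    """Read a polyline ROI from CSV (columns x, y) or JSON ({"vertices": [[x, y], ...]})."""
    import json
    from pathlib import Path

    path = Path(path)
    if path.suffix == ".json":
        data = json.loads(path.read_text())
        return JunctionRoi(vertices=np.asarray(data["vertices"], dtype=float),
                           homotypic=bool(data.get("homotypic", True)))
    df = pd.read_csv(path)
    if not {"x", "y"} <= set(df.columns):
        raise ValidationError("ROI CSV needs columns x, y")
    return JunctionRoi(vertices=df[["x", "y"]].to_numpy(dtype=float))
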