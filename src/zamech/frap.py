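"""FRAP normalization and one-phase association fitting.

Fluorescence recovery after photobleaching of junctional E-cadherin-GFP:
a circular ROI on the contact is bleached and the mean ROI intensity
F(t) recorded. With F(i) the mean of the pre-bleach frames and F(0) the
first post-bleach value, the normalized recovery is

    FRAP(t) = (F(t) - F(0)) / (F(i) - F(0))

which is 0 at the bleach and 1 at full recovery. The recovery is fitted
with the exponential one-phase association model anchored at Y0 = 0,

    FRAP(t) = Mf * (1 - exp(-ln2 * t / t_half)),

where the plateau Mf is the mobile fraction and t_half the half-time of
recovery; the immobile fraction is 1 - Mf. (The association model is
necessarily a decaying exponential: the rendered formula in some
write-ups shows a positive exponent, which cannot produce a plateau.)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ValidationError

LN2 = np.log(2.0)


@dataclass
class FrapSeries:
    """Raw intensity trace of one bleached junction.

    ``bleach_index`` is the index of the first post-bleach frame, whose
    value defines F(0); frames before ``n_prebleach`` define F(i).
    """

    times: np.ndarray          # s, strictly increasing, full acquisition
    intensities: np.ndarray    # mean ROI intensity, a.u.
    n_prebleach: int = 3
    bleach_index: int | None = None   # default: first frame after pre-bleach
    junction_id: str = ""
    condition: str = ""
    experiment: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.size != self.intensities.size:
            raise ValidationError("times and intensities must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if not 1 <= self.n_prebleach < self.times.size:
            raise ValidationError("invalid number of pre-bleach frames")
        if self.bleach_index is None:
            self.bleach_index = self.n_prebleach
        if not self.n_prebleach <= self.bleach_index < self.times.size:
            raise ValidationError("bleach_index out of range")

    @property
    def f_pre(self) -> float:
        """Pre-bleach reference F(i): mean of the pre-bleach frames."""
        return float(self.intensities[: self.n_prebleach].mean())

    @property
    def f0(self) -> float:
        """First post-bleach value F(0)."""
        return float(self.intensities[self.bleach_index])


@dataclass
class FrapFit:
    mobile_fraction: float     # Mf, recovery plateau
    half_time: float           # t_half, s
    rss: float
    converged: bool
    flags: list[str] = field(default_factory=list)
    junction_id: str = ""
    condition: str = ""
    experiment: str = ""

    #: tolerance above 1 before a fitted Mf is flagged as over-recovery
    MF_EPSILON = 0.05

    def __post_init__(self):
        if self.mobile_fraction < 0:
            raise ValidationError("mobile fraction must be >= 0")
        if self.mobile_fraction > 1.0 + self.MF_EPSILON:
            self.flags.append("over-recovery")
        if np.isfinite(self.half_time) and self.half_time <= 0:
            raise ValidationError("half-time must be > 0")

    @property
    def immobile_fraction(self) -> float:
        return 1.0 - self.mobile_fraction


def qc_bleach_depth(series: FrapSeries, threshold: float = 0.7):
    """Bleach depth 1 - F(0)/F(i) with a pass/warn flag (pass >= 70%)."""
    depth = 1.0 - series.f0 / series.f_pre
    return depth, ("pass" if depth >= threshold else "warn")


def normalize_frap(series: FrapSeries) -> tuple[np.ndarray, np.ndarray]:
    """Normalized recovery (t, FRAP) with t = 0 at the first post-bleach frame.

    FRAP is exactly 0 at the bleach frame and 1 at full recovery to the
    pre-bleach level. Raises if no bleaching occurred; warns if the
    bleach depth is below 50% (well short of the >= 70% design depth).
    """
    fi, f0 = series.f_pre, series.f0
    if fi <= f0:
        raise ValidationError("no bleach detected: F(i) <= F(0)")
    depth = 1.0 - f0 / fi
    if depth < 0.5:
        warnings.warn(f"shallow bleach: depth {depth:.2f} < 0.5", stacklevel=2)
    post = slice(series.bleach_index, None)
    t = series.times[post] - series.times[series.bleach_index]
    frap = (series.intensities[post] - f0) / (fi - f0)
    return t, frap


def fit_one_phase_association(
    t: np.ndarray,
    frap: np.ndarray,
    *,
    series: FrapSeries | None = None,
    flat_tol: float = 1e-9,
) -> FrapFit:
    """Fit Mf*(1 - exp(-ln2*t/t_half)) with the origin fixed at zero.

    A flat (non-recovering) trace yields Mf = 0 and immobile fraction 1
    with t_half flagged unidentifiable.
    """
    t = np.asarray(t, dtype=float)
    frap = np.asarray(frap, dtype=float)
    if t.size < 10:
        raise ValidationError("need >= 10 post-bleach points")
    meta = dict(junction_id=series.junction_id, condition=series.condition,
                experiment=series.experiment) if series is not None else {}

    if np.all(np.abs(frap) <= flat_tol) or np.max(frap) <= 0:
        return FrapFit(mobile_fraction=0.0, half_time=np.nan,
                       rss=float(np.sum(frap**2)), converged=True,
                       flags=["t-half-unidentifiable", "no-recovery"], **meta)

    model = lambda tt, mf, th: mf * (1.0 - np.exp(-LN2 * tt / th))
    mf0 = float(np.clip(np.max(frap), 0.05, 1.5))
    # first time the curve passes half its apparent plateau
    above = np.nonzero(frap >= 0.5 * mf0)[0]
    th0 = float(t[above[0]]) if above.size and t[above[0]] > 0 else float(t[t.size // 4] or 1.0)
    try:
        popt, _ = curve_fit(model, t, frap, p0=[mf0, th0],
                            bounds=([0.0, 1e-6], [np.inf, np.inf]), maxfev=20000)
        converged, flags = True, []
    except RuntimeError:
        popt, converged, flags = (mf0, th0), False, ["non-convergence"]
    mf, th = float(popt[0]), float(popt[1])
    rss = float(np.sum((model(t, mf, th) - frap) ** 2))
    return FrapFit(mobile_fraction=mf, half_time=th, rss=rss,
                   converged=converged, flags=flags, **meta)


def fit_series(series: FrapSeries) -> FrapFit:
    """Normalize then fit one raw series."""
    t, frap = normalize_frap(series)
    return fit_one_phase_association(t, frap, series=series)


def fits_to_frame(fits: list[FrapFit]) -> pd.DataFrame:
    return pd.DataFrame({
        "experiment": [f.experiment for f in fits],
        "condition": [f.condition for f in fits],
        "junction_id": [f.junction_id for f in fits],
        "mobile_fraction": [f.mobile_fraction for f in fits],
        "half_time_s": [f.half_time for f in fits],
        "immobile_fraction": [f.immobile_fraction for f in fits],
        "rss": [f.rss for f in fits],
        "converged": [f.converged for f in fits],
        "flags": [";".join(f.flags) for f in fits],
    })


def read_frap_csv(path) -> list[FrapSeries]:
    """Read raw FRAP traces.

    Expected columns: junction_id, frame, time_s, intensity, phase with
    phase in {pre, bleach, post}; ``bleach`` marks the first post-bleach
    frame. Optional columns condition, experiment.
    """
    df = pd.read_csv(path)
    required = {"junction_id", "time_s", "intensity", "phase"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"FRAP CSV missing column(s): {sorted(missing)}")
    out = []
    keys = ["junction_id"] + [c for c in ("condition", "experiment") if c in df.columns]
    for key, g in df.groupby(keys, sort=True):
        key = (key,) if not isinstance(key, tuple) else key
        g = g.sort_values("time_s").reset_index(drop=True)
        n_pre = int((g["phase"] == "pre").sum())
        bleach_rows = np.nonzero((g["phase"] == "bleach").to_numpy())[0]
        bleach_index = int(bleach_rows[0]) if bleach_rows.size else n_pre
        meta = dict(zip(keys, key))
        out.append(FrapSeries(
            times=g["time_s"].to_numpy(), intensities=g["intensity"].to_numpy(),
            n_prebleach=n_pre, bleach_index=bleach_index,
            junction_id=str(meta.get("junction_id", "")),
            condition=str(meta.get("condition", "")),
            experiment=str(meta.get("experiment", ""))))
    return out


def series_to_frame(series_list: list[FrapSeries]) -> pd.DataFrame:
    rows = []
    for s in series_list:
        phase = ["pre" if i < s.n_prebleach else "post" for i in range(s.times.size)]
        phase[s.bleach_index] = "bleach"
        rows.append(pd.DataFrame({
            "experiment": s.experiment, "condition": s.condition,
            "junction_id": s.junction_id, "frame": np.arange(s.times.size),
            "time_s": s.times, "intensity": s.intensities, "phase": phase}))
    return pd.concat(rows, ignore_index=True)
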