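"""Intraepithelial motility metrics: nuclear-track MSD and margin advance.

Nuclei of cells inside a confluent monolayer are tracked over several
hours; the ensemble mean squared displacement (MSD) as a function of
time lag summarizes how motile the population is. The MSD estimator is
time-averaged within each track (overlapping windows) and then
ensemble-averaged over tracks. A power law MSD(tau) = Gamma * tau^alpha
fitted on log-log axes extrapolates the curve to a fixed horizon
(default 6 h); relative motility of a condition is its fitted MSD at
the horizon divided by the control's. Wound-healing movies are instead
summarized by the mean perpendicular advance of the epithelial margin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class TrackSet:
    """Tidy table of nuclear trajectories.

    Columns: track_id, time_min, x_um, y_um (+ optional condition,
    experiment). Per-track times must be strictly increasing with at
    least two points.
    """

    table: pd.DataFrame
    condition: str = ""
    experiment: str = ""

    def __post_init__(self):
        required = {"track_id", "time_min", "x_um", "y_um"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"track table missing column(s): {sorted(missing)}")
        for tid, g in self.table.groupby("track_id"):
            t = g["time_min"].to_numpy()
            if t.size < 2:
                raise ValidationError(f"track {tid!r} has < 2 points")
            if np.any(np.diff(t) <= 0):
                raise ValidationError(f"track {tid!r} times not strictly increasing")

    def tracks(self):
        for tid, g in self.table.groupby("track_id", sort=True):
            g = g.sort_values("time_min")
            yield tid, g["time_min"].to_numpy(), g[["x_um", "y_um"]].to_numpy()


@dataclass
class MsdResult:
    lags_min: np.ndarray
    msd_um2: np.ndarray
    n_tracks: int
    prefactor: float | None = None   # Gamma of the power-law fit
    exponent: float | None = None    # alpha
    msd_at_horizon: float | None = None
    horizon_min: float | None = None
    condition: str = ""

    def __post_init__(self):
        self.lags_min = np.asarray(self.lags_min, dtype=float)
        self.msd_um2 = np.asarray(self.msd_um2, dtype=float)
        if np.any(self.msd_um2 < 0):
            raise ValidationError("MSD must be non-negative")


def compute_msd(tracks: TrackSet, max_lag_fraction: float = 0.25) -> MsdResult:
    """Time-averaged, then ensemble-averaged MSD.

    For each track, squared displacements over all overlapping pairs at
    each integer frame lag are averaged; track averages are then pooled
    across the ensemble (weighted by the number of pairs). Lags are
    restricted to ``max_lag_fraction`` of the track duration. All tracks
    must share a common frame interval.
    """
    if not 0 < max_lag_fraction <= 1:
        raise ValidationError("max_lag_fraction must be in (0, 1]")
    dts = []
    per_track = []
    for tid, t, xy in tracks.tracks():
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValidationError(f"track {tid!r} is not on a uniform frame interval")
        dts.append(dt[0])
        per_track.append((t, xy))
    if not np.allclose(dts, dts[0], rtol=1e-6):
        raise ValidationError("tracks do not share a common frame interval")
    dt = float(dts[0])

    max_len = max(xy.shape[0] for _, xy in per_track)
    max_lag = int(np.floor((max_len - 1) * max_lag_fraction))
    if max_lag < 1:
        raise ValidationError("no track is long enough for the requested lags")

    sums = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1)
    for _, xy in per_track:
        n = xy.shape[0]
        for lag in range(1, min(max_lag, n - 1) + 1):
            d = xy[lag:] - xy[:-lag]
            sq = np.einsum("ij,ij->i", d, d)
            sums[lag] += sq.sum()
            counts[lag] += sq.size
    valid = counts > 0
    valid[0] = True
    lags = np.arange(max_lag + 1)[valid] * dt
    msd = np.zeros(valid.sum())
    msd[1:] = sums[valid][1:] / counts[valid][1:]
    return MsdResult(lags_min=lags, msd_um2=msd, n_tracks=len(per_track),
                     condition=tracks.condition)


def fit_msd_and_project(msd: MsdResult, horizon_min: float = 360.0,
                        model: str = "power") -> MsdResult:
    """Fit the MSD curve and evaluate it at the horizon.

    ``model="power"`` fits MSD = Gamma * tau^alpha by least squares on
    log-log axes (non-positive MSD values are excluded); ``model="linear"``
    fits the purely diffusive form MSD = 4 D tau (alpha fixed at 1).
    """
    tau = msd.lags_min
    y = msd.msd_um2
    ok = (tau > 0) & (y > 0)
    if ok.sum() < 5:
        raise ValidationError("need >= 5 positive lag points for the MSD fit")
    if model == "power":
        coeffs = np.polyfit(np.log(tau[ok]), np.log(y[ok]), 1)
        alpha, gamma = float(coeffs[0]), float(np.exp(coeffs[1]))
    elif model == "linear":
        gamma = float(np.sum(tau[ok] * y[ok]) / np.sum(tau[ok] ** 2))
        alpha = 1.0
    else:
        raise ValidationError(f"unknown MSD model {model!r}")
    return MsdResult(
        lags_min=msd.lags_min, msd_um2=msd.msd_um2, n_tracks=msd.n_tracks,
        prefactor=gamma, exponent=alpha,
        msd_at_horizon=float(gamma * horizon_min ** alpha),
        horizon_min=horizon_min, condition=msd.condition)


def relative_msd(condition_msd: MsdResult, control_msd: MsdResult) -> float:
    """Fitted MSD at the horizon relative to the control condition."""
    for m in (condition_msd, control_msd):
        if m.msd_at_horizon is None:
            raise ValidationError("fit both MSD curves before taking the ratio")
    if control_msd.msd_at_horizon <= 0:
        raise ValidationError("control MSD at horizon must be > 0")
    return condition_msd.msd_at_horizon / control_msd.msd_at_horizon


# ---------------------------------------------------------------------------
# wound-margin displacement
# ---------------------------------------------------------------------------

def margin_displacement(margin_t0: np.ndarray, margin_t1: np.ndarray,
                        axis: str = "x", n_samples: int = 200) -> float:
    """Mean perpendicular advance of an epithelial margin.

    Margins are polylines (N, 2) sampled at two times; ``axis`` names
    the wound axis, i.e. the direction of advance (``"x"`` or ``"y"``).
    Both margins are interpolated onto a common grid of the transverse
    coordinate and the signed advance is averaged; negative values mean
    retreat.
    """
    m0 = np.asarray(margin_t0, dtype=float)
    m1 = np.asarray(margin_t1, dtype=float)
    for m in (m0, m1):
        if m.ndim != 2 or m.shape[1] != 2 or m.shape[0] < 2:
            raise ValidationError("margins must be (N >= 2, 2) polylines")
    if axis == "x":
        adv, trans = 0, 1
    elif axis == "y":
        adv, trans = 1, 0
    else:
        raise ValidationError("axis must be 'x' or 'y'")

    lo = max(m0[:, trans].min(), m1[:, trans].min())
    hi = min(m0[:, trans].max(), m1[:, trans].max())
    if hi <= lo:
        raise ValidationError("margins do not overlap along the transverse axis; "
                              "mismatched wound axes?")
    grid = np.linspace(lo, hi, n_samples)

    def interp(m):
        order = np.argsort(m[:, trans])
        return np.interp(grid, m[order, trans], m[order, adv])

    return float(np.mean(interp(m1) - interp(m0)))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_tracks_csv(path) -> dict[tuple[str, str], TrackSet]:
    """Read tracks CSV into one TrackSet per (condition, experiment)."""
    df = pd.read_csv(path)
    if "condition" not in df.columns:
        df["condition"] = ""
    if "experiment" not in df.columns:
        df["experiment"] = ""
    out = {}
    for (cond, exp), g in df.groupby(["condition", "experiment"], sort=True):
        out[(str(cond), str(exp))] = TrackSet(
            table=g.reset_index(drop=True), condition=str(cond), experiment=str(exp))
    return out
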