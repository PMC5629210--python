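"""Kelvin-Voigt fitting of post-ablation junction recoil.

After a cell-cell junction is cut by a two-photon laser, the flanking
vertices recoil apart. Modeling the junction as a Kelvin-Voigt element
(elastic spring in parallel with a viscous dashpot under constant
tension), the vertex separation follows

    L(t) = L0 + A * (1 - exp(-k t))

where L0 is the pre-ablation distance, A the asymptotic retraction
amplitude and k the relaxation rate constant. The initial recoil
velocity v0 = A*k is the tension index; k reflects the
elasticity/viscosity ratio (friction) and is reported separately so that
tension changes can be distinguished from friction changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ValidationError
from .normalize import normalize_to_control

#: post-ablation frame times (s): ablation occurs in the 12 s gap after the
#: pre-ablation frame, remaining frames follow at 8 s intervals
DEFAULT_FRAME_TIMES = (12.0, 20.0, 28.0, 36.0, 44.0)


@dataclass
class RecoilSeries:
    """Vertex-distance time series of one ablated junction (or a mean curve)."""

    times: np.ndarray          # s, t = 0 at ablation, strictly increasing
    distances: np.ndarray      # vertex separation, um
    l0: float                  # pre-ablation vertex distance, um
    condition: str = ""
    experiment: str = ""
    junction_id: str = ""
    n_averaged: np.ndarray | None = None  # per-point count for mean curves

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.times.size < 3:
            raise ValidationError("need >= 3 post-ablation points")
        if self.times.size != self.distances.size:
            raise ValidationError("times and distances must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(self.distances <= 0) or self.l0 <= 0:
            raise ValidationError("distances must be > 0")


@dataclass
class RecoilFit:
    """Kelvin-Voigt fit result; ``v0 == amplitude * rate`` by construction."""

    amplitude: float           # A, um
    rate: float                # k, 1/s
    rss: float
    converged: bool
    flags: list[str] = field(default_factory=list)
    condition: str = ""
    experiment: str = ""
    junction_id: str = ""

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValidationError("amplitude must be >= 0")
        if self.rate <= 0 and self.amplitude > 0:
            raise ValidationError("rate must be > 0")

    @property
    def v0(self) -> float:
        """Initial recoil velocity A*k (um/s), the tension index."""
        if self.amplitude == 0.0:
            return 0.0  # no recoil even when k is unidentifiable (NaN)
        return self.amplitude * self.rate


def mean_recoil_curve(series_list: list[RecoilSeries]) -> RecoilSeries:
    """Pointwise mean distance across junctions of one condition.

    Series on different frame grids are linearly resampled onto the grid
    of the first series before averaging; the per-point count is kept.
    """
    if not series_list:
        raise ValidationError("mean_recoil_curve requires >= 1 series")
    grid = series_list[0].times
    stack = []
    for s in series_list:
        if s.times.shape == grid.shape and np.allclose(s.times, grid):
            stack.append(s.distances)
        else:
            stack.append(np.interp(grid, s.times, s.distances))
    stack = np.asarray(stack)
    return RecoilSeries(
        times=grid,
        distances=stack.mean(axis=0),
        l0=float(np.mean([s.l0 for s in series_list])),
        condition=series_list[0].condition,
        experiment=series_list[0].experiment,
        junction_id="mean",
        n_averaged=np.full(grid.size, len(series_list)),
    )


def _init_guess(t, y):
    """Initialization from the log-linearized residual ln(1 - dL/A_hat)."""
    a0 = max(y[-1], y.max(), 1e-12)
    frac = np.clip(1.0 - y / (a0 * 1.0001), 1e-9, None)
    slope = np.polyfit(t, np.log(frac), 1)[0]
    k0 = max(-slope, 1e-4)
    return a0, k0


def fit_kelvin_voigt(series: RecoilSeries, *, flat_tol: float = 1e-9) -> RecoilFit:
    """Bounded nonlinear least squares of L(t) = L0 + A(1 - exp(-k t)).

    L0 is fixed from the pre-ablation frame rather than fitted, which
    avoids parameter correlation on the short 5-point curves. A flat
    series (no recoil) yields A = 0 and v0 = 0 with k flagged as
    unidentifiable rather than an error.
    """
    t = series.times
    dl = series.distances - series.l0

    if np.all(np.abs(dl) <= max(flat_tol, 1e-6 * abs(series.l0))) or np.max(dl) <= 0:
        return RecoilFit(amplitude=0.0, rate=np.nan, rss=float(np.sum(dl**2)),
                         converged=True, flags=["k-unidentifiable", "no-recoil"],
                         condition=series.condition, experiment=series.experiment,
                         junction_id=series.junction_id)

    model = lambda tt, A, k: A * (1.0 - np.exp(-k * tt))
    a0, k0 = _init_guess(t, dl)
    try:
        popt, _ = curve_fit(model, t, dl, p0=[a0, k0],
                            bounds=([0.0, 1e-8], [np.inf, np.inf]), maxfev=20000)
        converged = True
        flags = []
    except RuntimeError:
        popt, converged, flags = (a0, k0), False, ["non-convergence"]
    A, k = float(popt[0]), float(popt[1])
    rss = float(np.sum((model(t, A, k) - dl) ** 2))
    return RecoilFit(amplitude=A, rate=k, rss=rss, converged=converged, flags=flags,
                     condition=series.condition, experiment=series.experiment,
                     junction_id=series.junction_id)


def fits_to_frame(fits: list[RecoilFit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "experiment": [f.experiment for f in fits],
            "condition": [f.condition for f in fits],
            "junction_id": [f.junction_id for f in fits],
            "amplitude_um": [f.amplitude for f in fits],
            "rate_per_s": [f.rate for f in fits],
            "v0_um_per_s": [f.v0 for f in fits],
            "rss": [f.rss for f in fits],
            "converged": [f.converged for f in fits],
            "flags": [";".join(f.flags) for f in fits],
        }
    )


def normalize_initial_recoil(fits, control_label: str) -> pd.DataFrame:
    """Normalize v0 to the same-experiment control mean.

    Accepts a list of :class:`RecoilFit` or a tidy fit table; returns
    the table with a ``v0_um_per_s_norm`` column in which the control
    condition averages to exactly 1 within every experiment.
    """
    table = fits_to_frame(fits) if not isinstance(fits, pd.DataFrame) else fits
    return normalize_to_control(table, "v0_um_per_s", control_label)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_recoil_csv(path) -> list[RecoilSeries]:
    """Read per-junction recoil tables.

    Expected columns: experiment, condition, junction_id, frame, time_s,
    distance_um, phase (``pre`` marks the pre-ablation frame, everything
    else is post-ablation).
    """
    df = pd.read_csv(path)
    required = {"experiment", "condition", "junction_id", "time_s", "distance_um", "phase"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"recoil CSV missing column(s): {sorted(missing)}")
    out = []
    for (exp, cond, jid), g in df.groupby(["experiment", "condition", "junction_id"],
                                          sort=True):
        g = g.sort_values("time_s")
        pre = g[g["phase"] == "pre"]
        post = g[g["phase"] != "pre"]
        if pre.empty:
            raise ValidationError(f"junction {jid!r} has no pre-ablation frame")
        out.append(RecoilSeries(
            times=post["time_s"].to_numpy(),
            distances=post["distance_um"].to_numpy(),
            l0=float(pre["distance_um"].mean()),
            condition=str(cond), experiment=str(exp), junction_id=str(jid)))
    return out


def series_to_frame(series_list: list[RecoilSeries]) -> pd.DataFrame:
    rows = []
    for s in series_list:
        rows.append(pd.DataFrame({
            "experiment": s.experiment, "condition": s.condition,
            "junction_id": s.junction_id, "frame": 0, "time_s": -12.0,
            "distance_um": s.l0, "phase": "pre"}, index=[0]))
        rows.append(pd.DataFrame({
            "experiment": s.experiment, "condition": s.condition,
            "junction_id": s.junction_id,
            "frame": np.arange(1, s.times.size + 1),
            "time_s": s.times, "distance_um": s.distances, "phase": "post"}))
    return pd.concat(rows, ignore_index=True)
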