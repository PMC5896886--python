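"""Convergence, regional strain and shear rates from marker tracks, plus
sagittal-sectional-area (SSA) regression models.

Sign conventions follow the tabulated reporting: *convergence* rates are
positive when a width shrinks, while regional *strain* rates are signed
(negative = convergence). Shear with respect to the attachment strips is
edge convergence minus sled convergence — the part of explant convergence
accommodated by slippage rather than sled movement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np

from explantmech._util import as_1d_float, check_strictly_increasing

__all__ = [
    "MarkerTracks",
    "RateEstimate",
    "SSAModel",
    "convergence_rate",
    "regional_strain_rate",
    "shear_rate",
    "ssa_predict",
    "fit_ssa_model",
    "default_ssa_model",
    "SSA_EXPLANT_TYPES",
]


@dataclass
class MarkerTracks:
    """Labeled marker positions along the mediolateral axis over time.

    ``tracks`` maps a track id to ``(time_min, position_um)`` arrays;
    positions increase from anchor toward sled. ``regions`` maps a region
    label (dorsal, ventrolateral, sled, …) to the pair of track ids bounding
    it. ``meta`` may carry simulator ground truth.
    """

    tracks: Mapping[str, Tuple[np.ndarray, np.ndarray]]
    regions: Mapping[str, Tuple[str, str]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for name, (t, x) in self.tracks.items():
            t = as_1d_float(t, f"track {name!r} time")
            x = as_1d_float(x, f"track {name!r} position")
            if t.shape != x.shape:
                raise ValueError(f"track {name!r}: time/position length mismatch")
            check_strictly_increasing(t, f"track {name!r} time")
            clean[name] = (t, x)
        self.tracks = clean
        for region, pair in self.regions.items():
            if len(pair) != 2:
                raise ValueError(f"region {region!r} needs exactly 2 bounding tracks")
            for tid in pair:
                if tid not in self.tracks:
                    raise KeyError(f"region {region!r} references unknown track {tid!r}")

    def segment_series(self, track_a: str, track_b: str):
        """Return (time, |x_b − x_a|) on the overlapping time grid.

        Track b is linearly interpolated onto track a's times where the two
        grids differ.
        """
        ta, xa = self.tracks[track_a]
        tb, xb = self.tracks[track_b]
        lo, hi = max(ta[0], tb[0]), min(ta[-1], tb[-1])
        if lo > hi:
            raise ValueError(f"tracks {track_a!r} and {track_b!r} do not overlap in time")
        sel = (ta >= lo) & (ta <= hi)
        t = ta[sel]
        width = np.abs(np.interp(t, tb, xb) - xa[sel])
        return t, width


@dataclass(frozen=True)
class RateEstimate:
    """A rate plus the window it was estimated over (minutes after G0)."""

    um_per_min: float
    pct_per_hr: float
    window: Tuple[float, float]
    n: int


def _window_slope(time_min, series, window, method):
    t = as_1d_float(time_min, "time_min")
    y = as_1d_float(series, "series")
    if t.shape != y.shape:
        raise ValueError("time and series must have equal length")
    w0, w1 = float(window[0]), float(window[1])
    if w1 <= w0:
        raise ValueError(f"window must be increasing, got {window}")
    sel = (t >= w0) & (t <= w1)
    if sel.sum() < 2:
        raise ValueError(
            f"window {window} contains {int(sel.sum())} samples; need >= 2"
        )
    ts, ys = t[sel], y[sel]
    if method == "ols":
        slope, intercept = np.polyfit(ts, ys, 1)
        ref = slope * w0 + intercept  # fitted value at window start
    elif method == "endpoint":
        slope = (ys[-1] - ys[0]) / (ts[-1] - ts[0])
        ref = ys[0]
    else:
        raise ValueError(f"unknown method {method!r}; use 'ols' or 'endpoint'")
    return float(slope), float(ref), int(sel.sum())


def convergence_rate(
    time_min, width_um, window, method: str = "ols"
) -> RateEstimate:
    """Average convergence rate of a width series over a time window.

    The rate is the least-squares slope of width vs time over the window
    (``method='endpoint'`` uses simple endpoint differencing instead),
    sign-flipped so that convergence is positive. %/hr is normalized by the
    width at the window start.
    """
    slope, ref, n = _window_slope(time_min, width_um, window, method)
    um_per_min = -slope
    pct_per_hr = 100.0 * um_per_min * 60.0 / ref
    return RateEstimate(um_per_min, pct_per_hr, (float(window[0]), float(window[1])), n)


def regional_strain_rate(
    tracks: MarkerTracks, region: str, window, method: str = "ols"
) -> float:
    """Signed strain rate (%/hr) of the segment bounded by a region's tracks.

    Negative values indicate convergence (shrinking), positive values
    elongation — the tabulated strain-column convention, opposite in sign to
    :func:`convergence_rate` for the same segment.
    """
    if region not in tracks.regions:
        raise KeyError(
            f"region {region!r} not defined; available: {sorted(tracks.regions)}"
        )
    a, b = tracks.regions[region]
    t, width = tracks.segment_series(a, b)
    slope, ref, _ = _window_slope(t, width, window, method)
    return 100.0 * slope * 60.0 / ref


def shear_rate(
    edge_convergence: float,
    sled_convergence: float,
    edge_window: Optional[Tuple[float, float]] = None,
    sled_window: Optional[Tuple[float, float]] = None,
) -> float:
    """Shear w.r.t. attachment strips = edge convergence − sled convergence.

    Both rates are %/hr over the same window; if windows are supplied they
    must match exactly.
    """
    if edge_window is not None and sled_window is not None:
        if tuple(edge_window) != tuple(sled_window):
            raise ValueError(
                f"windows must match, got {edge_window} vs {sled_window}"
            )
    return edge_convergence - sled_convergence


# ---------------------------------------------------------------------------
# SSA regression models


@dataclass(frozen=True)
class SSAModel:
    """Sagittal-sectional-area model: polynomial in hours after G0 → mm².

    ``coefficients`` are in ascending order (constant first). For models
    with ``cap_hours`` set, the prediction is held constant at its value at
    the cap time for all later times.
    """

    explant_type: str
    coefficients: Tuple[float, ...]
    cap_hours: Optional[float] = None


#: Published regression coefficients, ascending order.
_DEFAULT_MODELS = {
    "giant_or_D180": SSAModel("giant_or_D180", (0.24, 0.085)),
    "V180": SSAModel("V180", (0.25, 0.085, -0.0042), cap_hours=10.0),
    "AC": SSAModel("AC", (0.16,)),
}

SSA_EXPLANT_TYPES = tuple(_DEFAULT_MODELS)


def default_ssa_model(explant_type: str) -> SSAModel:
    """Look up the shipped regression model for an explant type."""
    try:
        return _DEFAULT_MODELS[explant_type]
    except KeyError:
        raise ValueError(
            f"unknown explant type {explant_type!r}; known: {SSA_EXPLANT_TYPES}"
        )


def ssa_predict(model: SSAModel, hours_after_g0: float) -> float:
    """Evaluate an SSA model (mm²) at a time ≥ 0 hours after G0."""
    h = float(hours_after_g0)
    if not (np.isfinite(h) and h >= 0):
        raise ValueError(f"hours_after_g0 must be >= 0, got {hours_after_g0}")
    if model.cap_hours is not None:
        h = min(h, model.cap_hours)
    return float(np.polynomial.polynomial.polyval(h, model.coefficients))


def fit_ssa_model(
    observations: Sequence[Tuple[float, float]],
    form: str,
    explant_type: str = "custom",
    cap_hours: Optional[float] = None,
) -> SSAModel:
    """Least-squares fit of an SSA model to (hours, mm²) observations.

    ``form`` is one of ``linear``, ``quadratic_capped`` or ``constant``.
    A quadratic model is capped at the supplied ``cap_hours`` or, failing
    that, at its stationary point (where the fitted curve would turn over).
    """
    obs = np.asarray(observations, dtype=float)
    if obs.ndim != 2 or obs.shape[1] != 2:
        raise ValueError("observations must be a sequence of (hours, mm²) pairs")
    hours, ssa = obs[:, 0], obs[:, 1]
    degree = {"constant": 0, "linear": 1, "quadratic_capped": 2}.get(form)
    if degree is None:
        raise ValueError(f"unknown form {form!r}")
    if obs.shape[0] < degree + 2:
        raise ValueError(f"form {form!r} needs >= {degree + 2} observations")
    if degree > 0 and np.ptp(hours) == 0:
        raise ValueError("degenerate design: all observations at the same time")
    coeffs = np.polynomial.polynomial.polyfit(hours, ssa, degree)
    cap = cap_hours
    if form == "quadratic_capped" and cap is None:
        a2 = coeffs[2]
        if a2 < 0:
            cap = float(-coeffs[1] / (2.0 * a2))
    return SSAModel(explant_type, tuple(float(c) for c in coeffs), cap)
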