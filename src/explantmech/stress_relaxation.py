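"""Step-strain stress-relaxation analysis under a standard linear solid.

After a step strain, the structural stiffness of the composite explant
relaxes as

    SS(t) = S_inf + S_sp · exp(−t/τ)

with residual stiffness ``S_inf`` (Pa), decaying instantaneous component
``S_sp`` (Pa) and relaxation time ``τ`` (s). The associated viscosity is
``η = τ · S_inf``. Structural stiffness is stress over strain for the whole
explant — geometry dependent, not a material modulus — computed as
``(force / cross-sectional area) / strain`` with μN/mm² ≡ Pa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional

import numpy as np
from scipy.optimize import least_squares

from explantmech._util import as_1d_float, check_strictly_increasing

__all__ = [
    "SLSParameters",
    "SLSFit",
    "RelaxationTrace",
    "RecoilMeasurement",
    "sls_stress",
    "structural_stiffness_series",
    "fit_sls",
    "fit_relaxation",
    "residual_stiffness_180",
    "spring_stiffness",
    "plastic_fraction",
    "recoil_metrics",
    "FITTERS",
]


@dataclass(frozen=True)
class SLSParameters:
    """Standard-linear-solid constants.

    ``eta`` is always derived (``tau * s_inf``), never stored, so the
    identity holds exactly for every instance.
    """

    s_inf: float  # residual stiffness, Pa
    s_sp: float  # decaying (instantaneous-component) stiffness, Pa
    tau: float  # relaxation time, s

    def __post_init__(self) -> None:
        if not (np.isfinite(self.s_inf) and self.s_inf >= 0):
            raise ValueError(f"s_inf must be >= 0, got {self.s_inf}")
        if not (np.isfinite(self.s_sp) and self.s_sp >= 0):
            raise ValueError(f"s_sp must be >= 0, got {self.s_sp}")
        if not (np.isfinite(self.tau) and self.tau > 0):
            raise ValueError(f"tau must be > 0, got {self.tau}")

    @property
    def eta(self) -> float:
        """Viscosity η = τ·S_inf, Pa·s."""
        return self.tau * self.s_inf

    @property
    def instantaneous_stiffness(self) -> float:
        """SS at t = 0, i.e. S_inf + S_sp."""
        return self.s_inf + self.s_sp


@dataclass
class RelaxationTrace:
    """One step-strain relaxation experiment.

    ``strain`` optionally carries the *realized* per-sample strain measured
    from markers; when present it supersedes the nominal ``imposed_strain``
    in stiffness computations.
    """

    time_s: np.ndarray
    force_uN: np.ndarray
    imposed_strain: float
    area_mm2: float
    strain: Optional[np.ndarray] = None
    explant_type: str = "giant"
    stage_time_hr: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = as_1d_float(self.time_s, "time_s")
        self.force_uN = as_1d_float(self.force_uN, "force_uN")
        if self.time_s.shape != self.force_uN.shape:
            raise ValueError("time_s and force_uN must have equal length")
        check_strictly_increasing(self.time_s, "time_s")
        if self.time_s.size and self.time_s[0] < 0:
            raise ValueError("time_s must start at or after 0")
        if not (np.isfinite(self.imposed_strain) and self.imposed_strain > 0):
            raise ValueError(f"imposed_strain must be > 0, got {self.imposed_strain}")
        if not (np.isfinite(self.area_mm2) and self.area_mm2 > 0):
            raise ValueError(f"area_mm2 must be > 0, got {self.area_mm2}")
        if self.strain is not None:
            self.strain = as_1d_float(self.strain, "strain")
            if self.strain.shape != self.time_s.shape:
                raise ValueError("strain must have the same length as samples")

    def strain_at(self, t: float) -> float:
        if self.strain is not None:
            return float(np.interp(t, self.time_s, self.strain))
        return float(self.imposed_strain)


def sls_stress(t, params: SLSParameters):
    """Evaluate SS(t) = S_inf + S_sp·exp(−t/τ) for t ≥ 0 (seconds)."""
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ValueError("t must be >= 0")
    out = params.s_inf + params.s_sp * np.exp(-arr / params.tau)
    return float(out) if arr.ndim == 0 else out


def structural_stiffness_series(trace: RelaxationTrace):
    """Map each sample to structural stiffness in Pa.

    Returns ``(time_s, stiffness_pa)`` with stiffness =
    (force/area)/strain; 1 μN/mm² = 1 Pa so no numeric conversion factor is
    needed. Realized strain, when recorded, supersedes the nominal value.
    """
    if trace.strain is not None:
        strain = trace.strain
        if np.any(strain <= 0):
            raise ValueError("realized strain must be > 0 at every sample")
    else:
        strain = trace.imposed_strain
    stiffness = (trace.force_uN / trace.area_mm2) / strain
    return trace.time_s.copy(), stiffness


@dataclass
class SLSFit:
    """Result of an SLS fit: parameters plus diagnostics."""

    params: SLSParameters
    residual_rms: float
    converged: bool
    flags: list = field(default_factory=list)
    n_used: int = 0
    method: str = "trf"

    @property
    def tau_identifiable(self) -> bool:
        return "tau_unidentifiable" not in self.flags


def _initial_guess(t: np.ndarray, ss: np.ndarray) -> np.ndarray:
    s_inf0 = max(ss[-1], 0.0)
    s_sp0 = max(ss[0] - s_inf0, 1e-12)
    span = t[-1] - t[0]
    # time at which the decay has lost half its amplitude; fall back to span/3
    half_level = s_inf0 + 0.5 * s_sp0
    below = np.flatnonzero(ss <= half_level)
    if below.size and t[below[0]] > t[0]:
        tau0 = (t[below[0]] - t[0]) / np.log(2.0)
    else:
        tau0 = span / 3.0
    return np.array([s_inf0, s_sp0, max(tau0, 1e-9)])


def _fit_trf(t: np.ndarray, ss: np.ndarray, x0: np.ndarray):
    def resid(x):
        return x[0] + x[1] * np.exp(-t / x[2]) - ss

    return least_squares(
        resid,
        x0,
        bounds=([0.0, 0.0, 1e-12], [np.inf, np.inf, np.inf]),
        method="trf",
        x_scale=np.maximum(np.abs(x0), 1e-6),
    )


#: Pluggable fitters. One trust-region least-squares backend is provided; a
#: second analytical slot can be registered by downstream code.
FITTERS: Dict[str, Callable] = {"trf": _fit_trf}


def fit_sls(
    time_s,
    stiffness_pa,
    init: Optional[SLSParameters] = None,
    ramp_end_s: float = 3.0,
    method: str = "trf",
) -> SLSFit:
    """Fit SS(t) = S_inf + S_sp·exp(−t/τ) by bounded nonlinear least squares.

    Samples with ``t < ramp_end_s`` are excluded: the model assumes an
    instantaneous step strain, while the real ramp takes one to a few
    seconds (default exclusion window 3 s). Requires at least 4 usable
    samples. Non-convergence is flagged, never silently defaulted; a flat
    series is returned as ``S_sp = 0`` with ``tau`` flagged unidentifiable.
    """
    t = as_1d_float(time_s, "time_s")
    ss = as_1d_float(stiffness_pa, "stiffness_pa")
    if t.shape != ss.shape:
        raise ValueError("time and stiffness must have equal length")
    keep = t >= ramp_end_s
    t, ss = t[keep], ss[keep]
    if t.size < 4:
        raise ValueError(f"need >= 4 samples after ramp exclusion, got {t.size}")

    scale = max(abs(float(np.mean(ss))), 1e-12)
    if (ss.max() - ss.min()) <= 1e-9 * scale:
        # no decay: S_sp = 0 and tau cannot be identified
        params = SLSParameters(float(np.mean(ss)), 0.0, (t[-1] - t[0]) / 3.0)
        return SLSFit(params, 0.0, True, ["tau_unidentifiable"], t.size, method)

    x0 = (
        np.array([init.s_inf, init.s_sp, init.tau])
        if init is not None
        else _initial_guess(t, ss)
    )
    try:
        fitter = FITTERS[method]
    except KeyError:
        raise ValueError(f"unknown fit method {method!r}; available: {sorted(FITTERS)}")
    res = fitter(t, ss, x0)
    s_inf, s_sp, tau = (float(v) for v in res.x)
    params = SLSParameters(max(s_inf, 0.0), max(s_sp, 0.0), max(tau, 1e-12))
    rms = float(np.sqrt(np.mean(res.fun**2)))
    flags = []
    if not res.success:
        flags.append("non_convergence")
    if params.s_sp <= 1e-9 * scale:
        flags.append("tau_unidentifiable")
    return SLSFit(params, rms, bool(res.success), flags, t.size, method)


def fit_relaxation(trace: RelaxationTrace, **kwargs) -> SLSFit:
    """Convenience wrapper: stiffness series of a trace → :func:`fit_sls`."""
    t, ss = structural_stiffness_series(trace)
    return fit_sls(t, ss, **kwargs)


def residual_stiffness_180(trace: RelaxationTrace) -> float:
    """Structural stiffness 180 s after strain application, Pa.

    Force (and realized strain, if recorded) are linearly interpolated
    between the samples bracketing t = 180 s. The trace must span 180 s.
    """
    if trace.time_s[-1] < 180.0 or trace.time_s[0] > 180.0:
        raise ValueError(
            f"trace [{trace.time_s[0]}, {trace.time_s[-1]}] s does not span 180 s"
        )
    f180 = float(np.interp(180.0, trace.time_s, trace.force_uN))
    strain = trace.strain_at(180.0)
    if strain <= 0:
        raise ValueError("strain at 180 s must be > 0")
    return (f180 / trace.area_mm2) / strain


def spring_stiffness(force_at_180: float, strain_at_180: float) -> float:
    """Bulk spring stiffness = force at 180 s / strain at 180 s (μN).

    Strain is dimensionless, so the result carries force units; it weighs
    force-bearing capacity by cross-section, unlike structural stiffness.
    """
    if not (np.isfinite(strain_at_180) and strain_at_180 > 0):
        raise ValueError(f"strain must be > 0, got {strain_at_180}")
    return force_at_180 / strain_at_180


def plastic_fraction(
    initial_width: float, peak_strained_width: float, recovered_width: float
):
    """Plastic fraction of the applied strain after release from tension.

    Returns ``(plastic_fraction, residual_elongation_fraction)`` where
    applied = (peak − initial)/initial, residual = (recovered − initial)/initial
    and plastic fraction = residual/applied. For a tension test the widths
    must satisfy initial ≤ recovered ≤ peak.
    """
    if not (initial_width > 0):
        raise ValueError("initial_width must be > 0")
    if not (initial_width <= recovered_width <= peak_strained_width):
        raise ValueError(
            "expected initial <= recovered <= peak, got "
            f"initial={initial_width}, recovered={recovered_width}, "
            f"peak={peak_strained_width}"
        )
    applied = (peak_strained_width - initial_width) / initial_width
    if applied <= 0:
        raise ValueError("peak width must exceed initial width (no strain applied)")
    residual = (recovered_width - initial_width) / initial_width
    return residual / applied, residual


@dataclass(frozen=True)
class RecoilMeasurement:
    """Elastic recoil observed immediately after releasing tension.

    ``recoil_distance`` is a fraction of the total mediolateral explant
    width; ``recoil_window`` is the observation window in seconds (the first
    5 s by convention).
    """

    tension_released: float  # μN
    immediate_recoil_tension: float  # μN, within the recoil window
    recoil_distance: float  # fraction of ML width
    recoil_window: float = 5.0  # s

    def __post_init__(self) -> None:
        if not (0.0 <= self.immediate_recoil_tension <= self.tension_released):
            raise ValueError(
                "need 0 <= immediate_recoil_tension <= tension_released, got "
                f"{self.immediate_recoil_tension} vs {self.tension_released}"
            )
        if not (self.recoil_window > 0):
            raise ValueError("recoil_window must be > 0")


def recoil_metrics(m: RecoilMeasurement):
    """Return ``(fractional_recoil_pct, recoil_rate_pct_per_hr)``.

    Fractional recoil = 100 × immediate recoil tension / tension released.
    Recoil rate = recoil distance (% of explant width) per hour, measured
    over the (seconds-scale) recoil window but reported in %/hr.
    """
    if m.tension_released <= 0:
        raise ValueError("tension_released must be > 0")
    fractional = 100.0 * m.immediate_recoil_tension / m.tension_released
    rate = 100.0 * m.recoil_distance / m.recoil_window * 3600.0
    return fractional, rate
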