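"""Seeded generators for every input the pipeline consumes.

Three generators with exact ground truth:

* :func:`simulate_tractor_pull` — a quasi-static chain of active
  motor-spring-dashpot elements pulling against a calibrated probe spring.
  Each element is a contractile motor with a linear force–velocity relation
  (v = v₀(1 − T/F_stall)) in parallel with a spring, plus plastic dashpot
  flow above a yield tension. Elements may be "recruited" at a scheduled
  time, switching to stronger motor parameters (the convergent-thickening →
  convergent-extension transition). Measurement noise, linear probe drift
  and a static-friction dead band act only on the emitted deflection series;
  the returned ground truth is noise-free.
* :func:`simulate_relaxation` — forward standard-linear-solid relaxation
  traces with multiplicative Gaussian noise.
* :func:`simulate_marker_tracks` — marker tracks evolving under
  piecewise-uniform exponential regional strain.

All generators are bit-reproducible given a seed. The shipped default pull
configuration (:func:`default_pull_config`) is a *calibration* chosen to
reproduce landmark magnitudes of the real assay (first plateau ≈ 2 μN, final
force ≈ 4–5 μN, motor-only ceiling ≈ 2 μN); it is not a measurement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np

from explantmech.force_trace import ForceTrace, ProbeCalibration
from explantmech.morphometrics import MarkerTracks
from explantmech.stress_relaxation import RelaxationTrace, SLSParameters, sls_stress

__all__ = [
    "ChainElement",
    "PullSimConfig",
    "PullGroundTruth",
    "default_pull_config",
    "simulate_tractor_pull",
    "simulate_relaxation",
    "simulate_marker_tracks",
]


@dataclass(frozen=True)
class ChainElement:
    """One element of the series chain.

    The element's natural (contractile) length shortens at the motor
    velocity ``v = free_velocity · max(0, 1 − T/stall_force)`` and lengthens
    plastically at ``(T − yield_tension)/dashpot_viscosity`` when tension
    exceeds the yield. Elastic deformation ``T/spring_constant`` rides on
    top. ``recruitment_time`` (minutes) optionally switches the element to
    the ``recruited_*`` motor parameters, modelling replacement of an early
    motor by a later, stronger one.
    """

    kind: str = "CT"  # {'CT', 'CE', 'passive'} — label only
    stall_force: float = 0.0  # μN; 0 disables the motor
    free_velocity: float = 0.0  # μm/min at zero tension
    spring_constant: float = 0.05  # μN/μm
    dashpot_viscosity: float = math.inf  # μN·min/μm; inf = no plastic flow
    yield_tension: float = math.inf  # μN; may exceed stall (never yields)
    rest_length: float = 1000.0  # μm
    recruitment_time: Optional[float] = None  # min; None = never recruited
    recruited_kind: str = "CE"
    recruited_stall_force: Optional[float] = None
    recruited_free_velocity: Optional[float] = None
    recruited_yield_tension: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("stall_force", "free_velocity", "spring_constant",
                     "dashpot_viscosity", "rest_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.spring_constant <= 0:
            raise ValueError("spring_constant must be > 0 (elements are elastic)")

    def motor_params(self, t_min: float):
        """Active (stall, free velocity, yield) at simulation time t."""
        if self.recruitment_time is not None and t_min >= self.recruitment_time:
            return (
                self.recruited_stall_force
                if self.recruited_stall_force is not None
                else self.stall_force,
                self.recruited_free_velocity
                if self.recruited_free_velocity is not None
                else self.free_velocity,
                self.recruited_yield_tension
                if self.recruited_yield_tension is not None
                else self.yield_tension,
            )
        return self.stall_force, self.free_velocity, self.yield_tension


@dataclass
class PullSimConfig:
    """Full specification of one simulated pull (see module docstring)."""

    elements: List[ChainElement]
    probe_spring_constant: float = 0.1  # μN/μm
    magnification: float = 0.5  # μm/px of the emitted deflection record
    static_friction: float = 0.0  # μN dead band on probe updates
    drift_rate: float = 0.0  # px/min added to the emitted deflection
    noise_sd: float = 0.0  # μN measurement noise (emitted series only)
    dt: float = 0.1  # min
    duration: float = 1080.0  # min
    sample_every: float = 6.0  # min between emitted samples
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("need at least one chain element")
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be > 0")
        if self.probe_spring_constant <= 0 or self.magnification <= 0:
            raise ValueError("probe_spring_constant and magnification must be > 0")
        if self.static_friction < 0 or self.noise_sd < 0:
            raise ValueError("static_friction and noise_sd must be >= 0")


@dataclass
class PullGroundTruth:
    """Noise-free state of the simulated chain at every integration step."""

    time_min: np.ndarray  # (n_steps+1,)
    tension_uN: np.ndarray  # (n_steps+1,) chain tension = probe spring force
    natural_lengths_um: np.ndarray  # (n_steps+1, n_elements)
    element_lengths_um: np.ndarray  # (n_steps+1, n_elements) incl. elastic part
    max_active_stall_uN: np.ndarray  # (n_steps+1,)
    config: PullSimConfig = None

    def to_dict(self) -> dict:
        return {
            "time_min": self.time_min.tolist(),
            "tension_uN": self.tension_uN.tolist(),
            "natural_lengths_um": self.natural_lengths_um.tolist(),
            "element_lengths_um": self.element_lengths_um.tolist(),
            "max_active_stall_uN": self.max_active_stall_uN.tolist(),
            "config": asdict(self.config) if self.config is not None else None,
        }


def default_pull_config(seed: int = 0, d180_like: bool = False) -> PullSimConfig:
    """Calibrated three-element chain reproducing the landmark two-phase trace.

    Two flanking ventrolateral elements (weak motors, low yield) surround a
    central dorsal element (strong motor, no yield). Tension rises until it
    is pinned just above the flanking yield (first plateau ≈ 2 μN); at the
    recruitment time the flanks switch to strong, non-yielding motors and
    tension rises again toward the common stall (≈ 4.5 μN). With
    ``d180_like=True`` the flanking elements are omitted, which removes the
    plateau — the strong motor couples directly to the attachments.
    """
    central = ChainElement(
        kind="CE",
        stall_force=4.5,
        free_velocity=0.2,
        spring_constant=0.05,
        rest_length=1500.0,
    )
    flank = ChainElement(
        kind="CT",
        stall_force=2.2,
        free_velocity=0.2,
        spring_constant=0.05,
        dashpot_viscosity=1.0,
        yield_tension=2.0,
        rest_length=1000.0,
        recruitment_time=630.0,  # min after G0
        recruited_stall_force=4.5,
        recruited_free_velocity=0.6,
        recruited_yield_tension=math.inf,
    )
    elements = [central] if d180_like else [flank, central, flank]
    return PullSimConfig(elements=elements, seed=seed)


def simulate_tractor_pull(
    config: PullSimConfig,
) -> Tuple[ForceTrace, np.ndarray, PullGroundTruth]:
    """Integrate the quasi-static chain and emit a calibrated deflection trace.

    Returns ``(trace, element_lengths, ground_truth)``. The chain carries a
    single tension ``T`` satisfying force balance with the probe spring at
    every step: the total chain shortening ``C`` splits between probe
    deflection ``d`` and elastic extension ``T·Σ(1/k_i)``, giving the closed
    form ``T = K_P·C / (1 + K_P·Σ 1/k_i)`` (clipped at 0: the probe only
    pushes back while the cleat is in contact). Natural lengths advance by
    explicit Euler. A static-friction dead band freezes the probe (and hence
    the tension) until the frictionless target differs by at least the
    friction force. Noise and drift affect only the emitted pixel series;
    the pre/post unstressed reference positions are set so that drift
    correction can recover the clean trace.
    """
    cfg = config
    n_steps = int(round(cfg.duration / cfg.dt))
    k_p = cfg.probe_spring_constant
    compliance = sum(1.0 / e.spring_constant for e in cfg.elements)
    denom = 1.0 + k_p * compliance

    n_el = len(cfg.elements)
    l_nat = np.array([e.rest_length for e in cfg.elements], dtype=float)
    l0_total = float(l_nat.sum())

    times = np.empty(n_steps + 1)
    tension = np.empty(n_steps + 1)
    nat_hist = np.empty((n_steps + 1, n_el))
    stall_hist = np.empty(n_steps + 1)

    t_now = 0.0
    T = 0.0
    for step in range(n_steps + 1):
        times[step] = t_now
        tension[step] = T
        nat_hist[step] = l_nat
        actives = [e.motor_params(t_now) for e in cfg.elements]
        stalls = [s for s, v, _ in actives if s > 0 and v > 0]
        stall_hist[step] = max(stalls) if stalls else 0.0
        if step == n_steps:
            break

        # advance natural lengths under the current tension
        for i, (e, (stall, v0, yield_t)) in enumerate(zip(cfg.elements, actives)):
            dl = 0.0
            if stall > 0 and v0 > 0:
                dl -= v0 * max(0.0, 1.0 - T / stall)
            if math.isfinite(e.dashpot_viscosity) and e.dashpot_viscosity > 0 and T > yield_t:
                dl += (T - yield_t) / e.dashpot_viscosity
            l_nat[i] = max(l_nat[i] + dl * cfg.dt, 0.0)

        shortening = l0_total - float(l_nat.sum())
        t_target = max(k_p * shortening / denom, 0.0)
        if not math.isfinite(t_target):
            raise RuntimeError(f"force-balance solve failed at step {step + 1}")
        if cfg.static_friction == 0.0 or abs(t_target - T) >= cfg.static_friction:
            T = t_target
        t_now += cfg.dt

    elastic = tension[:, None] / np.array(
        [e.spring_constant for e in cfg.elements]
    )[None, :]
    lengths = nat_hist + elastic

    truth = PullGroundTruth(
        time_min=times,
        tension_uN=tension,
        natural_lengths_um=nat_hist,
        element_lengths_um=lengths,
        max_active_stall_uN=stall_hist,
        config=cfg,
    )

    # emit a calibrated pixel trace at the sampling cadence
    stride = max(int(round(cfg.sample_every / cfg.dt)), 1)
    idx = np.arange(0, n_steps + 1, stride)
    t_emit = times[idx]
    deflection_um = tension[idx] / k_p
    deflection_px = deflection_um / cfg.magnification
    rng = np.random.default_rng(cfg.seed)
    drift = cfg.drift_rate * t_emit
    noise_px = rng.normal(
        0.0, cfg.noise_sd / (k_p * cfg.magnification), size=t_emit.size
    ) if cfg.noise_sd > 0 else np.zeros_like(t_emit)
    emitted = deflection_px + drift + noise_px

    calibration = ProbeCalibration(
        spring_constant=k_p, magnification=cfg.magnification, probe_id="simulated"
    )
    trace = ForceTrace(
        time_min=t_emit,
        deflection_px=emitted,
        calibration=calibration,
        pre_unstressed_px=0.0,
        post_unstressed_px=float(cfg.drift_rate * cfg.duration),
        meta={"simulated": True, "seed": cfg.seed},
    )
    return trace, lengths, truth


def simulate_relaxation(
    params: SLSParameters,
    strain: float,
    area_mm2: float,
    noise_sd_rel: float = 0.0,
    n_samples: int = 200,
    duration_s: float = 300.0,
    seed: Optional[int] = None,
    explant_type: str = "giant",
) -> RelaxationTrace:
    """Forward-simulate a step-strain relaxation force trace.

    Samples are evenly spaced on [0, duration]; each force sample is
    ``SS(t)·area·strain·(1 + ε)`` with ``ε ~ N(0, noise_sd_rel)`` i.i.d.
    Reproducible under ``seed``.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if strain <= 0 or area_mm2 <= 0:
        raise ValueError("strain and area must be > 0")
    if noise_sd_rel < 0:
        raise ValueError("noise_sd_rel must be >= 0")
    t = np.linspace(0.0, duration_s, n_samples)
    force = sls_stress(t, params) * area_mm2 * strain
    if noise_sd_rel > 0:
        rng = np.random.default_rng(seed)
        force = force * (1.0 + rng.normal(0.0, noise_sd_rel, size=t.size))
    return RelaxationTrace(
        time_s=t,
        force_uN=force,
        imposed_strain=strain,
        area_mm2=area_mm2,
        explant_type=explant_type,
        meta={
            "simulated": True,
            "seed": seed,
            "truth": {"s_inf": params.s_inf, "s_sp": params.s_sp, "tau": params.tau},
        },
    )


def simulate_marker_tracks(
    regional_strain_rates: Sequence[Tuple[str, float]],
    initial_positions: Sequence[float],
    duration_min: float = 60.0,
    dt_min: float = 3.0,
    jitter_sd: float = 0.0,
    seed: Optional[int] = None,
) -> MarkerTracks:
    """Generate marker tracks under piecewise-uniform exponential strain.

    ``regional_strain_rates`` lists (region label, rate %/hr) for the
    regions tiling the axis between consecutive ``initial_positions``
    (strictly increasing, one more position than regions; the first marker
    is the fixed anchor side). Each region's length evolves as
    ``L(t) = L(0)·exp(rate·t)``; marker positions are cumulative sums.
    Gaussian positional jitter, when requested, is added to the emitted
    positions only; ground-truth rates are recorded in ``meta``.
    """
    pos0 = np.asarray(initial_positions, dtype=float)
    if pos0.ndim != 1 or pos0.size != len(regional_strain_rates) + 1:
        raise ValueError(
            "need exactly len(regional_strain_rates) + 1 initial positions"
        )
    if not np.all(np.diff(pos0) > 0):
        raise ValueError(
            "initial positions must be strictly increasing (regions must tile "
            "the axis without overlap)"
        )
    labels = [r for r, _ in regional_strain_rates]
    if len(set(labels)) != len(labels):
        raise ValueError("region labels must be unique")
    if duration_min <= 0 or dt_min <= 0:
        raise ValueError("duration_min and dt_min must be > 0")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")

    t = np.arange(0.0, duration_min + 0.5 * dt_min, dt_min)
    t_hr = t / 60.0
    rates = np.array([r for _, r in regional_strain_rates]) / 100.0  # frac/hr
    seg0 = np.diff(pos0)
    # (n_times, n_regions) region lengths
    seg = seg0[None, :] * np.exp(rates[None, :] * t_hr[:, None])
    positions = pos0[0] + np.concatenate(
        [np.zeros((t.size, 1)), np.cumsum(seg, axis=1)], axis=1
    )
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        positions = positions + rng.normal(0.0, jitter_sd, size=positions.shape)

    track_ids = [f"m{i}" for i in range(pos0.size)]
    tracks = {tid: (t.copy(), positions[:, i]) for i, tid in enumerate(track_ids)}
    regions = {
        label: (track_ids[i], track_ids[i + 1]) for i, label in enumerate(labels)
    }
    return MarkerTracks(
        tracks=tracks,
        regions=regions,
        meta={
            "simulated": True,
            "seed": seed,
            "truth_rates_pct_per_hr": dict(regional_strain_rates),
        },
    )
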