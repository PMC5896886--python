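"""Probe-deflection force traces: calibration, drift correction, summaries.

A pulling assay records the deflection of a calibrated cantilever probe (in
image pixels) every few minutes. Force is recovered as

    F = D(t) · M · K_P

with ``D`` the deflection in pixels, ``M`` the magnification in μm/pixel and
``K_P`` the probe spring constant in μN/μm. Probe drift is removed by
linearly interpolating the difference between the unstressed probe positions
recorded before and after the assay and subtracting it from the deflection
series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from explantmech._util import as_1d_float, check_strictly_increasing

__all__ = [
    "ProbeCalibration",
    "ForceTrace",
    "HourlyBin",
    "HourlySummary",
    "deflection_to_force",
    "correct_drift",
    "hourly_summary",
    "subtract_friction",
]


@dataclass(frozen=True)
class ProbeCalibration:
    """Calibration constants of one cantilever probe.

    Parameters
    ----------
    spring_constant : float
        Force per unit tip displacement, μN/μm. Must be positive.
    magnification : float
        Image scale, μm per pixel. Must be positive.
    probe_id : str
        Free-form label of the physical probe.
    """

    spring_constant: float
    magnification: float
    probe_id: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.spring_constant) and self.spring_constant > 0):
            raise ValueError(f"spring_constant must be > 0, got {self.spring_constant}")
        if not (np.isfinite(self.magnification) and self.magnification > 0):
            raise ValueError(f"magnification must be > 0, got {self.magnification}")


@dataclass
class ForceTrace:
    """Time series of probe deflection, optionally with derived forces.

    Times are minutes since the onset of gastrulation (G0); deflections are
    raw pixels. ``pre_unstressed_px`` / ``post_unstressed_px`` are the
    unstressed probe positions before and after the assay, used for drift
    correction. ``force_uN`` is present after calibration.
    """

    time_min: np.ndarray
    deflection_px: np.ndarray
    calibration: ProbeCalibration
    pre_unstressed_px: Optional[float] = None
    post_unstressed_px: Optional[float] = None
    force_uN: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_min = as_1d_float(self.time_min, "time_min")
        self.deflection_px = as_1d_float(self.deflection_px, "deflection_px")
        if self.time_min.shape != self.deflection_px.shape:
            raise ValueError("time_min and deflection_px must have equal length")
        check_strictly_increasing(self.time_min, "time_min")
        if self.force_uN is not None:
            self.force_uN = as_1d_float(self.force_uN, "force_uN")
            if self.force_uN.shape != self.time_min.shape:
                raise ValueError("force_uN must have the same length as samples")

    def __len__(self) -> int:
        return self.time_min.size

    def with_force(self) -> "ForceTrace":
        """Return a copy with ``force_uN`` computed from the deflections."""
        force = deflection_to_force(self.deflection_px, self.calibration)
        return replace(self, force_uN=force, meta=dict(self.meta))


def deflection_to_force(deflection, calibration: ProbeCalibration):
    """Convert probe deflection (pixels) to force (μN).

    Linear in deflection: ``F = D · M · K_P``. Sign is preserved — negative
    deflections yield negative forces, which downstream steps flag rather
    than clip.
    """
    arr = np.asarray(deflection, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("deflection must be finite")
    out = arr * calibration.magnification * calibration.spring_constant
    return float(out) if np.isscalar(deflection) or out.ndim == 0 else out


def correct_drift(trace: ForceTrace) -> ForceTrace:
    """Subtract linearly interpolated probe drift from a deflection trace.

    The corrected deflection equals the raw deflection minus the pre-assay
    unstressed position at the first sample and minus the post-assay
    unstressed position at the last sample, the subtraction varying linearly
    in time between them. Forces are (re)computed from the corrected
    deflections. Negative corrected forces are retained and flagged in
    ``meta['n_negative_force']`` — clipping would bias hourly means.

    If either reference position is missing the trace is returned unchanged
    except for an explicit ``meta['drift_correction'] = 'uncorrected'``
    marker, and a warning is emitted.
    """
    if trace.pre_unstressed_px is None or trace.post_unstressed_px is None:
        missing = [
            name
            for name, v in (
                ("pre_unstressed_px", trace.pre_unstressed_px),
                ("post_unstressed_px", trace.post_unstressed_px),
            )
            if v is None
        ]
        warnings.warn(
            f"drift correction skipped: missing {', '.join(missing)}",
            stacklevel=2,
        )
        meta = dict(trace.meta, drift_correction="uncorrected")
        return replace(trace, meta=meta).with_force()

    t = trace.time_min
    pre = float(trace.pre_unstressed_px)
    post = float(trace.post_unstressed_px)
    if t.size == 1:
        baseline = np.array([pre])
    else:
        baseline = pre + (post - pre) * (t - t[0]) / (t[-1] - t[0])
    corrected = trace.deflection_px - baseline
    force = deflection_to_force(corrected, trace.calibration)
    meta = dict(trace.meta, drift_correction="linear")
    n_neg = int(np.sum(force < 0))
    if n_neg:
        meta["n_negative_force"] = n_neg
    return replace(
        trace,
        deflection_px=corrected,
        pre_unstressed_px=0.0,
        post_unstressed_px=0.0,
        force_uN=force,
        meta=meta,
    )


@dataclass(frozen=True)
class HourlyBin:
    hour: int
    mean_force_uN: float
    sem_uN: Optional[float]  # None when n == 1 (SEM undefined)
    n: int


@dataclass
class HourlySummary:
    """Per-hour mean force with standard error of the hourly mean."""

    bins: list

    def to_rows(self):
        return [(b.hour, b.mean_force_uN, b.sem_uN, b.n) for b in self.bins]


def hourly_summary(trace: ForceTrace) -> HourlySummary:
    """Bin forces into half-open hour windows [h, h+1) after G0.

    Each non-empty bin reports the mean force, the SEM (sample SD / √n,
    absent when n = 1) and the sample count. Empty bins are omitted.
    Requires a force series (run :func:`correct_drift` or ``with_force``
    first).
    """
    if trace.force_uN is None:
        raise ValueError("trace has no force series; calibrate/drift-correct first")
    hours = np.floor(trace.time_min / 60.0).astype(int)
    bins = []
    for h in np.unique(hours):
        sel = trace.force_uN[hours == h]
        n = sel.size
        sem = float(np.std(sel, ddof=1) / np.sqrt(n)) if n > 1 else None
        bins.append(HourlyBin(int(h), float(np.mean(sel)), sem, n))
    return HourlySummary(bins=bins)


def subtract_friction(trace: ForceTrace, friction_offset: float) -> ForceTrace:
    """Compensate static sled-substrate friction by an additive offset.

    Friction makes the observed force a systematic *under*estimate, so the
    offset is **added** to every strictly positive force sample; samples at
    or below zero are untouched (no force is fabricated at rest). Disabled
    by default throughout the pipeline (offset 0); provenance is recorded in
    ``meta['friction_offset_uN']``.
    """
    if not (np.isfinite(friction_offset) and friction_offset >= 0):
        raise ValueError(f"friction_offset must be >= 0, got {friction_offset}")
    if trace.force_uN is None:
        raise ValueError("trace has no force series; calibrate/drift-correct first")
    force = trace.force_uN.copy()
    if friction_offset > 0:
        force[force > 0] += friction_offset
    meta = dict(trace.meta, friction_offset_uN=float(friction_offset))
    return replace(trace, force_uN=force, meta=meta)
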