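"""Air-puff pressure pulse and the force it applies to the corneal apex.

A non-contact tonometer fires a short collimated air jet at the cornea.  For
elastic-modulus work the jet is idealised as a time-varying uniform pressure
acting on a disc of effective radius ``rp`` centred on the apex, so that the
apex force is simply ``pressure(t) * pi * rp**2``.  The temporal profile of
the jet is instrument-specific; here it is a configurable smooth unimodal
pulse (Gaussian by default) whose defaults place simulated deformations in
the physiological range.  Units: pressure kPa, time ms, lengths mm, force mN
(kPa * mm**2 == mN, so no conversion constants appear).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: conversion used at I/O boundaries only; internals are kPa throughout
KPA_PER_MMHG = 0.133322


@dataclass(frozen=True)
class AirPuffConfig:
    """Parameters of the idealised air-puff pulse.

    Attributes
    ----------
    peak_pressure : float
        Maximum stagnation pressure of the jet, kPa.
    peak_time : float
        Time of the pressure maximum, ms.
    pulse_halfwidth : float
        Half-width at half-maximum of the pulse, ms.
    rp : float
        Effective puff radius over which the pressure acts, mm.  Clinically
        this is taken as the radius of the flattened zone at first
        applanation; see :func:`cornea_emod.extraction.effective_puff_radius`.
    duration : float
        Total examination duration, ms.
    sample_rate : float
        Camera frame rate, frames per ms.
    """

    peak_pressure: float = 9.5
    peak_time: float = 15.0
    pulse_halfwidth: float = 6.0
    rp: float = 1.25
    duration: float = 32.0
    sample_rate: float = 139.0 / 32.0  # 140 frames over 32 ms

    def __post_init__(self) -> None:
        if self.peak_pressure <= 0:
            raise ValueError("peak_pressure must be positive")
        if not 0 < self.peak_time < self.duration:
            raise ValueError("peak_time must lie strictly inside (0, duration)")
        if self.pulse_halfwidth <= 0:
            raise ValueError("pulse_halfwidth must be positive")
        if self.rp <= 0:
            raise ValueError("rp must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def sigma(self) -> float:
        """Gaussian standard deviation equivalent to the stated HWHM, ms."""
        return self.pulse_halfwidth / np.sqrt(2.0 * np.log(2.0))

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.sample_rate)) + 1

    def time_grid(self) -> np.ndarray:
        """Uniform frame-time grid spanning [0, duration], ms."""
        return np.linspace(0.0, self.duration, self.n_frames)

    def with_rp(self, rp: float) -> "AirPuffConfig":
        """Copy of this config with the effective puff radius replaced."""
        return replace(self, rp=rp)


def pressure_at(config: AirPuffConfig, time):
    """Pulse pressure at ``time`` (ms), kPa.  Accepts scalars or arrays.

    The pulse is a baseline-subtracted Gaussian: the Gaussian tail value at
    t = 0 is removed and the profile renormalised so the pulse starts at
    exactly zero pressure and still peaks at ``peak_pressure`` at
    ``peak_time`` (negative far-tail values are clipped to zero).  It is
    unimodal and decays to zero toward both ends of the window.
    """
    t = np.asarray(time, dtype=float)
    if np.any(t < 0) or np.any(t > config.duration):
        raise ValueError(
            f"time must lie within [0, {config.duration}] ms, got {time!r}"
        )
    g = np.exp(-((t - config.peak_time) ** 2) / (2.0 * config.sigma**2))
    g0 = np.exp(-(config.peak_time**2) / (2.0 * config.sigma**2))
    p = config.peak_pressure * np.clip((g - g0) / (1.0 - g0), 0.0, None)
    return p if p.ndim else float(p)


def apex_force(config: AirPuffConfig, time):
    """Force on the corneal apex at ``time``, mN.

    Uniform-disc pressure assumption: ``f = p(t) * pi * rp**2``.
    """
    return pressure_at(config, time) * np.pi * config.rp**2


def pulse_to_csv(config: AirPuffConfig, path) -> None:
    """Export the pulse as a two-column CSV (time_ms, pressure_kPa)."""
    t = config.time_grid()
    p = pressure_at(config, t)
    np.savetxt(
        path,
        np.column_stack([t, p]),
        delimiter=",",
        header="time_ms,pressure_kPa",
        comments="",
    )


def mmhg_to_kpa(p_mmhg):
    return np.asarray(p_mmhg, dtype=float) * KPA_PER_MMHG


def kpa_to_mmhg(p_kpa):
    return np.asarray(p_kpa, dtype=float) / KPA_PER_MMHG
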