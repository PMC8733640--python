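"""Synthetic cohorts and air-puff examinations with embedded ground truth.

Generates per-subject geometry/pressure covariates and auxiliary device
features for three groups (healthy, forme fruste keratoconus, clinical
keratoconus) from truncated normal distributions calibrated to published
group means and SDs, then simulates the time-resolved anterior-surface
elevation of each examination with a quasi-static forward model:

* apex deformation ``delta(t) = softclip(f(t) / k)`` where ``k`` is the
  shell stiffness implied by the subject's true modulus
  (:func:`cornea_emod.shell.forward_stiffness`) and the softclip is exactly
  linear up to a knee and saturates smoothly at ``DA_max``;
* a compactly supported Gaussian-shaped spatial bump distributes the apex
  deformation across the chord (zero at and beyond the peripheral zone used
  for whole-eye-motion estimation, so the peripheral estimator is unbiased);
* a quadratic whole-eye motion ``a t^2`` displaces the entire profile;
* i.i.d. Gaussian elevation noise is added per sample.

Every examination embeds its ground truth (true modulus, stiffness,
noiseless deformation series, construction-time applanation instants) so
extraction error can be measured without re-simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
from scipy import stats as sps

from .airpuff import AirPuffConfig, apex_force
from .shell import CorneaGeometry, forward_stiffness

GROUPS = ("healthy", "FFKC", "KC")

#: target coding used by the diagnosis network
GROUP_CODES = {"healthy": 1.0, "FFKC": 0.0, "KC": -1.0}

AUX_FEATURES = ("SP-A1", "ARTh", "B.Ele.Th", "Kmax", "Pachymin")


@dataclass(frozen=True)
class VariableSpec:
    """Truncated-normal spec for one subject-level variable.

    ``mean`` is the target mean of the *truncated* distribution: truncating
    an off-centre normal shifts its mean, so the underlying location is
    solved for numerically to make the sampled population mean match the
    stated target (this matters for steep keratoconic curvature radii,
    whose lower bound sits ~1.3 SD from the mean).
    """

    mean: float
    sd: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("SD must be non-negative")
        if self.low >= self.high:
            raise ValueError("low must be < high")
        if not self.low <= self.mean <= self.high:
            raise ValueError("target mean outside the truncation bounds")

    def _adjusted_loc(self) -> float:
        from scipy.optimize import brentq

        def gap(loc: float) -> float:
            a = (self.low - loc) / self.sd
            b = (self.high - loc) / self.sd
            return sps.truncnorm.mean(a, b, loc=loc, scale=self.sd) - self.mean

        lo = self.mean - 6.0 * self.sd
        hi = self.mean + 6.0 * self.sd
        if gap(lo) > 0 or gap(hi) < 0:  # target unreachable; fall back
            return self.mean
        return float(brentq(gap, lo, hi, xtol=1e-10))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0.0:  # degenerate: every subject at the mean
            return np.full(n, self.mean)
        loc = self._adjusted_loc()
        a = (self.low - loc) / self.sd
        b = (self.high - loc) / self.sd
        return sps.truncnorm.rvs(
            a, b, loc=loc, scale=self.sd, size=n, random_state=rng
        )


# Group calibration.  CCT/R/bIOP and E, SP-A1, ARTh follow published group
# means and SDs; B.Ele.Th (um), Kmax (D) and Pachymin (um) have no published
# distributions and use synthetic, clinically plausible group-separated
# normals (they only need to be group-informative for the classifier).
DEFAULT_GROUP_CONFIGS: Dict[str, Dict[str, VariableSpec]] = {
    "healthy": {
        "CCT": VariableSpec(534.5, 34.6, 300.0, 700.0),
        "R": VariableSpec(7.75, 0.92, 4.0, 10.0),
        "bIOP": VariableSpec(15.3, 2.0, 5.0, 40.0),
        "E": VariableSpec(0.35, 0.04, 0.02, 1.0),
        "SP-A1": VariableSpec(93.301, 14.487, 5.0, 160.0),
        "ARTh": VariableSpec(451.27, 112.74, 20.0, 900.0),
        "B.Ele.Th": VariableSpec(4.0, 3.0, -10.0, 120.0),
        "Kmax": VariableSpec(43.5, 1.5, 38.0, 75.0),
        "Pachymin": VariableSpec(528.0, 35.0, 300.0, 700.0),
    },
    "FFKC": {
        "CCT": VariableSpec(522.8, 39.5, 300.0, 700.0),
        "R": VariableSpec(6.94, 0.95, 4.0, 10.0),
        "bIOP": VariableSpec(14.6, 1.8, 5.0, 40.0),
        "E": VariableSpec(0.30, 0.08, 0.02, 1.0),
        "SP-A1": VariableSpec(79.574, 14.127, 5.0, 160.0),
        "ARTh": VariableSpec(400.41, 97.93, 20.0, 900.0),
        "B.Ele.Th": VariableSpec(8.0, 4.0, -10.0, 120.0),
        "Kmax": VariableSpec(45.0, 1.8, 38.0, 75.0),
        "Pachymin": VariableSpec(505.0, 40.0, 300.0, 700.0),
    },
    "KC": {
        "CCT": VariableSpec(462.8, 51.8, 300.0, 700.0),
        "R": VariableSpec(5.36, 1.01, 4.0, 10.0),
        "bIOP": VariableSpec(14.3, 2.5, 5.0, 40.0),
        "E": VariableSpec(0.16, 0.04, 0.02, 1.0),
        "SP-A1": VariableSpec(41.581, 13.542, 5.0, 160.0),
        "ARTh": VariableSpec(193.17, 109.83, 20.0, 900.0),
        "B.Ele.Th": VariableSpec(35.0, 15.0, -10.0, 120.0),
        "Kmax": VariableSpec(55.0, 6.0, 38.0, 75.0),
        "Pachymin": VariableSpec(438.0, 50.0, 300.0, 700.0),
    },
}

#: cohort sizes of the study design this generator emulates
DEFAULT_N_PER_GROUP = {"healthy": 50, "FFKC": 36, "KC": 50}


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str
    E_true: float  # MPa
    geometry: CorneaGeometry
    bIOP: float  # mmHg
    aux_features: Dict[str, float]
    seed: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.E_true <= 0:
            raise ValueError("E_true must be positive")
        if not 5.0 <= self.bIOP <= 40.0:
            raise ValueError("bIOP outside [5, 40] mmHg")

    def to_row(self) -> dict:
        row = {
            "subject_id": self.subject_id,
            "group": self.group,
            "E_true": self.E_true,
            "CCT_um": self.geometry.t * 1000.0,
            "R_mm": self.geometry.R,
            "nu": self.geometry.nu,
            "bIOP_mmHg": self.bIOP,
            "seed": self.seed,
        }
        row.update(self.aux_features)
        return row


@dataclass
class SimConfig:
    """Forward-model knobs for :func:`simulate_examination` (all mm/ms).

    ``bump_width`` is the Gaussian width of the spatial deformation bump;
    the bump is truncated to zero at ``bump_cutoff`` (the start of the
    peripheral whole-eye-motion zone) and renormalised to unit apex value.
    ``softclip_knee`` is the displacement up to which the response is
    exactly linear; beyond it the deformation saturates smoothly at
    ``da_max``.  ``eye_motion_a`` is the quadratic whole-eye drift
    coefficient (mm/ms^2) and ``noise_sigma`` the per-sample elevation noise
    SD (2 um default).
    """

    chord: float = 8.0
    n_x: int = 141
    bump_width: float = 2.0
    bump_cutoff: float = 3.5
    softclip_knee: float = 0.5
    da_max: float = 1.45
    eye_motion_a: float = 1e-4
    noise_sigma: float = 0.002
    central_zone: float = 1.0  # |x| half-width of the applanation fit zone
    check_window: bool = True  # warn if saturation makes 0.4 mm unreachable

    def __post_init__(self) -> None:
        if self.da_max <= self.softclip_knee:
            raise ValueError("da_max must exceed softclip_knee")
        if self.bump_width <= 0 or self.bump_cutoff <= 0:
            raise ValueError("bump dimensions must be positive")

    def x_grid(self) -> np.ndarray:
        return np.linspace(-self.chord / 2.0, self.chord / 2.0, self.n_x)


class SimulationWarningError(UserWarning):
    pass


@dataclass
class Examination:
    """One simulated examination: elevation surface y(x, t) plus truth.

    ``surface[i, j]`` is the anterior-surface elevation (mm) at frame ``i``
    and lateral position ``x_grid[j]``, measured from the resting apex with
    apex-ward (puff-direction) deformation positive, so the undeformed
    profile is the sagitta arc ``R - sqrt(R^2 - x^2)``.
    """

    subject_id: str
    time_grid: np.ndarray  # ms
    x_grid: np.ndarray  # mm
    surface: np.ndarray  # (n_t, n_x) mm
    truth: dict

    def __post_init__(self) -> None:
        dt = np.diff(self.time_grid)
        if not (np.all(dt > 0) and np.allclose(dt, dt[0])):
            raise ValueError("time_grid must be strictly increasing and uniform")
        if not np.all(np.isfinite(self.surface)):
            raise ValueError("surface contains non-finite values")


def generate_cohort(
    group_configs: Optional[Dict[str, Dict[str, VariableSpec]]] = None,
    n_per_group: Optional[Dict[str, int]] = None,
    seed: int = 0,
) -> List[SubjectRecord]:
    """Draw a cohort of subjects, deterministically given ``seed``.

    Variables are drawn independently per subject from truncated normals
    (truncation at the type invariants).  Per-subject seeds for the
    examination simulation are drawn from the same master stream, so a
    single subject is reproducible in isolation from its record alone.
    """
    configs = group_configs or DEFAULT_GROUP_CONFIGS
    sizes = n_per_group or dict(DEFAULT_N_PER_GROUP)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    subjects: List[SubjectRecord] = []
    for group in GROUPS:
        if group not in sizes:
            continue
        n = sizes[group]
        if n < 1:
            raise ValueError("n_per_group entries must be >= 1")
        spec = configs[group]
        draws = {name: spec[name].sample(n, rng) for name in spec}
        sub_seeds = rng.integers(0, 2**31 - 1, size=n)
        for i in range(n):
            geometry = CorneaGeometry(
                R=float(draws["R"][i]), t=float(draws["CCT"][i]) / 1000.0
            )
            aux = {
                name: float(draws[name][i])
                for name in AUX_FEATURES
                if name in draws
            }
            subjects.append(
                SubjectRecord(
                    subject_id=f"{group}-{i:04d}",
                    group=group,
                    E_true=float(draws["E"][i]),
                    geometry=geometry,
                    bIOP=float(draws["bIOP"][i]),
                    aux_features=aux,
                    seed=int(sub_seeds[i]),
                )
            )
    return subjects


def _softclip(u: np.ndarray, knee: float, cap: float) -> np.ndarray:
    """C1 saturation: identity below ``knee``, smooth approach to ``cap``."""
    u = np.asarray(u, dtype=float)
    span = cap - knee
    out = np.where(
        u <= knee, u, cap - span * np.exp(-(np.maximum(u, knee) - knee) / span)
    )
    return out


def _bump_profile(x: np.ndarray, width: float, cutoff: float) -> np.ndarray:
    """Compact unit-apex deformation profile; zero for |x| >= cutoff."""
    tail = np.exp(-(cutoff**2) / (2.0 * width**2))
    g = (np.exp(-(x**2) / (2.0 * width**2)) - tail) / (1.0 - tail)
    return np.clip(g, 0.0, None)


def _crossing_times(t: np.ndarray, series: np.ndarray, level: float):
    """Linearly interpolated times where ``series`` crosses ``level``."""
    s = series - level
    idx = np.nonzero(np.diff(np.signbit(s)))[0]
    times = []
    for i in idx:
        frac = s[i] / (s[i] - s[i + 1])
        times.append(float(t[i] + frac * (t[i + 1] - t[i])))
    return times


def simulate_examination(
    subject: SubjectRecord,
    airpuff: Optional[AirPuffConfig] = None,
    sim: Optional[SimConfig] = None,
) -> Examination:
    """Simulate the elevation surface of one examination.

    Deterministic given the subject's embedded seed.  The ``truth`` block
    carries the noiseless apex deformation, stiffness, applanation instants
    implied by the construction, the eye-motion coefficient and the noise
    sigma.
    """
    airpuff = airpuff or AirPuffConfig()
    sim = sim or SimConfig()
    t = airpuff.time_grid()
    x = sim.x_grid()
    rng = np.random.default_rng(np.random.SeedSequence(subject.seed))

    k = forward_stiffness(subject.E_true, subject.geometry, airpuff.rp)
    f = apex_force(airpuff, t)
    delta = _softclip(f / k, sim.softclip_knee, sim.da_max)

    if sim.check_window and float(delta.max()) < 0.4:
        import warnings

        warnings.warn(
            f"subject {subject.subject_id}: peak deformation "
            f"{delta.max():.3f} mm < 0.4 mm; stiffness window unreachable",
            SimulationWarningError,
        )

    sag = subject.geometry.R - np.sqrt(subject.geometry.R**2 - x**2)
    g = _bump_profile(x, sim.bump_width, sim.bump_cutoff)
    eye = sim.eye_motion_a * t**2
    surface = sag[None, :] + delta[:, None] * g[None, :] + eye[:, None]
    if sim.noise_sigma > 0:
        surface = surface + rng.normal(0.0, sim.noise_sigma, surface.shape)

    # construction-time applanation: the zero crossing of the central-zone
    # best-fit quadratic curvature (the event definition the extractor uses),
    # kappa(t) = kappa_fit[sag] + delta(t) * kappa_fit[bump]
    zone = np.abs(x) <= sim.central_zone
    k_sag = 2.0 * np.polyfit(x[zone], sag[zone], 2)[0]
    k_bump = 2.0 * np.polyfit(x[zone], g[zone], 2)[0]
    delta_appl = -k_sag / k_bump if k_bump < 0 else np.inf
    crossings = _crossing_times(t, delta, delta_appl)
    truth = {
        "E_true": subject.E_true,
        "stiffness_true": k,
        "delta_true": delta,
        "force": f,
        "delta_applanation": delta_appl,
        "a1t_true": crossings[0] if crossings else None,
        "a2t_true": crossings[-1] if len(crossings) > 1 else None,
        "eye_motion_a": sim.eye_motion_a,
        "noise_sigma": sim.noise_sigma,
        "rp": airpuff.rp,
        "R": subject.geometry.R,
        "t": subject.geometry.t,
        "nu": subject.geometry.nu,
        "bIOP": subject.bIOP,
    }
    return Examination(
        subject_id=subject.subject_id,
        time_grid=t,
        x_grid=x,
        surface=surface,
        truth=truth,
    )


@dataclass
class ImageConfig:
    """Rasterisation geometry for the optional edge-detection round trip."""

    mm_per_px: float = 0.016
    band_thickness_px: float = 3.0
    intensity: float = 1.0
    noise_sigma: float = 0.02
    margin_mm: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.band_thickness_px < 1.0:
            raise ValueError(
                "band thinner than 1 pixel cannot be represented; "
                "decrease mm_per_px or thicken the band"
            )


def rasterize_frames(exam: Examination, image_config: Optional[ImageConfig] = None):
    """Render each frame as a grayscale image with a bright band on y(x, t).

    Returns ``(stack, meta)`` where ``stack`` has shape
    (n_t, n_rows, n_x) and ``meta`` records the pixel geometry needed to
    invert the mapping (row r corresponds to elevation
    ``y0_mm + r * mm_per_px``).
    """
    cfg = image_config or ImageConfig()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    y0 = float(exam.surface.min()) - cfg.margin_mm
    y1 = float(exam.surface.max()) + cfg.margin_mm
    n_rows = int(np.ceil((y1 - y0) / cfg.mm_per_px)) + 1
    rows_mm = y0 + np.arange(n_rows) * cfg.mm_per_px
    sigma_mm = cfg.band_thickness_px * cfg.mm_per_px / 2.355  # FWHM -> sigma
    stack = cfg.intensity * np.exp(
        -((rows_mm[None, :, None] - exam.surface[:, None, :]) ** 2)
        / (2.0 * sigma_mm**2)
    )
    if cfg.noise_sigma > 0:
        stack = stack + rng.normal(0.0, cfg.noise_sigma, stack.shape)
    meta = {"y0_mm": y0, "mm_per_px": cfg.mm_per_px, "x_grid": exam.x_grid}
    return stack, meta


def cohort_to_dataframe(subjects: List[SubjectRecord]):
    import pandas as pd

    return pd.DataFrame([s.to_row() for s in subjects])


def subject_from_row(row: dict) -> SubjectRecord:
    """Rebuild a SubjectRecord from a cohort-table row."""
    aux = {k: float(row[k]) for k in AUX_FEATURES if k in row}
    return SubjectRecord(
        subject_id=str(row["subject_id"]),
        group=str(row["group"]),
        E_true=float(row["E_true"]),
        geometry=CorneaGeometry(
            R=float(row["R_mm"]), t=float(row["CCT_um"]) / 1000.0,
            nu=float(row.get("nu", 0.49)),
        ),
        bIOP=float(row["bIOP_mmHg"]),
        aux_features=aux,
        seed=int(row["seed"]),
    )
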