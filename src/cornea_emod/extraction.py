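"""Dynamic corneal response extraction from examination surfaces.

Pipeline per examination: estimate and remove whole-eye motion from the
peripheral chord, recover the apex deformation series, detect applanation
(central curvature zero crossings) and highest-concavity events, pair the
deformation with the air-puff force and fit the loading-window slope
S_TSC = dF/d(delta) on the approximately linear 0.2-0.4 mm segment.  That
slope is the stiffness input to the shallow-shell modulus relation.

Curvature here always means the best-fit quadratic coefficient doubled over
a central fitting zone (|x| <= 1 mm by default): applanation is "locally
flat", i.e. the first loading-phase zero crossing of that curvature, located
sub-frame by linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Set, Tuple

import numpy as np
from scipy import stats as sps

from .airpuff import AirPuffConfig, apex_force, kpa_to_mmhg, pressure_at
from .synth import Examination


class NoEdgeError(ValueError):
    """No image column carries a detectable bright band."""


class NotApplanatedError(ValueError):
    """Central curvature never crosses zero."""


class NoConcavityError(ValueError):
    """Deformation has no interior maximum (monotonic trace)."""


class InsufficientWindowError(ValueError):
    """Fewer than 3 loading samples fall inside the slope window."""


@dataclass
class ApexTrace:
    """Whole-eye-corrected apex displacement series.

    ``deformation`` is the corneal deflection delta entering the stiffness
    fit: raw apex elevation minus its frame-0 baseline minus the estimated
    whole-eye motion.
    """

    time: np.ndarray  # ms
    raw_apex: np.ndarray  # mm
    eye_motion: np.ndarray  # mm
    deformation: np.ndarray  # mm


@dataclass
class DCRParameters:
    A1T: float  # ms
    A1V: float  # mm/ms
    A2T: float  # ms
    A2V: float  # mm/ms
    HCT: float  # ms
    DA: float  # mm
    PD: float  # mm
    SPA1: Optional[float] = None  # mmHg/mm
    quality_flags: Set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "A1T": self.A1T,
            "A1V": self.A1V,
            "A2T": self.A2T,
            "A2V": self.A2V,
            "HCT": self.HCT,
            "DA": self.DA,
            "PD": self.PD,
            "SPA1": self.SPA1,
            "quality_flags": ",".join(sorted(self.quality_flags)),
        }


@dataclass
class ForceDisplacementCurve:
    delta: np.ndarray  # mm
    force: np.ndarray  # mN
    loading: np.ndarray  # bool per sample


@dataclass
class StiffnessResult:
    S_TSC: float  # mN/mm
    window_used: Tuple[float, float]
    fit_r2: float
    n_points: int


def detect_edge(frame: np.ndarray, meta: dict, threshold: float = 0.2) -> np.ndarray:
    """Sub-pixel anterior-surface curve from one rasterised frame.

    Per column: locate the brightest pixel, then take the intensity-weighted
    centroid of rows within +-4 pixels of it (values clipped at zero), and
    convert to mm with the recorded pixel geometry.  Columns whose maximum
    falls below ``threshold`` raise :class:`NoEdgeError`.
    """
    n_rows, n_cols = frame.shape
    col_max = frame.max(axis=0)
    if np.all(col_max < threshold):
        raise NoEdgeError("no column exceeds the intensity threshold")
    if np.any(col_max < threshold):
        raise NoEdgeError(
            f"{int(np.sum(col_max < threshold))} columns below threshold"
        )
    peak = frame.argmax(axis=0)
    rows = np.arange(n_rows)
    curve_px = np.empty(n_cols)
    for j in range(n_cols):
        lo = max(0, peak[j] - 4)
        hi = min(n_rows, peak[j] + 5)
        w = np.clip(frame[lo:hi, j], 0.0, None)
        curve_px[j] = np.sum(rows[lo:hi] * w) / np.sum(w)
    return meta["y0_mm"] + curve_px * meta["mm_per_px"]


def correct_whole_eye_motion(
    exam: Examination, x_periph: float = 3.5
) -> ApexTrace:
    """Remove rigid whole-eye displacement estimated from the periphery.

    The eye-motion series is the mean elevation change (relative to frame 0)
    over the peripheral zones |x| >= ``x_periph``, where the cornea is
    assumed undeformed by the puff; the apex deformation is the apex
    elevation change minus that series.
    """
    periph = np.abs(exam.x_grid) >= x_periph
    if not periph.any():
        raise ValueError(
            f"no x_grid samples with |x| >= {x_periph} mm; widen the chord "
            "or lower x_periph"
        )
    j_apex = int(np.argmin(np.abs(exam.x_grid)))
    raw_apex = exam.surface[:, j_apex]
    eye = (exam.surface[:, periph] - exam.surface[0, periph]).mean(axis=1)
    deformation = raw_apex - raw_apex[0] - eye
    return ApexTrace(
        time=exam.time_grid,
        raw_apex=raw_apex,
        eye_motion=eye,
        deformation=deformation,
    )


def _central_curvature(exam: Examination, halfwidth: float) -> np.ndarray:
    """Best-fit quadratic curvature (2a) of y(x, t) over |x| <= halfwidth."""
    mask = np.abs(exam.x_grid) <= halfwidth
    if mask.sum() < 3:
        raise ValueError("central fitting zone holds fewer than 3 columns")
    xc = exam.x_grid[mask]
    design = np.column_stack([np.ones_like(xc), xc, xc**2])
    pinv = np.linalg.pinv(design)  # (3, n_c); applies to every frame at once
    coefs = exam.surface[:, mask] @ pinv.T
    return 2.0 * coefs[:, 2]


def _interp_at(t: np.ndarray, series: np.ndarray, t_query: float) -> float:
    return float(np.interp(t_query, t, series))


def detect_events(
    trace: ApexTrace,
    exam: Examination,
    bIOP: Optional[float] = None,
    airpuff: Optional[AirPuffConfig] = None,
    central_halfwidth: float = 1.0,
) -> DCRParameters:
    """Applanation / highest-concavity events and the derived DCR metrics.

    A1T and A2T are the first and last linear-interpolated zero crossings of
    the central-zone curvature (loading and recovery applanation); A1V/A2V
    are the central-difference deformation velocities evaluated at those
    instants (A1V > 0, A2V < 0 by the inward/outward sign convention);
    HCT/DA mark the deformation maximum; PD is the lateral distance between
    the two surface crests flanking the apex at the HCT frame.  SPA1 (the
    stiffness parameter at first applanation) is computed when both the
    pulse model and bIOP are supplied.
    """
    flags: Set[str] = set()
    t = trace.time
    d = trace.deformation
    i_max = int(np.argmax(d))
    if i_max == 0 or i_max == len(d) - 1:
        raise NoConcavityError("deformation is monotonic over the record")

    kappa = _central_curvature(exam, central_halfwidth)
    sign_change = np.nonzero(np.diff(np.signbit(kappa)))[0]
    if sign_change.size == 0:
        raise NotApplanatedError("central curvature never crosses zero")

    def crossing_time(i: int) -> float:
        frac = kappa[i] / (kappa[i] - kappa[i + 1])
        return float(t[i] + frac * (t[i + 1] - t[i]))

    loading_idx = [i for i in sign_change if i < i_max]
    recovery_idx = [i for i in sign_change if i >= i_max]
    if not loading_idx or not recovery_idx:
        raise NotApplanatedError(
            "curvature does not cross zero in both loading and recovery"
        )
    a1t = crossing_time(loading_idx[0])
    a2t = crossing_time(recovery_idx[-1])

    velocity = np.gradient(d, t)
    a1v = _interp_at(t, velocity, a1t)
    a2v = _interp_at(t, velocity, a2t)
    if a1v <= 0:
        flags.add("a1v_nonpositive")
    if a2v >= 0:
        flags.add("a2v_nonnegative")

    hct = float(t[i_max])
    da = float(d[i_max])
    pd_mm = _peak_distance(exam, i_max, flags)

    spa1 = None
    if bIOP is not None and airpuff is not None:
        defl_a1 = _interp_at(t, d, a1t)
        if defl_a1 > 0:
            p_a1_mmhg = float(kpa_to_mmhg(pressure_at(airpuff, a1t)))
            spa1 = (p_a1_mmhg - bIOP) / defl_a1
        else:
            flags.add("spa1_undefined")

    return DCRParameters(
        A1T=a1t, A1V=a1v, A2T=a2t, A2V=a2v, HCT=hct, DA=da, PD=pd_mm,
        SPA1=spa1, quality_flags=flags,
    )


def _peak_distance(exam: Examination, i_hc: int, flags: Set[str]) -> float:
    """Distance between the two surface crests at the highest-concavity frame.

    In the elevation convention used here (deformation positive), the crests
    pointing toward the instrument are local minima of y(x).  Ties are
    broken toward larger |x|.
    """
    y = exam.surface[i_hc]
    x = exam.x_grid
    j_apex = int(np.argmin(np.abs(x)))
    interior = np.arange(1, len(y) - 1)
    is_min = (y[interior] < y[interior - 1]) & (y[interior] <= y[interior + 1])
    mins = interior[is_min]
    left = mins[mins < j_apex]
    right = mins[mins > j_apex]
    if left.size == 0 or right.size == 0:
        flags.add("no_crest")
        return float("nan")
    j_left = left[np.argmin(y[left])]
    j_right = right[np.argmin(y[right])]
    # tie toward larger |x|
    tie_l = left[np.isclose(y[left], y[j_left])]
    tie_r = right[np.isclose(y[right], y[j_right])]
    j_left = tie_l[np.argmax(np.abs(x[tie_l]))]
    j_right = tie_r[np.argmax(np.abs(x[tie_r]))]
    return float(x[j_right] - x[j_left])


def force_displacement(
    trace: ApexTrace, airpuff: AirPuffConfig
) -> ForceDisplacementCurve:
    """Pair the deformation samples with the apex force on the same grid."""
    if trace.time[-1] > airpuff.duration + 1e-9 or trace.time[0] < -1e-9:
        raise ValueError("trace time grid is not aligned with the pulse window")
    f = apex_force(airpuff, trace.time)
    i_max = int(np.argmax(trace.deformation))
    loading = np.arange(len(trace.time)) <= i_max
    return ForceDisplacementCurve(
        delta=trace.deformation.copy(), force=np.asarray(f), loading=loading
    )


def stiffness_slope(
    curve: ForceDisplacementCurve,
    window: Tuple[float, float] = (0.2, 0.4),
) -> StiffnessResult:
    """OLS slope of force on displacement over the loading-phase window.

    The air-puff force / apex displacement relation is approximately linear
    for displacements between 0.2 and 0.4 mm during loading; the fitted
    slope S_TSC (mN/mm) is the stiffness entering the shell relation.
    """
    lo, hi = window
    mask = curve.loading & (curve.delta >= lo) & (curve.delta <= hi)
    n = int(mask.sum())
    if n < 3:
        raise InsufficientWindowError(
            f"only {n} loading samples with displacement in [{lo}, {hi}] mm"
        )
    fit = sps.linregress(curve.delta[mask], curve.force[mask])
    return StiffnessResult(
        S_TSC=float(fit.slope),
        window_used=(lo, hi),
        fit_r2=float(fit.rvalue**2),
        n_points=n,
    )


def effective_puff_radius(
    exam: Examination,
    a1t: float,
    flat_depth_tol: float = 0.008,
    smooth_window: int = 5,
    default_rp: float = 1.25,
    min_rp: float = 0.5,
) -> Tuple[float, bool]:
    """Half-width of the flattened central zone at first applanation, mm.

    At the frame nearest A1T the surface is lightly smoothed
    (Savitzky-Golay, quadratic) and the flattened zone is the contiguous
    run around the apex whose elevation stays within ``flat_depth_tol`` mm
    of the apex elevation; the puff radius is half the width of that run.
    The depth criterion is far more noise-robust than a pointwise curvature
    threshold (2 um elevation noise would dominate a per-column second
    derivative).  An undeformed arc always has a small in-tolerance zone
    (~sqrt(2 R tol)), so zones narrower than ``min_rp`` are treated as "no
    flattening found".  Returns ``(rp, fell_back)``; on fallback the
    configured default is returned with ``fell_back=True``.
    """
    from scipy.signal import savgol_filter

    i = int(np.argmin(np.abs(exam.time_grid - a1t)))
    x = exam.x_grid
    y = exam.surface[i]
    if smooth_window > 2 and len(y) > smooth_window:
        y = savgol_filter(y, smooth_window, 2)
    j_apex = int(np.argmin(np.abs(x)))
    flat = np.abs(y - y[j_apex]) < flat_depth_tol
    if not flat[j_apex]:
        return default_rp, True
    hi = j_apex
    while hi + 1 < len(x) and flat[hi + 1]:
        hi += 1
    lo = j_apex
    while lo - 1 >= 0 and flat[lo - 1]:
        lo -= 1
    rp = 0.5 * float(x[hi] - x[lo])
    if rp < min_rp:
        return default_rp, True
    return rp, False


def extract_subject(
    exam: Examination,
    airpuff: AirPuffConfig,
    bIOP: Optional[float] = None,
    x_periph: float = 3.5,
    window: Tuple[float, float] = (0.2, 0.4),
):
    """Convenience: trace -> events -> slope for one examination.

    Returns ``(trace, params, stiffness)``; any stage error propagates with
    the examination's subject id attached.
    """
    try:
        trace = correct_whole_eye_motion(exam, x_periph=x_periph)
        params = detect_events(trace, exam, bIOP=bIOP, airpuff=airpuff)
        curve = force_displacement(trace, airpuff)
        stiff = stiffness_slope(curve, window=window)
    except ValueError as err:
        raise type(err)(f"[{exam.subject_id}] {err}") from err
    return trace, params, stiff
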