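"""Shallow-spherical-shell mechanics: from apex stiffness to elastic modulus.

The cornea under a central air puff is modelled as a thin shallow spherical
shell (Reissner theory).  Measuring the slope ``dF/d(delta)`` of the
apex-force / apex-displacement curve in its linear window yields the elastic
modulus through

    E = (dF/d delta) * (R - t/2) * sqrt(12 (1 - nu^2)) / (pi t (1 - c1 mu^2))

with the dimensionless shell parameter

    mu = rp * [ 12 (1 - nu^2) / ((R - t/2)^2 t^2) ]^(1/4)

where ``R`` is the central anterior curvature radius, ``t`` the central
thickness, ``nu`` Poisson's ratio (0.49 for the nearly incompressible
cornea) and ``rp`` the effective puff radius.  ``mu`` is the load radius
measured in units of the shell's bending-membrane decay length; the factor
``1 - c1 mu^2`` corrects the point-load relation for the finite footprint of
the air jet.

The correction coefficient is derived here from the classical equivalence of
the linear shallow spherical shell with a flat plate on a Winkler foundation
of modulus ``E t / R^2``.  For a uniform pressure over a disc of
dimensionless radius ``mu`` the centre deflection has the closed form
``w(0) = (p/k) (1 + mu * ker'(mu))`` (Kelvin function ``ker``), giving a
normalised apex stiffness

    S(mu) = (pi mu^2 / 8) / (1 + mu * ker'(mu)),   S(0) = 1,

and ``c1(mu) = (1 - S(mu)) / mu^2`` so that ``1 - c1 mu^2 == S(mu)``
exactly.  ``S > 1`` (a spread load deflects the apex less than a point load
of equal resultant), hence ``c1 < 0``; it varies logarithmically at small
``mu`` and is clamped below ``mu = 1e-5``, where the correction factor is 1
to machine precision anyway.  :func:`disc_load_stiffness_fd` provides an
independent finite-difference solution of the same bending problem for
validation.

Unit convention, fixed in :func:`_modulus_kpa` only: slope in mN/mm and
lengths in mm make the right-hand side numerically a kPa-scale modulus;
``E`` is reported in MPa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import special

__all__ = [
    "CorneaGeometry",
    "ElasticResult",
    "InvalidRegimeError",
    "compute_mu",
    "stiffness_ratio",
    "compute_c1",
    "elastic_modulus",
    "forward_stiffness",
    "disc_load_stiffness_fd",
    "MU_VALIDITY_MAX",
]

#: shallow-shell validity band; larger mu raises a quality flag, not an error
MU_VALIDITY_MAX = 5.0

#: below this mu the exact c1 is evaluated at the floor (log-divergent
#: coefficient, but 1 - c1*mu^2 -> 1 regardless)
_MU_FLOOR = 1e-5


class InvalidRegimeError(ValueError):
    """The shell correction factor 1 - c1*mu^2 is not positive."""


@dataclass(frozen=True)
class CorneaGeometry:
    """Central corneal geometry entering the shell relation.

    R : central anterior curvature radius, mm (healthy ~7.75, keratoconic
    corneas are steeper); t : central corneal thickness (CCT), mm; nu :
    Poisson ratio, dimensionless (default 0.49, near incompressible).
    """

    R: float
    t: float
    nu: float = 0.49

    def __post_init__(self) -> None:
        if not 4.0 <= self.R <= 10.0:
            raise ValueError(f"R={self.R} mm outside sanity bounds [4, 10]")
        if not 0.3 <= self.t <= 0.7:
            raise ValueError(f"t={self.t} mm outside sanity bounds [0.3, 0.7]")
        if not 0.0 < self.nu < 0.5:
            raise ValueError(f"nu={self.nu} outside (0, 0.5)")
        if self.t >= self.R:
            raise ValueError("shell assumption requires t < R")

    @property
    def mid_radius(self) -> float:
        """Mid-surface radius R - t/2, mm."""
        return self.R - self.t / 2.0


@dataclass(frozen=True)
class ElasticResult:
    """Elastic modulus with every intermediate needed for audit."""

    E: float  # MPa
    mu: float
    c1: float
    slope_used: float  # mN/mm
    geometry_echo: CorneaGeometry
    rp_used: float  # mm
    flags: frozenset = field(default_factory=frozenset)

    def to_dict(self) -> dict:
        return {
            "E_mpa": self.E,
            "mu": self.mu,
            "c1": self.c1,
            "slope_mn_per_mm": self.slope_used,
            "R_mm": self.geometry_echo.R,
            "t_mm": self.geometry_echo.t,
            "nu": self.geometry_echo.nu,
            "rp_mm": self.rp_used,
            "flags": ",".join(sorted(self.flags)),
        }


def compute_mu(geometry: CorneaGeometry, rp: float) -> float:
    """Dimensionless shell parameter mu (linear in rp; mu(rp=0) = 0)."""
    if rp < 0:
        raise ValueError("rp must be non-negative")
    if geometry.t >= 2.0 * geometry.R:
        raise ValueError("degenerate geometry: t >= 2R")
    lam4 = 12.0 * (1.0 - geometry.nu**2) / (
        geometry.mid_radius**2 * geometry.t**2
    )
    return rp * lam4**0.25


def stiffness_ratio(mu: float) -> float:
    """Normalised apex stiffness S(mu) of the uniform disc load.

    Ratio of the disc-load apex stiffness to the point-load stiffness of the
    same resultant force, from the Kelvin-function closed form.  S(0) = 1 and
    S increases monotonically with mu.
    """
    if mu < 0:
        raise ValueError("mu must be non-negative")
    if mu < _MU_FLOOR:
        return 1.0
    denom = 1.0 + mu * special.kerp(mu)
    return float(np.pi * mu**2 / 8.0 / denom)


def compute_c1(
    geometry: CorneaGeometry,
    rp: float,
    c1_override: Optional[Callable[[float], float]] = None,
) -> float:
    """Correction coefficient c1 such that 1 - c1*mu^2 = S(mu).

    ``c1_override``, if given, is called with mu and must return c1; this is
    the hook for substituting an alternative shell solution.
    """
    mu = compute_mu(geometry, rp)
    if c1_override is not None:
        return float(c1_override(mu))
    mu_c = max(mu, _MU_FLOOR)
    return (1.0 - stiffness_ratio(mu_c)) / mu_c**2


def _modulus_kpa(
    slope: float, geometry: CorneaGeometry, mu: float, c1: float
) -> float:
    """The single place the term grouping and unit convention live.

    slope mN/mm, lengths mm; the returned value is read as kPa.  Swap this
    function to adopt a different reading of the shell relation.
    """
    factor = 1.0 - c1 * mu**2
    if factor <= 0.0:
        raise InvalidRegimeError(
            f"correction factor 1 - c1*mu^2 = {factor:.4g} is not positive"
        )
    num = slope * geometry.mid_radius * np.sqrt(12.0 * (1.0 - geometry.nu**2))
    return num / (np.pi * geometry.t * factor)


def elastic_modulus(
    slope: float,
    geometry: CorneaGeometry,
    rp: float,
    c1_override: Optional[Callable[[float], float]] = None,
) -> ElasticResult:
    """Elastic modulus E (MPa) from the force-displacement slope (mN/mm).

    E is exactly linear in ``slope`` at fixed geometry.  Raises
    ``ValueError`` for a negative slope and :class:`InvalidRegimeError` if
    the correction factor is non-positive.  A ``mu_out_of_band`` flag is set
    when mu exceeds the shallow-shell validity band.
    """
    if slope < 0:
        raise ValueError("slope must be non-negative")
    mu = compute_mu(geometry, rp)
    c1 = compute_c1(geometry, rp, c1_override)
    e_kpa = _modulus_kpa(slope, geometry, mu, c1)
    flags = set()
    if mu > MU_VALIDITY_MAX:
        flags.add("mu_out_of_band")
    return ElasticResult(
        E=e_kpa / 1000.0,
        mu=mu,
        c1=c1,
        slope_used=slope,
        geometry_echo=geometry,
        rp_used=rp,
        flags=frozenset(flags),
    )


def forward_stiffness(
    E: float,
    geometry: CorneaGeometry,
    rp: float,
    c1_override: Optional[Callable[[float], float]] = None,
) -> float:
    """Algebraic inverse of :func:`elastic_modulus`: slope (mN/mm) from E (MPa).

    Used by the simulator; the round trip is exact to floating-point
    precision because both directions share the same grouping function.
    """
    if E < 0:
        raise ValueError("E must be non-negative")
    mu = compute_mu(geometry, rp)
    c1 = compute_c1(geometry, rp, c1_override)
    unit = _modulus_kpa(1.0, geometry, mu, c1)  # kPa per (mN/mm)
    return E * 1000.0 / unit


def disc_load_stiffness_fd(
    mu: float, n: int = 3000, domain_factor: float = 25.0
) -> float:
    """Normalised apex stiffness S(mu) by finite differences (validation oracle).

    Solves the axisymmetric bending problem of the shallow-shell-equivalent
    plate on a Winkler foundation, ``D lap^2 w + k w = q``, in units where
    the decay length is 1 (D = k = 1), with a conservative cell-centred
    discretisation of the axisymmetric Laplacian and a clamped far edge.
    The point-load reference applies the unit resultant to the innermost
    cell.  This route shares no code with the Kelvin-function closed form in
    :func:`stiffness_ratio`.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    L = max(domain_factor, 5.0 * mu + 15.0)
    h = L / n
    r = (np.arange(n) + 0.5) * h
    r_out = r + h / 2.0
    r_in = r - h / 2.0
    main = -(r_out + r_in) / (r * h * h)
    lower = r_in[1:] / (r[1:] * h * h)
    upper = r_out[:-1] / (r[:-1] * h * h)
    lap = sp.diags([lower, main, upper], [-1, 0, 1], format="csc")
    K = (lap @ lap + sp.identity(n, format="csc")).tocsc()
    lu = spla.splu(K)

    def apex(w: np.ndarray) -> float:
        # even-function quadratic extrapolation from the first three cells
        M = np.column_stack([np.ones(3), r[:3] ** 2])
        coef, *_ = np.linalg.lstsq(M, w[:3], rcond=None)
        return float(coef[0])

    # uniform unit pressure over the disc; the boundary cell is loaded by
    # its area fraction inside the disc so the resultant is O(h^2) accurate
    inner = np.clip(r - h / 2.0, 0.0, None)
    outer = r + h / 2.0
    covered = np.clip(np.minimum(mu, outer) ** 2 - inner**2, 0.0, None)
    q_disc = covered / (outer**2 - inner**2)
    resultant = float(2.0 * np.pi * np.sum(q_disc * r) * h)
    w_disc = apex(lu.solve(q_disc))
    # unit point resultant spread over the innermost annulus cell
    q_point = np.zeros(n)
    q_point[0] = 1.0 / (2.0 * np.pi * r[0] * h)
    w_point = apex(lu.solve(q_point))
    return float(resultant / w_disc * w_point)
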