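"""Axisymmetric tensed-membrane sessile-drop model of the yolk puddle.

A yolk separated from the egg and rested on a flat rigid plate spreads into a
puddle whose shape is set by the balance between gravity (driving spreading)
and the isotropic tension of the vitelline membrane (VM) that wraps it.  The
model treats the membrane as a structureless interface under uniform tension
``gamma`` (N/m) — no bending stiffness, no strain dependence — enclosing a
uniform liquid of density ``rho``.  Mechanical equilibrium is the
Young–Laplace balance along the meridian::

    gamma * (kappa_1 + kappa_2) = p0 - rho * g * z

with hydrostatic interior pressure and an apex overpressure ``p0``.  Because
the membrane wraps the yolk completely and the plate is non-adhesive, the
contact angle is ``pi``: the meridian meets the plate tangentially.

The single dimensionless control parameter is the Bond number::

    Bo = rho * g * V**(2/3) / gamma

small ``Bo`` giving a near-sphere (yolk index -> 1) and large ``Bo`` a
gravity-flattened pancake of height ``2*sqrt(gamma/(rho*g))``.  The *yolk
index* (puddle height / maximum diameter) is the shape observable used
throughout; it is strictly increasing in ``gamma`` at fixed volume, so the
forward model can be inverted for tension by bracketed root finding.

Numerics
--------
All computation is nondimensionalized by ``V**(1/3)`` (lengths) and
``gamma / V**(1/3)`` (pressures).  The meridian is solved as a two-point
boundary-value problem in normalized arc length with ``scipy``'s collocation
solver, with the apex overpressure and total arc length as free parameters
and the enclosed volume imposed as a boundary condition.  Solutions are
reached by continuation along a fixed ladder of Bond numbers starting from
the near-spherical regime, which makes every solve a pure function of
``(Bo, rtol)`` regardless of call history.

Above ``Bo ~ 1.5e3`` the flat film across the puddle interior makes the apex
overpressure numerically indistinguishable from zero in double precision
(its admissible window shrinks like ``exp(-sqrt(Bo))``), so the profile is
built instead from the exact planar-puddle edge solution — first integral
``1 - cos(phi) = u**2 / (2 * lambda**2)`` — wrapped around a flat top, with
the puddle radius chosen so the enclosed volume is exact.  The two branches
agree to better than 1% where they meet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad, solve_bvp
from scipy.optimize import brentq

from .errors import (
    BondNumberError,
    BracketError,
    DegenerateProfileError,
    ShapeSolverError,
)

__all__ = [
    "MembraneDropParams",
    "DropProfile",
    "solve_drop_shape",
    "yolk_index",
    "invert_tension",
    "tension_ratio",
    "BO_MIN",
    "BO_MAX",
]

#: supported Bond-number range of the forward solver
BO_MIN = 1e-3
BO_MAX = 1e4

#: switch from collocation to the asymptotic pancake construction
_BO_PANCAKE = 1.5e3

#: continuation ladder resolution (decades per step)
_LADDER_STEP = 0.125

STANDARD_GRAVITY = 9.8  # m/s^2


@dataclass(frozen=True)
class MembraneDropParams:
    """Physical parameters of one puddle problem (SI units).

    Parameters
    ----------
    tension : float
        Membrane tension gamma, N/m.
    density : float
        Density of the enclosed fluid, kg/m^3.  The exterior is massless.
    volume : float
        Enclosed volume, m^3.
    gravity : float
        Gravitational acceleration, m/s^2.
    """

    tension: float
    density: float
    volume: float
    gravity: float = STANDARD_GRAVITY

    def __post_init__(self):
        for name in ("tension", "density", "volume", "gravity"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")

    @classmethod
    def from_lab(cls, tension, volume_ml, density_g_per_cm3, gravity=STANDARD_GRAVITY):
        """Build from bench units (mL, g/cm^3); tension stays in N/m."""
        return cls(
            tension=tension,
            density=density_g_per_cm3 * 1e3,
            volume=volume_ml * 1e-6,
            gravity=gravity,
        )

    @property
    def capillary_length(self) -> float:
        """sqrt(gamma / (rho g)), m — sets the pancake height 2*lambda."""
        return math.sqrt(self.tension / (self.density * self.gravity))

    @property
    def bond_number(self) -> float:
        """rho g V^(2/3) / gamma, dimensionless."""
        return self.density * self.gravity * self.volume ** (2.0 / 3.0) / self.tension


@dataclass(frozen=True)
class DropProfile:
    """Solved axisymmetric puddle shape (SI units).

    ``meridian`` is an ``(n, 2)`` array of ``(r, z)`` points ordered from the
    apex ``(0, H)`` to the contact circle ``(r_base, 0)``; ``z`` decreases
    strictly along it.  ``diameter`` is the maximum horizontal extent of the
    meridian (what a side photograph measures), which can exceed the contact
    diameter because the membrane tucks under the bulge at contact angle pi.
    """

    meridian: np.ndarray
    height: float
    diameter: float
    base_radius: float
    enclosed_volume: float
    params: MembraneDropParams = field(repr=False)

    @property
    def yolk_index(self) -> float:
        """Height / maximum diameter, the shape observable of the model."""
        return yolk_index(self)

    def meridian_table(self):
        """Meridian as columns ``s_mm, r_mm, z_mm`` (arc length from apex)."""
        import pandas as pd

        r = self.meridian[:, 0]
        z = self.meridian[:, 1]
        ds = np.hypot(np.diff(r), np.diff(z))
        s = np.concatenate([[0.0], np.cumsum(ds)])
        return pd.DataFrame(
            {"s_mm": s * 1e3, "r_mm": r * 1e3, "z_mm": z * 1e3}
        )


# ---------------------------------------------------------------------------
# dimensionless collocation solve (lengths in units of V^(1/3))
# ---------------------------------------------------------------------------

# cache of ladder solutions: {(Bo, tol): bvp solution}
_LADDER_CACHE: dict = {}
_LADDER_CACHE_MAX = 512


def _bvp_rhs_factory(bo):
    def rhs(tau, y, p):
        r, u, phi, vol = y
        p0, arclen = p
        with np.errstate(divide="ignore", invalid="ignore"):
            curv = (p0 + bo * u) - np.sin(phi) / np.maximum(r, 1e-12)
        # L'Hopital at the apex: sin(phi)/r -> dphi/ds, so dphi/ds = p0/2
        curv = np.where(r > 1e-9, curv, p0 / 2.0)
        return arclen * np.vstack(
            [np.cos(phi), np.sin(phi), curv, np.pi * r**2 * np.sin(phi)]
        )

    return rhs


def _bvp_bc(ya, yb, p):
    # apex: r = u = phi = vol = 0 ; contact: phi = pi ; volume = 1
    return np.array([ya[0], ya[1], ya[2], ya[3], yb[2] - np.pi, yb[3] - 1.0])


def _sphere_guess():
    """Near-sphere initial mesh (exact at Bo -> 0)."""
    radius = (3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    tau = np.linspace(0.0, 1.0, 101)
    phi = np.pi * tau
    y = np.vstack(
        [
            radius * np.sin(phi),
            radius * (1.0 - np.cos(phi)),
            phi,
            (2.0 - 3.0 * np.cos(phi) + np.cos(phi) ** 3) / 4.0,
        ]
    )
    return tau, y, [2.0 / radius, np.pi * radius]


def _bvp_solve(bo, guess, tol):
    tau, y, p = guess
    return solve_bvp(
        _bvp_rhs_factory(bo),
        _bvp_bc,
        tau,
        y,
        p=p,
        tol=tol,
        max_nodes=120_000,
        verbose=0,
    )


def _ladder_points(bo):
    """Fixed continuation ladder from Bo = 1 toward ``bo`` (exclusive)."""
    if bo == 1.0:
        return []
    ndec = math.log10(bo)
    nsteps = int(math.floor(abs(ndec) / _LADDER_STEP))
    sign = 1.0 if ndec > 0 else -1.0
    return [10.0 ** (sign * _LADDER_STEP * k) for k in range(1, nsteps + 1)]


def _solve_dimless(bo, tol):
    """Dimensionless meridian at Bond number ``bo``; pure function of inputs.

    Continuation walks a fixed ladder of Bond numbers from 1 to the nearest
    ladder point, then makes one final step to ``bo``.  Ladder solutions are
    cached, so repeated solves (e.g. during inversion) cost one collocation
    call each.
    """
    key = (bo, tol)
    if key in _LADDER_CACHE:
        return _LADDER_CACHE[key]

    sol = _bvp_solve(1.0, _sphere_guess(), tol)
    if sol.status != 0:
        raise ShapeSolverError(
            f"collocation failed at Bo=1: {sol.message}", last_bond_number=1.0
        )
    last = 1.0
    for b in _ladder_points(bo):
        lkey = (b, tol)
        cached = _LADDER_CACHE.get(lkey)
        if cached is not None:
            sol = cached
            last = b
            continue
        sol = _bvp_solve(b, (sol.x, sol.y, sol.p), tol)
        if sol.status != 0:
            raise ShapeSolverError(
                f"continuation stalled at Bo={b:.4g}: {sol.message}",
                last_bond_number=last,
            )
        _cache_put((b, tol), sol)
        last = b
    if bo != last:
        sol = _bvp_solve(bo, (sol.x, sol.y, sol.p), tol)
        if sol.status != 0:
            raise ShapeSolverError(
                f"final step to Bo={bo:.4g} failed: {sol.message}",
                last_bond_number=last,
            )
    _cache_put(key, sol)
    return sol


def _cache_put(key, sol):
    if len(_LADDER_CACHE) >= _LADDER_CACHE_MAX:
        _LADDER_CACHE.pop(next(iter(_LADDER_CACHE)))
    _LADDER_CACHE[key] = sol


def _equator_radius(sol):
    """Maximum meridian radius, refined at the phi = pi/2 crossing."""
    r, _, phi, _ = sol.y
    rmax = float(r.max())
    # refine around the last upward crossing of pi/2 using dense output
    crossings = np.nonzero((phi[:-1] < np.pi / 2) & (phi[1:] >= np.pi / 2))[0]
    if crossings.size:
        i = crossings[-1]
        f = lambda t: sol.sol(t)[2] - np.pi / 2
        a, b = sol.x[i], sol.x[i + 1]
        if f(a) * f(b) < 0:
            tstar = brentq(f, a, b, xtol=1e-14)
            rmax = max(rmax, float(sol.sol(tstar)[0]))
    return rmax


def _profile_from_bvp(sol, params, n_points=801):
    scale = params.volume ** (1.0 / 3.0)
    tau = np.linspace(sol.x[0], sol.x[-1], n_points)
    r, u, phi, vol = sol.sol(tau)
    height = float(sol.y[1][-1])
    rmax = _equator_radius(sol)
    z = np.clip(height - u, 0.0, None)
    meridian = np.column_stack([r, z]) * scale
    meridian[0] = (0.0, height * scale)
    meridian[-1, 1] = 0.0
    return DropProfile(
        meridian=meridian,
        height=height * scale,
        diameter=2.0 * rmax * scale,
        base_radius=float(sol.y[0][-1]) * scale,
        enclosed_volume=float(sol.y[3][-1]) * params.volume,
        params=params,
    )


# ---------------------------------------------------------------------------
# asymptotic pancake branch (Bo > _BO_PANCAKE)
# ---------------------------------------------------------------------------


def _edge_F(t):
    """Antiderivative of cos(t) / (2 sin(t/2)): log(tan(t/4)) + 2 cos(t/2)."""
    return np.log(np.tan(t / 4.0)) + 2.0 * np.cos(t / 2.0)


def _pancake_profile(params, rtol):
    """Flat-top puddle with the exact planar contact-angle-pi edge.

    The planar (translationally invariant) puddle admits the first integral
    ``1 - cos(phi) = u^2 / (2 lam^2)``, i.e. ``u(phi) = 2 lam sin(phi/2)``
    with ``u`` the depth below the flat top and ``lam`` the capillary length.
    The horizontal edge coordinate follows by quadrature.  The puddle radius
    is root-found so the volume of revolution matches exactly; the neglected
    azimuthal curvature is O(lam / R) < 1% in this regime.
    """
    scale = params.volume ** (1.0 / 3.0)
    bo = params.bond_number
    lam = bo ** -0.5  # capillary length in V^(1/3) units
    height = 2.0 * lam

    delta = 1e-4  # truncation of the exponential flat-film tail
    phi_c = 2.0 * math.asin(delta)
    f_ref = _edge_F(np.pi / 2)

    def r_of_phi(phi, r_eq):
        return r_eq + lam * (_edge_F(phi) - f_ref)

    def volume_of(r_eq):
        integrand = lambda t: np.pi * r_of_phi(t, r_eq) ** 2 * lam * np.cos(t / 2.0)
        v, _ = quad(integrand, phi_c, np.pi, limit=200)
        return v

    r0 = math.sqrt(1.0 / (2.0 * np.pi * lam))
    try:
        r_eq = brentq(lambda r: volume_of(r) - 1.0, 0.3 * r0, 3.0 * r0, rtol=1e-13)
    except ValueError as exc:  # pragma: no cover - defensive
        raise ShapeSolverError(
            f"pancake volume bracket failed at Bo={bo:.3g}: {exc}",
            last_bond_number=bo,
        )

    phi = np.concatenate(
        [
            np.geomspace(phi_c, 0.5, 200),
            np.linspace(0.5, np.pi, 400)[1:],
        ]
    )
    r = r_of_phi(phi, r_eq)
    u = 2.0 * lam * np.sin(phi / 2.0)
    meridian = np.column_stack(
        [
            np.concatenate([[0.0], r]),
            np.concatenate([[height], height - u]),
        ]
    )
    meridian[-1, 1] = 0.0
    vol = volume_of(r_eq)
    return DropProfile(
        meridian=meridian * scale,
        height=height * scale,
        diameter=2.0 * r_eq * scale,
        base_radius=float(r[-1]) * scale,
        enclosed_volume=vol * params.volume,
        params=params,
    )


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def solve_drop_shape(params: MembraneDropParams, rtol: float = 1e-6) -> DropProfile:
    """Solve the forward puddle-shape problem.

    Parameters
    ----------
    params : MembraneDropParams
        Physical parameters (SI).
    rtol : float
        Relative tolerance on the enclosed volume, in ``(0, 1e-2]``.

    Returns
    -------
    DropProfile
        Converged shape; ``|enclosed_volume - V| / V <= rtol`` and the
        meridian meets the plate tangentially (contact angle pi).

    Raises
    ------
    BondNumberError
        If the Bond number falls outside ``[BO_MIN, BO_MAX]``.
    ShapeSolverError
        If the collocation continuation fails to converge.
    """
    if not (0.0 < rtol <= 1e-2):
        raise ValueError(f"rtol must be in (0, 1e-2], got {rtol!r}")
    bo = params.bond_number
    if not (BO_MIN <= bo <= BO_MAX):
        raise BondNumberError(bo, BO_MIN, BO_MAX)

    if bo > _BO_PANCAKE:
        profile = _pancake_profile(params, rtol)
        base_pressure_dimless = bo * 2.0 * bo**-0.5  # hydrostatic head over 2*lam
    else:
        tol = min(rtol, 1e-6)
        sol = _solve_dimless(bo, tol)
        profile = _profile_from_bvp(sol, params)
        base_pressure_dimless = sol.p[0] + bo * float(sol.y[1][-1])

    vol_err = abs(profile.enclosed_volume - params.volume) / params.volume
    if vol_err > rtol:
        raise ShapeSolverError(
            f"volume error {vol_err:.2e} exceeds rtol={rtol:.2e} at Bo={bo:.4g}",
            last_bond_number=bo,
        )
    if base_pressure_dimless <= 0:  # pragma: no cover - physics guard
        raise ShapeSolverError(
            f"non-positive base pressure at Bo={bo:.4g}", last_bond_number=bo
        )
    return profile


def yolk_index(profile: DropProfile) -> float:
    """Height divided by maximum diameter of a solved or measured profile."""
    if profile.diameter <= 0:
        raise DegenerateProfileError("profile has zero diameter")
    return profile.height / profile.diameter


def invert_tension(
    observed,
    volume: float,
    density: float,
    bracket=(1e-3, 10.0),
    gravity: float = STANDARD_GRAVITY,
    rtol: float = 1e-6,
) -> float:
    """Estimate membrane tension from an observed puddle shape.

    Parameters
    ----------
    observed : float or (height, diameter) pair
        Either the yolk index directly (in ``(0, 1)``) or a pair of height
        and maximum diameter in consistent length units.
    volume, density : float
        Enclosed volume (m^3) and fluid density (kg/m^3).
    bracket : (float, float)
        Tension bracket in N/m; must span a sign change of
        ``yolk_index(forward(gamma)) - observed``.

    Returns
    -------
    float
        Tension gamma (N/m) whose forward solution reproduces the observed
        yolk index.  Unique within the bracket because the yolk index is
        strictly increasing in gamma.

    Raises
    ------
    BracketError
        If the residual does not change sign across the bracket.
    """
    if np.ndim(observed) == 1 and len(observed) == 2:
        h, d = observed
        if d <= 0:
            raise DegenerateProfileError("observed diameter must be positive")
        target = h / d
    else:
        target = float(observed)
    if not (0.0 < target < 1.0):
        raise ValueError(f"yolk index must lie in (0, 1), got {target!r}")

    lo, hi = bracket
    if not (0.0 < lo < hi):
        raise ValueError(f"invalid bracket {bracket!r}")

    def residual(gamma):
        p = MembraneDropParams(gamma, density, volume, gravity)
        return solve_drop_shape(p, rtol=rtol).yolk_index - target

    f_lo, f_hi = residual(lo), residual(hi)
    if f_lo * f_hi > 0:
        raise BracketError(
            f"no sign change in bracket {bracket!r}: "
            f"residual({lo:g})={f_lo:.4g}, residual({hi:g})={f_hi:.4g}"
        )
    return brentq(residual, lo, hi, rtol=1e-11)


def tension_ratio(
    observed_a,
    observed_b,
    volume: float,
    density: float,
    gravity: float = STANDARD_GRAVITY,
    bracket=(1e-3, 10.0),
) -> float:
    """Ratio of inverted tensions gamma(B) / gamma(A) at shared volume.

    With A the earlier (rounder) observation and B the later (flatter) one,
    this is the fractional tension retained between the two states.
    """
    gamma_a = invert_tension(observed_a, volume, density, bracket, gravity)
    gamma_b = invert_tension(observed_b, volume, density, bracket, gravity)
    return gamma_b / gamma_a
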