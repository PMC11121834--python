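"""Geometric model behind the simplified right-ventricular volume formula.

The right-ventricular cavity is idealized as a *truncated cone minus a
truncated rhomboid pyramid*: at the tricuspid (basal) plane the cross-section
is a disc with a rhombic "bite" taken out of it (the interventricular septum
bulging into the RV), and every cross-section further toward the apex is the
same figure scaled down linearly.  The volume of such a solid is

    V = k * D**2 * L

where ``D`` is the basal cavity diameter measured along the four-chamber
line, ``L`` the baso-apical length, and ``k`` a dimensionless coefficient
fixed by the proportions of the solid.  The clinically used coefficient is
``k = 1.21`` (the cone-pyramid formula, CPF); :func:`calibrate_shape`
recovers a member of the shape family that reproduces any reachable target
coefficient exactly.

Construction (all lengths in cm, volumes in mL = cm**3):

* axis along z, base plane z = 0, apex plane z = L;
* linear taper ``s(z) = 1 - (1 - alpha) * z / L`` applied about the origin,
  so the apex cross-section is the base scaled by ``alpha``;
* base cross-section: disc of radius ``beta * D / 2`` (``beta = 1 + p0``)
  centred at the origin, minus a rhombus with diagonals ``p0 * D`` (along x)
  and ``q0 * D`` (along y) whose +x vertex touches the circle.  The cavity
  chord along the +x axis then has length exactly ``D`` — this is the
  "four-chamber" basal diameter, independent of ``p0`` and ``q0``;
* closed-form coefficient
  ``k = (1 + alpha + alpha**2) * (pi * beta**2 / 12 - p0 * q0 / 6)``.

An optional outflow-tract (RVOT) appendage — a half-cylinder patch attached
on the +y side of the base over ``z in [0, h_frac * L]`` — adds a prescribed
fraction ``f`` of the *total* volume while staying off the four-chamber
measurement line, so linear measurements are blind to it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "CPF_K",
    "DEFAULT_ALPHA",
    "DEFAULT_Q0",
    "ShapeParams",
    "RVOTSpec",
    "PhantomGeometry",
    "MonteCarloVolume",
    "shape_coefficient",
    "calibrate_shape",
    "default_shape",
    "analytic_volume",
    "cross_section_area",
    "contains_point",
    "contains_points",
    "monte_carlo_volume",
    "long_axis_section",
    "geometry_to_record",
    "geometry_from_record",
]

#: Published cone-pyramid coefficient: V = 1.21 * D^2 * L.
CPF_K = 1.21
#: Default apical taper ratio of the calibrated family.
DEFAULT_ALPHA = 0.3
#: Default rhombus short-diagonal fraction of the calibrated family.
DEFAULT_Q0 = 0.9

_P0_BRACKET = (0.0, 3.0)


@dataclass(frozen=True)
class ShapeParams:
    """Dimensionless proportions of the cone-minus-pyramid family.

    Parameters
    ----------
    alpha : float
        Apical taper ratio in (0, 1]: scale factor of the apex cross-section
        relative to the base (1 = prism, small = sharply tapered).
    p0 : float
        Rhombus long diagonal (along the four-chamber x-axis) as a fraction
        of the measured basal diameter ``D``.  ``beta = 1 + p0`` is the
        frustum basal diameter in units of ``D``.
    q0 : float
        Rhombus short diagonal (perpendicular, along y) as a fraction of
        ``D``.  The rhombus must stay inscribed in the basal circle:
        ``1 + q0**2 <= (1 + p0)**2``.
    """

    alpha: float
    p0: float
    q0: float

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.p0 < 0.0:
            raise ValueError(f"p0 must be >= 0, got {self.p0}")
        if self.q0 < 0.0:
            raise ValueError(f"q0 must be >= 0, got {self.q0}")
        if 1.0 + self.q0**2 > (1.0 + self.p0) ** 2 + 1e-12:
            raise ValueError(
                "rhombus not inscribed in the basal circle: requires "
                f"1 + q0^2 <= (1 + p0)^2, got q0={self.q0}, p0={self.p0}"
            )

    @property
    def beta(self) -> float:
        """Frustum basal diameter as a multiple of the measured D."""
        return 1.0 + self.p0


@dataclass(frozen=True)
class RVOTSpec:
    """Outflow-tract appendage: a half-cylinder patch on the +y side.

    ``f`` is the fraction of the *total* cavity volume contributed by the
    appendage (up to ~0.19 in adults); ``h_frac`` its axial extent as a
    fraction of the baso-apical length.  The appendage never intersects the
    y = 0 plane in which the four-chamber measurements are taken.
    """

    f: float
    h_frac: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 <= self.f < 1.0):
            raise ValueError(f"RVOT volume fraction must be in [0, 1), got {self.f}")
        if not (0.0 < self.h_frac <= 1.0):
            raise ValueError(f"RVOT h_frac must be in (0, 1], got {self.h_frac}")


@dataclass(frozen=True)
class PhantomGeometry:
    """One RV phantom instance: shape proportions plus absolute size.

    ``D`` is the basal (four-chamber) cavity diameter in cm, ``L`` the
    baso-apical length in cm.
    """

    shape: ShapeParams
    D: float
    L: float
    rvot: Optional[RVOTSpec] = None

    def __post_init__(self) -> None:
        if self.D <= 0.0:
            raise ValueError(f"D must be > 0, got {self.D}")
        if self.L <= 0.0:
            raise ValueError(f"L must be > 0, got {self.L}")


@dataclass(frozen=True)
class MonteCarloVolume:
    """Monte-Carlo volume estimate with its binomial standard error (mL)."""

    volume: float
    standard_error: float
    n: int
    n_inside: int


def shape_coefficient(shape: ShapeParams) -> float:
    """Closed-form volume coefficient ``k`` with ``V = k * D**2 * L``."""
    return _coefficient(shape.alpha, shape.p0, shape.q0)


def _coefficient(alpha: float, p0: float, q0: float) -> float:
    beta = 1.0 + p0
    return (1.0 + alpha + alpha**2) * (math.pi * beta**2 / 12.0 - p0 * q0 / 6.0)


def calibrate_shape(
    alpha: float = DEFAULT_ALPHA,
    q0: float = DEFAULT_Q0,
    target_k: float = CPF_K,
) -> ShapeParams:
    """Solve for the ``p0`` that gives the target volume coefficient.

    Brackets a root of ``k(p0) - target_k`` in ``p0 in [0, 3]``, solves by
    Brent's method and polishes with Newton steps so the returned shape
    reproduces ``target_k`` to machine precision (the formula-vs-geometry
    comparisons downstream rely on this exactness).

    Raises
    ------
    ValueError
        If no sign change exists in the bracket ("target coefficient
        unreachable for these parameters") or the calibrated shape violates
        the inscription invariant.
    """

    def g(p0: float) -> float:
        return _coefficient(alpha, p0, q0) - target_k

    lo, hi = _P0_BRACKET
    if g(lo) * g(hi) > 0.0:
        raise ValueError(
            f"target coefficient unreachable for these parameters: "
            f"k({lo})={g(lo) + target_k:.4f}, k({hi})={g(hi) + target_k:.4f}, "
            f"target={target_k}"
        )
    p0 = brentq(g, lo, hi, xtol=1e-14, rtol=8.9e-16)
    # Newton polish: k is smooth and monotone in p0 here, a few steps reach eps.
    pref = 1.0 + alpha + alpha**2
    for _ in range(4):
        resid = g(p0)
        deriv = pref * (math.pi * (1.0 + p0) / 6.0 - q0 / 6.0)
        if deriv == 0.0:
            break
        p0 -= resid / deriv
    try:
        shape = ShapeParams(alpha=alpha, p0=p0, q0=q0)
    except ValueError as exc:
        raise ValueError(f"calibrated shape is invalid: {exc}") from exc
    return shape


_DEFAULT_SHAPE: Optional[ShapeParams] = None


def default_shape() -> ShapeParams:
    """The reference family member: alpha=0.3, q0=0.9, p0 calibrated to k=1.21."""
    global _DEFAULT_SHAPE
    if _DEFAULT_SHAPE is None:
        _DEFAULT_SHAPE = calibrate_shape(DEFAULT_ALPHA, DEFAULT_Q0, CPF_K)
    return _DEFAULT_SHAPE


def _body_volume(geom: PhantomGeometry) -> float:
    return shape_coefficient(geom.shape) * geom.D**2 * geom.L


def appendage_volume(geom: PhantomGeometry) -> float:
    """Volume of the RVOT appendage (0 if absent), mL."""
    if geom.rvot is None or geom.rvot.f == 0.0:
        return 0.0
    body = _body_volume(geom)
    return geom.rvot.f / (1.0 - geom.rvot.f) * body


def appendage_radius(geom: PhantomGeometry) -> float:
    """Radius of the half-cylindrical RVOT patch (0 if absent), cm."""
    v_app = appendage_volume(geom)
    if v_app == 0.0:
        return 0.0
    h = geom.rvot.h_frac * geom.L
    return math.sqrt(2.0 * v_app / (math.pi * h))


def analytic_volume(geom: PhantomGeometry) -> float:
    """Exact cavity volume in mL: ``k * D**2 * L`` plus the RVOT appendage.

    The appendage is sized so that it contributes exactly fraction ``f`` of
    the returned total, i.e. total = body / (1 - f).
    """
    return _body_volume(geom) + appendage_volume(geom)


def cross_section_area(geom: PhantomGeometry, z: float) -> float:
    """Cross-section area at axial position ``z`` (cm), in cm**2.

    Zero outside ``[0, L]`` (outside the solid, not an error).  The integral
    of this function over ``[0, L]`` equals :func:`analytic_volume`.
    """
    if z < 0.0 or z > geom.L:
        return 0.0
    sh = geom.shape
    s = 1.0 - (1.0 - sh.alpha) * z / geom.L
    area = s**2 * (math.pi * sh.beta**2 / 4.0 - sh.p0 * sh.q0 / 2.0) * geom.D**2
    if geom.rvot is not None and geom.rvot.f > 0.0 and z <= geom.rvot.h_frac * geom.L:
        r = appendage_radius(geom)
        area += math.pi * r**2 / 2.0
    return area


def contains_points(geom, x, y, z):
    """Vectorized point membership test (closed solid, boundary included).

    Parameters are broadcastable arrays of coordinates in cm; returns a
    boolean array.  A point belongs to the cavity iff it lies in the scaled
    basal disc but not in the (open) scaled rhombus, at ``0 <= z <= L`` — or
    inside the RVOT appendage patch.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    sh = geom.shape
    D, L = geom.D, geom.L

    in_axial = (z >= 0.0) & (z <= L)
    s = 1.0 - (1.0 - sh.alpha) * np.clip(z, 0.0, L) / L  # s >= alpha > 0
    r_disc = s * sh.beta * D / 2.0
    in_disc = x**2 + y**2 <= r_disc**2
    if sh.p0 > 0.0 and sh.q0 > 0.0:
        # rhombus centre sits at x = D/2 (independent of p0), scaled with s
        xc = s * D / 2.0
        half_p = s * sh.p0 * D / 2.0
        half_q = s * sh.q0 * D / 2.0
        in_rhombus = np.abs(x - xc) / half_p + np.abs(y) / half_q < 1.0
    else:
        in_rhombus = np.zeros_like(in_disc, dtype=bool)
    inside = in_axial & in_disc & ~in_rhombus

    if geom.rvot is not None and geom.rvot.f > 0.0:
        r = appendage_radius(geom)
        y0 = sh.beta * D / 2.0
        in_app = (
            (z >= 0.0)
            & (z <= geom.rvot.h_frac * L)
            & (y >= y0)
            & (x**2 + (y - y0) ** 2 <= r**2)
        )
        inside = inside | in_app
    return inside


def contains_point(geom: PhantomGeometry, x: float, y: float, z: float) -> bool:
    """Scalar convenience wrapper around :func:`contains_points`."""
    return bool(contains_points(geom, x, y, z))


def bounding_box(geom: PhantomGeometry):
    """Axis-aligned bounding box ((xlo, xhi), (ylo, yhi), (zlo, zhi)) in cm."""
    R = geom.shape.beta * geom.D / 2.0
    r = appendage_radius(geom)
    xhi = max(R, r)
    yhi = R + r  # appendage tops out at y0 + r = R + r
    return (-xhi, xhi), (-R, yhi), (0.0, geom.L)


def monte_carlo_volume(
    geom: PhantomGeometry,
    n: int = 1_000_000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> MonteCarloVolume:
    """Unbiased Monte-Carlo volume estimate (mL) with its standard error.

    Uniform rejection sampling inside the bounding box; deterministic for a
    fixed ``seed``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if rng is None:
        rng = np.random.default_rng(seed)
    (xlo, xhi), (ylo, yhi), (zlo, zhi) = bounding_box(geom)
    box_vol = (xhi - xlo) * (yhi - ylo) * (zhi - zlo)
    n_inside = 0
    chunk = 2_000_000
    done = 0
    while done < n:
        m = min(chunk, n - done)
        pts = rng.random((3, m))
        xs = xlo + (xhi - xlo) * pts[0]
        ys = ylo + (yhi - ylo) * pts[1]
        zs = zlo + (zhi - zlo) * pts[2]
        n_inside += int(contains_points(geom, xs, ys, zs).sum())
        done += m
    p = n_inside / n
    volume = p * box_vol
    se = box_vol * math.sqrt(max(p * (1.0 - p), 0.0) / n)
    return MonteCarloVolume(volume=volume, standard_error=se, n=n, n_inside=n_inside)


def long_axis_section(geom: PhantomGeometry):
    """Four-chamber (x-z plane) section of the cavity as a trapezoid.

    Returns ``(basal_width, apical_width, height)`` in cm.  By construction
    the basal width equals ``D`` exactly — the rhombus +x vertex touches the
    circle, so the chord (beta - p0) * D = D regardless of p0, q0.
    """
    sh = geom.shape
    basal = (sh.beta - sh.p0) * geom.D
    return basal, sh.alpha * basal, geom.L


def geometry_to_record(geom: PhantomGeometry) -> dict:
    """Flat JSON-compatible record of a phantom geometry."""
    return {
        "alpha": geom.shape.alpha,
        "p0": geom.shape.p0,
        "q0": geom.shape.q0,
        "D_cm": geom.D,
        "L_cm": geom.L,
        "rvot_f": 0.0 if geom.rvot is None else geom.rvot.f,
        "rvot_hfrac": 0.3 if geom.rvot is None else geom.rvot.h_frac,
    }


def geometry_from_record(record: dict) -> PhantomGeometry:
    """Inverse of :func:`geometry_to_record`."""
    rvot_f = float(record.get("rvot_f", 0.0))
    rvot = None
    if rvot_f > 0.0:
        rvot = RVOTSpec(f=rvot_f, h_frac=float(record.get("rvot_hfrac", 0.3)))
    return PhantomGeometry(
        shape=ShapeParams(
            alpha=float(record["alpha"]),
            p0=float(record["p0"]),
            q0=float(record["q0"]),
        ),
        D=float(record["D_cm"]),
        L=float(record["L_cm"]),
        rvot=rvot,
    )
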