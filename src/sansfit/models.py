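"""Scattering models: the dumbbell form factor and the polymer
excluded-volume form factor, plus Guinier and Porod analysis.

The dumbbell geometry is two identical coaxial ellipsoids of revolution
(polar semi-axis ``a`` along the symmetry axis, equatorial semi-axes
``r_eq``), centers a distance ``d`` apart on the axis, pierced by an axial
cylindrical hole of radius ``Rh`` — the solution-scattering envelope of a
hexameric ring protein stack such as KaiC, whose two stacked rings form the
ellipsoid lobes and whose central channel forms the hole.

Two routes to the dumbbell amplitude are provided.  The *closed* route
superposes the closed-form ellipsoid and cylinder amplitudes; it
double-counts any ellipsoid overlap (both reference geometries overlap,
2a > d) and subtracts hole volume even beyond the ellipsoid caps, so it is
an approximation kept for limit checks and speed.  The *numeric* route is
the reference: it integrates the indicator density of the actual
union-minus-hole body,

    F(q, alpha) = 4 pi int_0^zmax int_0^r_eq chi(r, z)
                  J0(q sin(alpha) r) cos(q cos(alpha) z) r dr dz,

where the radial integral is analytic (int J0(k r) r dr = r J1(k r)/k
between the hole radius and the envelope), leaving one smooth z-integral
done by Gauss-Legendre quadrature.  Overlap is counted once and the hole
removes only material actually inside an ellipsoid.

1-D intensities are orientation averages
I(Q) = scale * <|F|^2>(Q) / <|F(0)|^2> + A_up * Q^-p + background,
with the optional additive power law modelling the low-Q clustering upturn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import gamma as _gamma_fn
from scipy.special import gammainc as _gammainc
from scipy.special import j1 as _j1

from . import _kernels
from .curves import ScatteringCurve

__all__ = [
    "ParameterError", "QuadratureError", "DumbbellParams", "PolymerEVParams",
    "sphere_amplitude", "ellipsoid_amplitude", "cylinder_amplitude",
    "dumbbell_amplitude_closed", "dumbbell_amplitude_numeric",
    "orientational_average", "dumbbell_intensity", "polymer_ev_intensity",
    "guinier_fit", "porod_exponent", "compare_shapes",
    "GuinierResult", "ShapeComparison",
]

logger = logging.getLogger(__name__)


class ParameterError(ValueError):
    """Invalid model parameters."""


class QuadratureError(RuntimeError):
    """A quadrature failed its internal self-convergence check."""


# --------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class DumbbellParams:
    """Geometry and intensity parameters of the dumbbell model (lengths in A).

    ``scale`` is I(0) - background (the model curve is normalized to its
    forward value); ``upturn_amplitude``/``upturn_exponent`` define the
    optional additive low-Q power law A_up * Q^-p.
    """

    center_distance: float
    polar_semiaxis: float
    equatorial_semiaxis: float
    hole_radius: float
    scale: float = 1.0
    background: float = 0.0
    upturn_amplitude: float = 0.0
    upturn_exponent: float = 3.0

    def __post_init__(self) -> None:
        if self.center_distance < 0:
            raise ParameterError("center_distance must be >= 0")
        if self.polar_semiaxis <= 0 or self.equatorial_semiaxis <= 0:
            raise ParameterError("semi-axes must be > 0")
        if not 0 <= self.hole_radius < self.equatorial_semiaxis:
            raise ParameterError("need 0 <= hole_radius < equatorial_semiaxis")
        if self.upturn_amplitude < 0:
            raise ParameterError("upturn_amplitude must be >= 0")
        if self.upturn_amplitude > 0 and self.upturn_exponent <= 0:
            raise ParameterError("upturn_exponent must be > 0")

    @property
    def overlapping(self) -> bool:
        """True when the two ellipsoids interpenetrate (2a > d)."""
        return 2 * self.polar_semiaxis > self.center_distance

    @property
    def axial_length(self) -> float:
        """Total extent along the symmetry axis, d + 2a."""
        return self.center_distance + 2 * self.polar_semiaxis

    def volume(self) -> float:
        """Exact volume of the union-minus-hole body, in A^3."""
        d, a, req, rh = (self.center_distance, self.polar_semiaxis,
                         self.equatorial_semiaxis, self.hole_radius)
        s = np.sqrt(max(0.0, 1 - (rh / req) ** 2))
        t0 = max(-s, -d / (2 * a))
        return 2 * np.pi * a * ((req ** 2 - rh ** 2) * (s - t0)
                                - req ** 2 * (s ** 3 - t0 ** 3) / 3)


@dataclass(frozen=True)
class PolymerEVParams:
    """Polymer excluded-volume model parameters.

    ``rg`` is the radius of gyration in nm (converted to A internally);
    ``porod_exponent`` m = 1/nu is the high-Q power-law exponent
    (m = 2 is a Gaussian coil, larger m is more compact; valid 1 < m <= 4).
    """

    rg: float
    porod_exponent: float
    scale: float = 1.0
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.rg <= 0:
            raise ParameterError("rg must be > 0")
        if not 1 < self.porod_exponent <= 4:
            raise ParameterError("need 1 < porod_exponent <= 4")


# --------------------------------------------------------------------------
# amplitudes


def sphere_amplitude(u):
    """Normalized sphere amplitude 3 (sin u - u cos u) / u^3 at u = qR.

    Continuous at u = 0 with value 1 (series 1 - u^2/10 for small u).
    """
    u = np.asarray(u, dtype=float)
    small = np.abs(u) < 1e-4
    us = np.where(small, 1.0, u)
    out = 3.0 * (np.sin(us) - us * np.cos(us)) / us ** 3
    return np.where(small, 1.0 - u * u / 10.0, out)


def ellipsoid_amplitude(q, alpha, polar_semiaxis, equatorial_semiaxis):
    """Amplitude of an ellipsoid of revolution at tilt alpha from the axis.

    Equals the sphere amplitude at the effective radius
    r_eff = sqrt(a^2 cos^2 alpha + r_eq^2 sin^2 alpha).
    """
    if polar_semiaxis <= 0 or equatorial_semiaxis <= 0:
        raise ParameterError("semi-axes must be > 0")
    q = np.asarray(q, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    r_eff = np.sqrt(polar_semiaxis ** 2 * np.cos(alpha) ** 2
                    + equatorial_semiaxis ** 2 * np.sin(alpha) ** 2)
    return sphere_amplitude(q * r_eff)


def _sinc(x):
    x = np.asarray(x, dtype=float)
    xs = np.where(np.abs(x) < 1e-8, 1.0, x)
    return np.where(np.abs(x) < 1e-8, 1.0 - x * x / 6.0, np.sin(xs) / xs)


def cylinder_amplitude(q, alpha, radius, length):
    """Amplitude of a cylinder (radius R, length L) at tilt alpha.

    [sin(qL cos(a)/2) / (qL cos(a)/2)] * [2 J1(qR sin(a)) / (qR sin(a))],
    both factors -> 1 at their 0/0 limits.
    """
    if radius <= 0 or length <= 0:
        raise ParameterError("radius and length must be > 0")
    q = np.asarray(q, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    ax = 0.5 * q * length * np.cos(alpha)
    rad = q * radius * np.sin(alpha)
    rs = np.where(np.abs(rad) < 1e-8, 1.0, rad)
    radial = np.where(np.abs(rad) < 1e-8, 1.0 - rad * rad / 8.0,
                      2.0 * _j1(rs) / rs)
    return _sinc(ax) * radial


def dumbbell_amplitude_closed(q, alpha, params: DumbbellParams):
    """Closed-form dumbbell amplitude (A^3): superposed ellipsoids minus hole.

    F = V_e A_ell(q, alpha) 2 cos(q d cos(alpha) / 2) - V_c A_cyl(q, alpha)
    with the hole as a full-length cylinder (L = d + 2a).  This
    approximation double-counts ellipsoid overlap and over-subtracts hole
    volume outside the caps; the numeric route is the reference.
    """
    d = params.center_distance
    a = params.polar_semiaxis
    req = params.equatorial_semiaxis
    rh = params.hole_radius
    q = np.asarray(q, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    ve = 4.0 / 3.0 * np.pi * a * req ** 2
    ltot = d + 2 * a
    pair = ve * ellipsoid_amplitude(q, alpha, a, req) \
        * 2.0 * np.cos(0.5 * q * d * np.cos(alpha))
    if rh == 0:
        return pair
    vc = np.pi * rh ** 2 * ltot
    return pair - vc * cylinder_amplitude(q, alpha, rh, ltot)


def _numeric_amplitude_raw(q, alpha, params: DumbbellParams, n_z: int):
    """Vectorized (broadcasting q, alpha) indicator-density amplitude."""
    d = params.center_distance
    a = params.polar_semiaxis
    req = params.equatorial_semiaxis
    rh = params.hole_radius
    q = np.asarray(q, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    qs = q * np.sin(alpha)
    qc = q * np.cos(alpha)
    s = np.sqrt(max(0.0, 1 - (rh / req) ** 2))
    zlo = max(0.0, d / 2 - a * s)
    zhi = d / 2 + a * s
    x, w = leggauss(n_z)
    z = 0.5 * (zhi - zlo) * x + 0.5 * (zhi + zlo)
    wz = 0.5 * (zhi - zlo) * w
    t = (z - d / 2) / a
    rmax = req * np.sqrt(np.maximum(0.0, 1 - t * t))
    qs_ = qs[..., None]
    qc_ = qc[..., None]
    small = np.abs(qs_) < 1e-9
    qss = np.where(small, 1.0, qs_)
    inner = (rmax * _j1(qs_ * rmax) - rh * _j1(qs_ * rh)) / qss
    inner = np.where(small, 0.5 * (rmax ** 2 - rh ** 2), inner)
    return 4 * np.pi * np.sum(np.cos(qc_ * z) * inner * wz, axis=-1)


def dumbbell_amplitude_numeric(q, alpha, params: DumbbellParams,
                               n_z: int = 64, check: bool = False,
                               rtol: float = 1e-6):
    """Reference dumbbell amplitude (A^3) of the union-minus-hole body.

    Exact in the radial direction; Gauss-Legendre with ``n_z`` nodes in z.
    With ``check=True`` the result is compared against a doubled grid and a
    :class:`QuadratureError` is raised if the relative change (against the
    largest amplitude) exceeds ``rtol``.
    """
    F = _numeric_amplitude_raw(q, alpha, params, n_z)
    if check:
        F2 = _numeric_amplitude_raw(q, alpha, params, 2 * n_z)
        scale = np.max(np.abs(F2))
        if np.max(np.abs(F - F2)) > rtol * scale:
            raise QuadratureError(
                f"z-quadrature with {n_z} nodes not converged "
                f"(max change {np.max(np.abs(F - F2)) / scale:.2e})")
    return F


# --------------------------------------------------------------------------
# orientational averaging and 1-D intensities


def _alpha_nodes(n_nodes: int):
    x, w = leggauss(n_nodes)
    alpha = 0.25 * np.pi * (x + 1.0)
    weight = 0.25 * np.pi * w * np.sin(alpha)
    return alpha, weight


def orientational_average(amplitude_fn, q, n_nodes: int = 76,
                          check: bool = True, rtol: float = 1e-4):
    """<|F|^2>(q) = int_0^{pi/2} |F(q, alpha)|^2 sin(alpha) d(alpha).

    ``amplitude_fn(q, alpha)`` must broadcast over its arguments.
    Gauss-Legendre in alpha; with ``check=True`` a doubled rule must agree
    to ``rtol`` relative or a :class:`QuadratureError` is raised.
    """
    if n_nodes < 16:
        raise ValueError("n_nodes must be >= 16")
    q = np.asarray(q, dtype=float)

    def _avg(n):
        alpha, w = _alpha_nodes(n)
        F = amplitude_fn(q[..., None], alpha)
        return np.sum(np.abs(F) ** 2 * w, axis=-1)

    avg = _avg(n_nodes)
    if check:
        ref = _avg(2 * n_nodes)
        denom = np.max(np.abs(ref))
        if np.max(np.abs(avg - ref)) > rtol * denom:
            raise QuadratureError(
                f"orientational average with {n_nodes} nodes not converged")
    return avg


def _msq_amplitude_batch(Q, geom, n_alpha: int, n_z: int) -> np.ndarray:
    """<|F|^2>(Q) for a (P, 4) batch of [d, a, r_eq, Rh] geometries."""
    alpha, w_a = _alpha_nodes(n_alpha)
    gl_x, gl_w = leggauss(n_z)
    out = np.zeros((geom.shape[0], Q.size))
    _kernels.dumbbell_msq_amplitude(
        np.ascontiguousarray(Q, dtype=float), np.sin(alpha), np.cos(alpha),
        w_a, gl_x, gl_w, np.ascontiguousarray(geom, dtype=float), out)
    return out


def dumbbell_intensity(Q, params: DumbbellParams, method: str = "numeric",
                       n_alpha: int = 76, n_z: int = 64) -> ScatteringCurve:
    """1-D dumbbell intensity on a Q grid (1/A).

    I(Q) = scale * <|F|^2>(Q) / <|F(0)|^2> + A_up Q^-p + background, so
    I -> scale + background as Q -> 0 when the upturn is off.  ``method``
    selects the reference numeric amplitude or the closed-form
    approximation (which logs a warning for overlapping ellipsoids).
    """
    Q = np.asarray(Q, dtype=float)
    if method == "numeric":
        msq = _msq_amplitude_batch(
            Q, np.array([[params.center_distance, params.polar_semiaxis,
                          params.equatorial_semiaxis, params.hole_radius]]),
            n_alpha, n_z)[0]
        norm = params.volume() ** 2
    elif method == "closed":
        if params.overlapping:
            logger.warning(
                "closed-form dumbbell amplitude with overlapping ellipsoids "
                "(2a = %.1f > d = %.1f A): overlap is double-counted",
                2 * params.polar_semiaxis, params.center_distance)
        msq = orientational_average(
            lambda q, al: dumbbell_amplitude_closed(q, al, params),
            Q, n_nodes=n_alpha, check=False)
        f0 = dumbbell_amplitude_closed(0.0, 0.0, params)
        norm = float(f0) ** 2
    else:
        raise ValueError(f"unknown method {method!r}")
    I = params.scale * msq / norm + params.background
    if params.upturn_amplitude > 0:
        I = I + params.upturn_amplitude * Q ** (-params.upturn_exponent)
    sigma = np.zeros_like(I)
    return ScatteringCurve(Q, I, sigma, label=f"dumbbell/{method}")


def _polymer_ev_form_factor(Q, rg_A, m) -> np.ndarray:
    """Excluded-volume chain form factor P(Q); P(0) = 1.

    With nu = 1/m and U = Q^2 Rg^2 (2nu+1)(2nu+2)/6,
    P = gamma_l(1/(2nu), U) / (nu U^(1/(2nu)))
      - gamma_l(1/nu, U) / (nu U^(1/nu)),
    gamma_l the lower incomplete gamma function.  Reduces to the Debye
    Gaussian-coil function at m = 2; high-Q asymptote ~ Q^-m.
    ``rg_A`` (in A) and ``m`` broadcast against ``Q``.
    """
    rg_A = np.asarray(rg_A, dtype=float)
    m = np.asarray(m, dtype=float)
    nu = 1.0 / m
    U = np.asarray(Q, dtype=float) ** 2 * rg_A ** 2 \
        * (2 * nu + 1) * (2 * nu + 2) / 6.0
    s1 = m / 2.0
    s2 = m
    small = U < 1e-5
    Us = np.where(small, 1.0, U)
    s1b, s2b = np.broadcast_arrays(s1, Us)[0], np.broadcast_arrays(s2, Us)[0]
    # gamma_l(s, U)/U^s = Gamma(s) * gammainc(s, U) / U^s
    t1 = _gamma_fn(s1b) * _gammainc(s1b, Us) / Us ** s1b
    t2 = _gamma_fn(s2b) * _gammainc(s2b, Us) / Us ** s2b
    P = (t1 - t2) / nu
    # series of gamma_l(s,U)/U^s = sum_k (-U)^k / (k! (s+k)) for tiny U
    ser = (1 / s1 - U / (s1 + 1) + U ** 2 / (2 * (s1 + 2))
           - 1 / s2 + U / (s2 + 1) - U ** 2 / (2 * (s2 + 2))) / nu
    return np.where(small, ser, P)


def polymer_ev_intensity(Q, params: PolymerEVParams) -> ScatteringCurve:
    """1-D polymer excluded-volume intensity, I = scale * P(Q) + background.

    ``params.rg`` is in nm (converted to A against the 1/A Q grid).
    """
    P = _polymer_ev_form_factor(Q, params.rg * 10.0, params.porod_exponent)
    I = params.scale * P + params.background
    return ScatteringCurve(np.asarray(Q, dtype=float), I, np.zeros_like(I),
                           label="polymer_ev")


# --------------------------------------------------------------------------
# model-free analysis


@dataclass(frozen=True)
class GuinierResult:
    rg: float            # A
    i0: float
    window: tuple        # (qmin, qmax) actually used
    n_points: int
    n_iterations: int


def guinier_fit(curve: ScatteringCurve, qrg_max: float = 1.3,
                max_iter: int = 50) -> GuinierResult:
    """Iterated Guinier fit: weighted straight line of ln I vs Q^2.

    The fit window Q * Rg <= ``qrg_max`` is determined self-consistently:
    starting from the lower half of the grid (small windows cannot resolve
    the decay against noise), the window implied by the fitted Rg is
    re-applied until it stabilizes.  Rg = sqrt(-3 * slope).
    """
    Q, I, sig = curve.Q, curve.I, curve.sigma_I
    mask = np.zeros(len(Q), dtype=bool)
    mask[:max(5, len(Q) // 2)] = True
    last = None
    for it in range(1, max_iter + 1):
        if mask.sum() < 5 or np.any(I[mask] <= 0):
            raise RuntimeError(
                "Guinier fit: fewer than 5 usable points in the window")
        x = Q[mask] ** 2
        y = np.log(I[mask])
        s = sig[mask]
        with np.errstate(divide="ignore"):
            w = np.where(s > 0, (I[mask] / np.where(s > 0, s, 1.0)) ** 2, 1.0)
        slope, intercept = np.polyfit(x, y, 1, w=np.sqrt(w))
        if slope >= 0:
            raise RuntimeError("Guinier fit: non-negative slope (no decay)")
        rg = float(np.sqrt(-3.0 * slope))
        new = Q * rg <= qrg_max
        if last is not None and np.array_equal(new, mask):
            return GuinierResult(rg, float(np.exp(intercept)),
                                 (float(Q[mask][0]), float(Q[mask][-1])),
                                 int(mask.sum()), it)
        last = mask
        if new.sum() < 5:
            raise RuntimeError(
                f"Guinier fit: window Q*Rg <= {qrg_max} holds fewer than 5 "
                f"points (Rg = {rg:.1f} A)")
        mask = new
    raise RuntimeError("Guinier fit: window did not stabilize")


def porod_exponent(curve: ScatteringCurve, q_window: tuple) -> float:
    """Negative weighted log-log slope of I(Q) over ``q_window``.

    Intensities in the window must be positive (subtract any flat
    background first).
    """
    sub = curve.window(*q_window)
    if len(sub) < 5:
        raise ValueError("Porod window holds fewer than 5 points")
    if np.any(sub.I <= 0):
        raise ValueError("nonpositive intensities in Porod window; "
                         "subtract the background first")
    x = np.log(sub.Q)
    y = np.log(sub.I)
    s = sub.sigma_I
    w = np.where(s > 0, (sub.I / np.where(s > 0, s, 1.0)), 1.0)
    slope, _ = np.polyfit(x, y, 1, w=w)
    return float(-slope)


@dataclass(frozen=True)
class ShapeComparison:
    """Percent differences (alt relative to ref) for candidate size measures."""

    axial_length_pct: float
    equatorial_pct: float
    volume_pct: float
    rg_pct: float
    rg_ref: float
    rg_alt: float
    rg_se: float

    def as_dict(self) -> dict:
        return {
            "axial_length_pct": self.axial_length_pct,
            "equatorial_pct": self.equatorial_pct,
            "volume_pct": self.volume_pct,
            "rg_pct": self.rg_pct,
            "rg_ref_A": self.rg_ref,
            "rg_alt_A": self.rg_alt,
            "rg_se_A": self.rg_se,
        }


def compare_shapes(params_ref: DumbbellParams, params_alt: DumbbellParams,
                   n_mc: int = 200_000, seed: int = 0) -> ShapeComparison:
    """Shape comparison of two dumbbell geometries.

    Reports percent differences of the candidate size measures — axial
    length d + 2a, equatorial diameter, envelope volume (exact), and
    Monte-Carlo radius of gyration — without privileging any single one as
    "the" size.
    """
    from .oracle import mc_rg

    def pct(ref, alt):
        return 100.0 * (alt - ref) / ref

    rg_ref, se_ref = mc_rg(params_ref, n=n_mc, seed=seed)
    rg_alt, se_alt = mc_rg(params_alt, n=n_mc, seed=seed + 1)
    return ShapeComparison(
        axial_length_pct=pct(params_ref.axial_length, params_alt.axial_length),
        equatorial_pct=pct(params_ref.equatorial_semiaxis,
                           params_alt.equatorial_semiaxis),
        volume_pct=pct(params_ref.volume(), params_alt.volume()),
        rg_pct=pct(rg_ref, rg_alt),
        rg_ref=rg_ref, rg_alt=rg_alt,
        rg_se=float(np.hypot(se_ref, se_alt)),
    )
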