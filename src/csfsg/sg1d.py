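"""One-dimensional standing-gradient model of a microvillar functional unit.

Solutes are pumped across the luminal membrane into the inter-microvillar
channel at an areal flux φ(z); the locally elevated osmolality C(z) > C0
drags water across the membrane (permeability Lp), which accumulates into an
axial velocity u(z) that expels near-isotonic fluid at the channel tip.  At
steady state, with z ∈ [0, l_mv] (base to tip):

    4 φ(z)/(ρ d) + D C'' − C u' − u C' = 0        (solute balance)
    u' = (4 Lp / d) (C − C0)                      (osmotic water entry)

with an impermeable base, C'(0) = 0 and u(0) = 0, and a protected-pool tip
condition.  The tip opens not into well-mixed bulk CSF but into a stagnant
pool of depth ``l_prot`` (CSF shielded between the macroscopic folds of the
choroid plexus) across which the produced flow must carry the solutes by
convection against back-diffusion; balancing the two across the pool gives

    D (1 − exp(u l_prot / D)) C' − u (C − C0) = 0     at z = l_mv.

The package evaluates this in the equivalent regularized form
C − C0 + l_prot·g(x)·C' = 0 with x = u l_prot/D and g(x) = expm1(x)/x, which
is smooth in the unknowns, reduces to the Robin form C − C0 + l_prot C' = 0
as u → 0, and to C(l_mv) = C0 exactly at l_prot = 0.

The baseline flux φ0 is not free: assuming all solutes leaving the
ventricles originate in the inter-microvillar spaces, the total solute
injection over the whole choroid plexus equals ρ·Q_meas·C0, so per FU

    φ0 = ρ Q_meas C0 / (N (π d l_mv + π d²/4)).

The π d²/4 term is delivered through a base-compensation boost: because the
1D channel base must be impermeable, the flux that would enter through the
base area is rerouted through the first d/2 of the side wall at a factor
1 + f_b with f_b = 0.5 (the area ratio of base to side over that section).

All transport quantities are CGS (cm, s, g, Osm); geometry inputs arrive in
µm via :class:`~csfsg.geometry.MicrovilliGeometry` and the protected length
and measured production in the printed units (µm, µL/min), converted here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import cumulative_trapezoid, simpson, solve_bvp

from .errors import InvalidParameterError, SolverError
from .geometry import UM_PER_CM, MicrovilliGeometry

#: µL/min per cm³/s
ULMIN_PER_CM3S = 6.0e4

__all__ = [
    "TransportParameters",
    "FluxProfile",
    "NumericsConfig",
    "FUSolution",
    "build_flux_profile",
    "solve_fu",
    "small_peclet_estimate",
    "production_rate",
    "solve_legacy_db",
    "LEGACY_DB_CASE",
]


@dataclass(frozen=True)
class TransportParameters:
    """Physiological inputs of the transport model.

    Attributes
    ----------
    D : float
        Solute (Na+) diffusion coefficient in CSF, cm²/s.
    C0 : float
        Bulk ventricular CSF osmolality, Osm.
    rho : float
        CSF density, g/mL.
    Lp : float
        Luminal membrane water permeability, cm/(s·Osm).
    l_prot : float
        Protected length — depth of the stagnant CSF pool the FU tip opens
        into, µm.
    Q_meas : float
        Measured whole-animal CSF production rate, µL/min; sets the solute
        flux via the mass-closure argument (see module docstring).
    """

    D: float
    C0: float
    rho: float
    Lp: float
    l_prot: float
    Q_meas: float

    def __post_init__(self) -> None:
        for name in ("D", "C0", "rho"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(
                    f"{name} must be > 0, got {getattr(self, name)!r}"
                )
        for name in ("Lp", "l_prot", "Q_meas"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(
                    f"{name} must be >= 0, got {getattr(self, name)!r}"
                )

    @property
    def l_prot_cm(self) -> float:
        return self.l_prot / UM_PER_CM

    @property
    def Q_meas_cm3s(self) -> float:
        return self.Q_meas / ULMIN_PER_CM3S


@dataclass(frozen=True)
class FluxProfile:
    """Piecewise-constant lateral solute flux of one FU.

    φ(z) = phi0 · (1 + boost_factor) for 0 <= z <= boost_extent, phi0 beyond.
    ``boost_extent`` is d/2 unless the FU is stubbier than its own diameter,
    in which case the boost region is clamped to the full length (and phi0
    recomputed so the lateral integral identity still holds exactly);
    ``clamped`` flags such degenerate draws.
    """

    phi0: float  # g·Osm/(s·cm²)
    boost_factor: float  # dimensionless, 0.5
    boost_extent: float  # cm
    clamped: bool = False

    def __call__(self, z: np.ndarray | float) -> np.ndarray | float:
        """Evaluate φ(z) (z in cm)."""
        return np.where(
            np.asarray(z, dtype=float) <= self.boost_extent,
            self.phi0 * (1.0 + self.boost_factor),
            self.phi0,
        )


@dataclass(frozen=True)
class NumericsConfig:
    """Solver knobs for the collocation BVP solve.

    ``mesh_size`` is the uniform part of the initial mesh (extra nodes are
    always inserted at flux breakpoints and inside the boost region);
    ``tol`` is the collocation residual tolerance; ``eps_u`` the tip-Péclet
    magnitude below which expm1(x)/x switches to its series (the degenerate-
    boundary-condition cutoff); ``continuation`` the Lp ramp start fractions
    tried, in order, when the direct solve fails.
    """

    mesh_size: int = 48
    tol: float = 1.0e-8
    max_nodes: int = 20000
    eps_u: float = 1.0e-8
    continuation: tuple[float, ...] = (1.0e-2, 1.0e-4)
    ramp_width: float = 0.02

    def __post_init__(self) -> None:
        if not self.tol > 0:
            raise InvalidParameterError(f"tol must be > 0, got {self.tol!r}")
        if self.mesh_size < 32:
            raise InvalidParameterError(
                f"mesh_size must be >= 32, got {self.mesh_size!r}"
            )


@dataclass(frozen=True)
class FUSolution:
    """Solved concentration/velocity profiles of one FU plus diagnostics.

    ``z`` runs from the FU base (0) to the tip (l_mv), in cm.  ``Q_FU`` is
    the per-FU volumetric outflow u(l_mv)·A_CS in cm³/s; ``Q_SG`` the
    whole-organ standing-gradient production N·Q_FU in µL/min.  Residuals
    are relative: ``solute_residual`` compares the advective+diffusive tip
    outflux with the total lateral solute injection, ``water_residual``
    compares u(l_mv) with the integral of the osmotic water influx.
    """

    z: np.ndarray
    C: np.ndarray
    u: np.ndarray
    Q_FU: float
    Q_SG: float
    solute_residual: float
    water_residual: float
    tip_peclet: float
    status: str
    message: str = ""
    dense: Callable[[np.ndarray], np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def converged(self) -> bool:
        return self.status == "converged"


def build_flux_profile(
    geom: MicrovilliGeometry, params: TransportParameters
) -> FluxProfile:
    """Baseline flux φ0 from the measured production rate (mass closure).

    φ0 = ρ Q_meas C0 / (N (π d l_mv + π d²/4)), with the base-compensation
    boost f_b = 0.5 over the first d/2.  By construction the lateral
    integral identity

        ∫ φ dA = φ0 (π d l_mv + π d²/4) = ρ Q_meas C0 / N

    holds to machine precision; if d/2 >= l_mv the boost region is clamped
    to the full length and φ0 recomputed to preserve the identity.
    """
    d = geom.d_cm
    l = geom.l_mv_cm
    if not geom.N > 0:
        raise InvalidParameterError("geometry has N == 0; no functional units")
    a = d / 2.0
    clamped = a >= l
    if clamped:
        a = l
    denom = math.pi * d * (l + a / 2.0)
    if denom <= 0:
        raise InvalidParameterError("zero lateral area in flux denominator")
    phi0 = params.rho * params.Q_meas_cm3s * params.C0 / (geom.N * denom)
    return FluxProfile(phi0=phi0, boost_factor=0.5, boost_extent=a, clamped=clamped)


# --------------------------------------------------------------------------
# Core nondimensional collocation solve
# --------------------------------------------------------------------------
#
# With zh = z/l, C = C0 + Cs*c, u = Us*v and the scales
#     Cs = 4 φ_ref l² / (ρ d D)      (diffusive concentration scale)
#     Us = 4 Lp Cs l / d             (osmotic velocity scale)
# the system becomes, with β = Us l / D (Péclet of the velocity scale) and
# γ = Cs/C0:
#     c' = s
#     s' = −f(zh) + (β/γ)(1 + γ c) c + β v s
#     v' = c
#     s(0) = 0, v(0) = 0, c(1) + λ g(βλ v(1)) s(1) = 0,   λ = l_prot/l
# where f = φ/φ_ref is the piecewise flux shape and g(x) = expm1(x)/x.


def _g_expm1_over_x(x: float, eps: float) -> float:
    if abs(x) < eps:
        return 1.0 + x / 2.0 + x * x / 6.0
    return math.expm1(x) / x


def _g_prime(x: float, eps: float) -> float:
    # d/dx [expm1(x)/x] = (x e^x − expm1(x)) / x²
    if abs(x) < max(eps, 1.0e-6):
        return 0.5 + x / 3.0 + x * x / 8.0
    return (x * math.exp(x) - math.expm1(x)) / (x * x)


def _flux_knots(
    edges: np.ndarray, values: np.ndarray, width_frac: float
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous (piecewise-linear) flux shape knots for the collocation solve.

    Each step of the piecewise-constant profile is replaced by a linear ramp
    of half-width ``width_frac``·(distance to the nearest break or domain
    edge), centred on the break.  The ramp is symmetric, so the integral of
    the shape — and with it the solute mass-closure identity — is preserved
    exactly; the collocation residual estimator, which assumes a continuous
    right-hand side, then converges under mesh refinement.
    """
    breaks = edges[:-1]
    knots = [0.0]
    fvals = [values[0]]
    bounds = np.concatenate([[0.0], breaks, [1.0]])
    for i, b in enumerate(breaks):
        w = width_frac * min(b - bounds[i], bounds[i + 2] - b)
        knots += [b - w, b + w]
        fvals += [values[i], values[i + 1]]
    knots.append(1.0)
    fvals.append(values[-1])
    return np.asarray(knots), np.asarray(fvals)


def _linear_guess(x: np.ndarray, f, lam: float):
    """Solution of the diffusion-only (small-Péclet) problem, numerically.

    c'' = −f, s(0) = 0, c(1) + λ s(1) = 0; evaluated by quadrature on a fine
    grid and interpolated onto the mesh.  Serves as the Newton starting
    point, from which the mildly nonlinear physiological cases converge in
    one or two iterations.
    """
    xf = np.linspace(0.0, 1.0, 2049)
    F = cumulative_trapezoid(f(xf), xf, initial=0.0)
    G = cumulative_trapezoid(F, xf, initial=0.0)
    c_f = lam * F[-1] + (G[-1] - G)
    v_f = cumulative_trapezoid(c_f, xf, initial=0.0)
    c = np.interp(x, xf, c_f)
    s = -np.interp(x, xf, F)
    v = np.interp(x, xf, v_f)
    return np.vstack([c, s, v])


def _make_mesh(mesh_size: int, knots: np.ndarray) -> np.ndarray:
    parts = [np.linspace(0.0, 1.0, mesh_size), knots]
    # resolve each ramp and the region upstream of the first break
    if knots.size > 2:
        parts.append(np.linspace(0.0, knots[1], 9))
        for lo, hi in zip(knots[1:-1:2], knots[2:-1:2]):
            parts.append(np.linspace(lo, hi, 5))
    return np.unique(np.concatenate(parts))


def _solve_nondim(
    beta: float,
    gamma: float,
    lam: float,
    edges: np.ndarray,
    values: np.ndarray,
    numerics: NumericsConfig,
):
    """Solve the nondimensional system; returns (sol, status, message)."""
    knots, fvals = _flux_knots(edges, values, numerics.ramp_width)

    def f(x):
        return np.interp(x, knots, fvals)

    eps = numerics.eps_u

    def make_odes(beta_eff: float):
        bg = beta_eff / gamma

        def fun(x, y):
            c, s, v = y
            return np.vstack(
                [s, -f(x) + bg * (1.0 + gamma * c) * c + beta_eff * v * s, c]
            )

        def fun_jac(x, y):
            c, s, v = y
            m = x.shape[0]
            J = np.zeros((3, 3, m))
            J[0, 1] = 1.0
            J[1, 0] = bg * (1.0 + 2.0 * gamma * c)
            J[1, 1] = beta_eff * v
            J[1, 2] = beta_eff * s
            J[2, 0] = 1.0
            return J

        def bc(ya, yb):
            xg = beta_eff * lam * yb[2]
            return np.array(
                [ya[1], ya[2], yb[0] + lam * _g_expm1_over_x(xg, eps) * yb[1]]
            )

        def bc_jac(ya, yb):
            xg = beta_eff * lam * yb[2]
            dya = np.zeros((3, 3))
            dya[0, 1] = 1.0
            dya[1, 2] = 1.0
            dyb = np.zeros((3, 3))
            dyb[2, 0] = 1.0
            dyb[2, 1] = lam * _g_expm1_over_x(xg, eps)
            dyb[2, 2] = lam * yb[1] * _g_prime(xg, eps) * beta_eff * lam
            return dya, dyb

        return fun, bc, fun_jac, bc_jac

    x0 = _make_mesh(numerics.mesh_size, knots)
    y0 = _linear_guess(x0, f, lam)

    def attempt(beta_eff, x, y):
        fun, bc, fun_jac, bc_jac = make_odes(beta_eff)
        return solve_bvp(
            fun,
            bc,
            x,
            y,
            fun_jac=fun_jac,
            bc_jac=bc_jac,
            tol=numerics.tol,
            max_nodes=numerics.max_nodes,
            verbose=0,
        )

    sol = attempt(beta, x0, y0)
    if sol.status == 0:
        return sol, "converged", ""

    # Continuation: geometric ramp of the water permeability (beta ∝ Lp),
    # re-using each converged solution as the next starting point.
    for start in numerics.continuation:
        n_steps = max(3, int(round(-3.0 * math.log10(start))) + 1)
        factors = np.geomspace(start, 1.0, n_steps)
        x, y = x0, y0
        ok = True
        for fac in factors:
            sol = attempt(beta * fac, x, y)
            if sol.status != 0:
                ok = False
                break
            x = sol.x
            y = sol.y
        if ok:
            return sol, "converged", f"continuation from {start:g}·Lp"
    return sol, "failed", f"solve_bvp status {sol.status}: {sol.message}"


def _trivial_solution(geom: MicrovilliGeometry, params: TransportParameters):
    z = np.linspace(0.0, geom.l_mv_cm, 65)
    C = np.full_like(z, params.C0)
    u = np.zeros_like(z)
    return FUSolution(
        z=z,
        C=C,
        u=u,
        Q_FU=0.0,
        Q_SG=0.0,
        solute_residual=0.0,
        water_residual=0.0,
        tip_peclet=0.0,
        status="converged",
        message="zero flux: isotonic rest state",
    )


def solve_fu(
    geom: MicrovilliGeometry,
    params: TransportParameters,
    flux: FluxProfile | None = None,
    numerics: NumericsConfig | None = None,
) -> FUSolution:
    """Solve the standing-gradient BVP for one functional unit.

    Returns the dimensional profiles and the whole-organ production rate
    ``Q_SG = N · u(l_mv) · π d²/4`` in µL/min.  Non-convergence (after the
    Lp continuation ramp) is reported via ``status='failed'``, never as a
    silent NaN.
    """
    numerics = numerics or NumericsConfig()
    if flux is None:
        flux = build_flux_profile(geom, params)
    if flux.phi0 == 0.0:
        return _trivial_solution(geom, params)

    l = geom.l_mv_cm
    d = geom.d_cm
    phi_ref = flux.phi0
    lam = params.l_prot_cm / l
    # fold the protected-pool amplification of the concentration elevation
    # into the scale, so the nondimensional unknowns stay O(1) and the
    # collocation residual estimate is not dominated by roundoff
    S = 1.0 + lam
    Cs = 4.0 * phi_ref * l * l / (params.rho * d * params.D) * S
    Us = 4.0 * params.Lp * Cs * l / d
    beta = Us * l / params.D
    gamma = Cs / params.C0
    ahat = min(1.0, flux.boost_extent / l)
    edges = np.array([ahat, 1.0]) if ahat < 1.0 else np.array([1.0])
    shape = (
        np.array([1.0 + flux.boost_factor, 1.0])
        if ahat < 1.0
        else np.array([1.0 + flux.boost_factor])
    )

    sol, status, message = _solve_nondim(
        beta, gamma, lam, edges, shape / S, numerics
    )

    zh = sol.x
    c, s, v = sol.y
    z = l * zh
    C = params.C0 + Cs * c
    u = Us * v
    u_tip = float(u[-1])
    Q_FU = u_tip * geom.A_CS_cm2
    Q_SG = geom.N * Q_FU * ULMIN_PER_CM3S

    # Diagnostics on the dense collocation output
    if status == "converged":
        xs = np.linspace(0.0, 1.0, 4097)
        cs_dense = sol.sol(xs)[0]
        v_int = simpson(cs_dense, x=xs)
        water_residual = abs(float(v[-1]) - v_int) / max(abs(float(v[-1])), 1e-300)
        # tip outflux (advective + diffusive, incl. the C0 background carried
        # by the produced flow) vs total lateral injection
        dCdz_tip = Cs * float(s[-1]) / l
        outflux = params.rho * geom.A_CS_cm2 * (u_tip * float(C[-1]) - params.D * dCdz_tip)
        # φ already carries the ρ factor (mass flux per unit wall area)
        injected = (
            geom.A_CS_cm2
            * (4.0 / d)
            * phi_ref
            * l
            * float(np.sum(shape * np.diff(np.concatenate([[0.0], edges]))))
        )
        solute_residual = abs(outflux - injected) / max(abs(injected), 1e-300)
    else:
        water_residual = math.nan
        solute_residual = math.nan
    tip_peclet = u_tip * params.l_prot_cm / params.D

    def dense(zq: np.ndarray) -> np.ndarray:
        y = sol.sol(np.asarray(zq, dtype=float) / l)
        return np.vstack([params.C0 + Cs * y[0], Us * y[2]])

    return FUSolution(
        z=z,
        C=C,
        u=u,
        Q_FU=Q_FU,
        Q_SG=Q_SG,
        solute_residual=solute_residual,
        water_residual=water_residual,
        tip_peclet=tip_peclet,
        status=status,
        message=message,
        dense=dense,
    )


def small_peclet_estimate(
    geom: MicrovilliGeometry,
    params: TransportParameters,
    flux: FluxProfile | None = None,
    warn: bool = True,
) -> float:
    """Closed-form production estimate in the small-Péclet limit, µL/min.

    Dropping the convective terms of the solute balance and linearizing the
    tip condition to C(l) − C0 = −l_prot C'(l) makes the problem quadrature:
    for the piecewise flux with boost extent a = min(d/2, l) and â = a/l,

        u(l) = (16 Lp φ0 / (ρ d² D)) · l³ ·
               [ 1/3 + â/4 − â³/12 + (l_prot/l)(1 + â/2) ]

    (the â terms are the boost's contribution; â → 0 recovers the uniform
    -flux form l³/3 + l² l_prot).  The estimate is linear in Lp, in l_prot
    and in the flux — hence in Q_meas — which is why production grows
    linearly with the protected length.  Checked against the full solve in
    the test suite; warns if the implied tip Péclet number is not small.
    """
    if flux is None:
        flux = build_flux_profile(geom, params)
    l = geom.l_mv_cm
    d = geom.d_cm
    ahat = min(1.0, flux.boost_extent / l)
    lam = params.l_prot_cm / l
    shape = 1.0 / 3.0 + ahat / 4.0 - ahat**3 / 12.0 + lam * (1.0 + ahat / 2.0)
    u_tip = (
        16.0 * params.Lp * flux.phi0 / (params.rho * d * d * params.D) * l**3 * shape
    )
    if warn:
        peclet = u_tip * params.l_prot_cm / params.D
        if peclet >= 0.1:
            warnings.warn(
                f"tip Péclet number {peclet:.3g} is not small; the linear "
                "estimate may be inaccurate",
                stacklevel=2,
            )
    return geom.N * u_tip * geom.A_CS_cm2 * ULMIN_PER_CM3S


def production_rate(solution: FUSolution, geom: MicrovilliGeometry) -> float:
    """Whole-organ production Q_SG = N · u(l_mv) · π d²/4, in µL/min."""
    if not solution.converged:
        raise SolverError(f"cannot aggregate an unconverged solution: {solution.message}")
    return geom.N * float(solution.u[-1]) * geom.A_CS_cm2 * ULMIN_PER_CM3S


# --------------------------------------------------------------------------
# Legacy verification case (original standing-gradient channel)
# --------------------------------------------------------------------------

#: Parameter set of the original standing-gradient channel used to verify
#: the solver: hydraulic diameter prescribed directly, solute flux pumped
#: only over the first tenth of the channel, no protected pool, no base
#: compensation.  Flux in the source's own units (per cm² of side wall).
LEGACY_DB_CASE = {
    "l_mv": 100.0,  # µm
    "d": 0.1,  # µm
    "l_prot": 0.0,  # µm
    "D": 1.0e-5,  # cm²/s
    "Lp": 2.0e-4,  # cm/(s·Osm)
    "C0": 0.3,  # Osm
    "rho": 1.0,  # g/mL
    "phi": 1.0e-5,  # flux over the pumped section
    "pumped_fraction": 0.1,
}


def solve_legacy_db(
    config: dict | None = None, numerics: NumericsConfig | None = None
) -> FUSolution:
    """Solve the legacy standing-gradient channel (solver verification).

    The hydraulic diameter is prescribed directly (no microvillar lawn), the
    solute flux is a step profile — ``phi`` on the first ``pumped_fraction``
    of the length, zero beyond — and there is no protected pool and no base
    compensation.  This regime is strongly convective (tip Péclet ~ 10), so
    the permeability continuation ramp is exercised here.
    """
    numerics = numerics or NumericsConfig()
    case = dict(LEGACY_DB_CASE)
    if config:
        case.update(config)
    l = case["l_mv"] / UM_PER_CM
    d = case["d"] / UM_PER_CM
    D, Lp, C0, rho = case["D"], case["Lp"], case["C0"], case["rho"]
    l_prot = case["l_prot"] / UM_PER_CM
    phi_ref = case["phi"]
    frac = case["pumped_fraction"]

    if phi_ref == 0.0:
        z = np.linspace(0.0, l, 65)
        return FUSolution(
            z=z, C=np.full_like(z, C0), u=np.zeros_like(z),
            Q_FU=0.0, Q_SG=math.nan,
            solute_residual=0.0, water_residual=0.0, tip_peclet=0.0,
            status="converged", message="zero flux: isotonic rest state",
        )

    lam = l_prot / l
    S = 1.0 + lam
    Cs = 4.0 * phi_ref * l * l / (rho * d * D) * S
    Us = 4.0 * Lp * Cs * l / d
    beta = Us * l / D
    gamma = Cs / C0
    edges = np.array([frac, 1.0])
    shape = np.array([1.0, 0.0])

    sol, status, message = _solve_nondim(
        beta, gamma, lam, edges, shape / S, numerics
    )
    if status != "converged":
        raise SolverError(f"legacy case failed to converge: {message}")

    zh = sol.x
    c, s, v = sol.y
    z = l * zh
    C = C0 + Cs * c
    u = Us * v
    u_tip = float(u[-1])
    A_CS = math.pi * d * d / 4.0

    xs = np.linspace(0.0, 1.0, 4097)
    v_int = simpson(sol.sol(xs)[0], x=xs)
    water_residual = abs(float(v[-1]) - v_int) / max(abs(float(v[-1])), 1e-300)
    dCdz_tip = Cs * float(s[-1]) / l
    outflux = rho * A_CS * (u_tip * float(C[-1]) - D * dCdz_tip)
    injected = A_CS * (4.0 / d) * phi_ref * frac * l
    solute_residual = abs(outflux - injected) / max(abs(injected), 1e-300)

    def dense(zq: np.ndarray) -> np.ndarray:
        y = sol.sol(np.asarray(zq, dtype=float) / l)
        return np.vstack([C0 + Cs * y[0], Us * y[2]])

    return FUSolution(
        z=z,
        C=C,
        u=u,
        Q_FU=u_tip * A_CS,
        Q_SG=math.nan,  # no organ aggregation for the single legacy channel
        solute_residual=solute_residual,
        water_residual=water_residual,
        tip_peclet=u_tip * l_prot / D,
        status=status,
        message=message,
        dense=dense,
    )
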