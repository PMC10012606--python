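"""Independent finite-difference/Picard reference solver for the FU problem.

Deliberately shares nothing with the package implementation: it works in
dimensional variables on a uniform grid, discretizes the solute balance with
second-order central differences, imposes the base symmetry through a ghost
node and the tip condition through a one-sided second-order derivative, and
resolves the solute–water coupling by damped Picard iteration (banded linear
solve for C given u, trapezoidal update of u from C).  Used only as an
oracle in tests.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.linalg import solve_banded


def solve_fd(
    l: float,
    d: float,
    D: float,
    C0: float,
    rho: float,
    Lp: float,
    l_prot: float,
    phi_fn,
    n: int = 10001,
    relax: float = 0.4,
    tol: float = 1.0e-11,
    maxit: int = 4000,
):
    """Solve the coupled FU problem; all lengths in cm, CGS units.

    Returns ``(z, C, u, converged)``; convergence refers to the Picard
    fixed-point iteration (the spatial error is O(h²) of the grid).
    """
    z = np.linspace(0.0, l, n)
    h = z[1] - z[0]
    phi = np.asarray(phi_fn(z), dtype=float)
    Ct = np.zeros(n)  # C - C0
    converged = False
    for _ in range(maxit):
        du = (4.0 * Lp / d) * Ct
        u = cumulative_trapezoid(du, z, initial=0.0)

        # banded storage for bandwidths (lower=2, upper=1):
        # ab[1 + i - j, j] = a[i, j]
        ab = np.zeros((4, n))
        rhs = np.zeros(n)
        # base row: ghost symmetry C'(0) = 0
        ab[1, 0] = -2.0 * D / h**2 - du[0]
        ab[0, 1] = 2.0 * D / h**2
        rhs[0] = -4.0 * phi[0] / (rho * d) + C0 * du[0]
        # interior rows: central differences on D C'' - u C' - u' C
        i = np.arange(1, n - 1)
        ab[0, i + 1] = D / h**2 - u[i] / (2.0 * h)
        ab[1, i] = -2.0 * D / h**2 - du[i]
        ab[2, i - 1] = D / h**2 + u[i] / (2.0 * h)
        rhs[i] = -4.0 * phi[i] / (rho * d) + C0 * du[i]
        # tip row: D(1 - exp(u l_prot/D)) C' - u (C - C0) = 0, one-sided C'
        x = u[-1] * l_prot / D
        if abs(x) < 1.0e-10:
            fac = l_prot * (1.0 + x / 2.0)  # Robin limit of the condition
            c_n = 1.0 + fac * 3.0 / (2.0 * h)
            c_n1 = -fac * 4.0 / (2.0 * h)
            c_n2 = fac / (2.0 * h)
        else:
            A = D * (-np.expm1(x))
            c_n = A * 3.0 / (2.0 * h) - u[-1]
            c_n1 = -A * 4.0 / (2.0 * h)
            c_n2 = A / (2.0 * h)
        ab[1, n - 1] = c_n
        ab[2, n - 2] = c_n1
        ab[3, n - 3] = c_n2
        rhs[n - 1] = 0.0

        Ct_new = solve_banded((2, 1), ab, rhs)
        err = np.max(np.abs(Ct_new - Ct)) / max(np.max(np.abs(Ct_new)), 1e-300)
        Ct = relax * Ct_new + (1.0 - relax) * Ct
        if err < tol:
            converged = True
            break
    u = cumulative_trapezoid((4.0 * Lp / d) * Ct, z, initial=0.0)
    return z, C0 + Ct, u, converged
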