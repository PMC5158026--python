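"""Forward mechanical model of pollen-tube micro-indentation.

The tube shank is idealized as a turgid, linear-elastic, thin-walled
circular cylinder.  A rigid indenter with a sub-micron tip applies a
localized radial load; the quantity of interest is the small-deflection
apparent stiffness ``k = F / w`` at the load center, i.e. the slope of the
force-deflection curve about the pressurized equilibrium state.

Model
-----
Linearized shallow-shell (Donnell) equations on the developed cylinder
surface (axial coordinate x, circumferential arc length s = R*theta), with
an Airy stress function phi carrying the membrane response and with the
turgor pretension entering as membrane forces:

    D lap^2 w - (1/R) phi_xx - N_x w_xx - N_th w_ss = q(x, s)
    lap^2 phi + (E t / R) w_xx = 0

where ``D = E t^3 / (12 (1 - nu^2))`` is the bending rigidity and the
pressure-vessel pretensions are ``N_th = p R`` (hoop) and ``N_x = p R / 2``
(axial).  Ends are simply supported (Navier conditions), the load is a
uniform pressure over a circular patch of radius ``a`` centered mid-length.

Two independent solvers are provided:

* :func:`stiffness_fourier` — double Fourier series (sin in x, cos in
  theta), the production solver, with adaptive truncation.
* :func:`stiffness_fd_oracle` — finite differences + sparse LU on the same
  equations, used as a cross-validation oracle in the test suite.

Unit system: µm, µN, MPa.  These are mutually consistent
(1 MPa = 1 µN/µm²), so forces come out in µN, pretensions in
MPa·µm = µN/µm = N/m, and stiffnesses directly in N/m.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.special import j1


class ConvergenceError(RuntimeError):
    """Series truncation (or grid) failed to converge within limits."""


@dataclass(frozen=True)
class ShellProblem:
    """Specification of one indentation forward problem.

    Attributes
    ----------
    R : float
        Tube radius (µm), half the tube diameter.
    t : float
        Cell-wall thickness (µm); thin-shell regime requires ``t/R <= 0.2``.
    L : float
        Shell length (µm) between the simply supported ends; ``L >= 10 R``
        so that end effects are negligible at mid-length.
    E : float
        Young's modulus of the wall (MPa).
    nu : float
        Poisson ratio, in ``[0, 0.5)``.
    p : float
        Turgor pressure (MPa); enters only through the membrane pretension.
    a : float
        Radius of the circular load patch (µm), i.e. half the indenter tip
        diameter.
    F_max : float
        Reference load (µN).  The model is linear, so ``F_max`` does not
        affect the stiffness; it is carried for provenance.
    """

    R: float
    t: float
    L: float
    E: float
    nu: float = 0.3
    p: float = 0.2
    a: float = 0.4
    F_max: float = 5.0

    def __post_init__(self) -> None:
        for name in ("R", "t", "L", "E", "a"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.p < 0:
            raise ValueError("p must be non-negative")
        if not 0 <= self.nu < 0.5:
            raise ValueError("nu must lie in [0, 0.5)")
        if self.t / self.R > 0.2:
            raise ValueError("thin-shell assumption requires t/R <= 0.2")
        if self.L < 10 * self.R:
            raise ValueError("L must be >= 10 R to decouple end effects")

    @classmethod
    def from_tube(
        cls,
        diameter: float,
        wall_thickness: float,
        turgor: float,
        E: float,
        nu: float = 0.3,
        tip_diameter: float = 0.8,
        length_factor: float = 20.0,
        F_max: float = 5.0,
    ) -> "ShellProblem":
        """Build a problem from tube-level quantities (diameters in µm)."""
        R = diameter / 2.0
        return cls(
            R=R,
            t=wall_thickness,
            L=length_factor * R,
            E=E,
            nu=nu,
            p=turgor,
            a=tip_diameter / 2.0,
            F_max=F_max,
        )


@dataclass(frozen=True)
class ModelResult:
    """Outcome of a forward stiffness evaluation."""

    k_model: float
    orders: tuple[int, int]
    converged: bool
    tail: float


def pretension(p: float, R: float) -> tuple[float, float]:
    """Pressure-vessel membrane forces (N_theta, N_x) in N/m.

    Hoop tension ``p R`` and axial tension ``p R / 2`` for a closed
    cylinder under internal pressure ``p`` (MPa) with radius ``R`` (µm).
    """
    if p < 0 or R <= 0:
        raise ValueError("require p >= 0 and R > 0")
    return p * R, p * R / 2.0


def bending_rigidity(E: float, t: float, nu: float) -> float:
    """Plate/shell bending rigidity ``D = E t^3 / (12 (1 - nu^2))`` (N·µm)."""
    if E <= 0 or t <= 0:
        raise ValueError("E and t must be positive")
    if not 0 <= nu < 0.5:
        raise ValueError("nu must lie in [0, 0.5)")
    return E * t**3 / (12.0 * (1.0 - nu**2))


# ---------------------------------------------------------------------------
# Fourier-series solver
# ---------------------------------------------------------------------------

# Mode-geometry cache keyed by (R, L, a, kappa_max); entries are
# dictionaries of arrays reused across E/t/p variations during inversion.
# Bounded by total array bytes, FIFO eviction.
_MODE_CACHE: dict[tuple[float, float, float, float], dict[str, np.ndarray]] = {}
_MODE_CACHE_MAX_BYTES = 200 * 1024 * 1024
_mode_cache_bytes = 0


def _mode_geometry(R: float, L: float, a: float, kappa_max: float) -> dict[str, np.ndarray]:
    key = (round(R, 12), round(L, 12), round(a, 12), round(kappa_max, 6))
    hit = _MODE_CACHE.get(key)
    if hit is not None:
        return hit
    m_max = max(int(np.ceil(kappa_max * L / np.pi)), 5)
    n_max = max(int(np.ceil(kappa_max * R)), 5)
    m = np.arange(1, m_max + 1, 2, dtype=float)  # odd modes only (center load)
    n = np.arange(0, n_max + 1, dtype=float)
    lam = (np.pi / L) * m  # axial wavenumber, column
    nbar = n / R  # circumferential wavenumber, row
    lam2 = lam[:, None] ** 2
    nbar2 = nbar[None, :] ** 2
    kap2 = lam2 + nbar2
    kap = np.sqrt(kap2)
    eps = np.where(n == 0, 1.0, 2.0)[None, :]
    # Patch-load Fourier coefficient of q for total force F = 1:
    #   q_mn = (2 eps_n / (pi a L R)) * J1(kappa a) / kappa
    qcoef = (2.0 * eps / (np.pi * a * L * R)) * j1(kap * a) / kap
    geo = {
        "lam2": lam2,
        "nbar2": nbar2,
        "kap2": kap2,
        "lam4_over_kap4": lam2**2 / kap2**2,
        "kap4": kap2**2,
        "qcoef": qcoef,
        "orders": np.array([m.size, n.size]),
    }
    global _mode_cache_bytes
    size = sum(v.nbytes for v in geo.values())
    while _MODE_CACHE and _mode_cache_bytes + size > _MODE_CACHE_MAX_BYTES:
        dropped = _MODE_CACHE.pop(next(iter(_MODE_CACHE)))
        _mode_cache_bytes -= sum(v.nbytes for v in dropped.values())
    if size <= _MODE_CACHE_MAX_BYTES:
        _MODE_CACHE[key] = geo
        _mode_cache_bytes += size
    return geo


def _center_compliance(problem: ShellProblem, kappa_max: float) -> float:
    """Deflection at the load center per unit force, at fixed truncation."""
    geo = _mode_geometry(problem.R, problem.L, problem.a, kappa_max)
    D = bending_rigidity(problem.E, problem.t, problem.nu)
    n_th, n_x = pretension(problem.p, problem.R) if problem.p > 0 else (0.0, 0.0)
    K = (
        D * geo["kap4"]
        + (problem.E * problem.t / problem.R**2) * geo["lam4_over_kap4"]
        + n_x * geo["lam2"]
        + n_th * geo["nbar2"]
    )
    return float(np.sum(geo["qcoef"] / K))


def stiffness_fourier(
    problem: ShellProblem,
    tol: float = 1.0e-4,
    kappa0: float | None = None,
    max_doublings: int = 5,
) -> ModelResult:
    """Apparent stiffness ``F / w(center)`` by double Fourier series.

    The series is evaluated at a truncation wavenumber ``kappa`` and the
    truncation is doubled until the relative change of the center
    compliance falls below ``tol``.  The starting truncation resolves both
    the load patch and the bending boundary layer ``sqrt(R t)``.

    Raises
    ------
    ConvergenceError
        If the tail is still above ``tol`` at the maximum truncation.
    """
    if kappa0 is None:
        kappa0 = max(6.0 / problem.a, 12.0 / np.sqrt(problem.R * problem.t))
        # quantize so nearby problems share cached mode geometry
        kappa0 = 5.0 * np.ceil(kappa0 / 5.0)
    kappa = kappa0
    w_prev = _center_compliance(problem, kappa)
    tail = np.inf
    for _ in range(max_doublings):
        kappa *= 2.0
        w_next = _center_compliance(problem, kappa)
        tail = abs(w_next - w_prev) / abs(w_next)
        w_prev = w_next
        if tail < tol:
            geo = _mode_geometry(problem.R, problem.L, problem.a, kappa)
            return ModelResult(
                k_model=1.0 / w_prev,
                orders=(int(geo["orders"][0]), int(geo["orders"][1])),
                converged=True,
                tail=float(tail),
            )
    raise ConvergenceError(
        f"series tail {tail:.3e} above tol {tol:.1e} at kappa_max {kappa:.1f}"
    )


# ---------------------------------------------------------------------------
# Finite-difference oracle
# ---------------------------------------------------------------------------


def _d2_dirichlet(n: int, h: float, neumann_last: bool) -> sp.csr_matrix:
    """1-D second difference; Dirichlet at the first (excluded) node.

    Nodes 0..n-1 are interior; the node before index 0 is a Dirichlet
    boundary (value 0, row simply truncated).  If ``neumann_last`` the last
    node is a symmetry plane (mirror ghost).
    """
    main = -2.0 * np.ones(n)
    off = np.ones(n - 1)
    d = sp.diags([off, main, off], [-1, 0, 1], format="lil")
    if neumann_last:
        d[n - 1, n - 2] = 2.0
    return (d / h**2).tocsr()


def _d2_neumann_both(n: int, h: float) -> sp.csr_matrix:
    """1-D second difference with symmetry (mirror) planes at both ends."""
    main = -2.0 * np.ones(n)
    off = np.ones(n - 1)
    d = sp.diags([off, main, off], [-1, 0, 1], format="lil")
    d[0, 1] = 2.0
    d[n - 1, n - 2] = 2.0
    return (d / h**2).tocsr()


def _patch_load_quarter(
    xs: np.ndarray, ss: np.ndarray, hx: float, hs: float, a: float, x_c: float
) -> np.ndarray:
    """Load density on the quarter grid for unit total force on the shell.

    The patch is centered at (x_c, 0); each node's cell (clipped to the
    quarter domain) is subsampled to estimate the covered fraction, and the
    result is normalized so the integrated quarter load is exactly 1/4.
    """
    nsub = 8
    off = (np.arange(nsub) + 0.5) / nsub  # cell-relative subsample offsets
    frac = np.zeros((xs.size, ss.size))
    for i, x in enumerate(xs):
        if abs(x - x_c) - hx / 2 > a:
            continue
        x_lo = min(x - hx / 2, x_c)  # clip at symmetry plane x = x_c
        x_hi = min(x + hx / 2, x_c)
        if x_hi <= x_lo:
            # node sits on the symmetry plane: cell extends only backwards
            x_lo, x_hi = x - hx / 2, x_c
        xsub = x_lo + (x_hi - x_lo) * off
        for jj, s_ in enumerate(ss):
            if s_ - hs / 2 > a:
                break
            s_lo = max(s_ - hs / 2, 0.0)
            s_hi = s_ + hs / 2
            ssub = s_lo + (s_hi - s_lo) * off
            inside = ((xsub[:, None] - x_c) ** 2 + ssub[None, :] ** 2) <= a**2
            cell_area = (x_hi - x_lo) * (s_hi - s_lo)
            frac[i, jj] = inside.mean() * cell_area
    total = frac.sum()
    if total <= 0:
        raise ValueError("load patch not resolved by the grid")
    return frac / total * 0.25  # integrated nodal forces; quarter of F = 1


def stiffness_fd_oracle(
    problem: ShellProblem,
    h: float = 0.2,
    quarter: bool = True,
) -> float:
    """Independent finite-difference solution of the same shell equations.

    Discretizes the coupled (w, phi) Donnell system on the developed
    surface with grid spacing ``h`` (µm) and solves it by sparse LU.  With
    ``quarter=True`` the symmetry of the mid-length, theta=0 patch load is
    exploited: the domain is x in (0, L/2] (simply supported at 0, mirror
    at L/2) and s in [0, pi R] (mirror at both ends).

    Intended for verification only; the production path is
    :func:`stiffness_fourier`.
    """
    bl = np.sqrt(problem.R * problem.t)
    if h > min(problem.a / 2.0, bl / 4.0) * (1 + 1e-9):
        raise ValueError(
            f"grid too coarse: h={h} must resolve the patch (a/2={problem.a/2:.3f}) "
            f"and the bending boundary layer (sqrt(Rt)/4={bl/4:.3f})"
        )
    R, L = problem.R, problem.L
    D = bending_rigidity(problem.E, problem.t, problem.nu)
    n_th, n_x = pretension(problem.p, problem.R) if problem.p > 0 else (0.0, 0.0)

    if quarter:
        x_len, s_len = L / 2.0, np.pi * R
        nx = int(np.round(x_len / h))
        ns = int(np.round(s_len / h)) + 1
        hx, hs = x_len / nx, s_len / (ns - 1)
        xs = hx * np.arange(1, nx + 1)  # node nx at x = L/2 (mirror)
        ss = hs * np.arange(0, ns)  # nodes at s = 0 and pi R (mirrors)
        dxx = _d2_dirichlet(nx, hx, neumann_last=True)
        dss = _d2_neumann_both(ns, hs)
        center = (nx - 1) * ns + 0  # node (x=L/2, s=0)
        x_c = L / 2.0
    else:
        x_len, s_len = L, 2.0 * np.pi * R
        nx = int(np.round(x_len / h)) - 1
        ns = int(np.round(s_len / h))
        hx, hs = x_len / (nx + 1), s_len / ns
        xs = hx * np.arange(1, nx + 1)
        ss = hs * np.arange(0, ns)
        dxx = _d2_dirichlet(nx, hx, neumann_last=False)
        # periodic second difference in s
        main = -2.0 * np.ones(ns)
        off = np.ones(ns - 1)
        dss = sp.diags([off, main, off], [-1, 0, 1], format="lil")
        dss[0, ns - 1] = 1.0
        dss[ns - 1, 0] = 1.0
        dss = (dss / hs**2).tocsr()
        i_mid = int(np.argmin(np.abs(xs - L / 2.0)))
        center = i_mid * ns + 0
        x_c = xs[i_mid]

    ix = sp.identity(nx, format="csr")
    is_ = sp.identity(ns, format="csr")
    kxx = sp.kron(dxx, is_, format="csr")
    kss = sp.kron(ix, dss, format="csr")
    lap = kxx + kss
    bih = (lap @ lap).tocsr()

    a11 = D * bih - n_x * kxx - n_th * kss
    a12 = -(1.0 / R) * kxx
    a21 = (problem.E * problem.t / R) * kxx
    a22 = bih
    amat = sp.bmat([[a11, a12], [a21, a22]], format="csc")

    if quarter:
        fnod = _patch_load_quarter(xs, ss, hx, hs, problem.a, x_c)
        # nodal cell areas (mirror-plane nodes own half cells)
        wx = np.full(nx, hx)
        wx[-1] = hx / 2.0
        ws = np.full(ns, hs)
        ws[0] = hs / 2.0
        ws[-1] = hs / 2.0
        area = wx[:, None] * ws[None, :]
        q = (fnod / area).ravel()
    else:
        nsub = 8
        offs = (np.arange(nsub) + 0.5) / nsub - 0.5
        frac = np.zeros((nx, ns))
        for i, x in enumerate(xs):
            if abs(x - x_c) - hx / 2 > problem.a:
                continue
            for jj, s_ in enumerate(ss):
                s_sh = s_ if s_ <= s_len / 2 else s_ - s_len
                if abs(s_sh) - hs / 2 > problem.a:
                    continue
                xsub = x + hx * offs
                ssub = s_sh + hs * offs
                inside = ((xsub[:, None] - x_c) ** 2 + ssub[None, :] ** 2) <= problem.a**2
                frac[i, jj] = inside.mean()
        fnod = frac * hx * hs
        fnod /= fnod.sum()
        q = (fnod / (hx * hs)).ravel()

    rhs = np.concatenate([q, np.zeros(q.size)])
    sol = spla.spsolve(amat, rhs)
    w_center = sol[center]
    if not w_center > 0:
        raise RuntimeError("finite-difference solve returned a non-positive deflection")
    return 1.0 / w_center


# ---------------------------------------------------------------------------
# Parametric scans
# ---------------------------------------------------------------------------

_SCAN_PARAMS = ("E", "t", "p", "d")


def monotonicity_scan(
    base: ShellProblem, parameter: str, grid: np.ndarray
) -> pd.DataFrame:
    """Evaluate ``k_model`` along a grid of one physiological parameter.

    ``parameter`` is one of E (MPa), t (µm), p (MPa) or d (µm, the tube
    diameter, which rescales R, L and the t/R check).  Returns a DataFrame
    with columns ``parameter, value, k_model``; trend assertions are left
    to the caller (k is strictly increasing in E, t and p; the diameter
    trend is reported, not asserted).
    """
    if parameter not in _SCAN_PARAMS:
        raise ValueError(f"parameter must be one of {_SCAN_PARAMS}")
    rows = []
    for v in np.asarray(grid, dtype=float):
        if parameter == "d":
            prob = ShellProblem(
                R=v / 2.0,
                t=base.t,
                L=(base.L / base.R) * v / 2.0,
                E=base.E,
                nu=base.nu,
                p=base.p,
                a=base.a,
                F_max=base.F_max,
            )
        else:
            prob = replace(base, **{parameter: v})
        rows.append({"parameter": parameter, "value": v,
                     "k_model": stiffness_fourier(prob).k_model})
    return pd.DataFrame(rows)
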