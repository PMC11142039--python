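"""Semi-analytic dipole potential in an N-shell concentric spherical conductor.

Independent oracle for the BEM solver: the potential of a current dipole
inside nested concentric spherical shells is expanded in spherical
harmonics.  Per degree n the radial profile in each conducting region is
``A (r/R_out)^n + B (R_in/r)^(n+1)`` (scaled powers, so no overflow at
high degree); the dipole's primary potential contributes the known
particular terms in its own region.  Continuity of potential and of radial
current density at every interface, plus zero radial current into the air
outside, closes a small linear system per degree, solved independently for
the axisymmetric (m=0, radial-moment) and cos(phi) (m=1,
tangential-moment) parts after rotating the dipole onto the z-axis.

Conventions: associated Legendre functions follow scipy (Condon-Shortley
phase).  The n=0 harmonic is omitted — it contributes only a spatially
constant offset interior to the source radius and nothing on the outer
surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import lpmv

from .forward import Dipole

__all__ = ["SphereModel", "SeriesTruncationError", "sphere_potential", "rdm_mag"]


class SeriesTruncationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SphereModel:
    """Concentric-shell conductor.

    ``radii`` are interface radii in meters, strictly decreasing (outermost
    first); ``sigmas`` are region conductivities from the innermost ball
    outwards, one per interface (air outside is implicit).
    """

    radii: tuple
    sigmas: tuple
    n_terms: int = 200

    def __post_init__(self):
        radii = tuple(float(r) for r in np.atleast_1d(self.radii))
        sigmas = tuple(float(s) for s in np.atleast_1d(self.sigmas))
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "sigmas", sigmas)
        if len(radii) != len(sigmas):
            raise ValueError("need one conductivity per interface")
        if any(np.diff(radii) >= 0) or radii[-1] <= 0:
            raise ValueError("radii must be positive and strictly decreasing")
        if any(s <= 0 for s in sigmas):
            raise ValueError("conductivities must be positive")
        if self.n_terms < 1:
            raise ValueError("n_terms must be >= 1")

    @property
    def ascending_radii(self) -> np.ndarray:
        return np.asarray(self.radii[::-1], float)

    def region_of(self, radius: float) -> int:
        """Region index of a radius: 0 = innermost ball."""
        return int(np.searchsorted(self.ascending_radii, radius, side="right"))


def _source_coeffs(n, q_r, q_t, b, sigma_s):
    """Coefficients of the primary-potential series, both radial branches.

    Returns per (m, branch) the scalar c such that the source term is
    c * (b/r)^(n-1) / r^2  (outer branch, r > b) or
    c * (r/b)^n / b^2      (inner branch, r < b),
    multiplying P_n (m=0) or P_n^1 cos(phi) (m=1).
    """
    cq = 1.0 / (4.0 * np.pi * sigma_s)
    return {
        (0, "out"): cq * n * q_r,
        (0, "in"): -cq * (n + 1) * q_r,
        (1, "out"): -cq * q_t,
        (1, "in"): -cq * q_t,
    }


def _source_val(coeff, branch, n, b, r):
    if branch == "out":
        return coeff * (b / r) ** (n - 1) / r**2
    return coeff * (r / b) ** n / b**2 if b > 0 else 0.0


def _source_deriv(coeff, branch, n, b, r):
    if branch == "out":
        return coeff * (-(n + 1)) * (b / r) ** (n - 1) / r**3
    return coeff * n * (r / b) ** n / (b * r) / b if b > 0 else 0.0


def _solve_degree(model: SphereModel, n: int, m: int, coeffs, b: float,
                  js: int):
    """Solve the per-degree matching system; return the outer-region
    evaluation data (A, B, source coeff/branch info)."""
    asc = model.ascending_radii
    L = len(asc)
    sig = model.sigmas
    nun = 2 * L - 1  # A_0, (A_j, B_j) j=1..L-1
    A_mat = np.zeros((nun, nun))
    rhs = np.zeros(nun)

    def col_A(j):
        return 0 if j == 0 else 2 * j - 1

    def col_B(j):
        return 2 * j

    def basis(j, r):
        """(psi, dpsi, chi, dchi) of region j at radius r (scaled powers)."""
        r_out = asc[j]
        psi = (r / r_out) ** n
        dpsi = n * psi / r
        if j == 0:
            return psi, dpsi, 0.0, 0.0
        r_in = asc[j - 1]
        chi = (r_in / r) ** (n + 1)
        dchi = -(n + 1) * chi / r
        return psi, dpsi, chi, dchi

    def src(j, r):
        if j != js:
            return 0.0, 0.0
        branch = "out" if r >= b else "in"
        c = coeffs[(m, branch)]
        return (_source_val(c, branch, n, b, r),
                _source_deriv(c, branch, n, b, r))

    row = 0
    for j in range(L - 1):  # interface between region j and j+1 at asc[j]
        a = asc[j]
        pj, dpj, cj, dcj = basis(j, a)
        pk, dpk, ck, dck = basis(j + 1, a)
        sv_j, sd_j = src(j, a)
        sv_k, sd_k = src(j + 1, a)
        # potential continuity
        A_mat[row, col_A(j)] += pj
        if j > 0:
            A_mat[row, col_B(j)] += cj
        A_mat[row, col_A(j + 1)] -= pk
        A_mat[row, col_B(j + 1)] -= ck
        rhs[row] = sv_k - sv_j
        row += 1
        # radial current continuity
        A_mat[row, col_A(j)] += sig[j] * dpj
        if j > 0:
            A_mat[row, col_B(j)] += sig[j] * dcj
        A_mat[row, col_A(j + 1)] -= sig[j + 1] * dpk
        A_mat[row, col_B(j + 1)] -= sig[j + 1] * dck
        rhs[row] = sig[j + 1] * sd_k - sig[j] * sd_j
        row += 1
    # outer boundary: zero radial current into air
    a = asc[-1]
    jL = L - 1
    pL, dpL, cL, dcL = basis(jL, a)
    svL, sdL = src(jL, a)
    A_mat[row, col_A(jL)] += dpL
    if jL > 0:
        A_mat[row, col_B(jL)] += dcL
    rhs[row] = -sdL

    x = np.linalg.solve(A_mat, rhs)
    return x[col_A(jL)], (x[col_B(jL)] if jL > 0 else 0.0)


def sphere_potential(model: SphereModel, dipole: Dipole, points) -> np.ndarray:
    """Potential (volts, infinity reference) at points on/near the outer
    surface for a dipole anywhere strictly inside the conductor.

    Raises :class:`SeriesTruncationError` when the Legendre series has not
    decayed below 1e-8 of the accumulated sum at ``n_terms`` (deep shells
    with dipole eccentricity close to 1 need more terms).
    """
    points = np.atleast_2d(np.asarray(points, float))
    asc = model.ascending_radii
    a_out = asc[-1]
    p = dipole.position
    q = dipole.moment
    b = float(np.linalg.norm(p))
    if b >= asc[-1]:
        raise ValueError("dipole must be strictly inside the conductor")
    js = model.region_of(b)
    sigma_s = model.sigmas[js]

    # rotate so the dipole sits on the +z axis, tangential moment along +x
    if b > 1e-12 * a_out:
        zh = p / b
    else:
        b = 0.0
        zh = q / np.linalg.norm(q)
    q_r = float(q @ zh)
    qt_vec = q - q_r * zh
    q_t = float(np.linalg.norm(qt_vec))
    if q_t > 1e-14 * np.linalg.norm(q):
        xh = qt_vec / q_t
    else:
        q_t = 0.0
        trial = np.array([1.0, 0.0, 0.0])
        if abs(trial @ zh) > 0.9:
            trial = np.array([0.0, 1.0, 0.0])
        xh = trial - (trial @ zh) * zh
        xh /= np.linalg.norm(xh)
    yh = np.cross(zh, xh)

    r = np.linalg.norm(points, axis=1)
    if np.any(r < asc[-2] if len(asc) > 1 else r < 0):
        raise ValueError("evaluation points must lie in or beyond the outer shell")
    cos_t = np.clip(points @ zh / r, -1.0, 1.0)
    px = points @ xh
    py = points @ yh
    rho_xy = np.hypot(px, py)
    cos_p = np.where(rho_xy > 0, px / np.maximum(rho_xy, 1e-300), 1.0)

    in_air = r > a_out
    r_eval = np.minimum(r, a_out)

    phi = np.zeros(len(points))
    run_max = 0.0
    tail = np.inf
    for n in range(1, model.n_terms + 1):
        coeffs = _source_coeffs(n, q_r, q_t, b, sigma_s)
        term = np.zeros(len(points))
        # outer-region radial profile at r_eval
        r_out = asc[-1]
        r_in = asc[-2] if len(asc) > 1 else None
        for m, qm in ((0, q_r), (1, q_t)):
            if qm == 0.0:
                continue
            A_L, B_L = _solve_degree(model, n, m, coeffs, b, js)
            prof = A_L * (r_eval / r_out) ** n
            if r_in is not None:
                prof = prof + B_L * (r_in / r_eval) ** (n + 1)
            if js == len(asc) - 1:
                c = coeffs[(m, "out")]
                prof = prof + _source_val(c, "out", n, b, r_eval)
            if m == 0:
                term += prof * lpmv(0, n, cos_t)
            else:
                term += prof * lpmv(1, n, cos_t) * cos_p
        # air continuation for points beyond the outer surface
        if np.any(in_air):
            term[in_air] *= (a_out / r[in_air]) ** (n + 1)
        phi += term
        tail = float(np.max(np.abs(term)))
        run_max = max(run_max, float(np.max(np.abs(phi))))
        if run_max > 0 and tail < 1e-10 * run_max:
            break
    if run_max > 0 and tail > 1e-8 * run_max:
        raise SeriesTruncationError(
            f"series not converged at n_terms={model.n_terms}: last term "
            f"{tail:.3e} vs partial sum {run_max:.3e}; increase n_terms "
            "(high dipole eccentricity)"
        )
    return phi


def sphere_model_from_head(head, n_terms: int = 200) -> SphereModel:
    """Concentric-sphere oracle model matching a concentric HeadModel.

    Interface radii are taken as the mean vertex radius of each shell
    (exact for icosphere phantoms); only meaningful for concentric,
    unjittered phantoms.
    """
    radii = tuple(
        float(np.linalg.norm(m.vertices - np.asarray(c), axis=1).mean())
        for m, c in zip(head.interfaces, head.centers)
    )
    sigmas = tuple(reversed(head.sigma_in))
    return SphereModel(radii, sigmas, n_terms)


def rdm_mag(V_ref, V_test) -> tuple[float, float]:
    """Relative difference measure (shape error) and magnitude ratio.

    RDM = || V_test/||V_test|| - V_ref/||V_ref|| ||_2  in [0, 2];
    MAG = ||V_test|| / ||V_ref||.
    """
    V_ref = np.asarray(V_ref, float)
    V_test = np.asarray(V_test, float)
    if V_ref.shape != V_test.shape:
        raise ValueError("potential vectors must have equal length")
    nr = np.linalg.norm(V_ref)
    nt = np.linalg.norm(V_test)
    if nr == 0:
        raise ValueError("reference potential vector is identically zero")
    rdm = float(np.linalg.norm(V_test / nt - V_ref / nr)) if nt > 0 else 2.0
    return rdm, float(nt / nr)
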