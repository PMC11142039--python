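"""Charge-based BEM forward engine.

The quasi-static EEG forward problem is solved for the induced surface
charge density on the conductivity interfaces of a :class:`HeadModel`.
Collocating the boundary integral equation at facet centroids, with
piecewise-constant charge density rho_m on facet m (area A_m, outward
normal n_m, contrast K_m), gives the linear system

    rho_m / 2  -  K_m n_m . sum_{s != m} (rho_s A_s / 4 pi)
                  (r_m - r_s)/|r_m - r_s|^3   =   K_m E_i(r_m) . n_m

where E_i is the impressed (primary) field of the source.  The solver
works throughout in the scaled density rho/eps0 (units V/m), so the vacuum
permittivity never appears numerically; all reported potentials are in
volts regardless.

Close facet pairs replace the centroid point kernel by exact flat-triangle
integration (see :mod:`headbem.nearfield`); the n-body far sum is delegated
to a pluggable backend (:mod:`headbem.nbody`).  The dense path assembles
and LU-factorizes the full operator, which is both the fastest option for
the small inverse-model meshes and the enabler of adjoint (transpose)
lead-field computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy.sparse.linalg import LinearOperator, gmres

from .headmodel import HeadModel
from .nbody import get_backend
from . import nearfield

__all__ = [
    "Dipole",
    "UniformFieldSource",
    "ChargeSolution",
    "EEGSample",
    "BemOperator",
    "SolverConvergenceError",
    "impressed_field",
    "impressed_potential",
    "apply_operator",
    "solve_charges",
    "surface_potential",
    "secondary_field",
    "electrode_voltages",
]

#: below this facet count the dense LU path is used by default
DENSE_THRESHOLD = 4500

_SINGULARITY_DIST = 1e-9  # m


class SolverConvergenceError(RuntimeError):
    def __init__(self, msg, residual_history=None):
        super().__init__(msg)
        self.residual_history = residual_history or []


@dataclass(frozen=True)
class Dipole:
    """Current dipole: position (m), moment (A·m), and the conductivity of
    the compartment containing it (S/m), which scales its primary field."""

    position: np.ndarray
    moment: np.ndarray
    local_sigma: float

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, float))
        object.__setattr__(self, "moment", np.asarray(self.moment, float))
        if np.linalg.norm(self.moment) <= 0:
            raise ValueError("dipole moment must be non-zero")
        if self.local_sigma <= 0:
            raise ValueError("local conductivity must be positive")

    def _displacements(self, points):
        d = np.asarray(points, float) - self.position
        r = np.linalg.norm(d, axis=-1)
        if np.any(r < _SINGULARITY_DIST):
            raise ValueError(
                "evaluation point coincides with the dipole position "
                f"(min distance {r.min():.3e} m)"
            )
        return d, r

    def potential_at(self, points) -> np.ndarray:
        """Primary potential q·(r-p)/(4 pi sigma |r-p|^3) in volts."""
        d, r = self._displacements(points)
        return d @ self.moment / (4.0 * np.pi * self.local_sigma * r**3)

    def field_at(self, points) -> np.ndarray:
        """Primary field -grad(phi_i) = [3 (q.Rh) Rh - q] / (4 pi sigma R^3)."""
        d, r = self._displacements(points)
        rh = d / r[:, None]
        qr = rh @ self.moment
        return (3.0 * qr[:, None] * rh - self.moment) / (
            4.0 * np.pi * self.local_sigma * r[:, None] ** 3
        )


@dataclass(frozen=True)
class UniformFieldSource:
    """Spatially uniform impressed field (validation source, e.g. the
    sphere-in-uniform-field closed form)."""

    E0: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "E0", np.asarray(self.E0, float))

    def potential_at(self, points) -> np.ndarray:
        return -np.asarray(points, float) @ self.E0

    def field_at(self, points) -> np.ndarray:
        return np.broadcast_to(self.E0, (len(points), 3)).copy()


def impressed_field(dipole: Dipole, points) -> np.ndarray:
    """Primary (infinite-medium) electric field of a current dipole, V/m."""
    return dipole.field_at(points)


def impressed_potential(dipole: Dipole, points) -> np.ndarray:
    return dipole.potential_at(points)


class BemOperator:
    """Matrix-free discretized boundary operator for one HeadModel.

    Caches the flattened facet arrays and the sparse near-field correction;
    provides ``matvec`` / ``rmatvec`` for Krylov solves and ``dense()`` for
    direct factorization.
    """

    def __init__(self, model: HeadModel, backend: str | None = None,
                 near_factor: float = 3.0, deflate: bool = False,
                 reuse: tuple | None = None):
        """``reuse=(old_operator, new_to_old)`` recycles near-field
        correction entries for facets unchanged by a refinement step
        (``new_to_old[j]`` is the old flat index of new facet j, or -1)."""
        self.model = model
        self.backend = get_backend(backend)
        self.near_factor = near_factor
        self._reuse = reuse
        #: when set, the operator acts on the charge-neutral subspace:
        #: inputs and outputs have their per-interface area-weighted mean
        #: removed, and the mean modes pass through as identity.  The
        #: continuous operator annihilates a constant layer on the outer
        #: (K=1) interface, and centroid collocation makes the mean
        #: equations inconsistent at the quadrature-error level, so the
        #: physical neutral solution is obtained by deflating those modes.
        self.deflate = deflate
        self.centroids = model.facet_centroids
        self.normals = model.facet_normals
        self.areas = model.facet_areas
        self.K = model.facet_K
        self.M = model.n_facets
        self._tri = self._triangle_arrays()
        self._C = self._build_field_correction()
        self._reuse = None  # release the previous operator chain
        self._CT = self._C.T.tocsr()
        self._dense_lu = None

    def _triangle_arrays(self):
        va, vb, vc = [], [], []
        for mesh in self.model.interfaces:
            v, f = mesh.vertices, mesh.faces
            va.append(v[f[:, 0]]); vb.append(v[f[:, 1]]); vc.append(v[f[:, 2]])
        return np.vstack(va), np.vstack(vb), np.vstack(vc)

    def _scales(self):
        return np.sqrt(self.areas * 4.0 / np.sqrt(3.0))

    def _build_field_correction(self):
        from scipy import sparse

        if self.near_factor <= 0:
            return sparse.csr_matrix((self.M, self.M))
        tgt, src = nearfield.near_pairs(
            self.centroids, self._scales(), self.centroids, self.near_factor
        )
        if self._reuse is not None:
            old_op, new_to_old = self._reuse
            # entries between facets untouched by refinement are geometry-
            # identical: copy them with a selection product and integrate
            # only the pairs that involve a new (child) facet
            mapped = new_to_old >= 0
            keep_j = np.flatnonzero(mapped)
            R = sparse.coo_matrix(
                (np.ones(len(keep_j)), (keep_j, new_to_old[keep_j])),
                shape=(self.M, old_op.M),
            ).tocsr()
            reused = R @ old_op._C @ R.T
            fresh = ~(mapped[tgt] & mapped[src])
            tgt, src = tgt[fresh], src[fresh]
        else:
            reused = None
        tri = (self._tri[0][src], self._tri[1][src], self._tri[2][src])
        C = nearfield.field_correction_matrix(
            tri, self.centroids, self.areas, self.centroids, self.normals,
            tgt, src, exclude_identical=True,
        )
        if reused is not None:
            C = (C + reused).tocsr()
        return C

    # -- linear algebra ----------------------------------------------------

    def project_neutral(self, x: np.ndarray) -> np.ndarray:
        """Remove the per-interface area-weighted mean (P x)."""
        x = np.array(x, float)
        for i in range(self.model.n_interfaces):
            s = self.model.interface_slice(i)
            x[s] -= (x[s] @ self.areas[s]) / self.areas[s].sum()
        return x

    def _project_neutral_T(self, x: np.ndarray) -> np.ndarray:
        x = np.array(x, float)
        for i in range(self.model.n_interfaces):
            s = self.model.interface_slice(i)
            x[s] -= self.areas[s] * x[s].sum() / self.areas[s].sum()
        return x

    def _raw_matvec(self, rho: np.ndarray) -> np.ndarray:
        fld = self.backend.coulomb_field(self.centroids, rho * self.areas,
                                         self.centroids)
        g = np.einsum("mk,mk->m", self.normals, fld) + self._C @ rho
        return 0.5 * rho - self.K * g

    def matvec(self, rho: np.ndarray) -> np.ndarray:
        rho = np.asarray(rho, float)
        if not self.deflate:
            return self._raw_matvec(rho)
        p = self.project_neutral(rho)
        return self.project_neutral(self._raw_matvec(p)) + (rho - p)

    def _raw_rmatvec(self, x: np.ndarray) -> np.ndarray:
        v = self.K * x
        dotted = self.backend.dotted_field(
            self.centroids, v[:, None] * self.normals, self.centroids
        )
        # G^T v = -areas * dotted + C^T v   (sign: dotted evaluates at the
        # source location, flipping the displacement vector)
        gtv = -self.areas * dotted + self._CT @ v
        return 0.5 * x - gtv

    def rmatvec(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        if not self.deflate:
            return self._raw_rmatvec(x)
        p = self._project_neutral_T(x)
        return self._project_neutral_T(self._raw_rmatvec(p)) + (x - p)

    def as_linear_operator(self) -> LinearOperator:
        return LinearOperator(
            (self.M, self.M), matvec=self.matvec, rmatvec=self.rmatvec,
            dtype=np.float64,
        )

    def dense(self) -> np.ndarray:
        """Assemble the full collocation matrix (near corrections included)."""
        M = self.M
        G = np.empty((M, M))
        chunk = max(1, int(2**22 // max(M, 1)))
        for s in range(0, M, chunk):
            t = self.centroids[s : s + chunk]
            d = t[:, None, :] - self.centroids[None, :, :]
            r2 = np.einsum("tnk,tnk->tn", d, d)
            with np.errstate(divide="ignore", invalid="ignore"):
                w = self.areas / (r2 * np.sqrt(r2))
            w[r2 == 0.0] = 0.0
            G[s : s + chunk] = (
                np.einsum("tk,tnk->tn", self.normals[s : s + chunk], d) * w
            ) / (4.0 * np.pi)
        C = self._C.tocoo()
        G[C.row, C.col] += C.data
        A = -self.K[:, None] * G
        A[np.diag_indices(M)] += 0.5
        if self.deflate:
            # B = P A P + (I - P), with P the per-interface area-weighted
            # mean-removal projector (rank-one update per interface)
            for i in range(self.model.n_interfaces):
                s = self.model.interface_slice(i)
                v = self.areas[s] / self.areas[s].sum()
                A[s, :] -= v @ A[s, :]
            for i in range(self.model.n_interfaces):
                s = self.model.interface_slice(i)
                v = self.areas[s] / self.areas[s].sum()
                A[:, s] -= np.outer(A[:, s].sum(axis=1), v)
                A[s, s] += v[None, :]
        return A

    def dense_lu(self):
        if self._dense_lu is None:
            self._dense_lu = sla.lu_factor(self.dense())
        return self._dense_lu


@dataclass
class ChargeSolution:
    """Per-facet scaled surface charge density rho/eps0 (V/m) on a model."""

    model: HeadModel
    rho: np.ndarray
    source: object
    solver_stats: dict = field(default_factory=dict)
    operator: BemOperator | None = None

    def charge_imbalance(self) -> float:
        """|sum rho A| / sum |rho| A — global neutrality measure."""
        A = self.model.facet_areas
        denom = float(np.abs(self.rho) @ A)
        if denom == 0.0:
            return 0.0
        return abs(float(self.rho @ A)) / denom


def apply_operator(model: HeadModel, rho: np.ndarray, backend: str | None = None,
                   near_factor: float = 3.0) -> np.ndarray:
    """One application of the discretized boundary operator (rho/eps0 units)."""
    rho = np.asarray(rho, float)
    if rho.shape != (model.n_facets,):
        raise ValueError(
            f"rho has shape {rho.shape}, expected ({model.n_facets},)"
        )
    return BemOperator(model, backend, near_factor).matvec(rho)


def solve_charges(
    model: HeadModel,
    source,
    tol: float = 1e-6,
    backend: str | None = None,
    near_factor: float = 3.0,
    method: str = "auto",
    restart: int = 200,
    maxiter: int = 400,
    x0: np.ndarray | None = None,
    operator: BemOperator | None = None,
    neutralize: bool = True,
) -> ChargeSolution:
    """Solve the discretized charge equation for a source (dipole or other).

    ``method`` is ``"gmres"``, ``"dense"`` or ``"auto"`` (dense below
    :data:`DENSE_THRESHOLD` facets).  With ``neutralize`` (the default) the
    system is solved on the charge-neutral subspace — the per-interface
    mean modes, whose continuous counterpart is the physically excluded
    monopole layer, are deflated — and the returned density has exactly
    zero net charge on every interface.  Solver statistics (iterations,
    relative residual of the discretized equation, method) are recorded.
    """
    if not (0.0 < tol <= 1e-2):
        raise ValueError(f"tol must be in (0, 1e-2], got {tol}")
    op = operator if operator is not None else BemOperator(
        model, backend, near_factor, deflate=neutralize
    )
    b = op.K * np.einsum("mk,mk->m", op.normals, source.field_at(op.centroids))
    if op.deflate:
        b = op.project_neutral(b)
    bnorm = np.linalg.norm(b)
    if bnorm == 0.0:
        return ChargeSolution(model, np.zeros(op.M), source,
                              {"iterations": 0, "residual": 0.0, "method": "trivial"},
                              operator=op)
    if method == "auto":
        method = "dense" if op.M <= DENSE_THRESHOLD else "gmres"
    if method == "dense":
        rho = sla.lu_solve(op.dense_lu(), b)
        iters = 1
    elif method == "gmres":
        history: list[float] = []
        rho, info = gmres(
            op.as_linear_operator(), b, x0=x0, rtol=tol * 0.5, atol=0.0,
            restart=restart, maxiter=maxiter,
            callback=lambda pr: history.append(float(pr)),
            callback_type="pr_norm",
        )
        iters = len(history)
        if info != 0:
            raise SolverConvergenceError(
                f"GMRES failed to reach rtol={tol} within {maxiter} outer "
                f"iterations (last residual {history[-1] if history else 'n/a'})",
                residual_history=history,
            )
    else:
        raise ValueError(f"unknown method {method!r}")
    if op.deflate:
        rho = op.project_neutral(rho)
    residual = float(np.linalg.norm(op.matvec(rho) - b) / bnorm)
    if residual > tol:
        raise SolverConvergenceError(
            f"post-solve residual {residual:.3e} exceeds tol {tol}"
        )
    return ChargeSolution(
        model, rho, source,
        {"iterations": iters, "residual": residual, "method": method},
        operator=op,
    )


def surface_potential(
    solution: ChargeSolution,
    points,
    source=None,
    backend: str | None = None,
    near_factor: float = 3.0,
) -> np.ndarray:
    """Total potential phi_i + phi_s at arbitrary points (volts).

    The secondary (induced-charge) potential uses the n-body point sum
    upgraded to exact flat-triangle integration for facets within
    ``near_factor`` mesh lengths — including the evaluation point's own
    facet, so skin centroids are legal evaluation points.
    """
    points = np.atleast_2d(np.asarray(points, float))
    source = source if source is not None else solution.source
    model = solution.model
    op = solution.operator
    be = get_backend(backend) if backend is not None else (
        op.backend if op is not None else get_backend(None)
    )
    centroids = model.facet_centroids
    areas = model.facet_areas
    phi = source.potential_at(points)
    phi = phi + be.coulomb_potential(centroids, solution.rho * areas, points)
    if near_factor > 0:
        scales = np.sqrt(areas * 4.0 / np.sqrt(3.0))
        tgt, src = nearfield.near_pairs(centroids, scales, points, near_factor)
        if len(tgt):
            if op is not None:
                tri = (op._tri[0][src], op._tri[1][src], op._tri[2][src])
            else:
                tri_all = BemOperator.__new__(BemOperator)
                tri_all.model = model
                ta, tb, tc = BemOperator._triangle_arrays(tri_all)
                tri = (ta[src], tb[src], tc[src])
            P = nearfield.potential_correction_matrix(
                tri, centroids, areas, points, tgt, src
            )
            phi = phi + P @ solution.rho
    return phi


def secondary_field(solution: ChargeSolution, points,
                    backend: str | None = None) -> np.ndarray:
    """Electric field of the induced surface charges at points (V/m)."""
    be = get_backend(backend)
    return be.coulomb_field(
        solution.model.facet_centroids,
        solution.rho * solution.model.facet_areas,
        np.atleast_2d(np.asarray(points, float)),
    )


@dataclass
class EEGSample:
    """Single-time-sample electrode potentials (volts)."""

    voltages: np.ndarray
    labels: tuple
    reference: str = "infinity"

    def __post_init__(self):
        self.voltages = np.asarray(self.voltages, float)
        if len(self.voltages) != len(self.labels):
            raise ValueError("voltage/label length mismatch")

    def average_reference(self) -> "EEGSample":
        return EEGSample(
            self.voltages - self.voltages.mean(), self.labels, "average"
        )


def electrode_voltages(solution: ChargeSolution, electrodes,
                       source=None, reference: str = "infinity") -> EEGSample:
    """Sample the surface potential at each electrode's skin-facet centroid."""
    model = solution.model
    skin = model.interfaces[0]
    idx = np.asarray(electrodes.facet_index, int)
    if idx.min() < 0 or idx.max() >= skin.n_facets:
        raise ValueError(
            "electrode facet assignment outside the skin interface "
            f"(facet counts: skin={skin.n_facets}, max index={idx.max()})"
        )
    points = skin.facet_centroid[idx]
    v = surface_potential(solution, points, source=source)
    sample = EEGSample(v, tuple(electrodes.labels), "infinity")
    if reference == "average":
        sample = sample.average_reference()
    elif reference != "infinity":
        raise ValueError(f"unknown reference {reference!r}")
    return sample
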