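"""Analytic near-field integrals for flat-triangle single layers.

Centroid (point-charge) collocation of the 1/R kernel is inaccurate, and
eventually divergent, when source and observation facets are only a few
mesh lengths apart — exactly the situation created by thin inter-layer
gaps and by adaptive refinement.  For such close pairs the point kernel is
replaced by the exact integral of a *uniform* charge layer over the flat
source triangle, using the classical edge-decomposition closed forms:

    P(r)  =  ∫_T  dS' / |r - r'|
    F(r)  =  ∫_T (r - r') / |r - r'|^3  dS'   ( = -grad P )

Both are regular for observation points off the (open) triangle, and P is
also finite on the triangle itself, so skin-facet centroids can evaluate
their own facet's potential contribution exactly.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

__all__ = [
    "triangle_potential_integral",
    "triangle_field_integral",
    "near_pairs",
    "field_correction_matrix",
    "potential_correction_matrix",
]

_TINY = 1e-300


def _edge_terms(tri_a, tri_b, tri_c, points):
    """Shared per-edge quantities for the edge-decomposition formulas.

    All inputs are (P, 3) arrays (one triangle per observation point).
    Yields, per edge, the tuple (m_hat, P0, log_term, atan_term) plus the
    signed height w0 and unit normal after the loop via closure state.
    """
    e1 = tri_b - tri_a
    e2 = tri_c - tri_a
    n = np.cross(e1, e2)
    n_norm = np.linalg.norm(n, axis=1, keepdims=True)
    n_hat = n / np.maximum(n_norm, _TINY)
    w0 = np.einsum("pk,pk->p", points - tri_a, n_hat)  # signed height
    rho = points - w0[:, None] * n_hat  # in-plane projection
    abs_w0 = np.abs(w0)

    edges = ((tri_a, tri_b), (tri_b, tri_c), (tri_c, tri_a))
    per_edge = []
    for A, B in edges:
        t = B - A
        t_hat = t / np.maximum(np.linalg.norm(t, axis=1, keepdims=True), _TINY)
        m_hat = np.cross(t_hat, n_hat)  # outward in-plane edge normal
        lm = np.einsum("pk,pk->p", A - rho, t_hat)
        lp = np.einsum("pk,pk->p", B - rho, t_hat)
        P0 = np.einsum("pk,pk->p", A - rho, m_hat)
        Rm = np.linalg.norm(points - A, axis=1)
        Rp = np.linalg.norm(points - B, axis=1)
        R02 = P0 * P0 + w0 * w0
        # log term; the argument degenerates only for observation points on
        # the edge's carrier line, where the P0 prefactor vanishes anyway
        num = np.maximum(Rp + lp, _TINY)
        den = np.maximum(Rm + lm, _TINY)
        log_t = np.log(num / den)
        at_p = np.arctan2(P0 * lp, R02 + abs_w0 * Rp)
        at_m = np.arctan2(P0 * lm, R02 + abs_w0 * Rm)
        per_edge.append((m_hat, P0, log_t, at_p - at_m))
    return per_edge, w0, abs_w0, n_hat


def triangle_potential_integral(tri_a, tri_b, tri_c, points) -> np.ndarray:
    """Exact ∫ 1/|r - r'| dS' over flat triangles, one per observation point."""
    per_edge, _w0, abs_w0, _n_hat = _edge_terms(
        np.asarray(tri_a, float), np.asarray(tri_b, float),
        np.asarray(tri_c, float), np.asarray(points, float),
    )
    out = np.zeros(len(_w0))
    for m_hat, P0, log_t, atan_t in per_edge:
        out += P0 * log_t - abs_w0 * atan_t
    return out


def triangle_field_integral(tri_a, tri_b, tri_c, points) -> np.ndarray:
    """Exact ∫ (r - r')/|r - r'|^3 dS' over flat triangles (one per point)."""
    per_edge, w0, abs_w0, n_hat = _edge_terms(
        np.asarray(tri_a, float), np.asarray(tri_b, float),
        np.asarray(tri_c, float), np.asarray(points, float),
    )
    out = np.zeros((len(w0), 3))
    omega = np.zeros(len(w0))
    for m_hat, _P0, log_t, atan_t in per_edge:
        out += m_hat * log_t[:, None]
        omega += atan_t
    out += n_hat * (np.sign(w0) * omega)[:, None]
    return out


def near_pairs(
    src_centroids: np.ndarray,
    src_scale: np.ndarray,
    targets: np.ndarray,
    factor: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Indices (target, source) of pairs closer than ``factor`` source scales.

    ``src_scale`` is the per-facet mesh length (equal-area equilateral edge).
    Includes exactly collocated pairs (distance 0), which the point-sum
    primitives skip; correction builders decide how to treat them.
    """
    tree = cKDTree(targets)
    radii = factor * np.asarray(src_scale, float)
    hits = tree.query_ball_point(src_centroids, r=radii)
    src_idx = np.concatenate(
        [np.full(len(h), i, dtype=np.int64) for i, h in enumerate(hits)]
    ) if len(hits) else np.empty(0, np.int64)
    tgt_idx = (
        np.concatenate([np.asarray(h, dtype=np.int64) for h in hits])
        if len(hits)
        else np.empty(0, np.int64)
    )
    return tgt_idx, src_idx


def _pair_arrays(vertices, faces, src_idx):
    f = faces[src_idx]
    return vertices[f[:, 0]], vertices[f[:, 1]], vertices[f[:, 2]]


def field_correction_matrix(
    tri_verts_per_src: tuple,
    src_centroids: np.ndarray,
    src_areas: np.ndarray,
    target_points: np.ndarray,
    target_normals: np.ndarray,
    tgt_idx: np.ndarray,
    src_idx: np.ndarray,
    exclude_identical: bool = True,
) -> sparse.csr_matrix:
    """Sparse correction C with C[t, s] = n_t·(F_exact - F_point)/(4π).

    Applied to the charge-density vector, ``C @ rho`` upgrades the point
    n-body normal-field sum to exact flat-triangle integration for the
    listed near pairs.  Collocated (self) pairs are dropped when
    ``exclude_identical`` — the analytic jump term owns the self response.
    """
    A, B, C = tri_verts_per_src
    vals = np.empty(len(tgt_idx))
    chunk = 200_000
    for s in range(0, len(tgt_idx), chunk):
        ti, si = tgt_idx[s : s + chunk], src_idx[s : s + chunk]
        a, b, c = A[s : s + chunk], B[s : s + chunk], C[s : s + chunk]
        pts = target_points[ti]
        d = pts - src_centroids[si]
        r2 = np.einsum("pk,pk->p", d, d)
        F_exact = triangle_field_integral(a, b, c, pts)
        with np.errstate(divide="ignore", invalid="ignore"):
            F_point = src_areas[si, None] * d / (r2 * np.sqrt(r2))[:, None]
        F_point[r2 == 0.0] = 0.0
        v = np.einsum("pk,pk->p", target_normals[ti], F_exact - F_point)
        if exclude_identical:
            v[r2 == 0.0] = 0.0
        vals[s : s + chunk] = v / (4.0 * np.pi)
    M_t, M_s = len(target_points), len(src_centroids)
    return sparse.coo_matrix((vals, (tgt_idx, src_idx)), shape=(M_t, M_s)).tocsr()


def potential_correction_matrix(
    tri_verts_per_src: tuple,
    src_centroids: np.ndarray,
    src_areas: np.ndarray,
    target_points: np.ndarray,
    tgt_idx: np.ndarray,
    src_idx: np.ndarray,
) -> sparse.csr_matrix:
    """Sparse correction P with P[t, s] = (P_exact - A_s/R)/(4π).

    For collocated pairs (R = 0, e.g. a skin centroid evaluating its own
    facet) the point term is absent from the n-body sum, so the correction
    is the exact self integral alone.
    """
    A, B, C = tri_verts_per_src
    vals = np.empty(len(tgt_idx))
    chunk = 200_000
    for s in range(0, len(tgt_idx), chunk):
        ti, si = tgt_idx[s : s + chunk], src_idx[s : s + chunk]
        a, b, c = A[s : s + chunk], B[s : s + chunk], C[s : s + chunk]
        pts = target_points[ti]
        d = pts - src_centroids[si]
        r2 = np.einsum("pk,pk->p", d, d)
        P_exact = triangle_potential_integral(a, b, c, pts)
        with np.errstate(divide="ignore", invalid="ignore"):
            P_point = src_areas[si] / np.sqrt(r2)
        P_point[r2 == 0.0] = 0.0
        vals[s : s + chunk] = (P_exact - P_point) / (4.0 * np.pi)
    M_t, M_s = len(target_points), len(src_centroids)
    return sparse.coo_matrix((vals, (tgt_idx, src_idx)), shape=(M_t, M_s)).tocsr()
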