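"""Pairwise Coulomb-sum backends for the charge-based BEM operator.

The discretized operator and potential evaluation both reduce to n-body
sums over facet centroids with the free-space kernel 1/(4*pi*R).  Two
interchangeable backends implement the same three primitives:

``numpy``
    Chunked vectorized direct sum; the reference implementation.
``numba``
    JIT-compiled direct sum (single-threaded, no fastmath so results agree
    with the reference to rounding order); the default when numba imports.

Additional backends (e.g. an external FMM library) can be registered via
:func:`register_backend`; they must satisfy the same primitive contract.
Pairs at exactly zero distance (a target collocated with a source, i.e.
the self term) are skipped by every primitive — the analytic jump term
handles the self interaction.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "get_backend",
    "register_backend",
    "available_backends",
    "default_backend_name",
]

_CHUNK = 1024  # target rows per numpy block; bounds peak memory at O(CHUNK * N)


class _NumpyBackend:
    """Chunked direct summation in pure numpy (reference backend)."""

    name = "numpy"

    @staticmethod
    def coulomb_field(sources, charges, targets):
        """sum_n q_n (t - r_n) / (4 pi |t - r_n|^3) for each target t."""
        out = np.zeros((len(targets), 3))
        for s in range(0, len(targets), _CHUNK):
            t = targets[s : s + _CHUNK]
            d = t[:, None, :] - sources[None, :, :]
            r2 = np.einsum("tnk,tnk->tn", d, d)
            with np.errstate(divide="ignore", invalid="ignore"):
                w = charges / (r2 * np.sqrt(r2))
            w[r2 == 0.0] = 0.0
            out[s : s + _CHUNK] = np.einsum("tn,tnk->tk", w, d)
        return out / (4.0 * np.pi)

    @staticmethod
    def coulomb_potential(sources, charges, targets):
        """sum_n q_n / (4 pi |t - r_n|) for each target t."""
        out = np.zeros(len(targets))
        for s in range(0, len(targets), _CHUNK):
            t = targets[s : s + _CHUNK]
            d = t[:, None, :] - sources[None, :, :]
            r2 = np.einsum("tnk,tnk->tn", d, d)
            with np.errstate(divide="ignore", invalid="ignore"):
                w = charges / np.sqrt(r2)
            w[r2 == 0.0] = 0.0
            out[s : s + _CHUNK] = w.sum(axis=1)
        return out / (4.0 * np.pi)

    @staticmethod
    def dotted_field(sources, weights, targets):
        """sum_n w_n . (t - r_n) / (4 pi |t - r_n|^3) for each target t."""
        out = np.zeros(len(targets))
        for s in range(0, len(targets), _CHUNK):
            t = targets[s : s + _CHUNK]
            d = t[:, None, :] - sources[None, :, :]
            r2 = np.einsum("tnk,tnk->tn", d, d)
            num = np.einsum("tnk,nk->tn", d, weights)
            with np.errstate(divide="ignore", invalid="ignore"):
                w = num / (r2 * np.sqrt(r2))
            w[r2 == 0.0] = 0.0
            out[s : s + _CHUNK] = w.sum(axis=1)
        return out / (4.0 * np.pi)


def _build_numba_backend():
    import numba

    @numba.njit(cache=True)
    def _field(sources, charges, targets):
        T = targets.shape[0]
        N = sources.shape[0]
        out = np.zeros((T, 3))
        for t in range(T):
            ax = ay = az = 0.0
            tx, ty, tz = targets[t, 0], targets[t, 1], targets[t, 2]
            for n in range(N):
                dx = tx - sources[n, 0]
                dy = ty - sources[n, 1]
                dz = tz - sources[n, 2]
                r2 = dx * dx + dy * dy + dz * dz
                if r2 == 0.0:
                    continue
                w = charges[n] / (r2 * np.sqrt(r2))
                ax += w * dx
                ay += w * dy
                az += w * dz
            out[t, 0] = ax
            out[t, 1] = ay
            out[t, 2] = az
        return out / (4.0 * np.pi)

    @numba.njit(cache=True)
    def _potential(sources, charges, targets):
        T = targets.shape[0]
        N = sources.shape[0]
        out = np.zeros(T)
        for t in range(T):
            acc = 0.0
            tx, ty, tz = targets[t, 0], targets[t, 1], targets[t, 2]
            for n in range(N):
                dx = tx - sources[n, 0]
                dy = ty - sources[n, 1]
                dz = tz - sources[n, 2]
                r2 = dx * dx + dy * dy + dz * dz
                if r2 == 0.0:
                    continue
                acc += charges[n] / np.sqrt(r2)
            out[t] = acc
        return out / (4.0 * np.pi)

    @numba.njit(cache=True)
    def _dotted(sources, weights, targets):
        T = targets.shape[0]
        N = sources.shape[0]
        out = np.zeros(T)
        for t in range(T):
            acc = 0.0
            tx, ty, tz = targets[t, 0], targets[t, 1], targets[t, 2]
            for n in range(N):
                dx = tx - sources[n, 0]
                dy = ty - sources[n, 1]
                dz = tz - sources[n, 2]
                r2 = dx * dx + dy * dy + dz * dz
                if r2 == 0.0:
                    continue
                num = weights[n, 0] * dx + weights[n, 1] * dy + weights[n, 2] * dz
                acc += num / (r2 * np.sqrt(r2))
            out[t] = acc
        return out / (4.0 * np.pi)

    class _NumbaBackend:
        name = "numba"
        coulomb_field = staticmethod(
            lambda s, q, t: _field(
                np.ascontiguousarray(s), np.ascontiguousarray(q, dtype=np.float64),
                np.ascontiguousarray(t),
            )
        )
        coulomb_potential = staticmethod(
            lambda s, q, t: _potential(
                np.ascontiguousarray(s), np.ascontiguousarray(q, dtype=np.float64),
                np.ascontiguousarray(t),
            )
        )
        dotted_field = staticmethod(
            lambda s, w, t: _dotted(
                np.ascontiguousarray(s), np.ascontiguousarray(w, dtype=np.float64),
                np.ascontiguousarray(t),
            )
        )

    return _NumbaBackend()


_REGISTRY: dict = {"numpy": _NumpyBackend()}
_DEFAULT: str | None = None


def register_backend(name: str, backend) -> None:
    for attr in ("coulomb_field", "coulomb_potential", "dotted_field"):
        if not callable(getattr(backend, attr, None)):
            raise TypeError(f"backend {name!r} lacks required primitive {attr!r}")
    _REGISTRY[name] = backend


def available_backends() -> tuple:
    _ensure_numba_registered()
    return tuple(_REGISTRY)


def _ensure_numba_registered() -> None:
    if "numba" not in _REGISTRY:
        try:
            _REGISTRY["numba"] = _build_numba_backend()
        except ImportError:
            pass


def default_backend_name() -> str:
    global _DEFAULT
    if _DEFAULT is None:
        _ensure_numba_registered()
        _DEFAULT = "numba" if "numba" in _REGISTRY else "numpy"
    return _DEFAULT


def get_backend(name: str | None = None):
    """Fetch an n-body backend by name (default: numba if available)."""
    if name is None:
        name = default_backend_name()
    _ensure_numba_registered()
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown n-body backend {name!r}; available: {tuple(_REGISTRY)}"
        ) from None
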