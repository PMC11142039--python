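"""Layered head phantoms: nested closed surfaces with conductivity contrasts.

A :class:`HeadModel` is an ordered list of closed interfaces (outermost to
innermost).  Each interface separates an outer compartment of conductivity
``sigma_out`` from an inner compartment of conductivity ``sigma_in``; the
dimensionless contrast ``K = (sigma_in - sigma_out) / (sigma_in + sigma_out)``
is what drives the induced surface charge in the charge-based BEM.  Air
outside the outermost (skin) interface has conductivity exactly 0, giving
K = 1 there.

Phantoms are nested icospheres standing in for MRI-derived head surfaces:
a 5-layer model (skin, skull, CSF, grey matter, white matter) whose default
radii include a deliberately thin 2 mm CSF-GM gap — the geometric hazard
that makes adaptive refinement necessary — and a decimated-resolution
3-layer model (SKIN, SKULL, BRAIN) used as the inverse volume conductor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

from .mesh import TriangleMesh, icosphere, subdivide_facets

__all__ = [
    "ConductivitySet",
    "HeadModel",
    "contrast",
    "conductivity_preset",
    "preset_names",
    "build_phantom_5",
    "build_phantom_3",
    "nesting_check",
    "FIVE_LAYER_TISSUES",
    "THREE_LAYER_TISSUES",
    "DEFAULT_RADII_5_MM",
    "DEFAULT_RADII_3_MM",
]

FIVE_LAYER_TISSUES = ("skin", "skull", "csf", "gm", "wm")
THREE_LAYER_TISSUES = ("SKIN", "SKULL", "BRAIN")

#: Default phantom radii (mm), outermost first.  The 80/78 pair creates the
#: thin CSF-GM gap (2 mm) typical of real intracortical geometry.
DEFAULT_RADII_5_MM = (92.0, 86.0, 80.0, 78.0, 70.0)
DEFAULT_RADII_3_MM = (92.0, 86.0, 80.0)


def contrast(sigma_in: float, sigma_out: float) -> float:
    """Conductivity contrast K = (s_in - s_out)/(s_in + s_out).

    ``sigma_out = 0`` encodes air (K = 1).  Both zero is undefined.
    """
    if sigma_in < 0 or sigma_out < 0:
        raise ValueError("conductivities must be non-negative")
    if sigma_in + sigma_out == 0:
        raise ValueError("contrast undefined: both conductivities are zero")
    return (sigma_in - sigma_out) / (sigma_in + sigma_out)


@dataclass(frozen=True)
class ConductivitySet:
    """Named tissue→conductivity map (S/m)."""

    name: str
    tissue_to_sigma: dict

    def __post_init__(self):
        for tissue, sigma in self.tissue_to_sigma.items():
            if sigma <= 0:
                raise ValueError(f"conductivity of {tissue!r} must be > 0, got {sigma}")

    def __getitem__(self, tissue: str) -> float:
        return self.tissue_to_sigma[tissue]

    def require(self, tissues) -> "ConductivitySet":
        missing = [t for t in tissues if t not in self.tissue_to_sigma]
        if missing:
            raise ValueError(f"conductivity set {self.name!r} lacks tissues {missing}")
        return self

    def scaled(self, factor: float) -> "ConductivitySet":
        return ConductivitySet(
            f"{self.name}*{factor:g}",
            {t: s * factor for t, s in self.tissue_to_sigma.items()},
        )


def _load_presets() -> dict:
    text = resources.files("headbem").joinpath("data/conductivities.yaml").read_text()
    raw = yaml.safe_load(text)
    return {name: ConductivitySet(name, dict(vals)) for name, vals in raw.items()}


_PRESETS: dict | None = None


def preset_names() -> tuple:
    global _PRESETS
    if _PRESETS is None:
        _PRESETS = _load_presets()
    return tuple(_PRESETS)


def conductivity_preset(name: str) -> ConductivitySet:
    """Look up a shipped preset (ITIS7, VWB7, SimNIBS7, ITIS3, VWB3, SimNIBS3).

    Apostrophes and case are ignored, so ``"IT'IS7"`` and ``"itis7"`` both
    resolve to the same set.
    """
    global _PRESETS
    if _PRESETS is None:
        _PRESETS = _load_presets()
    key = name.replace("'", "").replace("’", "").lower()
    for pname, preset in _PRESETS.items():
        if pname.lower() == key:
            return preset
    raise KeyError(f"unknown conductivity preset {name!r}; have {tuple(_PRESETS)}")


@dataclass(frozen=True)
class HeadModel:
    """Nested closed interfaces with per-facet conductivity contrasts.

    ``interfaces`` are ordered outermost → innermost.  ``sigma_in[i]`` /
    ``sigma_out[i]`` are the conductivities just inside / outside interface
    ``i``; consistency along the nesting chain (the region inside interface
    ``i`` is the region outside interface ``i+1``) is validated.
    """

    interfaces: tuple
    names: tuple
    sigma_in: tuple
    sigma_out: tuple
    refinable: tuple
    centers: tuple = None  # nominal shell centers; used for containment tests
    _flat: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        n = len(self.interfaces)
        if not (len(self.sigma_in) == len(self.sigma_out) == len(self.names) == n):
            raise ValueError("per-interface field lengths disagree")
        for i in range(n - 1):
            if not np.isclose(self.sigma_in[i], self.sigma_out[i + 1]):
                raise ValueError(
                    f"conductivity chain broken between interfaces {i} and {i+1}: "
                    f"sigma_in[{i}]={self.sigma_in[i]} != sigma_out[{i+1}]={self.sigma_out[i+1]}"
                )
        if self.centers is None:
            object.__setattr__(
                self,
                "centers",
                tuple(tuple(m.vertices.mean(axis=0)) for m in self.interfaces),
            )

    # -- flattened per-facet arrays (cached) ------------------------------

    @property
    def n_interfaces(self) -> int:
        return len(self.interfaces)

    @property
    def interface_K(self) -> np.ndarray:
        return np.array(
            [contrast(si, so) for si, so in zip(self.sigma_in, self.sigma_out)]
        )

    def _flatten(self) -> dict:
        if not self._flat:
            counts = [m.n_facets for m in self.interfaces]
            offsets = np.concatenate([[0], np.cumsum(counts)])
            self._flat.update(
                centroids=np.vstack([m.facet_centroid for m in self.interfaces]),
                normals=np.vstack([m.facet_normal for m in self.interfaces]),
                areas=np.concatenate([m.facet_area for m in self.interfaces]),
                K=np.concatenate(
                    [np.full(c, k) for c, k in zip(counts, self.interface_K)]
                ),
                offsets=offsets,
            )
        return self._flat

    @property
    def facet_centroids(self) -> np.ndarray:
        return self._flatten()["centroids"]

    @property
    def facet_normals(self) -> np.ndarray:
        return self._flatten()["normals"]

    @property
    def facet_areas(self) -> np.ndarray:
        return self._flatten()["areas"]

    @property
    def facet_K(self) -> np.ndarray:
        return self._flatten()["K"]

    @property
    def facet_offsets(self) -> np.ndarray:
        """Start offsets of each interface in the flat facet arrays."""
        return self._flatten()["offsets"]

    @property
    def n_facets(self) -> int:
        return int(sum(m.n_facets for m in self.interfaces))

    def interface_slice(self, i: int) -> slice:
        off = self.facet_offsets
        return slice(int(off[i]), int(off[i + 1]))

    def interface_of_facet(self, flat_index: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.facet_offsets, flat_index, side="right") - 1

    @property
    def refinable_facet_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_facets, dtype=bool)
        for i, r in enumerate(self.refinable):
            if r:
                mask[self.interface_slice(i)] = True
        return mask

    # -- physics helpers ---------------------------------------------------

    def compartment_sigma(self, point) -> float:
        """Conductivity of the compartment geometrically containing *point*.

        Uses distance to the nominal shell center against the interface's
        directional radius, which is exact for the (possibly offset)
        spherical phantoms this package generates.
        """
        point = np.asarray(point, float)
        sigma = self.sigma_out[0]  # air if outside everything
        for i, mesh in enumerate(self.interfaces):
            c = np.asarray(self.centers[i])
            r = np.linalg.norm(point - c)
            radii = np.linalg.norm(mesh.vertices - c, axis=1)
            if r < radii.min():
                sigma = self.sigma_in[i]
            elif r < radii.max():
                # between min and max vertex radius: fall back to a
                # containment test against the actual surface
                if bool(mesh.contains(point)[0]):
                    sigma = self.sigma_in[i]
                else:
                    return sigma
            else:
                return sigma
        return sigma

    def with_refined_interface(self, i: int, mesh: TriangleMesh) -> "HeadModel":
        interfaces = list(self.interfaces)
        interfaces[i] = mesh
        return replace(self, interfaces=tuple(interfaces), _flat={})


# -- phantom builders -----------------------------------------------------

def _check_radii(radii_mm, n: int) -> np.ndarray:
    radii = np.asarray(radii_mm, dtype=float)
    if radii.shape != (n,):
        raise ValueError(f"expected {n} radii, got {radii.shape}")
    if np.any(np.diff(radii) >= 0) or np.any(radii <= 0):
        raise ValueError(f"radii must be positive and strictly decreasing, got {radii_mm}")
    return radii * 1e-3  # mm -> m


def _build_phantom(radii_m, tissues, cond, n_subdiv, refinable, centers_m=None):
    sigmas = [cond[t] for t in tissues]
    sigma_out = [0.0] + sigmas[:-1]
    if centers_m is None:
        centers_m = [np.zeros(3)] * len(radii_m)
    if np.isscalar(n_subdiv):
        n_subdiv = [n_subdiv] * len(radii_m)
    elif len(n_subdiv) != len(radii_m):
        raise ValueError("need one subdivision level per interface")
    interfaces = tuple(
        icosphere(r, s, center=c)
        for r, s, c in zip(radii_m, n_subdiv, centers_m)
    )
    return HeadModel(
        interfaces=interfaces,
        names=tuple(tissues),
        sigma_in=tuple(sigmas),
        sigma_out=tuple(sigma_out),
        refinable=tuple(refinable),
        centers=tuple(tuple(np.asarray(c, float)) for c in centers_m),
    )


def build_phantom_5(
    radii_mm=DEFAULT_RADII_5_MM,
    conductivities: ConductivitySet | str = "ITIS7",
    n_subdiv: int = 3,
    centers_mm=None,
) -> HeadModel:
    """5-interface nested-sphere phantom: skin, skull, CSF, GM, WM.

    The skin interface is marked non-refinable — it is the observation
    surface for the AMR stopping criterion, so its facet set must stay
    fixed across refinement steps.
    """
    if isinstance(conductivities, str):
        conductivities = conductivity_preset(conductivities)
    conductivities.require(FIVE_LAYER_TISSUES)
    radii = _check_radii(radii_mm, 5)
    centers = None if centers_mm is None else [np.asarray(c, float) * 1e-3 for c in centers_mm]
    return _build_phantom(
        radii, FIVE_LAYER_TISSUES, conductivities, n_subdiv,
        refinable=(False, True, True, True, True), centers_m=centers,
    )


def build_phantom_3(
    radii_mm=DEFAULT_RADII_3_MM,
    conductivities: ConductivitySet | str = "ITIS3",
    n_subdiv: int = 4,
    centers_mm=None,
) -> HeadModel:
    """3-interface phantom: SKIN, SKULL, BRAIN (the inverse volume conductor).

    Default resolution (n_subdiv=4, 5120 facets per shell) plays the role of
    the decimated ~14k-triangle surfaces of practical inverse models, scaled
    to phantom size.
    """
    if isinstance(conductivities, str):
        conductivities = conductivity_preset(conductivities)
    conductivities.require(THREE_LAYER_TISSUES)
    radii = _check_radii(radii_mm, 3)
    centers = None if centers_mm is None else [np.asarray(c, float) * 1e-3 for c in centers_mm]
    return _build_phantom(
        radii, THREE_LAYER_TISSUES, conductivities, n_subdiv,
        refinable=(False, True, True), centers_m=centers,
    )


def nesting_check(model: HeadModel) -> tuple[bool, str | None]:
    """Verify that every vertex of interface i+1 lies strictly inside interface i.

    Returns ``(ok, first_violation_message)``.
    """
    for i in range(model.n_interfaces - 1):
        outer = model.interfaces[i]
        inner = model.interfaces[i + 1]
        inside = outer.contains(inner.vertices)
        if not np.all(inside):
            j = int(np.flatnonzero(~inside)[0])
            return False, (
                f"vertex {j} of interface {i+1} ({model.names[i+1]}) is not "
                f"strictly inside interface {i} ({model.names[i]})"
            )
    return True, None
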