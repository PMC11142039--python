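"""Electrode layouts on the phantom skin.

Real high-density EEG caps are placed using anatomical landmarks that a
sphere phantom does not have, so the layout here is a deterministic
Fibonacci (golden-angle) spiral over an upper spherical cap — near-uniform
coverage of the "scalp" with the face/neck region left bare.  Each
electrode direction is then assigned to one skin facet, and voltages are
read at that facet's centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import TriangleMesh

__all__ = [
    "ElectrodeArray",
    "fibonacci_layout",
    "project_to_skin",
    "read_layout",
    "write_layout",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class ElectrodeArray:
    """Labeled electrode positions with their skin-facet assignment."""

    labels: tuple
    positions: np.ndarray  # (E, 3) meters: assigned facet centroids
    facet_index: np.ndarray  # (E,) indices into the skin interface facets

    def __post_init__(self):
        object.__setattr__(self, "positions", np.asarray(self.positions, float))
        object.__setattr__(self, "facet_index", np.asarray(self.facet_index, np.int64))
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("electrode labels must be unique")
        if not (len(self.labels) == len(self.positions) == len(self.facet_index)):
            raise ValueError("electrode field lengths disagree")

    def __len__(self) -> int:
        return len(self.labels)


def fibonacci_layout(n: int, cap_fraction: float = 0.65) -> np.ndarray:
    """n near-uniform unit directions on the upper cap of area fraction
    ``cap_fraction`` (1 = whole sphere), centered on +z."""
    if n < 4:
        raise ValueError("need at least 4 electrodes")
    if not (0.0 < cap_fraction <= 1.0):
        raise ValueError("cap_fraction must be in (0, 1]")
    i = np.arange(n) + 0.5
    z = 1.0 - (2.0 * cap_fraction) * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = i * _GOLDEN_ANGLE
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def project_to_skin(directions: np.ndarray, skin: TriangleMesh,
                    labels=None) -> ElectrodeArray:
    """Assign each direction to the skin facet best aligned with it.

    Facet choice maximizes direction · (centroid - center)/|centroid - center|
    (the central-projection facet for a star-shaped skin); ties resolve to
    the lower facet index.  Electrode positions are the assigned facet
    centroids, so sampled voltages are exactly facet-centroid potentials.
    """
    directions = np.asarray(directions, float)
    center = skin.vertices.mean(axis=0)
    c = skin.facet_centroid - center
    c_hat = c / np.linalg.norm(c, axis=1)[:, None]
    # argmax returns the first (lowest-index) maximizer, our tie rule
    idx = np.argmax(directions @ c_hat.T, axis=1).astype(np.int64)
    if labels is None:
        width = len(str(len(directions)))
        labels = tuple(f"E{i+1:0{width}d}" for i in range(len(directions)))
    return ElectrodeArray(tuple(labels), skin.facet_centroid[idx], idx)


def write_layout(array: ElectrodeArray, path) -> None:
    """Whitespace-separated ``label x y z`` layout, coordinates in mm."""
    with open(path, "w") as fh:
        for lab, p in zip(array.labels, array.positions):
            fh.write(f"{lab} {p[0]*1e3:.6f} {p[1]*1e3:.6f} {p[2]*1e3:.6f}\n")


def read_layout(path, skin: TriangleMesh) -> ElectrodeArray:
    """Read a ``label x y z`` (mm) layout and re-assign to skin facets."""
    labels, pos = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) != 4:
                raise ValueError(f"malformed layout line: {line!r}")
            labels.append(parts[0])
            pos.append([float(x) * 1e-3 for x in parts[1:]])
    pos = np.asarray(pos)
    center = skin.vertices.mean(axis=0)
    d = pos - center
    d /= np.linalg.norm(d, axis=1)[:, None]
    return project_to_skin(d, skin, labels=tuple(labels))
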