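"""Rigid-body primitives: labelled 3-D point sets and proper rigid transforms.

Positions are millimetres in a right-handed head frame: +x toward the right
ear, +y toward the nose, +z superior. Angles are degrees at API boundaries
and radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

from .errors import DegenerateGeometryError

__all__ = [
    "LabeledPoints",
    "RigidTransform",
    "as_point",
    "minimal_rotation",
    "rotation_about_axis",
]

#: canonical anatomical fiducial labels (nasion, left/right preauricular)
FIDUCIALS = ("Nz", "LPA", "RPA")

_ORTHO_TOL = 1e-9


def as_point(p) -> np.ndarray:
    """Coerce to a finite float64 3-vector (mm)."""
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"non-finite coordinates: {a}")
    return a


class LabeledPoints:
    """An ordered mapping from marker/electrode label to a 3-D position (mm).

    The universal currency of the geometry stages. Labels are unique and
    case-sensitive; insertion order is preserved and used as the default
    channel order downstream.
    """

    def __init__(self, entries: Mapping[str, Iterable[float]] | Iterable[tuple[str, Iterable[float]]] = ()):
        items = entries.items() if isinstance(entries, Mapping) else entries
        self._d: dict[str, np.ndarray] = {}
        for label, p in items:
            if label in self._d:
                raise ValueError(f"duplicate label {label!r}")
            self._d[str(label)] = as_point(p)

    # -- mapping surface ---------------------------------------------------
    def __getitem__(self, label: str) -> np.ndarray:
        return self._d[label]

    def __contains__(self, label: str) -> bool:
        return label in self._d

    def __iter__(self) -> Iterator[str]:
        return iter(self._d)

    def __len__(self) -> int:
        return len(self._d)

    def __eq__(self, other) -> bool:
        if not isinstance(other, LabeledPoints):
            return NotImplemented
        return self.labels == other.labels and np.array_equal(self.array(), other.array())

    def __repr__(self) -> str:
        return f"LabeledPoints({len(self)} points: {', '.join(list(self._d)[:6])}{'...' if len(self) > 6 else ''})"

    def items(self):
        return self._d.items()

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self._d)

    # -- array views -------------------------------------------------------
    def array(self, order: Iterable[str] | None = None) -> np.ndarray:
        """Positions as an (n, 3) array, in ``order`` (default: insertion order)."""
        labels = self.labels if order is None else tuple(order)
        return np.array([self._d[l] for l in labels], dtype=float)

    @classmethod
    def from_array(cls, labels: Iterable[str], xyz: np.ndarray) -> "LabeledPoints":
        labels = tuple(labels)
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(labels), 3):
            raise ValueError(f"array shape {xyz.shape} does not match {len(labels)} labels")
        return cls(zip(labels, xyz))

    # -- functional updates ------------------------------------------------
    def subset(self, labels: Iterable[str]) -> "LabeledPoints":
        return LabeledPoints((l, self._d[l]) for l in labels)

    def updated(self, other: "LabeledPoints | Mapping[str, Iterable[float]]") -> "LabeledPoints":
        """Copy with positions of shared labels replaced by ``other``'s."""
        items = other.items() if hasattr(other, "items") else other
        new = dict(self._d)
        for l, p in items:
            new[l] = as_point(p)
        return LabeledPoints(new)

    def transform(self, t: "RigidTransform") -> "LabeledPoints":
        return LabeledPoints.from_array(self.labels, t.apply(self.array()))

    def electrodes(self, fiducials: Iterable[str] = FIDUCIALS) -> tuple[str, ...]:
        """Labels that are not fiducials, in order."""
        fid = set(fiducials)
        return tuple(l for l in self._d if l not in fid)


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid transform p -> R p + t (rotation is orthonormal, det +1)."""

    rotation: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = as_point(self.translation)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9) or not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation must be orthonormal with det +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def translation_only(cls, t) -> "RigidTransform":
        return cls(np.eye(3), as_point(t))

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, inner: "RigidTransform") -> "RigidTransform":
        """self ∘ inner: apply ``inner`` first, then ``self``."""
        return RigidTransform(self.rotation @ inner.rotation,
                              self.rotation @ inner.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


def rotation_about_axis(axis, angle_rad: float) -> np.ndarray:
    """Rotation matrix about an arbitrary axis (Rodrigues)."""
    a = as_point(axis)
    n = np.linalg.norm(a)
    if n < _ORTHO_TOL:
        raise DegenerateGeometryError("rotation axis has zero length")
    a = a / n
    K = np.array([[0.0, -a[2], a[1]], [a[2], 0.0, -a[0]], [-a[1], a[0], 0.0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1.0 - np.cos(angle_rad)) * (K @ K)


def minimal_rotation(u, v) -> np.ndarray:
    """Smallest rotation carrying unit direction u onto unit direction v.

    The axis is u x v; unique except in the antiparallel case, where an
    arbitrary perpendicular axis gives a 180-degree rotation.
    """
    u = as_point(u)
    v = as_point(v)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _ORTHO_TOL or nv < _ORTHO_TOL:
        raise DegenerateGeometryError("cannot rotate a zero-length direction")
    u, v = u / nu, v / nv
    c = float(np.clip(np.dot(u, v), -1.0, 1.0))
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    if s < _ORTHO_TOL:
        if c > 0:  # already aligned
            return np.eye(3)
        # antiparallel: pick any axis perpendicular to u
        probe = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        axis = np.cross(u, probe)
        return rotation_about_axis(axis, np.pi)
    return rotation_about_axis(axis, float(np.arctan2(s, c)))
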