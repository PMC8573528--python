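"""Fiducial-anchored local coordinate frame for sparse cap markers.

A cap is digitized with motion-capture markers on five electrodes (Cz, FPz,
Oz, T7, T8) and three anatomical fiducials (Nz = nasion, LPA/RPA = left/right
preauricular points). The raw positions live in an arbitrary camera frame;
this module re-expresses them in a head-fixed frame:

1. translate so the LPA/RPA midpoint is the origin;
2. rotate the nasion onto the +y axis, coordinates (0, y_Nz, 0);
3. rotate about y so LPA/RPA lie on the x axis (LPA at -x, RPA at +x);
4. apply a small correctional rotation to LPA/RPA so the origin->LPA/RPA
   vectors are exactly orthogonal to origin->Nz (fiducials are placed by hand
   and are never perfectly orthogonal; the applied angle is a useful QC
   diagnostic of cap/fiducial placement);
5. shift the origin's z to the mean z of the T7/T8/Oz/FPz markers, which
   centres the origin in the head the way template coordinates assume;
6. subtract the marker stem offset: the IR marker centre sits above the scalp
   electrode (marker base + electrode height, 10 mm + 11 mm = 21 mm by
   default), so electrode markers are pulled radially inward by that amount.

Steps 1-3 form one proper rigid transform, recorded in the provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .errors import DegenerateGeometryError, MissingMarkerError, OffsetExceedsRadiusError
from .geometry import (
    FIDUCIALS,
    LabeledPoints,
    RigidTransform,
    as_point,
    minimal_rotation,
    rotation_about_axis,
)

__all__ = [
    "OffsetConfig",
    "FrameProvenance",
    "AlignedMontage",
    "REQUIRED_LABELS",
    "build_local_frame",
    "orthogonalize_fiducials",
    "apply_marker_offset",
]

#: the eight markers the sparse protocol records
REQUIRED_LABELS = ("Cz", "FPz", "Oz", "T7", "T8", "Nz", "LPA", "RPA")

#: electrode markers whose mean z defines the final origin height
_Z_REFERENCE = ("T7", "T8", "Oz", "FPz")

_REL_TOL = 1e-6  # relative degeneracy threshold


@dataclass(frozen=True)
class OffsetConfig:
    """Stem-offset correction for IR markers sitting on top of electrodes.

    ``total`` (marker_to_base + electrode_height) is subtracted along the
    direction from each electrode marker toward the local-frame origin.
    ``direction='none'`` disables the correction; ``apply_to_fiducials``
    extends it to Nz/LPA/RPA (off by default: fiducial markers sit on skin,
    not on electrodes).
    """

    marker_to_base: float = 10.0  # mm, marker centre to base bottom
    electrode_height: float = 11.0  # mm
    direction: str = "radial"  # 'radial' | 'none'
    apply_to_fiducials: bool = False

    def __post_init__(self):
        if self.marker_to_base < 0 or self.electrode_height < 0:
            raise ValueError("offset components must be >= 0")
        if self.direction not in ("radial", "none"):
            raise ValueError(f"unknown offset direction {self.direction!r}")

    @property
    def total(self) -> float:
        """Total correction in mm (default 10 + 11 = 21)."""
        return self.marker_to_base + self.electrode_height


@dataclass(frozen=True)
class FrameProvenance:
    """What build_local_frame did: QC diagnostics plus the rigid transform
    (steps 1-3) from the camera frame into the pre-correction local frame."""

    correction_angle: float  # degrees, fiducial orthogonalization
    z_shift: float  # mm, origin drop onto the T7/T8/Oz/FPz plane
    offset_applied: float  # mm, stem offset removed from electrodes
    transform: RigidTransform

    def __post_init__(self):
        if self.correction_angle < 0 or self.offset_applied < 0:
            raise ValueError("correction_angle and offset_applied must be >= 0")


@dataclass(frozen=True)
class AlignedMontage:
    """Sparse markers expressed in the fiducial-anchored local frame."""

    points: LabeledPoints
    provenance: FrameProvenance


def orthogonalize_fiducials(lpa, rpa, nz) -> tuple[np.ndarray, np.ndarray, float]:
    """Rotate LPA and RPA so origin->LPA/RPA is orthogonal to origin->Nz.

    Inputs are positions in the frame after steps 1-3 (Nz on the +y axis).
    Each preauricular point is rotated, in the plane it spans with the Nz
    direction and preserving its norm, so that its component along Nz
    vanishes. Returns the corrected points and the applied in-plane rotation
    angle in degrees (mean over LPA/RPA; they coincide for pipeline inputs,
    where LPA = -RPA). Idempotent.
    """
    lpa, rpa, nz = as_point(lpa), as_point(rpa), as_point(nz)
    n_nz = np.linalg.norm(nz)
    if n_nz < _REL_TOL:
        raise DegenerateGeometryError("Nz coincides with the origin")
    y_hat = nz / n_nz

    corrected = []
    angles = []
    for p in (lpa, rpa):
        along = float(np.dot(p, y_hat))
        perp = p - along * y_hat
        n_perp = np.linalg.norm(perp)
        if n_perp <= _REL_TOL * max(np.linalg.norm(p), 1.0):
            raise DegenerateGeometryError("preauricular direction is parallel to the Nz direction")
        corrected.append(perp / n_perp * np.linalg.norm(p))
        angles.append(np.arctan2(abs(along), n_perp))
    angle_deg = float(np.degrees(np.mean(angles)))
    return corrected[0], corrected[1], angle_deg


def apply_marker_offset(points: LabeledPoints, offset: float) -> LabeledPoints:
    """Move each point ``offset`` mm along the unit vector toward the origin.

    The distance to the origin decreases by exactly ``offset``. Raises
    :class:`OffsetExceedsRadiusError` if any point is closer to the origin
    than the offset.
    """
    if offset < 0:
        raise ValueError("offset must be >= 0")
    if offset == 0 or len(points) == 0:
        return points
    xyz = points.array()
    r = np.linalg.norm(xyz, axis=1)
    bad = r <= offset
    if np.any(bad):
        lab = points.labels[int(np.argmax(bad))]
        raise OffsetExceedsRadiusError(
            f"marker {lab!r} at radius {r[bad][0]:.3f} mm cannot absorb a {offset:g} mm offset")
    return LabeledPoints.from_array(points.labels, xyz * (1.0 - offset / r)[:, None])


def _require(raw: LabeledPoints, labels: Iterable[str]) -> None:
    missing = [l for l in labels if l not in raw]
    if missing:
        raise MissingMarkerError(f"missing required marker(s): {', '.join(missing)}")


def build_local_frame(
    raw: LabeledPoints,
    cfg: OffsetConfig = OffsetConfig(),
    required: Iterable[str] = REQUIRED_LABELS,
) -> AlignedMontage:
    """Express raw camera-frame markers in the fiducial-anchored local frame.

    Runs the six alignment steps described in the module docstring and
    returns the aligned montage with full provenance. The output is invariant
    (to ~1e-6 mm) to any proper rigid motion of the input scene.
    """
    _require(raw, required)
    lpa, rpa, nz = raw["LPA"], raw["RPA"], raw["Nz"]

    scale = max(np.linalg.norm(rpa - lpa), 1.0)
    if np.linalg.norm(rpa - lpa) <= _REL_TOL * max(np.linalg.norm(lpa), np.linalg.norm(rpa), 1.0):
        raise DegenerateGeometryError("LPA and RPA coincide")
    mid = 0.5 * (lpa + rpa)
    if np.linalg.norm(np.cross(rpa - lpa, nz - mid)) <= _REL_TOL * scale**2:
        raise DegenerateGeometryError("Nz is collinear with the LPA-RPA line")

    # step 1: LPA/RPA midpoint to the origin
    xyz = raw.array() - mid
    labels = raw.labels
    idx = {l: i for i, l in enumerate(labels)}

    # step 2: minimal rotation taking the Nz direction onto +y
    r1 = minimal_rotation(xyz[idx["Nz"]], np.array([0.0, 1.0, 0.0]))
    xyz = xyz @ r1.T

    # step 3: rotate about y so RPA lands on +x (z-component zeroed)
    x_r, _, z_r = xyz[idx["RPA"]]
    r2 = rotation_about_axis([0.0, 1.0, 0.0], float(np.arctan2(z_r, x_r)))
    xyz = xyz @ r2.T

    transform = RigidTransform(r2 @ r1, (r2 @ r1) @ (-mid))

    # step 4: fiducial orthogonality correction (moves only LPA/RPA)
    lpa_c, rpa_c, angle = orthogonalize_fiducials(xyz[idx["LPA"]], xyz[idx["RPA"]], xyz[idx["Nz"]])
    xyz[idx["LPA"]] = lpa_c
    xyz[idx["RPA"]] = rpa_c

    # step 5: drop the origin onto the mean z of the equatorial electrodes
    z_ref = [l for l in _Z_REFERENCE if l in idx]
    z_shift = float(np.mean([xyz[idx[l]][2] for l in z_ref])) if z_ref else 0.0
    xyz[:, 2] -= z_shift

    points = LabeledPoints.from_array(labels, xyz)

    # step 6: remove the marker stem offset
    offset_applied = 0.0
    if cfg.direction == "radial" and cfg.total > 0:
        targets = list(points.labels) if cfg.apply_to_fiducials else list(points.electrodes())
        corrected = apply_marker_offset(points.subset(targets), cfg.total)
        points = points.updated(corrected)
        offset_applied = cfg.total

    prov = FrameProvenance(correction_angle=angle, z_shift=z_shift,
                           offset_applied=offset_applied, transform=transform)
    return AlignedMontage(points=points, provenance=prov)
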