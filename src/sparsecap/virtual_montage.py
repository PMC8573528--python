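"""Virtual electrode locations and displacement metrics.

The cap can be placed slightly rotated on the head even when the fiducials
are digitized perfectly. "Virtual" electrode locations undo that placement
error: keeping the fiducials fixed, the electrodes are rotated so that the
T7->T8 direction is parallel to LPA->RPA, and then about the x axis so Cz
lies in the x-z plane. The distance between actual and virtual positions
measures how far off the cap placement was; the distance between model
estimates and virtual positions measures head-model fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coordinate_frame import AlignedMontage
from .errors import DegenerateGeometryError, EmptyComparisonError
from .geometry import FIDUCIALS, LabeledPoints, RigidTransform, minimal_rotation, rotation_about_axis

__all__ = ["VirtualMontage", "DistanceReport", "to_virtual", "displacement"]


@dataclass(frozen=True)
class VirtualMontage:
    """Electrodes rotated into template-consistent pose; fiducials untouched.

    ``residual_cz_x`` is the x-component Cz retains after the alignment: the
    rotation about x can only zero Cz's y-component, so any forward/backward
    offset of the vertex marker survives and is reported as a diagnostic.
    """

    points: LabeledPoints
    applied_rotations: tuple[RigidTransform, ...]
    residual_cz_x: float  # mm


def to_virtual(aligned: AlignedMontage) -> VirtualMontage:
    """Rotate electrodes (about the frame origin) into the virtual pose.

    Rotation 1: minimal rotation carrying unit(T8 - T7) onto unit(RPA - LPA).
    Rotation 2: about the x axis, zeroing Cz's y-component (Cz ends with
    positive z). Fiducials are fixed; the map is idempotent and preserves all
    electrode pairwise distances.
    """
    pts = aligned.points
    for lab in ("Cz", "T7", "T8", "LPA", "RPA"):
        if lab not in pts:
            raise DegenerateGeometryError(f"virtual rotation requires marker {lab!r}")
    t7, t8 = pts["T7"], pts["T8"]
    if np.linalg.norm(t8 - t7) < 1e-9:
        raise DegenerateGeometryError("T7 and T8 coincide")

    r1 = minimal_rotation(t8 - t7, pts["RPA"] - pts["LPA"])

    elec = list(pts.electrodes(FIDUCIALS))
    xyz = pts.array(elec) @ r1.T

    cz = xyz[elec.index("Cz")]
    phi = float(np.arctan2(cz[1], cz[2]))  # about x: zero Cz_y, Cz_z > 0
    r2 = rotation_about_axis([1.0, 0.0, 0.0], phi)
    xyz = xyz @ r2.T

    points = pts.updated(LabeledPoints.from_array(elec, xyz))
    return VirtualMontage(
        points=points,
        applied_rotations=(RigidTransform(r1), RigidTransform(r2)),
        residual_cz_x=float(xyz[elec.index("Cz")][0]),
    )


@dataclass(frozen=True)
class DistanceReport:
    """Per-label Euclidean displacement (mm) with median and quartiles.

    Quartiles use linear interpolation between order statistics, so reported
    values are reproducible from the per-label distances.
    """

    per_label: dict[str, float]
    median: float
    q25: float
    q75: float

    @property
    def distances(self) -> np.ndarray:
        return np.array(list(self.per_label.values()))


def displacement(a: LabeledPoints, b: LabeledPoints) -> DistanceReport:
    """Euclidean distance between same-label points of two sets (symmetric)."""
    shared = [l for l in a.labels if l in b]
    if not shared:
        raise EmptyComparisonError("point sets share no labels")
    d = np.linalg.norm(a.array(shared) - b.array(shared), axis=1)
    q25, med, q75 = np.percentile(d, [25, 50, 75])
    return DistanceReport(per_label=dict(zip(shared, d.tolist())),
                          median=float(med), q25=float(q25), q75=float(q75))
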