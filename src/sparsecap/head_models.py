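"""Sphere and ellipsoid head models, template projection, model comparison.

From the virtual marker positions a head model is fit directly from marker
radii: the sphere uses r = |Cz|; the ellipsoid uses rx = |T8|, ry = |FPz|,
rz = |Cz|. The full montage is then reconstructed from the manufacturer-style
angle table via

    x = rx sin(theta) cos(phi),  y = ry sin(theta) sin(phi),  z = rz cos(theta)

with theta the inclination from the superior (+z) axis and phi the azimuth
from +x (right ear) toward +y (nose). Model quality is the per-electrode
distance to the virtual marker positions, compared between models with a
paired Wilcoxon signed-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .errors import DegenerateGeometryError, EmptyComparisonError
from .geometry import LabeledPoints
from .virtual_montage import DistanceReport, VirtualMontage, displacement

__all__ = [
    "HeadModel",
    "TemplateAngles",
    "EstimatedMontage",
    "ModelComparison",
    "fit_sphere",
    "fit_ellipsoid",
    "project_template",
    "compare_models",
]


@dataclass(frozen=True)
class HeadModel:
    """Sphere (rx = ry = rz) or ellipsoid head model; radii in mm."""

    kind: str  # 'sphere' | 'ellipsoid'
    rx: float
    ry: float
    rz: float

    def __post_init__(self):
        if self.kind not in ("sphere", "ellipsoid"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if min(self.rx, self.ry, self.rz) <= 0:
            raise ValueError("all radii must be > 0")
        if self.kind == "sphere" and not (self.rx == self.ry == self.rz):
            raise ValueError("a sphere requires rx = ry = rz")

    @property
    def radii(self) -> tuple[float, float, float]:
        return (self.rx, self.ry, self.rz)

    @classmethod
    def sphere(cls, r: float) -> "HeadModel":
        return cls("sphere", r, r, r)

    @classmethod
    def ellipsoid(cls, rx: float, ry: float, rz: float) -> "HeadModel":
        return cls("ellipsoid", rx, ry, rz)


class TemplateAngles:
    """Per-electrode (inclination theta, azimuth phi) in degrees.

    theta in [0, 180] from the +z axis; phi in (-180, 180] from +x toward +y.
    """

    def __init__(self, rows: Mapping[str, tuple[float, float]]):
        self._rows: dict[str, tuple[float, float]] = {}
        for lab, (theta, phi) in rows.items():
            theta, phi = float(theta), float(phi)
            if not (0.0 <= theta <= 180.0):
                raise ValueError(f"{lab}: inclination {theta} outside [0, 180]")
            if not (-180.0 < phi <= 180.0):
                raise ValueError(f"{lab}: azimuth {phi} outside (-180, 180]")
            if lab in self._rows:
                raise ValueError(f"duplicate label {lab!r}")
            self._rows[str(lab)] = (theta, phi)

    def __len__(self):
        return len(self._rows)

    def __contains__(self, lab):
        return lab in self._rows

    def __getitem__(self, lab) -> tuple[float, float]:
        return self._rows[lab]

    def items(self):
        return self._rows.items()

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self._rows)


@dataclass(frozen=True)
class EstimatedMontage:
    """Full montage on a head-model surface; tracks which points were measured."""

    points: LabeledPoints
    source: dict[str, str]  # label -> 'measured' | 'model_estimated'
    model: HeadModel


def _radius(virtual: VirtualMontage, label: str) -> float:
    if label not in virtual.points:
        raise DegenerateGeometryError(f"virtual montage lacks marker {label!r}")
    r = float(np.linalg.norm(virtual.points[label]))
    if r < 1e-9:
        raise DegenerateGeometryError(f"virtual {label} sits at the frame origin")
    return r


def fit_sphere(virtual: VirtualMontage) -> HeadModel:
    """Sphere with radius |virtual Cz|."""
    return HeadModel.sphere(_radius(virtual, "Cz"))


def fit_ellipsoid(virtual: VirtualMontage) -> HeadModel:
    """Ellipsoid with rx = |virtual T8|, ry = |virtual FPz|, rz = |virtual Cz|."""
    return HeadModel.ellipsoid(_radius(virtual, "T8"), _radius(virtual, "FPz"),
                               _radius(virtual, "Cz"))


def project_template(model: HeadModel, angles: TemplateAngles) -> EstimatedMontage:
    """Place every template electrode on the model surface from its angles."""
    labels = angles.labels
    th = np.radians([angles[l][0] for l in labels])
    ph = np.radians([angles[l][1] for l in labels])
    xyz = np.column_stack([
        model.rx * np.sin(th) * np.cos(ph),
        model.ry * np.sin(th) * np.sin(ph),
        model.rz * np.cos(th),
    ])
    return EstimatedMontage(
        points=LabeledPoints.from_array(labels, xyz),
        source={l: "model_estimated" for l in labels},
        model=model,
    )


@dataclass(frozen=True)
class ModelComparison:
    """Paired model-fit comparison: distances to a common reference."""

    report_a: DistanceReport
    report_b: DistanceReport
    kind_a: str
    kind_b: str
    wilcoxon_p: float
    winner: str  # kind_a | kind_b | 'tie'


def _signed_rank_p(d_a: np.ndarray, d_b: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p on paired distances.

    Zero differences dropped; exact null for n <= 25, else normal
    approximation with continuity correction.
    """
    diff = d_a - d_b
    nonzero = diff[diff != 0]
    if nonzero.size == 0:
        return 1.0
    if nonzero.size <= 25:
        method = "exact"
        kwargs = {}
    else:
        method = "approx"
        kwargs = {"correction": True}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = stats.wilcoxon(d_a, d_b, zero_method="wilcox",
                                 alternative="two-sided", method=method, **kwargs)
        except ValueError:
            # exact method can refuse tied ranks on some scipy versions
            res = stats.wilcoxon(d_a, d_b, zero_method="wilcox",
                                 alternative="two-sided", method="approx", correction=True)
    return float(res.pvalue)


def compare_models(reference: LabeledPoints, est_a: EstimatedMontage,
                   est_b: EstimatedMontage) -> ModelComparison:
    """Compare two estimated montages against reference positions.

    Per shared label, the Euclidean distance to the reference is computed for
    each montage; the paired distances are tested with a two-sided Wilcoxon
    signed-rank test, and the winner is the model with the smaller median
    distance (tie if equal).
    """
    shared = [l for l in reference.labels if l in est_a.points and l in est_b.points]
    if len(shared) < 5:
        raise EmptyComparisonError(
            f"need at least 5 shared labels for a paired comparison, got {len(shared)}")
    ref = reference.subset(shared)
    rep_a = displacement(ref, est_a.points)
    rep_b = displacement(ref, est_b.points)
    p = _signed_rank_p(rep_a.distances, rep_b.distances)
    if rep_a.median < rep_b.median:
        winner = est_a.model.kind
    elif rep_b.median < rep_a.median:
        winner = est_b.model.kind
    else:
        winner = "tie"
    return ModelComparison(report_a=rep_a, report_b=rep_b,
                           kind_a=est_a.model.kind, kind_b=est_b.model.kind,
                           wilcoxon_p=p, winner=winner)
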