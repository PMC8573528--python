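"""High-level workflows tying the stages together.

``localize``: sparse markers -> local frame -> virtual pose -> head models ->
full estimated montage, with the placement and model-fit diagnostics.

``erp_sensitivity``: cleaned epochs per participant -> rejection -> ERPs at
the actual electrode positions -> spatial interpolation to the template
positions -> mass-univariate paired comparison (actual vs template-
interpolated), Bonferroni-corrected over time samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .coordinate_frame import AlignedMontage, OffsetConfig, build_local_frame
from .erp import (
    ERP,
    ERPComparison,
    EpochArray,
    RejectionConfig,
    average_erp,
    epoch_trials,
    interpolate_to_template,
    mass_univariate_compare,
    reject_epochs,
)
from .errors import ConfigError
from .geometry import FIDUCIALS, LabeledPoints
from .head_models import (
    EstimatedMontage,
    ModelComparison,
    TemplateAngles,
    compare_models,
    fit_ellipsoid,
    fit_sphere,
    project_template,
)
from .virtual_montage import DistanceReport, VirtualMontage, displacement, to_virtual

__all__ = ["LocalizationResult", "ERPSensitivityResult", "localize", "erp_sensitivity",
           "merge_measured"]

MODEL_KINDS = ("sphere", "ellipsoid", "both")


def merge_measured(virtual: VirtualMontage, estimated: EstimatedMontage) -> EstimatedMontage:
    """Full montage: model estimates, with measured (virtual) positions kept
    for the electrodes that actually carried markers."""
    measured = [l for l in virtual.points.electrodes(FIDUCIALS) if l in estimated.points]
    points = estimated.points.updated(virtual.points.subset(measured))
    source = dict(estimated.source)
    for l in measured:
        source[l] = "measured"
    return EstimatedMontage(points=points, source=source, model=estimated.model)


@dataclass(frozen=True)
class LocalizationResult:
    aligned: AlignedMontage
    virtual: VirtualMontage
    actual_vs_virtual: DistanceReport
    models: dict[str, "EstimatedMontage"]  # kind -> template projection
    full_montages: dict[str, "EstimatedMontage"]  # kind -> measured + estimated
    model_vs_virtual: dict[str, DistanceReport]
    comparison: ModelComparison | None  # only when both models were fit


def localize(markers: LabeledPoints, angles: TemplateAngles,
             offset: OffsetConfig = OffsetConfig(),
             model_kind: str = "both") -> LocalizationResult:
    """Run the full sparse-marker localization workflow."""
    if model_kind not in MODEL_KINDS:
        raise ConfigError(f"model_kind must be one of {MODEL_KINDS}")
    aligned = build_local_frame(markers, offset)
    virtual = to_virtual(aligned)

    elec = aligned.points.electrodes(FIDUCIALS)
    actual_vs_virtual = displacement(aligned.points.subset(elec), virtual.points.subset(elec))

    kinds = ("sphere", "ellipsoid") if model_kind == "both" else (model_kind,)
    fits = {"sphere": fit_sphere, "ellipsoid": fit_ellipsoid}
    models, fulls, dists = {}, {}, {}
    virtual_elec = virtual.points.subset([l for l in elec if l in angles])
    for kind in kinds:
        est = project_template(fits[kind](virtual), angles)
        models[kind] = est
        fulls[kind] = merge_measured(virtual, est)
        dists[kind] = displacement(virtual_elec, est.points)

    comparison = None
    if model_kind == "both":
        comparison = compare_models(virtual_elec, models["sphere"], models["ellipsoid"])
    return LocalizationResult(aligned=aligned, virtual=virtual,
                              actual_vs_virtual=actual_vs_virtual, models=models,
                              full_montages=fulls, model_vs_virtual=dists,
                              comparison=comparison)


@dataclass(frozen=True)
class ERPSensitivityResult:
    comparison: ERPComparison
    actual_erps: tuple[ERP, ...]
    template_erps: tuple[ERP, ...]
    n_kept: tuple[int, ...]  # epochs surviving rejection, per participant


def erp_sensitivity(epochs_by_participant: Sequence[EpochArray],
                    actual_positions: LabeledPoints | Sequence[LabeledPoints],
                    template_positions: LabeledPoints,
                    window: tuple[float, float] | None = None,
                    baseline: tuple[float, float] = (-100.0, 0.0),
                    rejection: RejectionConfig = RejectionConfig(),
                    alpha: float = 0.05,
                    channel: str | None = None) -> ERPSensitivityResult:
    """Quantify how electrode-placement error changes the measured ERP.

    ``actual_positions`` may be one montage shared by all participants or a
    sequence with one montage per participant. With ``window`` given, epochs
    are first re-cut and baselined; rejection always runs.
    """
    n = len(epochs_by_participant)
    if n < 2:
        raise ConfigError("need at least 2 participants")
    if isinstance(actual_positions, LabeledPoints):
        positions = [actual_positions] * n
    else:
        positions = list(actual_positions)
        if len(positions) != n:
            raise ConfigError("one actual-position montage per participant required")

    actual_erps, template_erps, n_kept = [], [], []
    for epochs, pos in zip(epochs_by_participant, positions):
        if window is not None:
            epochs = epoch_trials(epochs, window, baseline)
        kept, mask = reject_epochs(epochs, rejection)
        erp = average_erp(kept, pos)
        actual_erps.append(erp)
        template_erps.append(interpolate_to_template(erp, template_positions))
        n_kept.append(mask.n_kept)

    comparison = mass_univariate_compare(actual_erps, template_erps, alpha=alpha,
                                         channel=channel)
    return ERPSensitivityResult(comparison=comparison,
                                actual_erps=tuple(actual_erps),
                                template_erps=tuple(template_erps),
                                n_kept=tuple(n_kept))
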