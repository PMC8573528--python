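"""Synthetic ground-truth heads, noisy marker captures, and ERP datasets.

Every pipeline stage is testable by parameter recovery without any recorded
data: a ground-truth ellipsoidal head is built from a template angle table,
perturbed the way a real capture is (cap-misplacement rotation, imperfect
fiducial placement, marker stem offset, capture jitter, arbitrary camera
pose), and handed to the pipeline, whose job is to undo everything and
recover the generating radii.

All randomness flows from a single integer seed through named substreams, so
each stage of a dataset is independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .coordinate_frame import OffsetConfig
from .errors import ConfigError, MissingMarkerError
from .geometry import FIDUCIALS, LabeledPoints, RigidTransform, rotation_about_axis
from .head_models import HeadModel, TemplateAngles, project_template

__all__ = [
    "SyntheticHeadConfig",
    "SyntheticERPConfig",
    "ERPComponent",
    "generate_head",
    "generate_erp_dataset",
]


def _substream(seed: int, stage: str) -> np.random.Generator:
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class SyntheticHeadConfig:
    """Ground-truth head and capture-perturbation settings.

    Defaults reflect a realistic adult head (ellipsoid semi-axes 75/95/90 mm)
    and a well-calibrated optical capture (0.5 mm marker jitter). The cap
    rotation models placement error of the cap on the head; the fiducial
    skew models hand-placed preauricular markers that are not exactly
    orthogonal to the nasion direction.
    """

    radii: tuple[float, float, float] = (75.0, 95.0, 90.0)  # rx, ry, rz mm
    cap_rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)  # deg about x, y, z
    fiducial_nonorthogonality: float = 0.0  # deg, in-plane LPA/RPA skew
    marker_noise_sd: float = 0.5  # mm, isotropic Gaussian jitter
    stem_offset: float = 21.0  # mm, marker sits this far above the scalp
    global_pose: RigidTransform = field(default_factory=RigidTransform.identity)
    seed: int = 0

    def __post_init__(self):
        if min(self.radii) <= 0:
            raise ConfigError("radii must be > 0")
        if self.marker_noise_sd < 0 or self.stem_offset < 0:
            raise ConfigError("marker_noise_sd and stem_offset must be >= 0")


def generate_head(cfg: SyntheticHeadConfig, angles: TemplateAngles
                  ) -> tuple[LabeledPoints, LabeledPoints]:
    """Return (truth, observed) labelled marker sets.

    ``truth``: electrodes on the ground-truth ellipsoid at template angles,
    plus fiducials LPA (-rx, 0, 0), RPA (rx, 0, 0), Nz (0, ry, 0).

    ``observed``: what the cameras would record — electrodes rotated by the
    cap-misplacement rotation (about the head origin), LPA/RPA rotated
    in-plane by the fiducial skew, every electrode pushed ``stem_offset`` mm
    radially outward (the marker rides on top of the electrode), isotropic
    Gaussian jitter added to all markers, and the whole scene moved by
    ``global_pose``.
    """
    model = HeadModel.ellipsoid(*cfg.radii)
    est = project_template(model, angles)
    fid = LabeledPoints({
        "Nz": (0.0, cfg.radii[1], 0.0),
        "LPA": (-cfg.radii[0], 0.0, 0.0),
        "RPA": (cfg.radii[0], 0.0, 0.0),
    })
    truth = LabeledPoints(list(est.points.items()) + list(fid.items()))

    elec_labels = truth.electrodes(FIDUCIALS)
    elec = truth.array(elec_labels)

    ax, ay, az = np.radians(cfg.cap_rotation)
    r_cap = (rotation_about_axis([0, 0, 1], az)
             @ rotation_about_axis([0, 1, 0], ay)
             @ rotation_about_axis([1, 0, 0], ax))
    elec = elec @ r_cap.T

    # stem offset: radially outward from the head origin
    if cfg.stem_offset > 0:
        r = np.linalg.norm(elec, axis=1)
        elec = elec * (1.0 + cfg.stem_offset / r)[:, None]

    r_fid = rotation_about_axis([0, 0, 1], np.radians(cfg.fiducial_nonorthogonality))
    observed = dict(zip(elec_labels, elec))
    observed["Nz"] = fid["Nz"]
    observed["LPA"] = r_fid @ fid["LPA"]
    observed["RPA"] = r_fid @ fid["RPA"]
    obs = LabeledPoints({l: observed[l] for l in truth.labels})

    if cfg.marker_noise_sd > 0:
        rng = _substream(cfg.seed, "marker-jitter")
        obs = LabeledPoints.from_array(
            obs.labels, obs.array() + rng.normal(0.0, cfg.marker_noise_sd, (len(obs), 3)))
    return truth, obs.transform(cfg.global_pose)


@dataclass(frozen=True)
class ERPComponent:
    """A Gaussian-in-time, Gaussian-on-scalp evoked component."""

    latency_ms: float = 300.0
    width_ms: float = 50.0
    amplitude_uv: float = 8.0
    focus_label: str = "Cz"
    spread_mm: float = 60.0  # spatial SD of the Euclidean scalp falloff


@dataclass(frozen=True)
class SyntheticERPConfig:
    """Multi-participant epoched-EEG generator settings.

    Epoch geometry mirrors a typical stimulus-locked design: a 1 s window
    from 200 ms before to 800 ms after the event at 512 Hz (512 samples).
    Each epoch is the sum of the configured components plus white Gaussian
    sensor noise; participants share the deterministic signal and differ in
    their noise realizations.
    """

    n_participants: int = 5
    components: tuple[ERPComponent, ...] = (ERPComponent(),)
    noise_sd: float = 5.0  # microvolts
    n_trials: int = 50
    fs: float = 512.0
    window_ms: tuple[float, float] = (-200.0, 800.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 2:
            raise ConfigError("need at least 2 participants")
        if self.fs <= 0:
            raise ConfigError("sampling rate must be > 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.n_trials < 1:
            raise ConfigError("need at least 1 trial")


def component_signal(cfg: SyntheticERPConfig, montage: LabeledPoints) -> np.ndarray:
    """Deterministic (channels x samples) signal shared by all participants."""
    labels = montage.labels
    n_samples = int(round((cfg.window_ms[1] - cfg.window_ms[0]) * cfg.fs / 1000.0))
    t = cfg.window_ms[0] + np.arange(n_samples) * 1000.0 / cfg.fs
    xyz = montage.array()
    sig = np.zeros((len(labels), n_samples))
    for comp in cfg.components:
        if comp.focus_label not in montage:
            raise MissingMarkerError(f"focus electrode {comp.focus_label!r} not in montage")
        d = np.linalg.norm(xyz - montage[comp.focus_label], axis=1)
        spatial = np.exp(-0.5 * (d / comp.spread_mm) ** 2)
        temporal = np.exp(-0.5 * ((t - comp.latency_ms) / comp.width_ms) ** 2)
        sig += comp.amplitude_uv * spatial[:, None] * temporal[None, :]
    return sig


def generate_erp_dataset(cfg: SyntheticERPConfig, montage: LabeledPoints):
    """One EpochArray per participant, deterministic under ``cfg.seed``."""
    from .erp import EpochArray

    if len(montage) == 0:
        raise ConfigError("montage is empty")
    sig = component_signal(cfg, montage)
    out = []
    for p in range(cfg.n_participants):
        rng = _substream(cfg.seed, f"participant-{p}")
        noise = rng.normal(0.0, cfg.noise_sd, (len(montage), sig.shape[1], cfg.n_trials)) \
            if cfg.noise_sd > 0 else np.zeros((len(montage), sig.shape[1], cfg.n_trials))
        out.append(EpochArray(sig[:, :, None] + noise, cfg.fs, cfg.window_ms[0],
                              montage.labels))
    return out
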