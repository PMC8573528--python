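"""Event-related potential pipeline: epoching, artifact rejection, averaging,
spatial interpolation to template electrode positions, and mass-univariate
paired comparison.

The question these stages answer: if electrodes were not where the template
says they were, how much does that change the measured ERP? ERPs recorded at
the actual electrode positions are spatially interpolated to the template
positions (piecewise-linear over a 3-D tessellation of the electrode cloud)
and compared point-by-point in time with a paired t test across participants,
Bonferroni-corrected over time samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import QhullError

from .errors import (
    AllRejectedError,
    ConfigError,
    DegenerateGeometryError,
    ShapeError,
    ShortEpochError,
)
from .geometry import LabeledPoints

__all__ = [
    "EpochArray",
    "ERP",
    "RejectionConfig",
    "RejectionMask",
    "ERPComparison",
    "epoch_trials",
    "reject_epochs",
    "average_erp",
    "interpolate_to_template",
    "mass_univariate_compare",
]


@dataclass(frozen=True)
class EpochArray:
    """Epoched EEG: channels x samples x trials, in microvolts.

    ``t0_offset`` is the time of the first sample in ms relative to the
    event (negative = pre-stimulus).
    """

    data: np.ndarray
    fs: float  # Hz
    t0_offset: float  # ms
    channel_labels: tuple[str, ...]

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 3:
            raise ShapeError(f"epoch data must be channels x samples x trials, got {d.shape}")
        labels = tuple(self.channel_labels)
        if len(labels) != d.shape[0]:
            raise ShapeError(f"{len(labels)} channel labels for {d.shape[0]} data rows")
        if len(set(labels)) != len(labels):
            raise ShapeError("channel labels must be unique")
        if self.fs <= 0:
            raise ConfigError("sampling rate must be > 0")
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "channel_labels", labels)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms relative to the event."""
        return self.t0_offset + np.arange(self.n_samples) * 1000.0 / self.fs


@dataclass(frozen=True)
class ERP:
    """Trial-averaged evoked response: channels x samples (microvolts)."""

    data: np.ndarray
    fs: float
    t0_offset: float
    n_trials: int
    channel_labels: tuple[str, ...]
    positions: LabeledPoints
    extrapolated_labels: tuple[str, ...] = ()

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != len(self.channel_labels):
            raise ShapeError(f"ERP data shape {d.shape} does not match channel labels")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0_offset + np.arange(self.n_samples) * 1000.0 / self.fs


@dataclass(frozen=True)
class RejectionConfig:
    """Artifact-rejection thresholds.

    An epoch is excluded if any sample exceeds ``amp_threshold`` in absolute
    value, or if its kurtosis or joint-log-probability z-score across epochs
    exceeds ``stat_threshold`` standard deviations.
    """

    amp_threshold: float = 75.0  # microvolts
    stat_threshold: float = 10.0  # SD units
    baseline_window: tuple[float, float] = (-100.0, 0.0)  # ms

    def __post_init__(self):
        if self.amp_threshold <= 0 or self.stat_threshold <= 0:
            raise ConfigError("rejection thresholds must be > 0")


@dataclass(frozen=True)
class RejectionMask:
    """Per-epoch keep/reject decision with the triggering criteria."""

    kept: np.ndarray  # boolean, one per input epoch
    reasons: tuple[tuple[str, ...], ...]  # per epoch: subset of {'amplitude','kurtosis','probability'}

    @property
    def n_kept(self) -> int:
        return int(np.count_nonzero(self.kept))


def _sample_index(t_ms: float, fs: float, t0: float) -> int:
    return int(round((t_ms - t0) * fs / 1000.0))


def epoch_trials(trials: EpochArray, window: tuple[float, float],
                 baseline: tuple[float, float] = (-100.0, 0.0)) -> EpochArray:
    """Crop epochs to ``window`` (half-open, ms) and baseline-correct.

    The per-channel, per-trial mean over the half-open baseline window is
    subtracted. Sample count is round((end - start)/1000 * fs): a [-200, 800)
    ms window at 512 Hz yields exactly 512 samples.
    """
    w0, w1 = float(window[0]), float(window[1])
    b0, b1 = float(baseline[0]), float(baseline[1])
    if w1 <= w0:
        raise ConfigError("window end must exceed window start")
    if b0 < w0 or b1 > w1 or b1 <= b0:
        raise ConfigError(f"baseline [{b0}, {b1}) must lie inside window [{w0}, {w1})")

    i0 = _sample_index(w0, trials.fs, trials.t0_offset)
    n = int(round((w1 - w0) * trials.fs / 1000.0))
    if i0 < 0 or i0 + n > trials.n_samples:
        raise ShortEpochError(
            f"window [{w0}, {w1}) ms needs samples [{i0}, {i0 + n}) but epochs have {trials.n_samples}")
    cropped = trials.data[:, i0:i0 + n, :]
    t0_new = trials.t0_offset + i0 * 1000.0 / trials.fs

    j0 = _sample_index(b0, trials.fs, t0_new)
    j1 = _sample_index(b1, trials.fs, t0_new)
    base = cropped[:, j0:j1, :].mean(axis=1, keepdims=True)
    return EpochArray(cropped - base, trials.fs, t0_new, trials.channel_labels)


def _epoch_stat_z(per_epoch: np.ndarray) -> np.ndarray:
    """Z-score a (channels x epochs) statistic across epochs, per channel;
    return each epoch's worst absolute z over channels."""
    mu = per_epoch.mean(axis=1, keepdims=True)
    sd = per_epoch.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (per_epoch - mu) / sd, 0.0)
    return np.max(np.abs(z), axis=0)


def _log_probability_stat(data: np.ndarray, n_bins: int = 64) -> np.ndarray:
    """Per-epoch joint log-probability under per-channel histogram densities.

    For each channel an empirical distribution is binned over all samples of
    all epochs; an epoch's statistic is the sum of log bin probabilities of
    its samples. Improbable (artifactual) epochs score low.
    """
    n_ch, n_s, n_ep = data.shape
    out = np.zeros((n_ch, n_ep))
    for c in range(n_ch):
        flat = data[c].ravel()
        counts, edges = np.histogram(flat, bins=n_bins)
        p = (counts + 1.0) / (counts.sum() + n_bins)  # Laplace-smoothed
        ix = np.clip(np.searchsorted(edges, data[c], side="right") - 1, 0, n_bins - 1)
        out[c] = np.log(p)[ix].sum(axis=0)
    return out


def reject_epochs(epochs: EpochArray, cfg: RejectionConfig = RejectionConfig()
                  ) -> tuple[EpochArray, RejectionMask]:
    """Drop artifactual epochs by amplitude, kurtosis, and probability criteria.

    * amplitude: any sample beyond +/- ``amp_threshold`` microvolts;
    * kurtosis: per-channel epoch kurtosis, z-scored across epochs, with the
      epoch's worst |z| over channels beyond ``stat_threshold``;
    * probability: per-epoch joint log-probability under per-channel
      empirical (histogram) distributions, z-scored the same way.
    """
    if epochs.n_trials < 2:
        raise ShapeError("statistical rejection needs at least 2 epochs")
    data = epochs.data

    amp_bad = np.any(np.abs(data) > cfg.amp_threshold, axis=(0, 1))
    kurt = stats.kurtosis(data, axis=1, fisher=True, bias=True)  # channels x epochs
    kurt_bad = _epoch_stat_z(kurt) > cfg.stat_threshold
    prob_bad = _epoch_stat_z(_log_probability_stat(data)) > cfg.stat_threshold

    kept = ~(amp_bad | kurt_bad | prob_bad)
    reasons = tuple(
        tuple(name for name, bad in (("amplitude", amp_bad[i]),
                                     ("kurtosis", kurt_bad[i]),
                                     ("probability", prob_bad[i])) if bad)
        for i in range(epochs.n_trials))
    if not np.any(kept):
        raise AllRejectedError("every epoch was rejected")
    kept_arr = EpochArray(data[:, :, kept], epochs.fs, epochs.t0_offset, epochs.channel_labels)
    return kept_arr, RejectionMask(kept=kept, reasons=reasons)


def average_erp(epochs: EpochArray, positions: LabeledPoints) -> ERP:
    """Arithmetic mean over trials; ``positions`` locate the channels in mm."""
    if epochs.n_trials < 1:
        raise AllRejectedError("no epochs to average")
    missing = [l for l in epochs.channel_labels if l not in positions]
    if missing:
        raise ShapeError(f"positions lack channel(s): {', '.join(missing)}")
    return ERP(epochs.data.mean(axis=2), epochs.fs, epochs.t0_offset,
               epochs.n_trials, epochs.channel_labels,
               positions.subset(epochs.channel_labels))


def interpolate_to_template(erp: ERP, template_positions: LabeledPoints) -> ERP:
    """Resample the scalp field at template electrode positions.

    Per time sample, the field known at the actual positions is interpolated
    at the template positions by piecewise-linear barycentric interpolation
    over a 3-D Delaunay tessellation of the source cloud (linear fields are
    reproduced exactly at interior points). Template points outside the
    convex hull fall back to the nearest source electrode's value and are
    listed in ``extrapolated_labels``.
    """
    src = erp.positions.array(erp.channel_labels)
    if len(erp.channel_labels) < 4:
        raise DegenerateGeometryError("interpolation needs >= 4 source electrodes")
    if np.linalg.matrix_rank(src - src.mean(axis=0), tol=1e-8) < 3:
        raise DegenerateGeometryError("source electrodes are coplanar")
    try:
        lin = LinearNDInterpolator(src, erp.data)
    except QhullError as e:  # pragma: no cover - rank check catches most cases
        raise DegenerateGeometryError(f"degenerate source cloud: {e}") from None

    tmpl_labels = template_positions.labels
    tgt = template_positions.array(tmpl_labels)
    vals = lin(tgt)  # (m, samples); NaN rows outside the hull
    outside = np.any(np.isnan(vals), axis=1)
    if np.any(outside):
        nearest = NearestNDInterpolator(src, erp.data)
        vals[outside] = nearest(tgt[outside])
    flagged = tuple(l for l, o in zip(tmpl_labels, outside) if o)
    return ERP(vals, erp.fs, erp.t0_offset, erp.n_trials, tmpl_labels,
               template_positions, extrapolated_labels=flagged)


@dataclass(frozen=True)
class ERPComparison:
    """Mass-univariate paired-comparison result.

    ``sig_mask`` is True exactly where p < alpha_corrected, with
    alpha_corrected = alpha / n_samples (Bonferroni over time points,
    channels treated independently). ``zero_variance`` flags time points
    where every participant's difference was identical (p set to 1 there).
    """

    t_stats: np.ndarray  # channels x samples
    p_values: np.ndarray
    alpha_corrected: float
    sig_mask: np.ndarray
    channel_labels: tuple[str, ...]
    zero_variance: np.ndarray = field(default=None)  # type: ignore[assignment]


def mass_univariate_compare(erps_a: Sequence[ERP], erps_b: Sequence[ERP],
                            alpha: float = 0.05, channel: str | None = None
                            ) -> ERPComparison:
    """Two-sided paired t test at every time point, Bonferroni over samples.

    ``erps_a`` and ``erps_b`` are paired by position in the lists (one entry
    per participant). With ``channel`` given, only that channel is tested;
    otherwise every channel shared by all ERPs is.
    """
    if len(erps_a) != len(erps_b):
        raise ShapeError("ERP lists must be the same length (paired by participant)")
    n = len(erps_a)
    if n < 2:
        raise ShapeError("paired t test needs at least 2 participants")
    if not (0.0 < alpha < 1.0):
        raise ConfigError("alpha must be in (0, 1)")

    n_samples = erps_a[0].n_samples
    if channel is None:
        chans = [l for l in erps_a[0].channel_labels
                 if all(l in e.channel_labels for e in list(erps_a) + list(erps_b))]
        if not chans:
            raise ShapeError("no channel is shared by every ERP")
    else:
        chans = [channel]
    for e in list(erps_a) + list(erps_b):
        if e.n_samples != n_samples:
            raise ShapeError("every ERP must have the same number of samples")
        missing = [c for c in chans if c not in e.channel_labels]
        if missing:
            raise ShapeError(f"ERP lacks channel(s): {', '.join(missing)}")

    def stack(erps):
        return np.stack([e.data[[e.channel_labels.index(c) for c in chans]] for e in erps])

    diff = stack(erps_a) - stack(erps_b)  # participants x channels x samples
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    zero_var = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(zero_var, 0.0, mean / np.where(zero_var, 1.0, sd / np.sqrt(n)))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p[zero_var] = 1.0
    alpha_corrected = alpha / n_samples
    return ERPComparison(t_stats=t, p_values=p, alpha_corrected=alpha_corrected,
                         sig_mask=p < alpha_corrected, channel_labels=tuple(chans),
                         zero_variance=zero_var)
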