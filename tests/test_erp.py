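"""Epoching, artifact rejection, averaging, spatial interpolation, and the
mass-univariate paired comparison."""

import numpy as np
import pytest
from scipy import stats

from sparsecap import (
    AllRejectedError,
    ConfigError,
    DegenerateGeometryError,
    EpochArray,
    ERP,
    LabeledPoints,
    RejectionConfig,
    ShortEpochError,
    average_erp,
    epoch_trials,
    interpolate_to_template,
    mass_univariate_compare,
    reject_epochs,
)

FS = 512.0


def make_epochs(data, t0=-200.0, fs=FS):
    labels = tuple(f"ch{i}" for i in range(data.shape[0]))
    return EpochArray(data, fs, t0, labels)


def raw_epochs(n_ch=2, n_trials=4, t0=-325.0, t1=925.0, fill=0.0, fs=FS):
    # t0 chosen on the 512 Hz grid relative to -200 ms (64 samples earlier)
    n = int(round((t1 - t0) * fs / 1000.0))
    return make_epochs(np.full((n_ch, n, n_trials), fill), t0=t0, fs=fs)


class TestEpochTrials:
    def test_window_sample_count(self):
        """A [-200, 800) ms half-open window at 512 Hz is exactly 512 samples."""
        out = epoch_trials(raw_epochs(), (-200.0, 800.0))
        assert out.n_samples == 512
        assert out.t0_offset == -200.0

    def test_baseline_mean_is_zero(self):
        rng = np.random.default_rng(0)
        raw = raw_epochs()
        raw = make_epochs(rng.normal(5.0, 3.0, raw.data.shape), t0=raw.t0_offset)
        out = epoch_trials(raw, (-200.0, 800.0), (-100.0, 0.0))
        i0 = int(round((-100.0 - out.t0_offset) * FS / 1000.0))
        i1 = int(round((0.0 - out.t0_offset) * FS / 1000.0))
        np.testing.assert_allclose(out.data[:, i0:i1, :].mean(axis=1), 0.0, atol=1e-9)

    def test_constant_signal_zeroed(self):
        out = epoch_trials(raw_epochs(fill=7.5), (-200.0, 800.0))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_baseline_outside_window(self):
        with pytest.raises(ConfigError):
            epoch_trials(raw_epochs(), (-200.0, 800.0), (-300.0, 0.0))

    def test_epoch_shorter_than_window(self):
        with pytest.raises(ShortEpochError):
            epoch_trials(raw_epochs(t0=-75.0, t1=425.0), (-200.0, 800.0))


class TestRejectEpochs:
    def test_amplitude_rejection(self):
        rng = np.random.default_rng(1)
        data = rng.normal(0, 5.0, (2, 128, 10))
        data[0, 60, 3] = 80.0  # one 80 uV sample trips the +/-75 uV criterion
        kept, mask = reject_epochs(make_epochs(data))
        assert not mask.kept[3] and "amplitude" in mask.reasons[3]
        assert kept.n_trials == 9

    def test_clean_gaussian_epochs_survive(self):
        rng = np.random.default_rng(2)
        kept, mask = reject_epochs(make_epochs(rng.normal(0, 5.0, (3, 256, 40))))
        assert mask.kept.all()

    def test_kurtosis_outlier_detected_against_independent_oracle(self):
        """A heavy-tailed epoch among Gaussian epochs is rejected by the
        kurtosis criterion; the z-score is recomputed here by brute force."""
        rng = np.random.default_rng(3)
        data = rng.normal(0, 5.0, (1, 256, 50))
        data[0, :, 7] = 5.0 * rng.standard_t(df=1, size=256)  # heavy tails
        data = np.clip(data, -70, 70)  # stay under the amplitude criterion
        cfg = RejectionConfig(stat_threshold=5.0)
        kept, mask = reject_epochs(make_epochs(data), cfg)
        kurt = np.array([stats.kurtosis(data[0, :, i]) for i in range(50)])
        z = (kurt - kurt.mean()) / kurt.std(ddof=1)
        assert abs(z[7]) > cfg.stat_threshold  # oracle agrees the epoch is anomalous
        assert not mask.kept[7] and "kurtosis" in mask.reasons[7]

    def test_all_rejected_raises(self):
        data = np.full((1, 64, 3), 100.0)
        with pytest.raises(AllRejectedError):
            reject_epochs(make_epochs(data))


class TestAverageErp:
    positions = LabeledPoints({"ch0": (0, 0, 90), "ch1": (50, 0, 60)})

    def test_single_epoch_identity(self):
        data = np.arange(2 * 8 * 1, dtype=float).reshape(2, 8, 1)
        erp = average_erp(make_epochs(data), self.positions)
        np.testing.assert_array_equal(erp.data, data[:, :, 0])
        assert erp.n_trials == 1

    def test_antisymmetric_epochs_cancel(self):
        v = np.random.default_rng(4).normal(size=(2, 16))
        data = np.stack([v, -v], axis=2)
        erp = average_erp(make_epochs(data), self.positions)
        np.testing.assert_allclose(erp.data, 0.0, atol=1e-12)

    def test_noise_suppression_bound(self):
        """Averaging 100 epochs of signal + noise stays within 5*sigma/sqrt(100)
        of the clean signal."""
        rng = np.random.default_rng(5)
        sig = np.sin(np.linspace(0, 4 * np.pi, 64))[None, :]
        sigma = 5.0
        data = sig[:, :, None] + rng.normal(0, sigma, (1, 64, 100))
        erp = average_erp(EpochArray(data, FS, -200.0, ("ch0",)),
                          LabeledPoints({"ch0": (0, 0, 90)}))
        assert np.max(np.abs(erp.data - sig)) < 5 * sigma / np.sqrt(100)


def tetra_erp(values_fn, n_samples=4):
    """ERP on 5 non-coplanar electrodes; per-sample values from values_fn(xyz)."""
    pos = LabeledPoints({
        "A": (0.0, 0.0, 90.0), "B": (80.0, 0.0, 0.0), "C": (-80.0, 0.0, 0.0),
        "D": (0.0, 90.0, 0.0), "E": (0.0, -90.0, 0.0),
    })
    xyz = pos.array()
    data = np.stack([values_fn(xyz) * (k + 1) for k in range(n_samples)], axis=1)
    return ERP(data, FS, -200.0, 10, pos.labels, pos)


class TestInterpolateToTemplate:
    def test_identity_at_source_positions(self):
        erp = tetra_erp(lambda xyz: xyz[:, 0] + 0.5 * xyz[:, 2])
        out = interpolate_to_template(erp, erp.positions)
        np.testing.assert_allclose(out.data, erp.data, atol=1e-9)

    def test_linear_field_exact_inside_hull(self):
        """Barycentric interpolation has linear precision: an affine field is
        reproduced exactly at interior points."""
        a, b, c = 0.3, -0.7, 0.2
        erp = tetra_erp(lambda xyz: a * xyz[:, 0] + b * xyz[:, 1] + c * xyz[:, 2])
        interior = LabeledPoints({"P1": (5.0, 10.0, 20.0), "P2": (-10.0, 5.0, 10.0)})
        out = interpolate_to_template(erp, interior)
        for k in range(erp.n_samples):
            for lab in interior.labels:
                x, y, z = interior[lab]
                assert out.data[out.channel_labels.index(lab), k] == pytest.approx(
                    (a * x + b * y + c * z) * (k + 1), abs=1e-9)
        assert out.extrapolated_labels == ()

    def test_outside_hull_uses_nearest_and_flags(self):
        erp = tetra_erp(lambda xyz: xyz[:, 2])
        far = LabeledPoints({"FAR": (500.0, 0.0, 0.0)})  # nearest source is B
        out = interpolate_to_template(erp, far)
        assert out.extrapolated_labels == ("FAR",)
        np.testing.assert_allclose(out.data[0], erp.data[erp.channel_labels.index("B")])

    def test_coplanar_sources_degenerate(self):
        pos = LabeledPoints({f"c{i}": (float(i), float(i % 2), 0.0) for i in range(5)})
        erp = ERP(np.zeros((5, 3)), FS, 0.0, 1, pos.labels, pos)
        with pytest.raises(DegenerateGeometryError):
            interpolate_to_template(erp, pos)


def flat_erp(values, positions):
    return ERP(np.asarray(values, dtype=float), FS, -200.0, 10,
               positions.labels, positions)


class TestMassUnivariateCompare:
    pos = LabeledPoints({"ch0": (0, 0, 90)})

    def test_identical_lists_give_empty_mask(self):
        rng = np.random.default_rng(6)
        erps = [flat_erp(rng.normal(size=(1, 32)), self.pos) for _ in range(4)]
        cmp = mass_univariate_compare(erps, erps)
        np.testing.assert_array_equal(cmp.t_stats, 0.0)
        assert not cmp.sig_mask.any()
        assert cmp.zero_variance.all()

    def test_bonferroni_threshold_for_512_samples(self):
        rng = np.random.default_rng(7)
        erps_a = [flat_erp(rng.normal(size=(1, 512)), self.pos) for _ in range(3)]
        erps_b = [flat_erp(rng.normal(size=(1, 512)), self.pos) for _ in range(3)]
        cmp = mass_univariate_compare(erps_a, erps_b, alpha=0.05)
        assert cmp.alpha_corrected == pytest.approx(9.765625e-5, abs=0)

    def test_hand_computed_t_statistic(self):
        """Five pairs differing by 1 uV plus tiny offsets: t computed by hand."""
        offsets = np.array([-0.02, -0.01, 0.0, 0.01, 0.02])
        erps_a = [flat_erp([[1.0 + o, 0.0]], self.pos) for o in offsets]
        erps_b = [flat_erp([[0.0, 0.0]], self.pos) for _ in offsets]
        cmp = mass_univariate_compare(erps_a, erps_b, alpha=0.05)
        d = 1.0 + offsets
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        assert cmp.t_stats[0, 0] == pytest.approx(expected_t)
        expected_p = 2 * stats.t.sf(abs(expected_t), df=4)
        assert cmp.p_values[0, 0] == pytest.approx(expected_p)
        assert bool(cmp.sig_mask[0, 0]) == (expected_p < 0.05 / 2)

    def test_antisymmetry(self):
        rng = np.random.default_rng(8)
        erps_a = [flat_erp(rng.normal(size=(1, 16)), self.pos) for _ in range(5)]
        erps_b = [flat_erp(rng.normal(size=(1, 16)), self.pos) for _ in range(5)]
        fwd = mass_univariate_compare(erps_a, erps_b)
        rev = mass_univariate_compare(erps_b, erps_a)
        np.testing.assert_allclose(fwd.t_stats, -rev.t_stats, atol=1e-12)
        np.testing.assert_allclose(fwd.p_values, rev.p_values, atol=1e-12)

    def test_channel_selection(self):
        pos = LabeledPoints({"ch0": (0, 0, 90), "ch1": (50, 0, 60)})
        rng = np.random.default_rng(9)
        erps_a = [flat_erp(rng.normal(size=(2, 16)), pos) for _ in range(4)]
        erps_b = [flat_erp(rng.normal(size=(2, 16)), pos) for _ in range(4)]
        cmp = mass_univariate_compare(erps_a, erps_b, channel="ch1")
        assert cmp.channel_labels == ("ch1",)
        assert cmp.t_stats.shape == (1, 16)
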