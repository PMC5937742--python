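import numpy as np
import pytest

from conftest import make_burst
from fmm.discrimination import (
    ClassifierSpec,
    FeatureVector,
    LabeledFeatureSet,
    average_spectrum,
    extract_features,
    jackknife_confusion,
    min_signal_length,
    pairwise_discrimination,
    pca_reduce,
    select_best_roi,
)
from fmm.errors import ValidationError
from fmm.intervals import Interval
from fmm.io_formats import MovementType
from fmm.segmentation import ROI


def roi(snr, channel=0):
    return ROI(channel=channel, interval=Interval(0, 1), snr=snr, peak_env=1.0)


def brute_force_loo_knn(X, y, k=5, n_components=3):
    """Independent leave-one-out kNN oracle.

    Standardization, PCA (eigendecomposition of the covariance) and the
    k-nearest-neighbour vote are all recomputed from first principles for
    every held-out row.
    """
    n = len(y)
    counts = np.zeros((2, 2), dtype=int)
    for i in range(n):
        tr = np.delete(np.arange(n), i)
        Xtr, ytr = X[tr], y[tr]
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        Ztr = (Xtr - mu) / sd
        Zte = (X[i] - mu) / sd
        C = Ztr.T @ Ztr
        w, V = np.linalg.eigh(C)
        comps = V[:, ::-1][:, :n_components]
        Ptr = Ztr @ comps
        Pte = Zte @ comps
        d = np.sqrt(((Ptr - Pte) ** 2).sum(axis=1))
        nearest = np.argsort(d, kind="stable")[:k]
        votes = ytr[nearest]
        pred = int(votes.sum() * 2 > len(votes))
        counts[y[i], pred] += 1
    return counts


def gaussian_feature_set(rng, n_per_class=15, sep=10.0, dim=12):
    centroid = rng.normal(size=dim)
    direction = rng.normal(size=dim)
    direction /= np.linalg.norm(direction)
    X0 = centroid + rng.normal(size=(n_per_class, dim))
    X1 = centroid + sep * direction + rng.normal(size=(n_per_class, dim))
    X = np.vstack([X0, X1])
    labels = [MovementType.BREATHE] * n_per_class + [MovementType.STARTLE] * n_per_class
    return LabeledFeatureSet(X=X, labels=labels)


class TestSelectBestRoi:
    def test_argmax_snr(self):
        rois = [roi(2.1), roi(7.3, channel=1), roi(4.0, channel=2)]
        assert select_best_roi(rois).snr == 7.3

    def test_single(self):
        r = roi(3.0)
        assert select_best_roi([r]) is r

    def test_tie_breaks_to_lowest_channel(self):
        rois = [roi(5.0, channel=3), roi(5.0, channel=1)]
        assert select_best_roi(rois).channel == 1

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            select_best_roi([])


class TestExtractFeatures:
    FS = 128.0

    def test_duration(self):
        x = make_burst(self.FS, 2.0, 5.0, 1.0)
        fv = extract_features(x, self.FS)
        assert fv.duration == pytest.approx(2.0, abs=1 / self.FS)
        assert fv.energy == pytest.approx(float((x**2).sum()))

    def test_pure_tone_band_ratio(self):
        t = np.arange(int(4 * self.FS)) / self.FS
        x = np.sin(2 * np.pi * 2.5 * t)
        fv = extract_features(x, self.FS)
        assert fv.band_ratio[1] > 0.9  # 2.2-3 Hz band
        assert fv.band_ratio[0] < 0.05
        assert fv.band_ratio[2] < 0.05

    def test_noise_entropy_exceeds_tone_entropy(self, rng):
        n = int(4 * self.FS)
        t = np.arange(n) / self.FS
        tone = np.sin(2 * np.pi * 3 * t)
        noise = rng.normal(size=n)
        noise *= np.sqrt((tone**2).sum() / (noise**2).sum())
        assert (
            extract_features(noise, self.FS).entropy
            > extract_features(tone, self.FS).entropy
        )

    def test_translation_invariance(self):
        x = make_burst(self.FS, 1.5, 4.0, 2.0)
        a = extract_features(x, self.FS).to_array()
        b = extract_features(x.copy(), self.FS).to_array()
        np.testing.assert_array_equal(a, b)

    def test_too_short_names_minimum(self):
        with pytest.raises(ValidationError, match="minimum"):
            extract_features(np.ones(min_signal_length(self.FS) - 1), self.FS)

    def test_wavelet_fractions_sum_below_one(self):
        x = make_burst(self.FS, 2.0, 5.0, 1.0)
        fv = extract_features(x, self.FS)
        assert 0 < sum(fv.wavelet_energy) <= 1.0 + 1e-9

    def test_low_freq_burst_energy_in_coarse_bands(self):
        """A 1 Hz burst loads the coarse wavelet bands, an 8 Hz burst the finer."""
        slow = extract_features(make_burst(self.FS, 4.0, 1.0, 1.0), self.FS)
        fast = extract_features(make_burst(self.FS, 4.0, 8.0, 1.0), self.FS)
        # coarse bands are listed first
        assert sum(slow.wavelet_energy[:3]) > sum(fast.wavelet_energy[:3])


class TestFeatureVectorInvariants:
    def test_band_ratio_range_enforced(self):
        with pytest.raises(ValidationError):
            FeatureVector(1.0, 1.0, 1.0, (0.1,) * 6, (0.5, 1.2, 0.1))

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValidationError):
            FeatureVector(0.0, 1.0, 1.0, (0.1,) * 6, (0.1, 0.1, 0.1))


class TestPCA:
    def test_line_explains_all_variance(self, rng):
        t = rng.normal(size=30)
        direction = rng.normal(size=12)
        X = np.outer(t, direction)
        fset = LabeledFeatureSet(
            X=X, labels=[MovementType.BREATHE] * 30
        )
        scores, tf = pca_reduce(fset, ClassifierSpec(standardize=False))
        assert tf.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_scores_orthogonal(self, rng):
        fset = gaussian_feature_set(rng, n_per_class=20)
        scores, _ = pca_reduce(fset, ClassifierSpec())
        G = scores.T @ scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()

    def test_constant_column_dropped_with_warning(self, rng):
        X = rng.normal(size=(20, 12))
        X[:, 4] = 7.0
        fset = LabeledFeatureSet(X=X, labels=[MovementType.GENERAL] * 20)
        with pytest.warns(UserWarning, match="constant"):
            scores, tf = pca_reduce(fset, ClassifierSpec())
        assert scores.shape == (20, 3)

    def test_retained_variance_bounded(self, rng):
        fset = gaussian_feature_set(rng, n_per_class=20)
        scores, _ = pca_reduce(fset, ClassifierSpec())
        # standardized input has total variance = n_features
        assert scores.var(axis=0, ddof=1).sum() <= 12.0 + 1e-9


class TestJackknife:
    def test_equals_bruteforce_oracle_exactly(self, rng):
        """kNN jackknife counts equal the from-scratch LOO oracle on
        instances up to 30 rows."""
        for n_per_class in (6, 10, 15):
            for sep in (0.5, 2.0, 8.0):
                fset = gaussian_feature_set(rng, n_per_class=n_per_class, sep=sep)
                spec = ClassifierSpec(method="knn", k=5)
                cm = jackknife_confusion(
                    fset, spec, (MovementType.BREATHE, MovementType.STARTLE)
                )
                y = np.array([0] * n_per_class + [1] * n_per_class)
                oracle = brute_force_loo_knn(fset.X, y, k=5)
                np.testing.assert_array_equal(cm.counts, oracle)

    def test_separated_clusters_high_diagonal(self, rng):
        fset = gaussian_feature_set(rng, n_per_class=30, sep=10.0)
        cm = jackknife_confusion(
            fset, ClassifierSpec(), (MovementType.BREATHE, MovementType.STARTLE)
        )
        assert (cm.diagonal_percent >= 95.0).all()

    def test_identical_distributions_near_chance(self):
        diags = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            fset = gaussian_feature_set(r, n_per_class=20, sep=0.0)
            cm = jackknife_confusion(
                fset, ClassifierSpec(), (MovementType.BREATHE, MovementType.STARTLE)
            )
            diags.append(cm.diagonal_percent.mean())
        assert np.mean(diags) == pytest.approx(50.0, abs=8.0)

    def test_small_class_rejected_by_name(self, rng):
        X = rng.normal(size=(8, 12))
        labels = [MovementType.BREATHE] * 6 + [MovementType.STARTLE] * 2
        fset = LabeledFeatureSet(X=X, labels=labels)
        with pytest.raises(ValidationError, match="startle"):
            jackknife_confusion(
                fset, ClassifierSpec(k=5),
                (MovementType.BREATHE, MovementType.STARTLE),
            )

    @pytest.mark.parametrize("method", ["lda", "qda"])
    def test_lda_qda_same_shapes(self, rng, method):
        fset = gaussian_feature_set(rng, n_per_class=15, sep=6.0)
        cm = jackknife_confusion(
            fset, ClassifierSpec(method=method),
            (MovementType.BREATHE, MovementType.STARTLE),
        )
        assert cm.counts.shape == (2, 2)
        assert cm.counts.sum() == 30

    def test_global_pca_scope_runs(self, rng):
        fset = gaussian_feature_set(rng, n_per_class=10, sep=6.0)
        cm = jackknife_confusion(
            fset, ClassifierSpec(pca_scope="global"),
            (MovementType.BREATHE, MovementType.STARTLE),
        )
        assert (cm.diagonal_percent >= 90.0).all()


class TestPairwise:
    def _three_class_set(self, rng, sep):
        # orthogonal class directions spread across the feature space so that
        # separation survives per-column standardization
        dirs, _ = np.linalg.qr(rng.normal(size=(12, 3)))
        sets = []
        labels = []
        for i, m in enumerate(MovementType):
            X = rng.normal(size=(20, 12)) + dirs[:, i] * sep * 3
            sets.append(X)
            labels += [m] * 20
        return LabeledFeatureSet(X=np.vstack(sets), labels=labels)

    def test_three_tables_with_valid_rows(self, rng):
        fset = self._three_class_set(rng, sep=5.0)
        tables = pairwise_discrimination(fset, ClassifierSpec())
        assert len(tables) == 3
        for cm in tables.values():
            sums = cm.row_percent.sum(axis=1)
            np.testing.assert_allclose(sums, 100.0, atol=0.1)
            assert (cm.row_totals == 20).all()

    def test_separable_classes_all_diagonals_high(self, rng):
        fset = self._three_class_set(rng, sep=8.0)
        tables = pairwise_discrimination(fset, ClassifierSpec())
        for cm in tables.values():
            assert (cm.diagonal_percent >= 95.0).all()

    def test_missing_class_named(self, rng):
        fset = gaussian_feature_set(rng)
        with pytest.raises(ValidationError, match="general"):
            pairwise_discrimination(fset, ClassifierSpec())

    def test_accuracy_degrades_toward_chance(self, rng):
        """Shrinking class separation never raises the median diagonal."""
        meds = []
        for sep in (8.0, 2.0, 0.0):
            diags = []
            for seed in range(10):
                r = np.random.default_rng(seed)
                fset = gaussian_feature_set(r, n_per_class=15, sep=sep)
                cm = jackknife_confusion(
                    fset, ClassifierSpec(),
                    (MovementType.BREATHE, MovementType.STARTLE),
                )
                diags.append(cm.diagonal_percent.mean())
            meds.append(np.median(diags))
        assert meds[0] >= meds[1] >= meds[2]


class TestAverageSpectrum:
    FS = 128.0

    def test_tone_rois_peak_at_tone(self):
        t = np.arange(int(2 * self.FS)) / self.FS
        sigs = [np.sin(2 * np.pi * 5 * t + p) for p in (0, 1, 2)]
        out = average_spectrum({MovementType.STARTLE: sigs}, self.FS)
        f, psd = out[MovementType.STARTLE]
        assert f[np.argmax(psd)] == pytest.approx(5.0, abs=0.5)

    def test_parseval_within_one_percent(self, rng):
        sigs = [rng.normal(size=n) for n in (100, 200, 333)]
        out = average_spectrum({MovementType.GENERAL: sigs}, self.FS)
        f, psd = out[MovementType.GENERAL]
        mean_energy = np.mean([(s**2).sum() for s in sigs])
        assert np.trapezoid(psd, f) == pytest.approx(mean_energy, rel=0.01)

    def test_single_roi_equals_own_periodogram(self, rng):
        x = rng.normal(size=256)
        out = average_spectrum({MovementType.BREATHE: [x]}, self.FS, nfft=256)
        from scipy.signal import periodogram

        f, ref = periodogram(x, fs=self.FS, nfft=256, detrend=False)
        scale = (x**2).sum() / np.trapezoid(ref, f)
        np.testing.assert_allclose(out[MovementType.BREATHE][1], ref * scale, rtol=1e-9)

    def test_startle_bursts_mass_below_10hz(self, rng):
        from fmm.synthetic import default_burst_models

        model = default_burst_models()[MovementType.STARTLE]
        sigs = []
        for _ in range(20):
            dur = rng.uniform(*model.duration_range)
            freq = rng.uniform(*model.center_freq_range)
            amp = rng.uniform(*model.amplitude_range)
            sigs.append(make_burst(self.FS, dur, freq, amp))
        out = average_spectrum({MovementType.STARTLE: sigs}, self.FS)
        f, psd = out[MovementType.STARTLE]
        frac = np.trapezoid(psd[f < 10], f[f < 10]) / np.trapezoid(psd, f)
        assert frac >= 0.90

    def test_empty_type_omitted_with_warning(self, rng):
        sigs = [rng.normal(size=64)]
        with pytest.warns(UserWarning, match="omitted"):
            out = average_spectrum(
                {MovementType.BREATHE: sigs, MovementType.STARTLE: []}, self.FS
            )
        assert MovementType.STARTLE not in out
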