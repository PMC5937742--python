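"""Feature extraction and pairwise movement-type discrimination.

For every candidate movement that matched a physician annotation, the ROI from
the acoustic channel with the highest SNR is excised from the *non-rectified*
conditioned signal and summarized by a 12-component feature vector:

1.  duration (s)
2.  energy (sum of squared samples)
3.  spectral (Shannon) entropy of the normalized periodogram, in bits
4.  six relative wavelet detail-band energies (Daubechies-4, the six coarsest
    detail levels, each as a fraction of total detail energy)
5.  three frequency-window energy ratios: band energy in 1.1-1.5 Hz,
    2.2-3 Hz and 6-9 Hz, each relative to the 0.5-20 Hz total

Vectors are standardized, reduced to the first three principal components,
and classified pairwise (breathe/startle, general/startle, breathe/general)
with a leave-one-out ("take one out" jackknife) protocol, accumulating a 2x2
confusion matrix per pair.  kNN is the primary classifier; LDA and QDA are
available for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pywt
from scipy import signal as sps
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler

from .errors import ConfigurationError, ValidationError
from .io_formats import MovementType
from .segmentation import ROI

__all__ = [
    "FeatureVector",
    "FEATURE_NAMES",
    "LabeledFeatureSet",
    "ClassifierSpec",
    "ConfusionMatrix",
    "select_best_roi",
    "extract_features",
    "min_signal_length",
    "pca_reduce",
    "jackknife_confusion",
    "pairwise_discrimination",
    "average_spectrum",
    "PAIRS",
]

BAND_WINDOWS_HZ = ((1.1, 1.5), (2.2, 3.0), (6.0, 9.0))
BAND_TOTAL_HZ = (0.5, 20.0)
N_WAVELET_BANDS = 6
WAVELET = "db4"

PAIRS = (
    (MovementType.BREATHE, MovementType.STARTLE),
    (MovementType.GENERAL, MovementType.STARTLE),
    (MovementType.BREATHE, MovementType.GENERAL),
)


@dataclass(frozen=True)
class FeatureVector:
    duration: float
    energy: float
    entropy: float
    wavelet_energy: tuple[float, ...]  # 6 fractions, coarse -> fine
    band_ratio: tuple[float, ...]  # 3 fractions

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValidationError("duration must be > 0")
        if self.energy < 0 or any(w < 0 for w in self.wavelet_energy):
            raise ValidationError("energies must be >= 0")
        if len(self.wavelet_energy) != N_WAVELET_BANDS or len(self.band_ratio) != 3:
            raise ValidationError("expected 6 wavelet + 3 band components")
        if any(not 0 <= b <= 1 for b in self.band_ratio):
            raise ValidationError("band ratios must lie in [0, 1]")

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.duration, self.energy, self.entropy]
            + list(self.wavelet_energy)
            + list(self.band_ratio)
        )


FEATURE_NAMES = (
    ["duration_s", "energy", "entropy_bits"]
    + [f"wavelet_e{i}" for i in range(1, N_WAVELET_BANDS + 1)]
    + ["band_1.1-1.5Hz", "band_2.2-3Hz", "band_6-9Hz"]
)


@dataclass
class LabeledFeatureSet:
    X: np.ndarray  # (n, 12)
    labels: list[MovementType]
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.labels):
            raise ValidationError("feature matrix rows must match labels")
        if not np.all(np.isfinite(self.X)):
            raise ValidationError("feature matrix contains missing values")
        if not self.subject_ids:
            self.subject_ids = [""] * self.X.shape[0]

    def subset(self, types: Sequence[MovementType]) -> "LabeledFeatureSet":
        keep = [i for i, m in enumerate(self.labels) if m in types]
        return LabeledFeatureSet(
            X=self.X[keep],
            labels=[self.labels[i] for i in keep],
            subject_ids=[self.subject_ids[i] for i in keep],
        )

    def __len__(self) -> int:
        return self.X.shape[0]


@dataclass(frozen=True)
class ClassifierSpec:
    method: str = "knn"
    k: int = 5
    n_components: int = 3
    standardize: bool = True
    pca_scope: str = "fold"  # "fold" (refit per jackknife fold) or "global"

    def __post_init__(self) -> None:
        if self.method not in ("knn", "lda", "qda"):
            raise ConfigurationError(f"unknown method {self.method!r}")
        if self.method == "knn" and (self.k < 1 or self.k % 2 == 0):
            raise ConfigurationError("k must be odd and >= 1")
        if self.pca_scope not in ("fold", "global"):
            raise ConfigurationError("pca_scope must be 'fold' or 'global'")
        if self.n_components < 1:
            raise ConfigurationError("n_components must be >= 1")


@dataclass
class ConfusionMatrix:
    """Pairwise confusion table: rows = observed type, columns = predicted."""

    labels: tuple[MovementType, MovementType]
    counts: np.ndarray  # (2, 2) ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (2, 2) or (self.counts < 0).any():
            raise ValidationError("counts must be a non-negative 2x2 matrix")

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def row_percent(self) -> np.ndarray:
        totals = self.row_totals.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.counts / totals[:, None]
        return pct

    @property
    def diagonal_percent(self) -> np.ndarray:
        return np.diag(self.row_percent)

    def to_rows(self) -> list[dict]:
        """Rows in the published table layout: observed type, percentages, Total."""
        out = []
        for i, lab in enumerate(self.labels):
            row = {"observed": lab.value}
            for j, pred in enumerate(self.labels):
                row[f"pred_{pred.value}_pct"] = round(float(self.row_percent[i, j]), 2)
            row["total"] = int(self.row_totals[i])
            out.append(row)
        return out


def select_best_roi(rois: Sequence[ROI]) -> ROI:
    """The overlapping ROI with maximal SNR; ties break to the lowest channel."""
    if not rois:
        raise ValidationError("no overlapping ROIs to select from")
    return min(rois, key=lambda r: (-r.snr, r.channel))


def min_signal_length(fs: float) -> int:
    """Minimum ROI length (samples) for feature extraction: the db4 support."""
    return pywt.Wavelet(WAVELET).dec_len


def _wavelet_depth(fs: float) -> int:
    # detail level j spans [fs/2^(j+1), fs/2^j] Hz; choose the depth whose
    # coarsest detail band reaches ~0.5 Hz, so the six coarsest bands tile
    # approximately 0.5 .. fs/4 Hz (0.5-32 Hz at fs=128)
    return max(N_WAVELET_BANDS, int(round(np.log2(fs))))


def _dwt_support(fs: float) -> int:
    flen = pywt.Wavelet(WAVELET).dec_len
    return (flen - 1) * 2 ** _wavelet_depth(fs) + 1


def _spectral_entropy_bits(pxx: np.ndarray) -> float:
    p = pxx[pxx > 0]
    total = p.sum()
    if total <= 0:
        return 0.0
    p = p / total
    return float(-(p * np.log2(p)).sum())


def extract_features(roi_signal: np.ndarray, fs: float) -> FeatureVector:
    """Compute the 12-component feature vector of one ROI signal.

    ``roi_signal`` is the conditioned, *non-rectified* excised segment.  It
    must be at least as long as the db4 wavelet support; segments shorter
    than the 6-band decomposition depth are zero-padded at the tail (zeros
    add no energy, so band fractions remain those of the burst itself).
    """
    x = np.asarray(roi_signal, dtype=float)
    need = min_signal_length(fs)
    if x.size < 2 or x.size < need:
        raise ValidationError(
            f"ROI of {x.size} samples too short for feature extraction; "
            f"minimum is {max(2, need)} samples at fs={fs}"
        )
    duration = x.size / fs
    energy = float((x**2).sum())

    f, pxx = sps.periodogram(x, fs=fs, detrend=False)
    entropy = _spectral_entropy_bits(pxx)

    level = _wavelet_depth(fs)
    support = _dwt_support(fs)
    xw = x if x.size >= support else np.pad(x, (0, support - x.size))
    coeffs = pywt.wavedec(xw, WAVELET, level=level)
    # coeffs = [a_L, d_L, d_{L-1}, ..., d_1]; the six coarsest details follow a_L
    details = coeffs[1 : 1 + N_WAVELET_BANDS]
    d_energy = np.array([(c**2).sum() for c in coeffs[1:]])
    total_detail = d_energy.sum()
    if total_detail > 0:
        wavelet_energy = tuple(
            float((c**2).sum() / total_detail) for c in details
        )
    else:
        wavelet_energy = tuple(0.0 for _ in range(N_WAVELET_BANDS))

    df_total = _band_energy(f, pxx, *BAND_TOTAL_HZ)
    ratios = []
    for lo, hi in BAND_WINDOWS_HZ:
        ratios.append(_band_energy(f, pxx, lo, hi) / df_total if df_total > 0 else 0.0)
    return FeatureVector(
        duration=duration,
        energy=energy,
        entropy=entropy,
        wavelet_energy=wavelet_energy,
        band_ratio=tuple(min(1.0, max(0.0, r)) for r in ratios),
    )


def _band_energy(f: np.ndarray, pxx: np.ndarray, lo: float, hi: float) -> float:
    m = (f >= lo) & (f <= hi)
    return float(pxx[m].sum())


# ---------------------------------------------------------------------------
# PCA + classification


class _FittedTransform:
    """Standardize (optionally) + project onto the leading PCA components."""

    def __init__(self, scaler: Optional[StandardScaler], pca: PCA, keep: np.ndarray):
        self.scaler = scaler
        self.pca = pca
        self.keep = keep

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)[:, self.keep]
        if self.scaler is not None:
            X = self.scaler.transform(X)
        return self.pca.transform(X)

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.pca.explained_variance_ratio_


def _fit_transform(X: np.ndarray, spec: ClassifierSpec) -> tuple[np.ndarray, _FittedTransform]:
    keep = np.arange(X.shape[1])
    scaler = None
    Z = X
    if spec.standardize:
        std = X.std(axis=0)
        const = std == 0
        if const.any():
            warnings.warn(
                f"dropping {int(const.sum())} constant feature column(s) "
                "before standardization",
                stacklevel=3,
            )
            keep = np.flatnonzero(~const)
        scaler = StandardScaler().fit(X[:, keep])
        Z = scaler.transform(X[:, keep])
    else:
        Z = X[:, keep]
    n_comp = min(spec.n_components, Z.shape[1], Z.shape[0])
    pca = PCA(n_components=n_comp).fit(Z)
    tf = _FittedTransform(scaler, pca, keep)
    return pca.transform(Z), tf


def pca_reduce(
    features: LabeledFeatureSet, spec: ClassifierSpec = ClassifierSpec()
) -> tuple[np.ndarray, _FittedTransform]:
    """Scores on the leading principal components plus the fitted transform."""
    if len(features) < spec.n_components + 1:
        raise ValidationError(
            f"need at least {spec.n_components + 1} rows for PCA, got {len(features)}"
        )
    return _fit_transform(features.X, spec)


def _make_classifier(spec: ClassifierSpec):
    if spec.method == "knn":
        return KNeighborsClassifier(n_neighbors=spec.k, metric="euclidean")
    if spec.method == "lda":
        return LinearDiscriminantAnalysis()
    return QuadraticDiscriminantAnalysis()


def jackknife_confusion(
    features: LabeledFeatureSet,
    spec: ClassifierSpec,
    class_pair: tuple[MovementType, MovementType],
) -> ConfusionMatrix:
    """Leave-one-out confusion matrix for one class pair.

    Each row in turn is held out; standardization, PCA and the classifier are
    fit on the remaining rows (``pca_scope='fold'``) or the global transform
    is reused (``pca_scope='global'``); the held-out row's prediction
    increments the counts.  Deterministic given the spec.
    """
    sub = features.subset(class_pair)
    y = np.array([class_pair.index(m) for m in sub.labels])
    for ci, cls in enumerate(class_pair):
        n_cls = int((y == ci).sum())
        need = spec.k if spec.method == "knn" else 2
        if n_cls < need:
            raise ValidationError(
                f"class {cls.value!r} has {n_cls} members; needs >= {need}"
            )
    X = sub.X
    n = len(sub)
    counts = np.zeros((2, 2), dtype=int)
    global_tf = None
    if spec.pca_scope == "global":
        _, global_tf = _fit_transform(X, spec)
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        if global_tf is None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                Ztr, tf = _fit_transform(X[train], spec)
            Zte = tf.transform(X[i : i + 1])
        else:
            Ztr = global_tf.transform(X[train])
            Zte = global_tf.transform(X[i : i + 1])
        clf = _make_classifier(spec)
        clf.fit(Ztr, y[train])
        pred = int(clf.predict(Zte)[0])
        counts[y[i], pred] += 1
    return ConfusionMatrix(labels=class_pair, counts=counts)


def pairwise_discrimination(
    features: LabeledFeatureSet, spec: ClassifierSpec = ClassifierSpec()
) -> dict[tuple[MovementType, MovementType], ConfusionMatrix]:
    """The three pairwise jackknife confusion matrices (published-table layout)."""
    present = set(features.labels)
    missing = [m.value for m in MovementType if m not in present]
    if missing:
        raise ValidationError(f"classes absent from feature set: {missing}")
    return {pair: jackknife_confusion(features, spec, pair) for pair in PAIRS}


# ---------------------------------------------------------------------------
# average spectra


def average_spectrum(
    rois_by_type: dict[MovementType, Sequence[np.ndarray]],
    fs: float,
    nfft: Optional[int] = None,
) -> dict[MovementType, tuple[np.ndarray, np.ndarray]]:
    """Per-type mean power spectral density of ROI signals.

    Each ROI's periodogram is computed on a common zero-padded grid and
    rescaled so it integrates (trapezoid in df) exactly to that ROI's energy
    (Parseval); the within-type average therefore integrates to the type's
    mean ROI energy.  Returns ``{type: (freqs, mean_psd)}``; empty types are
    omitted with a warning.
    """
    max_len = max(
        (len(x) for sigs in rois_by_type.values() for x in sigs), default=0
    )
    if max_len == 0:
        raise ValidationError("no ROI signals supplied")
    if nfft is None:
        nfft = int(2 ** np.ceil(np.log2(max(max_len, 16))))
    out: dict[MovementType, tuple[np.ndarray, np.ndarray]] = {}
    for mtype, sigs in rois_by_type.items():
        if not len(sigs):
            warnings.warn(f"no ROIs of type {mtype.value}; omitted", stacklevel=2)
            continue
        psds = []
        freqs = None
        for x in sigs:
            x = np.asarray(x, dtype=float)
            f, pxx = sps.periodogram(x, fs=fs, nfft=nfft, detrend=False)
            energy = float((x**2).sum())
            norm = np.trapezoid(pxx, f)
            if norm > 0:
                pxx = pxx * (energy / norm)
            psds.append(pxx)
            freqs = f
        out[mtype] = (freqs, np.mean(psds, axis=0))
    return out
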