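"""The six per-spike feature sets.

========= ==================================================== ====
name      content                                              dim
========= ==================================================== ====
simple    amplitude a and full-width-half-maximum w            2
SPDF_FV3  reduced SPDF subset [f14, f18, f19]                  3
SPDF_raw  full SPDF vector [f1, f2, f3, f5, ..., f24]          23
W_2-PCA   first two principal components of the raw waveform   2
W_3-PCA   first three principal components                     3
W_raw     the aligned waveform samples themselves              60
========= ==================================================== ====

Each extractor returns a :class:`FeatureMatrix` whose ``included`` mask
records which input spikes survived the set's exclusion rule, so that
``included rows + excluded spikes = input spikes`` always holds. ``W_raw``
never excludes anything; the two SPDF sets share one exclusion rule (an
undefined first fundamental point); ``simple`` drops spikes without a
positive peak or without half-amplitude crossings on both sides. PCA is
fitted per recording (mean-centered) on the raw-waveform matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .preprocessing import AlignedWaveform, ParameterError
from .spdf import (
    FV3_FEATURE_NAMES,
    SPDF_FEATURE_NAMES,
    fundamental_points,
    fv3_vector,
    spdf_vector,
)

FEATURE_SETS = ("simple", "SPDF_FV3", "SPDF_raw", "W_2-PCA", "W_3-PCA", "W_raw")


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-spike feature vectors for one feature set.

    ``X`` has one row per *included* spike; ``labels`` aligns with the rows;
    ``included`` is the mask over the input spike sequence.
    """

    feature_set: str
    X: np.ndarray
    labels: tuple
    included: np.ndarray
    feature_names: tuple

    @property
    def n_excluded(self) -> int:
        return int(np.sum(~self.included))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df["track"] = list(self.labels)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(Path(path), index=False)


@dataclass(frozen=True)
class PcaModel:
    """Fitted PCA: mean vector, orthonormal components, variance ratios."""

    mean: np.ndarray
    components: np.ndarray  # (n_comp, d_in)
    explained_variance_ratio: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X) - self.mean) @ self.components.T


# ---------------------------------------------------------------------------
# single-spike extractors


def feat_simple(w: AlignedWaveform):
    """Amplitude and FWHM, or ``None`` when the spike is excluded.

    Amplitude ``a`` is the positive peak voltage. The width ``w`` is the
    distance (in grid samples) between the two nearest points on either
    side of the peak where the signal falls below ``a / 2``, located by
    linear interpolation. Spikes with no positive peak (a <= 0) or with a
    missing half-amplitude crossing on either side are excluded.
    """
    s = w.samples
    peak = int(np.argmax(s))
    a = float(s[peak])
    if a <= 0:
        return None
    half = a / 2.0
    left = _cross_below(s, peak, half, step=-1)
    right = _cross_below(s, peak, half, step=+1)
    if left is None or right is None:
        return None
    return np.array([a, right - left])


def _cross_below(s: np.ndarray, peak: int, level: float, step: int):
    """Interpolated position where ``s`` first falls below ``level`` moving
    from the peak in direction ``step``; None when it never does."""
    i = peak
    while 0 <= i + step < len(s):
        j = i + step
        if s[j] < level:
            # linear interpolation between samples i (>= level) and j (< level)
            frac = (s[i] - level) / (s[i] - s[j])
            return i + step * frac
        i = j
    return None


def feat_raw(w: AlignedWaveform) -> np.ndarray:
    """The aligned waveform samples themselves; never excluded."""
    return w.samples.copy()


# re-exported single-spike SPDF extractors
feat_spdf = spdf_vector
feat_fv3 = fv3_vector


# ---------------------------------------------------------------------------
# recording-level extraction


def fit_pca(X: np.ndarray, n_comp: int):
    """Mean-centered PCA of the raw-waveform matrix.

    Returns ``(PcaModel, scores)``. ``n_comp`` must be smaller than the
    number of spikes.
    """
    X = np.asarray(X, dtype=np.float64)
    if n_comp >= X.shape[0]:
        raise ParameterError(
            f"n_comp={n_comp} must be < n_spikes={X.shape[0]}"
        )
    p = PCA(n_components=n_comp, svd_solver="full")
    scores = p.fit_transform(X)
    model = PcaModel(
        mean=p.mean_,
        components=p.components_,
        explained_variance_ratio=p.explained_variance_ratio_,
    )
    return model, scores


def extract_features(waveforms, feature_set: str) -> FeatureMatrix:
    """Build the FeatureMatrix of one feature set from aligned waveforms."""
    waveforms = list(waveforms)
    if feature_set not in FEATURE_SETS:
        raise ParameterError(f"unknown feature set {feature_set!r}")
    if feature_set in ("W_raw", "W_2-PCA", "W_3-PCA"):
        X = np.array([feat_raw(w) for w in waveforms])
        included = np.ones(len(waveforms), dtype=bool)
        labels = tuple(w.track for w in waveforms)
        if feature_set == "W_raw":
            names = tuple(f"w{i + 1}" for i in range(X.shape[1] if len(X) else 60))
            return FeatureMatrix(feature_set, X, labels, included, names)
        n_comp = 2 if feature_set == "W_2-PCA" else 3
        _, scores = fit_pca(X, n_comp)
        names = tuple(f"PC{i + 1}" for i in range(n_comp))
        return FeatureMatrix(feature_set, scores, labels, included, names)

    rows, labels, included = [], [], []
    for w in waveforms:
        if feature_set == "simple":
            vec = feat_simple(w)
        else:
            fp = fundamental_points(w)
            vec = (fv3_vector if feature_set == "SPDF_FV3" else spdf_vector)(w, fp)
        if vec is None:
            included.append(False)
        else:
            included.append(True)
            rows.append(vec)
            labels.append(w.track)
    names = {
        "simple": ("a", "w"),
        "SPDF_FV3": FV3_FEATURE_NAMES,
        "SPDF_raw": SPDF_FEATURE_NAMES,
    }[feature_set]
    X = np.array(rows) if rows else np.empty((0, len(names)))
    return FeatureMatrix(
        feature_set, X, tuple(labels), np.asarray(included, dtype=bool), names
    )


def extract_all_feature_sets(waveforms) -> dict:
    """All six FeatureMatrix objects, keyed by feature-set name."""
    return {fs: extract_features(waveforms, fs) for fs in FEATURE_SETS}
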