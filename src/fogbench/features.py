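"""Per-window feature extraction for the FoG classifier.

Each 128-sample window (3.2 s at 40 Hz) is summarised by 55 features in 12
groups: time-domain statistics of the three axes (means, increments of
consecutive windows' means, their cross-axis differences, standard
deviations, pairwise correlations, integrals), spectral-band statistics of
the plain DFT (band standard deviations, highest/second-highest harmonics,
centre of mass, spectral skewness and kurtosis), a 3-component PCA projection
of the cross-axis harmonic sums in the 0.1–8 Hz band, and 4th-order
autoregressive coefficients per axis.

Spectral conventions: the DFT is taken without any taper, so a unit cosine
aligned with bin ``h`` has magnitude N/2 at that bin.  With fs = 40 Hz and
N = 128 the bin width is 0.3125 Hz; a band [f1, f2] selects the bins whose
centre frequency lies inside the closed interval.  The 0.1–8 Hz analysis
band therefore covers bins 1–25.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.regression.linear_model import yule_walker

from .preprocess import FS_TARGET, WINDOW_SAMPLES, WindowSeries

logger = logging.getLogger(__name__)

# Named analysis bands (Hz).  The 0.1–0.68 Hz band captures postural
# transitions; 0.5–3 Hz is the walking band (WB); 3–8 Hz the freezing
# band (FB).
BAND_POSTURAL = (0.1, 0.68)
BAND_WALK = (0.5, 3.0)
BAND_FREEZE = (3.0, 8.0)
BAND_FULL = (0.1, 8.0)

AR_ORDER = 4
N_FEATURES = 55
N_PCA_COMPONENTS = 3

#: Per-group feature counts (must total 55).
FEATURE_ALLOCATION = {
    "g1": 3, "g2": 3, "g3": 3, "g4": 3, "g5": 3, "g6": 3,
    "g7": 7, "g8": 4, "g9": 8, "g10": 3, "g11": 3, "g12": 12,
}
assert sum(FEATURE_ALLOCATION.values()) == N_FEATURES

FEATURE_NAMES = (
    ["mean_x", "mean_y", "mean_z"],
    ["dmean_x", "dmean_y", "dmean_z"],
    ["ddmean_xy", "ddmean_xz", "ddmean_yz"],
    ["std_x", "std_y", "std_z"],
    ["corr_xy", "corr_xz", "corr_yz"],
    ["bandstd_post_mod", "bandstd_walk_mod", "bandstd_freeze_mod"],
    ["max_post_mod", "max2_post_mod", "max_freeze_mod", "max2_freeze_mod",
     "max_post_x", "max_post_y", "max_post_z"],
    ["scom_x", "scom_y", "scom_z", "scom_mod"],
    ["skew_x", "skew_y", "skew_z", "skew_mod",
     "kurt_x", "kurt_y", "kurt_z", "kurt_mod"],
    ["pca_1", "pca_2", "pca_3"],
    ["integ_x", "integ_y", "integ_z"],
    [f"ar{k}_{ax}" for ax in "xyz" for k in range(1, AR_ORDER + 1)],
)
FLAT_FEATURE_NAMES = [n for group in FEATURE_NAMES for n in group]
assert len(FLAT_FEATURE_NAMES) == N_FEATURES
#: Column names used in feature CSV files (f01..f55).
FEATURE_COLUMNS = [f"f{i + 1:02d}" for i in range(N_FEATURES)]

_EPS = 1e-12


def band_bins(
    f1: float, f2: float, fs: float = FS_TARGET, n: int = WINDOW_SAMPLES
) -> np.ndarray:
    """Indices of DFT bins whose centre frequency lies in [f1, f2] (closed)."""
    if not 0 <= f1 < f2 <= fs / 2:
        raise ValueError(f"invalid band [{f1}, {f2}] for fs={fs}")
    freqs = fs * np.arange(n // 2 + 1) / n
    bins = np.nonzero((freqs >= f1 - 1e-9) & (freqs <= f2 + 1e-9))[0]
    if len(bins) == 0:
        raise ValueError(f"band [{f1}, {f2}] contains no DFT bins at fs={fs}, N={n}")
    return bins


# Bins 1..25 span 0.1–8 Hz at the default resolution; the PCA basis and the
# spectral centre-of-mass / shape statistics operate on them.
FULL_BAND_BINS = band_bins(*BAND_FULL)


@dataclass
class Spectrum:
    """Plain DFT of one window: per-axis harmonics plus the modulus channel."""

    axes: np.ndarray      # (N, 3) complex
    modulus: np.ndarray   # (N,) complex — DFT of the modulus series
    fs: float = FS_TARGET

    @property
    def n(self) -> int:
        return len(self.modulus)

    @property
    def bin_width(self) -> float:
        return self.fs / self.n

    def magnitude(self, channel: str) -> np.ndarray:
        """|X_h| for one of channels 'x', 'y', 'z', 'modulus', 'S'."""
        if channel == "modulus":
            return np.abs(self.modulus)
        if channel == "S":
            return np.abs(self.axes).sum(axis=1)
        try:
            col = "xyz".index(channel)
        except ValueError:
            raise ValueError(f"unknown channel {channel!r}") from None
        return np.abs(self.axes[:, col])


def modulus_series(window: np.ndarray) -> np.ndarray:
    """Euclidean norm of the three axes per sample, in g."""
    return np.sqrt((np.asarray(window, dtype=float) ** 2).sum(axis=-1))


def stft(window: np.ndarray, fs: float = FS_TARGET) -> Spectrum:
    """DFT of one (N, 3) window, no taper."""
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[1] != 3:
        raise ValueError(f"window must have shape (N, 3), got {window.shape}")
    return Spectrum(
        axes=np.fft.fft(window, axis=0),
        modulus=np.fft.fft(modulus_series(window)),
        fs=fs,
    )


def band_sum(spec: Spectrum, f1: float, f2: float, channel: str = "modulus") -> float:
    """Sum of |X_h| over the bins whose centre frequency lies in [f1, f2]."""
    bins = band_bins(f1, f2, spec.fs, spec.n)
    return float(spec.magnitude(channel)[bins].sum())


@dataclass
class PCABasis:
    """3-component orthonormal basis for the 0.1–8 Hz harmonic-sum vectors.

    Fitted once on a per-subject subsample of training windows; prediction
    only ever applies the stored projection (never refits).
    """

    mean: np.ndarray              # (25,)
    components: np.ndarray        # (3, 25), orthonormal rows
    singular_values: np.ndarray   # (3,)
    seed: int | None = None

    def project(self, s: np.ndarray) -> np.ndarray:
        """Latent representation V·(S − mean) of harmonic-sum vector(s)."""
        return (np.asarray(s, dtype=float) - self.mean) @ self.components.T


def spectral_sum_vector(window: np.ndarray, fs: float = FS_TARGET) -> np.ndarray:
    """Cross-axis harmonic sums |X_h|+|Y_h|+|Z_h| over the 0.1–8 Hz bins."""
    mags = np.abs(np.fft.fft(np.asarray(window, dtype=float), axis=0))
    return mags.sum(axis=1)[FULL_BAND_BINS]


def fit_pca(
    windows_by_subject: dict[str, np.ndarray],
    fraction_per_subject: float = 0.10,
    seed: int = 0,
    n_components: int = N_PCA_COMPONENTS,
) -> PCABasis:
    """Fit the spectral PCA basis on a per-subject random subsample.

    For each subject a ``fraction_per_subject`` share of windows is drawn
    (at least one), their harmonic-sum vectors are stacked, columns centred,
    and an SVD taken; the first three right-singular directions form the
    change-of-basis matrix V.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for subject in sorted(windows_by_subject):
        wins = np.asarray(windows_by_subject[subject], dtype=float)
        n_take = max(1, int(round(fraction_per_subject * len(wins))))
        idx = rng.choice(len(wins), size=n_take, replace=False)
        for i in np.sort(idx):
            rows.append(spectral_sum_vector(wins[i]))
    if len(rows) < n_components:
        raise ValueError(
            f"need at least {n_components} windows to fit the basis, "
            f"got {len(rows)}"
        )
    m = np.vstack(rows)
    mean = m.mean(axis=0)
    _, sing, vt = np.linalg.svd(m - mean, full_matrices=False)
    if len(sing) < n_components or sing[n_components - 1] <= sing[0] * 1e-12:
        raise ValueError("training windows are rank-deficient in the 0.1-8 Hz band")
    v = vt[:n_components]
    # deterministic sign: largest-magnitude loading of each row positive
    for row in v:
        peak = row[np.argmax(np.abs(row))]
        if peak < 0:
            row *= -1.0
    return PCABasis(
        mean=mean,
        components=v,
        singular_values=sing[:n_components],
        seed=seed,
    )


def ar_coefficients(x: np.ndarray, order: int = AR_ORDER) -> np.ndarray:
    """Yule–Walker AR coefficients of one axis within a window.

    A zero-variance (constant) signal has no defined autocorrelation; by
    convention the coefficients are reported as zeros and a warning logged.
    """
    x = np.asarray(x, dtype=float)
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    if len(x) <= order:
        raise ValueError(f"window length {len(x)} too short for AR({order})")
    if np.var(x) < _EPS:
        logger.warning("constant window axis: AR coefficients defined as zero")
        return np.zeros(order)
    rho, _sigma = yule_walker(x, order=order, method="mle")
    return np.asarray(rho, dtype=float)


def _weighted_spectral_shape(mags: np.ndarray, freqs: np.ndarray) -> tuple[float, float, float]:
    """(centre of mass, skewness, kurtosis) of frequency weighted by |X_h|."""
    total = mags.sum()
    if total < _EPS:
        return 0.0, 0.0, 0.0
    w = mags / total
    mu = float(w @ freqs)
    var = float(w @ (freqs - mu) ** 2)
    if var < _EPS:
        return mu, 0.0, 0.0
    sd = np.sqrt(var)
    skew = float(w @ ((freqs - mu) / sd) ** 3)
    kurt = float(w @ ((freqs - mu) / sd) ** 4)
    return mu, skew, kurt


def _top_two(values: np.ndarray) -> tuple[float, float]:
    """Highest and second-highest value (second defined as 0 for one bin)."""
    if len(values) == 1:
        return float(values[0]), 0.0
    part = np.sort(values)[::-1]
    return float(part[0]), float(part[1])


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; 0 when either input has zero variance."""
    sa, sb = a.std(), b.std()
    if sa < _EPS or sb < _EPS:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def extract_features(
    window: np.ndarray,
    prev_window_means: np.ndarray,
    basis: PCABasis,
    fs: float = FS_TARGET,
) -> np.ndarray:
    """Compute the 55-value descriptor of one window.

    ``prev_window_means`` are the per-axis means of the immediately
    preceding overlapped window (zeros for the first window of a recording).
    """
    window = np.asarray(window, dtype=float)
    if not np.all(np.isfinite(window)):
        raise ValueError("window contains non-finite samples")
    if basis is None:
        raise ValueError("PCA basis must be fitted before feature extraction")
    prev = np.asarray(prev_window_means, dtype=float)

    spec = stft(window, fs)
    freqs = fs * np.arange(spec.n // 2 + 1) / spec.n
    full_freqs = freqs[FULL_BAND_BINS]

    means = window.mean(axis=0)                          # g1
    dmeans = means - prev                                # g2
    ddmeans = np.array(
        [dmeans[0] - dmeans[1], dmeans[0] - dmeans[2], dmeans[1] - dmeans[2]]
    )                                                    # g3
    stds = window.std(axis=0)                            # g4
    corrs = np.array(
        [
            _safe_corr(window[:, 0], window[:, 1]),
            _safe_corr(window[:, 0], window[:, 2]),
            _safe_corr(window[:, 1], window[:, 2]),
        ]
    )                                                    # g5

    mod_mag = spec.magnitude("modulus")
    bandstd = np.array(
        [
            mod_mag[band_bins(*band, fs, spec.n)].std()
            for band in (BAND_POSTURAL, BAND_WALK, BAND_FREEZE)
        ]
    )                                                    # g6

    post_bins = band_bins(*BAND_POSTURAL, fs, spec.n)
    freeze_bins = band_bins(*BAND_FREEZE, fs, spec.n)
    g7 = np.empty(7)
    g7[0], g7[1] = _top_two(mod_mag[post_bins])
    g7[2], g7[3] = _top_two(mod_mag[freeze_bins])
    for j, ch in enumerate("xyz"):
        g7[4 + j] = spec.magnitude(ch)[post_bins].max()

    channels = ["x", "y", "z", "modulus"]
    shape = [
        _weighted_spectral_shape(spec.magnitude(ch)[FULL_BAND_BINS], full_freqs)
        for ch in channels
    ]
    scom = np.array([s[0] for s in shape])               # g8
    skews = np.array([s[1] for s in shape])
    kurts = np.array([s[2] for s in shape])              # g9

    g10 = basis.project(spec.magnitude("S")[FULL_BAND_BINS])
    integrals = window.sum(axis=0) / fs                  # g11
    ar = np.concatenate(
        [ar_coefficients(window[:, j], AR_ORDER) for j in range(3)]
    )                                                    # g12

    out = np.concatenate(
        [means, dmeans, ddmeans, stds, corrs, bandstd, g7, scom, skews, kurts,
         g10, integrals, ar]
    )
    assert out.shape == (N_FEATURES,)
    return out


# Column indices of the PCA projection features (the only basis-dependent
# group), used to re-project cached features under a different basis.
_PCA_SLICE = slice(37, 40)
PCA_FEATURE_COLUMNS = FEATURE_COLUMNS[_PCA_SLICE]
assert [FLAT_FEATURE_NAMES[i] for i in range(37, 40)] == ["pca_1", "pca_2", "pca_3"]


def spectral_sums_matrix(series: WindowSeries) -> np.ndarray:
    """Harmonic-sum vectors S^W (n_windows, 25) for every window."""
    mags = np.abs(np.fft.fft(series.windows, axis=1))
    return mags.sum(axis=2)[:, FULL_BAND_BINS]


def reproject_pca_features(
    df: pd.DataFrame, s_matrix: np.ndarray, basis: PCABasis
) -> pd.DataFrame:
    """Return a copy of a feature frame with g10 recomputed under ``basis``.

    Only the 3 PCA projections depend on the fitted basis, so cached feature
    matrices can be reused across leave-one-out folds that each fit their own
    basis on their own training subjects.
    """
    out = df.copy()
    out[PCA_FEATURE_COLUMNS] = basis.project(s_matrix)
    return out


def feature_matrix(series: WindowSeries, basis: PCABasis) -> pd.DataFrame:
    """Feature vectors for every window of a recording.

    Returns a frame with ``subject``, ``session``, ``window_start_s`` and
    the 55 feature columns ``f01``..``f55``.
    """
    n = series.n_windows
    feats = np.empty((n, N_FEATURES))
    prev = np.zeros(3)
    for i in range(n):
        feats[i] = extract_features(series.windows[i], prev, basis, series.fs)
        prev = series.windows[i].mean(axis=0)
    df = pd.DataFrame(feats, columns=FEATURE_COLUMNS)
    df.insert(0, "subject", series.subject_id)
    df.insert(1, "session", series.session)
    df.insert(2, "window_start_s", series.start_times)
    return df
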