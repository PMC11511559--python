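"""Per-channel feature bank for motor-imagery epochs.

Seventeen features are computed for every channel and concatenated
channel-major into one fixed-length vector per epoch:

====================  =====================================================
mu_power, beta_power  Welch band power in the mu (8-12 Hz) and beta
                      (13-30 Hz) bands, where event-related
                      desynchronization expresses itself.
activity, mobility,   Hjorth parameters: variance, a normalized dominant-
complexity            frequency proxy, and a bandwidth proxy, computed with
                      the first difference as the discrete derivative.
ar1..ar4              Burg-estimated autoregressive coefficients, order 4.
higuchi_fd            Higuchi estimate of the curve's box-counting
                      (fractal) dimension, in [1, 2].
apen, sampen          Approximate and sample entropy (m=2, r=0.2*sd,
                      Chebyshev distance).
permen                Permutation entropy of ordinal patterns (m=3, lag 1,
                      natural log).
skewness, kurtosis    Biased (1/N) moment ratios; kurtosis is excess
                      (Gaussian = 0).
variance, std         Unbiased (1/(N-1)) variance and its square root.
====================  =====================================================

Degenerate inputs (e.g. a constant channel) yield NaN sentinels and flag
the epoch; flagged epochs are excluded from normalization statistics and
classifier training rather than imputed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal, stats

from .eeg_core import Epoch

__all__ = [
    "FeatureConfig",
    "FeatureVector",
    "NormParams",
    "FEATURE_NAMES",
    "band_power_welch",
    "hjorth",
    "ar_coefficients",
    "fractal_dimension",
    "approximate_entropy",
    "sample_entropy",
    "permutation_entropy",
    "higher_order_stats",
    "featurize_epoch",
    "featurize_epochs",
    "fit_normalizer",
    "apply_normalizer",
]


@dataclass
class FeatureConfig:
    mu_band: tuple[float, float] = (8.0, 12.0)
    beta_band: tuple[float, float] = (13.0, 30.0)
    ar_order: int = 4
    ar_method: str = "burg"  # or "yule_walker"
    apen_sampen_m: int = 2
    apen_sampen_r_scale: float = 0.2
    perm_order: int = 3
    perm_delay: int = 1
    higuchi_kmax: int = 10
    welch_segment_s: float = 1.0
    welch_overlap: float = 0.5

    def __post_init__(self) -> None:
        if self.ar_order < 1:
            raise ValueError("ar_order must be >= 1")
        if self.apen_sampen_r_scale <= 0:
            raise ValueError("r_scale must be positive")
        if self.perm_order < 2:
            raise ValueError("perm_order must be >= 2")


FEATURE_NAMES = [
    "mu_power",
    "beta_power",
    "activity",
    "mobility",
    "complexity",
    "ar1",
    "ar2",
    "ar3",
    "ar4",
    "higuchi_fd",
    "apen",
    "sampen",
    "permen",
    "skewness",
    "kurtosis",
    "variance",
    "std",
]


@dataclass
class FeatureVector:
    values: np.ndarray
    layout: list[tuple[str, str]]
    flagged: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.layout),):
            raise ValueError("values and layout lengths differ")


# ---------------------------------------------------------------------------
# spectral


def band_power_welch(
    x: np.ndarray, fs: float, band: tuple[float, float], cfg: FeatureConfig | None = None
) -> float:
    """Welch band power: the PSD integrated over [band.lo, band.hi].

    Hann window, 1 s segments with 50 % overlap by default, one-sided
    density; integration is trapezoidal over the bins whose centers fall in
    the band.
    """
    cfg = cfg or FeatureConfig()
    x = np.asarray(x, dtype=float)
    lo, hi = band
    if not (0.0 < lo < hi < fs / 2.0):
        raise ValueError(f"band {band} outside (0, fs/2) at fs={fs}")
    nperseg = int(round(cfg.welch_segment_s * fs))
    if x.size < nperseg:
        raise ValueError(f"signal of {x.size} samples shorter than one Welch segment")
    freqs, psd = signal.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(nperseg * cfg.welch_overlap),
        average="mean",
        scaling="density",
    )
    mask = (freqs >= lo) & (freqs <= hi)
    if mask.sum() < 2:
        # degenerate band narrower than one bin: fall back to bin sum
        return float(psd[mask].sum() * (freqs[1] - freqs[0]))
    return float(np.trapezoid(psd[mask], freqs[mask]))


# ---------------------------------------------------------------------------
# Hjorth


def hjorth(x: np.ndarray) -> tuple[float, float, float]:
    """Hjorth activity, mobility and complexity.

    The derivative is the per-sample first difference (no fs scaling), so a
    sinusoid of frequency f at rate fs has mobility ~ 2*pi*f/fs.  Variance
    uses the N-1 convention throughout.  A constant signal returns activity
    0 with NaN mobility/complexity.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("hjorth requires at least 3 samples")
    var_x = float(np.var(x, ddof=1))
    if var_x == 0.0:
        warnings.warn("constant signal: Hjorth mobility/complexity undefined")
        return 0.0, math.nan, math.nan
    dx = np.diff(x)
    ddx = np.diff(dx)
    var_dx = float(np.var(dx, ddof=1))
    mobility = math.sqrt(var_dx / var_x)
    if var_dx == 0.0:
        warnings.warn("linear signal: Hjorth complexity undefined")
        return var_x, mobility, math.nan
    var_ddx = float(np.var(ddx, ddof=1))
    complexity = math.sqrt(var_ddx / var_dx) / mobility
    return var_x, mobility, complexity


# ---------------------------------------------------------------------------
# autoregressive


def _burg(x: np.ndarray, p: int) -> np.ndarray:
    """Burg lattice estimate of AR coefficients phi_1..phi_p for the model
    x(t) = sum_i phi_i x(t-i) + e(t)."""
    f = x[1:].astype(float).copy()
    b = x[:-1].astype(float).copy()
    a = np.zeros(0)
    for m in range(p):
        den = float(f @ f + b @ b)
        if den == 0.0:
            raise ValueError("degenerate signal in Burg recursion")
        k = -2.0 * float(f @ b) / den
        # polynomial update: A_m(z) = A_{m-1}(z) + k z^-m A_{m-1}(1/z)
        a = np.concatenate([a, [0.0]]) + k * np.concatenate([a[::-1], [1.0]])
        f, b = f[1:] + k * b[1:], b[:-1] + k * f[:-1]
    return -a


def ar_coefficients(x: np.ndarray, p: int = 4, method: str = "burg") -> np.ndarray:
    """AR(p) coefficients in lag order, Burg estimator by default.

    ``method='yule_walker'`` uses the biased-autocovariance Levinson-Durbin
    solution instead (kept as a cross-check route).
    """
    x = np.asarray(x, dtype=float)
    if x.size <= 3 * p:
        raise ValueError(f"need more than {3 * p} samples for AR({p})")
    x = x - x.mean()
    if np.ptp(x) == 0.0:
        raise ValueError("constant signal has no AR representation")
    if method == "burg":
        return _burg(x, p)
    if method == "yule_walker":
        n = x.size
        r = np.array([x[: n - k] @ x[k:] for k in range(p + 1)]) / n
        import scipy.linalg as sla

        return sla.solve_toeplitz(r[:p], r[1 : p + 1])
    raise ValueError(f"unknown AR method {method!r}")


# ---------------------------------------------------------------------------
# fractal dimension


def fractal_dimension(x: np.ndarray, kmax: int = 10) -> float:
    """Higuchi estimate of the fractal (box-counting) dimension of a curve.

    Mean normalized curve length L(k) is computed for lags k = 1..kmax; the
    dimension is the slope of log L(k) against log(1/k).  Smooth curves
    approach 1, white noise approaches 2; estimates outside [1, 2] are
    clipped with a warning.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 10 * kmax:
        raise ValueError(f"need at least {10 * kmax} samples for kmax={kmax}")
    lk = np.empty(kmax)
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            n_int = idx.size - 1
            if n_int < 1:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            lengths.append(dist * (n - 1) / (n_int * k) / k)
        lk[k - 1] = np.mean(lengths)
    k_arr = np.arange(1, kmax + 1, dtype=float)
    valid = lk > 0
    if valid.sum() < 2:
        return 1.0  # flat curve: zero length at every scale
    slope = np.polyfit(np.log(1.0 / k_arr[valid]), np.log(lk[valid]), 1)[0]
    fd = float(slope)
    if not 1.0 <= fd <= 2.0:
        warnings.warn(f"Higuchi estimate {fd:.3f} outside [1, 2]; clipping")
        fd = min(max(fd, 1.0), 2.0)
    return fd


# ---------------------------------------------------------------------------
# entropies


def _chebyshev_distances(x: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Chebyshev distance matrices between all templates of length
    m and of length m+1.

    Built incrementally from the lag-0 |x_i - x_j| matrix:
    D_L[i, j] = max(D_{L-1}[i, j], |x_{i+L-1} - x_{j+L-1}|).
    """
    d = np.abs(x[:, None] - x[None, :])
    dm = d
    for lag in range(1, m):
        dm = np.maximum(dm[:-1, :-1], d[lag:, lag:])
    dm1 = np.maximum(dm[:-1, :-1], d[m:, m:])
    return dm, dm1


def approximate_entropy(x: np.ndarray, m: int = 2, r_abs: float | None = None) -> float:
    """Approximate entropy ApEn(m, r) = Phi_m(r) - Phi_{m+1}(r).

    Phi_m is the mean log fraction of templates of length m within
    Chebyshev distance r of each template (self-matches included, the
    Pincus convention).  ``r_abs`` is an absolute tolerance in signal
    units.
    """
    x = np.asarray(x, dtype=float)
    if r_abs is None or r_abs <= 0:
        raise ValueError("r_abs must be a positive absolute tolerance")
    if x.size <= m + 1:
        raise ValueError("signal too short for ApEn")
    dm, dm1 = _chebyshev_distances(x, m)
    phi_m = float(np.log((dm <= r_abs).mean(axis=1)).mean())
    phi_m1 = float(np.log((dm1 <= r_abs).mean(axis=1)).mean())
    return phi_m - phi_m1


def _sampen_from_distances(dm: np.ndarray, dm1: np.ndarray, r_abs: float) -> float:
    # equal numbers of m- and (m+1)-templates (N-m of each); the matrices
    # are symmetric with an all-match diagonal, so i<j pair counts are
    # (total - diagonal) / 2
    n_t = dm1.shape[0]
    b = (int((dm[:n_t, :n_t] <= r_abs).sum()) - n_t) // 2
    a = (int((dm1 <= r_abs).sum()) - n_t) // 2
    if b == 0 or a == 0:
        warnings.warn("sample entropy undefined (no template matches); returning inf")
        return math.inf
    return float(-math.log(a / b))


def sample_entropy(x: np.ndarray, m: int = 2, r_abs: float | None = None) -> float:
    """Sample entropy -log(A/B), self-matches excluded.

    B counts template pairs of length m within Chebyshev distance r, A the
    pairs of length m+1.  Returns +inf with a warning when no (m+1)-matches
    exist (the standard undefined case).
    """
    x = np.asarray(x, dtype=float)
    if r_abs is None or r_abs <= 0:
        raise ValueError("r_abs must be a positive absolute tolerance")
    if x.size <= m + 1:
        raise ValueError("signal too short for SampEn")
    dm, dm1 = _chebyshev_distances(x, m)
    return _sampen_from_distances(dm, dm1, r_abs)


def permutation_entropy(
    x: np.ndarray, m: int = 3, delay: int = 1, normalized: bool = False
) -> float:
    """Shannon entropy (natural log) of ordinal patterns of order m.

    Ties within a window are ranked by temporal order of appearance
    (stable argsort).  ``normalized=True`` divides by log(m!).
    """
    x = np.asarray(x, dtype=float)
    n_pat = x.size - (m - 1) * delay
    if n_pat < 1:
        raise ValueError("signal too short for the requested order/delay")
    idx = np.arange(n_pat)[:, None] + delay * np.arange(m)[None, :]
    patterns = np.argsort(x[idx], axis=1, kind="stable")
    codes = patterns @ (m ** np.arange(m))
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    return h / math.log(math.factorial(m)) if normalized else h


# ---------------------------------------------------------------------------
# moments


def higher_order_stats(x: np.ndarray) -> tuple[float, float, float, float]:
    """(skewness, excess kurtosis, variance, standard deviation).

    Skewness and kurtosis are the biased 1/N moment ratios with the
    population standard deviation in the denominator; kurtosis carries the
    -3 excess term so a Gaussian scores 0.  Variance uses 1/(N-1) and the
    standard deviation is its square root.  Zero spread yields NaN
    skewness/kurtosis.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    variance = float(np.var(x, ddof=1))
    sd = math.sqrt(variance)
    if np.ptp(x) == 0.0:
        warnings.warn("zero spread: skewness/kurtosis undefined")
        return math.nan, math.nan, variance, sd
    skew = float(stats.skew(x, bias=True))
    kurt = float(stats.kurtosis(x, fisher=True, bias=True))
    return skew, kurt, variance, sd


# ---------------------------------------------------------------------------
# assembly


def _channel_features(x: np.ndarray, fs: float, cfg: FeatureConfig) -> np.ndarray:
    out = np.full(len(FEATURE_NAMES), np.nan)
    sd_pop = float(np.std(x))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # one Welch PSD shared by both bands
        nperseg = int(round(cfg.welch_segment_s * fs))
        freqs, psd = signal.welch(
            x,
            fs=fs,
            window="hann",
            nperseg=nperseg,
            noverlap=int(nperseg * cfg.welch_overlap),
            average="mean",
            scaling="density",
        )
        for slot, band in ((0, cfg.mu_band), (1, cfg.beta_band)):
            mask = (freqs >= band[0]) & (freqs <= band[1])
            out[slot] = np.trapezoid(psd[mask], freqs[mask])
        out[2], out[3], out[4] = hjorth(x)
        if sd_pop > 0:
            try:
                out[5:9] = ar_coefficients(x, cfg.ar_order, cfg.ar_method)
            except ValueError:
                pass
            out[9] = fractal_dimension(x, cfg.higuchi_kmax)
            r = cfg.apen_sampen_r_scale * sd_pop
            m = cfg.apen_sampen_m
            # the two entropies share the template distance matrices
            dm, dm1 = _chebyshev_distances(np.asarray(x, dtype=float), m)
            phi_m = float(np.log((dm <= r).mean(axis=1)).mean())
            phi_m1 = float(np.log((dm1 <= r).mean(axis=1)).mean())
            out[10] = phi_m - phi_m1
            out[11] = _sampen_from_distances(dm, dm1, r)
        out[12] = permutation_entropy(x, cfg.perm_order, cfg.perm_delay)
        out[13], out[14], out[15], out[16] = higher_order_stats(x)
    return out


def featurize_epoch(epoch: Epoch, cfg: FeatureConfig | None = None) -> FeatureVector:
    """Compute the 17-feature bank per channel, concatenated channel-major.

    Any undefined feature leaves a NaN sentinel in place and flags the
    vector; flagged vectors are excluded from normalizer fitting and
    classifier training.
    """
    cfg = cfg or FeatureConfig()
    if cfg.ar_order != 4:
        raise ValueError("the fixed 17-feature bank uses AR order 4")
    labels = epoch.channel_labels or [f"ch{i}" for i in range(epoch.n_channels)]
    blocks = [_channel_features(epoch.data[c], epoch.fs, cfg) for c in range(epoch.n_channels)]
    values = np.concatenate(blocks)
    layout = [(ch, feat) for ch in labels for feat in FEATURE_NAMES]
    flagged = bool(~np.all(np.isfinite(values)))
    return FeatureVector(values=values, layout=layout, flagged=flagged)


def featurize_epochs(
    epochs: list[Epoch], cfg: FeatureConfig | None = None
) -> tuple[np.ndarray, list, list[tuple[str, str]], np.ndarray]:
    """Feature matrix for a list of epochs.

    Returns ``(X, labels, layout, flagged)`` where ``flagged`` marks rows
    containing sentinel values.
    """
    cfg = cfg or FeatureConfig()
    vecs = [featurize_epoch(ep, cfg) for ep in epochs]
    if not vecs:
        raise ValueError("no epochs to featurize")
    layout = vecs[0].layout
    for v in vecs[1:]:
        if v.layout != layout:
            raise ValueError("inconsistent feature layouts across epochs")
    X = np.vstack([v.values for v in vecs])
    labels = [ep.label for ep in epochs]
    flagged = np.array([v.flagged for v in vecs])
    return X, labels, layout, flagged


# ---------------------------------------------------------------------------
# normalization


@dataclass
class NormParams:
    mean: np.ndarray
    std: np.ndarray
    layout: list[tuple[str, str]] = field(default_factory=list)


def fit_normalizer(train_vectors: np.ndarray, layout: list | None = None) -> NormParams:
    """Per-feature z-score parameters from the training set only.

    Zero-spread features pass through unscaled (std set to 1) with a
    warning, so degenerate columns cannot blow up test vectors.
    """
    X = np.asarray(train_vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 training vectors")
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=0)
    degenerate = std == 0.0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} constant feature(s) left unscaled")
        std = np.where(degenerate, 1.0, std)
    return NormParams(mean=mean, std=std, layout=list(layout or []))


def apply_normalizer(v: np.ndarray, params: NormParams) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != params.mean.shape[0]:
        raise ValueError("vector length does not match normalizer layout")
    return (v - params.mean) / params.std
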