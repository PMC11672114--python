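"""Time- and frequency-domain feature bank for 30-second EEG epochs.

Every epoch is first divided by its maximum absolute value so that
amplitude-dependent features (std, IQR, maximum first derivative, Hjorth
activity, spectral energy) compensate for gain differences between devices;
shape/complexity features are scale-invariant anyway.  The PSD is a Welch
median periodogram over 5-second Hamming segments with 50 % overlap
(0.2 Hz bins); the median across segments damps isolated artifacts.

Entropy and fractal estimators are implemented here directly:

* approximate/sample entropy: Chebyshev neighbor counts via a k-d tree
  (m = 2, r = 0.2 x epoch std);
* permutation and SVD entropy: order 3, delay 1, normalized, base 2;
* Lempel-Ziv complexity: LZ76 phrase count of the median-binarized epoch,
  normalized by n / log2(n);
* DFA exponent: log-spaced windows from 16 to n/4 samples, linear detrend;
* Katz, Higuchi (k_max = 10) and Petrosian fractal dimensions.

Degenerate (constant) epochs return the documented fallbacks with a flag and
are excluded later at PDF-estimation time, feature by feature.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd
from scipy import signal, stats

from .consensus import IntersectionLabels
from .core import EpochedSignal, STAGES3
from .synth import DEFAULT_BANDS

# ---------------------------------------------------------------------------
# Welch PSD


@dataclass
class PSDEstimate:
    freqs: np.ndarray
    psd: np.ndarray
    seg_len_s: float
    overlap: float
    average: str
    window: str
    n_segments: int

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def welch_psd(
    x: np.ndarray,
    fs: float,
    seg_len_s: float = 5.0,
    overlap: float = 0.5,
    average: str = "median",
    window: str = "hamming",
) -> PSDEstimate:
    """Welch periodogram; 5-s segments give 0.2 Hz bins at any rate."""
    x = np.asarray(x, dtype=float)
    if fs <= 2 * 35.0:
        raise ValueError("sampling rate must exceed 70 Hz for the 0.5-35 Hz bands")
    nperseg = int(round(seg_len_s * fs))
    if len(x) < nperseg:
        raise ValueError("epoch shorter than one Welch segment")
    noverlap = int(round(nperseg * overlap))
    freqs, psd = signal.welch(
        x, fs=fs, window=window, nperseg=nperseg, noverlap=noverlap, average=average
    )
    n_segments = (len(x) - noverlap) // (nperseg - noverlap)
    return PSDEstimate(freqs, psd, seg_len_s, overlap, average, window, n_segments)


# ---------------------------------------------------------------------------
# entropy / complexity / fractal estimators


def _embed(x: np.ndarray, order: int, delay: int = 1) -> np.ndarray:
    n = len(x) - (order - 1) * delay
    return np.lib.stride_tricks.sliding_window_view(x, (order - 1) * delay + 1)[
        :n, :: delay
    ]


@numba.njit(fastmath=False)
def _template_match_counts(x: np.ndarray, m: int, r: float):  # pragma: no cover
    """Chebyshev template-match counts for lengths m and m+1 in one sweep.

    Templates are sorted by their first element so each inner scan stops as
    soon as that coordinate alone exceeds r.  Returns per-template match
    counts for length m (all n-m+1 templates, self-matches excluded) and
    length m+1, plus the pair totals B (length m, restricted to the first
    n-m templates) and A (length m+1).
    """
    n = len(x)
    n_m = n - m + 1
    n_m1 = n - m
    order = np.argsort(x[:n_m])
    c_m = np.zeros(n_m, dtype=np.int64)
    c_m1 = np.zeros(n_m1, dtype=np.int64)
    b_total = 0
    a_total = 0
    for a in range(n_m):
        i = order[a]
        for bb in range(a + 1, n_m):
            j = order[bb]
            if x[j] - x[i] > r:
                break
            ok = True
            for k in range(1, m):
                d = x[i + k] - x[j + k]
                if d < 0.0:
                    d = -d
                if d > r:
                    ok = False
                    break
            if not ok:
                continue
            c_m[i] += 1
            c_m[j] += 1
            if i < n_m1 and j < n_m1:
                b_total += 1
                d = x[i + m] - x[j + m]
                if d < 0.0:
                    d = -d
                if d <= r:
                    a_total += 1
                    c_m1[i] += 1
                    c_m1[j] += 1
    return c_m, c_m1, b_total, a_total


def _entropy_counts(x: np.ndarray, m: int, r: float):
    x = np.ascontiguousarray(x, dtype=np.float64)
    if len(x) <= m + 1:
        raise ValueError("epoch too short for the template length")
    return _template_match_counts(x, m, r)


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """SampEn(m, r): -ln(A/B) with Chebyshev template matching over the
    first n-m templates, self-matches excluded (Richman & Moorman)."""
    x = np.asarray(x, dtype=float)
    if r is None:
        r = 0.2 * x.std()
    if r <= 0:
        return float("nan")
    _, _, B, A = _entropy_counts(x, m, r)
    if A == 0 or B == 0:
        return float("nan")
    return float(-np.log(A / B))


def approximate_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """ApEn(m, r) = phi(m) - phi(m+1), self-matches included."""
    x = np.asarray(x, dtype=float)
    if r is None:
        r = 0.2 * x.std()
    if r <= 0:
        return float("nan")
    c_m, c_m1, _, _ = _entropy_counts(x, m, r)
    phi_m = np.mean(np.log((c_m + 1.0) / len(c_m)))
    phi_m1 = np.mean(np.log((c_m1 + 1.0) / len(c_m1)))
    return float(phi_m - phi_m1)


def permutation_entropy(x: np.ndarray, order: int = 3, delay: int = 1) -> float:
    """Normalized permutation entropy (base 2) of ordinal patterns."""
    emb = _embed(np.asarray(x, dtype=float), order, delay)
    ranks = emb.argsort(axis=1).argsort(axis=1)
    codes = ranks @ (order ** np.arange(order))
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = -(p * np.log2(p)).sum()
    return float(h / np.log2(math.factorial(order)))


def svd_entropy(x: np.ndarray, order: int = 3, delay: int = 1) -> float:
    """Normalized singular-value-spectrum entropy (base 2)."""
    emb = _embed(np.asarray(x, dtype=float), order, delay)
    s = np.linalg.svd(emb, compute_uv=False)
    if s.sum() == 0:
        return float("nan")
    s = s / s.sum()
    s = s[s > 0]
    return float(-(s * np.log2(s)).sum() / np.log2(order))


@numba.njit(fastmath=False)
def _lz76_phrases(s: np.ndarray) -> int:  # pragma: no cover
    """LZ76 exhaustive phrase count of a symbol sequence.

    Each phrase is the shortest extension of the parsed prefix that cannot
    be reproduced by copying from an earlier start position (copies may
    overlap into the phrase itself).
    """
    n = len(s)
    i = 0
    c = 0
    while i < n:
        best = 0  # longest reproducible run starting at i
        for p in range(i):
            m = 0
            while i + m < n and s[p + m] == s[i + m]:
                m += 1
            if m > best:
                best = m
        l = best + 1
        if i + l > n:
            l = n - i
        c += 1
        i += l
    return c


def lempel_ziv_complexity(x: np.ndarray) -> float:
    """LZ76 phrase count of the median-binarized signal, normalized by
    n / log2(n)."""
    x = np.asarray(x, dtype=float)
    s = (x > np.median(x)).astype(np.uint8)
    n = len(s)
    if n < 2:
        return float("nan")
    return float(_lz76_phrases(s) * np.log2(n) / n)


def dfa_exponent(
    x: np.ndarray, min_scale: int = 16, n_scales: int = 10
) -> float:
    """Detrended fluctuation analysis scaling exponent.

    Log-spaced window sizes from ``min_scale`` to n/4 samples, linear
    detrending within windows, least-squares slope of log F(s) vs log s.
    White noise gives ~0.5.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    max_scale = n // 4
    if max_scale <= min_scale:
        return float("nan")
    scales = np.unique(
        np.round(np.geomspace(min_scale, max_scale, n_scales)).astype(int)
    )
    profile = np.cumsum(x - x.mean())
    flucts = []
    for s in scales:
        n_win = n // s
        segs = profile[: n_win * s].reshape(n_win, s)
        t = np.arange(s, dtype=float)
        A = np.column_stack([t, np.ones(s)])
        coef, *_ = np.linalg.lstsq(A, segs.T, rcond=None)
        resid = segs.T - A @ coef
        flucts.append(np.sqrt(np.mean(resid**2)))
    flucts = np.asarray(flucts)
    good = flucts > 0
    if good.sum() < 2:
        return float("nan")
    slope, _ = np.polyfit(np.log(scales[good]), np.log(flucts[good]), 1)
    return float(slope)


def hjorth_parameters(x: np.ndarray) -> tuple[float, float, float]:
    """(activity, mobility, complexity) time-domain morphology descriptors."""
    x = np.asarray(x, dtype=float)
    dx = np.diff(x)
    ddx = np.diff(dx)
    var_x = x.var()
    if var_x == 0:
        return 0.0, float("nan"), float("nan")
    var_dx = dx.var()
    mobility = np.sqrt(var_dx / var_x)
    if var_dx == 0:
        return float(var_x), float(mobility), float("nan")
    complexity = np.sqrt(ddx.var() / var_dx) / mobility
    return float(var_x), float(mobility), float(complexity)


def katz_fd(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    dists = np.abs(np.diff(x))
    L = dists.sum()
    d = np.abs(x - x[0]).max()
    if L == 0 or d == 0:
        return float("nan")
    n = len(x) - 1
    return float(np.log10(n) / (np.log10(n) + np.log10(d / L)))


def higuchi_fd(x: np.ndarray, k_max: int = 10) -> float:
    x = np.asarray(x, dtype=float)
    n = len(x)
    lk = []
    ks = np.arange(1, k_max + 1)
    for k in ks:
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if len(idx) < 2:
                continue
            diff = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / (len(idx) - 1) / k
            lengths.append(diff * norm / k)
        if lengths:
            lk.append(np.mean(lengths))
    lk = np.asarray(lk)
    good = lk > 0
    if good.sum() < 2:
        return float("nan")
    slope, _ = np.polyfit(np.log(1.0 / ks[: len(lk)][good]), np.log(lk[good]), 1)
    return float(slope)


def petrosian_fd(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    n = len(x)
    dx = np.diff(x)
    n_delta = int(np.sum(dx[:-1] * dx[1:] < 0))
    if n_delta == 0:
        return float("nan")
    return float(np.log10(n) / (np.log10(n) + np.log10(n / (n + 0.4 * n_delta))))


def zero_crossings(x: np.ndarray) -> int:
    x = np.asarray(x, dtype=float)
    s = np.sign(x)
    # treat exact zeros as continuation of the previous sign
    for i in range(1, len(s)):
        if s[i] == 0:
            s[i] = s[i - 1]
    s = s[s != 0]
    if len(s) < 2:
        return 0
    return int(np.sum(s[:-1] * s[1:] < 0))


# ---------------------------------------------------------------------------
# feature blocks


@dataclass
class FeatureParams:
    """Tunable estimator settings (conventional defaults, all exposed)."""

    entropy_m: int = 2
    entropy_r_factor: float = 0.2     # r = factor x std(epoch)
    pattern_order: int = 3
    pattern_delay: int = 1
    higuchi_kmax: int = 10
    dfa_min_scale: int = 16
    renyi_order: float = 2.0
    rolloff_fraction: float = 0.85
    band_lo: float = 0.5
    band_hi: float = 35.0
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    seg_len_s: float = 5.0
    overlap: float = 0.5
    psd_average: str = "median"


TIME_FEATURES = (
    "std",
    "iqr",
    "skewness",
    "kurtosis",
    "max_first_derivative",
    "zero_crossings",
    "approximate_entropy",
    "sample_entropy",
    "svd_entropy",
    "permutation_entropy",
    "lempel_ziv",
    "dfa_exponent",
    "hjorth_activity",
    "hjorth_mobility",
    "hjorth_complexity",
    "katz_fd",
    "higuchi_fd",
    "petrosian_fd",
)

BAND_RATIOS = (
    ("delta_theta_ratio", ("delta",), ("theta",)),
    ("delta_sigma_ratio", ("delta",), ("sigma",)),
    ("delta_beta_ratio", ("delta",), ("beta",)),
    ("theta_alpha_ratio", ("theta",), ("alpha",)),
    ("delta_alpha_ratio", ("delta",), ("alpha",)),
    ("alpha_beta_ratio", ("alpha",), ("beta",)),
    ("delta_alphabeta_ratio", ("delta",), ("alpha", "beta")),
    ("theta_alphabeta_ratio", ("theta",), ("alpha", "beta")),
    ("delta_alphabetatheta_ratio", ("delta",), ("alpha", "beta", "theta")),
)

FREQ_FEATURES = (
    ("spectral_energy",)
    + tuple(f"relpow_{b}" for b in DEFAULT_BANDS)
    + tuple(name for name, _, _ in BAND_RATIOS)
    + (
        "spectral_mean",
        "spectral_variance",
        "spectral_skewness",
        "spectral_kurtosis",
        "spectral_entropy",
        "renyi_entropy",
        "spectral_centroid",
        "spectral_crest",
        "spectral_flatness",
        "spectral_rolloff",
        "spectral_spread",
    )
)

FEATURE_NAMES = TIME_FEATURES + FREQ_FEATURES

#: features whose raw value scales with signal amplitude (computed on the
#: max-normalized epoch)
AMPLITUDE_DEPENDENT = frozenset(
    {"std", "iqr", "max_first_derivative", "hjorth_activity", "spectral_energy"}
)


def time_features(x: np.ndarray, params: FeatureParams | None = None) -> dict[str, float]:
    """Time-domain block; ``x`` is assumed max-normalized by the caller."""
    params = params or FeatureParams()
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        raise ValueError("empty epoch")
    out: dict[str, float] = {}
    constant = np.ptp(x) == 0
    out["std"] = float(x.std())
    out["iqr"] = float(stats.iqr(x))
    out["skewness"] = 0.0 if constant else float(stats.skew(x))
    out["kurtosis"] = 0.0 if constant else float(stats.kurtosis(x))
    out["max_first_derivative"] = float(np.abs(np.diff(x)).max()) if len(x) > 1 else 0.0
    out["zero_crossings"] = float(zero_crossings(x))
    if constant:
        for name in (
            "approximate_entropy", "sample_entropy", "svd_entropy",
            "permutation_entropy", "lempel_ziv", "dfa_exponent",
            "hjorth_mobility", "hjorth_complexity",
            "katz_fd", "higuchi_fd", "petrosian_fd",
        ):
            out[name] = float("nan")
        out["hjorth_activity"] = 0.0
        return out
    r = params.entropy_r_factor * x.std()
    c_m, c_m1, B, A = _entropy_counts(x, params.entropy_m, r)  # one shared sweep
    out["approximate_entropy"] = float(
        np.mean(np.log((c_m + 1.0) / len(c_m))) - np.mean(np.log((c_m1 + 1.0) / len(c_m1)))
    )
    out["sample_entropy"] = float(-np.log(A / B)) if A > 0 and B > 0 else float("nan")
    out["svd_entropy"] = svd_entropy(x, params.pattern_order, params.pattern_delay)
    out["permutation_entropy"] = permutation_entropy(
        x, params.pattern_order, params.pattern_delay
    )
    out["lempel_ziv"] = lempel_ziv_complexity(x)
    out["dfa_exponent"] = dfa_exponent(x, params.dfa_min_scale)
    act, mob, comp = hjorth_parameters(x)
    out["hjorth_activity"] = act
    out["hjorth_mobility"] = mob
    out["hjorth_complexity"] = comp
    out["katz_fd"] = katz_fd(x)
    out["higuchi_fd"] = higuchi_fd(x, params.higuchi_kmax)
    out["petrosian_fd"] = petrosian_fd(x)
    return out


def freq_features(psd: PSDEstimate, params: FeatureParams | None = None) -> dict[str, float]:
    """Frequency-domain block from a PSD covering 0.5-35 Hz."""
    params = params or FeatureParams()
    f, p = psd.freqs, psd.psd
    lo, hi = params.band_lo, params.band_hi
    if f.max() < hi:
        raise ValueError(f"PSD does not cover the {lo}-{hi} Hz analysis band")
    mask = (f >= lo) & (f <= hi)
    f, p = f[mask], p[mask]
    total = p.sum() * psd.df
    out: dict[str, float] = {}
    if total <= 0:
        return {name: float("nan") for name in FREQ_FEATURES}
    out["spectral_energy"] = float(total)

    band_pow = {}
    for name, (b_lo, b_hi) in params.bands.items():
        if np.isclose(b_hi, hi):  # the top band closes at the filter edge
            sel = (f >= b_lo) & (f <= b_hi)
        else:
            sel = (f >= b_lo) & (f < b_hi)
        band_pow[name] = p[sel].sum() * psd.df
        out[f"relpow_{name}"] = float(band_pow[name] / total)

    for name, nums, dens in BAND_RATIOS:
        den = sum(band_pow[b] for b in dens)
        num = sum(band_pow[b] for b in nums)
        out[name] = float(num / den) if den > 0 else float("nan")

    prob = p / p.sum()
    mean = float((f * prob).sum())
    var = float(((f - mean) ** 2 * prob).sum())
    out["spectral_mean"] = mean
    out["spectral_variance"] = var
    sd = np.sqrt(var)
    if sd > 0:
        out["spectral_skewness"] = float((((f - mean) / sd) ** 3 * prob).sum())
        out["spectral_kurtosis"] = float((((f - mean) / sd) ** 4 * prob).sum() - 3.0)
    else:
        out["spectral_skewness"] = float("nan")
        out["spectral_kurtosis"] = float("nan")
    nz = prob[prob > 0]
    out["spectral_entropy"] = float(-(nz * np.log2(nz)).sum() / np.log2(len(prob)))
    q = params.renyi_order
    out["renyi_entropy"] = float(np.log2((nz**q).sum()) / (1.0 - q))
    out["spectral_centroid"] = mean
    out["spectral_crest"] = float(p.max() / p.mean())
    out["spectral_flatness"] = float(stats.gmean(p) / p.mean()) if np.all(p > 0) else 0.0
    cum = np.cumsum(prob)
    out["spectral_rolloff"] = float(f[np.searchsorted(cum, params.rolloff_fraction)])
    out["spectral_spread"] = float(sd)
    return out


def extract_epoch_features(
    x: np.ndarray, fs: float, params: FeatureParams | None = None
) -> dict[str, float]:
    """Full feature vector of one epoch (max-normalized first)."""
    params = params or FeatureParams()
    x = np.asarray(x, dtype=float)
    peak = np.abs(x).max()
    xn = x / peak if peak > 0 else x.copy()
    out = time_features(xn, params)
    if peak > 0:
        psd = welch_psd(
            xn, fs, params.seg_len_s, params.overlap, params.psd_average
        )
        out.update(freq_features(psd, params))
    else:
        out.update({name: float("nan") for name in FREQ_FEATURES})
    return out


# ---------------------------------------------------------------------------
# dataset assembly


@dataclass
class FeatureDataset:
    """M epochs x N features for one (subject, channel, stage)."""

    subject: str
    channel: str
    stage: str
    data: pd.DataFrame  # index: epoch index; columns: FEATURE_NAMES

    @property
    def n_epochs(self) -> int:
        return len(self.data)


def build_feature_dataset(
    epoched: EpochedSignal,
    intersection: IntersectionLabels,
    channel: str,
    subject: str = "S01",
    params: FeatureParams | None = None,
) -> dict[str, FeatureDataset | None]:
    """One feature matrix per stage, rows restricted to retained, non-noisy
    epochs of that stage; stages with zero rows are marked absent (None)."""
    if channel in epoched.excluded_channels:
        raise ValueError(f"channel {channel!r} was excluded as noisy")
    if channel not in epoched.epochs:
        raise KeyError(f"unknown channel {channel!r}")
    params = params or FeatureParams()
    mat = epoched.epochs[channel]
    fs = epoched.fs[channel]
    n_ep = len(mat)
    if len(intersection.mask) != n_ep:
        raise ValueError("intersection mask length does not match epoch count")
    retained = np.flatnonzero(intersection.mask & ~epoched.noisy_mask[channel])
    stage_of = dict(zip(np.flatnonzero(intersection.mask), intersection.labels))

    rows: dict[str, list] = {s: [] for s in STAGES3}
    index: dict[str, list] = {s: [] for s in STAGES3}
    for t in retained:
        stage = stage_of[t]
        rows[stage].append(extract_epoch_features(mat[t], fs, params))
        index[stage].append(int(t))

    out: dict[str, FeatureDataset | None] = {}
    for stage in STAGES3:
        if not rows[stage]:
            out[stage] = None
            continue
        df = pd.DataFrame(rows[stage], index=index[stage], columns=list(FEATURE_NAMES))
        out[stage] = FeatureDataset(subject, channel, stage, df)
    return out
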