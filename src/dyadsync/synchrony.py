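"""Inter-partner physiological synchrony measures.

Nine pairwise measures — DTW, derivative DTW, complexity-invariant DTW,
nonlinear interdependence, band-averaged coherence, lagged
cross-correlation, cosine distance, Hausdorff distance and the symmetric
segment-path distance (SSPD) — computed on four per-dyad signal pairs:
EDA, skin temperature, instantaneous heart rate and instantaneous
respiration rate, giving 36 features per dyad-interval.

Both series are z-scored per interval and placed on a common analysis grid
(default 4 Hz) before any measure is applied, so distances are comparable
across dyads and modalities.  All distance-type measures are symmetric,
non-negative and zero for identical inputs.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.spatial.distance import directed_hausdorff, pdist, squareform

from .signal_prep import PreparedInterval
from .types import SYNC_MODALITIES, RateSeries, SignalInterval

MEASURES = ("dtw", "ddtw", "cidtw", "nli", "coh", "xcorr", "cosd", "hausd", "sspd")

DEFAULT_GRID_HZ = 4.0
COHERENCE_BAND_HZ = (0.01, 0.5)
COHERENCE_WINDOW_S = 60.0
XCORR_MAX_LAG_S = 10.0
#: nonlinear-interdependence defaults: embedding dim, delay (samples),
#: neighbours, Theiler exclusion window (samples)
NLI_DEFAULTS = dict(m=3, tau=2, k=4, theiler=8)
CID_CAP = 1e6


@dataclass(frozen=True)
class SignalPair:
    """Two equal-length z-scored series on a common time grid."""

    modality: str
    series_a: np.ndarray
    series_b: np.ndarray
    grid_rate: float
    degenerate: bool = False  # a zero-variance input (centered only)

    def __post_init__(self) -> None:
        a = np.asarray(self.series_a, dtype=float)
        b = np.asarray(self.series_b, dtype=float)
        if len(a) != len(b):
            raise ValueError("paired series must have equal length")
        if len(a) < 8:
            raise ValueError("paired series must have at least 8 samples")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("non-finite values in signal pair")
        object.__setattr__(self, "series_a", a)
        object.__setattr__(self, "series_b", b)


def _zscore(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    mu, sd = x.mean(), x.std()
    if sd == 0:
        return x - mu, True
    return (x - mu) / sd, False


def _decimate(x: np.ndarray, fs: float, grid_rate: float) -> np.ndarray:
    if fs == grid_rate:
        return np.asarray(x, dtype=float)
    factor = fs / grid_rate
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(f"sampling rate {fs} not an integer multiple of grid "
                         f"{grid_rate}")
    factor = round(factor)
    n = (len(x) // factor) * factor
    return np.asarray(x[:n], dtype=float).reshape(-1, factor).mean(axis=1)


def prepare_pair(a: SignalInterval | RateSeries, b: SignalInterval | RateSeries,
                 modality: str, grid_rate: float = DEFAULT_GRID_HZ) -> SignalPair:
    """Build a z-scored, grid-aligned pair from both participants' data."""
    series, degenerate = [], False
    for obj in (a, b):
        fs = obj.sampling_rate
        x = obj.samples if isinstance(obj, SignalInterval) else obj.values
        x = _decimate(x, fs, grid_rate)
        z, degen = _zscore(x)
        degenerate |= degen
        series.append(z)
    n = min(len(series[0]), len(series[1]))
    return SignalPair(modality=modality, series_a=series[0][:n],
                      series_b=series[1][:n], grid_rate=grid_rate,
                      degenerate=degenerate)


# ---------------------------------------------------------------------------
# DTW family

try:  # compiled DP kernel; plain-Python fallback keeps semantics identical
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    def _njit(func):
        return func


@_njit
def _dtw_core(a, b):  # pragma: no cover - exercised via dtw_distance
    n, m = len(a), len(b)
    D = np.empty((n, m))
    L = np.empty((n, m), dtype=np.int64)
    D[0, 0] = abs(a[0] - b[0])
    L[0, 0] = 1
    for j in range(1, m):
        D[0, j] = D[0, j - 1] + abs(a[0] - b[j])
        L[0, j] = j + 1
    for i in range(1, n):
        D[i, 0] = D[i - 1, 0] + abs(a[i] - b[0])
        L[i, 0] = i + 1
        for j in range(1, m):
            c_diag = D[i - 1, j - 1]
            c_vert = D[i - 1, j]
            c_horz = D[i, j - 1]
            best = c_diag
            ln = L[i - 1, j - 1]
            if c_vert < best or (c_vert == best and L[i - 1, j] < ln):
                best = c_vert
                ln = L[i - 1, j]
            if c_horz < best or (c_horz == best and L[i, j - 1] < ln):
                best = c_horz
                ln = L[i, j - 1]
            D[i, j] = abs(a[i] - b[j]) + best
            L[i, j] = ln + 1
    return D[n - 1, m - 1], L[n - 1, m - 1]


def _dtw_normalized(a: np.ndarray, b: np.ndarray) -> float:
    """Classic unconstrained DTW, absolute-difference local cost, symmetric
    step pattern, normalized by the optimal warping path's length (fewest
    steps among minimum-cost paths)."""
    total, length = _dtw_core(np.ascontiguousarray(a, dtype=np.float64),
                              np.ascontiguousarray(b, dtype=np.float64))
    return float(total) / float(length)


def dtw_distance(pair: SignalPair) -> float:
    return _dtw_normalized(pair.series_a, pair.series_b)


def derivative_transform(x: np.ndarray) -> np.ndarray:
    """Local-slope transform d[i] = ((x[i]-x[i-1]) + (x[i+1]-x[i-1])/2)/2 for
    interior points, endpoints replicated."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("derivative transform needs length >= 3")
    d = ((x[1:-1] - x[:-2]) + (x[2:] - x[:-2]) / 2.0) / 2.0
    return np.concatenate([[d[0]], d, [d[-1]]])


def derivative_dtw(pair: SignalPair) -> float:
    if len(pair.series_a) < 3:
        return float("nan")
    return _dtw_normalized(derivative_transform(pair.series_a),
                           derivative_transform(pair.series_b))


def complexity_estimate(x: np.ndarray) -> float:
    """CE(x) = sqrt(sum of squared successive differences)."""
    return float(np.sqrt(np.sum(np.diff(np.asarray(x, dtype=float)) ** 2)))


def complexity_factor(a: np.ndarray, b: np.ndarray) -> float:
    ce_a, ce_b = complexity_estimate(a), complexity_estimate(b)
    if ce_a == 0 and ce_b == 0:
        return 1.0
    lo, hi = min(ce_a, ce_b), max(ce_a, ce_b)
    if lo == 0:
        return CID_CAP  # documented cap for the flat-vs-varying edge case
    return hi / lo


def cid_dtw(pair: SignalPair, dtw_value: float | None = None) -> float:
    """Complexity-invariant DTW = DTW x max(CE)/min(CE)."""
    if dtw_value is None:
        dtw_value = dtw_distance(pair)
    return dtw_value * complexity_factor(pair.series_a, pair.series_b)


# ---------------------------------------------------------------------------
# state-space and spectral measures

def _delay_embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    n = len(x) - (m - 1) * tau
    if n < 1:
        raise ValueError("series too short for embedding")
    return np.stack([x[i * tau:i * tau + n] for i in range(m)], axis=1)


def _neighbor_indices(d2: np.ndarray, k: int, theiler: int) -> np.ndarray:
    """Indices (N, k) of each point's k nearest neighbours outside the
    Theiler window, by squared Euclidean distance."""
    n = len(d2)
    idx = np.arange(n)
    masked = d2.copy()
    masked[np.abs(idx[:, None] - idx[None, :]) <= theiler] = np.inf
    return np.argpartition(masked, k - 1, axis=1)[:, :k]


def nonlinear_interdependence(pair: SignalPair, m: int = NLI_DEFAULTS["m"],
                              tau: int = NLI_DEFAULTS["tau"],
                              k: int = NLI_DEFAULTS["k"],
                              theiler: int = NLI_DEFAULTS["theiler"]) -> float:
    """Symmetrized state-space measure S = (S(A|B) + S(B|A)) / 2.

    S(A|B) = mean_i R_i(A) / R_i(A|B), with R_i(A) the mean squared distance
    from embedded point i to its k true nearest neighbours and R_i(A|B) the
    mean squared distance to A's points at the time indices of B's
    neighbours.  1 for identical series, smaller for independent ones.
    """
    n_embed = min(len(pair.series_a), len(pair.series_b)) - (m - 1) * tau
    if n_embed < k + 2 * theiler + 2:
        return float("nan")
    emb_a = _delay_embed(pair.series_a, m, tau)
    emb_b = _delay_embed(pair.series_b, m, tau)
    d2a = squareform(pdist(emb_a, "sqeuclidean"))
    d2b = squareform(pdist(emb_b, "sqeuclidean"))
    nbr_a = _neighbor_indices(d2a, k, theiler)
    nbr_b = _neighbor_indices(d2b, k, theiler)
    rows = np.arange(len(emb_a))[:, None]

    def s_cond(d2x: np.ndarray, nbr_x: np.ndarray, nbr_y: np.ndarray) -> float:
        r_true = d2x[rows, nbr_x].mean(axis=1)
        r_cond = d2x[rows, nbr_y].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(r_cond > 0, r_true / r_cond,
                             np.where(r_true == 0, 1.0, np.inf))
        return float(np.mean(ratio))

    return 0.5 * (s_cond(d2a, nbr_a, nbr_b) + s_cond(d2b, nbr_b, nbr_a))


def coherence(pair: SignalPair, band_hz: tuple[float, float] = COHERENCE_BAND_HZ,
              window_s: float = COHERENCE_WINDOW_S) -> float:
    """Magnitude-squared coherence, Welch-averaged (50% overlap), then
    averaged over ``band_hz``.  Requires >= 2 windows of data."""
    nperseg = round(window_s * pair.grid_rate)
    if len(pair.series_a) < 2 * nperseg:
        return float("nan")
    f, cxy = sps.coherence(pair.series_a, pair.series_b, fs=pair.grid_rate,
                           nperseg=nperseg, noverlap=nperseg // 2)
    mask = (f >= band_hz[0]) & (f <= band_hz[1])
    if not mask.any():
        return float("nan")
    return float(np.clip(np.mean(cxy[mask]), 0.0, 1.0))


def cross_correlation(pair: SignalPair, max_lag_s: float = XCORR_MAX_LAG_S,
                      return_lag: bool = False):
    """Maximum over lags in +-max_lag_s of |Pearson r|; magnitude convention."""
    a, b = pair.series_a, pair.series_b
    n = len(a)
    max_lag = min(round(max_lag_s * pair.grid_rate), n - 2)
    best, best_lag = -1.0, 0
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            x, y = a[lag:], b[:n - lag]
        else:
            x, y = a[:n + lag], b[-lag:]
        if len(x) < 2 or x.std() == 0 or y.std() == 0:
            continue
        r = abs(float(np.corrcoef(x, y)[0, 1]))
        if r > best:
            best, best_lag = r, lag
    if best < 0:
        result = float("nan")
    else:
        result = best
    if return_lag:
        return result, best_lag / pair.grid_rate
    return result


def cosine_distance(pair: SignalPair) -> float:
    """1 - cos(angle) between the two series as vectors; in [0, 2]."""
    a, b = pair.series_a, pair.series_b
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return float("nan")
    return float(np.clip(1.0 - float(a @ b) / (na * nb), 0.0, 2.0))


# ---------------------------------------------------------------------------
# planar trajectory distances

def _planar_points(pair: SignalPair) -> tuple[np.ndarray, np.ndarray]:
    """Embed both series as 2-D point sets (t * lambda, value) with the time
    axis rescaled so the interval span matches the joint value range."""
    n = len(pair.series_a)
    t = np.arange(n) / pair.grid_rate
    both = np.concatenate([pair.series_a, pair.series_b])
    vrange = float(both.max() - both.min())
    lam = vrange / t[-1] if (t[-1] > 0 and vrange > 0) else 1.0
    pa = np.column_stack([t * lam, pair.series_a])
    pb = np.column_stack([t * lam, pair.series_b])
    return pa, pb


def hausdorff_distance(pair: SignalPair) -> float:
    """Symmetric Hausdorff distance between the two planar point sets."""
    pa, pb = _planar_points(pair)
    return float(max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0]))


def _point_segment_distances(points: np.ndarray, path: np.ndarray) -> np.ndarray:
    """Min Euclidean distance from each point to any segment of ``path``."""
    p0, p1 = path[:-1], path[1:]  # (m-1, 2)
    seg = p1 - p0
    seg_len2 = (seg**2).sum(-1)
    seg_len2 = np.where(seg_len2 == 0, 1.0, seg_len2)
    diff = points[:, None, :] - p0[None, :, :]  # (n, m-1, 2)
    t = np.clip((diff * seg[None, :, :]).sum(-1) / seg_len2, 0.0, 1.0)
    proj = p0[None, :, :] + t[..., None] * seg[None, :, :]
    d = np.sqrt(((points[:, None, :] - proj) ** 2).sum(-1))
    return d.min(axis=1)


def sspd_distance(pair: SignalPair) -> float:
    """Symmetric segment-path distance between the two planar trajectories:
    mean over points of A of min point-to-segment distance to B, symmetrized."""
    pa, pb = _planar_points(pair)
    spd_ab = float(_point_segment_distances(pa, pb).mean())
    spd_ba = float(_point_segment_distances(pb, pa).mean())
    return 0.5 * (spd_ab + spd_ba)


# ---------------------------------------------------------------------------

def synchrony_measures(pair: SignalPair) -> dict[str, float]:
    """All nine measures for one prepared pair."""
    dtw = _dtw_normalized(pair.series_a, pair.series_b)
    xcorr = float("nan") if pair.degenerate else cross_correlation(pair)
    return {
        "dtw": dtw,
        "ddtw": (_dtw_normalized(derivative_transform(pair.series_a),
                                 derivative_transform(pair.series_b))
                 if len(pair.series_a) >= 3 else float("nan")),
        "cidtw": cid_dtw(pair, dtw_value=dtw),
        "nli": nonlinear_interdependence(pair),
        "coh": coherence(pair),
        "xcorr": xcorr,
        "cosd": cosine_distance(pair),
        "hausd": hausdorff_distance(pair),
        "sspd": sspd_distance(pair),
    }


def synchrony_features_for_interval(prep1: PreparedInterval, prep2: PreparedInterval,
                                    grid_rate: float = DEFAULT_GRID_HZ,
                                    ) -> dict[str, float]:
    """The 36 named synchrony features (9 measures x 4 modalities) for one
    dyad-interval; a missing modality yields NaN for its 9 features."""
    sources = {
        "eda": (prep1.eda, prep2.eda),
        "temp": (prep1.temp, prep2.temp),
        "hr": (prep1.heart_rate, prep2.heart_rate),
        "rr": (prep1.resp_rate, prep2.resp_rate),
    }
    out: dict[str, float] = {}
    for modality in SYNC_MODALITIES:
        a, b = sources[modality]
        if a is None or b is None:
            out.update({f"{modality}_{m}": float("nan") for m in MEASURES})
            continue
        pair = prepare_pair(a, b, modality, grid_rate)
        values = synchrony_measures(pair)
        out.update({f"{modality}_{m}": values[m] for m in MEASURES})
    return out


SYNCHRONY_FEATURE_NAMES = tuple(f"{mod}_{m}" for mod in SYNC_MODALITIES
                                for m in MEASURES)
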