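"""The 20 per-participant features computed for each 2-min interval.

ECG/HRV (9): mean_hr, min_hr, max_hr (statistics of 60000/IBI), sdnn,
rmssd, pnn50, lf_power (0.04-0.15 Hz), hf_power (0.15-0.40 Hz) and their
ratio.  Band powers come from a Lomb-Scargle spectrum of the unevenly
sampled IBI tachogram (no resampling bias on 2-min windows).

Respiration (2): mean and standard deviation of the instantaneous
respiration-rate series.

EDA (6): mean, final, final-initial, SCR count, mean and SD of SCR
amplitudes (mean missing with 0 SCRs, SD missing with < 2).

Temperature (3): mean, final, final-initial.

Sample (n-1) standard deviations are used throughout.  Missing values are
represented as NaN and imputed downstream from training data only.
"""
from __future__ import annotations

import numpy as np
from scipy.signal import lombscargle

from .errors import DataError
from .signal_prep import PreparedInterval
from .types import PeakTrain, RateSeries, SignalInterval

LF_BAND_HZ = (0.04, 0.15)
HF_BAND_HZ = (0.15, 0.40)

FEATURE_NAMES = (
    "mean_hr", "min_hr", "max_hr", "sdnn", "rmssd", "pnn50",
    "lf_power", "hf_power", "lf_hf_ratio",
    "mean_rr", "sd_rr",
    "mean_eda", "final_eda", "delta_eda", "n_scr", "mean_scr_amp", "sd_scr_amp",
    "mean_temp", "final_temp", "delta_temp",
)


def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if len(x) >= 2 else float("nan")


def band_power(ibis_ms: np.ndarray, band_hz: tuple[float, float],
               df_hz: float = 1e-3) -> float:
    """Lomb-Scargle power of the IBI tachogram integrated over a band (ms^2).

    Beat times are the cumulative sums of the IBIs; the tachogram is the
    centered IBI sequence at those times.
    """
    t = np.cumsum(ibis_ms) / 1000.0  # seconds
    x = ibis_ms - np.mean(ibis_ms)
    freqs = np.arange(band_hz[0] + df_hz / 2, band_hz[1], df_hz)
    if len(x) < 3 or np.allclose(x, 0):
        return 0.0
    pgram = lombscargle(t, x, 2 * np.pi * freqs)
    # scipy's normalization: P(w) ~ (N/4) * A^2 for a sinusoid of amplitude A.
    # 2P/N recovers that sinusoid's variance; summed over the band grid this
    # gives a relative band power (consistent across features, so the LF/HF
    # ratio is well defined even though absolute ms^2 calibration is nominal).
    return float(np.sum(pgram) * 2.0 / len(x))


def hrv_features(ibis_ms: np.ndarray) -> dict[str, float]:
    """The nine ECG features from a sequence of inter-beat intervals (ms)."""
    ibis_ms = np.asarray(ibis_ms, dtype=float)
    if len(ibis_ms) < 2:
        raise DataError("need at least 2 inter-beat intervals")
    if np.any(ibis_ms <= 0):
        raise DataError("non-positive inter-beat interval")
    hr = 60000.0 / ibis_ms
    diffs = np.diff(ibis_ms)
    lf = band_power(ibis_ms, LF_BAND_HZ)
    hf = band_power(ibis_ms, HF_BAND_HZ)
    return {
        "mean_hr": float(np.mean(hr)),
        "min_hr": float(np.min(hr)),
        "max_hr": float(np.max(hr)),
        "sdnn": _sd(ibis_ms),
        "rmssd": float(np.sqrt(np.mean(diffs**2))) if len(diffs) else float("nan"),
        "pnn50": float(100.0 * np.mean(np.abs(diffs) > 50.0)) if len(diffs)
                 else float("nan"),
        "lf_power": lf,
        "hf_power": hf,
        "lf_hf_ratio": lf / hf if hf > 0 else float("nan"),
    }


def respiration_features(rate: RateSeries | None) -> dict[str, float]:
    """Mean and SD of the instantaneous respiration-rate series."""
    if rate is None or len(rate.values) < 2:
        return {"mean_rr": float("nan"), "sd_rr": float("nan")}
    return {"mean_rr": float(np.mean(rate.values)), "sd_rr": _sd(rate.values)}


def eda_features(interval: SignalInterval, scrs: PeakTrain) -> dict[str, float]:
    if interval.channel != "eda":
        raise DataError("eda_features requires an eda interval")
    x = interval.samples
    amps = scrs.amplitudes if scrs.amplitudes is not None else np.array([])
    return {
        "mean_eda": float(np.mean(x)),
        "final_eda": float(x[-1]),
        "delta_eda": float(x[-1] - x[0]),
        "n_scr": float(len(scrs)),
        "mean_scr_amp": float(np.mean(amps)) if len(amps) >= 1 else float("nan"),
        "sd_scr_amp": _sd(amps),
    }


def temperature_features(interval: SignalInterval) -> dict[str, float]:
    if interval.channel != "temp":
        raise DataError("temperature_features requires a temp interval")
    x = interval.samples
    return {"mean_temp": float(np.mean(x)), "final_temp": float(x[-1]),
            "delta_temp": float(x[-1] - x[0])}


def individual_features(prepared: PreparedInterval) -> dict[str, float]:
    """All 20 features for one participant-interval; NaN where quality failed."""
    out: dict[str, float] = {}
    if prepared.r_peaks is not None and len(prepared.r_peaks) >= 3:
        out.update(hrv_features(np.diff(prepared.r_peaks.times) * 1000.0))
    else:
        out.update({k: float("nan") for k in FEATURE_NAMES[:9]})
    out.update(respiration_features(prepared.resp_rate))
    out.update(eda_features(prepared.eda, prepared.scrs))
    out.update(temperature_features(prepared.temp))
    assert tuple(out) == FEATURE_NAMES
    return out
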