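"""Segmentation, peak / SCR detection and instantaneous rate signals.

Detection contracts:

* R-peaks: prominence-based detection with a 0.25 s refractory period
  (~240 bpm ceiling); intervals with implausible inter-beat intervals
  (< 0.3 s or > 2 s) are flagged rather than manually inspected.
* Respiration peaks: 1.0 s refractory period.
* Skin-conductance responses: a local maximum is a valid SCR when it rises
  at least ``min_amplitude`` (default 0.05 microsiemens) above the most
  recent preceding local minimum (the valley) and peaks within
  ``max_rise_s`` (default 5 s) of that valley.

Instantaneous rate signals are piecewise-constant 60/IBI resampled on a
fixed output grid (default 4 Hz) with edge extension outside the first and
last event.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import DataError, QualityError
from .types import CHANNELS, PeakTrain, RateSeries, SignalInterval

#: documented smoothing defaults; the exact coefficients are not load-bearing
FILTER_DEFAULTS = {
    "ecg": ("highpass", 0.5),
    "eda": ("lowpass", 1.0),
    "resp": ("bandpass", (0.05, 1.0)),
    "temp": ("lowpass", 0.1),
}

R_PEAK_REFRACTORY_S = 0.25
RESP_REFRACTORY_S = 1.0
SCR_MIN_AMPLITUDE_US = 0.05
SCR_MAX_RISE_S = 5.0
IBI_PLAUSIBLE_S = (0.3, 2.0)
DEFAULT_RATE_GRID_HZ = 4.0


def filter_channel(samples: np.ndarray, fs: float, channel: str) -> np.ndarray:
    """Apply the documented default band-limiting filter for ``channel``."""
    kind, edge = FILTER_DEFAULTS[channel]
    nyq = fs / 2.0
    if kind == "bandpass":
        lo, hi = edge
        sos = sps.butter(2, [lo / nyq, min(hi, 0.95 * nyq) / nyq], "bandpass",
                         output="sos")
    else:
        sos = sps.butter(2, min(edge, 0.95 * nyq) / nyq, kind, output="sos")
    return sps.sosfiltfilt(sos, samples)


def segment_recording(raw: dict[tuple[int, str], np.ndarray], fs: float,
                      boundaries: list[tuple[float, float]], dyad_id: int = -1,
                      ) -> list[SignalInterval]:
    """Cut continuous per-(participant, channel) recordings into intervals.

    ``boundaries`` are (start_s, end_s) pairs, one per interval, ordered and
    non-overlapping; samples outside them (questionnaire breaks, trailing
    data) are discarded.
    """
    for (s0, e0), (s1, _) in zip(boundaries, boundaries[1:]):
        if e0 > s1 or s0 >= e0:
            raise DataError("interval boundaries must be ordered and non-overlapping")
    if boundaries[0][0] < 0:
        raise DataError("boundaries must lie within the recording span")
    expected = {(p, ch) for p in (1, 2) for ch in CHANNELS}
    missing = expected - set(raw)
    if missing:
        raise DataError(f"dyad {dyad_id}: missing channels {sorted(missing)}")
    out = []
    for (p, ch), samples in sorted(raw.items()):
        samples = np.asarray(samples, dtype=float)
        for ii, (start, end) in enumerate(boundaries):
            i0, i1 = round(start * fs), round(end * fs)
            if i1 > len(samples):
                raise DataError(
                    f"dyad {dyad_id} participant {p} channel {ch}: interval {ii} "
                    f"truncated (needs {i1} samples, recording has {len(samples)})")
            out.append(SignalInterval(dyad_id=dyad_id, participant=p,
                                      interval_index=ii, channel=ch,
                                      sampling_rate=fs, samples=samples[i0:i1]))
    return out


def read_interval_file(path, dyad_id: int, participant: int, interval_index: int,
                       channel: str) -> SignalInterval:
    """Read a one-interval delimited text file with columns time_s,value.

    The sampling rate is inferred from the (uniform) time column.
    """
    import pandas as pd

    df = pd.read_csv(path).sort_values("time_s")
    if not {"time_s", "value"} <= set(df.columns):
        raise DataError(f"{path}: expected columns time_s,value")
    dt = np.diff(df["time_s"].to_numpy())
    if len(dt) < 1 or np.ptp(dt) > 1e-6:
        raise DataError(f"{path}: time grid must be uniform")
    return SignalInterval(dyad_id=dyad_id, participant=participant,
                          interval_index=interval_index, channel=channel,
                          sampling_rate=1.0 / float(dt[0]),
                          samples=df["value"].to_numpy())


def _find_prominent_peaks(x: np.ndarray, fs: float, refractory_s: float,
                          rel_prominence: float) -> np.ndarray:
    span = float(np.max(x) - np.min(x))
    if span <= 0:
        return np.array([], dtype=int)
    idx, _ = sps.find_peaks(x, distance=max(1, round(refractory_s * fs)),
                            prominence=rel_prominence * span)
    return idx


def detect_r_peaks(interval: SignalInterval) -> PeakTrain:
    """Detect ECG R-peaks; raises :class:`QualityError` for unusable intervals."""
    if interval.channel != "ecg":
        raise DataError("detect_r_peaks requires an ecg interval")
    if interval.duration < 10.0:
        raise DataError("need at least 10 s of ECG")
    idx = _find_prominent_peaks(interval.samples, interval.sampling_rate,
                                R_PEAK_REFRACTORY_S, 0.5)
    if len(idx) < 2:
        raise QualityError(
            f"dyad {interval.dyad_id} participant {interval.participant} interval "
            f"{interval.interval_index}: fewer than 2 R-peaks")
    return PeakTrain(channel="ecg", times=idx / interval.sampling_rate)


def ibi_quality_flag(peaks: PeakTrain) -> bool:
    """True when all inter-beat intervals are physiologically plausible."""
    ibis = np.diff(peaks.times)
    lo, hi = IBI_PLAUSIBLE_S
    return bool(len(ibis) > 0 and np.all((ibis >= lo) & (ibis <= hi)))


def detect_respiration_peaks(interval: SignalInterval) -> PeakTrain:
    """Detect breath peaks with a 1 s refractory period."""
    if interval.channel != "resp":
        raise DataError("detect_respiration_peaks requires a resp interval")
    idx = _find_prominent_peaks(interval.samples, interval.sampling_rate,
                                RESP_REFRACTORY_S, 0.3)
    if len(idx) < 2:
        raise QualityError(
            f"dyad {interval.dyad_id} participant {interval.participant} interval "
            f"{interval.interval_index}: fewer than 2 breath peaks")
    return PeakTrain(channel="resp", times=idx / interval.sampling_rate)


def detect_scrs(interval: SignalInterval,
                min_amplitude: float = SCR_MIN_AMPLITUDE_US,
                max_rise_s: float = SCR_MAX_RISE_S) -> PeakTrain:
    """Detect skin-conductance responses by the trough-to-peak criterion.

    Zero detected SCRs is a valid outcome.
    """
    if interval.channel != "eda":
        raise DataError("detect_scrs requires an eda interval")
    x = interval.samples
    fs = interval.sampling_rate
    maxima, _ = sps.find_peaks(x)
    minima, _ = sps.find_peaks(-x)
    times, amps, valleys = [], [], []
    for p in maxima:
        prior = minima[minima < p]
        if len(prior) == 0:
            continue
        v = prior[-1]  # most recent local minimum = "previous valley"
        amplitude = x[p] - x[v]
        if amplitude >= min_amplitude and (p - v) / fs <= max_rise_s:
            times.append(p / fs)
            amps.append(amplitude)
            valleys.append(v / fs)
    return PeakTrain(channel="eda", times=np.asarray(times),
                     amplitudes=np.asarray(amps), valley_times=np.asarray(valleys))


def instantaneous_rate(peaks: PeakTrain, out_rate: float = DEFAULT_RATE_GRID_HZ,
                       duration: float | None = None) -> RateSeries:
    """Piecewise-constant 60/IBI signal on an even grid, in events/minute.

    The value at time t is 60 over the inter-event interval containing t;
    before the first event and after the last the nearest interval's value
    is extended.
    """
    if len(peaks) < 2:
        raise QualityError("instantaneous rate needs at least 2 events")
    t = peaks.times
    rates = 60.0 / np.diff(t)
    if duration is None:
        duration = float(t[-1])
    grid = np.arange(round(duration * out_rate)) / out_rate
    # interval k = [t[k], t[k+1]) carries rates[k]; clip for edge extension
    k = np.clip(np.searchsorted(t, grid, side="right") - 1, 0, len(rates) - 1)
    kind = "heart" if peaks.channel == "ecg" else "respiration"
    return RateSeries(kind=kind, sampling_rate=out_rate, values=rates[k])


@dataclass(frozen=True)
class PreparedInterval:
    """All derived per-participant signals for one interval."""

    r_peaks: PeakTrain | None
    resp_peaks: PeakTrain | None
    scrs: PeakTrain
    heart_rate: RateSeries | None
    resp_rate: RateSeries | None
    eda: SignalInterval
    temp: SignalInterval
    ibi_ok: bool


def prepare_interval(ecg: SignalInterval, eda: SignalInterval,
                     resp: SignalInterval, temp: SignalInterval,
                     rate_grid_hz: float = DEFAULT_RATE_GRID_HZ,
                     apply_filters: bool = True) -> PreparedInterval:
    """Run all detections for one participant-interval; quality failures on
    ECG/respiration yield None fields that propagate as missing features."""
    if apply_filters:
        fs = ecg.sampling_rate
        ecg = SignalInterval(ecg.dyad_id, ecg.participant, ecg.interval_index, "ecg",
                             fs, filter_channel(ecg.samples, fs, "ecg"))
        eda = SignalInterval(eda.dyad_id, eda.participant, eda.interval_index, "eda",
                             eda.sampling_rate,
                             filter_channel(eda.samples, eda.sampling_rate, "eda"))
        resp = SignalInterval(resp.dyad_id, resp.participant, resp.interval_index,
                              "resp", resp.sampling_rate,
                              filter_channel(resp.samples, resp.sampling_rate, "resp"))
        temp = SignalInterval(temp.dyad_id, temp.participant, temp.interval_index,
                              "temp", temp.sampling_rate,
                              filter_channel(temp.samples, temp.sampling_rate, "temp"))
    duration = ecg.duration
    try:
        r_peaks = detect_r_peaks(ecg)
        heart_rate = instantaneous_rate(r_peaks, rate_grid_hz, duration)
        ibi_ok = ibi_quality_flag(r_peaks)
    except QualityError:
        r_peaks, heart_rate, ibi_ok = None, None, False
    try:
        resp_peaks = detect_respiration_peaks(resp)
        resp_rate = instantaneous_rate(resp_peaks, rate_grid_hz, duration)
    except QualityError:
        resp_peaks, resp_rate = None, None
    scrs = detect_scrs(eda)
    return PreparedInterval(r_peaks=r_peaks, resp_peaks=resp_peaks, scrs=scrs,
                            heart_rate=heart_rate, resp_rate=resp_rate,
                            eda=eda, temp=temp, ibi_ok=ibi_ok)
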