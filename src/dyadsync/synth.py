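"""Synthetic dyadic recordings with controllable inter-partner coupling.

The generator emulates the statistical structure the downstream analysis
assumes, not physiological realism: per dyad, two baseline intervals and
``n_conversation_intervals`` conversation intervals, two participants, four
channels (ECG-like pulse train, EDA with skin-conductance responses,
respiration oscillation, slow skin temperature), and 1-9 self/observer
ratings of valence and arousal that depend on a latent affective state.

Partners share a common latent driver weighted by ``coupling`` both at the
per-interval level (which feeds the ratings) and within intervals (a slow
common process modulating heart rate, respiration rate, EDA and
temperature), so synchrony measures and feature->label regression have
recoverable signal.  Baseline intervals have latent state exactly zero
(quiet rest), which makes baseline-normalized features affine in the
conversation latents.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .errors import ConfigurationError
from .types import CHANNELS, DyadRecord, SignalInterval

GENDERS = ("female", "male", "nonbinary")

#: trait instruments: (mean, sd, low, high) of the self-report scales
TRAIT_DISTRIBUTIONS = {
    "cognitive_empathy": (55.7, 8.9, 19, 95),
    "affective_empathy": (34.0, 5.4, 12, 60),
    "social_anxiety": (39.8, 10.1, 12, 60),
    "depression": (17.2, 11.4, 0, 60),
}


def _default_label_weights() -> dict[str, dict[str, float]]:
    # rating stream -> contribution of each latent component
    return {"valence": {"valence": 1.0, "arousal": 0.0},
            "arousal": {"valence": 0.0, "arousal": 1.0}}


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration; defaults are the study conditions."""

    n_dyads: int = 41
    sampling_rate: float = 100.0  # Hz; the study recorded at 600
    interval_duration: float = 120.0  # seconds
    n_conversation_intervals: int = 10
    coupling: float = 0.5  # shared-driver weight in [0, 1]
    divergence_scale: float = 0.4  # AR(1) per-participant rating divergence
    label_noise_sd: float = 0.5  # latent->rating noise before rounding
    label_scale: float = 1.5  # rating points per unit latent
    label_feature_weights: dict[str, dict[str, float]] = field(
        default_factory=_default_label_weights)
    hr_base: float = 72.0  # bpm; per-participant offset added
    hr_gain: float = 8.0  # bpm per unit latent arousal
    scr_rate_base: float = 3.0  # events per interval at zero arousal
    scr_rate_gain: float = 2.0  # extra events per unit latent arousal
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dyads < 1:
            raise ConfigurationError("n_dyads must be >= 1")
        if self.sampling_rate <= 0 or self.interval_duration <= 0:
            raise ConfigurationError("sampling rate and duration must be positive")
        if not 0.0 <= self.coupling <= 1.0:
            raise ConfigurationError("coupling must lie in [0, 1]")
        if self.label_noise_sd < 0 or self.divergence_scale < 0:
            raise ConfigurationError("noise scales must be >= 0")
        n = self.sampling_rate * self.interval_duration
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                "interval_duration x sampling_rate must be an integer sample count")

    @property
    def samples_per_interval(self) -> int:
        return round(self.sampling_rate * self.interval_duration)

    @property
    def n_intervals(self) -> int:
        return self.n_conversation_intervals + 2


def _dyad_rng(config: SynthConfig, dyad_index: int) -> np.random.Generator:
    # distinct, reproducible substream per dyad
    return np.random.Generator(np.random.PCG64(
        np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, int(dyad_index)])))


def _smooth_noise(rng: np.random.Generator, n: int, fs: float,
                  timescale_s: float) -> np.ndarray:
    """Zero-mean unit-SD Gaussian noise band-limited to ~1/timescale Hz.

    Generated on a coarse grid (4 points per timescale) and linearly
    interpolated to the sampling grid, so cost is independent of fs.
    """
    step = timescale_s / 4.0
    n_coarse = int(np.ceil(n / fs / step)) + 8
    coarse = gaussian_filter1d(rng.standard_normal(n_coarse), sigma=4.0,
                               mode="reflect")
    t = np.arange(n) / fs
    x = np.interp(t, (np.arange(n_coarse) - 4) * step, coarse)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def _map_to_scale(raw: np.ndarray) -> np.ndarray:
    return np.clip(_round_half_up(raw), 1, 9).astype(int)


def _interval_latents(config: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-interval latent valence/arousal for both partners.

    latent_p = coupling * shared + (1 - coupling) * own + divergence_p with
    AR(1) shared and divergence streams; baselines are exactly zero (rest).
    """
    n = config.n_conversation_intervals
    rows = []
    for comp in ("valence", "arousal"):
        shared = np.empty(n)
        phi = 0.6
        innov_sd = np.sqrt(1 - phi**2)
        shared[0] = rng.standard_normal()
        for i in range(1, n):
            shared[i] = phi * shared[i - 1] + innov_sd * rng.standard_normal()
        own = {p: rng.standard_normal(n) for p in (1, 2)}
        div = {}
        for p in (1, 2):
            d = np.empty(n)
            d[0] = rng.standard_normal()
            for i in range(1, n):
                d[i] = phi * d[i - 1] + innov_sd * rng.standard_normal()
            div[p] = config.divergence_scale * d
        for p in (1, 2):
            lat = config.coupling * shared + (1 - config.coupling) * own[p] + div[p]
            rows.append(pd.DataFrame({
                "interval_index": np.arange(1, n + 1), "participant": p,
                "component": comp, "latent": lat, "shared": shared}))
    df = pd.concat(rows, ignore_index=True)
    wide = df.pivot_table(index=["interval_index", "participant"],
                          columns="component", values="latent").reset_index()
    sh = df[df.participant == 1].pivot_table(
        index="interval_index", columns="component", values="shared")
    wide = wide.merge(sh.rename(columns={"valence": "shared_valence",
                                         "arousal": "shared_arousal"}),
                      on="interval_index")
    return wide


def _ecg_interval(rng: np.random.Generator, hr_bpm: np.ndarray, fs: float) -> np.ndarray:
    """Pulse-train ECG whose R-peak spacing follows the target rate signal."""
    n = len(hr_bpm)
    phase = np.cumsum(hr_bpm / 60.0) / fs  # beats elapsed
    beat_samples = np.searchsorted(phase, np.arange(1, int(phase[-1]) + 1))
    sig = 0.02 * rng.standard_normal(n) + 0.05 * _smooth_noise(rng, n, fs, 1.0)
    width = max(1, round(0.01 * fs))  # ~10 ms half-width
    t = np.arange(-3 * width, 3 * width + 1)
    pulse = np.exp(-0.5 * (t / width) ** 2)
    for b in beat_samples:
        lo, hi = b - 3 * width, b + 3 * width + 1
        plo, phi_ = max(0, -lo), len(t) - max(0, hi - n)
        sig[max(0, lo):min(n, hi)] += pulse[plo:phi_]
    return sig


def _scr_kernel(fs: float, rise_s: float, decay_s: float) -> np.ndarray:
    """Unit-amplitude bump: smoothstep rise completing at rise_s, exp decay."""
    n_rise = round(rise_s * fs)
    u = np.linspace(0, 1, n_rise + 1)
    rise = u * u * (3 - 2 * u)
    t_dec = np.arange(1, round(6 * decay_s * fs)) / fs
    decay = np.exp(-t_dec / decay_s)
    return np.concatenate([rise, decay])


def _eda_interval(rng: np.random.Generator, n: int, fs: float, tonic_level: float,
                  arousal: float, driver: np.ndarray,
                  config: SynthConfig) -> np.ndarray:
    tonic = tonic_level + 0.15 * _smooth_noise(rng, n, fs, 15.0) + 0.08 * driver
    lam = float(np.clip(config.scr_rate_base + config.scr_rate_gain * arousal, 0.2, 12.0))
    n_events = rng.poisson(lam)
    sig = tonic.copy()
    for _ in range(n_events):
        onset = rng.uniform(0.0, n / fs - 8.0)
        amp = 0.08 + rng.lognormal(mean=-1.8, sigma=0.6)
        rise = rng.uniform(1.0, 2.5)  # completes well inside the 5 s window
        kern = amp * _scr_kernel(fs, rise, 4.0)
        i0 = round(onset * fs)
        i1 = min(n, i0 + len(kern))
        sig[i0:i1] += kern[: i1 - i0]
    return sig


def _resp_interval(rng: np.random.Generator, rr_bpm: np.ndarray, fs: float) -> np.ndarray:
    phase = np.cumsum(rr_bpm / 60.0) / fs
    return np.sin(2 * np.pi * phase) + 0.05 * rng.standard_normal(len(rr_bpm))


def _temp_interval(rng: np.random.Generator, n: int, fs: float, base: float,
                   valence: float, driver: np.ndarray) -> np.ndarray:
    drift = 0.25 * _smooth_noise(rng, n, fs, 20.0)
    trend = 0.1 * valence * np.linspace(0, 1, n)
    return base + drift + trend + 0.05 * driver


def generate_dyad(config: SynthConfig, dyad_index: int) -> DyadRecord:
    """Generate one dyad's full recording.

    Returns 12 intervals (with defaults) x 2 participants x 4 channels plus
    self ratings for every conversation interval, observer ratings mapped
    from the dyad-mean latent, and participant characteristics.
    """
    if dyad_index >= config.n_dyads:
        raise ConfigurationError(f"dyad_index {dyad_index} >= n_dyads {config.n_dyads}")
    rng = _dyad_rng(config, dyad_index)
    n = config.samples_per_interval
    fs = config.sampling_rate
    lat = _interval_latents(config, rng)
    record = DyadRecord(dyad_id=dyad_index,
                        n_conversation_intervals=config.n_conversation_intervals,
                        latents=lat)

    # stable per-participant physiological offsets
    hr_base = {p: config.hr_base + rng.normal(0, 5) for p in (1, 2)}
    eda_base = {p: rng.uniform(2.0, 8.0) for p in (1, 2)}
    temp_base = {p: rng.normal(33.0, 0.6) for p in (1, 2)}
    rr_base = {p: rng.normal(15.0, 1.5) for p in (1, 2)}

    for interval_index in range(config.n_intervals):
        if interval_index in (0, config.n_intervals - 1):
            latents = {p: {"valence": 0.0, "arousal": 0.0} for p in (1, 2)}
        else:
            sub = lat[lat.interval_index == interval_index]
            latents = {int(r.participant): {"valence": r.valence, "arousal": r.arousal}
                       for r in sub.itertuples()}
        # within-interval common driver (zero mean, unit SD), mixed per partner
        shared_fast = _smooth_noise(rng, n, fs, 3.0)
        for p in (1, 2):
            own_fast = _smooth_noise(rng, n, fs, 3.0)
            driver = config.coupling * shared_fast + (1 - config.coupling) * own_fast
            driver -= driver.mean()
            ar, va = latents[p]["arousal"], latents[p]["valence"]

            rsa = np.sin(2 * np.pi * 0.25 * np.arange(n) / fs)
            hr = hr_base[p] + config.hr_gain * ar + 2.0 * (rsa - rsa.mean()) + 2.5 * driver
            hr = np.clip(hr, 40.0, 180.0)
            ecg = _ecg_interval(rng, hr, fs)

            eda = _eda_interval(rng, n, fs, eda_base[p], ar, driver, config)
            rr = np.clip(rr_base[p] + 2.0 * ar + 1.5 * driver, 6.0, 30.0)
            resp = _resp_interval(rng, rr, fs)
            temp = _temp_interval(rng, n, fs, temp_base[p], va, driver)

            for channel, samples in zip(CHANNELS, (ecg, eda, resp, temp)):
                record.signals[(p, interval_index, channel)] = SignalInterval(
                    dyad_id=dyad_index, participant=p, interval_index=interval_index,
                    channel=channel, sampling_rate=fs, samples=samples)

    record.ratings = _make_ratings(config, rng, lat)
    record.characteristics = _make_characteristics(rng)
    return record


def _combine(weights: dict[str, float], valence: np.ndarray,
             arousal: np.ndarray) -> np.ndarray:
    return weights.get("valence", 0.0) * valence + weights.get("arousal", 0.0) * arousal


def _make_ratings(config: SynthConfig, rng: np.random.Generator,
                  lat: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for p in (1, 2):
        sub = lat[lat.participant == p].sort_values("interval_index")
        lat_v, lat_a = sub["valence"].to_numpy(), sub["arousal"].to_numpy()
        out = {"interval_index": sub["interval_index"].to_numpy(),
               "participant": p, "rater": "self"}
        for target in ("valence", "arousal"):
            raw = 5.0 + config.label_scale * _combine(
                config.label_feature_weights[target], lat_v, lat_a)
            raw = raw + rng.normal(0, config.label_noise_sd, len(raw))
            out[f"{target}_raw"] = raw
            out[target] = _map_to_scale(raw)
        rows.append(pd.DataFrame(out))
    # observer: dyad-mean latent, one rating per interval (participant 0)
    mean_lat = lat.groupby("interval_index")[["valence", "arousal"]].mean()
    obs = {"interval_index": mean_lat.index.to_numpy(), "participant": 0,
           "rater": "observer"}
    for target in ("valence", "arousal"):
        raw = 5.0 + config.label_scale * _combine(
            config.label_feature_weights[target],
            mean_lat["valence"].to_numpy(), mean_lat["arousal"].to_numpy())
        obs[f"{target}_raw"] = raw
        obs[target] = _map_to_scale(raw)
    rows.append(pd.DataFrame(obs))
    return pd.concat(rows, ignore_index=True)[
        ["interval_index", "participant", "rater",
         "valence", "arousal", "valence_raw", "arousal_raw"]]


def _make_characteristics(rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for p in (1, 2):
        row = {"participant": p,
               "age": int(np.clip(round(rng.normal(21.1, 3.8)), 18, 33)),
               "gender": GENDERS[rng.choice(3, p=[0.55, 0.40, 0.05])]}
        for trait, (mu, sd, lo, hi) in TRAIT_DISTRIBUTIONS.items():
            row[trait] = float(np.clip(round(rng.normal(mu, sd)), lo, hi))
        rows.append(row)
    return pd.DataFrame(rows)


def generate_cohort(config: SynthConfig) -> list[DyadRecord]:
    """Generate all ``n_dyads`` records from deterministic per-dyad substreams."""
    return [generate_dyad(config, i) for i in range(config.n_dyads)]


# ---------------------------------------------------------------------------
# tidy long-format serialization

def write_cohort(records: list[DyadRecord], out_dir: str | Path) -> None:
    """Write signals (one file per dyad), ratings and characteristics tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ratings, chars = [], []
    for rec in records:
        frames = []
        for (p, ii, ch), si in sorted(rec.signals.items()):
            frames.append(pd.DataFrame({
                "dyad_id": rec.dyad_id, "participant": p, "interval_index": ii,
                "channel": ch, "time_s": si.times, "value": si.samples}))
        pd.concat(frames, ignore_index=True).to_csv(
            out / f"dyad_{rec.dyad_id:03d}_signals.csv", index=False)
        ratings.append(rec.ratings.assign(dyad_id=rec.dyad_id))
        chars.append(rec.characteristics.assign(dyad_id=rec.dyad_id))
    pd.concat(ratings, ignore_index=True).to_csv(out / "ratings.csv", index=False)
    pd.concat(chars, ignore_index=True).to_csv(out / "characteristics.csv", index=False)


def read_cohort(in_dir: str | Path, sampling_rate: float) -> list[DyadRecord]:
    """Read the tidy long format written by :func:`write_cohort`."""
    in_dir = Path(in_dir)
    ratings = pd.read_csv(in_dir / "ratings.csv")
    chars = pd.read_csv(in_dir / "characteristics.csv")
    records = []
    for path in sorted(in_dir.glob("dyad_*_signals.csv")):
        df = pd.read_csv(path)
        dyad_id = int(df["dyad_id"].iloc[0])
        n_conv = int(df["interval_index"].max()) - 1
        rec = DyadRecord(dyad_id=dyad_id, n_conversation_intervals=n_conv)
        for (p, ii, ch), g in df.groupby(["participant", "interval_index", "channel"]):
            rec.signals[(int(p), int(ii), str(ch))] = SignalInterval(
                dyad_id=dyad_id, participant=int(p), interval_index=int(ii),
                channel=str(ch), sampling_rate=sampling_rate,
                samples=g.sort_values("time_s")["value"].to_numpy())
        rec.ratings = ratings[ratings.dyad_id == dyad_id].drop(columns="dyad_id") \
            .reset_index(drop=True)
        rec.characteristics = chars[chars.dyad_id == dyad_id] \
            .drop(columns="dyad_id").reset_index(drop=True)
        records.append(rec)
    return records


def synthetic_feature_table(n_dyads: int = 41, seed: int = 0,
                            label_mode: str = "features",
                            noise_sd: float = 0.5,
                            n_conversation_intervals: int = 10,
                            weights: dict[str, float] | None = None):
    """Feature-level synthetic cohort for exercising selection/regression.

    Builds a normalized-style feature table directly (no signal synthesis):
    correlated individual and synchrony feature columns per
    participant-interval, with self ratings that are either an affine
    function of three named features plus Gaussian noise
    (``label_mode="features"``) or independent of all features
    (``label_mode="independent"``).  Observer ratings mirror the dyad mean.
    """
    from .feature_table import assemble_table
    from .individual_features import FEATURE_NAMES
    from .synchrony import SYNCHRONY_FEATURE_NAMES

    if label_mode not in ("features", "independent"):
        raise ConfigurationError("label_mode must be 'features' or 'independent'")
    rng = np.random.default_rng(seed)
    n_conv = n_conversation_intervals
    # labels driven by two individual features and one synchrony feature
    if weights is None:
        weights = {"mean_hr": 0.125, "n_scr": 0.225, "eda_dtw": 0.6}
    ind_rows, sync_rows, ratings = [], [], []
    for d in range(n_dyads):
        # two latent per-interval drives shared by partners: one expressed in
        # individual features, one only in the dyad's synchrony features
        drive = rng.normal(0, 1.0, n_conv)
        drive_sync = rng.normal(0, 1.0, n_conv)
        sync_vals = {n: rng.normal(0, 1, n_conv) for n in SYNCHRONY_FEATURE_NAMES}
        sync_vals["eda_dtw"] = 1.5 + 0.8 * drive_sync + 0.1 * rng.normal(0, 1, n_conv)
        for ii in range(1, n_conv + 1):
            sync_rows.append({"dyad_id": d, "interval_index": ii,
                              **{n: float(v[ii - 1]) for n, v in sync_vals.items()}})
        raw_dyad = np.zeros(n_conv)
        for p in (1, 2):
            feats = {n: rng.normal(0, 1, n_conv) for n in FEATURE_NAMES}
            feats["mean_hr"] = 6.0 * drive + rng.normal(0, 0.5, n_conv)
            feats["n_scr"] = np.round(np.clip(4 + 2.5 * drive
                                              + rng.normal(0, 0.5, n_conv), 0, 14))
            for ii in range(1, n_conv + 1):
                ind_rows.append({"dyad_id": d, "interval_index": ii,
                                 "participant": p,
                                 **{n: float(v[ii - 1]) for n, v in feats.items()}})
            if label_mode == "features":
                raw = (5.0 + weights["mean_hr"] * feats["mean_hr"]
                       + weights["n_scr"] * (feats["n_scr"] - 4.0)
                       + weights["eda_dtw"] * (sync_vals["eda_dtw"] - 1.5))
            else:
                raw = rng.normal(5.0, 1.5, n_conv)
            raw = raw + rng.normal(0, noise_sd, n_conv)
            vals = _map_to_scale(raw)
            raw_dyad += raw / 2.0
            for ii in range(1, n_conv + 1):
                ratings.append({"dyad_id": d, "interval_index": ii,
                                "participant": p, "rater": "self",
                                "valence": int(vals[ii - 1]),
                                "arousal": int(vals[ii - 1])})
        obs = _map_to_scale(raw_dyad)
        for ii in range(1, n_conv + 1):
            ratings.append({"dyad_id": d, "interval_index": ii, "participant": 0,
                            "rater": "observer", "valence": int(obs[ii - 1]),
                            "arousal": int(obs[ii - 1])})
    table = assemble_table(pd.DataFrame(ind_rows), pd.DataFrame(sync_rows),
                           pd.DataFrame(ratings),
                           n_conversation_intervals=n_conv)
    table.normalized = True  # built directly on the conversation-interval scale
    return table


def config_from_dict(d: dict) -> SynthConfig:
    known = {f.name for f in dataclasses.fields(SynthConfig)}
    bad = set(d) - known
    if bad:
        raise ConfigurationError(f"unknown SynthConfig keys: {sorted(bad)}")
    return SynthConfig(**d)
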