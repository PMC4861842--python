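"""Rumination classification from tri-axial accelerometer traces.

A synthetic 12 Hz signal is generated from a labelled activity schedule;
windows of the resultant magnitude are summarized by sample variance and
discrete-Fourier band powers; a Gaussian-emission HMM segments the
windows; the state with the highest chew-band-to-broadband power ratio is
labelled rumination; contiguous rumination windows are merged into
events and scored against the schedule at window level.
"""
from __future__ import annotations

import json
import logging
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM

# hmmlearn reports benign EM oscillations through logging; keep it quiet
logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)

__all__ = [
    "RawSignal",
    "FeatureSeries",
    "Decoding",
    "ClassificationReport",
    "AccelConfig",
    "synthesize_accel",
    "window_features",
    "decode_states",
    "states_to_events",
    "evaluate_events",
]

#: default DFT bands (Hz): rhythmic chewing band, then broadband
DEFAULT_BANDS = ((0.5, 2.0), (2.0, 6.0))


@dataclass
class AccelConfig:
    """Knobs of the synthetic accelerometer."""

    sample_rate: float = 12.0
    chew_freq_hz: float = 1.1      # jaw rhythm during rumination
    rum_amplitude: float = 0.30
    rum_noise_sd: float = 0.05
    feed_noise_sd: float = 0.45    # broadband, high energy
    other_noise_sd: float = 0.05
    snr: float = 1.0               # divides all signal amplitudes' contrast

    @property
    def noise_floor(self) -> float:
        return self.other_noise_sd


@dataclass
class RawSignal:
    cow_id: int
    sample_rate: float
    data: np.ndarray  # (n_samples, 3)
    t0: float = 0.0

    @property
    def duration_s(self) -> float:
        return self.data.shape[0] / self.sample_rate

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.data, axis=1)


@dataclass
class FeatureSeries:
    window_start_s: np.ndarray
    variance: np.ndarray
    band_power: np.ndarray       # (n_windows, n_bands)
    bands: tuple = DEFAULT_BANDS
    window_s: float = 30.0


@dataclass
class Decoding:
    path: np.ndarray             # raw state indices
    rumination_state: int
    converged: bool
    loglik: float
    state_ratio: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def rum_mask(self) -> np.ndarray:
        return self.path == self.rumination_state


@dataclass
class ClassificationReport:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def sensitivity(self) -> float | None:
        if self.tp + self.fn == 0:
            return None
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def ppv(self) -> float | None:
        if self.tp + self.fp == 0:
            return None
        return 100.0 * self.tp / (self.tp + self.fp)


# ---------------------------------------------------------------------------
# synthesis


def synthesize_accel(schedule: pd.DataFrame, config: AccelConfig | None = None,
                     seed: int = 0, duration_s: float | None = None,
                     cow_id: int = 0) -> RawSignal:
    """Generate a 12 Hz tri-axial trace from labelled activity intervals.

    *schedule* columns: ``start_s, end_s, label`` with labels in
    ``{"rumination", "feeding", "other"}``; intervals must not overlap.
    Rumination adds a rhythmic component near 1.1 Hz on two axes; feeding
    adds strong broadband noise; everywhere else only the noise floor
    (scaled by ``1/snr``) remains.
    """
    config = config or AccelConfig()
    rng = np.random.default_rng(seed)
    if len(schedule):
        iv = schedule.sort_values("start_s")[["start_s", "end_s"]].to_numpy()
        if np.any(iv[:, 1] <= iv[:, 0]):
            raise ValueError("schedule intervals must have end > start")
        if np.any(iv[1:, 0] < iv[:-1, 1]):
            raise ValueError("schedule intervals overlap")
        total = float(iv[:, 1].max())
    else:
        total = 0.0
    if duration_s is None:
        duration_s = total
    n = int(round(duration_s * config.sample_rate))
    fs = config.sample_rate

    noise_sd = config.other_noise_sd / config.snr
    data = rng.normal(0.0, noise_sd, size=(n, 3))
    data[:, 2] += 1.0  # gravity along z

    t = np.arange(n) / fs
    for row in schedule.itertuples(index=False):
        i0 = int(round(row.start_s * fs))
        i1 = min(n, int(round(row.end_s * fs)))
        if i1 <= i0:
            continue
        seg = slice(i0, i1)
        m = i1 - i0
        if row.label == "rumination":
            phase = rng.uniform(0, 2 * np.pi)
            wobble = rng.normal(0.0, 0.02)
            osc = config.rum_amplitude * np.sin(
                2 * np.pi * (config.chew_freq_hz + wobble) * t[seg] + phase)
            # oscillation partly along gravity so the resultant magnitude
            # keeps a first-order rhythmic component
            data[seg, 2] += osc
            data[seg, 0] += 0.4 * osc
            data[seg, :2] += rng.normal(0.0, config.rum_noise_sd / config.snr,
                                        size=(m, 2))
        elif row.label == "feeding":
            data[seg, :] += rng.normal(0.0, config.feed_noise_sd,
                                       size=(m, 3))
        elif row.label != "other":
            raise ValueError(f"unknown activity label {row.label!r}")
    return RawSignal(cow_id=cow_id, sample_rate=fs, data=data)


# ---------------------------------------------------------------------------
# features


def window_features(signal: RawSignal, window_s: float = 30.0,
                    bands=DEFAULT_BANDS) -> FeatureSeries:
    """Variance and DFT band powers per non-overlapping window.

    Features are computed on the resultant magnitude.  Band power is the
    sum of two-sided squared DFT magnitudes (DC excluded) over the band,
    normalized by the window length, so the powers over a full partition
    of (0, Nyquist] sum to the window variance (Parseval).
    """
    fs = signal.sample_rate
    nwin = int(round(window_s * fs))
    if nwin < 8:
        raise ValueError("window must span at least 8 samples")
    mag = signal.magnitude()
    if nwin > len(mag):
        raise ValueError("window longer than signal")
    nfull = len(mag) // nwin
    segs = mag[: nfull * nwin].reshape(nfull, nwin)

    var = segs.var(axis=1, ddof=0)
    spec = np.fft.rfft(segs - segs.mean(axis=1, keepdims=True), axis=1)
    power = (np.abs(spec) ** 2) / (nwin ** 2)
    # two-sided correction: double everything but DC and (even n) Nyquist
    power[:, 1:] *= 2.0
    if nwin % 2 == 0:
        power[:, -1] /= 2.0
    freqs = np.fft.rfftfreq(nwin, d=1.0 / fs)

    bp = np.empty((nfull, len(bands)))
    for b, (lo, hi) in enumerate(bands):
        sel = (freqs > 0) & (freqs >= lo) & (freqs < hi)
        bp[:, b] = power[:, sel].sum(axis=1)
    starts = np.arange(nfull) * window_s + signal.t0
    return FeatureSeries(window_start_s=starts, variance=var,
                         band_power=bp, bands=tuple(bands),
                         window_s=window_s)


# ---------------------------------------------------------------------------
# decoding


def decode_states(features: FeatureSeries, n_states: int = 3, seed: int = 0,
                  n_restarts: int = 5, n_iter: int = 100) -> Decoding:
    """Segment windows with a Gaussian-emission HMM on log features.

    The EM fit is restarted ``n_restarts`` times and the best
    log-likelihood kept; the Viterbi path is decoded and the state with
    the highest mean chew-band to broadband power ratio is labelled
    rumination (invariant to state-label permutations across restarts).
    """
    if n_states not in (2, 3):
        raise ValueError("n_states must be 2 or 3")
    nwin = len(features.variance)
    if nwin < 10:
        raise ValueError("need at least 10 windows")

    eps = 1e-12
    X = np.column_stack([
        np.log(features.variance + eps),
        np.log(features.band_power + eps),
    ])

    best = None
    converged = False
    for r in range(n_restarts):
        model = GaussianHMM(n_components=n_states, covariance_type="full",
                            n_iter=n_iter, random_state=seed + r,
                            tol=1e-4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model.fit(X)
            except Exception:
                continue
            score = model.score(X)
        if best is None or score > best[0]:
            best = (score, model)
            converged = converged or model.monitor_.converged
    if best is None:
        raise RuntimeError("all HMM restarts failed")
    if not converged:
        warnings.warn("EM did not converge in any restart; "
                      "best-so-far model used")
    score, model = best
    path = model.predict(X)

    # identify the rumination state from the raw band powers
    chew = features.band_power[:, 0]
    broad = features.band_power[:, 1] if features.band_power.shape[1] > 1 \
        else np.full(nwin, eps)
    ratio = np.empty(n_states)
    for s in range(n_states):
        sel = path == s
        if sel.sum() == 0:
            ratio[s] = -np.inf
        else:
            ratio[s] = chew[sel].mean() / (broad[sel].mean() + eps)
    return Decoding(path=path, rumination_state=int(np.argmax(ratio)),
                    converged=converged, loglik=float(score),
                    state_ratio=ratio)


def states_to_events(rum_mask: np.ndarray, window_s: float,
                     merge_gap_s: float = 0.0, min_event_s: float = 0.0,
                     t0: float = 0.0) -> pd.DataFrame:
    """Turn per-window rumination flags into merged, filtered events."""
    if merge_gap_s < 0 or min_event_s < 0:
        raise ValueError("merge_gap_s and min_event_s must be >= 0")
    mask = np.asarray(rum_mask, dtype=bool)
    events: list[list[float]] = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            events.append([t0 + start * window_s, t0 + i * window_s])
            start = None
    if start is not None:
        events.append([t0 + start * window_s, t0 + len(mask) * window_s])

    merged: list[list[float]] = []
    for ev in events:
        if merged and ev[0] - merged[-1][1] < merge_gap_s:
            merged[-1][1] = ev[1]
        else:
            merged.append(ev)
    kept = [ev for ev in merged if ev[1] - ev[0] >= min_event_s]
    return pd.DataFrame(kept, columns=["start_s", "end_s"]).assign(
        duration_min=lambda d: (d["end_s"] - d["start_s"]) / 60.0)


# ---------------------------------------------------------------------------
# evaluation


def _rasterize(events: pd.DataFrame, edges: np.ndarray) -> np.ndarray:
    """True for windows whose majority lies inside an event."""
    mids_cov = np.zeros(len(edges) - 1)
    for ev in events.itertuples(index=False):
        lo = np.clip(ev.start_s, edges[0], edges[-1])
        hi = np.clip(ev.end_s, edges[0], edges[-1])
        overlap = np.clip(np.minimum(edges[1:], hi)
                          - np.maximum(edges[:-1], lo), 0, None)
        mids_cov += overlap
    width = np.diff(edges)
    return mids_cov >= 0.5 * width


def evaluate_events(predicted: pd.DataFrame, truth: pd.DataFrame,
                    span_s: tuple[float, float], window_s: float = 30.0,
                    ) -> ClassificationReport:
    """Window-level confusion of predicted vs true rumination events."""
    lo, hi = span_s
    if hi <= lo:
        raise ValueError("span must be non-empty")
    edges = np.arange(lo, hi + window_s / 2, window_s)
    pred = _rasterize(predicted, edges)
    true = _rasterize(truth, edges)
    return ClassificationReport(
        tp=int((pred & true).sum()),
        fp=int((pred & ~true).sum()),
        fn=int((~pred & true).sum()),
        tn=int((~pred & ~true).sum()),
    )


# ---------------------------------------------------------------------------
# signal I/O (binary array + JSON sidecar)


def save_signal(signal: RawSignal, path: str) -> None:
    np.save(path + ".npy", signal.data)
    with open(path + ".json", "w") as fh:
        json.dump({"cow_id": signal.cow_id, "sample_rate": signal.sample_rate,
                   "t0": signal.t0}, fh)


def load_signal(path: str) -> RawSignal:
    with open(path + ".json") as fh:
        meta = json.load(fh)
    data = np.load(path + ".npy")
    return RawSignal(cow_id=meta["cow_id"], sample_rate=meta["sample_rate"],
                     data=data, t0=meta.get("t0", 0.0))
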