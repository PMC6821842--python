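"""Continuous-recording preprocessing and per-trial response extraction.

The high-frequency amplitude (HFA, 48–154 Hz) is the workhorse signal: a
proxy for aggregate local firing rate. It is estimated in nine 10-Hz-wide
sub-bands spanning 48–154 Hz (skipping 59–61 and 117–121 Hz to avoid line
noise and its harmonic). Each sub-band is band-passed with a zero-phase
Hamming-window FIR filter, its instantaneous amplitude taken as the absolute
Hilbert transform, divided by its own temporal mean — so the 1/f spectral
profile cannot let low sub-bands dominate — and the nine normalized traces
are averaged. The resulting trace has temporal mean 1 by construction.

Trial responses are expressed as percent signal change from a *global*
per-channel baseline: the mean of the amplitude trace over every trial's
[−200, 0) ms pre-stimulus window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from mne.filter import filter_data, resample
from scipy.signal import hilbert

from .protocols import TaskProtocol

#: nine 10-Hz sub-bands inside 48–154 Hz avoiding 59–61 and 117–121 Hz
DEFAULT_HFA_BANDS: tuple = (
    (48, 58),
    (62, 72),
    (72, 82),
    (82, 92),
    (92, 102),
    (102, 112),
    (122, 132),
    (132, 142),
    (144, 154),
)

TARGET_FS = 500.0
ACCEPTED_FS = (500.0, 512.0)


@dataclass
class Recording:
    """Continuous multi-channel recording (channels x samples, µV)."""

    data: np.ndarray
    sampling_rate_hz: float
    channel_names: list
    units: str = "uV"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_names):
            raise ValueError("data must be channels x samples matching channel_names")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def save(self, path) -> None:
        """Flat binary array + JSON sidecar."""
        path = Path(path)
        self.data.astype("<f8").tofile(path.with_suffix(".dat"))
        sidecar = {
            "sampling_rate_hz": self.sampling_rate_hz,
            "channel_names": list(self.channel_names),
            "units": self.units,
            "n_samples": self.n_samples,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path) -> "Recording":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        data = np.fromfile(path.with_suffix(".dat"), dtype="<f8")
        data = data.reshape(len(meta["channel_names"]), meta["n_samples"])
        return cls(data, meta["sampling_rate_hz"], meta["channel_names"], meta["units"])


@dataclass
class EpochedResponse:
    """Per-trial responses: trials x channels x time.

    ``times_ms`` is relative to stimulus onset over [−200, 500) by default;
    units are percent signal change for HFA and µV for ERP. ``trials`` holds
    the retained trials' metadata, row-aligned with the tensor.
    """

    data: np.ndarray
    times_ms: np.ndarray
    channel_names: list
    trials: pd.DataFrame
    units: str
    baseline_window_ms: tuple = (-200, 0)
    analysis_window_ms: tuple = (50, 500)

    def time_mask(self, window_ms) -> np.ndarray:
        lo, hi = window_ms
        return (self.times_ms >= lo) & (self.times_ms < hi)

    def mean_response(self, window_ms=None) -> np.ndarray:
        """Per-trial, per-channel mean over an analysis window: trials x channels."""
        m = self.time_mask(window_ms or self.analysis_window_ms)
        return self.data[:, :, m].mean(axis=2)


def ensure_target_rate(recording: Recording) -> Recording:
    """Accept 500 or 512 Hz; polyphase-resample 512 Hz input to 500 Hz."""
    fs = float(recording.sampling_rate_hz)
    if fs not in ACCEPTED_FS:
        raise ValueError(f"sampling rate {fs} Hz unsupported; expected one of {ACCEPTED_FS}")
    if fs == TARGET_FS:
        return recording
    data = resample(recording.data, up=TARGET_FS, down=fs, npad="auto", verbose="error")
    return Recording(data, TARGET_FS, list(recording.channel_names), recording.units)


def common_average_reference(recording: Recording, bad_channels=()) -> Recording:
    """Subtract the mean over intact channels from every intact channel.

    Bad channels pass through unchanged and do not contribute to the mean.
    """
    bad = set(bad_channels)
    unknown = bad - set(recording.channel_names)
    if unknown:
        raise ValueError(f"bad_channels not in recording: {sorted(unknown)}")
    intact = np.array([c not in bad for c in recording.channel_names])
    if not intact.any():
        raise ValueError("all channels marked bad; nothing to reference against")
    car = recording.data[intact].mean(axis=0)
    data = recording.data.copy()
    data[intact] -= car
    return Recording(data, recording.sampling_rate_hz, list(recording.channel_names), recording.units)


def _band_amplitude(data: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    filtered = filter_data(
        data, sfreq=fs, l_freq=lo, h_freq=hi, method="fir", phase="zero",
        fir_window="hamming", fir_design="firwin", verbose="error",
    )
    n = filtered.shape[-1]
    nfft = 1 << int(np.ceil(np.log2(n)))  # pad to power of two for the Hilbert FFT
    return np.abs(hilbert(filtered, N=nfft)[..., :n])


def estimate_hfa(recording: Recording, bands=DEFAULT_HFA_BANDS) -> Recording:
    """High-frequency amplitude trace per channel.

    Band-pass each sub-band, take the Hilbert amplitude, divide each band's
    trace by its temporal mean, and average across bands. The output trace is
    non-negative with temporal mean 1 per channel.
    """
    rec = ensure_target_rate(recording)
    if rec.sampling_rate_hz < 2 * max(hi for _, hi in bands):
        raise ValueError("sampling rate below Nyquist for the requested bands")
    acc = np.zeros_like(rec.data)
    for lo, hi in bands:
        amp = _band_amplitude(rec.data, rec.sampling_rate_hz, lo, hi)
        acc += amp / amp.mean(axis=1, keepdims=True)
    acc /= len(bands)
    return Recording(acc, rec.sampling_rate_hz, list(rec.channel_names), units="a.u.")


def _epoch(
    data: np.ndarray, fs: float, protocol: TaskProtocol, window_ms, drop_excluded=True
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    lo, hi = window_ms
    trials = protocol.included_trials() if drop_excluded else protocol.trials
    start = np.round(trials["onset_ms"].values / 1000 * fs + lo / 1000 * fs).astype(int)
    n_t = int(round((hi - lo) / 1000 * fs))
    if start.min() < 0 or (start + n_t).max() > data.shape[1]:
        raise ValueError("epoch window falls outside the recording")
    idx = start[:, None] + np.arange(n_t)[None, :]
    tensor = data[:, idx].transpose(1, 0, 2)  # trials x channels x time
    times = lo + np.arange(n_t) * 1000.0 / fs
    return tensor, times, trials.reset_index(drop=True)


def epoch_and_normalize(
    amplitude: Recording,
    protocol: TaskProtocol,
    window_ms=(-200, 500),
    baseline_ms=(-200, 0),
) -> EpochedResponse:
    """Epoch an amplitude trace and express it as % change from global baseline.

    The baseline B is per channel: the mean over *all* retained trials'
    baseline-window samples; every sample maps to 100·(x − B)/B. Hit, miss
    and false-alarm trials (protocol ``excluded`` flag) are dropped first.
    """
    tensor, times, trials = _epoch(amplitude.data, amplitude.sampling_rate_hz, protocol, window_ms)
    bmask = (times >= baseline_ms[0]) & (times < baseline_ms[1])
    baseline = tensor[:, :, bmask].mean(axis=(0, 2))  # per channel
    if (baseline <= 0).any():
        raise ValueError("non-positive global baseline; input is not an amplitude trace")
    data = 100.0 * (tensor - baseline[None, :, None]) / baseline[None, :, None]
    return EpochedResponse(
        data, times, list(amplitude.channel_names), trials, units="% signal change",
        baseline_window_ms=tuple(baseline_ms),
    )


def extract_erp(
    referenced: Recording, protocol: TaskProtocol, window_ms=(-200, 500)
) -> EpochedResponse:
    """Event-related potentials of the common-referenced raw signal.

    Epochs are kept per trial (µV); average across repetitions with
    :func:`repetition_average`. The analysis window is fixed at [125, 250) ms.
    """
    tensor, times, trials = _epoch(referenced.data, referenced.sampling_rate_hz, protocol, window_ms)
    return EpochedResponse(
        tensor, times, list(referenced.channel_names), trials, units="uV",
        analysis_window_ms=(125, 250),
    )


def extract_low_freq_blp(
    referenced: Recording, protocol: TaskProtocol, band=(8.0, 13.0), window_ms=(-200, 500)
) -> EpochedResponse:
    """Band-limited power (8–13 Hz Hilbert amplitude) epochs, window [125, 250) ms."""
    amp = _band_amplitude(referenced.data, referenced.sampling_rate_hz, *band)
    tensor, times, trials = _epoch(amp, referenced.sampling_rate_hz, protocol, window_ms)
    return EpochedResponse(
        tensor, times, list(referenced.channel_names), trials, units="a.u.",
        analysis_window_ms=(125, 250),
    )


def repetition_average(epochs: EpochedResponse) -> tuple[np.ndarray, list]:
    """Average epochs across repetitions of the same stimulus.

    Returns (exemplars x channels x time, exemplar ids in sorted order).
    """
    ids = sorted(epochs.trials["stimulus_id"].unique())
    out = np.stack(
        [epochs.data[(epochs.trials["stimulus_id"] == s).values].mean(axis=0) for s in ids]
    )
    return out, ids
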