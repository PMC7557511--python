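"""Filtering and epoching of raw EMG recordings.

The acquisition chain band-passes raw signals to 50-500 Hz with a
Butterworth filter and removes 50 Hz mains interference with a notch
filter.  Offline processing uses zero-phase forward-backward filtering so
epoch boundaries are not shifted by group delay; the online simulator
requests causal single-pass filtering instead (``zero_phase=False``).

The upper band edge defaults to 499 Hz: at a 1000 Hz sampling rate a
band edge placed exactly at the 500 Hz Nyquist frequency is degenerate
for an IIR design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .synth_emg import ActionClass, EmgRecording, TrialTimeline

__all__ = [
    "FilterSpec",
    "Epoch",
    "apply_bandpass",
    "apply_notch",
    "extract_epochs",
    "epochs_from_dataset",
]


@dataclass(frozen=True)
class FilterSpec:
    """Record of one filtering step (kept in recording metadata)."""

    kind: str                 # "bandpass" | "notch"
    low: float | None = None
    high: float | None = None
    order: int | None = None
    freq: float | None = None
    q: float | None = None
    zero_phase: bool = True


@dataclass
class Epoch:
    """One 1.5 s action window cut from a recording."""

    signal: np.ndarray        # (channels, window samples)
    label: ActionClass
    sampling_rate: float
    channels: tuple[str, ...]
    trial_id: int | None = None
    session_id: int | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("epoch signal must be 2-D (channels x samples)")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


def _record_filter(rec: EmgRecording, spec: FilterSpec) -> None:
    rec.meta.setdefault("filters", []).append(spec)


def apply_bandpass(
    rec: EmgRecording,
    low: float = 50.0,
    high: float = 499.0,
    order: int = 4,
    zero_phase: bool = True,
) -> EmgRecording:
    """Butterworth band-pass each channel (zero-phase by default)."""
    nyq = rec.sampling_rate / 2.0
    if order < 1:
        raise ValueError("filter order must be >= 1")
    if not 0 < low < high < nyq:
        raise ValueError(
            f"band edges must satisfy 0 < low < high < Nyquist ({nyq} Hz); "
            f"got low={low}, high={high}"
        )
    sos = sps.butter(order, [low, high], btype="bandpass",
                     fs=rec.sampling_rate, output="sos")
    out = rec.copy()
    if zero_phase:
        out.signal = sps.sosfiltfilt(sos, out.signal, axis=1)
    else:
        out.signal = sps.sosfilt(sos, out.signal, axis=1)
    _record_filter(out, FilterSpec(kind="bandpass", low=low, high=high,
                                   order=order, zero_phase=zero_phase))
    return out


def apply_notch(
    rec: EmgRecording,
    freq: float = 50.0,
    q: float = 30.0,
    zero_phase: bool = True,
) -> EmgRecording:
    """Second-order IIR notch at ``freq`` Hz (default 50 Hz mains)."""
    nyq = rec.sampling_rate / 2.0
    if not 0 < freq < nyq:
        raise ValueError(
            f"notch frequency must lie in (0, Nyquist={nyq} Hz), got {freq}"
        )
    if q <= 0:
        raise ValueError("quality factor must be positive")
    b, a = sps.iirnotch(freq, q, fs=rec.sampling_rate)
    out = rec.copy()
    if zero_phase:
        out.signal = sps.filtfilt(b, a, out.signal, axis=1)
    else:
        out.signal = sps.lfilter(b, a, out.signal, axis=1)
    _record_filter(out, FilterSpec(kind="notch", freq=freq, q=q,
                                   zero_phase=zero_phase))
    return out


def extract_epochs(
    rec: EmgRecording,
    timeline: TrialTimeline | None = None,
) -> list[Epoch]:
    """Cut one epoch per event, spanning [onset, onset + action_s)."""
    timeline = timeline or TrialTimeline()
    n_win = int(round(timeline.action_s * rec.sampling_rate))
    epochs: list[Epoch] = []
    for i, (onset, label) in enumerate(rec.events):
        if onset + n_win > rec.n_samples:
            raise ValueError(
                f"event {i} (onset {onset}) window of {n_win} samples "
                f"exceeds recording length {rec.n_samples}"
            )
        epochs.append(
            Epoch(
                signal=rec.signal[:, onset:onset + n_win].copy(),
                label=label,
                sampling_rate=rec.sampling_rate,
                channels=tuple(rec.channels),
                trial_id=rec.meta.get("trial"),
                session_id=rec.meta.get("session"),
            )
        )
    return epochs


def epochs_from_dataset(
    recordings: list[EmgRecording],
    timeline: TrialTimeline | None = None,
    bandpass: bool = True,
    notch: bool = True,
    **filter_kwargs,
) -> list[Epoch]:
    """Filter every trial recording and concatenate the extracted epochs.

    Convenience wrapper for the offline pipeline: zero-phase band-pass
    (50-499 Hz, order 4) and 50 Hz notch, then epoch extraction.
    """
    epochs: list[Epoch] = []
    for rec in recordings:
        r = rec
        if bandpass:
            r = apply_bandpass(r, **{k: v for k, v in filter_kwargs.items()
                                     if k in ("low", "high", "order")})
        if notch:
            r = apply_notch(r, **{k: v for k, v in filter_kwargs.items()
                                  if k in ("freq", "q")})
        epochs.extend(extract_epochs(r, timeline))
    return epochs
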