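"""Synthetic facial surface-EMG generation.

Real facial-action EMG is recorded from scalp electrodes placed over the
facial musculature (F7/F8 over the left/right anterior temporal region,
FC5/FC6 slightly posterior, referenced to CPz with AFz as ground).  The
decoder downstream of this module consumes only two properties of those
recordings: the spatial distribution of signal amplitude across the four
electrodes, and the distribution of signal power across three frequency
bands (64-128, 128-256, 256-500 Hz).  The generator therefore models a
facial action as band-shaped Gaussian noise with class-specific channel
gains and band-power fractions, ramped on and off with a raised-cosine
envelope, superimposed on a white baseline noise floor, with optional
50 Hz mains interference.

Four facial actions are modelled:

* ``raising_brow`` / ``furrowing_brow`` — bilateral (left/right symmetric)
  actions that differ in their frontal-vs-posterior emphasis and in how
  power is distributed across the bands;
* ``left_smirking`` / ``right_smirking`` — lateralised actions whose
  channel gains are left/right mirror images of each other.

The offline protocol structure is reproduced exactly: trials of 1 s
preparation + 1.5 s action + 1 s break, 6 trials per action per session,
10 sessions, i.e. 60 trials per action and 240 labelled trials in total.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ActionClass",
    "RecordingConfig",
    "TrialTimeline",
    "SessionPlan",
    "SpatialSpectralProfile",
    "SubjectProfile",
    "EmgRecording",
    "DEFAULT_BANDS",
    "make_action_profile",
    "draw_subject",
    "synthesize_trial",
    "synthesize_dataset",
    "inject_interference",
]

#: Frequency bands (Hz) used both for synthesis and for feature extraction.
#: The top band ends at 500 Hz, the Nyquist frequency of a 1000 Hz recording.
DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (64.0, 128.0),
    (128.0, 256.0),
    (256.0, 500.0),
)

LEFT_CHANNELS = ("F7", "FC5")
RIGHT_CHANNELS = ("F8", "FC6")
FRONTAL_CHANNELS = ("F7", "F8")
POSTERIOR_CHANNELS = ("FC5", "FC6")


class ActionClass(enum.Enum):
    """The four facial actions used as prosthesis control signals."""

    FURROWING_BROW = "furrowing_brow"
    RAISING_BROW = "raising_brow"
    LEFT_SMIRKING = "left_smirking"
    RIGHT_SMIRKING = "right_smirking"

    @classmethod
    def coerce(cls, value: "ActionClass | str") -> "ActionClass":
        if isinstance(value, cls):
            return value
        try:
            return cls(value)
        except ValueError:
            valid = ", ".join(a.value for a in cls)
            raise ValueError(
                f"unknown facial action {value!r}; expected one of: {valid}"
            ) from None


@dataclass(frozen=True)
class RecordingConfig:
    """Acquisition metadata: 1000 Hz sampling, four scalp channels."""

    sampling_rate: float = 1000.0
    channels: tuple[str, ...] = ("F7", "F8", "FC5", "FC6")
    reference: str = "CPz"
    ground: str = "AFz"

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.channels:
            raise ValueError("channel list must be non-empty")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")

    @property
    def nyquist(self) -> float:
        return self.sampling_rate / 2.0


@dataclass(frozen=True)
class TrialTimeline:
    """Trial structure: preparation, action window, break (seconds)."""

    prep_s: float = 1.0
    action_s: float = 1.5
    break_s: float = 1.0

    def __post_init__(self) -> None:
        for name in ("prep_s", "action_s", "break_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def total_s(self) -> float:
        return self.prep_s + self.action_s + self.break_s


@dataclass(frozen=True)
class SessionPlan:
    """Offline protocol: sessions x trials-per-action-per-session."""

    n_sessions: int = 10
    trials_per_action: int = 6

    def __post_init__(self) -> None:
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be at least 1")
        if self.trials_per_action < 1:
            raise ValueError("trials_per_action must be at least 1")

    @property
    def trials_per_action_total(self) -> int:
        return self.n_sessions * self.trials_per_action

    @property
    def total_trials(self) -> int:
        return len(ActionClass) * self.trials_per_action_total


@dataclass(frozen=True)
class SpatialSpectralProfile:
    """Spatial gains and band-power fractions for one facial action.

    ``channel_gains`` scale the action-burst RMS per channel;
    ``band_fractions`` apportion the burst power across ``bands`` and must
    sum to 1.  ``baseline_rms`` is the white noise floor present throughout
    the trial; ``action_rms`` is the burst RMS for a unit-gain channel.
    """

    action: ActionClass
    channel_gains: dict[str, float]
    band_fractions: tuple[float, ...]
    baseline_rms: float = 1.0
    action_rms: float = 4.0
    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        if any(g < 0 for g in self.channel_gains.values()):
            raise ValueError("channel gains must be non-negative")
        fr = np.asarray(self.band_fractions, dtype=float)
        if len(fr) != len(self.bands):
            raise ValueError("one band fraction per band required")
        if np.any(fr < 0) or np.any(fr > 1):
            raise ValueError("band fractions must lie in [0, 1]")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("band fractions must sum to 1 (within 1e-9)")
        if self.baseline_rms < 0 or self.action_rms < 0:
            raise ValueError("RMS levels must be non-negative")


def make_action_profile(
    action: ActionClass | str,
    asymmetry: float = 2.0,
    band_contrast: float = 0.3,
    *,
    action_rms: float = 4.0,
    baseline_rms: float = 1.0,
    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS,
) -> SpatialSpectralProfile:
    """Build the spatial/spectral profile of one facial action.

    ``asymmetry`` (>= 1) is the spatial contrast ratio: for the smirking
    actions it multiplies the gains of the ipsilateral channel pair
    (left smirk boosts F7/FC5, right smirk boosts F8/FC6); for the brow
    actions, which are left/right symmetric, it contrasts the frontal
    pair (raising brow, F7/F8) against the posterior pair (furrowing
    brow, FC5/FC6) so that the four profiles remain pairwise distinct
    whenever ``asymmetry > 1``.

    ``band_contrast`` c in [0, 2/3] sets the spectral contrast between the
    two brow actions: starting from uniform thirds, raising brow shifts a
    fraction c/2 of the power from the top band to the bottom band and
    furrowing brow shifts it the other way, so their band-fraction vectors
    differ by 2c in L1 norm.  The smirking actions use a fixed mid-band
    dominant spectrum (1/4, 1/2, 1/4).
    """
    action = ActionClass.coerce(action)
    if asymmetry < 1:
        raise ValueError("asymmetry must be >= 1")
    if not 0 <= band_contrast <= 2 / 3:
        raise ValueError("band_contrast must lie in [0, 2/3]")

    a = float(asymmetry)
    c = float(band_contrast)
    third = 1.0 / 3.0
    if action is ActionClass.RAISING_BROW:
        gains = {"F7": a, "F8": a, "FC5": 1.0, "FC6": 1.0}
        fractions = (third + c / 2, third, third - c / 2)
    elif action is ActionClass.FURROWING_BROW:
        gains = {"F7": 1.0, "F8": 1.0, "FC5": a, "FC6": a}
        fractions = (third - c / 2, third, third + c / 2)
    elif action is ActionClass.LEFT_SMIRKING:
        gains = {"F7": a, "F8": 1.0, "FC5": a, "FC6": 1.0}
        fractions = (0.25, 0.5, 0.25)
    elif action is ActionClass.RIGHT_SMIRKING:
        gains = {"F7": 1.0, "F8": a, "FC5": 1.0, "FC6": a}
        fractions = (0.25, 0.5, 0.25)
    else:  # pragma: no cover - coerce() already rejects unknown labels
        raise ValueError(f"unknown facial action: {action}")

    return SpatialSpectralProfile(
        action=action,
        channel_gains=gains,
        band_fractions=fractions,
        baseline_rms=baseline_rms,
        action_rms=action_rms,
        bands=bands,
    )


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject generator parameters.

    ``amplitude_jitter_cv`` is the trial-to-trial coefficient of variation
    of the burst amplitude (effort varies between repetitions);
    ``mains_amplitude`` is the 50 Hz interference amplitude added to every
    channel, removed downstream by the notch filter.
    """

    asymmetry: float = 2.0
    band_contrast: float = 0.3
    action_rms: float = 4.0
    baseline_rms: float = 1.0
    amplitude_jitter_cv: float = 0.15
    mains_amplitude: float = 2.0

    def profile_for(self, action: ActionClass | str) -> SpatialSpectralProfile:
        return make_action_profile(
            action,
            asymmetry=self.asymmetry,
            band_contrast=self.band_contrast,
            action_rms=self.action_rms,
            baseline_rms=self.baseline_rms,
        )


def draw_subject(seed: int) -> SubjectProfile:
    """Draw a random subject from documented inter-subject ranges."""
    rng = np.random.default_rng(_check_seed(seed))
    return SubjectProfile(
        asymmetry=rng.uniform(1.6, 2.6),
        band_contrast=rng.uniform(0.2, 0.4),
        action_rms=rng.uniform(3.0, 6.0),
        baseline_rms=1.0,
        amplitude_jitter_cv=0.15,
        mains_amplitude=rng.uniform(1.0, 3.0),
    )


@dataclass
class EmgRecording:
    """A multi-channel EMG record with event markers.

    ``signal`` has shape (channels, samples); ``events`` is a list of
    (onset_sample, ActionClass) marking action-window onsets, sorted
    ascending.
    """

    signal: np.ndarray
    sampling_rate: float
    channels: tuple[str, ...]
    events: list[tuple[int, ActionClass]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if self.signal.shape[0] != len(self.channels):
            raise ValueError("signal row count must match channel count")
        onsets = [int(s) for s, _ in self.events]
        if onsets != sorted(onsets):
            raise ValueError("events must be sorted by onset")
        for s, _ in self.events:
            if not 0 <= s < self.n_samples:
                raise ValueError(f"event onset {s} outside recording")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    def copy(self) -> "EmgRecording":
        return EmgRecording(
            self.signal.copy(),
            self.sampling_rate,
            tuple(self.channels),
            list(self.events),
            dict(self.meta),
        )


def _check_seed(seed: int) -> int:
    """Seeds must be non-negative integers (numpy BitGenerator contract)."""
    if not isinstance(seed, (int, np.integer)) or seed < 0:
        raise ValueError(f"seed must be a non-negative integer, got {seed!r}")
    return int(seed)


def _raised_cosine_envelope(n: int, fs: float, ramp_s: float = 0.1) -> np.ndarray:
    """Unit envelope with raised-cosine on/off ramps (default 100 ms)."""
    env = np.ones(n)
    n_ramp = int(round(ramp_s * fs))
    n_ramp = min(n_ramp, n // 2)
    if n_ramp > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] = ramp
        env[-n_ramp:] = ramp[::-1]
    return env


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                low: float, high: float) -> np.ndarray:
    """White Gaussian noise spectrally restricted to [low, high) Hz."""
    w = rng.standard_normal(n)
    spec = np.fft.rfft(w)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(f < low) | (f >= high)] = 0.0
    return np.fft.irfft(spec, n)


def synthesize_trial(
    profile: SpatialSpectralProfile,
    timeline: TrialTimeline | None = None,
    config: RecordingConfig | None = None,
    seed: int = 0,
) -> EmgRecording:
    """Synthesize one trial (default 3.5 s) for a single facial action.

    The action window carries band-shaped Gaussian noise whose per-band
    power matches the profile's band fractions exactly (spectral-domain
    shaping) and whose per-channel RMS is ``gain * action_rms``, ramped
    with a 100 ms raised-cosine envelope and added on top of the white
    baseline floor.  Preparation and break segments contain baseline
    noise only.  One event marker is placed at the action onset.
    Identical arguments and seed yield identical output.
    """
    timeline = timeline or TrialTimeline()
    config = config or RecordingConfig()
    rng = np.random.default_rng(_check_seed(seed))

    missing = [ch for ch in config.channels if ch not in profile.channel_gains]
    if missing:
        raise ValueError(
            f"profile has no gain for channel(s) {missing}; profile/config mismatch"
        )
    for low, high in profile.bands:
        if high > config.nyquist:
            raise ValueError(
                f"profile band {low}-{high} Hz exceeds Nyquist ({config.nyquist} Hz)"
            )

    fs = config.sampling_rate
    n_total = int(round(timeline.total_s * fs))
    n_prep = int(round(timeline.prep_s * fs))
    n_act = int(round(timeline.action_s * fs))
    if n_prep + n_act > n_total:
        raise ValueError("action window does not fit the trial; timeline mismatch")

    sig = rng.standard_normal((len(config.channels), n_total)) * profile.baseline_rms
    env = _raised_cosine_envelope(n_act, fs)

    for ci, ch in enumerate(config.channels):
        target_rms = profile.channel_gains[ch] * profile.action_rms
        if target_rms == 0:
            continue
        burst = np.zeros(n_act)
        for (low, high), frac in zip(profile.bands, profile.band_fractions):
            if frac <= 0:
                continue
            wb = _band_noise(rng, n_act, fs, low, high)
            s = wb.std()
            if s > 0:
                wb *= target_rms * math.sqrt(frac) / s
            burst += wb
        sig[ci, n_prep:n_prep + n_act] += burst * env

    return EmgRecording(
        signal=sig,
        sampling_rate=fs,
        channels=tuple(config.channels),
        events=[(n_prep, profile.action)],
        meta={"seed": int(seed), "action": profile.action.value},
    )


def inject_interference(
    rec: EmgRecording,
    freq: float = 50.0,
    amplitude: float = 1.0,
    seed: int = 0,
) -> EmgRecording:
    """Add a mains-style sinusoid (random phase per channel) to all channels."""
    nyq = rec.sampling_rate / 2.0
    if not 0 < freq < nyq:
        raise ValueError(
            f"interference frequency must lie in (0, Nyquist={nyq} Hz), got {freq}"
        )
    out = rec.copy()
    if amplitude == 0:
        return out
    rng = np.random.default_rng(_check_seed(seed))
    t = np.arange(rec.n_samples) / rec.sampling_rate
    phases = rng.uniform(0.0, 2.0 * np.pi, size=rec.n_channels)
    out.signal = out.signal + amplitude * np.sin(
        2.0 * np.pi * freq * t[None, :] + phases[:, None]
    )
    out.meta.setdefault("interference", []).append(
        {"freq": freq, "amplitude": amplitude}
    )
    return out


def synthesize_dataset(
    plan: SessionPlan | None = None,
    timeline: TrialTimeline | None = None,
    config: RecordingConfig | None = None,
    seed: int = 0,
    subject: SubjectProfile | None = None,
) -> tuple[list[EmgRecording], pd.DataFrame]:
    """Synthesize a full offline dataset: one recording per trial.

    Each session interleaves ``trials_per_action`` trials of each of the
    four actions in a seeded random order (24 trials per session at
    defaults; 240 trials in total).  Trial amplitude is jittered with a
    mean-one log-normal factor and 50 Hz interference is added when the
    subject's ``mains_amplitude`` is non-zero.

    Returns the list of trial recordings and a label table with columns
    ``trial``, ``session``, ``label`` (row order matches the list).
    """
    plan = plan or SessionPlan()
    timeline = timeline or TrialTimeline()
    config = config or RecordingConfig()
    subject = subject or SubjectProfile()
    ss = np.random.SeedSequence(_check_seed(seed))

    actions = list(ActionClass)
    sigma = math.sqrt(math.log(1.0 + subject.amplitude_jitter_cv ** 2))

    recordings: list[EmgRecording] = []
    rows: list[dict] = []
    trial_counter = 0
    for session in range(plan.n_sessions):
        order_rng = np.random.default_rng(ss.spawn(1)[0])
        session_actions = np.repeat(np.arange(len(actions)), plan.trials_per_action)
        order_rng.shuffle(session_actions)
        for ai in session_actions:
            action = actions[int(ai)]
            jit_child, trial_child, mains_child = ss.spawn(3)
            jitter_rng = np.random.default_rng(jit_child)
            factor = jitter_rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma)
            profile = replace(
                subject.profile_for(action),
                action_rms=subject.action_rms * factor,
            )
            rec = synthesize_trial(
                profile,
                timeline,
                config,
                seed=int(trial_child.generate_state(1, np.uint32)[0]),
            )
            if subject.mains_amplitude > 0:
                rec = inject_interference(
                    rec,
                    freq=50.0,
                    amplitude=subject.mains_amplitude,
                    seed=int(mains_child.generate_state(1, np.uint32)[0]),
                )
            rec.meta.update({"trial": trial_counter, "session": session})
            recordings.append(rec)
            rows.append(
                {"trial": trial_counter, "session": session, "label": action.value}
            )
            trial_counter += 1

    labels = pd.DataFrame(rows, columns=["trial", "session", "label"])
    return recordings, labels
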