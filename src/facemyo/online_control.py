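"""Online decision loop and 2-DOF prosthesis state machine.

In the online protocol the user holds one facial action for a 1.5 s
decision window; at the window's end the decoder classifies the window
and the recognized action is mapped to a prosthesis command:

    raising brow   -> hand open
    furrowing brow -> hand close
    left smirking  -> wrist rotate right
    right smirking -> wrist rotate left

The prosthesis keeps its previous gesture until a new command arrives;
wrist rotation is modelled as discrete saturating steps within a bounded
orientation range.  Online filtering is causal single-pass (a real-time
loop cannot look ahead), unlike the offline zero-phase chain.

The simulated drinking task presets an action sequence (open the hand,
close it around the cup, tip the wrist right to drink, return left),
synthesizes the cued EMG stream, and scores the decoder's decisions
against the preset.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

from .features import BandSet, FeatureScaler, fft_band_energy
from .preprocess import Epoch, apply_bandpass, apply_notch
from .lmbp import LabelCodec, NetworkWeights, forward
from .synth_emg import (
    ActionClass,
    EmgRecording,
    RecordingConfig,
    SubjectProfile,
    TrialTimeline,
    inject_interference,
    synthesize_trial,
)

__all__ = [
    "Command",
    "ProsthesisState",
    "Decision",
    "OnlineResult",
    "TrainedDecoder",
    "RandomDecoder",
    "action_to_command",
    "step_prosthesis",
    "stream_decide",
    "run_drinking_task",
    "DEFAULT_DRINKING_SEQUENCE",
]


class Command(enum.Enum):
    HAND_OPEN = "hand_open"
    HAND_CLOSE = "hand_close"
    WRIST_ROTATE_RIGHT = "wrist_rotate_right"
    WRIST_ROTATE_LEFT = "wrist_rotate_left"


_ACTION_TO_COMMAND = {
    ActionClass.RAISING_BROW: Command.HAND_OPEN,
    ActionClass.FURROWING_BROW: Command.HAND_CLOSE,
    ActionClass.LEFT_SMIRKING: Command.WRIST_ROTATE_RIGHT,
    ActionClass.RIGHT_SMIRKING: Command.WRIST_ROTATE_LEFT,
}

#: Drinking-water task preset: open the hand, grasp the cup, tip right to
#: drink, rotate back left.
DEFAULT_DRINKING_SEQUENCE = (
    ActionClass.RAISING_BROW,
    ActionClass.FURROWING_BROW,
    ActionClass.LEFT_SMIRKING,
    ActionClass.RIGHT_SMIRKING,
)


def action_to_command(action: ActionClass | str) -> Command:
    """Map a recognized facial action to its prosthesis command."""
    return _ACTION_TO_COMMAND[ActionClass.coerce(action)]


@dataclass(frozen=True)
class ProsthesisState:
    """Hand open/closed plus discrete wrist orientation (saturating)."""

    hand: str = "open"                 # "open" | "closed"
    wrist: int = 0
    wrist_min: int = -2
    wrist_max: int = 2

    def __post_init__(self) -> None:
        if self.hand not in ("open", "closed"):
            raise ValueError("hand must be 'open' or 'closed'")
        if not self.wrist_min <= self.wrist <= self.wrist_max:
            raise ValueError("wrist orientation out of bounds")


def step_prosthesis(state: ProsthesisState, cmd: Command | None) -> ProsthesisState:
    """Advance the state machine by one command (None leaves it unchanged).

    Hand commands set the hand field (idempotent); wrist commands move the
    orientation one step, right = +1, saturating at the bounds.
    """
    if cmd is None:
        return state
    if cmd is Command.HAND_OPEN:
        return replace(state, hand="open")
    if cmd is Command.HAND_CLOSE:
        return replace(state, hand="closed")
    if cmd is Command.WRIST_ROTATE_RIGHT:
        return replace(state, wrist=min(state.wrist + 1, state.wrist_max))
    if cmd is Command.WRIST_ROTATE_LEFT:
        return replace(state, wrist=max(state.wrist - 1, state.wrist_min))
    raise ValueError(f"unknown command {cmd!r}")


@dataclass
class Decision:
    """One decision-window classification."""

    index: int
    onset_sample: int
    predicted: ActionClass
    outputs: np.ndarray
    low_confidence: bool


class TrainedDecoder:
    """Scaler + trained network bundled behind a predict interface."""

    def __init__(self, net: NetworkWeights, scaler: FeatureScaler,
                 bands: BandSet | None = None) -> None:
        self.net = net
        self.scaler = scaler
        self.bands = bands or BandSet()

    def decide(self, features: np.ndarray) -> tuple[ActionClass, np.ndarray]:
        x = self.scaler.transform(features[None, :])
        outputs, _ = forward(self.net, x)
        bits = (outputs[0] >= 0.5).astype(int)
        return LabelCodec.decode_bits(bits), outputs[0]


class RandomDecoder:
    """Uniform-random stub decoder (chance-level reference)."""

    def __init__(self, seed: int = 0) -> None:
        self._rng = np.random.default_rng(seed)
        self.bands = BandSet()

    def decide(self, features: np.ndarray) -> tuple[ActionClass, np.ndarray]:
        action = self._rng.choice(list(ActionClass))
        return action, np.asarray(LabelCodec.TARGETS[action], dtype=float)


def stream_decide(
    stream: EmgRecording,
    decoder,
    window_s: float = 1.5,
    low_confidence_margin: float = 0.1,
) -> list[Decision]:
    """Classify the cued decision windows of an online stream.

    The stream is causally filtered (single-pass band-pass + notch), cut
    at the cued window onsets (the stream's event markers), featurized
    with the FFT band energies, and classified; one decision is emitted
    at the end of each window.  A decision is flagged low-confidence when
    every output unit lies within ``low_confidence_margin`` of the 0.5
    threshold.
    """
    n_win = int(round(window_s * stream.sampling_rate))
    if stream.n_samples < n_win:
        raise ValueError(
            f"stream of {stream.n_samples} samples is shorter than one "
            f"{n_win}-sample decision window"
        )
    filtered = apply_notch(
        apply_bandpass(stream, zero_phase=False), zero_phase=False
    )
    decisions: list[Decision] = []
    for i, (onset, _) in enumerate(stream.events):
        if onset + n_win > stream.n_samples:
            raise ValueError(f"decision window {i} exceeds the stream")
        epoch = Epoch(
            signal=filtered.signal[:, onset:onset + n_win],
            label=stream.events[i][1],
            sampling_rate=stream.sampling_rate,
            channels=tuple(stream.channels),
        )
        feats = fft_band_energy(epoch, getattr(decoder, "bands", None))
        predicted, outputs = decoder.decide(feats)
        # degenerate (zero-energy) windows or outputs hovering at the 0.5
        # threshold are flagged low-confidence
        low_conf = bool(
            feats.sum() <= 0.0
            or np.all(np.abs(outputs - 0.5) < low_confidence_margin)
        )
        decisions.append(
            Decision(
                index=i,
                onset_sample=onset,
                predicted=predicted,
                outputs=np.asarray(outputs, dtype=float),
                low_confidence=low_conf,
            )
        )
    return decisions


@dataclass
class OnlineResult:
    """Scored online session."""

    truths: list[ActionClass]
    decisions: list[Decision]
    commands: list[Command]
    states: list[ProsthesisState]       # trajectory after each command
    accuracy: float                      # percent correct decisions
    completed: bool                      # trajectory matches the cued one

    @property
    def n_decisions(self) -> int:
        return len(self.decisions)


def synthesize_stream(
    subject: SubjectProfile,
    sequence,
    seed: int = 0,
    timeline: TrialTimeline | None = None,
    config: RecordingConfig | None = None,
) -> EmgRecording:
    """Concatenate cued trials for an action sequence into one stream."""
    timeline = timeline or TrialTimeline()
    config = config or RecordingConfig()
    ss = np.random.SeedSequence(seed)
    chunks = []
    events: list[tuple[int, ActionClass]] = []
    offset = 0
    for action in sequence:
        trial_child, mains_child = ss.spawn(2)
        rec = synthesize_trial(
            subject.profile_for(action),
            timeline,
            config,
            seed=int(trial_child.generate_state(1, np.uint32)[0]),
        )
        if subject.mains_amplitude > 0:
            rec = inject_interference(
                rec, 50.0, subject.mains_amplitude,
                seed=int(mains_child.generate_state(1, np.uint32)[0]),
            )
        chunks.append(rec.signal)
        events.append((offset + rec.events[0][0], action))
        offset += rec.n_samples
    return EmgRecording(
        signal=np.concatenate(chunks, axis=1),
        sampling_rate=config.sampling_rate,
        channels=tuple(config.channels),
        events=events,
    )


def run_drinking_task(
    decoder,
    subject: SubjectProfile | None = None,
    sequence=DEFAULT_DRINKING_SEQUENCE,
    seed: int = 0,
    timeline: TrialTimeline | None = None,
    config: RecordingConfig | None = None,
) -> OnlineResult:
    """Simulate one cued online session of the drinking task.

    Synthesizes the cued EMG stream for the preset action sequence, runs
    the decision loop, maps decisions to commands, advances the
    prosthesis state machine, and scores accuracy against the preset.
    ``completed`` is true when the driven state trajectory matches the
    trajectory the cued sequence itself would produce.
    """
    sequence = [ActionClass.coerce(a) for a in sequence]
    if not sequence:
        raise ValueError("action sequence must be non-empty")
    subject = subject or SubjectProfile()
    stream = synthesize_stream(subject, sequence, seed=seed,
                               timeline=timeline, config=config)
    decisions = stream_decide(stream, decoder)

    state = ProsthesisState()
    states: list[ProsthesisState] = []
    commands: list[Command] = []
    for d in decisions:
        cmd = action_to_command(d.predicted)
        state = step_prosthesis(state, cmd)
        commands.append(cmd)
        states.append(state)

    ref_state = ProsthesisState()
    ref_states = []
    for a in sequence:
        ref_state = step_prosthesis(ref_state, action_to_command(a))
        ref_states.append(ref_state)

    correct = sum(d.predicted is t for d, t in zip(decisions, sequence))
    accuracy = 100.0 * correct / len(sequence)
    return OnlineResult(
        truths=sequence,
        decisions=decisions,
        commands=commands,
        states=states,
        accuracy=accuracy,
        completed=states == ref_states,
    )
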