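"""Synthetic multi-muscle surface-EMG generator with known synergy structure.

Emulates a multi-directional isometric force task: each trial has a rest
phase followed by a static hold phase, a 3-D force-target direction and a
repetition index.  Muscle activity during the hold phase is organised by a
small set of muscle synergies with cosine-tuned, direction-dependent
activation, and muscles within a synergy share band-limited common drives so
that intermuscular coherence carries a known spectral signature.

The generator is the ground-truth oracle for every downstream stage: the
synergy weight matrix, the preferred directions, and the drive-band
assignment are stored alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy import signal

__all__ = [
    "CANONICAL_BANDS",
    "DEFAULT_MUSCLES",
    "SimulationConfig",
    "GroundTruth",
    "TrialRecording",
    "ParticipantData",
    "Dataset",
    "band_limited_drive",
    "cosine_tuned_activation",
    "fibonacci_sphere",
    "generate_trial",
    "generate_participant",
    "generate_dataset",
]

#: Mean subject-specific layer boundaries reported for healthy adults, used as
#: the default edges of the generative common-drive bands (Hz).
CANONICAL_BANDS: tuple[tuple[float, float], ...] = (
    (1.0, 8.7),
    (8.7, 16.9),
    (16.9, 25.7),
    (25.7, 35.8),
    (35.8, 48.6),
    (48.6, 60.0),
)

#: Upper-limb muscle set of the emulated recording montage (17 muscles acting
#: on shoulder and elbow).
DEFAULT_MUSCLES: tuple[str, ...] = (
    "TeresMaj", "InfraSp", "LatDorsi", "TrapInf", "TrapMid", "TrapSup",
    "BracRad", "BicLong", "BicShort", "TriLat", "TriLong", "TriMed",
    "DeltA", "DeltM", "DeltP", "PectClav", "PectStern",
)


def fibonacci_sphere(n: int) -> np.ndarray:
    """Return ``n`` approximately uniformly distributed unit vectors (n, 3)."""
    if n < 1:
        raise ValueError("need at least one direction")
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Experimental-design and signal-model constants of one synthetic study.

    Defaults reproduce the emulated study's design: 8 participants, 17
    muscles, 6 synergies, 32 force directions x 5 repetitions at 1 kHz, 3-s
    rest and 3-s hold phases, and one band-limited common drive per canonical
    frequency band.

    ``drive_gain`` (kappa in [0, 1]) sets the share of each muscle's
    hold-phase carrier taken by the synergy's shared band drives, the rest
    being muscle-specific broadband noise scaled by ``noise_gain``.
    """

    n_participants: int = 8
    n_muscles: int = 17
    n_synergies: int = 6
    directions: np.ndarray = field(default_factory=lambda: fibonacci_sphere(32))
    n_repetitions: int = 5
    fs: float = 1000.0
    rest_duration: float = 3.0
    hold_duration: float = 3.0
    drive_bands: tuple[tuple[float, float], ...] = CANONICAL_BANDS
    drive_gain: float = 0.6
    noise_gain: float = 1.0
    #: synergy index -> band indices carrying that synergy's common drive;
    #: None assigns band ``s % len(drive_bands)`` to synergy ``s``.
    band_assignment: tuple[tuple[int, ...], ...] | None = None
    #: band indices whose drive is shared by ALL muscles (synergy-independent
    #: common input; produces coherence without a pair-type difference).
    shared_bands: tuple[int, ...] = ()
    #: baseline + gain of the cosine directional tuning of synergy activations;
    #: the negative default baseline acts as a recruitment threshold, so each
    #: synergy is recruited only within ~77 degrees of its preferred direction
    activation_baseline: float = -0.4
    activation_gain: float = 1.4
    #: rest-phase (and hold-phase additive floor) noise amplitude, as a
    #: fraction of the mean hold-phase envelope
    rest_noise_level: float = 0.05
    mvc_scale: np.ndarray | None = None
    muscles: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "directions", np.atleast_2d(np.asarray(self.directions, float)))

    def validate(self) -> None:
        if self.n_muscles < 2 or self.n_synergies < 1:
            raise ValueError("need at least 2 muscles and 1 synergy")
        if self.n_synergies > self.n_muscles:
            raise ValueError("more synergies than muscles")
        if not 0.0 <= self.drive_gain <= 1.0:
            raise ValueError(f"drive_gain must be in [0, 1], got {self.drive_gain}")
        norms = np.linalg.norm(self.directions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("directions must be unit vectors")
        prev_hi = 0.0
        for lo, hi in self.drive_bands:
            if not (0.0 < lo < hi):
                raise ValueError(f"bad drive band ({lo}, {hi})")
            if lo < prev_hi:
                raise ValueError("drive bands must be disjoint and ordered")
            if lo < 1.0 or hi > 60.0:
                raise ValueError("drive bands must lie within [1, 60] Hz")
            prev_hi = hi
        if self.fs < 2.0 * max(hi for _, hi in self.drive_bands):
            raise ValueError("sampling rate below twice the highest band edge")
        for idx in self.shared_bands:
            if not 0 <= idx < len(self.drive_bands):
                raise ValueError(f"shared band index {idx} out of range")
        if self.band_assignment is not None:
            if len(self.band_assignment) != self.n_synergies:
                raise ValueError("band_assignment must list bands per synergy")
            for bands in self.band_assignment:
                for idx in bands:
                    if not 0 <= idx < len(self.drive_bands):
                        raise ValueError(f"band index {idx} out of range")
        if self.muscles is not None and len(self.muscles) != self.n_muscles:
            raise ValueError("muscle label count does not match n_muscles")
        if self.mvc_scale is not None:
            mvc = np.asarray(self.mvc_scale, float)
            if mvc.shape != (self.n_muscles,) or np.any(mvc <= 0):
                raise ValueError("mvc_scale must be positive, one value per muscle")

    @property
    def muscle_names(self) -> tuple[str, ...]:
        if self.muscles is not None:
            return tuple(self.muscles)
        if self.n_muscles == len(DEFAULT_MUSCLES):
            return DEFAULT_MUSCLES
        return tuple(f"M{i + 1:02d}" for i in range(self.n_muscles))

    @property
    def n_rest(self) -> int:
        return int(round(self.rest_duration * self.fs))

    @property
    def n_hold(self) -> int:
        return int(round(self.hold_duration * self.fs))

    @property
    def n_trials_per_participant(self) -> int:
        return len(self.directions) * self.n_repetitions

    def resolved_band_assignment(self) -> tuple[tuple[int, ...], ...]:
        if self.band_assignment is not None:
            return tuple(tuple(b) for b in self.band_assignment)
        nb = len(self.drive_bands)
        return tuple((s % nb,) for s in range(self.n_synergies))


@dataclass
class GroundTruth:
    """Generative parameters of one participant (the recovery oracle)."""

    W_true: np.ndarray                      # (muscles, synergies), nonnegative
    preferred_directions: np.ndarray        # (synergies, 3), unit rows
    drive_band_assignment: tuple[tuple[int, ...], ...]
    shared_bands: tuple[int, ...]
    dominant_synergy: np.ndarray            # (muscles,) int
    mvc: np.ndarray                         # (muscles,) positive scalars
    seed: int


@dataclass
class TrialRecording:
    """Raw multi-muscle EMG of one trial plus its phase boundaries."""

    participant_id: int
    trial_id: int
    direction: np.ndarray       # 3-D unit vector
    repetition: int
    emg: np.ndarray             # (samples, muscles), zero-mean raw signal
    phase_bounds: tuple[int, int, int]   # (rest start, hold start, end)
    fs: float
    direction_index: int = -1

    @property
    def rest(self) -> np.ndarray:
        a, b, _ = self.phase_bounds
        return self.emg[a:b]

    @property
    def hold(self) -> np.ndarray:
        _, b, c = self.phase_bounds
        return self.emg[b:c]


@dataclass
class ParticipantData:
    participant_id: int
    trials: list[TrialRecording]
    ground_truth: GroundTruth
    muscles: tuple[str, ...]
    fs: float


@dataclass
class Dataset:
    config: SimulationConfig
    participants: list[ParticipantData]

    @property
    def n_trials(self) -> int:
        return sum(len(p.trials) for p in self.participants)


def band_limited_drive(band: tuple[float, float], duration: float, fs: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-variance noise with power concentrated in ``band``.

    White Gaussian noise passed through a zero-phase 4th-order Butterworth
    band-pass (applied forward-backward), with generous padding so the
    returned stretch is stationary.
    """
    lo, hi = band
    if not (0.0 < lo < hi < fs / 2.0):
        raise ValueError(
            f"band ({lo}, {hi}) Hz must lie strictly inside (0, {fs / 2}) Hz")
    n = int(round(duration * fs))
    pad = max(int(2.0 * fs / lo), 500)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n + 2 * pad))[pad:pad + n]
    x = x - x.mean()
    sd = x.std()
    if sd == 0.0:
        raise ValueError("degenerate drive: filtered noise has zero variance")
    return x / sd


def cosine_tuned_activation(direction: np.ndarray, preferred: np.ndarray,
                            baseline: float, gain: float,
                            normalize: bool = False) -> float:
    """Rectified cosine tuning: ``max(0, baseline + gain * <d, p>)``."""
    d = np.asarray(direction, float)
    p = np.asarray(preferred, float)
    if gain < 0:
        raise ValueError("gain must be nonnegative")
    for name, v in (("direction", d), ("preferred", p)):
        nrm = np.linalg.norm(v)
        if abs(nrm - 1.0) > 1e-6:
            if not normalize:
                raise ValueError(f"{name} vector is not unit-norm (|v|={nrm:.4f})")
            if nrm == 0:
                raise ValueError(f"{name} vector is zero")
            v /= nrm
    return float(max(0.0, baseline + gain * float(d @ p)))


def _make_ground_truth(config: SimulationConfig, participant_id: int,
                       rng: np.random.Generator) -> GroundTruth:
    m, s = config.n_muscles, config.n_synergies
    dominant = np.arange(m) % s
    W = rng.uniform(0.0, 0.2, size=(m, s))
    W[np.arange(m), dominant] = 1.0
    # preferred directions: well spread, with a small participant-specific twist
    base = fibonacci_sphere(s)
    jitter = rng.normal(scale=0.05, size=(s, 3))
    pref = base + jitter
    pref /= np.linalg.norm(pref, axis=1, keepdims=True)
    if config.mvc_scale is not None:
        mvc = np.asarray(config.mvc_scale, float).copy()
    else:
        mvc = rng.uniform(0.5, 1.5, size=m)
    return GroundTruth(
        W_true=W,
        preferred_directions=pref,
        drive_band_assignment=config.resolved_band_assignment(),
        shared_bands=tuple(config.shared_bands),
        dominant_synergy=dominant,
        mvc=mvc,
        seed=participant_id,
    )


def _synergy_activations(config: SimulationConfig, truth: GroundTruth,
                         direction: np.ndarray) -> np.ndarray:
    return np.array([
        cosine_tuned_activation(direction, truth.preferred_directions[s],
                                config.activation_baseline, config.activation_gain)
        for s in range(config.n_synergies)
    ])


def mean_envelope(config: SimulationConfig, truth: GroundTruth) -> float:
    """Mean hold-phase envelope over muscles and target directions."""
    amps = [truth.W_true @ _synergy_activations(config, truth, d)
            for d in config.directions]
    return float(np.mean(amps))


def generate_trial(config: SimulationConfig, truth: GroundTruth,
                   direction: np.ndarray, repetition: int,
                   rng: np.random.Generator, participant_id: int = 0,
                   trial_id: int = 0, direction_index: int = -1) -> TrialRecording:
    """Synthesize the raw EMG of one trial.

    Hold-phase EMG of muscle ``m`` is an envelope ``a_m = sum_s W[m,s] c_s``
    modulating a unit-variance carrier that mixes the synergy's shared
    band-limited drives (weight kappa) with muscle-specific broadband noise
    (weight (1-kappa) * noise_gain).  A low-amplitude broadband floor, equal
    to the rest-phase noise, is present throughout.
    """
    config.validate()
    n_rest, n_hold = config.n_rest, config.n_hold
    m = config.n_muscles
    c = _synergy_activations(config, truth, direction)
    amp = truth.W_true @ c                          # (muscles,)
    floor = config.rest_noise_level * mean_envelope(config, truth)

    # one drive realization per band per trial, shared within the trial
    needed = sorted({b for bands in truth.drive_band_assignment for b in bands}
                    | set(truth.shared_bands))
    drives = {b: band_limited_drive(config.drive_bands[b], config.hold_duration,
                                    config.fs, rng)
              for b in needed}

    kappa = config.drive_gain
    wn = (1.0 - kappa) * config.noise_gain
    norm = np.hypot(kappa, wn)
    emg = np.empty((n_rest + n_hold, m))
    for i in range(m):
        bands = tuple(truth.drive_band_assignment[truth.dominant_synergy[i]]) \
            + tuple(truth.shared_bands)
        if bands and kappa > 0:
            D = np.sum([drives[b] for b in bands], axis=0) / np.sqrt(len(bands))
        else:
            D = 0.0
        carrier = kappa * D + wn * rng.standard_normal(n_hold)
        if norm > 0:
            carrier = carrier / norm
        hold = amp[i] * carrier + floor * rng.standard_normal(n_hold)
        rest = floor * rng.standard_normal(n_rest)
        emg[:n_rest, i] = truth.mvc[i] * rest
        emg[n_rest:, i] = truth.mvc[i] * hold
    return TrialRecording(
        participant_id=participant_id, trial_id=trial_id,
        direction=np.asarray(direction, float), repetition=repetition,
        emg=emg, phase_bounds=(0, n_rest, n_rest + n_hold), fs=config.fs,
        direction_index=direction_index,
    )


def generate_participant(config: SimulationConfig, participant_id: int,
                         seed_seq: np.random.SeedSequence) -> ParticipantData:
    truth_rng = np.random.default_rng(seed_seq)
    truth = _make_ground_truth(config, participant_id, truth_rng)
    trial_seeds = seed_seq.spawn(config.n_trials_per_participant)
    trials = []
    tid = 0
    for d_idx, direction in enumerate(config.directions):
        for rep in range(1, config.n_repetitions + 1):
            rng = np.random.default_rng(trial_seeds[tid])
            trials.append(generate_trial(
                config, truth, direction, rep, rng,
                participant_id=participant_id, trial_id=tid,
                direction_index=d_idx))
            tid += 1
    return ParticipantData(participant_id=participant_id, trials=trials,
                           ground_truth=truth, muscles=config.muscle_names,
                           fs=config.fs)


def generate_dataset(config: SimulationConfig) -> Dataset:
    """Generate the full multi-participant dataset, reproducibly from the seed."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    part_seeds = root.spawn(config.n_participants)
    participants = [
        generate_participant(config, pid, part_seeds[pid])
        for pid in range(config.n_participants)
    ]
    return Dataset(config=config, participants=participants)
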