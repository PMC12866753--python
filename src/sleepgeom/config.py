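"""Session configuration and seeded random-stream management."""

from __future__ import annotations

import zlib
from dataclasses import dataclass, fields

import numpy as np

#: canonical sound-category labels, 6 groups of 10 sounds (sound_id // 10)
SOUND_CATEGORIES = ("tone", "chirp", "am_ramp", "am_sine", "complex", "noise")


def stream(seed: int, name: str) -> np.random.Generator:
    """Return an independent, named random stream derived from one global seed.

    Streams with different names are statistically independent, so pipeline
    stages can be re-run in isolation without perturbing each other.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass(frozen=True)
class SessionConfig:
    """Parameters of a synthetic imaging session.

    Defaults follow the study protocol: 60 sounds presented in randomized
    order inside 2 min stimulation blocks alternating with silence blocks,
    ~43 ms imaging frames, 500 ms sounds with a 2 s inter-sound interval.
    """

    n_neurons: int = 300
    n_sounds: int = 60
    presentations_per_sound_per_state: int = 20
    frame_rate: float = 23.26
    sound_duration: float = 0.5
    isi: float = 2.0
    block_duration: float = 120.0

    # state-dependent multiplicative response gain
    wake_gain_mean: float = 1.0
    nrem_gain_scale: float = 0.5
    gate_prob_nrem: float = 0.17
    gate_prob_wake: float = 0.078
    gain_sd: float = 0.0          # coordinated lognormal trial-gain jitter (off by default)

    # spontaneous dynamics
    spont_rank: int = 10
    spont_amp: float = 5.0        # per-component latent amplitude (rate units)
    burst_rate: float = 0.2       # population bursts per second, riding on latent 1
    burst_amp: float = 4.0
    evoked_overlap: float = 0.2   # cosine of tuning directions with span(spont loadings)

    # rates and noise
    baseline_rate: float = 2.0    # events/s
    tuning_mean: float = 5.0      # mean evoked rate of tuned responses (events/s)
    tuning_mean_sd: float = 2.0   # across-neuron spread of overall responsiveness
    tuning_sd: float = 3.0        # per-neuron spread of tuning across sounds
    noise_sd: float = 1.0         # independent per-frame rate noise (events/s)
    quantize: bool = False        # round rectified counts to integers (see docs)

    # session composition
    states: tuple[str, ...] = ("wake", "nrem")
    n_silence_blocks: int | None = None   # default: as many as sound blocks
    n_rem_blocks: int = 0                 # extra silence blocks scored as REM
    spindle_rate: float = 0.05            # spindles per second of NREM
    max_duration: float | None = None     # reject schedules longer than this (s)
    seed: int = 0

    @property
    def frame_duration(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def onset_spacing(self) -> float:
        """Onset-to-onset spacing of consecutive presentations."""
        return self.sound_duration + self.isi

    @property
    def trials_per_block(self) -> int:
        return int(self.block_duration // self.onset_spacing)

    def validate(self) -> None:
        for name in ("n_neurons", "n_sounds", "presentations_per_sound_per_state"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("gate_prob_nrem", "gate_prob_wake"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.evoked_overlap <= 1.0:
            raise ValueError("evoked_overlap must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.spont_rank < 0:
            raise ValueError("spont_rank must be >= 0")
        if self.spont_rank > self.n_neurons:
            raise ValueError("spont_rank cannot exceed n_neurons")
        if self.frame_rate <= 0 or self.sound_duration <= 0 or self.block_duration <= 0:
            raise ValueError("frame_rate, sound_duration and block_duration must be > 0")
        if self.trials_per_block < 1:
            raise ValueError(
                "block_duration too short to fit a single presentation "
                f"(needs >= {self.onset_spacing} s)"
            )
        unknown = set(self.states) - {"wake", "nrem"}
        if unknown:
            raise ValueError(f"unsupported states: {sorted(unknown)}")

    def replace(self, **kwargs) -> "SessionConfig":
        values = {f.name: getattr(self, f.name) for f in fields(self)}
        values.update(kwargs)
        return SessionConfig(**values)
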