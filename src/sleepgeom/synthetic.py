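"""Synthetic session generator with full ground truth.

Sessions emulate the statistical structure the downstream analyses assume:
alternating silence / sound-presentation blocks, state-dependent
multiplicative response gain with a zero-gain "gated" mixture component,
low-rank autocorrelated spontaneous dynamics with population bursts, and
physiological signals (bimodal EMG power, hippocampal theta/delta,
NREM sigma spindles, olfactory-bulb gamma).

Evoked response model for a presentation of sound ``s`` in state ``st``::

    rate(neuron, frame) = baseline + gain * tuning[:, s]
                          + spont_amp * loadings @ latent(frame)
                          + noise_sd * eps

with ``gain = 0`` on gated trials and ``gain = state_scale`` otherwise
(optionally jittered by a coordinated lognormal factor). Rates are rectified
at zero; the stored raster holds expected event counts per frame
(``rate * frame_duration``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SOUND_CATEGORIES, SessionConfig, stream
from .signal import Raster, bandpass, frames_in_window

PHYSIO_RATE = 1250.0

# state -> (EMG amplitude, OB gamma amplitude, HPC delta amp, HPC theta amp)
_STATE_AMPS = {
    "wake": dict(emg=5.0, ob=5.0, delta=0.5, theta=1.0),
    "nrem": dict(emg=1.0, ob=1.0, delta=4.0, theta=0.25),
    "rem": dict(emg=1.0, ob=1.0, delta=0.25, theta=6.0),
}


@dataclass
class SessionTruth:
    """Generative ground truth of one synthetic session."""

    tuning: np.ndarray              # (n_neurons, n_sounds), non-negative, events/s
    trial_gain: np.ndarray          # (n_trials,)
    gated: np.ndarray               # (n_trials,) bool
    state_sequence: np.ndarray      # per-frame state label
    spont_loadings: np.ndarray      # (n_neurons, spont_rank), orthonormal columns
    spindle_intervals: list[tuple[float, float]]
    baseline_rate: float
    block_table: pd.DataFrame       # columns: start_s, end_s, kind, state
    frame_rate: float
    seed: int

    def __post_init__(self) -> None:
        if np.any(self.trial_gain[self.gated] != 0):
            raise ValueError("gated trials must have zero gain")


@dataclass
class PhysioRecord:
    """Multi-channel physiological signals at a common sampling rate."""

    channels: dict[str, np.ndarray]
    rate: float

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    @property
    def duration(self) -> float:
        n = len(next(iter(self.channels.values())))
        return n / self.rate


def _build_schedule(config: SessionConfig, rng: np.random.Generator):
    """Lay out blocks and presentations; returns (block_table, trial_table)."""
    per_block = config.trials_per_block
    blocks: list[dict] = []
    trials: list[dict] = []
    t = 0.0

    n_trials_state = config.n_sounds * config.presentations_per_sound_per_state
    n_sound_blocks = int(np.ceil(n_trials_state / per_block))
    n_silence = config.n_silence_blocks
    if n_silence is None:
        n_silence = n_sound_blocks

    for state in config.states:
        sounds = np.repeat(
            np.arange(config.n_sounds), config.presentations_per_sound_per_state
        )
        rng.shuffle(sounds)
        chunks = [sounds[i:i + per_block] for i in range(0, len(sounds), per_block)]
        silence_left = n_silence
        # extra REM-scored silence blocks live inside the sleep portion
        rem_left = config.n_rem_blocks if state == "nrem" else 0
        for i, chunk in enumerate(chunks):
            if silence_left > 0:
                blocks.append(dict(start_s=t, end_s=t + config.block_duration,
                                   kind="silence", state=state))
                t += config.block_duration
                silence_left -= 1
            if rem_left > 0:
                blocks.append(dict(start_s=t, end_s=t + config.block_duration,
                                   kind="silence", state="rem"))
                t += config.block_duration
                rem_left -= 1
            blocks.append(dict(start_s=t, end_s=t + config.block_duration,
                               kind="sound", state=state))
            for j, s in enumerate(chunk):
                onset = t + j * config.onset_spacing
                trials.append(dict(
                    sound_id=int(s),
                    category=SOUND_CATEGORIES[int(s) * len(SOUND_CATEGORIES) // config.n_sounds],
                    intensity_db=60.0 if s % 2 == 0 else 70.0,
                    onset_s=onset,
                    duration_s=config.sound_duration,
                    state=state,
                ))
            t += config.block_duration
        while silence_left > 0 or rem_left > 0:
            st = "rem" if rem_left > 0 else state
            blocks.append(dict(start_s=t, end_s=t + config.block_duration,
                               kind="silence", state=st))
            t += config.block_duration
            if rem_left > 0:
                rem_left -= 1
            else:
                silence_left -= 1

    if config.max_duration is not None and t > config.max_duration:
        raise ValueError(
            f"schedule of {t:.0f} s exceeds max_duration={config.max_duration:.0f} s; "
            "reduce presentations_per_sound_per_state or n_sounds"
        )

    block_table = pd.DataFrame(blocks)
    trial_table = pd.DataFrame(trials).sort_values("onset_s").reset_index(drop=True)
    trial_table.insert(0, "trial_id", np.arange(len(trial_table)))
    return block_table, trial_table


def _make_tuning(config: SessionConfig, loadings: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n, s = config.n_neurons, config.n_sounds
    if config.tuning_mean_sd > 0:
        shape = (config.tuning_mean / config.tuning_mean_sd) ** 2
        scale = config.tuning_mean_sd**2 / config.tuning_mean
        mean_level = rng.gamma(shape=shape, scale=scale, size=n)
    else:
        mean_level = np.full(n, config.tuning_mean)
    alpha = config.evoked_overlap
    directions = np.empty((n, s))
    for j in range(s):
        if loadings.shape[1] > 0:
            c = rng.standard_normal(loadings.shape[1])
            d_in = loadings @ c
            d_in /= np.linalg.norm(d_in)
            g = rng.standard_normal(n)
            d_out = g - loadings @ (loadings.T @ g)
            d_out /= np.linalg.norm(d_out)
            directions[:, j] = alpha * d_in + np.sqrt(1.0 - alpha**2) * d_out
        else:
            g = rng.standard_normal(n)
            directions[:, j] = g / np.linalg.norm(g)
    tuning = mean_level[:, None] + config.tuning_sd * np.sqrt(n) * directions
    return np.clip(tuning, 0.0, None)


def _latent_series(config: SessionConfig, n_frames: int, rng: np.random.Generator) -> np.ndarray:
    """AR(1) latents (unit stationary variance) with bursts on the first stream."""
    r = config.spont_rank
    if r == 0:
        return np.zeros((0, n_frames))
    phi = 0.9
    z = np.zeros((r, n_frames))
    innov = rng.standard_normal((r, n_frames)) * np.sqrt(1 - phi**2)
    z[:, 0] = rng.standard_normal(r)
    for t in range(1, n_frames):
        z[:, t] = phi * z[:, t - 1] + innov[:, t]
    if config.burst_rate > 0 and config.burst_amp > 0:
        duration = n_frames / config.frame_rate
        n_bursts = rng.poisson(config.burst_rate * duration)
        if n_bursts > 0:
            train = np.zeros(n_frames)
            idx = rng.integers(0, n_frames, size=n_bursts)
            np.add.at(train, idx, config.burst_amp)
            tau_frames = 0.15 * config.frame_rate
            k = np.exp(-np.arange(int(4 * tau_frames) + 1) / tau_frames)
            z[0] += np.convolve(train, k)[:n_frames]
    return z


def _draw_spindles(config: SessionConfig, block_table: pd.DataFrame,
                   rng: np.random.Generator) -> list[tuple[float, float]]:
    intervals: list[tuple[float, float]] = []
    nrem_blocks = block_table[block_table.state == "nrem"]
    for _, blk in nrem_blocks.iterrows():
        span = blk.end_s - blk.start_s
        n = rng.poisson(config.spindle_rate * span)
        t = blk.start_s + 1.0
        for _ in range(n):
            gap = rng.exponential(max(span / max(n, 1), 2.0))
            dur = rng.uniform(0.8, 2.0)
            start = t + gap
            if start + dur > blk.end_s - 1.0:
                break
            intervals.append((float(start), float(start + dur)))
            t = start + dur + 0.3   # keep events separable (> 200 ms apart)
    return intervals


def generate_session(config: SessionConfig) -> tuple[Raster, pd.DataFrame, SessionTruth]:
    """Generate a full synthetic session: raster, trial table and ground truth.

    Identical config (including seed) yields bit-identical output.
    """
    config.validate()
    rng_sched = stream(config.seed, "schedule")
    rng_tuning = stream(config.seed, "tuning")
    rng_gain = stream(config.seed, "gains")
    rng_latent = stream(config.seed, "latent")
    rng_noise = stream(config.seed, "noise")
    rng_spindle = stream(config.seed, "spindles")

    block_table, trial_table = _build_schedule(config, rng_sched)
    dt = config.frame_duration
    duration = float(block_table.end_s.iloc[-1])
    n_frames = int(np.round(duration / dt))
    n = config.n_neurons

    # state label per frame from the block layout
    state_sequence = np.empty(n_frames, dtype=object)
    for _, blk in block_table.iterrows():
        idx = frames_in_window(blk.start_s, blk.end_s, dt, n_frames)
        state_sequence[idx] = blk.state
    state_sequence = state_sequence.astype(str)

    if config.spont_rank > 0:
        g = rng_latent.standard_normal((n, config.spont_rank))
        loadings, _ = np.linalg.qr(g)
    else:
        loadings = np.zeros((n, 0))
    tuning = _make_tuning(config, loadings, rng_tuning)

    # per-trial coordinated gains with a zero-gain gated component
    n_trials = len(trial_table)
    state_scale = {"wake": config.wake_gain_mean,
                   "nrem": config.wake_gain_mean * config.nrem_gain_scale}
    gate_prob = {"wake": config.gate_prob_wake, "nrem": config.gate_prob_nrem}
    gains = np.empty(n_trials)
    gated = np.zeros(n_trials, dtype=bool)
    for i, row in enumerate(trial_table.itertuples()):
        gated[i] = rng_gain.random() < gate_prob[row.state]
        jitter = 1.0
        if config.gain_sd > 0:
            jitter = rng_gain.lognormal(-0.5 * config.gain_sd**2, config.gain_sd)
        gains[i] = 0.0 if gated[i] else state_scale[row.state] * jitter

    rate = np.full((n, n_frames), config.baseline_rate)
    if config.spont_rank > 0:
        z = _latent_series(config, n_frames, rng_latent)
        rate += config.spont_amp * (loadings @ z)
    window = config.sound_duration + 0.25
    for i, row in enumerate(trial_table.itertuples()):
        if gains[i] == 0.0:
            continue
        idx = frames_in_window(row.onset_s, row.onset_s + window, dt, n_frames)
        rate[:, idx] += gains[i] * tuning[:, row.sound_id:row.sound_id + 1]
    if config.noise_sd > 0:
        rate += config.noise_sd * rng_noise.standard_normal(rate.shape)

    counts = np.clip(rate, 0.0, None) * dt
    if config.quantize:
        counts = np.rint(counts)
    raster = Raster(counts=counts, frame_duration=dt)

    spindles = _draw_spindles(config, block_table, rng_spindle)
    truth = SessionTruth(
        tuning=tuning,
        trial_gain=gains,
        gated=gated,
        state_sequence=state_sequence,
        spont_loadings=loadings,
        spindle_intervals=spindles,
        baseline_rate=config.baseline_rate,
        block_table=block_table,
        frame_rate=config.frame_rate,
        seed=config.seed,
    )
    return raster, trial_table, truth


def _narrowband(n: int, rate: float, band: tuple[float, float],
                rng: np.random.Generator) -> np.ndarray:
    """Unit-variance narrowband noise (band-passed white noise)."""
    x = bandpass(rng.standard_normal(n), rate, band)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_physio(config: SessionConfig, truth: SessionTruth,
                    rate: float = PHYSIO_RATE) -> PhysioRecord:
    """Synthesize EMG and LFP channels (auditory cortex, hippocampus, OB).

    EMG broadband power is bimodal across wake vs sleep, the hippocampal
    theta/delta ratio is elevated in REM, OB gamma (50-70 Hz) is elevated in
    wake, and 10-15 Hz spindle bursts are injected into the AC channel at
    ``truth.spindle_intervals`` (NREM only by construction).
    """
    highest_band = 300.0
    if rate < 2 * highest_band:
        raise ValueError(f"sampling rate must be >= {2 * highest_band} Hz")
    rng = stream(truth.seed, "physio")
    duration = len(truth.state_sequence) / truth.frame_rate
    n = int(np.round(duration * rate))
    t = np.arange(n) / rate

    frame_idx = np.minimum((t * truth.frame_rate).astype(int),
                           len(truth.state_sequence) - 1)
    states = truth.state_sequence[frame_idx]
    amp = {key: np.empty(n) for key in ("emg", "ob", "delta", "theta")}
    for st, vals in _STATE_AMPS.items():
        mask = states == st
        for key in amp:
            amp[key][mask] = vals[key]

    emg = amp["emg"] * rng.standard_normal(n)
    ob = amp["ob"] * _narrowband(n, rate, (50.0, 70.0), rng) + 0.5 * rng.standard_normal(n)
    hpc = (amp["delta"] * _narrowband(n, rate, (2.0, 5.0), rng)
           + amp["theta"] * _narrowband(n, rate, (5.0, 10.0), rng)
           + 0.3 * rng.standard_normal(n))

    ac = rng.standard_normal(n)
    for start, end in truth.spindle_intervals:
        i0, i1 = int(start * rate), int(end * rate)
        if i1 > n:
            continue
        seg = np.arange(i1 - i0) / rate
        envelope = np.hanning(i1 - i0)
        phase = rng.uniform(0, 2 * np.pi)
        ac[i0:i1] += 6.0 * envelope * np.sin(2 * np.pi * 12.0 * seg + phase)

    return PhysioRecord(channels=dict(emg=emg, ob=ob, hpc=hpc, ac=ac), rate=rate)
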