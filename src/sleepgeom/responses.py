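"""Trial tables, window-averaged response matrices and firing-rate summaries."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scoring import Hypnogram
from .signal import Raster, frames_in_window

log = logging.getLogger(__name__)

RESPONSE_OFFSET = 0.25   # response window extends this far past sound offset
BASELINE_WINDOW = 0.5    # pre-onset baseline length (s)


@dataclass
class ResponseMatrix:
    """Trials x neurons window-averaged rates with matched baselines.

    ``responses`` averages the half-open window [onset, onset + duration +
    0.25 s); ``baselines`` the 0.5 s immediately preceding onset. Units are
    events/s. ``trial_ids`` maps rows back to the trial table (trials whose
    response window is truncated by the session end are dropped).
    """

    responses: np.ndarray
    baselines: np.ndarray
    window: tuple[float, float]
    trial_ids: np.ndarray
    dropped: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.responses.shape != self.baselines.shape:
            raise ValueError("responses and baselines must have the same shape")
        if not (np.all(np.isfinite(self.responses)) and np.all(np.isfinite(self.baselines))):
            raise ValueError("response matrix entries must be finite")

    @property
    def n_trials(self) -> int:
        return self.responses.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.responses.shape[1]

    def evoked(self) -> np.ndarray:
        """Baseline-subtracted responses."""
        return self.responses - self.baselines

    def subset(self, trial_ids: np.ndarray) -> "ResponseMatrix":
        pos = {tid: i for i, tid in enumerate(self.trial_ids)}
        rows = np.array([pos[t] for t in trial_ids], dtype=int)
        return ResponseMatrix(
            responses=self.responses[rows],
            baselines=self.baselines[rows],
            window=self.window,
            trial_ids=np.asarray(trial_ids),
        )


def build_trial_table(schedule: pd.DataFrame, hypnogram: Hypnogram) -> pd.DataFrame:
    """Label each presentation with the scored state at its onset.

    REM-onset trials are flagged ``excluded`` for wake/NREM contrasts. Onsets
    outside the hypnogram span raise.
    """
    table = schedule.copy()
    states = [hypnogram.state_at(t) for t in table.onset_s]
    table["state"] = states
    table["excluded"] = table.state == "rem"
    return table


def extract_responses(
    raster: Raster,
    trials: pd.DataFrame,
    baseline_window: float = BASELINE_WINDOW,
) -> ResponseMatrix:
    """Per-trial, per-neuron mean rate in the response and baseline windows."""
    dt = raster.frame_duration
    nf = raster.n_frames
    resp_rows, base_rows, kept, dropped = [], [], [], []
    for row in trials.itertuples():
        t0 = row.onset_s
        t1 = t0 + row.duration_s + RESPONSE_OFFSET
        ridx = frames_in_window(t0, t1, dt, nf)
        expected = len(frames_in_window(t0, t1, dt, nf + 10**6))
        if len(ridx) < expected:
            dropped.append(row.trial_id)
            log.info("trial %d dropped: response window truncated by session end", row.trial_id)
            continue
        bidx = frames_in_window(max(t0 - baseline_window, 0.0), t0, dt, nf)
        if len(bidx) == 0:
            dropped.append(row.trial_id)
            log.info("trial %d dropped: no baseline frames", row.trial_id)
            continue
        resp_rows.append(raster.counts[:, ridx].mean(axis=1) / dt)
        base_rows.append(raster.counts[:, bidx].mean(axis=1) / dt)
        kept.append(row.trial_id)
    if not kept:
        raise ValueError("no usable trials")
    first = trials.iloc[0]
    return ResponseMatrix(
        responses=np.asarray(resp_rows),
        baselines=np.asarray(base_rows),
        window=(0.0, float(first.duration_s + RESPONSE_OFFSET)),
        trial_ids=np.asarray(kept),
        dropped=dropped,
    )


def _aligned(resp: ResponseMatrix, trials: pd.DataFrame) -> pd.DataFrame:
    t = trials.set_index("trial_id").loc[resp.trial_ids].reset_index()
    return t


def tuning_summary(resp: ResponseMatrix, trials: pd.DataFrame) -> dict:
    """Per-sound/per-state population rates and single-neuron response stats.

    Returns a dict with:

    - ``per_sound``: DataFrame (sound_id, state, mean_rate) of population-mean
      baseline-subtracted rates,
    - ``per_neuron``: DataFrame (state, neuron, p_nonzero, amp_nonzero),
      the fraction of trials with a strictly positive response-window count
      and the mean amplitude conditional on non-zero,
    - ``state_ratio``: overall NREM/wake ratio of mean evoked rates (NaN if a
      state is missing, flagged in ``missing``).
    """
    t = _aligned(resp, trials)
    evoked = resp.evoked()
    rows = []
    missing = []
    for (sound, state), grp in t.groupby(["sound_id", "state"]):
        if len(grp) < 2:
            missing.append((sound, state))
            continue
        rows.append(dict(sound_id=sound, state=state,
                         mean_rate=float(evoked[grp.index].mean())))
    per_sound = pd.DataFrame(rows)

    neuron_rows = []
    for state, grp in t.groupby("state"):
        e = evoked[grp.index]                      # trials x neurons
        nz = e > 0
        p = nz.mean(axis=0)
        with np.errstate(invalid="ignore"):
            amp = np.where(nz.sum(axis=0) > 0,
                           np.divide(np.where(nz, e, 0.0).sum(axis=0),
                                     np.maximum(nz.sum(axis=0), 1)),
                           np.nan)
        for i in range(e.shape[1]):
            neuron_rows.append(dict(state=state, neuron=i,
                                    p_nonzero=float(p[i]),
                                    amp_nonzero=float(amp[i])))
    per_neuron = pd.DataFrame(neuron_rows)

    means = {state: evoked[grp.index].mean() for state, grp in t.groupby("state")}
    if "wake" in means and "nrem" in means and means["wake"] != 0:
        state_ratio = float(means["nrem"] / means["wake"])
    else:
        state_ratio = float("nan")
    return dict(per_sound=per_sound, per_neuron=per_neuron,
                state_ratio=state_ratio, missing=missing)


def rescale_to_wake_max(wake: np.ndarray, nrem: np.ndarray) -> np.ndarray:
    """Rescale the NREM per-sound curve so its value at the wake-argmax sound
    equals the wake maximum."""
    wake = np.asarray(wake, dtype=float)
    nrem = np.asarray(nrem, dtype=float)
    if wake.shape != nrem.shape:
        raise ValueError("wake and NREM vectors must have the same length")
    k = int(np.argmax(wake))
    if wake[k] <= 0:
        raise ValueError("wake maximum must be positive")
    if nrem[k] <= 0:
        raise ValueError("NREM value at the wake-argmax sound must be positive")
    return nrem * (wake[k] / nrem[k])
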