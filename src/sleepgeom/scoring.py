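"""Two-step automated sleep scoring, spindle detection and event-related power.

Step 1 separates wake from sleep on the intersection threshold of a
two-Gaussian fit to smoothed EMG (50-300 Hz) or olfactory-bulb gamma
(50-70 Hz) power. Step 2 splits sleep into NREM/REM on the hippocampal
theta/delta power ratio. NREM/REM bouts shorter than 3 s are merged into the
surrounding state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .signal import band_power, bandpass
from .synthetic import PhysioRecord

MIN_BOUT = 3.0          # s, NREM/REM bouts shorter than this are merged away
SPINDLE_BAND = (10.0, 15.0)
SPINDLE_MERGE_GAP = 0.2
SPINDLE_MIN_DUR = 0.4
SPINDLE_MAX_DUR = 3.0


@dataclass
class Hypnogram:
    """Ordered, contiguous, non-overlapping state intervals over scored time."""

    intervals: list[tuple[float, float, str]]

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("hypnogram must contain at least one interval")
        for (s0, e0, _), (s1, _, _) in zip(self.intervals, self.intervals[1:]):
            if not np.isclose(e0, s1):
                raise ValueError("hypnogram intervals must be contiguous")
        for s, e, st in self.intervals:
            if e <= s:
                raise ValueError("empty hypnogram interval")
            if st not in ("wake", "nrem", "rem"):
                raise ValueError(f"unknown state {st!r}")

    @property
    def span(self) -> tuple[float, float]:
        return self.intervals[0][0], self.intervals[-1][1]

    def state_at(self, t: float) -> str:
        """State of the half-open interval containing ``t``."""
        lo, hi = self.span
        if not (lo <= t < hi):
            raise ValueError(f"time {t} outside hypnogram span {self.span}")
        starts = np.array([s for s, _, _ in self.intervals])
        i = int(np.searchsorted(starts, t, side="right") - 1)
        return self.intervals[i][2]

    def mask(self, times: np.ndarray, state: str) -> np.ndarray:
        """Boolean mask over sample times that fall inside the given state."""
        out = np.zeros(len(times), dtype=bool)
        for s, e, st in self.intervals:
            if st == state:
                out |= (times >= s) & (times < e)
        return out

    def duration(self, state: str | None = None) -> float:
        return sum(e - s for s, e, st in self.intervals
                   if state is None or st == state)


def _em_fit(values: np.ndarray, seed: int = 0) -> GaussianMixture:
    """Two-component 1-D GMM; percentile init plus seeded restarts, best kept."""
    x = values.reshape(-1, 1)
    best = None
    inits = [np.percentile(values, [25, 75]).reshape(-1, 1)]
    for means_init, rs in [(inits[0], 0), (None, 1), (None, 2), (None, 3)]:
        gm = GaussianMixture(n_components=2, means_init=means_init,
                             random_state=seed + rs, n_init=1)
        gm.fit(x)
        if best is None or gm.lower_bound_ > best.lower_bound_:
            best = gm
    return best


def bimodal_threshold(values: np.ndarray) -> tuple[float, bool]:
    """Intersection of the two unit-area Gaussians fitted to ``values``.

    The mixture weights are discarded: each component density is rescaled to
    unit area and the intersection abscissa between the two means is
    returned. ``separation_ok`` is False when the means differ by less than
    one pooled SD.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 100:
        raise ValueError("need at least 100 samples")
    if np.ptp(values) == 0:
        raise ValueError("degenerate (constant) input")
    gm = _em_fit(values)
    (m1,), (m2,) = gm.means_
    s1, s2 = np.sqrt(gm.covariances_.ravel())
    w1, w2 = gm.weights_
    if m1 > m2:
        m1, m2, s1, s2, w1, w2 = m2, m1, s2, s1, w2, w1
    pooled = np.sqrt((s1**2 + s2**2) / 2)
    # mean separation alone misfires on unimodal data (EM splits one Gaussian
    # into two components ~1.5 pooled SDs apart); additionally require a real
    # dip of the mixture density between the component means
    grid = np.linspace(m1, m2, 201)
    mix = w1 * norm.pdf(grid, m1, s1) + w2 * norm.pdf(grid, m2, s2)
    has_dip = mix.min() < 0.5 * min(mix[0], mix[-1])
    separation_ok = bool(abs(m2 - m1) >= pooled and has_dip)

    if np.isclose(s1, s2):
        return float((m1 + m2) / 2), bool(separation_ok)
    # N(x; m1, s1) = N(x; m2, s2)  ->  quadratic in x
    a = 1 / s2**2 - 1 / s1**2
    b = 2 * (m1 / s1**2 - m2 / s2**2)
    c = m2**2 / s2**2 - m1**2 / s1**2 + 2 * np.log(s2 / s1)
    roots = np.roots([a, b, c])
    roots = roots[np.isreal(roots)].real
    inside = roots[(roots > m1) & (roots < m2)]
    if len(inside) > 0:
        return float(inside[0]), bool(separation_ok)
    # numeric fallback: brute-force grid between the means
    grid = np.linspace(m1, m2, 10001)
    diff = norm.pdf(grid, m1, s1) - norm.pdf(grid, m2, s2)
    return float(grid[np.argmin(np.abs(diff))]), bool(separation_ok)


def rem_threshold(values: np.ndarray, density_floor: float = 0.02) -> float:
    """Theta/delta threshold where a single-Gaussian fit stops explaining the data.

    Interpretation of the published rule (the estimator itself is not defined
    there): fit a robust Gaussian (median, IQR-based sigma) to the sleep
    theta/delta values, and return the smallest value above the fitted mode
    where the fitted density falls below 50% of the histogram-smoothed
    empirical density while the empirical density is still >= ``density_floor``
    of its maximum. Returns +inf when no such point exists (no REM).
    """
    values = np.asarray(values, dtype=float)
    mu = np.median(values)
    # one-sided robust sigma from the lower quartile: the upper quartile can sit
    # inside the REM mode when REM occupies a large share of sleep
    sigma = (mu - np.percentile(values, 25)) / 0.6745
    if sigma <= 0:
        sigma = values.std()
    if sigma == 0:
        return np.inf
    hist, edges = np.histogram(values, bins=100, density=True)
    kernel = np.ones(5) / 5
    smooth = np.convolve(hist, kernel, mode="same")
    centers = (edges[:-1] + edges[1:]) / 2
    floor = density_floor * smooth.max()
    for x, d in zip(centers, smooth):
        # within ~2 sigma the fit explains the data by construction; only the
        # tail beyond it can reveal a second (REM) mode
        if x <= mu + 2 * sigma or d < floor:
            continue
        if norm.pdf(x, mu, sigma) < 0.5 * d:
            return float(x)
    return np.inf


def _runs_to_intervals(labels: np.ndarray, rate: float) -> list[tuple[float, float, str]]:
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(labels)]])
    return [(s / rate, e / rate, str(labels[s])) for s, e in zip(starts, ends)]


def _merge_short(intervals: list[tuple[float, float, str]],
                 min_bout: float = MIN_BOUT) -> list[tuple[float, float, str]]:
    """Absorb sub-threshold NREM/REM bouts into the longer neighbor (ties: preceding)."""
    iv = [list(x) for x in intervals]
    changed = True
    while changed:
        changed = False
        for i, (s, e, st) in enumerate(iv):
            if st not in ("nrem", "rem") or e - s >= min_bout:
                continue
            prev_len = iv[i - 1][1] - iv[i - 1][0] if i > 0 else -1.0
            next_len = iv[i + 1][1] - iv[i + 1][0] if i < len(iv) - 1 else -1.0
            if prev_len < 0 and next_len < 0:
                break
            target = i - 1 if prev_len >= next_len else i + 1
            iv[i][2] = iv[target][2]
            changed = True
            break
        # coalesce adjacent same-state intervals
        merged = [iv[0]]
        for s, e, st in iv[1:]:
            if st == merged[-1][2]:
                merged[-1][1] = e
            else:
                merged.append([s, e, st])
        iv = merged
    return [tuple(x) for x in iv]


def score_session(
    physio: PhysioRecord,
    channel: str = "emg",
    score_rate: float = 10.0,
    wake_smooth: float = 3.0,
    ratio_smooth: float = 2.0,
) -> Hypnogram:
    """Two-step automated hypnogram from physiological channels.

    Step 1: smoothed (3 s) EMG 50-300 Hz (or OB 50-70 Hz) power, two-Gaussian
    intersection threshold, below-threshold = sleep. Step 2: within sleep,
    smoothed (2 s) hippocampal theta(5-10)/delta(2-5) power ratio; above the
    REM threshold = REM, else NREM. Sub-3 s NREM/REM bouts are merged.
    """
    if channel not in ("emg", "ob"):
        raise ValueError("channel must be 'emg' or 'ob'")
    needed = {channel, "hpc"}
    missing = needed - set(physio.channels)
    if missing:
        raise ValueError(f"missing channels: {sorted(missing)}")
    if physio.duration < 60.0:
        raise ValueError("need at least 60 s of signal to score")

    band = (50.0, 300.0) if channel == "emg" else (50.0, 70.0)
    step = max(int(physio.rate / score_rate), 1)
    power = band_power(physio[channel], physio.rate, band, smooth_window=wake_smooth).values
    logp = np.log10(power[::step] + 1e-12)
    thr, separated = bimodal_threshold(logp)
    # no detectable sleep/wake bimodality -> score the whole span as wake
    asleep = (logp < thr) if separated else np.zeros(len(logp), dtype=bool)

    theta = band_power(physio["hpc"], physio.rate, (5.0, 10.0), smooth_window=ratio_smooth).values
    delta = band_power(physio["hpc"], physio.rate, (2.0, 5.0), smooth_window=ratio_smooth).values
    log_ratio = np.log10((theta[::step] + 1e-12) / (delta[::step] + 1e-12))

    labels = np.full(len(logp), "wake", dtype=object)
    if asleep.any():
        rem_thr = rem_threshold(log_ratio[asleep])
        labels[asleep] = np.where(log_ratio[asleep] > rem_thr, "rem", "nrem")
    eff_rate = physio.rate / step
    intervals = _merge_short(_runs_to_intervals(labels, eff_rate))
    return Hypnogram(intervals=intervals)


def awakening_stats(hypnogram: Hypnogram, trials: pd.DataFrame,
                    window: float = 1.0) -> dict:
    """Sleep-to-wake transition rate and sound-evoked awakening probability.

    The probability counts presentations whose onset falls in sleep and is
    followed by a sleep-to-wake transition within ``window`` seconds.
    """
    transitions = [
        s1 for (_, _, st0), (s1, _, st1) in zip(hypnogram.intervals, hypnogram.intervals[1:])
        if st0 in ("nrem", "rem") and st1 == "wake"
    ]
    total = hypnogram.duration()
    rate = len(transitions) / total if total > 0 else 0.0

    in_sleep = [row.onset_s for row in trials.itertuples()
                if hypnogram.state_at(row.onset_s) in ("nrem", "rem")]
    if not in_sleep:
        return dict(awakening_rate=rate, sound_evoked_awakening_prob=float("nan"),
                    defined=False, n_sleep_onsets=0)
    hits = sum(
        any(onset < t <= onset + window for t in transitions) for onset in in_sleep
    )
    return dict(awakening_rate=rate,
                sound_evoked_awakening_prob=hits / len(in_sleep),
                defined=True, n_sleep_onsets=len(in_sleep))


@dataclass
class SpindleEvents:
    events: list[tuple[float, float]]
    channel: str = "ac"
    threshold_sd: float = 2.0
    no_nrem: bool = False

    def __post_init__(self) -> None:
        for s, e in self.events:
            if not SPINDLE_MIN_DUR <= e - s <= SPINDLE_MAX_DUR:
                raise ValueError("spindle duration outside [0.4, 3] s")
        for (_, e0), (s1, _) in zip(self.events, self.events[1:]):
            if s1 - e0 < SPINDLE_MERGE_GAP:
                raise ValueError("spindle events closer than the merge gap")


def detect_spindles(
    lfp: np.ndarray,
    rate: float,
    hypnogram: Hypnogram,
    threshold_sd: float = 2.0,
    channel: str = "ac",
) -> SpindleEvents:
    """Sigma-band (10-15 Hz) spindle events during NREM sleep.

    Zero-phase filter, element-wise square as instantaneous amplitude,
    threshold at mean + ``threshold_sd`` SD (statistics over NREM samples),
    merge events separated by < 200 ms, discard events outside 0.4-3 s.
    """
    if rate < 100:
        raise ValueError("sampling rate must be >= 100 Hz")
    times = np.arange(len(lfp)) / rate
    nrem = hypnogram.mask(times, "nrem")
    if not nrem.any():
        return SpindleEvents(events=[], channel=channel,
                             threshold_sd=threshold_sd, no_nrem=True)
    sq = bandpass(lfp, rate, SPINDLE_BAND) ** 2
    stats = sq[nrem]
    thr = stats.mean() + threshold_sd * stats.std()
    above = (sq > thr) & nrem
    raw = [(s, e) for s, e, flag in _runs_to_intervals(above.astype(int), rate)
           if flag == "1"]
    merged: list[list[float]] = []
    for s, e in raw:
        if merged and s - merged[-1][1] < SPINDLE_MERGE_GAP:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    events = [(s, e) for s, e in merged if SPINDLE_MIN_DUR <= e - s <= SPINDLE_MAX_DUR]
    return SpindleEvents(events=events, channel=channel, threshold_sd=threshold_sd)


def event_related_power(
    physio: PhysioRecord,
    trials: pd.DataFrame,
    labels: pd.DataFrame,
    band: tuple[float, float],
    window: float = 1.5,
    channel: str = "ac",
    spindles: SpindleEvents | None = None,
    prob_range: float = 3.0,
    prob_bin: float = 0.5,
) -> dict:
    """Contrast of band power around non-responsive vs responsive presentations.

    Per trial, the band power is averaged in a ``window``-long interval
    centered on the middle of the presentation; the contrast is
    ``(mean_nonresponsive - mean_responsive) / mean_responsive``. Also returns
    the probability of finding a spindle as a function of time from onset.
    """
    merged = trials.merge(labels[["trial_id", "label"]], on="trial_id")
    if (merged.label == "responsive").sum() == 0 or (merged.label == "non-responsive").sum() == 0:
        raise ValueError("both label classes must be non-empty")
    power = band_power(physio[channel], physio.rate, band).values
    n = len(power)
    per_trial = []
    for row in merged.itertuples():
        center = row.onset_s + row.duration_s / 2
        i0 = max(int((center - window / 2) * physio.rate), 0)
        i1 = min(int((center + window / 2) * physio.rate), n)
        per_trial.append(power[i0:i1].mean())
    merged = merged.assign(power=per_trial)
    mean_r = merged.loc[merged.label == "responsive", "power"].mean()
    mean_nr = merged.loc[merged.label == "non-responsive", "power"].mean()
    contrast = (mean_nr - mean_r) / mean_r

    edges = np.arange(-prob_range, prob_range + prob_bin / 2, prob_bin)
    prob = np.zeros(len(edges) - 1)
    if spindles is not None and spindles.events:
        for k in range(len(prob)):
            lo, hi = edges[k], edges[k + 1]
            hits = 0
            for row in merged.itertuples():
                a, b = row.onset_s + lo, row.onset_s + hi
                if any(s < b and e > a for s, e in spindles.events):
                    hits += 1
            prob[k] = hits / len(merged)
    return dict(contrast=float(contrast), mean_responsive=float(mean_r),
                mean_nonresponsive=float(mean_nr),
                spindle_prob=prob, spindle_prob_edges=edges)
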