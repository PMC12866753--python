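"""Bootstrap detection of "non-responsive" population events.

A trial is non-responsive when the cosine similarity of its
baseline-subtracted population response with the sound's template response
is statistically indistinguishable from 0 under a bootstrap over neurons:
the label is non-responsive iff 0 lies within the [5th, 95th] percentile of
the bootstrapped cosine distribution.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import stream
from .responses import ResponseMatrix

log = logging.getLogger(__name__)


def build_templates(
    resp: ResponseMatrix,
    trials: pd.DataFrame,
    top_frac: float = 0.3,
    n_sounds: int = 10,
    template_state: str = "wake",
    rank_by: str = "mean",
) -> dict[int, np.ndarray]:
    """Per-sound template vectors from the strongest single-trial responses.

    Sounds are ranked by mean baseline-subtracted population response (over
    ``template_state`` trials) and the top ``n_sounds`` kept. Per sound,
    trials are ranked by population response intensity (mean
    baseline-subtracted rate across neurons, or vector norm with
    ``rank_by="norm"``) and the strongest ``top_frac`` fraction (ceiling)
    averaged. Ties break by trial id for determinism.
    """
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must be in (0, 1]")
    t = trials[trials.trial_id.isin(resp.trial_ids)]
    pos = {tid: k for k, tid in enumerate(resp.trial_ids)}
    evoked = resp.evoked()

    strength = {}
    for sound, grp in t[t.state == template_state].groupby("sound_id"):
        rows = [pos[tid] for tid in grp.trial_id]
        strength[int(sound)] = evoked[rows].mean()
    if not strength:
        raise ValueError(f"no trials in template state {template_state!r}")
    ranked = sorted(strength, key=lambda s: (-strength[s], s))[:n_sounds]

    templates: dict[int, np.ndarray] = {}
    for sound in ranked:
        grp = t[(t.sound_id == sound) & (t.state == template_state)]
        n_top = int(np.ceil(top_frac * len(grp)))
        if n_top < 1:
            raise ValueError(f"too few trials for sound {sound}")
        rows = np.array([pos[tid] for tid in grp.trial_id])
        if rank_by == "mean":
            intensity = evoked[rows].mean(axis=1)
        elif rank_by == "norm":
            intensity = np.linalg.norm(evoked[rows], axis=1)
        else:
            raise ValueError("rank_by must be 'mean' or 'norm'")
        order = np.lexsort((grp.trial_id.to_numpy(), -intensity))
        templates[sound] = evoked[rows[order[:n_top]]].mean(axis=0)
    return templates


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return float("nan")
    return float(a @ b / (na * nb))


def label_trials(
    resp: ResponseMatrix,
    trials: pd.DataFrame,
    templates: dict[int, np.ndarray],
    n_boot: int = 1000,
    pct: tuple[float, float] = (5.0, 95.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap gating labels for every trial of the template sounds.

    Returns a DataFrame with columns trial_id, sound_id, state, cosine, lo,
    hi, label. Neurons are resampled with replacement ``n_boot`` times (one
    seeded resampling-weight matrix shared across trials); a trial is
    non-responsive iff 0 lies inside the percentile interval. Zero trial
    vectors have undefined cosine and are labeled non-responsive by
    convention (logged).
    """
    for sound, tpl in templates.items():
        if np.linalg.norm(tpl) == 0:
            raise ValueError(f"zero template for sound {sound}")
    rng = stream(seed, "gating-boot")
    n = resp.n_neurons
    weights = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot).astype(float)

    t = trials[trials.trial_id.isin(resp.trial_ids)]
    t = t[t.sound_id.isin(templates)]
    pos = {tid: k for k, tid in enumerate(resp.trial_ids)}
    evoked = resp.evoked()

    rows = []
    for sound, grp in t.groupby("sound_id"):
        tpl = templates[int(sound)]
        ridx = np.array([pos[tid] for tid in grp.trial_id])
        X = evoked[ridx]                                # trials x neurons
        P = X * tpl[None, :]
        X2, T2 = X**2, np.broadcast_to(tpl**2, X.shape)
        bp = P @ weights.T                              # trials x n_boot
        bx = X2 @ weights.T
        bt = T2 @ weights.T
        with np.errstate(invalid="ignore", divide="ignore"):
            boot = bp / np.sqrt(bx * bt)
        lo = np.nanpercentile(boot, pct[0], axis=1)
        hi = np.nanpercentile(boot, pct[1], axis=1)
        for k, row in enumerate(grp.itertuples()):
            cos = _cosine(X[k], tpl)
            if np.isnan(cos):
                log.info("trial %d has a zero response vector; labeled non-responsive",
                         row.trial_id)
                label = "non-responsive"
            else:
                label = "non-responsive" if lo[k] <= 0.0 <= hi[k] else "responsive"
            rows.append(dict(trial_id=row.trial_id, sound_id=int(sound),
                             state=row.state, cosine=cos,
                             lo=float(lo[k]), hi=float(hi[k]), label=label))
    return pd.DataFrame(rows).sort_values("trial_id").reset_index(drop=True)


def gating_summary(
    labels: pd.DataFrame,
    resp: ResponseMatrix,
    trials: pd.DataFrame,
    templates: dict[int, np.ndarray],
    seed: int = 0,
) -> dict:
    """Per-state non-responsive fractions, shuffle-control similarity
    distributions, and amplitude contrasts by label.

    The shuffle control independently permutes each neuron's responses across
    trials (within sound and state), destroying coordination but preserving
    marginals, then recomputes the cosine similarities.
    """
    rng = stream(seed, "gating-shuffle")
    pos = {tid: k for k, tid in enumerate(resp.trial_ids)}
    evoked = resp.evoked()

    fractions = {}
    for state, grp in labels.groupby("state"):
        if len(grp) == 0:
            raise ValueError(f"no labeled trials in state {state!r}")
        fractions[state] = float((grp.label == "non-responsive").mean())

    t = trials[trials.trial_id.isin(labels.trial_id)]
    shuffled_cos = {state: [] for state in labels.state.unique()}
    observed_cos = {state: grp.cosine.to_numpy()
                    for state, grp in labels.groupby("state")}
    for (sound, state), grp in t.groupby(["sound_id", "state"]):
        tpl = templates[int(sound)]
        ridx = np.array([pos[tid] for tid in grp.trial_id])
        X = evoked[ridx].copy()
        for j in range(X.shape[1]):
            X[:, j] = X[rng.permutation(X.shape[0]), j]
        for k in range(X.shape[0]):
            shuffled_cos[state].append(_cosine(X[k], tpl))

    amp_rows = []
    merged = labels.merge(t[["trial_id"]], on="trial_id")
    for (state, label), grp in merged.groupby(["state", "label"]):
        ridx = np.array([pos[tid] for tid in grp.trial_id])
        amp_rows.append(dict(state=state, label=label,
                             mean_amplitude=float(evoked[ridx].mean()),
                             n=len(grp)))
    return dict(
        fraction_nonresponsive=fractions,
        observed_cosine=observed_cos,
        shuffled_cosine={s: np.asarray(v) for s, v in shuffled_cos.items()},
        amplitude=pd.DataFrame(amp_rows),
    )
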