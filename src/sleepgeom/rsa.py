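"""Noise-corrected representational similarity within and across states.

The similarity of two sound representations is the mean of the cross-split
Pearson correlations of trial-averaged population vectors, divided by the
geometric mean of the two split-half reliabilities. With this normalization,
identical underlying representations score 1 in expectation, independent of
response amplitude or trial-to-trial noise level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import stream
from .responses import ResponseMatrix


@dataclass
class SplitScheme:
    """Disjoint per-sound trial-id groups with exactly equal per-sound counts.

    ``groups[sound]`` is a list of ``n_groups`` arrays of trial ids. For
    within-state similarity the two groups are the ensembles (r, r'); for
    cross-state similarity groups 0-1 come from the first state (r, r') and
    groups 2-3 from the second (q, q').
    """

    groups: dict[int, list[np.ndarray]]
    seed: int

    def __post_init__(self) -> None:
        for sound, gs in self.groups.items():
            sizes = {len(g) for g in gs}
            if len(sizes) != 1:
                raise ValueError(f"unequal group sizes for sound {sound}")
            flat = np.concatenate(gs)
            if len(np.unique(flat)) != len(flat):
                raise ValueError(f"overlapping groups for sound {sound}")

    @property
    def n_groups(self) -> int:
        return len(next(iter(self.groups.values())))


def make_split_scheme(
    trials: pd.DataFrame,
    states: tuple[str, ...],
    seed: int,
    groups_per_state: int = 2,
) -> SplitScheme:
    """Random per-sound split into equal-count groups, per state.

    For each sound, each state contributes ``groups_per_state`` groups of
    exactly ``floor(n_state / groups_per_state)`` trials (leftovers dropped so
    counts are equal, never off by one).
    """
    rng = stream(seed, "rsa-split")
    groups: dict[int, list[np.ndarray]] = {}
    for sound, grp in trials.groupby("sound_id"):
        gs: list[np.ndarray] = []
        for state in states:
            ids = grp.loc[grp.state == state, "trial_id"].to_numpy()
            per = len(ids) // groups_per_state
            if per < 1:
                raise ValueError(
                    f"sound {sound} has too few {state} presentations to split"
                )
            ids = rng.permutation(ids)[: per * groups_per_state]
            gs.extend(np.array_split(ids, groups_per_state))
        groups[int(sound)] = gs
    return SplitScheme(groups=groups, seed=seed)


@dataclass
class SimilarityMatrix:
    values: np.ndarray          # sounds x sounds, NaN where unreliable
    mode: str                   # "within" | "cross"
    reliability: np.ndarray     # per sound, mean split-half correlation
    sound_ids: np.ndarray

    @property
    def n_unreliable(self) -> int:
        return int((self.reliability <= 0).sum())


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a, b)[0, 1])


def _group_mean(x: np.ndarray, trial_ids: np.ndarray, ids: np.ndarray) -> np.ndarray:
    pos = np.searchsorted(trial_ids, ids)
    return x[pos].mean(axis=0)


def noise_corrected_similarity(
    resp: ResponseMatrix,
    scheme: SplitScheme,
    pair: tuple[int, int],
    mode: str = "within",
    subtract_baseline: bool = False,
) -> float:
    """Noise-corrected similarity of two sound representations.

    Within-state: mean of the two cross-split correlations over the geometric
    mean of the two split-half reliabilities. Cross-state: mean of the four
    cross-ensemble correlations over the geometric mean of the within-state
    reliabilities. Returns NaN (flagged-undefined, never clipped) when a
    reliability is non-positive.
    """
    i, j = pair
    x = resp.evoked() if subtract_baseline else resp.responses
    order = np.argsort(resp.trial_ids)
    tid = resp.trial_ids[order]
    x = x[order]
    gi = [_group_mean(x, tid, g) for g in scheme.groups[i]]
    gj = [_group_mean(x, tid, g) for g in scheme.groups[j]]
    if mode == "within":
        if scheme.n_groups < 2:
            raise ValueError("within-state similarity needs 2 groups")
        num = 0.5 * (_pearson(gi[0], gj[1]) + _pearson(gi[1], gj[0]))
        rel_i = _pearson(gi[0], gi[1])
        rel_j = _pearson(gj[0], gj[1])
    elif mode == "cross":
        if scheme.n_groups < 4:
            raise ValueError("cross-state similarity needs 4 groups (r, r', q, q')")
        num = np.mean([_pearson(gi[a], gj[b]) for a in (0, 1) for b in (2, 3)])
        rel_i = _pearson(gi[0], gi[1])
        rel_j = _pearson(gj[2], gj[3])
    else:
        raise ValueError("mode must be 'within' or 'cross'")
    if rel_i <= 0 or rel_j <= 0:
        return float("nan")
    return float(num / np.sqrt(rel_i * rel_j))


def _matrix_for_scheme(
    x: np.ndarray,
    trial_ids: np.ndarray,
    scheme: SplitScheme,
    sounds: np.ndarray,
    mode: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized similarity matrix for one split scheme."""
    n_sounds = len(sounds)
    means = {}  # (sound, group) -> z-scored mean vector
    for s in sounds:
        for g, ids in enumerate(scheme.groups[int(s)]):
            m = _group_mean(x, trial_ids, ids)
            sd = m.std()
            means[(int(s), g)] = (m - m.mean()) / (sd if sd > 0 else 1.0)

    def corr_block(ga: int, gb: int) -> np.ndarray:
        A = np.stack([means[(int(s), ga)] for s in sounds])
        B = np.stack([means[(int(s), gb)] for s in sounds])
        return A @ B.T / A.shape[1]

    if mode == "within":
        c01 = corr_block(0, 1)
        num = 0.5 * (c01 + c01.T)
        rel = np.diag(c01).copy()
        rel_j = rel
    else:
        num = 0.25 * (corr_block(0, 2) + corr_block(0, 3)
                      + corr_block(1, 2) + corr_block(1, 3))
        rel = np.diag(corr_block(0, 1)).copy()
        rel_j = np.diag(corr_block(2, 3)).copy()
    denom = np.sqrt(np.outer(np.clip(rel, 0, None), np.clip(rel_j, 0, None)))
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(denom > 0, num / denom, np.nan)
    reliability = 0.5 * (rel + rel_j)
    return values, reliability


def rsa_summary(
    resp: ResponseMatrix,
    trials: pd.DataFrame,
    mode: str = "within",
    states: tuple[str, ...] = ("wake",),
    n_splits: int = 20,
    seed: int = 0,
    subtract_baseline: bool = False,
    ceiling_state: str | None = None,
) -> dict:
    """Averaged similarity matrix with chance and ceiling distributions.

    The matrix is averaged over ``n_splits`` random split schemes. Chance
    values come from identity-mismatched (deranged) sound pairings of the
    diagonal; the ceiling splits one state's trials into 4 non-overlapping
    groups and applies the cross-state formula to them (centered at 1 for
    identical representations).
    """
    if mode == "cross" and len(states) != 2:
        raise ValueError("cross mode needs exactly two states")
    if mode == "within" and len(states) != 1:
        raise ValueError("within mode needs exactly one state")
    x = resp.evoked() if subtract_baseline else resp.responses
    order = np.argsort(resp.trial_ids)
    tid = resp.trial_ids[order]
    x = x[order]
    t = trials[trials.trial_id.isin(tid)]
    sounds = np.sort(t.sound_id.unique())

    rng = stream(seed, "rsa-summary")
    mats, rels, chance = [], [], []
    for k in range(n_splits):
        scheme = make_split_scheme(t, states, seed=int(rng.integers(2**31)),
                                   groups_per_state=2)
        values, reliability = _matrix_for_scheme(x, tid, scheme, sounds, mode)
        mats.append(values)
        rels.append(reliability)
        diag = np.diag(values)
        perm = _derangement(len(sounds), rng)
        chance.extend(values[np.arange(len(sounds)), perm])

    ceiling: list[float] = []
    ceil_state = ceiling_state or states[0]
    min_count = t[t.state == ceil_state].groupby("sound_id").size().min()
    if min_count >= 4:
        for k in range(n_splits):
            scheme4 = make_split_scheme(t, (ceil_state,),
                                        seed=int(rng.integers(2**31)),
                                        groups_per_state=4)
            vals4, _ = _matrix_for_scheme(x, tid, scheme4, sounds, "cross")
            ceiling.extend(np.diag(vals4))
    values = np.nanmean(np.stack(mats), axis=0)
    reliability = np.nanmean(np.stack(rels), axis=0)
    matrix = SimilarityMatrix(values=values, mode=mode,
                              reliability=reliability, sound_ids=sounds)
    diag = np.diag(values)
    ok = reliability > 0
    return dict(
        matrix=matrix,
        chance=np.asarray(chance, dtype=float),
        ceiling=np.asarray(ceiling, dtype=float),
        diag_mean=float(np.nanmean(diag[ok])) if ok.any() else float("nan"),
        diag_sd=float(np.nanstd(diag[ok])) if ok.any() else float("nan"),
        ceiling_available=len(ceiling) > 0,
    )


def _derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random permutation of range(n) with no fixed points."""
    if n < 2:
        raise ValueError("derangement needs n >= 2")
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm
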