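"""Balanced, stratified cross-validated linear decoding of sound identity."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, f1_score
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .config import stream
from .responses import ResponseMatrix

log = logging.getLogger(__name__)


@dataclass
class DecodingResult:
    accuracy: float                 # pooled weighted F1, in [0, 1]
    confusion: np.ndarray           # sounds x sounds counts (rows = true)
    per_fold: list[float]
    n_per_class: int
    sound_ids: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")


def prepare_balanced_folds(
    resp: ResponseMatrix,
    trials: pd.DataFrame,
    state: str,
    k: int = 5,
    seed: int = 0,
    equalize_with: str | None = None,
) -> pd.DataFrame:
    """Stratified fold assignment with exactly equal per-sound counts.

    Each sound contributes ``k * floor(m / k)`` trials, where ``m`` is its
    presentation count in ``state`` (optionally first equalized down to the
    poorer of two states via ``equalize_with``). Sounds with fewer than ``k``
    presentations are dropped and logged. Returns a DataFrame with columns
    trial_id, sound_id, fold.
    """
    rng = stream(seed, f"folds-{state}")
    t = trials[trials.trial_id.isin(resp.trial_ids)]
    if "excluded" in t.columns:
        t = t[~t.excluded]
    here = t[t.state == state]
    counts = here.groupby("sound_id").size()
    cap = None
    if equalize_with is not None:
        other = t[t.state == equalize_with].groupby("sound_id").size()
        cap = pd.concat([counts, other], axis=1).min(axis=1).fillna(0).astype(int)

    rows = []
    for sound, grp in here.groupby("sound_id"):
        m = len(grp) if cap is None else int(cap.loc[sound])
        per_fold = m // k
        if per_fold < 1:
            log.info("sound %s dropped: %d < %d presentations", sound, m, k)
            continue
        ids = rng.permutation(grp.trial_id.to_numpy())[: per_fold * k]
        folds = np.repeat(np.arange(k), per_fold)
        for tid, f in zip(ids, folds):
            rows.append(dict(trial_id=int(tid), sound_id=int(sound), fold=int(f)))
    if not rows:
        raise ValueError(f"no sound has >= {k} presentations in state {state!r}")
    return pd.DataFrame(rows)


def decode(
    folds: pd.DataFrame,
    resp: ResponseMatrix,
    model: str = "svc",
    C: float = 1.0,
    seed: int = 0,
) -> DecodingResult:
    """Linear one-vs-rest decoding with weighted-F1 scoring over pooled test folds."""
    sound_ids = np.sort(folds.sound_id.unique())
    if len(sound_ids) < 2:
        raise ValueError("need at least 2 classes")
    sub = resp.subset(folds.trial_id.to_numpy())
    X = sub.responses
    if np.allclose(X, X[0]):
        raise ValueError("degenerate features: all trials identical")
    y = folds.sound_id.to_numpy()
    assign = folds.fold.to_numpy()

    y_true_all, y_pred_all, per_fold = [], [], []
    for f in np.unique(assign):
        train, test = assign != f, assign == f
        scaler = StandardScaler().fit(X[train])
        with np.errstate(all="ignore"):
            Xtr = scaler.transform(X[train])
            Xte = scaler.transform(X[test])
        if model == "svc":
            clf = LinearSVC(C=C, dual=False, tol=1e-3, max_iter=2000)
        elif model == "logistic":
            clf = LogisticRegression(C=C, max_iter=2000)
        else:
            raise ValueError("model must be 'svc' or 'logistic'")
        clf.fit(Xtr, y[train])
        pred = clf.predict(Xte)
        per_fold.append(float(f1_score(y[test], pred, average="weighted",
                                       zero_division=0)))
        y_true_all.append(y[test])
        y_pred_all.append(pred)

    y_true = np.concatenate(y_true_all)
    y_pred = np.concatenate(y_pred_all)
    accuracy = float(f1_score(y_true, y_pred, average="weighted", zero_division=0))
    cm = confusion_matrix(y_true, y_pred, labels=sound_ids)
    n_per_class = int((y == sound_ids[0]).sum())
    return DecodingResult(accuracy=accuracy, confusion=cm, per_fold=per_fold,
                          n_per_class=n_per_class, sound_ids=sound_ids, seed=seed)
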