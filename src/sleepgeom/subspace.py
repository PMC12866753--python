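"""Cross-validated PCA dimensionality and the spontaneous/evoked inclusion index.

Dimensionality: activity (z-scored frames x neurons) is split into 5 equal
contiguous blocks; principal components fitted on 4 blocks are tested on the
held-out block, and the per-component captured test-variance ratio is compared
against a null obtained by circularly shifting each neuron's test trace
independently in time (95th percentile of 20 shuffles). The dimensionality is
the initial run of components above that chance curve.

Inclusion index: I = (%Var_projected - %Var_chance) / (%Var_max - %Var_chance),
where %Var(X) is the variance of X captured by the reference spontaneous
subspace, normalized by the variance X's own first-n subspace captures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import stream
from .signal import Raster, frames_in_window, zscore_columns


def session_activity(raster: Raster) -> np.ndarray:
    """Frames x neurons activity, z-scored over the whole recording."""
    return zscore_columns(raster.counts.T)


def condition_masks(raster: Raster, trials, frame_states: np.ndarray,
                    state: str, response_offset: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (spontaneous, evoked) frame masks for one state.

    Evoked frames lie inside a response window (onset to offset + 250 ms);
    spontaneous frames are all remaining frames of the state.
    """
    n = raster.n_frames
    in_sound = np.zeros(n, dtype=bool)
    for row in trials.itertuples():
        idx = frames_in_window(row.onset_s,
                               row.onset_s + row.duration_s + response_offset,
                               raster.frame_duration, n)
        in_sound[idx] = True
    in_state = np.asarray(frame_states) == state
    return in_state & ~in_sound, in_state & in_sound


@dataclass
class ScreePlot:
    cv_variance_ratio: np.ndarray
    chance_95: np.ndarray
    dimensionality: int


@dataclass
class SubspaceModel:
    components: np.ndarray      # neurons x n, orthonormal columns
    n: int
    source: str = ""

    def __post_init__(self) -> None:
        eye = self.components.T @ self.components
        if not np.allclose(eye, np.eye(self.n), atol=1e-8):
            raise ValueError("components must be orthonormal")


def _principal_components(x: np.ndarray, n: int | None = None) -> np.ndarray:
    """Right singular vectors of the centered matrix (neurons x components)."""
    xc = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    v = vt.T
    return v if n is None else v[:, :n]


def _circular_shift(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently roll each column by a uniform shift in [1, T-1]."""
    t, n = x.shape
    shifts = rng.integers(1, t, size=n)
    rows = (np.arange(t)[:, None] - shifts[None, :]) % t
    return x[rows, np.arange(n)[None, :]]


def cv_scree(
    activity: np.ndarray,
    k_folds: int = 5,
    n_shuffles: int = 20,
    seed: int = 0,
    percentile: float = 95.0,
) -> ScreePlot:
    """Cross-validated PC scree plot with a circular-shift chance curve.

    ``activity`` must be z-scored over the whole recording upstream. Blocks
    are contiguous in time; test data is centered with training means.
    """
    activity = np.asarray(activity, dtype=float)
    t, n = activity.shape
    if k_folds > t:
        raise ValueError("more folds than frames")
    if t < k_folds * 10:
        raise ValueError("need at least 10 frames per fold")
    if np.any(activity.std(axis=0) == 0):
        raise ValueError("constant neuron in activity matrix")
    rng = stream(seed, "cv-scree")
    blocks = np.array_split(np.arange(t), k_folds)
    n_comp = min(n, min(t - len(b) for b in blocks))

    cv = np.zeros(n_comp)
    null: list[np.ndarray] = []
    for fold, test_idx in enumerate(blocks):
        train_idx = np.concatenate([b for k, b in enumerate(blocks) if k != fold])
        train = activity[train_idx]
        mean = train.mean(axis=0)
        v = _principal_components(train, n_comp)  # centers with train means
        test = activity[test_idx] - mean
        total = (test**2).sum()
        if total == 0:
            raise ValueError("test block has zero variance")
        proj = test @ v
        cv += (proj**2).sum(axis=0) / total
        for _ in range(n_shuffles):
            shuffled = _circular_shift(test, rng)
            sproj = shuffled @ v
            null.append((sproj**2).sum(axis=0) / (shuffled**2).sum())
    cv /= k_folds
    chance = np.percentile(np.stack(null), percentile, axis=0)

    above = cv > chance
    dim = int(np.argmin(above)) if not above.all() else len(above)
    if len(above) and not above[0]:
        dim = 0
    return ScreePlot(cv_variance_ratio=cv, chance_95=chance, dimensionality=dim)


def _captured_fraction(x: np.ndarray, v_ref: np.ndarray) -> float:
    """Var(X V_ref V_ref^T) / Var(X V_source V_source^T), X centered."""
    xc = x - x.mean(axis=0)
    n = v_ref.shape[1]
    v_source = _principal_components(xc, n)
    num = ((xc @ v_ref) ** 2).sum()
    den = ((xc @ v_source) ** 2).sum()
    return float(num / den)


def inclusion_index(
    spont: np.ndarray,
    evoked: np.ndarray,
    seed: int = 0,
    n_blocks: int = 10,
    n_components: int | None = None,
    n_shuffles: int = 20,
    k_folds: int = 5,
) -> dict:
    """How much evoked-activity variance lives in the spontaneous subspace.

    The spontaneous frames are split into ``n_blocks`` contiguous blocks;
    odd-numbered blocks define the reference subspace (first n significant
    components per :func:`cv_scree`, unless ``n_components`` is given),
    even-numbered blocks give the maximum attainable overlap, and per-neuron
    circular shifts of the evoked data give chance.
    """
    spont = np.asarray(spont, dtype=float)
    evoked = np.asarray(evoked, dtype=float)
    if spont.shape[1] != evoked.shape[1]:
        raise ValueError("spont and evoked must cover the same neurons")
    blocks = np.array_split(np.arange(spont.shape[0]), n_blocks)
    odd = np.concatenate(blocks[0::2])    # 1-based odd labels
    even = np.concatenate(blocks[1::2])
    ref = spont[odd]

    if n_components is None:
        n_components = cv_scree(ref, k_folds=k_folds, seed=seed).dimensionality
    if n_components == 0:
        raise ValueError("degenerate reference subspace (0 significant components)")
    v_ref = _principal_components(ref, n_components)

    var_max = _captured_fraction(spont[even], v_ref)
    var_projected = _captured_fraction(evoked, v_ref)
    rng = stream(seed, "inclusion-chance")
    var_chance = float(np.mean([
        _captured_fraction(_circular_shift(evoked, rng), v_ref)
        for _ in range(n_shuffles)
    ]))
    denom = var_max - var_chance
    if denom == 0:
        raise ValueError("degenerate normalization (%Var_max == %Var_chance)")
    index = (var_projected - var_chance) / denom
    return dict(index=float(index), var_max=var_max,
                var_projected=var_projected, var_chance=var_chance,
                n_components=int(n_components))
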